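"""File I/O for SIR series, parameter maps and simulated phantoms.

Series are accepted as NIfTI-1 (.nii/.nii.gz) or MATLAB MAT containers
(v5 via scipy.io, v7.3/HDF5 via h5py).  Parameter maps are written as one
float32 NIfTI per map sharing the input affine, plus a JSON provenance
sidecar sufficient to re-run the fit bit-identically.
"""

from __future__ import annotations

import json
from dataclasses import asdict
from pathlib import Path

import h5py
import nibabel as nib
import numpy as np
from scipy.io import loadmat, savemat

from . import __version__
from .fitting import FitConfig, ParameterMaps, SirSeries
from .model import AcquisitionScheme
from .simulation import PhantomTruth

__all__ = ["read_series", "write_maps", "write_simulation"]


def _load_mat_4d(path: Path, var_name: str | None) -> np.ndarray:
    """First 4-D variable from a MAT file (v5 or v7.3), name overridable."""
    if h5py.is_hdf5(path):  # MAT v7.3 is an HDF5 container
        with h5py.File(path, "r") as fh:
            # HDF5/MAT stores arrays transposed relative to MATLAB order
            arrays = {
                k: np.asarray(fh[k]).T
                for k in fh.keys()
                if isinstance(fh[k], h5py.Dataset)
            }
    else:
        contents = loadmat(path)
        arrays = {
            k: np.asarray(v)
            for k, v in contents.items()
            if not k.startswith("__") and hasattr(v, "ndim")
        }
    if var_name is not None:
        if var_name not in arrays:
            raise ValueError(
                f"variable {var_name!r} not found in {path.name}; "
                f"available: {sorted(arrays)}"
            )
        return arrays[var_name]
    four_d = {k: v for k, v in arrays.items() if v.ndim == 4}
    if not four_d:
        raise ValueError(
            f"no 4-D variable in {path.name}; available: "
            + ", ".join(f"{k}{v.shape}" for k, v in sorted(arrays.items()))
        )
    if len(four_d) > 1:
        raise ValueError(
            f"ambiguous MAT contents in {path.name}; 4-D candidates: "
            f"{sorted(four_d)} — pass an explicit variable name"
        )
    return next(iter(four_d.values()))


def read_series(
    path: str | Path,
    ti,
    td,
    mask_path: str | Path | None = None,
    mat_var: str | None = None,
) -> SirSeries:
    """Load a 4-D SIR series with its acquisition scheme (times in seconds).

    NIfTI affine and spacing are preserved; MAT input gets an identity
    affine.  A 3-D file is rejected rather than guessed at: volumes must
    be stacked in the 4th dimension.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    suffixes = "".join(path.suffixes)
    if suffixes.endswith((".nii", ".nii.gz")):
        img = nib.load(path)
        data = np.asanyarray(img.dataobj, dtype=float)
        affine = img.affine
    elif path.suffix == ".mat":
        data = np.asarray(_load_mat_4d(path, mat_var), dtype=float)
        affine = np.eye(4)
    else:
        raise ValueError(f"unsupported input format: {path.name} (need .nii/.nii.gz/.mat)")
    if data.ndim == 3:
        raise ValueError(
            f"{path.name} is 3-D {data.shape}; volumes must be stacked in a 4th "
            "dimension, not the 3rd"
        )
    if data.ndim != 4:
        raise ValueError(f"{path.name} is {data.ndim}-D; a 4-D series is required")

    scheme = AcquisitionScheme(ti=tuple(ti), td=tuple(td))
    if data.shape[3] != len(scheme):
        raise ValueError(
            f"scheme mismatch: {len(scheme)} (ti, td) pairs but {data.shape[3]} volumes"
        )

    mask = None
    if mask_path is not None:
        mask_img = nib.load(Path(mask_path))
        mask = np.asanyarray(mask_img.dataobj) > 0
        if mask.shape != data.shape[:3]:
            raise ValueError(
                f"mask shape {mask.shape} does not match series spatial shape "
                f"{data.shape[:3]}"
            )
    return SirSeries(data=data, scheme=scheme, mask=mask, affine=affine)


def _save_nifti(arr: np.ndarray, affine: np.ndarray, path: Path, dtype) -> None:
    img = nib.Nifti1Image(np.asarray(arr, dtype=dtype), affine)
    nib.save(img, path)


def write_maps(
    maps: ParameterMaps,
    ref: SirSeries,
    output_dir: str | Path,
    config: FitConfig | None = None,
    seed: int | None = None,
) -> list[Path]:
    """Write fitted maps as float32 NIfTI files plus a provenance sidecar.

    One file per map (psr, r1f, sf, m0f, optional kmf, residual_norm,
    converged); ``converged`` is stored as 0/1 integers.  The sidecar
    records the scheme (in ms), fit configuration, seed and version —
    enough to reproduce the maps bit-identically.
    """
    if maps.psr.shape != ref.spatial_shape:
        raise ValueError(
            f"maps shape {maps.psr.shape} does not match series spatial shape "
            f"{ref.spatial_shape}"
        )
    out = Path(output_dir)
    out.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []
    for name, arr in maps.named_maps().items():
        path = out / f"{name}.nii.gz"
        dtype = np.uint8 if arr.dtype == bool else np.float32
        _save_nifti(arr, ref.affine, path, dtype)
        written.append(path)
    sidecar = {
        "toolkit": "sirqmt",
        "version": __version__,
        "ti_ms": [round(t * 1000.0, 9) for t in ref.scheme.ti],
        "td_ms": [round(t * 1000.0, 9) for t in ref.scheme.td],
        "seed": seed,
        "config": _config_dict(config),
        "maps": sorted(p.name for p in written),
    }
    sidecar_path = out / "fit_provenance.json"
    with open(sidecar_path, "w") as fh:
        json.dump(sidecar, fh, indent=2)
    written.append(sidecar_path)
    return written


def _config_dict(config: FitConfig | None) -> dict | None:
    if config is None:
        return None
    d = asdict(config)
    return d


def write_simulation(
    truth: PhantomTruth,
    noise_free: np.ndarray,
    noisy: np.ndarray,
    scheme: AcquisitionScheme,
    output_dir: str | Path,
    seed: int,
    snr: float,
    kmf: float,
    sm: float,
) -> list[Path]:
    """Write a simulated phantom: series, truth grids, sidecar, MAT mirror.

    Outputs NIfTI files for the noisy and noise-free series and both
    truth grids, a JSON sidecar with the full generation recipe, and a
    single MAT container mirroring the accepted input formats.
    """
    out = Path(output_dir)
    out.mkdir(parents=True, exist_ok=True)
    eye = np.eye(4)
    written: list[Path] = []
    rows, cols = truth.shape
    for name, arr in (
        ("sir_noisy", noisy),
        ("sir_noise_free", noise_free),
        ("truth_psr", truth.psr_grid.reshape(rows, cols, 1)),
        ("truth_r1f", truth.r1f_grid.reshape(rows, cols, 1)),
    ):
        path = out / f"{name}.nii.gz"
        _save_nifti(arr, eye, path, np.float64)
        written.append(path)
    mat_path = out / "sir_simulation.mat"
    savemat(
        mat_path,
        {
            "sir_noisy": noisy,
            "sir_noise_free": noise_free,
            "truth_psr": truth.psr_grid,
            "truth_r1f": truth.r1f_grid,
        },
    )
    written.append(mat_path)
    sidecar = {
        "toolkit": "sirqmt",
        "version": __version__,
        "ti_ms": [round(t * 1000.0, 9) for t in scheme.ti],
        "td_ms": [round(t * 1000.0, 9) for t in scheme.td],
        "seed": seed,
        "snr": snr,
        "kmf": kmf,
        "sm": sm,
        "sf": truth.sf,
        "m0f": truth.m0f,
        "shape": list(truth.shape),
        "psr_range": [float(truth.psr_grid.min()), float(truth.psr_grid.max())],
        "r1f_range": [float(truth.r1f_grid.min()), float(truth.r1f_grid.max())],
        "axis_convention": "psr varies along columns (axis 1), r1f along rows (axis 0)",
    }
    sidecar_path = out / "simulation_provenance.json"
    with open(sidecar_path, "w") as fh:
        json.dump(sidecar, fh, indent=2)
    written.append(sidecar_path)
    return written
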