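"""Agreement statistics for parameter-map validation.

Fitted maps are compared against the generating truth with Lin's
concordance correlation coefficient (LCCC), relative root-mean-square
error in percent, and percent-difference histograms.  Also provides the
PSR -> macromolecular-fraction conversion used for phantom calibration.
"""

from __future__ import annotations

import csv
import json
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np

__all__ = [
    "ConcordanceResult",
    "lccc",
    "rmse_percent",
    "percent_difference_histogram",
    "psr_to_fraction",
    "export_evaluation",
]


@dataclass(frozen=True)
class ConcordanceResult:
    """Lin's concordance decomposition: lccc = pearson_r * bias_correction."""

    lccc: float
    pearson_r: float
    bias_correction: float
    n: int


def lccc(x, y) -> ConcordanceResult:
    """Lin's concordance correlation coefficient between two samples.

    lccc = 2*cov(x, y) / (var(x) + var(y) + (mean(x) - mean(y))^2)

    using population (1/n) moments — the classic Lin estimator, matching
    the convention of the standard epidemiological packages.  LCCC equals
    1 only for perfect agreement with the identity line; it is bounded in
    absolute value by the Pearson correlation.
    """
    x = np.asarray(x, dtype=float).ravel()
    y = np.asarray(y, dtype=float).ravel()
    if x.shape != y.shape:
        raise ValueError(f"length mismatch: {x.shape[0]} vs {y.shape[0]}")
    if x.shape[0] < 2:
        raise ValueError("need at least 2 observations")
    if not (np.all(np.isfinite(x)) and np.all(np.isfinite(y))):
        raise ValueError("inputs must be finite")
    mx, my = x.mean(), y.mean()
    vx = float(np.mean((x - mx) ** 2))
    vy = float(np.mean((y - my) ** 2))
    cov = float(np.mean((x - mx) * (y - my)))
    denom = vx + vy + (mx - my) ** 2
    if denom == 0.0:
        raise ValueError(
            "degenerate input: both samples constant with equal means (0/0)"
        )
    ccc = 2.0 * cov / denom
    if vx > 0 and vy > 0:
        r = cov / np.sqrt(vx * vy)
        cb = ccc / r if r != 0 else 0.0
    else:
        r = 0.0
        cb = 0.0
    return ConcordanceResult(
        lccc=float(ccc),
        pearson_r=float(r),
        bias_correction=float(cb),
        n=int(x.shape[0]),
    )


def rmse_percent(truth, estimate) -> float:
    """Relative root-mean-square error, in percent of the true value.

    100 * sqrt(mean(((estimate - truth) / truth)^2)).  Relative (not
    native-unit) RMSE lets quantities with different units share one
    scale; it is invariant to a common positive rescaling of truth and
    estimate, and undefined when any true value is zero.
    """
    truth = np.asarray(truth, dtype=float).ravel()
    estimate = np.asarray(estimate, dtype=float).ravel()
    if truth.shape != estimate.shape:
        raise ValueError(f"length mismatch: {truth.shape[0]} vs {estimate.shape[0]}")
    if np.any(truth == 0):
        raise ValueError("relative RMSE undefined: truth contains zeros")
    rel = (estimate - truth) / truth
    return float(100.0 * np.sqrt(np.mean(rel**2)))


def percent_difference_histogram(
    truth, estimate, bins: int = 50
) -> tuple[np.ndarray, np.ndarray]:
    """Probability-density histogram of 100*(estimate - truth)/truth.

    Returns ``(edges, densities)`` with densities normalized so that
    sum(densities * diff(edges)) == 1.
    """
    truth = np.asarray(truth, dtype=float).ravel()
    estimate = np.asarray(estimate, dtype=float).ravel()
    if truth.shape != estimate.shape:
        raise ValueError(f"length mismatch: {truth.shape[0]} vs {estimate.shape[0]}")
    if np.any(truth == 0):
        raise ValueError("percent difference undefined: truth contains zeros")
    pct = 100.0 * (estimate - truth) / truth
    densities, edges = np.histogram(pct, bins=bins, density=True)
    return edges, densities


def psr_to_fraction(psr):
    """Macromolecular fraction f = M0m/(M0m + M0f) = PSR/(1 + PSR).

    Strictly increasing in PSR and bounded in [0, 1); linear in
    macromolecular content, which makes it the natural axis for phantom
    concentration calibration.
    """
    arr = np.asarray(psr, dtype=float)
    if np.any(arr < 0):
        raise ValueError("psr must be >= 0")
    out = arr / (1.0 + arr)
    return float(out) if np.isscalar(psr) or arr.ndim == 0 else out


def export_evaluation(
    truth_by_param: dict[str, np.ndarray],
    estimate_by_param: dict[str, np.ndarray],
    out_dir: str | Path,
    valid: np.ndarray | None = None,
) -> dict:
    """Write per-voxel (truth, estimate) CSVs and a JSON agreement summary.

    Evaluation is restricted to ``valid`` voxels (e.g. converged and
    mask-true); the number excluded is reported per parameter.  Returns
    the summary dict that is also written to ``summary.json``.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    summary: dict[str, dict] = {}
    for name, truth in truth_by_param.items():
        est = estimate_by_param[name]
        truth = np.asarray(truth, dtype=float).ravel()
        est = np.asarray(est, dtype=float).ravel()
        keep = np.ones(truth.shape[0], dtype=bool) if valid is None else np.asarray(valid).ravel()
        t, e = truth[keep], est[keep]
        with open(out_dir / f"{name}_pairs.csv", "w", newline="") as fh:
            writer = csv.writer(fh)
            writer.writerow(["truth", "estimate"])
            writer.writerows(zip(t, e))
        cc = lccc(t, e)
        summary[name] = {
            "lccc": cc.lccc,
            "pearson_r": cc.pearson_r,
            "rmse_percent": rmse_percent(t, e),
            "n": int(t.shape[0]),
            "n_excluded": int(truth.shape[0] - t.shape[0]),
        }
    with open(out_dir / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=2)
    return summary
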