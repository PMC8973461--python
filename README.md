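# sirqmt

Voxelwise parameter mapping for **selective inversion recovery (SIR)
quantitative magnetization transfer** imaging.

SIR is a qMT technique that quantifies exchange between free water
protons and protons bound in macromolecules such as myelin.  Its key
output, the macromolecular pool size ratio **PSR = M0m/M0f**, tracks
myelin content in white matter and is of direct interest in multiple
sclerosis and other demyelinating disease.  `sirqmt` takes a 4-D SIR
image series (one volume per inversion-time/pre-delay pair), fits the
two-pool recovery model in every voxel, and writes NIfTI parameter maps
for PSR, R1f, Sf and M0f (optionally kmf).  A digital-phantom simulator
and agreement statistics are included for validation.

## Model

The coupled longitudinal magnetization Mz = [Mzf, Mzm]ᵀ after an
inversion preparation with reduced pre-delay t_D and inversion time t_I
is

```
Mz(t_I, t_D) = [ e^{A t_I} S (I − e^{A t_D}) + (I − e^{A t_I}) ] M0

A = [ −(R1f + k_fm)    k_mf        ]      S  = diag(Sf, Sm)
    [   k_fm          −(R1m + k_mf)]      M0 = [M0f, PSR·M0f]ᵀ
```

with k_fm = PSR·k_mf by detailed balance.  The observed signal is
proportional to Mzf, a biexponential in t_I.  Standard reductions leave
four free parameters per voxel — PSR, R1f, Sf, M0f — by fixing
Sm = 0.83, tying R1m = R1f, and fixing k_mf at a literature value
(12.5 s⁻¹ for human brain, 35.0 s⁻¹ for cross-linked BSA phantoms);
k_mf can instead be estimated when five or more samples are acquired.
Each voxel is fit by bounded Levenberg–Marquardt least squares with a
forward-difference Jacobian; the 2×2 matrix exponential is evaluated in
closed form from its eigendecomposition for speed.

## Worked example

Simulate a small phantom whose PSR varies 5–25% along columns and R1f
0.5–1.5 s⁻¹ along rows, corrupt it with Rician noise at SNR 250, fit it,
and measure agreement with the generating truth:

```python
import numpy as np
import sirqmt as sq

scheme = sq.AcquisitionScheme.default()      # tI 15/15/278/1007 ms, tD 648/4171/2730/10 ms
truth = sq.make_phantom(shape=(32, 32))
noise_free = sq.simulate_series(truth, scheme, kmf=12.5, sm=0.83)
noisy = sq.add_rician_noise(noise_free, sq.NoiseSpec(snr=250, seed=42))
series = sq.SirSeries(data=noisy, scheme=scheme)
maps = sq.fit_image(series, sq.FitConfig(kmf=12.5))

ok = maps.converged[..., 0]
for name, tru, est in (("R1f", truth.r1f_grid, maps.r1f[..., 0]),
                       ("PSR", truth.psr_grid, maps.psr[..., 0])):
    cc = sq.lccc(tru[ok], est[ok])
    err = sq.rmse_percent(tru[ok], est[ok])
    print(f"{name}: LCCC = {cc.lccc:.3f}, relative RMSE = {err:.2f}%")
print(f"converged voxels: {int(ok.sum())}/{ok.size}")
print(f"median fitted Sf: {np.median(maps.sf[..., 0][ok]):.3f}")
```

prints

```
R1f: LCCC = 0.999, relative RMSE = 1.74%
PSR: LCCC = 0.992, relative RMSE = 6.44%
converged voxels: 1024/1024
median fitted Sf: -1.000
```

R1f is recovered almost perfectly; PSR, the noise-sensitive myelin
index, still agrees with truth at LCCC ≈ 0.99 with a few percent
relative error — the noise floor of SNR-250 magnitude data, not fitter
bias (the noise-free fit is exact to 1e−6).  Fitted Sf sits at the true
inversion efficiency of −1.

The same pipeline is available from the shell:

```
sirqmt simulate --out phantom/
sirqmt fit --input phantom/sir_noisy.nii.gz \
    --ti "15 15 278 1007" --td "648 4171 2730 10" --kmf 12.5 --out maps/
```

`sirqmt fit` accepts NIfTI-1 or MAT series, an optional brain mask,
`--fit-kmf` for the five-parameter model, and `--units s` for schemes
given in seconds; it writes one NIfTI per map plus a JSON provenance
sidecar that is sufficient to re-run the fit bit-identically.

## Layout

- `sirqmt.model` — forward signal model and its biexponential structure
- `sirqmt.fitting` — per-voxel and whole-image least-squares estimation
- `sirqmt.simulation` — digital phantom and Rician noise
- `sirqmt.stats` — LCCC, relative RMSE, percent-difference histograms,
  PSR→macromolecular-fraction conversion
- `sirqmt.io` / `sirqmt.cli` — NIfTI/MAT I/O and the `sirqmt` command

See `docs/methods.md` for the modelling assumptions, fitting defaults
and known limitations.
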