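# Methods

## Signal model

Selective inversion recovery (SIR) prepares the two-pool longitudinal
magnetization Mz = [Mzf, Mzm]ᵀ with a low-power on-resonance inversion
that acts differently on the free-water and macromolecular pools, then
samples the coupled recovery at paired inversion times t_I and
pre-delays t_D:

    Mz(t_I, t_D) = [ e^{A t_I} S (I − e^{A t_D}) + (I − e^{A t_I}) ] M0

The reduced-pre-delay boundary condition assumes both pools are fully
saturated at t_D = 0, which is what makes short pre-delays usable and
gives the second term its form.  A is the relaxation-exchange generator
with free-pool rate R1f, macromolecular rate R1m and exchange rates
k_mf (macromolecular→free) and k_fm = PSR·k_mf (detailed balance with
static pool sizes).  S = diag(Sf, Sm) holds the per-pool inversion
efficiencies and M0 = [M0f, PSR·M0f]ᵀ the equilibrium magnetization.
The acquired signal is proportional to Mzf, which is a biexponential in
t_I whose fast rate is dominated by exchange and whose slow rate is
close to R1f.

Model reductions applied during fitting, all standard for this
acquisition:

| parameter | treatment | default | why |
|---|---|---|---|
| Sm | fixed | 0.83 | numerical estimate for a 1-ms hard inversion pulse with Gaussian lineshape and T2m = 10–20 µs; the ±0.07 uncertainty of that estimate is not propagated. Exposed as an override for site-specific recalibration. |
| R1m | tied | R1m = R1f | the signal is nearly insensitive to R1m; the tie is enforced at every iterate, not frozen at the initial guess, because it is a constraint rather than an initialization. A fixed override is available. |
| k_mf | fixed | 12.5 s⁻¹ (brain), 35.0 s⁻¹ (BSA phantoms) | consistent across normal and diseased neural tissue; the sampling scheme was optimized to minimize bias in PSR/R1f under an assumed k_mf. Estimating k_mf per voxel is supported and requires ≥ 5 samples. |

That leaves θ = (PSR, R1f, Sf, M0f) free per voxel, estimable from four
(t_I, t_D) samples.

All internal times are seconds and rates s⁻¹; the CLI accepts
milliseconds by default (`--units {ms,s}`) because protocols quote ms,
and converts exactly once at the boundary.

## Matrix exponential

Per-voxel fitting evaluates e^{At} hundreds of millions of times over a
whole-brain series, so it is computed in closed form from the 2×2
eigendecomposition: the discriminant (a11 − a22)² + 4·k_mf·k_fm is
non-negative by the sign structure of A, so the eigenvalues are always
real.  When the eigenvalue gap falls below 1e−9 (possible only in
measure-zero corners such as PSR = 0 with R1f = R1m + k_mf) the
implementation falls back to SciPy's scaling-and-squaring Padé routine.
The closed form is pinned against that general routine to 1e−10 over
random parameter sweeps, and against an independent series-expansion
oracle in the test suite.

## Magnitude convention

Magnitude-reconstructed MR images carry Rician noise and are
non-negative, while Mzf is negative at short t_I after a good inversion.
The fitter therefore compares |Mzf| to the data by default; a signed
option exists for phase-sensitive reconstructions.  The rectification
makes the model non-smooth exactly at Mzf = 0, which in practice is far
from the optimum at the sampled (t_I, t_D) points and does not impede
convergence.

## Fitting

Each voxel is fit independently by bounded least squares
(`scipy.optimize.least_squares`, trust-region reflective — a
Levenberg–Marquardt-type damped Gauss–Newton that honors box
constraints; voxel independence makes the whole-image result invariant
to threading and visitation order).  Choices that the data do not fix,
and their rationale:

- **Initial guess**: PSR = 0.10, R1f = 1.0 s⁻¹, Sf = −0.95,
  M0f = 1.2 × max|signal| (k_mf starts at its configured value when
  free).  Mid-range of the biological box, with M0f scaled to the data.
- **Bounds**: PSR ∈ [0, 1], R1f ∈ [0.05, 10] s⁻¹, Sf ∈ [−1.05, 1.05],
  M0f ∈ (0, 10 × max|signal|], k_mf ∈ [0, 100] s⁻¹.  Physical ranges
  with headroom; Sf deliberately extends slightly past ±1 so that noise
  does not pin estimates to the boundary.
- **Jacobian**: forward finite differences with step 1e−8·(1 + |θ|).
  Forward (one-sided) differencing halves the cost of central
  differencing at negligible accuracy cost for this smooth model.
- **Tolerances**: cost, step and gradient tolerances all 1e−10, at most
  500 model evaluations.  Tight enough that the solver tolerance is
  never the accuracy bottleneck at realistic SNR (noise-free voxels
  recover truth to better than 1e−6 relative).
- **Failure policy**: non-convergent voxels are flagged
  (`converged = False`, maps hold 0) and never retried; there is no
  multi-start.  An all-zero signal (background) is skipped outright.
  The `iterations` diagnostic counts solver model evaluations.

## Digital phantom

The simulator regenerates the validation study: a 128×128 grid with PSR
varying linearly 0.05–0.25 along columns and R1f 0.5–1.5 s⁻¹ along rows
(both endpoints included; the axis convention is recorded in the output
sidecar), Sf = −1 and M0f = 1 held constant, forward signals on the
optimized scheme t_I = 15, 15, 278, 1007 ms / t_D = 648, 4171, 2730,
10 ms with k_mf = 12.5 s⁻¹ and Sm = 0.83, and Rician noise at SNR 250
relative to M0f.  Noise uses the canonical two-channel construction —
independent zero-mean Gaussians of σ = M0f/SNR added in quadrature to
the signed model value — so the corrupted series is non-negative and
exactly reproducible from its seed (default 20220329, always
overridable and always logged).

The phantom emulates the parameter ranges and noise statistics of
white-matter imaging at 3 T, not the acquisition physics: there is no
k-space sampling, readout blurring, B0/B1 inhomogeneity, partial
volume, motion, or spatial noise correlation, and the true k_mf, Sm and
R1m match the fitting assumptions exactly.  Passing the phantom study
therefore demonstrates estimator correctness and noise robustness — not
that those model assumptions hold in vivo, where assumed-k_mf bias and
slow-R1m effects are real concerns.

## Evaluation statistics

- **LCCC** (Lin's concordance correlation coefficient):
  2·cov(x,y) / (var(x) + var(y) + (mean x − mean y)²) with population
  (1/n) moments — the classic Lin estimator used by the standard
  epidemiological packages.  No confidence intervals are computed.
- **RMSE** is reported as *relative* RMSE in percent,
  100·√(mean(((est − truth)/truth)²)): quantities with different native
  units (s⁻¹ and a ratio) then share one scale, and the statistic is
  invariant to common rescaling.  This interpretation is a documented
  choice; an absolute-units reading would change the numbers.
- Evaluation is restricted to converged, mask-true voxels; the excluded
  count is reported alongside each summary.
- **f = PSR/(1 + PSR)** converts PSR to the macromolecular fraction,
  which is linear in macromolecular content and is the natural axis for
  concentration-calibration phantoms.

## Problem sizes

The validation suite fits the full 128×128 phantom (16,384 voxels,
≈ 2.2 ms per voxel on one CPU core); `scripts/acceptance.py` repeats it
for five independent noise realizations.  Unit and property tests use
8×8 to 32×32 grids and random parameter sweeps of a few hundred points.

## Known limitations

- No spatial regularization, uncertainty maps, or multi-start refits.
- Pulse-shape simulation of Sm, lineshape models, off-resonance/B0
  effects and transverse dynamics are out of scope; Sm enters only as a
  scalar efficiency.
- DICOM/PARREC conversion, registration and brain extraction are
  upstream of this toolkit (use your usual tools and hand it NIfTI/MAT).
- Bounded estimates near PSR = 0 are truncated at the physical boundary,
  so background-like voxels inside a loose mask bias toward 0 rather
  than fluctuating symmetrically.
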