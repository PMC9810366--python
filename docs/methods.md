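# Methods

This note documents the models, numerical choices and limitations behind
`netrai`. It is written for a reader who wants to know exactly what the
package computes and what passing its test suite does and does not
establish about real data.

## Latent network model

The four network signals (SN, DMN, L.CEN, R.CEN) are generated as a vector
AR(1) process

    x_t = φ·x_{t−1} + e_t,   e_t ~ N(0, Q),

with a scalar autoregressive coefficient φ and the innovation covariance Q
solved from the discrete Lyapunov relation S = φ²S + Q at the target
stationary covariance S (a correlation matrix), i.e. Q = (1 − φ²)·S. The
initial state is drawn from N(0, S), so every finite sample is exactly
stationary and the population cross-correlation matrix equals the target
entry-for-entry — the property every downstream recovery test relies on.
Targets are validated for symmetry, unit diagonal and positive
semidefiniteness (the offending eigenvalue is reported otherwise), and
rank-deficient targets are handled through an eigendecomposition square
root.

Because φ is scalar, the cross-spectral matrix factorises as S·g(f) with a
scalar spectral shape g; any common linear filter (including the bandpass
below) therefore leaves the expected cross-correlations unchanged. This is
deliberate: it makes the end-to-end pipeline an unbiased estimator of the
generative correlations, so recovery error isolates implementation faults
from filter-induced bias.

Defaults: SN–DMN 0.30, SN–L.CEN = SN–R.CEN 0.40, DMN–CEN −0.10, bilateral
CEN 0.50; φ = 0.4 (a moderate TR=2 s BOLD autocorrelation); T = 245
volumes at TR = 2 s, matching the emulated acquisition. HIV+ cells shift
the SN–DMN entry by +0.15 (0.30 → 0.45); the shifted matrix is re-checked
for positive semidefiniteness before any subject is drawn.

## Voxel rendering

Subjects are rendered on an 18×6×6 grid (3.44×3.44×3.4 mm affine): four
72-voxel network slabs, plus disjoint WM and CSF slabs. Each network voxel
carries its latent signal plus shared nuisance leakage plus white noise
(default SD 0.5, about one third of signal variance at the 72-voxel
network mean); tissue voxels carry weighted mixtures of slowly varying
AR(1) nuisance sources (φ = 0.9) plus small tissue noise. Motion
parameters are zero except for sustained translation steps at spike
volumes (default magnitude 0.45–0.9 mm, above the 0.35 mm censoring
threshold); a spike at volume k therefore produces exactly one FD
excursion at k. The default per-volume spike probability (0.02) yields a
mean censored fraction near 6%, the scale of volume loss the emulated
study reports.

What the renderer does *not* emulate: hemodynamic forward convolution of
resting fluctuations, physiological (cardiac/respiratory) noise,
scanner drift spectra, field-map distortion, spatial autocorrelation of
noise, registration error. Passing recovery tests therefore shows the
*measurement chain* is correct, not that the pipeline is robust to every
real-data artifact.

## Preprocessing

- **FD** follows the sum-of-absolute-differences convention: Σ|Δtrans| +
  r·Σ|Δrot| with r = 50 mm; FD of the first volume is defined as 0.
- **Mean FD** (the motion covariate) is computed over all volumes before
  censoring — the study covaries "mean FD" without qualification, and the
  pre-censoring mean is the common convention; this choice is configurable
  in spirit by recomputing from the stored FD trace.
- **Censoring**: volumes with FD > 0.35 mm are censored along with their
  immediate neighbors (clipped at run boundaries), unioned with the first
  `n_nonsteady` volumes. Censored volumes are dropped, not interpolated;
  all downstream correlations use retained samples only.
- **aCompCor**: per tissue, the voxel series are demeaned, linearly
  detrended and variance-normalized, then the top-3 left singular vectors
  are used as component time courses (unit norm, sign fixed so each
  component's largest-magnitude element is positive). Effectively
  rank-deficient input returns fewer components with a warning.
- **Cleaning** is one least-squares projection of the retained rows on
  [nuisance | stop-band regressors]: nuisance = 3 CSF + 3 WM components,
  6 motion parameters, their backward differences (first row 0), and
  non-steady-state indicators. Residuals are exactly orthogonal to every
  retained-row regressor; collinearity is absorbed by the pseudoinverse.
- **Temporal dof check**: a subject is excluded when the regressor count
  reaches the retained-volume count.

### Stop-band basis

The passband is the open interval (0.01, 0.1) Hz. The high stop-band
(f ≥ 0.1 Hz) uses sine/cosine pairs at the DFT frequencies k/(T·TR) up to
Nyquist. For the low stop-band we use a DCT-II cosine block at half-cycle
resolution (frequencies k/(2·T·TR) ≤ 0.01, the standard fMRI drift basis)
rather than plain DFT bins. The reason is leakage: a slow oscillation that
does not complete an integer number of cycles in the run (e.g. 0.005 Hz
over 490 s = 2.45 cycles) keeps ~10% of its variance in the in-band DFT
bins, which bin-only regression cannot remove; the half-cycle block
reduces that residual below 0.1% while still retaining ≥ 99% of genuinely
in-band variance and costing only ~10 extra regressors. `low_basis="dft"`
restores the bin-only behaviour for comparison.

## Connectivity

Region means are computed first and then standardized (the labels-masker
convention); a flag supports z-scoring voxels before averaging — Pearson
correlations downstream are invariant to the final standardization either
way. Network order (SN, DMN, L.CEN, R.CEN) is fixed and recorded, since
the RAI is order-sensitive in naming. Correlations are computed on
retained samples with no correction for autocorrelation-reduced effective
degrees of freedom, matching standard practice; this inflates per-subject
sampling variance (z-noise ≈ 0.10 at T = 245 after bandpass) but leaves
group means unbiased.

## Task model

The EAT simulator draws Go/NoGo trials (20% NoGo, 225 trials/run, 6 runs)
with a per-subject monotone difficulty→P(commission error) mapping
(logistic, width 0.15, floor 0.02, ceiling 0.98). The staircase evaluates
the running NoGo-error rate over a sliding window of the last 20 NoGo
trials after every NoGo trial: below 45% difficulty steps up by 0.05,
above 50% it steps down; difficulty persists across runs. Only the target
band is protocol-specified; the window/step controller is this package's
design, chosen as the simplest rule that converges for any subject whose
response function spans the band. Awareness is signalled per error with
fixed probability (default 0.75) or a caller-supplied model.

Subject-level GLMs are ordinary least squares on voxel-mean-scaled data
(each voxel ×100/mean, so event βs read as % BOLD change over the implicit
Go baseline). Event impulses are placed at the onset-nearest volume and
convolved with the single-gamma HRF h(t) = (t/(p·q))^p·e^{p−t/q}, p = 8.6,
q = 0.547 (unit peak at p·q ≈ 4.70 s); both parameters are configurable
since only the kernel family is protocol-level. Drift is modelled by
per-run Legendre polynomials of orders 0–4 on [−1, 1] (numerical
conditioning); motion regressors enter as columns concatenated across
runs. No prewhitening is applied by default: the generator's noise is
white, and OLS on white noise is efficient; an autocorrelation-robust
variant would be needed for real data.

## Group inference

Factorial models use sum-to-zero factor coding with Type-III F tests —
with unbalanced cells the test type is consequential, and Type III matches
per-factor F reporting in the presence of the interaction. Partial eta
squared is SS_effect/(SS_effect + SS_error). Follow-up t tests pool
variances (df = n₁+n₂−2). The unaware-count model is maximum-likelihood
negative binomial with quadratic variance μ + αμ² and jointly estimated α
(BFGS with a Nelder–Mead fallback), preceded by the auxiliary-regression
overdispersion test ((y−μ̂)²−y)/μ̂ on μ̂ without intercept, one-sided. The
OLS sensitivity model uses log10(x+1). QC removes Go-error rates above 50%
and count outliers with |z| > 3 (the emulated study names one removed
outlier but no rule; the z-rule is exposed in config and logged). All p
values are two-sided except the dispersion test.

## Problem sizes used in validation

Stationary-correlation recovery is checked at T = 100,000 (±0.01); RAI
consistency over 200 subjects at T = 245 (±0.02 around
atanh 0.4 − atanh 0.3 = 0.1141); factorial type-I error over 500 null
cohorts of n = 100; NB slope recovery and CI coverage over 200 cohorts of
n = 85; dispersion-test calibration over 1,000 Poisson replicates of
n = 5,000 and power over 200 NB replicates of n = 200; the qualitative
three-way pattern over 100 effect-bearing cohorts of n = 25/cell; the EAT
band over 24 subjects × 6 runs. These sizes keep the full suite under a
minute per heavy check while holding Monte-Carlo noise well inside each
stated tolerance.

## Known limitations

- With the ground-truth convention that all subjects in a cell share one
  true correlation matrix, between-subject variance in *measured* coupling
  is mostly sampling noise; regressions of behaviour on measured coupling
  are therefore attenuated roughly threefold (errors-in-variables) relative
  to the generative slope. Recovery claims about the NB slope are made on
  directly supplied predictors, and the analysis drivers report the true-z
  regression alongside the measured-z one.
- The EAT simulator abstracts NoGo trials generically; stimulus-level
  structure (repeat/Stroop conditions) is out of scope.
- No multiple-comparison correction is applied across analysis families,
  matching the emulated analysis style.
- Clinical-marker regressions (viral load, CD4 counts) have no generative
  model here and are not implemented.
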