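# netrai

Triple-network resting-state connectivity and error-processing analysis for a
2×2 HIV × cannabis-use (CB) fMRI study design, built validation-first: every
stage of the pipeline is exercised against a synthetic-cohort generator with
known ground truth.

## The problem

The triple-network model holds that the salience network (SN) allocates
processing resources between the central executive network (CEN) and the
default mode network (DMN). Dysregulated SN–DMN coupling has been proposed as
a mechanism for attentional and error-monitoring deficits in chronic
infection and substance use. The core per-subject statistic is the
**Resource Allocation Index** computed from resting-state network
correlations *CC*:

```
fCC       = 0.5 · ln((1 + CC) / (1 − CC))          (Fisher z)
L.RAI     = fCC(SN–L.CEN) − fCC(SN–DMN)
R.RAI     = fCC(SN–R.CEN) − fCC(SN–DMN)
```

Higher RAI means SN coupling biased toward the executive network and away
from the default mode network. Around this statistic the package implements:

- **`netrai.preprocess`** — framewise displacement (FD) from rigid-body
  motion parameters, spike censoring (FD > 0.35 mm plus the volumes
  immediately before and after), 3 CSF + 3 WM aCompCor components, and a
  single least-squares projection that removes nuisance regressors and all
  frequencies outside 0.01–0.1 Hz simultaneously from the retained volumes,
  with a temporal degrees-of-freedom check.
- **`netrai.connectivity`** — atlas-label network extraction,
  Pearson/Fisher-z coupling, RAI.
- **`netrai.task_response`** — subject-level event-related GLMs (single-gamma
  HRF, per-run Legendre drift polynomials, voxel-mean scaling to % BOLD
  change) yielding per-network NoGo-error βs from a Go/NoGo error awareness
  task (EAT).
- **`netrai.group_inference`** — Type-III HIV × CB factorial models with
  covariates and partial η², pooled follow-up t tests, overdispersion-tested
  negative-binomial models of unaware-error counts (plus an OLS sensitivity
  model on log10(x+1)), partial Pearson correlations, and cohort QC rules.
- **`netrai.synthetic`** — the ground-truth generator: latent network signals
  as a vector AR(1) process with exactly controlled stationary correlations,
  voxel rendering with WM/CSF nuisance sources and motion spikes,
  adaptive-staircase EAT sessions, and negative-binomial unaware-error
  counts linked to SN–DMN coupling.
- **`netrai.pipeline` / `netrai` CLI** — stage orchestration with YAML
  configs, NIfTI/TSV/CSV/JSON artifacts and a reproducibility manifest.

## Worked example

The numbered scripts under `analysis/` run the full study on a synthetic
cohort (25 subjects per cell, seed 7) and write tables under `results/`.
`python analysis/02_preprocess_connectivity.py` renders every subject's
245-volume resting run, cleans it, and measures the coupling profile:

```
measured 100 subjects (0 temporal-dof exclusions); mean censored fraction 5.6%
SN-DMN recovery: mean error +0.0114, mean |error| 0.0819 (per-subject sampling noise at T=245)
group means, measured SN-DMN z: HIV+ 0.502, HIV- 0.331
```

The per-subject |error| ≈ 0.08 is the expected sampling noise of a
correlation estimated from ~90 effective in-band samples; the group means
recover the generative shift (true z: 0.48 vs 0.31). The factorial models
(`analysis/03_group_models.py`) then detect the pattern the cohort encodes —
an HIV main effect on both RAIs driven by SN–DMN coupling, with SN–CEN flat:

```
       r_rai ~ HIV   : F[1, 92] = 22.22, p = 0.0000, eta_p2 = 0.195
  fcc_sn_dmn ~ HIV   : F[1, 92] = 30.87, p = 0.0000, eta_p2 = 0.251
 fcc_sn_lcen ~ HIV   : F[1, 92] =  0.78, p = 0.3803, eta_p2 = 0.008
```

A quick end-to-end demo of the packaged pipeline (16 subjects, ~3 s):

```bash
netrai run-all --run-dir /tmp/demo --seed 11
```

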