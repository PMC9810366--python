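"""Synthetic cohorts with known ground truth for pipeline validation.

The study design this package analyses — a 2×2 HIV-serostatus × cannabis-use
cohort scanned at rest (245 volumes, TR = 2 s) and during a Go/NoGo error
awareness task (EAT) — is emulated here so that every downstream stage can
be checked by parameter recovery:

* four latent network signals (SN, DMN, L.CEN, R.CEN) follow a vector AR(1)
  process with an exactly controlled stationary correlation matrix;
* HIV+ cells receive a configurable additive shift of the SN–DMN population
  correlation;
* voxel data, WM/CSF nuisance sources and motion-spike confounds are
  rendered on a small labelled grid in NIfTI-compatible arrays;
* EAT sessions run under an adaptive staircase holding the NoGo-error rate
  in the 45–50% band, with aware/unaware error signalling;
* unaware-error counts follow a negative-binomial model whose log-mean is
  linear in the subject's true SN–DMN Fisher-z coupling.

Every generator is a pure function of its configuration and seed.
"""

from __future__ import annotations

import warnings
from collections import deque
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.linalg import solve_discrete_lyapunov
from scipy.special import expit

from .connectivity import NETWORK_LABELS, NETWORKS

__all__ = [
    "SimulationConfig",
    "GroundTruthEntry",
    "MaskGeometry",
    "NuisanceSpec",
    "MotionSpec",
    "RenderedSubject",
    "LogisticInhibitionModel",
    "Staircase",
    "EATSessionResult",
    "default_population_corr",
    "simulate_network_timeseries",
    "render_voxel_data",
    "simulate_cohort",
    "simulate_eat_session",
    "simulate_unaware_counts",
]

_IDX = {name: i for i, name in enumerate(NETWORKS)}


def default_population_corr() -> np.ndarray:
    """Plausible stationary correlations among (SN, DMN, L.CEN, R.CEN).

    Moderate positive SN–CEN coupling (0.40), weaker positive SN–DMN
    coupling (0.30), mild DMN–CEN anticorrelation and strong bilateral CEN
    homotopy — the qualitative structure of triple-network resting data.
    """
    c = np.eye(4)

    def put(a: str, b: str, r: float) -> None:
        c[_IDX[a], _IDX[b]] = c[_IDX[b], _IDX[a]] = r

    put("SN", "DMN", 0.30)
    put("SN", "L.CEN", 0.40)
    put("SN", "R.CEN", 0.40)
    put("DMN", "L.CEN", -0.10)
    put("DMN", "R.CEN", -0.10)
    put("L.CEN", "R.CEN", 0.50)
    return c


def _check_corr(corr: np.ndarray, what: str = "correlation matrix") -> np.ndarray:
    corr = np.asarray(corr, dtype=float)
    if corr.ndim != 2 or corr.shape[0] != corr.shape[1]:
        raise ValueError(f"{what} must be square, got {corr.shape}")
    if not np.allclose(corr, corr.T, atol=1e-10):
        raise ValueError(f"{what} must be symmetric")
    if not np.allclose(np.diag(corr), 1.0, atol=1e-10):
        raise ValueError(f"{what} must have a unit diagonal")
    w = np.linalg.eigvalsh(corr)
    if w.min() < -1e-10:
        raise ValueError(
            f"{what} is not positive semidefinite: smallest eigenvalue {w.min():.6g}"
        )
    return corr


def _psd_factor(cov: np.ndarray) -> np.ndarray:
    """Square root of a PSD matrix via eigendecomposition (tolerates rank loss)."""
    w, v = np.linalg.eigh(cov)
    return v * np.sqrt(np.clip(w, 0.0, None))


def simulate_network_timeseries(
    corr: np.ndarray, phi: float, T: int, seed=None
) -> np.ndarray:
    """Stationary vector AR(1) sample whose cross-correlation matrix is ``corr``.

    x_t = phi·x_{t−1} + e_t with innovation covariance Q solved from the
    discrete Lyapunov relation S = phi²·S + Q at target stationary
    covariance S = corr (so Q = (1 − phi²)·corr for the scalar-phi case).
    x_0 is drawn from the stationary distribution, so every sample is
    exactly stationary.
    """
    corr = _check_corr(corr, "target correlation")
    if not (0 <= phi < 1):
        raise ValueError("ar1 coefficient must lie in [0, 1)")
    if T < 10:
        raise ValueError("need T >= 10 volumes")
    d = corr.shape[0]
    A = phi * np.eye(d)
    Q = corr - A @ corr @ A.T
    # round-trip check: stationary covariance implied by (A, Q) equals corr
    S = solve_discrete_lyapunov(A, Q)
    assert np.allclose(S, corr, atol=1e-8)

    rng = np.random.default_rng(seed)
    e = rng.standard_normal((T, d)) @ _psd_factor(Q).T
    e[0] = rng.standard_normal(d) @ _psd_factor(corr).T  # stationary start
    x = np.empty((T, d))
    x[0] = e[0]
    for t in range(1, T):
        x[t] = phi * x[t - 1] + e[t]
    return x


# ---------------------------------------------------------------------------
# voxel rendering


@dataclass
class MaskGeometry:
    """Integer-labelled grid with disjoint network, WM and CSF regions."""

    labels: np.ndarray  # 3D int, 1..4 per NETWORKS order, 0 background
    wm: np.ndarray  # 3D bool
    csf: np.ndarray  # 3D bool

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        self.wm = np.asarray(self.wm, dtype=bool)
        self.csf = np.asarray(self.csf, dtype=bool)
        if not (self.labels.shape == self.wm.shape == self.csf.shape):
            raise ValueError("labels, wm and csf grids must share one shape")
        occupied = self.labels > 0
        if np.any(occupied & self.wm) or np.any(occupied & self.csf) or np.any(self.wm & self.csf):
            raise ValueError("network, WM and CSF regions overlap")
        for name, lab in NETWORK_LABELS.items():
            n = int(np.sum(self.labels == lab))
            if n < 10:
                raise ValueError(f"network {name} has only {n} voxels (need >= 10)")
        for tissue, mask in (("WM", self.wm), ("CSF", self.csf)):
            if mask.sum() < 10:
                raise ValueError(f"{tissue} mask has fewer than 10 voxels")

    @classmethod
    def default(cls) -> "MaskGeometry":
        """18×6×6 grid: four 2-voxel-wide network slabs, then WM and CSF slabs."""
        shape = (18, 6, 6)
        labels = np.zeros(shape, dtype=np.int16)
        for k, name in enumerate(NETWORKS):
            labels[3 * k : 3 * k + 2] = NETWORK_LABELS[name]
        wm = np.zeros(shape, dtype=bool)
        wm[12:14] = True
        csf = np.zeros(shape, dtype=bool)
        csf[15:17] = True
        return cls(labels=labels, wm=wm, csf=csf)

    @property
    def affine(self) -> np.ndarray:
        return np.diag([3.44, 3.44, 3.4, 1.0])


@dataclass
class NuisanceSpec:
    """Shared WM/CSF-sourced structured noise.

    ``n_sources`` slowly varying AR(1) sources load onto every tissue voxel
    (uniform weights) and leak into network voxels with per-network weights
    of scale ``network_coupling``.
    """

    n_sources: int = 2
    source_phi: float = 0.9
    network_coupling: float = 0.5
    tissue_weight_range: tuple[float, float] = (0.5, 1.5)
    tissue_noise_sd: float = 0.05


@dataclass
class MotionSpec:
    """Sustained head-position steps producing FD excursions.

    Either an explicit list of spike volumes or a per-volume spike
    probability; each spike adds a sustained translation step of magnitude
    drawn from ``step_range_mm`` (above the 0.35 mm censoring threshold by
    default) on a random axis with random sign.
    """

    spike_volumes: tuple[int, ...] | None = None
    spike_rate: float = 0.0
    step_range_mm: tuple[float, float] = (0.45, 0.9)

    def draw_motion(self, T: int, rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray]:
        """Return (T×6 motion parameters, spike volume indices)."""
        if self.spike_volumes is not None:
            spikes = np.asarray(sorted(self.spike_volumes), dtype=int)
            if np.any(spikes < 1) or np.any(spikes >= T):
                raise ValueError("spike volumes must lie in [1, T)")
        else:
            if not (0 <= self.spike_rate < 0.5):
                raise ValueError("spike_rate must be in [0, 0.5)")
            spikes = np.flatnonzero(rng.random(T - 1) < self.spike_rate) + 1
        motion = np.zeros((T, 6))
        for s in spikes:
            step = rng.uniform(*self.step_range_mm) * rng.choice([-1.0, 1.0])
            motion[s:, rng.integers(0, 3)] += step
        return motion, spikes


@dataclass
class RenderedSubject:
    """One rendered resting run: 4D data plus masks, motion and sources."""

    bold: np.ndarray  # (x, y, z, t)
    geometry: MaskGeometry
    motion: np.ndarray  # (t, 6)
    spike_volumes: np.ndarray
    nuisance_sources: np.ndarray  # (t, n_sources)

    def to_nifti(self):
        """(bold, labels, wm, csf) as NIfTI-1 images on the grid's affine."""
        import nibabel as nib

        aff = self.geometry.affine
        return (
            nib.Nifti1Image(self.bold.astype(np.float32), aff),
            nib.Nifti1Image(self.geometry.labels.astype(np.int16), aff),
            nib.Nifti1Image(self.geometry.wm.astype(np.uint8), aff),
            nib.Nifti1Image(self.geometry.csf.astype(np.uint8), aff),
        )

    def confounds_frame(self) -> pd.DataFrame:
        """BIDS-style confounds table, one row per volume."""
        cols = ["trans_x", "trans_y", "trans_z", "rot_x", "rot_y", "rot_z"]
        return pd.DataFrame(self.motion, columns=cols)

    def tissue_series(self) -> tuple[np.ndarray, np.ndarray]:
        """(T×V_csf, T×V_wm) voxel series for aCompCor."""
        flat = self.bold.reshape(-1, self.bold.shape[3]).T
        return (
            flat[:, self.geometry.csf.reshape(-1)],
            flat[:, self.geometry.wm.reshape(-1)],
        )


def _ar1_sources(n: int, T: int, phi: float, rng: np.random.Generator) -> np.ndarray:
    if n == 0:
        return np.zeros((T, 0))
    s = simulate_network_timeseries(np.eye(n) if n > 1 else np.ones((1, 1)), phi, T, rng)
    return s


def render_voxel_data(
    latent: np.ndarray,
    geometry: MaskGeometry | None = None,
    voxel_noise_sd: float = 0.0,
    nuisance_spec: NuisanceSpec | None = None,
    motion_spec: MotionSpec | None = None,
    seed=None,
) -> RenderedSubject:
    """Render latent network signals into a labelled 4D volume.

    Each network voxel carries its network's latent signal plus the shared
    nuisance leakage plus white noise; WM/CSF voxels carry weighted nuisance
    sources plus tissue noise; motion parameters carry the injected
    sustained steps.  With zero noise and no nuisance the network-mean
    series equals the latent series exactly.
    """
    rng = np.random.default_rng(seed)
    latent = np.asarray(latent, dtype=float)
    if latent.ndim != 2 or latent.shape[1] != len(NETWORKS):
        raise ValueError(f"latent must be T x {len(NETWORKS)}")
    T = latent.shape[0]
    geometry = geometry or MaskGeometry.default()
    motion_spec = motion_spec or MotionSpec()
    motion, spikes = motion_spec.draw_motion(T, rng)

    shape = geometry.labels.shape
    bold = np.zeros(shape + (T,))

    if nuisance_spec is not None and nuisance_spec.n_sources > 0:
        sources = _ar1_sources(nuisance_spec.n_sources, T, nuisance_spec.source_phi, rng)
    else:
        sources = np.zeros((T, 0))

    for name, lab in NETWORK_LABELS.items():
        sel = geometry.labels == lab
        n_vox = int(sel.sum())
        sig = latent[:, _IDX[name]].copy()
        if sources.shape[1]:
            w = rng.normal(0.0, nuisance_spec.network_coupling, size=sources.shape[1])
            sig = sig + sources @ w
        block = np.tile(sig, (n_vox, 1))
        if voxel_noise_sd > 0:
            block = block + rng.normal(0.0, voxel_noise_sd, size=block.shape)
        bold[sel] = block

    for mask in (geometry.wm, geometry.csf):
        n_vox = int(mask.sum())
        if sources.shape[1]:
            lo, hi = nuisance_spec.tissue_weight_range
            w = rng.uniform(lo, hi, size=(n_vox, sources.shape[1]))
            block = w @ sources.T
            block += rng.normal(0.0, nuisance_spec.tissue_noise_sd, size=block.shape)
        else:
            block = rng.normal(0.0, voxel_noise_sd, size=(n_vox, T)) if voxel_noise_sd > 0 else np.zeros((n_vox, T))
        bold[mask] = block

    return RenderedSubject(
        bold=bold,
        geometry=geometry,
        motion=motion,
        spike_volumes=spikes,
        nuisance_sources=sources,
    )


# ---------------------------------------------------------------------------
# cohort


@dataclass
class SimulationConfig:
    """Generative settings for one synthetic 2×2 (HIV × CB) cohort.

    Defaults mirror the emulated study: 245-volume TR=2 s resting runs,
    four latent networks with moderate autocorrelation, an SN–DMN
    population-correlation shift of +0.15 in HIV+ cells, spike rates giving
    a few percent of censored volumes, and a negative-binomial
    unaware-error model with slope 1.7 on the true SN–DMN Fisher-z.
    """

    n_per_group: int = 25
    T: int = 245
    TR: float = 2.0
    population_corr: np.ndarray = field(default_factory=default_population_corr)
    ar1_phi: float = 0.4
    group_delta_sn_dmn: float = 0.15
    voxel_noise_sd: float = 0.5
    spike_rate: float = 0.02
    nb_intercept: float = 0.95
    nb_slope: float = 1.7
    nb_dispersion: float = 0.5
    seed: int = 0
    # covariate distributions (age truncated to the 18–60 eligibility range;
    # male fraction higher in HIV+ cells, as in US HIV-diagnosis demographics)
    age_mean: float = 35.0
    age_sd: float = 10.0
    age_range: tuple[float, float] = (18.0, 60.0)
    male_prob_hiv_pos: float = 0.80
    male_prob_hiv_neg: float = 0.55
    nic_prob: float = 0.5
    # true error-related network responses (% BOLD change) and the HIV shift
    # on DMN suppression (positive shift = less suppression)
    beta_mean: dict = field(
        default_factory=lambda: {"SN": 0.30, "DMN": -0.25, "L.CEN": 0.20, "R.CEN": 0.20}
    )
    beta_sd: float = 0.10
    hiv_dmn_beta_shift: float = 0.15
    # EAT behaviour
    n_task_runs: int = 6
    trials_per_run: int = 225
    nogo_prop: float = 0.20

    def __post_init__(self) -> None:
        self.population_corr = _check_corr(np.asarray(self.population_corr, float))
        if self.n_per_group < 2:
            raise ValueError("need n_per_group >= 2")
        if not (0 <= self.spike_rate < 0.5):
            raise ValueError("spike_rate must be in [0, 0.5)")
        if self.nb_dispersion <= 0:
            raise ValueError("nb_dispersion must be positive")
        _check_corr(self.corr_for_group(hiv=True), "HIV-shifted correlation matrix")

    def corr_for_group(self, hiv: bool) -> np.ndarray:
        corr = self.population_corr.copy()
        if hiv:
            i, j = _IDX["SN"], _IDX["DMN"]
            corr[i, j] += self.group_delta_sn_dmn
            corr[j, i] = corr[i, j]
        return corr


@dataclass
class GroundTruthEntry:
    """Generative truth for one subject, for parameter-recovery checks."""

    latent: np.ndarray  # (T, 4)
    true_corr: dict  # {"sn_dmn": r, "sn_lcen": r, "sn_rcen": r}
    spike_volumes: np.ndarray
    censored_volumes: np.ndarray
    nb_linpred: float


def simulate_cohort(
    config: SimulationConfig,
) -> tuple[pd.DataFrame, dict[str, GroundTruthEntry]]:
    """Draw one 4·n_per_group cohort with matching ground truth.

    HIV+ cells use the population correlation matrix with the SN–DMN entry
    shifted by ``group_delta_sn_dmn`` (rejected before simulation if the
    shifted matrix loses positive semidefiniteness).  Unaware-error counts
    follow the negative-binomial model on the *true* SN–DMN Fisher-z.
    """
    rng = np.random.default_rng(config.seed)
    rows = []
    truth: dict[str, GroundTruthEntry] = {}
    cells = [(1, 1), (1, 0), (0, 1), (0, 0)]
    corr_by_hiv = {h: config.corr_for_group(bool(h)) for h in (0, 1)}
    sid = 0
    for hiv, cb in cells:
        corr = corr_by_hiv[hiv]
        z_true = {
            "sn_dmn": float(np.arctanh(corr[_IDX["SN"], _IDX["DMN"]])),
            "sn_lcen": float(np.arctanh(corr[_IDX["SN"], _IDX["L.CEN"]])),
            "sn_rcen": float(np.arctanh(corr[_IDX["SN"], _IDX["R.CEN"]])),
        }
        for _ in range(config.n_per_group):
            sid += 1
            subject = f"sub-{sid:03d}"
            latent = simulate_network_timeseries(corr, config.ar1_phi, config.T, rng)
            motion, spikes = MotionSpec(spike_rate=config.spike_rate).draw_motion(
                config.T, rng
            )
            censored = np.unique(
                np.clip(
                    np.concatenate([spikes - 1, spikes, spikes + 1])
                    if len(spikes)
                    else np.empty(0, dtype=int),
                    0,
                    config.T - 1,
                )
            )
            fd_steps = np.abs(np.diff(motion, axis=0)).sum()
            mean_fd = float(fd_steps / config.T)

            age = _truncated_normal(rng, config.age_mean, config.age_sd, config.age_range)
            male_p = config.male_prob_hiv_pos if hiv else config.male_prob_hiv_neg
            sex = int(rng.random() < male_p)
            nic = int(rng.random() < config.nic_prob)

            linpred = config.nb_intercept + config.nb_slope * z_true["sn_dmn"]
            unaware = int(
                simulate_unaware_counts(
                    np.array([z_true["sn_dmn"]]),
                    config.nb_intercept,
                    config.nb_slope,
                    config.nb_dispersion,
                    seed=rng,
                )[0]
            )
            n_nogo = int(config.n_task_runs * config.trials_per_run * config.nogo_prop)
            total_errors = int(rng.binomial(n_nogo, 0.475))
            unaware = min(unaware, total_errors)
            go_error_rate = float(rng.beta(2.0, 30.0))

            betas = {
                net: rng.normal(config.beta_mean[net], config.beta_sd)
                for net in NETWORKS
            }
            if hiv:
                betas["DMN"] += config.hiv_dmn_beta_shift

            rows.append(
                {
                    "subject": subject,
                    "hiv": hiv,
                    "cb": cb,
                    "age": age,
                    "sex": sex,
                    "nic": nic,
                    "mean_fd": mean_fd,
                    "true_z_sn_dmn": z_true["sn_dmn"],
                    "true_z_sn_lcen": z_true["sn_lcen"],
                    "true_z_sn_rcen": z_true["sn_rcen"],
                    "unaware_errors": unaware,
                    "total_nogo_errors": total_errors,
                    "go_error_rate": go_error_rate,
                    "beta_sn": betas["SN"],
                    "beta_dmn": betas["DMN"],
                    "beta_lcen": betas["L.CEN"],
                    "beta_rcen": betas["R.CEN"],
                }
            )
            truth[subject] = GroundTruthEntry(
                latent=latent,
                true_corr={k: float(np.tanh(v)) for k, v in z_true.items()},
                spike_volumes=spikes,
                censored_volumes=censored,
                nb_linpred=float(linpred),
            )
    return pd.DataFrame(rows), truth


def _truncated_normal(
    rng: np.random.Generator, mean: float, sd: float, bounds: tuple[float, float]
) -> float:
    lo, hi = bounds
    for _ in range(1000):
        x = rng.normal(mean, sd)
        if lo <= x <= hi:
            return float(x)
    return float(np.clip(rng.normal(mean, sd), lo, hi))


# ---------------------------------------------------------------------------
# EAT behaviour


@dataclass
class LogisticInhibitionModel:
    """Monotone difficulty → P(NoGo commission error) mapping.

    P(error | d) = floor + (ceiling − floor)·logistic((d − midpoint)/width).
    """

    midpoint: float = 0.5
    width: float = 0.15
    floor: float = 0.02
    ceiling: float = 0.98

    def __call__(self, difficulty: float) -> float:
        return self.floor + (self.ceiling - self.floor) * float(
            expit((difficulty - self.midpoint) / self.width)
        )


@dataclass
class Staircase:
    """Adaptive difficulty controller targeting a NoGo-error band.

    After every NoGo trial the running error rate over a sliding window of
    the last ``window`` NoGo trials is compared with the band: below the
    lower edge difficulty steps up, above the upper edge it steps down.
    """

    lower: float = 0.45
    upper: float = 0.50
    step: float = 0.05
    window: int = 20
    initial: float = 0.5
    bounds: tuple[float, float] = (0.0, 1.0)


@dataclass
class EATSessionResult:
    """Simulated error-awareness-task session for one subject."""

    trials: pd.DataFrame  # run, trial, is_nogo, difficulty, is_error, aware
    nogo_error_rate: float
    per_run_error_rate: list[float]
    n_aware: int
    n_unaware: int

    def events(self, iti: float = 1.5) -> pd.DataFrame:
        """BIDS-style event table: onset (s), duration, trial_type, run.

        NoGo trials become NoGo-correct / NoGo-error events; Go trials are
        the implicit baseline except that a configurable fraction could be
        Go-errors — here Go-errors are not trial-resolved, so only NoGo
        events are emitted.
        """
        rows = []
        for run, sub in self.trials.groupby("run"):
            for _, t in sub[sub.is_nogo].iterrows():
                rows.append(
                    {
                        "onset": float(t.trial * iti),
                        "duration": 0.0,
                        "trial_type": "NoGo-error" if t.is_error else "NoGo-correct",
                        "run": int(run),
                    }
                )
        return pd.DataFrame(rows)


def _validate_monotone(subject_model) -> None:
    grid = np.linspace(0.0, 1.0, 41)
    p = np.array([subject_model(d) for d in grid])
    if np.any(p < 0) or np.any(p > 1):
        raise ValueError("subject model must return probabilities in [0, 1]")
    if np.any(np.diff(p) < -1e-9):
        raise ValueError("subject model must be monotone nondecreasing in difficulty")


def simulate_eat_session(
    subject_model,
    controller: Staircase | None = None,
    n_runs: int = 6,
    trials_per_run: int = 225,
    nogo_prop: float = 0.20,
    awareness=0.75,
    seed=None,
) -> EATSessionResult:
    """Simulate one adaptive Go/NoGo (EAT) session.

    ``subject_model`` maps difficulty to P(NoGo commission error) and must
    be monotone; ``awareness`` is P(signalling awareness | error), either a
    constant or a callable of nothing.  Difficulty carries over across runs.
    """
    if trials_per_run < 50:
        raise ValueError("need trials_per_run >= 50")
    _validate_monotone(subject_model)
    ctrl = controller or Staircase()
    rng = np.random.default_rng(seed)

    difficulty = float(ctrl.initial)
    recent: deque = deque(maxlen=ctrl.window)
    records = []
    n_nogo_per_run = int(round(nogo_prop * trials_per_run))
    for run in range(n_runs):
        is_nogo = np.zeros(trials_per_run, dtype=bool)
        is_nogo[rng.choice(trials_per_run, size=n_nogo_per_run, replace=False)] = True
        for trial in range(trials_per_run):
            if not is_nogo[trial]:
                records.append((run, trial, False, difficulty, False, False))
                continue
            p_err = subject_model(difficulty)
            err = bool(rng.random() < p_err)
            aware = False
            if err:
                p_aw = awareness() if callable(awareness) else float(awareness)
                aware = bool(rng.random() < p_aw)
            records.append((run, trial, True, difficulty, err, aware))
            recent.append(err)
            rate = float(np.mean(recent))
            if rate < ctrl.lower:
                difficulty += ctrl.step
            elif rate > ctrl.upper:
                difficulty -= ctrl.step
            difficulty = float(np.clip(difficulty, *ctrl.bounds))

    trials = pd.DataFrame(
        records, columns=["run", "trial", "is_nogo", "difficulty", "is_error", "aware"]
    )
    nogo = trials[trials.is_nogo]
    per_run = (
        nogo.groupby("run")["is_error"].mean().reindex(range(n_runs)).tolist()
    )
    n_err = int(nogo.is_error.sum())
    n_aware = int((nogo.is_error & nogo.aware).sum())
    return EATSessionResult(
        trials=trials,
        nogo_error_rate=float(nogo.is_error.mean()),
        per_run_error_rate=[float(r) for r in per_run],
        n_aware=n_aware,
        n_unaware=n_err - n_aware,
    )


# ---------------------------------------------------------------------------
# unaware-error counts


def simulate_unaware_counts(
    sn_dmn_z: np.ndarray,
    nb_intercept: float,
    nb_slope: float,
    nb_dispersion: float,
    covariate_effects: np.ndarray | None = None,
    seed=None,
) -> np.ndarray:
    """Negative-binomial unaware-error counts with log-link mean.

    mean_i = exp(intercept + slope·z_i + covariate_effects_i); the NB2
    variance is mean + dispersion·mean².  ``nb_dispersion`` may be 0, which
    degenerates to the Poisson limit.  Sampling uses the gamma–Poisson
    mixture, reproducible under a fixed seed.
    """
    rng = np.random.default_rng(seed)
    z = np.asarray(sn_dmn_z, dtype=float)
    lin = nb_intercept + nb_slope * z
    if covariate_effects is not None:
        lin = lin + np.asarray(covariate_effects, dtype=float)
    if not np.all(np.isfinite(lin)):
        raise ValueError("non-finite linear predictor")
    if nb_dispersion < 0:
        raise ValueError("nb_dispersion must be nonnegative")
    mu = np.exp(lin)
    if nb_dispersion < 1e-12:
        return rng.poisson(mu)
    shape = 1.0 / nb_dispersion
    lam = rng.gamma(shape, nb_dispersion * mu)
    return rng.poisson(lam)
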