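"""Motion censoring and confound removal for resting-state BOLD runs.

Implements the scrubbing-plus-projection stage of a standard rs-fMRI
pipeline: framewise displacement (FD) from rigid-body motion parameters,
spike censoring with one-back/one-forward neighbor removal, anatomical
CompCor nuisance components from CSF and white-matter voxels, and a single
least-squares projection that removes nuisance regressors and all
frequencies outside the 0.01–0.1 Hz band simultaneously from the retained
volumes.  Motion *correction* itself is upstream; motion parameters are
consumed as input.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.signal import detrend

__all__ = [
    "FDTrace",
    "CensorPlan",
    "NuisanceSet",
    "compute_framewise_displacement",
    "build_censor_mask",
    "acompcor_components",
    "spectral_stopband_regressors",
    "project_clean",
    "check_temporal_dof",
]

#: Rotation-to-translation conversion radius in mm (Power FD convention).
DEFAULT_HEAD_RADIUS_MM = 50.0

#: Censoring threshold in mm of framewise displacement.
DEFAULT_FD_THRESHOLD_MM = 0.35


@dataclass
class FDTrace:
    """Per-volume framewise displacement in mm; first entry defined as 0.

    ``mean_fd`` is computed over all volumes before any censoring — the
    usual convention for the motion covariate entered in group models.
    """

    fd: np.ndarray
    mean_fd: float

    def __len__(self) -> int:
        return len(self.fd)


@dataclass
class CensorPlan:
    """Keep/censor flags with reason codes.

    ``reasons`` maps censored volume index to a tuple drawn from
    {"fd_spike", "fd_neighbor", "non_steady_state"}; a volume can carry
    several codes (e.g. a spike adjacent to another spike).
    """

    keep: np.ndarray
    reasons: dict[int, tuple[str, ...]]
    n_retained: int

    @property
    def censored(self) -> np.ndarray:
        return np.flatnonzero(~self.keep)


def compute_framewise_displacement(
    motion: np.ndarray, head_radius: float = DEFAULT_HEAD_RADIUS_MM
) -> FDTrace:
    """Power framewise displacement from T×6 rigid-body parameters.

    Columns are 3 translations (mm) then 3 rotations (radians);
    FD_t = Σ|Δtrans| + radius·Σ|Δrot| for t ≥ 1 and FD_0 = 0.
    """
    motion = np.asarray(motion, dtype=float)
    if motion.ndim != 2 or motion.shape[1] != 6:
        raise ValueError(f"motion parameters must be T x 6, got {motion.shape}")
    if motion.shape[0] < 2:
        raise ValueError("need at least 2 volumes to difference")
    if not np.all(np.isfinite(motion)):
        raise ValueError("non-finite motion parameters")
    d = np.abs(np.diff(motion, axis=0))
    fd = np.zeros(motion.shape[0])
    fd[1:] = d[:, :3].sum(axis=1) + head_radius * d[:, 3:].sum(axis=1)
    return FDTrace(fd=fd, mean_fd=float(fd.mean()))


def build_censor_mask(
    fd: FDTrace | np.ndarray,
    threshold: float = DEFAULT_FD_THRESHOLD_MM,
    n_nonsteady: int = 0,
) -> CensorPlan:
    """Censor FD spikes, their immediate neighbors, and initial dummy volumes.

    A volume with FD strictly above ``threshold`` is censored together with
    the volumes immediately preceding and following it (clipped to the run);
    the first ``n_nonsteady`` volumes are censored as non-steady-state.
    """
    trace = fd.fd if isinstance(fd, FDTrace) else np.asarray(fd, dtype=float)
    T = len(trace)
    if threshold <= 0:
        raise ValueError("threshold must be positive")
    if n_nonsteady < 0 or n_nonsteady >= T:
        raise ValueError(f"n_nonsteady must be in [0, {T}), got {n_nonsteady}")

    reasons: dict[int, list[str]] = {}

    def add(idx: int, code: str) -> None:
        reasons.setdefault(idx, []).append(code)

    spikes = np.flatnonzero(trace > threshold)
    for s in spikes:
        add(int(s), "fd_spike")
    for s in spikes:
        for nb in (s - 1, s + 1):
            if 0 <= nb < T and nb not in spikes:
                add(int(nb), "fd_neighbor")
    for t in range(n_nonsteady):
        add(t, "non_steady_state")

    keep = np.ones(T, dtype=bool)
    keep[list(reasons)] = False
    return CensorPlan(
        keep=keep,
        reasons={k: tuple(dict.fromkeys(v)) for k, v in sorted(reasons.items())},
        n_retained=int(keep.sum()),
    )


def acompcor_components(voxel_series: np.ndarray, k: int = 3) -> np.ndarray:
    """Anatomical CompCor: top-k principal-component time courses of a tissue mask.

    The T×V input is demeaned, linearly detrended and variance-normalized
    per voxel, then the first ``k`` left singular vectors are returned as
    unit-norm T×k columns ordered by singular value, each signed so its
    largest-magnitude element is positive.  Effectively rank-deficient
    input yields fewer columns with a warning.
    """
    x = np.asarray(voxel_series, dtype=float)
    if x.ndim != 2:
        raise ValueError("expected a T x V matrix")
    T, V = x.shape
    if V < k or T < k:
        raise ValueError(f"need at least k={k} voxels and timepoints, got {x.shape}")
    x = detrend(x - x.mean(axis=0), axis=0, type="linear")
    sd = x.std(axis=0)
    nz = sd > 0
    if not np.any(nz):
        raise ValueError("all voxels constant: no components")
    x = x[:, nz] / sd[nz]
    u, s, _ = np.linalg.svd(x, full_matrices=False)
    tol = s[0] * max(x.shape) * np.finfo(float).eps if s.size else 0.0
    rank = int(np.sum(s > tol))
    if rank < k:
        warnings.warn(
            f"tissue series has rank {rank} < k={k}; returning {rank} components",
            stacklevel=2,
        )
        k = rank
    comps = u[:, :k]
    sign = np.sign(comps[np.argmax(np.abs(comps), axis=0), np.arange(k)])
    sign[sign == 0] = 1.0
    return comps * sign


@dataclass
class NuisanceSet:
    """Confound regressors entered into the cleaning projection.

    3 CSF + 3 WM aCompCor component time courses, the six motion
    parameters, their backward-difference derivatives (first row 0), and
    one indicator column per non-steady-state volume.
    """

    compcor_csf: np.ndarray
    compcor_wm: np.ndarray
    motion: np.ndarray
    motion_deriv: np.ndarray
    nonsteady: np.ndarray = field(default_factory=lambda: np.zeros((0, 0)))

    @classmethod
    def build(
        cls,
        motion: np.ndarray,
        csf_series: np.ndarray,
        wm_series: np.ndarray,
        k: int = 3,
        n_nonsteady: int = 0,
    ) -> "NuisanceSet":
        motion = np.asarray(motion, dtype=float)
        T = motion.shape[0]
        deriv = np.zeros_like(motion)
        deriv[1:] = np.diff(motion, axis=0)
        ns = np.zeros((T, n_nonsteady))
        for j in range(n_nonsteady):
            ns[j, j] = 1.0
        return cls(
            compcor_csf=acompcor_components(csf_series, k),
            compcor_wm=acompcor_components(wm_series, k),
            motion=motion,
            motion_deriv=deriv,
            nonsteady=ns,
        )

    def as_matrix(self) -> np.ndarray:
        blocks = [self.compcor_csf, self.compcor_wm, self.motion, self.motion_deriv]
        if self.nonsteady.size:
            blocks.append(self.nonsteady)
        return np.column_stack(blocks)

    @property
    def n_regressors(self) -> int:
        return self.as_matrix().shape[1]


def spectral_stopband_regressors(
    T: int,
    tr: float,
    band: tuple[float, float] = (0.01, 0.1),
    low_basis: str = "dct",
) -> np.ndarray:
    """Regressors spanning all frequencies outside the (f_lo, f_hi) passband.

    The high stop-band (f ≥ f_hi) uses sine/cosine pairs at the DFT
    frequencies k/(T·TR) up to and including Nyquist.  The low stop-band
    (f ≤ f_lo) uses, by default, a DCT-II cosine block at half-cycle
    resolution k/(2·T·TR) — the standard fMRI drift basis — whose finer
    frequency spacing suppresses slow signals that do not complete an
    integer number of cycles in the run; the k = 0 term is the constant.
    ``low_basis="dft"`` instead uses plain DFT bins on the low side, which
    leaves noticeable leakage from non-bin slow frequencies.
    """
    f_lo, f_hi = band
    if not (0 <= f_lo < f_hi):
        raise ValueError("band must satisfy 0 <= f_lo < f_hi")
    if low_basis not in ("dct", "dft"):
        raise ValueError("low_basis must be 'dct' or 'dft'")
    t = np.arange(T)
    eps = 1e-12
    cols = []
    if low_basis == "dct":
        k = 0
        while k / (2 * T * tr) <= f_lo + eps:
            cols.append(np.cos(np.pi * k * (2 * t + 1) / (2 * T)))
            k += 1
    else:
        for k in range(T // 2 + 1):
            if k / (T * tr) > f_lo + eps:
                break
            ang = 2 * np.pi * k * t / T
            cols.append(np.cos(ang))
            if k != 0:
                cols.append(np.sin(ang))
    for k in range(T // 2 + 1):
        f = k / (T * tr)
        if f < f_hi - eps:
            continue
        ang = 2 * np.pi * k * t / T
        cols.append(np.cos(ang))
        if not (T % 2 == 0 and k == T // 2):
            cols.append(np.sin(ang))
    return np.column_stack(cols)


def project_clean(
    series: np.ndarray,
    nuisance: NuisanceSet | np.ndarray | None,
    band: tuple[float, float] = (0.01, 0.1),
    tr: float = 2.0,
    plan: CensorPlan | None = None,
    low_basis: str = "dct",
) -> np.ndarray:
    """Simultaneous nuisance regression and bandpass on retained volumes.

    Builds [nuisance | stop-band sines/cosines], drops censored rows from
    both data and regressors, and returns least-squares residuals of the
    retained rows.  Residuals are exactly orthogonal to every retained-row
    regressor; collinear regressors are handled by the pseudoinverse.
    """
    y = np.asarray(series, dtype=float)
    if y.ndim == 1:
        y = y[:, None]
    T = y.shape[0]
    blocks = [spectral_stopband_regressors(T, tr, band, low_basis)]
    if nuisance is not None:
        nmat = nuisance.as_matrix() if isinstance(nuisance, NuisanceSet) else np.asarray(nuisance, dtype=float)
        if nmat.ndim == 1:
            nmat = nmat[:, None]
        if nmat.shape[0] != T:
            raise ValueError(f"nuisance has {nmat.shape[0]} rows, data has {T}")
        blocks.insert(0, nmat)
    X = np.column_stack(blocks)
    if plan is not None:
        if len(plan.keep) != T:
            raise ValueError("censor plan length does not match data")
        y, X = y[plan.keep], X[plan.keep]
    if y.shape[0] == 0:
        raise ValueError("all volumes censored: nothing to clean")
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    return y - X @ beta


def check_temporal_dof(n_retained: int, n_regressors: int) -> bool:
    """Temporal degrees-of-freedom check for the cleaning projection.

    Returns True (pass) iff the regressors are strictly fewer than the
    retained volumes; subjects failing this are excluded from analysis.
    """
    if n_retained < 0 or n_regressors < 0:
        raise ValueError("counts must be nonnegative")
    return n_regressors < n_retained
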