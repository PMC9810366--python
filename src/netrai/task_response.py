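"""Event-related GLM estimation of error-related network responsivity.

Task runs are scaled to the voxel-wise mean so regression coefficients read
as approximate % BOLD signal change, then entered into a subject-level GLM
with three event regressors (NoGo-correct, NoGo-error, Go-error) modelled
as onset impulses convolved with a single-gamma hemodynamic response,
concatenated-run motion regressors and per-run Legendre baseline
polynomials.  Event βs are therefore responses over and above the ongoing
Go-trial baseline; the per-network summary is the mean NoGo-error β across
a network's voxels.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .connectivity import NETWORK_LABELS, NETWORKS

__all__ = [
    "EVENT_TYPES",
    "SubjectTaskFit",
    "gamma_hrf",
    "build_design_matrix",
    "scale_to_percent_bold",
    "fit_subject_glm",
    "extract_network_beta",
]

EVENT_TYPES = ("NoGo-correct", "NoGo-error", "Go-error")

#: Classic single-gamma HRF shape/scale; peak at p·q ≈ 4.70 s.
DEFAULT_HRF_SHAPE = 8.6
DEFAULT_HRF_SCALE = 0.547


def gamma_hrf(
    dt: float,
    duration: float = 25.0,
    p: float = DEFAULT_HRF_SHAPE,
    q: float = DEFAULT_HRF_SCALE,
) -> np.ndarray:
    """Sampled single-gamma hemodynamic response kernel.

    h(t) = (t/(p·q))^p · exp(p − t/q): zero at t = 0, unit peak at the
    single mode t = p·q seconds.  Sampled on a grid of spacing ``dt`` over
    [0, duration].
    """
    if dt <= 0 or p <= 0 or q <= 0:
        raise ValueError("dt, p and q must be positive")
    if duration < p * q:
        raise ValueError(f"duration {duration} s is shorter than the peak time {p * q:.3f} s")
    t = np.arange(0.0, duration + dt / 2, dt)
    with np.errstate(divide="ignore", invalid="ignore"):
        h = (t / (p * q)) ** p * np.exp(p - t / q)
    h[0] = 0.0
    return h


@dataclass
class SubjectTaskFit:
    """OLS fit of one subject's concatenated task runs."""

    beta: np.ndarray  # (n_regressors, n_voxels)
    columns: list[str]
    resid_var: np.ndarray  # per voxel, df-corrected
    cond: float

    def beta_for(self, name: str) -> np.ndarray:
        if name not in self.columns:
            raise KeyError(f"no regressor named {name!r}; have {self.columns}")
        return self.beta[self.columns.index(name)]


def _legendre_block(T: int, order: int) -> np.ndarray:
    x = np.linspace(-1.0, 1.0, T)
    return np.column_stack(
        [np.polynomial.legendre.Legendre.basis(d)(x) for d in range(order + 1)]
    )


def build_design_matrix(
    events: pd.DataFrame,
    n_volumes,
    tr: float,
    motion=None,
    poly_order: int = 4,
    hrf_p: float = DEFAULT_HRF_SHAPE,
    hrf_q: float = DEFAULT_HRF_SCALE,
) -> pd.DataFrame:
    """Concatenated-run design matrix for the subject-level task GLM.

    Parameters
    ----------
    events : DataFrame with columns ``run``, ``onset`` (s, relative to the
        run start) and ``trial_type`` (one of :data:`EVENT_TYPES`).
    n_volumes : int or sequence of int
        Volumes per run (a scalar means every run has that length).
    tr : float
        Sampling interval in seconds.
    motion : optional (total_volumes × 6) array
        Motion regressors, concatenated across runs as single columns.
    poly_order : int
        Per-run Legendre baseline polynomials of orders 0..poly_order,
        entered run-blocked (zero outside their run).

    Event impulses are placed at the onset-nearest volume, convolved with
    the gamma HRF sampled at TR, and concatenated across runs into one
    column per event type.  Event types with zero events are omitted with
    a warning; an event beyond its run's end is rejected.
    """
    runs = sorted(events["run"].unique()) if len(events) else []
    if np.isscalar(n_volumes):
        runs = runs or [0]
        run_lengths = {r: int(n_volumes) for r in runs}
    else:
        n_volumes = list(n_volumes)
        runs = runs or list(range(len(n_volumes)))
        if len(runs) != len(n_volumes):
            raise ValueError(
                f"{len(n_volumes)} run lengths given for {len(runs)} runs in events"
            )
        run_lengths = {r: int(n) for r, n in zip(runs, n_volumes)}
    total = sum(run_lengths.values())
    kernel = gamma_hrf(tr, p=hrf_p, q=hrf_q)

    cols: dict[str, np.ndarray] = {}
    present_types = [t for t in EVENT_TYPES if (events["trial_type"] == t).any()] if len(events) else []
    for missing in set(EVENT_TYPES) - set(present_types):
        warnings.warn(f"no {missing!r} events: column omitted", stacklevel=2)
    for etype in present_types:
        segs = []
        for r in runs:
            T = run_lengths[r]
            imp = np.zeros(T)
            sub = events[(events["run"] == r) & (events["trial_type"] == etype)]
            for onset in sub["onset"].to_numpy(dtype=float):
                vol = int(round(onset / tr))
                if onset < 0 or vol >= T:
                    raise ValueError(
                        f"event at {onset} s ({etype}) falls outside run {r} "
                        f"of {T} volumes"
                    )
                imp[vol] += 1.0
            segs.append(np.convolve(imp, kernel)[:T])
        cols[etype] = np.concatenate(segs)

    offset = 0
    for r in runs:
        T = run_lengths[r]
        block = _legendre_block(T, poly_order)
        for d in range(poly_order + 1):
            col = np.zeros(total)
            col[offset : offset + T] = block[:, d]
            cols[f"poly{d}_run{r}"] = col
        offset += T

    if motion is not None:
        motion = np.asarray(motion, dtype=float)
        if motion.shape != (total, 6):
            raise ValueError(f"motion must be ({total}, 6), got {motion.shape}")
        for j, name in enumerate(
            ["trans_x", "trans_y", "trans_z", "rot_x", "rot_y", "rot_z"]
        ):
            cols[f"motion_{name}"] = motion[:, j]

    return pd.DataFrame(cols)


def scale_to_percent_bold(series: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Scale each voxel series to its temporal mean (mean becomes 100).

    Returns (scaled T×V series, boolean mask of usable voxels); voxels with
    a nonpositive mean are flagged False and returned as NaN columns.
    """
    x = np.asarray(series, dtype=float)
    if x.ndim == 1:
        x = x[:, None]
    mean = x.mean(axis=0)
    good = mean > 0
    if not np.all(good):
        warnings.warn(
            f"{int((~good).sum())} voxel(s) with nonpositive mean excluded from scaling",
            stacklevel=2,
        )
    scaled = np.full_like(x, np.nan)
    scaled[:, good] = 100.0 * x[:, good] / mean[good]
    return scaled, good


def fit_subject_glm(scaled: np.ndarray, design: pd.DataFrame) -> SubjectTaskFit:
    """Ordinary least squares over voxels for one subject.

    Requires a full-column-rank design; event βs on %BOLD-scaled data read
    as % signal change relative to the implicit Go-trial baseline.
    """
    y = np.asarray(scaled, dtype=float)
    if y.ndim == 1:
        y = y[:, None]
    X = design.to_numpy(dtype=float)
    if y.shape[0] != X.shape[0]:
        raise ValueError(f"{y.shape[0]} data rows vs {X.shape[0]} design rows")
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        # name the aliased columns by QR pivoting
        from scipy.linalg import qr

        _, _, piv = qr(X, pivoting=True)
        bad = sorted(design.columns[i] for i in piv[rank:])
        raise ValueError(f"design is rank deficient; aliased columns: {bad}")
    beta, res, _, sv = np.linalg.lstsq(X, y, rcond=None)
    fitted = X @ beta
    dof = max(y.shape[0] - X.shape[1], 1)
    resid_var = ((y - fitted) ** 2).sum(axis=0) / dof
    return SubjectTaskFit(
        beta=beta,
        columns=list(design.columns),
        resid_var=resid_var,
        cond=float(sv[0] / sv[-1]),
    )


def extract_network_beta(
    fit: SubjectTaskFit,
    labels: np.ndarray,
    regressor: str = "NoGo-error",
) -> dict[str, float]:
    """Mean β of one regressor across each network's voxels.

    ``labels`` is flattened to one integer label per β-map voxel; the
    result is reported for every network in canonical order.
    """
    lab = np.asarray(labels).reshape(-1)
    bmap = fit.beta_for(regressor)
    if lab.size != bmap.size:
        raise ValueError(f"label grid has {lab.size} voxels, beta map has {bmap.size}")
    out = {}
    for name in NETWORKS:
        sel = lab == NETWORK_LABELS[name]
        if not np.any(sel):
            raise ValueError(f"network {name!r} has no voxels in the mask")
        out[name] = float(np.nanmean(bmap[sel]))
    return out
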