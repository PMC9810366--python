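"""Inter-network correlation metrics: Fisher-z couplings and Resource Allocation Index.

The triple-network model treats the salience network (SN) as a switch that
allocates processing resources between the central executive network (CEN,
split by hemisphere) and the default mode network (DMN).  The Resource
Allocation Index (RAI) summarises that balance for one subject as

    RAI = z(SN–CEN) − z(SN–DMN),        z(r) = 0.5·ln((1+r)/(1−r))

computed separately against the left and right CEN.  Higher RAI means SN
coupling is biased toward the executive network and away from the default
mode network.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "NETWORKS",
    "ConnectivityProfile",
    "extract_network_timeseries",
    "standardize_columns",
    "correlation_matrix",
    "fisher_z",
    "compute_rai",
    "connectivity_profile",
]

#: Canonical network order used everywhere in this package.
NETWORKS = ("SN", "DMN", "L.CEN", "R.CEN")

#: Integer labels in atlas volumes, matching :data:`NETWORKS` order.
NETWORK_LABELS = {name: i + 1 for i, name in enumerate(NETWORKS)}


@dataclass
class ConnectivityProfile:
    """Per-subject network coupling summary.

    ``cc`` is the 4×4 Pearson matrix in :data:`NETWORKS` order; the three
    ``fcc_*`` fields are Fisher-z transforms of the SN rows used by the RAI,
    and ``l_rai`` / ``r_rai`` the left/right Resource Allocation Indexes.
    """

    cc: np.ndarray
    fcc_sn_dmn: float
    fcc_sn_lcen: float
    fcc_sn_rcen: float
    l_rai: float
    r_rai: float
    networks: tuple[str, ...] = field(default=NETWORKS)

    def as_row(self, subject: str | None = None) -> dict:
        """Flatten to one cohort-CSV row (6 unique correlations + metrics)."""
        row: dict = {} if subject is None else {"subject": subject}
        n = len(self.networks)
        for i in range(n):
            for j in range(i + 1, n):
                key = f"cc_{self.networks[i]}_{self.networks[j]}"
                row[key.replace(".", "").replace("-", "_")] = self.cc[i, j]
        row.update(
            fcc_sn_dmn=self.fcc_sn_dmn,
            fcc_sn_lcen=self.fcc_sn_lcen,
            fcc_sn_rcen=self.fcc_sn_rcen,
            l_rai=self.l_rai,
            r_rai=self.r_rai,
        )
        return row


def standardize_columns(x: np.ndarray) -> np.ndarray:
    """Shift each column to zero mean and scale to unit variance (ddof=0)."""
    x = np.asarray(x, dtype=float)
    mu = x.mean(axis=0)
    sd = x.std(axis=0)
    if np.any(sd == 0):
        bad = np.flatnonzero(sd == 0)
        raise ValueError(f"zero-variance column(s) {bad.tolist()}: cannot standardize")
    return (x - mu) / sd


def extract_network_timeseries(
    data,
    labels: np.ndarray,
    plan=None,
    *,
    standardize_voxels: bool = False,
) -> np.ndarray:
    """Average voxels within each network label and standardize the result.

    Parameters
    ----------
    data : ndarray, 4D (x, y, z, t) or 2D (t, voxels)
        Cleaned BOLD data.  A 4D array is flattened against ``labels``; a 2D
        array expects ``labels`` flattened to one entry per voxel column.
    labels : ndarray of int
        Atlas with labels 1..4 in :data:`NETWORKS` order (0 = background).
    plan : CensorPlan, optional
        If given, only retained volumes enter the average.  Pass ``None``
        when the data are already censored.
    standardize_voxels : bool
        If True, z-score each voxel before averaging (the alternative
        reading of "standardized and averaged"); the region mean is always
        standardized afterwards either way, so downstream Pearson
        correlations are unaffected by the final scaling.

    Returns
    -------
    (n_retained, 4) array, columns ordered (SN, DMN, L.CEN, R.CEN), each
    zero-mean and unit-variance.
    """
    data = np.asarray(data, dtype=float)
    labels = np.asarray(labels)
    if data.ndim == 4:
        if data.shape[:3] != labels.shape:
            raise ValueError(
                f"grid mismatch: data spatial shape {data.shape[:3]} vs "
                f"labels shape {labels.shape}"
            )
        flat = data.reshape(-1, data.shape[3]).T  # (t, voxels)
        lab = labels.reshape(-1)
    elif data.ndim == 2:
        if data.shape[1] != labels.size:
            raise ValueError(
                f"grid mismatch: {data.shape[1]} voxel columns vs {labels.size} labels"
            )
        flat, lab = data, labels.reshape(-1)
    else:
        raise ValueError("data must be 4D (x,y,z,t) or 2D (t,voxels)")

    if plan is not None:
        flat = flat[plan.keep]

    cols = []
    for name in NETWORKS:
        sel = lab == NETWORK_LABELS[name]
        if not np.any(sel):
            raise ValueError(f"network label {name!r} has no voxels in the mask")
        block = flat[:, sel]
        if standardize_voxels:
            block = standardize_columns(block)
        cols.append(block.mean(axis=1))
    return standardize_columns(np.column_stack(cols))


def correlation_matrix(ts: np.ndarray) -> np.ndarray:
    """Pearson correlation matrix of network time-series columns.

    Requires at least 3 retained samples and nonzero column variance.
    """
    ts = np.asarray(ts, dtype=float)
    if ts.ndim != 2:
        raise ValueError("expected a 2D (time x network) array")
    if ts.shape[0] < 3:
        raise ValueError(f"need >= 3 retained timepoints, got {ts.shape[0]}")
    sd = ts.std(axis=0)
    if np.any(sd == 0):
        raise ValueError("zero-variance column: correlation undefined")
    cc = np.corrcoef(ts, rowvar=False)
    # enforce exact symmetry / unit diagonal against fp round-off
    cc = (cc + cc.T) / 2.0
    np.fill_diagonal(cc, 1.0)
    return cc


def fisher_z(cc):
    """Variance-stabilizing Fisher transform z = 0.5·ln((1+r)/(1−r)).

    Odd and strictly increasing on (−1, 1); rejects |r| ≥ 1 where the
    transform diverges.
    """
    cc = np.asarray(cc, dtype=float)
    if np.any(np.abs(cc) >= 1):
        raise ValueError("Fisher transform requires |r| < 1")
    out = np.arctanh(cc)
    return float(out) if out.ndim == 0 else out


def compute_rai(fcc_sn_dmn: float, fcc_sn_lcen: float, fcc_sn_rcen: float) -> tuple[float, float]:
    """Left/right Resource Allocation Index from the three Fisher-z couplings.

    L.RAI = z(SN–L.CEN) − z(SN–DMN);  R.RAI = z(SN–R.CEN) − z(SN–DMN).
    Both decrease strictly as SN–DMN coupling rises.
    """
    vals = np.array([fcc_sn_dmn, fcc_sn_lcen, fcc_sn_rcen], dtype=float)
    if not np.all(np.isfinite(vals)):
        raise ValueError("Fisher-z couplings must be finite")
    return float(fcc_sn_lcen - fcc_sn_dmn), float(fcc_sn_rcen - fcc_sn_dmn)


def connectivity_profile(ts: np.ndarray) -> ConnectivityProfile:
    """Full coupling profile (correlations, Fisher-z, RAIs) for one subject.

    ``ts`` is a retained-timepoint × 4 matrix in :data:`NETWORKS` order; it
    is standardized internally (Pearson r is invariant to that).
    """
    cc = correlation_matrix(np.asarray(ts, dtype=float))
    i = {name: k for k, name in enumerate(NETWORKS)}
    fcc_sn_dmn = fisher_z(cc[i["SN"], i["DMN"]])
    fcc_sn_lcen = fisher_z(cc[i["SN"], i["L.CEN"]])
    fcc_sn_rcen = fisher_z(cc[i["SN"], i["R.CEN"]])
    l_rai, r_rai = compute_rai(fcc_sn_dmn, fcc_sn_lcen, fcc_sn_rcen)
    return ConnectivityProfile(cc, fcc_sn_dmn, fcc_sn_lcen, fcc_sn_rcen, l_rai, r_rai)
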