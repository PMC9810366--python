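"""Run configuration: every pipeline threshold in one serializable object.

Defaults are the analysis constants of the emulated study: 0.35 mm FD
censoring threshold, 0.01–0.1 Hz passband, 3 aCompCor components per
tissue, 4th-order baseline polynomials, and the >50% Go-error performance
cap.  Configs round-trip through YAML unchanged.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field, fields
from pathlib import Path

import yaml

__all__ = ["RunConfig"]


@dataclass
class RunConfig:
    # simulation
    n_per_group: int = 4
    T: int = 245
    TR: float = 2.0
    ar1_phi: float = 0.4
    group_delta_sn_dmn: float = 0.15
    voxel_noise_sd: float = 0.5
    spike_rate: float = 0.02
    nb_intercept: float = 0.95
    nb_slope: float = 1.7
    nb_dispersion: float = 0.5
    seed: int = 0
    # preprocessing
    fd_threshold_mm: float = 0.35
    head_radius_mm: float = 50.0
    band_hz: tuple[float, float] = (0.01, 0.1)
    acompcor_k: int = 3
    n_nonsteady: int = 0
    # task GLM
    poly_order: int = 4
    task_runs: int = 6
    task_volumes_per_run: int = 169
    hrf_p: float = 8.6
    hrf_q: float = 0.547
    # QC / inference
    go_error_cap: float = 0.5
    outlier_z: float = 3.0
    rsfc_covariates: tuple[str, ...] = ("age", "sex", "mean_fd", "nic")
    behavior_covariates: tuple[str, ...] = ("age", "sex", "nic")
    nb_covariates: tuple[str, ...] = ("age", "sex", "mean_fd", "nic")

    def __post_init__(self) -> None:
        self.band_hz = tuple(self.band_hz)
        self.rsfc_covariates = tuple(self.rsfc_covariates)
        self.behavior_covariates = tuple(self.behavior_covariates)
        self.nb_covariates = tuple(self.nb_covariates)
        if self.fd_threshold_mm <= 0:
            raise ValueError("fd_threshold_mm must be positive")
        if not (0 <= self.band_hz[0] < self.band_hz[1]):
            raise ValueError("band_hz must be an increasing nonnegative pair")
        if self.acompcor_k < 1 or self.poly_order < 0:
            raise ValueError("acompcor_k must be >= 1 and poly_order >= 0")
        if not (0 < self.go_error_cap <= 1):
            raise ValueError("go_error_cap must lie in (0, 1]")

    def to_yaml(self, path: str | Path) -> None:
        data = asdict(self)
        for key, val in data.items():
            if isinstance(val, tuple):
                data[key] = list(val)
        Path(path).write_text(yaml.safe_dump(data, sort_keys=True))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)
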