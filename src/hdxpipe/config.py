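"""Run configuration: one YAML block drives every pipeline stage.

Defaults reproduce the study conditions the synthetic generator emulates:
75% D2O, pD 7, on-ice exchange (273.15 K), a five-point log-spaced time
grid 10^1..10^5 s, ~18% mean per-peptide back-exchange.
"""

from __future__ import annotations

import dataclasses
import hashlib
from dataclasses import dataclass, field

import yaml

from .chemistry import Direction, ExchangeConditions

__all__ = ["RunConfig", "DEFAULT_TIME_GRID"]

DEFAULT_TIME_GRID = (1e1, 1e2, 1e3, 1e4, 1e5)


@dataclass
class RunConfig:
    # exchange conditions
    pD: float = 7.0
    pD_correction: float = 0.0  # add +0.4 for the electrode-corrected convention
    temperature_K: float = 273.15
    d2o_fraction: float = 0.75
    time_grid: tuple[float, ...] = DEFAULT_TIME_GRID

    # synthetic-data generation
    backexchange_mean: float = 0.18
    backexchange_sd: float = 0.05
    backexchange_bounds: tuple[float, float] = (0.0, 0.5)
    noise_sd: float = 0.02  # multiplicative log-normal, fraction of peak height
    intensity_floor: float = 1e-3  # relative cutoff after noise
    digest_mean_len: float = 10.0
    digest_len_sd: float = 3.0
    digest_redundancy: float = 3.0

    # envelope analysis
    bimodal_aic_delta: float = 10.0
    bimodal_min_separation_da: float = 1.5
    bimodal_min_weight: float = 0.05
    charge_merge_tolerance: float = 10.0  # %D dispersion across charges before QC flag
    plateau_corrected: bool = False  # divide deuteron counts by the D2O plateau

    # rate mapping
    exhaustive_max_residues: int = 6
    n_restarts: int = 10
    ambiguity_tol: float = 1e-6
    residual_flag_tol: float = 1.0  # deuterons, per peptide-time, map QC

    # differential
    fold_time_level: float = 50.0  # % of the FD-normalized scale
    fold_bins: tuple[float, float] = (10.0, 1000.0)

    # structure
    probe_radius_A: float = 1.4
    sphere_points: int = 960

    seed: int = 0

    @property
    def conditions(self) -> ExchangeConditions:
        return ExchangeConditions(
            pD=self.pD + self.pD_correction,
            temperature_K=self.temperature_K,
            d2o_fraction=self.d2o_fraction,
            direction=Direction.H_TO_D,
        )

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["time_grid"] = list(self.time_grid)
        d["backexchange_bounds"] = list(self.backexchange_bounds)
        d["fold_bins"] = list(self.fold_bins)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        kw = dict(d)
        for key in ("time_grid", "backexchange_bounds", "fold_bins"):
            if key in kw:
                kw[key] = tuple(kw[key])
        return cls(**kw)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})

    def hash(self) -> str:
        blob = yaml.safe_dump(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha1(blob).hexdigest()[:12]
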