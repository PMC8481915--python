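"""Run configuration: every tunable of the pipeline with its default."""

from __future__ import annotations

from dataclasses import dataclass, asdict, field
from pathlib import Path

import yaml

from .io_plate import config_hash

__all__ = ["RunConfig"]


@dataclass
class RunConfig:
    """All pipeline tunables in one place (YAML round-trippable).

    Defaults reproduce the documented behavior of every stage; any field can
    be overridden from a config file or CLI flag.
    """

    seed: int = 0

    # synthetic screen
    n_drugs: int = 16
    n_selective: int = 0
    n_seed_cells: int = 1000
    assay_hours: float = 96.0
    c_max_uM: float = 5.0
    n_doses: int = 5
    dilution_fold: float = 2.0
    noise: str = "poisson"
    n_negative: int = 14
    n_positive: int = 6
    n_growth: int = 6
    n_stain: int = 6

    # gating
    gating_quantile: float = 0.99
    min_control_cells: int = 100

    # GR normalization
    neg_filter_limit: float = 1.5
    growth_filter_limit: float = 1.0
    min_control_wells: int = 2

    # dose-response / selectivity
    cytotox_threshold: float = 0.0

    # RPPA
    rppa_log_base: float = 2.0
    rppa_z_ddof: int = 1
    rppa_z_scope: str = "marker"
    rppa_z_threshold: float = 2.0

    # synergy
    fa_level: float = 0.5
    fa_source: str = "counts"   # "counts" | "gr"
    ratio_a: float = 1.0
    ratio_b: float = 5.0

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        unknown = set(data) - set(cls.__dataclass_fields__)
        if unknown:
            raise ValueError(f"unknown config key(s): {', '.join(sorted(unknown))}")
        return cls(**data)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(asdict(self), sort_keys=True))

    def to_dict(self) -> dict:
        return asdict(self)

    @property
    def hash(self) -> str:
        return config_hash(self.to_dict())
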