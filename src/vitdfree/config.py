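"""Pipeline configuration: binding constants, thresholds, YAML round-trip.

The affinity constants and molar masses are configuration values, never
literals inside the computational operations: the literature disagrees on
whether VDBP affinity is genotype-specific at all, and the VDBP molar mass
materially shifts absolute free levels, so both must be swappable without
touching code.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import yaml

from .binding import BindingScheme

__all__ = ["BindingConfig", "Thresholds", "PipelineConfig",
           "load_config", "save_config"]


@dataclass
class BindingConfig:
    """The ``binding:`` block — affinities (M^-1), molar masses (g/mol), mode."""

    k_dbp_constant: float = 0.7e9
    k_alb: float = 6e5
    allele_k_dbp: dict[str, float] = field(
        default_factory=lambda: {"Gc1f": 1.12e9, "Gc1s": 0.60e9, "Gc2": 0.36e9}
    )
    mw_25ohd: float = 400.64
    mw_vdbp: float = 58_000.0
    mw_albumin: float = 66_500.0
    mode: str = "linear"  # 'linear' (binder-total) or 'exact' (depletion-corrected)

    def constant_scheme(self) -> BindingScheme:
        return BindingScheme(
            k_dbp=self.k_dbp_constant, k_alb=self.k_alb,
            mw_25ohd=self.mw_25ohd, mw_vdbp=self.mw_vdbp,
            mw_albumin=self.mw_albumin, label="constant",
        )


@dataclass
class Thresholds:
    """Clinical cut-offs and statistical rules used throughout the pipeline."""

    deficiency_ng_ml: float = 20.0
    bmi_overweight_pct: float = 85.0
    bmi_obese_pct: float = 95.0
    activity_min_per_day: float = 60.0
    activity_days_per_week: float = 3.0
    vif_limit: float = 3.0
    bonferroni_family: int = 15  # C(6,2) pairwise diplotype comparisons
    alpha: float = 0.05

    def __post_init__(self) -> None:
        for f in dataclasses.fields(self):
            if getattr(self, f.name) <= 0:
                raise ValueError(f"threshold {f.name} must be positive")


@dataclass
class PipelineConfig:
    """Everything the simulate → derive → analyze pipeline needs."""

    binding: BindingConfig = field(default_factory=BindingConfig)
    thresholds: Thresholds = field(default_factory=Thresholds)
    reference_table: str | None = None  # None -> packaged synthetic reference
    seed: int = 0

    def to_dict(self) -> dict[str, Any]:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict[str, Any]) -> "PipelineConfig":
        return cls(
            binding=BindingConfig(**d.get("binding", {})),
            thresholds=Thresholds(**d.get("thresholds", {})),
            reference_table=d.get("reference_table"),
            seed=int(d.get("seed", 0)),
        )


def load_config(path: str | Path | None = None) -> PipelineConfig:
    """Load a YAML config; with ``path=None`` return defaults."""
    if path is None:
        return PipelineConfig()
    with open(path, "r", encoding="utf-8") as fh:
        data = yaml.safe_load(fh) or {}
    return PipelineConfig.from_dict(data)


def save_config(config: PipelineConfig, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        yaml.safe_dump(config.to_dict(), fh, sort_keys=True)
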