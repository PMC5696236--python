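"""Run configuration: thresholds of the CT screen with validated defaults.

Defaults encode the screen's published operating point: a testis-proportion
tier of 0.9 (0.99 as the stringent alternative), an expression cutoff of 1
(strict ``> 1`` in the matrix's native unit), CT prevalence of 10% (15%
stringent, both inclusive), q-value cutoff 0.05, oncogene/suppressor S-score
cutoffs +3/-3 (inclusive), and 10,000 Monte Carlo simulations.
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields, asdict
from typing import Any, Mapping

import yaml

__all__ = ["RunConfig", "load_config", "ConfigError"]


class ConfigError(ValueError):
    """A configuration value is missing or out of range."""


@dataclass
class RunConfig:
    proportional_tiers: tuple[float, ...] = (0.9, 0.99)
    active_tier: float = 0.9
    consensus_mode: str = "union"  # or "intersection"
    expr_cutoff: float = 1.0
    prevalence_thresholds: tuple[float, ...] = (0.10, 0.15)
    active_prevalence: float = 0.10
    onco_cutoff: float = 3.0
    supp_cutoff: float = -3.0
    inclusive_sscore_cutoffs: bool = True
    n_sims: int = 10000
    enrichment_alpha: float = 0.05
    q_cutoff: float = 0.05
    pool_qvalues_across_tumors: bool = False
    min_expressed: int = 30
    min_tier_size: int = 10
    seed: int = 0
    log_level: str = "INFO"

    def __post_init__(self) -> None:
        self.proportional_tiers = tuple(sorted(float(t) for t in self.proportional_tiers))
        self.prevalence_thresholds = tuple(sorted(float(t) for t in self.prevalence_thresholds))
        for t in self.proportional_tiers + (self.active_tier,):
            if not 0.0 < t <= 1.0:
                raise ConfigError(f"proportional tier must lie in (0, 1], got {t}")
        for p in self.prevalence_thresholds + (self.active_prevalence,):
            if not 0.0 < p <= 1.0:
                raise ConfigError(f"prevalence threshold must lie in (0, 1], got {p}")
        if self.consensus_mode not in ("union", "intersection"):
            raise ConfigError(f"consensus_mode must be union|intersection, got {self.consensus_mode!r}")
        if self.expr_cutoff < 0:
            raise ConfigError(f"expr_cutoff must be >= 0, got {self.expr_cutoff}")
        if not self.supp_cutoff < self.onco_cutoff:
            raise ConfigError(
                f"supp_cutoff ({self.supp_cutoff}) must be < onco_cutoff ({self.onco_cutoff})"
            )
        if self.n_sims < 1:
            raise ConfigError(f"n_sims must be >= 1, got {self.n_sims}")
        if not 0.0 < self.q_cutoff <= 1.0:
            raise ConfigError(f"q_cutoff must lie in (0, 1], got {self.q_cutoff}")
        if self.min_expressed < 0:
            raise ConfigError(f"min_expressed must be >= 0, got {self.min_expressed}")

    def to_dict(self) -> dict[str, Any]:
        d = asdict(self)
        d["proportional_tiers"] = list(self.proportional_tiers)
        d["prevalence_thresholds"] = list(self.prevalence_thresholds)
        return d


def _from_mapping(mapping: Mapping[str, Any]) -> RunConfig:
    known = {f.name for f in fields(RunConfig)}
    unknown = set(mapping) - known
    if unknown:
        raise ConfigError(f"unknown configuration keys: {sorted(unknown)}")
    kwargs = dict(mapping)
    for key in ("proportional_tiers", "prevalence_thresholds"):
        if key in kwargs:
            kwargs[key] = tuple(kwargs[key])
    return RunConfig(**kwargs)


def load_config(path) -> RunConfig:
    """Load a YAML run configuration; an empty file yields all defaults."""
    with open(path, encoding="utf-8") as fh:
        raw = yaml.safe_load(fh)
    if raw is None:
        raw = {}
    if not isinstance(raw, Mapping):
        raise ConfigError(f"{path}: top level must be a mapping")
    return _from_mapping(raw)
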