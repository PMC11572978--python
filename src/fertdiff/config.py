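"""Run configuration: YAML-backed settings shared by the CLI subcommands."""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import yaml

__all__ = ["RunConfig", "ConfigError", "DEFAULT_PATHS"]

DEFAULT_PATHS = {
    "surface": "fertility_surface.csv",
    "cohort_cfr": "cohort_cfr.csv",
    "slamys": "slamys.csv",
    "weights": "education_weights.csv",
    "microdata": "microdata.csv",
    "rates": "diffusion_rates.csv",
    "projected": "projected_cfr.csv",
    "report": "validation_report.csv",
    "coefficients": "coefficients.csv",
    "curves": "curves.csv",
}


class ConfigError(ValueError):
    """Configuration invariant violated; message names the field."""


@dataclass
class RunConfig:
    """Settings shared across pipeline stages.

    Cohorts are labelled by the start year of their 5-year interval and the
    step is fixed at 5 (the resolution of the fertility surfaces).
    ``est_start``/``est_end`` are the endpoint cohorts of the diffusion-rate
    estimator; ``truncation_cohort``/``horizon_cohort`` drive out-of-sample
    validation; ``rates_region`` is the aggregate whose SLAMYS series the
    estimator uses.
    """

    paths: dict = field(default_factory=lambda: dict(DEFAULT_PATHS))
    cohort_start: int = 1955
    cohort_end: int = 1985
    step: int = 5
    est_start: int = 1955
    est_end: int = 1985
    truncation_cohort: int = 1965
    horizon_cohort: int = 1985
    rates_region: str = "AFRICA"
    country: str = "AFRICA"
    seed: int = 0
    log_level: str = "INFO"
    last_observed_period: int | None = None
    scenario: dict = field(default_factory=dict)
    strata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.step != 5:
            raise ConfigError(f"step must be 5, got {self.step}")
        if self.cohort_start > self.cohort_end:
            raise ConfigError("cohort_start must not exceed cohort_end")
        if not (isinstance(self.seed, int) and self.seed >= 0):
            raise ConfigError(f"seed must be a nonnegative integer, "
                              f"got {self.seed!r}")
        paths = dict(DEFAULT_PATHS)
        paths.update(self.paths or {})
        self.paths = paths

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        if not isinstance(raw, dict):
            raise ConfigError("config file must contain a mapping")
        unknown = set(raw) - {f for f in cls.__dataclass_fields__}
        if unknown:
            raise ConfigError(f"unknown config fields: {sorted(unknown)}")
        return cls(**raw)

    @property
    def cohorts(self) -> list[int]:
        return list(range(self.cohort_start, self.cohort_end + 1, self.step))

    def digest(self) -> str:
        """Stable hash of the full configuration, for run logging."""
        canon = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(canon.encode()).hexdigest()[:12]
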