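"""Configuration objects for the measurement-continuity pipeline.

All stage parameters live in small dataclasses that serialize to/from a single
YAML document.  Defaults encode the study conventions the rest of the package
assumes: the 28-day inactivity rule, 14-day observation windows, prediction
horizons from 28 to 91 days in 7-day steps, and fivefold cross-validation.
"""

from __future__ import annotations

import dataclasses
import hashlib
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import yaml

# Day 0 of every simulated calendar: a Monday, so weekday structure is
# reproducible.  2018-01-01 is a Monday.
CALENDAR_ORIGIN = "2018-01-01"

INACTIVITY_THRESHOLD_DAYS = 28
WINDOW_DAYS = 14
HORIZON_GRID = tuple(range(28, 92, 7))  # 28, 35, ..., 91
RESUMPTION_WEEKS = 4
CV_FOLDS = 5
NON_RESUMPTION_FOLLOWUP_DAYS = 180


class ConfigError(ValueError):
    """Invalid configuration value or section."""


class DataError(ValueError):
    """Input data violates the declared schema or a contract."""


@dataclass
class GeneratorConfig:
    """Parameters of the synthetic measurement-cohort generator.

    The demographics default to the reference cohort's marginals (age
    55.5 +/- 11.4 years; 61.4 / 29.1 / 9.5 % male / female / unspecified;
    user-level mean SBP centred at 128 mmHg).  The behavioural and hazard
    parameters are the generator's own model of measurement habits: a daily
    Bernoulli measurement probability with a slowly decaying habit term, an
    absorbing dropout state entered with a covariate-dependent daily hazard
    and left only through rare resumption, and a linear decline of weekday
    measurement probability in the weeks preceding dropout.
    """

    n_users: int = 1000
    seed: int = 0
    calendar_span_days: int = 450
    start_day_spread: int = 60  # first measurements uniform on [0, spread]
    sex_probs: tuple[float, float, float] = (0.614, 0.291, 0.095)
    age_mean_sd: tuple[float, float] = (55.5, 11.4)
    age_bounds: tuple[float, float] = (18.0, 95.0)
    sbp_user_mean_sd: tuple[float, float] = (128.0, 12.0)
    sbp_daily_sd: float = 6.0
    base_daily_meas_prob: float = 0.70
    habit_decay_rate: float = 0.003  # per day, on the logit scale
    two_readings_prob: float = 0.30  # P(2 readings | measured day)
    baseline_hazard: float = 0.0020  # per day
    effect_age_quadratic: float = 0.25  # on ((age - 60) / 15)^2
    effect_female: float = 0.30
    effect_unspecified: float = 0.60
    effect_sbp_ushape: float = 0.45  # on ((s* - 130) / 20)^2
    weekday_decline_days: int = 28
    resumption_prob: float = 0.0012  # per day in the dropped state
    regime_B_fraction: float = 0.75
    regime_B_hazard_multiplier: float = 1.3

    def validate(self) -> "GeneratorConfig":
        if self.n_users < 0:
            raise ConfigError("n_users must be non-negative")
        if self.calendar_span_days <= 0:
            raise ConfigError("calendar_span_days must be positive")
        if abs(sum(self.sex_probs) - 1.0) > 1e-12:
            raise ConfigError("sex_probs must sum to 1")
        probs = (
            *self.sex_probs,
            self.base_daily_meas_prob,
            self.two_readings_prob,
            self.resumption_prob,
            self.regime_B_fraction,
        )
        if any(p < 0 or p > 1 for p in probs):
            raise ConfigError("probabilities must lie in [0, 1]")
        if self.baseline_hazard < 0 or self.sbp_daily_sd < 0:
            raise ConfigError("hazards and SDs must be non-negative")
        if self.age_mean_sd[1] < 0 or self.sbp_user_mean_sd[1] < 0:
            raise ConfigError("hazards and SDs must be non-negative")
        if self.habit_decay_rate < 0:
            raise ConfigError("habit_decay_rate must be non-negative")
        if self.regime_B_hazard_multiplier < 0:
            raise ConfigError("regime_B_hazard_multiplier must be non-negative")
        if self.start_day_spread < 0 or self.start_day_spread >= self.calendar_span_days:
            raise ConfigError("start_day_spread must lie in [0, calendar_span_days)")
        return self


@dataclass
class LabelingConfig:
    inactivity_threshold: int = INACTIVITY_THRESHOLD_DAYS
    window_days: int = WINDOW_DAYS
    horizons: tuple[int, ...] = HORIZON_GRID
    keep_empty_windows: bool = True

    def validate(self) -> "LabelingConfig":
        if self.inactivity_threshold < 1 or self.window_days < 1:
            raise ConfigError("threshold and window length must be positive")
        for x in self.horizons:
            if x not in HORIZON_GRID:
                raise ConfigError(f"horizon {x} is off the 28..91 step-7 grid")
        return self


@dataclass
class TrainingConfig:
    model_types: tuple[str, ...] = ("gbt", "logistic")
    n_folds: int = CV_FOLDS
    budget_trials: int = 50
    seed: int = 0
    horizons: tuple[int, ...] = HORIZON_GRID

    def validate(self) -> "TrainingConfig":
        if self.budget_trials < 1:
            raise ConfigError("budget_trials must be >= 1")
        if self.n_folds < 2:
            raise ConfigError("n_folds must be >= 2")
        for m in self.model_types:
            if m not in ("gbt", "logistic"):
                raise ConfigError(f"unknown model type {m!r}")
        return self


@dataclass
class PipelineConfig:
    """One document configuring simulate -> label -> featurize -> train ->
    explain -> describe."""

    generator: GeneratorConfig = field(default_factory=GeneratorConfig)
    labeling: LabelingConfig = field(default_factory=LabelingConfig)
    training: TrainingConfig = field(default_factory=TrainingConfig)
    explain_horizon: int = 56
    out_dir: str = "pipeline_out"
    log_level: str = "INFO"

    def validate(self) -> "PipelineConfig":
        self.generator.validate()
        self.labeling.validate()
        self.training.validate()
        if self.explain_horizon not in HORIZON_GRID:
            raise ConfigError("explain_horizon must lie on the 28..91 grid")
        return self

    def to_dict(self) -> dict[str, Any]:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict[str, Any]) -> "PipelineConfig":
        def build(tp, section):
            if section is None:
                return tp()
            fields = {f.name for f in dataclasses.fields(tp)}
            unknown = set(section) - fields
            if unknown:
                raise ConfigError(f"unknown keys in {tp.__name__}: {sorted(unknown)}")
            kwargs = {
                k: tuple(v) if isinstance(v, list) else v for k, v in section.items()
            }
            return tp(**kwargs)

        cfg = cls(
            generator=build(GeneratorConfig, d.get("generator")),
            labeling=build(LabelingConfig, d.get("labeling")),
            training=build(TrainingConfig, d.get("training")),
            explain_horizon=d.get("explain_horizon", 56),
            out_dir=d.get("out_dir", "pipeline_out"),
            log_level=d.get("log_level", "INFO"),
        )
        return cfg.validate()

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        d = yaml.safe_load(Path(path).read_text()) or {}
        return cls.from_dict(d)

    def content_hash(self) -> str:
        """Hash of the scientific parameters (output location and verbosity
        do not affect results and are excluded)."""
        d = self.to_dict()
        d.pop("out_dir", None)
        d.pop("log_level", None)
        canonical = yaml.safe_dump(d, sort_keys=True)
        return hashlib.sha256(canonical.encode()).hexdigest()[:16]
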