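"""Configuration objects and deterministic seed derivation.

Every stochastic component draws from a child seed derived from one master
seed via :func:`child_seed`, keyed by *what* is being computed (imputation
copy, target hour, person slot) rather than by execution order, so any
single model fit is reproducible in isolation and results do not depend on
parallelism or iteration order.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict, is_dataclass
from pathlib import Path
from typing import Mapping

import numpy as np
import yaml

from .exceptions import ConfigError

# Study-cohort race composition (21 + 2 + 1 + 5 + 2 = 31 persons).
DEFAULT_RACE_DISTRIBUTION: dict[str, float] = {
    "caucasian": 21 / 31,
    "african_american": 2 / 31,
    "hispanic_latino": 1 / 31,
    "asian_american": 5 / 31,
    "other": 2 / 31,
}


def child_seed(master: int, *key: int) -> int:
    """Derive a reproducible child seed < 2**31 from a master seed and a key.

    The key identifies the unit of work, e.g. ``(imputation, hour, person)``.
    """
    ss = np.random.SeedSequence(int(master), spawn_key=tuple(int(k) for k in key))
    return int(ss.generate_state(1, dtype=np.uint32)[0] % (2**31))


def child_rng(master: int, *key: int) -> np.random.Generator:
    return np.random.default_rng(child_seed(master, *key))


@dataclass
class CohortConfig:
    """Parameters of the synthetic EMA + passive-sensing cohort.

    Defaults emulate the study design this generator stands in for: 31
    persons enrolled ~8 days, hourly on-the-hour sensor indexing, mood
    prompts only during self-reported wake hours (16/day) over 7 prompting
    days, with ~46% prompt compliance (≈52 completed prompts per person).
    """

    n_persons: int = 31
    n_days: int = 8
    wake_hours_per_day: int = 16
    #: mood prompts are issued during the first `prompt_days` days only
    #: (enrollment ends with a lab visit, so the last day yields no prompts);
    #: None means min(7, n_days).
    prompt_days: int | None = None
    compliance_rate: float = 0.46
    ar_coefficient: float = 0.7
    diurnal_amplitude: float = 8.0  # mood units, peak of the 24-h sinusoid
    #: habitual (between-person) mood level: mean + slope * (DASS-D - 20)
    #: + N(0, intercept_sd).  Setting slope and SD to 0 makes persons
    #: exchangeable — the fully null cohort used in calibration tests.
    intercept_mean: float = 27.0
    intercept_dass_slope: float = 0.6
    intercept_sd: float = 4.0
    coupling_scale: float = 1.0  # multiplies every sensor-mood coupling
    coupling_heterogeneity: float = 0.5  # SD of person-specific coupling deviations
    noise_sd: float = 6.0  # mood units, AR(1) innovation SD
    #: SD of the independent item noise added to the sad / lonely readouts;
    #: None picks the value that targets a sad-lonely correlation ≈ 0.66
    #: at the current latent-variance settings.
    item_noise_sd: float | None = None
    #: probability that a within-wake mood rating is forced to 0 (floor
    #: effects are plausible on a 0-100 scale; off by default).
    zero_inflation: float = 0.0
    sensor_missing_rate: float = 0.05
    #: fraction of persons whose sensor-mood couplings are sign-flipped —
    #: used to build cohorts where idiographic weighting must beat the
    #: pooled model.
    flip_fraction: float = 0.0
    race_distribution: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_RACE_DISTRIBUTION)
    )
    seed: int = 0

    @property
    def n_hours(self) -> int:
        return self.n_days * 24

    @property
    def effective_prompt_days(self) -> int:
        return min(7, self.n_days) if self.prompt_days is None else self.prompt_days

    def validate(self) -> None:
        if self.n_persons < 1:
            raise ConfigError("n_persons must be >= 1")
        if self.n_days < 1:
            raise ConfigError("n_days must be >= 1")
        if not 0 <= self.compliance_rate <= 1:
            raise ConfigError("compliance_rate must lie in [0, 1]")
        if not abs(self.ar_coefficient) < 1:
            raise ConfigError("|ar_coefficient| must be < 1 for a stationary process")
        if not 0 <= self.wake_hours_per_day <= 24:
            raise ConfigError("wake_hours_per_day must lie in [0, 24]")
        if not 0 <= self.flip_fraction <= 1:
            raise ConfigError("flip_fraction must lie in [0, 1]")
        if not 0 <= self.zero_inflation <= 1:
            raise ConfigError("zero_inflation must lie in [0, 1]")
        probs = list(self.race_distribution.values())
        if len(self.race_distribution) < 1 or any(p < 0 for p in probs):
            raise ConfigError("race_distribution must map categories to probabilities >= 0")
        if abs(sum(probs) - 1.0) > 1e-9:
            raise ConfigError(
                f"race probabilities must sum to 1 (got {sum(probs)!r})"
            )


@dataclass
class WeightScheme:
    """Observation weights of the idiographic stage: the target person's rows
    get `target_weight`, everyone else's `other_weight` (study used 1 / 0.2)."""

    target_weight: float = 1.0
    other_weight: float = 0.2

    def validate(self) -> None:
        # other_weight = 0 is the person-only degenerate scheme, kept legal
        if self.target_weight <= 0 or self.other_weight < 0:
            raise ConfigError("target_weight must be > 0 and other_weight >= 0")
        if self.target_weight < self.other_weight:
            raise ConfigError("target_weight must be >= other_weight")


@dataclass
class NomotheticConfig:
    """Pooled gradient-boosted stage (XGBoost) over within-person-centered mood."""

    rounds: int = 100
    depth: int = 3
    learning_rate: float = 0.1
    center_within_person: bool = True

    def validate(self) -> None:
        if self.rounds < 1:
            raise ConfigError("rounds must be >= 1")
        if self.depth < 1:
            raise ConfigError("depth must be >= 1")


@dataclass
class IdiographicConfig:
    """Per-person weighted randomized-forest stage.

    Grid search tunes the per-split candidate count (three evenly spaced
    integers in [1, p]) crossed with the split rule (variance vs extremely
    randomized); `grid_search=False` skips tuning and uses sqrt(p) with the
    variance rule, which is how bulk simulation runs keep their footprint
    small.
    """

    forest_size: int = 300
    grid_search: bool = True
    cv_folds: int = 3

    def validate(self) -> None:
        if self.forest_size < 1:
            raise ConfigError("forest_size must be >= 1")
        if self.cv_folds < 2:
            raise ConfigError("cv_folds must be >= 2")


@dataclass
class RunConfig:
    """Everything one end-to-end run needs; serializes losslessly to YAML."""

    cohort: CohortConfig = field(default_factory=CohortConfig)
    m_imputations: int = 5
    lookback: int = 24
    #: fit/predict every `hour_stride`-th target hour (1 = every hour)
    hour_stride: int = 1
    weights: WeightScheme = field(default_factory=WeightScheme)
    nomothetic: NomotheticConfig = field(default_factory=NomotheticConfig)
    idiographic: IdiographicConfig = field(default_factory=IdiographicConfig)
    output_dir: str = "results"
    seed: int = 0

    def validate(self) -> None:
        self.cohort.validate()
        self.weights.validate()
        self.nomothetic.validate()
        self.idiographic.validate()
        if self.m_imputations < 1:
            raise ConfigError("m_imputations must be >= 1")
        if self.lookback < 1:
            raise ConfigError("lookback must be >= 1")
        if self.hour_stride < 1:
            raise ConfigError("hour_stride must be >= 1")

    # ---- serialization ----------------------------------------------------
    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: Mapping) -> "RunConfig":
        d = dict(d)
        kwargs = {}
        for name, sub in [
            ("cohort", CohortConfig),
            ("weights", WeightScheme),
            ("nomothetic", NomotheticConfig),
            ("idiographic", IdiographicConfig),
        ]:
            if name in d:
                val = d.pop(name)
                kwargs[name] = sub(**val) if isinstance(val, Mapping) else val
        known = {f for f in cls.__dataclass_fields__}  # type: ignore[attr-defined]
        for key in d:
            if key not in known:
                raise ConfigError(f"unknown config key: {key!r}")
        kwargs.update(d)
        return cls(**kwargs)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=False))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text())
        if not isinstance(raw, Mapping):
            raise ConfigError(f"config file {path} does not contain a mapping")
        cfg = cls.from_dict(raw)
        cfg.validate()
        return cfg


def config_hash(cfg: RunConfig) -> str:
    """Stable short hash of a run configuration, for manifests."""
    import hashlib
    import json

    def default(o):
        if is_dataclass(o):
            return asdict(o)
        raise TypeError(type(o))

    blob = json.dumps(cfg.to_dict(), sort_keys=True, default=default).encode()
    return hashlib.sha256(blob).hexdigest()[:16]
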