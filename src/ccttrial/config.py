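"""Run configuration: dataclasses, YAML round-trip, seed substreams.

Every stochastic component draws from a named substream derived from one
root seed, so a whole run (cohort -> screening -> randomisation -> training
responses -> measurement) can be replayed exactly from ``(config, seed)``.
"""

from __future__ import annotations

import dataclasses
import hashlib
from dataclasses import dataclass, field

import numpy as np
import yaml

#: Named substreams of the root seed. The index is part of the replay
#: contract: changing it changes every downstream draw.
_STREAMS = {
    "cohort": 0,
    "screening": 1,
    "randomisation": 2,
    "responses": 3,
    "usage": 4,
    "measurement": 5,
    "dropout": 6,
}


def substream(root_seed: int, name: str) -> np.random.Generator:
    """Return the named child generator of ``root_seed``."""
    if name not in _STREAMS:
        raise KeyError(f"unknown random substream {name!r}")
    return np.random.default_rng([int(root_seed) % (2**31), _STREAMS[name]])


@dataclass
class CohortConfig:
    """Marginal distributions of the virtual study sample.

    Defaults target the baseline table of the trial being emulated
    (n = 89, age 73.5 +/- 7.3 years, 41.6% female, activity hours,
    vascular-risk count 0-4, medication sum score, PHQ-9).
    """

    n: int = 89
    age_mean: float = 73.5
    age_sd: float = 7.3
    female_fraction: float = 0.416
    #: primary / secondary / higher education / university
    education_probs: tuple[float, ...] = (0.112, 0.326, 0.135, 0.427)
    cognitive_hours: tuple[float, float] = (19.6, 12.6)
    physical_hours: tuple[float, float] = (10.5, 6.8)
    social_hours: tuple[float, float] = (6.9, 4.3)
    #: vascular risk = number of risk factors, Binomial(4, p)
    vascular_p: float = 0.275
    #: medication sum score distribution on {-2..2}
    medication_probs: tuple[float, ...] = (0.005, 0.08, 0.90, 0.015, 0.0)
    phq9_mean: float = 3.1
    phq9_sd: float = 2.8
    charlson_probs: tuple[float, ...] = (0.90, 0.09, 0.01)
    #: latent ability: shared component across the four functions + axis noise
    ability_common_sd: float = 0.50
    ability_axis_sd: float = 0.40
    #: per-participant learning-rate multiplier ~ lognormal(0, sigma)
    learning_rate: float = 0.022
    learning_rate_lognorm_sd: float = 0.30
    #: fraction of participants enrolled as same-household couples
    couple_fraction: float = 0.10
    tech_ok_prob: float = 0.95

    def validate(self) -> None:
        if self.n < 0:
            raise ValueError("n must be >= 0")
        for name in ("age_sd", "phq9_sd", "ability_common_sd",
                     "ability_axis_sd", "learning_rate_lognorm_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        for name in ("cognitive_hours", "physical_hours", "social_hours"):
            if getattr(self, name)[1] < 0:
                raise ValueError(f"{name} SD must be >= 0")
        if not 0 <= self.female_fraction <= 1:
            raise ValueError("female_fraction must be in [0, 1]")
        if not 0 <= self.couple_fraction <= 1:
            raise ValueError("couple_fraction must be in [0, 1]")
        if abs(sum(self.education_probs) - 1) > 1e-9:
            raise ValueError("education_probs must sum to 1")
        if self.learning_rate < 0:
            raise ValueError("learning_rate must be >= 0")


@dataclass
class MeasurementConfig:
    """Latent-ability -> instrument-score maps (MoCA, MMSE, CCTB status).

    The MoCA map is anchored so that a participant at the ability midpoint
    (0 on the latent scale) scores the configured anchor (22 points); the
    parallel-form noise SD of 1.0 point reflects repeat administrations of
    alternate MoCA versions.
    """

    moca_anchor: float = 22.0
    moca_slope: float = 3.0
    moca_noise_sd: float = 1.0
    mmse_anchor: float = 27.0
    mmse_slope: float = 2.0
    mmse_noise_sd: float = 1.0
    #: CCTB subscore measurement noise on the standardised ability scale
    status_noise_sd: float = 0.25

    def validate(self) -> None:
        for name in ("moca_noise_sd", "mmse_noise_sd", "status_noise_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.moca_slope <= 0 or self.mmse_slope <= 0:
            raise ValueError("score slopes must be > 0")


@dataclass
class LearnerConfig:
    """Practice-gain model for the simulated learner."""

    #: cap on cumulative practice gain per cognitive function (logit units)
    gain_max: float = 0.9
    #: fraction of the success increment earned on a failed attempt
    failure_fraction: float = 0.25
    #: fraction of basic-programme practice that transfers to the four
    #: trained functions (its simpler quiz-style tasks lean on long-term
    #: memory, which the outcome instruments do not credit)
    basic_transfer: float = 0.6

    def validate(self) -> None:
        if self.gain_max <= 0:
            raise ValueError("gain_max must be > 0")
        if not 0 <= self.failure_fraction <= 1:
            raise ValueError("failure_fraction must be in [0, 1]")
        if not 0 < self.basic_transfer <= 1:
            raise ValueError("basic_transfer must be in (0, 1]")


@dataclass
class EngineConfig:
    """Adaptive-engine parameters: classifiers, levels, selection cut-off."""

    n_levels: int = 9
    level_spacing: float = 0.5
    cutoff: float = 0.65
    l2_penalty: float = 1.0
    #: pseudo-observations per classifier for the cold start
    prior_size: int = 8

    def validate(self) -> None:
        if self.n_levels < 2:
            raise ValueError("n_levels must be >= 2")
        if not 0 < self.cutoff < 1:
            raise ValueError("cutoff must be in (0, 1)")
        if self.l2_penalty <= 0:
            raise ValueError("l2_penalty must be > 0")
        if self.prior_size < 2:
            raise ValueError("prior_size must be >= 2")


@dataclass
class UsageConfig:
    """Session scheduling: counts and durations per arm.

    Monthly session counts interpolate linearly between the first- and
    last-month means; defaults follow the observed usage of the trial
    (adaptive arm 15.6 -> 12.7 sessions/month, ~34 min/session; basic arm
    13.7 -> 12.3 sessions/month, ~38 min/session).
    """

    months: int = 6
    sessions_first_adaptive: float = 15.6
    sessions_last_adaptive: float = 12.7
    sessions_sd_adaptive: float = 6.9
    sessions_first_basic: float = 13.7
    sessions_last_basic: float = 12.3
    sessions_sd_basic: float = 6.0
    minutes_mean_adaptive: float = 33.9
    minutes_sd_adaptive: float = 11.8
    minutes_mean_basic: float = 37.7
    minutes_sd_basic: float = 12.1
    task_minutes: float = 3.0

    def validate(self) -> None:
        if self.months < 0:
            raise ValueError("months must be >= 0")
        if self.task_minutes <= 0:
            raise ValueError("task_minutes must be > 0")
        for name in ("sessions_sd_adaptive", "sessions_sd_basic",
                     "minutes_sd_adaptive", "minutes_sd_basic"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")


@dataclass
class AnalysisConfig:
    """Statistical-pipeline options."""

    include_outliers: bool = False
    #: intention-to-treat (impute missing follow-ups) vs completers
    itt: bool = True
    mci_cutoff: int = 24
    effect_size_floor: float = 0.10
    correlation_ceiling: float = 0.80
    #: follow-up missingness rate injected by the simulator
    dropout_rate: float = 0.10

    def validate(self) -> None:
        if not 0 <= self.dropout_rate < 1:
            raise ValueError("dropout_rate must be in [0, 1)")
        if not 0 < self.correlation_ceiling <= 1:
            raise ValueError("correlation_ceiling must be in (0, 1]")


@dataclass
class RunConfig:
    """Everything a full virtual-trial run needs, minus the root seed."""

    cohort: CohortConfig = field(default_factory=CohortConfig)
    measurement: MeasurementConfig = field(default_factory=MeasurementConfig)
    learner: LearnerConfig = field(default_factory=LearnerConfig)
    engine: EngineConfig = field(default_factory=EngineConfig)
    usage: UsageConfig = field(default_factory=UsageConfig)
    analysis: AnalysisConfig = field(default_factory=AnalysisConfig)
    #: probability that minimisation assigns the imbalance-reducing arm
    minimisation_bias: float = 0.8

    def validate(self) -> None:
        for sub in (self.cohort, self.measurement, self.learner,
                    self.engine, self.usage, self.analysis):
            sub.validate()
        if not 0.5 <= self.minimisation_bias <= 1:
            raise ValueError("minimisation_bias must be in [0.5, 1]")

    # -- YAML round-trip ----------------------------------------------------

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        def build(klass, sub):
            fields = {f.name for f in dataclasses.fields(klass)}
            unknown = set(sub) - fields
            if unknown:
                raise ValueError(f"unknown {klass.__name__} keys: {sorted(unknown)}")
            kw = {}
            for f in dataclasses.fields(klass):
                if f.name in sub:
                    v = sub[f.name]
                    kw[f.name] = tuple(v) if isinstance(v, list) else v
            return klass(**kw)

        cfg = cls(
            cohort=build(CohortConfig, d.get("cohort", {})),
            measurement=build(MeasurementConfig, d.get("measurement", {})),
            learner=build(LearnerConfig, d.get("learner", {})),
            engine=build(EngineConfig, d.get("engine", {})),
            usage=build(UsageConfig, d.get("usage", {})),
            analysis=build(AnalysisConfig, d.get("analysis", {})),
            minimisation_bias=d.get("minimisation_bias", 0.8),
        )
        cfg.validate()
        return cfg

    def to_yaml(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path, encoding="utf-8") as fh:
            d = yaml.safe_load(fh) or {}
        return cls.from_dict(d)

    def hash(self) -> str:
        """Short stable digest of the configuration, for output provenance."""
        blob = yaml.safe_dump(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha1(blob).hexdigest()[:12]
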