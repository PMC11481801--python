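"""Virtual participants: generation, screening cascade, randomisation.

The generator draws participants whose marginals match the baseline table
of the emulated trial; the screening cascade applies the study's
psychometric eligibility rules (MoCA <= 24, MMSE >= 24, PHQ-9 <= 12 plus
a technology check); the randomiser is a biased-coin stochastic
minimisation on sex with household coupling.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from functools import lru_cache

import numpy as np
from scipy import optimize, stats

from .config import CohortConfig, MeasurementConfig

EDUCATION_LEVELS = ("primary", "secondary", "higher", "university")


@dataclass
class ParticipantProfile:
    """One virtual participant: latent four-function ability plus the
    baseline covariates carried into the analysis."""

    participant_id: str
    household_id: str
    age: float
    sex: str  # "female" | "male"
    education_level: str
    ability: np.ndarray  # (4,) latent skill, logit scale
    learning_rate: np.ndarray  # (4,) practice gain per function
    cognitive_hours: float
    physical_hours: float
    social_hours: float
    vascular_risk: int
    medication_score: int
    phq9: int
    charlson: int
    tech_ok: bool = True
    #: cumulative practice gain per function (for the saturating learner)
    practice_gain: np.ndarray = field(
        default_factory=lambda: np.zeros(4))

    def validate(self) -> None:
        if self.vascular_risk not in (0, 1, 2, 3, 4):
            raise ValueError("vascular_risk must be in {0..4}")
        if not 0 <= self.phq9 <= 27:
            raise ValueError("phq9 must be in [0, 27]")
        if not 0 <= self.charlson <= 24:
            raise ValueError("charlson must be in [0, 24]")
        for name in ("cognitive_hours", "physical_hours", "social_hours"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if (np.asarray(self.learning_rate) < 0).any():
            raise ValueError("learning_rate must be nonnegative")

    def copy(self) -> "ParticipantProfile":
        return replace(self, ability=self.ability.copy(),
                       learning_rate=self.learning_rate.copy(),
                       practice_gain=self.practice_gain.copy())

    @property
    def mean_ability(self) -> float:
        return float(np.mean(self.ability))


@dataclass(frozen=True)
class ScreeningScores:
    """Instrument scores entering the eligibility cascade."""

    moca: int
    mmse: int
    phq9: int
    tech_ok: bool

    def __post_init__(self):
        if not 0 <= self.moca <= 30:
            raise ValueError("moca must be in [0, 30]")
        if not 0 <= self.mmse <= 30:
            raise ValueError("mmse must be in [0, 30]")
        if not 0 <= self.phq9 <= 27:
            raise ValueError("phq9 must be in [0, 27]")


@lru_cache(maxsize=64)
def _truncnorm_params(target_mean: float, target_sd: float):
    """Parameters of a zero-left-truncated normal whose mean and SD equal
    the targets (so configured marginals are hit exactly despite the
    nonnegativity constraint on hours-type variables)."""
    if target_sd == 0:
        return target_mean, 0.0

    def moments(p):
        mu, log_sigma = p
        sigma = np.exp(log_sigma)
        a = -mu / sigma
        m, v = stats.truncnorm.stats(a, np.inf, loc=mu, scale=sigma,
                                     moments="mv")
        return [m - target_mean, np.sqrt(v) - target_sd]

    sol = optimize.fsolve(moments, [target_mean, np.log(target_sd)],
                          full_output=False)
    return float(sol[0]), float(np.exp(sol[1]))


def _sample_nonneg(rng, mean, sd, size):
    if sd == 0:
        return np.full(size, float(mean))
    mu, sigma = _truncnorm_params(float(mean), float(sd))
    a = -mu / sigma
    u = rng.uniform(stats.norm.cdf(a), 1.0, size=size)
    return mu + sigma * stats.norm.ppf(u)


def generate_cohort(config: CohortConfig, seed=None,
                    rng: np.random.Generator | None = None,
                    id_offset: int = 0) -> list[ParticipantProfile]:
    """Draw ``config.n`` participants; reproducible given the seed.

    A configurable fraction of participants are enrolled as same-household
    couples (ids shared via household_id); couple partners have correlated
    ages and, usually, opposite sex.
    """
    config.validate()
    if rng is None:
        rng = np.random.default_rng(seed)
    n = config.n
    profiles: list[ParticipantProfile] = []
    n_couples = int(round(config.couple_fraction * n / 2.0))
    couple_members = set()
    partner_of = {}
    idx = rng.permutation(n)
    for k in range(n_couples):
        a, b = idx[2 * k], idx[2 * k + 1]
        couple_members |= {a, b}
        partner_of[b] = a

    ages = rng.normal(config.age_mean, config.age_sd, size=n)
    female = rng.random(n) < config.female_fraction
    edu = rng.choice(len(EDUCATION_LEVELS), size=n, p=config.education_probs)
    cog = _sample_nonneg(rng, *config.cognitive_hours, size=n)
    phy = _sample_nonneg(rng, *config.physical_hours, size=n)
    soc = _sample_nonneg(rng, *config.social_hours, size=n)
    vasc = rng.binomial(4, config.vascular_p, size=n)
    med = rng.choice(np.arange(-2, 3), size=n, p=config.medication_probs)
    phq = np.clip(np.rint(_sample_nonneg(rng, config.phq9_mean,
                                         config.phq9_sd, n)),
                  0, 27).astype(int)
    charl = rng.choice(len(config.charlson_probs), size=n,
                       p=config.charlson_probs)
    common = rng.normal(0.0, config.ability_common_sd, size=n)
    axis = rng.normal(0.0, config.ability_axis_sd, size=(n, 4))
    lr_mult = rng.lognormal(0.0, config.learning_rate_lognorm_sd, size=n)
    tech = rng.random(n) < config.tech_ok_prob
    partner_age_jitter = rng.normal(0.0, 3.0, size=n)
    partner_flip = rng.random(n) < 0.9

    for i in range(n):
        pid = f"P{id_offset + i + 1:04d}"
        if i in partner_of:
            j = partner_of[i]
            hid = f"H{id_offset + j + 1:04d}"
            ages[i] = ages[j] + partner_age_jitter[i]
            if partner_flip[i]:
                female[i] = not female[j]
        else:
            hid = f"H{id_offset + i + 1:04d}"
        p = ParticipantProfile(
            participant_id=pid,
            household_id=hid,
            age=float(ages[i]),
            sex="female" if female[i] else "male",
            education_level=EDUCATION_LEVELS[edu[i]],
            ability=common[i] + axis[i],
            learning_rate=np.full(4, config.learning_rate * lr_mult[i]),
            cognitive_hours=float(cog[i]),
            physical_hours=float(phy[i]),
            social_hours=float(soc[i]),
            vascular_risk=int(vasc[i]),
            medication_score=int(med[i]),
            phq9=int(phq[i]),
            charlson=int(charl[i]),
            tech_ok=bool(tech[i]),
        )
        p.validate()
        profiles.append(p)
    return profiles


# ---------------------------------------------------------------------------
# Screening
# ---------------------------------------------------------------------------

def _scored(anchor, slope, noise_sd, ability, rng, lo=0, hi=30) -> int:
    raw = anchor + slope * ability
    if noise_sd > 0:
        if rng is None:
            raise ValueError("rng required when noise_sd > 0")
        raw += rng.normal(0.0, noise_sd)
    return int(np.clip(np.rint(raw), lo, hi))


def screening_scores(profile: ParticipantProfile,
                     measurement: MeasurementConfig | None = None,
                     rng: np.random.Generator | None = None,
                     noise_seed=None) -> ScreeningScores:
    """Map latent ability to MoCA/MMSE screening scores.

    Monotone in mean ability before rounding, clamped to instrument ranges;
    parallel-form noise is drawn from ``rng`` (or ``noise_seed``).
    """
    m = measurement or MeasurementConfig()
    if rng is None and noise_seed is not None:
        rng = np.random.default_rng(noise_seed)
    a = profile.mean_ability
    return ScreeningScores(
        moca=_scored(m.moca_anchor, m.moca_slope, m.moca_noise_sd, a, rng),
        mmse=_scored(m.mmse_anchor, m.mmse_slope, m.mmse_noise_sd, a, rng),
        phq9=profile.phq9,
        tech_ok=profile.tech_ok,
    )


#: exclusion reasons, checked in cascade order
REASON_NO_IMPAIRMENT = "no cognitive impairment"
REASON_DEMENTIA = "dementia screen"
REASON_DEPRESSION = "acute depression"
REASON_TECH = "technical requirements"


def screen_eligibility(scores: ScreeningScores) -> tuple[bool, str | None]:
    """Apply the eligibility cascade; the reason names the first failed
    criterion in the order MoCA, MMSE, PHQ-9, technology."""
    if scores.moca > 24:
        return False, REASON_NO_IMPAIRMENT
    if scores.mmse < 24:
        return False, REASON_DEMENTIA
    if scores.phq9 > 12:
        return False, REASON_DEPRESSION
    if not scores.tech_ok:
        return False, REASON_TECH
    return True, None


# ---------------------------------------------------------------------------
# Randomisation
# ---------------------------------------------------------------------------

GROUPS = ("IG", "CG")


def randomise_minimisation(participants, seed=None, bias: float = 0.8,
                           rng: np.random.Generator | None = None,
                           batch_size: int | None = None) -> dict[str, str]:
    """Biased-coin minimisation on sex, with household coupling.

    Households are allocated as units, in recruitment order (optionally in
    blockwise batches, which only affects bookkeeping — the imbalance totals
    carry across batches). For each unit the arm that reduces the sex
    imbalance is chosen with probability ``bias`` (an exact tie is a fair
    coin); ``bias=1.0`` gives deterministic minimisation.
    """
    if not 0.5 <= bias <= 1.0:
        raise ValueError("bias must be in [0.5, 1.0]")
    if rng is None:
        rng = np.random.default_rng(seed)
    units: list[list[ParticipantProfile]] = []
    by_household: dict[str, int] = {}
    for p in participants:
        if p.household_id in by_household:
            units[by_household[p.household_id]].append(p)
        else:
            by_household[p.household_id] = len(units)
            units.append([p])

    counts = {g: {"female": 0, "male": 0} for g in GROUPS}
    assignment: dict[str, str] = {}
    for unit in units:
        imbalances = {}
        for g in GROUPS:
            trial = {h: dict(c) for h, c in counts.items()}
            for p in unit:
                trial[g][p.sex] += 1
            imbalances[g] = sum(
                abs(trial["IG"][s] - trial["CG"][s])
                for s in ("female", "male"))
        if imbalances["IG"] < imbalances["CG"]:
            favoured = "IG"
        elif imbalances["CG"] < imbalances["IG"]:
            favoured = "CG"
        else:
            favoured = "IG" if rng.random() < 0.5 else "CG"
            group = favoured
            for p in unit:
                counts[group][p.sex] += 1
                assignment[p.participant_id] = group
            continue
        group = favoured if rng.random() < bias else \
            ("CG" if favoured == "IG" else "IG")
        for p in unit:
            counts[group][p.sex] += 1
            assignment[p.participant_id] = group
    return assignment
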