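"""End-to-end virtual randomised trial.

Wires the pieces together the way the emulated study ran: screen a
recruitment stream until the target cohort is eligible, randomise by
stochastic minimisation with household coupling, give every adaptive-arm
participant their own locally-retraining engine, simulate six months of
home training, and measure the follow-up outcome with a parallel-form
MoCA administration.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .catalog import default_catalog
from .cohort import (ParticipantProfile, generate_cohort,
                     randomise_minimisation, screen_eligibility,
                     screening_scores)
from .config import RunConfig, substream
from .engine import CognitiveStatus, EngineState, init_engine
from .learner import UsageLog, simulate_usage


@dataclass
class SimulatedTrial:
    """All artefacts of one virtual trial run."""

    subjects: pd.DataFrame
    training_log: pd.DataFrame
    usage_summary: pd.DataFrame
    assignment: dict[str, str]
    screening_counts: dict[str, int]
    seed: int
    profiles: dict[str, ParticipantProfile] = field(default_factory=dict)
    engines: dict[str, EngineState] = field(default_factory=dict)


def recruit_eligible(config: RunConfig, seed: int,
                     max_batches: int = 60):
    """Screen a simulated recruitment stream until the cohort is filled.

    Returns the eligible profiles, their screening scores, and the
    exclusion counts by reason.
    """
    rng_cohort = substream(seed, "cohort")
    rng_screen = substream(seed, "screening")
    target = config.cohort.n
    eligible: list[ParticipantProfile] = []
    scores = {}
    counts: dict[str, int] = {"screened": 0, "eligible": 0}
    offset = 0
    batch_cfg = config.cohort
    for _ in range(max_batches):
        if len(eligible) >= target:
            break
        batch = generate_cohort(batch_cfg, rng=rng_cohort, id_offset=offset)
        offset += len(batch)
        # keep couples intact: screen per household
        by_house: dict[str, list[ParticipantProfile]] = {}
        for p in batch:
            by_house.setdefault(p.household_id, []).append(p)
        for members in by_house.values():
            if len(eligible) >= target:
                break
            member_scores = [screening_scores(p, config.measurement,
                                              rng=rng_screen)
                             for p in members]
            results = [screen_eligibility(s) for s in member_scores]
            counts["screened"] += len(members)
            for p, s, (ok, reason) in zip(members, member_scores, results):
                if ok and len(eligible) < target:
                    eligible.append(p)
                    scores[p.participant_id] = s
                    counts["eligible"] += 1
                elif not ok:
                    counts[reason] = counts.get(reason, 0) + 1
    if len(eligible) < target:
        raise RuntimeError(
            f"recruitment exhausted after screening {counts['screened']} "
            f"applicants; {len(eligible)}/{target} eligible")
    return eligible, scores, counts


def _measure_status(profile: ParticipantProfile, noise_sd: float,
                    rng: np.random.Generator) -> CognitiveStatus:
    noisy = profile.ability + rng.normal(0.0, noise_sd, size=4)
    return CognitiveStatus.from_array(noisy)


def simulate_trial(config: RunConfig | None = None, seed: int = 0,
                   keep_state: bool = False) -> SimulatedTrial:
    """Run one complete virtual trial and return its data tables."""
    config = config or RunConfig()
    config.validate()
    eligible, scores, screening_counts = recruit_eligible(config, seed)
    assignment = randomise_minimisation(
        eligible, rng=substream(seed, "randomisation"),
        bias=config.minimisation_bias)

    rng_measure = substream(seed, "measurement")
    rng_dropout = substream(seed, "dropout")
    catalog = default_catalog(config.engine.n_levels)
    base_engine = init_engine(
        catalog, cutoff=config.engine.cutoff,
        l2_penalty=config.engine.l2_penalty,
        level_spacing=config.engine.level_spacing,
        prior_size=config.engine.prior_size)

    subj_rows, log_rows, usage_rows = [], [], []
    profiles, engines = {}, {}
    root = int(seed) % (2**31)
    for i, profile in enumerate(eligible):
        group = assignment[profile.participant_id]
        moca_t0 = scores[profile.participant_id].moca
        status = _measure_status(profile, config.measurement.status_noise_sd,
                                 rng_measure)
        trained = profile.copy()
        rng_p = np.random.default_rng([root, 3, i])
        if group == "IG":
            engine = base_engine.clone()
            logs = simulate_usage(trained, "adaptive", engine,
                                  rng=rng_p, usage=config.usage,
                                  learner=config.learner, status=status,
                                  catalog=catalog,
                                  spacing=config.engine.level_spacing,
                                  measurement=config.measurement)
        else:
            engine = None
            logs = simulate_usage(trained, "basic", None, rng=rng_p,
                                  usage=config.usage,
                                  learner=config.learner, catalog=catalog,
                                  spacing=config.engine.level_spacing)

        t6 = screening_scores(trained, config.measurement, rng=rng_measure)
        moca_t6: float | None = float(t6.moca)
        if rng_dropout.random() < config.analysis.dropout_rate:
            moca_t6 = np.nan

        subj_rows.append({
            "participant_id": profile.participant_id,
            "household_id": profile.household_id,
            "group": group,
            "age": round(profile.age, 1),
            "sex": profile.sex,
            "education_level": profile.education_level,
            "cognitive_hours": round(profile.cognitive_hours, 1),
            "physical_hours": round(profile.physical_hours, 1),
            "social_hours": round(profile.social_hours, 1),
            "vascular_risk": profile.vascular_risk,
            "medication_score": profile.medication_score,
            "phq9": profile.phq9,
            "charlson": profile.charlson,
            "moca_t0": moca_t0,
            "moca_t6": moca_t6,
            "clinical_reason": "",
        })
        for log in logs:
            usage_rows.append({
                "participant_id": log.participant_id,
                "group": group,
                "month_index": log.month_index,
                "sessions": log.sessions,
                "minutes_per_session": round(log.minutes_per_session, 1),
            })
            for rec in log.records:
                log_rows.append({
                    "participant_id": rec.participant_id,
                    "group": group,
                    "month_index": log.month_index,
                    "session_index": rec.session_index,
                    "exercise_id": rec.exercise_id,
                    "level": rec.level,
                    "success": int(rec.success),
                })
        if keep_state:
            profiles[profile.participant_id] = trained
            if engine is not None:
                engines[profile.participant_id] = engine

    return SimulatedTrial(
        subjects=pd.DataFrame(subj_rows),
        training_log=pd.DataFrame(log_rows),
        usage_summary=pd.DataFrame(usage_rows),
        assignment=assignment,
        screening_counts=screening_counts,
        seed=seed,
        profiles=profiles,
        engines=engines,
    )


def paired_gain(config: RunConfig | None = None, seed: int = 0,
                n_per_arm: int = 16) -> tuple[float, float]:
    """Train one eligible cohort under BOTH policies; return the mean
    simulated MoCA gain (adaptive, basic).

    The same participants, baseline scores and follow-up measurement noise
    are used in both arms, so the comparison isolates the policy effect.
    """
    config = config or RunConfig()
    import copy

    cfg = copy.deepcopy(config)
    cfg.cohort.n = n_per_arm
    cfg.cohort.couple_fraction = 0.0
    eligible, scores, _ = recruit_eligible(cfg, seed)
    catalog = default_catalog(cfg.engine.n_levels)
    base_engine = init_engine(
        catalog, cutoff=cfg.engine.cutoff, l2_penalty=cfg.engine.l2_penalty,
        level_spacing=cfg.engine.level_spacing,
        prior_size=cfg.engine.prior_size)
    rng_measure = substream(seed, "measurement")
    root = int(seed) % (2**31)
    gains = {"adaptive": [], "basic": []}
    for i, profile in enumerate(eligible):
        moca_t0 = scores[profile.participant_id].moca
        status = _measure_status(profile, cfg.measurement.status_noise_sd,
                                 rng_measure)
        noise_t6 = rng_measure.normal(0.0, cfg.measurement.moca_noise_sd)
        for policy in ("adaptive", "basic"):
            trained = profile.copy()
            rng_p = np.random.default_rng(
                [root, 3, i, 0 if policy == "adaptive" else 1])
            engine = base_engine.clone() if policy == "adaptive" else None
            simulate_usage(trained, policy, engine, rng=rng_p,
                           usage=cfg.usage, learner=cfg.learner,
                           status=status, catalog=catalog,
                           spacing=cfg.engine.level_spacing,
                           measurement=cfg.measurement)
            m = cfg.measurement
            t6 = int(np.clip(np.rint(m.moca_anchor + m.moca_slope
                                     * trained.mean_ability + noise_t6),
                             0, 30))
            gains[policy].append(t6 - moca_t0)
    return (float(np.mean(gains["adaptive"])),
            float(np.mean(gains["basic"])))
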