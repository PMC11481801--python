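"""Simulated learner: exercise responses, practice gains, usage schedule.

Responses follow a one-parameter logistic model: the success probability of
an attempt is ``logistic(effective_ability - difficulty(level))`` where
effective ability is the exercise's function-weighted mean of the
participant's latent ability. Practice gains are error-driven and
saturating: a success at a challenging level (low predicted success) teaches
more than a success at a trivially easy one, and cumulative gains per
function are capped.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.special import expit

from .catalog import ExerciseSpec, basic_catalog, default_catalog, difficulty
from .cohort import ParticipantProfile
from .config import LearnerConfig, MeasurementConfig, UsageConfig
from .engine import CognitiveStatus, EngineState, TrainingRecord


def success_probability(profile: ParticipantProfile, exercise: ExerciseSpec,
                        level: int, spacing: float = 0.5) -> float:
    """Closed-form success probability of one attempt."""
    d = difficulty(level, exercise.n_levels, spacing)
    eff = float(exercise.weights @ profile.ability)
    return float(expit(eff - d))


def respond(profile: ParticipantProfile, exercise: ExerciseSpec, level: int,
            rng: np.random.Generator | None = None, seed=None,
            spacing: float = 0.5, session_index: int = 0) -> TrainingRecord:
    """Draw one attempt outcome for ``profile`` at ``(exercise, level)``."""
    if not 1 <= level <= exercise.n_levels:
        raise KeyError(f"level {level} outside exercise "
                       f"{exercise.exercise_id}'s range")
    if rng is None:
        rng = np.random.default_rng(seed)
    p = success_probability(profile, exercise, level, spacing)
    return TrainingRecord(profile.participant_id, exercise.exercise_id,
                          level, bool(rng.random() < p), session_index)


def practice_update(profile: ParticipantProfile, record: TrainingRecord,
                    exercise: ExerciseSpec,
                    learner: LearnerConfig | None = None,
                    spacing: float = 0.5,
                    transfer: float = 1.0) -> ParticipantProfile:
    """Apply the practice gain of one attempt to ``profile`` (in place).

    Per function f the increment is::

        learning_rate_f * w_f * (1 - p_success) * max(0, 1 - gain_f/gain_max)

    on success, and ``failure_fraction`` of that on failure. The
    ``(1 - p_success)`` surprise factor concentrates learning at challenging
    difficulty; the ``(1 - gain/gain_max)`` factor makes cumulative gains
    saturate. ``transfer`` scales the increment for programmes whose tasks
    only partly exercise the trained functions. Abilities never decrease.
    """
    if record.participant_id != profile.participant_id:
        raise ValueError("record does not refer to this profile")
    if record.exercise_id != exercise.exercise_id:
        raise ValueError("record/exercise mismatch")
    if not 0 <= transfer <= 1:
        raise ValueError("transfer must be in [0, 1]")
    cfg = learner or LearnerConfig()
    p = success_probability(profile, exercise, record.level, spacing)
    room = np.clip(1.0 - profile.practice_gain / cfg.gain_max, 0.0, None)
    inc = (profile.learning_rate * exercise.weights * (1.0 - p) * room
           * transfer)
    if not record.success:
        inc = inc * cfg.failure_fraction
    profile.ability = profile.ability + inc
    profile.practice_gain = profile.practice_gain + inc
    return profile


@dataclass
class UsageLog:
    """One participant-month of training activity."""

    participant_id: str
    month_index: int
    sessions: int
    minutes_per_session: float
    records: list[TrainingRecord] = field(default_factory=list)


def _monthly_session_means(first: float, last: float, months: int):
    if months == 1:
        return np.array([first])
    return np.linspace(first, last, months)


def simulate_usage(profile: ParticipantProfile, policy: str,
                   engine_state: EngineState | None = None,
                   months: int | None = None,
                   rng: np.random.Generator | None = None, seed=None,
                   usage: UsageConfig | None = None,
                   learner: LearnerConfig | None = None,
                   status: CognitiveStatus | None = None,
                   catalog: list[ExerciseSpec] | None = None,
                   spacing: float = 0.5,
                   measurement: MeasurementConfig | None = None
                   ) -> list[UsageLog]:
    """Simulate the training period for one participant.

    The adaptive policy plans each session with the engine and feeds every
    completed exercise back into it; the basic policy runs its fixed
    five-task catalogue at level 1 and never touches any engine state.

    When ``measurement`` is given, the digital test battery is
    re-administered at the start of each month, so the cognitive status fed
    to the classifiers tracks the participant's practice gains between the
    trial's main assessments; with ``measurement=None`` the baseline status
    is used throughout.
    """
    if policy not in ("adaptive", "basic"):
        raise ValueError("policy must be 'adaptive' or 'basic'")
    ucfg = usage or UsageConfig()
    months = ucfg.months if months is None else months
    if rng is None:
        rng = np.random.default_rng(seed)
    if policy == "adaptive":
        if engine_state is None:
            raise ValueError("adaptive policy requires an engine state")
        if status is None:
            raise ValueError("adaptive policy requires a cognitive status")
        mu = _monthly_session_means(ucfg.sessions_first_adaptive,
                                    ucfg.sessions_last_adaptive, months)
        sd, min_mu, min_sd = (ucfg.sessions_sd_adaptive,
                              ucfg.minutes_mean_adaptive,
                              ucfg.minutes_sd_adaptive)
        tasks = None
    else:
        mu = _monthly_session_means(ucfg.sessions_first_basic,
                                    ucfg.sessions_last_basic, months)
        sd, min_mu, min_sd = (ucfg.sessions_sd_basic,
                              ucfg.minutes_mean_basic, ucfg.minutes_sd_basic)
        tasks = basic_catalog(catalog)
    full = {e.exercise_id: e
            for e in (catalog if catalog is not None else default_catalog())}

    logs: list[UsageLog] = []
    session_index = 0
    for month in range(1, months + 1):
        if (policy == "adaptive" and measurement is not None
                and month > 1):
            noisy = profile.ability + rng.normal(
                0.0, measurement.status_noise_sd, size=4)
            status = CognitiveStatus.from_array(noisy)
        n_sessions = int(max(0, round(rng.normal(mu[month - 1], sd))))
        month_records: list[TrainingRecord] = []
        month_minutes = []
        for _ in range(n_sessions):
            session_index += 1
            minutes = max(ucfg.task_minutes, rng.normal(min_mu, min_sd))
            month_minutes.append(minutes)
            if policy == "adaptive":
                plan = engine_state.plan_session(status, minutes,
                                                 ucfg.task_minutes)
            else:
                n_tasks = max(1, int(minutes // ucfg.task_minutes))
                plan = [(tasks[k % len(tasks)].exercise_id, 1)
                        for k in range(n_tasks)]
            lcfg = learner or LearnerConfig()
            transfer = 1.0 if policy == "adaptive" else lcfg.basic_transfer
            for eid, level in plan:
                ex = full[eid]
                rec = respond(profile, ex, level, rng=rng, spacing=spacing,
                              session_index=session_index)
                practice_update(profile, rec, ex, learner, spacing,
                                transfer=transfer)
                if policy == "adaptive":
                    engine_state.record_result(rec, status)
                month_records.append(rec)
        logs.append(UsageLog(
            participant_id=profile.participant_id,
            month_index=month,
            sessions=n_sessions,
            minutes_per_session=float(np.mean(month_minutes))
            if month_minutes else 0.0,
            records=month_records))
    return logs
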