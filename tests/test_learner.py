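"""Learner model: response probabilities, practice gains, usage schedule."""

import numpy as np
import pytest
from scipy.special import expit

import ccttrial as ct
from ccttrial.catalog import basic_catalog, default_catalog, difficulty
from ccttrial.learner import success_probability


@pytest.fixture
def exercise():
    return default_catalog()[8]  # evenly weighted across functions


class TestRespond:
    def test_midpoint_probability(self, profile, exercise):
        """Effective ability equal to the difficulty gives p = 0.5."""
        p = profile.copy()
        level = 4
        p.ability = np.full(4, difficulty(level))
        assert success_probability(p, exercise, level) == pytest.approx(0.5)

    def test_probability_decreases_with_level(self, profile, exercise):
        probs = [success_probability(profile, exercise, lv)
                 for lv in range(1, exercise.n_levels + 1)]
        assert all(a > b for a, b in zip(probs, probs[1:]))

    def test_probability_increases_with_ability(self, profile, exercise):
        for lv in (1, 4, 7):
            last = 0.0
            for a in np.linspace(-2, 2, 9):
                p = profile.copy()
                p.ability = np.full(4, a)
                cur = success_probability(p, exercise, lv)
                assert cur > last
                last = cur

    def test_empirical_frequency_matches_model(self, profile, exercise):
        """10,000 seeded draws land within +/-0.02 of the closed form."""
        rng = np.random.default_rng(123)
        level = 5
        p_true = success_probability(profile, exercise, level)
        hits = sum(ct.respond(profile, exercise, level, rng=rng).success
                   for _ in range(10_000))
        assert abs(hits / 10_000 - p_true) < 0.02

    def test_unknown_level_rejected(self, profile, exercise):
        with pytest.raises(KeyError):
            ct.respond(profile, exercise, exercise.n_levels + 1, seed=0)


class TestPracticeUpdate:
    def _record(self, profile, exercise, level=4, success=True):
        return ct.TrainingRecord(profile.participant_id,
                                 exercise.exercise_id, level, success)

    def test_zero_learning_rate_is_identity(self, profile, exercise):
        p = profile.copy()
        p.learning_rate = np.zeros(4)
        before = p.ability.copy()
        ct.practice_update(p, self._record(p, exercise), exercise)
        assert np.array_equal(p.ability, before)

    def test_repeated_successes_have_diminishing_increments(self, profile,
                                                            exercise):
        p = profile.copy()
        p.ability = np.zeros(4)
        increments = []
        for _ in range(30):
            before = p.ability.copy()
            ct.practice_update(p, self._record(p, exercise), exercise)
            increments.append(np.sum(p.ability - before))
        assert all(a > b > 0 for a, b in zip(increments, increments[1:]))

    def test_ability_never_decreases_and_gain_bounded(self, profile,
                                                      exercise):
        cfg = ct.LearnerConfig()
        p = profile.copy()
        start = p.ability.copy()
        rng = np.random.default_rng(5)
        for _ in range(3000):
            rec = ct.respond(p, exercise, 4, rng=rng)
            ct.practice_update(p, rec, exercise, cfg)
            assert (p.ability >= start - 1e-12).all()
        assert (p.practice_gain <= cfg.gain_max + 1e-9).all()

    def test_failure_earns_configured_fraction(self, profile, exercise):
        cfg = ct.LearnerConfig(failure_fraction=0.25)
        ps, pf = profile.copy(), profile.copy()
        ps.ability = pf.ability = np.zeros(4)
        ps.practice_gain = np.zeros(4)
        pf.practice_gain = np.zeros(4)
        ct.practice_update(ps, self._record(ps, exercise, success=True),
                           exercise, cfg)
        ct.practice_update(pf, self._record(pf, exercise, success=False),
                           exercise, cfg)
        gain_s = ps.practice_gain.sum()
        gain_f = pf.practice_gain.sum()
        assert gain_f == pytest.approx(0.25 * gain_s)

    def test_mismatched_record_rejected(self, profile, exercise):
        rec = ct.TrainingRecord("someone-else", exercise.exercise_id, 1,
                                True)
        with pytest.raises(ValueError):
            ct.practice_update(profile.copy(), rec, exercise)


class TestSimulateUsage:
    def test_zero_months_empty_log(self, profile):
        logs = ct.simulate_usage(profile.copy(), "basic", months=0, seed=0)
        assert logs == []

    def test_basic_policy_never_mutates_engine(self, profile):
        engine = ct.init_engine(default_catalog()[:2])
        snapshot = engine.to_json()
        ct.simulate_usage(profile.copy(), "basic", engine, months=2, seed=1)
        assert engine.to_json() == snapshot

    def test_basic_policy_uses_level_one_of_basic_catalogue(self, profile):
        logs = ct.simulate_usage(profile.copy(), "basic", months=2, seed=2)
        basic_ids = {e.exercise_id for e in basic_catalog()}
        recs = [r for lg in logs for r in lg.records]
        assert recs
        assert all(r.level == 1 for r in recs)
        assert {r.exercise_id for r in recs} <= basic_ids

    def test_first_month_session_count_matches_configured_mean(self):
        """Mean first-month sessions ~= the configured 15.6 over 1,000
        simulated participants (sampling error only)."""
        catalog = default_catalog()[:1]
        engine = ct.init_engine(catalog)
        usage = ct.UsageConfig(minutes_mean_adaptive=3.0,
                               minutes_sd_adaptive=0.0)
        cohort = ct.generate_cohort(ct.CohortConfig(n=1000), seed=3)
        status = ct.CognitiveStatus(0, 0, 0, 0)
        counts = []
        rng = np.random.default_rng(17)
        for p in cohort:
            logs = ct.simulate_usage(p.copy(), "adaptive", engine.clone(),
                                     months=1, rng=rng, usage=usage,
                                     status=status, catalog=catalog)
            counts.append(logs[0].sessions)
        se = 6.9 / np.sqrt(len(counts))
        # rounding and the >=0 clip shift the mean by < 0.1 sessions
        assert abs(np.mean(counts) - 15.6) < 3 * se + 0.1

    def test_invalid_policy_rejected(self, profile):
        with pytest.raises(ValueError):
            ct.simulate_usage(profile.copy(), "adaptive-ish", months=1,
                              seed=0)

    def test_adaptive_requires_engine_and_status(self, profile):
        with pytest.raises(ValueError):
            ct.simulate_usage(profile.copy(), "adaptive", None, months=1,
                              seed=0)
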