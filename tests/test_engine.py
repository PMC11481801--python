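"""Adaptive engine: penalised logistic fits, level selection, online
retraining, replay determinism."""

import numpy as np
import pytest
from scipy.special import expit
from sklearn.linear_model import LogisticRegression

import ccttrial as ct
from ccttrial.catalog import default_catalog
from ccttrial.engine import N_FEATURES, fit_logistic


def sklearn_ridge_logistic(X, y, lam):
    """Reference fit with the intercept as an explicit penalised column."""
    Xd = np.column_stack([np.ones(len(X)), X])
    clf = LogisticRegression(C=1.0 / lam, fit_intercept=False,
                             solver="lbfgs", tol=1e-12, max_iter=20_000)
    clf.fit(Xd, y)
    return clf.coef_.ravel()


class TestFitLogistic:
    @pytest.mark.parametrize("seed", range(6))
    def test_agrees_with_reference_implementation(self, seed):
        rng = np.random.default_rng(seed)
        n = rng.integers(12, 60)
        X = rng.normal(size=(n, 4))
        beta_true = rng.normal(size=4)
        y = (rng.random(n) < expit(X @ beta_true)).astype(float)
        if y.min() == y.max():  # keep both outcome classes
            y[0] = 1 - y[0]
        lam = float(rng.uniform(0.3, 3.0))
        ours = fit_logistic(X, y, lam)
        ref = sklearn_ridge_logistic(X, y, lam)
        assert np.allclose(ours, ref, atol=1e-5)

    def test_separable_data_stays_finite(self):
        X = np.array([[-2.0], [-1.0], [1.0], [2.0]])
        y = np.array([0.0, 0.0, 1.0, 1.0])
        beta = fit_logistic(X, y, 1.0)
        assert np.isfinite(beta).all()

    def test_all_success_outcomes(self):
        X = np.random.default_rng(0).normal(size=(20, 2)) * 0.1
        beta = fit_logistic(X, np.ones(20), 1.0)
        assert beta[0] > 0
        assert expit(beta[0]) > 0.5

    def test_duplicated_data_with_scaled_penalty(self):
        rng = np.random.default_rng(3)
        X = rng.normal(size=(15, 3))
        y = (rng.random(15) < 0.5).astype(float)
        single = fit_logistic(X, y, 1.0)
        doubled = fit_logistic(np.vstack([X, X]), np.concatenate([y, y]),
                               2.0)
        assert np.allclose(single, doubled, atol=1e-9)

    def test_deterministic(self):
        rng = np.random.default_rng(4)
        X = rng.normal(size=(25, 4))
        y = (rng.random(25) < 0.5).astype(float)
        assert np.array_equal(fit_logistic(X, y, 1.0),
                              fit_logistic(X, y, 1.0))

    def test_rejects_bad_input(self):
        with pytest.raises(ValueError):
            fit_logistic(np.empty((0, 2)), np.empty(0), 1.0)
        with pytest.raises(ValueError):
            fit_logistic(np.array([[np.nan, 1.0]]), np.array([1.0]), 1.0)
        with pytest.raises(ValueError):
            fit_logistic(np.ones((3, 2)), np.ones(3), 0.0)


class TestInitEngine:
    def test_symmetric_prior_predicts_half_at_origin(self):
        catalog = default_catalog()[:2]
        prior = {}
        for ex in catalog:
            for lv in range(1, ex.n_levels + 1):
                X = np.zeros((8, N_FEATURES))
                y = np.array([1.0, 0.0] * 4)
                prior[(ex.exercise_id, lv)] = (X, y)
        engine = ct.init_engine(catalog, prior=prior)
        status = ct.CognitiveStatus(0, 0, 0, 0)
        for ex in catalog:
            for lv in range(1, ex.n_levels + 1):
                assert engine.predict_success(ex.exercise_id, lv,
                                              status) == pytest.approx(0.5)

    def test_cutoff_outside_unit_interval_rejected(self):
        with pytest.raises(ValueError):
            ct.init_engine(cutoff=1.0)
        with pytest.raises(ValueError):
            ct.init_engine(cutoff=0.0)

    def test_empty_prior_rejected(self):
        catalog = default_catalog()[:1]
        prior = {(1, lv): (np.zeros((0, N_FEATURES)), np.zeros(0))
                 for lv in range(1, catalog[0].n_levels + 1)}
        with pytest.raises(ValueError, match="prior"):
            ct.init_engine(catalog, prior=prior)

    def test_success_only_at_high_status_gives_positive_coefficient(self):
        """Matches an independent reference fit on the same pseudo-data."""
        catalog = default_catalog()[:1]
        rngs = np.random.default_rng(1)
        prior = {}
        for lv in range(1, catalog[0].n_levels + 1):
            first = rngs.normal(size=8)
            X = np.column_stack([first, *(np.zeros(8) for _ in range(3))])
            y = (first > 0).astype(float)
            prior[(1, lv)] = (X, y)
        engine = ct.init_engine(catalog, prior=prior)
        for lv in range(1, catalog[0].n_levels + 1):
            beta = engine.coefficients(1, lv)
            ref = sklearn_ridge_logistic(*prior[(1, lv)], 1.0)
            assert beta[1] > 0
            assert np.allclose(beta, ref, atol=1e-5)

    def test_default_prior_orders_levels(self):
        engine = ct.init_engine()
        status = ct.CognitiveStatus(0, 0, 0, 0)
        for eid in engine.exercises:
            p = engine.predict_all_levels(eid, status)
            assert (np.diff(p) < 0).all()


class TestPrediction:
    def test_closed_form_evaluation(self, small_engine):
        engine = small_engine.clone()
        clf = engine._clf[(1, 1)]
        clf.beta = np.array([0.0, 1.0, 0.0, 0.0, 0.0])
        status = ct.CognitiveStatus(0.847, -5.0, 2.0, 0.0)
        assert engine.predict_success(1, 1, status) == pytest.approx(
            expit(0.847))

    def test_probability_limits(self, small_engine):
        hi = ct.CognitiveStatus(40, 40, 40, 40)
        p = small_engine.predict_success(1, 1, hi)
        assert 0.99 < p < 1.0

    def test_unknown_classifier_rejected(self, small_engine):
        with pytest.raises(KeyError):
            small_engine.predict_success(99, 1, ct.CognitiveStatus(0, 0, 0, 0))


class TestSelectLevel:
    def test_brute_force_equivalence_on_random_engines(self, small_engine):
        """Selection equals the enumeration rule: hardest level clearing
        the cut-off, else level 1."""
        rng = np.random.default_rng(7)
        engine = small_engine.clone()
        for _ in range(300):
            eid = int(rng.choice(list(engine.exercises)))
            for lv in range(1, engine.exercises[eid].n_levels + 1):
                engine._clf[(eid, lv)].beta = rng.normal(scale=1.2, size=5)
            status = ct.CognitiveStatus(*rng.normal(size=4))
            probs = [engine.predict_success(eid, lv, status)
                     for lv in range(1, engine.exercises[eid].n_levels + 1)]
            qualifying = [i + 1 for i, p in enumerate(probs)
                          if p >= engine.cutoff]
            expected = qualifying[-1] if qualifying else 1
            assert engine.select_level(eid, status) == expected

    def test_all_levels_qualify(self, small_engine):
        engine = small_engine.clone()
        n_levels = engine.exercises[1].n_levels
        for lv in range(1, n_levels + 1):
            engine._clf[(1, lv)].beta = np.array([5.0, 0, 0, 0, 0])
        assert engine.select_level(1, ct.CognitiveStatus(0, 0, 0, 0)) \
            == n_levels

    def test_no_level_qualifies_falls_back_to_one(self, small_engine):
        engine = small_engine.clone()
        for lv in range(1, engine.exercises[1].n_levels + 1):
            engine._clf[(1, lv)].beta = np.array([-5.0, 0, 0, 0, 0])
        assert engine.select_level(1, ct.CognitiveStatus(0, 0, 0, 0)) == 1

    def test_monotone_in_dominating_status(self, small_engine):
        """With nonnegative feature coefficients, a dominating status never
        selects an easier level."""
        engine = small_engine.clone()
        rng = np.random.default_rng(11)
        assert all((engine._clf[k].beta[1:] >= 0).all()
                   for k in engine._clf)
        for _ in range(200):
            s2 = rng.normal(size=4)
            s1 = s2 + rng.uniform(0, 1.5, size=4)
            assert engine.select_level(1, ct.CognitiveStatus(*s1)) >= \
                engine.select_level(1, ct.CognitiveStatus(*s2))


class TestRecordResult:
    def test_refit_deterministic_on_identical_data(self, small_engine):
        a, b = small_engine.clone(), small_engine.clone()
        status = ct.CognitiveStatus(0.2, -0.1, 0.3, 0.0)
        rec = ct.TrainingRecord("p", 1, 2, True)
        for eng in (a, b):
            eng.record_result(rec, status)
        assert np.array_equal(a.coefficients(1, 2), b.coefficients(1, 2))

    def test_failures_lower_predicted_success(self, small_engine):
        engine = small_engine.clone()
        status = ct.CognitiveStatus(0.0, 0.0, 0.0, 0.0)
        before = engine.predict_success(1, 3, status)
        for _ in range(50):
            engine.record_result(ct.TrainingRecord("p", 1, 3, False), status)
        after = engine.predict_success(1, 3, status)
        assert after < before
        assert after < 0.2

    def test_other_classifiers_bit_identical(self, small_engine):
        engine = small_engine.clone()
        snapshot = {k: c.beta.copy() for k, c in engine._clf.items()}
        status = ct.CognitiveStatus(1.0, 0.0, -1.0, 0.5)
        engine.record_result(ct.TrainingRecord("p", 3, 2, True), status)
        for key, beta in snapshot.items():
            if key == (3, 2):
                assert not np.array_equal(engine._clf[key].beta, beta)
            else:
                assert np.array_equal(engine._clf[key].beta, beta)

    def test_training_sets_only_grow(self, small_engine):
        engine = small_engine.clone()
        status = ct.CognitiveStatus(0, 0, 0, 0)
        n0 = engine.training_size(1, 1)
        engine.record_result(ct.TrainingRecord("p", 1, 1, True), status)
        assert engine.training_size(1, 1) == n0 + 1

    def test_unknown_target_rejected(self, small_engine):
        engine = small_engine.clone()
        status = ct.CognitiveStatus(0, 0, 0, 0)
        with pytest.raises(KeyError):
            engine.record_result(ct.TrainingRecord("p", 42, 1, True), status)
        with pytest.raises(KeyError):
            engine.record_result(ct.TrainingRecord("p", 1, 99, True), status)


class TestPlanSession:
    def test_thirty_minutes_of_three_minute_tasks(self):
        engine = ct.init_engine()
        status = ct.CognitiveStatus(0, 0, 0, 0)
        plan = engine.plan_session(status, 30, task_minutes=3.0)
        assert len(plan) == 10
        assert [eid for eid, _ in plan] == sorted(engine.exercises)

    def test_three_minutes_single_task(self):
        engine = ct.init_engine()
        plan = engine.plan_session(ct.CognitiveStatus(0, 0, 0, 0), 3.0)
        assert len(plan) == 1

    def test_levels_match_elementwise_selection(self):
        engine = ct.init_engine()
        status = ct.CognitiveStatus(0.4, -0.2, 0.1, 0.6)
        plan = engine.plan_session(status, 45, task_minutes=3.0)
        for eid, level in plan:
            assert level == engine.select_level(eid, status)

    def test_nonpositive_duration_rejected(self):
        engine = ct.init_engine()
        with pytest.raises(ValueError):
            engine.plan_session(ct.CognitiveStatus(0, 0, 0, 0), 0)


class TestBasicPolicy:
    def test_always_level_one(self):
        for eid in ct.DEFAULT_BASIC_IDS:
            assert ct.bcct_select_level(eid) == 1

    def test_excluded_exercise_rejected(self):
        excluded = set(range(1, 11)) - set(ct.DEFAULT_BASIC_IDS)
        for eid in excluded:
            with pytest.raises(KeyError):
                ct.bcct_select_level(eid)

    def test_stateless(self):
        assert all(ct.bcct_select_level(1) == 1 for _ in range(10))


class TestReplayAndSerialisation:
    def _run_some_training(self, engine, n=60, seed=13):
        rng = np.random.default_rng(seed)
        statuses = {f"p{i}": ct.CognitiveStatus(*rng.normal(size=4))
                    for i in range(4)}
        log = []
        for _ in range(n):
            pid = f"p{int(rng.integers(4))}"
            eid = int(rng.choice(list(engine.exercises)))
            lv = int(rng.integers(1, engine.exercises[eid].n_levels + 1))
            rec = ct.TrainingRecord(pid, eid, lv,
                                    bool(rng.random() < 0.6), 0)
            engine.record_result(rec, statuses[pid])
            log.append(rec)
        return log, statuses

    def test_replaying_log_reproduces_state_exactly(self):
        catalog = default_catalog()[:3]
        engine = ct.init_engine(catalog)
        log, statuses = self._run_some_training(engine)
        rebuilt = ct.replay(catalog, log, statuses)
        for key in engine._clf:
            assert np.array_equal(engine._clf[key].beta,
                                  rebuilt._clf[key].beta)
            assert np.array_equal(engine._clf[key].y, rebuilt._clf[key].y)

    def test_json_round_trip(self):
        catalog = default_catalog()[:2]
        engine = ct.init_engine(catalog)
        self._run_some_training(engine, n=20)
        restored = ct.EngineState.from_json(engine.to_json())
        assert restored.cutoff == engine.cutoff
        assert len(restored.records) == len(engine.records)
        for key in engine._clf:
            assert np.array_equal(engine._clf[key].beta,
                                  restored._clf[key].beta)
        status = ct.CognitiveStatus(0.3, 0.1, -0.2, 0.5)
        for eid in engine.exercises:
            assert restored.select_level(eid, status) == \
                engine.select_level(eid, status)
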