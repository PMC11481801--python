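"""Cohort generation, screening cascade, minimisation randomiser."""

import numpy as np
import pytest

import ccttrial as ct
from ccttrial.cohort import (REASON_DEMENTIA, REASON_DEPRESSION,
                             REASON_NO_IMPAIRMENT, REASON_TECH)


class TestGenerateCohort:
    def test_empty_cohort(self):
        assert ct.generate_cohort(ct.CohortConfig(n=0), seed=1) == []

    def test_same_seed_identical(self):
        a = ct.generate_cohort(ct.CohortConfig(n=30), seed=9)
        b = ct.generate_cohort(ct.CohortConfig(n=30), seed=9)
        for p, q in zip(a, b):
            assert p.participant_id == q.participant_id
            assert p.age == q.age and p.sex == q.sex
            assert np.array_equal(p.ability, q.ability)

    def test_negative_sd_rejected(self):
        with pytest.raises(ValueError):
            ct.generate_cohort(ct.CohortConfig(n=5, age_sd=-1), seed=0)

    def test_profiles_satisfy_invariants(self):
        for p in ct.generate_cohort(ct.CohortConfig(n=200), seed=2):
            p.validate()
            assert p.vascular_risk in range(5)
            assert 0 <= p.phq9 <= 27
            assert min(p.cognitive_hours, p.physical_hours,
                       p.social_hours) >= 0

    def test_couples_share_household(self):
        cfg = ct.CohortConfig(n=100, couple_fraction=0.4)
        cohort = ct.generate_cohort(cfg, seed=3)
        sizes = {}
        for p in cohort:
            sizes[p.household_id] = sizes.get(p.household_id, 0) + 1
        n_paired = sum(s for s in sizes.values() if s == 2)
        assert n_paired == 2 * round(0.4 * 100 / 2)

    def test_marginals_converge_to_targets(self):
        """Each configured marginal lands within 2 Monte-Carlo SEs."""
        n = 10_000
        cfg = ct.CohortConfig(n=n, couple_fraction=0.0)
        cohort = ct.generate_cohort(cfg, seed=11)
        cols = {
            "age": (np.array([p.age for p in cohort]), 73.5, 7.3),
            "physical": (np.array([p.physical_hours for p in cohort]),
                         10.5, 6.8),
            "cognitive": (np.array([p.cognitive_hours for p in cohort]),
                          19.6, 12.6),
            "social": (np.array([p.social_hours for p in cohort]), 6.9, 4.3),
            "phq9": (np.array([p.phq9 for p in cohort]), 3.1, 2.8),
            "vascular": (np.array([p.vascular_risk for p in cohort]),
                         1.1, 0.893),
        }
        for name, (x, target, sd) in cols.items():
            se = sd / np.sqrt(n)
            assert abs(x.mean() - target) < 2.5 * se, name
        female = np.mean([p.sex == "female" for p in cohort])
        assert abs(female - 0.416) < 2.5 * np.sqrt(0.416 * 0.584 / n)
        edu = np.mean([p.education_level == "university" for p in cohort])
        assert abs(edu - 0.427) < 2.5 * np.sqrt(0.427 * 0.573 / n)


class TestScreeningScores:
    def test_calibration_anchor(self, profile):
        p = profile.copy()
        p.ability = np.zeros(4)
        s = ct.screening_scores(p, ct.MeasurementConfig(
            moca_noise_sd=0, mmse_noise_sd=0))
        assert s.moca == 22 and s.mmse == 27

    def test_ceiling(self, profile):
        p = profile.copy()
        p.ability = np.full(4, 50.0)
        s = ct.screening_scores(p, ct.MeasurementConfig(
            moca_noise_sd=0, mmse_noise_sd=0))
        assert s.moca == 30 and s.mmse == 30

    def test_monotone_in_ability(self, profile):
        """Uniformly higher ability never lowers the noise-free MoCA."""
        m = ct.MeasurementConfig(moca_noise_sd=0, mmse_noise_sd=0)
        grid = np.linspace(-3, 3, 25)
        last = -1
        for a in grid:
            p = profile.copy()
            p.ability = np.full(4, a)
            s = ct.screening_scores(p, m)
            assert s.moca >= last
            last = s.moca
            shifted = profile.copy()
            shifted.ability = np.full(4, a + 1.0)
            assert ct.screening_scores(shifted, m).moca >= s.moca


class TestEligibility:
    @pytest.mark.parametrize("scores, eligible, reason", [
        ((24, 24, 12, True), True, None),
        ((25, 30, 0, True), False, REASON_NO_IMPAIRMENT),
        ((20, 23, 0, True), False, REASON_DEMENTIA),
        ((20, 28, 13, True), False, REASON_DEPRESSION),
        ((20, 28, 5, False), False, REASON_TECH),
        # cascade order: the first failed criterion names the reason
        ((25, 20, 20, False), False, REASON_NO_IMPAIRMENT),
    ])
    def test_cascade(self, scores, eligible, reason):
        s = ct.ScreeningScores(*scores)
        ok, why = ct.screen_eligibility(s)
        assert ok is eligible and why == reason

    def test_idempotent(self):
        s = ct.ScreeningScores(22, 27, 3, True)
        assert ct.screen_eligibility(s) == ct.screen_eligibility(s)

    def test_exclusion_counts_sum(self):
        """Excluded-by-reason counts account for everyone screened."""
        cfg = ct.RunConfig()
        cfg.cohort.n = 40
        _, _, counts = ct.recruit_eligible(cfg, seed=6)
        reasons = [REASON_NO_IMPAIRMENT, REASON_DEMENTIA,
                   REASON_DEPRESSION, REASON_TECH]
        excluded = sum(counts.get(r, 0) for r in reasons)
        # the last batch may stop short once the target is reached
        assert counts["screened"] - counts["eligible"] - excluded >= 0
        assert counts["eligible"] == 40
        assert counts["screened"] - excluded >= counts["eligible"]


class TestRandomisation:
    def test_households_always_co_assigned(self):
        cfg = ct.CohortConfig(n=60, couple_fraction=0.3)
        cohort = ct.generate_cohort(cfg, seed=4)
        for seed in range(20):
            assign = ct.randomise_minimisation(cohort, seed=seed)
            for p in cohort:
                partners = [q for q in cohort
                            if q.household_id == p.household_id]
                assert len({assign[q.participant_id]
                            for q in partners}) == 1

    def test_deterministic_given_seed(self):
        cohort = ct.generate_cohort(ct.CohortConfig(n=89), seed=5)
        a = ct.randomise_minimisation(cohort, seed=3)
        assert a == ct.randomise_minimisation(cohort, seed=3)

    def test_deterministic_minimisation_balances_alternating_sex(self):
        cohort = ct.generate_cohort(
            ct.CohortConfig(n=40, couple_fraction=0.0), seed=7)
        for i, p in enumerate(cohort):
            p.sex = "female" if i % 2 == 0 else "male"
        assign = ct.randomise_minimisation(cohort, seed=0, bias=1.0)
        for sex in ("female", "male"):
            ig = sum(1 for p in cohort
                     if p.sex == sex and assign[p.participant_id] == "IG")
            cg = sum(1 for p in cohort
                     if p.sex == sex and assign[p.participant_id] == "CG")
            assert abs(ig - cg) <= 1

    def test_group_sizes_balanced_across_seeds(self):
        """89 singletons: arm sizes within tolerance in >=95% of replicates."""
        cohort = ct.generate_cohort(
            ct.CohortConfig(n=89, couple_fraction=0.0), seed=8)
        ok = 0
        n_rep = 1000
        for seed in range(n_rep):
            assign = ct.randomise_minimisation(cohort, seed=seed)
            n_ig = sum(1 for g in assign.values() if g == "IG")
            ok += abs(n_ig - (89 - n_ig)) <= 5
        assert ok / n_rep >= 0.95

    def test_minimisation_beats_simple_randomisation(self):
        """Sex imbalance under minimisation is stochastically smaller."""
        cohort = ct.generate_cohort(
            ct.CohortConfig(n=89, couple_fraction=0.0), seed=9)
        rng = np.random.default_rng(0)

        def sex_imbalance(assign):
            tot = 0
            for sex in ("female", "male"):
                ig = sum(1 for p in cohort if p.sex == sex
                         and assign[p.participant_id] == "IG")
                cg = sum(1 for p in cohort if p.sex == sex
                         and assign[p.participant_id] == "CG")
                tot += abs(ig - cg)
            return tot

        mini, simple = [], []
        for seed in range(300):
            mini.append(sex_imbalance(
                ct.randomise_minimisation(cohort, seed=seed)))
            coin = rng.random(len(cohort)) < 0.5
            simple.append(sex_imbalance(
                {p.participant_id: ("IG" if c else "CG")
                 for p, c in zip(cohort, coin)}))
        assert np.mean(mini) < np.mean(simple)
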