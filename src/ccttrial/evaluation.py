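"""Reproduction and calibration studies.

Self-contained routines that re-derive the published worked statistics
from the printed summaries, check the ANCOVA implementation against an
independent GLM route, calibrate its type-I error and effect-size
recovery by simulation, and exercise the adaptive engine in closed loop.
Both the test suite and the acceptance script drive these.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from . import reference as ref
from .ancova import mixed_ancova
from .catalog import default_catalog
from .cohort import generate_cohort
from .config import RunConfig, substream
from .effects import chi_square_2x2, cohen_d_independent, cramers_v_2x2
from .engine import CognitiveStatus, TrainingRecord, init_engine, replay
from .imputation import impute_em
from .learner import simulate_usage
from .pipeline import select_covariates
from .trial import _measure_status, paired_gain, recruit_eligible
from .ueq import compare_groups

# ---------------------------------------------------------------------------
# Worked statistics from the published summaries
# ---------------------------------------------------------------------------


def worked_statistics() -> dict[str, float]:
    """Every group-summary statistic reproducible from the printed tables,
    at the paper's 2-decimal presentation."""
    out = {}
    out["chi2_transition_outlier_excluded"] = round(chi_square_2x2(
        *_transition_table(ref.TRANSITIONS_EXCL))[0], 2)
    out["chi2_transition_outlier_included"] = round(chi_square_2x2(
        *_transition_table(ref.TRANSITIONS_INCL))[0], 2)
    (ig, cg) = ref.TABLE1_CONTINUOUS["physical_hours"]
    out["cohen_d_physical_activity"] = round(cohen_d_independent(
        *ig, ref.N_IG, *cg, ref.N_CG), 2)
    (ig, cg) = ref.TABLE1_CONTINUOUS["cognitive_hours"]
    out["cohen_d_cognitive_activity"] = round(cohen_d_independent(
        *ig, ref.N_IG, *cg, ref.N_CG), 2)
    (ig, cg) = (ref.EXERCISE_DURATION_HOURS["IG"],
                ref.EXERCISE_DURATION_HOURS["CG"])
    out["cohen_d_exercise_duration"] = round(cohen_d_independent(
        *ig, ref.N_IG, *cg, ref.N_CG), 2)
    ueq = {r.variable: round(r.value, 2) for r in compare_groups(
        ref.UEQ_TABLE3, ref.UEQ_N_IG, ref.UEQ_N_CG)}
    out["cohen_d_ueq_attractiveness"] = ueq["attractiveness"]
    out["cohen_d_ueq_efficiency"] = ueq["efficiency"]
    out["cohen_d_ueq_novelty"] = ueq["novelty"]
    out["cohen_d_ueq_perspicuity"] = ueq["perspicuity"]
    out["cramers_v_sex"] = round(
        cramers_v_2x2(*ref.TABLE1_BINARY["sex_female"]), 2)
    return out


def _transition_table(counts):
    ig_t, ig_n = counts["IG"]
    cg_t, cg_n = counts["CG"]
    return ig_t, ig_n - ig_t, cg_t, cg_n - cg_t


def selected_covariates() -> list[str]:
    """The covariate rule applied to the published baseline table."""
    return sorted(select_covariates(ref.table1_candidates()).selected)


# ---------------------------------------------------------------------------
# ANCOVA validation
# ---------------------------------------------------------------------------


def _simulate_table(rng, n, interaction=0.0, k_cov=2, sd_change=2.0,
                    balanced=False):
    if balanced:
        group = np.where(np.arange(n) % 2 == 0, "IG", "CG")
    else:
        group = np.where(rng.random(n) < 0.5, "IG", "CG")
    pre = rng.normal(22, 1.6, n)
    change = rng.normal(1.0, sd_change, n) + np.where(
        group == "IG", interaction / 2.0, -interaction / 2.0)
    df = pd.DataFrame({"group": group, "moca_t0": pre,
                       "moca_t6": pre + change})
    for i in range(k_cov):
        df[f"cov{i}"] = rng.normal(size=n)
    return df, [f"cov{i}" for i in range(k_cov)]


def ancova_oracle_error(n_datasets: int = 20, seed: int = 0) -> float:
    """Max relative disagreement of term F/p values with an independent
    statsmodels OLS fit of the same two-occasion decomposition."""
    import statsmodels.api as sm

    rng = np.random.default_rng([seed, 101])
    worst = 0.0
    for _ in range(n_datasets):
        n = int(rng.integers(20, 50))
        k = int(rng.integers(0, 4))
        df, covs = _simulate_table(rng, n,
                                   interaction=float(rng.normal(0, 1)),
                                   k_cov=k)
        res = mixed_ancova(df, covs)
        d = (df["moca_t6"] - df["moca_t0"]).to_numpy()
        g = df["group"].map({"IG": 0.5, "CG": -0.5}).to_numpy(float)
        C = df[covs].to_numpy(float) if covs else np.empty((n, 0))
        Z = np.column_stack([np.ones(n), C - C.mean(axis=0), g])
        fit = sm.OLS(d, Z).fit()
        labels = ["T"] + [f"T x {c}" for c in covs] + ["T x group"]
        for j, lab in enumerate(labels):
            row = res.terms[res.terms["term"] == lab].iloc[0]
            f_ref = fit.tvalues[j] ** 2
            worst = max(worst,
                        abs(row["F"] - f_ref) / max(abs(f_ref), 1e-12),
                        abs(row["p"] - fit.pvalues[j])
                        / max(fit.pvalues[j], 1e-12))
    return worst


def type_one_error(n_rep: int = 1000, n: int = 89, alpha: float = 0.05,
                   seed: int = 0) -> float:
    """Rejection rate of the time-by-group test under a null simulation."""
    rng = np.random.default_rng([seed, 102])
    hits = 0
    for _ in range(n_rep):
        df, covs = _simulate_table(rng, n, interaction=0.0)
        res = mixed_ancova(df, covs)
        hits += res.term("T x group")["p"] < alpha
    return hits / n_rep


def interaction_recovery(n_rep: int = 500, n: int = 200,
                         interaction: float = 1.2, sd_change: float = 2.0,
                         seed: int = 0) -> dict[str, float]:
    """Parameter recovery of an injected time-by-group effect.

    Returns the Monte-Carlo mean of the estimated interaction contrast and
    of partial eta squared, together with their exact expectations (the
    noncentral-F expectation of eta-hat via its Poisson-mixture form) and
    Monte-Carlo standard errors.
    """
    rng = np.random.default_rng([seed, 103])
    betas, etas = [], []
    k_cov = 2
    for _ in range(n_rep):
        df, covs = _simulate_table(rng, n, interaction=interaction,
                                   k_cov=k_cov, sd_change=sd_change,
                                   balanced=True)
        res = mixed_ancova(df, covs)
        chg = res.changes.set_index("group")["change"]
        betas.append(chg["IG"] - chg["CG"])
        etas.append(res.term("T x group")["partial_eta2"])
    betas, etas = np.asarray(betas), np.asarray(etas)
    nu = n - (k_cov + 2)
    lam = n * interaction**2 / (4 * sd_change**2)
    ks = np.arange(0, 400)
    pois = stats.poisson.pmf(ks, lam / 2)
    expected_eta = float(np.sum(pois * (1 + 2 * ks) / (1 + 2 * ks + nu)))
    return {
        "mean_interaction_estimate": float(betas.mean()),
        "true_interaction": interaction,
        "se_interaction": float(betas.std(ddof=1) / np.sqrt(n_rep)),
        "mean_partial_eta2": float(etas.mean()),
        "expected_partial_eta2": expected_eta,
        "se_partial_eta2": float(etas.std(ddof=1) / np.sqrt(n_rep)),
    }


# ---------------------------------------------------------------------------
# EM imputation oracle
# ---------------------------------------------------------------------------


def em_oracle_error(n_cases: int = 10, seed: int = 0) -> float:
    """Worst-case deviation of the EM imputations from the closed-form
    conditional expectation on random two-variable problems."""
    rng = np.random.default_rng([seed, 104])
    worst = 0.0
    for _ in range(n_cases):
        n = int(rng.integers(25, 60))
        x = rng.normal(size=n)
        y = rng.normal() + rng.normal() * x + rng.normal(scale=0.7, size=n)
        df = pd.DataFrame({"x": x, "y": y})
        miss = np.sort(rng.choice(n, size=max(2, n // 10), replace=False))
        df.loc[miss, "y"] = np.nan
        cc = df.dropna()
        X = np.column_stack([np.ones(len(cc)), cc["x"]])
        beta, *_ = np.linalg.lstsq(X, cc["y"], rcond=None)
        expected = beta[0] + beta[1] * df.loc[miss, "x"].to_numpy()
        out, _ = impute_em(df, "y", ["x"], tol=1e-13)
        worst = max(worst, float(np.max(np.abs(
            out.loc[miss, "y"].to_numpy() - expected))))
    return worst


# ---------------------------------------------------------------------------
# Engine behaviour
# ---------------------------------------------------------------------------


def engine_property_violations(n_draws: int = 1000,
                               seed: int = 0) -> dict[str, int]:
    """Randomised checks of the selection rule and classifier isolation."""
    rng = np.random.default_rng([seed, 105])
    catalog = default_catalog()[:4]
    engine = init_engine(catalog)
    cutoff_viol = isolation_viol = 0
    eids = [e.exercise_id for e in catalog]
    for k in range(n_draws):
        eid = int(rng.choice(eids))
        ex = engine.exercises[eid]
        for lv in range(1, ex.n_levels + 1):
            engine._clf[(eid, lv)].beta = rng.normal(scale=1.2, size=5)
        status = CognitiveStatus(*rng.normal(size=4))
        probs = [engine.predict_success(eid, lv, status)
                 for lv in range(1, ex.n_levels + 1)]
        sel = engine.select_level(eid, status)
        qualifying = [i + 1 for i, p in enumerate(probs)
                      if p >= engine.cutoff]
        expected = qualifying[-1] if qualifying else 1
        if sel != expected:
            cutoff_viol += 1
        if qualifying and probs[sel - 1] < engine.cutoff:
            cutoff_viol += 1
        if k % 50 == 0:  # isolation spot-check (refits are the slow part)
            other = {key: c.beta.copy() for key, c in engine._clf.items()
                     if key[0] != eid}
            lv = int(rng.integers(1, ex.n_levels + 1))
            engine.record_result(
                TrainingRecord("probe", eid, lv, bool(rng.random() < 0.5)),
                status)
            for key, beta in other.items():
                if not np.array_equal(engine._clf[key].beta, beta):
                    isolation_viol += 1
    return {"cutoff_violations": cutoff_viol,
            "isolation_violations": isolation_viol}


def replay_reproduces_state(seed: int = 0) -> bool:
    """Replaying a training log from the same priors rebuilds the engine
    bit-for-bit."""
    rng = np.random.default_rng([seed, 106])
    catalog = default_catalog()[:3]
    engine = init_engine(catalog)
    statuses = {f"p{i}": CognitiveStatus(*rng.normal(size=4))
                for i in range(5)}
    log = []
    for _ in range(80):
        pid = f"p{int(rng.integers(5))}"
        eid = int(rng.choice([e.exercise_id for e in catalog]))
        lv = int(rng.integers(1, catalog[0].n_levels + 1))
        rec = TrainingRecord(pid, eid, lv, bool(rng.random() < 0.6))
        engine.record_result(rec, statuses[pid])
        log.append(rec)
    rebuilt = replay(catalog, log, statuses)
    return all(np.array_equal(engine._clf[k].beta, rebuilt._clf[k].beta)
               for k in engine._clf)


def tracking_study(n_participants: int = 200,
                   seed: int = 0) -> dict[str, float]:
    """Closed-loop difficulty tracking over six simulated months.

    For each participant, the cumulative success rate is checked at every
    month-end after a 50-attempt burn-in against the [0.55, 0.85] band;
    the overall post-burn-in success rate is reported as well.
    """
    cfg = RunConfig()
    cfg.cohort.n = n_participants
    cfg.cohort.couple_fraction = 0.0
    eligible, _, _ = recruit_eligible(cfg, seed)
    catalog = default_catalog(cfg.engine.n_levels)
    base = init_engine(catalog, cutoff=cfg.engine.cutoff,
                       l2_penalty=cfg.engine.l2_penalty,
                       level_spacing=cfg.engine.level_spacing)
    rng_measure = substream(seed, "measurement")
    root = int(seed) % (2**31)
    in_band = 0
    checked = 0
    post_rates = []
    for i, profile in enumerate(eligible):
        status = _measure_status(profile,
                                 cfg.measurement.status_noise_sd,
                                 rng_measure)
        trained = profile.copy()
        logs = simulate_usage(trained, "adaptive", base.clone(),
                              rng=np.random.default_rng([root, 3, i]),
                              usage=cfg.usage, learner=cfg.learner,
                              status=status, catalog=catalog,
                              spacing=cfg.engine.level_spacing,
                              measurement=cfg.measurement)
        successes = []
        checkpoints = []
        for lg in logs:
            successes.extend(r.success for r in lg.records)
            if len(successes) > 50:
                checkpoints.append(np.mean(successes))
        if not checkpoints:
            continue
        checked += 1
        in_band += all(0.55 <= c <= 0.85 for c in checkpoints)
        post_rates.append(np.mean(np.asarray(successes, dtype=float)[50:]))
    return {
        "fraction_in_band": in_band / checked,
        "n_participants": checked,
        "mean_post_burnin_success": float(np.mean(post_rates)),
    }


def direction_study(n_trials: int = 200, n_per_arm: int = 16,
                    seed: int = 0) -> dict[str, float]:
    """Paired adaptive-vs-basic trials: how often does the adaptive arm's
    mean simulated MoCA gain exceed the basic arm's?"""
    wins = 0
    diffs = []
    for k in range(n_trials):
        adaptive, basic = paired_gain(seed=(seed * 100_003 + k) % (2**31),
                                      n_per_arm=n_per_arm)
        wins += adaptive > basic
        diffs.append(adaptive - basic)
    return {
        "fraction_adaptive_wins": wins / n_trials,
        "mean_gain_difference": float(np.mean(diffs)),
        "n_trials": n_trials,
    }
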