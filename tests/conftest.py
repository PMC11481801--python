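"""Shared fixtures: small synthetic subject tables and engines."""

import numpy as np
import pandas as pd
import pytest

import ccttrial as ct


@pytest.fixture
def rng():
    return np.random.default_rng(42)


def make_subjects(n=80, seed=0, interaction=0.0, missing=0, outlier=None,
                  sd_change=1.2):
    """Synthetic analysis-ready subject table.

    ``interaction`` is the extra mean MoCA change given to the IG arm;
    ``outlier`` optionally injects one extreme change score as
    ``(delta, clinical_reason)``.
    """
    r = np.random.default_rng(seed)
    group = np.where(np.arange(n) % 2 == 0, "IG", "CG")
    moca_t0 = np.clip(np.rint(r.normal(22, 1.6, n)), 10, 24)
    change = r.normal(1.0, sd_change, n) + np.where(group == "IG",
                                                    interaction, 0.0)
    moca_t6 = np.clip(np.rint(moca_t0 + change), 0, 30).astype(float)
    df = pd.DataFrame({
        "participant_id": [f"P{i:04d}" for i in range(n)],
        "household_id": [f"H{i:04d}" for i in range(n)],
        "group": group,
        "age": np.round(r.normal(73.5, 7.3, n), 1),
        "sex": r.choice(["female", "male"], n),
        "education_level": r.choice(
            ["primary", "secondary", "higher", "university"], n),
        "cognitive_hours": np.round(np.abs(r.normal(19.6, 12.6, n)), 1),
        "physical_hours": np.round(np.abs(r.normal(10.5, 6.8, n)), 1),
        "social_hours": np.round(np.abs(r.normal(6.9, 4.3, n)), 1),
        "vascular_risk": r.binomial(4, 0.275, n),
        "medication_score": r.choice([-2, -1, 0, 1], n,
                                     p=[0.01, 0.08, 0.9, 0.01]),
        "phq9": r.integers(0, 13, n),
        "charlson": r.choice([0, 1, 2], n, p=[0.9, 0.09, 0.01]),
        "moca_t0": moca_t0,
        "moca_t6": moca_t6,
        "clinical_reason": "",
    })
    if outlier is not None:
        delta, reason = outlier
        df.loc[0, "moca_t6"] = float(np.clip(df.loc[0, "moca_t0"] + delta,
                                             0, 30))
        df.loc[0, "clinical_reason"] = reason
    if missing:
        idx = r.choice(n, size=missing, replace=False)
        df.loc[idx, "moca_t6"] = np.nan
    return df


@pytest.fixture
def subjects():
    return make_subjects(n=80, seed=1, interaction=1.0)


@pytest.fixture(scope="session")
def small_engine():
    """Three-exercise engine with default priors."""
    catalog = ct.default_catalog()[:3]
    return ct.init_engine(catalog)


@pytest.fixture(scope="session")
def profile():
    cfg = ct.CohortConfig(n=1)
    return ct.generate_cohort(cfg, seed=5)[0]
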