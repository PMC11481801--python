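"""Published summary statistics of the MCI-CCT trial sample.

These are the printed group summaries (means, SDs, counts, and the
baseline-table effect-size column) of the randomised trial this package
emulates. They serve as worked-example inputs: recomputing effect sizes
and contingency statistics from them checks the statistics layer against
the published values, and the synthetic-cohort generator targets the same
marginals.
"""

from __future__ import annotations

from .pipeline import CandidateCovariate

N_IG, N_CG = 44, 45

#: continuous baseline rows: (IG mean, IG sd), (CG mean, CG sd)
TABLE1_CONTINUOUS = {
    "age": ((73.4, 8.1), (73.5, 6.5)),
    "household_income": ((3658, 1218), (3644, 1178)),
    "phq9": ((3.1, 2.8), (3.0, 2.8)),
    "vascular_risk": ((1.0, 0.9), (1.2, 0.9)),
    "medication_score": ((0.0, 0.2), (-0.1, 0.4)),
    "cognitive_hours": ((20.8, 13.1), (18.4, 12.0)),
    "physical_hours": ((11.8, 7.3), (9.3, 6.2)),
    "social_hours": ((6.7, 3.8), (7.1, 4.8)),
    "charlson": ((0.2, 0.4), (0.1, 0.4)),
}

#: binary baseline rows as 2x2 counts (IG yes, IG no, CG yes, CG no)
TABLE1_BINARY = {
    "sex_female": (19, 25, 18, 27),
    "employed": (5, 39, 6, 39),
    "other_household_members": (35, 9, 38, 7),
    "bmi_normal": (22, 22, 22, 23),
}

#: the baseline table's printed |effect size| column
TABLE1_PRINTED_EFFECTS = {
    "age": 0.01,
    "sex_female": 0.03,
    "education_level": 0.08,
    "household_income": 0.01,
    "employed": 0.03,
    "other_household_members": 0.06,
    "phq9": 0.01,
    "vascular_risk": 0.13,
    "medication_score": 0.19,
    "cognitive_hours": 0.19,
    "physical_hours": 0.37,
    "social_hours": 0.10,
    "charlson": 0.06,
    "bmi_normal": 0.01,
}

#: variables whose preventive influence on cognitive decline is
#: evidence-based (criterion A of the covariate rule)
EVIDENCE_FLAGS = {
    "age": False,
    "sex_female": False,
    "education_level": False,
    "household_income": False,
    "employed": False,
    "other_household_members": False,
    "phq9": True,
    "vascular_risk": True,
    "medication_score": True,
    "cognitive_hours": True,
    "physical_hours": True,
    "social_hours": True,
    "charlson": True,
    "bmi_normal": True,
}

#: six-month MCI transition counts (moved above the MCI cutoff / group n),
#: with the clinically explained outlier excluded and included
TRANSITIONS_EXCL = {"IG": (22, 43), "CG": (13, 45)}
TRANSITIONS_INCL = {"IG": (22, 44), "CG": (13, 45)}

#: total exercise duration over six months, hours: (mean, sd) per arm
EXERCISE_DURATION_HOURS = {"IG": (44.1, 24.1), "CG": (43.2, 24.9)}

#: user-experience scale summaries (mean, sd) per arm, n = 40 / 39
UEQ_TABLE3 = {
    "attractiveness": ((1.77, 0.81), (1.18, 1.02)),
    "perspicuity": ((1.64, 1.03), (1.56, 1.01)),
    "efficiency": ((1.11, 0.67), (0.98, 0.63)),
    "dependability": ((1.25, 0.74), (1.39, 0.81)),
    "stimulation": ((1.59, 0.79), (0.91, 1.29)),
    "novelty": ((0.87, 0.91), (0.54, 1.32)),
}
UEQ_N_IG, UEQ_N_CG = 40, 39

#: usage frequency (times per month) and session duration (minutes),
#: first and last month, (mean, sd)
USAGE = {
    "IG": {"sessions_first": (15.6, 6.9), "sessions_last": (12.7, 5.6),
           "minutes_first": (33.9, 11.8), "minutes_last": (33.6, 10.8)},
    "CG": {"sessions_first": (13.7, 6.0), "sessions_last": (12.3, 6.4),
           "minutes_first": (37.7, 12.1), "minutes_last": (37.4, 20.9)},
}


def table1_candidates(use_printed_effects: bool = True
                      ) -> list[CandidateCovariate]:
    """The baseline table as covariate-selection input.

    With ``use_printed_effects`` the table's own effect-size column is
    used (the published rule operated on those values); otherwise effect
    sizes are recomputed from the rounded group summaries, which shifts
    rows whose printed means/SDs carry rounding error.
    """
    out = []
    for name, (ig, cg) in TABLE1_CONTINUOUS.items():
        out.append(CandidateCovariate(
            name, "continuous", EVIDENCE_FLAGS[name],
            ig=(ig[0], ig[1], N_IG), cg=(cg[0], cg[1], N_CG),
            effect_size=TABLE1_PRINTED_EFFECTS[name]
            if use_printed_effects else None))
    for name, counts in TABLE1_BINARY.items():
        out.append(CandidateCovariate(
            name, "binary", EVIDENCE_FLAGS[name], counts=counts,
            effect_size=TABLE1_PRINTED_EFFECTS[name]
            if use_printed_effects else None))
    return out
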