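"""The trial's analysis pipeline, in protocol order.

Stages: outlier screen on the follow-up change scores -> EM imputation of
missing follow-ups (intention-to-treat) -> covariate selection by the
evidence + effect-size rule -> mixed-model ANCOVA -> MCI transition
sensitivity analysis. :class:`TrialAnalysis` bundles the stages behind a
single fit() with a full audit trail.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .ancova import MixedAncovaResults, mixed_ancova
from .config import AnalysisConfig
from .effects import (EffectSizeReport, chi_square_2x2, cohen_d_independent,
                      cramers_v_2x2, interpret_d, interpret_v)
from .imputation import EMInfo, impute_em

# ---------------------------------------------------------------------------
# Covariate selection
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class CandidateCovariate:
    """One baseline variable offered to the covariate-selection rule.

    Continuous candidates carry group summaries ``(mean, sd, n)`` per arm;
    binary ones a 2x2 count table ``(a, b, c, d)`` = (IG yes, IG no,
    CG yes, CG no). ``evidence`` flags variables with established
    preventive influence on cognitive decline; ``effect_size`` may be
    supplied directly (e.g. from a published baseline table), otherwise it
    is computed from the summaries.
    """

    name: str
    kind: str  # "continuous" | "binary"
    evidence: bool
    ig: tuple | None = None
    cg: tuple | None = None
    counts: tuple | None = None
    effect_size: float | None = None

    def compute_effect(self) -> EffectSizeReport:
        if self.effect_size is not None:
            value = abs(self.effect_size)
            kind = "cohen_d" if self.kind == "continuous" else "cramers_v"
        elif self.kind == "continuous":
            value = cohen_d_independent(*self.ig, *self.cg)
            kind = "cohen_d"
        elif self.kind == "binary":
            value = cramers_v_2x2(*self.counts)
            kind = "cramers_v"
        else:
            raise ValueError(f"unknown candidate kind {self.kind!r}")
        band = interpret_d(value) if kind == "cohen_d" else interpret_v(value)
        return EffectSizeReport(self.name, kind, value, band)


@dataclass
class CovariateSelection:
    selected: list[str]
    effects: dict[str, EffectSizeReport]
    audit: list[str] = field(default_factory=list)


def select_covariates(candidates, effect_floor: float = 0.10,
                      correlation_ceiling: float = 0.80,
                      data: pd.DataFrame | None = None) -> CovariateSelection:
    """Apply the two-step covariate rule with a multicollinearity ceiling.

    A candidate is kept when it is evidence-flagged AND its group-difference
    effect size is at least ``effect_floor``. If subject-level ``data`` is
    supplied, pairs of kept covariates with |Pearson r| above
    ``correlation_ceiling`` are resolved by dropping the member with the
    smaller effect size. Every decision is written to the audit trail.
    """
    effects: dict[str, EffectSizeReport] = {}
    audit: list[str] = []
    kept: list[str] = []
    for cand in candidates:
        rep = cand.compute_effect()
        effects[cand.name] = rep
        if not cand.evidence:
            audit.append(f"{cand.name}: excluded (no evidence flag); "
                         f"{rep.kind} = {rep.value:.2f}")
            continue
        if rep.value < effect_floor:
            audit.append(f"{cand.name}: excluded ({rep.kind} = "
                         f"{rep.value:.2f} < {effect_floor:.2f})")
            continue
        kept.append(cand.name)
        audit.append(f"{cand.name}: kept ({rep.kind} = {rep.value:.2f} "
                     f">= {effect_floor:.2f})")

    if data is not None and len(kept) > 1:
        cols = [c for c in kept if c in data.columns]
        corr = data[cols].corr().abs()
        changed = True
        while changed:
            changed = False
            for i, a in enumerate(cols):
                for b in cols[i + 1:]:
                    if a in kept and b in kept and \
                            corr.loc[a, b] > correlation_ceiling:
                        drop = a if effects[a].value <= effects[b].value \
                            else b
                        kept.remove(drop)
                        audit.append(
                            f"{drop}: dropped (|r({a},{b})| = "
                            f"{corr.loc[a, b]:.2f} > "
                            f"{correlation_ceiling:.2f}; smaller effect)")
                        changed = True
        audit.append("multicollinearity ceiling checked on subject data")
    elif len(kept) > 1:
        audit.append("no subject-level data: correlation ceiling not "
                     "evaluated")
    return CovariateSelection(kept, effects, audit)


# ---------------------------------------------------------------------------
# Outliers
# ---------------------------------------------------------------------------


@dataclass
class OutlierResult:
    fences: tuple[float, float]
    flagged: list[str]
    excluded: list[str]
    audit: list[str] = field(default_factory=list)


def detect_outliers(records: pd.DataFrame, pre="moca_t0", post="moca_t6",
                    id_col="participant_id",
                    reason_col="clinical_reason") -> OutlierResult:
    """1.5 x IQR screen on the follow-up change scores.

    Quartiles use linear interpolation. Flagged cases are *excluded* only
    when a clinical reason is recorded for them; statistical outliers
    without a clinical explanation stay in the analysis.
    """
    obs = records.dropna(subset=[post])
    if len(obs) < 4:
        raise ValueError("need at least 4 observed follow-ups")
    change = (obs[post] - obs[pre]).to_numpy(float)
    q1, q3 = np.quantile(change, [0.25, 0.75])  # linear interpolation
    iqr = q3 - q1
    lo, hi = q1 - 1.5 * iqr, q3 + 1.5 * iqr
    audit = [f"change-score quartiles (linear interpolation): "
             f"Q1 = {q1:.2f}, Q3 = {q3:.2f}; fences [{lo:.2f}, {hi:.2f}]"]
    out_mask = (change < lo) | (change > hi)
    flagged, excluded = [], []
    for (_, row), is_out in zip(obs.iterrows(), out_mask):
        if not is_out:
            continue
        pid = str(row[id_col])
        flagged.append(pid)
        reason = row.get(reason_col, "")
        reason = "" if pd.isna(reason) else str(reason).strip()
        if reason:
            excluded.append(pid)
            audit.append(f"{pid}: change {row[post] - row[pre]:+.0f} "
                         f"outside fences; excluded ({reason})")
        else:
            audit.append(f"{pid}: change {row[post] - row[pre]:+.0f} "
                         f"outside fences; retained (no clinical reason)")
    if not flagged:
        audit.append("no statistical outliers")
    return OutlierResult((float(lo), float(hi)), flagged, excluded, audit)


# ---------------------------------------------------------------------------
# Transition analysis
# ---------------------------------------------------------------------------


@dataclass
class TransitionResult:
    counts: dict[str, tuple[int, int]]  # group -> (transitioned, total)
    fractions: dict[str, float]
    chi2: float
    p: float

    def table(self) -> tuple[int, int, int, int]:
        ig_t, ig_n = self.counts["IG"]
        cg_t, cg_n = self.counts["CG"]
        return ig_t, ig_n - ig_t, cg_t, cg_n - cg_t


def transition_analysis(records: pd.DataFrame, mci_cutoff: int = 24,
                        post="moca_t6", group="group") -> TransitionResult:
    """Per-group transition out of the MCI range (follow-up above cutoff)."""
    obs = records.dropna(subset=[post])
    counts, fractions = {}, {}
    for g in ("IG", "CG"):
        sub = obs[obs[group] == g]
        t = int((sub[post] > mci_cutoff).sum())
        counts[g] = (t, len(sub))
        fractions[g] = t / len(sub) if len(sub) else float("nan")
    a, b, c, d = (counts["IG"][0], counts["IG"][1] - counts["IG"][0],
                  counts["CG"][0], counts["CG"][1] - counts["CG"][0])
    if a + c == 0 or b + d == 0:
        chi2, p = 0.0, 1.0
    else:
        chi2, p = chi_square_2x2(a, b, c, d)
    return TransitionResult(counts, fractions, chi2, p)


# ---------------------------------------------------------------------------
# Orchestrator
# ---------------------------------------------------------------------------

#: default candidate set mirroring the baseline table: risk-factor block
#: carries the evidence flag, sociodemographics do not
DEFAULT_CANDIDATE_COLUMNS = (
    ("age", "continuous", False),
    ("cognitive_hours", "continuous", True),
    ("physical_hours", "continuous", True),
    ("social_hours", "continuous", True),
    ("vascular_risk", "continuous", True),
    ("medication_score", "continuous", True),
    ("phq9", "continuous", True),
    ("charlson", "continuous", True),
)


def candidates_from_data(data: pd.DataFrame,
                         spec=DEFAULT_CANDIDATE_COLUMNS
                         ) -> list[CandidateCovariate]:
    """Build candidate summaries from a subject table."""
    out = []
    for name, kind, evidence in spec:
        if name not in data.columns:
            continue
        ig = data[data["group"] == "IG"][name]
        cg = data[data["group"] == "CG"][name]
        if kind == "continuous":
            out.append(CandidateCovariate(
                name, kind, evidence,
                ig=(ig.mean(), ig.std(ddof=1), len(ig)),
                cg=(cg.mean(), cg.std(ddof=1), len(cg))))
        else:
            out.append(CandidateCovariate(
                name, kind, evidence,
                counts=(int(ig.sum()), int((1 - ig).sum()),
                        int(cg.sum()), int((1 - cg).sum()))))
    return out


class TrialAnalysis:
    """The full statistics pipeline as a single model-like object.

    ``TrialAnalysis(subjects, config).fit()`` runs outlier screening,
    EM imputation, covariate selection, the mixed-model ANCOVA and the
    transition analysis, and returns a :class:`TrialAnalysisResults`
    carrying every stage's output and audit trail.
    """

    def __init__(self, subjects: pd.DataFrame,
                 config: AnalysisConfig | None = None,
                 candidates: list[CandidateCovariate] | None = None):
        self.subjects = subjects.reset_index(drop=True)
        self.config = config or AnalysisConfig()
        self.candidates = candidates

    @classmethod
    def from_dataframe(cls, subjects, config=None, candidates=None):
        return cls(subjects, config, candidates)

    def fit(self) -> "TrialAnalysisResults":
        cfg = self.config
        log: list[str] = []
        df = self.subjects.copy()
        log.append(f"input: {len(df)} subjects "
                   f"({(df['group'] == 'IG').sum()} IG, "
                   f"{(df['group'] == 'CG').sum()} CG)")

        outliers = detect_outliers(df)
        if not cfg.include_outliers and outliers.excluded:
            df = df[~df["participant_id"].astype(str)
                    .isin(outliers.excluded)]
            log.append(f"outliers: {len(outliers.flagged)} flagged, "
                       f"{len(outliers.excluded)} excluded -> {len(df)} "
                       "subjects")
        else:
            log.append(f"outliers: {len(outliers.flagged)} flagged, "
                       "0 excluded (include_outliers set)"
                       if cfg.include_outliers else
                       f"outliers: {len(outliers.flagged)} flagged, "
                       "none excluded")

        candidates = self.candidates
        if candidates is None:
            candidates = candidates_from_data(df)
        selection = select_covariates(
            candidates, cfg.effect_size_floor, cfg.correlation_ceiling,
            data=df)
        log.append(f"covariates: selected {selection.selected}")

        n_missing = int(df["moca_t6"].isna().sum())
        if cfg.itt and n_missing:
            predictors = [c for c in
                          ["moca_t0", *selection.selected, "age"]
                          if c in df.columns]
            df_grp = df.copy()
            df_grp["_group_code"] = (df_grp["group"] == "IG").astype(float)
            completed, em_info = impute_em(
                df_grp, "moca_t6", predictors + ["_group_code"])
            df = completed.drop(columns="_group_code")
            log.append(f"imputation: {em_info.n_imputed} follow-ups imputed "
                       f"by EM in {em_info.n_iter} iterations")
        else:
            em_info = EMInfo(0, True, 0.0, 0)
            if n_missing:
                df = df.dropna(subset=["moca_t6"])
                log.append(f"completers analysis: {n_missing} missing "
                           f"follow-ups dropped -> {len(df)} subjects")
            else:
                log.append("imputation: no missing follow-ups (no-op)")

        ancova = mixed_ancova(df, selection.selected)
        log.append("ANCOVA fitted: " + ", ".join(
            f"{r['term']} F = {r['F']:.2f}" for _, r in
            ancova.terms.iterrows() if r["term"] in ("T", "T x group")))

        transitions = transition_analysis(df, cfg.mci_cutoff)
        log.append(
            "transitions: IG {}/{} ({:.0%}), CG {}/{} ({:.0%}), "
            "chi2 = {:.2f}, p = {:.3f}".format(
                *transitions.counts["IG"], transitions.fractions["IG"],
                *transitions.counts["CG"], transitions.fractions["CG"],
                transitions.chi2, transitions.p))

        return TrialAnalysisResults(
            analysis_data=df, outliers=outliers, selection=selection,
            em_info=em_info, ancova=ancova, transitions=transitions,
            log=log, config=cfg)


@dataclass
class TrialAnalysisResults:
    """Everything the pipeline computed, with audit trails."""

    analysis_data: pd.DataFrame
    outliers: OutlierResult
    selection: CovariateSelection
    em_info: EMInfo
    ancova: MixedAncovaResults
    transitions: TransitionResult
    log: list[str]
    config: AnalysisConfig

    def summary(self) -> str:
        parts = ["Trial analysis report", "=" * 60, ""]
        parts += ["Pipeline log:"] + [f"  {line}" for line in self.log]
        parts += ["", "Outlier screen:"] + \
            [f"  {line}" for line in self.outliers.audit]
        parts += ["", "Covariate selection:"] + \
            [f"  {line}" for line in self.selection.audit]
        parts += ["", self.ancova.summary()]
        tr = self.transitions
        parts += ["", "MCI transition (follow-up above cutoff):",
                  f"  IG: {tr.counts['IG'][0]}/{tr.counts['IG'][1]} "
                  f"({tr.fractions['IG']:.0%})",
                  f"  CG: {tr.counts['CG'][0]}/{tr.counts['CG'][1]} "
                  f"({tr.fractions['CG']:.0%})",
                  f"  chi2 = {tr.chi2:.2f}, p = {tr.p:.3f}"]
        return "\n".join(parts)

    def to_frame(self) -> pd.DataFrame:
        """Machine-readable table of every reported statistic."""
        rows = []
        for _, r in self.ancova.terms.iterrows():
            rows.append(("ancova", r["term"], "F", r["F"]))
            rows.append(("ancova", r["term"], "p", r["p"]))
            rows.append(("ancova", r["term"], "partial_eta2",
                         r["partial_eta2"]))
        for _, r in self.ancova.emmeans.iterrows():
            rows.append(("emmeans", f"{r['group']}_{r['time']}", "emmean",
                         r["emmean"]))
            rows.append(("emmeans", f"{r['group']}_{r['time']}", "se",
                         r["se"]))
        for name, rep in self.selection.effects.items():
            rows.append(("baseline_effect", name, rep.kind, rep.value))
        for g in ("IG", "CG"):
            rows.append(("transition", g, "count", self.transitions.counts[g][0]))
            rows.append(("transition", g, "total", self.transitions.counts[g][1]))
        rows.append(("transition", "both", "chi2", self.transitions.chi2))
        rows.append(("transition", "both", "p", self.transitions.p))
        return pd.DataFrame(rows, columns=["section", "item", "statistic",
                                           "value"])
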