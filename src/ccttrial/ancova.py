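"""Two-occasion mixed-model ANCOVA (repeated-measures GLM with covariates).

The model is the classical repeated-measures general linear model for two
time points with a between-subject group factor and centred baseline
covariates, including every time-by-covariate and the time-by-group
interaction. With exactly two occasions the model decomposes exactly into
two orthogonal univariate GLMs:

* the *within* part — an OLS regression of the change score
  ``d_i = y_post - y_pre`` on the centred covariates and the group code —
  carries the time main effect (the intercept), every time x covariate
  term and the time x group term;
* the *between* part — the same regression for the subject mean
  ``m_i = (y_pre + y_post)/2`` — carries the group main effect.

Each reported term is a single-df Type-III F test; partial eta squared is
``SS_effect / (SS_effect + SS_error)``. Estimated marginal means per
group x time cell are evaluated at the covariate means, with standard
errors combining the between- and within-part covariances (orthogonal
under the model's equal-variance assumption).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import linalg, stats

from .effects import interpret_eta2

#: effect coding of the arms; IG - CG contrasts are +1 on this scale
GROUP_CODE = {"IG": 0.5, "CG": -0.5}


@dataclass
class _OLSPart:
    params: np.ndarray
    cov: np.ndarray
    rss: float
    df_resid: int
    xtx_inv: np.ndarray


def _fit_part(Z: np.ndarray, y: np.ndarray, names) -> _OLSPart:
    n, p = Z.shape
    rank = np.linalg.matrix_rank(Z)
    if rank < p:
        # name the aliased columns via pivoted QR
        _, R, piv = linalg.qr(Z, mode="economic", pivoting=True)
        diag = np.abs(np.diag(R))
        bad = [names[piv[i]] for i in range(len(diag))
               if diag[i] < 1e-8 * diag[0]] or [names[piv[rank]]]
        raise np.linalg.LinAlgError(
            f"singular design: aliased terms {bad}")
    xtx_inv = np.linalg.inv(Z.T @ Z)
    params = xtx_inv @ Z.T @ y
    resid = y - Z @ params
    rss = float(resid @ resid)
    df_resid = n - p
    if df_resid <= 0:
        raise ValueError("not enough observations for the model")
    cov = xtx_inv * (rss / df_resid)
    return _OLSPart(params, cov, rss, df_resid, xtx_inv)


class MixedAncova:
    """Two-occasion repeated-measures ANCOVA model.

    Parameters
    ----------
    data : DataFrame with one row per subject.
    covariates : baseline covariate column names (centred internally).
    pre, post : the two occasion columns (e.g. MoCA at t0 and t6).
    group : column with arm labels ``"IG"``/``"CG"``.
    """

    def __init__(self, data: pd.DataFrame, covariates=(), pre="moca_t0",
                 post="moca_t6", group="group"):
        self.data = data.reset_index(drop=True)
        self.covariates = list(covariates)
        self.pre, self.post, self.group = pre, post, group
        missing = [c for c in [pre, post, group, *self.covariates]
                   if c not in data.columns]
        if missing:
            raise KeyError(f"missing columns: {missing}")
        if self.data[[pre, post, *self.covariates]].isna().any().any():
            raise ValueError("model input contains missing values "
                             "(impute or drop first)")
        bad = set(self.data[group]) - set(GROUP_CODE)
        if bad:
            raise ValueError(f"unknown group labels: {sorted(bad)}")

    @classmethod
    def from_dataframe(cls, data, covariates=(), **kw) -> "MixedAncova":
        return cls(data, covariates, **kw)

    def fit(self) -> "MixedAncovaResults":
        df = self.data
        n = len(df)
        g = df[self.group].map(GROUP_CODE).to_numpy(float)
        C = df[self.covariates].to_numpy(float) if self.covariates \
            else np.empty((n, 0))
        cov_means = C.mean(axis=0) if C.size else np.empty(0)
        Cc = C - cov_means
        Z = np.column_stack([np.ones(n), Cc, g])
        names = ["const", *self.covariates, "group"]

        d = (df[self.post] - df[self.pre]).to_numpy(float)
        m = ((df[self.post] + df[self.pre]) / 2.0).to_numpy(float)
        within = _fit_part(Z, d, names)
        between = _fit_part(Z, m, names)

        term_labels = ["T"] + [f"T x {c}" for c in self.covariates] \
            + ["T x group"]
        rows = []
        mse = within.rss / within.df_resid
        for j, label in enumerate(term_labels):
            ss = within.params[j] ** 2 / within.xtx_inv[j, j]
            F = ss / mse
            p = float(stats.f.sf(F, 1, within.df_resid))
            eta2 = ss / (ss + within.rss)
            rows.append((label, F, p, eta2, interpret_eta2(eta2)))
        terms = pd.DataFrame(rows, columns=["term", "F", "p", "partial_eta2",
                                            "band"])

        # between-subject effects (group main effect and covariate slopes)
        brows = []
        bmse = between.rss / between.df_resid
        for j, label in enumerate(["const", *self.covariates, "group"]):
            ss = between.params[j] ** 2 / between.xtx_inv[j, j]
            F = ss / bmse
            brows.append((label, F,
                          float(stats.f.sf(F, 1, between.df_resid))))
        between_terms = pd.DataFrame(brows, columns=["term", "F", "p"])

        # estimated marginal means at covariate means
        emm_rows, chg_rows = [], []
        k = len(self.covariates)
        for label, code in GROUP_CODE.items():
            z = np.zeros(k + 2)
            z[0], z[-1] = 1.0, code
            mean_g = float(z @ between.params)
            chg_g = float(z @ within.params)
            var_m = float(z @ between.cov @ z)
            var_d = float(z @ within.cov @ z)
            for t, sgn in (("t0", -0.5), ("t6", 0.5)):
                emm_rows.append((label, t, mean_g + sgn * chg_g,
                                 np.sqrt(var_m + 0.25 * var_d)))
            se_c = np.sqrt(var_d)
            tq = stats.t.ppf(0.975, within.df_resid)
            pval = 2 * stats.t.sf(abs(chg_g) / se_c, within.df_resid)
            chg_rows.append((label, chg_g, se_c, chg_g - tq * se_c,
                             chg_g + tq * se_c, float(pval)))
        emmeans = pd.DataFrame(
            emm_rows, columns=["group", "time", "emmean", "se"])
        changes = pd.DataFrame(
            chg_rows,
            columns=["group", "change", "se", "ci_low", "ci_high", "p"])

        return MixedAncovaResults(
            model=self, n=n, terms=terms, between_terms=between_terms,
            emmeans=emmeans, changes=changes, cov_means=cov_means,
            df_resid=within.df_resid)


@dataclass
class MixedAncovaResults:
    """Fitted two-occasion ANCOVA: term tests, marginal means, changes."""

    model: MixedAncova
    n: int
    terms: pd.DataFrame
    between_terms: pd.DataFrame
    emmeans: pd.DataFrame
    changes: pd.DataFrame
    cov_means: np.ndarray
    df_resid: int

    def term(self, label: str) -> pd.Series:
        hit = self.terms[self.terms["term"] == label]
        if hit.empty:
            raise KeyError(f"unknown term {label!r}")
        return hit.iloc[0]

    def summary(self) -> str:
        lines = [
            "Mixed-model ANCOVA (two occasions)",
            f"n = {self.n}; within-part residual df = {self.df_resid}",
            "",
            "Within-subject effects (Type III, 1 df each)",
            f"{'term':<28}{'F':>8}{'p':>8}{'partial eta2':>14}  band",
        ]
        for _, r in self.terms.iterrows():
            lines.append(f"{r['term']:<28}{r['F']:>8.2f}{r['p']:>8.3f}"
                         f"{r['partial_eta2']:>14.3f}  {r['band']}")
        lines += ["", "Estimated marginal means (covariates at their means)"]
        for _, r in self.emmeans.iterrows():
            lines.append(f"  {r['group']} {r['time']}: "
                         f"{r['emmean']:.1f} (SE = {r['se']:.2f})")
        lines += ["", "Within-group change t0 -> t6"]
        for _, r in self.changes.iterrows():
            lines.append(
                f"  {r['group']}: {r['change']:+.1f} points "
                f"(95% CI [{r['ci_low']:.1f}, {r['ci_high']:.1f}], "
                f"p = {r['p']:.3f})")
        return "\n".join(lines)

    def plot_emmeans(self, ax=None):
        """Group x time profile plot of the estimated marginal means."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots(figsize=(5, 4))
        for grp, style in (("IG", "o-"), ("CG", "s--")):
            sub = self.emmeans[self.emmeans["group"] == grp]
            sub = sub.sort_values("time")
            ax.errorbar(sub["time"], sub["emmean"], yerr=sub["se"],
                        fmt=style, capsize=4, label=grp)
        ax.set_xlabel("time")
        ax.set_ylabel("estimated marginal mean")
        ax.legend()
        return ax


def mixed_ancova(records: pd.DataFrame, covariates=(), pre="moca_t0",
                 post="moca_t6", group="group") -> MixedAncovaResults:
    """Functional wrapper: fit the two-occasion ANCOVA on ``records``."""
    return MixedAncova(records, covariates, pre=pre, post=post,
                       group=group).fit()
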