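"""Effect sizes and contingency tests used throughout the trial reports.

Conventions follow the trial's analysis plan: Cohen's d from the pooled SD
of two independent groups, Cramér's V = sqrt(chi2/n) for 2x2 tables with
the Pearson chi-square computed without continuity correction, and the
small/medium/large interpretation bands 0.20/0.50/0.80 (d), 0.10/0.30/0.50
(V) and 0.010/0.059/0.138 (partial eta squared).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from scipy.stats import chi2 as chi2_dist

D_BANDS = (0.20, 0.50, 0.80)
V_BANDS = (0.10, 0.30, 0.50)
ETA2_BANDS = (0.010, 0.059, 0.138)


def _band(value: float, limits) -> str:
    v = abs(value)
    if v >= limits[2]:
        return "large"
    if v >= limits[1]:
        return "medium"
    if v >= limits[0]:
        return "small"
    return "negligible"


def interpret_d(d: float) -> str:
    return _band(d, D_BANDS)


def interpret_v(v: float) -> str:
    return _band(v, V_BANDS)


def interpret_eta2(e: float) -> str:
    return _band(e, ETA2_BANDS)


@dataclass(frozen=True)
class EffectSizeReport:
    """One variable's group-difference effect size with its band."""

    variable: str
    kind: str  # "cohen_d" | "cramers_v"
    value: float
    band: str


def cohen_d_independent(mean1, sd1, n1, mean2, sd2, n2) -> float:
    """Unsigned Cohen's d for two independent groups (pooled SD)."""
    if sd1 < 0 or sd2 < 0:
        raise ValueError("standard deviations must be >= 0")
    if n1 < 2 or n2 < 2:
        raise ValueError("each group needs n >= 2")
    pooled_var = ((n1 - 1) * sd1**2 + (n2 - 1) * sd2**2) / (n1 + n2 - 2)
    diff = abs(mean1 - mean2)
    if pooled_var == 0:
        if diff == 0:
            return 0.0
        raise ValueError("zero pooled SD with unequal means: d undefined")
    return diff / math.sqrt(pooled_var)


def chi_square_2x2(a, b, c, d) -> tuple[float, float]:
    """Pearson chi-square (1 df, no continuity correction) and its p value
    for the 2x2 table [[a, b], [c, d]]."""
    for cell in (a, b, c, d):
        if cell < 0 or int(cell) != cell:
            raise ValueError("cells must be nonnegative integers")
    n = a + b + c + d
    r1, r2, c1, c2 = a + b, c + d, a + c, b + d
    if n == 0 or 0 in (r1, r2, c1, c2):
        raise ValueError("empty margin: chi-square undefined")
    stat = n * (a * d - b * c) ** 2 / (r1 * r2 * c1 * c2)
    return float(stat), float(chi2_dist.sf(stat, df=1))


def cramers_v_2x2(a, b, c, d) -> float:
    """Cramér's V = sqrt(chi2 / n) for a 2x2 table."""
    stat, _ = chi_square_2x2(a, b, c, d)
    n = a + b + c + d
    return math.sqrt(stat / n)
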