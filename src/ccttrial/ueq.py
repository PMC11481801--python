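"""User Experience Questionnaire (UEQ) scoring and benchmarking.

26 semantic-differential items answered on a 1-7 scale are recoded to
[-3, +3] (half the items reverse-keyed) and averaged into six scales:
attractiveness (6 items), perspicuity, efficiency, dependability,
stimulation and novelty (4 items each). Perspicuity, efficiency and
dependability cluster into pragmatic quality; stimulation and novelty into
hedonic quality. Scale values are classified against a benchmark
distribution of software evaluations.

The item-to-scale assignment, the reverse-keyed set and the benchmark
thresholds are instrument configuration, shipped here as editable defaults
with the published structure (6/4/4/4/4/4 items, 13 reverse-keyed).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .effects import EffectSizeReport, cohen_d_independent, interpret_d

SCALES = ("attractiveness", "perspicuity", "efficiency", "dependability",
          "stimulation", "novelty")
PRAGMATIC = ("perspicuity", "efficiency", "dependability")
HEDONIC = ("stimulation", "novelty")


@dataclass(frozen=True)
class Item:
    """One questionnaire item: its scale and polarity."""

    number: int  # 1..26
    scale: str
    reversed: bool


#: default item map: published scale structure; the reverse-keyed set is an
#: editable convention (13 of 26 items)
DEFAULT_ITEM_MAP: tuple[Item, ...] = tuple(
    Item(n, s, r) for n, s, r in [
        (1, "attractiveness", True), (2, "perspicuity", False),
        (3, "novelty", False), (4, "perspicuity", True),
        (5, "stimulation", False), (6, "stimulation", True),
        (7, "stimulation", False), (8, "dependability", False),
        (9, "efficiency", False), (10, "novelty", True),
        (11, "dependability", True), (12, "attractiveness", False),
        (13, "perspicuity", False), (14, "attractiveness", True),
        (15, "novelty", False), (16, "attractiveness", False),
        (17, "dependability", False), (18, "stimulation", True),
        (19, "dependability", True), (20, "efficiency", True),
        (21, "perspicuity", True), (22, "efficiency", False),
        (23, "efficiency", True), (24, "attractiveness", True),
        (25, "attractiveness", False), (26, "novelty", True),
    ])


def validate_item_map(item_map=DEFAULT_ITEM_MAP) -> None:
    """Check the instrument structure: 26 items, scale sizes 6/4/4/4/4/4."""
    numbers = sorted(i.number for i in item_map)
    if numbers != list(range(1, 27)):
        raise ValueError("item map must cover items 1..26 exactly once")
    sizes = {s: sum(1 for i in item_map if i.scale == s) for s in SCALES}
    expected = {"attractiveness": 6, "perspicuity": 4, "efficiency": 4,
                "dependability": 4, "stimulation": 4, "novelty": 4}
    if sizes != expected:
        raise ValueError(f"scale sizes {sizes} != expected {expected}")


@dataclass
class UeqScales:
    """Six scale means in [-3, +3] plus the two quality clusters."""

    attractiveness: float
    perspicuity: float
    efficiency: float
    dependability: float
    stimulation: float
    novelty: float

    @property
    def pragmatic_quality(self) -> float:
        return float(np.mean([getattr(self, s) for s in PRAGMATIC]))

    @property
    def hedonic_quality(self) -> float:
        return float(np.mean([getattr(self, s) for s in HEDONIC]))

    def as_dict(self) -> dict[str, float]:
        return {s: getattr(self, s) for s in SCALES}


def recode(answer: float, reversed_: bool) -> float:
    """Map a 1-7 answer onto [-3, +3] respecting item polarity."""
    if not 1 <= answer <= 7:
        raise ValueError(f"answer {answer} outside 1..7")
    return (4 - answer) if reversed_ else (answer - 4)


def score_ueq(response, item_map=DEFAULT_ITEM_MAP,
              log: list | None = None) -> UeqScales:
    """Score one 26-item response into the six scale means.

    ``response`` maps item numbers (or ``item_<n>`` labels) to answers;
    missing items are tolerated per scale as long as at least half of the
    scale's items are answered, otherwise that scale is NaN (and logged).
    """
    validate_item_map(item_map)

    def get(n):
        for key in (f"item_{n}", n, str(n)):
            try:
                present = key in response
            except TypeError:
                present = False
            if present:
                v = response[key]
                return None if pd.isna(v) else float(v)
        return None

    values: dict[str, list[float]] = {s: [] for s in SCALES}
    sizes: dict[str, int] = {s: 0 for s in SCALES}
    for item in item_map:
        sizes[item.scale] += 1
        v = get(item.number)
        if v is None:
            continue
        values[item.scale].append(recode(v, item.reversed))
    out = {}
    for s in SCALES:
        if len(values[s]) * 2 >= sizes[s] and values[s]:
            out[s] = float(np.mean(values[s]))
        else:
            out[s] = float("nan")
            if log is not None:
                log.append(f"{s}: {len(values[s])}/{sizes[s]} items "
                           "answered; scale set to missing")
    return UeqScales(**out)


def score_table(responses: pd.DataFrame, item_map=DEFAULT_ITEM_MAP
                ) -> pd.DataFrame:
    """Score a table with one row per respondent (columns item_1..item_26)."""
    rows = []
    for _, row in responses.iterrows():
        scales = score_ueq(row, item_map)
        rows.append(scales.as_dict())
    out = pd.DataFrame(rows, index=responses.index)
    for col in ("participant_id", "group"):
        if col in responses.columns:
            out.insert(0, col, responses[col])
    return out


# ---------------------------------------------------------------------------
# Benchmark
# ---------------------------------------------------------------------------

CATEGORIES = ("excellent", "good", "above average", "below average", "poor")


@dataclass(frozen=True)
class BenchmarkTable:
    """Per-scale thresholds for excellent / good / above average / below
    average; anything at or below the last threshold is poor. Comparison
    is strict ("better than")."""

    thresholds: dict  # scale -> (excellent, good, above_avg, below_avg)

    def __post_init__(self):
        for scale, t in self.thresholds.items():
            if list(t) != sorted(t, reverse=True) or len(set(t)) != len(t):
                raise ValueError(
                    f"benchmark thresholds for {scale!r} must be strictly "
                    "decreasing")

    def classify(self, scale: str, value: float) -> str:
        t = self.thresholds[scale]
        for thr, cat in zip(t, CATEGORIES[:4]):
            if value > thr:
                return cat
        return "poor"


#: illustrative default thresholds on the [-3, +3] scale; real analyses
#: should load the benchmark distribution they compare against
DEFAULT_BENCHMARK = BenchmarkTable({
    "attractiveness": (1.75, 1.52, 1.17, 0.70),
    "perspicuity": (1.90, 1.56, 1.08, 0.64),
    "efficiency": (1.78, 1.47, 0.98, 0.54),
    "dependability": (1.65, 1.48, 1.14, 0.78),
    "stimulation": (1.55, 1.31, 0.99, 0.50),
    "novelty": (1.40, 1.05, 0.71, 0.30),
})


def classify_benchmark(scales: UeqScales,
                       benchmark: BenchmarkTable = DEFAULT_BENCHMARK
                       ) -> dict[str, str]:
    """Per-scale benchmark category (NaN scales map to 'missing')."""
    out = {}
    for s in SCALES:
        v = getattr(scales, s)
        out[s] = "missing" if np.isnan(v) else benchmark.classify(s, v)
    return out


def compare_groups(summaries: dict, n_ig: int, n_cg: int
                   ) -> list[EffectSizeReport]:
    """Cohen's d per scale from per-group (mean, sd) summaries.

    ``summaries`` maps scale -> ((ig_mean, ig_sd), (cg_mean, cg_sd)).
    """
    out = []
    for scale, ((m1, s1), (m2, s2)) in summaries.items():
        d = cohen_d_independent(m1, s1, n_ig, m2, s2, n_cg)
        out.append(EffectSizeReport(scale, "cohen_d", d, interpret_d(d)))
    return out
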