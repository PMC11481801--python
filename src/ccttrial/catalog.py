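"""Exercise catalogue.

Ten training tasks, each weighting the four trained cognitive functions
(information-processing speed, memory span, short-term memory, decision
complexity) differently; the basic comparator programme uses a fixed
subset of five tasks at the easiest level.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

FUNCTIONS = ("speed", "memory_span", "short_term_memory", "decision_complexity")


@dataclass(frozen=True)
class ExerciseSpec:
    """One training task: id, cognitive-function weighting, level count."""

    exercise_id: int
    name: str
    function_weights: tuple[float, float, float, float]
    n_levels: int = 9

    def __post_init__(self):
        w = np.asarray(self.function_weights, dtype=float)
        if w.shape != (4,) or (w < 0).any():
            raise ValueError("function_weights must be 4 nonnegative values")
        if abs(w.sum() - 1.0) > 1e-9:
            raise ValueError("function_weights must sum to 1")
        if self.n_levels < 2:
            raise ValueError("n_levels must be >= 2")

    @property
    def weights(self) -> np.ndarray:
        return np.asarray(self.function_weights, dtype=float)


def difficulty(level: int, n_levels: int = 9, spacing: float = 0.5) -> float:
    """Logit-scale difficulty of ``level``; strictly increasing in level.

    Centred so the middle level sits at 0, matching the reference-population
    midpoint of the standardised cognitive-status scale.
    """
    if not 1 <= level <= n_levels:
        raise ValueError(f"level {level} outside 1..{n_levels}")
    return spacing * (level - (n_levels + 1) / 2.0)


def default_catalog(n_levels: int = 9) -> list[ExerciseSpec]:
    """The ten-task adaptive catalogue."""
    rows = [
        (1, "symbol_sort", (0.70, 0.10, 0.10, 0.10)),
        (2, "digit_span", (0.10, 0.70, 0.10, 0.10)),
        (3, "pair_recall", (0.10, 0.10, 0.70, 0.10)),
        (4, "logic_grid", (0.10, 0.10, 0.10, 0.70)),
        (5, "speeded_span", (0.45, 0.45, 0.05, 0.05)),
        (6, "span_store", (0.05, 0.45, 0.45, 0.05)),
        (7, "store_reason", (0.05, 0.05, 0.45, 0.45)),
        (8, "speeded_reason", (0.45, 0.05, 0.05, 0.45)),
        (9, "multitask_mix", (0.25, 0.25, 0.25, 0.25)),
        (10, "speeded_store", (0.45, 0.05, 0.45, 0.05)),
    ]
    return [ExerciseSpec(i, nm, w, n_levels) for i, nm, w in rows]


#: exercises available in the basic (fixed-difficulty) comparator programme
DEFAULT_BASIC_IDS = (1, 2, 3, 4, 9)


def basic_catalog(catalog: list[ExerciseSpec] | None = None,
                  basic_ids=DEFAULT_BASIC_IDS) -> list[ExerciseSpec]:
    catalog = catalog if catalog is not None else default_catalog()
    by_id = {e.exercise_id: e for e in catalog}
    return [by_id[i] for i in basic_ids]
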