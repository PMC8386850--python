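"""Sample-size rule for choice-based conjoint studies.

The standard rule of thumb requires the number of times each analysis cell
is observed, n * t * a / c, to reach a threshold (500 by default), where n is
the number of respondents, t the tasks per questionnaire, a the alternatives
per task and c the number of cells — the largest level count of any single
attribute for a main-effects analysis, or the largest product of level
counts over attribute pairs when all two-way interactions are of interest.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from itertools import combinations

from .core import SpecError, StudySpec


@dataclass(frozen=True)
class PowerInputs:
    """Inputs of the conjoint sample-size rule."""

    tasks: int
    alternatives: int
    cells: int
    threshold: int = 500

    def __post_init__(self) -> None:
        for name in ("tasks", "alternatives", "cells", "threshold"):
            value = getattr(self, name)
            if not isinstance(value, int) or value < 1:
                raise SpecError(f"{name} must be a positive integer, got {value!r}")


def min_sample_size(
    tasks: int, alternatives: int, cells: int, threshold: int = 500
) -> int:
    """Smallest n with n * tasks * alternatives / cells >= threshold."""
    inputs = PowerInputs(tasks, alternatives, cells, threshold)
    return math.ceil(inputs.threshold * inputs.cells / (inputs.tasks * inputs.alternatives))


def main_effect_cells(spec: StudySpec) -> int:
    """Cell count for a main-effects analysis: the largest level count."""
    return max(spec.level_counts)


def interaction_cells(spec: StudySpec) -> int:
    """Cell count for two-way interactions: the largest product of level
    counts over any pair of attributes."""
    if len(spec.attributes) < 2:
        raise SpecError("interaction cells need at least two attributes")
    return max(a.n_levels * b.n_levels for a, b in combinations(spec.attributes, 2))
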