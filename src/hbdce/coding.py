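"""Effects coding of categorical attribute levels.

Each attribute with r levels is represented by r - 1 basis columns.  Level
j < r maps to the unit vector e_j; the reference level (by default the last
listed level) maps to a vector of -1s.  Summed over all levels of an
attribute the coded vectors cancel, which is what makes the expanded
part-worths zero-centred within each attribute.

In a partial-profile task an unshown attribute contributes a zero vector —
under effects coding this holds it at the attribute mean, the standard
partial-profile assumption.
"""

from __future__ import annotations

import json
from collections.abc import Mapping

import numpy as np
import pandas as pd

from .core import AttributeSpec, SpecError, StudySpec


def code_level(attribute: AttributeSpec, level: str, reference: str | None = None) -> np.ndarray:
    """Effects-coded vector (length r - 1) for one level of one attribute.

    ``reference`` names the level coded as all -1; default is the last
    listed level.
    """
    if reference is None:
        reference = attribute.levels[-1]
    if reference not in attribute.levels:
        raise SpecError(
            f"reference {reference!r} is not a level of {attribute.name!r}"
        )
    idx = attribute.level_index(level)
    basis = [lv for lv in attribute.levels if lv != reference]
    vec = np.zeros(attribute.n_levels - 1)
    if level == reference:
        vec[:] = -1.0
    else:
        vec[basis.index(level)] = 1.0
    return vec


class CodingMap:
    """Stacked effects coding for all attributes of a study.

    The stacked parameter vector has length P = sum_t (r_t - 1); column order
    follows attribute order, then level order within each attribute with the
    reference level dropped.  Column order is part of the public contract and
    can be exported with :meth:`to_dict` for audit.
    """

    def __init__(self, spec: StudySpec, reference_levels: Mapping[str, str] | None = None):
        self.spec = spec
        refs = dict(reference_levels or {})
        self.reference_levels: dict[str, str] = {}
        self.columns: list[tuple[str, str]] = []
        for attr in spec.attributes:
            ref = refs.pop(attr.name, attr.levels[-1])
            if ref not in attr.levels:
                raise SpecError(
                    f"reference {ref!r} is not a level of {attr.name!r}"
                )
            self.reference_levels[attr.name] = ref
            self.columns.extend(
                (attr.name, lv) for lv in attr.levels if lv != ref
            )
        if refs:
            raise SpecError(f"reference levels for unknown attributes {sorted(refs)}")
        self.column_index = {col: i for i, col in enumerate(self.columns)}
        #: all (attribute, level) pairs in study order, reference included
        self.level_rows: list[tuple[str, str]] = [
            (attr.name, lv) for attr in spec.attributes for lv in attr.levels
        ]
        self._expansion = self._build_expansion()

    @property
    def n_parameters(self) -> int:
        return len(self.columns)

    def _build_expansion(self) -> np.ndarray:
        """Matrix E (n_levels_total x P) with E @ beta = per-level utilities."""
        E = np.zeros((len(self.level_rows), self.n_parameters))
        for row, (attr_name, level) in enumerate(self.level_rows):
            attr = self.spec.attribute(attr_name)
            ref = self.reference_levels[attr_name]
            if level == ref:
                for lv in attr.levels:
                    if lv != ref:
                        E[row, self.column_index[(attr_name, lv)]] = -1.0
            else:
                E[row, self.column_index[(attr_name, level)]] = 1.0
        return E

    @property
    def expansion_matrix(self) -> np.ndarray:
        return self._expansion.copy()

    # -- encoding --------------------------------------------------------

    def code_level(self, attribute: str, level: str) -> np.ndarray:
        attr = self.spec.attribute(attribute)
        return code_level(attr, level, self.reference_levels[attribute])

    def code_alternative(self, shown_levels: Mapping[str, str]) -> np.ndarray:
        """Length-P design row for one alternative.

        Shown attributes place their coded vector at their columns; unshown
        attributes contribute zeros (held at the attribute mean).
        """
        row = np.zeros(self.n_parameters)
        for attr_name, level in shown_levels.items():
            attr = self.spec.attribute(attr_name)
            ref = self.reference_levels[attr_name]
            if level not in attr.levels:
                raise SpecError(
                    f"unknown level {level!r} for attribute {attr_name!r}"
                )
            if level == ref:
                for lv in attr.levels:
                    if lv != ref:
                        row[self.column_index[(attr_name, lv)]] = -1.0
            else:
                row[self.column_index[(attr_name, level)]] = 1.0
        return row

    # -- expansion -------------------------------------------------------

    def expand(self, beta: np.ndarray) -> pd.Series:
        """Per-level utilities for a part-worth vector.

        Non-reference levels read off their coefficient; the reference level
        of each attribute gets minus the sum of its attribute's coefficients,
        so utilities sum to zero within every attribute.
        """
        beta = np.asarray(beta, dtype=float)
        if beta.shape != (self.n_parameters,):
            raise SpecError(
                f"expected part-worth vector of length {self.n_parameters}, "
                f"got shape {beta.shape}"
            )
        values = self._expansion @ beta
        index = pd.MultiIndex.from_tuples(self.level_rows, names=["attribute", "level"])
        return pd.Series(values, index=index, name="utility")

    # -- export ----------------------------------------------------------

    def to_dict(self) -> dict:
        return {
            "reference_levels": dict(self.reference_levels),
            "columns": [list(c) for c in self.columns],
        }

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2)


def code_alternative(shown_levels: Mapping[str, str], coding: CodingMap) -> np.ndarray:
    return coding.code_alternative(shown_levels)


def expand_partworths(beta: np.ndarray, coding: CodingMap) -> pd.Series:
    return coding.expand(beta)
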