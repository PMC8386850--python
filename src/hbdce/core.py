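"""Core domain types for discrete choice experiment (DCE) studies.

A DCE study is described by a :class:`StudySpec`: a list of attributes, each
with at least two categorical levels, optional cross-attribute prohibitions
(level pairs that may never co-occur within one hypothetical alternative),
and the dimensions of the choice exercise (tasks per respondent, alternatives
per task, attributes shown per task, number of questionnaire versions).

Observed or simulated choices live in a :class:`ChoiceDataset`, a thin
validated wrapper around a long-format pandas DataFrame with one row per
respondent x task x alternative.  Respondent demographics are kept as a plain
DataFrame checked by :func:`validate_demographics`.
"""

from __future__ import annotations

import warnings
from collections.abc import Mapping
from dataclasses import dataclass, field

import pandas as pd


class SpecError(ValueError):
    """A study specification violates one of its structural invariants."""


class DataError(ValueError):
    """Choice or demographic data are inconsistent with the study design."""


class InfeasibleDesignError(RuntimeError):
    """No prohibition-respecting alternative exists for a task."""


#: columns every long-format choice table must carry besides the attributes
CHOICE_ID_COLUMNS = ("respondent_id", "version_id", "task", "alt", "chosen")

#: schema of the demographics table
DEMOGRAPHIC_COLUMNS = (
    "respondent_id",
    "gender",
    "age",
    "income",
    "travel_time",
    "language",
    "education",
)


@dataclass(frozen=True)
class AttributeSpec:
    """One attribute of a care model with its ordered categorical levels."""

    name: str
    levels: tuple[str, ...]
    shown_label: str | None = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "levels", tuple(self.levels))
        if not self.name:
            raise SpecError("attribute name must be a non-empty string")
        if len(self.levels) < 2:
            raise SpecError(
                f"attribute {self.name!r} needs at least two levels, "
                f"got {len(self.levels)}"
            )
        if len(set(self.levels)) != len(self.levels):
            raise SpecError(f"attribute {self.name!r} has duplicate level labels")

    @property
    def n_levels(self) -> int:
        return len(self.levels)

    def level_index(self, level: str) -> int:
        try:
            return self.levels.index(level)
        except ValueError:
            raise SpecError(
                f"unknown level {level!r} for attribute {self.name!r}"
            ) from None


@dataclass(frozen=True)
class Prohibition:
    """A forbidden pairing of two levels of different attributes.

    An alternative showing ``attribute_a`` at ``level_a`` may never also show
    ``attribute_b`` at ``level_b`` (e.g. medication refills at the facility
    combined with a home viral-load draw).
    """

    attribute_a: str
    level_a: str
    attribute_b: str
    level_b: str

    def forbids(self, shown_levels: Mapping[str, str]) -> bool:
        """Whether this prohibition rules out the given alternative."""
        return (
            shown_levels.get(self.attribute_a) == self.level_a
            and shown_levels.get(self.attribute_b) == self.level_b
        )


@dataclass(frozen=True)
class StudySpec:
    """Full description of a choice experiment's structure."""

    attributes: tuple[AttributeSpec, ...]
    prohibitions: tuple[Prohibition, ...] = ()
    n_tasks_per_respondent: int = 10
    n_alternatives: int = 3
    n_attributes_shown: int = 4
    n_versions: int = 12
    forced_choice: bool = True
    name: str = "study"

    def __post_init__(self) -> None:
        object.__setattr__(self, "attributes", tuple(self.attributes))
        object.__setattr__(self, "prohibitions", tuple(self.prohibitions))
        if not self.attributes:
            raise SpecError("a study needs at least one attribute")
        names = [a.name for a in self.attributes]
        if len(set(names)) != len(names):
            raise SpecError("attribute names must be unique within a study")
        if self.n_alternatives < 2:
            raise SpecError("n_alternatives must be at least 2")
        if not 1 <= self.n_attributes_shown <= len(self.attributes):
            raise SpecError(
                f"n_attributes_shown={self.n_attributes_shown} must lie in "
                f"[1, {len(self.attributes)}]"
            )
        if self.n_tasks_per_respondent < 1 or self.n_versions < 1:
            raise SpecError("task and version counts must be positive")
        for p in self.prohibitions:
            if p.attribute_a == p.attribute_b:
                raise SpecError(
                    f"prohibition must span two attributes, got {p.attribute_a!r} twice"
                )
            for attr_name, level in (
                (p.attribute_a, p.level_a),
                (p.attribute_b, p.level_b),
            ):
                attr = self._find(attr_name)
                if attr is None:
                    raise SpecError(
                        f"prohibition references unknown attribute {attr_name!r}"
                    )
                if level not in attr.levels:
                    raise SpecError(
                        f"prohibition references unknown level {level!r} "
                        f"of attribute {attr_name!r}"
                    )

    # -- lookups ---------------------------------------------------------

    def _find(self, name: str) -> AttributeSpec | None:
        for a in self.attributes:
            if a.name == name:
                return a
        return None

    def attribute(self, name: str) -> AttributeSpec:
        attr = self._find(name)
        if attr is None:
            raise SpecError(f"unknown attribute {name!r}")
        return attr

    @property
    def attribute_names(self) -> tuple[str, ...]:
        return tuple(a.name for a in self.attributes)

    @property
    def level_counts(self) -> tuple[int, ...]:
        return tuple(a.n_levels for a in self.attributes)

    @property
    def n_parameters(self) -> int:
        """Length of the effects-coded part-worth vector, sum of (r_t - 1)."""
        return sum(a.n_levels - 1 for a in self.attributes)

    # -- prohibition checks ----------------------------------------------

    def violations(self, shown_levels: Mapping[str, str]) -> list[Prohibition]:
        return [p for p in self.prohibitions if p.forbids(shown_levels)]

    def is_allowed(self, shown_levels: Mapping[str, str]) -> bool:
        return not self.violations(shown_levels)


@dataclass
class ChoiceDataset:
    """Long-format choice records validated against a :class:`StudySpec`.

    ``data`` has columns ``respondent_id, version_id, task, alt,
    <one column per attribute>, chosen``; attribute cells of unshown
    attributes are missing (NaN).  Task and alternative indices are 1-based.
    """

    data: pd.DataFrame
    spec: StudySpec
    demographics: pd.DataFrame | None = field(default=None)

    def __post_init__(self) -> None:
        self.validate()

    # -- validation ------------------------------------------------------

    def validate(self) -> None:
        df = self.data
        missing = [c for c in CHOICE_ID_COLUMNS if c not in df.columns]
        if missing:
            raise DataError(f"choice data missing required columns {missing}")
        for attr in self.spec.attributes:
            if attr.name not in df.columns:
                raise DataError(f"choice data missing attribute column {attr.name!r}")
            observed = set(df[attr.name].dropna().unique())
            unknown = observed - set(attr.levels)
            if unknown:
                raise DataError(
                    f"unknown levels {sorted(unknown)} in column {attr.name!r}"
                )
        if df.empty:
            return

        grouped = df.groupby(["respondent_id", "task"], sort=False)
        chosen_counts = grouped["chosen"].sum()
        if self.spec.forced_choice:
            bad = chosen_counts[chosen_counts != 1]
            if not bad.empty:
                rid, task = bad.index[0]
                raise DataError(
                    f"respondent {rid!r} task {task} has {int(bad.iloc[0])} chosen "
                    "alternatives; a forced-choice task needs exactly one"
                )
        # all alternatives of one task must show the same attribute subset
        attr_cols = list(self.spec.attribute_names)
        shown_mask = df[attr_cols].notna()
        for (rid, task), idx in grouped.groups.items():
            sub = shown_mask.loc[idx]
            if not (sub.nunique(dropna=False) == 1).all():
                raise DataError(
                    f"respondent {rid!r} task {task}: alternatives show "
                    "different attribute subsets"
                )
        if self.demographics is not None:
            validate_demographics(self.demographics)
            known = set(self.demographics["respondent_id"])
            orphans = set(df["respondent_id"]) - known
            if orphans:
                raise DataError(
                    f"respondents {sorted(orphans)[:5]} missing from demographics"
                )

    # -- summaries -------------------------------------------------------

    @property
    def respondent_ids(self) -> list:
        return list(pd.unique(self.data["respondent_id"]))

    @property
    def n_respondents(self) -> int:
        return len(self.respondent_ids)

    @property
    def n_records(self) -> int:
        return len(self.data)

    @property
    def n_choices(self) -> int:
        return int(self.data["chosen"].sum()) if not self.data.empty else 0


def empty_choice_frame(spec: StudySpec) -> pd.DataFrame:
    """An empty DataFrame with the long-format choice schema for ``spec``."""
    cols = list(CHOICE_ID_COLUMNS[:-1]) + list(spec.attribute_names) + ["chosen"]
    return pd.DataFrame(columns=cols)


def validate_demographics(df: pd.DataFrame) -> pd.DataFrame:
    """Check the demographics table schema and basic plausibility bounds."""
    missing = [c for c in DEMOGRAPHIC_COLUMNS if c not in df.columns]
    if missing:
        raise DataError(f"demographics missing required columns {missing}")
    if df["respondent_id"].duplicated().any():
        dup = df.loc[df["respondent_id"].duplicated(), "respondent_id"].iloc[0]
        raise DataError(f"duplicate respondent_id {dup!r} in demographics")
    if df.empty:
        return df
    if (df["age"] <= 0).any():
        raise DataError("age must be strictly positive")
    for col in ("income", "travel_time"):
        if (df[col] < 0).any():
            raise DataError(f"{col} must be non-negative")
    if df["gender"].isna().any():
        warnings.warn("demographics contain missing gender values", stacklevel=2)
    return df
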