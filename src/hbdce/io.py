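"""Readers and writers for every file format the pipeline touches.

Study specifications are YAML (or JSON, which YAML subsumes); choice data
and demographics are long-format CSV; reports can be rendered as a directory
of CSV tables (rounded to one decimal, the field's display convention) or a
single lossless JSON bundle; designs export to the same CSV schema as choice
data minus the respondent columns so they round-trip into the simulator.
"""

from __future__ import annotations

import json
import warnings
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .core import (
    CHOICE_ID_COLUMNS,
    AttributeSpec,
    ChoiceDataset,
    DataError,
    Prohibition,
    SpecError,
    StudySpec,
    empty_choice_frame,
    validate_demographics,
)
from .design import ChoiceDesign, DesignTask, designs_to_frame
from .report import PreferenceReport

# ---------------------------------------------------------------------------
# study specification


def read_study_spec(path) -> StudySpec:
    """Parse and validate a YAML/JSON study configuration.

    Layout::

        name: my-study
        design:
          tasks_per_respondent: 10
          alternatives_per_task: 3
          attributes_shown_per_task: 4
          questionnaire_versions: 12
          forced_choice: true
        attributes:
          - name: ...
            levels: [..., ...]
        prohibitions:
          - {attribute_a: ..., level_a: ..., attribute_b: ..., level_b: ...}
    """
    with open(path) as fh:
        payload = yaml.safe_load(fh)
    if not isinstance(payload, dict):
        raise SpecError(f"{path}: expected a mapping at the top level")
    raw_attrs = payload.get("attributes")
    if not raw_attrs:
        raise SpecError(f"{path}: missing required key 'attributes'")
    attributes = []
    for i, entry in enumerate(raw_attrs):
        if "name" not in entry:
            raise SpecError(f"{path}: attribute #{i + 1} is missing 'name'")
        if "levels" not in entry:
            raise SpecError(f"{path}: attribute {entry['name']!r} is missing 'levels'")
        attributes.append(
            AttributeSpec(
                name=str(entry["name"]),
                levels=tuple(str(lv) for lv in entry["levels"]),
                shown_label=entry.get("shown_label"),
            )
        )
    prohibitions = []
    for i, entry in enumerate(payload.get("prohibitions") or []):
        try:
            prohibitions.append(
                Prohibition(
                    attribute_a=str(entry["attribute_a"]),
                    level_a=str(entry["level_a"]),
                    attribute_b=str(entry["attribute_b"]),
                    level_b=str(entry["level_b"]),
                )
            )
        except KeyError as exc:
            raise SpecError(f"{path}: prohibition #{i + 1} is missing {exc}") from None
    design = payload.get("design") or {}
    return StudySpec(
        attributes=tuple(attributes),
        prohibitions=tuple(prohibitions),
        n_tasks_per_respondent=int(design.get("tasks_per_respondent", 10)),
        n_alternatives=int(design.get("alternatives_per_task", 3)),
        n_attributes_shown=int(
            design.get("attributes_shown_per_task", len(attributes))
        ),
        n_versions=int(design.get("questionnaire_versions", 1)),
        forced_choice=bool(design.get("forced_choice", True)),
        name=str(payload.get("name", "study")),
    )


def write_study_spec(spec: StudySpec, path) -> None:
    payload = {
        "name": spec.name,
        "design": {
            "tasks_per_respondent": spec.n_tasks_per_respondent,
            "alternatives_per_task": spec.n_alternatives,
            "attributes_shown_per_task": spec.n_attributes_shown,
            "questionnaire_versions": spec.n_versions,
            "forced_choice": spec.forced_choice,
        },
        "attributes": [
            {"name": a.name, "levels": list(a.levels)}
            | ({"shown_label": a.shown_label} if a.shown_label else {})
            for a in spec.attributes
        ],
        "prohibitions": [
            {
                "attribute_a": p.attribute_a,
                "level_a": p.level_a,
                "attribute_b": p.attribute_b,
                "level_b": p.level_b,
            }
            for p in spec.prohibitions
        ],
    }
    with open(path, "w") as fh:
        yaml.safe_dump(payload, fh, sort_keys=False)


# ---------------------------------------------------------------------------
# choice data and demographics


def read_choice_data(path, spec: StudySpec) -> ChoiceDataset:
    """Load long-format choice records; unshown attributes are empty cells."""
    try:
        df = pd.read_csv(path, dtype={"respondent_id": str})
    except pd.errors.EmptyDataError:
        warnings.warn(f"{path}: empty choice file, returning empty dataset", stacklevel=2)
        return ChoiceDataset(data=empty_choice_frame(spec), spec=spec)
    if df.empty:
        warnings.warn(f"{path}: no choice records, returning empty dataset", stacklevel=2)
        return ChoiceDataset(data=empty_choice_frame(spec), spec=spec)
    missing = [c for c in CHOICE_ID_COLUMNS if c not in df.columns]
    if missing:
        raise DataError(f"{path}: missing required columns {missing}")
    df["chosen"] = df["chosen"].astype(int)
    return ChoiceDataset(data=df, spec=spec)


def write_choice_data(dataset: ChoiceDataset, path) -> None:
    dataset.data.to_csv(path, index=False)


def read_demographics(path) -> pd.DataFrame:
    df = pd.read_csv(path, dtype={"respondent_id": str})
    return validate_demographics(df)


def write_demographics(df: pd.DataFrame, path) -> None:
    validate_demographics(df).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# designs


def write_designs(designs: list[ChoiceDesign], path, format: str = "csv") -> None:
    """Export questionnaire versions (CSV table or JSON)."""
    if format == "csv":
        designs_to_frame(designs).to_csv(path, index=False)
    elif format == "json":
        payload = [
            {
                "version_id": d.version_id,
                "seed": d.seed,
                "tasks": [
                    {"shown": list(t.shown), "alternatives": [dict(a) for a in t.alternatives]}
                    for t in d.tasks
                ],
            }
            for d in designs
        ]
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=2)
    else:
        raise ValueError(f"unknown design export format {format!r}")


def read_designs(path, spec: StudySpec) -> list[ChoiceDesign]:
    """Read back a CSV design export (the inverse of ``write_designs``)."""
    df = pd.read_csv(path)
    designs = []
    for vid, vdf in df.groupby("version", sort=True):
        tasks = []
        for _, tdf in vdf.groupby("task", sort=True):
            tdf = tdf.sort_values("alt")
            alts = []
            shown = None
            for _, row in tdf.iterrows():
                alt = {
                    a: row[a]
                    for a in spec.attribute_names
                    if a in row and pd.notna(row[a])
                }
                shown = tuple(alt)
                alts.append(alt)
            tasks.append(DesignTask(shown=shown, alternatives=tuple(alts)))
        designs.append(ChoiceDesign(version_id=int(vid), tasks=tuple(tasks), seed=-1))
    return designs


# ---------------------------------------------------------------------------
# reports

_ONE_DECIMAL_COLS = ("mean", "sd", "ci_low", "ci_high")


def _display_round(df: pd.DataFrame) -> pd.DataFrame:
    out = df.copy()
    for col in out.columns:
        if any(col.startswith(p) for p in _ONE_DECIMAL_COLS) or col.startswith(
            ("mean_", "summary_")
        ):
            out[col] = out[col].astype(float).round(1)
        elif col in ("statistic",):
            out[col] = out[col].astype(float).round(3)
        elif col in ("p_value",):
            out[col] = out[col].astype(float).round(4)
    return out


def write_report(report: PreferenceReport, path, format: str = "csv") -> None:
    """Render a report as CSV tables (rounded) or a lossless JSON bundle.

    CSV: ``path`` is a directory receiving ``utilities.csv``,
    ``importances.csv`` and, when present, ``contrasts.csv`` and
    ``demographics.csv``.  JSON: ``path`` is a single file that
    :func:`read_report` restores exactly.
    """
    path = Path(path)
    if format == "csv":
        path.mkdir(parents=True, exist_ok=True)
        _display_round(report.utilities.reset_index()).to_csv(
            path / "utilities.csv", index=False
        )
        _display_round(report.importances.reset_index()).to_csv(
            path / "importances.csv", index=False
        )
        if report.contrasts is not None:
            _display_round(report.contrasts.reset_index()).to_csv(
                path / "contrasts.csv", index=False
            )
        if report.demographics is not None:
            _display_round(report.demographics).to_csv(
                path / "demographics.csv", index=False
            )
    elif format == "json":
        path.parent.mkdir(parents=True, exist_ok=True)
        with open(path, "w") as fh:
            json.dump(report.to_json_dict(), fh, indent=2, default=_json_default)
    else:
        raise ValueError(f"unknown report format {format!r}")


def read_report(path) -> PreferenceReport:
    with open(path) as fh:
        return PreferenceReport.from_json_dict(json.load(fh))


def _json_default(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, (np.bool_,)):
        return bool(obj)
    raise TypeError(f"cannot serialize {type(obj)}")
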