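import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

import hbdce
from hbdce.coding import CodingMap

settings.register_profile("suite", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def kisumu_spec():
    return hbdce.kisumu_study()


@pytest.fixture(scope="session")
def kisumu_coding(kisumu_spec):
    return CodingMap(kisumu_spec)


@pytest.fixture(scope="session")
def kisumu_truth_config(kisumu_spec):
    return hbdce.kisumu_truth(kisumu_spec)


@pytest.fixture(scope="session")
def kisumu_cohort(kisumu_truth_config):
    """One default-size synthetic cohort shared across the suite."""
    return hbdce.simulate_cohort(kisumu_truth_config, seed=5)


@pytest.fixture
def toy_spec_2x2():
    """Two binary attributes, full profile, two alternatives, two tasks."""
    return hbdce.StudySpec(
        attributes=(
            hbdce.AttributeSpec("A", ("a1", "a2")),
            hbdce.AttributeSpec("B", ("b1", "b2")),
        ),
        n_tasks_per_respondent=2,
        n_alternatives=2,
        n_attributes_shown=2,
        n_versions=1,
    )


def make_choice_frame(spec, tasks_per_respondent, choices):
    """Build a long-format choice DataFrame from explicit task structures.

    ``tasks_per_respondent``: list of tasks, each a tuple of alternatives,
    each alternative a dict attribute -> level.  ``choices``: mapping
    respondent_id -> list of 1-based chosen alternative indices.
    """
    rows = []
    for rid, picks in choices.items():
        for t, (alts, pick) in enumerate(zip(tasks_per_respondent, picks), start=1):
            for a, alt in enumerate(alts, start=1):
                rec = {
                    "respondent_id": rid,
                    "version_id": 1,
                    "task": t,
                    "alt": a,
                    "chosen": int(a == pick),
                }
                rec.update(alt)
                rows.append(rec)
    df = pd.DataFrame(rows)
    for attr in spec.attribute_names:
        if attr not in df.columns:
            df[attr] = pd.NA
    cols = ["respondent_id", "version_id", "task", "alt", *spec.attribute_names, "chosen"]
    return df[cols]
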