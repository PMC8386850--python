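"""Built-in study configuration and simulation defaults.

`kisumu_study` is the differentiated-service-delivery choice experiment run
with clinically stable HIV patients in Kisumu, Kenya: seven attributes of a
care model (where and how often drugs are collected and clinical reviews
happen, who hands out drugs, what adherence support looks like, and when
refills can be picked up), ten partial-profile tasks of three alternatives.

`kisumu_truth` turns the study's published population-level preference
estimates into a simulation ground truth.  Reported utilities sit on an
arbitrary estimation scale; divided by 100 they land on a logit scale where
the strongest preferences flip roughly 70-90% of affected choices, which is
the realistic amount of choice determinism for this kind of survey.  The
between-gender contrasts reported for the significantly different levels are
used as the default gender shift.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

from .core import StudySpec
from .io import read_study_spec
from .simulate import TruthConfig

#: published cohort-level mean utilities (estimation scale, ~[-70, 70])
KISUMU_LEVEL_MEANS = {
    ("Location of ART refills", "Health facility"): 49.95,
    ("Location of ART refills", "Community meeting point"): -46.07,
    ("Location of ART refills", "Home"): -3.88,
    ("Frequency of ART refills", "Every month"): -49.53,
    ("Frequency of ART refills", "Every 3 months"): 15.89,
    ("Frequency of ART refills", "Every 6 months"): 33.63,
    ("Person providing ART refills", "Nurse"): -2.83,
    ("Person providing ART refills", "Lay health worker"): 5.87,
    ("Person providing ART refills", "Pharmacist"): 21.45,
    ("Person providing ART refills", "PLHIV peer"): -24.49,
    ("Adherence support", "No support"): -19.27,
    ("Adherence support", "Individual support"): 15.03,
    ("Adherence support", "Group support"): 4.23,
    ("Refill pickup time", "Weekday regular hours"): 16.31,
    ("Refill pickup time", "Weekday off hours"): -1.80,
    ("Refill pickup time", "Weekend"): -14.51,
    ("Location of clinical review", "Health facility"): 69.28,
    ("Location of clinical review", "Community meeting point"): -53.10,
    ("Location of clinical review", "Home"): -16.19,
    ("Frequency of clinical visits", "Every month"): -50.71,
    ("Frequency of clinical visits", "Every 3 months"): 7.38,
    ("Frequency of clinical visits", "Every 6 months"): 40.12,
    ("Frequency of clinical visits", "Every 12 months"): 3.21,
}

#: published across-respondent SDs of the same utilities
KISUMU_LEVEL_SDS = {
    ("Location of ART refills", "Health facility"): 64.26,
    ("Location of ART refills", "Community meeting point"): 51.05,
    ("Location of ART refills", "Home"): 54.15,
    ("Frequency of ART refills", "Every month"): 35.24,
    ("Frequency of ART refills", "Every 3 months"): 19.60,
    ("Frequency of ART refills", "Every 6 months"): 29.96,
    ("Person providing ART refills", "Nurse"): 20.81,
    ("Person providing ART refills", "Lay health worker"): 23.27,
    ("Person providing ART refills", "Pharmacist"): 22.39,
    ("Person providing ART refills", "PLHIV peer"): 23.40,
    ("Adherence support", "No support"): 23.15,
    ("Adherence support", "Individual support"): 22.19,
    ("Adherence support", "Group support"): 24.92,
    ("Refill pickup time", "Weekday regular hours"): 24.18,
    ("Refill pickup time", "Weekday off hours"): 23.90,
    ("Refill pickup time", "Weekend"): 20.93,
    ("Location of clinical review", "Health facility"): 58.30,
    ("Location of clinical review", "Community meeting point"): 44.93,
    ("Location of clinical review", "Home"): 59.71,
    ("Frequency of clinical visits", "Every month"): 31.58,
    ("Frequency of clinical visits", "Every 3 months"): 18.42,
    ("Frequency of clinical visits", "Every 6 months"): 33.95,
    ("Frequency of clinical visits", "Every 12 months"): 26.90,
}

#: women-minus-men contrasts (same scale) for the levels reported as
#: significantly different between genders; other attributes get no shift
KISUMU_GENDER_SHIFT = {
    ("Location of ART refills", "Health facility"): -17.1,
    ("Location of ART refills", "Community meeting point"): -17.1,
    ("Location of ART refills", "Home"): 34.3,
    ("Frequency of ART refills", "Every month"): 11.4,
    ("Frequency of ART refills", "Every 3 months"): -22.9,
    ("Frequency of ART refills", "Every 6 months"): 11.4,
    ("Person providing ART refills", "Nurse"): -14.0,
    ("Person providing ART refills", "Lay health worker"): 25.4,
    ("Person providing ART refills", "Pharmacist"): -5.6,
    ("Person providing ART refills", "PLHIV peer"): -5.6,
    ("Adherence support", "No support"): 19.4,
    ("Adherence support", "Individual support"): 19.4,
    ("Adherence support", "Group support"): -38.8,
    ("Frequency of clinical visits", "Every month"): 16.9,
    ("Frequency of clinical visits", "Every 3 months"): -1.2,
    ("Frequency of clinical visits", "Every 6 months"): 16.9,
    ("Frequency of clinical visits", "Every 12 months"): -32.5,
}

#: division applied to the published-scale numbers to land on the logit scale
UTILITY_SCALE = 100.0


def kisumu_study() -> StudySpec:
    """The packaged seven-attribute differentiated-care study specification."""
    path = resources.files("hbdce.data").joinpath("kisumu.yaml")
    with resources.as_file(path) as p:
        return read_study_spec(p)


def _series(mapping: dict) -> pd.Series:
    idx = pd.MultiIndex.from_tuples(mapping.keys(), names=["attribute", "level"])
    return pd.Series(list(mapping.values()), index=idx, dtype=float)


def kisumu_truth(
    spec: StudySpec | None = None,
    n_respondents: int = 104,
    with_gender_shift: bool = True,
) -> TruthConfig:
    """Simulation ground truth emulating the Kisumu cohort.

    Population mean part-worths and SDs are the published cohort estimates
    divided by ``UTILITY_SCALE``; the population covariance is diagonal (no
    correlations were reported).  The gender shift is applied centred, so the
    marginal population mean equals the published estimates independent of
    the gender mix.
    """
    spec = spec or kisumu_study()
    shift = _series(KISUMU_GENDER_SHIFT) / UTILITY_SCALE if with_gender_shift else None
    return TruthConfig(
        spec=spec,
        level_means=_series(KISUMU_LEVEL_MEANS) / UTILITY_SCALE,
        level_sds=_series(KISUMU_LEVEL_SDS) / UTILITY_SCALE,
        gender_shift=shift,
        n_respondents=n_respondents,
    )
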