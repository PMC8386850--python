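"""Synthetic respondent cohorts with the structure the estimator assumes.

The generator emulates a cohort of clinically stable HIV patients answering
a partial-profile choice questionnaire: demographics are drawn to match the
study population's marginals (gender split, age, skewed income and travel
time, survey language, education), per-respondent part-worth vectors come
from a multivariate normal population whose mean can differ by gender, and
choices follow the multinomial logit given each respondent's part-worths.

Because the data-generating process is exactly the model the estimator fits,
a fitted run on a default cohort is a parameter-recovery experiment: the
posterior population mean should reproduce the configured truth.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .coding import CodingMap
from .core import ChoiceDataset, DataError, SpecError, StudySpec
from .design import ChoiceDesign, generate_version_set
from .hb import choice_probabilities


@dataclass
class TruthConfig:
    """True population preference structure for a simulated cohort.

    ``level_means``, ``level_sds`` and ``gender_shift`` are indexed by
    (attribute, level) over all levels of the study; means and shift must be
    (or are recentred to be) zero-sum within each attribute, matching the
    effects-coded parameterization.  ``gender_shift`` is the women-minus-men
    difference in level utilities; it is applied centred at the expected
    female fraction, so ``level_means`` stays the marginal cohort mean
    regardless of the shift.
    """

    spec: StudySpec
    level_means: pd.Series
    level_sds: pd.Series
    gender_shift: pd.Series | None = None
    n_respondents: int = 104
    female_fraction: float = 0.625
    age_mean: float = 41.06
    age_sd: float = 10.89
    age_min: float = 18.0
    income_mean: float = 9161.0
    income_sd: float = 12966.0
    travel_mean: float = 48.08
    travel_sd: float = 44.9
    language_probs: dict = field(
        default_factory=lambda: {"English": 0.490, "Kiswahili": 0.115, "Dholuo": 0.394}
    )
    education_probs: dict = field(
        default_factory=lambda: {
            "None": 0.010,
            "Primary": 0.481,
            "Secondary": 0.394,
            "Univ/Postgrad": 0.115,
        }
    )

    def __post_init__(self) -> None:
        if self.n_respondents < 1:
            raise SpecError("cohort size must be at least 1")
        if not 0.0 <= self.female_fraction <= 1.0:
            raise SpecError("female_fraction must lie in [0, 1]")
        expected = pd.MultiIndex.from_tuples(
            [(a.name, lv) for a in self.spec.attributes for lv in a.levels],
            names=["attribute", "level"],
        )
        for name in ("level_means", "level_sds"):
            series = getattr(self, name)
            if not expected.equals(series.index):
                series = series.reindex(expected)
                if series.isna().any():
                    raise SpecError(f"{name} does not cover every (attribute, level)")
                setattr(self, name, series)
        if (self.level_sds < 0).any():
            raise SpecError("level_sds must be non-negative")
        self.level_means = _recenter(self.level_means)
        if self.gender_shift is None:
            self.gender_shift = pd.Series(0.0, index=expected)
        else:
            shift = self.gender_shift.reindex(expected).fillna(0.0)
            self.gender_shift = _recenter(shift)

    # -- effects-coded views --------------------------------------------

    def beta_mean(self, coding: CodingMap) -> np.ndarray:
        """Population mean part-worths in the stacked coefficient space."""
        return np.array([self.level_means[col] for col in coding.columns])

    def beta_shift(self, coding: CodingMap) -> np.ndarray:
        return np.array([self.gender_shift[col] for col in coding.columns])

    def beta_cov(self, coding: CodingMap) -> np.ndarray:
        """Diagonal population covariance from the per-level SDs."""
        sds = np.array([self.level_sds[col] for col in coding.columns])
        return np.diag(sds**2)


def _recenter(series: pd.Series) -> pd.Series:
    """Force zero-sum within each attribute (effects-coded identifiability)."""
    means = series.groupby(level="attribute", sort=False).transform("mean")
    return series - means


# ---------------------------------------------------------------------------
# demographics


def simulate_demographics(truth: TruthConfig, rng: np.random.Generator) -> pd.DataFrame:
    """Draw a demographics table whose marginals match the configuration.

    Ages are normal, floored at ``age_min`` (an adult cohort); income and
    travel time are lognormal with moments matched to the configured mean
    and SD, reproducing their right skew.
    """
    n = truth.n_respondents
    ids = [f"r{i:04d}" for i in range(1, n + 1)]
    gender = np.where(rng.random(n) < truth.female_fraction, "female", "male")
    age = np.maximum(rng.normal(truth.age_mean, truth.age_sd, size=n), truth.age_min)
    income = _lognormal_matched(truth.income_mean, truth.income_sd, n, rng)
    travel = _lognormal_matched(truth.travel_mean, truth.travel_sd, n, rng)
    lang_labels, lang_p = _normalized_probs(truth.language_probs, "language_probs")
    edu_labels, edu_p = _normalized_probs(truth.education_probs, "education_probs")
    return pd.DataFrame(
        {
            "respondent_id": ids,
            "gender": gender,
            "age": np.round(age, 1),
            "income": np.round(income, 0),
            "travel_time": np.round(travel, 1),
            "language": rng.choice(lang_labels, size=n, p=lang_p),
            "education": rng.choice(edu_labels, size=n, p=edu_p),
        }
    )


def _lognormal_matched(mean: float, sd: float, n: int, rng: np.random.Generator) -> np.ndarray:
    if mean <= 0:
        raise SpecError("lognormal mean must be positive")
    cv2 = (sd / mean) ** 2
    sigma2 = np.log1p(cv2)
    mu = np.log(mean) - sigma2 / 2
    return rng.lognormal(mu, np.sqrt(sigma2), size=n)


def _normalized_probs(probs: dict, name: str):
    labels = list(probs)
    p = np.asarray([probs[k] for k in labels], dtype=float)
    if (p < 0).any() or p.sum() <= 0:
        raise SpecError(f"{name} must be non-negative and sum to a positive value")
    return labels, p / p.sum()


# ---------------------------------------------------------------------------
# part-worths


def simulate_partworths(
    truth: TruthConfig,
    demographics: pd.DataFrame,
    rng: np.random.Generator,
    coding: CodingMap | None = None,
) -> pd.DataFrame:
    """Draw per-respondent part-worth vectors from the population model.

    beta_i ~ N(mu_g, V) where mu_g is the configured population mean shifted
    by the centred gender contrast (men: mean - f * shift; women: mean +
    (1 - f) * shift, f the expected female fraction).  Deterministic given
    the generator state.
    """
    coding = coding or CodingMap(truth.spec)
    mean = truth.beta_mean(coding)
    shift = truth.beta_shift(coding)
    V = truth.beta_cov(coding)
    f = truth.female_fraction
    n = len(demographics)
    is_female = (demographics["gender"] == "female").to_numpy()
    mu = np.where(
        is_female[:, None], mean + (1.0 - f) * shift, mean - f * shift
    )
    if np.allclose(V, 0.0):
        betas = mu.copy()
    else:
        try:
            chol = np.linalg.cholesky(V)
        except np.linalg.LinAlgError:
            raise SpecError("population covariance must be positive definite") from None
        betas = mu + rng.standard_normal((n, len(mean))) @ chol.T
    cols = pd.MultiIndex.from_tuples(coding.columns, names=["attribute", "level"])
    return pd.DataFrame(
        betas,
        index=pd.Index(demographics["respondent_id"].to_numpy(), name="respondent_id"),
        columns=cols,
    )


# ---------------------------------------------------------------------------
# choices


def simulate_choices(
    betas: pd.DataFrame,
    designs: list[ChoiceDesign],
    spec: StudySpec,
    rng: np.random.Generator,
    demographics: pd.DataFrame | None = None,
) -> ChoiceDataset:
    """Answer every task of each respondent's questionnaire by logit sampling.

    Respondents are randomly allocated to questionnaire versions; each task
    is answered by sampling one alternative from the respondent's choice
    probabilities (forced choice: exactly one chosen row per task).
    """
    if not designs:
        raise DataError("need at least one questionnaire version")
    coding = CodingMap(spec)
    version_ids = [d.version_id for d in designs]
    assignments = rng.integers(len(designs), size=len(betas))
    # pre-code every version once
    coded: dict[int, list[tuple[list[dict], np.ndarray]]] = {}
    for d in designs:
        tasks = []
        for task in d.tasks:
            rows = np.vstack([coding.code_alternative(alt) for alt in task.alternatives])
            tasks.append((list(task.alternatives), rows))
        coded[d.version_id] = tasks

    records = []
    for (rid, beta_row), which in zip(betas.iterrows(), assignments):
        beta = beta_row.to_numpy(dtype=float)
        vid = version_ids[which]
        for t, (alts, rows) in enumerate(coded[vid], start=1):
            probs = choice_probabilities(beta, rows)
            chosen = rng.choice(len(alts), p=probs)
            for a, alt in enumerate(alts, start=1):
                records.append(
                    {
                        "respondent_id": rid,
                        "version_id": vid,
                        "task": t,
                        "alt": a,
                        **alt,
                        "chosen": int(a - 1 == chosen),
                    }
                )
    df = pd.DataFrame(records)
    for attr in spec.attribute_names:
        if attr not in df.columns:
            df[attr] = pd.NA
    cols = ["respondent_id", "version_id", "task", "alt", *spec.attribute_names, "chosen"]
    return ChoiceDataset(data=df[cols], spec=spec, demographics=demographics)


# ---------------------------------------------------------------------------
# one-call cohort


@dataclass
class SyntheticCohort:
    """A complete simulated study: designs, demographics, truth and choices."""

    dataset: ChoiceDataset
    demographics: pd.DataFrame
    partworths: pd.DataFrame  # true per-respondent betas
    designs: list[ChoiceDesign]
    truth: TruthConfig


def simulate_cohort(
    truth: TruthConfig,
    seed: int = 0,
    designs: list[ChoiceDesign] | None = None,
    optimize_passes: int = 4,
) -> SyntheticCohort:
    """Generate designs, demographics, part-worths and choices from one seed.

    The master seed is split into independent streams for each stage, so
    e.g. enlarging the cohort leaves the designs unchanged.
    """
    ss = np.random.SeedSequence(seed)
    s_design, s_demo, s_beta, s_choice = ss.spawn(4)
    if designs is None:
        designs = generate_version_set(
            truth.spec,
            master_seed=int(s_design.generate_state(1)[0]),
            optimize_passes=optimize_passes,
        )
    demographics = simulate_demographics(truth, np.random.default_rng(s_demo))
    betas = simulate_partworths(truth, demographics, np.random.default_rng(s_beta))
    dataset = simulate_choices(
        betas, designs, truth.spec, np.random.default_rng(s_choice), demographics
    )
    return SyntheticCohort(
        dataset=dataset,
        demographics=demographics,
        partworths=betas,
        designs=designs,
        truth=truth,
    )
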