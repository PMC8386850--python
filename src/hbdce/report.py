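"""Turn part-worth draws into the standard conjoint deliverables.

* per-level average utilities with SDs and t-based 95% confidence intervals
  across respondents;
* per-attribute average importances (each respondent's utility range for an
  attribute divided by the sum of their ranges, averaged over respondents);
* zero-centred-diffs normalization of individual utilities, the de facto
  conjoint convention for comparing subgroups on a common scale;
* two-group subgroup contrasts of normalized level utilities with
  significance flags;
* demographic comparison tables (t / rank-sum for continuous variables,
  chi-square / exact for categorical ones).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .coding import CodingMap
from .core import DataError
from .hb import PartworthDraws


@dataclass
class PreferenceReport:
    """Bundle of summary tables produced from one fitted or simulated cohort."""

    utilities: pd.DataFrame  # index (attribute, level): mean, sd, ci_low, ci_high, n
    importances: pd.DataFrame  # index attribute: mean, sd, ci_low, ci_high, n
    contrasts: pd.DataFrame | None = None
    demographics: pd.DataFrame | None = None

    def to_json_dict(self) -> dict:
        out = {
            "utilities": self.utilities.reset_index().to_dict(orient="records"),
            "importances": self.importances.reset_index().to_dict(orient="records"),
        }
        if self.contrasts is not None:
            out["contrasts"] = self.contrasts.reset_index().to_dict(orient="records")
        if self.demographics is not None:
            out["demographics"] = self.demographics.to_dict(orient="records")
        return out

    @classmethod
    def from_json_dict(cls, payload: dict) -> "PreferenceReport":
        util = pd.DataFrame(payload["utilities"]).set_index(["attribute", "level"])
        imp = pd.DataFrame(payload["importances"]).set_index("attribute")
        contrasts = None
        if "contrasts" in payload:
            contrasts = pd.DataFrame(payload["contrasts"]).set_index(
                ["attribute", "level"]
            )
        demo = pd.DataFrame(payload["demographics"]) if "demographics" in payload else None
        return cls(utilities=util, importances=imp, contrasts=contrasts, demographics=demo)


# ---------------------------------------------------------------------------
# individual-level quantities


def individual_utilities(draws: PartworthDraws, coding: CodingMap) -> pd.DataFrame:
    """Expand each respondent's posterior-mean part-worths to level utilities.

    Rows are respondents; columns are all (attribute, level) pairs.  Within
    every attribute each respondent's utilities sum to zero (an exact
    property of effects coding, inherited by the expansion).
    """
    point = draws.betas.mean(axis=0)  # (n, P)
    if point.shape[1] != coding.n_parameters:
        raise DataError(
            f"draws have {point.shape[1]} parameters but the coding map has "
            f"{coding.n_parameters}"
        )
    values = point @ coding.expansion_matrix.T
    cols = pd.MultiIndex.from_tuples(coding.level_rows, names=["attribute", "level"])
    return pd.DataFrame(
        values, index=pd.Index(draws.respondent_ids, name="respondent_id"), columns=cols
    )


def t_confidence_interval(
    mean: float, sd: float, n: int, level: float = 0.95
) -> tuple[float, float]:
    """Classic t interval: mean +/- t(n-1, (1+level)/2) * sd / sqrt(n)."""
    if n < 2:
        return (float("nan"), float("nan"))
    half = stats.t.ppf(0.5 + level / 2, df=n - 1) * sd / np.sqrt(n)
    return (mean - half, mean + half)


def _summarize(frame: pd.DataFrame) -> pd.DataFrame:
    n = len(frame)
    mean = frame.mean(axis=0)
    sd = frame.std(axis=0, ddof=1) if n > 1 else pd.Series(np.nan, index=frame.columns)
    ci = [t_confidence_interval(m, s, n) for m, s in zip(mean, sd)]
    out = pd.DataFrame(
        {
            "mean": mean,
            "sd": sd,
            "ci_low": [c[0] for c in ci],
            "ci_high": [c[1] for c in ci],
            "n": n,
        }
    )
    return out


def average_utilities(indiv: pd.DataFrame) -> pd.DataFrame:
    """Across-respondent mean, SD and 95% t interval for every level."""
    if indiv.empty:
        raise DataError("no respondents to summarize")
    out = _summarize(indiv)
    out.index.names = ["attribute", "level"]
    return out


def importance_per_respondent(indiv: pd.DataFrame) -> pd.DataFrame:
    """Attribute importances (%) for each respondent.

    A respondent's importance of an attribute is its utility range (best
    minus worst level) divided by the sum of ranges over all attributes,
    times 100; the seven (in general K) values sum to 100 for everyone.
    Respondents with an all-zero utility profile have no defined importances
    and are dropped with a warning.
    """
    ranges = indiv.T.groupby(level="attribute", sort=False).agg(lambda c: c.max() - c.min()).T
    total = ranges.sum(axis=1)
    degenerate = total <= 0
    if degenerate.any():
        warnings.warn(
            f"{int(degenerate.sum())} respondent(s) with zero total utility range "
            "excluded from importances",
            stacklevel=2,
        )
        ranges = ranges.loc[~degenerate]
        total = total.loc[~degenerate]
    return 100.0 * ranges.div(total, axis=0)


def importances(indiv: pd.DataFrame) -> pd.DataFrame:
    """Average importances across respondents, with SD and 95% t interval."""
    per_resp = importance_per_respondent(indiv)
    if per_resp.empty:
        raise DataError("no respondents with defined importances")
    out = _summarize(per_resp)
    out.index.name = "attribute"
    return out.sort_values("mean", ascending=False)


def normalize_utilities(
    indiv: pd.DataFrame, scheme: str = "zero_centered_diffs"
) -> pd.DataFrame:
    """Rescale each respondent so their attribute ranges sum to 100 x K.

    Zero-centred diffs is the conjoint convention that makes utilities
    comparable across respondents and subgroups: within-attribute zero sums
    are preserved (the transform is a pure per-respondent rescaling), and a
    respondent whose ranges already sum to 100 x K is left unchanged.
    """
    if scheme != "zero_centered_diffs":
        raise ValueError(f"unknown normalization scheme {scheme!r}")
    n_attrs = indiv.columns.get_level_values("attribute").nunique()
    ranges = indiv.T.groupby(level="attribute", sort=False).agg(lambda c: c.max() - c.min()).T
    total = ranges.sum(axis=1)
    degenerate = total <= 0
    if degenerate.any():
        warnings.warn(
            f"{int(degenerate.sum())} respondent(s) with zero total utility range "
            "excluded from normalization",
            stacklevel=2,
        )
    keep = indiv.loc[~degenerate]
    factor = 100.0 * n_attrs / total.loc[~degenerate]
    return keep.mul(factor, axis=0)


# ---------------------------------------------------------------------------
# subgroup contrasts


def subgroup_contrast(
    indiv: pd.DataFrame,
    demographics: pd.DataFrame,
    group_var: str = "gender",
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Two-sample comparison of level utilities between two subgroups.

    For every attribute level, a Welch two-sample t test compares the two
    groups' individual utilities; a level is flagged significant at the given
    alpha.  Pass normalized utilities to compare subgroups on a common scale.
    """
    if group_var not in demographics.columns:
        raise DataError(f"demographics have no column {group_var!r}")
    groups = demographics.set_index("respondent_id")[group_var]
    merged_groups = groups.reindex(indiv.index)
    if merged_groups.isna().any():
        missing = list(indiv.index[merged_groups.isna()])[:5]
        raise DataError(f"respondents {missing} missing a {group_var!r} value")
    labels = sorted(merged_groups.unique())
    if len(labels) != 2:
        raise DataError(
            f"subgroup contrast needs exactly two groups, found {labels}"
        )
    ga, gb = labels
    a_frame = indiv.loc[merged_groups == ga]
    b_frame = indiv.loc[merged_groups == gb]
    rows = []
    for col in indiv.columns:
        xa, xb = a_frame[col].to_numpy(), b_frame[col].to_numpy()
        if len(xa) < 2 or len(xb) < 2:
            stat, p = np.nan, np.nan
        else:
            stat, p = stats.ttest_ind(xa, xb, equal_var=False)
        rows.append(
            {
                "attribute": col[0],
                "level": col[1],
                f"mean_{ga}": xa.mean() if len(xa) else np.nan,
                f"mean_{gb}": xb.mean() if len(xb) else np.nan,
                "statistic": stat,
                "p_value": p,
                "significant": bool(p < alpha) if np.isfinite(p) else False,
            }
        )
    return pd.DataFrame(rows).set_index(["attribute", "level"])


# ---------------------------------------------------------------------------
# demographic comparison tables


CONTINUOUS_VARS = ("age", "income", "travel_time")
CATEGORICAL_VARS = ("language", "education")
#: variables compared with a rank-sum test instead of a t test (skewed scales)
DEFAULT_RANK_VARS = ("income", "travel_time")


def _permutation_chi2(
    table: pd.DataFrame, values: pd.Series, groups: pd.Series, rng: np.random.Generator,
    n_permutations: int = 10_000,
) -> tuple[float, float]:
    """Monte-Carlo permutation test of independence for r x c tables.

    Used where expected counts are too small for the chi-square
    approximation and the table is larger than 2 x 2 (where no exact test is
    available in scipy): group labels are permuted, the chi-square statistic
    recomputed, and the p-value is the permutation tail probability.
    """
    obs_stat = stats.chi2_contingency(table, correction=False).statistic
    g = pd.Categorical(groups).codes
    v = pd.Categorical(values).codes
    count = 0
    for _ in range(n_permutations):
        perm = rng.permutation(g)
        t = np.zeros((v.max() + 1, g.max() + 1))
        np.add.at(t, (v, perm), 1)
        # chi2 statistic by hand; scipy object creation is the bottleneck here
        rowsum = t.sum(axis=1, keepdims=True)
        colsum = t.sum(axis=0, keepdims=True)
        expected = rowsum @ colsum / t.sum()
        with np.errstate(divide="ignore", invalid="ignore"):
            cells = np.where(expected > 0, (t - expected) ** 2 / expected, 0.0)
        if cells.sum() >= obs_stat - 1e-12:
            count += 1
    return float(obs_stat), (count + 1) / (n_permutations + 1)


def demographic_table(
    demographics: pd.DataFrame,
    group_var: str = "gender",
    continuous: tuple[str, ...] = CONTINUOUS_VARS,
    categorical: tuple[str, ...] = CATEGORICAL_VARS,
    rank_vars: tuple[str, ...] = DEFAULT_RANK_VARS,
    alpha: float = 0.05,
    seed: int = 0,
) -> pd.DataFrame:
    """Two-group comparison of demographic variables.

    Continuous variables use Student's t test, except those named in
    ``rank_vars`` (skewed money/time scales), which use the Wilcoxon rank-sum
    test; group summaries show means for t-tested and medians for rank-tested
    variables.  Categorical variables use the chi-square test of independence
    unless any expected cell count is below 5, in which case an exact test is
    used (Fisher for 2 x 2, a seeded permutation test otherwise).
    """
    if group_var not in demographics.columns:
        raise DataError(f"demographics have no column {group_var!r}")
    df = demographics.dropna(subset=[group_var])
    labels = sorted(df[group_var].unique())
    if len(labels) != 2:
        raise DataError(f"demographic table needs exactly two groups, found {labels}")
    ga, gb = labels
    sub_a = df[df[group_var] == ga]
    sub_b = df[df[group_var] == gb]
    rng = np.random.default_rng(seed)
    rows = []
    for var in continuous:
        xa = sub_a[var].dropna().to_numpy(dtype=float)
        xb = sub_b[var].dropna().to_numpy(dtype=float)
        if len(xa) == 0 or len(xb) == 0:
            rows.append(
                {"variable": var, "kind": "continuous", "test": "omitted (empty stratum)",
                 f"summary_{ga}": np.nan, f"summary_{gb}": np.nan,
                 "statistic": np.nan, "p_value": np.nan, "significant": False}
            )
            continue
        if var in rank_vars:
            stat, p = stats.ranksums(xa, xb)
            test = "wilcoxon_rank_sum"
            sa, sb = np.median(xa), np.median(xb)
        else:
            stat, p = stats.ttest_ind(xa, xb)
            test = "t"
            sa, sb = xa.mean(), xb.mean()
        rows.append(
            {"variable": var, "kind": "continuous", "test": test,
             f"summary_{ga}": sa, f"summary_{gb}": sb,
             "statistic": float(stat), "p_value": float(p),
             "significant": bool(p < alpha)}
        )
    for var in categorical:
        table = pd.crosstab(df[var], df[group_var])
        if table.empty or table.shape[1] < 2:
            rows.append(
                {"variable": var, "kind": "categorical", "test": "omitted (empty stratum)",
                 f"summary_{ga}": np.nan, f"summary_{gb}": np.nan,
                 "statistic": np.nan, "p_value": np.nan, "significant": False}
            )
            continue
        res = stats.chi2_contingency(table, correction=False)
        if (res.expected_freq < 5).any():
            if table.shape == (2, 2):
                stat, p = stats.fisher_exact(table)
                test = "fisher"
            else:
                stat, p = _permutation_chi2(table, df[var], df[group_var], rng)
                test = "permutation_chi2"
        else:
            stat, p = float(res.statistic), float(res.pvalue)
            test = "chi2"
        rows.append(
            {"variable": var, "kind": "categorical", "test": test,
             f"summary_{ga}": float(len(sub_a)), f"summary_{gb}": float(len(sub_b)),
             "statistic": float(stat), "p_value": float(p),
             "significant": bool(p < alpha)}
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# one-call report


def build_report(
    draws: PartworthDraws,
    coding: CodingMap,
    demographics: pd.DataFrame | None = None,
    group_var: str = "gender",
) -> PreferenceReport:
    """Assemble the full preference report from draws (deterministic)."""
    indiv = individual_utilities(draws, coding)
    util = average_utilities(indiv)
    imp = importances(indiv)
    contrasts = None
    demo = None
    if demographics is not None:
        normalized = normalize_utilities(indiv)
        contrasts = subgroup_contrast(normalized, demographics, group_var=group_var)
        demo = demographic_table(demographics, group_var=group_var)
    return PreferenceReport(
        utilities=util, importances=imp, contrasts=contrasts, demographics=demo
    )
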