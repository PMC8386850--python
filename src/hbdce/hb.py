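"""Hierarchical Bayesian multinomial logit estimation of part-worths.

The model has two levels.  At the upper level, respondent part-worth vectors
beta_i (length P, effects-coded) are draws from a multivariate normal
population, beta_i ~ N(alpha, V).  At the lower level each respondent is a
multinomial logit chooser: the utility of an alternative is the inner product
of its coded design row with beta_i, and the probability of choosing
alternative j in a task is softmax over the task's utilities.

Estimation is Metropolis-within-Gibbs MCMC:

* each beta_i moves by a random-walk Metropolis step whose proposal
  covariance is the current population covariance scaled by a per-respondent
  factor, adapted towards a target acceptance rate during burn-in and frozen
  afterwards;
* alpha is drawn from its exact normal full conditional (normal prior);
* V is drawn from its exact inverse-Wishart full conditional
  (inverse-Wishart prior).

Priors default to weakly informative choices standard in choice-based
conjoint work: alpha ~ N(0, 100 I), V ~ IW(P + 5, I).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import linalg
from scipy.stats import invwishart

from .coding import CodingMap
from .core import ChoiceDataset, DataError, SpecError, StudySpec


class ConvergenceWarning(UserWarning):
    """The sampler shows signs of poor mixing or non-convergence."""


# ---------------------------------------------------------------------------
# configuration


@dataclass
class HBPriors:
    """Priors for the population distribution of part-worths.

    ``mean_prior_cov`` and ``iw_scale`` accept either a scalar (times the
    identity) or a full matrix.  ``iw_df`` defaults to P + 5 once the
    parameter count is known.
    """

    mean_prior_mean: np.ndarray | float = 0.0
    mean_prior_cov: np.ndarray | float = 100.0
    iw_df: int | None = None
    iw_scale: np.ndarray | float = 1.0

    def resolve(self, n_parameters: int) -> "_ResolvedPriors":
        p = n_parameters
        mu0 = np.broadcast_to(np.atleast_1d(np.asarray(self.mean_prior_mean, float)), (p,)).copy()
        A0 = _as_cov(self.mean_prior_cov, p, "mean_prior_cov")
        df = self.iw_df if self.iw_df is not None else p + 5
        if df <= p - 1:
            raise SpecError(f"inverse-Wishart df must exceed P - 1 = {p - 1}, got {df}")
        S0 = _as_cov(self.iw_scale, p, "iw_scale")
        return _ResolvedPriors(mu0=mu0, A0=A0, iw_df=float(df), iw_scale=S0)


@dataclass
class _ResolvedPriors:
    mu0: np.ndarray
    A0: np.ndarray
    iw_df: float
    iw_scale: np.ndarray


def _as_cov(value, p: int, name: str) -> np.ndarray:
    arr = np.asarray(value, dtype=float)
    if arr.ndim == 0:
        if arr <= 0:
            raise SpecError(f"{name} scalar must be positive")
        return float(arr) * np.eye(p)
    if arr.shape != (p, p):
        raise SpecError(f"{name} must be scalar or ({p}, {p}), got {arr.shape}")
    if not np.allclose(arr, arr.T):
        raise SpecError(f"{name} must be symmetric")
    try:
        np.linalg.cholesky(arr)
    except np.linalg.LinAlgError:
        raise SpecError(f"{name} must be positive definite") from None
    return arr.copy()


@dataclass
class MCMCConfig:
    """Chain length and random-walk tuning knobs."""

    n_iterations: int = 20_000
    n_burnin: int = 10_000
    thinning: int = 10
    proposal_scale: float = 0.3
    target_acceptance: float = 0.30
    adapt_interval: int = 50
    adapt_step: float = 0.8
    scale_bounds: tuple[float, float] = (1e-3, 10.0)
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 <= self.n_burnin < self.n_iterations:
            raise SpecError("need 0 <= n_burnin < n_iterations")
        if self.thinning < 1:
            raise SpecError("thinning must be at least 1")
        if self.proposal_scale <= 0:
            raise SpecError("proposal_scale must be positive")
        if not 0 < self.target_acceptance < 1:
            raise SpecError("target_acceptance must lie in (0, 1)")


# ---------------------------------------------------------------------------
# likelihood primitives


def choice_probabilities(beta: np.ndarray, task_rows: np.ndarray) -> np.ndarray:
    """Softmax choice probabilities for one task.

    ``task_rows`` is (n_alternatives, P); utilities are task_rows @ beta.
    Probabilities are strictly positive and sum to one; adding a constant to
    every alternative's utility leaves them unchanged.
    """
    beta = np.asarray(beta, dtype=float)
    task_rows = np.atleast_2d(np.asarray(task_rows, dtype=float))
    u = task_rows @ beta
    if not np.all(np.isfinite(u)):
        raise DataError("non-finite utilities in choice task")
    u = u - u.max()
    e = np.exp(u)
    return e / e.sum()


def log_likelihood(beta: np.ndarray, respondent_records) -> float:
    """Multinomial-logit log likelihood of one respondent's choices.

    ``respondent_records`` is a sequence of ``(task_rows, chosen_index)``
    pairs.  Always non-positive.
    """
    records = list(respondent_records)
    if not records:
        raise DataError("respondent has no choice tasks")
    total = 0.0
    for task_rows, chosen in records:
        p = choice_probabilities(beta, task_rows)
        total += float(np.log(p[chosen]))
    return total


# ---------------------------------------------------------------------------
# Gibbs full conditionals


def gibbs_update_alpha(
    betas: np.ndarray,
    V: np.ndarray,
    priors: HBPriors | _ResolvedPriors,
    rng: np.random.Generator,
) -> np.ndarray:
    """Draw the population mean from its exact normal full conditional.

    With prior alpha ~ N(mu0, A0) and betas ~ iid N(alpha, V), the
    conditional is N(m, Lambda^-1) with Lambda = A0^-1 + n V^-1 and
    m = Lambda^-1 (A0^-1 mu0 + V^-1 sum_i beta_i).
    """
    betas = np.atleast_2d(np.asarray(betas, dtype=float))
    n, p = betas.shape
    pri = priors.resolve(p) if isinstance(priors, HBPriors) else priors
    try:
        Vinv = np.linalg.inv(V)
    except np.linalg.LinAlgError:
        raise SpecError("population covariance is singular") from None
    A0inv = np.linalg.inv(pri.A0)
    precision = A0inv + n * Vinv
    mean = np.linalg.solve(precision, A0inv @ pri.mu0 + Vinv @ betas.sum(axis=0))
    chol = np.linalg.cholesky(precision)
    z = rng.standard_normal(p)
    return mean + linalg.solve_triangular(chol.T, z, lower=False)


def gibbs_update_V(
    betas: np.ndarray,
    alpha: np.ndarray,
    priors: HBPriors | _ResolvedPriors,
    rng: np.random.Generator,
) -> np.ndarray:
    """Draw the population covariance from its inverse-Wishart conditional.

    Posterior: IW(df0 + n, S0 + sum_i (beta_i - alpha)(beta_i - alpha)').
    The conditional mode is (S0 + scatter) / (df0 + n + P + 1).
    """
    betas = np.atleast_2d(np.asarray(betas, dtype=float))
    n, p = betas.shape
    pri = priors.resolve(p) if isinstance(priors, HBPriors) else priors
    dev = betas - np.asarray(alpha, dtype=float)
    scatter = dev.T @ dev
    draw = invwishart.rvs(df=pri.iw_df + n, scale=pri.iw_scale + scatter, random_state=rng)
    draw = np.atleast_2d(draw)
    return 0.5 * (draw + draw.T)


def mh_update_beta(
    beta: np.ndarray,
    respondent_records,
    alpha: np.ndarray,
    V: np.ndarray,
    proposal_scale: float,
    rng: np.random.Generator,
) -> tuple[np.ndarray, bool]:
    """One random-walk Metropolis step for a single respondent.

    Target density is likelihood(beta) x N(beta; alpha, V); the proposal is
    beta + scale * chol(V) z with z standard normal, which is symmetric, so
    the acceptance ratio is the plain posterior-density ratio.
    """
    beta = np.asarray(beta, dtype=float)
    alpha = np.asarray(alpha, dtype=float)
    try:
        cholV = np.linalg.cholesky(V)
    except np.linalg.LinAlgError:
        raise SpecError("population covariance must be positive definite") from None
    Vinv = np.linalg.inv(V)

    def log_target(b: np.ndarray) -> float:
        d = b - alpha
        lp = -0.5 * float(d @ Vinv @ d)
        records = list(respondent_records)
        if records:
            lp += log_likelihood(b, records)
        return lp

    proposal = beta + proposal_scale * (cholV @ rng.standard_normal(beta.shape))
    log_ratio = log_target(proposal) - log_target(beta)
    if np.log(rng.random()) < log_ratio:
        return proposal, True
    return beta.copy(), False


# ---------------------------------------------------------------------------
# draws container


@dataclass
class PartworthDraws:
    """Thinned post-burn-in MCMC draws plus chain diagnostics."""

    alpha: np.ndarray  # (n_draws, P)
    cov: np.ndarray  # (n_draws, P, P)
    betas: np.ndarray  # (n_draws, n_respondents, P)
    respondent_ids: list
    columns: list[tuple[str, str]]  # (attribute, level) per parameter
    acceptance_rates: np.ndarray  # per respondent, post burn-in
    log_likelihood_trace: np.ndarray  # total data log likelihood per iteration
    config: MCMCConfig

    @property
    def n_draws(self) -> int:
        return self.alpha.shape[0]

    @property
    def n_parameters(self) -> int:
        return self.alpha.shape[1]

    def _index(self) -> pd.MultiIndex:
        return pd.MultiIndex.from_tuples(self.columns, names=["attribute", "level"])

    def posterior_mean_alpha(self) -> pd.Series:
        return pd.Series(self.alpha.mean(axis=0), index=self._index(), name="alpha")

    def posterior_mean_betas(self) -> pd.DataFrame:
        """Per-respondent posterior-mean part-worths (the point estimates
        downstream individual utilities are built from)."""
        return pd.DataFrame(
            self.betas.mean(axis=0), index=pd.Index(self.respondent_ids, name="respondent_id"),
            columns=self._index(),
        )

    def diagnostics(self) -> dict:
        """Acceptance-rate summary and effective sample sizes of alpha."""
        import arviz as az

        ess = az.ess(az.convert_to_dataset(self.alpha[np.newaxis, :, :])).x.values
        return {
            "n_draws": int(self.n_draws),
            "acceptance_rate_mean": float(self.acceptance_rates.mean()),
            "acceptance_rate_min": float(self.acceptance_rates.min()),
            "acceptance_rate_max": float(self.acceptance_rates.max()),
            "alpha_ess_min": float(np.min(ess)),
            "alpha_ess_median": float(np.median(ess)),
        }

    def save(self, path) -> None:
        np.savez_compressed(
            path,
            alpha=self.alpha,
            cov=self.cov,
            betas=self.betas,
            respondent_ids=np.asarray(self.respondent_ids, dtype=object),
            columns=np.asarray(self.columns, dtype=object),
            acceptance_rates=self.acceptance_rates,
            log_likelihood_trace=self.log_likelihood_trace,
        )

    @classmethod
    def load(cls, path, config: MCMCConfig | None = None) -> "PartworthDraws":
        with np.load(path, allow_pickle=True) as z:
            return cls(
                alpha=z["alpha"],
                cov=z["cov"],
                betas=z["betas"],
                respondent_ids=list(z["respondent_ids"]),
                columns=[tuple(c) for c in z["columns"]],
                acceptance_rates=z["acceptance_rates"],
                log_likelihood_trace=z["log_likelihood_trace"],
                config=config or MCMCConfig(),
            )


# ---------------------------------------------------------------------------
# panel assembly and the vectorized likelihood


def build_panel(dataset: ChoiceDataset, coding: CodingMap):
    """Pack a choice dataset into padded arrays for the sampler.

    Returns ``(ids, X, chosen, task_mask, alt_mask)`` where X is
    (n, T_max, A_max, P), ``chosen`` holds the 0-based index of the chosen
    alternative, and the masks flag real (non-padding) tasks/alternatives.
    """
    df = dataset.data
    if df.empty:
        raise DataError("cannot fit on an empty choice dataset")
    spec = dataset.spec
    attr_cols = list(spec.attribute_names)
    ids = list(pd.unique(df["respondent_id"]))
    per_resp: list[list[tuple[np.ndarray, int]]] = []
    for rid, rdf in df.groupby("respondent_id", sort=False):
        tasks = []
        for _, tdf in rdf.groupby("task", sort=True):
            tdf = tdf.sort_values("alt")
            rows = []
            chosen_idx = None
            for pos, (_, rec) in enumerate(tdf.iterrows()):
                shown = {
                    a: rec[a] for a in attr_cols if pd.notna(rec[a]) and rec[a] != ""
                }
                rows.append(coding.code_alternative(shown))
                if rec["chosen"]:
                    chosen_idx = pos
            if chosen_idx is None:
                raise DataError(f"respondent {rid!r} has a task with no chosen alternative")
            tasks.append((np.asarray(rows), chosen_idx))
        if not tasks:
            raise DataError(f"respondent {rid!r} has no tasks")
        per_resp.append(tasks)

    n = len(per_resp)
    T = max(len(tasks) for tasks in per_resp)
    A = max(rows.shape[0] for tasks in per_resp for rows, _ in tasks)
    P = coding.n_parameters
    X = np.zeros((n, T, A, P))
    chosen = np.zeros((n, T), dtype=int)
    task_mask = np.zeros((n, T), dtype=bool)
    alt_mask = np.zeros((n, T, A), dtype=bool)
    for i, tasks in enumerate(per_resp):
        for t, (rows, c) in enumerate(tasks):
            a = rows.shape[0]
            X[i, t, :a] = rows
            chosen[i, t] = c
            task_mask[i, t] = True
            alt_mask[i, t, :a] = True
    return ids, X, chosen, task_mask, alt_mask


def _panel_loglik(X, chosen, task_mask, alt_mask, betas) -> np.ndarray:
    """Total log likelihood per respondent, vectorized over the panel."""
    u = np.einsum("ntap,np->nta", X, betas)
    u = np.where(alt_mask, u, -np.inf)
    m = np.max(u, axis=-1, keepdims=True)
    lse = (m[..., 0] + np.log(np.sum(np.exp(u - m), axis=-1)))
    chosen_u = np.take_along_axis(u, chosen[..., np.newaxis], axis=-1)[..., 0]
    ll_task = np.where(task_mask, chosen_u - lse, 0.0)
    return ll_task.sum(axis=1)


# ---------------------------------------------------------------------------
# the full sampler


def fit_hb(
    dataset: ChoiceDataset,
    spec: StudySpec | None = None,
    priors: HBPriors | None = None,
    config: MCMCConfig | None = None,
    coding: CodingMap | None = None,
) -> PartworthDraws:
    """Fit the hierarchical Bayesian multinomial logit by MCMC.

    Per iteration: every respondent's beta_i takes one Metropolis step
    (vectorized across respondents), then alpha and V are drawn from their
    exact conditionals.  Proposal scales adapt only during burn-in.  The run
    is deterministic given ``config.seed``.
    """
    spec = spec or dataset.spec
    coding = coding or CodingMap(spec)
    priors = priors or HBPriors()
    config = config or MCMCConfig()
    pri = priors.resolve(coding.n_parameters)

    ids, X, chosen, task_mask, alt_mask = build_panel(dataset, coding)
    n, _, _, P = X.shape
    rng = np.random.default_rng(config.seed)

    A0inv = np.linalg.inv(pri.A0)
    betas = np.zeros((n, P))
    alpha = pri.mu0.copy()
    V = np.eye(P)
    scales = np.full(n, config.proposal_scale)
    lo, hi = config.scale_bounds

    n_draws = int(np.ceil((config.n_iterations - config.n_burnin) / config.thinning))
    draws_alpha = np.empty((n_draws, P))
    draws_V = np.empty((n_draws, P, P))
    draws_betas = np.empty((n_draws, n, P))
    ll_trace = np.empty(config.n_iterations)
    accept_post = np.zeros(n)
    n_post_iters = 0
    window_accepts = np.zeros(n)

    cholV = np.linalg.cholesky(V)
    Vinv = np.linalg.inv(V)
    ll_cur = _panel_loglik(X, chosen, task_mask, alt_mask, betas)
    d = 0
    for it in range(config.n_iterations):
        # Metropolis step for every respondent
        z = rng.standard_normal((n, P))
        prop = betas + scales[:, None] * (z @ cholV.T)
        ll_prop = _panel_loglik(X, chosen, task_mask, alt_mask, prop)
        dev_p = prop - alpha
        dev_c = betas - alpha
        quad_p = np.einsum("np,pq,nq->n", dev_p, Vinv, dev_p)
        quad_c = np.einsum("np,pq,nq->n", dev_c, Vinv, dev_c)
        log_ratio = (ll_prop - 0.5 * quad_p) - (ll_cur - 0.5 * quad_c)
        accept = np.log(rng.random(n)) < log_ratio
        betas[accept] = prop[accept]
        ll_cur[accept] = ll_prop[accept]
        window_accepts += accept
        if it >= config.n_burnin:
            accept_post += accept
            n_post_iters += 1

        # conjugate population updates
        precision = A0inv + n * Vinv
        mean = np.linalg.solve(precision, A0inv @ pri.mu0 + Vinv @ betas.sum(axis=0))
        cholP = np.linalg.cholesky(precision)
        alpha = mean + linalg.solve_triangular(
            cholP.T, rng.standard_normal(P), lower=False
        )
        dev = betas - alpha
        V = invwishart.rvs(
            df=pri.iw_df + n, scale=pri.iw_scale + dev.T @ dev, random_state=rng
        )
        V = 0.5 * (np.atleast_2d(V) + np.atleast_2d(V).T)
        cholV = np.linalg.cholesky(V)
        Vinv = np.linalg.inv(V)

        ll_trace[it] = ll_cur.sum()

        # proposal adaptation, burn-in only
        if it < config.n_burnin and (it + 1) % config.adapt_interval == 0:
            rates = window_accepts / config.adapt_interval
            scales = np.clip(
                scales * np.exp(config.adapt_step * (rates - config.target_acceptance)),
                lo,
                hi,
            )
            window_accepts[:] = 0.0

        if it >= config.n_burnin and (it - config.n_burnin) % config.thinning == 0:
            draws_alpha[d] = alpha
            draws_V[d] = V
            draws_betas[d] = betas
            d += 1

    draws = PartworthDraws(
        alpha=draws_alpha[:d],
        cov=draws_V[:d],
        betas=draws_betas[:d],
        respondent_ids=ids,
        columns=list(coding.columns),
        acceptance_rates=accept_post / max(n_post_iters, 1),
        log_likelihood_trace=ll_trace,
        config=config,
    )
    _warn_if_suspicious(draws)
    return draws


def _warn_if_suspicious(draws: PartworthDraws) -> None:
    """Flag poor mixing rather than letting it pass silently."""
    rate = draws.acceptance_rates.mean()
    if not 0.05 <= rate <= 0.75:
        warnings.warn(
            f"mean post-burn-in acceptance rate {rate:.2f} is outside [0.05, 0.75]; "
            "the chain may be poorly tuned",
            ConvergenceWarning,
            stacklevel=3,
        )
    half = draws.n_draws // 2
    if half >= 10:
        first, second = draws.alpha[:half], draws.alpha[half:]
        pooled_sd = draws.alpha.std(axis=0, ddof=1) + 1e-12
        shift = np.abs(first.mean(axis=0) - second.mean(axis=0)) / pooled_sd
        if np.any(shift > 1.0):
            worst = int(np.argmax(shift))
            warnings.warn(
                f"population mean component {worst} drifts between chain halves "
                f"({shift[worst]:.2f} posterior SDs); consider a longer burn-in",
                ConvergenceWarning,
                stacklevel=3,
            )
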