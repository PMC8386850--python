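# Methods

This note documents the statistical model, the algorithms, the defaults and
the known limitations of `hbdce`, in the spirit of a model-methods appendix.

## The choice model

A study is a set of attributes, each with ordered categorical levels
(`StudySpec`). Respondent $i$ facing task $t$ with alternatives $j$ chooses
according to a multinomial logit:

$$
P_i(j \mid t) = \frac{\exp(x_{jt}^\top \beta_i)}{\sum_k \exp(x_{kt}^\top \beta_i)},
$$

where $x_{jt}$ is the effects-coded design row and $\beta_i$ the
respondent's part-worth vector. At the population level,
$\beta_i \sim \mathcal N(\alpha, V)$. Two modelling conventions deserve
comment:

- **Effects coding.** Each attribute with $r$ levels occupies $r-1$
  columns; non-reference levels are unit indicators and the reference level
  (the last listed level, configurable) is coded $-1$ everywhere. Expanded
  level utilities therefore sum to zero within each attribute — exactly,
  for every respondent, every draw. This is the identifiability convention
  under which conjoint utilities are conventionally reported, and it is the
  reason reported utility rows such as (50.0, −46.1, −3.9) sum to zero.
- **Partial profiles.** A task shows only a subset of attributes (4 of 7 in
  the built-in study). Unshown attributes are coded as zero vectors, i.e.
  held at the attribute mean — the standard partial-profile assumption.
  Utility differences within a task are unaffected by unshown attributes,
  which is what makes this coding innocuous for the logit likelihood.

The choice probability is the softmax of utilities. A verbal description of
logit choice as "utility divided by the sum of utilities" circulates in the
applied literature; taken literally it is not scale-invariant and can go
negative, so this package implements the logit proper.

## Design generation

Commercial conjoint software produces "balanced and near-orthogonal"
randomized designs; the algorithm here reproduces that behaviour
transparently:

1. **Subset rotation.** The shown-attribute subsets of the tasks are chosen
   by always picking the attributes with the fewest appearances so far
   (random tie-breaks), so each attribute appears ⌊mT/K⌋ or ⌈mT/K⌉ times
   across the T tasks.
2. **Random start.** Each alternative samples one level per shown
   attribute uniformly, rejecting prohibited combinations and duplicate
   alternatives within a task (an alternative that cannot be sampled after
   2000 tries raises an infeasibility error naming the blocking
   prohibitions). Prohibition compliance is a hard constraint, never a
   penalty.
3. **Greedy improvement.** Single-cell level changes are accepted when they
   strictly reduce `balance_score + orthogonality_score`, where
   `balance_score` is the max-minus-min level frequency summed over
   attributes and `orthogonality_score` the max-minus-min co-occurrence
   count summed over attribute pairs (both zero iff perfect). Accepted
   moves additionally may not push either component above its value at the
   random start, so an optimized design is never worse than the random one
   on either criterion. The improver sweeps deterministically with a pass
   cap and stops at the first pass with no accepted move; optional random
   restarts guard against the occasional local minimum in tiny designs.

Pooled diagnostics over a version set are computed on per-version mean
frequencies so they are comparable to single-version scores. An optional
D-efficiency, $\det(X^\top X/n)^{1/P}$ on the effects-coded matrix, is
reported for reference; the optimizer does not target it.

## Estimation

`fit_hb` runs Metropolis-within-Gibbs MCMC. Per iteration, in order:

1. every $\beta_i$ takes one random-walk Metropolis step with proposal
   $\beta_i' = \beta_i + s_i\, L z$, $L L^\top = V$ (the *current*
   population covariance), $z$ standard normal — vectorized across
   respondents;
2. $\alpha$ is drawn from its exact normal full conditional
   ($\Lambda = A_0^{-1} + n V^{-1}$,
   $m = \Lambda^{-1}(A_0^{-1}\mu_0 + V^{-1}\sum_i \beta_i)$);
3. $V$ is drawn from its exact inverse-Wishart full conditional
   $\mathcal{IW}(\nu_0 + n,\; S_0 + \sum_i (\beta_i-\alpha)(\beta_i-\alpha)^\top)$.

Defaults: $\mu_0 = 0$, $A_0 = 100 I$ (diffuse on the logit scale, where
part-worths are order 0.1–1), $\nu_0 = P + 5$, $S_0 = I$ — weakly
informative settings standard in hierarchical choice modelling, all
configurable through `HBPriors`.

The per-respondent proposal scales $s_i$ start at 0.3 and adapt
multiplicatively every 50 iterations **during burn-in only** towards a 0.30
acceptance rate, then freeze, so the post-burn-in chain is a valid
time-homogeneous Markov chain. Default chain: 20 000 iterations, 10 000
burn-in, thinning 10 (1000 stored draws) — sized for a desk-scale problem
of ~100 respondents and P = 16. Everything is driven by one
`numpy.random.Generator`, so runs are bit-reproducible given the seed.
Non-convergence is surfaced, not swallowed: the fit warns when the mean
acceptance rate leaves [0.05, 0.75] or when the population-mean chain
drifts between halves by more than one posterior SD, and
`PartworthDraws.diagnostics()` reports acceptance rates and effective
sample sizes (via arviz).

**Validation.** The sampler is checked three independent ways in the test
suite: (a) each full-conditional update against its closed form; (b) the
whole sampler against a dense grid-evaluated posterior on a 2-parameter,
3-respondent problem in which the population covariance is pinned by a
tight inverse-Wishart prior and the population mean is marginalized by
quadrature — marginal means agree to well under 0.05 prior-SD units; (c) a
parameter-recovery experiment at the study's scale (next section).

Point estimates for downstream reporting are posterior means: of $\alpha$
for population part-worths and of each $\beta_i$ for individual utilities.

## Synthetic cohorts

The generator emulates the study population the pipeline is intended for:

- **Demographics** — 62.5% women; age normal (mean 41.06, SD 10.89,
  floored at 18); monthly income and one-way travel time lognormal with
  moments matched to mean 9161 / SD 12966 KSH and mean 48.1 / SD 44.9
  minutes (reproducing their right skew); survey language 49/11.5/39.4%
  English/Kiswahili/Dholuo; education 1/48/39/11.5%
  none/primary/secondary/university.
- **Part-worths** — the default population mean is the published cohort
  estimate divided by 100. That scaling is a modelling choice: reported
  conjoint utilities sit on an arbitrary scale, and /100 places them on a
  logit scale where the strongest preferences flip roughly 70–90% of the
  affected choices — realistic determinism for this kind of survey. The
  population covariance is diagonal with SDs equal to the published
  across-respondent SDs /100 (no correlations were reported; the diagonal
  is a declared default, not an inference).
- **Gender differences** — the default women-minus-men shift reproduces
  the published significant gender contrasts, recentred to zero-sum within
  each attribute. The shift is applied *centred at the expected gender
  mix*: men draw from mean $-f\,\delta$ and women from mean
  $+(1-f)\,\delta$ with $f = 0.625$, so the configured population mean is
  the marginal cohort mean regardless of the shift. This matters because
  the default mean is itself a population-level (gender-averaged) estimate;
  an uncentred shift would double-count it.
- **Choices** — respondents are randomly allocated to questionnaire
  versions and answer every task by sampling from their logit
  probabilities (forced choice, one chosen alternative per task). One
  master seed splits into independent streams for designs, demographics,
  part-worths and choices.

Because the generating process is exactly the fitted model, a fitted run on
a default cohort is a parameter-recovery experiment. At the default scale
(104 respondents × 10 tasks × 3 alternatives, default chain, ~15 s on one
core) the posterior population mean recovers the sign of every substantial
effect (|truth| ≥ 0.15) and the headline preference orderings
(facility > home > community for clinical review; 6 > 3 > 1 months for
refill spacing; individual > group > no adherence support). What passing
does **not** show: robustness to violations the generator omits —
attribute non-attendance, straight-lining, context effects, non-normal or
correlated heterogeneity — none of which are simulated.

## Reporting conventions

- **Average utilities** (per level): mean, across-respondent SD, and a 95%
  interval of the classic form $\bar u \pm t_{n-1,0.975}\, s/\sqrt n$ —
  the convention that reproduces the published interval (49.95 ± on
  SD 64.26, n 104 → (37.45, 62.45)). Intervals are across respondents, not
  across posterior draws.
- **Importances**: per respondent, each attribute's utility range divided
  by the sum of ranges, ×100 (sums to 100 per respondent); then averaged.
  Respondents with an all-zero profile have undefined importances and are
  excluded with a warning.
- **Normalization** for subgroup comparison: per-respondent zero-centred
  diffs — rescale so attribute ranges sum to 100 × (number of attributes)
  (700 here). A pure rescaling: zero sums and within-attribute orderings
  are preserved.
- **Subgroup contrasts**: Welch two-sample t tests per level on normalized
  individual utilities, flagged at p < 0.05. Exactly two groups are
  required; a group with fewer than two members yields no test.
- **Demographic tables**: Student's t for approximately symmetric
  variables (age), Wilcoxon rank-sum for skewed money/time scales (income,
  travel time) — a fixed documented rule rather than a data-driven
  normality test, to keep the table deterministic. Categorical variables
  use the chi-square test of independence unless an expected cell is below
  5, in which case a 2×2 table gets Fisher's exact test and a larger table
  a seeded Monte-Carlo permutation chi-square test (scipy has no r×c exact
  test; the permutation analogue mirrors simulated-p-value practice).

## Sample-size rule

`min_sample_size` returns the smallest integer n with
n·t·a/c ≥ threshold, i.e. ⌈threshold·c/(t·a)⌉. The cell count c is the
largest single-attribute level count for main effects and the largest
product of level counts over attribute pairs for two-way interactions
(`main_effect_cells` / `interaction_cells`). For the built-in design
(t = 10, a = 3): c = 4 → 67 respondents; c = 16 → 267. The rule is
monotone: non-increasing in t and a, non-decreasing in c and the
threshold.

## Numerical choices and degenerate inputs

- Log-sum-exp is max-stabilized everywhere; non-finite utilities raise.
- Drawn covariance matrices are symmetrized (`(V + Vᵀ)/2`) before
  factorization; singular or non-PD inputs raise informative errors.
- A zero population covariance in the simulator is honoured (all
  respondents at the group mean) rather than factorized.
- Ties in the design improver are not accepted (strict decrease only), so
  the improvement trace is strictly decreasing and terminates.
- Empty choice files yield an empty dataset with a warning; an empty
  dataset cannot be fitted.

## Known limitations

- **Individual-level shrinkage.** With 10 partial-profile tasks per
  respondent, each respondent contributes little likelihood information,
  so posterior means of $\beta_i$ are strongly shrunk towards $\alpha$.
  Population-level estimates are well identified, but subgroup contrasts
  computed from *fitted* individual utilities are heavily attenuated at
  this design size; detection power for gender differences is
  correspondingly low unless tasks per respondent (or the effect size)
  grow. The subgroup-power simulation therefore characterizes the contrast
  machinery at the cohort's true individual utilities.
- The reference level of each attribute inherits the summed variance of
  its attribute's coefficients under the diagonal-covariance default, so
  simulated heterogeneity at reference levels exceeds the published SDs.
- No interaction terms (the motivating design is not powered for them), no
  opt-out alternative, no willingness-to-pay conversion (no cost
  attribute), and no market-share simulator.
- Whether the 12 questionnaire versions share tasks is left open; the data
  model and generator permit either (set `n_versions` as desired).
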