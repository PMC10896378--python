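# Methods

This note documents the models, algorithms, parameter choices and known
limitations of `metalclique`. Everything quantitative stated here is
computed by the test suite or by `scripts/acceptance.py`.

## Cohort model and data contract

One row per participant. Exposures are 22 maternal blood concentrations
(µg/L): 11 metals (Pb, As, Cd, Cr, Zn, Se, Sb, Cu, Cs, Co, Mn) at two
trimesters (T2, T3), columns named `<metal>_<T2|T3>`. The outcome `tcdi` is
a t-scored depression inventory normalized to [0, 100]; all models use its
natural log (`log_tcdi`), so regression coefficients are approximately
proportional changes in the t-score. Covariates: child sex, 3-level
socioeconomic status (expanded to indicator contrasts), maternal age (y),
maternal BMI (kg/m²), child age at stool collection (y), sequencing batch.
`microbe_present` is a presence/absence flag; `pet` is a binary
negative-control outcome. Rows with missing outcome are dropped at read
time (the analysis sample is participants with complete outcome data).

Missing covariates (by design restricted to maternal age and child age,
each under 5%) are imputed by chained-equation predictive mean matching:
linear predictive fit on complete rows, match on predicted value, draw
uniformly among the `k = 5` nearest donors; 5 chain iterations, one
completed dataset carried forward (multiple-imputation pooling across m
datasets is out of scope because the discovery stage needs a single
rectangle). Imputed values are always members of the observed support.

## Synthetic cohort generator

The generator emulates the statistical structure the analysis assumes, not
any particular real dataset:

- **Exposures**: correlated log-normals via a Gaussian copula on the log
  scale; per-metal geometric means are typical maternal blood levels (e.g.
  Zn 5000 µg/L, Pb 35 µg/L, Co 0.3 µg/L), log-SD 0.5, exchangeable latent
  correlation ρ = 0.2 ("minimal" inter-metal correlation; configurable).
  Generation fails loudly if the supplied correlation is not PSD.
- **Covariates**: sex ~ Bernoulli(0.607), SES ~ (0.545, 0.366, 0.089),
  maternal age ~ N(28.7, 5.8²), BMI ~ N(27.3, 4.5²), child age ~
  N(9.7, 0.9²) (clipped to plausible ranges), batch ~ Bernoulli(73/123).
- **Microbe**: Bernoulli with logit linked to centered covariates (default
  mildly confounded: lower BMI and younger mothers more likely positive);
  the intercept is solved by root-finding so expected prevalence equals the
  configured 0.24.
- **Outcome**: log-scale linear model. Baseline log-normal parameters are
  chosen so that, under null effects, t-CDI has mean 53.0 and SD 8.1
  (`σ_log = sqrt(log(1 + (8.1/53)²)) ≈ 0.152`); centered covariate effects
  and the planted clique effects (`effect_in_absent`, `effect_in_present`,
  log-scale shifts applied to the clique indicator crossed with the microbe
  flag) add on top; the exponentiated score is capped at 100.
- **Negative control**: fair coin, independent of everything, so its true
  odds ratio against any clique is 1.
- **Missingness**: MCAR at 2% on maternal age and child age only.

What the generator does *not* emulate: measurement error and detection
limits in the assays, informative missingness, within-family correlation,
non-log-normal exposure tails, and any real metal-microbe dependence.
Passing recovery tests therefore demonstrate algorithmic correctness under
the assumed structure, not field performance on real cohorts.

## Descriptive statistics

Stratified summaries use Fisher's exact test for categoricals — 2×2 via the
conditional hypergeometric distribution, 2×k (k > 2) by exact enumeration of
all tables with the observed margins (Freeman–Halton), two-sided by summing
probabilities ≤ the observed table's (relative tolerance 1e-7 for ties) —
and the Wilcoxon rank-sum test for continuous variables (exact when both
groups ≤ 25 without ties, otherwise normal approximation with continuity
correction). Exposure correlations are Spearman by default (mid-ranks for
ties); Pearson is available, since both conventions appear in the field.

## Quantile convention

All sample percentiles use linear interpolation (the "type 7" convention).
This is load-bearing: clique membership is defined by strict `>` for `+`
members and `≤` for `-` members relative to these quantiles, and the
indicator is then invariant to strictly increasing transforms of each
exposure (a property the test suite asserts).

## rh-SiRF discovery engine

Defaults are the study-scale design: 500 holdouts at a 60/40 train/test
split, 250 bootstraps per holdout. Desk-scale studies in the tests use 100
holdouts × 50 bootstraps. Per holdout:

1. **Iterated forest** (3 iterations × 30 trees, depth ≤ 5, min leaf 8,
   mtry 4): split-candidate features are sampled with probability
   proportional to the previous iteration's impurity-decrease importances
   (iteration 1 uniform). The forest is implemented in numba because
   per-split weighted feature sampling is not expressible in scikit-learn's
   trees. Small mtry keeps the sampling weights, not within-node gain
   competition, in control of feature usage — the mechanism by which
   iterated reweighting concentrates the search.
2. **Predictivity gate**: a 100-tree forest grown from the final weights
   must achieve test-half R² > 0 (floor configurable); otherwise the holdout
   contributes nothing. The larger gate forest gives a lower-variance R²
   than the 30-tree iteration forests.
3. **Bootstrap + RIT**: on each bootstrap replicate of the training half, a
   10-tree weighted forest is grown; signed root-to-leaf paths (`+` = right
   branch, `-` = left; the last-encountered sign wins if a feature repeats)
   are read from leaves above the 0.75 count-weighted leaf-value quantile —
   the regression analogue of running RIT on positive-class leaves, and the
   "signed" part of the method: the search targets subgroups with *high*
   predicted outcome. Random Intersection Trees (150 trees, depth 2,
   branching 2) intersect weighted draws of these path sets; surviving
   intersections of order ≥ 2 are the bootstrap's signatures.
4. **Counting**: a signature counts for the holdout when found in ≥ 10% of
   its bootstraps. Stability = holdouts counted / total holdouts. Ranking
   is deterministic: stability, then mean weighted leaf-prevalence, then
   canonical signature string. Rows are processed in participant-id order,
   making results invariant to input row order.

The iterative reweighting is estimated once per holdout on the training
half and reused by all of that holdout's bootstrap forests (iterating inside
every bootstrap would multiply cost roughly tenfold without changing the
weights' information content). The public `extract_signed_paths` operation
keeps the plain contract — all leaves, count weights — while the engine's
high-leaf restriction is a configuration field (`leaf_value_quantile`).

The top-k (default 3) signatures of orders 2–3 form a network (nodes =
signed features, edges = within-signature pairs); a cycle through ≥ 3
distinct nodes marks a closed loop, and the union of the top signatures is
passed to threshold finding.

## Threshold finding

Exhaustive search over a percentile grid (default 5th–95th in steps of 5,
one percentile per member), keeping candidates whose subgroup prevalence
lies in [0.05, 0.95] (degenerate subgroups are uninformative at cohort
sizes near 112), and maximizing |t| of the indicator in the
covariate-adjusted model — computed for all candidates at once via
Frisch–Waugh–Lovell residualization. Ties break toward percentiles nearest
the 50th, then lexicographically. The |t| objective is the main
methodological free parameter of this stage: the underlying literature does
not pin down whether association strength, prediction, or another criterion
is optimized, so the choice is explicit and configurable.

Because the search maximizes over a grid, the |t| of the *returned* clique
is optimistically biased under the null (the selection effect the
repeated-holdout design addresses at the discovery stage); downstream
p-values for a clique found on the same data should be read as descriptive.

## Covariate balancing

Logistic propensity model of microbe presence on all covariates (fitted
probabilities at the 0/1 boundary are tolerated and clipped when they come
from sparse cells — mirroring standard practice — but widespread separation
raises an error). Participants are cut into 6 subclasses at propensity
quantiles; subclasses missing a group merge toward the median subclass
(logged). Weights follow marginal-mean-weighting-through-stratification,
`w = (n_s/N)·(N_g/n_{s,g})`, an ATE-style estimand that preserves each
group's total weight exactly. Standardized mean differences use the
unweighted pooled SD `sqrt((s₀² + s₁²)/2)` from the full sample as a fixed
denominator so before/after values share a scale; zero-SD covariates report
SMD 0 with a flag.

## Inference

Weighted least squares of log t-CDI on the clique indicator plus covariates,
overall and within microbe strata (each stratum uses its slice of the
balancing weights); the interaction model (clique × microbe product term) is
always reported alongside, and without covariates the stratum-effect
difference equals the interaction coefficient exactly (asserted to machine
precision). Randomization p-values permute the outcome only, keep design
and weights fixed, use |t| of the focal coefficient as the statistic, and
apply the add-one convention `p = (1 + #{|t*| ≥ |t|})/(1 + B)` so p is never
0; default B = 10⁴ in tests, 10⁶ available for full runs. Binarized-outcome
and negative-control analyses use (weighted) logistic regression on the
odds-ratio scale; quasi-separation raises with a suggestion to use a
penalized fallback rather than returning silently unstable estimates.

## Numerical choices

- Tree thresholds are midpoints of adjacent distinct values; constant
  outcomes yield zero importances and no splits.
- Feature-weight renormalization falls back to uniform when all importances
  are zero.
- Seeds: a single global seed fans out to per-stage seeds through
  `numpy.random.SeedSequence.spawn` with a fixed stage order, so every stage
  is independently reproducible; identical seeds give bitwise-identical
  synthetic cohorts.
- The permutation test vectorizes over permutation batches (chunks of
  2000) using a precomputed pseudoinverse.

## Validation and known limitations

The engine and estimators are validated by planted-truth simulation:

- At planted effect **1.0 SD** of the log outcome (n = 300, 100 holdouts ×
  50 bootstraps), a true 2-subset of the planted clique is the *top-1*
  stability record in every tested seed, and threshold search recovers all
  three planted percentiles within one grid step in 10/10 seeds (n = 500).
- At planted effect **0.5 SD**, top-3 recovery is *not identifiable*: an
  exhaustive max-|t| search over all signed thresholded pairs — an upper
  bound for any method that ranks patterns within one dataset — places a
  true pair in the top 3 in only about half of seeds, because the planted
  pair's |t| (~4) sits below the maximum over the ~7.5×10⁴ candidate noise
  patterns (~4.2–5.4). The acceptance studies report the honest recovery
  rate at these conditions rather than a tuned one.
- Similarly, at effect 0.6 SD the threshold grid search lands within one
  grid step on all three members in roughly half of seeds: the |t| surface
  is nearly flat within ±1–2 steps of the truth, so the argmax is decided
  by sampling noise. A "near-tie band" variant of the toward-the-median
  tie-break was evaluated and rejected (wider bands drag estimates toward
  the 50th percentile).

Other limitations: the discovery engine's bootstrap-counting rule,
predictivity floor and leaf-value quantile are explicit knobs with
documented defaults, not claims about any upstream implementation; weighted
logistic models use var_weights (estimating-equation style), so their CIs
are approximate under extreme weights; and the pipeline estimates
association and effect modification, not mediation.
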