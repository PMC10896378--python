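# metalclique

Signed exposure-clique discovery and effect-modification inference for
prenatal metal-exposure cohorts.

## The problem

Blood-metal mixtures during pregnancy may influence children's depressive
symptoms years later, but the relevant exposure pattern is often not a
single metal, nor the whole mixture — it is a *metal-clique*: a small,
signed, thresholded combination (e.g. zinc above its 20th sample percentile
in the 2nd trimester, cobalt below its 80th percentile in the 3rd, chromium
below its 55th in the 2nd) that defines a vulnerable subgroup of children.
This package implements the full analysis pipeline for discovering such
cliques in a wide cohort table, estimating their association with a
log-transformed t-scored depression outcome (log t-CDI), and testing whether
a binary gut-microbe presence flag (e.g. *Akkermansia muciniphila*) modifies
that association — plus a synthetic-cohort generator so every stage runs and
is testable without access to restricted cohort data.

## The method

The pipeline has three stages:

1. **Screening.** Covariate-adjusted linear models of log t-CDI on each of
   the 22 exposures (11 metals x 2 trimesters), with Benjamini–Hochberg FDR
   over the exposure family, and on microbe presence.

2. **Clique discovery (rh-SiRF)** — repeated-holdout signed iterated Random
   Forest. For each of `H` train/test holdouts (60/40 split):
   grow an importance-reweighted regression forest on the training half
   (iteration *k+1* samples split candidates with probability proportional
   to iteration *k*'s impurity-decrease importances); gate the holdout on
   test-half predictivity (R² > 0); then, on each of `B` bootstrap
   replicates, grow a small weighted forest, read **signed decision paths**
   off its high-outcome leaves (`+` = high side of a split, `-` = low side)
   and distill frequently co-occurring signed sets with **Random
   Intersection Trees**. A signature's **stability** is the fraction of
   holdouts in which it is discovered (in ≥10% of that holdout's
   bootstraps). The top signatures form a network whose closed loop
   identifies the clique.

3. **Binarization and inference.** The chosen signature's percentile
   thresholds are found by exhaustive grid search maximizing the |t| of the
   induced indicator in the covariate-adjusted model. Covariates are
   balanced across microbe strata by propensity-score subclassification
   (marginal-mean weighting through stratification), checked with love-plot
   standardized mean differences. Weighted regressions give the clique's
   overall and microbe-stratified associations with randomization p-values
   (*P*<sub>rand</sub>, outcome permutation), followed by sensitivity
   analyses: threshold perturbation (±10 percentiles), a binarized outcome
   (≥ 75th percentile, odds-ratio scale), the unbalanced microbe fit, and a
   negative-control outcome (pet ownership).

## Worked example

Simulate a 250-child cohort in which a planted three-component clique raises
the log outcome by 0.17 only in microbe-absent children, then run the whole
pipeline at a reduced holdout budget:

```bash
metalclique simulate --seed 7 --n 250 \
    --planted-clique "Zn_T2+@20 & Co_T3-@80 & Cr_T2-@55" \
    --effect-absent 0.17 --effect-present 0.0 --out cohort.tsv
metalclique run-all --seed 7 --outdir out/   # with rh_sirf reduced in the config
```

On this run the stability table's top three pairs include the true
`Cr_T2- & Zn_T2+` (stability 0.17), threshold search returns
`Cr_T2-@55 … Zn_T2+@20` (the planted percentiles) for the union signature,
and the inference stage prints:

```
overall          beta = 0.122  [0.081, 0.162]   P_rand = 1.0e-04  (prevalence 0.32)
microbe absent   beta = 0.153  [0.108, 0.199]   P_rand = 1.0e-04
microbe present  beta = 0.001  [-0.086, 0.088]  P_rand = 0.98
interaction      beta = -0.152 [-0.250, -0.053] P_rand = 0.0032
```

Read: children in the clique subgroup (32% of the sample) have a higher log
depression score overall; the association is concentrated entirely in the
microbe-absent stratum and vanishes when the microbe is present — the
planted effect modification, recovered end to end.

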