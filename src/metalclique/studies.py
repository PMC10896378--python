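"""Self-contained validation studies for the pipeline.

Each study regenerates its inputs from the synthetic-cohort generator (or
from printed summary counts), runs the relevant stage, and returns a scalar
metric.  They back both the acceptance test suite and the acceptance
script, so every reported number is recomputed from scratch at run time.
"""

from __future__ import annotations

import itertools

import numpy as np
import pandas as pd
from scipy import stats

from .balance import balance_cohort
from .binarize import find_thresholds
from .cliques import ThresholdedClique
from .cohort import fisher_exact, validate_cohort
from .discovery import RhSirfConfig, random_intersection_trees, rh_sirf
from .inference import negative_control, permutation_pvalue
from .screen import bh_fdr
from .synthetic import SynthConfig, generate_cohort

#: the three-component reference clique used across recovery studies
REFERENCE_CLIQUE = ThresholdedClique.parse("Zn_T2+@20 & Co_T3-@80 & Cr_T2-@55")

#: SD of the log outcome implied by the default t-score calibration
LOG_SD = float(np.sqrt(np.log1p((8.1 / 53.0) ** 2)))

#: Cohort summary counts by microbe stratum (absent, present):
#: sex (male, female), SES (lower, middle, higher), microbe totals
SEX_COUNTS = [[51, 34], [17, 10]]
SES_COUNTS = [[48, 29, 8], [13, 12, 2]]
MICROBE_COUNTS = (85, 27)


def table1_checks(seed: int = 0) -> dict:
    """Quantities recomputable from printed cohort summary counts.

    The analysis-sample size is exercised end to end: a 123-row synthetic
    cohort with 11 missing outcomes must validate down to 112 rows.
    """
    df = generate_cohort(SynthConfig(n_participants=123, seed=seed))
    raw = df.drop(columns="log_tcdi").copy()
    raw.loc[raw.index[:11], "tcdi"] = np.nan
    n_analysis = len(validate_cohort(raw))
    return {
        "fisher_sex_p": fisher_exact(SEX_COUNTS),
        "fisher_ses_p": fisher_exact(SES_COUNTS),
        "analysis_n": n_analysis,
        "microbe_prevalence_pct": 100.0 * MICROBE_COUNTS[1] / sum(MICROBE_COUNTS),
    }


def _planted_config(effect_sd: float, n: int, seed: int) -> SynthConfig:
    eff = effect_sd * LOG_SD
    return SynthConfig(
        n_participants=n, planted_clique=REFERENCE_CLIQUE,
        effect_in_absent=eff, effect_in_present=eff,
        missing_rate=0.0, seed=seed,
    )


def planted_clique_recovery_study(
    n_seeds: int = 20,
    effect_sd: float = 0.5,
    n: int = 300,
    seed: int = 0,
) -> dict:
    """Fraction of seeds in which the planted signature (or a 2-subset of
    it) ranks in the top-3 stability records under the reduced engine
    configuration (100 holdouts, 50 bootstraps)."""
    cfg = RhSirfConfig(n_holdouts=100, n_bootstraps=50)
    truth = {
        frozenset(map(str, pair))
        for r in (2, 3)
        for pair in itertools.combinations(REFERENCE_CLIQUE.signature.members, r)
    }
    rng = np.random.default_rng(seed)
    hits = 0
    for s in range(n_seeds):
        df = generate_cohort(
            _planted_config(effect_sd, n, int(rng.integers(2**31 - 1)))
        )
        recs = rh_sirf(df, cfg, seed=int(rng.integers(2**31 - 1)))
        top3 = {frozenset(map(str, r.signature.members)) for r in recs[:3]}
        hits += any(t in top3 for t in truth)
    return {"recovery_rate": hits / n_seeds, "n_seeds": n_seeds}


def threshold_recovery_study(
    n_seeds: int = 20,
    effect_sd: float = 0.6,
    n: int = 500,
    seed: int = 0,
) -> dict:
    """Fraction of seeds in which every recovered threshold lies within one
    grid step (5 percentiles) of the planted truth."""
    truth = {(sf.exposure, sf.sign): p for sf, p in REFERENCE_CLIQUE.members}
    rng = np.random.default_rng(seed)
    hits = 0
    for s in range(n_seeds):
        df = generate_cohort(
            _planted_config(effect_sd, n, int(rng.integers(2**31 - 1)))
        )
        out = find_thresholds(REFERENCE_CLIQUE.signature, df)
        hits += all(
            abs(p - truth[(sf.exposure, sf.sign)]) <= 5.0
            for sf, p in out.members
        )
    return {"recovery_rate": hits / n_seeds, "n_seeds": n_seeds}


def rit_enumeration_agreement(n_seeds: int = 2000, seed: int = 0) -> dict:
    """|MC frequency - exact enumeration| for RIT on a small weighted fixture.

    With depth 1 and a single child, each intersection tree intersects two
    weighted draws, so the survival probability of a target set is an exact
    sum over ordered pairs.
    """
    from .cliques import CliqueSignature, SignedFeature

    sf = lambda s: SignedFeature(s[:-1], s[-1])
    family = [
        frozenset({sf("A+"), sf("B+")}),
        frozenset({sf("A+"), sf("B+"), sf("C-")}),
        frozenset({sf("A+"), sf("D+")}),
        frozenset({sf("B+"), sf("C-")}),
    ]
    weights = [4.0, 3.0, 2.0, 1.0]
    target = frozenset({sf("A+"), sf("B+")})
    probs = np.asarray(weights) / sum(weights)
    exact = sum(
        probs[i] * probs[j]
        for i, j in itertools.product(range(len(family)), repeat=2)
        if family[i] & family[j] == target
    )
    rng = np.random.default_rng(seed)
    sets = list(zip(family, weights))
    hits = sum(
        CliqueSignature(target) in random_intersection_trees(
            sets, depth=1, n_children=1, n_trees=1,
            seed=int(rng.integers(2**31 - 1)),
        )
        for _ in range(n_seeds)
    )
    return {
        "abs_error": abs(hits / n_seeds - float(exact)),
        "n_seeds": n_seeds,
    }


def permutation_exhaustive_agreement(seed: int = 0) -> dict:
    """|Monte-Carlo p_rand - exhaustive p| at n=6 (all 720 permutations)."""
    rng = np.random.default_rng(seed)
    x = rng.binomial(1, 0.5, 6).astype(float)
    while len(np.unique(x)) < 2:
        x = rng.binomial(1, 0.5, 6).astype(float)
    y = rng.normal(size=6)
    X = np.column_stack([np.ones(6), x])

    pinv = np.linalg.pinv(X)
    xtx_jj = float((pinv @ pinv.T)[1, 1])

    def tval(yv):
        beta = pinv @ yv
        resid = yv - X @ beta
        sigma2 = (resid**2).sum() / (6 - 2)
        return abs(beta[1]) / np.sqrt(sigma2 * xtx_jj)

    t_obs = tval(y)
    count = sum(
        tval(np.asarray(p)) >= t_obs - 1e-12
        for p in itertools.permutations(y)
    )
    exact = count / 720
    mc = permutation_pvalue(
        y, X, focal=1, n_permutations=100_000,
        seed=int(rng.integers(2**31 - 1)),
    )
    return {"abs_error": abs(mc - exact), "n_permutations": 100_000}


def null_permutation_uniformity(
    n_seeds: int = 200, n: int = 50, n_permutations: int = 199, seed: int = 0
) -> dict:
    """KS p-value of null permutation p-values against Uniform(0, 1)."""
    rng = np.random.default_rng(seed)
    pvals = []
    for _ in range(n_seeds):
        x = rng.normal(size=n)
        y = rng.normal(size=n)
        X = np.column_stack([np.ones(n), x])
        pvals.append(permutation_pvalue(
            y, X, focal=1, n_permutations=n_permutations,
            seed=int(rng.integers(2**31 - 1)),
        ))
    ks = stats.kstest(pvals, "uniform")
    return {"ks_pvalue": float(ks.pvalue), "n_seeds": n_seeds}


def smd_reduction_study(n_seeds: int = 50, n: int = 300, seed: int = 0) -> dict:
    """Fraction of confounded cohorts in which subclassification strictly
    reduces the mean absolute standardized mean difference."""
    rng = np.random.default_rng(seed)
    reduced = 0
    for _ in range(n_seeds):
        cfg = SynthConfig(
            n_participants=n, missing_rate=0.0,
            seed=int(rng.integers(2**31 - 1)),
            microbe_covariate_link={
                "maternal_bmi": -0.15, "maternal_age": -0.12,
            },
        )
        df = generate_cohort(cfg)
        res = balance_cohort(df)
        reduced += res.smd_after.abs().mean() < res.smd_before.abs().mean()
    return {"reduction_fraction": reduced / n_seeds, "n_seeds": n_seeds}


def bh_fdr_brute_force_check(n_vectors: int = 50, seed: int = 0) -> dict:
    """Max |BH step-up - brute-force definition| over random p-vectors."""
    rng = np.random.default_rng(seed)
    worst = 0.0
    for _ in range(n_vectors):
        p = rng.uniform(size=int(rng.integers(2, 50)))
        n = len(p)
        order = np.argsort(p)
        ranks = np.empty(n, dtype=int)
        ranks[order] = np.arange(1, n + 1)
        brute = np.array([
            min(
                min(p[j] * n / ranks[j] for j in range(n)
                    if ranks[j] >= ranks[i]),
                1.0,
            )
            for i in range(n)
        ])
        worst = max(worst, float(np.abs(bh_fdr(p) - brute).max()))
    return {"max_abs_diff": worst, "n_vectors": n_vectors}


def negative_control_coverage(
    n_seeds: int = 200, n: int = 112, seed: int = 0
) -> dict:
    """Coverage of 1 by the negative-control odds-ratio CI on null cohorts."""
    rng = np.random.default_rng(seed)
    covered = 0
    for _ in range(n_seeds):
        cfg = SynthConfig(
            n_participants=n, planted_clique=REFERENCE_CLIQUE,
            missing_rate=0.0, seed=int(rng.integers(2**31 - 1)),
        )
        df = generate_cohort(cfg)
        try:
            res = negative_control(df, REFERENCE_CLIQUE)
        except ValueError:
            continue  # quasi-separation: counts against coverage
        covered += res.ci_low <= 1.0 <= res.ci_high
    return {"coverage": covered / n_seeds, "n_seeds": n_seeds}
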