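import itertools

import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm

from metalclique.binarize import indicator
from metalclique.cliques import SignedFeature, ThresholdedClique
from metalclique.inference import (
    binarized_outcome_analysis,
    clique_association,
    effect_modification,
    negative_control,
    permutation_pvalue,
    run_sensitivity_suite,
)
from metalclique.synthetic import SynthConfig, generate_cohort

from .conftest import LOG_SD, PLANTED


class TestPermutationPvalue:
    def _design(self, x, n):
        return np.column_stack([np.ones(n), x])

    def test_extreme_statistic_attains_floor(self):
        rng = np.random.default_rng(0)
        n = 60
        x = rng.normal(size=n)
        y = 5 * x  # observed |t| far beyond any permutation
        p = permutation_pvalue(y, self._design(x, n), focal=1,
                               n_permutations=999, seed=1)
        assert p == pytest.approx(1 / 1000)

    def test_invariant_to_participant_relabeling(self):
        rng = np.random.default_rng(2)
        n = 40
        x, y = rng.normal(size=n), rng.normal(size=n)
        X = self._design(x, n)
        p1 = permutation_pvalue(y, X, 1, n_permutations=2000, seed=9)
        perm = rng.permutation(n)
        p2 = permutation_pvalue(y[perm], X[perm], 1, n_permutations=2000, seed=9)
        assert p1 == pytest.approx(p2, abs=0.02)

    def test_agrees_with_exhaustive_enumeration_n6(self):
        # all 720 permutations of a 6-vector are enumerable exactly
        x = np.array([0.0, 1.0, 0.0, 1.0, 1.0, 0.0])
        y = np.array([1.3, 2.1, 0.7, 2.6, 1.9, 1.1])
        X = self._design(x, 6)

        def tstat(yv):
            fit = sm.OLS(yv, X).fit()
            return abs(fit.tvalues[1])

        t_obs = tstat(y)
        count = sum(
            tstat(np.array(p)) >= t_obs - 1e-12
            for p in itertools.permutations(y)
        )
        exact = count / 720
        approx = permutation_pvalue(y, X, 1, n_permutations=100_000, seed=3)
        assert approx == pytest.approx(exact, abs=0.01)

    def test_minimum_permutations_enforced(self):
        with pytest.raises(ValueError):
            permutation_pvalue(np.zeros(5), np.ones((5, 1)), 0, n_permutations=10)


class TestCliqueAssociation:
    def test_recovers_planted_effect(self):
        betas = []
        eff = 0.08
        for s in range(15):
            cfg = SynthConfig(
                n_participants=500, planted_clique=PLANTED,
                effect_in_absent=eff, effect_in_present=eff,
                missing_rate=0.0, seed=500 + s,
            )
            df = generate_cohort(cfg)
            betas.append(clique_association(df, PLANTED).beta)
        assert np.mean(betas) == pytest.approx(eff, abs=0.02)

    def test_null_coverage(self):
        covered = 0
        n_seeds = 60
        for s in range(n_seeds):
            cfg = SynthConfig(
                n_participants=200, planted_clique=PLANTED,
                missing_rate=0.0, seed=700 + s,
            )
            df = generate_cohort(cfg)
            res = clique_association(df, PLANTED)
            covered += res.ci_low <= 0.0 <= res.ci_high
        assert covered / n_seeds >= 0.88

    def test_equal_weights_match_unweighted(self, cohort_planted):
        a = clique_association(cohort_planted, PLANTED)
        b = clique_association(
            cohort_planted, PLANTED, weights=np.ones(len(cohort_planted))
        )
        assert a.beta == pytest.approx(b.beta, abs=1e-12)

    def test_degenerate_indicator_rejected(self, cohort_planted):
        clique = ThresholdedClique([(SignedFeature("Zn_T2", "-"), 100.0)])
        with pytest.raises(ValueError, match="degenerate"):
            clique_association(cohort_planted, clique)


class TestEffectModification:
    def test_recovers_stratum_specific_effects(self):
        betas_absent, betas_present = [], []
        for s in range(5):
            cfg = SynthConfig(
                n_participants=2000, planted_clique=PLANTED,
                effect_in_absent=0.11, effect_in_present=-0.05,
                missing_rate=0.0, seed=77 + s,
            )
            df = generate_cohort(cfg)
            em = effect_modification(df, PLANTED)
            betas_absent.append(em.stratum_absent.beta)
            betas_present.append(em.stratum_present.beta)
        assert np.mean(betas_absent) == pytest.approx(0.11, abs=0.02)
        assert np.mean(betas_present) == pytest.approx(-0.05, abs=0.02)
        assert np.mean(betas_absent) > 0 > np.mean(betas_present)

    def test_prevalences_sum_to_overall(self, cohort_planted):
        em = effect_modification(cohort_planted, PLANTED)
        assert em.prevalence_absent + em.prevalence_present == pytest.approx(
            em.overall.subgroup_prevalence
        )

    def test_stratified_difference_equals_interaction_without_covariates(
        self, cohort_planted
    ):
        em = effect_modification(cohort_planted, PLANTED, covariates=())
        diff = em.stratum_present.beta - em.stratum_absent.beta
        assert em.interaction.beta == pytest.approx(diff, abs=1e-10)

    def test_clique_microbe_cells_match_independence(self, cohort_planted):
        vec, _ = indicator(PLANTED, cohort_planted)
        m = cohort_planted["microbe_present"].to_numpy()
        obs = pd.crosstab(vec, m).to_numpy()
        expected = np.outer(obs.sum(1), obs.sum(0)) / obs.sum()
        chi2 = ((obs - expected) ** 2 / expected).sum()
        assert chi2 < 15.0  # no association planted between clique and microbe


class TestLogisticAnalyses:
    def test_negative_control_or_is_one_on_balanced_fixture(self):
        # pet x clique counts [[30,10],[30,10]] -> OR = (30*10)/(10*30) = 1
        rows = []
        for pet, clique, n in ((0, 0, 30), (0, 1, 10), (1, 0, 30), (1, 1, 10)):
            rows += [(pet, clique)] * n
        df = pd.DataFrame(rows, columns=["pet", "X"])
        df["X"] = df["X"].astype(float)
        clique = ThresholdedClique([(SignedFeature("X", "+"), 50.0)])
        res = negative_control(df, clique, covariates=())
        assert res.beta == pytest.approx(1.0, abs=1e-6)
        assert res.ci_low <= 1.0 <= res.ci_high

    def test_negative_control_null_coverage(self):
        covered = 0
        n_seeds = 40
        for s in range(n_seeds):
            df = generate_cohort(
                SynthConfig(n_participants=300, planted_clique=PLANTED,
                            missing_rate=0.0, seed=900 + s)
            )
            res = negative_control(df, PLANTED)
            covered += res.ci_low <= 1.0 <= res.ci_high
        assert covered / n_seeds >= 0.85

    def test_binarized_outcome_direction_concordant(self):
        agree = 0
        n_seeds = 12
        for s in range(n_seeds):
            cfg = SynthConfig(
                n_participants=500, planted_clique=PLANTED,
                effect_in_absent=0.8 * LOG_SD, effect_in_present=0.8 * LOG_SD,
                missing_rate=0.0, seed=1200 + s,
            )
            df = generate_cohort(cfg)
            cont = clique_association(df, PLANTED)
            binr = binarized_outcome_analysis(df, PLANTED)
            agree += (cont.beta > 0) == (binr.beta > 1.0)
        assert agree >= 0.75 * n_seeds

    def test_constant_outcome_rejected(self, cohort_planted):
        df = cohort_planted.copy()
        df["pet"] = 1
        with pytest.raises(ValueError, match="degenerate"):
            negative_control(df, PLANTED)


class TestSensitivitySuite:
    def test_disabled_item_marked_skipped(self, cohort_planted):
        report = run_sensitivity_suite(
            cohort_planted, PLANTED, n_permutations=None,
            enabled=(2, 3, 5, 6),
        )
        assert report["randomization_pvalues"]["status"] == "skipped"
        assert report["negative_control"]["status"] == "ok"

    def test_strong_effect_preserves_directionality(self):
        cfg = SynthConfig(
            n_participants=500, planted_clique=PLANTED,
            effect_in_absent=LOG_SD, effect_in_present=LOG_SD,
            missing_rate=0.0, seed=55,
        )
        df = generate_cohort(cfg)
        report = run_sensitivity_suite(
            df, PLANTED, n_permutations=None, enabled=(4,)
        )
        item = report["threshold_perturbation"]
        assert item["status"] == "ok"
        overall = [r for r in item["result"]["perturbed"]
                   if r["stratum"] == "overall"]
        assert all(r["sign_preserved"] for r in overall)

    def test_partial_failure_recorded_not_raised(self, cohort_planted):
        df = cohort_planted.copy()
        df = df.drop(columns=["pet"])
        report = run_sensitivity_suite(
            df, PLANTED, n_permutations=None, enabled=(6,)
        )
        assert report["negative_control"]["status"] == "failed"
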