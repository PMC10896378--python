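import itertools

import numpy as np
import pytest

from metalclique.cliques import CliqueSignature, SignedFeature
from metalclique.discovery import (
    Forest,
    ForestParams,
    RhSirfConfig,
    RITParams,
    clique_network,
    extract_signed_paths,
    grow_weighted_forest,
    iterate_forest,
    random_intersection_trees,
    rh_sirf,
)
from metalclique.cliques import StabilityRecord


def _signal_data(n=500, p=8, j=3, seed=0, noise=0.3):
    rng = np.random.default_rng(seed)
    X = rng.normal(size=(n, p))
    y = (X[:, j] > 0.5).astype(float) + rng.normal(scale=noise, size=n)
    return X, y


class TestGrowWeightedForest:
    def test_planted_step_feature_dominates_importance(self):
        X, y = _signal_data()
        f = grow_weighted_forest(X, y, seed=1)
        assert int(np.argmax(f.importance)) == 3

    def test_all_weight_on_one_feature_forces_every_split(self):
        X, y = _signal_data(p=5, j=0)
        w = np.zeros(5)
        w[2] = 1.0
        f = grow_weighted_forest(X, y, w, seed=2)
        for t in f.trees:
            used = t["feature"][t["feature"] >= 0]
            assert (used == 2).all()

    def test_constant_outcome_gives_zero_importance(self):
        rng = np.random.default_rng(3)
        X = rng.normal(size=(100, 4))
        f = grow_weighted_forest(X, np.full(100, 2.0), seed=3)
        assert np.allclose(f.importance, 0.0)

    def test_invalid_inputs_rejected(self):
        X, y = _signal_data(n=50, p=3, j=0)
        with pytest.raises(ValueError, match="non-negative"):
            grow_weighted_forest(X, y, np.array([-1.0, 1.0, 1.0]))
        with pytest.raises(ValueError, match="zero"):
            grow_weighted_forest(X, y, np.zeros(3))
        with pytest.raises(ValueError, match="2 samples"):
            grow_weighted_forest(X[:1], y[:1])

    def test_prediction_reduces_error_below_null(self):
        X, y = _signal_data(seed=5)
        Xt, yt = _signal_data(seed=6)
        f = grow_weighted_forest(X, y, seed=5)
        pred = f.predict(Xt)
        assert ((yt - pred) ** 2).mean() < ((yt - yt.mean()) ** 2).mean()


class TestIterateForest:
    def test_single_iteration_equals_uniform_forest(self):
        X, y = _signal_data(n=200)
        a = iterate_forest(X, y, n_iterations=1, seed=7)
        b = grow_weighted_forest(X, y, None, None, seed=7)
        assert np.allclose(a.predict(X), b.predict(X))

    def test_importance_share_grows_with_iterations(self):
        shares = []
        for n_iter in (1, 3):
            vals = []
            for s in range(5):
                X, y = _signal_data(seed=40 + s)
                f = iterate_forest(X, y, n_iterations=n_iter, seed=s)
                w = f.importance / f.importance.sum()
                vals.append(w[3])
            shares.append(np.median(vals))
        assert shares[1] >= shares[0]

    def test_all_noise_importances_roughly_uniform(self):
        rng = np.random.default_rng(9)
        X = rng.normal(size=(400, 6))
        y = rng.normal(size=400)
        f = iterate_forest(X, y, n_iterations=2, seed=9)
        w = f.importance / f.importance.sum()
        assert w.max() / w.min() < 12.0

    def test_zero_iterations_rejected(self):
        X, y = _signal_data(n=50)
        with pytest.raises(ValueError):
            iterate_forest(X, y, n_iterations=0)


def _manual_forest(trees, p):
    return Forest(
        trees=[
            {k: np.asarray(v) for k, v in t.items()} for t in trees
        ],
        importance=np.zeros(p),
        feature_weights=np.full(p, 1 / p),
        n_features=p,
    )


class TestExtractSignedPaths:
    def test_depth_one_tree_gives_both_signs(self):
        tree = {
            "feature": [0, -1, -1], "threshold": [1.5, 0, 0],
            "left": [1, -1, -1], "right": [2, -1, -1],
            "value": [0.0, 0.0, 1.0], "count": [10, 6, 4],
        }
        out = extract_signed_paths(_manual_forest([tree], 2), ["Zn_T2", "Co_T3"])
        got = {(frozenset(map(str, s)), w) for s, w in out}
        assert got == {
            (frozenset({"Zn_T2-"}), 6), (frozenset({"Zn_T2+"}), 4),
        }

    def test_depth_two_combines_features(self):
        tree = {
            "feature": [0, 1, -1, -1, -1],
            "threshold": [1.5, 0.5, 0, 0, 0],
            "left": [1, 3, -1, -1, -1], "right": [2, 4, -1, -1, -1],
            "value": [0.0] * 5, "count": [10, 6, 4, 2, 4],
        }
        out = extract_signed_paths(_manual_forest([tree], 2), ["Zn", "Co"])
        sets = {frozenset(map(str, s)) for s, _ in out}
        assert frozenset({"Zn-", "Co-"}) in sets
        assert frozenset({"Zn-", "Co+"}) in sets
        assert frozenset({"Zn+"}) in sets

    def test_repeated_feature_keeps_last_sign(self):
        # root splits f0, left child splits f0 again: leaf signs from the
        # second split must overwrite the first
        tree = {
            "feature": [0, 0, -1, -1, -1],
            "threshold": [2.0, 1.0, 0, 0, 0],
            "left": [1, 3, -1, -1, -1], "right": [2, 4, -1, -1, -1],
            "value": [0.0] * 5, "count": [10, 6, 4, 3, 3],
        }
        out = extract_signed_paths(_manual_forest([tree], 1), ["X"])
        sets = sorted((sorted(map(str, s)), w) for s, w in out)
        assert (["X+"], 3) in sets and (["X-"], 3) in sets and (["X+"], 4) in sets

    def test_leaf_weights_sum_to_training_n(self):
        X, y = _signal_data(n=150, p=4)
        f = grow_weighted_forest(
            X, y, params=ForestParams(n_trees=5, bootstrap=False), seed=11
        )
        for t in f.trees:
            leaves = t["feature"] < 0
            assert t["count"][leaves].sum() == 150


def _sf(s):
    return SignedFeature(s[:-1], s[-1])


class TestRandomIntersectionTrees:
    def test_identical_sets_survive_exactly(self):
        sets = [(frozenset({_sf("A+"), _sf("B-")}), 1.0)] * 5
        out = random_intersection_trees(sets, seed=1)
        assert out == {CliqueSignature({_sf("A+"), _sf("B-")})}

    def test_disjoint_families_never_mix(self):
        # intersections across disjoint families are empty, so any survivor
        # must lie entirely within one input set
        fam_a = frozenset({_sf("A+"), _sf("B+")})
        fam_b = frozenset({_sf("C-"), _sf("D-")})
        sets = [(fam_a, 1.0)] * 5 + [(fam_b, 1.0)] * 5
        out = random_intersection_trees(sets, depth=2, n_trees=50, seed=2)
        for sig in out:
            assert sig.members <= fam_a or sig.members <= fam_b

    def test_matches_exhaustive_enumeration_on_small_fixture(self):
        # depth 1, one child: each tree intersects two weighted draws; the
        # survival probability of {A+,B+} is exactly sum of w_i*w_j over
        # ordered pairs whose intersection is that set
        family = [
            frozenset({_sf("A+"), _sf("B+")}),
            frozenset({_sf("A+"), _sf("B+"), _sf("C-")}),
            frozenset({_sf("A+"), _sf("D+")}),
            frozenset({_sf("B+"), _sf("C-")}),
        ]
        weights = [4.0, 3.0, 2.0, 1.0]
        target = frozenset({_sf("A+"), _sf("B+")})
        wsum = sum(weights)
        probs = [w / wsum for w in weights]
        exact = sum(
            probs[i] * probs[j]
            for i, j in itertools.product(range(4), repeat=2)
            if family[i] & family[j] == target
        )
        sets = list(zip(family, weights))
        hits = sum(
            CliqueSignature(target) in random_intersection_trees(
                sets, depth=1, n_children=1, n_trees=1, seed=s
            )
            for s in range(4000)
        )
        assert hits / 4000 == pytest.approx(exact, abs=0.03)

    def test_parameter_validation(self):
        sets = [(frozenset({_sf("A+"), _sf("B+")}), 1.0)]
        with pytest.raises(ValueError):
            random_intersection_trees(sets, depth=0)
        with pytest.raises(ValueError):
            random_intersection_trees(sets, n_children=0)
        with pytest.raises(ValueError):
            random_intersection_trees([])


class TestRhSirf:
    def test_single_holdout_stabilities_binary(self, cohort_planted):
        cfg = RhSirfConfig(
            n_holdouts=1, n_bootstraps=10,
            forest=ForestParams(n_trees=10),
            rit=RITParams(n_trees=50),
        )
        recs = rh_sirf(cohort_planted, cfg, seed=1)
        assert all(r.stability in (0.0, 1.0) for r in recs)

    def test_row_order_invariance(self, cohort_planted):
        cfg = RhSirfConfig(
            n_holdouts=5, n_bootstraps=10, forest=ForestParams(n_trees=10)
        )
        a = rh_sirf(cohort_planted, cfg, seed=4)
        shuffled = cohort_planted.sample(frac=1, random_state=8).reset_index(
            drop=True
        )
        b = rh_sirf(shuffled, cfg, seed=4)
        assert [(str(r.signature), r.stability) for r in a] == [
            (str(r.signature), r.stability) for r in b
        ]

    def test_recovers_clearly_identifiable_planted_clique(self):
        # effect 1.0 SD of the log outcome, n=300: a true 2-subset of the
        # planted clique should top the stability ranking
        from metalclique.synthetic import SynthConfig, generate_cohort
        from .conftest import LOG_SD, PLANTED

        truth = {frozenset(map(str, pair)) for pair in itertools.combinations(
            PLANTED.signature.members, 2
        )}
        truth.add(frozenset(map(str, PLANTED.signature.members)))
        cfg = RhSirfConfig(n_holdouts=100, n_bootstraps=50)
        hits = 0
        n_seeds = 3
        for s in range(n_seeds):
            df = generate_cohort(SynthConfig(
                n_participants=300, planted_clique=PLANTED,
                effect_in_absent=LOG_SD, effect_in_present=LOG_SD,
                missing_rate=0.0, seed=s,
            ))
            recs = rh_sirf(df, cfg, seed=1000 + s)
            top3 = {
                frozenset(map(str, r.signature.members)) for r in recs[:3]
            }
            hits += any(t in top3 for t in truth)
        assert hits == n_seeds

    def test_pure_noise_outcome_stays_below_stability_floor(self):
        from metalclique.synthetic import SynthConfig, generate_cohort

        cfg = RhSirfConfig(n_holdouts=50, n_bootstraps=25)
        for s in range(3):
            df = generate_cohort(SynthConfig(
                n_participants=300, missing_rate=0.0, seed=60 + s,
            ))
            recs = rh_sirf(df, cfg, seed=2000 + s)
            top = max((r.stability for r in recs), default=0.0)
            assert top <= 0.15

    def test_train_fraction_validated(self, cohort_planted):
        with pytest.raises(ValueError, match="train_fraction"):
            rh_sirf(cohort_planted, RhSirfConfig(train_fraction=1.5))

    def test_too_few_training_rows_rejected(self, cohort_planted):
        small = cohort_planted.head(12)
        with pytest.raises(ValueError, match="training rows"):
            rh_sirf(small, RhSirfConfig(n_holdouts=1))


class TestCliqueNetwork:
    def _rec(self, *feats, stability=0.1):
        return StabilityRecord(
            CliqueSignature({_sf(f) for f in feats}),
            stability, 0.2, len(feats),
        )

    def test_triangle_is_closed_loop(self):
        records = [
            self._rec("A+", "B+"), self._rec("B+", "C-"), self._rec("A+", "C-"),
        ]
        edges, closed = clique_network(records, k=3)
        assert closed
        assert len(edges) == 3

    def test_disjoint_edges_not_closed(self):
        records = [self._rec("A+", "B+"), self._rec("C+", "D+")]
        edges, closed = clique_network(records, k=2)
        assert not closed

    def test_single_edge_not_closed(self):
        edges, closed = clique_network([self._rec("A+", "B+")], k=2)
        assert not closed
        assert len(edges) == 1

    def test_k_validation(self):
        with pytest.raises(ValueError):
            clique_network([self._rec("A+", "B+")], k=1)
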