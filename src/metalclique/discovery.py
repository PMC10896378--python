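"""rh-SiRF: repeated-holdout signed iterated random forest clique discovery.

The engine repeatedly splits the cohort into training/test halves, grows
importance-reweighted regression forests on bootstrap replicates of the
training half, reads signed feature sets off the root-to-leaf decision paths
(``+`` for the high side of a split, ``-`` for the low side), distills
frequently co-occurring sets with Random Intersection Trees, filters each
holdout by test-half predictivity, and ranks the surviving signed cliques by
*stability* — the frequency of occurrence across holdouts.

Signed feature sets are carried internally as bitmasks (bit ``2j`` = feature
j with sign ``-``, bit ``2j+1`` = feature j with sign ``+``), so set
intersection is a bitwise AND.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import networkx as nx
import numpy as np
import pandas as pd

from ._tree import _grow_tree, _predict_tree
from .cliques import (
    EXPOSURE_KEYS,
    CliqueSignature,
    SignedFeature,
    StabilityRecord,
    signature_sort_key,
)


# ---------------------------------------------------------------------------
# Forest
# ---------------------------------------------------------------------------

@dataclass
class ForestParams:
    """Hyperparameters of the weighted regression forest."""

    n_trees: int = 25
    max_depth: int = 4
    min_leaf: int = 5
    mtry: int | None = None  # default: ceil(p / 3)
    bootstrap: bool = True


@dataclass
class Forest:
    """A fitted forest: per-tree flat node arrays plus feature importances."""

    trees: list[dict]
    importance: np.ndarray  # raw SSE-reduction totals per feature
    feature_weights: np.ndarray
    n_features: int

    def predict(self, X: np.ndarray) -> np.ndarray:
        X = np.ascontiguousarray(X, dtype=np.float64)
        out = np.zeros(X.shape[0])
        for t in self.trees:
            _predict_tree(
                X, t["feature"], t["threshold"], t["left"], t["right"],
                t["value"], out,
            )
        return out / len(self.trees)


def grow_weighted_forest(
    X: np.ndarray,
    y: np.ndarray,
    feature_weights: np.ndarray | None = None,
    params: ForestParams | None = None,
    seed: int | np.random.Generator = 0,
) -> Forest:
    """Grow a regression forest whose split candidates are drawn with
    probability proportional to ``feature_weights``.

    Importance is the total impurity (SSE) decrease credited to each
    feature across all trees.
    """
    X = np.ascontiguousarray(X, dtype=np.float64)
    y = np.ascontiguousarray(y, dtype=np.float64)
    n, p = X.shape
    if p == 0:
        raise ValueError("empty feature set")
    if n < 2:
        raise ValueError("need at least 2 samples")
    params = params or ForestParams()
    if feature_weights is None:
        w = np.full(p, 1.0 / p)
    else:
        w = np.asarray(feature_weights, dtype=np.float64)
        if (w < 0).any():
            raise ValueError("feature weights must be non-negative")
        if w.sum() <= 0:
            raise ValueError("feature weights must not all be zero")
        w = w / w.sum()
    cdf = np.cumsum(w)
    cdf[-1] = 1.0
    mtry = params.mtry if params.mtry is not None else int(np.ceil(p / 3))
    rng = (
        seed if isinstance(seed, np.random.Generator)
        else np.random.default_rng(seed)
    )
    max_nodes = 4 * max(1, n // max(1, params.min_leaf)) + 8
    importance = np.zeros(p)
    trees = []
    for _ in range(params.n_trees):
        if params.bootstrap:
            idx = rng.integers(0, n, n).astype(np.int64)
        else:
            idx = np.arange(n, dtype=np.int64)
        tree_seed = int(rng.integers(0, 2**31 - 1))
        feature = np.empty(max_nodes, dtype=np.int64)
        threshold = np.zeros(max_nodes)
        left = np.empty(max_nodes, dtype=np.int64)
        right = np.empty(max_nodes, dtype=np.int64)
        value = np.zeros(max_nodes)
        cnt = np.zeros(max_nodes, dtype=np.int64)
        n_nodes = _grow_tree(
            X, y, idx, cdf, mtry, params.max_depth, params.min_leaf,
            tree_seed, feature, threshold, left, right, value, cnt, importance,
        )
        trees.append({
            "feature": feature[:n_nodes], "threshold": threshold[:n_nodes],
            "left": left[:n_nodes], "right": right[:n_nodes],
            "value": value[:n_nodes], "count": cnt[:n_nodes],
        })
    return Forest(trees=trees, importance=importance, feature_weights=w,
                  n_features=p)


def iterate_forest(
    X: np.ndarray,
    y: np.ndarray,
    n_iterations: int = 3,
    params: ForestParams | None = None,
    seed: int | np.random.Generator = 0,
) -> Forest:
    """Iterated random forest: reweight split-candidate sampling by the
    previous iteration's normalized importances (iteration 1 is uniform).
    """
    if n_iterations < 1:
        raise ValueError("n_iterations must be >= 1")
    rng = (
        seed if isinstance(seed, np.random.Generator)
        else np.random.default_rng(seed)
    )
    p = X.shape[1]
    w = np.full(p, 1.0 / p)
    forest = None
    for _ in range(n_iterations):
        forest = grow_weighted_forest(X, y, w, params, rng)
        tot = forest.importance.sum()
        w = forest.importance / tot if tot > 0 else np.full(p, 1.0 / p)
    return forest


# ---------------------------------------------------------------------------
# Signed decision paths and Random Intersection Trees
# ---------------------------------------------------------------------------

def _signed_path_masks(
    forest: Forest, leaf_value_quantile: float = 0.0
) -> tuple[list[int], list[int]]:
    """Per-leaf signed feature sets as bitmasks, weighted by leaf counts.

    Following a split left (``<= threshold``) contributes sign ``-``, right
    contributes ``+``; a feature met with both signs on one path keeps the
    last-encountered sign.  With ``leaf_value_quantile`` > 0 only leaves
    whose predicted value lies above that count-weighted quantile of the
    tree's leaf values are kept — the regression analogue of running RIT on
    positive-class leaves, focusing the search on subgroups with a *high*
    outcome.
    """
    masks: list[int] = []
    weights: list[int] = []
    for t in forest.trees:
        feature, lchild, rchild, cnt, val = (
            t["feature"], t["left"], t["right"], t["count"], t["value"],
        )
        keep = None
        if leaf_value_quantile > 0.0:
            leaves = np.flatnonzero(feature < 0)
            order = leaves[np.argsort(val[leaves], kind="stable")]
            cw = np.cumsum(cnt[order]) / cnt[leaves].sum()
            cut = int(np.searchsorted(cw, leaf_value_quantile))
            keep = set(order[cut:].tolist())
        stack = [(0, 0)]
        while stack:
            node, mask = stack.pop()
            f = int(feature[node])
            if f < 0:
                if mask and (keep is None or node in keep):
                    masks.append(mask)
                    weights.append(int(cnt[node]))
                continue
            cleared = mask & ~(0b11 << (2 * f))
            stack.append((int(lchild[node]), cleared | (1 << (2 * f))))
            stack.append((int(rchild[node]), cleared | (1 << (2 * f + 1))))
    return masks, weights


def extract_signed_paths(
    forest: Forest, feature_names: Sequence[str] | None = None
) -> list[tuple[frozenset[SignedFeature], int]]:
    """Signed root-to-leaf feature sets with leaf training counts."""
    names = list(feature_names) if feature_names is not None else [
        f"f{j}" for j in range(forest.n_features)
    ]
    masks, weights = _signed_path_masks(forest)
    return [(_decode_mask(m, names), w) for m, w in zip(masks, weights)]


def _decode_mask(mask: int, names: Sequence[str]) -> frozenset[SignedFeature]:
    out = []
    j = 0
    while mask >> (2 * j):
        bits = (mask >> (2 * j)) & 0b11
        if bits & 0b01:
            out.append(SignedFeature(names[j], "-"))
        if bits & 0b10:
            out.append(SignedFeature(names[j], "+"))
        j += 1
    return frozenset(out)


def _encode_members(members, names: Sequence[str]) -> int:
    index = {n: j for j, n in enumerate(names)}
    mask = 0
    for sf in members:
        j = index[sf.exposure]
        mask |= 1 << (2 * j + (1 if sf.sign == "+" else 0))
    return mask


def _rit_masks(
    masks: Sequence[int],
    weights: Sequence[float],
    depth: int,
    n_children: int,
    n_trees: int,
    min_order: int,
    rng: np.random.Generator,
) -> set[int]:
    """Random Intersection Trees over bitmask sets; returns surviving
    intersections of order >= min_order."""
    if depth < 1:
        raise ValueError("depth must be >= 1")
    if n_children < 1:
        raise ValueError("n_children must be >= 1")
    if len(masks) == 0:
        raise ValueError("need at least one signed set")
    cum = np.cumsum(np.asarray(weights, dtype=np.float64))
    total = cum[-1]
    n_draws = sum(n_children**d for d in range(depth + 1))

    survivors: set[int] = set()
    for _ in range(n_trees):
        draws = np.searchsorted(cum, rng.random(n_draws) * total)
        level = [masks[draws[0]]]
        di = 1
        for _ in range(depth):
            nxt = []
            for s in level:
                for _ in range(n_children):
                    t = s & masks[draws[di]]
                    di += 1
                    if t:
                        nxt.append(t)
            level = nxt
            if not level:
                break
        for s in level:
            if s.bit_count() >= min_order:
                survivors.add(s)
    return survivors


def random_intersection_trees(
    signed_sets: Sequence[tuple[frozenset[SignedFeature], float]],
    depth: int = 3,
    n_children: int = 2,
    n_trees: int = 20,
    min_order: int = 2,
    seed: int | np.random.Generator = 0,
) -> set[CliqueSignature]:
    """Find signed feature sets that co-occur in many weighted input sets.

    Each intersection tree draws input sets with probability proportional to
    weight down a ``depth``-level, ``n_children``-ary tree, intersecting
    along every root-to-leaf path; non-empty leaf intersections of order at
    least ``min_order`` survive and are deduplicated.
    """
    rng = (
        seed if isinstance(seed, np.random.Generator)
        else np.random.default_rng(seed)
    )
    names = sorted({sf.exposure for s, _ in signed_sets for sf in s})
    masks = [_encode_members(s, names) for s, _ in signed_sets]
    weights = [w for _, w in signed_sets]
    out = _rit_masks(masks, weights, depth, n_children, n_trees, min_order, rng)
    return {CliqueSignature(_decode_mask(m, names)) for m in out}


# ---------------------------------------------------------------------------
# Repeated-holdout engine
# ---------------------------------------------------------------------------

@dataclass
class RITParams:
    depth: int = 2
    n_children: int = 2
    n_trees: int = 150
    min_order: int = 2


def _default_discovery_forest() -> ForestParams:
    # small mtry keeps the importance-weighted sampling pressure high
    return ForestParams(n_trees=30, max_depth=5, min_leaf=8, mtry=4)


@dataclass
class RhSirfConfig:
    """Configuration of the repeated-holdout discovery engine.

    Defaults follow the study design: 500 train/test holdouts at a 60/40
    split with 250 bootstraps per holdout; reduced configurations are used
    for desk-scale simulation studies.
    """

    n_holdouts: int = 500
    train_fraction: float = 0.6
    n_bootstraps: int = 250
    n_iterations: int = 3
    forest: ForestParams = field(default_factory=_default_discovery_forest)
    #: trees per bootstrap-replicate forest feeding RIT
    bootstrap_forest_trees: int = 10
    rit: RITParams = field(default_factory=RITParams)
    #: retain a holdout's signatures only if test-half R^2 exceeds this
    predictivity_floor: float = 0.0
    #: trees in the forest used to evaluate test-half predictivity
    gate_forest_trees: int = 100
    #: a signature counts for a holdout if found in >= this fraction of bootstraps
    bootstrap_fraction: float = 0.1
    #: RIT reads only leaves above this count-weighted leaf-value quantile
    leaf_value_quantile: float = 0.75


def rh_sirf(
    table: pd.DataFrame,
    config: RhSirfConfig | None = None,
    seed: int = 0,
    outcome: str = "log_tcdi",
    features: Sequence[str] = EXPOSURE_KEYS,
) -> list[StabilityRecord]:
    """Run repeated-holdout signed iterated random forest discovery.

    Per holdout: split train/test; run the iterated forest on the training
    half; if its test-half R^2 passes the predictivity floor, grow a small
    weighted forest (final iteration weights) on each bootstrap replicate of
    the training half, extract signed decision paths, and distill signatures
    with RIT; a signature counts for the holdout when it appears in enough
    bootstraps.  Stability is the fraction of holdouts in which a signature
    counts.  Results are sorted by stability, then mean leaf-weight
    prevalence, then canonical signature string.  Rows are processed in
    participant-id order, so the result is invariant to row order.
    """
    config = config or RhSirfConfig()
    if not (0.0 < config.train_fraction < 1.0):
        raise ValueError("train_fraction must be in (0, 1)")
    table = table.sort_values("participant_id").reset_index(drop=True)
    names = list(features)
    X = table[names].to_numpy(dtype=np.float64)
    y = table[outcome].to_numpy(dtype=np.float64)
    if np.isnan(X).any() or np.isnan(y).any():
        raise ValueError("outcome and exposures must be complete")
    n = len(table)
    n_train = int(round(config.train_fraction * n))
    if n_train < 10:
        raise ValueError("fewer than 10 training rows")
    rng = np.random.default_rng(seed)

    min_count = max(1, int(np.ceil(config.bootstrap_fraction * config.n_bootstraps)))
    hold_counts: dict[int, int] = {}
    prev_sums: dict[int, float] = {}
    prev_ns: dict[int, int] = {}

    boot_params = replace(
        config.forest, n_trees=config.bootstrap_forest_trees
    )
    gate_params = replace(config.forest, n_trees=config.gate_forest_trees)
    for _ in range(config.n_holdouts):
        perm = rng.permutation(n)
        tr, te = perm[:n_train], perm[n_train:]
        forest = iterate_forest(
            X[tr], y[tr], config.n_iterations, config.forest, rng
        )
        w = forest.importance
        if w.sum() <= 0:
            w = np.full(len(names), 1.0 / len(names))
        # test-half predictivity gate: a larger forest grown with the final
        # weights gives a lower-variance R^2 estimate than the 30-tree one
        gate = grow_weighted_forest(X[tr], y[tr], w, gate_params, rng)
        pred = gate.predict(X[te])
        sst = ((y[te] - y[te].mean()) ** 2).sum()
        r2 = 1.0 - ((y[te] - pred) ** 2).sum() / sst if sst > 0 else 0.0
        if r2 <= config.predictivity_floor:
            continue
        counts: dict[int, int] = {}
        prevs: dict[int, float] = {}
        for _ in range(config.n_bootstraps):
            bidx = tr[rng.integers(0, n_train, n_train)]
            bforest = grow_weighted_forest(X[bidx], y[bidx], w, boot_params, rng)
            masks, mweights = _signed_path_masks(
                bforest, config.leaf_value_quantile
            )
            if not masks:
                continue
            sigs = _rit_masks(
                masks, mweights, config.rit.depth, config.rit.n_children,
                config.rit.n_trees, config.rit.min_order, rng,
            )
            if not sigs:
                continue
            mw = np.asarray(mweights, dtype=np.float64)
            tot = mw.sum()
            for s in sigs:
                counts[s] = counts.get(s, 0) + 1
                contain = sum(
                    wgt for m, wgt in zip(masks, mweights) if (m & s) == s
                )
                prevs[s] = prevs.get(s, 0.0) + contain / tot
        for s, c in counts.items():
            if c >= min_count:
                hold_counts[s] = hold_counts.get(s, 0) + 1
                prev_sums[s] = prev_sums.get(s, 0.0) + prevs[s] / c
                prev_ns[s] = prev_ns.get(s, 0) + 1

    records = [
        StabilityRecord(
            signature=CliqueSignature(_decode_mask(s, names)),
            stability=c / config.n_holdouts,
            mean_prevalence=prev_sums[s] / prev_ns[s],
            order=s.bit_count(),
        )
        for s, c in hold_counts.items()
    ]
    return sorted(records, key=signature_sort_key)


def clique_network(
    top: Sequence[StabilityRecord], k: int = 3
) -> tuple[pd.DataFrame, bool]:
    """Union network of the top-k signatures and its closed-loop flag.

    Nodes are signed features; edges join features co-occurring in a
    signature; the flag is True when the union graph contains a cycle
    visiting at least 3 distinct nodes.
    """
    if k < 2:
        raise ValueError("k must be >= 2")
    chosen = list(top)[:k]
    G = nx.Graph()
    rows = []
    for rec in chosen:
        members = sorted(rec.signature.members)
        for i in range(len(members)):
            for j in range(i + 1, len(members)):
                a, b = str(members[i]), str(members[j])
                G.add_edge(a, b)
                rows.append({
                    "source": a, "target": b,
                    "signature": str(rec.signature),
                    "stability": rec.stability,
                })
    closed = len(nx.cycle_basis(G)) > 0 if len(G) else False
    return pd.DataFrame(rows, columns=["source", "target", "signature",
                                       "stability"]), closed
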