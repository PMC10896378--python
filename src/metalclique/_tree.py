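"""Low-level regression-tree kernels with weighted per-split feature sampling.

scikit-learn's trees cannot sample split-candidate features with per-feature
probabilities, which is the defining ingredient of an importance-reweighted
(iterated) random forest, so the tree grower is implemented here as numba
kernels.  Trees are stored as flat arrays (feature, threshold, left, right,
value, count); ``feature == -1`` marks a leaf.  Split quality is the usual
variance (SSE) reduction; thresholds are midpoints between adjacent distinct
values; candidate features at every split are drawn i.i.d. from the supplied
feature distribution.
"""

from __future__ import annotations

import numpy as np
from numba import njit


@njit(cache=True)
def _grow_tree(
    X, y, idx, feat_cdf, mtry, max_depth, min_leaf, seed,
    feature, threshold, left, right, value, count, importance,
):
    """Grow one tree on rows ``idx`` of X/y.  Returns the node count.

    feat_cdf: cumulative feature-sampling probabilities (len p, last == 1).
    Node arrays must be preallocated; importance (len p) accumulates raw SSE
    reductions in place.
    """
    np.random.seed(seed)
    n = idx.shape[0]
    # stack of (node_id, start, end, depth)
    max_nodes = feature.shape[0]
    stack = np.empty((max_nodes, 4), dtype=np.int64)
    stack[0, 0] = 0
    stack[0, 1] = 0
    stack[0, 2] = n
    stack[0, 3] = 0
    top = 1
    n_nodes = 1
    buf = np.empty(n, dtype=np.int64)
    while top > 0:
        top -= 1
        node = stack[top, 0]
        start = stack[top, 1]
        end = stack[top, 2]
        depth = stack[top, 3]
        n_node = end - start
        total = 0.0
        for i in range(start, end):
            total += y[idx[i]]
        mean = total / n_node
        value[node] = mean
        count[node] = n_node
        feature[node] = -1
        left[node] = -1
        right[node] = -1
        if depth >= max_depth or n_node < 2 * min_leaf:
            continue
        best_gain = 1e-10
        best_f = -1
        best_thr = 0.0
        for _ in range(mtry):
            u = np.random.random()
            f = np.searchsorted(feat_cdf, u)
            if f >= feat_cdf.shape[0]:
                f = feat_cdf.shape[0] - 1
            v = np.empty(n_node)
            for i in range(n_node):
                v[i] = X[idx[start + i], f]
            order = np.argsort(v, kind="mergesort")
            left_sum = 0.0
            for i in range(n_node - 1):
                left_sum += y[idx[start + order[i]]]
                nl = i + 1
                if nl < min_leaf or n_node - nl < min_leaf:
                    continue
                if v[order[i]] == v[order[i + 1]]:
                    continue
                nr = n_node - nl
                right_sum = total - left_sum
                gain = (
                    left_sum * left_sum / nl
                    + right_sum * right_sum / nr
                    - total * total / n_node
                )
                if gain > best_gain:
                    best_gain = gain
                    best_f = f
                    best_thr = 0.5 * (v[order[i]] + v[order[i + 1]])
        if best_f < 0:
            continue
        # stable partition: <= threshold first
        nl = 0
        for i in range(start, end):
            if X[idx[i], best_f] <= best_thr:
                buf[nl] = idx[i]
                nl += 1
        nr = nl
        for i in range(start, end):
            if X[idx[i], best_f] > best_thr:
                buf[nr] = idx[i]
                nr += 1
        for i in range(n_node):
            idx[start + i] = buf[i]
        lchild = n_nodes
        rchild = n_nodes + 1
        n_nodes += 2
        feature[node] = best_f
        threshold[node] = best_thr
        left[node] = lchild
        right[node] = rchild
        importance[best_f] += best_gain
        stack[top, 0] = lchild
        stack[top, 1] = start
        stack[top, 2] = start + nl
        stack[top, 3] = depth + 1
        top += 1
        stack[top, 0] = rchild
        stack[top, 1] = start + nl
        stack[top, 2] = end
        stack[top, 3] = depth + 1
        top += 1
    return n_nodes


@njit(cache=True)
def _predict_tree(X, feature, threshold, left, right, value, out):
    for i in range(X.shape[0]):
        node = 0
        while feature[node] >= 0:
            if X[i, feature[node]] <= threshold[node]:
                node = left[node]
            else:
                node = right[node]
        out[i] += value[node]
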