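"""Numba kernels for the multitask decision forest.

A tree is grown on a bootstrap sample; at every node ``mtry`` candidate
features are drawn and the split maximizing the *multitask* score -- the
unweighted mean over tasks of the per-task Gini impurity decrease -- is
taken. Leaves store the per-task positive-class frequency. The kernels are
deliberately task-count agnostic: with a single task the procedure is a
standard classification tree, and with duplicated label columns it consumes
the RNG identically, so multitask and single-task trees coincide exactly
when the tasks coincide.
"""

from __future__ import annotations

import numpy as np
from numba import njit

NO_FEATURE = -1


@njit(cache=True)
def _node_counts(Y, idx, start, end, T):
    pos = np.zeros(T)
    for k in range(start, end):
        for t in range(T):
            pos[t] += Y[idx[k], t]
    return pos


@njit(cache=True)
def _best_split(X, Y, idx, start, end, mtry, min_leaf, feat_perm):
    """Return (feature, threshold, score) of the best multitask split, or
    (NO_FEATURE, 0, 0) when no split improves the mean Gini."""
    n = end - start
    T = Y.shape[1]
    n_feat = X.shape[1]

    parent_pos = _node_counts(Y, idx, start, end, T)
    parent_gini = np.empty(T)
    for t in range(T):
        p = parent_pos[t] / n
        parent_gini[t] = 2.0 * p * (1.0 - p)

    # partial Fisher-Yates over the shared permutation buffer
    for k in range(mtry):
        j = k + np.random.randint(0, n_feat - k)
        feat_perm[k], feat_perm[j] = feat_perm[j], feat_perm[k]

    best_score = 0.0
    best_feat = NO_FEATURE
    best_thr = 0.0

    vals = np.empty(n)
    ypos = np.empty((n, T))
    for c in range(mtry):
        f = feat_perm[c]
        for k in range(n):
            vals[k] = X[idx[start + k], f]
        order = np.argsort(vals, kind="mergesort")
        for k in range(n):
            for t in range(T):
                ypos[k, t] = Y[idx[start + order[k]], t]
        cum = np.zeros(T)
        for k in range(n - 1):
            for t in range(T):
                cum[t] += ypos[k, t]
            nl = k + 1
            nr = n - nl
            if nl < min_leaf or nr < min_leaf:
                continue
            v_lo = vals[order[k]]
            v_hi = vals[order[k + 1]]
            if v_hi <= v_lo:
                continue
            score = 0.0
            for t in range(T):
                pl = cum[t] / nl
                pr = (parent_pos[t] - cum[t]) / nr
                child = (nl * 2.0 * pl * (1.0 - pl) + nr * 2.0 * pr * (1.0 - pr)) / n
                score += parent_gini[t] - child
            score /= T
            if score > best_score + 1e-15:
                best_score = score
                best_feat = f
                best_thr = 0.5 * (v_lo + v_hi)
    return best_feat, best_thr, best_score


@njit(cache=True)
def grow_tree(X, Y, sample_idx, mtry, max_depth, min_leaf, seed,
              feature, threshold, left, right, leaf, node_n, importance):
    """Grow one tree in place into the preallocated node arrays.

    Returns the number of nodes used. ``importance`` accumulates
    (node fraction) * (multitask split score) per feature.
    """
    np.random.seed(seed)
    n_root = sample_idx.shape[0]
    T = Y.shape[1]
    n_feat = X.shape[1]
    feat_perm = np.arange(n_feat)

    idx = sample_idx.copy()
    # explicit stack: node id, segment start/end, depth
    stack_node = np.empty(2 * n_root + 2, dtype=np.int64)
    stack_lo = np.empty(2 * n_root + 2, dtype=np.int64)
    stack_hi = np.empty(2 * n_root + 2, dtype=np.int64)
    stack_depth = np.empty(2 * n_root + 2, dtype=np.int64)
    top = 0
    stack_node[0], stack_lo[0], stack_hi[0], stack_depth[0] = 0, 0, n_root, 0
    top = 1
    n_nodes = 1
    buf = np.empty(n_root, dtype=np.int64)

    while top > 0:
        top -= 1
        node = stack_node[top]
        lo = stack_lo[top]
        hi = stack_hi[top]
        depth = stack_depth[top]
        n = hi - lo
        pos = _node_counts(Y, idx, lo, hi, T)

        make_leaf = True
        if depth < max_depth and n >= 2 * min_leaf:
            pure = True
            for t in range(T):
                if 0 < pos[t] < n:
                    pure = False
                    break
            if not pure:
                f, thr, score = _best_split(X, Y, idx, lo, hi, mtry, min_leaf, feat_perm)
                if f != NO_FEATURE:
                    make_leaf = False
                    importance[f] += (n / n_root) * score
                    # stable partition of the segment by the split
                    nl = 0
                    nb = 0
                    for k in range(lo, hi):
                        if X[idx[k], f] <= thr:
                            idx[lo + nl] = idx[k]
                            nl += 1
                        else:
                            buf[nb] = idx[k]
                            nb += 1
                    for k in range(nb):
                        idx[lo + nl + k] = buf[k]
                    feature[node] = f
                    threshold[node] = thr
                    left[node] = n_nodes
                    right[node] = n_nodes + 1
                    node_n[node] = n
                    stack_node[top] = n_nodes
                    stack_lo[top] = lo
                    stack_hi[top] = lo + nl
                    stack_depth[top] = depth + 1
                    top += 1
                    stack_node[top] = n_nodes + 1
                    stack_lo[top] = lo + nl
                    stack_hi[top] = hi
                    stack_depth[top] = depth + 1
                    top += 1
                    n_nodes += 2
        if make_leaf:
            feature[node] = NO_FEATURE
            node_n[node] = n
            for t in range(T):
                leaf[node, t] = pos[t] / n
    return n_nodes


@njit(cache=True)
def predict_tree(X, feature, threshold, left, right, leaf, out):
    """Accumulate leaf frequencies of one tree into ``out`` (n, T)."""
    n = X.shape[0]
    T = leaf.shape[1]
    for i in range(n):
        node = 0
        while feature[node] != NO_FEATURE:
            if X[i, feature[node]] <= threshold[node]:
                node = left[node]
            else:
                node = right[node]
        for t in range(T):
            out[i, t] += leaf[node, t]
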