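"""Compiled kernels for CART-style binary classification trees.

These kernels implement the split search, tree growth and traversal used by
the forest module. Trees are stored as flat parallel arrays (one slot per
node) so that a whole tree is built in a single compiled call.

Conventions, shared with :mod:`bloodpanel.forest`:

* labels are int8 with 1 = disease (positive class), 0 = control;
* split thresholds sit at midpoints between consecutive distinct sorted
  values of the chosen feature; samples with value <= threshold go left;
* node impurity is Gini (1 - sum p_i^2); a node's recorded ``decrease`` is
  parent impurity minus the child-size-weighted mean child impurity
  (unweighted by node size — the node-size weighting is applied when
  importances are aggregated);
* the first feature (in random draw order) attaining the strictly largest
  decrease wins, which makes growth a pure function of the seed.
"""

import numpy as np
from numba import njit

__all__ = ["build_tree_arrays", "predict_tree", "NO_FEATURE"]

NO_FEATURE = -1


@njit(cache=True)
def _build_tree_impl(X, y, f, max_depth, min_leaf, seed, bootstrap):  # pragma: no cover
    n, n_features = X.shape
    np.random.seed(seed)

    inbag = np.zeros(n, np.int32)
    idx = np.empty(n, np.int64)
    if bootstrap:
        for i in range(n):
            j = np.random.randint(0, n)
            idx[i] = j
            inbag[j] += 1
    else:
        for i in range(n):
            idx[i] = i
            inbag[i] = 1

    max_nodes = 2 * n + 1
    feature = np.full(max_nodes, -1, np.int64)
    threshold = np.zeros(max_nodes, np.float64)
    left = np.full(max_nodes, -1, np.int64)
    right = np.full(max_nodes, -1, np.int64)
    decrease = np.zeros(max_nodes, np.float64)
    node_n = np.zeros(max_nodes, np.int64)
    count0 = np.zeros(max_nodes, np.int64)
    count1 = np.zeros(max_nodes, np.int64)

    # explicit DFS stack: (node id, slice lo, slice hi, depth)
    st_node = np.empty(max_nodes, np.int64)
    st_lo = np.empty(max_nodes, np.int64)
    st_hi = np.empty(max_nodes, np.int64)
    st_depth = np.empty(max_nodes, np.int64)
    st_node[0] = 0
    st_lo[0] = 0
    st_hi[0] = n
    st_depth[0] = 0
    top = 1
    n_nodes = 1

    perm = np.empty(n_features, np.int64)
    vbuf = np.empty(n, np.float64)
    pbuf = np.empty(n, np.int64)
    f_eff = f if f < n_features else n_features

    while top > 0:
        top -= 1
        node = st_node[top]
        lo = st_lo[top]
        hi = st_hi[top]
        depth = st_depth[top]
        m = hi - lo

        ones = 0
        for i in range(lo, hi):
            ones += y[idx[i]]
        node_n[node] = m
        count1[node] = ones
        count0[node] = m - ones

        if ones == 0 or ones == m or m < 2 * min_leaf or depth >= max_depth:
            continue

        p1 = ones / m
        g_parent = 2.0 * p1 * (1.0 - p1)

        for i in range(n_features):
            perm[i] = i

        best_dec = 0.0
        best_feature = -1
        best_threshold = 0.0
        for t in range(f_eff):
            # partial Fisher-Yates: perm[t] is the t-th drawn feature
            r = t + np.random.randint(0, n_features - t)
            tmp = perm[t]
            perm[t] = perm[r]
            perm[r] = tmp
            j = perm[t]

            for i in range(m):
                vbuf[i] = X[idx[lo + i], j]
            order = np.argsort(vbuf[:m])

            left_ones = 0
            for k in range(1, m):
                left_ones += y[idx[lo + order[k - 1]]]
                v_prev = vbuf[order[k - 1]]
                v_here = vbuf[order[k]]
                if v_here <= v_prev:
                    continue
                if k < min_leaf or (m - k) < min_leaf:
                    continue
                pl = left_ones / k
                pr = (ones - left_ones) / (m - k)
                g_left = 2.0 * pl * (1.0 - pl)
                g_right = 2.0 * pr * (1.0 - pr)
                dec = g_parent - (k * g_left + (m - k) * g_right) / m
                if dec > best_dec:
                    best_dec = dec
                    best_feature = j
                    best_threshold = 0.5 * (v_prev + v_here)

        if best_feature < 0:
            continue

        # stable partition of idx[lo:hi] around the chosen threshold
        nl = 0
        for i in range(lo, hi):
            if X[idx[i], best_feature] <= best_threshold:
                pbuf[nl] = idx[i]
                nl += 1
        nr = nl
        for i in range(lo, hi):
            if X[idx[i], best_feature] > best_threshold:
                pbuf[nr] = idx[i]
                nr += 1
        for i in range(m):
            idx[lo + i] = pbuf[i]

        lid = n_nodes
        rid = n_nodes + 1
        n_nodes += 2
        feature[node] = best_feature
        threshold[node] = best_threshold
        decrease[node] = best_dec
        left[node] = lid
        right[node] = rid

        st_node[top] = rid
        st_lo[top] = lo + nl
        st_hi[top] = hi
        st_depth[top] = depth + 1
        top += 1
        st_node[top] = lid
        st_lo[top] = lo
        st_hi[top] = lo + nl
        st_depth[top] = depth + 1
        top += 1

    return (
        feature[:n_nodes],
        threshold[:n_nodes],
        left[:n_nodes],
        right[:n_nodes],
        decrease[:n_nodes],
        node_n[:n_nodes],
        count0[:n_nodes],
        count1[:n_nodes],
        inbag,
    )


@njit(cache=True)
def _predict_tree_impl(feature, threshold, left, right, count0, count1, X):  # pragma: no cover
    n = X.shape[0]
    out = np.empty(n, np.int8)
    for i in range(n):
        node = 0
        while feature[node] >= 0:
            if X[i, feature[node]] <= threshold[node]:
                node = left[node]
            else:
                node = right[node]
        # leaf majority vote; exact tie -> disease (positive class)
        out[i] = 1 if count1[node] >= count0[node] else 0
    return out


def build_tree_arrays(X, y, f, max_depth, min_leaf, seed, bootstrap):
    """Grow one tree; returns flat node arrays plus per-sample in-bag counts.

    ``X`` is (n_samples, n_features) float64, ``y`` int8 in {0, 1}. With
    ``bootstrap`` the training multiset is n draws with replacement under
    ``seed``; otherwise every sample is used once.
    """
    X = np.ascontiguousarray(X, dtype=np.float64)
    y = np.ascontiguousarray(y, dtype=np.int8)
    return _build_tree_impl(
        X, y, int(f), int(max_depth), int(min_leaf), int(seed), bool(bootstrap)
    )


def predict_tree(feature, threshold, left, right, count0, count1, X):
    """Per-sample leaf-majority class votes of one tree on rows of ``X``."""
    X = np.ascontiguousarray(X, dtype=np.float64)
    return _predict_tree_impl(feature, threshold, left, right, count0, count1, X)
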