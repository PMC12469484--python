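"""Path-dependent TreeSHAP for sklearn decision-tree ensembles.

Computes exact Shapley additive attributions for regression trees under
the tree-path-dependent feature perturbation: the conditional
expectation for a feature subset S follows the split when the split
feature is in S and otherwise averages the children weighted by their
training cover.  The polynomial-time algorithm maintains, along each
root-to-leaf path, the weights of all feature-subset permutations
(EXTEND / UNWIND recursions), giving attributions that satisfy local
accuracy exactly: ``base_value + sum(phi) == prediction`` for every row.

The hot loops are numba-jitted; cost is O(trees * leaves * depth^2) per
explained row, so summaries are typically computed on a capped sample
of the evaluation set.

For a forest (average of trees), attributions are the average of the
per-tree attributions and the base value is the average of per-tree
training means.
"""

from __future__ import annotations

import numpy as np
from numba import njit

__all__ = ["tree_shap_values", "forest_shap_values", "shap_base_value"]


@njit(cache=False)
def _extend(pd_frac, po_frac, pi_feat, pw, off, m, pz, po, pi):
    """Append one path element; maintain permutation weights.

    ``m`` is the number of elements already in the path at ``off``.
    """
    pd_frac[off + m] = pz
    po_frac[off + m] = po
    pi_feat[off + m] = pi
    pw[off + m] = 1.0 if m == 0 else 0.0
    for i in range(m - 1, -1, -1):
        pw[off + i + 1] += po * pw[off + i] * (i + 1.0) / (m + 1.0)
        pw[off + i] = pz * pw[off + i] * (m - i) / (m + 1.0)


@njit(cache=False)
def _unwind(pd_frac, po_frac, pi_feat, pw, off, m, k):
    """Remove path element ``k`` from a path of ``m`` elements."""
    po = po_frac[off + k]
    pz = pd_frac[off + k]
    n = pw[off + m - 1]
    if po != 0.0:
        for j in range(m - 2, -1, -1):
            t = pw[off + j]
            pw[off + j] = n * m / ((j + 1.0) * po)
            n = t - pw[off + j] * pz * (m - j - 1.0) / m
    else:
        for j in range(m - 2, -1, -1):
            pw[off + j] = pw[off + j] * m / (pz * (m - j - 1.0))
    for j in range(k, m - 1):
        pd_frac[off + j] = pd_frac[off + j + 1]
        po_frac[off + j] = po_frac[off + j + 1]
        pi_feat[off + j] = pi_feat[off + j + 1]


@njit(cache=False)
def _unwound_sum(pd_frac, po_frac, pw, off, m, k):
    """Sum of permutation weights after (virtually) removing element ``k``."""
    po = po_frac[off + k]
    pz = pd_frac[off + k]
    total = 0.0
    n = pw[off + m - 1]
    if po != 0.0:
        for j in range(m - 2, -1, -1):
            t = n / ((j + 1.0) * po)
            total += t
            n = pw[off + j] - t * pz * (m - j - 1.0)
    else:
        for j in range(m - 2, -1, -1):
            total += pw[off + j] / (pz * (m - j - 1.0))
    return total * m


@njit(cache=False)
def _recurse(
    children_left, children_right, feature, threshold, cover, value,
    x, phi,
    pd_frac, po_frac, pi_feat, pw,
    node, m_parent, off, parent_off,
    parent_zero, parent_one, parent_feat,
):
    # copy the parent's path into this call's workspace region
    for i in range(m_parent):
        pd_frac[off + i] = pd_frac[parent_off + i]
        po_frac[off + i] = po_frac[parent_off + i]
        pi_feat[off + i] = pi_feat[parent_off + i]
        pw[off + i] = pw[parent_off + i]
    _extend(pd_frac, po_frac, pi_feat, pw, off, m_parent, parent_zero, parent_one, parent_feat)
    m = m_parent + 1

    if children_left[node] < 0:  # leaf
        leaf = value[node]
        for i in range(1, m):
            w = _unwound_sum(pd_frac, po_frac, pw, off, m, i)
            phi[pi_feat[off + i]] += w * (po_frac[off + i] - pd_frac[off + i]) * leaf
        return

    f = feature[node]
    if x[f] <= threshold[node]:
        hot, cold = children_left[node], children_right[node]
    else:
        hot, cold = children_right[node], children_left[node]

    incoming_zero = 1.0
    incoming_one = 1.0
    k = -1
    for i in range(1, m):
        if pi_feat[off + i] == f:
            k = i
            break
    if k >= 0:
        incoming_zero = pd_frac[off + k]
        incoming_one = po_frac[off + k]
        _unwind(pd_frac, po_frac, pi_feat, pw, off, m, k)
        m -= 1

    r_node = cover[node]
    child_off = off + m
    _recurse(
        children_left, children_right, feature, threshold, cover, value,
        x, phi, pd_frac, po_frac, pi_feat, pw,
        hot, m, child_off, off,
        incoming_zero * cover[hot] / r_node, incoming_one, f,
    )
    _recurse(
        children_left, children_right, feature, threshold, cover, value,
        x, phi, pd_frac, po_frac, pi_feat, pw,
        cold, m, child_off, off,
        incoming_zero * cover[cold] / r_node, 0.0, f,
    )


@njit(cache=False)
def _tree_shap_matrix(
    children_left, children_right, feature, threshold, cover, value,
    X, max_depth,
):
    n, p = X.shape
    phi = np.zeros((n, p))
    size = (max_depth + 2) * (max_depth + 3) // 2 + 1
    pd_frac = np.zeros(size)
    po_frac = np.zeros(size)
    pi_feat = np.zeros(size, dtype=np.int64)
    pw = np.zeros(size)
    for s in range(n):
        _recurse(
            children_left, children_right, feature, threshold, cover, value,
            X[s], phi[s], pd_frac, po_frac, pi_feat, pw,
            0, 0, 0, 0, 1.0, 1.0, -1,
        )
    return phi


def _tree_arrays(tree):
    """Flat arrays from a fitted sklearn ``Tree`` object."""
    t = tree.tree_
    return (
        t.children_left.astype(np.int64),
        t.children_right.astype(np.int64),
        t.feature.astype(np.int64),
        t.threshold.astype(np.float64),
        t.weighted_n_node_samples.astype(np.float64),
        t.value.reshape(-1).astype(np.float64),
        int(t.max_depth),
    )


def tree_shap_values(tree, X: np.ndarray) -> np.ndarray:
    """Per-row SHAP attribution matrix ``(n, p)`` for one fitted tree."""
    X = np.ascontiguousarray(X, dtype=np.float64)
    left, right, feat, thr, cover, value, max_depth = _tree_arrays(tree)
    return _tree_shap_matrix(left, right, feat, thr, cover, value, X, max_depth)


def shap_base_value(tree_or_forest) -> float:
    """Expected prediction (cover-weighted mean of leaves = root value)."""
    if hasattr(tree_or_forest, "estimators_"):
        return float(
            np.mean([t.tree_.value.reshape(-1)[0] for t in tree_or_forest.estimators_])
        )
    return float(tree_or_forest.tree_.value.reshape(-1)[0])


def forest_shap_values(forest, X: np.ndarray) -> np.ndarray:
    """SHAP attribution matrix for a fitted sklearn forest (tree average)."""
    X = np.ascontiguousarray(X, dtype=np.float64)
    phi = np.zeros((X.shape[0], X.shape[1]))
    for est in forest.estimators_:
        phi += tree_shap_values(est, X)
    phi /= len(forest.estimators_)
    return phi
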