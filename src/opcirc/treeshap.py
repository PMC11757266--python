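"""Exact path-dependent TreeSHAP for scikit-learn decision trees.

Computes per-feature Shapley attributions for a tree ensemble under
the path-dependent feature perturbation: the conditional expectation
for a feature subset S is defined by descending the tree, following
the recorded value for features in S and splitting proportionally to
training cover otherwise. Attributions satisfy local accuracy: for
each sample, base value + sum of attributions equals the tree's
output exactly.

The polynomial-time algorithm maintains, along each root-to-leaf
path, the proportion of all feature subsets of each size that flow to
the leaf, extending the path at each internal node and unwinding it
to measure each feature's marginal contribution.
"""

from __future__ import annotations

import numpy as np

__all__ = ["tree_shap_values", "forest_shap_values"]


def _extend(fi, zf, of, pw, depth, zero_fraction, one_fraction, feature_index):
    fi[depth] = feature_index
    zf[depth] = zero_fraction
    of[depth] = one_fraction
    pw[depth] = 1.0 if depth == 0 else 0.0
    for i in range(depth - 1, -1, -1):
        pw[i + 1] += one_fraction * pw[i] * (i + 1.0) / (depth + 1.0)
        pw[i] = zero_fraction * pw[i] * (depth - i) / (depth + 1.0)


def _unwind(fi, zf, of, pw, depth, path_index):
    one_fraction = of[path_index]
    zero_fraction = zf[path_index]
    next_one = pw[depth]
    for i in range(depth - 1, -1, -1):
        if one_fraction != 0.0:
            tmp = pw[i]
            pw[i] = next_one * (depth + 1.0) / ((i + 1.0) * one_fraction)
            next_one = tmp - pw[i] * zero_fraction * (depth - i) / (depth + 1.0)
        else:
            pw[i] = pw[i] * (depth + 1.0) / (zero_fraction * (depth - i))
    for i in range(path_index, depth):
        fi[i] = fi[i + 1]
        zf[i] = zf[i + 1]
        of[i] = of[i + 1]


def _unwound_sum(zf, of, pw, depth, path_index):
    one_fraction = of[path_index]
    zero_fraction = zf[path_index]
    next_one = pw[depth]
    total = 0.0
    for i in range(depth - 1, -1, -1):
        if one_fraction != 0.0:
            tmp = next_one * (depth + 1.0) / ((i + 1.0) * one_fraction)
            total += tmp
            next_one = pw[i] - tmp * zero_fraction * (depth - i) / (depth + 1.0)
        else:
            total += pw[i] / (zero_fraction * (depth - i) / (depth + 1.0))
    return total


def _recurse(
    tree, x, phi, node, depth, fi, zf, of, pw,
    parent_zero_fraction, parent_one_fraction, parent_feature,
):
    fi, zf, of, pw = fi.copy(), zf.copy(), of.copy(), pw.copy()
    _extend(fi, zf, of, pw, depth, parent_zero_fraction, parent_one_fraction, parent_feature)

    left = tree["children_left"][node]
    right = tree["children_right"][node]
    if left < 0:  # leaf
        leaf_value = tree["values"][node]
        for i in range(1, depth + 1):
            w = _unwound_sum(zf, of, pw, depth, i)
            phi[fi[i]] += w * (of[i] - zf[i]) * leaf_value
        return

    split_feature = tree["features"][node]
    cover = tree["cover"]
    if x[split_feature] <= tree["thresholds"][node]:
        hot, cold = left, right
    else:
        hot, cold = right, left

    # undo a previous split on the same feature along this path
    hot_zero = cold_zero = 1.0
    one_fraction = 1.0
    path_index = 1
    while path_index <= depth:
        if fi[path_index] == split_feature:
            break
        path_index += 1
    new_depth = depth
    if path_index != depth + 1:
        hot_zero = zf[path_index]
        one_fraction = of[path_index]
        _unwind(fi, zf, of, pw, depth, path_index)
        new_depth -= 1
        hot_zero_fraction = hot_zero * cover[hot] / cover[node]
        cold_zero_fraction = hot_zero * cover[cold] / cover[node]
    else:
        hot_zero_fraction = cover[hot] / cover[node]
        cold_zero_fraction = cover[cold] / cover[node]

    _recurse(
        tree, x, phi, hot, new_depth + 1, fi, zf, of, pw,
        hot_zero_fraction, one_fraction, split_feature,
    )
    _recurse(
        tree, x, phi, cold, new_depth + 1, fi, zf, of, pw,
        cold_zero_fraction, 0.0, split_feature,
    )


def _tree_dict(sk_tree) -> dict:
    """Flatten an sklearn tree; leaf values are class-1 probabilities
    for classifiers, raw values for regressors."""
    t = sk_tree.tree_
    values = t.value.copy()
    if values.shape[-1] == 2:  # classifier: normalize to P(class 1)
        totals = values.sum(axis=2, keepdims=True)
        probs = values / np.where(totals == 0, 1.0, totals)
        leaf_out = probs[:, 0, 1]
    else:
        leaf_out = values[:, 0, 0]
    return {
        "children_left": t.children_left,
        "children_right": t.children_right,
        "features": t.feature,
        "thresholds": t.threshold,
        "values": leaf_out,
        "cover": t.weighted_n_node_samples,
    }


def _expected_value(tree: dict) -> float:
    """Cover-weighted expectation of the tree output (recursive)."""

    def rec(node):
        if tree["children_left"][node] < 0:
            return tree["values"][node]
        l, r = tree["children_left"][node], tree["children_right"][node]
        wl = tree["cover"][l] / tree["cover"][node]
        return wl * rec(l) + (1 - wl) * rec(r)

    return float(rec(0))


def tree_shap_values(sk_tree, X: np.ndarray) -> tuple[np.ndarray, float]:
    """SHAP values and base value for a single fitted sklearn tree."""
    X = np.asarray(X, dtype=float)
    tree = _tree_dict(sk_tree)
    base = _expected_value(tree)
    n, d = X.shape
    phis = np.zeros((n, d))
    maxd = int(sk_tree.get_depth()) + 2
    for row in range(n):
        fi = np.full(maxd + 1, -1, dtype=np.int64)
        zf = np.zeros(maxd + 1)
        of = np.zeros(maxd + 1)
        pw = np.zeros(maxd + 1)
        _recurse(tree, X[row], phis[row], 0, 0, fi, zf, of, pw, 1.0, 1.0, -1)
    return phis, base


def forest_shap_values(forest, X: np.ndarray) -> tuple[np.ndarray, float]:
    """SHAP values for a fitted RandomForestClassifier/Regressor.

    The forest output is the mean over trees, so attributions and the
    base value are tree-averages; local accuracy carries over: base +
    row sum equals predict_proba[:, 1] (classifier) within float error.
    """
    X = np.asarray(X, dtype=float)
    phis = np.zeros((X.shape[0], X.shape[1]))
    base = 0.0
    for est in forest.estimators_:
        p, b = tree_shap_values(est, X)
        phis += p
        base += b
    k = len(forest.estimators_)
    return phis / k, base / k
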