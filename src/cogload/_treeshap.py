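"""Path-dependent TreeSHAP for scikit-learn gradient-boosted trees.

Shapley additive explanations for a tree are the exact Shapley values of
the game v(S) = E[f(x) | x_S], with the conditional expectation
estimated path-dependently from the training cover stored at each node
(``weighted_n_node_samples``).  This module implements the polynomial
time algorithm that carries, down each root-to-leaf path, the weighted
fractions of all subset permutations that reach the node with each
possible number of "active" features, so that every feature's Shapley
contribution is accumulated exactly (Shapley additivity holds to
floating-point precision).

Only what the attribution stage needs is provided: per-row SHAP values
for a binary :class:`~sklearn.ensemble.GradientBoostingClassifier` on
the margin (log-odds) scale, plus the matching expected value, so that
``phi.sum(axis=1) + base == decision_function(X)``.

The hot recursion is jitted with numba when available and silently falls
back to pure Python otherwise.
"""

from __future__ import annotations

import numpy as np


def _tree_shap_recursive(
    children_left,
    children_right,
    features,
    thresholds,
    values,
    node_weight,
    x,
    phi,
    node,
    unique_depth,
    offset,
    feat_buf,
    z_buf,
    o_buf,
    w_buf,
    parent_zero_fraction,
    parent_one_fraction,
    parent_feature,
):
    # copy the parent's path into this call's region and extend it
    new_off = offset + unique_depth
    for i in range(unique_depth):
        feat_buf[new_off + i] = feat_buf[offset + i]
        z_buf[new_off + i] = z_buf[offset + i]
        o_buf[new_off + i] = o_buf[offset + i]
        w_buf[new_off + i] = w_buf[offset + i]
    # extend_path
    feat_buf[new_off + unique_depth] = parent_feature
    z_buf[new_off + unique_depth] = parent_zero_fraction
    o_buf[new_off + unique_depth] = parent_one_fraction
    w_buf[new_off + unique_depth] = 1.0 if unique_depth == 0 else 0.0
    for i in range(unique_depth - 1, -1, -1):
        w_buf[new_off + i + 1] += (
            parent_one_fraction * w_buf[new_off + i] * (i + 1.0) / (unique_depth + 1.0)
        )
        w_buf[new_off + i] = (
            parent_zero_fraction * w_buf[new_off + i] * (unique_depth - i) / (unique_depth + 1.0)
        )

    if children_left[node] < 0:  # leaf
        leaf_value = values[node]
        for pi in range(1, unique_depth + 1):
            # unwound_path_sum at index pi
            one_fraction = o_buf[new_off + pi]
            zero_fraction = z_buf[new_off + pi]
            next_one = w_buf[new_off + unique_depth]
            total = 0.0
            if one_fraction != 0.0:
                for i in range(unique_depth - 1, -1, -1):
                    tmp = next_one * (unique_depth + 1.0) / ((i + 1.0) * one_fraction)
                    total += tmp
                    next_one = w_buf[new_off + i] - tmp * zero_fraction * (
                        (unique_depth - i) / (unique_depth + 1.0)
                    )
            else:
                for i in range(unique_depth - 1, -1, -1):
                    total += w_buf[new_off + i] / (
                        zero_fraction * ((unique_depth - i) / (unique_depth + 1.0))
                    )
            phi[feat_buf[new_off + pi]] += (
                total * (one_fraction - zero_fraction) * leaf_value
            )
        return

    split = features[node]
    left = children_left[node]
    right = children_right[node]
    if x[split] <= thresholds[node]:
        hot, cold = left, right
    else:
        hot, cold = right, left
    w = node_weight[node]
    hot_zero = node_weight[hot] / w
    cold_zero = node_weight[cold] / w
    incoming_zero = 1.0
    incoming_one = 1.0
    # if this feature was split on above, unwind its previous entry
    path_index = -1
    for i in range(unique_depth + 1):
        if feat_buf[new_off + i] == split:
            path_index = i
            break
    depth_here = unique_depth
    if path_index >= 0:
        incoming_zero = z_buf[new_off + path_index]
        incoming_one = o_buf[new_off + path_index]
        # unwind_path
        one_fraction = incoming_one
        zero_fraction = incoming_zero
        next_one = w_buf[new_off + depth_here]
        if one_fraction != 0.0:
            for i in range(depth_here - 1, -1, -1):
                tmp = w_buf[new_off + i]
                w_buf[new_off + i] = next_one * (depth_here + 1.0) / ((i + 1.0) * one_fraction)
                next_one = tmp - w_buf[new_off + i] * zero_fraction * (
                    (depth_here - i) / (depth_here + 1.0)
                )
        else:
            for i in range(depth_here - 1, -1, -1):
                w_buf[new_off + i] = (w_buf[new_off + i] * (depth_here + 1.0)) / (
                    zero_fraction * (depth_here - i)
                )
        # shift the path entries past the removed one; the recomputed
        # pweights already occupy the shortened path and stay in place
        for i in range(path_index, depth_here):
            feat_buf[new_off + i] = feat_buf[new_off + i + 1]
            z_buf[new_off + i] = z_buf[new_off + i + 1]
            o_buf[new_off + i] = o_buf[new_off + i + 1]
        depth_here -= 1

    _tree_shap_recursive(
        children_left, children_right, features, thresholds, values, node_weight,
        x, phi, hot, depth_here + 1, new_off, feat_buf, z_buf, o_buf, w_buf,
        hot_zero * incoming_zero, incoming_one, split,
    )
    _tree_shap_recursive(
        children_left, children_right, features, thresholds, values, node_weight,
        x, phi, cold, depth_here + 1, new_off, feat_buf, z_buf, o_buf, w_buf,
        cold_zero * incoming_zero, 0.0, split,
    )


try:  # pragma: no cover - exercised implicitly
    from numba import njit

    _tree_shap_recursive = njit(cache=False)(_tree_shap_recursive)
    _HAVE_NUMBA = True
except Exception:  # pragma: no cover
    _HAVE_NUMBA = False


def _tree_arrays(tree):
    t = tree.tree_
    return (
        t.children_left.astype(np.int64),
        t.children_right.astype(np.int64),
        t.feature.astype(np.int64),
        t.threshold.astype(np.float64),
        t.value[:, 0, 0].astype(np.float64),
        t.weighted_n_node_samples.astype(np.float64),
    )


def tree_expected_value(tree) -> float:
    """Cover-weighted mean leaf value: E[f(x)] under the path-dependent law."""
    t = tree.tree_
    leaves = t.children_left < 0
    w = t.weighted_n_node_samples
    return float(np.sum(w[leaves] * t.value[leaves, 0, 0]) / w[0])


def single_tree_shap(tree, X: np.ndarray) -> np.ndarray:
    """SHAP values of one fitted sklearn regression tree, rows of X."""
    cl, cr, feat, thr, val, w = _tree_arrays(tree)
    max_depth = int(tree.tree_.max_depth)
    buf_len = (max_depth + 2) * (max_depth + 3) // 2 + max_depth + 2
    X = np.ascontiguousarray(X, dtype=np.float64)
    n, p = X.shape
    phi = np.zeros((n, p), dtype=np.float64)
    feat_buf = np.zeros(buf_len, dtype=np.int64)
    z_buf = np.zeros(buf_len, dtype=np.float64)
    o_buf = np.zeros(buf_len, dtype=np.float64)
    w_buf = np.zeros(buf_len, dtype=np.float64)
    for i in range(n):
        _tree_shap_recursive(
            cl, cr, feat, thr, val, w, X[i], phi[i], 0, 0, 0,
            feat_buf, z_buf, o_buf, w_buf, 1.0, 1.0, -1,
        )
    return phi


def shap_values(model, X, n_trees: int | None = None):
    """Margin-scale SHAP values for a binary GradientBoostingClassifier.

    Parameters
    ----------
    model
        Fitted binary ``GradientBoostingClassifier``.
    X
        Rows to explain (array or DataFrame).
    n_trees
        Use only the first ``n_trees`` boosting stages (for models tuned
        by early stopping); defaults to all fitted stages.

    Returns
    -------
    (phi, base_value)
        ``phi`` has one column per feature; ``phi.sum(axis=1) +
        base_value`` equals the model margin (``decision_function``)
        restricted to the same stages, to floating-point precision.
    """
    X = np.ascontiguousarray(np.asarray(X, dtype=np.float64))
    estimators = model.estimators_[:, 0]
    if n_trees is not None:
        estimators = estimators[:n_trees]
    lr = model.learning_rate
    n, p = X.shape
    phi = np.zeros((n, p), dtype=np.float64)
    base = 0.0
    for tree in estimators:
        phi += lr * single_tree_shap(tree, X)
        base += lr * tree_expected_value(tree)
    # init raw prediction (prior log-odds), recovered without private API:
    # margin(x) = init + lr * sum_t tree_t(x)
    margin_full = model.decision_function(X[:1])
    tree_part = sum(
        model.learning_rate * t.predict(X[:1]) for t in model.estimators_[:, 0]
    )
    init = float(np.asarray(margin_full).ravel()[0] - np.asarray(tree_part).ravel()[0])
    return phi, base + init
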