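"""Vectorized prediction over fitted sklearn tree structures.

Permutation importance needs, for every tree, a re-prediction of the
tree's evaluation rows once per variable the tree uses, each time with
that one variable's values shuffled. Routing each of those through
``DecisionTree.predict`` would require materializing a matrix copy per
variable; the helpers here instead walk the flat node arrays directly for
*all* permuted variants of a tree's evaluation rows in one batched
traversal, injecting each shuffled column on the fly.
"""

from __future__ import annotations

import numpy as np


def tree_arrays(estimator):
    """Extract the flat node arrays of a fitted sklearn tree.

    Returns ``(children_left, children_right, feature, threshold, value)``
    where ``value`` holds per-node class probabilities (classification)
    or responses (regression).
    """
    t = estimator.tree_
    value = t.value[:, 0, :]
    if value.shape[1] == 1:
        value = value[:, 0]
    return (
        t.children_left.copy(),
        t.children_right.copy(),
        t.feature.copy(),
        t.threshold.copy(),
        value.copy(),
    )


def predict_leaf_batch(arrays, X, rows, override_feature, override_values):
    """Leaf node index for a batch of (row, override) evaluation units.

    ``rows[i]`` indexes the row of ``X`` to route; whenever a split tests
    feature ``override_feature[i]`` (-1 for none), the value
    ``override_values[i]`` is used instead of the matrix entry. This lets
    one call evaluate the unpermuted baseline and every single-variable
    permutation of the same rows without copying ``X``.
    """
    children_left, children_right, feature, threshold, _ = arrays
    m = rows.shape[0]
    nodes = np.zeros(m, dtype=np.intp)
    active = np.arange(m)
    while active.size:
        cur = nodes[active]
        feat = feature[cur]
        internal = feat >= 0
        if not internal.all():
            active = active[internal]
            if not active.size:
                break
            cur = nodes[active]
            feat = feature[cur]
        x = X[rows[active], feat]
        hit = feat == override_feature[active]
        if hit.any():
            x = np.where(hit, override_values[active], x)
        go_left = x <= threshold[cur]
        nodes[active] = np.where(go_left, children_left[cur], children_right[cur])
    return nodes


_NO_OVERRIDE = np.empty(0)


def predict_leaf(arrays, X, rows=None):
    """Leaf node index for plain rows (no permutation override)."""
    if rows is None:
        rows = np.arange(X.shape[0])
    m = rows.shape[0]
    return predict_leaf_batch(
        arrays, X, rows, np.full(m, -1, dtype=np.intp), np.zeros(m)
    )


def tree_permutation_drops(arrays, X, rows, y, task, variables, rng):
    """Performance drop per permuted variable for one tree.

    Evaluates the tree on ``rows`` of ``X`` once unpermuted and once per
    entry of ``variables`` with that column's values (restricted to the
    evaluation rows) freshly shuffled, all in a single batched traversal.
    Performance is accuracy (classification, integer-encoded ``y``) or
    negative mean squared error (regression); the return value is
    ``perf(baseline) - perf(permuted)`` per variable, positive when the
    variable mattered.
    """
    value = arrays[4]
    n_eval = rows.shape[0]
    k = len(variables)
    batch_rows = np.tile(rows, k + 1)
    over_feat = np.concatenate(
        [np.full(n_eval, -1, dtype=np.intp)]
        + [np.full(n_eval, v, dtype=np.intp) for v in variables]
    )
    over_val = np.empty((k + 1) * n_eval)
    for s, v in enumerate(variables):
        col = X[rows, v]
        over_val[(s + 1) * n_eval : (s + 2) * n_eval] = col[rng.permutation(n_eval)]
    leaves = predict_leaf_batch(arrays, X, batch_rows, over_feat, over_val)
    if task == "classification":
        pred = np.argmax(value[leaves], axis=1).reshape(k + 1, n_eval)
        perf = np.mean(pred == y[None, :], axis=1)
    else:
        pred = value[leaves].reshape(k + 1, n_eval)
        perf = -np.mean((pred - y[None, :]) ** 2, axis=1)
    return perf[0] - perf[1:]


def used_features(arrays) -> np.ndarray:
    feature = arrays[2]
    return np.unique(feature[feature >= 0])
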