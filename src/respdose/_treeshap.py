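"""Exact Shapley attributions for decision-tree ensembles.

Implements the polynomial-time path-dependent tree-traversal algorithm:
feature coalitions absent from the conditioning set are marginalised using
the training coverage stored in each node, and the per-path polynomial
bookkeeping (extend/unwind) yields exactly the Shapley values of the
conditional-expectation set function.  Satisfies local accuracy exactly:
base value + sum of attributions = model prediction for every sample.
"""

from __future__ import annotations

import numpy as np


def _extend(path: list[list[float]], pz: float, po: float, pi: int) -> list[list[float]]:
    l = len(path)
    path = [row[:] for row in path]
    path.append([pi, pz, po, 1.0 if l == 0 else 0.0])
    for i in range(l - 1, -1, -1):
        path[i + 1][3] += po * path[i][3] * (i + 1) / (l + 1)
        path[i][3] = pz * path[i][3] * (l - i) / (l + 1)
    return path


def _unwind(path: list[list[float]], i: int) -> list[list[float]]:
    l = len(path) - 1
    z, o = path[i][1], path[i][2]
    n = path[l][3]
    path = [row[:] for row in path]
    if o != 0.0:
        for j in range(l - 1, -1, -1):
            t = path[j][3]
            path[j][3] = n * (l + 1) / ((j + 1) * o)
            n = t - path[j][3] * z * (l - j) / (l + 1)
    else:
        for j in range(l - 1, -1, -1):
            path[j][3] = path[j][3] * (l + 1) / (z * (l - j))
    for j in range(i, l):
        path[j][0], path[j][1], path[j][2] = path[j + 1][0], path[j + 1][1], path[j + 1][2]
    path.pop()
    return path


def _unwound_sum(path: list[list[float]], i: int) -> float:
    l = len(path) - 1
    z, o = path[i][1], path[i][2]
    total = 0.0
    if o != 0.0:
        n = path[l][3]
        for j in range(l - 1, -1, -1):
            t = n * (l + 1) / ((j + 1) * o)
            total += t
            n = path[j][3] - t * z * (l - j) / (l + 1)
    else:
        for j in range(l - 1, -1, -1):
            total += path[j][3] * (l + 1) / (z * (l - j))
    return total


def _recurse(node, path, pz, po, pi, left, right, feature, threshold,
             value, coverage, x, phi) -> None:
    path = _extend(path, pz, po, pi)
    if left[node] < 0:  # leaf
        leaf_value = value[node]
        for i in range(1, len(path)):
            w = _unwound_sum(path, i)
            phi[path[i][0]] += w * (path[i][2] - path[i][1]) * leaf_value
        return
    f = feature[node]
    if x[f] <= threshold[node]:
        hot, cold = left[node], right[node]
    else:
        hot, cold = right[node], left[node]
    iz, io = 1.0, 1.0
    k = None
    for j in range(1, len(path)):
        if path[j][0] == f:
            k = j
            break
    if k is not None:
        iz, io = path[k][1], path[k][2]
        path = _unwind(path, k)
    r = coverage[node]
    _recurse(hot, path, iz * coverage[hot] / r, io, f,
             left, right, feature, threshold, value, coverage, x, phi)
    _recurse(cold, path, iz * coverage[cold] / r, 0.0, f,
             left, right, feature, threshold, value, coverage, x, phi)


def tree_shap_values(tree, X: np.ndarray) -> tuple[np.ndarray, float]:
    """Shapley attributions for one fitted sklearn regression tree.

    Returns ``(phi, base)`` where ``phi`` has shape (n_samples, n_features)
    and ``base`` is the coverage-weighted root expectation.
    """
    t = tree.tree_
    left = t.children_left
    right = t.children_right
    feature = t.feature
    threshold = t.threshold
    value = t.value[:, 0, 0]
    coverage = t.weighted_n_node_samples
    X = np.asarray(X, dtype=float)
    phi = np.zeros(X.shape)
    for row in range(X.shape[0]):
        _recurse(0, [], 1.0, 1.0, -1, left, right, feature, threshold,
                 value, coverage, X[row], phi[row])
    return phi, float(value[0])


def forest_shap_values(forest, X: np.ndarray) -> tuple[np.ndarray, float]:
    """Average exact tree attributions over a fitted random-forest regressor."""
    X = np.asarray(X, dtype=float)
    phi = np.zeros(X.shape)
    base = 0.0
    for est in forest.estimators_:
        p, b = tree_shap_values(est, X)
        phi += p
        base += b
    n = len(forest.estimators_)
    return phi / n, base / n
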