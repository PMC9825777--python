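"""Exact Shapley values for gradient-boosted tree ensembles.

Implements the polynomial-time path-dependent algorithm for single trees
(expectations taken over the tree's own training cover weights) and sums
per-tree values across a scikit-learn ``GradientBoostingClassifier``
ensemble, scaled by the learning rate and offset by the initial raw
prediction. Additivity holds exactly: base value + sum of SHAP values
equals the model's margin (``decision_function``) output.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.ensemble import GradientBoostingClassifier

__all__ = ["tree_shap", "tree_shap_single_tree", "tree_expected_value",
           "shap_family_summary", "ShapExplanation"]


@dataclass
class ShapExplanation:
    values: np.ndarray  # (n_rows, n_features)
    base_value: float

    def margins(self) -> np.ndarray:
        return self.base_value + self.values.sum(axis=1)


class _PathElement:
    __slots__ = ("feature_index", "zero_fraction", "one_fraction", "pweight")

    def __init__(self, feature_index, zero_fraction, one_fraction, pweight):
        self.feature_index = feature_index
        self.zero_fraction = zero_fraction
        self.one_fraction = one_fraction
        self.pweight = pweight

    def copy(self):
        return _PathElement(
            self.feature_index, self.zero_fraction, self.one_fraction, self.pweight
        )


def _extend(path, zero_fraction, one_fraction, feature_index):
    depth = len(path)
    path.append(
        _PathElement(feature_index, zero_fraction, one_fraction,
                     1.0 if depth == 0 else 0.0)
    )
    for i in range(depth - 1, -1, -1):
        path[i + 1].pweight += one_fraction * path[i].pweight * (i + 1) / (depth + 1)
        path[i].pweight = zero_fraction * path[i].pweight * (depth - i) / (depth + 1)


def _unwind(path, path_index):
    depth = len(path) - 1
    one_fraction = path[path_index].one_fraction
    zero_fraction = path[path_index].zero_fraction
    next_one_portion = path[depth].pweight
    for i in range(depth - 1, -1, -1):
        if one_fraction != 0.0:
            tmp = path[i].pweight
            path[i].pweight = next_one_portion * (depth + 1) / ((i + 1) * one_fraction)
            next_one_portion = tmp - path[i].pweight * zero_fraction * (depth - i) / (depth + 1)
        else:
            path[i].pweight = path[i].pweight * (depth + 1) / (zero_fraction * (depth - i))
    for i in range(path_index, depth):
        path[i].feature_index = path[i + 1].feature_index
        path[i].zero_fraction = path[i + 1].zero_fraction
        path[i].one_fraction = path[i + 1].one_fraction
    path.pop()


def _unwound_sum(path, path_index):
    depth = len(path) - 1
    one_fraction = path[path_index].one_fraction
    zero_fraction = path[path_index].zero_fraction
    total = 0.0
    next_one_portion = path[depth].pweight
    for i in range(depth - 1, -1, -1):
        if one_fraction != 0.0:
            tmp = next_one_portion * (depth + 1) / ((i + 1) * one_fraction)
            total += tmp
            next_one_portion = path[i].pweight - tmp * zero_fraction * (depth - i) / (depth + 1)
        else:
            total += path[i].pweight / (zero_fraction * (depth - i) / (depth + 1))
    return total


def tree_shap_single_tree(tree, x: np.ndarray, phi: np.ndarray,
                          scale: float = 1.0) -> None:
    """Accumulate one tree's exact Shapley values for row ``x`` into ``phi``.

    ``tree`` is a fitted sklearn ``Tree`` (the ``tree_`` attribute); cover
    weights come from ``weighted_n_node_samples``.
    """
    left = tree.children_left
    right = tree.children_right
    feature = tree.feature
    threshold = tree.threshold
    values = tree.value[:, 0, 0]
    weights = tree.weighted_n_node_samples

    def recurse(node, path, parent_zero, parent_one, parent_feature):
        path = [el.copy() for el in path]
        _extend(path, parent_zero, parent_one, parent_feature)
        if left[node] < 0:  # leaf
            for i in range(1, len(path)):
                w = _unwound_sum(path, i)
                el = path[i]
                phi[el.feature_index] += (
                    scale * w * (el.one_fraction - el.zero_fraction) * values[node]
                )
            return
        f = feature[node]
        if x[f] <= threshold[node]:
            hot, cold = left[node], right[node]
        else:
            hot, cold = right[node], left[node]
        incoming_zero = incoming_one = 1.0
        path_index = next(
            (i for i in range(1, len(path)) if path[i].feature_index == f), None
        )
        if path_index is not None:
            incoming_zero = path[path_index].zero_fraction
            incoming_one = path[path_index].one_fraction
            _unwind(path, path_index)
        recurse(hot, path, incoming_zero * weights[hot] / weights[node],
                incoming_one, f)
        recurse(cold, path, incoming_zero * weights[cold] / weights[node],
                0.0, f)

    recurse(0, [], 1.0, 1.0, -1)


def tree_expected_value(tree) -> float:
    """Cover-weighted mean leaf value of one tree."""
    leaves = tree.children_left < 0
    weights = tree.weighted_n_node_samples[leaves]
    return float(np.average(tree.value[leaves, 0, 0], weights=weights))


def tree_shap(
    model: GradientBoostingClassifier,
    X: np.ndarray,
    class_index: int = 0,
) -> ShapExplanation:
    """Exact SHAP values for every row of ``X`` on the margin (raw score)
    scale of ``model``.

    For binary models ``class_index`` must be 0 (the positive-class margin);
    multiclass models have one margin per class.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    n, d = X.shape
    trees = [est.tree_ for est in model.estimators_[:, class_index]]
    lr = model.learning_rate
    init_raw = model._raw_predict_init(X[:1])[0]
    base = float(init_raw[class_index] if init_raw.size > 1 else init_raw[0])
    base += lr * sum(tree_expected_value(t) for t in trees)
    values = np.zeros((n, d))
    for row in range(n):
        phi = np.zeros(d)
        for tree in trees:
            tree_shap_single_tree(tree, X[row], phi, scale=lr)
        values[row] = phi
    return ShapExplanation(values=values, base_value=base)


def shap_family_summary(
    shap_values: np.ndarray,
    feature_names: list[str],
    predicted_class: np.ndarray,
) -> pd.DataFrame:
    """Mean |SHAP| per feature family, stratified by predicted class.

    Feature names carry their family as a dot-separated prefix (``motif.``,
    ``chrom.``, ``hic.``, ``seq.``). Rows are predicted classes, columns are
    families sorted by overall importance (largest first).
    """
    shap_values = np.atleast_2d(shap_values)
    if shap_values.shape[1] != len(feature_names):
        raise ValueError("feature_names must align with SHAP columns")
    families = [name.split(".", 1)[0] for name in feature_names]
    known = {"seq", "motif", "chrom", "hic"}
    unknown = sorted(set(families) - known)
    if unknown:
        raise ValueError(f"unknown feature families: {unknown}")
    df = pd.DataFrame(np.abs(shap_values), columns=feature_names)
    df["_class"] = np.asarray(predicted_class)
    rows = {}
    for cls, group in df.groupby("_class"):
        means = group.drop(columns="_class").to_numpy()
        rows[cls] = {
            fam: float(means[:, [i for i, f in enumerate(families) if f == fam]].mean())
            for fam in sorted(set(families))
        }
    summary = pd.DataFrame(rows).T
    order = summary.mean(axis=0).sort_values(ascending=False).index
    return summary[order]
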