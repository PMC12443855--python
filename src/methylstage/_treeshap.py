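"""Exact interventional Shapley values for tree ensembles.

The Shapley value of feature i for one prediction is

    phi_i = sum over S subset of F\\{i} of
            |S|! (|F|-|S|-1)! / |F|! * [ f_{S+i}(x) - f_S(x) ]

with the restricted model f_S(x) defined interventionally against a background
dataset Z: f_S(x) = mean over z in Z of f(x with features outside S replaced
by z).  For a decision tree this is computable exactly, leaf by leaf: for a
foreground/background pair (x, z), each leaf is reached precisely when every
path feature on which x and z disagree takes x's branch (call that set U) or
z's branch (set V).  Features outside U and V are null players, so the Shapley
weights collapse to a closed form per leaf:

    i in U:  phi_i += value * (|U|-1)! |V|! / (|U|+|V|)!
    i in V:  phi_i -= value * |U|! (|V|-1)! / (|U|+|V|)!

Averaging over the background and summing over trees gives attributions that
satisfy local accuracy exactly: sum_i phi_i + base = model output, where base
is the background-mean output.  No sampling is involved anywhere.

The ensemble output attributed here is the model's additive raw score:
class probabilities for a random forest (the mean of per-tree leaf class
distributions) and the per-class margin for gradient-boosted trees.
"""

from __future__ import annotations

from dataclasses import dataclass
from math import factorial

import numpy as np


@dataclass
class Leaf:
    """One leaf: its (n_outputs,) value and path conditions grouped by feature.

    ``conds[feat]`` is a list of (threshold, take_left) pairs; a point
    satisfies the leaf's f-conditions when every comparison holds, where
    "left" means ``x <= thr`` for sklearn trees and ``x < thr`` for xgboost.
    """

    value: np.ndarray
    conds: dict[int, list[tuple[float, bool]]]


@dataclass
class FlatEnsemble:
    """A tree ensemble flattened to leaves, sufficient for exact attribution."""

    leaves: list[Leaf]
    n_features: int
    n_outputs: int
    strict: bool  # True: left branch is x < thr (xgboost); False: x <= thr

    def _satisfies(self, X: np.ndarray, conds: list[tuple[float, bool]], j: int) -> np.ndarray:
        ok = np.ones(len(X), dtype=bool)
        col = X[:, j]
        for thr, left in conds:
            if self.strict:
                ok &= (col < thr) if left else ~(col < thr)
            else:
                ok &= (col <= thr) if left else ~(col <= thr)
        return ok

    def predict_raw(self, X: np.ndarray) -> np.ndarray:
        """Ensemble raw output, accumulated in float64 from the leaf table."""
        X = self._cast(X)
        out = np.zeros((len(X), self.n_outputs))
        for leaf in self.leaves:
            reach = np.ones(len(X), dtype=bool)
            for j, conds in leaf.conds.items():
                reach &= self._satisfies(X, conds, j)
            out[reach] += leaf.value
        return out

    def _cast(self, X: np.ndarray) -> np.ndarray:
        # xgboost thresholds and comparisons are float32; match them exactly
        return np.asarray(X, dtype=np.float32 if self.strict else np.float64)


def _weight_tables(n_max: int) -> tuple[np.ndarray, np.ndarray]:
    """W_pos[u, n] = (u-1)!(n-u)!/n!;  W_neg[u, n] = u!(n-u-1)!/n!."""
    wpos = np.zeros((n_max + 1, n_max + 1))
    wneg = np.zeros((n_max + 1, n_max + 1))
    for n in range(1, n_max + 1):
        for u in range(0, n + 1):
            if u >= 1:
                wpos[u, n] = factorial(u - 1) * factorial(n - u) / factorial(n)
            if n - u >= 1:
                wneg[u, n] = factorial(u) * factorial(n - u - 1) / factorial(n)
    return wpos, wneg


def interventional_shap(
    ensemble: FlatEnsemble, X_fore: np.ndarray, X_back: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Exact interventional Shapley values against a background dataset.

    Returns ``(phi, base)`` with ``phi`` of shape (n_fore, n_features,
    n_outputs) and ``base`` the background-mean raw output (n_outputs,).
    ``phi.sum(axis=1) + base`` equals ``predict_raw(X_fore)`` exactly (up to
    float64 accumulation).
    """
    Xf = ensemble._cast(X_fore)
    Xb = ensemble._cast(X_back)
    n_fore, n_back = len(Xf), len(Xb)
    phi = np.zeros((n_fore, ensemble.n_features, ensemble.n_outputs))

    max_pf = max((len(leaf.conds) for leaf in ensemble.leaves), default=1)
    wpos_t, wneg_t = _weight_tables(max(max_pf, 1))

    for leaf in ensemble.leaves:
        feats = list(leaf.conds.keys())
        if not feats:
            continue  # constant leaf: contributes only to the base
        A = np.stack([ensemble._satisfies(Xf, leaf.conds[j], j) for j in feats])
        B = np.stack([ensemble._satisfies(Xb, leaf.conds[j], j) for j in feats])
        # per-pair membership of each path feature in U (needs x) / V (needs z)
        inU = A[:, :, None] & ~B[:, None, :]  # (n_pf, n_fore, n_back)
        inV = ~A[:, :, None] & B[:, None, :]
        dead = (~A[:, :, None] & ~B[:, None, :]).any(axis=0)
        u = inU.sum(axis=0)
        v = inV.sum(axis=0)
        n_play = u + v
        alive = ~dead
        wpos = wpos_t[u, n_play]
        wneg = wneg_t[u, n_play]
        for k, j in enumerate(feats):
            contrib = (
                np.where(inU[k] & alive, wpos, 0.0) - np.where(inV[k] & alive, wneg, 0.0)
            ).mean(axis=1)
            phi[:, j, :] += contrib[:, None] * leaf.value[None, :]

    base = ensemble.predict_raw(Xb).mean(axis=0)
    return phi, base


# ---------------------------------------------------------------------------
# model adapters
# ---------------------------------------------------------------------------


def _sklearn_tree_leaves(tree, scale: float) -> list[Leaf]:
    """Flatten one sklearn decision tree into leaves of class-fraction values."""
    left, right = tree.children_left, tree.children_right
    feat, thr = tree.feature, tree.threshold
    leaves: list[Leaf] = []

    def walk(node: int, conds: dict[int, list[tuple[float, bool]]]) -> None:
        if left[node] == -1:
            dist = tree.value[node][0].astype(np.float64)
            total = dist.sum()
            value = (dist / total if total > 0 else dist) * scale
            leaves.append(Leaf(value=value, conds={k: list(v) for k, v in conds.items()}))
            return
        j = int(feat[node])
        t = float(thr[node])
        conds.setdefault(j, []).append((t, True))
        walk(int(left[node]), conds)
        conds[j][-1] = (t, False)
        walk(int(right[node]), conds)
        conds[j].pop()
        if not conds[j]:
            del conds[j]

    walk(0, {})
    return leaves


def from_random_forest(rf) -> FlatEnsemble:
    """Flatten a fitted RandomForestClassifier.

    Leaf values are per-tree class fractions divided by the number of trees,
    so ``predict_raw`` equals ``rf.predict_proba`` exactly.
    """
    leaves: list[Leaf] = []
    n_trees = len(rf.estimators_)
    for est in rf.estimators_:
        leaves.extend(_sklearn_tree_leaves(est.tree_, 1.0 / n_trees))
    return FlatEnsemble(
        leaves=leaves,
        n_features=rf.n_features_in_,
        n_outputs=len(rf.classes_),
        strict=False,
    )


def from_xgboost(clf) -> FlatEnsemble:
    """Flatten a fitted XGBClassifier into per-class margin leaves.

    Multiclass boosters assign trees to classes round-robin (tree t scores
    class ``t % n_classes``); binary models have a single margin output.
    ``predict_raw`` equals ``predict(output_margin=True)`` minus the constant
    intercept, which cancels in the attribution base.
    """
    booster = clf.get_booster()
    df = booster.trees_to_dataframe()
    n_classes = int(getattr(clf, "n_classes_", 2))
    n_outputs = n_classes if n_classes > 2 else 1
    leaves: list[Leaf] = []
    for tree_id, sub in df.groupby("Tree"):
        out = int(tree_id) % n_outputs
        nodes = sub.set_index("Node")
        kids: dict[int, tuple[int, int, int, float]] = {}
        for node_id, row in nodes.iterrows():
            if row["Feature"] == "Leaf":
                continue
            yes = int(str(row["Yes"]).split("-")[1])
            no = int(str(row["No"]).split("-")[1])
            kids[int(node_id)] = (yes, no, int(str(row["Feature"])[1:]), np.float32(row["Split"]))

        def walk(node: int, conds: dict[int, list[tuple[float, bool]]]) -> None:
            if node not in kids:
                value = np.zeros(n_outputs)
                value[out] = float(nodes.loc[node, "Gain"])  # leaf weight
                leaves.append(Leaf(value=value, conds={k: list(v) for k, v in conds.items()}))
                return
            yes, no, j, t = kids[node]
            conds.setdefault(j, []).append((t, True))
            walk(yes, conds)
            conds[j][-1] = (t, False)
            walk(no, conds)
            conds[j].pop()
            if not conds[j]:
                del conds[j]

        walk(0, {})
    return FlatEnsemble(
        leaves=leaves,
        n_features=int(clf.n_features_in_),
        n_outputs=n_outputs,
        strict=True,
    )
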