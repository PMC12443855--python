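"""Tree-ensemble training, attribution and four-view consensus selection.

The selection protocol trains a random forest and a gradient-boosted ensemble
on the same labeled methylation matrix and scores every feature from four
perspectives: RF impurity (Gini) importance, XGBoost split-gain importance,
and the mean |Shapley| attribution of each model.  Only features with
strictly positive importance in *all four* views are retained (the
"integrated" consensus); the threshold is exactly zero, with no epsilon,
because tree importances and exact tree attributions are exact sums rather
than noisy estimates.

Selection on the full labeled dataset reproduces the published protocol but
leaks label information into any subsequent cross-validation of the selected
features; per-fold (nested) selection is available in
:func:`methylstage.evaluate.nested_benefit_pvalue` and is the honest choice
for new analyses.
"""

from __future__ import annotations

import logging
import warnings
from collections import Counter
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier
from xgboost import XGBClassifier

from . import _treeshap
from .features import MethylationMatrix
from .methio import STAGES


@dataclass
class RFConfig:
    """Random-forest settings (library-conventional defaults)."""

    n_trees: int = 100
    max_features_per_split: str | int | float = "sqrt"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_trees < 1:
            raise ValueError("n_trees must be >= 1")


@dataclass
class XGBConfig:
    """Gradient-boosting settings: the regularized-objective contract.

    ``reg_gamma`` is the minimum split gain (per-leaf complexity penalty) and
    ``reg_lambda`` the L2 penalty on leaf weights; optimization itself is
    delegated to xgboost.  The defaults are a boosted-stump configuration
    suited to methylation matrices with far more features than samples and
    per-locus (additive) signal: depth-1 trees cannot chase spurious
    interaction splits, the slow learning rate with column subsampling
    spreads usage across redundant informative loci instead of stopping at
    the first few, and the minimum split gain prunes noise stumps.
    """

    n_rounds: int = 900
    learning_rate: float = 0.05
    max_depth: int = 1
    reg_gamma: float = 0.1
    reg_lambda: float = 1.0
    subsample: float = 1.0
    colsample_bytree: float = 0.15
    seed: int = 0

    def __post_init__(self) -> None:
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be > 0")
        if self.reg_gamma < 0 or self.reg_lambda < 0:
            raise ValueError("regularization parameters must be >= 0")


def canonical_class_order(labels: Sequence[str]) -> tuple[str, ...]:
    """Dormancy stages in their canonical order; other labels alphabetical."""
    uniq = set(labels)
    if uniq <= set(STAGES):
        return tuple(s for s in STAGES if s in uniq)
    return tuple(sorted(uniq))


@dataclass
class FittedModel:
    """A fitted ensemble handle with a fixed class order."""

    model: object
    classes: tuple[str, ...]
    kind: str  # "rf" | "xgb"

    def predict(self, X: np.ndarray) -> np.ndarray:
        codes = self.model.predict(np.asarray(X))
        return np.asarray([self.classes[int(c)] for c in codes])

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        return self.model.predict_proba(np.asarray(X))

    def importances(self) -> np.ndarray:
        """Impurity decrease (RF) or split gain (XGB) per feature, >= 0."""
        return np.asarray(self.model.feature_importances_, dtype=float)


def _encode(y: Sequence[str], classes: tuple[str, ...]) -> np.ndarray:
    lut = {c: i for i, c in enumerate(classes)}
    try:
        return np.asarray([lut[v] for v in y])
    except KeyError as exc:
        raise ValueError(f"label {exc} not in class order {classes}") from exc


def _check_two_classes(y: Sequence[str]) -> None:
    if len(set(y)) < 2:
        raise ValueError("training requires at least two classes")


def train_rf(X: np.ndarray, y: Sequence[str], config: RFConfig | None = None) -> FittedModel:
    """Fit a random forest (bootstrap + random feature subsets per split)."""
    config = config or RFConfig()
    _check_two_classes(y)
    classes = canonical_class_order(y)
    rf = RandomForestClassifier(
        n_estimators=config.n_trees,
        max_features=config.max_features_per_split,
        random_state=config.seed,
        n_jobs=1,
    )
    rf.fit(np.asarray(X), _encode(y, classes))
    return FittedModel(model=rf, classes=classes, kind="rf")


def train_xgb(X: np.ndarray, y: Sequence[str], config: XGBConfig | None = None) -> FittedModel:
    """Fit a gradient-boosted tree ensemble with the regularized objective."""
    config = config or XGBConfig()
    _check_two_classes(y)
    classes = canonical_class_order(y)
    xgb = XGBClassifier(
        n_estimators=config.n_rounds,
        learning_rate=config.learning_rate,
        max_depth=config.max_depth,
        gamma=config.reg_gamma,
        reg_lambda=config.reg_lambda,
        subsample=config.subsample,
        colsample_bytree=config.colsample_bytree,
        random_state=config.seed,
        n_jobs=1,
        tree_method="hist",
        importance_type="gain",
    )
    xgb.fit(np.asarray(X), _encode(y, classes))
    return FittedModel(model=xgb, classes=classes, kind="xgb")


def majority_vote(votes: Sequence[str], class_order: Sequence[str] | None = None) -> str:
    """Consensus of per-tree class votes; ties break to the lowest class index.

    The canonical class order (paradormancy < endodormancy < ecodormancy for
    stage labels) defines the tie-break.
    """
    if len(votes) == 0:
        raise ValueError("majority_vote requires a non-empty vote list")
    order = tuple(class_order) if class_order is not None else canonical_class_order(votes)
    counts = Counter(votes)
    return max(order, key=lambda c: (counts.get(c, 0), -order.index(c)))


@dataclass
class ShapleyAttribution:
    """Per-(sample, feature, output) exact attributions with their base values.

    ``phi`` has shape (n_samples, n_features, n_outputs); ``base`` is the
    background-mean raw model output and ``raw`` the raw output per sample, so
    ``phi.sum(axis=1) + base == raw`` (local accuracy).  Outputs are class
    probabilities for RF and per-class margins for XGB.
    """

    phi: np.ndarray
    base: np.ndarray
    raw: np.ndarray
    feature_ids: tuple[str, ...] = field(default_factory=tuple)
    classes: tuple[str, ...] = field(default_factory=tuple)

    def global_importance(self) -> np.ndarray:
        """Mean |phi| over samples and outputs -> one score per feature."""
        return np.abs(self.phi).mean(axis=(0, 2))

    def local_accuracy_gap(self) -> float:
        return float(np.abs(self.phi.sum(axis=1) + self.base - self.raw).max())


def attribution(
    fitted: FittedModel,
    X: np.ndarray | pd.DataFrame,
    background: np.ndarray | pd.DataFrame | None = None,
    feature_ids: Sequence[str] | None = None,
) -> ShapleyAttribution:
    """Exact interventional Shapley attribution of a fitted tree ensemble.

    ``background`` defaults to ``X`` itself (attribution relative to the
    dataset mean).  Raises for non-tree models.
    """
    if isinstance(X, pd.DataFrame):
        feature_ids = feature_ids or tuple(X.columns)
        X = X.to_numpy()
    X = np.asarray(X, dtype=float)
    Z = X if background is None else np.asarray(
        background.to_numpy() if isinstance(background, pd.DataFrame) else background,
        dtype=float,
    )
    if fitted.kind == "rf":
        ens = _treeshap.from_random_forest(fitted.model)
    elif fitted.kind == "xgb":
        ens = _treeshap.from_xgboost(fitted.model)
    else:
        raise TypeError(f"unsupported (non-tree) model kind: {fitted.kind}")
    phi, base = _treeshap.interventional_shap(ens, X, Z)
    raw = ens.predict_raw(X)
    fids = tuple(feature_ids) if feature_ids is not None else tuple(
        f"f{i}" for i in range(ens.n_features)
    )
    return ShapleyAttribution(
        phi=phi, base=base, raw=raw, feature_ids=fids, classes=fitted.classes
    )


def importance_table(
    feature_ids: Sequence[str],
    rf_model: FittedModel,
    xgb_model: FittedModel,
    shap_rf: ShapleyAttribution,
    shap_xgb: ShapleyAttribution,
) -> pd.DataFrame:
    """The four importance views, one row per feature (keyed by feature_id)."""
    table = pd.DataFrame(
        {
            "imp_rf": rf_model.importances(),
            "imp_xgb": xgb_model.importances(),
            "shap_rf": shap_rf.global_importance(),
            "shap_xgb": shap_xgb.global_importance(),
        },
        index=pd.Index(feature_ids, name="feature_id"),
    )
    if (table < 0).any().any():
        raise ValueError("importance scores must be non-negative")
    return table


def consensus_select(table: pd.DataFrame) -> list[str]:
    """Features with strictly positive importance in all four views.

    The result is ordered by mean rank across the four views (rank 1 = most
    important in a view), ties broken by feature id.  An empty result is
    allowed and warned about.
    """
    views = ["imp_rf", "imp_xgb", "shap_rf", "shap_xgb"]
    keep = (table[views] > 0).all(axis=1)
    if not keep.any():
        warnings.warn("consensus selection is empty", stacklevel=2)
        return []
    ranks = table[views].rank(ascending=False, method="average")
    mean_rank = ranks.mean(axis=1)[keep]
    order = sorted(mean_rank.index, key=lambda fid: (mean_rank[fid], fid))
    return list(order)


def select_features(
    matrix: MethylationMatrix,
    rf_config: RFConfig | None = None,
    xgb_config: XGBConfig | None = None,
) -> tuple[list[str], pd.DataFrame]:
    """Train both ensembles on the full labeled matrix and apply the consensus.

    Returns the ordered selected feature ids and the full importance table.
    Note this is selection-before-CV (the published protocol); for unbiased
    performance estimates combine with per-fold selection in the evaluation
    module.
    """
    X = matrix.values.to_numpy()
    y = matrix.labels["stage"].to_numpy()
    rf = train_rf(X, y, rf_config)
    xgb = train_xgb(X, y, xgb_config)
    shap_rf = attribution(rf, X, feature_ids=matrix.feature_ids)
    shap_xgb = attribution(xgb, X, feature_ids=matrix.feature_ids)
    table = importance_table(matrix.feature_ids, rf, xgb, shap_rf, shap_xgb)
    selected = consensus_select(table)
    n_total = len(matrix.feature_ids)
    logging.getLogger(__name__).info(
        "consensus selection: %d -> %d features (%.2f%%)",
        n_total,
        len(selected),
        100.0 * len(selected) / n_total,
    )
    return selected, table
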