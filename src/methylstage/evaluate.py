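"""Repeated stratified cross-validation, metrics and the selection-benefit test.

The two study scenarios are 3-stage classification (paradormancy /
endodormancy / ecodormancy; 3 folds so that every fold holds at least one
sample of the 9-member minority class) and 2-stage classification
(endodormancy vs ecodormancy after dropping paradormancy; 10 folds).  Fold
assignments are computed once per (labels, scheme) and shared between the
full-feature and selected-feature evaluations, which makes the paired t-test
on per-fold accuracies valid.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, NamedTuple, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.metrics import roc_auc_score
from sklearn.model_selection import RepeatedStratifiedKFold

from .features import MethylationMatrix
from .selector import (
    RFConfig,
    XGBConfig,
    canonical_class_order,
    consensus_select,
    select_features,
    train_rf,
    train_xgb,
)


@dataclass
class CVScheme:
    """Repeated stratified k-fold settings."""

    n_splits: int = 3
    n_repeats: int = 10
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_splits < 2:
            raise ValueError("n_splits must be >= 2")
        if self.n_repeats < 1:
            raise ValueError("n_repeats must be >= 1")


class Fold(NamedTuple):
    repeat: int
    fold: int
    train_idx: np.ndarray
    test_idx: np.ndarray


def stratified_folds(labels: Sequence[str], scheme: CVScheme) -> list[Fold]:
    """Deterministic repeated stratified fold assignments.

    Guarantees (inherited from proportional stratified allocation): folds
    partition the samples; each fold's per-class count differs from the ideal
    proportional share by at most one; every class appears in every fold.
    Raises if any class has fewer members than ``n_splits``, naming the class.
    """
    y = np.asarray(labels)
    classes, counts = np.unique(y, return_counts=True)
    for cls, cnt in zip(classes, counts):
        if cnt < scheme.n_splits:
            raise ValueError(
                f"class '{cls}' has {cnt} samples, fewer than n_splits={scheme.n_splits}"
            )
    splitter = RepeatedStratifiedKFold(
        n_splits=scheme.n_splits, n_repeats=scheme.n_repeats, random_state=scheme.seed
    )
    folds = []
    for i, (train_idx, test_idx) in enumerate(splitter.split(np.zeros(len(y)), y)):
        folds.append(Fold(i // scheme.n_splits, i % scheme.n_splits, train_idx, test_idx))
    return folds


def metrics_from_confusion(
    confusion: np.ndarray, class_names: Sequence[str] | None = None
) -> dict:
    """Accuracy and per-class precision/recall/F1 from a confusion matrix.

    Rows are true classes, columns predicted.  The 0/0 convention sets a
    metric to 0 (with a warning) when its denominator is zero.
    """
    cm = np.asarray(confusion)
    if cm.ndim != 2 or cm.shape[0] != cm.shape[1]:
        raise ValueError("confusion matrix must be square")
    if (cm < 0).any():
        raise ValueError("confusion matrix must be non-negative")
    k = cm.shape[0]
    names = list(class_names) if class_names is not None else [str(i) for i in range(k)]
    total = cm.sum()
    accuracy = float(np.trace(cm) / total) if total > 0 else 0.0
    per_class = {}
    for i, name in enumerate(names):
        tp = cm[i, i]
        pred = cm[:, i].sum()
        true = cm[i, :].sum()
        if pred == 0 or true == 0:
            warnings.warn(
                f"class '{name}': zero denominator; metric set to 0", stacklevel=2
            )
        precision = float(tp / pred) if pred > 0 else 0.0
        recall = float(tp / true) if true > 0 else 0.0
        f1 = (
            2 * precision * recall / (precision + recall)
            if (precision + recall) > 0
            else 0.0
        )
        per_class[name] = {"precision": precision, "recall": recall, "f1": f1}
    return {
        "accuracy": accuracy,
        "per_class": per_class,
        "macro_precision": float(np.mean([m["precision"] for m in per_class.values()])),
        "macro_recall": float(np.mean([m["recall"] for m in per_class.values()])),
        "macro_f1": float(np.mean([m["f1"] for m in per_class.values()])),
    }


@dataclass
class CVReport:
    """Per-fold metrics plus the pooled confusion matrix for one evaluation."""

    folds: pd.DataFrame  # repeat, fold, accuracy, macro_*, auc
    confusion: np.ndarray  # pooled over all repeats and folds
    classes: tuple[str, ...]
    meta: dict = field(default_factory=dict)

    @property
    def fold_accuracies(self) -> np.ndarray:
        return self.folds["accuracy"].to_numpy()

    def mean_accuracy(self) -> float:
        return float(self.folds["accuracy"].mean())

    def mean_auc(self) -> float:
        return float(self.folds["auc"].mean())

    def pooled_metrics(self) -> dict:
        return metrics_from_confusion(self.confusion, self.classes)


def _fit(X, y, model_config):
    if isinstance(model_config, RFConfig):
        return train_rf(X, y, model_config)
    if isinstance(model_config, XGBConfig):
        return train_xgb(X, y, model_config)
    raise TypeError(f"unsupported model config: {type(model_config)!r}")


def _fold_auc(y_true_codes, proba, n_classes) -> float:
    if n_classes == 2:
        return float(roc_auc_score(y_true_codes, proba[:, 1]))
    return float(
        roc_auc_score(
            y_true_codes, proba, multi_class="ovr", average="macro", labels=range(n_classes)
        )
    )


def cross_validate(
    X: np.ndarray | pd.DataFrame,
    labels: Sequence[str],
    model_config: RFConfig | XGBConfig,
    scheme: CVScheme,
    folds: list[Fold] | None = None,
    meta: dict | None = None,
) -> CVReport:
    """Repeated stratified k-fold evaluation of one model on one matrix.

    Trains on each fold's training split only and predicts the held-out
    samples; any training failure aborts the run.  AUC is one-vs-rest
    macro-averaged over class-probability outputs for the multiclass case.
    """
    X = np.asarray(X.to_numpy() if isinstance(X, pd.DataFrame) else X, dtype=float)
    y = np.asarray(labels)
    classes = canonical_class_order(y)
    code = {c: i for i, c in enumerate(classes)}
    if folds is None:
        folds = stratified_folds(y, scheme)
    rows = []
    pooled = np.zeros((len(classes), len(classes)), dtype=int)
    for fd in folds:
        fitted = _fit(X[fd.train_idx], y[fd.train_idx], model_config)
        pred = fitted.predict(X[fd.test_idx])
        proba_local = fitted.predict_proba(X[fd.test_idx])
        # re-embed fold-local class columns into the global class order
        proba = np.zeros((len(fd.test_idx), len(classes)))
        for j, c in enumerate(fitted.classes):
            proba[:, code[c]] = proba_local[:, j]
        cm = np.zeros((len(classes), len(classes)), dtype=int)
        for t, p in zip(y[fd.test_idx], pred):
            cm[code[t], code[p]] += 1
        pooled += cm
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            m = metrics_from_confusion(cm, classes)
        true_codes = np.asarray([code[t] for t in y[fd.test_idx]])
        rows.append(
            {
                "repeat": fd.repeat,
                "fold": fd.fold,
                "accuracy": m["accuracy"],
                "macro_precision": m["macro_precision"],
                "macro_recall": m["macro_recall"],
                "macro_f1": m["macro_f1"],
                "auc": _fold_auc(true_codes, proba, len(classes)),
            }
        )
    return CVReport(
        folds=pd.DataFrame(rows),
        confusion=pooled,
        classes=classes,
        meta=dict(meta or {}),
    )


class BenefitTest(NamedTuple):
    """Paired t-test of per-fold score differences (selected - full)."""

    t: float
    p: float
    degenerate: bool


def selection_benefit_test(
    scores_full: Sequence[float], scores_selected: Sequence[float]
) -> BenefitTest:
    """Two-sided paired t-test on per-fold accuracies under identical folds.

    Zero-variance differences are flagged degenerate: p = 1 when the mean
    difference is exactly 0, else p = 0 with an infinite t (never NaN).
    """
    a = np.asarray(scores_full, dtype=float)
    b = np.asarray(scores_selected, dtype=float)
    if a.shape != b.shape:
        raise ValueError("paired score vectors must have identical shape")
    d = b - a
    if np.allclose(d.std(ddof=1) if len(d) > 1 else 0.0, 0.0):
        if np.allclose(d.mean(), 0.0):
            return BenefitTest(0.0, 1.0, True)
        return BenefitTest(float(np.sign(d.mean()) * np.inf), 0.0, True)
    t, p = stats.ttest_rel(b, a)
    return BenefitTest(float(t), float(p), False)


def grouping_score(X: np.ndarray | pd.DataFrame, labels: Sequence[str]) -> float:
    """Leave-one-out nearest-centroid accuracy: how well a labeling groups X.

    Each sample is assigned to the label whose centroid (computed without the
    sample itself) is nearest in Euclidean distance; the score is the fraction
    of samples assigned their own label.  Comparing the score for stage labels
    vs cultivar labels quantifies which structure dominates a feature space.
    """
    X = np.asarray(X.to_numpy() if isinstance(X, pd.DataFrame) else X, dtype=float)
    y = np.asarray(labels)
    classes = np.unique(y)
    sums = {c: X[y == c].sum(axis=0) for c in classes}
    counts = {c: int((y == c).sum()) for c in classes}
    if min(counts.values()) < 2:
        raise ValueError("grouping_score requires >= 2 samples per label")
    correct = 0
    for i in range(len(X)):
        best, best_d = None, np.inf
        for c in classes:
            if c == y[i]:
                cen = (sums[c] - X[i]) / (counts[c] - 1)
            else:
                cen = sums[c] / counts[c]
            d = float(np.linalg.norm(X[i] - cen))
            if d < best_d:
                best, best_d = c, d
        correct += int(best == y[i])
    return correct / len(X)


@dataclass
class ScenarioReport:
    """All CV reports and benefit tests for one scenario run."""

    reports: dict  # (dataset_kind, variant, model) -> CVReport
    benefit: dict  # (dataset_kind, model) -> BenefitTest
    scenario: str


def run_scenario(
    datasets: Mapping[str, Mapping[str, MethylationMatrix]],
    scenario: str,
    scheme: CVScheme,
    models: Mapping[str, RFConfig | XGBConfig] | None = None,
) -> ScenarioReport:
    """Evaluate full vs selected matrices for every dataset kind and model.

    ``datasets`` maps a dataset kind ("cytosine", "region") to its "full" and
    "selected" matrices over the same samples.  The 2-stage scenario removes
    paradormancy samples before anything else.  Fold assignments are shared
    between the full and selected variant of each (kind, model) pair.
    """
    if scenario not in ("3stage", "2stage"):
        raise ValueError(f"unknown scenario: {scenario}")
    models = dict(models) if models is not None else {"rf": RFConfig(), "xgb": XGBConfig()}
    reports: dict = {}
    benefit: dict = {}
    for kind, variants in datasets.items():
        if set(variants) != {"full", "selected"}:
            raise ValueError(f"dataset '{kind}' must provide 'full' and 'selected'")
        mats = dict(variants)
        if scenario == "2stage":
            keep = [
                s
                for s, stg in mats["full"].labels["stage"].items()
                if stg != "paradormancy"
            ]
            mats = {v: m.subset_samples(keep) for v, m in mats.items()}
        if list(mats["full"].sample_ids) != list(mats["selected"].sample_ids):
            raise ValueError(f"dataset '{kind}': sample sets differ between variants")
        y = mats["full"].labels["stage"].to_numpy()
        if scenario == "3stage" and len(set(y)) != 3:
            raise ValueError("3stage scenario requires all three stages present")
        folds = stratified_folds(y, scheme)
        for model_name, config in models.items():
            scores = {}
            for variant in ("full", "selected"):
                rep = cross_validate(
                    mats[variant].values,
                    y,
                    config,
                    scheme,
                    folds=folds,
                    meta={
                        "scenario": scenario,
                        "dataset": kind,
                        "variant": variant,
                        "model": model_name,
                        "seed": scheme.seed,
                    },
                )
                reports[(kind, variant, model_name)] = rep
                scores[variant] = rep.fold_accuracies
            benefit[(kind, model_name)] = selection_benefit_test(
                scores["full"], scores["selected"]
            )
    return ScenarioReport(reports=reports, benefit=benefit, scenario=scenario)


def nested_benefit_pvalue(
    matrix: MethylationMatrix,
    scheme: CVScheme,
    model_config: RFConfig | XGBConfig | None = None,
    rf_config: RFConfig | None = None,
    xgb_config: XGBConfig | None = None,
) -> tuple[BenefitTest, pd.DataFrame]:
    """Selection benefit with per-fold (nested) consensus selection.

    For every fold the consensus selection is recomputed from the training
    split only, so no label information from the held-out samples reaches the
    selected feature set.  This is the honest protocol for judging whether
    selection helps; selection on the full data (the published protocol)
    overstates the benefit.  If a fold's consensus is empty, the single
    feature with the best mean rank is used so the comparison stays defined.
    """
    model_config = model_config or RFConfig()
    rf_config = rf_config or RFConfig()
    xgb_config = xgb_config or XGBConfig()
    X = matrix.values
    y = matrix.labels["stage"].to_numpy()
    folds = stratified_folds(y, scheme)
    rows = []
    for fd in folds:
        train_mat = MethylationMatrix(
            values=X.iloc[fd.train_idx],
            coords=matrix.coords,
            labels=matrix.labels.iloc[fd.train_idx],
        )
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            selected, table = select_features(train_mat, rf_config, xgb_config)
        if not selected:
            ranks = table.rank(ascending=False, method="average").mean(axis=1)
            selected = [ranks.idxmin()]
        Xtr, Xte = X.iloc[fd.train_idx], X.iloc[fd.test_idx]
        ytr, yte = y[fd.train_idx], y[fd.test_idx]
        acc = {}
        for variant, cols in (("full", list(X.columns)), ("selected", selected)):
            fitted = _fit(Xtr[cols].to_numpy(), ytr, model_config)
            pred = fitted.predict(Xte[cols].to_numpy())
            acc[variant] = float(np.mean(pred == yte))
        rows.append(
            {
                "repeat": fd.repeat,
                "fold": fd.fold,
                "accuracy_full": acc["full"],
                "accuracy_selected": acc["selected"],
                "n_selected": len(selected),
            }
        )
    df = pd.DataFrame(rows)
    test = selection_benefit_test(
        df["accuracy_full"].to_numpy(), df["accuracy_selected"].to_numpy()
    )
    return test, df
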