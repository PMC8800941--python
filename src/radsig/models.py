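"""Response-to-therapy classifiers and their cross-validated evaluation.

Three classifiers — CART (Gini binary splits), SVM with RBF kernel and L2
regularization, and Gaussian Naive Bayes — are evaluated under stratified
10-fold cross-validation. Features are standardized inside each training
fold only. Out-of-fold predictions are pooled into a single confusion
matrix from which accuracy, F-score, sensitivity, specificity, precision,
and NPV are computed (macro-averaged one-vs-rest for the 3-class task).
All metrics are reported in percent.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.model_selection import StratifiedKFold
from sklearn.naive_bayes import GaussianNB
from sklearn.pipeline import make_pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC
from sklearn.tree import DecisionTreeClassifier

MODEL_KINDS = ("cart", "svm_rbf", "gaussian_nb")


@dataclass
class ModelSpec:
    kind: str = "gaussian_nb"
    max_depth: int | None = None  # cart
    svm_c: float = 1.0
    svm_gamma: str | float = "scale"
    nb_var_smoothing: float = 1e-9
    seed: int = 0

    def build(self):
        if self.kind == "cart":
            clf = DecisionTreeClassifier(
                criterion="gini", max_depth=self.max_depth,
                random_state=self.seed,
            )
        elif self.kind == "svm_rbf":
            clf = SVC(kernel="rbf", C=self.svm_c, gamma=self.svm_gamma)
        elif self.kind == "gaussian_nb":
            clf = GaussianNB(var_smoothing=self.nb_var_smoothing)
        else:
            raise ValueError(f"unknown model kind {self.kind!r}")
        return make_pipeline(StandardScaler(), clf)


@dataclass
class PerformanceReport:
    """Pooled-confusion performance of one model on one task (percent)."""

    model: str
    task: str
    classes: list[str]
    confusion: np.ndarray  # rows = true, cols = predicted
    accuracy: float
    f_score: float
    sensitivity: float
    specificity: float
    precision: float
    npv: float
    n_folds: int
    seed: int

    def metrics(self) -> dict[str, float]:
        return {
            "accuracy": self.accuracy,
            "f_score": self.f_score,
            "sensitivity": self.sensitivity,
            "specificity": self.specificity,
            "precision": self.precision,
            "npv": self.npv,
        }


def confusion_metrics(
    confusion: np.ndarray, positive_index: int | None = None
) -> dict[str, float]:
    """The six performance metrics (percent) from an integer confusion
    matrix.

    Binary tasks report positive-class sensitivity/specificity/precision/
    NPV/F (``positive_index`` selects the positive class, default 0);
    multi-class values are macro-averaged one-vs-rest. Accuracy is overall.
    """
    cm = np.asarray(confusion, dtype=float)
    n = cm.sum()
    acc = np.trace(cm) / n
    if cm.shape[0] == 2:
        class_range = [0 if positive_index is None else positive_index]
    else:
        class_range = range(cm.shape[0])
    sens, spec, prec, npv, f1 = [], [], [], [], []
    for c in class_range:
        tp = cm[c, c]
        fn = cm[c].sum() - tp
        fp = cm[:, c].sum() - tp
        tn = n - tp - fn - fp
        s = tp / (tp + fn) if tp + fn > 0 else 0.0
        p = tp / (tp + fp) if tp + fp > 0 else 0.0
        sens.append(s)
        spec.append(tn / (tn + fp) if tn + fp > 0 else 0.0)
        prec.append(p)
        npv.append(tn / (tn + fn) if tn + fn > 0 else 0.0)
        f1.append(2 * p * s / (p + s) if p + s > 0 else 0.0)
    return {
        "accuracy": 100.0 * acc,
        "f_score": 100.0 * float(np.mean(f1)),
        "sensitivity": 100.0 * float(np.mean(sens)),
        "specificity": 100.0 * float(np.mean(spec)),
        "precision": 100.0 * float(np.mean(prec)),
        "npv": 100.0 * float(np.mean(npv)),
    }


def _fold_iter(y: np.ndarray, folds: int, seed: int):
    """Stratified folds; reduce fold count when a class is too small."""
    _, counts = np.unique(y, return_counts=True)
    k = min(folds, int(counts.min()), len(y))
    if k < folds:
        warnings.warn(f"reducing folds from {folds} to {k} (small class)")
    if k < 2:
        raise ValueError("not enough samples per class for cross-validation")
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    return k, skf.split(np.zeros_like(y), y)


def cross_validate(
    table: pd.DataFrame,
    labels: pd.Series,
    spec: ModelSpec | None = None,
    folds: int = 10,
    seed: int = 0,
    task: str = "prediction",
) -> PerformanceReport:
    """Stratified k-fold CV with one pooled confusion matrix."""
    if spec is None:
        spec = ModelSpec()
    x = table.to_numpy(dtype=float)
    idx = (
        table.index.get_level_values("subject_id")
        if isinstance(table.index, pd.MultiIndex)
        else table.index
    )
    y = np.asarray(labels.loc[idx])
    classes = sorted(np.unique(y).tolist())
    class_pos = {c: i for i, c in enumerate(classes)}
    cm = np.zeros((len(classes), len(classes)), dtype=int)
    k, splits = _fold_iter(y, folds, seed)
    for train, test in splits:
        model = spec.build()
        model.fit(x[train], y[train])
        pred = model.predict(x[test])
        for t, p in zip(y[test], pred):
            cm[class_pos[t], class_pos[p]] += 1
    positive = None
    if len(classes) == 2:
        for cand in ("pCR", "response", "Yes", "class_1"):
            if cand in class_pos:
                positive = class_pos[cand]
                break
        if positive is None:
            positive = 0
    m = confusion_metrics(cm, positive)
    return PerformanceReport(
        model=spec.kind, task=task, classes=classes, confusion=cm,
        n_folds=k, seed=seed, **m,
    )


def evaluate_predictors(
    predictors: dict[str, pd.DataFrame],
    labels: pd.Series,
    spec: ModelSpec | None = None,
    folds: int = 10,
    seed: int = 0,
    task: str = "prediction",
    reference: str = "radsig",
) -> pd.DataFrame:
    """Same model, same folds, different predictor sets (RadSig vs single
    SUV metrics); returns metrics plus percent improvement of the reference
    predictor over each other predictor."""
    reports = {
        name: cross_validate(tbl, labels, spec, folds, seed, task)
        for name, tbl in predictors.items()
    }
    rows = []
    ref = reports[reference].metrics() if reference in reports else None
    for name, rep in reports.items():
        row = {"predictor": name, **rep.metrics()}
        if ref is not None and name != reference:
            for metric, value in rep.metrics().items():
                row[f"improvement_{metric}"] = (
                    100.0 * (ref[metric] - value) / value if value > 0 else np.nan
                )
        rows.append(row)
    return pd.DataFrame(rows).set_index("predictor")


def accuracy_vs_feature_count(
    table: pd.DataFrame,
    labels: pd.Series,
    ranked_features: list[str],
    specs: list[ModelSpec] | None = None,
    max_n: int | None = None,
    folds: int = 10,
    seed: int = 0,
) -> pd.DataFrame:
    """Pooled-CV accuracy at each feature count 1..max_n along the ranked
    list, one column per model; used to locate the saturation point."""
    if specs is None:
        specs = [ModelSpec(kind=k) for k in MODEL_KINDS]
    if max_n is None:
        max_n = len(ranked_features)
    max_n = min(max_n, len(ranked_features))
    rows = []
    for n_feat in range(1, max_n + 1):
        sub = table[ranked_features[:n_feat]]
        row = {"n_features": n_feat}
        for spec in specs:
            rep = cross_validate(sub, labels, spec, folds, seed)
            row[spec.kind] = rep.accuracy
        rows.append(row)
    return pd.DataFrame(rows).set_index("n_features")


def saturation_point(curve: pd.Series, tolerance: float = 0.98) -> int:
    """Smallest feature count reaching ``tolerance`` x the curve maximum."""
    target = tolerance * curve.max()
    for n, v in curve.items():
        if v >= target:
            return int(n)
    return int(curve.index[-1])
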