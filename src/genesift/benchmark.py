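"""Multi-classifier cross-validated benchmark of a gene subset.

Evaluates a subset (or the full matrix) with ten classifier families —
XGBoost, LightGBM, random forest, extra trees, Gaussian naive Bayes, k-NN,
logistic regression, decision tree, RBF-kernel SVM and LDA — under
stratified k-fold cross-validation (default k = 10, shuffled from a fixed
seed).  Accuracy, recall, precision and F1 are computed from the pooled
out-of-fold predictions (positive class = 1, i.e. ruptured), yielding a
single pooled 2x2 confusion matrix per model, while ROC AUC is reported as
the per-fold mean ± SD.  Hyperparameters for the families are pinned in
``config/benchmark_models.yaml``.
"""

from __future__ import annotations

import logging
import warnings
from contextlib import contextmanager
from dataclasses import dataclass, field
from importlib import resources

import numpy as np
import pandas as pd
import yaml
from lightgbm import LGBMClassifier
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis
from sklearn.ensemble import ExtraTreesClassifier, RandomForestClassifier
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import (
    accuracy_score,
    confusion_matrix,
    f1_score,
    precision_score,
    recall_score,
    roc_auc_score,
)
from sklearn.model_selection import StratifiedKFold
from sklearn.naive_bayes import GaussianNB
from sklearn.neighbors import KNeighborsClassifier
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC
from sklearn.tree import DecisionTreeClassifier
from xgboost import XGBClassifier

log = logging.getLogger(__name__)

__all__ = [
    "MODEL_NAMES",
    "BenchmarkReport",
    "build_model",
    "cross_validate",
    "compute_metrics",
    "benchmark_suite",
]

_FACTORIES = {
    "XGBoost": XGBClassifier,
    "LightGBM": LGBMClassifier,
    "RandomForest": RandomForestClassifier,
    "ExtraTrees": ExtraTreesClassifier,
    "GaussianNB": GaussianNB,
    "KNN": KNeighborsClassifier,
    "LogisticRegression": LogisticRegression,
    "DecisionTree": DecisionTreeClassifier,
    "SVM": SVC,
    "LDA": LinearDiscriminantAnalysis,
}
# families without a random_state parameter
_NO_SEED = {"GaussianNB", "KNN", "LDA"}

MODEL_NAMES = tuple(_FACTORIES)


@contextmanager
def _quiet_fit():
    # lightgbm's sklearn wrapper records synthetic feature names and then
    # complains when plain arrays come back at predict time
    with warnings.catch_warnings():
        warnings.filterwarnings("ignore", message="X does not have valid feature names")
        yield


def _load_params() -> dict:
    text = resources.files("genesift").joinpath("config/benchmark_models.yaml").read_text()
    return yaml.safe_load(text)


def build_model(name: str, seed: int | None = None) -> Pipeline:
    """Instantiate one pinned model family inside a StandardScaler pipeline."""
    if name not in _FACTORIES:
        raise ValueError(f"unknown model {name!r}; choose from {sorted(_FACTORIES)}")
    params = dict(_load_params().get(name, {}))
    if name not in _NO_SEED:
        params["random_state"] = seed
    clf = _FACTORIES[name](**params)
    return Pipeline([("scale", StandardScaler()), ("clf", clf)])


def cross_validate(model_name: str, X, y, k: int = 10, seed: int | None = None) -> dict:
    """Stratified k-fold CV of one family; every sample predicted once.

    Returns pooled out-of-fold hard predictions and continuous scores
    (probability of class 1, or the decision value for margin classifiers)
    plus the per-fold ROC AUC list.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y).astype(int)
    if k < 2:
        raise ValueError("k must be >= 2")
    counts = np.bincount(y, minlength=2)
    if counts.min() < k:
        raise ValueError(
            f"class with {counts.min()} members cannot be split into {k} "
            "stratified folds; use a smaller k"
        )
    folds = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    y_pred = np.empty(len(y), dtype=int)
    y_score = np.empty(len(y), dtype=float)
    fold_auc = []
    for tr, te in folds.split(X, y):
        model = build_model(model_name, seed=seed)
        with _quiet_fit():
            model.fit(X[tr], y[tr])
            if hasattr(model, "predict_proba"):
                score = model.predict_proba(X[te])[:, 1]
            else:
                score = model.decision_function(X[te])
            y_pred[te] = model.predict(X[te])
        y_score[te] = score
        fold_auc.append(float(roc_auc_score(y[te], score)))
    return {
        "y_true": y,
        "y_pred": y_pred,
        "y_score": y_score,
        "fold_auc": np.array(fold_auc),
    }


def compute_metrics(y_true, y_pred, y_score=None) -> dict:
    """Accuracy / recall / precision / F1 / confusion matrix, class 1 positive.

    Precision is 0 (with a warning) when no positive predictions exist.
    The confusion matrix has rows = true label, columns = predicted label.
    """
    y_true = np.asarray(y_true).astype(int)
    y_pred = np.asarray(y_pred).astype(int)
    if y_true.shape != y_pred.shape:
        raise ValueError("y_true and y_pred must have equal length")
    if np.unique(y_true).size < 2:
        raise ValueError("y_true must contain both classes")
    if (y_pred == 1).sum() == 0:
        log.warning("no positive predictions; precision set to 0")
    out = {
        "accuracy": float(accuracy_score(y_true, y_pred)),
        "recall": float(recall_score(y_true, y_pred, pos_label=1, zero_division=0)),
        "precision": float(precision_score(y_true, y_pred, pos_label=1, zero_division=0)),
        "f1": float(f1_score(y_true, y_pred, pos_label=1, zero_division=0)),
        "confusion": confusion_matrix(y_true, y_pred, labels=[0, 1]),
    }
    if y_score is not None:
        out["auc"] = float(roc_auc_score(y_true, np.asarray(y_score, dtype=float)))
    return out


@dataclass
class BenchmarkReport:
    """Per-model CV metrics plus a mean row and pooled confusion matrices."""

    table: pd.DataFrame  # rows = model families + final "Mean" row
    confusions: dict = field(default_factory=dict)  # model -> 2x2 int array
    k: int = 10
    seed: int | None = None
    subset: list | None = None

    @property
    def mean_row(self) -> pd.Series:
        return self.table.iloc[-1]

    def to_tsv(self, path) -> None:
        self.table.to_csv(path, sep="\t", index=False, float_format="%.6f")


def benchmark_suite(X, y, gene_ids=None, subset="all", k: int = 10, seed: int | None = None) -> BenchmarkReport:
    """Run all ten families on the chosen gene subset and aggregate.

    ``subset`` is either ``"all"`` or a list of gene identifiers present in
    ``gene_ids`` (column indices when ``gene_ids`` is None).  Identical
    seeds give identical reports.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y).astype(int)
    if gene_ids is None:
        gene_ids = list(range(X.shape[1]))
    gene_ids = list(gene_ids)
    if isinstance(subset, str) and subset == "all":
        cols = np.arange(X.shape[1])
        chosen = gene_ids
    else:
        index = {g: j for j, g in enumerate(gene_ids)}
        missing = [g for g in subset if g not in index]
        if missing:
            raise ValueError(f"subset genes not in matrix: {missing}")
        cols = np.array([index[g] for g in subset], dtype=int)
        chosen = list(subset)
    sub = X[:, cols]

    rows = []
    confusions = {}
    for name in MODEL_NAMES:
        cv = cross_validate(name, sub, y, k=k, seed=seed)
        m = compute_metrics(cv["y_true"], cv["y_pred"])
        rows.append(
            {
                "model": name,
                "accuracy": m["accuracy"],
                "recall": m["recall"],
                "precision": m["precision"],
                "f1": m["f1"],
                "auc_mean": float(cv["fold_auc"].mean()),
                "auc_sd": float(cv["fold_auc"].std(ddof=1)),
            }
        )
        confusions[name] = m["confusion"]
    table = pd.DataFrame(rows)
    mean = table.drop(columns="model").mean()
    table = pd.concat(
        [table, pd.DataFrame([{"model": "Mean", **mean.to_dict()}])],
        ignore_index=True,
    )
    return BenchmarkReport(table=table, confusions=confusions, k=k, seed=seed, subset=chosen)
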