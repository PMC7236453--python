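"""Comparison classifiers: SVM (RBF, grid-searched), random forest, logistic regression.

These follow the conventional workflow the wavelet-CNN is compared against:
a t-test + fold-change gene pre-filter, then an off-the-shelf classifier on
the retained genes.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.ensemble import RandomForestClassifier
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import GridSearchCV, StratifiedKFold
from sklearn.preprocessing import StandardScaler
from sklearn.pipeline import Pipeline
from sklearn.svm import SVC

logger = logging.getLogger(__name__)

BASELINE_KINDS = ("svm", "random_forest", "logistic")

_EPS = 1e-9


@dataclass
class FilterResult:
    gene_ids: list            # retained genes
    p_values: pd.Series       # per-gene, all genes
    fold_changes: pd.Series   # ratio of class-1 to class-0 means, all genes

    def __len__(self):
        return len(self.gene_ids)


def ttest_fc_filter(
    expr: pd.DataFrame,
    labels,
    p_threshold: float = 0.05,
    log2fc_threshold: float = 1.0,
    log_transform: bool = False,
) -> FilterResult:
    """Student's t-test (pooled variance) + fold-change gene filter.

    A gene is retained when p < p_threshold and |log2 FC| > log2fc_threshold
    (fold change = ratio of class means with a small pseudocount, i.e.
    "fold change > 2 or < 0.5" at the default threshold). Empty retention is
    allowed and logged.
    """
    labels = np.asarray(labels, dtype=int)
    vals = expr.to_numpy(dtype=float)
    if log_transform:
        vals = np.log2(vals + 1.0)
    g1 = vals[:, labels == 1]
    g0 = vals[:, labels == 0]
    if g1.shape[1] < 2 or g0.shape[1] < 2:
        raise ValueError("need at least 2 samples per class for the t-test")
    with np.errstate(divide="ignore", invalid="ignore"):
        _, p = stats.ttest_ind(g1, g0, axis=1, equal_var=True)
    fc = (g1.mean(axis=1) + _EPS) / (g0.mean(axis=1) + _EPS)
    p = np.where(np.isnan(p), 1.0, p)
    keep = (p < p_threshold) & (np.abs(np.log2(fc)) > log2fc_threshold)
    retained = expr.index[keep].tolist()
    if not retained:
        logger.warning("ttest_fc_filter retained no genes at p<%.3g, |log2FC|>%.3g",
                       p_threshold, log2fc_threshold)
    return FilterResult(retained, pd.Series(p, index=expr.index),
                        pd.Series(fc, index=expr.index))


class _MarginScorer:
    """Expose an SVM decision margin through the predict_proba column convention."""

    def __init__(self, model):
        self.model = model

    def predict(self, X):
        return self.model.predict(X)

    def predict_proba(self, X):
        margin = self.model.decision_function(X)
        return np.column_stack([-margin, margin])


def fit_baseline(
    kind: str,
    X_train: np.ndarray,
    y_train: np.ndarray,
    random_state: int = 0,
    svm_grid=None,
    cv_folds: int = 3,
):
    """Fit a baseline classifier on pre-filtered expression (samples x genes).

    SVM uses an RBF kernel with cost/width chosen by inner cross-validated
    grid search on logarithmic grids; random forest and logistic regression
    run at library defaults with a fixed seed. The returned object exposes
    ``predict_proba``; use column 1 as the continuous score for AUC.
    """
    if kind not in BASELINE_KINDS:
        raise ValueError(f"unknown baseline {kind!r}; choose from {BASELINE_KINDS}")
    X_train = np.asarray(X_train, dtype=float)
    y_train = np.asarray(y_train, dtype=int)
    if X_train.shape[1] == 0:
        raise ValueError("empty gene set after filtering; relax the filter thresholds")

    if kind == "svm":
        grid = svm_grid or {"svc__C": np.logspace(-3, 3, 7), "svc__gamma": np.logspace(-3, 3, 7)}
        pipe = Pipeline([("scale", StandardScaler()), ("svc", SVC(kernel="rbf"))])
        cv = StratifiedKFold(cv_folds, shuffle=True, random_state=random_state)
        search = GridSearchCV(pipe, grid, cv=cv, scoring="roc_auc", n_jobs=1)
        search.fit(X_train, y_train)
        return _MarginScorer(search.best_estimator_)
    if kind == "random_forest":
        return RandomForestClassifier(random_state=random_state).fit(X_train, y_train)
    return Pipeline(
        [("scale", StandardScaler()), ("lr", LogisticRegression(max_iter=1000, random_state=random_state))]
    ).fit(X_train, y_train)
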