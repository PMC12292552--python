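"""Classical baselines over utterance-level acoustic features.

Two classifier families mirror the usual comparison points for encoder
fine-tuning studies:

* :class:`MLPBaseline` — a multilayer perceptron with exactly the same head
  architecture as the deep model's classifier (input → 64 → ReLU → dropout →
  2 logits), trained with AdamW.
* :class:`GradientBoostedTreesBaseline` — gradient-boosted trees (xgboost)
  behind a small cross-validated grid search over depth, learning rate and
  number of estimators.

Both are scikit-learn compatible estimators producing calibrated class
probabilities (two columns summing to one).
"""

from __future__ import annotations

import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.model_selection import GridSearchCV
from sklearn.utils.validation import check_is_fitted

from .autodiff import Tensor
from .model import ClassifierHead
from .nn import AdamW, cross_entropy

__all__ = ["MLPBaseline", "GradientBoostedTreesBaseline", "train_baseline"]

DEFAULT_GBT_GRID = {
    "max_depth": [3, 5, 7],
    "learning_rate": [0.05, 0.1],
    "n_estimators": [100, 300],
}


def _validate_xy(X, y):
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    if X.ndim != 2:
        raise ValueError("feature matrix must be 2-D with uniform row length")
    if not np.all(np.isfinite(X)):
        raise ValueError("features contain non-finite values")
    classes = np.unique(y)
    if classes.size < 2:
        raise ValueError("training labels contain a single class")
    return X, y, classes


class MLPBaseline(BaseEstimator, ClassifierMixin):
    """MLP with the deep model's classification-head architecture."""

    def __init__(self, epochs: int = 200, batch_size: int = 32, lr: float = 1e-3,
                 dropout: float = 0.2, weight_decay: float = 0.01, seed: int = 0):
        self.epochs = epochs
        self.batch_size = batch_size
        self.lr = lr
        self.dropout = dropout
        self.weight_decay = weight_decay
        self.seed = seed

    def fit(self, X, y):
        X, y, classes = _validate_xy(X, y)
        self.classes_ = classes
        y_idx = np.searchsorted(classes, y)
        # standardise features: tree-free nets want comparable scales
        self.mean_ = X.mean(axis=0)
        self.scale_ = np.where(X.std(axis=0) > 0, X.std(axis=0), 1.0)
        Xs = (X - self.mean_) / self.scale_
        head = ClassifierHead(X.shape[1], n_classes=classes.size,
                              dropout=self.dropout, seed=self.seed)
        optimizer = AdamW(head.parameters(), lr=self.lr, weight_decay=self.weight_decay)
        rng = np.random.default_rng(self.seed)
        n = X.shape[0]
        for _ in range(self.epochs):
            head.train(True)
            order = rng.permutation(n)
            for lo in range(0, n, self.batch_size):
                idx = order[lo:lo + self.batch_size]
                logits = head(Tensor(Xs[idx]))
                loss = cross_entropy(logits, y_idx[idx])
                optimizer.zero_grad()
                loss.backward()
                optimizer.step()
        head.eval()
        self.head_ = head
        return self

    def predict_proba(self, X):
        check_is_fitted(self, "head_")
        Xs = (np.asarray(X, dtype=float) - self.mean_) / self.scale_
        logits = self.head_(Tensor(Xs)).data
        shifted = logits - logits.max(axis=1, keepdims=True)
        e = np.exp(shifted)
        return e / e.sum(axis=1, keepdims=True)

    def predict(self, X):
        return self.classes_[np.argmax(self.predict_proba(X), axis=1)]


class GradientBoostedTreesBaseline(BaseEstimator, ClassifierMixin):
    """xgboost classifier behind a small CV grid search."""

    def __init__(self, param_grid: dict | None = None, cv: int = 3, seed: int = 0):
        self.param_grid = param_grid
        self.cv = cv
        self.seed = seed

    def fit(self, X, y):
        from xgboost import XGBClassifier

        X, y, classes = _validate_xy(X, y)
        self.classes_ = classes
        y_idx = np.searchsorted(classes, y)
        grid = self.param_grid if self.param_grid is not None else DEFAULT_GBT_GRID
        base = XGBClassifier(random_state=self.seed, n_jobs=1, eval_metric="logloss",
                             tree_method="hist")
        search = GridSearchCV(base, grid, cv=self.cv, scoring="f1", n_jobs=1)
        search.fit(X, y_idx)
        self.model_ = search.best_estimator_
        self.best_params_ = search.best_params_
        return self

    def predict_proba(self, X):
        check_is_fitted(self, "model_")
        return self.model_.predict_proba(np.asarray(X, dtype=float))

    def predict(self, X):
        return self.classes_[np.argmax(self.predict_proba(X), axis=1)]


def train_baseline(features, labels, model_kind: str = "MLP", config: dict | None = None,
                   seed: int = 0):
    """Fit one of the baseline classifiers; returns the fitted estimator.

    ``model_kind`` is ``"MLP"`` or ``"GBT"``; ``config`` holds estimator
    keyword arguments.
    """
    config = dict(config or {})
    if model_kind == "MLP":
        est = MLPBaseline(seed=seed, **config)
    elif model_kind == "GBT":
        est = GradientBoostedTreesBaseline(seed=seed, **config)
    else:
        raise ValueError(f"model_kind must be 'MLP' or 'GBT', got {model_kind!r}")
    return est.fit(np.asarray(features, dtype=float), np.asarray(labels))
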