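"""Feature selection, the MLP classifier and evaluation metrics.

Selection fits a random forest, ranks features by impurity importance and
keeps those at or above a threshold tuned by cross-validation over a grid
spanning 0 to the maximum importance (maximizing mean validation balanced
accuracy). The classifier is a two-hidden-layer MLP (40 and 10 nodes, two
softmax outputs) with dropout 0.4 on the input layer, trained with Adam on
the cross-entropy loss; the input-dropout layer is part of the specified
architecture, so the network is implemented directly on numpy arrays and is
fully deterministic for a fixed seed.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from sklearn.ensemble import RandomForestClassifier
from sklearn.metrics import balanced_accuracy_score, roc_auc_score, roc_curve
from sklearn.model_selection import StratifiedKFold


# ------------------------------------------------------------- selection

@dataclass
class SelectionConfig:
    """Importance-threshold feature selection settings.

    The importance forest uses ``n_trees``; candidate thresholds are
    ``threshold_grid_size`` even steps over [0, max importance]; each
    candidate subset is scored by ``cv_folds``-fold CV balanced accuracy of
    a lighter ``eval_trees`` forest.
    """

    n_trees: int = 500
    threshold_grid_size: int = 50
    cv_folds: int = 5
    eval_trees: int = 50
    seed: int = 0

    def __post_init__(self) -> None:
        if self.cv_folds < 2:
            raise ValueError("cv_folds must be >= 2")
        if self.threshold_grid_size < 2:
            raise ValueError("threshold_grid_size must be >= 2")


def select_features(X, y, cfg: SelectionConfig | None = None, feature_names=None) -> list[str]:
    """Return the feature-name subset at the CV-tuned importance threshold.

    Never returns an empty set: if the tuned threshold would drop every
    feature, the single most important feature is kept.
    """
    cfg = cfg or SelectionConfig()
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    if len(np.unique(y)) < 2:
        raise ValueError("need at least 2 classes for feature selection")
    if feature_names is None:
        feature_names = [f"f{i}" for i in range(X.shape[1])]
    feature_names = list(feature_names)

    forest = RandomForestClassifier(n_estimators=cfg.n_trees, random_state=cfg.seed)
    forest.fit(X, y)
    imp = forest.feature_importances_
    grid = np.linspace(0.0, float(imp.max()), cfg.threshold_grid_size)

    # thresholds inducing identical subsets are evaluated once
    subsets: dict[tuple[int, ...], float] = {}
    order = {}
    for thr in grid:
        keep = np.flatnonzero(imp >= thr)
        if keep.size == 0:
            keep = np.array([int(np.argmax(imp))])
        key = tuple(keep)
        if key not in order:
            order[key] = thr
        else:  # keep the lowest threshold that induces this subset
            order[key] = min(order[key], thr)

    skf = StratifiedKFold(n_splits=cfg.cv_folds, shuffle=True, random_state=cfg.seed)
    splits = list(skf.split(X, y))
    for key in order:
        keep = np.array(key)
        scores = []
        for tr, va in splits:
            clf = RandomForestClassifier(n_estimators=cfg.eval_trees, random_state=cfg.seed)
            clf.fit(X[np.ix_(tr, keep)], y[tr])
            scores.append(balanced_accuracy_score(y[va], clf.predict(X[np.ix_(va, keep)])))
        subsets[key] = float(np.mean(scores))

    # best balanced accuracy; ties resolved toward the smaller subset
    best_key = max(subsets, key=lambda k: (subsets[k], -len(k)))
    return [feature_names[i] for i in best_key]


# ------------------------------------------------------------------- MLP

@dataclass
class MLPConfig:
    """Architecture and training hyperparameters of the detection MLP."""

    hidden_sizes: tuple[int, int] = (40, 10)
    n_outputs: int = 2
    input_dropout: float = 0.4
    learning_rate: float = 1e-3
    epochs: int = 200
    patience: int = 20
    validation_fraction: float = 0.2
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 <= self.input_dropout < 1.0):
            raise ValueError("input_dropout must be in [0, 1)")
        if any(h <= 0 for h in self.hidden_sizes):
            raise ValueError("hidden sizes must be positive")


def _softmax(z: np.ndarray) -> np.ndarray:
    z = z - z.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


class MLPDetector:
    """Minimal feed-forward network: ReLU hiddens, softmax output,
    full-batch Adam with early stopping on validation loss."""

    def __init__(self, cfg: MLPConfig):
        self.cfg = cfg
        self.weights_: list[np.ndarray] | None = None
        self.biases_: list[np.ndarray] | None = None

    def _init_params(self, n_in: int, rng: np.random.Generator):
        sizes = [n_in, *self.cfg.hidden_sizes, self.cfg.n_outputs]
        ws, bs = [], []
        for a, b in zip(sizes[:-1], sizes[1:]):
            ws.append(rng.standard_normal((a, b)) * np.sqrt(2.0 / a))
            bs.append(np.zeros(b))
        return ws, bs

    def _forward(self, X, ws, bs, drop_mask=None):
        acts = [X if drop_mask is None else X * drop_mask]
        h = acts[0]
        for w, b in zip(ws[:-1], bs[:-1]):
            h = np.maximum(h @ w + b, 0.0)
            acts.append(h)
        acts.append(_softmax(h @ ws[-1] + bs[-1]))
        return acts

    @staticmethod
    def _loss(probs: np.ndarray, y: np.ndarray) -> float:
        return float(-np.log(np.clip(probs[np.arange(len(y)), y], 1e-12, None)).mean())

    def fit(self, X, y):
        cfg = self.cfg
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=int)
        if not np.isfinite(X).all():
            raise ValueError("non-finite values in X")
        rng = np.random.default_rng(cfg.seed)

        n = len(X)
        idx = rng.permutation(n)
        n_val = int(round(cfg.validation_fraction * n))
        # keep both classes in training; fall back to train-loss stopping
        val_idx, tr_idx = idx[:n_val], idx[n_val:]
        if n_val == 0 or len(np.unique(y[tr_idx])) < 2:
            tr_idx, val_idx = idx, np.array([], dtype=int)

        ws, bs = self._init_params(X.shape[1], rng)
        m = [np.zeros_like(w) for w in ws + bs]
        v = [np.zeros_like(w) for w in ws + bs]
        beta1, beta2, eps = 0.9, 0.999, 1e-8
        keep_p = 1.0 - cfg.input_dropout

        best_loss, best_params, wait = np.inf, None, 0
        Xtr, ytr = X[tr_idx], y[tr_idx]
        for epoch in range(cfg.epochs):
            drop = (rng.random(Xtr.shape) < keep_p) / keep_p if cfg.input_dropout > 0 else None
            acts = self._forward(Xtr, ws, bs, drop)
            probs = acts[-1]

            grad_z = probs.copy()
            grad_z[np.arange(len(ytr)), ytr] -= 1.0
            grad_z /= len(ytr)
            grads_w, grads_b = [], []
            for layer in range(len(ws) - 1, -1, -1):
                grads_w.insert(0, acts[layer].T @ grad_z)
                grads_b.insert(0, grad_z.sum(axis=0))
                if layer > 0:
                    grad_z = (grad_z @ ws[layer].T) * (acts[layer] > 0)

            params = ws + bs
            grads = grads_w + grads_b
            t = epoch + 1
            for k, (p, g) in enumerate(zip(params, grads)):
                m[k] = beta1 * m[k] + (1 - beta1) * g
                v[k] = beta2 * v[k] + (1 - beta2) * g**2
                p -= cfg.learning_rate * (m[k] / (1 - beta1**t)) / (np.sqrt(v[k] / (1 - beta2**t)) + eps)

            monitor = (
                self._loss(self._forward(X[val_idx], ws, bs)[-1], y[val_idx])
                if len(val_idx)
                else self._loss(self._forward(Xtr, ws, bs)[-1], ytr)
            )
            if monitor < best_loss - 1e-6:
                best_loss, wait = monitor, 0
                best_params = ([w.copy() for w in ws], [b.copy() for b in bs])
            else:
                wait += 1
                if wait >= cfg.patience:
                    break
        self.weights_, self.biases_ = best_params if best_params else (ws, bs)
        return self

    def predict_proba(self, X) -> np.ndarray:
        if self.weights_ is None:
            raise RuntimeError("fit the model first")
        X = np.asarray(X, dtype=float)
        return self._forward(X, self.weights_, self.biases_)[-1]

    def decision_scores(self, X) -> np.ndarray:
        """Softmax output of the lesion node, in [0, 1]."""
        return self.predict_proba(X)[:, 1]


def train_mlp(X, y, cfg: MLPConfig | None = None) -> MLPDetector:
    """Train the detection MLP; reproducible for a fixed config seed."""
    return MLPDetector(cfg or MLPConfig()).fit(X, y)


# --------------------------------------------------------------- metrics

@dataclass
class Metrics:
    """Classification metrics at the Youden-optimal score threshold."""

    accuracy: float
    balanced_accuracy: float
    specificity: float
    sensitivity: float
    auc: float
    optimal_threshold: float
    n: int = 0

    def to_dict(self) -> dict:
        return {
            "accuracy": self.accuracy,
            "balanced_accuracy": self.balanced_accuracy,
            "specificity": self.specificity,
            "sensitivity": self.sensitivity,
            "auc": self.auc,
            "optimal_threshold": self.optimal_threshold,
            "n": self.n,
        }


def youden_threshold(y_true, scores) -> float:
    """Score cut maximizing sensitivity + specificity (lowest cut on ties)."""
    fpr, tpr, thr = roc_curve(y_true, scores)
    j = tpr - fpr
    best = np.flatnonzero(j == j.max())[-1]  # thresholds descend: last = lowest
    return float(np.clip(thr[best], 0.0, 1.0))


def evaluate(y_true, scores) -> Metrics:
    """AUC (rank statistic, midrank ties) plus threshold metrics.

    Hard predictions use the Youden-optimal cut; balanced accuracy is the
    mean of sensitivity and specificity. A single-class truth vector gives
    AUC = nan with a warning.
    """
    y_true = np.asarray(y_true, dtype=int)
    scores = np.asarray(scores, dtype=float)
    if len(np.unique(y_true)) < 2:
        warnings.warn("one-class truth: AUC undefined", stacklevel=2)
        auc, cut = float("nan"), 0.5
    else:
        auc = float(roc_auc_score(y_true, scores))
        cut = youden_threshold(y_true, scores)
    pred = (scores >= cut).astype(int)
    pos = y_true == 1
    neg = ~pos
    sens = float((pred[pos] == 1).mean()) if pos.any() else float("nan")
    spec = float((pred[neg] == 0).mean()) if neg.any() else float("nan")
    return Metrics(
        accuracy=float((pred == y_true).mean()),
        balanced_accuracy=float(np.nanmean([sens, spec])),
        specificity=spec,
        sensitivity=sens,
        auc=auc,
        optimal_threshold=cut,
        n=len(y_true),
    )
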