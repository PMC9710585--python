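"""Binding-site predictors for paratope and epitope residues.

The three residue-level models (initial paratope, initial epitope, final
antibody-specific epitope) share one architecture family — a feed-forward
network on windowed residue features — and differ only in depth (7, 11 and
7 hidden layers respectively) and in their input blocks.  Class imbalance
is handled by weighting each class with half the ratio of the molecule
length to the class size, so a 10%-positive molecule weights positives
5x and negatives ~0.56x.

:class:`SiteBindingClassifier` is a scikit-learn style estimator wrapping
the numpy MLP; ``fit``/``predict_proba``/``predict`` and
``get_params``/``set_params`` compose with sklearn tooling.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.metrics import (
    average_precision_score,
    precision_score,
    recall_score,
    roc_auc_score,
    roc_curve,
)

from .nn import MLPBinaryClassifier

PARATOPE_HIDDEN_LAYERS = 7
INITIAL_EPITOPE_HIDDEN_LAYERS = 11
FINAL_EPITOPE_HIDDEN_LAYERS = 7


def class_weights(n_class: int, antigen_length: int) -> float:
    """Loss weight for a class: half the molecule length over the class size.

    Raises
    ------
    ValueError
        If the class is empty (degenerate labels).
    """
    if n_class <= 0:
        raise ValueError("class has no members; labels are degenerate")
    return 0.5 * antigen_length / n_class


def geometric_widths(n_hidden: int, first: int = 256, last: int = 32) -> list[int]:
    """Default geometric width ramp for the hidden layers."""
    return [int(round(w)) for w in np.geomspace(first, last, n_hidden)]


class SiteBindingClassifier(BaseEstimator, ClassifierMixin):
    """Residue binding-site classifier (feed-forward network).

    Parameters
    ----------
    n_hidden:
        Number of hidden layers (7 for paratope/final epitope, 11 for the
        initial epitope model).
    widths:
        Explicit hidden widths; ``None`` selects a geometric 256->32 ramp.
    val_fraction:
        Fraction of groups (or rows, if no groups are given) held out for
        early stopping.
    threshold:
        Probability cutoff for the binary call in :meth:`predict`.
    """

    def __init__(
        self,
        n_hidden: int = PARATOPE_HIDDEN_LAYERS,
        widths=None,
        dropout: float = 0.2,
        lr: float = 1e-3,
        batch_size: int = 32,
        max_epochs: int = 150,
        patience: int = 12,
        val_fraction: float = 0.1,
        threshold: float = 0.5,
        batch_norm: bool = True,
        weight_decay: float = 0.0,
        random_state: int = 17,
    ):
        self.n_hidden = n_hidden
        self.widths = widths
        self.dropout = dropout
        self.lr = lr
        self.batch_size = batch_size
        self.max_epochs = max_epochs
        self.patience = patience
        self.val_fraction = val_fraction
        self.threshold = threshold
        self.batch_norm = batch_norm
        self.weight_decay = weight_decay
        self.random_state = random_state

    # ------------------------------------------------------------------- fit
    def _split(self, X, y, groups, rng):
        n = len(y)
        if self.val_fraction <= 0:
            return np.ones(n, dtype=bool), np.zeros(n, dtype=bool)
        if groups is not None:
            groups = np.asarray(groups)
            uniq = np.unique(groups)
            if len(uniq) >= 2:
                k = max(1, int(round(self.val_fraction * len(uniq))))
                val_groups = rng.permutation(uniq)[:k]
                val_mask = np.isin(groups, val_groups)
                # never early-stop on a degenerate or empty holdout
                if 0 < val_mask.sum() < n and len(np.unique(y[~val_mask])) == 2:
                    return ~val_mask, val_mask
        idx = rng.permutation(n)
        k = max(1, int(round(self.val_fraction * n)))
        val_mask = np.zeros(n, dtype=bool)
        val_mask[idx[:k]] = True
        if len(np.unique(y[~val_mask])) < 2:
            val_mask[:] = False
        return ~val_mask, val_mask

    def fit(self, X, y, groups=None):
        """Train with class weighting and grouped early stopping.

        ``groups`` identifies the source complex of each row; the early
        stopping split never separates rows of one complex.
        """
        X = np.asarray(X, dtype=float)
        y = np.asarray(y).astype(int).ravel()
        if X.ndim != 2 or X.shape[0] != len(y):
            raise ValueError("X must be 2-D and aligned with y")
        classes = np.unique(y)
        if len(classes) < 2:
            raise ValueError("need both classes to train")
        n = len(y)
        cw = {c: class_weights(int(np.sum(y == c)), n) for c in (0, 1)}
        rng = np.random.default_rng(self.random_state)
        # column standardisation (training statistics only)
        self.feature_mean_ = X.mean(axis=0)
        sd = X.std(axis=0)
        self.feature_std_ = np.where(sd > 0, sd, 1.0)
        X = (X - self.feature_mean_) / self.feature_std_
        train_mask, val_mask = self._split(X, y, groups, rng)
        widths = self.widths if self.widths is not None else geometric_widths(self.n_hidden)
        if len(widths) != self.n_hidden:
            raise ValueError("widths length must equal n_hidden")
        net = MLPBinaryClassifier(
            widths=widths,
            dropout=self.dropout,
            batch_norm=self.batch_norm,
            lr=self.lr,
            batch_size=self.batch_size,
            max_epochs=self.max_epochs,
            patience=self.patience,
            weight_decay=self.weight_decay,
            seed=int(rng.integers(2**31 - 1)),
        )
        validation = (X[val_mask], y[val_mask]) if val_mask.any() else None
        net.fit(X[train_mask], y[train_mask], class_weight=cw, validation=validation)
        self.model_ = net
        self.classes_ = np.array([0, 1])
        self.n_features_in_ = X.shape[1]
        self.class_weight_ = cw
        self.history_ = net.history_
        return self

    # -------------------------------------------------------------- predict
    def _check(self, X):
        if not hasattr(self, "model_"):
            raise RuntimeError("classifier is not fitted")
        X = np.asarray(X, dtype=float)
        if X.shape[1] != self.n_features_in_:
            raise ValueError(
                f"feature signature mismatch: got {X.shape[1]} columns, "
                f"expected {self.n_features_in_}"
            )
        return X

    def predict_proba(self, X):
        X = (self._check(X) - self.feature_mean_) / self.feature_std_
        p = self.model_.predict_proba(X)
        return np.column_stack([1 - p, p])

    def predict(self, X):
        return (self.predict_proba(X)[:, 1] >= self.threshold).astype(int)

    # ------------------------------------------------------------ persistence
    def save(self, path) -> None:
        path = Path(path)
        path.mkdir(parents=True, exist_ok=True)
        meta = {
            "params": {k: (list(v) if isinstance(v, (list, tuple)) else v)
                       for k, v in self.get_params().items()},
            "n_features_in": int(self.n_features_in_),
            "class_weight": {str(k): v for k, v in self.class_weight_.items()},
        }
        (path / "model.json").write_text(json.dumps(meta))
        np.savez(
            path / "weights.npz",
            __feature_mean=self.feature_mean_,
            __feature_std=self.feature_std_,
            **self.model_.state_dict(),
        )

    @classmethod
    def load(cls, path) -> "SiteBindingClassifier":
        path = Path(path)
        meta = json.loads((path / "model.json").read_text())
        est = cls(**meta["params"])
        est.n_features_in_ = meta["n_features_in"]
        est.classes_ = np.array([0, 1])
        est.class_weight_ = {int(k): v for k, v in meta["class_weight"].items()}
        net = MLPBinaryClassifier()
        with np.load(path / "weights.npz") as z:
            est.feature_mean_ = z["__feature_mean"]
            est.feature_std_ = z["__feature_std"]
            net.load_state_dict(
                {k: z[k] for k in z.files if not k.startswith("__feature")}
            )
        est.model_ = net
        return est


# -------------------------------------------------------------------- tuner
def tune_site_model(
    X,
    y,
    n_hidden: int,
    n_trials: int = 10,
    groups=None,
    random_state: int = 17,
    **fixed,
) -> tuple[SiteBindingClassifier, list]:
    """Random search over hidden widths and dropout.

    Samples ``n_trials`` configurations (geometric width ramps with random
    endpoints, uniform dropout in [0, 0.5)), scores each by ROC AUC on a
    held-out split, and returns the refitted best estimator together with
    the trial log. Off by default in every pipeline; provided for users who
    want to re-tune on their own data.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y).astype(int).ravel()
    rng = np.random.default_rng(random_state)
    n = len(y)
    if groups is not None:
        groups = np.asarray(groups)
        uniq = rng.permutation(np.unique(groups))
        val_mask = np.isin(groups, uniq[: max(1, len(uniq) // 5)])
    else:
        val_mask = np.zeros(n, dtype=bool)
        val_mask[rng.permutation(n)[: max(1, n // 5)]] = True
    if len(np.unique(y[~val_mask])) < 2 or len(np.unique(y[val_mask])) < 2:
        raise ValueError("tuning split lost a class; provide more data")
    trials = []
    for _ in range(n_trials):
        first = int(rng.choice([64, 128, 256]))
        last = int(rng.choice([16, 32]))
        widths = geometric_widths(n_hidden, first=first, last=max(last, 8))
        dropout = float(rng.uniform(0.0, 0.5))
        est = SiteBindingClassifier(
            n_hidden=n_hidden, widths=widths, dropout=dropout,
            random_state=int(rng.integers(2**31 - 1)), **fixed,
        ).fit(X[~val_mask], y[~val_mask])
        auc = roc_auc_score(y[val_mask], est.predict_proba(X[val_mask])[:, 1])
        trials.append({"widths": widths, "dropout": dropout, "val_roc_auc": float(auc)})
    best = max(trials, key=lambda t: t["val_roc_auc"])
    final = SiteBindingClassifier(
        n_hidden=n_hidden, widths=best["widths"], dropout=best["dropout"],
        random_state=random_state, **fixed,
    ).fit(X, y, groups=groups)
    return final, trials


# ------------------------------------------------------------------ metrics
def evaluate_binary(probs, labels, threshold: float = 0.5, youden: bool = False) -> dict:
    """Standard binary-classification metric suite.

    Returns ROC AUC, PR AUC, precision/recall at the threshold (optionally
    the Youden-optimal threshold) and the positive rate.
    """
    probs = np.asarray(probs, dtype=float)
    labels = np.asarray(labels).astype(int)
    if len(np.unique(labels)) < 2:
        raise ValueError("both classes required for AUC evaluation")
    if youden:
        fpr, tpr, thr = roc_curve(labels, probs)
        threshold = float(thr[np.argmax(tpr - fpr)])
    calls = (probs >= threshold).astype(int)
    return {
        "roc_auc": float(roc_auc_score(labels, probs)),
        "pr_auc": float(average_precision_score(labels, probs)),
        "precision": float(precision_score(labels, calls, zero_division=0)),
        "recall": float(recall_score(labels, calls, zero_division=0)),
        "positive_rate": float(labels.mean()),
        "threshold": float(threshold),
    }
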