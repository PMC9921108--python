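"""Two-output MLP training protocol and the evaluation battery.

The classifier is a single-hidden-layer perceptron with tanh hidden units and
a probabilistic output pair (interacting / non-interacting) that sums to 1.
Training follows the repeated random-split protocol: each candidate model
draws its own 70/30 training/validation split and its own random initial
weights, so agreement across models is itself evidence against overfitting.

Fitting delegates to scikit-learn's MLP optimizer; after fitting, the weight
matrices are extracted and *all* predictions run through the package's own
forward pass, which makes serialized models reproduce their predictions
bit-for-bit.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.metrics import auc as _trapezoid_auc
from sklearn.metrics import roc_curve as _sk_roc_curve
from sklearn.neural_network import MLPClassifier
from sklearn.utils.validation import check_is_fitted

from .errors import DegenerateLabelsError, EmptyClassError, LengthMismatchError

DEFAULT_TRAIN_FRACTION = 0.70


@dataclass(frozen=True)
class SplitAssignment:
    """Random pair-level partition into training and validation."""

    tags: tuple[str, ...]  # "training" | "validation" per record
    fraction: float
    seed: int

    @property
    def train_indices(self) -> np.ndarray:
        return np.array([i for i, t in enumerate(self.tags) if t == "training"])

    @property
    def valid_indices(self) -> np.ndarray:
        return np.array([i for i, t in enumerate(self.tags) if t == "validation"])


def split_dataset(
    n_or_records, fraction: float = DEFAULT_TRAIN_FRACTION, seed: int = 0
) -> SplitAssignment:
    """Uniform random 70/30 (by default) split, reproducible for a fixed seed.

    The training partition size is ``round(fraction * n)``, so a 100-record
    dataset yields exactly 70 training and 30 validation records.
    """
    n = n_or_records if isinstance(n_or_records, int) else len(n_or_records)
    if n < 1:
        raise ValueError("cannot split an empty dataset")
    if not 0.0 < fraction < 1.0:
        raise ValueError("fraction must be in (0, 1)")
    n_train = int(round(fraction * n))
    perm = np.random.default_rng(seed).permutation(n)
    tags = ["validation"] * n
    for i in perm[:n_train]:
        tags[i] = "training"
    return SplitAssignment(tags=tuple(tags), fraction=fraction, seed=seed)


# ---------------------------------------------------------------------------
# confusion statistics
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ConfusionStats:
    """TP/TN/FP/FN counts with the derived binary-classification statistics."""

    tp: int
    tn: int
    fp: int
    fn: int

    @property
    def total(self) -> int:
        return self.tp + self.tn + self.fp + self.fn

    @property
    def sensitivity(self) -> float:
        d = self.tp + self.fn
        return self.tp / d if d else float("nan")

    @property
    def specificity(self) -> float:
        d = self.tn + self.fp
        return self.tn / d if d else float("nan")

    @property
    def accuracy(self) -> float:
        return (self.tp + self.tn) / self.total if self.total else float("nan")

    @property
    def mcc_degenerate(self) -> bool:
        return 0 in (
            self.tp + self.fp, self.tp + self.fn, self.tn + self.fp, self.tn + self.fn
        )

    @property
    def mcc(self) -> float:
        """Matthews correlation coefficient; defined as 0 when any margin is
        empty (see :attr:`mcc_degenerate`)."""
        if self.mcc_degenerate:
            return 0.0
        num = self.tp * self.tn - self.fp * self.fn
        den = math.sqrt(
            (self.tp + self.fp) * (self.tp + self.fn) * (self.tn + self.fp) * (self.tn + self.fn)
        )
        return num / den

    def as_dict(self) -> dict:
        return {
            "tp": self.tp, "tn": self.tn, "fp": self.fp, "fn": self.fn,
            "sensitivity": self.sensitivity, "specificity": self.specificity,
            "accuracy": self.accuracy, "mcc": self.mcc,
        }


def confusion_stats(predicted, true) -> ConfusionStats:
    """Exact integer confusion counts for binary labels (1 = interacting)."""
    predicted = np.asarray(predicted)
    true = np.asarray(true)
    if predicted.shape != true.shape:
        raise LengthMismatchError(
            f"predicted ({predicted.shape}) and true ({true.shape}) differ"
        )
    tp = int(np.sum((predicted == 1) & (true == 1)))
    tn = int(np.sum((predicted == 0) & (true == 0)))
    fp = int(np.sum((predicted == 1) & (true == 0)))
    fn = int(np.sum((predicted == 0) & (true == 1)))
    return ConfusionStats(tp=tp, tn=tn, fp=fp, fn=fn)


def roc_auc(scores, true) -> tuple[np.ndarray, float]:
    """ROC curve points and trapezoid-rule area under the curve.

    ``scores`` are interacting-class probabilities in [0, 1].  Returns an
    ``(n_points, 2)`` array of (FPR, TPR) pairs and the area.
    """
    scores = np.asarray(scores, dtype=float)
    true = np.asarray(true)
    if scores.shape != true.shape:
        raise LengthMismatchError("scores and labels differ in length")
    if len(np.unique(true)) < 2:
        raise DegenerateLabelsError("ROC needs both classes present")
    fpr, tpr, _ = _sk_roc_curve(true, scores)
    return np.column_stack([fpr, tpr]), float(_trapezoid_auc(fpr, tpr))


@dataclass
class PerClassReport:
    """Per-enzyme-subclass accuracy, split by true label."""

    rows: pd.DataFrame  # columns: ec_family, total, acc_interacting, acc_non_interacting


def per_class_report(y_true, y_pred, families) -> PerClassReport:
    """Accuracy per subclass on interacting and non-interacting pairs."""
    df = pd.DataFrame({
        "ec_family": list(families),
        "true": np.asarray(y_true),
        "pred": np.asarray(y_pred),
    })
    if df.empty:
        raise EmptyClassError("no records to report on")
    rows = []
    for ec, grp in df.groupby("ec_family", sort=True):
        pos = grp[grp["true"] == 1]
        neg = grp[grp["true"] == 0]
        rows.append({
            "ec_family": ec,
            "total": len(grp),
            "acc_interacting": (pos["pred"] == 1).mean() if len(pos) else float("nan"),
            "acc_non_interacting": (neg["pred"] == 0).mean() if len(neg) else float("nan"),
        })
    key = lambda s: tuple(int(x) for x in s.split("."))
    frame = pd.DataFrame(rows)
    frame = frame.iloc[sorted(range(len(frame)), key=lambda i: key(frame["ec_family"][i]))]
    return PerClassReport(rows=frame.reset_index(drop=True))


# ---------------------------------------------------------------------------
# the MLP estimator
# ---------------------------------------------------------------------------

def _sigmoid(z: np.ndarray) -> np.ndarray:
    out = np.empty_like(z)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


@dataclass
class MLPWeights:
    """Standardization parameters plus the network's weight arrays."""

    x_mean: np.ndarray
    x_scale: np.ndarray
    w1: np.ndarray  # (n_inputs, n_hidden)
    b1: np.ndarray  # (n_hidden,)
    w2: np.ndarray  # (n_hidden,)
    b2: float

    def forward(self, X: np.ndarray) -> np.ndarray:
        """Interacting-class probability per row (deterministic numpy path)."""
        Z = (np.asarray(X, dtype=float) - self.x_mean) / self.x_scale
        H = np.tanh(Z @ self.w1 + self.b1)
        return _sigmoid(H @ self.w2 + self.b2)


class InteractionMLPClassifier(BaseEstimator, ClassifierMixin):
    """Single-hidden-layer perceptron for binary interaction labels.

    Topology ``MLP n_inputs-n_hidden-2``: tanh hidden layer and a
    probabilistic output pair (the two class probabilities sum to 1).  Inputs
    are z-standardized with training statistics inside the estimator.  With
    ``early_stopping`` a carve-out of the *training* data monitors progress —
    the external validation partition is never touched during training.  The
    default ``"auto"`` enables the carve-out only when the training set is
    large enough (>= 1000 rows) for the 10% monitor split to give a stable
    stopping signal; on smaller data the optimizer runs to ``max_iter``.
    """

    def __init__(
        self,
        n_hidden: int = 50,
        seed: int = 0,
        max_iter: int = 300,
        early_stopping: bool | str = "auto",
        learning_rate_init: float = 1e-3,
    ):
        self.n_hidden = n_hidden
        self.seed = seed
        self.max_iter = max_iter
        self.early_stopping = early_stopping
        self.learning_rate_init = learning_rate_init

    def fit(self, X, y):
        if self.n_hidden < 1:
            raise ValueError("n_hidden must be >= 1")
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=int)
        if X.ndim != 2 or len(X) != len(y):
            raise ValueError("X must be 2-D and aligned with y")
        mean = X.mean(axis=0)
        scale = X.std(axis=0)
        scale[scale == 0.0] = 1.0
        Z = (X - mean) / scale
        if self.early_stopping == "auto":
            use_early_stopping = len(y) >= 1000
        else:
            use_early_stopping = bool(self.early_stopping)
        net = MLPClassifier(
            hidden_layer_sizes=(self.n_hidden,),
            activation="tanh",
            solver="adam",
            random_state=self.seed,
            max_iter=self.max_iter,
            early_stopping=use_early_stopping,
            validation_fraction=0.1,
            n_iter_no_change=15,
            learning_rate_init=self.learning_rate_init,
        )
        net.fit(Z, y)
        self.classes_ = net.classes_
        self.weights_ = MLPWeights(
            x_mean=mean,
            x_scale=scale,
            w1=net.coefs_[0].copy(),
            b1=net.intercepts_[0].copy(),
            w2=net.coefs_[1].ravel().copy(),
            b2=float(net.intercepts_[1][0]),
        )
        self.n_inputs_ = X.shape[1]
        self.topology_ = f"MLP {self.n_inputs_}-{self.n_hidden}-2"
        return self

    def predict_proba(self, X) -> np.ndarray:
        check_is_fitted(self, "weights_")
        p1 = self.weights_.forward(np.asarray(X, dtype=float))
        return np.column_stack([1.0 - p1, p1])

    def predict(self, X) -> np.ndarray:
        return (self.predict_proba(X)[:, 1] > 0.5).astype(int)


def train_mlp(
    features, labels, n_hidden: int = 50, seed: int = 0, **config
) -> InteractionMLPClassifier:
    """Functional wrapper over :class:`InteractionMLPClassifier`."""
    clf = InteractionMLPClassifier(n_hidden=n_hidden, seed=seed, **config)
    return clf.fit(features, labels)


def repeat_model_search(*args, **kwargs):
    """Repeated split-train-evaluate model search (see :mod:`mtqsar.pipeline`)."""
    from .pipeline import repeat_model_search as _impl

    return _impl(*args, **kwargs)
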