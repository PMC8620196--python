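"""The three base classifiers behind the hybrid interaction predictor.

* DNN — a feed-forward ReLU network with a sigmoid output, trained by
  Adam on binary cross-entropy with dropout and an early stop once
  training accuracy reaches 0.99 (implemented natively in numpy).
* GBT — gradient-boosted trees under a logistic objective with a
  second-order split criterion; training is delegated to
  scikit-learn's gradient-boosting engine, while the defining leaf
  weight and split gain formulas are exposed here as reference
  operations for direct verification.
* C-SVM — a soft-margin RBF support vector machine on standardized
  features with Platt-calibrated probability outputs, delegated to
  scikit-learn's libsvm wrapper.

All three expose the same contract: ``train_*`` returns a
:class:`TrainedModel` and :func:`score_model` maps feature rows to
interaction probabilities in [0, 1].
"""

from __future__ import annotations

import enum
import warnings
from dataclasses import dataclass, field

import numpy as np
from sklearn.ensemble import GradientBoostingClassifier
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

from ._dnn import MLPBinaryClassifier


@dataclass(frozen=True)
class DNNConfig:
    hidden_sizes: tuple[int, ...] = (256, 64)
    learning_rate: float = 1e-4
    batch_size: int = 128
    epochs: int = 100
    dropout: float = 0.25
    early_stop_accuracy: float = 0.99


@dataclass(frozen=True)
class GBTConfig:
    learning_rate: float = 0.1
    n_estimators: int = 100
    max_depth: int = 6
    colsample: float = 0.8
    validation_fraction: float = 0.1
    n_iter_no_change: int = 10


@dataclass(frozen=True)
class SVMConfig:
    kernel: str = "rbf"
    C: float = 1.0
    gamma: str = "auto"
    probability: bool = True


@dataclass(frozen=True)
class ClassifierConfig:
    dnn: DNNConfig = field(default_factory=DNNConfig)
    gbt: GBTConfig = field(default_factory=GBTConfig)
    svm: SVMConfig = field(default_factory=SVMConfig)


class ModelKind(enum.Enum):
    DNN = "dnn"
    GBT = "gbt"
    SVM = "svm"


@dataclass
class TrainedModel:
    """A fitted base classifier plus the state needed to score new rows."""

    kind: ModelKind
    estimator: object
    input_dim: int
    scaler: StandardScaler | None = None  # SVM path only


def _check_binary(y: np.ndarray) -> np.ndarray:
    y = np.asarray(y)
    classes = set(np.unique(y))
    if classes == {-1, 1}:
        y = np.where(y == 1, 1, 0)
    elif not classes <= {0, 1}:
        raise ValueError(f"labels must be binary, got {sorted(classes)}")
    if len(np.unique(y)) < 2:
        raise ValueError("training requires both classes present")
    return y.astype(np.int64)


# ---------------------------------------------------------------------------
# DNN


def train_dnn(
    X: np.ndarray, y: np.ndarray, config: DNNConfig = DNNConfig(), seed: int = 0
) -> TrainedModel:
    """Train the feed-forward network on {0,1}-labeled feature rows.

    Inputs are expected min-max scaled (fit on training data). Training
    halts early once full-pass training accuracy reaches
    ``config.early_stop_accuracy``.
    """
    X = np.asarray(X, dtype=np.float64)
    y = _check_binary(y)
    net = MLPBinaryClassifier(
        hidden_sizes=config.hidden_sizes,
        learning_rate=config.learning_rate,
        batch_size=config.batch_size,
        epochs=config.epochs,
        dropout=config.dropout,
        early_stop_accuracy=config.early_stop_accuracy,
        seed=seed,
    )
    net.fit(X, y)
    return TrainedModel(ModelKind.DNN, net, X.shape[1])


def score_dnn(model: TrainedModel, X: np.ndarray) -> np.ndarray:
    """Per-row sigmoid outputs of a trained network."""
    if model.kind is not ModelKind.DNN:
        raise ValueError("score_dnn requires a DNN model")
    return score_model(model, X)


# ---------------------------------------------------------------------------
# Gradient-boosted trees: reference formulas + delegated training


def gbt_leaf_weight(g_values, h_values, lam: float) -> float:
    """Optimal leaf weight w* = -sum(g) / (sum(h) + lambda).

    ``g``/``h`` are the per-sample first/second derivatives of the loss
    at the current prediction for the samples routed to the leaf.
    """
    g = np.asarray(g_values, dtype=np.float64)
    h = np.asarray(h_values, dtype=np.float64)
    if g.shape != h.shape:
        raise ValueError("gradient and Hessian lists must have equal length")
    denom = h.sum() + lam
    if denom == 0:
        raise ZeroDivisionError("sum of Hessians plus lambda is zero")
    return float(-g.sum() / denom)


def gbt_split_gain(
    G_L: float, H_L: float, G_R: float, H_R: float, lam: float, gamma: float
) -> float:
    """Loss reduction of a split under the second-order objective.

    gain = 1/2 [G_L^2/(H_L+lam) + G_R^2/(H_R+lam) - (G_L+G_R)^2/(H_L+H_R+lam)] - gamma
    """
    for denom in (H_L + lam, H_R + lam, H_L + H_R + lam):
        if denom == 0:
            raise ZeroDivisionError("Hessian sum plus lambda is zero")
    return float(
        0.5
        * (
            G_L**2 / (H_L + lam)
            + G_R**2 / (H_R + lam)
            - (G_L + G_R) ** 2 / (H_L + H_R + lam)
        )
        - gamma
    )


def train_gbt(
    X: np.ndarray, y: np.ndarray, config: GBTConfig = GBTConfig(), seed: int = 0
) -> TrainedModel:
    """Train the boosted-tree classifier under a logistic objective.

    A seeded 10% validation split of the training rows drives early
    stopping; 80% of features are sampled per split.
    """
    X = np.asarray(X, dtype=np.float64)
    y = _check_binary(y)
    est = GradientBoostingClassifier(
        loss="log_loss",
        learning_rate=config.learning_rate,
        n_estimators=config.n_estimators,
        max_depth=config.max_depth,
        max_features=config.colsample,
        validation_fraction=config.validation_fraction,
        n_iter_no_change=config.n_iter_no_change,
        random_state=seed,
    )
    est.fit(X, y)
    return TrainedModel(ModelKind.GBT, est, X.shape[1])


# ---------------------------------------------------------------------------
# C-SVM


def train_csvm(
    X: np.ndarray, y: np.ndarray, config: SVMConfig = SVMConfig(), seed: int = 0
) -> TrainedModel:
    """Train a soft-margin RBF SVM on standardized features.

    Columns are standardized to zero mean / unit variance with training
    statistics (zero-variance columns map to 0); the stored scaler is
    reapplied at scoring time. Probability outputs come from the
    solver's Platt-style calibration.
    """
    X = np.asarray(X, dtype=np.float64)
    y = _check_binary(y)
    scaler = StandardScaler().fit(X)
    Xs = scaler.transform(X)
    est = SVC(
        kernel=config.kernel,
        C=config.C,
        gamma=config.gamma,
        probability=config.probability,
        random_state=seed,
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", FutureWarning)
        est.fit(Xs, y)
    return TrainedModel(ModelKind.SVM, est, X.shape[1], scaler=scaler)


# ---------------------------------------------------------------------------
# Uniform scoring facade


def score_model(model: TrainedModel, X: np.ndarray) -> np.ndarray:
    """Interaction probabilities in [0, 1], one per row of ``X``."""
    X = np.asarray(X, dtype=np.float64)
    if X.ndim != 2:
        raise ValueError("X must be 2-D")
    if X.shape[1] != model.input_dim:
        raise ValueError(
            f"model expects {model.input_dim} features, got {X.shape[1]}"
        )
    if X.shape[0] == 0:
        return np.empty(0)
    if model.kind is ModelKind.DNN:
        return model.estimator.predict_proba(X)
    if model.kind is ModelKind.SVM:
        Xs = model.scaler.transform(X)
        if getattr(model.estimator, "probability", False):
            return model.estimator.predict_proba(Xs)[:, 1]
        # uncalibrated fallback: squash the decision function
        from ._dnn import _sigmoid

        return _sigmoid(model.estimator.decision_function(Xs))
    return model.estimator.predict_proba(X)[:, 1]
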