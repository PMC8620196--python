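"""Weighted combination of the three base classifiers' scores.

The final interaction score of a pair is a fixed linear blend

    score = alpha * p_dnn + beta * p_gbt + theta * p_svm

with default weights (0.4, 0.3, 0.3). The weights are configuration
values; no meta-learner is fitted. Hard labels use a strict 0.5
threshold.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np


@dataclass(frozen=True)
class EnsembleWeights:
    """Non-negative blend weights for (DNN, GBT, SVM) scores."""

    alpha: float = 0.4
    beta: float = 0.3
    theta: float = 0.3

    def __post_init__(self) -> None:
        if min(self.alpha, self.beta, self.theta) < 0:
            raise ValueError("ensemble weights must be non-negative")


def combine_scores(
    p_dnn: np.ndarray,
    p_gbt: np.ndarray,
    p_svm: np.ndarray,
    weights: EnsembleWeights = EnsembleWeights(),
) -> np.ndarray:
    """Blend per-classifier probabilities into the final score vector."""
    p_dnn = np.asarray(p_dnn, dtype=np.float64)
    p_gbt = np.asarray(p_gbt, dtype=np.float64)
    p_svm = np.asarray(p_svm, dtype=np.float64)
    if not (p_dnn.shape == p_gbt.shape == p_svm.shape):
        raise ValueError("score vectors must have equal length")
    return weights.alpha * p_dnn + weights.beta * p_gbt + weights.theta * p_svm


def decide(scores: np.ndarray, threshold: float = 0.5) -> np.ndarray:
    """Hard labels: 1 iff score strictly exceeds the threshold."""
    scores = np.asarray(scores, dtype=np.float64)
    if not np.isfinite(scores).all():
        raise ValueError("scores must be finite")
    return (scores > threshold).astype(np.int64)
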