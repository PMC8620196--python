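"""Negative sampling, cross-validation schemes, metrics, and the driver.

Four 5-fold cross-validation schemes probe different prediction
settings on the bipartite interaction matrix:

* ``CV_LP`` — random pairs are hidden (the standard setting);
* ``CV_L`` — whole lncRNAs are hidden, so test lncRNAs are unseen;
* ``CV_P`` — whole proteins are hidden;
* ``CV_IND`` — 20% of lncRNAs *and* 20% of proteins are drawn as a
  node test set; training uses only pairs between train nodes, testing
  only pairs between test nodes, and cross pairs (one endpoint on each
  side) are discarded entirely.

Negative pairs are drawn uniformly from the zero entries of the matrix
at a 1:1 ratio to positives, freshly for each repeat. The experiment
driver runs the full pipeline per fold — encode pairs, select features
on the training fold, min-max scale with training statistics, train the
three classifiers, blend — and averages the six metrics over
repeats x folds.
"""

from __future__ import annotations

import enum
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.metrics import auc as _trapezoid_auc
from sklearn.metrics import precision_recall_curve, roc_auc_score

from . import classifiers as clf
from .config import PipelineConfig
from .ensemble import combine_scores, decide
from .feature_selection import reduce_matrix, select_features
from .io_formats import InteractionMatrix, SequenceRecord
from .sequence_features import (
    FeatureMatrix,
    NormalizationParams,
    apply_normalization,
    build_pair_matrix,
    encode_lncrna_set,
    encode_protein_set,
    min_max_normalize,
)

logger = logging.getLogger(__name__)

LabeledPair = tuple[str, str, int]


class CVScheme(enum.Enum):
    CV_L = "l"
    CV_P = "p"
    CV_LP = "lp"
    CV_IND = "ind"


@dataclass
class CVSplit:
    """One train/test partition under a named scheme."""

    scheme: CVScheme
    fold_index: int
    train_pairs: list[LabeledPair]
    test_pairs: list[LabeledPair]


@dataclass(frozen=True)
class MetricsReport:
    """The six evaluation metrics of one scoring run."""

    precision: float
    recall: float
    accuracy: float
    f1: float
    auc: float
    aupr: float

    def as_dict(self) -> dict[str, float]:
        return {
            "precision": self.precision,
            "recall": self.recall,
            "accuracy": self.accuracy,
            "f1": self.f1,
            "auc": self.auc,
            "aupr": self.aupr,
        }


METRIC_NAMES = ("precision", "recall", "accuracy", "f1", "auc", "aupr")


# ---------------------------------------------------------------------------
# Negative sampling


def sample_negatives(
    Y: InteractionMatrix, ratio: float = 1.0, seed: int = 0
) -> list[tuple[str, str]]:
    """Uniform sample (without replacement) of zero entries of Y.

    The sample size is round(ratio x number of positives).
    """
    zeros = Y.zero_pairs()
    n_pos = int(Y.Y.sum())
    count = int(round(ratio * n_pos))
    if count > len(zeros):
        raise ValueError(
            f"cannot draw {count} negatives from {len(zeros)} zero entries"
        )
    rng = np.random.default_rng(seed)
    idx = rng.choice(len(zeros), size=count, replace=False)
    return [zeros[i] for i in idx]


# ---------------------------------------------------------------------------
# Cross-validation splits


def make_splits(
    scheme: CVScheme,
    Y: InteractionMatrix,
    pairs: list[LabeledPair],
    n_folds: int = 5,
    seed: int = 0,
) -> list[CVSplit]:
    """Partition labeled pairs into train/test under the given scheme.

    ``CV_L``/``CV_P`` partition the entity sets into folds; ``CV_LP``
    partitions the pair list. ``CV_IND`` draws, independently per fold,
    1/n_folds of the lncRNAs and of the proteins as test nodes: train
    pairs need both endpoints among train nodes, test pairs need both
    among test nodes, and cross pairs are discarded (its folds are not
    a partition of the pair list).
    """
    rng = np.random.default_rng(seed)
    splits: list[CVSplit] = []
    if scheme in (CVScheme.CV_L, CVScheme.CV_P):
        ids = Y.lnc_ids if scheme is CVScheme.CV_L else Y.prot_ids
        side = 0 if scheme is CVScheme.CV_L else 1
        if len(ids) < n_folds:
            raise ValueError(f"need at least {n_folds} entities for {n_folds} folds")
        order = rng.permutation(len(ids))
        folds = np.array_split(order, n_folds)
        for f, fold in enumerate(folds):
            held = {ids[i] for i in fold}
            test = [p for p in pairs if p[side] in held]
            train = [p for p in pairs if p[side] not in held]
            splits.append(CVSplit(scheme, f, train, test))
    elif scheme is CVScheme.CV_LP:
        if len(pairs) < n_folds:
            raise ValueError("fewer pairs than folds")
        order = rng.permutation(len(pairs))
        folds = np.array_split(order, n_folds)
        for f, fold in enumerate(folds):
            held = set(fold.tolist())
            test = [pairs[i] for i in sorted(held)]
            train = [pairs[i] for i in range(len(pairs)) if i not in held]
            splits.append(CVSplit(scheme, f, train, test))
    elif scheme is CVScheme.CV_IND:
        n_test_l = max(1, int(round(len(Y.lnc_ids) / n_folds)))
        n_test_p = max(1, int(round(len(Y.prot_ids) / n_folds)))
        if n_test_l >= len(Y.lnc_ids) or n_test_p >= len(Y.prot_ids):
            raise ValueError("too few entities for an independent node split")
        for f in range(n_folds):
            test_l = {
                Y.lnc_ids[i]
                for i in rng.choice(len(Y.lnc_ids), size=n_test_l, replace=False)
            }
            test_p = {
                Y.prot_ids[j]
                for j in rng.choice(len(Y.prot_ids), size=n_test_p, replace=False)
            }
            train = [
                p for p in pairs if p[0] not in test_l and p[1] not in test_p
            ]
            test = [p for p in pairs if p[0] in test_l and p[1] in test_p]
            splits.append(CVSplit(scheme, f, train, test))
    else:  # pragma: no cover - exhaustive enum
        raise ValueError(f"unknown scheme {scheme!r}")
    return splits


# ---------------------------------------------------------------------------
# Metrics


def compute_metrics(
    y_true: np.ndarray, scores: np.ndarray, threshold: float = 0.5
) -> MetricsReport:
    """Threshold metrics plus ranking metrics for one scored set.

    AUC is the tie-aware probability that a random positive outranks a
    random negative (ties count 1/2). AUPR integrates the
    precision-recall curve by the trapezoid rule on recall — this
    convention is fixed here and used everywhere in the package.
    Precision and F1 are defined as 0 when nothing is predicted
    positive.
    """
    y_true = np.asarray(y_true).astype(np.int64)
    scores = np.asarray(scores, dtype=np.float64)
    if len(y_true) != len(scores):
        raise ValueError("labels and scores must have equal length")
    if len(np.unique(y_true)) < 2:
        raise ValueError("AUC/AUPR need both classes present")
    preds = decide(scores, threshold)
    tp = int(np.sum((preds == 1) & (y_true == 1)))
    fp = int(np.sum((preds == 1) & (y_true == 0)))
    fn = int(np.sum((preds == 0) & (y_true == 1)))
    precision = tp / (tp + fp) if (tp + fp) else 0.0
    recall = tp / (tp + fn) if (tp + fn) else 0.0
    accuracy = float(np.mean(preds == y_true))
    f1 = (
        2 * precision * recall / (precision + recall)
        if (precision + recall)
        else 0.0
    )
    auc = float(roc_auc_score(y_true, scores))
    prec_curve, rec_curve, _ = precision_recall_curve(y_true, scores)
    aupr = float(_trapezoid_auc(rec_curve, prec_curve))
    return MetricsReport(precision, recall, accuracy, f1, auc, aupr)


# ---------------------------------------------------------------------------
# Model stack: selection + scaling + three classifiers + blend


@dataclass
class ModelStack:
    """Everything fitted on one training fold, ready to score new pairs."""

    f_o: list[str]
    norm: NormalizationParams
    dnn: clf.TrainedModel
    gbt: clf.TrainedModel
    svm: clf.TrainedModel
    config: PipelineConfig

    def score_pairs(self, X: FeatureMatrix) -> np.ndarray:
        """Blended interaction scores for rows of a full pair matrix."""
        Xr = apply_normalization(self.norm, reduce_matrix(X, self.f_o))
        p_dnn = clf.score_model(self.dnn, Xr.values)
        p_gbt = clf.score_model(self.gbt, Xr.values)
        p_svm = clf.score_model(self.svm, Xr.values)
        return combine_scores(p_dnn, p_gbt, p_svm, self.config.weights)


def fit_stack(
    X_train: FeatureMatrix,
    y_train: np.ndarray,
    config: PipelineConfig,
    seed: int = 0,
) -> ModelStack:
    """Select features, fit scaling and the three classifiers on one fold."""
    k = min(config.k_features, len(X_train.feature_names))
    state = select_features(X_train, y_train, k)
    logger.info("selected %d features (first: %s)", k, state.f_o[:3])
    X_sel = reduce_matrix(X_train, state.f_o)
    X_norm, norm = min_max_normalize(X_sel)
    y01 = np.where(np.asarray(y_train) == 1, 1, 0)
    ss = np.random.SeedSequence(seed)
    s_dnn, s_gbt, s_svm = (int(c.generate_state(1)[0]) for c in ss.spawn(3))
    dnn = clf.train_dnn(X_norm.values, y01, config.classifier.dnn, seed=s_dnn)
    gbt = clf.train_gbt(X_norm.values, y01, config.classifier.gbt, seed=s_gbt)
    svm = clf.train_csvm(X_norm.values, y01, config.classifier.svm, seed=s_svm)
    return ModelStack(state.f_o, norm, dnn, gbt, svm, config)


# ---------------------------------------------------------------------------
# Experiment driver


@dataclass
class ExperimentResult:
    """Per-fold metrics table plus repeat-averaged summary."""

    table: pd.DataFrame
    mean: MetricsReport
    std: MetricsReport
    repeat_means: pd.DataFrame = field(repr=False, default=None)


def labeled_pairs(
    Y: InteractionMatrix, negatives: list[tuple[str, str]]
) -> list[LabeledPair]:
    """Positives from the matrix plus the sampled negatives, labeled."""
    pos = [(l, p, 1) for l, p in Y.positive_pairs()]
    neg = [(l, p, 0) for l, p in negatives]
    return pos + neg


def run_experiment(
    lnc_records: list[SequenceRecord],
    prot_records: list[SequenceRecord],
    Y: InteractionMatrix,
    scheme: CVScheme,
    config: PipelineConfig = PipelineConfig(),
    n_repeats: int | None = None,
    seed: int = 0,
) -> ExperimentResult:
    """Repeat-averaged cross-validated evaluation of the full pipeline.

    Per repeat: draw negatives, split under the scheme; per fold:
    build pair matrices, select features on the training fold, fit
    min-max scaling on it, train DNN/GBT/SVM, blend scores, compute the
    six metrics on the test fold. Folds whose train or test side lacks
    one of the classes are skipped with a log message (possible for the
    cold-start schemes on small data). All randomness derives from
    ``seed``.
    """
    if n_repeats is None:
        n_repeats = config.n_repeats
    lnc_feats = encode_lncrna_set(lnc_records, config.descriptor)
    prot_feats = encode_protein_set(prot_records, config.descriptor)
    rows = []
    master = np.random.SeedSequence(seed)
    for repeat, ss_rep in enumerate(master.spawn(n_repeats)):
        s_neg, s_split, s_fit = (int(c.generate_state(1)[0]) for c in ss_rep.spawn(3))
        negatives = sample_negatives(Y, config.negative_ratio, seed=s_neg)
        pairs = labeled_pairs(Y, negatives)
        splits = make_splits(scheme, Y, pairs, config.n_folds, seed=s_split)
        for split in splits:
            y_train = np.array([p[2] for p in split.train_pairs])
            y_test = np.array([p[2] for p in split.test_pairs])
            if (
                len(np.unique(y_train)) < 2
                or len(np.unique(y_test)) < 2
            ):
                logger.info(
                    "skipping repeat %d fold %d: single-class side",
                    repeat,
                    split.fold_index,
                )
                continue
            X_train = build_pair_matrix(
                lnc_feats, prot_feats, [(p[0], p[1]) for p in split.train_pairs]
            )
            X_test = build_pair_matrix(
                lnc_feats, prot_feats, [(p[0], p[1]) for p in split.test_pairs]
            )
            stack = fit_stack(X_train, y_train, config, seed=s_fit + split.fold_index)
            scores = stack.score_pairs(X_test)
            report = compute_metrics(y_test, scores, config.threshold)
            rows.append(
                {
                    "repeat": repeat,
                    "fold": split.fold_index,
                    "scheme": scheme.value,
                    **report.as_dict(),
                }
            )
    if not rows:
        raise RuntimeError("every fold was skipped; dataset too small for scheme")
    table = pd.DataFrame(rows)
    mean = MetricsReport(**{m: float(table[m].mean()) for m in METRIC_NAMES})
    std = MetricsReport(**{m: float(table[m].std(ddof=0)) for m in METRIC_NAMES})
    repeat_means = table.groupby("repeat")[list(METRIC_NAMES)].mean().reset_index()
    return ExperimentResult(table, mean, std, repeat_means)


# ---------------------------------------------------------------------------
# Case-study ranking


class RankMode(enum.Enum):
    PROTEINS_FOR_LNCRNA = "proteins_for_lncrna"
    LNCRNAS_FOR_PROTEIN = "lncrnas_for_protein"


def rank_for_entity(
    stack: ModelStack,
    lnc_feats: FeatureMatrix,
    prot_feats: FeatureMatrix,
    entity_id: str,
    mode: RankMode,
    Y: InteractionMatrix,
) -> list[tuple[str, str, float, bool]]:
    """Score every candidate partner of one entity.

    The caller is responsible for having trained ``stack`` with the
    entity's known edges hidden (see :func:`case_study`). Known
    interactions are flagged in the output, which is ready for
    ``write_predictions``.
    """
    if mode is RankMode.PROTEINS_FOR_LNCRNA:
        if entity_id not in Y.lnc_ids:
            raise KeyError(f"unknown lncRNA id {entity_id!r}")
        pairs = [(entity_id, p) for p in Y.prot_ids]
    else:
        if entity_id not in Y.prot_ids:
            raise KeyError(f"unknown protein id {entity_id!r}")
        pairs = [(l, entity_id) for l in Y.lnc_ids]
    if not pairs:
        return []
    X = build_pair_matrix(lnc_feats, prot_feats, pairs)
    scores = stack.score_pairs(X)
    li = {x: i for i, x in enumerate(Y.lnc_ids)}
    pi = {x: j for j, x in enumerate(Y.prot_ids)}
    return [
        (l, p, float(s), bool(Y.Y[li[l], pi[p]]))
        for (l, p), s in zip(pairs, scores)
    ]


def case_study(
    lnc_records: list[SequenceRecord],
    prot_records: list[SequenceRecord],
    Y: InteractionMatrix,
    entity_id: str,
    mode: RankMode,
    config: PipelineConfig = PipelineConfig(),
    seed: int = 0,
) -> list[tuple[str, str, float, bool]]:
    """Treat one entity as new: hide its edges, train, rank its partners.

    All pairs involving the entity are removed from training (its known
    interactions are zeroed before negative sampling, and no pair of
    the entity enters the training set), then every candidate partner
    is scored and flagged against the original matrix.
    """
    hidden = Y.Y.copy()
    if mode is RankMode.PROTEINS_FOR_LNCRNA:
        if entity_id not in Y.lnc_ids:
            raise KeyError(f"unknown lncRNA id {entity_id!r}")
        hidden[Y.lnc_ids.index(entity_id), :] = 0
    else:
        if entity_id not in Y.prot_ids:
            raise KeyError(f"unknown protein id {entity_id!r}")
        hidden[:, Y.prot_ids.index(entity_id)] = 0
    Y_hidden = InteractionMatrix(list(Y.lnc_ids), list(Y.prot_ids), hidden)
    ss = np.random.SeedSequence(seed)
    s_neg, s_fit = (int(c.generate_state(1)[0]) for c in ss.spawn(2))
    negatives = [
        (l, p)
        for l, p in sample_negatives(Y_hidden, config.negative_ratio, seed=s_neg)
        if l != entity_id and p != entity_id
    ]
    pairs = [
        p for p in labeled_pairs(Y_hidden, negatives)
        if p[0] != entity_id and p[1] != entity_id
    ]
    lnc_feats = encode_lncrna_set(lnc_records, config.descriptor)
    prot_feats = encode_protein_set(prot_records, config.descriptor)
    X = build_pair_matrix(lnc_feats, prot_feats, [(p[0], p[1]) for p in pairs])
    y = np.array([p[2] for p in pairs])
    stack = fit_stack(X, y, config, seed=s_fit)
    return rank_for_entity(stack, lnc_feats, prot_feats, entity_id, mode, Y)
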