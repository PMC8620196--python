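"""Forward feature selection driven by AdaBoost with decision stumps.

Each round trains one depth-1 threshold classifier (stump) per remaining
candidate feature on the current sample weights, moves the feature with
the smallest weighted error into the selected set, assigns that round a
classifier weight beta = 0.5 * ln((1 - eps) / eps), and reweights the
samples (misclassified up, correct down, renormalized to sum 1). Sample
weights persist across rounds, so successive features are chosen to fix
what earlier ones got wrong.

Stump convention: a stump with polarity +1 predicts +1 where
``x <= threshold`` and -1 elsewhere; polarity -1 flips both sides.
Candidate thresholds are midpoints between consecutive distinct sorted
values plus -inf/+inf sentinels. Ties are broken toward the smaller
threshold, then polarity +1, and across features toward the lower
canonical column index, so selection is fully deterministic.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .sequence_features import FeatureMatrix

#: Weighted errors are clamped into [EPS_CLAMP, 1 - EPS_CLAMP] before the
#: log-odds, so a perfect stump yields a large finite beta instead of inf.
EPS_CLAMP = 1e-10


@dataclass(frozen=True)
class Stump:
    """Depth-1 threshold classifier on a single named feature."""

    feature_name: str
    threshold: float
    polarity: int  # +1: predict +1 where x <= threshold; -1: flipped
    weighted_error: float

    def predict(self, column: np.ndarray) -> np.ndarray:
        """Labels in {+1, -1} for one feature column."""
        below = np.asarray(column, dtype=np.float64) <= self.threshold
        return np.where(below, self.polarity, -self.polarity).astype(np.int64)


@dataclass
class SelectionState:
    """Bookkeeping of a selection run.

    ``history`` holds one (feature_name, epsilon, beta) triple per round,
    epsilon already clamped into (0, 1).
    """

    D: np.ndarray
    f_o: list[str] = field(default_factory=list)
    remaining: list[str] = field(default_factory=list)
    history: list[tuple[str, float, float]] = field(default_factory=list)


def init_weights(n: int) -> np.ndarray:
    """Uniform sample weights 1/n."""
    if n < 1:
        raise ValueError("need at least one sample")
    return np.full(n, 1.0 / n)


def compute_beta(eps: float) -> float:
    """Classifier weight beta = 0.5 * ln((1 - eps) / eps), eps clamped."""
    eps = min(max(eps, EPS_CLAMP), 1.0 - EPS_CLAMP)
    return 0.5 * np.log((1.0 - eps) / eps)


def update_weights(
    D: np.ndarray, predictions: np.ndarray, y: np.ndarray, beta: float
) -> np.ndarray:
    """Reweight samples: correct * e^-beta, wrong * e^+beta, renormalize."""
    D = np.asarray(D, dtype=np.float64)
    correct = np.asarray(predictions) == np.asarray(y)
    D_new = D * np.where(correct, np.exp(-beta), np.exp(beta))
    return D_new / D_new.sum()


def _split_threshold(xs_sorted: np.ndarray, k: int) -> float:
    if k == 0:
        return -np.inf
    if k == len(xs_sorted):
        return np.inf
    return 0.5 * (xs_sorted[k - 1] + xs_sorted[k])


def fit_stump(column: np.ndarray, y: np.ndarray, D: np.ndarray) -> Stump:
    """Best weighted stump for one feature column.

    Minimizes the weighted misclassification over every midpoint
    threshold (plus the +/-inf sentinels), both polarities; ties prefer
    the smaller threshold, then polarity +1.

    The search uses the identity err_plus(k) = W(+1) - cumsum(D*y)[k]
    for the split putting the first k sorted samples on the ``<=``
    (predict +1) side: moving a sample across the threshold changes the
    error by exactly its signed weight. The polarity -1 error is the
    complement 1 - err_plus, so the best split of either polarity
    maximizes |err_plus - 1/2|.
    """
    column = np.asarray(column, dtype=np.float64)
    y = np.asarray(y)
    D = np.asarray(D, dtype=np.float64)
    if not (len(column) == len(y) == len(D)):
        raise ValueError("column, labels and weights must have equal length")
    n = len(column)
    order = np.argsort(column, kind="stable")
    xs = column[order]
    w_pos = float(D[y == 1].sum())
    err_plus = np.empty(n + 1)
    err_plus[0] = w_pos
    err_plus[1:] = w_pos - np.cumsum((D * y)[order])
    valid = np.ones(n + 1, dtype=bool)
    valid[1:n] = xs[1:] != xs[:-1]
    deviation = np.where(valid, np.abs(err_plus - 0.5), -1.0)
    # equivalent predictors (e.g. all-below vs all-above) tie only up to
    # rounding, so resolve ties with a tolerance: smallest threshold wins,
    # then polarity +1
    near_best = np.flatnonzero(deviation >= deviation.max() - 1e-12)
    k = int(near_best[0])
    polarity = 1 if err_plus[k] <= 0.5 else -1
    eps = err_plus[k] if polarity == 1 else 1.0 - err_plus[k]
    return Stump("", float(_split_threshold(xs, k)), polarity, float(eps))


def _best_splits_all(
    y: np.ndarray,
    D: np.ndarray,
    orders_T: np.ndarray,
    invalid_flat: np.ndarray,
    active: np.ndarray,
    buffers: tuple[np.ndarray, np.ndarray],
) -> int:
    """Vectorized screening for the feature with the smallest stump error.

    ``orders_T`` is the per-column argsort of X transposed to (features,
    samples) for row-contiguous access; ``invalid_flat`` flat-indexes
    split positions not realizable by a midpoint. Same arithmetic as
    :func:`fit_stump`: the winning split of a column maximizes
    |err_plus - 1/2|, and the winning column maximizes that deviation,
    with np.argmax's first-occurrence rule realizing the deterministic
    canonical-index tie-break. Returns the winning column index; the
    exact stump is then re-fit on that single column.
    """
    m, n = orders_T.shape
    Dy_buf, dev = buffers
    # argsort output is always in range, so skip per-element bounds checks
    np.take(D * y, orders_T, out=Dy_buf, mode="clip")
    w_pos = float(D[y == 1].sum())
    dev[:, 0] = w_pos - 0.5
    np.cumsum(Dy_buf, axis=1, out=dev[:, 1:])
    np.subtract(w_pos - 0.5, dev[:, 1:], out=dev[:, 1:])
    np.abs(dev, out=dev)
    dev.ravel()[invalid_flat] = -1.0
    best_dev = dev.max(axis=1)
    best_dev[~active] = -np.inf
    return int(np.argmax(best_dev))


def select_features(
    X: FeatureMatrix, y: np.ndarray, k: int, seed: int | None = None
) -> SelectionState:
    """Run k rounds of AdaBoost forward selection on a labeled matrix.

    ``y`` may be given as {0, 1} or {+1, -1}; it is mapped to the signed
    convention internally. The procedure is deterministic given its
    inputs; ``seed`` is accepted for interface uniformity only.
    """
    y = np.asarray(y)
    if set(np.unique(y)) == {0, 1}:
        y = np.where(y == 1, 1, -1)
    y = y.astype(np.int64)
    if len(np.unique(y)) < 2:
        raise ValueError("selection requires both classes present")
    n, m = X.shape
    if k > m:
        raise ValueError(f"cannot select {k} features out of {m}")
    if len(y) != n:
        raise ValueError("label length does not match sample count")

    values_T = np.ascontiguousarray(X.values.T)
    orders_T = np.argsort(values_T, axis=1, kind="stable")
    xs_sorted_T = np.take_along_axis(values_T, orders_T, axis=1)
    invalid_T = np.zeros((m, n + 1), dtype=bool)
    invalid_T[:, 1:n] = xs_sorted_T[:, 1:] == xs_sorted_T[:, :-1]
    invalid_flat = np.flatnonzero(invalid_T.ravel())

    state = SelectionState(D=init_weights(n), remaining=list(X.feature_names))
    active = np.ones(m, dtype=bool)
    names = X.feature_names
    buffers = (np.empty((m, n)), np.empty((m, n + 1)))
    for _ in range(k):
        j = _best_splits_all(y, state.D, orders_T, invalid_flat, active, buffers)
        stump = fit_stump(values_T[j], y, state.D)
        stump = Stump(names[j], stump.threshold, stump.polarity, stump.weighted_error)
        eps_c = min(max(stump.weighted_error, EPS_CLAMP), 1.0 - EPS_CLAMP)
        beta = compute_beta(stump.weighted_error)
        state.f_o.append(names[j])
        state.remaining.remove(names[j])
        state.history.append((names[j], eps_c, beta))
        active[j] = False
        state.D = update_weights(state.D, stump.predict(values_T[j]), y, beta)
    return state


def reduce_matrix(X: FeatureMatrix, f_o: list[str]) -> FeatureMatrix:
    """Restrict a feature matrix to the selected features, in selection order."""
    return X.select_columns(f_o)


def write_selection_state(state: SelectionState, path) -> None:
    """Persist selection history as TSV: round, feature_name, epsilon, beta."""
    with open(path, "w") as fh:
        fh.write("round\tfeature_name\tepsilon\tbeta\n")
        for t, (name, eps, beta) in enumerate(state.history, start=1):
            fh.write(f"{t}\t{name}\t{eps:.10g}\t{beta:.10g}\n")
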