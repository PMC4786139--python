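"""Wrapper fitness: continuous position -> feature mask -> KNN score.

The optimizer works in [0, 1]^D; each dimension is a feature.  A position
is thresholded at 0.5 into a binary mask, a k-nearest-neighbour classifier
is trained on the training split restricted to the selected columns, and
its error on the validation split is blended with the selection ratio:

    fitness = alpha * (1 - P) + (1 - alpha) * N_f / N_t

minimized, with P the validation accuracy, N_f the number of selected
features and N_t the total.  alpha close to 1 makes accuracy dominant.

The KNN here is deliberately hand-specified so that every tie is broken
deterministically: equal distances resolve to the lower training-row
index, and a tied majority vote resolves to the label of the single
nearest neighbour.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class FitnessConfig:
    """Weights and classifier settings for the subset fitness.

    alpha blends classification error against selection ratio (accuracy
    dominates at the 0.99 default); k is the number of neighbours; scale
    toggles min-max feature scaling from training-split statistics.
    """

    alpha: float = 0.99
    k: int = 5
    scale: bool = True

    def __post_init__(self):
        if not 0.0 <= self.alpha <= 1.0:
            raise ValueError(f"alpha must be in [0, 1], got {self.alpha}")
        if self.k < 1 or self.k % 2 == 0:
            raise ValueError(f"k must be an odd positive integer, got {self.k}")


def binarize(position: np.ndarray) -> np.ndarray:
    """Threshold a continuous position at 0.5 into a feature mask.

    Values >= 0.5 select the feature (the boundary itself selects).
    """
    position = np.asarray(position, dtype=float)
    if position.size and (position.min() < 0.0 or position.max() > 1.0):
        raise ValueError("position values must lie in [0, 1]")
    return (position >= 0.5).astype(np.int8)


def knn_predict(
    train_X: np.ndarray,
    train_y: np.ndarray,
    query_X: np.ndarray,
    k: int,
) -> np.ndarray:
    """Euclidean k-NN majority vote with deterministic tie-breaking."""
    train_X = np.asarray(train_X, dtype=float)
    train_y = np.asarray(train_y)
    query_X = np.asarray(query_X, dtype=float)
    n_train = train_X.shape[0]
    if n_train == 0:
        raise ValueError("training set is empty")
    if k > n_train:
        logger.warning("k=%d exceeds %d training rows; clamping", k, n_train)
        k = n_train

    # squared distances suffice for ranking
    d2 = (
        (query_X**2).sum(axis=1)[:, None]
        + (train_X**2).sum(axis=1)[None, :]
        - 2.0 * query_X @ train_X.T
    )
    # stable sort: equal distances resolve to the lower training-row index
    order = np.argsort(d2, axis=1, kind="stable")[:, :k]

    n_labels = int(train_y.max()) + 1
    pred = np.empty(query_X.shape[0], dtype=train_y.dtype)
    for q in range(query_X.shape[0]):
        votes = np.bincount(train_y[order[q]], minlength=n_labels)
        top = votes.max()
        winners = np.flatnonzero(votes == top)
        if winners.size == 1:
            pred[q] = winners[0]
        else:
            pred[q] = train_y[order[q, 0]]  # vote tie -> nearest neighbour
    return pred


def classification_performance(pred: np.ndarray, ref: np.ndarray) -> float:
    """Fraction of correctly classified instances, N_c / N."""
    pred = np.asarray(pred)
    ref = np.asarray(ref)
    if pred.shape != ref.shape or pred.size == 0:
        raise ValueError("prediction and reference labels must be nonempty and equal-length")
    return float(np.mean(pred == ref))


def subset_fitness(mask: np.ndarray, data, cfg: FitnessConfig = FitnessConfig()) -> float:
    """Bi-objective fitness of a feature mask on the train/validation splits.

    The empty mask is infeasible (no classifier can be trained) and returns
    the worst value 1.0, keeping the objective total over [0, 1]^D.
    """
    mask = np.asarray(mask).astype(bool)
    n_total = data.X.shape[1]
    if mask.shape != (n_total,):
        raise ValueError(f"mask length {mask.shape} does not match {n_total} features")
    n_sel = int(mask.sum())
    if n_sel == 0:
        return 1.0
    X = data.scaled_X if cfg.scale else data.X
    cols = X[:, mask]
    pred = knn_predict(cols[data.train_idx], data.y[data.train_idx], cols[data.valid_idx], cfg.k)
    perf = classification_performance(pred, data.y[data.valid_idx])
    return cfg.alpha * (1.0 - perf) + (1.0 - cfg.alpha) * (n_sel / n_total)


def holdout_accuracy(mask: np.ndarray, data, cfg: FitnessConfig = FitnessConfig()):
    """Test-split predictions and accuracy for a final selected mask.

    The test third is touched only here, never during optimization.
    """
    mask = np.asarray(mask).astype(bool)
    if mask.sum() == 0:
        raise ValueError("cannot evaluate an empty feature mask on the test split")
    X = data.scaled_X if cfg.scale else data.X
    cols = X[:, mask]
    pred = knn_predict(cols[data.train_idx], data.y[data.train_idx], cols[data.test_idx], cfg.k)
    return pred, classification_performance(pred, data.y[data.test_idx])
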