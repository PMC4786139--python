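"""Aggregate statistics over repeated optimizer runs.

A stochastic optimizer is characterised over M independent applications by
the mean / best / worst / standard deviation of the per-run best fitness,
the mean test-set accuracy of the selected subsets, the mean selection
size (fraction of features kept), and a Fisher-score-based quality of the
selected features.

The Fisher score of feature j is

    F_j = sum_k n_k (mu_kj - mu_j)^2 / sigma_j^2

with mu_j and sigma_j the mean and standard deviation of feature j over
the entire dataset (population convention, divide by N) and mu_kj the
class-k mean — large when class means separate relative to overall spread.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .objective import classification_performance


@dataclass
class RunCollection:
    """Best-of-run results from M independent optimizer applications."""

    fitnesses: np.ndarray                       # per-run best fitness, length M
    masks: np.ndarray                           # M x N_t binary
    test_predictions: list | None = None        # per-run test-split labels
    dataset: object | None = None               # SplitDataset the runs used
    seeds: list = field(default_factory=list)

    def __post_init__(self):
        self.fitnesses = np.asarray(self.fitnesses, dtype=float)
        self.masks = np.atleast_2d(np.asarray(self.masks))
        if self.fitnesses.size == 0:
            raise ValueError("a run collection needs at least one run")
        if self.masks.shape[0] != self.fitnesses.size:
            raise ValueError("one mask per run required")

    @property
    def n_runs(self) -> int:
        return int(self.fitnesses.size)


def run_statistics(rc: RunCollection) -> dict:
    """Mean, best (min), worst (max) and sample std of per-run best fitness.

    With a single run the std is undefined and reported as None.
    """
    g = rc.fitnesses
    std = float(np.std(g, ddof=1)) if g.size >= 2 else None
    return {
        "mean": float(np.mean(g)),
        "best": float(np.min(g)),
        "worst": float(np.max(g)),
        "std": std,
    }


def average_accuracy(rc: RunCollection) -> float:
    """Mean over runs of the test-split accuracy of each selected subset."""
    if rc.test_predictions is None or rc.dataset is None:
        raise ValueError("run collection has no test predictions to average")
    ref = rc.dataset.y[rc.dataset.test_idx]
    return float(
        np.mean([classification_performance(p, ref) for p in rc.test_predictions])
    )


def average_selection_size(rc: RunCollection) -> float:
    """Mean fraction of features selected across runs."""
    n_total = rc.masks.shape[1]
    return float(np.mean(rc.masks.sum(axis=1) / n_total))


def fisher_scores(X: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Per-feature class-separability scores F_j (see module docstring).

    Features with zero overall spread get score 0 with a warning.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    classes = np.unique(y)
    if classes.size < 2:
        raise ValueError("Fisher scores require at least two classes")
    mu = X.mean(axis=0)
    var = X.var(axis=0)  # population convention (divide by N)
    num = np.zeros(X.shape[1])
    for cls in classes:
        rows = y == cls
        num += rows.sum() * (X[rows].mean(axis=0) - mu) ** 2
    scores = np.zeros(X.shape[1])
    nonzero = var > 0
    if not nonzero.all():
        warnings.warn(
            f"{int((~nonzero).sum())} feature(s) have zero spread; Fisher score set to 0",
            stacklevel=2,
        )
    scores[nonzero] = num[nonzero] / var[nonzero]
    return scores


def average_fisher(rc: RunCollection, mode: str = "sum") -> float:
    """Mean over runs of the Fisher quality of each run's selected subset.

    ``sum`` (default) totals F_j over the selected features of each run;
    ``mean`` averages per selected feature instead.
    """
    if rc.dataset is None:
        raise ValueError("run collection has no dataset reference")
    if mode not in ("sum", "mean"):
        raise ValueError(f"mode must be 'sum' or 'mean', got {mode!r}")
    F = fisher_scores(rc.dataset.X, rc.dataset.y)
    per_run = []
    for mask in rc.masks.astype(bool):
        sel = F[mask]
        if mode == "sum":
            per_run.append(sel.sum())
        else:
            per_run.append(sel.mean() if sel.size else 0.0)
    return float(np.mean(per_run))
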