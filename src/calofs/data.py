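"""Dataset ingestion, the three-way split, and synthetic benchmarks.

Real inputs are UCI-style delimited text: one row per sample, numeric
feature columns and one class-label column.  Every dataset is partitioned
into stratified equal thirds — training (fits the classifier), validation
(drives the optimizer's fitness) and testing (final reporting only).

The synthetic generator plants a known set of informative features
(class-separated Gaussians) among pure-noise columns, so feature-recovery
claims can be checked against ground truth; the exhaustive oracle scores
every nonempty mask on small feature spaces and is the gold standard the
optimizer is compared against.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .objective import FitnessConfig, subset_fitness

ORACLE_MAX_FEATURES = 15


@dataclass
class SplitDataset:
    """Feature matrix, integer labels and disjoint train/valid/test thirds."""

    X: np.ndarray
    y: np.ndarray
    train_idx: np.ndarray
    valid_idx: np.ndarray
    test_idx: np.ndarray
    _scaled: np.ndarray | None = field(default=None, repr=False)

    def __post_init__(self):
        n = self.X.shape[0]
        all_idx = np.concatenate([self.train_idx, self.valid_idx, self.test_idx])
        if len(np.unique(all_idx)) != n or len(all_idx) != n:
            raise ValueError("split index sets must be disjoint and cover all rows")
        if len(np.unique(self.y[self.train_idx])) < len(np.unique(self.y)):
            raise ValueError("every class must appear in the training split")

    @property
    def n_features(self) -> int:
        return self.X.shape[1]

    @property
    def scaled_X(self) -> np.ndarray:
        """X min-max scaled per feature using training-split statistics.

        Constant training columns scale to 0 everywhere (no spread to map).
        """
        if self._scaled is None:
            lo = self.X[self.train_idx].min(axis=0)
            hi = self.X[self.train_idx].max(axis=0)
            span = hi - lo
            span[span == 0.0] = 1.0
            self._scaled = (self.X - lo) / span
        return self._scaled


@dataclass(frozen=True)
class SynthSpec:
    """Recipe for a planted-feature classification benchmark.

    ``n_informative`` columns get class-conditional normal values whose
    means are ``delta * sigma`` apart between adjacent classes;
    ``n_noise`` columns are class-independent N(0, sigma) draws.
    """

    n_samples: int = 300
    n_informative: int = 3
    n_noise: int = 7
    delta: float = 3.0
    sigma: float = 1.0
    n_classes: int = 2
    class_weights: tuple | None = None  # None -> balanced
    seed: int = 0

    def __post_init__(self):
        if self.n_informative < 1:
            raise ValueError("need at least one informative feature")
        if self.delta < 0:
            raise ValueError("delta must be >= 0")
        if self.n_classes < 2:
            raise ValueError("need at least two classes")


def load_dataset(path, label_column="last"):
    """Read a delimited numeric table into (X, y).

    The delimiter is chosen from the extension (.tsv/.txt tab, else comma).
    Labels are mapped to 0..c-1 in first-appearance order.
    """
    path = Path(path)
    sep = "\t" if path.suffix.lower() in (".tsv", ".txt") else ","
    df = pd.read_csv(path, sep=sep)
    if label_column == "last":
        label_column = df.columns[-1]
    if label_column not in df.columns:
        raise ValueError(f"label column {label_column!r} not found in {path.name}")
    raw_labels = df[label_column]
    feats = df.drop(columns=[label_column])

    bad = feats.columns[~feats.apply(lambda c: pd.to_numeric(c, errors="coerce").notna().all())]
    if len(bad) or feats.isna().any().any():
        col = bad[0] if len(bad) else feats.columns[feats.isna().any()][0]
        row = int(feats[pd.to_numeric(feats[col], errors="coerce").isna()].index[0])
        raise ValueError(f"non-numeric or missing value at row {row}, column {col!r}")

    codes, uniques = pd.factorize(raw_labels)  # first-appearance order
    if len(uniques) < 2:
        raise ValueError(f"need at least 2 classes, found {len(uniques)}")
    return feats.to_numpy(dtype=float), codes.astype(np.int64)


def three_way_split(X: np.ndarray, y: np.ndarray, seed: int | None = None) -> SplitDataset:
    """Stratified shuffle into equal train/validation/test thirds.

    Within each class the thirds differ in size by at most one row, with
    any remainder going to training first.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    rng = np.random.default_rng(seed)
    parts = [[], [], []]
    for cls in np.unique(y):
        idx = np.flatnonzero(y == cls)
        if len(idx) < 3:
            raise ValueError(f"class {cls} has {len(idx)} samples; need at least 3")
        idx = rng.permutation(idx)
        for part, chunk in zip(parts, np.array_split(idx, 3)):
            part.append(chunk)
    train, valid, test = (np.sort(np.concatenate(p)) for p in parts)
    return SplitDataset(X, y, train, valid, test)


def generate_synthetic(spec: SynthSpec):
    """Sample a planted-feature dataset; returns (X, y, informative_indices).

    Classes are balanced by default (remainder rows go to the lower class
    labels); informative columns occupy indices 0..n_informative-1.
    """
    rng = np.random.default_rng(spec.seed)
    c = spec.n_classes
    if spec.class_weights is None:
        counts = np.full(c, spec.n_samples // c)
        counts[: spec.n_samples % c] += 1
    else:
        w = np.asarray(spec.class_weights, dtype=float)
        counts = np.round(w / w.sum() * spec.n_samples).astype(int)
        counts[0] += spec.n_samples - counts.sum()
    y = np.repeat(np.arange(c), counts)

    n_feat = spec.n_informative + spec.n_noise
    X = rng.normal(0.0, spec.sigma, size=(spec.n_samples, n_feat))
    means = np.arange(c)[:, None] * spec.delta * spec.sigma  # adjacent classes delta·sigma apart
    X[:, : spec.n_informative] += means[y]

    perm = rng.permutation(spec.n_samples)
    return X[perm], y[perm], np.arange(spec.n_informative)


def synthetic_split(spec: SynthSpec, split_seed: int | None = None):
    """Convenience: generate and three-way split in one call."""
    X, y, informative = generate_synthetic(spec)
    seed = spec.seed if split_seed is None else split_seed
    return three_way_split(X, y, seed=seed), informative


def exhaustive_oracle(data: SplitDataset, cfg: FitnessConfig = FitnessConfig()):
    """Score every nonempty feature mask and return (best_mask, best_fitness).

    Feasible only for small feature spaces (<= 15 features, 2^15 - 1 masks);
    ties resolve to the lexicographically smallest bit vector.
    """
    n = data.n_features
    if n > ORACLE_MAX_FEATURES:
        raise ValueError(
            f"{n} features means 2^{n}-1 masks; the exhaustive oracle is capped at "
            f"{ORACLE_MAX_FEATURES} — use the optimizer for larger spaces"
        )
    best_mask, best_fit = None, np.inf
    # MSB = feature 0, so ascending integers enumerate masks in
    # lexicographic bit-vector order and the first minimum wins ties
    for m in range(1, 2**n):
        mask = np.array([(m >> (n - 1 - j)) & 1 for j in range(n)], dtype=np.int8)
        fit = subset_fitness(mask, data, cfg)
        if fit < best_fit:
            best_mask, best_fit = mask, fit
    return best_mask, float(best_fit)


def write_dataset(X: np.ndarray, y: np.ndarray, path) -> None:
    """Write (X, y) in the same delimited format ``load_dataset`` reads."""
    path = Path(path)
    sep = "\t" if path.suffix.lower() in (".tsv", ".txt") else ","
    df = pd.DataFrame(X, columns=[f"f{j}" for j in range(X.shape[1])])
    df["label"] = y
    df.to_csv(path, sep=sep, index=False)
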