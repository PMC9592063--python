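"""Dataset preparation: stratified splitting, Gaussian augmentation, PCA at a
target explained variance, and k-fold assignments.

PCA and augmentation statistics are always fit on training rows only; the
split is stratified by task label so per-task proportions are preserved in
every partition.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "DatasetSplit",
    "PCAModel",
    "stratified_split",
    "augment_gaussian",
    "fit_pca",
    "apply_pca",
    "make_folds",
]


@dataclass
class DatasetSplit:
    """Disjoint, exhaustive train/test partition with fold ids on train.

    ``fold`` is 1..k for trainable frames and 0 for frames pinned to
    training (degenerate strata); test frames carry -1.
    """

    test_idx: np.ndarray
    train_idx: np.ndarray
    labels: np.ndarray
    fold: np.ndarray  # per-frame fold id over all frames
    k: int

    def __post_init__(self) -> None:
        both = np.intersect1d(self.test_idx, self.train_idx)
        if both.size:
            raise ValueError("train/test overlap")
        n = len(self.labels)
        if len(np.union1d(self.test_idx, self.train_idx)) != n:
            raise ValueError("partitions must be exhaustive")


@dataclass
class PCAModel:
    mean: np.ndarray
    scale: np.ndarray
    components: np.ndarray  # (k, n_features)
    explained_variance_ratio: np.ndarray  # all components
    n_components: int
    variance_target: float = 0.90
    input_names: list[str] = field(default_factory=list)


def stratified_split(
    labels,
    seed: int,
    test_fraction: float = 0.20,
    k: int = 5,
) -> DatasetSplit:
    """Task-stratified holdout plus stratified fold assignment.

    Per label stratum: a shuffled ``test_fraction`` share goes to test and
    the remainder is dealt round-robin into k folds.  Strata with fewer than
    k frames are pinned to training (fold 0) with a warning.
    """
    labels = np.asarray(labels)
    n = labels.size
    rng = np.random.default_rng(seed)
    fold = np.full(n, -1, dtype=np.int64)
    test_mask = np.zeros(n, dtype=bool)
    for lab in np.unique(labels):
        idx = np.flatnonzero(labels == lab)
        if idx.size < k:
            warnings.warn(
                f"stratum {lab!r} has {idx.size} < {k} frames; "
                "assigned wholly to training",
                stacklevel=2,
            )
            fold[idx] = 0
            continue
        perm = rng.permutation(idx)
        n_test = int(round(test_fraction * idx.size))
        test_mask[perm[:n_test]] = True
        rest = perm[n_test:]
        fold[rest] = 1 + (np.arange(rest.size) % k)
    test_idx = np.flatnonzero(test_mask)
    train_idx = np.flatnonzero(~test_mask)
    return DatasetSplit(
        test_idx=test_idx, train_idx=train_idx, labels=labels, fold=fold, k=k
    )


def augment_gaussian(
    features: np.ndarray,
    scale: float,
    seed: int,
    targets: np.ndarray | None = None,
):
    """Append one noisy copy per row: row + N(0, (scale * sigma_feature)^2).

    Targets, when given, are duplicated unchanged.  Intended for training
    rows only.
    """
    if scale < 0:
        raise ValueError("scale must be nonnegative")
    X = np.asarray(features, dtype=np.float64)
    if X.size == 0:
        raise ValueError("empty training set")
    sigma = X.std(axis=0)
    rng = np.random.default_rng(seed)
    noisy = X + rng.standard_normal(X.shape) * (scale * sigma)[None, :]
    X_aug = np.vstack([X, noisy])
    if targets is None:
        return X_aug
    t = np.asarray(targets)
    return X_aug, np.concatenate([t, t])


def fit_pca(
    features: np.ndarray,
    variance_target: float = 0.90,
    standardize: bool = True,
) -> PCAModel:
    """PCA on (z-scored) training features, retaining the minimal component
    count whose cumulative explained-variance ratio reaches the target."""
    X = np.asarray(features, dtype=np.float64)
    mean = X.mean(axis=0)
    if standardize:
        scale = X.std(axis=0)
        scale = np.where(scale > 1e-12, scale, 1.0)  # constant columns
    else:
        scale = np.ones(X.shape[1])
    Z = (X - mean) / scale
    # SVD of the centered matrix == eigendecomposition of the covariance
    _, s, vt = np.linalg.svd(Z, full_matrices=False)
    var = s**2 / max(X.shape[0] - 1, 1)
    total = var.sum()
    ratio = var / total if total > 0 else np.zeros_like(var)
    cum = np.cumsum(ratio)
    n_comp = int(np.searchsorted(cum, variance_target - 1e-12) + 1)
    n_comp = min(n_comp, len(ratio))
    return PCAModel(
        mean=mean,
        scale=scale,
        components=vt[:n_comp],
        explained_variance_ratio=ratio,
        n_components=n_comp,
        variance_target=variance_target,
    )


def apply_pca(model: PCAModel, features: np.ndarray) -> np.ndarray:
    X = np.asarray(features, dtype=np.float64)
    return ((X - model.mean) / model.scale) @ model.components.T


def make_folds(split: DatasetSplit) -> list[tuple[np.ndarray, np.ndarray]]:
    """(train, validation) index pairs, one per fold.

    Fold-0 frames (degenerate strata) appear in every training set and no
    validation set.  PCA/augmentation must be re-fit per fold on the train
    member only.
    """
    pairs = []
    for f in range(1, split.k + 1):
        val = np.flatnonzero(split.fold == f)
        train = np.flatnonzero((split.fold >= 0) & (split.fold != f))
        pairs.append((train, val))
    return pairs
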