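"""Sample expansion: corruption-based augmentation for tiny training sets.

Given a training matrix with m genes and a corruption parameter ``a``
(1 ≤ a ≤ m), each training sample yields floor(m/a) corrupted copies: one
random permutation of the gene indices is chunked into consecutive groups of
``a``, and each copy has one group's values forced to exactly 0. The groups
of a single source sample are therefore pairwise disjoint ("non-repeated"
corruption locations), and when a does not divide m the leftover m mod a
indices are never corrupted for that sample. Expanded copies inherit the
source label; expanded and raw rows are merged into one training set of
n × (floor(m/a) + 1) rows.

Corruption is applied to whatever values are passed in; in the standard
pipeline that is the row-normalized matrix, so a zeroed entry sits at the
gene's training mean.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .data_io import ExpressionMatrix, LabelVector

__all__ = [
    "SEConfig",
    "ExpandedSet",
    "expand_sample",
    "expand_training_set",
    "expand_all",
    "stratified_split",
]


@dataclass
class SEConfig:
    """Configuration for sample expansion.

    a
        Number of genes zeroed per expanded copy, 1 ≤ a ≤ m.
    seed
        Seed for the per-sample corruption permutations.
    """

    a: int = 1
    seed: int = 0

    def validate(self, m: int) -> None:
        if not (1 <= self.a <= m):
            raise ValueError(f"corruption parameter a={self.a} outside 1..{m}")


@dataclass
class ExpandedSet:
    """Merged raw + corrupted training rows with provenance.

    values
        Row-per-sample matrix, shape (n_rows, m).
    labels
        Inherited class label per row.
    source_sample
        Id of the raw sample each row derives from.
    corrupted_indices
        0-based gene indices zeroed in each row; empty array for raw rows.
    """

    values: np.ndarray
    labels: np.ndarray
    source_sample: list[str]
    corrupted_indices: list[np.ndarray]
    gene_ids: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.labels = np.asarray(self.labels, dtype=int)
        n = self.values.shape[0]
        if not (len(self.labels) == len(self.source_sample) == len(self.corrupted_indices) == n):
            raise ValueError("inconsistent row metadata")
        if not self.gene_ids:
            self.gene_ids = [f"g{i}" for i in range(self.values.shape[1])]

    @property
    def n_rows(self) -> int:
        return self.values.shape[0]

    @property
    def raw_mask(self) -> np.ndarray:
        return np.array([len(ix) == 0 for ix in self.corrupted_indices])

    def __eq__(self, other) -> bool:
        if not isinstance(other, ExpandedSet):
            return NotImplemented
        return (
            np.allclose(self.values, other.values, atol=1e-12)
            and np.array_equal(self.labels, other.labels)
            and self.source_sample == other.source_sample
            and all(
                np.array_equal(a, b)
                for a, b in zip(self.corrupted_indices, other.corrupted_indices)
            )
            and self.gene_ids == other.gene_ids
        )


def expand_sample(
    x: np.ndarray, a: int, rng: np.random.Generator
) -> tuple[list[np.ndarray], list[np.ndarray]]:
    """Corrupted copies of one sample vector.

    Returns floor(m/a) copies of ``x`` and the index group zeroed in each.
    One uniform permutation of 0..m-1 is chunked into consecutive groups of
    ``a``; the first floor(m/a) groups are the corruption sets.
    """
    x = np.asarray(x, dtype=float)
    m = x.shape[0]
    if not (1 <= a <= m):
        raise ValueError(f"a={a} outside 1..{m}")
    n_copies = m // a
    perm = rng.permutation(m)
    groups = [np.sort(perm[i * a : (i + 1) * a]) for i in range(n_copies)]
    copies = []
    for g in groups:
        c = x.copy()
        c[g] = 0.0
        copies.append(c)
    return copies, groups


def expand_training_set(
    X_train: ExpressionMatrix, y_train: np.ndarray | LabelVector, cfg: SEConfig
) -> ExpandedSet:
    """Expand every training sample and merge with the raw rows.

    The result has n_train × (floor(m/a) + 1) rows: each raw sample followed
    by its floor(m/a) corrupted copies. Deterministic under ``cfg.seed``.
    """
    labels = y_train.labels if isinstance(y_train, LabelVector) else np.asarray(y_train, dtype=int)
    m, n = X_train.values.shape
    if len(labels) != n:
        raise ValueError("label vector length does not match training sample count")
    cfg.validate(m)
    rng = np.random.default_rng(cfg.seed)
    rows, row_labels, sources, corrupted = [], [], [], []
    for j in range(n):
        x = X_train.values[:, j]
        sid = X_train.sample_ids[j]
        rows.append(x.copy())
        row_labels.append(labels[j])
        sources.append(sid)
        corrupted.append(np.array([], dtype=int))
        copies, groups = expand_sample(x, cfg.a, rng)
        for c, g in zip(copies, groups):
            rows.append(c)
            row_labels.append(labels[j])
            sources.append(sid)
            corrupted.append(g)
    return ExpandedSet(
        values=np.vstack(rows),
        labels=np.array(row_labels),
        source_sample=sources,
        corrupted_indices=corrupted,
        gene_ids=list(X_train.gene_ids),
    )


def expand_all(X: ExpressionMatrix, y: LabelVector, cfg: SEConfig) -> ExpandedSet:
    """Expand every sample of the dataset (training and held-out alike)."""
    return expand_training_set(X, y, cfg)


def stratified_split(
    y: LabelVector, train_fraction: float, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """Per-class train/test partition with ceiling rounding.

    For each class of size n_c, ceil(train_fraction · n_c) samples are drawn
    uniformly without replacement for training; the rest are test. With the
    20% fraction this gives 5 training samples for class sizes {8, 12} and 13
    for {12, 20, 10, 18} or {22, 40}.
    """
    if not (0.0 < train_fraction < 1.0):
        raise ValueError("train_fraction must be in (0, 1)")
    train_idx: list[int] = []
    test_idx: list[int] = []
    for c in range(1, y.n_classes + 1):
        members = np.flatnonzero(y.labels == c)
        n_take = math.ceil(train_fraction * len(members))
        chosen = rng.choice(members, size=n_take, replace=False)
        chosen_set = set(chosen.tolist())
        train_idx.extend(sorted(chosen_set))
        test_idx.extend(i for i in members.tolist() if i not in chosen_set)
    return np.array(sorted(train_idx), dtype=int), np.array(sorted(test_idx), dtype=int)
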