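"""Reading and writing expression tables, label vectors and expanded sets.

Conventions: the in-memory :class:`ExpressionMatrix` is always oriented
genes × samples (one row per gene), matching the usual microarray layout.
On-disk tables may be stored either way; the reader reorients.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "ExpressionMatrix",
    "LabelVector",
    "read_expression_table",
    "read_labels",
    "write_expression_table",
    "write_labels",
    "write_expanded_set",
    "read_expanded_set",
]


@dataclass
class ExpressionMatrix:
    """A genes × samples real-valued expression matrix with identifiers.

    Parameters
    ----------
    values
        Array of shape ``(m, n)``: ``m`` genes, ``n`` samples.
    gene_ids
        ``m`` unique gene identifiers.
    sample_ids
        ``n`` unique sample identifiers.
    """

    values: np.ndarray
    gene_ids: list[str]
    sample_ids: list[str]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.gene_ids = [str(g) for g in self.gene_ids]
        self.sample_ids = [str(s) for s in self.sample_ids]
        if self.values.ndim != 2:
            raise ValueError("values must be a 2-D genes × samples array")
        m, n = self.values.shape
        if m < 1 or n < 1:
            raise ValueError("expression matrix needs at least one gene and one sample")
        if len(self.gene_ids) != m:
            raise ValueError(f"{len(self.gene_ids)} gene ids for {m} rows")
        if len(self.sample_ids) != n:
            raise ValueError(f"{len(self.sample_ids)} sample ids for {n} columns")
        if len(set(self.gene_ids)) != m:
            raise ValueError("duplicate gene identifiers")
        if len(set(self.sample_ids)) != n:
            raise ValueError("duplicate sample identifiers")
        if not np.isfinite(self.values).all():
            raise ValueError("expression matrix contains missing or non-finite values")

    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    def restrict_genes(self, indices: Sequence[int]) -> "ExpressionMatrix":
        """Return a new matrix restricted to the given gene rows, in order."""
        idx = np.asarray(indices, dtype=int)
        return ExpressionMatrix(
            values=self.values[idx, :].copy(),
            gene_ids=[self.gene_ids[i] for i in idx],
            sample_ids=list(self.sample_ids),
        )

    def restrict_samples(self, indices: Sequence[int]) -> "ExpressionMatrix":
        """Return a new matrix restricted to the given sample columns, in order."""
        idx = np.asarray(indices, dtype=int)
        return ExpressionMatrix(
            values=self.values[:, idx].copy(),
            gene_ids=list(self.gene_ids),
            sample_ids=[self.sample_ids[i] for i in idx],
        )


@dataclass
class LabelVector:
    """Integer class labels 1..C, one per sample.

    ``class_names`` records the original label of each class in
    first-appearance order when the labels were mapped from strings.
    """

    labels: np.ndarray
    class_names: list[str] | None = field(default=None)

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=int)
        if self.labels.ndim != 1 or self.labels.size < 1:
            raise ValueError("labels must be a non-empty 1-D vector")
        c = int(self.labels.max())
        if self.labels.min() < 1:
            raise ValueError("labels must be in 1..C")
        present = set(np.unique(self.labels).tolist())
        if present != set(range(1, c + 1)):
            missing = sorted(set(range(1, c + 1)) - present)
            raise ValueError(f"classes {missing} have no samples")
        if self.class_names is not None and len(self.class_names) != c:
            raise ValueError("class_names length must equal the number of classes")

    @property
    def n_classes(self) -> int:
        return int(self.labels.max())

    def subset(self, indices: Sequence[int]) -> np.ndarray:
        return self.labels[np.asarray(indices, dtype=int)]


def _sep_for(path: Path) -> str:
    return "," if path.suffix.lower() == ".csv" else "\t"


def read_expression_table(
    path: str | Path,
    orientation: str = "genes-in-rows",
    impute: bool = False,
) -> ExpressionMatrix:
    """Read a delimited expression table into a genes × samples matrix.

    Parameters
    ----------
    path
        TSV (default) or CSV file with a header row and identifiers in the
        first column.
    orientation
        ``"genes-in-rows"`` (default) or ``"samples-in-rows"``; the result is
        always genes × samples.
    impute
        If True, replace missing values by the per-gene median instead of
        rejecting the table.
    """
    path = Path(path)
    if orientation not in ("genes-in-rows", "samples-in-rows"):
        raise ValueError(f"unknown orientation {orientation!r}")
    df = pd.read_csv(path, sep=_sep_for(path), index_col=0)
    if df.index.has_duplicates:
        dupes = df.index[df.index.duplicated()].unique().tolist()
        raise ValueError(f"duplicate row identifiers in {path.name}: {dupes[:5]}")
    if df.columns.has_duplicates:
        raise ValueError(f"duplicate column identifiers in {path.name}")
    try:
        df = df.astype(float)
    except (ValueError, TypeError) as exc:
        bad = [
            (str(df.index[i]), str(df.columns[j]))
            for i in range(df.shape[0])
            for j in range(df.shape[1])
            if not _is_number(df.iat[i, j])
        ]
        raise ValueError(f"non-numeric cells at (row, column): {bad[:5]}") from exc
    if orientation == "samples-in-rows":
        df = df.T
    if df.isna().any().any():
        if not impute:
            rows = df.index[df.isna().any(axis=1)].tolist()
            raise ValueError(f"missing values in genes {rows[:5]}; pass impute=True to fill")
        med = df.median(axis=1)
        df = df.apply(lambda col: col.fillna(med), axis=0)
    return ExpressionMatrix(
        values=df.to_numpy(dtype=float),
        gene_ids=[str(i) for i in df.index],
        sample_ids=[str(c) for c in df.columns],
    )


def _is_number(v) -> bool:
    if v is None or (isinstance(v, float) and np.isnan(v)):
        return True  # missingness handled separately
    try:
        float(v)
        return True
    except (TypeError, ValueError):
        return False


def write_expression_table(X: ExpressionMatrix, path: str | Path) -> None:
    path = Path(path)
    df = pd.DataFrame(X.values, index=X.gene_ids, columns=X.sample_ids)
    df.index.name = "gene_id"
    df.to_csv(path, sep=_sep_for(path), float_format="%.17g")


def read_labels(
    path: str | Path,
    expression: ExpressionMatrix | None = None,
) -> LabelVector:
    """Read per-sample labels and map them to contiguous integers 1..C.

    The file is either two columns ``sample_id,label`` or a single ``label``
    column in sample order. Labels that are already the integers 1..C are kept
    as-is; anything else is mapped by first appearance. When ``expression`` is
    given, sample ids must match it exactly and rows are reordered to the
    expression matrix's sample order.
    """
    path = Path(path)
    df = pd.read_csv(path, sep=_sep_for(path))
    if df.shape[1] == 1:
        raw = df.iloc[:, 0]
        if expression is not None and len(raw) != expression.n_samples:
            raise ValueError("label count does not match sample count")
    elif df.shape[1] == 2:
        sid = df.iloc[:, 0].astype(str)
        if sid.duplicated().any():
            raise ValueError("duplicate sample ids in label file")
        raw = df.iloc[:, 1]
        if expression is not None:
            unknown = set(sid) - set(expression.sample_ids)
            if unknown:
                raise ValueError(f"labels for unknown sample ids: {sorted(unknown)[:5]}")
            missing = set(expression.sample_ids) - set(sid)
            if missing:
                raise ValueError(f"no label for samples: {sorted(missing)[:5]}")
            order = pd.Series(range(len(sid)), index=sid)
            raw = raw.iloc[order.loc[expression.sample_ids].to_numpy()]
    else:
        raise ValueError("label file must have one or two columns")
    return labels_from_values(raw.tolist())


def labels_from_values(raw: Sequence) -> LabelVector:
    """Map arbitrary label values to 1..C (first-appearance order)."""
    vals = list(raw)
    as_int = None
    try:
        as_int = [int(v) for v in vals]
        if any(int(v) != float(v) for v in vals):
            as_int = None
    except (TypeError, ValueError):
        as_int = None
    if as_int is not None:
        c = max(as_int)
        if min(as_int) >= 1 and set(as_int) == set(range(1, c + 1)):
            return LabelVector(labels=np.array(as_int), class_names=None)
    seen: dict = {}
    mapped = []
    for v in vals:
        if v not in seen:
            seen[v] = len(seen) + 1
        mapped.append(seen[v])
    return LabelVector(labels=np.array(mapped), class_names=[str(k) for k in seen])


def write_labels(y: LabelVector, sample_ids: Sequence[str], path: str | Path) -> None:
    path = Path(path)
    pd.DataFrame({"sample_id": list(sample_ids), "label": y.labels}).to_csv(
        path, sep=_sep_for(path), index=False
    )


# -- ExpandedSet persistence ------------------------------------------------
# Columns: source_sample_id, is_raw, corrupted_indices (semicolon-joined,
# 0-based, empty for raw rows), label, then one column per gene.


def write_expanded_set(es, path: str | Path) -> None:
    """Write an :class:`~seclass.sample_expansion.ExpandedSet` to CSV."""
    path = Path(path)
    if es.values.shape[0] == 0:
        raise ValueError("refusing to write an empty expanded set")
    meta = pd.DataFrame(
        {
            "source_sample_id": es.source_sample,
            "is_raw": [int(len(ix) == 0) for ix in es.corrupted_indices],
            "corrupted_indices": [
                ";".join(str(i) for i in ix) for ix in es.corrupted_indices
            ],
            "label": es.labels,
        }
    )
    data = pd.DataFrame(es.values, columns=es.gene_ids)
    pd.concat([meta, data], axis=1).to_csv(path, index=False, float_format="%.17g")


def read_expanded_set(path: str | Path):
    """Read an expanded set written by :func:`write_expanded_set`."""
    from .sample_expansion import ExpandedSet

    df = pd.read_csv(str(path), keep_default_na=False)
    meta_cols = ["source_sample_id", "is_raw", "corrupted_indices", "label"]
    gene_ids = [c for c in df.columns if c not in meta_cols]
    corrupted = [
        np.array([int(t) for t in str(s).split(";") if t != ""], dtype=int)
        for s in df["corrupted_indices"]
    ]
    return ExpandedSet(
        values=df[gene_ids].to_numpy(dtype=float),
        labels=df["label"].to_numpy(dtype=int),
        source_sample=[str(s) for s in df["source_sample_id"]],
        corrupted_indices=corrupted,
        gene_ids=gene_ids,
    )
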