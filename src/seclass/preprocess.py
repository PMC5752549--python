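"""Per-gene standardization of the dimensionality-reduced matrix.

Each gene row is transformed to zero mean and unit standard deviation
(population SD, i.e. dividing by n). Constant rows map to all zeros — the
limit of the transform's intent without a division by zero. The scaler can
be fitted on training samples only and applied to held-out samples, or fit
on the whole matrix in one go via :func:`normalize_rows`.
"""

from __future__ import annotations

import numpy as np

from .data_io import ExpressionMatrix

__all__ = ["RowNormalizer", "normalize_rows", "normalize_rows_values"]


class RowNormalizer:
    """Per-gene location/scale fitted on one set of samples.

    Fit on training columns; transform any matrix with the same genes.
    Rows with zero training SD are mapped to 0.
    """

    def __init__(self) -> None:
        self.mean_: np.ndarray | None = None
        self.sd_: np.ndarray | None = None

    def fit(self, values: np.ndarray) -> "RowNormalizer":
        values = np.asarray(values, dtype=float)
        self.mean_ = values.mean(axis=1)
        self.sd_ = values.std(axis=1)  # population SD (ddof=0)
        return self

    def transform(self, values: np.ndarray) -> np.ndarray:
        if self.mean_ is None or self.sd_ is None:
            raise RuntimeError("normalizer not fitted")
        values = np.asarray(values, dtype=float)
        if values.shape[0] != self.mean_.shape[0]:
            raise ValueError("gene count differs from the fitted matrix")
        sd = np.where(self.sd_ > 0, self.sd_, 1.0)
        out = (values - self.mean_[:, None]) / sd[:, None]
        out[self.sd_ == 0, :] = 0.0
        return out

    def fit_transform(self, values: np.ndarray) -> np.ndarray:
        return self.fit(values).transform(values)


def normalize_rows_values(values: np.ndarray) -> np.ndarray:
    """Standardize each row of a plain array to mean 0, SD 1."""
    return RowNormalizer().fit_transform(values)


def normalize_rows(X: ExpressionMatrix) -> ExpressionMatrix:
    """Standardize each gene of an :class:`ExpressionMatrix` in place-free form."""
    return ExpressionMatrix(
        values=normalize_rows_values(X.values),
        gene_ids=list(X.gene_ids),
        sample_ids=list(X.sample_ids),
    )
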