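"""Infinite Feature Selection: graph-based unsupervised gene ranking.

Genes are vertices of a fully connected weighted graph; the edge weight
between genes i and j mixes a dispersion term and an anti-redundancy term:

    A_ij = alpha · max(σ̂_i, σ̂_j) + (1 − alpha) · (1 − |ρ_ij|)

where σ̂ is each gene's standard deviation rescaled to [0, 1] by the maximum
SD across genes, and ρ_ij is the Spearman rank correlation across samples.
A gene's score sums the weights of paths of every length through the graph:
with r = r_fraction / ρ(A) (spectral radius), the geometric series
Σ_{l≥1} r^l A^l converges to S = (I − rA)^{-1} − I, and score_i = Σ_j S_ij.
Large scores mean high dispersion and low redundancy with the rest of the
transcriptome. The ranking uses no label information.

The exact mixing coefficients of the originally published method are not
restated here; this module implements the std/Spearman formulation above
(alpha = 0.5 by default) and additionally offers a plain variance ranking
for users who prefer a simpler criterion.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.stats import rankdata

from .data_io import ExpressionMatrix, LabelVector

__all__ = ["InfFSConfig", "build_cost_matrix", "inf_fs_scores", "select_genes"]


@dataclass
class InfFSConfig:
    """alpha mixes dispersion vs anti-correlation; k genes kept;
    r_fraction < 1 scales the series factor below the spectral radius."""

    alpha: float = 0.5
    k: int = 500
    r_fraction: float = 0.9

    def __post_init__(self) -> None:
        if not (0.0 <= self.alpha <= 1.0):
            raise ValueError("alpha must be in [0, 1]")
        if self.k < 1:
            raise ValueError("k must be positive")
        if not (0.0 < self.r_fraction < 1.0):
            raise ValueError("r_fraction must be in (0, 1) for series convergence")


def build_cost_matrix(X: ExpressionMatrix, alpha: float) -> np.ndarray:
    """Pairwise gene-graph weights A_ij (symmetric, nonnegative)."""
    V = X.values
    m, n = V.shape
    if m < 2:
        raise ValueError("need at least 2 genes")
    if n < 2:
        raise ValueError("correlation undefined with fewer than 2 samples")
    sd = V.std(axis=1)
    sd_max = sd.max()
    sd_hat = sd / sd_max if sd_max > 0 else np.zeros(m)

    ranks = rankdata(V, axis=1)
    # Spearman rho = Pearson correlation of ranks; constant genes give rho 0.
    rk = ranks - ranks.mean(axis=1, keepdims=True)
    norm = np.sqrt((rk**2).sum(axis=1))
    safe = np.where(norm > 0, norm, 1.0)
    rho = (rk @ rk.T) / np.outer(safe, safe)
    rho[norm == 0, :] = 0.0
    rho[:, norm == 0] = 0.0
    np.clip(rho, -1.0, 1.0, out=rho)

    disp = np.maximum.outer(sd_hat, sd_hat)
    A = alpha * disp + (1.0 - alpha) * (1.0 - np.abs(rho))
    return A


def inf_fs_scores(A: np.ndarray, r_fraction: float = 0.9) -> np.ndarray:
    """Path-sum score per gene via the closed form (I − rA)^{-1} − I."""
    A = np.asarray(A, dtype=float)
    if not np.isfinite(A).all():
        raise ValueError("cost matrix must be finite")
    if (A < 0).any():
        raise ValueError("cost matrix must be nonnegative")
    m = A.shape[0]
    if not A.any():
        radius = 0.0
    elif np.array_equal(A, A.T):
        radius = float(np.abs(np.linalg.eigvalsh(A)).max())
    else:
        radius = float(np.abs(np.linalg.eigvals(A)).max())
    r = r_fraction / radius if radius > 0 else r_fraction
    M = np.eye(m) - r * A
    sign, logdet = np.linalg.slogdet(M)
    if sign == 0:
        raise np.linalg.LinAlgError("I - rA is singular")
    S = np.linalg.inv(M) - np.eye(m)
    scores = S.sum(axis=1)
    if not np.isfinite(scores).all():
        raise ValueError("non-finite scores")
    return scores


def select_genes(
    X: ExpressionMatrix,
    y: LabelVector | None,
    cfg: InfFSConfig,
    method: str = "inf-fs",
) -> tuple[ExpressionMatrix, np.ndarray]:
    """Keep the top-k genes by descending score (ties: ascending index).

    ``y`` is accepted for interface symmetry but unused: the ranking is
    unsupervised. ``method`` is ``"inf-fs"`` or ``"variance"`` (top-k by SD).
    """
    m = X.n_genes
    if cfg.k > m:
        raise ValueError(f"k={cfg.k} exceeds gene count {m}")
    if method == "inf-fs":
        if m < 2:
            scores = np.zeros(m)
        else:
            A = build_cost_matrix(X, cfg.alpha)
            scores = inf_fs_scores(A, cfg.r_fraction)
    elif method == "variance":
        scores = X.values.std(axis=1)
    else:
        raise ValueError(f"unknown selector {method!r}")
    order = np.lexsort((np.arange(m), -scores))
    ranked = order[: cfg.k]
    return X.restrict_genes(ranked), ranked
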