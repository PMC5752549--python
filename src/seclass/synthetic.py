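"""Synthetic class-structured expression data with the small-n/high-p shape.

The generator emulates microarray-style experiments: many genes, very few
samples, a handful of classes, and a subset of informative genes whose mean
is shifted in exactly one class. Gene g has a baseline μ_g ~ N(0, baseline_sd);
the value of sample j is μ_g + shift + N(0, noise_sd), where shift is
effect_size · noise_sd when gene g is informative for sample j's class and 0
otherwise. A log-normal option exponentiates the values for positive,
intensity-like data.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .data_io import ExpressionMatrix, LabelVector

__all__ = ["SynthSpec", "generate_dataset"]


@dataclass
class SynthSpec:
    """Parameters of the synthetic expression generator.

    m_genes
        Number of genes (rows).
    class_sizes
        Samples per class; length C. Mirrors the shapes the method targets,
        e.g. [8, 12] (20 samples, 2 classes) or [22, 40].
    n_informative
        Number of genes carrying a class-specific mean shift.
    effect_size
        Mean shift in units of noise_sd (≥ 0; 0 = no signal).
    noise_sd
        Within-class standard deviation of each gene.
    baseline_sd
        Spread of per-gene baselines.
    seed
        Generator seed; same seed, same dataset.
    log_normal
        If True, exponentiate values to mimic positive intensity scales.
    """

    m_genes: int
    class_sizes: list[int] = field(default_factory=lambda: [8, 12])
    n_informative: int = 50
    effect_size: float = 2.0
    noise_sd: float = 1.0
    baseline_sd: float = 1.0
    seed: int = 0
    log_normal: bool = False

    def __post_init__(self) -> None:
        if self.m_genes < 1:
            raise ValueError("m_genes must be positive")
        if not self.class_sizes or any(s < 1 for s in self.class_sizes):
            raise ValueError("every class size must be ≥ 1")
        if not (0 <= self.n_informative <= self.m_genes):
            raise ValueError("n_informative must be in 0..m_genes")
        if self.effect_size < 0:
            raise ValueError("effect_size must be ≥ 0")
        if self.noise_sd <= 0 or self.baseline_sd <= 0:
            raise ValueError("noise_sd and baseline_sd must be > 0")


def generate_dataset(
    spec: SynthSpec,
) -> tuple[ExpressionMatrix, LabelVector, np.ndarray]:
    """Draw one dataset from the generative model.

    Returns the genes × samples matrix, the label vector (classes 1..C in
    block order) and the sorted indices of the informative genes. Each
    informative gene is assigned one class (cycling through classes so every
    class receives signal) whose samples are shifted by
    ``effect_size · noise_sd``.
    """
    rng = np.random.default_rng(spec.seed)
    m = spec.m_genes
    n = int(sum(spec.class_sizes))
    C = len(spec.class_sizes)

    labels = np.concatenate(
        [np.full(sz, c + 1, dtype=int) for c, sz in enumerate(spec.class_sizes)]
    )
    baseline = rng.normal(0.0, spec.baseline_sd, size=m)
    values = baseline[:, None] + rng.normal(0.0, spec.noise_sd, size=(m, n))

    informative = np.sort(rng.choice(m, size=spec.n_informative, replace=False))
    shift = spec.effect_size * spec.noise_sd
    for rank, g in enumerate(informative):
        target_class = (rank % C) + 1
        values[g, labels == target_class] += shift

    if spec.log_normal:
        values = np.exp(values)

    X = ExpressionMatrix(
        values=values,
        gene_ids=[f"gene_{i:05d}" for i in range(m)],
        sample_ids=[f"s{j:03d}" for j in range(n)],
    )
    y = LabelVector(labels=labels)
    return X, y, informative
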