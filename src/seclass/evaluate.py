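"""Experiment orchestration: select → normalize → split → expand → train → test.

The evaluation protocol is repeated stratified splitting: in each repeat,
ceil(20%) of every class is drawn for training, the training part is
sample-expanded (for the SE models), a classifier is fitted on the merged
expanded + raw rows and scored on the held-out raw samples. Accuracies are
reported per repeat and pooled (total correct / total predictions), in
percent. Gene selection is unsupervised and applied once to the whole
matrix before splitting; normalization statistics are fitted on the
training columns of each repeat by default (a whole-matrix mode exists).

``expand_all`` mode instead tests whether *corrupted* samples are correctly
classified: held-out samples are themselves expanded and the model is
scored on their corrupted rows.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .cnn1d import CNNConfig, fit_se1dcnn, predict_se1dcnn
from .data_io import ExpressionMatrix, LabelVector
from .inf_fs import InfFSConfig, select_genes
from .preprocess import RowNormalizer
from .sae import SAEConfig, fit_sesae, predict_sesae
from .sample_expansion import (
    ExpandedSet,
    SEConfig,
    expand_training_set,
    stratified_split,
)

__all__ = ["ExperimentSpec", "EvalResult", "run_experiment", "report", "load_report"]

MODEL_KINDS = ("sesae", "se1dcnn", "sae", "1dcnn")


@dataclass
class ExperimentSpec:
    """Everything needed to reproduce one evaluation run.

    model
        "sesae" / "se1dcnn" use sample expansion; "sae" / "1dcnn" are the
        SE-disabled baselines trained on raw rows only.
    """

    model: str = "sesae"
    model_cfg: SAEConfig | CNNConfig = field(default_factory=SAEConfig)
    se: SEConfig = field(default_factory=SEConfig)
    selector: InfFSConfig | None = None
    selector_method: str = "inf-fs"
    train_fraction: float = 0.2
    repeats: int = 10
    expand_all: bool = False
    normalize_all: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if self.model not in MODEL_KINDS:
            raise ValueError(f"model must be one of {MODEL_KINDS}")
        if self.repeats < 1:
            raise ValueError("repeats must be ≥ 1")
        if not (0.0 < self.train_fraction < 1.0):
            raise ValueError("train_fraction must be in (0, 1)")
        wants_cnn = self.model in ("se1dcnn", "1dcnn")
        if wants_cnn and not isinstance(self.model_cfg, CNNConfig):
            raise TypeError("1-D CNN models need a CNNConfig")
        if not wants_cnn and not isinstance(self.model_cfg, SAEConfig):
            raise TypeError("autoencoder models need an SAEConfig")


@dataclass
class EvalResult:
    """Per-repeat and pooled accuracies (percent) with confusion counts."""

    per_repeat_accuracy: list[float]
    pooled_accuracy: float
    confusions: list[np.ndarray]
    n_classes: int
    provenance: dict = field(default_factory=dict)

    def __eq__(self, other) -> bool:
        if not isinstance(other, EvalResult):
            return NotImplemented
        return (
            np.allclose(self.per_repeat_accuracy, other.per_repeat_accuracy)
            and abs(self.pooled_accuracy - other.pooled_accuracy) < 1e-9
            and len(self.confusions) == len(other.confusions)
            and all(np.array_equal(a, b) for a, b in zip(self.confusions, other.confusions))
            and self.n_classes == other.n_classes
        )


def _raw_expanded_set(X: ExpressionMatrix, labels: np.ndarray) -> ExpandedSet:
    """Wrap raw samples (no corruption) in the training container."""
    n = X.n_samples
    return ExpandedSet(
        values=X.values.T.copy(),
        labels=labels,
        source_sample=list(X.sample_ids),
        corrupted_indices=[np.array([], dtype=int) for _ in range(n)],
        gene_ids=list(X.gene_ids),
    )


def _derive_seed(ss: np.random.SeedSequence) -> int:
    return int(ss.generate_state(1)[0] % (2**31))


def run_experiment(X: ExpressionMatrix, y: LabelVector, spec: ExperimentSpec) -> EvalResult:
    """Run the full pipeline; deterministic given ``spec.seed``."""
    if spec.selector is not None:
        X, _ = select_genes(X, y, spec.selector, method=spec.selector_method)
    m = X.n_genes
    if spec.model in ("sesae", "se1dcnn") or spec.expand_all:
        spec.se.validate(m)
    if isinstance(spec.model_cfg, CNNConfig):
        spec.model_cfg.validate(m)

    master = np.random.SeedSequence(spec.seed)
    accs: list[float] = []
    confusions: list[np.ndarray] = []
    total_correct = 0
    total_pred = 0
    C = y.n_classes

    for rep, child in enumerate(master.spawn(spec.repeats)):
        split_ss, se_ss, model_ss, test_se_ss = child.spawn(4)
        train_idx, test_idx = stratified_split(
            y, spec.train_fraction, np.random.default_rng(split_ss)
        )
        norm = RowNormalizer()
        norm.fit(X.values if spec.normalize_all else X.values[:, train_idx])
        Xtr = ExpressionMatrix(
            values=norm.transform(X.values[:, train_idx]),
            gene_ids=list(X.gene_ids),
            sample_ids=[X.sample_ids[i] for i in train_idx],
        )
        Xte = ExpressionMatrix(
            values=norm.transform(X.values[:, test_idx]),
            gene_ids=list(X.gene_ids),
            sample_ids=[X.sample_ids[i] for i in test_idx],
        )
        y_tr = y.subset(train_idx)
        y_te = y.subset(test_idx)

        uses_se = spec.model in ("sesae", "se1dcnn")
        if uses_se:
            se_cfg = dataclasses.replace(spec.se, seed=_derive_seed(se_ss))
            train_set = expand_training_set(Xtr, y_tr, se_cfg)
        else:
            train_set = _raw_expanded_set(Xtr, y_tr)

        if spec.expand_all:
            # score on the corrupted rows of the held-out samples
            test_cfg = dataclasses.replace(spec.se, seed=_derive_seed(test_se_ss))
            test_set = expand_training_set(Xte, y_te, test_cfg)
            keep = ~test_set.raw_mask
            X_eval = test_set.values[keep]
            y_eval = test_set.labels[keep]
        else:
            X_eval = Xte.values.T
            y_eval = y_te

        model_seed = _derive_seed(model_ss)
        cfg = dataclasses.replace(spec.model_cfg, seed=model_seed)
        if spec.model in ("sesae", "sae"):
            model = fit_sesae(train_set, cfg, C)
            pred = predict_sesae(model, X_eval)
        else:
            model = fit_se1dcnn(train_set, cfg, C)
            pred = predict_se1dcnn(model, X_eval)

        correct = int((pred == y_eval).sum())
        total_correct += correct
        total_pred += len(y_eval)
        accs.append(100.0 * correct / len(y_eval))
        conf = np.zeros((C, C), dtype=int)
        for t, p in zip(y_eval, pred):
            conf[t - 1, p - 1] += 1
        confusions.append(conf)

    pooled = 100.0 * total_correct / total_pred
    return EvalResult(
        per_repeat_accuracy=accs,
        pooled_accuracy=pooled,
        confusions=confusions,
        n_classes=C,
        provenance={
            "model": spec.model,
            "seed": spec.seed,
            "repeats": spec.repeats,
            "train_fraction": spec.train_fraction,
            "expand_all": spec.expand_all,
            "normalize_all": spec.normalize_all,
            "a": spec.se.a if spec.model in ("sesae", "se1dcnn") or spec.expand_all else None,
            "selector": spec.selector_method if spec.selector else None,
            "k": spec.selector.k if spec.selector else None,
            "model_cfg": dataclasses.asdict(spec.model_cfg),
        },
    )


def report(result: EvalResult, path: str | Path) -> None:
    """Write a JSON report plus a small human-readable summary table.

    ``path`` is the JSON file; a ``.txt`` sibling holds the table.
    Accuracies are formatted to two decimals in percent (e.g. "87.33").
    """
    path = Path(path)
    payload = {
        "per_repeat_accuracy": result.per_repeat_accuracy,
        "pooled_accuracy": result.pooled_accuracy,
        "confusions": [c.tolist() for c in result.confusions],
        "n_classes": result.n_classes,
        "provenance": result.provenance,
    }
    path.write_text(json.dumps(payload, indent=2))
    lines = ["repeat\taccuracy(%)"]
    for i, a in enumerate(result.per_repeat_accuracy):
        lines.append(f"{i}\t{a:.2f}")
    lines.append(f"pooled\t{result.pooled_accuracy:.2f}")
    path.with_suffix(".txt").write_text("\n".join(lines) + "\n")


def load_report(path: str | Path) -> EvalResult:
    payload = json.loads(Path(path).read_text())
    return EvalResult(
        per_repeat_accuracy=payload["per_repeat_accuracy"],
        pooled_accuracy=payload["pooled_accuracy"],
        confusions=[np.array(c, dtype=int) for c in payload["confusions"]],
        n_classes=payload["n_classes"],
        provenance=payload.get("provenance", {}),
    )
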