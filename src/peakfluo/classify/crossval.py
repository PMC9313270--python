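"""Stratified k-fold cross-validation of the curve classifier."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.model_selection import StratifiedKFold

from .cnn import build_cnn
from .data import CurveDataset


@dataclass(frozen=True)
class CVReport:
    fold_accuracies: tuple[float, ...]
    fold_losses: tuple[float, ...]
    mean_accuracy: float
    sd_accuracy: float
    mean_loss: float
    sd_loss: float
    fold_assignments: tuple[int, ...]  # fold index of every sample
    seed: int

    def to_dict(self) -> dict:
        return {
            "fold_accuracies": list(self.fold_accuracies),
            "fold_losses": list(self.fold_losses),
            "mean_accuracy": self.mean_accuracy,
            "sd_accuracy": self.sd_accuracy,
            "mean_loss": self.mean_loss,
            "sd_loss": self.sd_loss,
            "fold_assignments": list(self.fold_assignments),
            "seed": self.seed,
        }


def cross_validate(
    dataset: CurveDataset,
    k: int = 10,
    seed: int = 0,
    epochs: int = 20,
    batch_size: int = 32,
    lr: float = 1e-3,
    conv1_filters: int = 16,
    conv2_filters: int = 32,
    labels: np.ndarray | None = None,
) -> CVReport:
    """Train ``k`` seeded models, each evaluated on its held-out fold.

    ``labels`` overrides the dataset labels (e.g. for permutation nulls).
    Stratification keeps every fold's class ratio within one sample of the
    global ratio.
    """
    if len(dataset) == 0:
        raise ValueError("empty dataset")
    y = dataset.labels if labels is None else np.asarray(labels, dtype=np.int8)
    if len(y) != len(dataset):
        raise ValueError("label vector length mismatch")
    classes, counts = np.unique(y, return_counts=True)
    if len(classes) < 2:
        raise ValueError("cross-validation requires both classes present")
    if k > counts.min():
        raise ValueError(
            f"k={k} exceeds the minority class size {counts.min()}"
        )
    x = dataset.images
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    assignments = np.full(len(y), -1, dtype=int)
    accs, losses = [], []
    for fold, (train_idx, test_idx) in enumerate(skf.split(x, y)):
        assignments[test_idx] = fold
        model = build_cnn(
            x.shape[1:3],
            conv1_filters=conv1_filters,
            conv2_filters=conv2_filters,
            seed=seed + fold,
        )
        model.fit(
            x[train_idx],
            y[train_idx].astype(float),
            epochs=epochs,
            batch_size=batch_size,
            lr=lr,
            seed=seed + fold,
        )
        loss, acc = model.evaluate(x[test_idx], y[test_idx])
        accs.append(acc)
        losses.append(loss)
    return CVReport(
        tuple(accs),
        tuple(losses),
        float(np.mean(accs)),
        float(np.std(accs)),
        float(np.mean(losses)),
        float(np.std(losses)),
        tuple(int(a) for a in assignments),
        seed,
    )
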