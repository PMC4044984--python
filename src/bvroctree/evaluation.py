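"""Repeated stratified k-fold cross-validation of the tree.

The protocol is k folds stratified by class, repeated with fresh seeded
partitions; per held-out fold the report records accuracy (percent
correct), AUC of the tree's leaf-proportion scores against the true
labels, and the fitted tree's size. Aggregates are the mean and sample
(n-1) standard deviation over all repeats x folds.

Fold bookkeeping is delegated to scikit-learn's ``StratifiedKFold``.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.model_selection import StratifiedKFold

from .dataset import Dataset
from .exceptions import DegenerateLabelsError
from .roc import auc
from .tree import TreeConfig, fit, tree_size

__all__ = ["FoldResult", "CvReport", "cross_validate"]


@dataclass(frozen=True)
class FoldResult:
    repeat: int
    fold: int
    accuracy: float  # percent correct on the held-out fold
    auc: float  # NaN when the fold has a single class (e.g. leave-one-out)
    tree_size: int


@dataclass
class CvReport:
    """Per-fold records plus the mean ± std aggregates."""

    per_fold: list[FoldResult]
    k: int
    repeats: int
    accuracy_mean: float
    accuracy_std: float
    auc_mean: float
    auc_std: float
    size_range: tuple[int, int]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame([vars(f) for f in self.per_fold])

    def summary(self) -> dict:
        return {
            "k": self.k,
            "repeats": self.repeats,
            "accuracy_mean": self.accuracy_mean,
            "accuracy_std": self.accuracy_std,
            "auc_mean": self.auc_mean,
            "auc_std": self.auc_std,
            "size_min": self.size_range[0],
            "size_max": self.size_range[1],
        }

    def __str__(self) -> str:
        return (
            f"{self.repeats}x{self.k}-fold CV: "
            f"accuracy {self.accuracy_mean:.2f} ± {self.accuracy_std:.2f} %, "
            f"AUC {self.auc_mean:.2f} ± {self.auc_std:.2f}, "
            f"tree size {self.size_range[0]}–{self.size_range[1]}"
        )


def _std(values: np.ndarray) -> float:
    return float(np.std(values, ddof=1)) if len(values) > 1 else 0.0


def cross_validate(
    data: Dataset,
    k: int = 10,
    repeats: int = 5,
    seed: int = 0,
    config: TreeConfig | None = None,
) -> CvReport:
    """Repeated stratified k-fold cross-validation.

    Parameters
    ----------
    data
        Full dataset; both classes must be present.
    k
        Folds per repeat; reduced (with a warning) to the minority-class
        count when a class has fewer than ``k`` members.
    repeats
        Number of independent fold partitions.
    seed
        Master seed; each repeat draws its partition seed from one
        ``default_rng(seed)`` stream.
    config
        Tree induction parameters for every fold.
    """
    y = data.labels
    if y.min() == y.max():
        raise DegenerateLabelsError("cross-validation needs both classes")
    counts = (int(np.sum(y == -1)), int(np.sum(y == 1)))
    k_eff = min(k, min(counts))
    if k_eff < k:
        warnings.warn(
            f"reducing k from {k} to {k_eff}: minority class has only "
            f"{min(counts)} samples",
            RuntimeWarning,
            stacklevel=2,
        )
    if k_eff < 2:
        raise DegenerateLabelsError("each class needs at least 2 samples for CV")

    rng = np.random.default_rng(seed)
    records: list[FoldResult] = []
    for rep in range(repeats):
        splitter = StratifiedKFold(
            n_splits=k_eff, shuffle=True, random_state=int(rng.integers(2**31 - 1))
        )
        for fold, (train_idx, test_idx) in enumerate(
            splitter.split(data.matrix, y)
        ):
            tree = fit(data.subset(train_idx), config)
            test = data.subset(test_idx)
            pred = tree.predict(test.matrix)
            accuracy = 100.0 * float(np.mean(pred == test.labels))
            scores = tree.predict_score(test.matrix)
            try:
                fold_auc = auc(scores, test.labels)
            except DegenerateLabelsError:
                fold_auc = float("nan")
            records.append(
                FoldResult(
                    repeat=rep,
                    fold=fold,
                    accuracy=accuracy,
                    auc=fold_auc,
                    tree_size=tree_size(tree),
                )
            )

    acc = np.array([r.accuracy for r in records])
    aucs = np.array([r.auc for r in records])
    sizes = np.array([r.tree_size for r in records])
    finite = aucs[np.isfinite(aucs)]
    return CvReport(
        per_fold=records,
        k=k_eff,
        repeats=repeats,
        accuracy_mean=float(np.mean(acc)),
        accuracy_std=_std(acc),
        auc_mean=float(np.mean(finite)) if len(finite) else float("nan"),
        auc_std=_std(finite) if len(finite) else float("nan"),
        size_range=(int(sizes.min()), int(sizes.max())),
    )
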