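"""The universal in-memory container: an expression matrix with binary labels.

Samples are rows, genes are columns; labels are encoded {-1, +1} with +1 the
positive class throughout the library.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .exceptions import InputError

__all__ = ["Dataset", "validate_labels"]


def validate_labels(labels: np.ndarray) -> np.ndarray:
    """Coerce ``labels`` to an int array and check every entry is -1 or +1."""
    y = np.asarray(labels)
    if y.ndim != 1:
        raise InputError(f"labels must be 1-D, got shape {y.shape}")
    if not np.all(np.isin(y, (-1, 1))):
        bad = sorted(set(np.unique(y)) - {-1, 1})
        raise InputError(f"labels must be -1 or +1; found {bad}")
    return y.astype(np.int8)


@dataclass
class Dataset:
    """Expression matrix (samples x genes) with {-1,+1} class labels.

    Parameters
    ----------
    matrix
        Float array of shape ``(n_samples, n_genes)``; all values finite.
    labels
        Length ``n_samples`` vector over {-1, +1}.
    feature_names
        One identifier per gene column.
    sample_ids
        One identifier per sample row.
    """

    matrix: np.ndarray
    labels: np.ndarray
    feature_names: list[str] = field(default_factory=list)
    sample_ids: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        X = np.asarray(self.matrix, dtype=float)
        if X.ndim != 2:
            raise InputError(f"matrix must be 2-D, got shape {X.shape}")
        if not np.all(np.isfinite(X)):
            r, c = np.argwhere(~np.isfinite(X))[0]
            raise InputError(f"non-finite expression value at row {r}, column {c}")
        y = validate_labels(self.labels)
        if len(y) != X.shape[0]:
            raise InputError(
                f"{X.shape[0]} samples but {len(y)} labels"
            )
        if not self.feature_names:
            self.feature_names = [f"g{j:04d}" for j in range(X.shape[1])]
        if not self.sample_ids:
            self.sample_ids = [f"s{i:03d}" for i in range(X.shape[0])]
        if len(self.feature_names) != X.shape[1]:
            raise InputError(
                f"{X.shape[1]} gene columns but {len(self.feature_names)} feature names"
            )
        if len(set(self.feature_names)) != len(self.feature_names):
            raise InputError("duplicate feature names")
        if len(self.sample_ids) != X.shape[0]:
            raise InputError(
                f"{X.shape[0]} samples but {len(self.sample_ids)} sample ids"
            )
        self.matrix = X
        self.labels = y

    @property
    def n_samples(self) -> int:
        return self.matrix.shape[0]

    @property
    def n_genes(self) -> int:
        return self.matrix.shape[1]

    def subset(self, rows: np.ndarray) -> "Dataset":
        """Row-subset view used during tree induction and cross-validation."""
        idx = np.asarray(rows)
        return Dataset(
            matrix=self.matrix[idx],
            labels=self.labels[idx],
            feature_names=list(self.feature_names),
            sample_ids=[self.sample_ids[i] for i in np.atleast_1d(idx)],
        )
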