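"""Least-squares mapping of selected gene features onto one derived feature.

Given the sample x selected-feature submatrix ``D_s`` and the numeric class
labels ``Y`` (encoded {-1, +1}), the coefficients are

    b = (D_s^T D_s)^{-1} D_s^T Y

i.e. the ordinary least-squares fit through the origin (no intercept
column), and the derived feature is the row-wise inner product
``Y' = D_s b``. When ``D_s^T D_s`` is singular (collinear gene pairs are
common in expression data) the minimum-norm minimizer is returned instead
of failing, so results stay deterministic.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .dataset import validate_labels
from .exceptions import InputError

__all__ = ["LseFit", "lse_coefficients", "derive_feature", "fit_derived"]


@dataclass(frozen=True)
class LseFit:
    """A fitted linear combination of selected gene features."""

    coefficients: np.ndarray  # b, one entry per selected feature
    feature_indices: tuple[int, ...]
    derived: np.ndarray  # Y' = D_s b, one entry per sample


def _check_matrix(feature_matrix) -> np.ndarray:
    X = np.asarray(feature_matrix, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    if X.ndim != 2 or X.size == 0:
        raise InputError(f"feature matrix must be non-empty 2-D, got shape {X.shape}")
    if not np.all(np.isfinite(X)):
        raise InputError("feature matrix contains non-finite values")
    return X


def lse_coefficients(feature_matrix, labels) -> np.ndarray:
    """Least-squares coefficients regressing {-1,+1} labels on the features.

    Parameters
    ----------
    feature_matrix
        ``(m, k)`` array of the selected features' values, ``m >= k >= 1``.
    labels
        Length-``m`` labels over {-1, +1}, used directly as the real-valued
        regression target.

    Returns
    -------
    numpy.ndarray
        Length-``k`` coefficient vector minimizing ``||D_s b - Y||^2``
        (minimum-norm solution if the normal matrix is singular).
    """
    X = _check_matrix(feature_matrix)
    y = validate_labels(labels).astype(float)
    m, k = X.shape
    if len(y) != m:
        raise InputError(f"{m} rows but {len(y)} labels")
    if m < k:
        raise InputError(f"need at least {k} samples to fit {k} coefficients, got {m}")
    b, _, rank, _ = np.linalg.lstsq(X, y, rcond=None)
    if rank < k:
        warnings.warn(
            "rank-deficient feature submatrix; using the minimum-norm "
            "least-squares solution",
            RuntimeWarning,
            stacklevel=2,
        )
    return b


def derive_feature(feature_matrix, coefficients) -> np.ndarray:
    """Per-sample inner product ``Y' = D_s b`` (no normalization)."""
    X = _check_matrix(feature_matrix)
    b = np.asarray(coefficients, dtype=float).ravel()
    if X.shape[1] != len(b):
        raise InputError(
            f"matrix has {X.shape[1]} columns but b has {len(b)} coefficients"
        )
    return X @ b


def fit_derived(feature_matrix, labels, feature_indices: tuple[int, ...]) -> LseFit:
    """Convenience: fit coefficients and derive ``Y'`` in one step."""
    b = lse_coefficients(feature_matrix, labels)
    return LseFit(
        coefficients=b,
        feature_indices=tuple(int(i) for i in feature_indices),
        derived=derive_feature(feature_matrix, b),
    )
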