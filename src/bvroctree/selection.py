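"""Greedy AUC-guided selection of the feature (or feature pair) for a node.

The search is two-stage: first the single gene with the highest AUC
against the labels is found; then that gene is paired in turn with every
remaining candidate, each pair mapped to a derived feature by least
squares, and the pair is adopted only when its AUC *strictly* exceeds the
best single gene's. The search is greedy — a returned pair always
contains the best singleton; globally better pairs whose members are both
individually weak are unreachable by construction.

Ties (singleton scan and partner scan alike) are broken toward the lowest
feature index so that identical data always yield identical nodes.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .dataset import Dataset
from .exceptions import DegenerateLabelsError, FeatureExhaustionError
from .linear import derive_feature, lse_coefficients
from .roc import auc

__all__ = ["NodeModel", "best_single_feature", "select_genes"]


@dataclass
class NodeModel:
    """The decision rule at an internal node.

    ``feature_indices`` holds 1 or 2 gene indices; ``coefficients`` the
    matching weights (a lone unpaired feature gets coefficient 1, or -1
    when orientation flipping is enabled and the feature is inverted);
    ``derived`` the per-sample combination on the node's data; ``auc`` its
    area under the ROC curve there. ``threshold`` is filled in later by
    the split-threshold search.
    """

    feature_indices: tuple[int, ...]
    coefficients: np.ndarray
    derived: np.ndarray
    auc: float
    threshold: float | None = field(default=None)

    def evaluate(self, X: np.ndarray) -> np.ndarray:
        """Derived value of each row of a full (n, n_genes) matrix."""
        return X[:, list(self.feature_indices)] @ self.coefficients


def best_single_feature(
    data: Dataset,
    excluded: frozenset[int] | set[int] = frozenset(),
    orient: bool = False,
) -> tuple[int, float]:
    """Index and AUC of the non-excluded gene with the highest raw AUC.

    With ``orient=True`` each gene is scored by ``max(AUC, 1 - AUC)`` so
    inverted markers (low expression in the positive class) compete on
    discriminative power rather than direction. Ties go to the lowest
    index.
    """
    y = data.labels
    if y.min() == y.max():
        raise DegenerateLabelsError("both classes required for feature selection")
    best_idx, best_auc = -1, -np.inf
    for j in range(data.n_genes):
        if j in excluded:
            continue
        a = auc(data.matrix[:, j], y)
        if orient:
            a = max(a, 1.0 - a)
        if a > best_auc:
            best_idx, best_auc = j, a
    if best_idx < 0:
        raise FeatureExhaustionError("every feature is excluded")
    return best_idx, float(best_auc)


def select_genes(
    data: Dataset,
    excluded: frozenset[int] | set[int] = frozenset(),
    limit: int = 2,
    orient: bool = False,
) -> NodeModel:
    """Greedy AUC-maximizing feature set of size <= ``limit`` for a node.

    Starting from the best single gene, the current set is repeatedly
    paired (via a least-squares combination) with each remaining gene;
    the extension is kept only when the combined AUC strictly improves.
    With the default ``limit=2`` this is a single pairing pass: the node
    tests either one raw gene or a two-gene linear combination.

    Parameters
    ----------
    data
        The node's samples and candidate genes.
    excluded
        Gene indices used at ancestor nodes (never reused on a path).
    limit
        Maximum number of genes combined at the node (default 2).
    orient
        Allow the singleton scan to flip inverted markers (default off).

    Returns
    -------
    NodeModel
        The selected rule; ``threshold`` is left unset.
    """
    if limit < 1:
        raise ValueError(f"limit must be >= 1, got {limit}")
    alpha, auc_alpha = best_single_feature(data, excluded, orient=orient)
    raw = data.matrix[:, alpha]
    coef0 = 1.0
    if orient and auc(raw, data.labels) < auc_alpha:
        coef0 = -1.0
    current = NodeModel(
        feature_indices=(alpha,),
        coefficients=np.array([coef0]),
        derived=coef0 * raw,
        auc=auc_alpha,
    )
    y = data.labels
    while len(current.feature_indices) < limit:
        best_ext: NodeModel | None = None
        for i in range(data.n_genes):
            if i in excluded or i in current.feature_indices:
                continue
            cols = list(current.feature_indices) + [i]
            D_s = data.matrix[:, cols]
            b = lse_coefficients(D_s, y)
            derived = derive_feature(D_s, b)
            a = auc(derived, y)
            if best_ext is None or a > best_ext.auc:
                best_ext = NodeModel(
                    feature_indices=tuple(cols),
                    coefficients=b,
                    derived=derived,
                    auc=float(a),
                )
        if best_ext is None or best_ext.auc <= current.auc:
            break  # no partner strictly improves: keep the smaller set
        current = best_ext
    return current
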