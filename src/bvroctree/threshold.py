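"""Hinge-Rank-Loss (HRL) and split-threshold selection.

Once a node's derived feature Y' is fixed, the node needs a cut point
theta. A candidate theta partitions the rank-sorted samples into
``D_neg`` (Y' <= theta, predicted -1) and ``D_pos`` (Y' > theta,
predicted +1). Every misclassified sample is charged its rank distance
from the boundary:

* a sample in ``D_neg`` whose desired label is +1, sitting at 1-based
  position ``i`` within ``D_neg`` (ascending scores), costs
  ``|D_neg| - i + 1``;
* a sample in ``D_pos`` whose desired label is -1, at 1-based position
  ``i`` within ``D_pos``, costs ``i``.

The HRL of theta is the sum of these penalties, and the split threshold is
the observed Y' value minimizing it (smallest theta on ties). Because only
ranks enter, the loss is invariant under strictly increasing rescalings of
the scores.

Tied score values always fall on the same side of the cut (the partition
rule compares values, not ranks). The best-(HRL, theta) bookkeeping is
updated once per candidate after both partition penalties are summed, so
candidates are compared on their full loss, reproducing e.g. a total of
2 + 3 = 5 on the eight-instance illustration used in the tests.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .dataset import validate_labels
from .exceptions import DegenerateSplitError, InputError

__all__ = ["SplitResult", "hinge_rank_loss", "calculate_split_threshold"]


@dataclass(frozen=True)
class SplitResult:
    """A candidate (or chosen) split threshold with its hinge rank loss.

    ``hrl == neg_partition_penalty + pos_partition_penalty`` always, and
    ``hrl == 0`` exactly when the rule "Y' <= theta -> -1, else +1"
    classifies every sample correctly.
    """

    theta: float
    hrl: int
    neg_partition_penalty: int
    pos_partition_penalty: int


def _check(scores, labels) -> tuple[np.ndarray, np.ndarray]:
    s = np.asarray(scores, dtype=float)
    if s.ndim != 1 or s.size == 0:
        raise InputError(f"scores must be a non-empty 1-D vector, got shape {s.shape}")
    if not np.all(np.isfinite(s)):
        raise InputError("scores contain non-finite values")
    y = validate_labels(labels)
    if len(s) != len(y):
        raise InputError(f"{len(s)} scores but {len(y)} labels")
    return s, y


def hinge_rank_loss(scores, labels, theta: float) -> SplitResult:
    """Rank-distance penalty of cutting ``scores`` at ``theta``.

    Parameters
    ----------
    scores
        Classifier outputs (the derived feature Y'), one per sample.
    labels
        Desired labels over {-1, +1}.
    theta
        Candidate split threshold; samples with score <= theta are
        predicted -1, the rest +1.
    """
    s, y = _check(scores, labels)
    if not np.isfinite(theta):
        raise InputError("theta must be finite")
    order = np.argsort(s, kind="stable")
    y_sorted = y[order]
    in_neg = s[order] <= theta

    y_neg = y_sorted[in_neg]
    y_pos = y_sorted[~in_neg]
    n_neg = len(y_neg)

    # positions are 1-based within each partition, ascending score order
    pos_in_neg = np.nonzero(y_neg == 1)[0] + 1
    neg_in_pos = np.nonzero(y_pos == -1)[0] + 1
    neg_pen = int(np.sum(n_neg - pos_in_neg + 1))
    pos_pen = int(np.sum(neg_in_pos))
    return SplitResult(
        theta=float(theta),
        hrl=neg_pen + pos_pen,
        neg_partition_penalty=neg_pen,
        pos_partition_penalty=pos_pen,
    )


def calculate_split_threshold(labels, derived) -> SplitResult:
    """Choose the derived-feature value minimizing the hinge rank loss.

    Evaluates :func:`hinge_rank_loss` at every distinct value of
    ``derived`` in ascending order and returns the minimizer; ties keep
    the smallest theta.

    Raises
    ------
    DegenerateSplitError
        If all derived values are identical (no split can separate
        anything; the caller should convert the node to a leaf).
    """
    s, y = _check(derived, labels)
    candidates = np.unique(s)  # ascending, distinct
    if len(candidates) < 2:
        raise DegenerateSplitError(
            "all derived values are identical; no split threshold exists"
        )
    best: SplitResult | None = None
    for theta in candidates:
        result = hinge_rank_loss(s, y, float(theta))
        if best is None or result.hrl < best.hrl:
            best = result
    assert best is not None
    return best
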