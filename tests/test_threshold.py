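"""Hinge rank loss and split-threshold selection against brute-force oracles."""
import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from bvroctree import (
    DegenerateSplitError,
    InputError,
    calculate_split_threshold,
    hinge_rank_loss,
)

from _oracles import best_threshold_bruteforce, hrl_trace


def test_eight_instance_worked_example(worked_example):
    """Cut at -0.4: penalty 2 in the <=theta partition, 3 in the >theta one."""
    scores, labels = worked_example
    r = hinge_rank_loss(scores, labels, -0.4)
    assert (r.hrl, r.neg_partition_penalty, r.pos_partition_penalty) == (5, 2, 3)
    assert r.hrl == r.neg_partition_penalty + r.pos_partition_penalty


def test_worked_example_other_cut_matches_trace(worked_example):
    scores, labels = worked_example
    r = hinge_rank_loss(scores, labels, 0.5)
    assert (r.hrl, r.neg_partition_penalty, r.pos_partition_penalty) == (4, 4, 0)
    assert (r.hrl, r.neg_partition_penalty, r.pos_partition_penalty) == hrl_trace(
        scores, labels, 0.5
    )


def test_best_threshold_on_worked_example(worked_example):
    scores, labels = worked_example
    best = calculate_split_threshold(labels, scores)
    # brute force over all 8 candidates: minimum loss 4, first reached at 0.01
    assert (best.theta, best.hrl) == (0.01, 4)
    assert (best.theta, best.hrl) == best_threshold_bruteforce(labels, scores)
    assert best.hrl <= 5


def test_perfect_separation_gives_zero_loss():
    scores = np.array([-3.0, -2.0, -1.0, 1.0, 2.0, 3.0])
    labels = np.array([-1, -1, -1, 1, 1, 1])
    assert hinge_rank_loss(scores, labels, 0.0).hrl == 0
    best = calculate_split_threshold(labels, scores)
    assert best.hrl == 0
    assert best.theta == -1.0  # smallest zero-loss candidate


def test_labels_as_scores():
    y = np.array([-1, 1, 1, -1, -1])
    best = calculate_split_threshold(y, y.astype(float))
    assert (best.theta, best.hrl) == (-1.0, 0)


def test_rank_invariance_under_monotone_transform(rng):
    """HRL depends only on ranks: transforming scores and theta together."""
    for _ in range(20):
        n = int(rng.integers(3, 12))
        scores = rng.standard_normal(n)
        labels = rng.choice([-1, 1], size=n)
        theta = float(rng.choice(scores))
        base = hinge_rank_loss(scores, labels, theta)
        f = lambda v: np.exp(v) + 1.0
        trans = hinge_rank_loss(f(scores), labels, float(f(np.array([theta]))[0]))
        assert (trans.hrl, trans.neg_partition_penalty, trans.pos_partition_penalty) == (
            base.hrl,
            base.neg_partition_penalty,
            base.pos_partition_penalty,
        )


@settings(deadline=None, max_examples=200, derandomize=True)
@given(data=st.data(), m=st.integers(2, 10))
def test_split_threshold_matches_exhaustive_oracle(data, m):
    scores = data.draw(
        st.lists(
            st.sampled_from([-2.0, -1.0, -0.5, 0.0, 0.5, 1.0, 2.0]),
            min_size=m,
            max_size=m,
        )
    )
    labels = data.draw(st.lists(st.sampled_from([-1, 1]), min_size=m, max_size=m))
    if len(set(scores)) < 2:
        return  # degenerate case covered separately
    best = calculate_split_threshold(labels, scores)
    theta_o, hrl_o = best_threshold_bruteforce(labels, scores)
    assert (best.theta, best.hrl) == (theta_o, hrl_o)


def test_zero_loss_iff_ranking_separates(rng):
    """Some theta reaches loss 0 exactly when every -1 scores below every +1."""
    for _ in range(50):
        n = int(rng.integers(2, 10))
        scores = rng.standard_normal(n)
        labels = rng.choice([-1, 1], size=n)
        if len(set(labels.tolist())) < 2 or len(set(scores.tolist())) < 2:
            continue
        best = calculate_split_threshold(labels, scores)
        order = np.argsort(scores)
        sorted_labels = labels[order]
        separable = np.all(np.diff(sorted_labels) >= 0)
        assert (best.hrl == 0) == bool(separable)


def test_degenerate_and_error_contracts():
    with pytest.raises(DegenerateSplitError):
        calculate_split_threshold([-1, 1, 1], [2.0, 2.0, 2.0])
    with pytest.raises(InputError):
        hinge_rank_loss([], [], 0.0)
    with pytest.raises(InputError):
        hinge_rank_loss([1.0, 2.0], [-1], 0.0)
    with pytest.raises(InputError):
        hinge_rank_loss([1.0, 2.0], [-1, 1], np.nan)
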