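"""Model zoo: analytic predictions, oracles, and their equivalences."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from hypothesis.extra.numpy import arrays

from netlearn.graphs import (
    FAMILIAR_BETWEEN,
    FAMILIAR_WITHIN,
    NEW_BETWEEN,
    NEW_WITHIN,
)
from netlearn.models import (
    communicability_model,
    condition_scores,
    femm_model,
    femm_series_oracle,
    hebbian_decay_learn,
    hitting_time_analytic,
    hitting_time_simulated,
    inverse_proximity,
    natp_model,
    tp_model,
)
from netlearn.streams import random_walk

TWO_CYCLE = np.array([[0.0, 1.0], [1.0, 0.0]])


def test_tp_is_the_transition_matrix(matrices):
    A = matrices["full"]
    pred = tp_model(A)
    assert (pred.score == A).all()
    nz = pred.score[pred.score > 0]
    np.testing.assert_allclose(nz, 0.2)


def test_natp_is_the_two_step_chain(matrices):
    A = matrices["full"]
    pred = natp_model(A)
    np.testing.assert_allclose(pred.score.sum(axis=1), 1.0, atol=1e-12)
    np.testing.assert_allclose(pred.score, A @ A)
    # 2-step return probability on the full graph: 5 neighbors x (1/5)^2
    np.testing.assert_allclose(np.diag(pred.score), 0.2)
    np.testing.assert_allclose(natp_model(TWO_CYCLE).score, np.eye(2))


def test_communicability_series_and_row_sums(matrices):
    A = matrices["sparse"]
    pred = communicability_model(A)
    series = sum(
        np.linalg.matrix_power(A, k) / math.factorial(k) for k in range(31)
    )
    np.testing.assert_allclose(pred.score, series, atol=1e-12)
    np.testing.assert_allclose(pred.score.sum(axis=1), np.e, atol=1e-10)
    np.testing.assert_allclose(
        communicability_model(np.eye(3)).score, np.e * np.eye(3)
    )


@pytest.mark.parametrize("paradigm", ["full", "sparse", "high_sparse"])
def test_femm_matches_series_oracle(matrices, paradigm):
    A = matrices[paradigm]
    closed = femm_model(A, 0.06).score
    series = femm_series_oracle(A, 0.06, K=5000)
    assert np.abs(closed - series).max() < 1e-10
    np.testing.assert_allclose(closed.sum(axis=1), 1.0, atol=1e-10)


def test_femm_limits(matrices):
    A = matrices["sparse"]
    # large beta: memory errors vanish, objective TPs recovered
    assert np.abs(femm_model(A, 20.0).score - A).max() < 1e-6
    # small beta: rows approach the walk's stationary distribution (uniform
    # on a regular graph)
    low = femm_model(A, 1e-9).score
    assert np.abs(low - 1 / 12).max() < 1e-6


def test_femm_series_truncation_behaviour(matrices):
    A = matrices["full"]
    np.testing.assert_allclose(femm_series_oracle(A, 0.06, 0), A)
    closed = femm_model(A, 0.5).score
    res = [
        np.linalg.norm(femm_series_oracle(A, 0.5, K) - closed)
        for K in (5, 10, 20, 40)
    ]
    assert all(a > b for a, b in zip(res, res[1:]))


@settings(max_examples=20, derandomize=True, deadline=None)
@given(
    raw=arrays(
        float, (5, 5), elements=st.floats(0.01, 1.0, allow_nan=False)
    ),
    beta=st.floats(0.01, 5.0),
)
def test_femm_row_stochastic_for_any_chain(raw, beta):
    A = raw / raw.sum(axis=1, keepdims=True)
    out = femm_model(A, beta).score
    np.testing.assert_allclose(out.sum(axis=1), 1.0, atol=1e-9)
    assert (out >= -1e-12).all()


def test_hitting_time_closed_forms():
    # two-state chain with switch probability p: geometric waiting time 1/p
    p = 0.25
    A = np.array([[1 - p, p], [p, 1 - p]])
    H = hitting_time_analytic(A)
    assert H[0, 1] == pytest.approx(1 / p)
    assert H[0, 0] == 0.0
    np.testing.assert_allclose(hitting_time_analytic(TWO_CYCLE), [[0, 1], [1, 0]])
    with pytest.raises(ValueError):
        hitting_time_analytic(np.eye(3))  # reducible


def test_hitting_time_simulation_agrees_with_solver(matrices):
    A = matrices["full"]
    Ha = hitting_time_analytic(A)
    Hs = hitting_time_simulated(A, 50_000, rng_seed=17)
    off = ~np.eye(12, dtype=bool)
    rel = np.abs(Hs[off] - Ha[off]) / Ha[off]
    assert rel.mean() < 0.05
    assert (np.diag(Hs) == 0).all()


def test_hitting_time_missing_pairs():
    # a 20-item walk cannot realize every ordered pair of a 12-node graph
    A = np.full((12, 12), 1 / 11)
    np.fill_diagonal(A, 0.0)
    with pytest.raises(RuntimeError):
        hitting_time_simulated(A, 20, rng_seed=0)
    H = hitting_time_simulated(A, 20, rng_seed=0, on_missing="impute")
    assert np.isfinite(H).all()


def test_inverse_proximity(graphs, matrices):
    g, A = graphs["sparse"], matrices["sparse"]
    H = hitting_time_analytic(A)
    P = inverse_proximity(H).score
    off = ~np.eye(12, dtype=bool)
    np.testing.assert_allclose(P[off], 1.0 / H[off])
    assert (np.diag(P) == 0).all()
    # connected pairs are hit sooner than unseen same-community pairs
    fw = np.mean([H[i, j] for e in g.edges if g.is_within(*e) for i, j in (e, e[::-1])])
    nw = np.mean([H[i, j] for e in g.removed_within for i, j in (e, e[::-1])])
    assert fw < nw
    with pytest.raises(ValueError):
        inverse_proximity(np.zeros((3, 3)))


def test_hebbian_limits_and_consistency(matrices):
    A = matrices["full"]
    walk = random_walk(A, 30_000, rng_seed=5)
    # very fast decay: only lag-1 pairs carry weight -> empirical bigram TPs
    W = hebbian_decay_learn(walk, beta=15.0, n_nodes=12).score
    big = np.zeros((12, 12))
    np.add.at(big, (walk.items[:-1], walk.items[1:]), 1.0)
    big /= big.sum(axis=1, keepdims=True)
    assert np.abs(W - big).max() < 1e-4
    # 3-state cycle: learned weights approach the FEMM closed form
    C = np.array([[0, 1.0, 0], [0, 0, 1.0], [1.0, 0, 0]])
    cyc = random_walk(C, 10_000, rng_seed=6)
    Wc = hebbian_decay_learn(cyc, beta=0.06, n_nodes=3).score
    assert np.abs(Wc - femm_model(C, 0.06).score).max() < 0.02
    with pytest.raises(ValueError):
        hebbian_decay_learn(np.array([3]), beta=0.06)


def test_hebbian_estimates_femm_on_the_designs(graphs, matrices):
    """The neural-style learner converges to the analytic FEMM."""
    rs = []
    for p, A in matrices.items():
        walk = random_walk(A, 50_000, rng_seed=31)
        W = hebbian_decay_learn(walk, beta=0.06, n_nodes=12).score
        F = femm_model(A, 0.06).score
        off = ~np.eye(12, dtype=bool)
        rs.append(np.corrcoef(W[off], F[off])[0, 1])
    assert min(rs) > 0.99


def test_condition_scores(graphs, matrices):
    g, A = graphs["sparse"], matrices["sparse"]
    tp = condition_scores(tp_model(A), g)
    assert tp[FAMILIAR_WITHIN] == 1.0
    assert tp[NEW_WITHIN] == 0.0 and tp[NEW_BETWEEN] == 0.0
    femm = condition_scores(femm_model(A, 0.06), g)
    assert femm[FAMILIAR_WITHIN] == pytest.approx(1.0)
    # completion: unseen within-community transitions look more familiar
    # than unseen between-community ones
    assert femm[NEW_WITHIN] > femm[NEW_BETWEEN]
    # pruning: familiar between-community transitions look less familiar
    assert femm[FAMILIAR_BETWEEN] < femm[FAMILIAR_WITHIN]
    assert femm[NEW_BETWEEN] < femm[NEW_WITHIN] < femm[FAMILIAR_WITHIN]
    # identical matrices give identical scores
    assert condition_scores(tp_model(A), g) == condition_scores(tp_model(A), g)
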