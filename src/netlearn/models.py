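"""Candidate models of sequence learning over a community graph.

Each model maps the walk's transition matrix A (or a stream sampled from
it) to a pairwise familiarity/proximity matrix Ahat:

- transition probabilities (TP):      Ahat = A
- non-adjacent TP:                    Ahat = A^2
- communicability:                    Ahat = expm(A)   (on the TP matrix)
- free-energy minimization (FEMM):    Ahat = (1 - e^-b) A (I - e^-b A)^-1
- hitting time:                       expected first-passage steps, inverted
- Hebbian learning with decay:        associative weights from a stream,
                                      with an exponential eligibility trace

The FEMM mixes all powers of A with Boltzmann weights P(dt) ~ exp(-beta*dt),
modelling memory errors of geometrically distributed size: the learner
sometimes binds the current item to the item dt+1 steps back instead of the
previous one.  beta = 0.06 is the value previously estimated on comparable
human data and is the default everywhere.

Condition scores divide each condition's mean Ahat by the familiar-within
mean, so the reference condition always scores exactly 1.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import lru_cache

import numpy as np
import scipy.linalg

from .graphs import FAMILIAR_WITHIN, CommunityGraph, pairs_by_condition
from .streams import Stream, random_walk

DEFAULT_BETA = 0.06


@dataclass(frozen=True)
class ModelPrediction:
    """A model's pairwise familiarity matrix plus its parameters."""

    model_name: str
    score: np.ndarray
    params: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not np.all(np.isfinite(self.score)):
            raise ValueError("prediction matrix must be finite")


def _as_stochastic(A: np.ndarray) -> np.ndarray:
    A = np.asarray(A, dtype=float)
    if A.ndim != 2 or A.shape[0] != A.shape[1]:
        raise ValueError("A must be square")
    if not np.allclose(A.sum(axis=1), 1.0, atol=1e-9):
        raise ValueError("A must be row-stochastic")
    return A


def tp_model(A: np.ndarray) -> ModelPrediction:
    """Objective transition probabilities (identical to any Ngram model on
    a Markov walk)."""
    return ModelPrediction("tp", _as_stochastic(A).copy())


def natp_model(A: np.ndarray) -> ModelPrediction:
    """Non-adjacent transition probabilities, one intervening item."""
    A = _as_stochastic(A)
    return ModelPrediction("natp", A @ A)


def communicability_model(A: np.ndarray) -> ModelPrediction:
    """Matrix-exponential communicability, computed on the TP matrix so the
    walk's edge weights (not mere adjacency) enter the series."""
    A = _as_stochastic(A)
    return ModelPrediction("communicability", scipy.linalg.expm(A))


def femm_model(A: np.ndarray, beta: float = DEFAULT_BETA) -> ModelPrediction:
    """Free-energy-minimization estimate of the transition structure.

    Closed form of the geometric mixture sum_{dt>=0} P(dt) A^(dt+1) with
    P(dt) proportional to exp(-beta*dt).  Row-stochastic for any
    row-stochastic A and beta > 0 (the spectral radius of e^-beta A is
    below 1, so the solve cannot be singular).
    """
    if beta <= 0:
        raise ValueError("beta must be positive")
    A = _as_stochastic(A)
    e = np.exp(-beta)
    n = A.shape[0]
    # Ahat = (1-e) A (I - e A)^-1, via a transposed solve
    Ahat = (1.0 - e) * np.linalg.solve((np.eye(n) - e * A).T, A.T).T
    return ModelPrediction("femm", Ahat, {"beta": beta})


def femm_series_oracle(A: np.ndarray, beta: float, K: int) -> np.ndarray:
    """Truncated-series evaluation of the FEMM, sum_{dt=0..K} P(dt) A^(dt+1),
    with the Boltzmann weights renormalized over 0..K.  Independent check of
    the closed form."""
    if beta <= 0 or K < 0:
        raise ValueError("need beta > 0 and K >= 0")
    A = _as_stochastic(A)
    w = np.exp(-beta * np.arange(K + 1))
    w /= w.sum()
    out = np.zeros_like(A)
    power = A.copy()
    for dt in range(K + 1):
        out += w[dt] * power
        if dt < K:
            power = power @ A
    return out


def hitting_time_analytic(A: np.ndarray) -> np.ndarray:
    """Expected first-passage steps H[i, j] of the chain A, by linear solve.

    H[j, j] = 0 and H[i, j] = 1 + sum_k A[i, k] H[k, j] for i != j; one
    system per target node.  Raises on reducible chains.
    """
    A = _as_stochastic(A)
    n = A.shape[0]
    # irreducibility: the walk must reach every node from every node
    reach = (np.linalg.matrix_power(np.eye(n) + A, n) > 0)
    if not reach.all():
        raise ValueError("chain is reducible; hitting times are infinite")
    H = np.zeros((n, n))
    for j in range(n):
        others = [k for k in range(n) if k != j]
        M = np.eye(n - 1) - A[np.ix_(others, others)]
        H[others, j] = np.linalg.solve(M, np.ones(n - 1))
    return H


def hitting_time_simulated(
    A: np.ndarray,
    stream_length: int = 50_000,
    rng_seed: int | np.random.Generator | None = None,
    on_missing: str = "raise",
) -> np.ndarray:
    """Monte-Carlo hitting times from a single long walk.

    For every occurrence of node i, count the steps to the next occurrence
    of node j; H[i, j] is the mean over occurrences.  Pairs never realized
    raise by default (``on_missing='impute'`` substitutes the analytic
    value instead).
    """
    A = _as_stochastic(A)
    n = A.shape[0]
    items = random_walk(A, stream_length, rng_seed).items
    sums = np.zeros((n, n))
    counts = np.zeros((n, n), dtype=np.int64)
    next_pos = np.full(n, -1, dtype=np.int64)
    for t in range(stream_length - 1, -1, -1):
        i = items[t]
        seen = next_pos >= 0
        sums[i, seen] += next_pos[seen] - t
        counts[i, seen] += 1
        next_pos[i] = t
    np.fill_diagonal(counts, 1)  # H[i, i] = 0 by convention
    np.fill_diagonal(sums, 0)
    missing = counts == 0
    if missing.any():
        if on_missing == "impute":
            ana = hitting_time_analytic(A)
            sums[missing] = ana[missing]
            counts[missing] = 1
        else:
            pairs = np.argwhere(missing)
            raise RuntimeError(
                f"{len(pairs)} ordered pairs never realized in the walk; "
                "increase stream_length or pass on_missing='impute'"
            )
    return sums / counts


def inverse_proximity(H: np.ndarray) -> ModelPrediction:
    """Inverse hitting time, a proximity comparable with the other models.
    The diagonal is set to 0 and is excluded from condition scoring."""
    H = np.asarray(H, dtype=float)
    off = ~np.eye(H.shape[0], dtype=bool)
    if np.any(H[off] <= 0):
        raise ValueError("off-diagonal hitting times must be positive")
    P = np.zeros_like(H)
    P[off] = 1.0 / H[off]
    return ModelPrediction("hitting_time", P)


def hitting_time_model(
    A: np.ndarray,
    stream_length: int = 50_000,
    rng_seed: int | np.random.Generator | None = None,
) -> ModelPrediction:
    """Convenience: simulated hitting times, inverted."""
    pred = inverse_proximity(hitting_time_simulated(A, stream_length, rng_seed))
    return ModelPrediction(
        "hitting_time", pred.score, {"stream_length": stream_length}
    )


def hebbian_decay_learn(
    stream: Stream | np.ndarray,
    beta: float = DEFAULT_BETA,
    learning_rate: float = 1.0,
    n_nodes: int | None = None,
) -> ModelPrediction:
    """Hebbian associative learning with an exponentially decaying trace.

    One unit per node keeps firing after its item with activity decaying by
    e^-beta per step.  At each step the weights from all still-active units
    onto the current item's unit are reinforced in proportion to their
    activity, then the current unit's activity is reset to 1.  A lag-k pair
    is therefore credited e^(-beta*k); after row normalization the expected
    weights equal the FEMM closed form, so this is a neural-style estimator
    of the same quantity.
    """
    if beta <= 0:
        raise ValueError("beta must be positive")
    items = stream.items if isinstance(stream, Stream) else np.asarray(stream)
    if len(items) < 2:
        raise ValueError("stream must contain at least 2 items")
    n = int(n_nodes if n_nodes is not None else items.max() + 1)
    decay = np.exp(-beta)
    trace = np.zeros(n)
    W = np.zeros((n, n))
    for x in items:
        trace *= decay
        W[:, x] += learning_rate * trace
        trace[x] += 1.0
    rowsum = W.sum(axis=1, keepdims=True)
    rowsum[rowsum == 0] = 1.0
    return ModelPrediction("hebbian", W / rowsum, {"beta": beta})


@lru_cache(maxsize=512)
def _condition_masks(graph: CommunityGraph) -> dict[str, np.ndarray]:
    """Boolean ordered-pair masks per condition (diagonal excluded)."""
    pairs = pairs_by_condition(graph)
    n = graph.n_nodes
    masks = {}
    for cond, pp in pairs.items():
        m = np.zeros((n, n), dtype=bool)
        for i, j in pp:
            m[i, j] = True
        masks[cond] = m
    return masks


def condition_scores(
    pred: ModelPrediction, graph: CommunityGraph
) -> dict[str, float]:
    """Mean prediction per condition, normalized by the familiar-within mean.

    Diagonal entries never enter (self-transitions cannot occur in a walk).
    """
    masks = _condition_masks(graph)
    means = {
        cond: float(pred.score[m].mean())
        for cond, m in masks.items()
        if m.any()
    }
    ref = means[FAMILIAR_WITHIN]
    if ref == 0:
        raise ValueError("familiar-within mean is zero; cannot normalize")
    return {cond: v / ref for cond, v in means.items()}


#: model name -> callable(A) -> ModelPrediction, for the analytic models
ANALYTIC_MODELS = {
    "tp": tp_model,
    "natp": natp_model,
    "communicability": communicability_model,
    "femm": femm_model,
}


def model_prediction(
    name: str,
    A: np.ndarray,
    beta: float = DEFAULT_BETA,
    rng_seed: int | np.random.Generator | None = None,
    stream_length: int = 50_000,
) -> ModelPrediction:
    """Dispatch a model by name, covering analytic and stream-based models."""
    if name == "femm":
        return femm_model(A, beta)
    if name in ANALYTIC_MODELS:
        return ANALYTIC_MODELS[name](A)
    if name == "hitting_time":
        return hitting_time_model(A, stream_length, rng_seed)
    if name == "hebbian":
        walk = random_walk(A, stream_length, rng_seed)
        return hebbian_decay_learn(walk, beta, n_nodes=A.shape[0])
    raise ValueError(f"unknown model {name!r}")
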