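"""Random-walk stimulus streams and the forced-choice test battery.

A stream is a uniform random walk on a community graph presented at 4 Hz
(275 ms per item).  The familiarization stream lasts 4.4 min (960 items) and
each active-listening stream 2.2 min (480 items, 479 transitions).

The two-alternative forced-choice battery presents quadruplets whose first
and last transitions are always familiar within-community transitions; the
middle transition of the tested quadruplet carries the condition under test,
while the reference quadruplet's middle transition is familiar within.
Catch trials repeat the same quadruplet twice.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .graphs import (
    FAMILIAR_BETWEEN,
    FAMILIAR_WITHIN,
    NEW_BETWEEN,
    NEW_WITHIN,
    CommunityGraph,
    condition_of,
    new_within_candidates,
    pairs_by_condition,
)

ITEM_DURATION_S = 0.275


@dataclass(frozen=True)
class Stream:
    """An ordered sequence of node ids presented at a fixed rate."""

    items: np.ndarray
    item_duration_s: float = ITEM_DURATION_S

    def __len__(self) -> int:
        return len(self.items)

    @property
    def duration_s(self) -> float:
        return len(self.items) * self.item_duration_s

    @property
    def onsets_s(self) -> np.ndarray:
        return np.arange(len(self.items)) * self.item_duration_s

    @property
    def n_transitions(self) -> int:
        return len(self.items) - 1

    def transition_offsets_s(self) -> np.ndarray:
        """Time of each transition, taken as the onset of its second item."""
        return np.arange(1, len(self.items)) * self.item_duration_s


def stream_length_for(duration_s: float, item_duration_s: float = ITEM_DURATION_S) -> int:
    """Number of items fitting in a stream of the given duration."""
    if duration_s <= 0 or item_duration_s <= 0:
        raise ValueError("durations must be positive")
    # guard against 264/0.275 = 959.9999... in binary floating point
    return int(math.floor(duration_s / item_duration_s + 1e-9))


def random_walk(
    A: np.ndarray,
    length: int,
    rng_seed: int | np.random.Generator | None = None,
    start: int | None = None,
) -> Stream:
    """Sample a random walk of ``length`` items from transition matrix A."""
    if length < 2:
        raise ValueError("a walk needs at least 2 items")
    A = np.asarray(A, dtype=float)
    if not np.allclose(A.sum(axis=1), 1.0, atol=1e-9):
        raise ValueError("A must be row-stochastic")
    rng = np.random.default_rng(rng_seed) if not isinstance(
        rng_seed, np.random.Generator
    ) else rng_seed
    n = A.shape[0]
    items = np.empty(length, dtype=np.int64)
    items[0] = rng.integers(n) if start is None else start
    # inverse-CDF sampling against a single uniform draw per step
    cdf = np.cumsum(A, axis=1)
    u = rng.random(length - 1)
    for t in range(1, length):
        items[t] = np.searchsorted(cdf[items[t - 1]], u[t - 1], side="right")
    return Stream(items=items)


@dataclass(frozen=True)
class ForcedChoiceTrial:
    reference_quadruplet: tuple[int, int, int, int]
    tested_quadruplet: tuple[int, int, int, int]
    tested_condition: str
    is_catch: bool = False
    direction: str = "AB"

    def middle_pair(self) -> tuple[int, int]:
        return self.tested_quadruplet[1], self.tested_quadruplet[2]


def _flank(
    middle: tuple[int, int],
    graph: CommunityGraph,
    rng: np.random.Generator,
) -> tuple[int, int, int, int]:
    """Wrap a middle transition with familiar-within flankers, no repeats.

    The pair (a, d) is sampled jointly: with sparse graphs a border node may
    have only two within-community neighbors, so choosing the left flanker
    first could leave no legal right flanker.
    """
    b, c = middle
    combos = [
        (a, d)
        for a in graph.within_neighbors(b)
        if a not in (b, c)
        for d in graph.within_neighbors(c)
        if d not in (a, b, c)
    ]
    if not combos:
        raise ValueError(f"no familiar-within flankers for middle pair {middle}")
    a, d = combos[rng.integers(len(combos))]
    return (int(a), b, c, int(d))


def _reference_quadruplet(
    graph: CommunityGraph, rng: np.random.Generator
) -> tuple[int, int, int, int]:
    fw = [e for e in graph.edges if graph.is_within(*e)]
    b, c = fw[rng.integers(len(fw))]
    if rng.random() < 0.5:
        b, c = c, b
    return _flank((b, c), graph, rng)


def _condition_candidates(graph: CommunityGraph, condition: str) -> list[tuple[int, int]]:
    if condition == NEW_WITHIN:
        return new_within_candidates(graph)
    if condition == FAMILIAR_BETWEEN:
        return graph.between_edges()
    if condition == NEW_BETWEEN:
        pairs = pairs_by_condition(graph)[NEW_BETWEEN]
        return sorted({tuple(sorted(p)) for p in pairs})
    if condition == FAMILIAR_WITHIN:
        return sorted(e for e in graph.edges if graph.is_within(*e))
    raise ValueError(f"unknown condition {condition!r}")


def build_test_battery(
    graph: CommunityGraph,
    rng_seed: int | np.random.Generator | None = None,
    trials_per_condition: int = 8,
    new_within_trials: int = 4,
    n_catch: int = 4,
) -> list[ForcedChoiceTrial]:
    """Build the forced-choice battery for one graph.

    Eight trials per tested condition (familiar between, new between) and
    four new-within trials, each middle transition appearing in both
    directions; four catch trials with identical quadruplets.
    """
    rng = np.random.default_rng(rng_seed) if not isinstance(
        rng_seed, np.random.Generator
    ) else rng_seed
    counts = {
        FAMILIAR_BETWEEN: trials_per_condition,
        NEW_WITHIN: new_within_trials,
        NEW_BETWEEN: trials_per_condition,
    }
    trials: list[ForcedChoiceTrial] = []
    for condition, n_trials in counts.items():
        candidates = _condition_candidates(graph, condition)
        if not candidates:
            raise ValueError(f"no candidate pairs for condition {condition}")
        n_slots = (n_trials + 1) // 2
        # each undirected slot yields an AB and a BA trial
        idx = rng.permutation(len(candidates))
        slots = [candidates[idx[k % len(candidates)]] for k in range(n_slots)]
        directed = []
        for b, c in slots:
            directed.append(((b, c), "AB"))
            directed.append(((c, b), "BA"))
        for (b, c), direction in directed[:n_trials]:
            trials.append(
                ForcedChoiceTrial(
                    reference_quadruplet=_reference_quadruplet(graph, rng),
                    tested_quadruplet=_flank((b, c), graph, rng),
                    tested_condition=condition,
                    direction=direction,
                )
            )
    for _ in range(n_catch):
        quad = _reference_quadruplet(graph, rng)
        trials.append(
            ForcedChoiceTrial(
                reference_quadruplet=quad,
                tested_quadruplet=quad,
                tested_condition=FAMILIAR_WITHIN,
                is_catch=True,
            )
        )
    order = rng.permutation(len(trials))
    return [trials[k] for k in order]


def validate_stream(stream: Stream, graph: CommunityGraph) -> None:
    """Raise if any consecutive pair of the stream is not a graph edge."""
    items = stream.items
    for t in range(len(items) - 1):
        if not graph.has_edge(int(items[t]), int(items[t + 1])):
            raise ValueError(f"non-edge transition at position {t}")


def transition_conditions(stream: Stream, graph: CommunityGraph) -> list[str]:
    """Condition label of every stream transition, in order."""
    items = stream.items
    return [
        condition_of(graph, int(items[t]), int(items[t + 1]))
        for t in range(len(items) - 1)
    ]
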