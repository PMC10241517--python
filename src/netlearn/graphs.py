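"""Community graphs, their random-walk transition matrices, and condition labels.

The stimulus space is a 12-node graph made of two communities of six nodes.
Within a community every pair of nodes is connected except the two *border*
nodes, which instead carry the only two between-community edges.  This keeps
the degree identical across nodes, so a uniform random walk has flat
transition probabilities and a uniform stationary distribution.

Three paradigms differ only in how many within-community edges are removed:

- ``full``        : nothing removed, degree 5
- ``sparse``      : one perfect matching removed per community, degree 4
- ``high_sparse`` : two edge-disjoint matchings removed per community, degree 3

Every ordered node pair is labelled with one of four experimental conditions
(familiar/new x within/between) used throughout the behavioral analysis.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import networkx as nx
import numpy as np

PARADIGMS = ("full", "sparse", "high_sparse")

FAMILIAR_WITHIN = "familiar_within"
FAMILIAR_BETWEEN = "familiar_between"
NEW_WITHIN = "new_within"
NEW_BETWEEN = "new_between"
CONDITIONS = (FAMILIAR_WITHIN, FAMILIAR_BETWEEN, NEW_WITHIN, NEW_BETWEEN)

#: conditions tested against the familiar-within reference in the choice task
TESTED_CONDITIONS = (FAMILIAR_BETWEEN, NEW_WITHIN, NEW_BETWEEN)

# number of matchings removed per community for each paradigm
_N_REMOVED = {"full": 0, "sparse": 1, "high_sparse": 2}


def _pair(i: int, j: int) -> tuple[int, int]:
    return (i, j) if i < j else (j, i)


@dataclass(frozen=True)
class CommunityGraph:
    """An undirected two-community graph with equal node degrees.

    ``removed_within`` records the within-community pairs absent relative to
    the full design, which are exactly the candidate "new within community"
    transitions of the sparse paradigms.
    """

    n_nodes: int
    paradigm: str
    community_of: tuple[int, ...]
    edges: frozenset[tuple[int, int]]
    removed_within: frozenset[tuple[int, int]] = frozenset()
    border_nodes: tuple[tuple[int, int], tuple[int, int]] = ((4, 5), (6, 7))
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.paradigm not in PARADIGMS:
            raise ValueError(f"unknown paradigm {self.paradigm!r}")
        if len(self.community_of) != self.n_nodes:
            raise ValueError("community_of length must equal n_nodes")

    # -- basic structure -------------------------------------------------
    def has_edge(self, i: int, j: int) -> bool:
        return _pair(i, j) in self.edges

    def is_within(self, i: int, j: int) -> bool:
        return self.community_of[i] == self.community_of[j]

    def degree(self, i: int) -> int:
        return sum(1 for e in self.edges if i in e)

    def degrees(self) -> np.ndarray:
        deg = np.zeros(self.n_nodes, dtype=int)
        for i, j in self.edges:
            deg[i] += 1
            deg[j] += 1
        return deg

    def neighbors(self, i: int) -> list[int]:
        return sorted(j for e in self.edges for j in e if i in e and j != i)

    def within_neighbors(self, i: int) -> list[int]:
        return [j for j in self.neighbors(i) if self.is_within(i, j)]

    def community_members(self, label: int) -> list[int]:
        return [i for i, c in enumerate(self.community_of) if c == label]

    def between_edges(self) -> list[tuple[int, int]]:
        return sorted(e for e in self.edges if not self.is_within(*e))

    def to_networkx(self) -> nx.Graph:
        g = nx.Graph()
        g.add_nodes_from(range(self.n_nodes))
        g.add_edges_from(self.edges)
        return g

    # -- serialization ---------------------------------------------------
    def to_json(self) -> str:
        return json.dumps(
            {
                "n_nodes": self.n_nodes,
                "paradigm": self.paradigm,
                "communities": list(self.community_of),
                "edges": sorted(map(list, self.edges)),
                "removed_within": sorted(map(list, self.removed_within)),
                "border_nodes": [list(b) for b in self.border_nodes],
                "seed": self.seed,
            },
            indent=1,
        )

    @classmethod
    def from_json(cls, text: str) -> "CommunityGraph":
        d = json.loads(text)
        return cls(
            n_nodes=d["n_nodes"],
            paradigm=d["paradigm"],
            community_of=tuple(d["communities"]),
            edges=frozenset(_pair(*e) for e in d["edges"]),
            removed_within=frozenset(_pair(*e) for e in d["removed_within"]),
            border_nodes=tuple(tuple(b) for b in d["border_nodes"]),
            seed=d.get("seed"),
        )


def _full_design(n_nodes: int):
    """Edge set of the full paradigm, pinned for the two-community layout.

    Communities are {0..m-1} and {m..2m-1}.  The border nodes are the last
    two of community 0 and the first two of community 1; the border-border
    pair inside each community is absent and replaced by the two
    between-community edges (m-2, m+1) and (m-1, m), so every node has
    degree m-1.
    """
    if n_nodes % 2 or n_nodes < 6:
        raise ValueError("n_nodes must be even and at least 6")
    m = n_nodes // 2
    community_of = tuple([0] * m + [1] * m)
    border = ((m - 2, m - 1), (m, m + 1))
    edges: set[tuple[int, int]] = set()
    for members, miss in (((range(0, m)), border[0]), ((range(m, 2 * m)), border[1])):
        for i in members:
            for j in members:
                if i < j and _pair(i, j) != miss:
                    edges.add((i, j))
    edges.add(_pair(m - 2, m + 1))
    edges.add(_pair(m - 1, m))
    return community_of, frozenset(edges), border


def _sample_matching(
    nodes: Sequence[int],
    allowed: set[tuple[int, int]],
    rng: np.random.Generator,
    max_attempts: int = 200,
) -> frozenset[tuple[int, int]]:
    """Draw a uniform-ish perfect matching over ``nodes`` using only ``allowed`` pairs."""
    nodes = list(nodes)
    for _ in range(max_attempts):
        perm = [int(x) for x in rng.permutation(nodes)]
        pairs = [_pair(perm[k], perm[k + 1]) for k in range(0, len(perm), 2)]
        if all(p in allowed for p in pairs):
            return frozenset(pairs)
    raise RuntimeError("no valid perfect matching found; graph too constrained")


def build_graph(
    paradigm: str,
    n_nodes: int = 12,
    rng_seed: int | None = 0,
    max_attempts: int = 1000,
) -> CommunityGraph:
    """Construct a community graph for one of the three paradigms.

    For the sparse paradigms, one (resp. two edge-disjoint) perfect
    matchings per community are removed from the full design so that every
    node loses exactly one (resp. two) within-community edges; candidate
    removals are rejection-sampled until the remaining graph is connected.
    """
    if paradigm not in PARADIGMS:
        raise ValueError(f"unknown paradigm {paradigm!r}; expected one of {PARADIGMS}")
    community_of, full_edges, border = _full_design(n_nodes)
    n_remove = _N_REMOVED[paradigm]
    rng = np.random.default_rng(rng_seed)

    if n_remove == 0:
        return CommunityGraph(
            n_nodes, paradigm, community_of, full_edges,
            border_nodes=border, seed=rng_seed,
        )

    m = n_nodes // 2
    for _ in range(max_attempts):
        removed: set[tuple[int, int]] = set()
        try:
            for label in (0, 1):
                members = [i for i in range(n_nodes) if community_of[i] == label]
                avail = {
                    e for e in full_edges
                    if e[0] in members and e[1] in members
                }
                for _k in range(n_remove):
                    matching = _sample_matching(members, avail - removed, rng)
                    removed |= matching
        except RuntimeError:
            continue
        edges = frozenset(full_edges - removed)
        g = nx.Graph(list(edges))
        g.add_nodes_from(range(n_nodes))
        if nx.is_connected(g):
            return CommunityGraph(
                n_nodes, paradigm, community_of, edges,
                removed_within=frozenset(removed),
                border_nodes=border, seed=rng_seed,
            )
    raise RuntimeError(
        f"no valid {paradigm} removal found in {max_attempts} attempts"
    )


def transition_matrix(graph: CommunityGraph) -> np.ndarray:
    """Row-stochastic transition matrix A of the uniform random walk."""
    n = graph.n_nodes
    A = np.zeros((n, n))
    for i, j in graph.edges:
        A[i, j] = 1.0
        A[j, i] = 1.0
    deg = A.sum(axis=1)
    if np.any(deg == 0):
        raise ValueError("graph has isolated nodes")
    return A / deg[:, None]


def condition_of(graph: CommunityGraph, i: int, j: int) -> str:
    """Experimental condition of the ordered transition i -> j."""
    if i == j:
        raise ValueError("self-transitions have no condition")
    familiar = graph.has_edge(i, j)
    within = graph.is_within(i, j)
    if familiar:
        return FAMILIAR_WITHIN if within else FAMILIAR_BETWEEN
    return NEW_WITHIN if within else NEW_BETWEEN


def pairs_by_condition(graph: CommunityGraph) -> dict[str, list[tuple[int, int]]]:
    """All ordered node pairs grouped by condition."""
    out: dict[str, list[tuple[int, int]]] = {c: [] for c in CONDITIONS}
    for i in range(graph.n_nodes):
        for j in range(graph.n_nodes):
            if i != j:
                out[condition_of(graph, i, j)].append((i, j))
    return out


def new_within_candidates(graph: CommunityGraph) -> list[tuple[int, int]]:
    """Undirected pairs eligible as 'new within community' test transitions.

    In the sparse paradigms these are the removed within-community edges; in
    the full paradigm the only never-presented within pairs are the two
    border-border pairs.
    """
    if graph.removed_within:
        return sorted(graph.removed_within)
    return sorted(_pair(*b) for b in graph.border_nodes)
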