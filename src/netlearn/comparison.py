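"""Bootstrap model comparison, noise ceiling, and beta estimation.

The behavioral pattern is a pooled vector of condition means: per paradigm,
the three non-reference condition means divided by 50 so they live on the
same familiar-within = 1 scale as the normalized model predictions (9 cells
for the three paradigms; 4 cells in the restricted variant that isolates
the conditions where communicability and FEMM disagree).

Participants are resampled with replacement within paradigm (5000
bootstrap occurrences by default); each resample's pooled vector is
correlated with every model's prediction vector, and model i dominates
model j in the fraction of resamples where it correlates more (ties split).
The noise ceiling correlates two independent resamples of the data with
each other.  The beta sweep recomputes the FEMM prediction vector over a
log-spaced grid spanning 1e-15..1e15 and reports the smoothed correlation
curve, its maximum and argmax.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .graphs import CommunityGraph, transition_matrix
from .models import (
    condition_scores,
    femm_model,
    hitting_time_simulated,
    inverse_proximity,
)

#: non-reference conditions, in pooled-vector order
CONDITION_ORDER = ("familiar_between", "new_within", "new_between")
PARADIGM_ORDER = ("full", "sparse", "high_sparse")
FAMILIAR_WITHIN = "familiar_within"

#: cells where communicability makes qualitatively different predictions
RESTRICTED_CELLS = (
    ("sparse", "new_within"),
    ("sparse", "familiar_between"),
    ("high_sparse", "new_within"),
    ("high_sparse", "familiar_between"),
)


def _cells(
    paradigms: tuple[str, ...],
    restrict: tuple[tuple[str, str], ...] | None,
    include_reference: bool = False,
) -> list[tuple[str, str]]:
    if restrict is None:
        conds = ((FAMILIAR_WITHIN,) if include_reference else ()) + CONDITION_ORDER
        return [(p, c) for p in paradigms for c in conds]
    return [cell for cell in restrict if cell[0] in paradigms]


def pooled_vector(
    tables: dict[str, pd.DataFrame],
    restrict: tuple[tuple[str, str], ...] | None = None,
    include_reference: bool = False,
) -> np.ndarray:
    """Pool per-paradigm familiarity tables into one normalized data vector.

    Each cell is a paradigm x condition mean over participants, divided by
    the 50% chance level so the behavioral reference matches the models'
    familiar-within normalization.  With ``include_reference`` the
    familiar-within cells (identically 1 under the normalization) are kept.
    """
    paradigms = tuple(p for p in PARADIGM_ORDER if p in tables)
    if not paradigms:
        raise ValueError("no paradigm tables supplied")
    cells = _cells(paradigms, restrict, include_reference)
    return np.array([
        1.0 if c == FAMILIAR_WITHIN else tables[p][c].mean() / 50.0
        for p, c in cells
    ])


def model_vector(
    scores_by_paradigm: dict[str, dict[str, float]],
    restrict: tuple[tuple[str, str], ...] | None = None,
    include_reference: bool = False,
) -> np.ndarray:
    """Align a model's normalized condition scores with the pooled data vector."""
    paradigms = tuple(p for p in PARADIGM_ORDER if p in scores_by_paradigm)
    cells = _cells(paradigms, restrict, include_reference)
    return np.array([scores_by_paradigm[p][c] for p, c in cells])


def _pearson_rows(X: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Pearson correlation of each row of X with y."""
    Xc = X - X.mean(axis=1, keepdims=True)
    yc = y - y.mean()
    denom = np.sqrt((Xc**2).sum(axis=1) * (yc**2).sum())
    with np.errstate(invalid="ignore", divide="ignore"):
        r = (Xc @ yc) / denom
    return np.where(np.isfinite(r), r, 0.0)


@dataclass
class BootstrapComparison:
    model_names: list[str]
    correlations: dict[str, np.ndarray]      # per model, length n_boot
    dominance: pd.DataFrame                  # fraction of resamples i beats j
    n_boot: int
    noise_ceiling: float | None = None

    def mean_correlation(self) -> pd.Series:
        return pd.Series(
            {m: float(np.mean(r)) for m, r in self.correlations.items()}
        ).sort_values(ascending=False)


def _paradigm_matrices(
    tables: dict[str, pd.DataFrame]
) -> dict[str, np.ndarray]:
    """Participant x condition matrices (condition order pinned), NaNs dropped."""
    out = {}
    for p, tab in tables.items():
        M = tab[list(CONDITION_ORDER)].dropna().to_numpy()
        if len(M) == 0:
            raise ValueError(f"paradigm {p} has no complete participants")
        out[p] = M
    return out


def _bootstrap_vectors(
    matrices: dict[str, np.ndarray],
    n_boot: int,
    rng: np.random.Generator,
    restrict: tuple[tuple[str, str], ...] | None,
) -> np.ndarray:
    """(n_boot, n_cells) pooled vectors from within-paradigm resampling."""
    paradigms = tuple(p for p in PARADIGM_ORDER if p in matrices)
    cells = _cells(paradigms, restrict)
    cols = []
    means = {}
    for p in paradigms:
        M = matrices[p]
        idx = rng.integers(len(M), size=(n_boot, len(M)))
        means[p] = M[idx].mean(axis=1)  # (n_boot, 3)
    cond_index = {c: k for k, c in enumerate(CONDITION_ORDER)}
    for p, c in cells:
        cols.append(means[p][:, cond_index[c]] / 50.0)
    return np.column_stack(cols)


def bootstrap_correlations(
    tables: dict[str, pd.DataFrame],
    model_vectors: dict[str, np.ndarray],
    n_boot: int = 5000,
    rng_seed: int | np.random.Generator | None = None,
    restrict: tuple[tuple[str, str], ...] | None = None,
) -> BootstrapComparison:
    """Bootstrap the data-model correlations and tabulate pairwise dominance."""
    rng = np.random.default_rng(rng_seed) if not isinstance(
        rng_seed, np.random.Generator
    ) else rng_seed
    matrices = _paradigm_matrices(tables)
    boot = _bootstrap_vectors(matrices, n_boot, rng, restrict)
    corr = {m: _pearson_rows(boot, v) for m, v in model_vectors.items()}
    names = list(model_vectors)
    dom = pd.DataFrame(np.full((len(names), len(names)), 0.5),
                       index=names, columns=names)
    for i, a in enumerate(names):
        for b in names[i + 1:]:
            wins = np.mean(corr[a] > corr[b]) + 0.5 * np.mean(corr[a] == corr[b])
            dom.loc[a, b] = wins
            dom.loc[b, a] = 1.0 - wins
    return BootstrapComparison(
        model_names=names, correlations=corr, dominance=dom, n_boot=n_boot
    )


def noise_ceiling(
    tables: dict[str, pd.DataFrame],
    n_boot: int = 5000,
    rng_seed: int | np.random.Generator | None = None,
    restrict: tuple[tuple[str, str], ...] | None = None,
) -> float:
    """Mean correlation between two independent participant resamples."""
    rng = np.random.default_rng(rng_seed) if not isinstance(
        rng_seed, np.random.Generator
    ) else rng_seed
    matrices = _paradigm_matrices(tables)
    a = _bootstrap_vectors(matrices, n_boot, rng, restrict)
    b = _bootstrap_vectors(matrices, n_boot, rng, restrict)
    ac = a - a.mean(axis=1, keepdims=True)
    bc = b - b.mean(axis=1, keepdims=True)
    denom = np.sqrt((ac**2).sum(axis=1) * (bc**2).sum(axis=1))
    with np.errstate(invalid="ignore", divide="ignore"):
        r = (ac * bc).sum(axis=1) / denom
    return float(np.mean(np.where(np.isfinite(r), r, 0.0)))


def default_beta_grid(n: int = 601) -> np.ndarray:
    """Log-spaced beta grid spanning 1e-15 to 1e15.

    601 points give 0.05 decades per step, enough to resolve two
    significant figures of an argmax near 0.05.
    """
    return np.logspace(-15, 15, n)


def smooth_curve(y: np.ndarray, window: int = 5) -> np.ndarray:
    """Centered moving average with shrinking edges."""
    return (
        pd.Series(y).rolling(window, center=True, min_periods=1).mean().to_numpy()
    )


@dataclass
class BetaSweepResult:
    grid: np.ndarray
    correlation: np.ndarray
    smoothed: np.ndarray
    beta_hat: float
    max_correlation: float
    plateau: tuple[float, float]
    target_vector: np.ndarray | None = None


def _femm_vectors_over_grid(
    graphs_by_paradigm: dict[str, list[CommunityGraph]],
    grid: np.ndarray,
    restrict: tuple[tuple[str, str], ...] | None,
    include_reference: bool = False,
) -> np.ndarray:
    """(n_grid, n_cells) FEMM prediction vectors, averaged over graph instances."""
    mats = {
        p: [(g, transition_matrix(g)) for g in gs]
        for p, gs in graphs_by_paradigm.items()
    }
    rows = []
    for beta in grid:
        scores = {}
        for p, pairs in mats.items():
            per_graph = [
                condition_scores(femm_model(A, beta), g) for g, A in pairs
            ]
            scores[p] = {
                c: float(np.mean([s[c] for s in per_graph]))
                for c in per_graph[0]
            }
        rows.append(model_vector(scores, restrict, include_reference))
    return np.stack(rows)


def _sweep(
    target: np.ndarray,
    femm_vecs: np.ndarray,
    grid: np.ndarray,
    smoothing_window: int,
    plateau_tol: float = 0.005,
) -> BetaSweepResult:
    corr = _pearson_rows(femm_vecs, target)
    smoothed = smooth_curve(corr, smoothing_window)
    k = int(np.argmax(smoothed))
    on_plateau = smoothed >= smoothed[k] - plateau_tol
    lo = k
    while lo > 0 and on_plateau[lo - 1]:
        lo -= 1
    hi = k
    while hi < len(grid) - 1 and on_plateau[hi + 1]:
        hi += 1
    return BetaSweepResult(
        grid=grid,
        correlation=corr,
        smoothed=smoothed,
        beta_hat=float(grid[k]),
        max_correlation=float(smoothed[k]),
        plateau=(float(grid[lo]), float(grid[hi])),
        target_vector=target,
    )


def beta_grid_fit(
    target_vector: np.ndarray,
    graphs_by_paradigm: dict[str, list[CommunityGraph]],
    grid: np.ndarray | None = None,
    smoothing_window: int = 5,
    restrict: tuple[tuple[str, str], ...] | None = None,
) -> BetaSweepResult:
    """Correlate a target condition vector with FEMM predictions over a
    beta grid; return the smoothed curve with its argmax and plateau."""
    grid = default_beta_grid() if grid is None else np.asarray(grid)
    femm_vecs = _femm_vectors_over_grid(graphs_by_paradigm, grid, restrict)
    return _sweep(target_vector, femm_vecs, grid, smoothing_window)


def femm_hitting_time_curve(
    graphs_by_paradigm: dict[str, list[CommunityGraph]],
    grid: np.ndarray | None = None,
    stream_length: int = 50_000,
    rng_seed: int | np.random.Generator | None = None,
    smoothing_window: int = 5,
    include_reference: bool = True,
) -> BetaSweepResult:
    """Equivalence curve between the FEMM and inverse hitting time.

    Hitting times are estimated from one ``stream_length``-item walk per
    graph, inverted and condition-scored; the pooled vector is correlated
    with the FEMM prediction vector at every beta on the grid.  The
    reference (familiar-within) cells are included by default: both models
    are normalized to 1 there, and the equivalence is over the full
    condition pattern rather than only its non-reference part.
    """
    rng = np.random.default_rng(rng_seed) if not isinstance(
        rng_seed, np.random.Generator
    ) else rng_seed
    grid = default_beta_grid() if grid is None else np.asarray(grid)
    ht_scores = {}
    for p, gs in graphs_by_paradigm.items():
        per_graph = []
        for g in gs:
            A = transition_matrix(g)
            H = hitting_time_simulated(A, stream_length, rng)
            per_graph.append(condition_scores(inverse_proximity(H), g))
        ht_scores[p] = {
            c: float(np.mean([s[c] for s in per_graph])) for c in per_graph[0]
        }
    target = model_vector(ht_scores, include_reference=include_reference)
    femm_vecs = _femm_vectors_over_grid(
        graphs_by_paradigm, grid, None, include_reference
    )
    return _sweep(target, femm_vecs, grid, smoothing_window)
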