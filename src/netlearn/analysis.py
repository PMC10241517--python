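"""Behavioral data processing: key-press parsing curves and forced-choice
familiarity statistics, with the study's exclusion rules.

Key-press pipeline: each participant's press train becomes a Dirac comb on
a 1-ms grid, convolved with a causal unit-area exponential kernel, epoched
from -2.75 to +2.75 s around every transition offset, averaged per
condition (all familiar-between transitions vs. 1000 random groups of four
familiar-within transitions), normalized per subject, and grand-averaged.
Per-millisecond unpaired t-tests with Bonferroni correction over the
[-0.1, 2.75] s window mark where the between curve exceeds the within curve.

Forced-choice pipeline: per participant and condition, the percentage of
trials on which the tested quadruplet was preferred to the familiar-within
reference (chance 50).  One-sample t-tests against chance and pairwise
condition contrasts are corrected with Benjamini-Hochberg FDR.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .behavior import CohortDataset
from .graphs import FAMILIAR_BETWEEN, FAMILIAR_WITHIN
from .streams import transition_conditions

EPOCH_HALF_S = 2.75
TEST_WINDOW_S = (-0.1, 2.75)
MIN_PRESSES, MAX_PRESSES = 10, 200
MAX_CATCH_FAILURES = 2
GRID_DT_S = 0.001


@dataclass
class ExclusionReport:
    n_total: int
    n_excluded_presses: int
    n_excluded_catch: int
    press_retained: list[int]
    choice_retained: list[int]

    def summary(self) -> dict:
        return {
            "n_total": self.n_total,
            "excluded_press_count_rule": self.n_excluded_presses,
            "excluded_catch_rule": self.n_excluded_catch,
            "retained_press_analysis": len(self.press_retained),
            "retained_choice_analysis": len(self.choice_retained),
        }


def apply_exclusions(cohort: CohortDataset) -> tuple[CohortDataset, ExclusionReport]:
    """Flag participants excluded by the press-count and catch-trial rules.

    Pressing fewer than 10 or more than 200 times excludes a participant
    from the key-press analysis; failing more than two of the four catch
    trials excludes from the forced-choice analysis.  The two rules are
    independent, as in the study.  Adds boolean columns ``keep_press`` and
    ``keep_choice`` to the participants table.
    """
    parts = cohort.participants.copy()
    press_counts = (
        cohort.keypresses.groupby("participant_id").size()
        .reindex(parts["participant_id"], fill_value=0).to_numpy()
    )
    parts["n_presses"] = press_counts
    parts["keep_press"] = (press_counts >= MIN_PRESSES) & (press_counts <= MAX_PRESSES)
    parts["keep_choice"] = parts["catch_failures"] <= MAX_CATCH_FAILURES
    report = ExclusionReport(
        n_total=len(parts),
        n_excluded_presses=int((~parts["keep_press"]).sum()),
        n_excluded_catch=int((~parts["keep_choice"]).sum()),
        press_retained=parts.loc[parts["keep_press"], "participant_id"].tolist(),
        choice_retained=parts.loc[parts["keep_choice"], "participant_id"].tolist(),
    )
    filtered = CohortDataset(
        paradigm=cohort.paradigm,
        participants=parts,
        choices=cohort.choices,
        keypresses=cohort.keypresses,
        graphs=cohort.graphs,
        batteries=cohort.batteries,
        streams=cohort.streams,
    )
    return filtered, report


@dataclass
class ParsingCurve:
    """Per-condition press-density time courses around transition offsets."""

    times_s: np.ndarray                    # epoch axis, 1-ms grid
    between: np.ndarray                    # grand-average normalized density
    within: np.ndarray
    between_by_subject: np.ndarray         # (n_subjects, n_times)
    within_by_subject: np.ndarray
    significance_mask: np.ndarray | None = None
    participant_ids: list[int] = field(default_factory=list)


def _exponential_kernel(tau_s: float, dt: float) -> np.ndarray:
    """Causal exponential window, unit area, truncated at 6 tau."""
    t = np.arange(0, 6 * tau_s, dt)
    k = np.exp(-t / tau_s)
    return k / k.sum()


def _epoch_indices(offsets_s: np.ndarray, n_samples: int, dt: float) -> np.ndarray:
    half = int(round(EPOCH_HALF_S / dt))
    centers = np.round(offsets_s / dt).astype(int)
    return centers, half


def parsing_probability(
    cohort: CohortDataset,
    kernel_tau_s: float = 0.5,
    n_within_groups: int = 1000,
    rng_seed: int | np.random.Generator | None = None,
) -> ParsingCurve:
    """Normalized press-density curves around transition offsets.

    For each retained participant, the continuous press signal is epoched
    at every transition offset of their group's stream.  The between curve
    averages all familiar-between epochs; the within curve averages
    ``n_within_groups`` random groups of four directed familiar-within
    transitions (all occurrences of the four).  Both are divided by the
    subject's within grand mean before averaging across subjects.
    """
    rng = np.random.default_rng(rng_seed) if not isinstance(
        rng_seed, np.random.Generator
    ) else rng_seed
    parts = cohort.participants
    if "keep_press" in parts.columns:
        parts = parts[parts["keep_press"]]
    if parts.empty:
        raise ValueError("no retained participants for the press analysis")
    dt = GRID_DT_S
    half = int(round(EPOCH_HALF_S / dt))
    times = (np.arange(2 * half + 1) - half) * dt
    kernel = _exponential_kernel(kernel_tau_s, dt)

    # per group: epoch sample centers and directed-transition labels
    group_info: dict[int, dict] = {}
    for g, stream in cohort.streams.items():
        graph = cohort.graphs[g]
        conds = np.array(transition_conditions(stream, graph))
        items = stream.items
        directed = [
            (int(items[t]), int(items[t + 1])) for t in range(len(items) - 1)
        ]
        centers = np.round(stream.transition_offsets_s() / dt).astype(int)
        n_samples = int(round(stream.duration_s / dt))
        between_mask = conds == FAMILIAR_BETWEEN
        within_mask = conds == FAMILIAR_WITHIN
        within_types = sorted({d for d, m in zip(directed, within_mask) if m})
        group_info[g] = dict(
            n_samples=n_samples, centers=centers, directed=directed,
            between_mask=between_mask, within_mask=within_mask,
            within_types=within_types,
        )

    presses_by_pid = dict(tuple(cohort.keypresses.groupby("participant_id")))
    between_rows, within_rows, pids = [], [], []
    for _, prow in parts.iterrows():
        pid, g = int(prow["participant_id"]), int(prow["group"])
        info = group_info[g]
        n_samples = info["n_samples"]
        signal = np.zeros(n_samples)
        df = presses_by_pid.get(pid)
        if df is not None:
            idx = np.clip((df["time_s"].to_numpy() / dt).astype(int), 0, n_samples - 1)
            np.add.at(signal, idx, 1.0)
        signal = np.convolve(signal, kernel)[:n_samples]
        padded = np.concatenate(
            [np.zeros(half), signal, np.zeros(half + 1)]
        )
        epochs = np.stack(
            [padded[c:c + 2 * half + 1] for c in info["centers"]]
        )
        between_curve = epochs[info["between_mask"]].mean(axis=0)
        # mean epoch and occurrence count per directed within-transition type
        type_means, type_counts = {}, {}
        wmask = info["within_mask"]
        for ttype in info["within_types"]:
            sel = wmask & np.array([d == ttype for d in info["directed"]])
            type_means[ttype] = epochs[sel].mean(axis=0)
            type_counts[ttype] = int(sel.sum())
        types = info["within_types"]
        group_curves = np.empty((n_within_groups, len(times)))
        for k in range(n_within_groups):
            chosen = [types[i] for i in rng.choice(len(types), 4, replace=False)]
            w = np.array([type_counts[t] for t in chosen], dtype=float)
            M = np.stack([type_means[t] for t in chosen])
            group_curves[k] = (w[:, None] * M).sum(axis=0) / w.sum()
        within_curve = group_curves.mean(axis=0)
        norm = within_curve.mean()
        if norm > 0:
            between_curve = between_curve / norm
            within_curve = within_curve / norm
        between_rows.append(between_curve)
        within_rows.append(within_curve)
        pids.append(pid)

    between_by_subject = np.stack(between_rows)
    within_by_subject = np.stack(within_rows)
    curve = ParsingCurve(
        times_s=times,
        between=between_by_subject.mean(axis=0),
        within=within_by_subject.mean(axis=0),
        between_by_subject=between_by_subject,
        within_by_subject=within_by_subject,
        participant_ids=pids,
    )
    curve.significance_mask = timecourse_test(
        between_by_subject, within_by_subject, times
    )
    return curve


def timecourse_test(
    curves_a: np.ndarray,
    curves_b: np.ndarray,
    times_s: np.ndarray,
    window_s: tuple[float, float] = TEST_WINDOW_S,
    alpha: float = 0.05,
) -> np.ndarray:
    """Per-millisecond unpaired t-test, Bonferroni-corrected over the window.

    Returns a boolean mask over ``times_s``; True only inside the window
    where the corrected test rejects.
    """
    in_window = (times_s >= window_s[0]) & (times_s <= window_s[1])
    n_tests = int(in_window.sum())
    if n_tests == 0:
        return np.zeros_like(times_s, dtype=bool)
    with np.errstate(invalid="ignore"):
        _, p = stats.ttest_ind(curves_a, curves_b, axis=0)
    p = np.where(np.isnan(p), 1.0, p)
    mask = np.zeros_like(times_s, dtype=bool)
    mask[in_window] = p[in_window] < alpha / n_tests
    return mask


def familiarity_scores(cohort: CohortDataset, block: int = 2) -> pd.DataFrame:
    """Percent tested-quadruplet choices per participant and condition.

    Ranges from 0 (reference always preferred) to 100, chance 50.  Only
    participants retained by the catch rule enter (if exclusions were
    applied).  The study reports block 2, the default here.
    """
    if block not in (1, 2):
        raise ValueError("block must be 1 or 2")
    parts = cohort.participants
    if "keep_choice" in parts.columns:
        keep = set(parts.loc[parts["keep_choice"], "participant_id"])
    else:
        keep = set(parts["participant_id"])
    ch = cohort.choices
    ch = ch[(ch["block"] == block) & ch["participant_id"].isin(keep)]
    table = (
        ch.groupby(["participant_id", "condition"])["chose_tested"]
        .mean().mul(100.0).unstack("condition")
    )
    table.columns.name = None
    return table


def condition_tests(
    table: pd.DataFrame,
    stimulus: pd.Series | None = None,
    alpha: float = 0.05,
) -> dict[str, pd.DataFrame]:
    """Condition-level statistics on a familiarity table.

    ``vs_chance``: one-sample t-tests against 50 per condition, BH-FDR
    corrected across the condition family.  ``pairwise``: paired t-tests
    between conditions, BH-FDR corrected.  ``group``: unpaired t-test per
    condition between stimulus groups (tone vs syllable) when a stimulus
    label per participant is supplied.
    """
    conds = list(table.columns)
    rows = []
    for c in conds:
        x = table[c].dropna()
        t, p = stats.ttest_1samp(x, 50.0)
        rows.append((c, float(x.mean()), float(x.sem()), len(x), float(t), float(p)))
    vs_chance = pd.DataFrame(
        rows, columns=["condition", "mean", "sem", "n", "t", "p"]
    )
    vs_chance["p_fdr"] = multipletests(vs_chance["p"], method="fdr_bh")[1]
    vs_chance["significant"] = vs_chance["p_fdr"] < alpha

    rows = []
    for i, a in enumerate(conds):
        for b in conds[i + 1:]:
            sub = table[[a, b]].dropna()
            t, p = stats.ttest_rel(sub[a], sub[b])
            rows.append((a, b, float(sub[a].mean() - sub[b].mean()),
                         len(sub), float(t), float(p)))
    pairwise = pd.DataFrame(
        rows, columns=["condition_a", "condition_b", "mean_diff", "n", "t", "p"]
    )
    if len(pairwise):
        pairwise["p_fdr"] = multipletests(pairwise["p"], method="fdr_bh")[1]
        pairwise["significant"] = pairwise["p_fdr"] < alpha

    out = {"vs_chance": vs_chance, "pairwise": pairwise}
    if stimulus is not None:
        rows = []
        for c in conds:
            joined = table[[c]].join(stimulus.rename("stimulus"), how="inner").dropna()
            g1 = joined.loc[joined["stimulus"] == "tone", c]
            g2 = joined.loc[joined["stimulus"] == "syllable", c]
            if len(g1) > 1 and len(g2) > 1:
                t, p = stats.ttest_ind(g1, g2)
                rows.append((c, float(t), float(p)))
        out["group"] = pd.DataFrame(rows, columns=["condition", "t", "p"])
    return out
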