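"""Run configuration, deterministic seeding, file I/O, and the end-to-end
reproduction pipeline: graphs -> streams -> model predictions -> synthetic
cohort -> behavioral analysis -> bootstrap model comparison.

Every stochastic stage draws from a child of one root SeedSequence, so a
run is fully determined by its config; a manifest recording the config and
seeds accompanies every output bundle.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import comparison as cmp
from .analysis import apply_exclusions, condition_tests, familiarity_scores
from .behavior import (
    CohortDataset,
    ParticipantParams,
    cohort_model_scores,
    simulate_cohort,
)
from .graphs import PARADIGMS, build_graph, transition_matrix
from .models import DEFAULT_BETA
from .streams import random_walk

DEFAULT_MODELS = ("tp", "natp", "communicability", "femm", "hitting_time", "hebbian")


@dataclass
class RunConfig:
    paradigms: tuple[str, ...] = PARADIGMS
    n_participants: int = 200            # per paradigm
    seed: int = 0
    beta: float = DEFAULT_BETA
    familiarization_items: int = 960     # 4.4 min at 275 ms/item
    active_items: int = 480              # 2.2 min, 479 transitions
    trials_per_condition: int = 8
    new_within_trials: int = 4
    n_catch: int = 4
    kernel_tau_s: float = 0.5
    n_boot: int = 5000
    model_stream_length: int = 50_000
    models: tuple[str, ...] = DEFAULT_MODELS
    out_dir: str = "results/reproduction"

    def validate(self) -> None:
        unknown = [p for p in self.paradigms if p not in PARADIGMS]
        if unknown:
            raise ValueError(f"unknown paradigms: {unknown}")
        positive = {
            "n_participants": self.n_participants,
            "familiarization_items": self.familiarization_items,
            "active_items": self.active_items,
            "trials_per_condition": self.trials_per_condition,
            "new_within_trials": self.new_within_trials,
            "n_boot": self.n_boot,
            "model_stream_length": self.model_stream_length,
            "kernel_tau_s": self.kernel_tau_s,
            "beta": self.beta,
        }
        for name, v in positive.items():
            if v <= 0:
                raise ValueError(f"{name} must be positive, got {v}")
        if self.n_catch < 0:
            raise ValueError("n_catch must be non-negative")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        cfg = cls(**{
            k: tuple(v) if isinstance(v, list) else v for k, v in raw.items()
        })
        cfg.validate()
        return cfg

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["paradigms"] = list(d["paradigms"])
        d["models"] = list(d["models"])
        return d

    def config_hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


def child_seeds(seed: int, n: int) -> list[int]:
    """Derive n independent 31-bit child seeds from one root seed."""
    ss = np.random.SeedSequence(seed)
    return [int(s.generate_state(1)[0] % 2**31) for s in ss.spawn(n)]


def write_cohort_csvs(cohort: CohortDataset, out_dir: Path, prefix: str = "") -> None:
    out_dir.mkdir(parents=True, exist_ok=True)
    cohort.participants.to_csv(out_dir / f"{prefix}participants.csv", index=False)
    cohort.choices.to_csv(out_dir / f"{prefix}choices.csv", index=False)
    cohort.keypresses.to_csv(out_dir / f"{prefix}keypresses.csv", index=False)


def run_reproduction(config: RunConfig) -> dict:
    """Execute the full pipeline and write all artifacts under
    ``config.out_dir``.  Returns a summary dict (also written as JSON)."""
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    seeds = child_seeds(config.seed, 4 * len(config.paradigms) + 2)
    seed_iter = iter(seeds)

    tables = {}
    model_scores_by_paradigm: dict[str, dict[str, dict[str, float]]] = {}
    exclusion_summaries = {}
    for paradigm in config.paradigms:
        graph_seed = next(seed_iter)
        graph = build_graph(paradigm, rng_seed=graph_seed)
        (out / f"graph_{paradigm}.json").write_text(graph.to_json())
        A = transition_matrix(graph)
        stream = random_walk(A, config.familiarization_items, next(seed_iter))
        np.savetxt(out / f"stream_{paradigm}.txt", stream.items, fmt="%d")

        cohort = simulate_cohort(
            config.n_participants, paradigm,
            ParticipantParams(beta=config.beta),
            rng_seed=next(seed_iter),
        )
        write_cohort_csvs(cohort, out, prefix=f"{paradigm}_")
        cohort, report = apply_exclusions(cohort)
        exclusion_summaries[paradigm] = report.summary()
        tables[paradigm] = familiarity_scores(cohort, block=2)
        model_scores_by_paradigm[paradigm] = cohort_model_scores(
            cohort, list(config.models), beta=config.beta,
            rng_seed=next(seed_iter), stream_length=config.model_stream_length,
        )

    # tidy predictions table
    rows = [
        (p, m, c, s)
        for p, per_model in model_scores_by_paradigm.items()
        for m, scores in per_model.items()
        for c, s in scores.items()
    ]
    pd.DataFrame(
        rows, columns=["paradigm", "model", "condition", "score"]
    ).to_csv(out / "model_predictions.csv", index=False)

    # familiarity statistics per paradigm
    stats_rows = []
    for p, tab in tables.items():
        tests = condition_tests(tab)
        for _, r in tests["vs_chance"].iterrows():
            stats_rows.append((p, r["condition"], r["mean"], r["sem"],
                               r["t"], r["p"], r["p_fdr"]))
    pd.DataFrame(
        stats_rows,
        columns=["paradigm", "condition", "mean", "sem", "t", "p", "p_fdr"],
    ).to_csv(out / "familiarity_stats.csv", index=False)

    # bootstrap model comparison on the pooled pattern
    mv = {
        m: cmp.model_vector({
            p: model_scores_by_paradigm[p][m] for p in config.paradigms
        })
        for m in config.models
    }
    boot = cmp.bootstrap_correlations(
        tables, mv, n_boot=config.n_boot, rng_seed=next(seed_iter)
    )
    ceiling = cmp.noise_ceiling(
        tables, n_boot=config.n_boot, rng_seed=next(seed_iter)
    )
    summary = {
        "config": config.to_dict(),
        "config_hash": config.config_hash(),
        "seeds": seeds,
        "exclusions": exclusion_summaries,
        "mean_correlations": boot.mean_correlation().to_dict(),
        "noise_ceiling": ceiling,
        "dominance": boot.dominance.round(4).to_dict(),
        "condition_means": {
            p: {c: float(tab[c].mean()) for c in tab.columns}
            for p, tab in tables.items()
        },
    }
    (out / "comparison_report.json").write_text(json.dumps(summary, indent=1))
    (out / "manifest.json").write_text(json.dumps(
        {"config": config.to_dict(), "config_hash": config.config_hash(),
         "seeds": seeds}, indent=1))
    return summary
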