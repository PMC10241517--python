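#!/usr/bin/env python
"""Simulate the synthetic behavioral cohorts for the three paradigms.

Generates FEMM-driven participants (beta = 0.06, logistic choice rule,
lapses, between-community press bumps) with the study's sample sizes
(250 / 249 / 228) and writes the cohort CSVs under results/cohorts/.
"""

from pathlib import Path

from netlearn.behavior import ParticipantParams, simulate_cohort
from netlearn.pipeline import child_seeds, write_cohort_csvs

OUT = Path("results/cohorts")
SEED = 2026
N_PER_PARADIGM = {"full": 250, "sparse": 249, "high_sparse": 228}


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    seeds = child_seeds(SEED, len(N_PER_PARADIGM))
    for seed, (paradigm, n) in zip(seeds, N_PER_PARADIGM.items()):
        cohort = simulate_cohort(n, paradigm, ParticipantParams(), rng_seed=seed)
        write_cohort_csvs(cohort, OUT, prefix=f"{paradigm}_")
        print(f"{paradigm}: {n} participants, "
              f"{len(cohort.choices)} choices, {len(cohort.keypresses)} key presses")
    print(f"\nCohort CSVs written to {OUT}/")


if __name__ == "__main__":
    main()
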