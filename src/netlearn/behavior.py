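"""Synthetic behavioral cohorts.

Emulates the study's data layout — per-participant two-alternative
forced-choice responses (two blocks) and key-press event trains over a
2.2-min active-listening stream — so the downstream analysis and
model-comparison pipelines can be exercised and validated end to end
without the archived human data.

Choices follow a logistic (softmax) decision rule over a generating model's
condition scores, with a lapse rate; key presses follow an inhomogeneous
Poisson process with a Gaussian bump of extra presses after every
between-community transition.  Each paradigm is split into 8 groups, each
with its own graph instance, battery and active-listening stream, mirroring
the study's counterbalancing groups.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import expit

from .graphs import FAMILIAR_BETWEEN, CommunityGraph, build_graph
from .models import DEFAULT_BETA, condition_scores, model_prediction
from .graphs import transition_matrix
from .streams import (
    ForcedChoiceTrial,
    Stream,
    build_test_battery,
    random_walk,
    stream_length_for,
    transition_conditions,
)

ACTIVE_LISTENING_S = 132.0  # 2.2 min per active-listening stream
N_GROUPS = 8


@dataclass(frozen=True)
class ParticipantParams:
    """Generative parameters of one simulated participant.

    ``choice_temperature`` scales the condition-score difference entering
    the logistic choice rule (scores live on the familiar-within = 1
    scale); ``bump_amplitude`` is the expected number of extra presses per
    between-community transition.  The defaults (temperature 0.5, lapse
    0.2) put FEMM-generated condition means in the 30-45% range observed
    in the study; a temperature of 0.1 makes choices nearly deterministic
    and is the convention for model-recovery checks.
    """

    generating_model: str = "femm"
    beta: float = DEFAULT_BETA
    choice_temperature: float = 0.5
    lapse_rate: float = 0.2
    baseline_rate: float = 0.3      # presses / s
    bump_amplitude: float = 0.3     # extra presses per between transition
    bump_latency_s: float = 0.5
    bump_width_s: float = 0.3
    catch_accuracy: float = 0.95
    block1_temperature_multiplier: float = 1.0

    def __post_init__(self) -> None:
        if not 0 <= self.lapse_rate <= 1:
            raise ValueError("lapse_rate must be in [0, 1]")
        if not 0 <= self.catch_accuracy <= 1:
            raise ValueError("catch_accuracy must be in [0, 1]")
        if self.choice_temperature < 0:
            raise ValueError("choice_temperature must be non-negative")
        for r in (self.baseline_rate, self.bump_amplitude,
                  self.bump_latency_s, self.bump_width_s):
            if r < 0:
                raise ValueError("rates and bump parameters must be non-negative")


@dataclass
class CohortDataset:
    """A simulated (or imported) cohort for one paradigm.

    ``participants``: one row per participant (paradigm, group, stimulus
    type, catch failures out of 4, press count).
    ``choices``: one row per non-catch forced-choice trial
    (participant_id, block, trial, condition, direction, chose_tested).
    ``keypresses``: one row per press (participant_id, time_s).
    """

    paradigm: str
    participants: pd.DataFrame
    choices: pd.DataFrame
    keypresses: pd.DataFrame
    graphs: dict[int, CommunityGraph] = field(default_factory=dict)
    batteries: dict[int, list[ForcedChoiceTrial]] = field(default_factory=dict)
    streams: dict[int, Stream] = field(default_factory=dict)

    @property
    def n_participants(self) -> int:
        return len(self.participants)


def simulate_choice(
    trial: ForcedChoiceTrial,
    scores: dict[str, float],
    temperature: float,
    lapse_rate: float,
    rng_seed: int | np.random.Generator | None = None,
) -> bool:
    """Simulate one forced choice; True means the tested quadruplet was chosen.

    P(choose tested) = lapse/2 + (1-lapse) * logistic((v_t - v_r)/T) where
    v are the condition scores of the two middle transitions.
    """
    if trial.is_catch:
        raise ValueError("catch trials have no familiarity choice")
    rng = np.random.default_rng(rng_seed) if not isinstance(
        rng_seed, np.random.Generator
    ) else rng_seed
    p = choice_probability(
        scores[trial.tested_condition], scores["familiar_within"],
        temperature, lapse_rate,
    )
    return bool(rng.random() < p)


def choice_probability(
    v_tested: float, v_reference: float, temperature: float, lapse_rate: float
) -> float:
    diff = v_tested - v_reference
    if temperature == 0:
        core = 0.5 if diff == 0 else (1.0 if diff > 0 else 0.0)
    elif np.isinf(temperature):
        core = 0.5
    else:
        core = float(expit(diff / temperature))
    return lapse_rate / 2 + (1 - lapse_rate) * core


def simulate_key_presses(
    stream: Stream,
    graph: CommunityGraph,
    params: ParticipantParams,
    rng_seed: int | np.random.Generator | None = None,
) -> np.ndarray:
    """Simulate a press train as an inhomogeneous Poisson process.

    Baseline-rate events over the stream duration, plus, for each
    between-community transition, Poisson(bump_amplitude) extra events at
    Gaussian(offset + latency, width) times.  Events outside the stream are
    dropped.  Exact by superposition of the two components.
    """
    rng = np.random.default_rng(rng_seed) if not isinstance(
        rng_seed, np.random.Generator
    ) else rng_seed
    T = stream.duration_s
    n_base = rng.poisson(params.baseline_rate * T)
    times = [rng.random(n_base) * T]
    if params.bump_amplitude > 0:
        conds = transition_conditions(stream, graph)
        offsets = stream.transition_offsets_s()
        for off, cond in zip(offsets, conds):
            if cond == FAMILIAR_BETWEEN:
                k = rng.poisson(params.bump_amplitude)
                if k:
                    times.append(
                        rng.normal(off + params.bump_latency_s,
                                   params.bump_width_s, k)
                    )
    t = np.concatenate(times)
    return np.sort(t[(t >= 0) & (t < T)])


def _group_scores(
    graph: CommunityGraph, params: ParticipantParams, rng: np.random.Generator
) -> dict[str, float]:
    A = transition_matrix(graph)
    pred = model_prediction(
        params.generating_model, A, beta=params.beta, rng_seed=rng
    )
    return condition_scores(pred, graph)


def simulate_cohort(
    n_participants: int,
    paradigm: str,
    params: ParticipantParams | None = None,
    rng_seed: int | np.random.Generator | None = None,
    n_groups: int = N_GROUPS,
    simulate_presses: bool = True,
) -> CohortDataset:
    """Simulate a full cohort for one paradigm.

    Participants are assigned round-robin to ``n_groups`` groups; each group
    gets its own graph instance, forced-choice battery and active-listening
    stream (shared within the group, as in the study).  Each participant
    contributes two blocks of choices, four catch outcomes and one press
    train.  Half the participants are tagged 'tone', half 'syllable' (the
    tag only matters for the group-difference test).
    """
    params = params or ParticipantParams()
    rng = np.random.default_rng(rng_seed) if not isinstance(
        rng_seed, np.random.Generator
    ) else rng_seed
    graphs: dict[int, CommunityGraph] = {}
    batteries: dict[int, list[ForcedChoiceTrial]] = {}
    streams: dict[int, Stream] = {}
    scores: dict[int, dict[str, float]] = {}
    n_active = stream_length_for(ACTIVE_LISTENING_S)
    for g in range(n_groups):
        seed = int(rng.integers(2**31))
        graphs[g] = build_graph(paradigm, rng_seed=seed)
        A = transition_matrix(graphs[g])
        batteries[g] = build_test_battery(graphs[g], rng)
        streams[g] = random_walk(A, n_active, rng)
        scores[g] = _group_scores(graphs[g], params, rng)

    part_rows, choice_rows, press_rows = [], [], []
    for pid in range(n_participants):
        g = pid % n_groups
        battery = batteries[g]
        for block in (1, 2):
            temp = params.choice_temperature * (
                params.block1_temperature_multiplier if block == 1 else 1.0
            )
            for t_idx, trial in enumerate(battery):
                if trial.is_catch:
                    continue
                chose = simulate_choice(
                    trial, scores[g], temp, params.lapse_rate, rng
                )
                choice_rows.append(
                    (pid, block, t_idx, trial.tested_condition,
                     trial.direction, chose)
                )
        n_catch = sum(t.is_catch for t in battery)
        catch_ok = rng.random(n_catch) < params.catch_accuracy
        if simulate_presses:
            presses = simulate_key_presses(streams[g], graphs[g], params, rng)
        else:
            presses = np.empty(0)
        press_rows.extend((pid, t) for t in presses)
        part_rows.append(
            (pid, paradigm, g, graphs[g].seed,
             "tone" if pid % 2 == 0 else "syllable",
             int(n_catch - catch_ok.sum()), len(presses))
        )

    participants = pd.DataFrame(
        part_rows,
        columns=["participant_id", "paradigm", "group", "graph_seed",
                 "stimulus", "catch_failures", "n_presses"],
    )
    choices = pd.DataFrame(
        choice_rows,
        columns=["participant_id", "block", "trial", "condition",
                 "direction", "chose_tested"],
    )
    keypresses = pd.DataFrame(press_rows, columns=["participant_id", "time_s"])
    return CohortDataset(
        paradigm=paradigm,
        participants=participants,
        choices=choices,
        keypresses=keypresses,
        graphs=graphs,
        batteries=batteries,
        streams=streams,
    )


def cohort_model_scores(
    cohort: CohortDataset,
    model_names: list[str],
    beta: float = DEFAULT_BETA,
    rng_seed: int | np.random.Generator | None = None,
    stream_length: int = 50_000,
) -> dict[str, dict[str, float]]:
    """Condition scores per model, averaged over the cohort's group graphs."""
    rng = np.random.default_rng(rng_seed) if not isinstance(
        rng_seed, np.random.Generator
    ) else rng_seed
    out: dict[str, dict[str, float]] = {}
    for name in model_names:
        per_graph = []
        for g, graph in cohort.graphs.items():
            A = transition_matrix(graph)
            pred = model_prediction(
                name, A, beta=beta, rng_seed=rng, stream_length=stream_length
            )
            per_graph.append(condition_scores(pred, graph))
        keys = per_graph[0].keys()
        out[name] = {
            k: float(np.mean([s[k] for s in per_graph])) for k in keys
        }
    return out
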