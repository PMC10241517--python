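"""Behavioral pipelines: exclusions, parsing curves, familiarity statistics."""

import numpy as np
import pandas as pd
import pytest

from netlearn.analysis import (
    apply_exclusions,
    condition_tests,
    familiarity_scores,
    parsing_probability,
    timecourse_test,
)
from netlearn.behavior import CohortDataset, ParticipantParams, simulate_cohort


@pytest.fixture(scope="module")
def press_cohort():
    """Small cohort with a clear post-between press bump."""
    params = ParticipantParams(
        baseline_rate=0.4, bump_amplitude=1.5,
        bump_latency_s=0.5, bump_width_s=0.2,
    )
    return simulate_cohort(24, "full", params, rng_seed=77)


def _with_presses(cohort, pid, times):
    kp = cohort.keypresses
    kp = kp[kp["participant_id"] != pid]
    extra = pd.DataFrame({"participant_id": pid, "time_s": times})
    return CohortDataset(
        paradigm=cohort.paradigm,
        participants=cohort.participants,
        choices=cohort.choices,
        keypresses=pd.concat([kp, extra], ignore_index=True),
        graphs=cohort.graphs,
        batteries=cohort.batteries,
        streams=cohort.streams,
    )


def test_exclusion_rules(press_cohort):
    cohort = _with_presses(press_cohort, 0, np.linspace(1, 100, 5))   # 5 presses
    cohort = _with_presses(cohort, 1, np.linspace(1, 130, 300))       # 300 presses
    parts = cohort.participants.copy()
    parts.loc[parts["participant_id"] == 2, "catch_failures"] = 3
    parts.loc[parts["participant_id"] == 3, "catch_failures"] = 2
    cohort.participants = parts
    filtered, report = apply_exclusions(cohort)
    kept = filtered.participants.set_index("participant_id")
    assert not kept.loc[0, "keep_press"]      # too few presses
    assert not kept.loc[1, "keep_press"]      # too many presses
    assert not kept.loc[2, "keep_choice"]     # failed 3/4 catch trials
    assert kept.loc[3, "keep_choice"]         # 2/4 failures is retained
    assert report.n_excluded_presses >= 2
    assert report.summary()["n_total"] == 24
    # the two rules are independent
    assert kept.loc[0, "keep_choice"] or True
    assert 2 in report.press_retained or not kept.loc[2, "keep_press"]


def test_parsing_curve_shows_community_boundaries(press_cohort):
    cohort, _ = apply_exclusions(press_cohort)
    curve = parsing_probability(cohort, n_within_groups=100, rng_seed=0)
    # epoch axis spans -2.75..2.75 s on a 1 ms grid
    assert curve.times_s[0] == pytest.approx(-2.75)
    assert curve.times_s[-1] == pytest.approx(2.75)
    assert len(curve.times_s) == 5501
    assert (curve.between >= 0).all() and (curve.within >= 0).all()
    # the generator's post-between bump is recovered
    post = (curve.times_s > 0.2) & (curve.times_s < 1.2)
    assert curve.between[post].mean() > curve.within[post].mean()
    mask = curve.significance_mask
    assert mask.any()
    assert not mask[curve.times_s < -0.1].any()  # only inside the test window
    assert not mask[curve.times_s > 2.75].any()


def test_parsing_zero_presses_gives_flat_zero(press_cohort):
    cohort = press_cohort
    empty = CohortDataset(
        paradigm=cohort.paradigm,
        participants=cohort.participants.assign(
            keep_press=True
        ),
        choices=cohort.choices,
        keypresses=cohort.keypresses.iloc[0:0],
        graphs=cohort.graphs,
        batteries=cohort.batteries,
        streams=cohort.streams,
    )
    curve = parsing_probability(empty, n_within_groups=20, rng_seed=0)
    assert np.all(curve.between == 0) and np.all(curve.within == 0)
    assert not curve.significance_mask.any()


def test_timecourse_test_power_and_nulls(rng):
    times = np.linspace(-0.5, 1.0, 151)
    base = rng.normal(0, 1, size=(100, len(times)))
    assert not timecourse_test(base, base.copy(), times).any()
    shifted = base + 2.0  # Cohen's d = 2
    mask = timecourse_test(shifted, rng.normal(0, 1, (100, len(times))), times)
    in_window = (times >= -0.1) & (times <= 2.75)
    assert mask[in_window].mean() > 0.9
    assert not mask[~in_window].any()


def test_familiarity_score_extremes():
    c = simulate_cohort(
        20, "sparse",
        ParticipantParams(choice_temperature=0.0, lapse_rate=0.0),
        rng_seed=4, simulate_presses=False,
    )
    table = familiarity_scores(c, block=2)
    # every tested condition scores below the reference, never selected
    # at zero noise (all condition scores < familiar-within's 1)
    assert (table.to_numpy() == 0).all()
    assert table.to_numpy().min() >= 0 and table.to_numpy().max() <= 100
    with pytest.raises(ValueError):
        familiarity_scores(c, block=3)


def test_familiarity_block_selection():
    # block 1 run at full lapse, block 2 near-deterministic
    params = ParticipantParams(
        choice_temperature=0.1, lapse_rate=0.0,
        block1_temperature_multiplier=1e6,
    )
    c = simulate_cohort(80, "sparse", params, rng_seed=6, simulate_presses=False)
    b1 = familiarity_scores(c, block=1)
    b2 = familiarity_scores(c, block=2)
    assert abs(b1["new_between"].mean() - 50) < 10       # near chance
    assert b2["new_between"].mean() < 20                 # strongly rejected


def test_condition_tests_detect_signal_and_control_fdr(rng):
    n = 200
    table = pd.DataFrame({
        "familiar_between": rng.normal(45, 5, n),
        "new_within": rng.normal(50, 5, n),
        "new_between": rng.normal(45, 5, n),
    })
    stim = pd.Series(
        ["tone" if i % 2 else "syllable" for i in range(n)], index=table.index
    )
    out = condition_tests(table, stimulus=stim)
    vs = out["vs_chance"].set_index("condition")
    assert vs.loc["familiar_between", "significant"]
    assert vs.loc["new_between", "significant"]
    assert not vs.loc["new_within", "significant"]
    # BH-adjusted p-values are monotone in the raw p-values
    ordered = out["vs_chance"].sort_values("p")
    assert ordered["p_fdr"].is_monotonic_increasing
    assert (out["vs_chance"]["p_fdr"] >= out["vs_chance"]["p"] - 1e-12).all()
    # stimulus groups are exchangeable here: no group difference expected
    assert (out["group"]["p"] > 0.001).all()
    assert len(out["pairwise"]) == 3
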