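"""Bootstrap comparison, noise ceiling, and the beta sweep machinery."""

import numpy as np
import pandas as pd
import pytest

from netlearn import comparison as cmp
from netlearn.analysis import familiarity_scores
from netlearn.behavior import ParticipantParams, simulate_cohort
from netlearn.graphs import PARADIGMS, build_graph, transition_matrix
from netlearn.models import condition_scores, femm_model, tp_model


@pytest.fixture(scope="module")
def paradigm_scores(graphs):
    mats = {p: transition_matrix(g) for p, g in graphs.items()}
    return {
        "femm": {p: condition_scores(femm_model(mats[p], 0.06), graphs[p])
                 for p in PARADIGMS},
        "tp": {p: condition_scores(tp_model(mats[p]), graphs[p])
               for p in PARADIGMS},
    }


def _table_from_scores(scores, n=40, noise=0.0, seed=0):
    """Familiarity table whose participant means equal scores x 50."""
    rng = np.random.default_rng(seed)
    data = {
        c: scores[c] * 50 + rng.normal(0, noise, n)
        for c in cmp.CONDITION_ORDER
    }
    return pd.DataFrame(data)


def test_pooled_vector_shapes(paradigm_scores):
    tables = {
        p: _table_from_scores(paradigm_scores["femm"][p]) for p in PARADIGMS
    }
    assert cmp.pooled_vector(tables).shape == (9,)
    assert cmp.pooled_vector(tables, include_reference=True).shape == (12,)
    assert cmp.pooled_vector(tables, restrict=cmp.RESTRICTED_CELLS).shape == (4,)
    assert cmp.pooled_vector({"sparse": tables["sparse"]}).shape == (3,)
    with pytest.raises(ValueError):
        cmp.pooled_vector({})


def test_model_vector_alignment(paradigm_scores):
    v = cmp.model_vector(paradigm_scores["femm"])
    k = 0
    for p in cmp.PARADIGM_ORDER:
        for c in cmp.CONDITION_ORDER:
            assert v[k] == paradigm_scores["femm"][p][c]
            k += 1


def test_bootstrap_degenerate_data_picks_generating_model(paradigm_scores):
    # data equal to the FEMM predictions exactly: FEMM wins every resample
    tables = {
        p: _table_from_scores(paradigm_scores["femm"][p], noise=1.0, seed=i)
        for i, p in enumerate(PARADIGMS)
    }
    mv = {m: cmp.model_vector(paradigm_scores[m]) for m in ("femm", "tp")}
    mv["femm_twin"] = mv["femm"].copy()
    boot = cmp.bootstrap_correlations(tables, mv, n_boot=500, rng_seed=1)
    assert boot.dominance.loc["femm", "tp"] > 0.99
    # identical models split the resamples evenly
    assert boot.dominance.loc["femm", "femm_twin"] == pytest.approx(0.5)
    # antisymmetry
    d = boot.dominance
    for a in d.index:
        for b in d.columns:
            assert d.loc[a, b] + d.loc[b, a] == pytest.approx(1.0)
    for r in boot.correlations.values():
        assert (np.abs(r) <= 1.0 + 1e-12).all()


def test_noise_ceiling_limits(paradigm_scores):
    # noiseless responders: both resamples always produce the same vector
    exact = {p: _table_from_scores(paradigm_scores["femm"][p]) for p in PARADIGMS}
    assert cmp.noise_ceiling(exact, n_boot=200, rng_seed=0) > 0.999
    # pure-chance responders: no true condition pattern.  Both resamples
    # are drawn from the same cohort, so they share its empirical mean
    # pattern and the estimate stays positive (about 0.5, since shared
    # sampling deviation and bootstrap noise have equal variance), but it
    # drops far below the noiseless ceiling.
    rng = np.random.default_rng(3)
    chance = {
        p: pd.DataFrame({
            c: 50 + rng.normal(0, 8, 60) for c in cmp.CONDITION_ORDER
        })
        for p in PARADIGMS
    }
    ceiling = cmp.noise_ceiling(chance, n_boot=500, rng_seed=1)
    assert 0.0 < ceiling < 0.8
    # noisier cohorts cannot have a higher ceiling than noiseless ones
    signal = {
        p: _table_from_scores(
            paradigm_scores["femm"][p], n=60, noise=8.0, seed=4
        )
        for p in PARADIGMS
    }
    mid = cmp.noise_ceiling(signal, n_boot=500, rng_seed=1)
    assert ceiling < 1.0 and mid < 1.0


def test_beta_fit_single_point_grid(graphs, paradigm_scores):
    target = cmp.model_vector(paradigm_scores["femm"])
    gb = {p: [graphs[p]] for p in PARADIGMS}
    fit = cmp.beta_grid_fit(target, gb, grid=np.array([0.06]))
    assert fit.beta_hat == 0.06


def test_beta_self_recovery(graphs, paradigm_scores):
    """A FEMM(0.06) target is recovered on the documented plateau."""
    target = cmp.model_vector(paradigm_scores["femm"])
    gb = {p: [graphs[p]] for p in PARADIGMS}
    fit = cmp.beta_grid_fit(target, gb, grid=cmp.default_beta_grid(121))
    assert 1e-4 <= fit.beta_hat <= 1e-1
    # the unsmoothed curve reaches 1 at the generating beta; smoothing
    # shaves a little off the peak on a coarse grid
    assert np.max(fit.correlation) > 0.9999
    assert fit.max_correlation > 0.99
    assert fit.plateau[0] <= fit.beta_hat <= fit.plateau[1]


def test_smooth_curve_properties():
    y = np.arange(10.0)
    s = cmp.smooth_curve(y, 5)
    assert len(s) == 10
    np.testing.assert_allclose(s[2:8], y[2:8])  # linear interior unchanged
    const = cmp.smooth_curve(np.full(7, 3.0), 5)
    np.testing.assert_allclose(const, 3.0)


def test_bootstrap_on_simulated_cohort(graphs):
    """End to end: a FEMM cohort is matched better by FEMM than by TP."""
    tables, model_scores = {}, {"femm": {}, "tp": {}}
    for p in PARADIGMS:
        c = simulate_cohort(
            80, p, ParticipantParams(), rng_seed=19, simulate_presses=False
        )
        tables[p] = familiarity_scores(c, block=2)
        mats = {g: transition_matrix(gr) for g, gr in c.graphs.items()}
        for m, fn in (("femm", lambda A: femm_model(A, 0.06)), ("tp", tp_model)):
            per = [condition_scores(fn(mats[g]), c.graphs[g]) for g in c.graphs]
            model_scores[m][p] = {
                k: float(np.mean([s[k] for s in per])) for k in per[0]
            }
    mv = {m: cmp.model_vector(model_scores[m]) for m in model_scores}
    boot = cmp.bootstrap_correlations(tables, mv, n_boot=1000, rng_seed=2)
    assert boot.dominance.loc["femm", "tp"] > 0.95
    assert boot.mean_correlation().idxmax() == "femm"
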