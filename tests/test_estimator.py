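"""EE estimation: CD initialization and EE loop closed-form checks,
reproducibility, and non-mutation guarantees."""

import numpy as np
import pytest

from ergmee import (DirectedGraph, EEConfig, ModelSpec, cd_init, ee_estimate,
                    run_parallel, simulate)
from ergmee.estimator import _update_theta

from conftest import random_graph


def bernoulli_graph(rng, n=100, n_arcs=990) -> DirectedGraph:
    dyads = [(i, j) for i in range(n) for j in range(n) if i != j]
    idx = rng.choice(len(dyads), size=n_arcs, replace=False)
    return DirectedGraph.from_arcs(n, [dyads[k] for k in idx])


def test_update_rule_signs_and_zero():
    theta = np.array([1.0, -2.0, 0.5, 0.0])
    dz = np.array([3.0, -1.0, 0.0, 0.0])
    out = _update_theta(theta, dz, 0.01, 0.01, "multiplicative")
    # positive divergence lowers theta by rate*max(|theta|, theta_min)
    np.testing.assert_allclose(out, [1.0 - 0.01, -2.0 + 0.02, 0.5, 0.0])
    out2 = _update_theta(theta, dz, 0.05, 0.01, "simple")
    np.testing.assert_allclose(out2, theta - 0.05 * dz)


def test_cd_init_bernoulli_closed_form(rng):
    """Arc-only CD initial value near log(d/(1-d)) for a density-d graph."""
    g = bernoulli_graph(rng)
    model = ModelSpec(["Arc"])
    cfg = EEConfig(cd_steps=500, cd_updates=100, seed=1)
    theta0 = cd_init(g, model, None, cfg)
    assert theta0[0] == pytest.approx(np.log(0.1 / 0.9), abs=0.5)


def test_cd_init_rejects_empty_graph():
    with pytest.raises(ValueError):
        cd_init(DirectedGraph(5), ModelSpec(["Arc"]), None, EEConfig())


def test_ee_estimate_bernoulli_mle(rng):
    """Arc-only EE estimate within 0.15 of the Bernoulli MLE
    log(0.1/0.9) = -2.197 on a 100-node, 990-arc graph."""
    g = bernoulli_graph(rng)
    model = ModelSpec(["Arc"])
    cfg = EEConfig(ee_steps=400, steps_per_update=500, cd_steps=500,
                   cd_updates=100, seed=2)
    theta0 = cd_init(g, model, None, cfg, seed=11)
    res = ee_estimate(g, model, None, theta0, cfg, seed=12)
    assert res.converged
    assert res.theta_hat[0] == pytest.approx(np.log(1 / 9), abs=0.15)
    assert res.se[0] > 0


def test_ee_estimate_does_not_mutate_observed(rng):
    g = random_graph(rng, 20, 0.2)
    arcs_before = sorted(g.arc_list)
    tables_before = (dict(g.mix2), dict(g.in2), dict(g.out2))
    model = ModelSpec(["Arc", "Reciprocity"])
    cfg = EEConfig(ee_steps=50, steps_per_update=100, cd_steps=100,
                   cd_updates=20, seed=3)
    theta0 = cd_init(g, model, None, cfg)
    ee_estimate(g, model, None, theta0, cfg)
    assert sorted(g.arc_list) == arcs_before
    assert (g.mix2, g.in2, g.out2) == tables_before


def test_ee_small_learning_rate_stays_near_theta0(rng):
    g = random_graph(rng, 15, 0.2)
    model = ModelSpec(["Arc"])
    lr = 1e-6
    cfg = EEConfig(ee_steps=50, steps_per_update=50, learning_rate=lr,
                   theta_min=0.01, seed=4)
    theta0 = np.array([-1.0])
    res = ee_estimate(g, model, None, theta0, cfg)
    bound = lr * cfg.ee_steps * max(abs(theta0[0]) * 2, 0.01)
    assert np.max(np.abs(res.theta_trace - theta0[0])) <= bound


def test_monotone_density_response():
    """Mean simulated density strictly increases with the Arc parameter
    (exponential-family monotonicity)."""
    model = ModelSpec(["Arc"])
    dens = []
    for k, th in enumerate([-2.0, -1.0, 0.0, 1.0]):
        samples = simulate(model, [th], 25, burn_in=20_000, sample_gap=2_000,
                           n_samples=10, seed=20 + k)
        dens.append(np.mean([g.density() for g in samples]))
    assert all(a < b for a, b in zip(dens, dens[1:]))


def test_run_parallel_reproducible_and_sized(rng):
    g = random_graph(rng, 25, 0.15)
    model = ModelSpec(["Arc", "Reciprocity"])
    cfg = EEConfig(ee_steps=60, steps_per_update=100, cd_steps=100,
                   cd_updates=30, n_runs=3, seed=5)
    runs1 = run_parallel(g, model, None, cfg)
    runs2 = run_parallel(g, model, None, cfg)
    assert len(runs1) == 3
    for a, b in zip(runs1, runs2):
        np.testing.assert_array_equal(a.theta_trace, b.theta_trace)
        np.testing.assert_array_equal(a.dz_trace, b.dz_trace)
    single = run_parallel(g, model, None,
                          EEConfig(ee_steps=60, steps_per_update=100,
                                   cd_steps=100, cd_updates=30, n_runs=1,
                                   seed=6))
    assert len(single) == 1


def test_parameter_recovery_arc_reciprocity():
    """Estimates on a graph simulated from known (theta_L, theta_R) land
    within 4 combined standard errors of the truth."""
    truth = np.array([-2.0, 1.5])
    model = ModelSpec(["Arc", "Reciprocity"])
    g = simulate(model, truth, 60, burn_in=300_000, n_samples=1, seed=30)[0]
    cfg = EEConfig(ee_steps=300, steps_per_update=400, cd_steps=400,
                   cd_updates=250, n_runs=4, seed=31)
    runs = run_parallel(g, model, None, cfg)
    assert any(r.converged for r in runs)
    from ergmee import combine_runs
    est = combine_runs(runs)
    for k in range(2):
        assert abs(est.theta_hat[k] - truth[k]) < 4 * max(est.se[k], 0.05), \
            f"effect {k}: {est.theta_hat[k]} vs {truth[k]} (se {est.se[k]})"


def test_ifd_mode_estimates_non_arc_effects(rng):
    """With the IFD sampler the density is fixed: dz_Arc stays 0, Arc is
    not updated, and the other effects are still estimated."""
    truth = np.array([-2.0, 1.5])
    model = ModelSpec(["Arc", "Reciprocity"])
    g = simulate(model, truth, 50, burn_in=200_000, n_samples=1, seed=40)[0]
    cfg = EEConfig(ee_steps=300, steps_per_update=400, cd_steps=400,
                   cd_updates=250, sampler_mode="ifd", seed=41)
    theta0 = cd_init(g, model, None, cfg)
    res = ee_estimate(g, model, None, theta0, cfg)
    assert np.all(res.dz_trace[:, 0] == 0.0)
    np.testing.assert_allclose(res.theta_trace[:, 0], theta0[0])
    assert np.isinf(res.se[0])
    assert abs(res.theta_hat[1] - truth[1]) < 1.0
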