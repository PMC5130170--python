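"""Gillespie engine: analytic means, stationary laws, conservation, scaling."""

import numpy as np
import pytest
from scipy import stats

from erknoise.deterministic import integrate
from erknoise.models import build_mini_cascade
from erknoise.stochastic import run_intrinsic_ensemble, spawn_seeds, ssa_simulate

from conftest import make_ab_network, make_birth_death


def test_linear_decay_ensemble_mean_within_three_se():
    """A -> B, k = 0.05/s, A0 = 100: mean B(t) tracks 100 (1 - e^{-kt})."""
    net = make_ab_network(k_ab=0.05, a0=100)
    n_paths = 2000
    t_grid_vals = None
    b_sum = None
    b_sq = None
    for seed in spawn_seeds(123, n_paths):
        traj = ssa_simulate(net, 0.0, 60.0, int(seed), output_dt=10.0,
                            equilibrate=False)
        b = traj.species("B")
        t_grid_vals = traj.times
        b_sum = b if b_sum is None else b_sum + b
        b_sq = b**2 if b_sq is None else b_sq + b**2
    mean = b_sum / n_paths
    sd = np.sqrt(b_sq / n_paths - mean**2)
    se = sd / np.sqrt(n_paths)
    expected = 100.0 * (1.0 - np.exp(-0.05 * t_grid_vals))
    # skip t=0 where SE is 0
    assert np.all(np.abs(mean[1:] - expected[1:]) <= 3.0 * se[1:] + 1e-9)


def test_birth_death_stationary_distribution_is_poisson():
    """0 -> A at lam, A -> 0 at mu n: stationary counts ~ Poisson(lam/mu)."""
    lam, mu = 30.0, 0.1
    net = make_birth_death(lam=lam, mu=mu)
    n_samples = 5000
    samples = np.empty(n_samples, dtype=int)
    for i, seed in enumerate(spawn_seeds(99, n_samples)):
        traj = ssa_simulate(net, 0.0, 60.0, int(seed), output_dt=60.0,
                            equilibrate=False)
        samples[i] = int(traj.species("A")[-1])
    m = lam / mu
    lo, hi = int(m - 4 * np.sqrt(m)), int(m + 4 * np.sqrt(m))
    edges = np.arange(lo, hi + 2)
    observed, _ = np.histogram(samples, bins=edges)
    probs = stats.poisson.pmf(edges[:-1], m)
    probs = np.append(probs, 1.0 - probs.sum())
    observed = np.append(observed, n_samples - observed.sum())
    keep = probs * n_samples >= 5
    chi2 = np.sum((observed[keep] - n_samples * probs[keep]) ** 2
                  / (n_samples * probs[keep]))
    p = stats.chi2.sf(chi2, keep.sum() - 1)
    assert p > 0.01


def test_closed_system_conserves_total_on_every_path():
    net = make_ab_network(k_ab=0.05, k_ba=0.03, a0=60, b0=40)
    for seed in (1, 2, 3):
        traj = ssa_simulate(net, 0.0, 200.0, seed, output_dt=10.0,
                            equilibrate=False)
        totals = traj.species("A") + traj.species("B")
        assert np.all(totals == 100)


def test_identical_seed_reproduces_path_bitwise(mini_network):
    a = ssa_simulate(mini_network, 1.0, 300.0, 42, output_dt=10.0)
    b = ssa_simulate(mini_network, 1.0, 300.0, 42, output_dt=10.0)
    assert np.array_equal(a.states, b.states)
    c = ssa_simulate(mini_network, 1.0, 300.0, 43, output_dt=10.0)
    assert not np.array_equal(a.states, c.states)


def test_intrinsic_ensemble_reproducible_and_seeded(mini_network):
    r1 = run_intrinsic_ensemble(mini_network, 1.0, 5, master_seed=7, t_end=300.0)
    r2 = run_intrinsic_ensemble(mini_network, 1.0, 5, master_seed=7, t_end=300.0)
    assert np.array_equal(r1["values"], r2["values"])
    assert np.array_equal(r1["seeds"], r2["seeds"])


def test_ssa_ensemble_mean_converges_to_ode():
    """On the reduced cascade the SSA ensemble mean tracks the ODE solution
    (relative error < 2% for pools of >= 1000 molecules)."""
    net = build_mini_cascade()
    n_paths = 500
    acc = None
    for seed in spawn_seeds(2024, n_paths):
        traj = ssa_simulate(net, 1.0, 600.0, int(seed), output_dt=60.0)
        acc = traj.states if acc is None else acc + traj.states
    mean = acc / n_paths
    ode = integrate(net, 1.0, t_end=600.0, output_dt=60.0)
    big = ode.states >= 1000
    rel = np.abs(mean[big] - ode.states[big]) / ode.states[big]
    assert rel.max() < 0.02


def test_intrinsic_cv_shrinks_as_inverse_sqrt_of_counts():
    """Scaling every pool x100 shrinks the intrinsic CV of the response ~x10."""
    cvs = {}
    for scale in (1.0, 100.0):
        net = build_mini_cascade(scale=scale)
        res = run_intrinsic_ensemble(
            net, 1.0, 40, master_seed=11, t_end=400.0, output_dt=20.0,
            statistic="endpoint",
        )
        v = res["values"]
        cvs[scale] = v.std(ddof=1) / v.mean()
    ratio = cvs[1.0] / cvs[100.0]
    assert 5.0 < ratio < 20.0


def test_zero_propensity_state_is_absorbing():
    net = make_ab_network(k_ab=0.5, a0=5)  # all A converts, then nothing
    traj = ssa_simulate(net, 0.0, 100.0, 3, output_dt=10.0, equilibrate=False)
    assert traj.species("B")[-1] == 5
    assert np.all(traj.species("A") >= 0)


def test_tau_leaping_agrees_with_direct_method():
    """Tau-leaping mean matches the exact direct method on the reduced model."""
    net = build_mini_cascade()
    means = {}
    for method in ("direct", "tau"):
        vals = []
        for seed in spawn_seeds(5, 200):
            traj = ssa_simulate(net, 1.0, 400.0, int(seed), output_dt=100.0,
                                method=method)
            vals.append(traj.observable("nERK")[-1])
        means[method] = np.mean(vals)
    assert means["tau"] == pytest.approx(means["direct"], rel=0.02)
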