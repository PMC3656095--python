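"""Integration of the coupled system: derivatives, relaxation, shocks."""

import numpy as np
import pytest

from reinworld import (BioticPopulation, ModelConfig, NicheShape,
                       PerturbationProtocol, Trajectory, apply_shock,
                       biotic_derivative, env_derivative, integrate, relax,
                       sample_population, total_biotic_force)


def test_env_derivative_basics():
    np.testing.assert_allclose(env_derivative([5.0], None, [1.0], 1.0), [1.0])
    np.testing.assert_allclose(env_derivative([5.0], None, [1.0], 2.0), [0.5])
    pop = BioticPopulation([[40.0]], [[0.5]], NicheShape("gaussian", 5.0))
    P = -total_biotic_force(pop, [40.0])
    np.testing.assert_allclose(env_derivative([40.0], pop, P, 1.0), [0.0],
                               atol=1e-15)
    with pytest.raises(ValueError):
        env_derivative([5.0], None, [1.0], 0.0)


def test_biotic_derivative_and_closed_form_relaxation():
    np.testing.assert_allclose(biotic_derivative([1.0], [1.0], 1.0), [0.0])
    np.testing.assert_allclose(biotic_derivative([0.0], [1.0], 1.0), [1.0])
    with pytest.raises(ValueError):
        biotic_derivative([0.0], [1.0], 0.0)
    # alpha(t) = 1 - exp(-t/tau) for constant steady state 1; check the
    # RK4 stepper against the closed form at t = tau
    from reinworld.dynamics import _rk4_step
    y, t, dt = np.array([0.0]), 0.0, 0.01
    f = lambda t, y: biotic_derivative(y, [1.0], 1.0)
    while t < 1.0 - 1e-12:
        y = _rk4_step(f, t, y, dt)
        t += dt
    assert y[0] == pytest.approx(1.0 - np.exp(-1.0), rel=1e-8)


def test_empty_system_is_inert():
    cfg = ModelConfig(K=1, n_env=2, seed=0)
    traj = integrate(None, np.array([30.0, 70.0]),
                     PerturbationProtocol.constant(0.0, 2), cfg, t_end=5.0)
    np.testing.assert_allclose(traj.env, np.broadcast_to([30.0, 70.0],
                                                         traj.env.shape))


def test_constructed_equilibrium_is_stationary():
    shape = NicheShape("gaussian", 5.0)
    pop = BioticPopulation([[40.0]], [[0.7]], shape)
    E0 = np.array([42.0])
    P = -total_biotic_force(pop, E0)
    cfg = ModelConfig(K=1, n_env=1, dt=0.01)
    traj = integrate(pop, E0, PerturbationProtocol.constant(P[0], 1), cfg,
                     t_end=10.0)
    np.testing.assert_allclose(traj.env[:, 0], E0[0], atol=1e-10)


def test_integrator_order_rk4_vs_euler(std_config, rng):
    pop = sample_population(std_config, rng)
    proto = PerturbationProtocol.linear_ramp(0.01, n_env=1)

    def final(dt, method):
        cfg = ModelConfig(**{**std_config.to_dict(), "dt": dt})
        return integrate(pop, np.array([30.0]), proto, cfg, t_end=20.0,
                         stride=10 ** 9, method=method).env[-1, 0]

    ref = final(0.025, "rk4")
    err_rk = [abs(final(dt, "rk4") - ref) for dt in (0.4, 0.2)]
    assert err_rk[0] / err_rk[1] > 8  # fourth-order: expect ~16
    err_eu = [abs(final(dt, "euler") - ref) for dt in (0.4, 0.2)]
    assert err_eu[0] / err_eu[1] > 1.5  # first-order: expect ~2
    assert err_rk[1] < err_eu[1]


def test_quasi_steady_matches_full_integration():
    """With tau_biotic <= tau_env/100, slaving the abundances changes the
    E trajectory by well under 1% on a ramped run."""
    cfgq = ModelConfig(K=30, n_env=1, seed=5, quasi_steady_biota=True, dt=0.05)
    cfgf = ModelConfig(K=30, n_env=1, seed=5, quasi_steady_biota=False,
                       tau_biotic=0.01, dt=0.002)
    pop = sample_population(cfgq)
    proto = PerturbationProtocol.linear_ramp(3.0 / 200.0, n_env=1)
    tq = integrate(pop, np.array([10.0]), proto, cfgq, t_end=60.0, stride=20)
    tf = integrate(pop, np.array([10.0]), proto, cfgf, t_end=60.0, stride=500)
    Eq = np.interp(tf.times, tq.times, tq.env[:, 0])
    rel = np.max(np.abs(Eq - tf.env[:, 0]) / np.maximum(np.abs(tf.env[:, 0]), 1e-9))
    assert rel < 0.01


def test_apply_shock_and_shock_protocol():
    assert np.array_equal(apply_shock([1.0, 2.0], [0.0, 0.0]), [1.0, 2.0])
    np.testing.assert_allclose(apply_shock([1.0], [3.0]), [4.0])
    with pytest.raises(ValueError):
        apply_shock([1.0], [1.0, 2.0])
    # a shock protocol displaces E by exactly the shock magnitude
    cfg = ModelConfig(K=1, n_env=1, dt=0.01)
    proto = PerturbationProtocol.shock(5.0, [7.0], n_env=1)
    traj = integrate(None, np.array([20.0]), proto, cfg, t_end=10.0)
    before = traj.env[traj.times <= 4.99, 0]
    after = traj.env[traj.times >= 5.01, 0]
    assert np.allclose(before, 20.0) and np.allclose(after, 27.0)


def test_nonfinite_state_raises_with_time():
    cfg = ModelConfig(K=1, n_env=1, dt=0.5)
    runaway = lambda E: E ** 3  # super-linear growth blows up
    with pytest.raises(FloatingPointError, match="t="):
        integrate(runaway, np.array([10.0]), None, cfg, t_end=50.0)


def test_trajectory_round_trip_and_invariants(std_config, rng):
    pop = sample_population(std_config, rng)
    proto = PerturbationProtocol.linear_ramp(0.02, n_env=1)
    traj = integrate(pop, np.array([10.0]), proto, std_config, t_end=5.0,
                     stride=20)
    back = Trajectory.from_text(traj.to_text())
    np.testing.assert_allclose(back.times, traj.times)
    np.testing.assert_allclose(back.env, traj.env)
    np.testing.assert_allclose(back.force, traj.force)
    np.testing.assert_allclose(back.perturbation, traj.perturbation)
    with pytest.raises(ValueError):
        Trajectory(times=np.array([0.0, 0.0]), env=np.zeros((2, 1)),
                   force=np.zeros((2, 1)), perturbation=np.zeros((2, 1)))


def test_relax_settles_on_linear_restoring_force():
    cfg = ModelConfig(K=1, n_env=1, dt=0.05)
    res = relax(lambda E: -(E - 50.0), np.array([20.0]), cfg, t_max=300.0)
    assert res.settled and not res.escaped
    assert res.E[0] == pytest.approx(50.0, abs=1e-3)


def test_relax_escape_on_outward_force():
    cfg = ModelConfig(K=1, n_env=1)
    res = relax(lambda E: np.ones_like(E), np.array([90.0]), cfg, t_max=300.0)
    assert res.escaped and not res.settled
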