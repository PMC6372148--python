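"""ODE and CLE integration: closed-form oracles, conservation, determinism."""
import numpy as np
import pytest

import hubsens as hs
from hubsens.models import build_linear_toy, evaluate_rates
from hubsens.simulate import DEFAULT_SAMPLE_TIMES


def test_linear_toy_matches_closed_form(constant_signal):
    """dXa/dt = k1*s - k2*Xa with s=1, Xa(0)=0  ->  (k1/k2)(1 - e^{-k2 t})."""
    k1, k2 = 2.0, 0.07
    toy = build_linear_toy(k1, k2)
    t = np.linspace(5, 300, 60)
    traj = hs.integrate_ode(toy, toy.reference_params, constant_signal,
                            sample_times=t, rtol=1e-10, atol=1e-12)
    expected = (k1 / k2) * (1 - np.exp(-k2 * t))
    np.testing.assert_allclose(traj.output, expected, rtol=1e-8)


def test_conservation_along_trajectory(models, patterns):
    for m in models.values():
        cm = m.compile()
        traj = hs.integrate_ode(m, m.reference_params, patterns[3])
        for y in traj.states:
            full = cm.full_state(y)
            idx = {s: i for i, s in enumerate(m.species)}
            for pool in m.pools:
                tot = sum(full[idx[sp]] for sp in pool.members)
                assert abs(tot - pool.total) / pool.total < 1e-6


def test_zero_time_identity(m1, patterns):
    traj = hs.integrate_ode(m1, m1.reference_params, patterns[0], t_end=0.0,
                            sample_times=[0.0])
    np.testing.assert_array_equal(traj.states[0], m1.compile().y0_dyn)


def test_reduced_equals_full_state_formulation(models, patterns):
    """Explicit-substitution dynamics match integrating all species via scipy."""
    from scipy.integrate import solve_ivp
    for m in models.values():
        pat = patterns[2]
        p = dict(m.reference_params)

        def rhs(t, y_full):
            st = dict(zip(m.species, y_full))
            a = evaluate_rates(m, {k: max(v, 0.0) for k, v in st.items()},
                               float(pat.value(t)), p)
            return m.stoichiometry() @ a

        t_eval = DEFAULT_SAMPLE_TIMES
        sol = solve_ivp(rhs, (0, 300), m.initial_full(), t_eval=t_eval,
                        method="LSODA", rtol=1e-10, atol=1e-10)
        traj = hs.integrate_ode(m, p, pat, rtol=1e-10, atol=1e-10)
        out_idx = m.species.index(m.output)
        np.testing.assert_allclose(traj.output, sol.y[out_idx], rtol=1e-6, atol=1e-8)


def test_tolerance_robustness(models, patterns):
    """Tightening tolerances 10x moves sampled outputs by < 1e-4 relative."""
    for m in models.values():
        a = hs.integrate_ode(m, m.reference_params, patterns[0], rtol=1e-8, atol=1e-8)
        b = hs.integrate_ode(m, m.reference_params, patterns[0], rtol=1e-9, atol=1e-9)
        np.testing.assert_allclose(a.output, b.output, rtol=1e-4)


def test_integration_error_carries_set_id(m1, patterns):
    bad = np.array([np.exp(5.0)] * 3)  # fast corner, tiny budget forces failure
    with pytest.raises(hs.IntegrationError) as exc:
        hs.integrate_ode(m1, bad, patterns[0], max_steps=3, method="rk45",
                         set_id="set-7")
    assert exc.value.set_id == "set-7"


# ---------------------------------------------------------------------------
# stochastic


def test_ou_moments_match_closed_form():
    """Euler-Maruyama on dX = -kX dt + sigma dW reproduces OU mean/variance."""
    k, sigma, x0 = 0.5, 0.8, 5.0
    times = np.array([1.0, 5.0, 20.0])
    n = 5000
    _, x = hs.euler_maruyama(lambda x, t: -k * x, lambda x, t: sigma, x0,
                             dt=0.01, t_end=20.0, n_replicates=n, seed=99,
                             sample_times=times)
    mean_th = x0 * np.exp(-k * times)
    var_th = sigma ** 2 / (2 * k) * (1 - np.exp(-2 * k * times))
    se_mean = np.sqrt(var_th / n)
    se_var = var_th * np.sqrt(2.0 / (n - 1))
    assert np.all(np.abs(x.mean(axis=0) - mean_th) < 3 * se_mean)
    assert np.all(np.abs(x.var(axis=0, ddof=1) - var_th) < 3 * se_var)


def test_cle_zero_noise_equals_ode(m1, patterns):
    traj = hs.simulate_cle(m1, m1.reference_params, patterns[0], dt=0.01,
                           seed=1, noise_scale=0.0)
    ode = hs.integrate_ode(m1, m1.reference_params, patterns[0])
    np.testing.assert_allclose(traj.output, ode.output, rtol=2e-3)


def test_cle_seed_determinism(m1, patterns):
    a = hs.simulate_cle(m1, m1.reference_params, patterns[1], dt=0.05, seed=123)
    b = hs.simulate_cle(m1, m1.reference_params, patterns[1], dt=0.05, seed=123)
    np.testing.assert_array_equal(a.output, b.output)
    c = hs.simulate_cle(m1, m1.reference_params, patterns[1], dt=0.05, seed=124)
    assert not np.array_equal(a.output, c.output)


def test_cle_ensemble_mean_tracks_ode(m1, patterns):
    """Weak consistency: ensemble mean near the ODE solution within MC error."""
    out = hs.cle_ensemble(m1, m1.reference_params, patterns[0], n_replicates=200,
                          dt=0.02, seed=5)
    ode = hs.integrate_ode(m1, m1.reference_params, patterns[0])
    se = out.std(axis=0, ddof=1) / np.sqrt(out.shape[0])
    assert np.all(np.abs(out.mean(axis=0) - ode.output) < 5 * se + 0.005 * ode.output)


def test_cle_weak_convergence_in_dt(m1, patterns):
    """Halving dt moves the ensemble mean by less than the Monte-Carlo SE."""
    kw = dict(n_replicates=150, t_end=120.0, sample_times=[60.0, 120.0], seed=21)
    coarse = hs.cle_ensemble(m1, m1.reference_params, patterns[0], dt=0.05, **kw)
    fine = hs.cle_ensemble(m1, m1.reference_params, patterns[0], dt=0.025, **kw)
    se = np.sqrt(coarse.var(axis=0, ddof=1) / 150 + fine.var(axis=0, ddof=1) / 150)
    assert np.all(np.abs(coarse.mean(axis=0) - fine.mean(axis=0)) < 3 * se)


def test_control_data_se_and_determinism(m1_control, m1):
    np.testing.assert_allclose(m1_control.se,
                               m1_control.sd / np.sqrt(m1_control.n_replicates))
    assert m1_control.sample_times.tolist() == list(np.arange(30.0, 301.0, 30.0))
    assert len(m1_control.sample_times) == 10
    again = hs.generate_control_data(m1, n_replicates=100, dt=0.01, seed=2024)
    np.testing.assert_array_equal(again.mean, m1_control.mean)
    np.testing.assert_array_equal(again.sd, m1_control.sd)


def test_control_data_low_noise_limit(m1, patterns):
    ctrl = hs.generate_control_data(m1, n_replicates=10, dt=0.02, seed=3,
                                    noise_scale=1e-6)
    ode = hs.simulate_patterns(m1, m1.reference_params)
    # fixed-step Euler carries an O(dt) deterministic bias; relative error
    # accumulates on decaying tails, hence the small absolute allowance
    np.testing.assert_allclose(ctrl.mean, ode, rtol=5e-3, atol=0.05)
    assert ctrl.sd.max() < 1e-2


def test_dt_must_divide_sampling_interval(m1, patterns):
    with pytest.raises(ValueError):
        hs.simulate_cle(m1, m1.reference_params, patterns[0], dt=7.0, seed=1)
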