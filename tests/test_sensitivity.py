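"""Time-integral target and forward-difference log-sensitivities."""
import numpy as np
import pytest
import sympy

import hubsens as hs
from hubsens.models import build_linear_toy
from hubsens.sensitivity import build_sensitivity_table, local_sensitivity, time_integral
from hubsens.simulate import Trajectory


def _traj(times, values):
    return Trajectory("T", np.asarray(times, float), np.asarray(values, float)[:, None],
                      ("Xa",), np.asarray(values, float))


def test_time_integral_constant_and_ramp():
    t = np.linspace(0, 300, 601)
    assert time_integral(_traj(t, np.full_like(t, 2.5))) == pytest.approx(750.0)
    assert time_integral(_traj(t, t)) == pytest.approx(45000.0)


def test_time_integral_exponential_oracle():
    t = np.linspace(0, 300, 20001)
    q = time_integral(_traj(t, np.exp(-t)))
    # composite trapezoid converges as h^2; h = 0.015 gives ~2e-5 relative
    assert q == pytest.approx(1.0 - np.exp(-300.0), rel=1e-4)


def test_time_integral_rejects_empty():
    with pytest.raises(ValueError):
        time_integral(_traj([1.0], [2.0]))


def test_toy_sensitivity_k1_is_exactly_one(constant_signal, rng):
    """q is proportional to k1, so d ln q / d ln k1 = 1 to rounding error."""
    for _ in range(10):
        k1 = float(np.exp(rng.uniform(-2, 2)))
        k2 = float(np.exp(rng.uniform(-5, -1)))
        toy = build_linear_toy(k1, k2)
        s = local_sensitivity(toy, toy.reference_params, constant_signal)
        assert s["A"] == pytest.approx(1.0, abs=1e-9)


def test_toy_sensitivity_k2_matches_symbolic_derivative(constant_signal):
    """Closed form q(k2) = (k1/k2)(300 - (1 - e^{-300 k2})/k2), differentiated
    symbolically, is the oracle for the forward-difference estimate."""
    k1v, k2v = 2.0, 0.02
    k2 = sympy.symbols("k2", positive=True)
    q = (k1v / k2) * (300 - (1 - sympy.exp(-300 * k2)) / k2)
    slog = sympy.simplify(k2 * sympy.diff(q, k2) / q)
    expected = float(slog.subs(k2, k2v))
    toy = build_linear_toy(k1v, k2v)
    s = local_sensitivity(toy, toy.reference_params, constant_signal)
    assert s["D"] == pytest.approx(expected, abs=1e-3)


def test_forward_difference_tracks_central_difference(m1, patterns, rng):
    """One-sided 0.1% difference within 5% of a central-difference oracle."""
    pat = patterns[2]
    for _ in range(5):
        p = {k: v * float(np.exp(rng.uniform(-0.2, 0.2)))
             for k, v in m1.reference_params.items()}
        fwd = local_sensitivity(m1, p, pat)
        for rxn, kname in zip(m1.reaction_labels, m1.rate_constant_names):
            h = 0.001
            qs = {}
            for mult in (1 - h, 1 + h):
                pp = dict(p); pp[kname] *= mult
                traj = hs.integrate_ode(m1, pp, pat,
                                        sample_times=np.linspace(0, 300, 601),
                                        max_step=0.5)
                qs[mult] = np.trapezoid(traj.output, traj.times)
            central = (qs[1 + h] - qs[1 - h]) / (2 * h * np.trapezoid(
                hs.integrate_ode(m1, p, pat, sample_times=np.linspace(0, 300, 601),
                                 max_step=0.5).output, np.linspace(0, 300, 601)))
            assert fwd[rxn] == pytest.approx(central, rel=0.05, abs=1e-4)


def test_sensitivity_invariant_to_output_rescaling(constant_signal):
    """s_log is a ratio of integrals of the same trajectory: any positive
    rescaling of the output (e.g. the alpha scale) cancels exactly."""
    toy = build_linear_toy(3.0, 0.04)
    s1 = local_sensitivity(toy, toy.reference_params, constant_signal)
    scaled = build_linear_toy(3.0 * 7.3, 0.04)  # k1 scales the output linearly
    s2 = local_sensitivity(scaled, scaled.reference_params, constant_signal)
    assert s1["D"] == pytest.approx(s2["D"], rel=1e-9)


def test_table_cardinality_and_partition(m1, patterns):
    sets = [hs.ParameterSet.from_values(m1, m1.reference_params, id="a",
                                        provenance="original", label="positive"),
            hs.ParameterSet.from_values(
                m1, {"k1": 40.0, "km1": 150.0, "k2a": 0.04}, id="b",
                provenance="random", label="negative")]
    table = build_sensitivity_table(m1, sets, patterns)
    assert len(table) == 2 * 10 * 2  # sets x patterns x reactions
    pos = table[table["label"] == "positive"]
    assert set(pos["set_id"]) == {"a"}
    assert (table["q"] > 0).all()


def test_failed_base_integration_excludes_whole_set(m1, patterns):
    good = hs.ParameterSet.from_values(m1, m1.reference_params, id="ok",
                                       provenance="original", label="positive")
    bad = hs.ParameterSet(id="bad", model_id="M1", param_names=m1.param_names,
                          log_values=np.array([5.0, -15.0, 5.0]), label="negative")
    table = build_sensitivity_table(m1, [good, bad], patterns[:2], rtol=1e-6,
                                    atol=1e-6)
    # the stiff set is either excluded or solved by the fallback; the good
    # set must contribute exactly its 2 patterns x 2 reactions
    assert len(table[table["set_id"] == "ok"]) == 4


def test_empty_input_gives_empty_table(m1):
    table = build_sensitivity_table(m1, [])
    assert len(table) == 0
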