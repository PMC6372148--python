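"""Cosine fitness, scaling factor, band classification."""
import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st_h

import hubsens as hs
from hubsens.fit import classify, cosine_fitness, scaling_factor
from hubsens.simulate import ControlData


def _control(mean, sd, n=1000):
    mean = np.atleast_2d(np.asarray(mean, float))
    sd = np.atleast_2d(np.asarray(sd, float))
    return ControlData("M1", tuple(f"S{i+1}" for i in range(mean.shape[0])),
                       np.arange(30.0, 30.0 * (mean.shape[1] + 1), 30.0),
                       mean, sd, sd / np.sqrt(n), n, 0.01, 0)


@pytest.mark.parametrize("sim,ctrl,expected", [
    ([[1.0, 2.0]], [[2.0, 4.0]], 0.0),          # collinear
    ([[1.0, 0.0]], [[0.0, 1.0]], 1.0),          # orthogonal
    ([[1.0, 1.0]], [[1.0, 0.0]], 0.5),          # cos^2(45 deg)
])
def test_cosine_fitness_reference_values(sim, ctrl, expected):
    assert cosine_fitness(np.array(sim), np.array(ctrl)) == pytest.approx(expected)


def test_cosine_fitness_bounded_by_pattern_count(rng):
    sim = rng.normal(size=(10, 10))
    ctrl = rng.normal(size=(10, 10))
    f = cosine_fitness(sim, ctrl)
    assert 0.0 <= f <= 10.0


def test_zero_norm_sim_counts_as_orthogonal():
    f = cosine_fitness(np.zeros((1, 4)), np.ones((1, 4)))
    assert f == pytest.approx(1.0)


def test_zero_norm_control_is_configuration_error():
    with pytest.raises(ValueError):
        cosine_fitness(np.ones((1, 4)), np.zeros((1, 4)))


@settings(max_examples=50, deadline=None)
@given(st_h.floats(min_value=1e-6, max_value=1e6),
       st_h.integers(min_value=0, max_value=10 ** 6))
def test_cosine_fitness_scale_invariance(c, seed):
    rng = np.random.default_rng(seed)
    sim = rng.normal(size=(3, 10))
    ctrl = rng.normal(size=(3, 10)) + 2.0
    assert cosine_fitness(c * sim, ctrl) == pytest.approx(cosine_fitness(sim, ctrl),
                                                          rel=1e-9)


def test_scaling_factor_identities(rng):
    sim = rng.normal(size=10)
    ctrl = 2.0 * sim
    assert scaling_factor(sim, ctrl) == pytest.approx(2.0)
    unit = sim / np.linalg.norm(sim)
    assert scaling_factor(unit, ctrl) == pytest.approx(np.linalg.norm(ctrl))
    a = scaling_factor(sim, ctrl)
    assert a * np.linalg.norm(sim) == pytest.approx(np.linalg.norm(ctrl))
    with pytest.raises(ZeroDivisionError):
        scaling_factor(np.zeros(4), ctrl[:4])


def test_classify_center_of_band_positive():
    mean = np.arange(1.0, 11.0)[None, :]
    ctrl = _control(mean, np.full_like(mean, 0.5))
    rep = classify(0.37 * mean, ctrl)  # scaled copy of the mean itself
    assert rep.label == "positive"
    assert rep.alpha_per_pattern[0] == pytest.approx(1 / 0.37)


def test_classify_single_point_violation_is_negative():
    mean = np.full((1, 10), 100.0)
    sd = np.full((1, 10), 1.0)
    sim = mean.copy()
    sim[0, 4] += 10.0  # pushes one time point out after alpha-scaling
    rep = classify(sim, _control(mean, sd))
    assert rep.label == "negative"
    assert rep.pattern_pass_mask.sum() == 0


def test_classify_monotone_in_band_width(rng):
    mean = np.abs(rng.normal(100, 10, size=(3, 10))) + 50
    sd = np.full_like(mean, 2.0)
    sim = mean + rng.normal(0, 1.0, size=mean.shape)
    narrow = classify(sim, _control(mean, sd, n=1000), band="se")
    wide = classify(sim, _control(mean, sd, n=1000), band="sd")
    if narrow.label == "positive":
        assert wide.label == "positive"


def test_excluded_sets_are_neither_class(m1, m1_control):
    ps = hs.ParameterSet(id="bad", model_id="M1", param_names=m1.param_names,
                         log_values=np.array([5.0, -15.0, 5.0]))
    rep = hs.evaluate_parameter_set(m1, ps, m1_control, max_steps=5, method="rk45")
    assert rep.excluded and rep.label == "excluded"


def test_original_set_positive_under_sd_band(m1, m1_control):
    orig = hs.ParameterSet.from_values(m1, m1.reference_params, id="orig",
                                       provenance="original")
    rep = hs.evaluate_parameter_set(m1, orig, m1_control, band="sd")
    assert rep.label == "positive"
    assert 0 <= rep.fitness <= 10
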