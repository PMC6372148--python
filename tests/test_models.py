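"""Model definitions: structure, conservation, rate-law evaluation vs oracles."""
import numpy as np
import pytest

import hubsens as hs
from hubsens.models import evaluate_rates


def test_build_model_structures(models):
    assert models["M1"].reaction_labels == ("A", "D")
    assert len(models["M1"].pools) == 1
    assert models["M2"].reaction_labels == ("A", "D", "R")
    assert "FBA" in models["M3"].reaction_labels
    for lbl in ("FFA", "FFR", "D", "DS"):
        assert lbl in models["M4"].reaction_labels


def test_unknown_model_id_is_fatal():
    with pytest.raises(KeyError):
        hs.build_model("M9")


def test_parameter_names_unique_per_reaction(models):
    for m in models.values():
        names = m.param_names
        assert len(names) == len(set(names))


def test_stoichiometry_conserves_pools(models, rng):
    """Conservation vector . (v a) == 0 for every model at random states/params."""
    for m in models.values():
        v = m.stoichiometry()
        idx = {s: i for i, s in enumerate(m.species)}
        for pool in m.pools:
            cons = np.zeros(m.n_species)
            for sp in pool.members:
                cons[idx[sp]] = 1.0
            for _ in range(5):
                state = rng.uniform(0, 500, m.n_species)
                a = evaluate_rates(m, state, s=0.7, params=m.reference_params)
                assert abs(cons @ (v @ a)) < 1e-10


# ---- independent scalar transcription of every rate law ----------------

def _oracle_rates(mid, st, s, p):
    """Hand-written formulas, one per model, independent of ReactionSpec.rate."""
    if mid == "M1":
        return [p["k1"] * s * st["X"] / (p["km1"] + st["X"]),
                p["k2a"] * st["Xa"]]
    if mid == "M2":
        return [p["k1"] * s * st["X"] / (p["km1"] + st["X"]),
                p["k2a"] * st["Xa"],
                p["k3"] * st["Y"] / (p["km3"] + st["Y"])]
    if mid == "M3":
        return [p["k1"] * s * st["X"] / (p["km1"] + st["X"]),
                p["k2b"] * st["Xa"] * st["Ya"],
                p["k3"] * st["Xa"] * st["Y"] / (p["km3"] + st["Y"]),
                p["k4"] * st["Ya"]]
    if mid == "M4":
        return [p["k1"] * s * st["X"] / (p["km1"] + st["X"]),
                p["k2a"] * st["Xa"],
                p["k2b"] * st["Ya"] * st["Xa"] / (p["km2"] + st["Xa"]),
                p["k3"] * s * st["Y"] / (p["km3"] + st["Y"]),
                p["k4"] * st["Ya"]]
    raise KeyError(mid)


def test_evaluate_rates_matches_hand_transcription(models, rng):
    for mid, m in models.items():
        for _ in range(5):
            state = dict(zip(m.species, rng.uniform(0, 800, m.n_species)))
            s = float(rng.uniform(0, 1))
            got = evaluate_rates(m, state, s, m.reference_params)
            expected = _oracle_rates(mid, state, s, dict(m.reference_params))
            np.testing.assert_allclose(got, expected, rtol=1e-12)


def test_rates_nonnegative_and_zero_at_zero_substrate(models):
    for m in models.values():
        zero = {sp: 0.0 for sp in m.species}
        a = evaluate_rates(m, zero, 1.0, m.reference_params)
        np.testing.assert_array_equal(a, np.zeros(m.n_reactions))


def test_michaelis_menten_half_saturation(m1):
    p = dict(m1.reference_params)
    half = evaluate_rates(m1, {"X": p["km1"], "Xa": 0.0}, 1.0, p)[0]
    sat = p["k1"]  # substrate -> infinity limit of k1*s*X/(km1+X) at s=1
    assert half == pytest.approx(sat / 2)


def test_mass_action_linear_in_rate_constant(m1):
    p = dict(m1.reference_params)
    st = {"X": 100.0, "Xa": 321.0}
    base = evaluate_rates(m1, st, 1.0, p)[1]
    p["k2a"] *= 2
    assert evaluate_rates(m1, st, 1.0, p)[1] == pytest.approx(2 * base)


def test_domain_errors(m1):
    with pytest.raises(ValueError):
        evaluate_rates(m1, {"X": -1.0, "Xa": 0.0}, 1.0, m1.reference_params)
    bad = dict(m1.reference_params, k1=0.0)
    with pytest.raises(ValueError):
        evaluate_rates(m1, {"X": 1.0, "Xa": 0.0}, 1.0, bad)


def test_compiled_full_state_reconstruction(models):
    for m in models.values():
        cm = m.compile()
        y_dyn = cm.y0_dyn + 10.0
        full = cm.full_state(y_dyn)
        for pool in m.pools:
            idx = {s: i for i, s in enumerate(m.species)}
            total = sum(full[idx[sp]] for sp in pool.members)
            assert total == pytest.approx(pool.total)
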