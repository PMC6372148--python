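"""Ensemble statistics: PCA, z-scores, dominance, ratios, correlations."""
import numpy as np
import pandas as pd
import pytest

from hubsens.trend_stats import (integral_sensitivity_correlation, pairwise_dominance,
                                 pca, sensitivity_ratio, zscore_across_reactions)


def _table(values, label="positive", pattern="S1", q=None):
    """Long table from a dict reaction -> per-set value list."""
    rows = []
    n = len(next(iter(values.values())))
    for i in range(n):
        for rxn, vals in values.items():
            rows.append((f"set{i}", label, pattern, rxn,
                         1.0 if q is None else q[i], vals[i]))
    return pd.DataFrame(rows, columns=["set_id", "label", "pattern", "reaction",
                                       "q", "s_log"])


# ---- PCA ------------------------------------------------------------------

def test_pca_rank_one_data(rng):
    t = rng.normal(size=200)
    x = np.c_[t, 2 * t]
    res = pca(x, standardize=False)
    assert res.explained_variance_ratio[0] == pytest.approx(1.0)


def test_pca_isotropic_gaussian(rng):
    x = rng.normal(size=(10000, 2))
    res = pca(x, standardize=False)
    assert res.explained_variance_ratio == pytest.approx([0.5, 0.5], abs=0.03)


def test_pca_reconstruction_identity(rng):
    x = rng.normal(size=(50, 4)) @ rng.normal(size=(4, 4))
    res = pca(x, standardize=False)
    recon = res.scores @ res.loadings.T + x.mean(axis=0)
    np.testing.assert_allclose(recon, x, atol=1e-10)
    # components orthonormal, ratios non-increasing
    np.testing.assert_allclose(res.loadings.T @ res.loadings, np.eye(4), atol=1e-10)
    assert np.all(np.diff(res.explained_variance_ratio) <= 1e-12)
    assert res.explained_variance_ratio.sum() <= 1.0 + 1e-12


def test_pca_sign_convention(rng):
    x = rng.normal(size=(100, 3))
    res = pca(x)
    for c in range(res.loadings.shape[1]):
        jmax = np.argmax(np.abs(res.loadings[:, c]))
        assert res.loadings[jmax, c] > 0


def test_pca_input_validation():
    with pytest.raises(ValueError):
        pca(np.ones((1, 3)))
    with pytest.raises(ValueError):
        pca(np.array([[1.0, np.nan], [2.0, 3.0]]))


# ---- z-scores -------------------------------------------------------------

def test_zscore_three_reactions():
    tab = _table({"A": [1.0], "B": [2.0], "C": [3.0]})
    z = zscore_across_reactions(tab, "S1").iloc[0]
    np.testing.assert_allclose(sorted(z), [-1.0, 0.0, 1.0])


def test_zscore_two_reactions_is_pm_0707():
    tab = _table({"A": [1.0], "D": [5.0]})
    z = zscore_across_reactions(tab, "S1").iloc[0]
    np.testing.assert_allclose(sorted(z), [-np.sqrt(0.5), np.sqrt(0.5)])


def test_zscore_location_invariance_and_row_moments(rng):
    vals = {r: list(rng.normal(size=20)) for r in "ABCD"}
    tab = _table(vals)
    z = zscore_across_reactions(tab, "S1")
    shifted = _table({r: [v + 13.7 for v in vs] for r, vs in vals.items()})
    z2 = zscore_across_reactions(shifted, "S1")
    np.testing.assert_allclose(z.to_numpy(), z2.to_numpy(), atol=1e-9)
    np.testing.assert_allclose(z.mean(axis=1), 0.0, atol=1e-12)
    np.testing.assert_allclose(z.std(axis=1, ddof=1), 1.0, atol=1e-12)


def test_zscore_degenerate_row_is_zeros():
    tab = _table({"A": [2.0], "B": [2.0]})
    z = zscore_across_reactions(tab, "S1")
    np.testing.assert_array_equal(z.to_numpy(), [[0.0, 0.0]])


# ---- dominance ------------------------------------------------------------

def test_dominance_forced_ordering(rng):
    a = rng.normal(5, 1, 40)
    tab = _table({"A": list(a), "D": list(a - 3)})
    dom = pairwise_dominance(tab, "S1")
    row = dom[(dom["upper"] == "A") & (dom["left"] == "D")].iloc[0]
    assert row["pct_greater"] == 100.0 and row["pct_less"] == 0.0
    assert row["pct_equal"] == 0.0


def test_dominance_all_ties(rng):
    a = list(rng.normal(size=30))
    dom = pairwise_dominance(_table({"A": a, "D": a}), "S1")
    assert (dom["pct_equal"] == 100.0).all()


def test_dominance_antisymmetry_and_total(rng):
    vals = {r: list(rng.normal(size=37)) for r in ("A", "D", "R")}
    dom = pairwise_dominance(_table(vals), "S1").set_index(["upper", "left"])
    for (u, l), row in dom.iterrows():
        assert row["pct_greater"] == dom.loc[(l, u), "pct_less"]
        assert row["pct_greater"] + row["pct_less"] + row["pct_equal"] == 100.0


def test_dominance_requires_positive_sets():
    with pytest.raises(ValueError):
        pairwise_dominance(_table({"A": [1.0], "D": [2.0]}, label="negative"), "S1")


# ---- ratios and correlation ------------------------------------------------

def test_sensitivity_ratio_identities():
    tab = _table({"A": [2.0, -4.0], "B": [2.0, 1.0]})
    r = sensitivity_ratio(tab, ("A", "B"), pattern="S1")
    np.testing.assert_allclose(r.to_numpy(), [0.0, 2.0])
    r_swap = sensitivity_ratio(tab, ("B", "A"), pattern="S1")
    np.testing.assert_allclose(r.to_numpy(), -r_swap.to_numpy())


def test_sensitivity_ratio_drops_zero_denominator():
    tab = _table({"A": [1.0, 1.0], "B": [0.0, 2.0]})
    r = sensitivity_ratio(tab, ("A", "B"), pattern="S1")
    assert len(r) == 1


def test_correlation_exact_linear_cases(rng):
    q = list(rng.uniform(1, 10, 30))
    tab = _table({"A": [2 * x + 1 for x in q], "D": [-x for x in q]}, q=q)
    corr = integral_sensitivity_correlation(tab).set_index("reaction")
    assert corr.loc["A", "pearson_r"] == pytest.approx(1.0)
    assert corr.loc["D", "pearson_r"] == pytest.approx(-1.0)


def test_correlation_null_case(rng):
    q = list(rng.uniform(1, 10, 1000))
    tab = _table({"A": list(rng.normal(size=1000))}, q=q)
    r = integral_sensitivity_correlation(tab)["pearson_r"].iloc[0]
    assert abs(r) < 0.1


def test_correlation_degenerate_reported_missing():
    tab = _table({"A": [1.0, 1.0, 1.0]}, q=[1.0, 2.0, 3.0])
    assert np.isnan(integral_sensitivity_correlation(tab)["pearson_r"].iloc[0])
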