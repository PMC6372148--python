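"""Downstream statistics over the sensitivity table.

All of the ensemble-level summaries: PCA of sensitivity strengths and of
log-parameter values, per-set z-scores across reactions, pairwise dominance
percentages (how often one reaction's sensitivity exceeds another's across
the reproducible sets), pairwise log2 sensitivity-magnitude ratios, and the
Pearson correlation between the output integral and the sensitivity.
"""
from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats as sps
from sklearn.decomposition import PCA as _SKPCA

__all__ = ["PCAResult", "pca", "sensitivity_matrix", "zscore_across_reactions",
           "pairwise_dominance", "sensitivity_ratio", "integral_sensitivity_correlation"]


@dataclass
class PCAResult:
    scores: np.ndarray                  # observations x components
    loadings: np.ndarray                # variables x components
    explained_variance_ratio: np.ndarray
    columns: tuple[str, ...] = ()
    index: tuple = ()


def pca(matrix, *, standardize: bool = True, n_components: int | None = None) -> PCAResult:
    """PCA via SVD of the (optionally column-standardised) centred matrix.

    Standardising (correlation PCA) is the default because sensitivity
    magnitudes differ between reactions by orders of magnitude.  Component
    signs are fixed so the largest-magnitude loading of each component is
    positive, making results deterministic.
    """
    if isinstance(matrix, pd.DataFrame):
        cols = tuple(map(str, matrix.columns))
        index = tuple(matrix.index)
        x = matrix.to_numpy(dtype=float)
    else:
        x = np.asarray(matrix, dtype=float)
        cols = tuple(f"v{i}" for i in range(x.shape[1]))
        index = tuple(range(x.shape[0]))
    if x.ndim != 2 or x.shape[0] < 2 or x.shape[1] < 2:
        raise ValueError("PCA needs at least 2 observations and 2 variables")
    if np.isnan(x).any():
        raise ValueError("PCA input contains missing values")
    if standardize:
        sd = x.std(axis=0, ddof=1)
        sd[sd == 0] = 1.0
        x = (x - x.mean(axis=0)) / sd
    model = _SKPCA(n_components=n_components, svd_solver="full")
    scores = model.fit_transform(x)
    loadings = model.components_.T.copy()
    for c in range(loadings.shape[1]):
        jmax = int(np.argmax(np.abs(loadings[:, c])))
        if loadings[jmax, c] < 0:
            loadings[:, c] *= -1.0
            scores[:, c] *= -1.0
    return PCAResult(scores, loadings, model.explained_variance_ratio_, cols, index)


def sensitivity_matrix(table: pd.DataFrame, *, label_filter: str | None = None,
                       pattern: str | None = None) -> pd.DataFrame:
    """Pivot the long table to sets x (reaction[, pattern]) wide form.

    Sets with any missing cell are dropped (keeps the matrix complete).
    """
    df = table
    if label_filter is not None:
        df = df[df["label"] == label_filter]
    if pattern is not None:
        df = df[df["pattern"] == pattern]
        wide = df.pivot_table(index="set_id", columns="reaction", values="s_log")
    else:
        wide = df.pivot_table(index="set_id", columns=["pattern", "reaction"],
                              values="s_log")
    return wide.dropna(axis=0)


def zscore_across_reactions(table: pd.DataFrame, pattern: str, *,
                            label_filter: str | None = "positive",
                            ddof: int = 1) -> pd.DataFrame:
    """Per-set z-score of s_log across the model's reactions at one pattern.

    Each row (parameter set) is centred and scaled by its own mean/SD over
    reactions, so rows have mean 0 and SD 1; rows with zero spread become all
    zeros.  ``ddof=1`` (sample SD) by default, ``ddof=0`` for population SD.
    """
    wide = sensitivity_matrix(table, label_filter=label_filter, pattern=pattern)
    if wide.shape[1] < 2:
        raise ValueError("z-score needs at least 2 reactions")
    mu = wide.mean(axis=1)
    sd = wide.std(axis=1, ddof=ddof)
    sd = sd.replace(0.0, np.nan)
    z = wide.sub(mu, axis=0).div(sd, axis=0).fillna(0.0)
    return z


def pairwise_dominance(table: pd.DataFrame, pattern: str, *,
                       label_filter: str = "positive", use_magnitude: bool = False,
                       tie_rel_tol: float = 1e-9) -> pd.DataFrame:
    """Percentage of sets in which the *upper* reaction's sensitivity exceeds
    the *left* reaction's, per ordered reaction pair.

    Ties are counted when the two values agree within ``tie_rel_tol`` relative
    tolerance (structurally identical reactions produce exact ties).  The
    three percentages sum to exactly 100 per cell.  ``use_magnitude``
    compares |s_log| ("sensitivity strength") instead of signed values.
    """
    wide = sensitivity_matrix(table, label_filter=label_filter, pattern=pattern)
    if wide.shape[0] < 1:
        raise ValueError("no parameter sets with the requested label; relax the band "
                         "or enlarge the search")
    vals = wide.to_numpy()
    if use_magnitude:
        vals = np.abs(vals)
    reactions = list(wide.columns)
    rows = []
    n = vals.shape[0]
    for i, j in combinations(range(len(reactions)), 2):
        a, b = vals[:, i], vals[:, j]
        tol = tie_rel_tol * np.maximum(np.abs(a), np.abs(b))
        eq = np.abs(a - b) <= tol
        gt = (a > b) & ~eq
        lt = (a < b) & ~eq
        pg = 100.0 * gt.sum() / n
        pl = 100.0 * lt.sum() / n
        rows.append((reactions[i], reactions[j], pg, pl, 100.0 - pg - pl))
        rows.append((reactions[j], reactions[i], pl, pg, 100.0 - pg - pl))
    return pd.DataFrame(rows, columns=["upper", "left", "pct_greater", "pct_less",
                                       "pct_equal"])


def sensitivity_ratio(table: pd.DataFrame, pair: tuple[str, str], *,
                      pattern: str | None = None,
                      label_filter: str | None = "positive") -> pd.Series:
    """Per-set log2 ratio of sensitivity magnitudes |s_A| / |s_B|.

    Zero denominators are dropped.  0 means equal magnitude; the ratio is
    antisymmetric under swapping the pair.
    """
    a, b = pair
    wide = sensitivity_matrix(table, label_filter=label_filter, pattern=pattern)
    if pattern is None:  # average magnitude over patterns if not restricted
        num = wide.xs(a, axis=1, level="reaction").abs().mean(axis=1)
        den = wide.xs(b, axis=1, level="reaction").abs().mean(axis=1)
    else:
        num, den = wide[a].abs(), wide[b].abs()
    keep = (den > 0) & (num > 0)
    return np.log2(num[keep] / den[keep]).rename(f"log2|{a}|/|{b}|")


def integral_sensitivity_correlation(table: pd.DataFrame, *,
                                     label_filter: str = "positive") -> pd.DataFrame:
    """Pearson r between the base integral q and s_log across sets.

    One correlation per (pattern, reaction) cell; cells with fewer than 3
    sets or zero variance are reported as NaN.
    """
    df = table[table["label"] == label_filter]
    rows = []
    for (pat, rxn), grp in df.groupby(["pattern", "reaction"], sort=False):
        q, s = grp["q"].to_numpy(float), grp["s_log"].to_numpy(float)
        if len(grp) < 3 or np.std(q) == 0 or np.std(s) == 0:
            r = np.nan
        else:
            r = float(sps.pearsonr(q, s).statistic)
        rows.append((pat, rxn, r, len(grp)))
    return pd.DataFrame(rows, columns=["pattern", "reaction", "pearson_r", "n"])
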