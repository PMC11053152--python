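"""Differential protein expression and small comparison utilities.

Group comparisons use a two-sided unpaired Welch's t test on log2 abundances
with Benjamini-Hochberg adjustment across the tested proteins; fold changes
are ratios of linear-scale group means.  Also provides direction-aware
overlap of two DEP tables, Tukey's-fences outlier trimming and pairwise
Pearson feature-fraction correlations.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .containers import AbundanceMatrix


def welch_test(values_a, values_b):
    """Welch's unequal-variance t test with Satterthwaite df.

    Returns ``(t, df, p)``; NaN triple when either group has fewer than two
    finite values.
    """
    a = np.asarray(values_a, float)
    b = np.asarray(values_b, float)
    a = a[np.isfinite(a)]
    b = b[np.isfinite(b)]
    if a.size < 2 or b.size < 2:
        return (np.nan, np.nan, np.nan)
    va, vb = a.var(ddof=1), b.var(ddof=1)
    if va == 0 and vb == 0:
        if a.mean() == b.mean():
            return (0.0, float(a.size + b.size - 2), 1.0)
        return (np.inf, float(a.size + b.size - 2), 0.0)
    sa, sb = va / a.size, vb / b.size
    t = (a.mean() - b.mean()) / np.sqrt(sa + sb)
    df = (sa + sb) ** 2 / (sa**2 / (a.size - 1) + sb**2 / (b.size - 1))
    p = 2.0 * stats.t.sf(abs(t), df)
    return (float(t), float(df), float(p))


def bh_adjust(pvals):
    """Benjamini-Hochberg step-up adjustment; NaNs pass through unchanged."""
    p = np.asarray(pvals, float)
    out = np.full(p.shape, np.nan)
    ok = np.isfinite(p)
    if ((p[ok] < 0) | (p[ok] > 1)).any():
        raise ValueError("p-values must lie in [0, 1]")
    if ok.sum():
        out[ok] = multipletests(p[ok], method="fdr_bh")[1]
    return out


def _welch_vectorized(A: np.ndarray, B: np.ndarray):
    """Row-wise Welch test on two (proteins x samples) arrays with NaNs."""
    def moments(X):
        n = np.sum(np.isfinite(X), axis=1)
        m = np.nanmean(np.where(np.isfinite(X), X, np.nan), axis=1)
        v = np.nanvar(np.where(np.isfinite(X), X, np.nan), axis=1, ddof=1)
        return n, m, v

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        na, ma, va = moments(A)
        nb, mb, vb = moments(B)
    valid = (na >= 2) & (nb >= 2)
    sa, sb = va / na, vb / nb
    with np.errstate(invalid="ignore", divide="ignore"):
        t = (ma - mb) / np.sqrt(sa + sb)
        df = (sa + sb) ** 2 / (sa**2 / (na - 1) + sb**2 / (nb - 1))
        p = 2.0 * stats.t.sf(np.abs(t), df)
    # zero-variance-in-both rows: t undefined; identical means -> p = 1
    degen = valid & (va == 0) & (vb == 0)
    t[degen & (ma == mb)] = 0.0
    p[degen & (ma == mb)] = 1.0
    p[degen & (ma != mb)] = 0.0
    t[~valid] = np.nan
    df[~valid] = np.nan
    p[~valid] = np.nan
    return t, df, p


def call_deps(matrix: AbundanceMatrix, group_a: str, group_b: str,
              fc_threshold: float = 1.5, alpha: float = 0.05,
              sample_subsets: dict | None = None) -> pd.DataFrame:
    """Call differential proteins between two groups.

    Fold change is the ratio of linear-scale group means (group_a over
    group_b); the Welch test runs on log2 values; BH adjustment spans all
    proteins tested in this comparison.  A protein is ``up`` when
    ``fc > fc_threshold`` and ``p_adj < alpha``, ``down`` when
    ``fc < 1/fc_threshold`` and ``p_adj < alpha``, otherwise ``ns``.

    ``sample_subsets`` may map group name -> explicit sample list (e.g. to
    restrict DEP calling to training-set patients).
    """
    def cols(g):
        if sample_subsets and g in sample_subsets:
            return list(sample_subsets[g])
        return matrix.samples_in_group(g)

    ca, cb = cols(group_a), cols(group_b)
    if not ca or not cb:
        raise ValueError(f"group(s) absent from matrix: {group_a if not ca else group_b}")

    log2 = matrix if matrix.scale == "log2" else matrix.to_log2()
    A = log2.values[ca].to_numpy(float)
    B = log2.values[cb].to_numpy(float)
    t, df, p = _welch_vectorized(A, B)

    lin = matrix.to_linear() if matrix.scale == "log2" else matrix
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        mean_a = np.nanmean(lin.values[ca].to_numpy(float), axis=1)
        mean_b = np.nanmean(lin.values[cb].to_numpy(float), axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        fc = mean_a / mean_b

    p_adj = bh_adjust(p)
    call = np.full(len(fc), "ns", dtype=object)
    sig = np.isfinite(p_adj) & (p_adj < alpha)
    call[sig & (fc > fc_threshold)] = "up"
    call[sig & (fc < 1.0 / fc_threshold)] = "down"
    table = pd.DataFrame(
        {
            "mean_" + group_a: mean_a,
            "mean_" + group_b: mean_b,
            "fc": fc,
            "log2fc": np.log2(fc, out=np.full_like(fc, np.nan), where=fc > 0),
            "t": t,
            "df": df,
            "p_raw": p,
            "p_adj": p_adj,
            "call": call,
        },
        index=matrix.protein_ids,
    )
    table.attrs.update(
        comparison=f"{group_a}_vs_{group_b}", fc_threshold=fc_threshold, alpha=alpha,
        n_up=int((call == "up").sum()), n_down=int((call == "down").sum()),
    )
    return table


def overlap_deps(dep_a: pd.DataFrame, dep_b: pd.DataFrame) -> dict:
    """Direction-aware overlap of two DEP tables sharing a protein universe."""
    sets = {}
    for direction in ("up", "down"):
        sa = set(dep_a.index[dep_a["call"] == direction])
        sb = set(dep_b.index[dep_b["call"] == direction])
        sets[f"co_{direction}"] = sa & sb
        sets[f"only_a_{direction}"] = sa - sb
        sets[f"only_b_{direction}"] = sb - sa
    sets["co_regulated"] = sets["co_up"] | sets["co_down"]
    return sets


def tukey_fences_filter(values, k: float = 1.5):
    """Retain values inside [Q1 - k*IQR, Q3 + k*IQR].

    Quartiles use linear interpolation.  Fewer than four finite values are
    returned unchanged with a warning.
    """
    if k <= 0:
        raise ValueError("k must be positive")
    v = np.asarray(values, float)
    v = v[np.isfinite(v)]
    if v.size < 4:
        warnings.warn("fewer than 4 values; Tukey's fences not applied")
        return v
    q1, q3 = np.percentile(v, [25, 75], method="linear")
    iqr = q3 - q1
    if not np.isfinite(k * iqr):  # k = inf with zero IQR
        return v
    return v[(v >= q1 - k * iqr) & (v <= q3 + k * iqr)]


def correlate_features(feature_matrix: pd.DataFrame,
                       fraction_matrix: pd.DataFrame) -> pd.DataFrame:
    """Pairwise Pearson correlations between feature and fraction columns.

    Rows are matched by index; each pair uses its complete observations and
    needs at least three of them, otherwise the result is NaN.  Returns a
    long-format table (feature, fraction, r, p, n).
    """
    common = feature_matrix.index.intersection(fraction_matrix.index)
    rows = []
    for f in feature_matrix.columns:
        x_all = feature_matrix.loc[common, f]
        for c in fraction_matrix.columns:
            y_all = fraction_matrix.loc[common, c]
            ok = x_all.notna() & y_all.notna()
            n = int(ok.sum())
            if n < 3 or x_all[ok].std() == 0 or y_all[ok].std() == 0:
                rows.append((f, c, np.nan, np.nan, n))
                continue
            r, p = stats.pearsonr(x_all[ok], y_all[ok])
            rows.append((f, c, float(r), float(p), n))
    return pd.DataFrame(rows, columns=["feature", "fraction", "r", "p", "n"])
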