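"""Quality control and normalisation of the protein abundance matrix.

The preprocessing chain, in the order the pipeline enforces:

    filter_by_missingness -> impute_sequential -> correct_batch
        -> replace_nonpositive (linear scale) -> merge_replicates

CV-based quality control (pooled channels, technical replicate pairs) can be
run at any point on the log2 matrix.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .containers import AbundanceMatrix


class DataError(ValueError):
    """Structural problem in the data (e.g. a protein with no usable values)."""


# ----------------------------------------------------------------------
# Quality control
# ----------------------------------------------------------------------
def compute_cv(matrix: AbundanceMatrix, sample_subset) -> pd.Series:
    """Per-protein coefficient of variation over a sample subset.

    Computed as sd/mean of the non-missing log2 abundances (sample standard
    deviation, ddof=1).  Proteins with fewer than two observed values, or a
    zero mean, yield NaN.
    """
    subset = list(sample_subset)
    if len(subset) == 0:
        raise ValueError("sample subset is empty")
    if len(subset) < 2:
        raise ValueError("CV needs at least two samples")
    log2 = matrix if matrix.scale == "log2" else matrix.to_log2()
    sub = log2.values[subset]
    mean = sub.mean(axis=1, skipna=True)
    sd = sub.std(axis=1, ddof=1, skipna=True)
    n_obs = sub.notna().sum(axis=1)
    cv = sd / mean
    cv[(n_obs < 2) | (mean == 0)] = np.nan
    return cv


@dataclass
class QCReport:
    """CVs across pooled channels and replicate pairs, plus NA rates."""

    pooled_cv: pd.Series                 # per protein, across all pooled channels
    replicate_cv: pd.DataFrame           # proteins x replicate pairs
    median_pooled_cv: float
    median_replicate_cv: pd.Series       # per pair
    na_rate: pd.Series                   # per protein, over tissue columns

    def to_dict(self) -> dict:
        return {
            "median_pooled_cv": self.median_pooled_cv,
            "median_replicate_cv": {
                k: float(v) for k, v in self.median_replicate_cv.items()
            },
            "n_proteins": int(len(self.na_rate)),
            "mean_na_rate": float(self.na_rate.mean()),
        }


def qc_report(matrix: AbundanceMatrix) -> QCReport:
    """CV quality control across pooled channels and technical replicate pairs."""
    pooled = matrix.samples_in_group("POOL")
    if len(pooled) >= 2:
        pooled_cv = compute_cv(matrix, pooled)
    else:
        pooled_cv = pd.Series(np.nan, index=matrix.protein_ids)

    pairs = {}
    if "replicate_of" in matrix.meta.columns:
        links = matrix.meta["replicate_of"].dropna()
        for rep, orig in links.items():
            if rep in matrix.values.columns and orig in matrix.values.columns:
                pairs[f"{orig}|{rep}"] = compute_cv(matrix, [orig, rep])
    replicate_cv = pd.DataFrame(pairs) if pairs else pd.DataFrame(index=matrix.protein_ids)

    tissue = [s for s in matrix.sample_ids if matrix.meta.loc[s, "group"] != "POOL"]
    na = matrix.values[tissue].isna().mean(axis=1)
    return QCReport(
        pooled_cv=pooled_cv,
        replicate_cv=replicate_cv,
        median_pooled_cv=float(pooled_cv.median()),
        median_replicate_cv=replicate_cv.median(),
        na_rate=na,
    )


# ----------------------------------------------------------------------
# Filtering
# ----------------------------------------------------------------------
def filter_by_missingness(matrix: AbundanceMatrix, max_na_rate: float = 0.85) -> AbundanceMatrix:
    """Drop proteins whose NA rate is strictly above ``max_na_rate``.

    Proteins exactly at the threshold are retained; row order is preserved.
    """
    if not (0 <= max_na_rate <= 1):
        raise ValueError("max_na_rate must lie in [0, 1]")
    keep = matrix.na_rate() <= max_na_rate
    out = matrix.copy()
    out.values = out.values.loc[keep]
    out.history = list(matrix.history) + ["filter"]
    return out


# ----------------------------------------------------------------------
# Imputation
# ----------------------------------------------------------------------
def _trimmed_lstsq(X: np.ndarray, y: np.ndarray, coverage: float) -> np.ndarray:
    """Least squares refit on the ``coverage`` fraction of points with the
    smallest absolute residuals from an initial full fit."""
    design = np.column_stack([np.ones(len(y)), X])
    beta, *_ = np.linalg.lstsq(design, y, rcond=None)
    n_keep = max(int(np.ceil(coverage * len(y))), design.shape[1])
    if n_keep < len(y):
        resid = np.abs(y - design @ beta)
        keep = np.argsort(resid, kind="stable")[:n_keep]
        beta, *_ = np.linalg.lstsq(design[keep], y[keep], rcond=None)
    return beta


def impute_sequential(matrix: AbundanceMatrix, top_k: int = 5,
                      coverage: float = 0.75) -> AbundanceMatrix:
    """Robust sequential-regression imputation.

    Proteins are processed in order of increasing missingness; each incomplete
    protein is regressed on the ``top_k`` already-completed proteins most
    correlated with it (over its observed samples), using a trimmed
    least-squares fit that refits on the ``coverage`` fraction of
    best-fitting points, and its gaps are filled from the fitted line.
    Observed entries are never changed; the procedure is deterministic.
    """
    vals = matrix.values.to_numpy(float).copy()
    n_missing = np.isnan(vals).sum(axis=1)
    all_missing = np.where(n_missing == vals.shape[1])[0]
    if len(all_missing):
        raise DataError(
            f"protein {matrix.protein_ids[all_missing[0]]} has no observed values"
        )
    if not np.isnan(vals).any():
        out = matrix.copy()
        out.history = list(matrix.history) + ["impute"]
        return out

    complete = np.where(n_missing == 0)[0]
    incomplete = np.argsort(n_missing, kind="stable")
    incomplete = [i for i in incomplete if n_missing[i] > 0]

    if len(complete) == 0:
        # seed the completed set with the least-missing protein, mean-filled
        i0 = incomplete.pop(0)
        row = vals[i0]
        row[np.isnan(row)] = np.nanmean(row)
        complete = np.array([i0])

    completed = list(complete)
    comp_mat = vals[completed]  # grows as proteins are completed

    for i in incomplete:
        row = vals[i]
        obs = ~np.isnan(row)
        y = row[obs]
        filled = False
        if y.size >= 3:
            Xo = comp_mat[:, obs]
            # Pearson correlation of each completed protein with y on obs
            Xc = Xo - Xo.mean(axis=1, keepdims=True)
            yc = y - y.mean()
            denom = np.sqrt((Xc**2).sum(axis=1) * (yc**2).sum())
            with np.errstate(invalid="ignore", divide="ignore"):
                r = (Xc @ yc) / denom
            r[~np.isfinite(r)] = 0.0
            k = min(top_k, len(completed), max(y.size - 2, 1))
            if k >= 1 and np.any(r != 0):
                top = np.argsort(-np.abs(r), kind="stable")[:k]
                beta = _trimmed_lstsq(Xo[top].T, y, coverage)
                pred = beta[0] + comp_mat[top][:, ~obs].T @ beta[1:]
                row[~obs] = pred
                filled = True
        if not filled:
            row[~obs] = y.mean()
        completed.append(i)
        comp_mat = np.vstack([comp_mat, row])

    out = matrix.copy()
    out.values = pd.DataFrame(vals, index=matrix.protein_ids, columns=matrix.sample_ids)
    out.history = list(matrix.history) + ["impute"]
    return out


def impute_half_min(matrix: AbundanceMatrix) -> AbundanceMatrix:
    """Fill each protein's gaps with half its minimum observed value.

    On the log2 scale this subtracts one from the minimum (half on the linear
    scale); provided as a simple baseline behind the same interface.
    """
    vals = matrix.values.to_numpy(float).copy()
    if np.isnan(vals).all(axis=1).any():
        raise DataError("a protein has no observed values")
    row_min = np.nanmin(vals, axis=1)
    fill = row_min - 1.0 if matrix.scale == "log2" else row_min / 2.0
    idx = np.where(np.isnan(vals))
    vals[idx] = fill[idx[0]]
    out = matrix.copy()
    out.values = pd.DataFrame(vals, index=matrix.protein_ids, columns=matrix.sample_ids)
    out.history = list(matrix.history) + ["impute"]
    return out


def impute_median(matrix: AbundanceMatrix) -> AbundanceMatrix:
    """Per-protein median fill; the baseline the sequential imputer must beat."""
    vals = matrix.values.to_numpy(float).copy()
    if np.isnan(vals).all(axis=1).any():
        raise DataError("a protein has no observed values")
    med = np.nanmedian(vals, axis=1)
    idx = np.where(np.isnan(vals))
    vals[idx] = med[idx[0]]
    out = matrix.copy()
    out.values = pd.DataFrame(vals, index=matrix.protein_ids, columns=matrix.sample_ids)
    out.history = list(matrix.history) + ["impute"]
    return out


IMPUTERS = {
    "sequential": impute_sequential,
    "half_min": impute_half_min,
    "median": impute_median,
}


# ----------------------------------------------------------------------
# Batch correction
# ----------------------------------------------------------------------
def correct_batch(matrix: AbundanceMatrix, parametric: bool = True,
                  covariates=None) -> AbundanceMatrix:
    """Empirical-Bayes (ComBat) location/scale batch correction.

    Operates on the complete log2 matrix; per-batch per-protein means and
    variances are shrunk toward pooled priors and removed.  ``covariates``
    may name columns of the sample metadata to protect (e.g. ``["group"]``).
    A single batch is returned unchanged.
    """
    if matrix.values.isna().any().any():
        raise DataError("batch correction requires a complete (imputed) matrix")
    if matrix.scale != "log2":
        raise ValueError("batch correction operates on the log2 scale")
    if not parametric:
        raise NotImplementedError("only the parametric prior is implemented")
    batches = matrix.meta.loc[matrix.sample_ids, "batch"]
    counts = batches.value_counts()
    if (counts < 2).any():
        small = counts[counts < 2].index.tolist()
        raise DataError(f"batches with fewer than two samples: {small}")
    if counts.size < 2:
        out = matrix.copy()
        out.history = list(matrix.history) + ["combat"]
        return out

    import anndata as ad
    import scanpy as sc

    obs = pd.DataFrame({"batch": batches.astype(str).to_numpy()},
                       index=matrix.sample_ids.astype(str))
    cov_names = None
    if covariates:
        cov_names = list(covariates)
        for c in cov_names:
            obs[c] = matrix.meta.loc[matrix.sample_ids, c].to_numpy()
    adata = ad.AnnData(
        X=matrix.values.to_numpy(float).T.copy(),
        obs=obs,
        var=pd.DataFrame(index=matrix.protein_ids.astype(str)),
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        sc.pp.combat(adata, key="batch", covariates=cov_names)
    out = matrix.copy()
    out.values = pd.DataFrame(adata.X.T, index=matrix.protein_ids,
                              columns=matrix.sample_ids)
    out.history = list(matrix.history) + ["combat"]
    return out


def batch_r2(matrix: AbundanceMatrix) -> pd.Series:
    """Per-protein R^2 of a one-way batch ANOVA (variance explained by batch)."""
    vals = matrix.values.to_numpy(float)
    batches = matrix.meta.loc[matrix.sample_ids, "batch"].to_numpy()
    grand = np.nanmean(vals, axis=1, keepdims=True)
    sst = np.nansum((vals - grand) ** 2, axis=1)
    ssb = np.zeros(vals.shape[0])
    for b in np.unique(batches):
        cols = batches == b
        bm = np.nanmean(vals[:, cols], axis=1)
        ssb += cols.sum() * (bm - grand[:, 0]) ** 2
    with np.errstate(invalid="ignore", divide="ignore"):
        r2 = ssb / sst
    return pd.Series(r2, index=matrix.protein_ids)


# ----------------------------------------------------------------------
# Linear-scale cleanup and replicate merging
# ----------------------------------------------------------------------
def replace_nonpositive(matrix: AbundanceMatrix) -> AbundanceMatrix:
    """Replace non-positive linear abundances by half the protein's minimum
    positive value.  Idempotent; errors on a protein with no positive value."""
    if matrix.scale != "linear":
        raise ValueError("replace_nonpositive operates on the linear scale")
    vals = matrix.values.to_numpy(float).copy()
    pos = np.where(vals > 0, vals, np.nan)
    no_positive = np.isnan(pos).all(axis=1) & ~np.isnan(vals).all(axis=1)
    if no_positive.any():
        pid = matrix.protein_ids[np.where(no_positive)[0][0]]
        raise DataError(f"protein {pid} has no positive abundance")
    half_min = np.nanmin(pos, axis=1) / 2.0
    bad = ~np.isnan(vals) & (vals <= 0)
    idx = np.where(bad)
    vals[idx] = half_min[idx[0]]
    out = matrix.copy()
    out.values = pd.DataFrame(vals, index=matrix.protein_ids, columns=matrix.sample_ids)
    if "replace_nonpositive" not in out.history:
        out.history = list(matrix.history) + ["replace_nonpositive"]
    return out


def merge_replicates(matrix: AbundanceMatrix) -> AbundanceMatrix:
    """Collapse each technical replicate pair to its element-wise mean and
    drop pooled reference channels, leaving one column per biological sample."""
    meta = matrix.meta
    vals = matrix.values
    links = meta["replicate_of"].dropna() if "replicate_of" in meta.columns else pd.Series(dtype=object)
    dangling = [r for r, o in links.items() if o not in vals.columns and r in vals.columns]
    if dangling:
        raise DataError(f"replicate columns with missing partner: {dangling}")
    new_vals = vals.copy()
    for rep, orig in links.items():
        if rep not in new_vals.columns:
            continue
        pair = vals[[orig, rep]]
        new_vals[orig] = pair.mean(axis=1, skipna=True)
        new_vals = new_vals.drop(columns=rep)
    pooled = [s for s in new_vals.columns if meta.loc[s, "group"] == "POOL"]
    new_vals = new_vals.drop(columns=pooled)
    new_meta = meta.loc[new_vals.columns].copy()
    new_meta["replicate_of"] = None
    out = AbundanceMatrix(new_vals, new_meta, matrix.scale,
                          list(matrix.history))
    if "merge" not in out.history:
        out.history.append("merge")
    return out
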