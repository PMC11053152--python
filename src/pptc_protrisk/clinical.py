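"""Clinical-feature recurrence-risk analysis.

Univariate and multivariate Cox proportional-hazards models over the eleven
clinical covariates, Kaplan-Meier curves with log-rank tests for median
splits of significant factors, and the continuous-vs-categorical age coding
comparison by global p, AIC and Harrell's C-index.

Fitting is delegated to lifelines (Efron handling of tied event times).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter, KaplanMeierFitter
from lifelines.statistics import logrank_test

from .containers import CLINICAL_FEATURES


@dataclass
class CoxResult:
    """Fitted Cox model summary.

    ``summary`` has one row per covariate: coef (log-HR), HR, ci_lower,
    ci_upper, p (Wald).  Model-level: global likelihood-ratio p, AIC
    (partial), Harrell C-index, sample and event counts.
    """

    summary: pd.DataFrame
    global_p: float
    aic: float
    c_index: float
    n: int
    n_events: int
    converged: bool = True
    warnings: list = field(default_factory=list)
    fitter: object = None

    def hr(self, covariate: str) -> float:
        return float(self.summary.loc[covariate, "HR"])

    def to_dict(self) -> dict:
        return {
            "covariates": {
                c: {
                    k: float(self.summary.loc[c, k])
                    for k in ("coef", "HR", "ci_lower", "ci_upper", "p")
                }
                for c in self.summary.index
            },
            "global_p": float(self.global_p),
            "aic": float(self.aic),
            "c_index": float(self.c_index),
            "n": self.n,
            "n_events": self.n_events,
            "converged": self.converged,
        }


def fit_cox(table: pd.DataFrame, covariates, duration_col: str = "time",
            event_col: str = "event", penalizer: float = 0.0) -> CoxResult:
    """Fit a Cox proportional-hazards model (Efron ties).

    Raises on a table with no events; non-convergence or separation is
    returned as a flagged result rather than an exception when lifelines can
    still produce estimates.
    """
    covariates = list(covariates)
    if table[event_col].sum() < 1:
        raise ValueError("cannot fit a Cox model with no events")
    for c in covariates:
        if table[c].nunique(dropna=True) < 2:
            raise ValueError(f"covariate {c!r} is constant")
    data = table[covariates + [duration_col, event_col]].astype(float)
    cph = CoxPHFitter(penalizer=penalizer)
    issues: list = []
    converged = True
    with warnings.catch_warnings(record=True) as caught:
        warnings.simplefilter("always")
        try:
            cph.fit(data, duration_col=duration_col, event_col=event_col)
        except Exception:
            # retry with a small ridge penalty (separation / collinearity)
            converged = False
            cph = CoxPHFitter(penalizer=0.1)
            cph.fit(data, duration_col=duration_col, event_col=event_col)
        issues = [str(w.message) for w in caught]

    s = cph.summary
    summary = pd.DataFrame(
        {
            "coef": s["coef"],
            "HR": s["exp(coef)"],
            "ci_lower": s["exp(coef) lower 95%"],
            "ci_upper": s["exp(coef) upper 95%"],
            "p": s["p"],
        }
    )
    lr = cph.log_likelihood_ratio_test()
    return CoxResult(
        summary=summary,
        global_p=float(lr.p_value),
        aic=float(cph.AIC_partial_),
        c_index=float(cph.concordance_index_),
        n=int(len(data)),
        n_events=int(data[event_col].sum()),
        converged=converged,
        warnings=issues,
        fitter=cph,
    )


def univariate_screen(table: pd.DataFrame, covariates=None,
                      alpha: float = 0.05) -> pd.DataFrame:
    """Univariate Cox model per covariate; flags those with Wald p < alpha."""
    covariates = list(covariates) if covariates is not None else list(CLINICAL_FEATURES)
    rows = []
    for c in covariates:
        res = fit_cox(table, [c])
        r = res.summary.loc[c]
        rows.append(
            (c, r["coef"], r["HR"], r["ci_lower"], r["ci_upper"], r["p"], r["p"] < alpha)
        )
    return pd.DataFrame(
        rows, columns=["covariate", "coef", "HR", "ci_lower", "ci_upper", "p", "significant"]
    ).set_index("covariate")


def categorize_age(ages, cutoff: float | None = None):
    """Binary age coding: 0 below the cutoff (default cohort median), 1 otherwise."""
    a = np.asarray(ages, float)
    if a.size == 0:
        return np.array([], dtype=int)
    if cutoff is None:
        cutoff = float(np.median(a))
    return (a >= cutoff).astype(int)


def median_split(values):
    """Label 0 below the sample median, 1 at or above it.

    Returns ``(labels, median)``; warns when all values are equal (single
    group).
    """
    v = np.asarray(values, float)
    if v.size < 2:
        raise ValueError("median split needs at least two values")
    med = float(np.median(v))
    labels = (v >= med).astype(int)
    if len(np.unique(labels)) == 1:
        warnings.warn("all values on one side of the median; single group")
    return labels, med


def km_logrank(table: pd.DataFrame, group_labels, duration_col: str = "time",
               event_col: str = "event"):
    """Kaplan-Meier curves per group and the two-group log-rank test.

    Returns ``(curves, stat, p)`` where curves maps group label -> survival
    DataFrame (timeline, survival probability).
    """
    labels = np.asarray(group_labels)
    uniq = np.unique(labels)
    if len(uniq) != 2:
        raise ValueError("exactly two non-empty groups required")
    curves = {}
    for g in uniq:
        mask = labels == g
        if mask.sum() == 0:
            raise ValueError(f"group {g} is empty")
        kmf = KaplanMeierFitter()
        kmf.fit(table[duration_col][mask], table[event_col][mask], label=str(g))
        curves[g] = kmf.survival_function_
    m0, m1 = labels == uniq[0], labels == uniq[1]
    res = logrank_test(
        table[duration_col][m0], table[duration_col][m1],
        event_observed_A=table[event_col][m0], event_observed_B=table[event_col][m1],
    )
    return curves, float(res.test_statistic), float(res.p_value)


def compare_age_codings(table: pd.DataFrame, covariates=None, cutoff=None) -> dict:
    """Fit the multivariate clinical model with continuous vs categorical age.

    Returns both CoxResults and, per criterion (global p, AIC, C-index), which
    coding wins (lower p, lower AIC, higher C).
    """
    covariates = list(covariates) if covariates is not None else list(CLINICAL_FEATURES)
    if "age" not in covariates:
        raise ValueError("covariates must include age")
    cont = fit_cox(table, covariates)
    cat_table = table.copy()
    cat_table["age"] = categorize_age(table["age"].to_numpy(), cutoff)
    cat = fit_cox(cat_table, covariates)
    winners = {
        "global_p": "categorical" if cat.global_p < cont.global_p else "continuous",
        "aic": "categorical" if cat.aic < cont.aic else "continuous",
        "c_index": "categorical" if cat.c_index > cont.c_index else "continuous",
    }
    return {"continuous": cont, "categorical": cat, "winners": winners}


def descriptive_stats(table: pd.DataFrame) -> dict:
    """Cohort descriptives: mean tumor size, node-positive count, median follow-up."""
    return {
        "n": int(len(table)),
        "n_events": int(table["event"].sum()),
        "mean_tumor_size_cm": float(table["max_nodule_size"].mean()),
        "n_node_positive": int((table["TLNN"] > 0).sum()),
        "median_followup_months": float(table["time"].median()),
        "mean_age": float(table["age"].mean()),
    }
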