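"""Individualized risk stratification from predicted survival curves.

Each patient's predicted survival curve is summarised by its expectation
restricted to the training horizon (RMST, trapezoid rule); the continuous
risk ranking ("Crank") is ``horizon - RMST`` (expected event exposure), so
higher scores mean higher recurrence risk.  The high/low threshold is the
midpoint of the mean Cranks of the recurrent and non-recurrent training
patients; patients at or above the threshold are called high-risk.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .clinical import km_logrank
from .models import FittedModel


def predict_survival_curve(model: FittedModel, patient_features: pd.DataFrame):
    """Predicted survival curves with the S(0) = 1 boundary prepended.

    Returns ``(times, S)``; S has one row per patient and is non-increasing
    along the (ascending) time grid.
    """
    times, S = model.predict_survival(patient_features)
    if len(times) == 0:
        raise ValueError("model has an empty time grid")
    if times[0] > 0:
        times = np.concatenate([[0.0], times])
        S = np.column_stack([np.ones(S.shape[0]), S])
    # guard against numerical wiggle from ensemble averaging
    S = np.minimum.accumulate(np.clip(S, 0.0, 1.0), axis=1)
    return times, S


def compute_crank(times, survival, horizon: float | None = None):
    """Crank score(s): ``horizon - RMST`` of the survival curve.

    RMST is the trapezoid-rule integral of S(t) over [0, horizon]; the curve
    is extended flat beyond its last grid point.  ``survival`` may be a
    single curve or a (patients x times) matrix.
    """
    t = np.asarray(times, float)
    if t.size == 0:
        raise ValueError("empty time grid")
    S = np.atleast_2d(np.asarray(survival, float))
    if horizon is None:
        horizon = float(t[-1])
    if horizon <= 0:
        raise ValueError("horizon must be positive")
    keep = t <= horizon
    tg = t[keep]
    Sg = S[:, keep]
    if tg.size == 0 or tg[0] > 0:
        tg = np.concatenate([[0.0], tg])
        Sg = np.column_stack([np.ones(S.shape[0]), Sg])
    if tg[-1] < horizon:
        tg = np.concatenate([tg, [horizon]])
        Sg = np.column_stack([Sg, Sg[:, -1]])
    rmst = np.trapezoid(Sg, tg, axis=1)
    crank = horizon - rmst
    return crank if np.asarray(survival).ndim > 1 else float(crank[0])


def compute_threshold(cranks_train, events_train) -> float:
    """Midpoint of the mean Cranks of the recurrence and no-recurrence groups.

    Training data only; errors if either group is empty.
    """
    cranks = np.asarray(cranks_train, float)
    events = np.asarray(events_train).astype(bool)
    if events.all() or not events.any():
        raise ValueError("both recurrence and non-recurrence groups are required")
    return float((cranks[events].mean() + cranks[~events].mean()) / 2.0)


def fisher_threshold(cranks_train, events_train) -> float:
    """Pooled-variance Fisher/LDA boundary between the two Crank groups,
    provided as an alternative to the group-mean midpoint."""
    cranks = np.asarray(cranks_train, float)
    events = np.asarray(events_train).astype(bool)
    if events.all() or not events.any():
        raise ValueError("both groups required")
    m1, m0 = cranks[events].mean(), cranks[~events].mean()
    v1 = cranks[events].var(ddof=1) if events.sum() > 1 else 0.0
    v0 = cranks[~events].var(ddof=1) if (~events).sum() > 1 else 0.0
    n1, n0 = events.sum(), (~events).sum()
    pooled = ((n1 - 1) * v1 + (n0 - 1) * v0) / max(n1 + n0 - 2, 1)
    if pooled == 0:
        return float((m1 + m0) / 2.0)
    # equal-covariance LDA boundary with empirical priors
    prior = np.log(n1 / n0)
    return float((m1 + m0) / 2.0 - pooled * prior / (m1 - m0))


def stratify(cranks, threshold: float) -> np.ndarray:
    """High/low labels: ``high`` iff crank >= threshold (boundary goes high)."""
    if not np.isfinite(threshold):
        raise ValueError("threshold must be finite")
    cranks = np.asarray(cranks, float)
    return np.where(cranks >= threshold, "high", "low")


@dataclass
class Stratification:
    """Confusion counts of predicted risk group against observed recurrence."""

    threshold: float
    labels: pd.Series
    tp: int
    fp: int
    tn: int
    fn: int
    accuracy: float
    logrank: dict   # partition name -> (statistic, p) or None

    def to_dict(self) -> dict:
        return {
            "threshold": self.threshold,
            "tp": self.tp, "fp": self.fp, "tn": self.tn, "fn": self.fn,
            "accuracy": self.accuracy,
            "logrank": {k: v for k, v in self.logrank.items()},
        }


def evaluate_stratification(labels, outcomes: pd.DataFrame, threshold: float,
                            partitions: dict | None = None) -> Stratification:
    """Confusion matrix, accuracy and per-partition KM log-rank separation.

    ``labels`` are high/low calls aligned with ``outcomes`` (event, time);
    high-risk counts as predicted recurrence.  ``partitions`` maps a name
    (e.g. train/test) to the patient ids it contains; each gets a log-rank
    test of high vs low when both groups are present.
    """
    labels = pd.Series(np.asarray(labels, dtype=object), index=outcomes.index)
    pred = (labels == "high").astype(int)
    obs = outcomes["event"].astype(int)
    tp = int(((pred == 1) & (obs == 1)).sum())
    fp = int(((pred == 1) & (obs == 0)).sum())
    tn = int(((pred == 0) & (obs == 0)).sum())
    fn = int(((pred == 0) & (obs == 1)).sum())
    acc = (tp + tn) / len(obs)

    logrank = {}
    parts = partitions if partitions is not None else {"all": list(outcomes.index)}
    for name, ids in parts.items():
        sub = outcomes.loc[ids]
        lab = labels.loc[ids]
        if lab.nunique() < 2:
            warnings.warn(f"partition {name!r} has a single risk group; log-rank skipped")
            logrank[name] = None
            continue
        _, stat, p = km_logrank(sub, lab.to_numpy())
        logrank[name] = {"statistic": stat, "p": p}
    return Stratification(
        threshold=float(threshold), labels=labels,
        tp=tp, fp=fp, tn=tn, fn=fn, accuracy=float(acc), logrank=logrank,
    )


def patient_report(model: FittedModel, features: pd.DataFrame,
                   outcomes: pd.DataFrame, horizon: float | None = None) -> pd.DataFrame:
    """Long-format per-patient curve report (patient, time, survival) plus
    crank and follow-up columns, as used for case-level review plots."""
    times, S = predict_survival_curve(model, features)
    cranks = compute_crank(times, S, horizon)
    rows = []
    for i, pid in enumerate(features.index):
        for t, s in zip(times, S[i]):
            rows.append((pid, float(t), float(s)))
    long = pd.DataFrame(rows, columns=["patient", "time", "survival"])
    info = pd.DataFrame(
        {
            "crank": cranks,
            "event": outcomes.loc[features.index, "event"].to_numpy(),
            "followup": outcomes.loc[features.index, "time"].to_numpy(),
        },
        index=features.index,
    )
    return long.merge(info, left_on="patient", right_index=True)
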