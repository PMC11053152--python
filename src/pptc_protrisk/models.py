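"""Prognostic recurrence models for PM patients.

Five model families over two learners (Cox proportional hazards, random
survival forest) and two feature pools (the eleven clinical covariates,
differential proteins at FC > 1.2):

    CliCox      coxph  on clinical features, no selection
    CliRsf      rsf    on clinical features, no selection
    ProtCox     coxph  on proteins, LASSO selection
    ProtRsf     rsf    on proteins, stability selection
    CliProtRsf  rsf    on clinical + proteins, stability selection

Stability selection fits the forest ``n_repeats`` times with different RNG
states, ranks features by permutation importance (drop in Harrell's C-index
when a feature column is permuted, computed on out-of-bag predictions by
default), records the top ``top_k`` per repeat, and keeps features selected
at least ``min_count`` times.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from itertools import product

import numpy as np
import pandas as pd
from sklearn.ensemble._forest import (
    _generate_unsampled_indices,
    _get_n_samples_bootstrap,
)
from sksurv.ensemble import RandomSurvivalForest
from sksurv.linear_model import CoxnetSurvivalAnalysis, CoxPHSurvivalAnalysis
from sksurv.metrics import concordance_index_censored
from sksurv.util import Surv

from .containers import CLINICAL_FEATURES

MODEL_NAMES = ("CliCox", "CliRsf", "ProtCox", "ProtRsf", "CliProtRsf")

#: default random-survival-forest hyperparameter grid
DEFAULT_RSF_GRID = {
    "n_estimators": [250, 500, 1000],
    "max_features": ["sqrt", 0.333],
    "min_samples_leaf": [3, 6, 15],
}


@dataclass
class ModelSpec:
    """Declarative description of one of the five prognostic models."""

    name: str
    feature_pool: str   # clinical | protein | both
    learner: str        # coxph | rsf
    selector: str       # none | lasso | stability
    hyper_grid: dict = field(default_factory=dict)
    seed: int = 0

    def __post_init__(self):
        if self.name not in MODEL_NAMES:
            raise ValueError(f"unknown model {self.name}")
        expected = {
            "CliCox": ("clinical", "coxph", "none"),
            "CliRsf": ("clinical", "rsf", "none"),
            "ProtCox": ("protein", "coxph", "lasso"),
            "ProtRsf": ("protein", "rsf", "stability"),
            "CliProtRsf": ("both", "rsf", "stability"),
        }[self.name]
        if (self.feature_pool, self.learner, self.selector) != expected:
            raise ValueError(
                f"{self.name} requires pool/learner/selector {expected}"
            )


def model_spec(name: str, seed: int = 0, hyper_grid: dict | None = None) -> ModelSpec:
    pools = {
        "CliCox": ("clinical", "coxph", "none"),
        "CliRsf": ("clinical", "rsf", "none"),
        "ProtCox": ("protein", "coxph", "lasso"),
        "ProtRsf": ("protein", "rsf", "stability"),
        "CliProtRsf": ("both", "rsf", "stability"),
    }
    pool, learner, selector = pools[name]
    grid = hyper_grid if hyper_grid is not None else (
        dict(DEFAULT_RSF_GRID) if learner == "rsf" else {}
    )
    return ModelSpec(name, pool, learner, selector, grid, seed)


# ----------------------------------------------------------------------
# Outcome helpers
# ----------------------------------------------------------------------
def to_surv(event, time):
    return Surv.from_arrays(event=np.asarray(event).astype(bool),
                            time=np.asarray(time, float))


def harrell_cindex(event, time, risk) -> float:
    """Harrell's concordance index; tied risk scores count one half.

    Returns 0.5 when every pair is tied in risk; NaN when no pair is
    comparable.
    """
    event = np.asarray(event).astype(bool)
    time = np.asarray(time, float)
    risk = np.asarray(risk, float)
    try:
        c = concordance_index_censored(event, time, risk)[0]
    except Exception:
        return float("nan")
    return float(c)


def _comparable_pairs(event, time):
    """Index pairs (a, b) where a's event time is observed to precede b's."""
    event = np.asarray(event).astype(bool)
    time = np.asarray(time, float)
    n = len(time)
    a_idx, b_idx = [], []
    for i in range(n):
        if not event[i]:
            continue
        for j in range(n):
            if j == i:
                continue
            if time[j] > time[i] or (time[j] == time[i] and not event[j]):
                a_idx.append(i)
                b_idx.append(j)
    return np.asarray(a_idx, dtype=int), np.asarray(b_idx, dtype=int)


def _cindex_from_pairs(risk, a_idx, b_idx) -> float:
    if len(a_idx) == 0:
        return float("nan")
    ra, rb = risk[a_idx], risk[b_idx]
    return float((np.sum(ra > rb) + 0.5 * np.sum(ra == rb)) / len(a_idx))


# ----------------------------------------------------------------------
# Train/test split
# ----------------------------------------------------------------------
@dataclass
class SplitDefinition:
    train_ids: list
    test_ids: list
    seed: int
    stratified: bool


def split_train_test(pm_table: pd.DataFrame, ratio: float = 0.6, seed: int = 0,
                     stratify: bool = True) -> SplitDefinition:
    """Random train/test partition of PM patients, optionally event-stratified.

    With stratification the event fraction in each partition is preserved to
    within one patient.  Deterministic per seed.
    """
    if not (0 < ratio < 1):
        raise ValueError("ratio must lie in (0, 1)")
    ids = np.asarray(pm_table.index)
    events = pm_table["event"].to_numpy().astype(bool)
    rng = np.random.default_rng(seed)
    n_train = int(round(ratio * len(ids)))
    if stratify:
        if events.sum() < 2:
            raise ValueError("stratified split needs at least two events")
        ev_ids = ids[events]
        cen_ids = ids[~events]
        n_ev_train = int(round(ratio * len(ev_ids)))
        n_ev_train = min(max(n_ev_train, 1), len(ev_ids) - 1)
        ev_perm = rng.permutation(ev_ids)
        cen_perm = rng.permutation(cen_ids)
        n_cen_train = n_train - n_ev_train
        train = np.concatenate([ev_perm[:n_ev_train], cen_perm[:n_cen_train]])
        test = np.concatenate([ev_perm[n_ev_train:], cen_perm[n_cen_train:]])
    else:
        perm = rng.permutation(ids)
        train, test = perm[:n_train], perm[n_train:]
    return SplitDefinition(sorted(train.tolist()), sorted(test.tolist()),
                           seed, stratify)


# ----------------------------------------------------------------------
# Learner factories and fitted-model wrapper
# ----------------------------------------------------------------------
def _make_learner(learner: str, params: dict, seed: int):
    if learner == "rsf":
        p = dict(params)
        return RandomSurvivalForest(random_state=int(seed) % (2**31), n_jobs=1, **p)
    if learner == "coxph":
        return CoxPHSurvivalAnalysis(alpha=params.get("alpha", 1e-6))
    raise ValueError(f"unknown learner {learner!r}")


@dataclass
class FittedModel:
    """A fitted prognostic model with its selected feature panel."""

    name: str
    learner: str
    features: list
    estimator: object
    params: dict
    scaler: tuple | None = None        # (mean, sd) Series pair for proteins
    selection: object = None           # StabilityResult / lasso info
    cv_cindex: float = float("nan")

    def _design(self, X: pd.DataFrame) -> np.ndarray:
        missing = [f for f in self.features if f not in X.columns]
        if missing:
            raise KeyError(f"features missing from input: {missing}")
        Z = X[self.features].astype(float)
        if self.scaler is not None:
            mean, sd = self.scaler
            Z = (Z - mean[self.features]) / sd[self.features]
        return Z.to_numpy()

    def predict_risk(self, X: pd.DataFrame) -> np.ndarray:
        return np.asarray(self.estimator.predict(self._design(X)), float)

    def predict_survival(self, X: pd.DataFrame):
        """Predicted survival curves on the training event-time grid.

        Returns ``(times, S)`` with S of shape (n_patients, n_times).
        """
        fns = self.estimator.predict_survival_function(self._design(X),
                                                       return_array=True)
        times = np.asarray(self.estimator.unique_times_
                           if hasattr(self.estimator, "unique_times_")
                           else self.estimator.event_times_, float)
        return times, np.asarray(fns, float)


# ----------------------------------------------------------------------
# Hyperparameter tuning
# ----------------------------------------------------------------------
def _event_folds(event, k_folds, seed, max_attempts=10):
    """k-fold assignment with at least one event in every fold (and thus in
    every training part); reshuffles on failure."""
    event = np.asarray(event).astype(bool)
    n = len(event)
    for attempt in range(max_attempts):
        rng = np.random.default_rng((seed + attempt) % (2**31))
        order = rng.permutation(n)
        folds = [order[i::k_folds] for i in range(k_folds)]
        if all(event[f].any() for f in folds):
            if attempt:
                warnings.warn(f"refolded {attempt} time(s) to place events in all folds")
            return folds
        # move one event into the empty fold deterministically
    raise ValueError("could not build folds with events in every fold")


def tune_hyperparameters(learner: str, grid: dict, X, y_event, y_time,
                         k_folds: int = 3, seed: int = 0):
    """Exhaustive grid search scored by mean held-out Harrell C-index.

    Ties are broken toward the simpler model (fewer trees, larger terminal
    nodes), then by grid order.  Returns ``(best_params, best_score, table)``.
    """
    if not grid:
        return {}, float("nan"), pd.DataFrame()
    if k_folds < 2:
        raise ValueError("k_folds must be >= 2")
    X = np.asarray(X, float)
    y_event = np.asarray(y_event).astype(bool)
    y_time = np.asarray(y_time, float)
    folds = _event_folds(y_event, k_folds, seed)
    y = to_surv(y_event, y_time)

    keys = list(grid.keys())
    rows = []
    for gi, combo in enumerate(product(*(grid[k] for k in keys))):
        params = dict(zip(keys, combo))
        scores = []
        for f in range(k_folds):
            val = folds[f]
            trn = np.concatenate([folds[j] for j in range(k_folds) if j != f])
            est = _make_learner(learner, params, seed + 1000 * gi + f)
            est.fit(X[trn], y[trn])
            risk = est.predict(X[val])
            scores.append(harrell_cindex(y_event[val], y_time[val], risk))
        rows.append({**params, "cv_cindex": float(np.nanmean(scores)), "_order": gi})
    table = pd.DataFrame(rows)

    def sort_key(row):
        return (
            -row["cv_cindex"],
            row.get("n_estimators", 0),
            -row.get("min_samples_leaf", 0),
            row["_order"],
        )

    best = min(rows, key=sort_key)
    best_params = {k: best[k] for k in keys}
    return best_params, float(best["cv_cindex"]), table.drop(columns="_order")


# ----------------------------------------------------------------------
# Permutation importance
# ----------------------------------------------------------------------
def _forest_tree_state(rsf: RandomSurvivalForest, X: np.ndarray, oob: bool):
    """Per-tree risk predictions, per-tree used-feature sets and the
    OOB membership mask (trees x samples)."""
    n = X.shape[0]
    X32 = np.asarray(X, np.float32)
    n_trees = len(rsf.estimators_)
    P = np.empty((n_trees, n))
    used = []
    W = np.ones((n_trees, n), bool)
    nsb = _get_n_samples_bootstrap(n, rsf.max_samples, None)
    for t, est in enumerate(rsf.estimators_):
        leaf = est.tree_.apply(X32)
        P[t] = est.tree_.value[leaf][:, est.is_event_time_, 0].sum(1)
        used.append(np.unique(est.tree_.feature[est.tree_.feature >= 0]))
        if oob:
            W[t] = False
            idx = _generate_unsampled_indices(est.random_state, n, nsb, None)
            W[t, idx] = True
    return P, used, W, X32


def _aggregate_risk(P: np.ndarray, W: np.ndarray) -> np.ndarray:
    counts = W.sum(axis=0)
    risk = (P * W).sum(axis=0)
    full = P.mean(axis=0)
    with np.errstate(invalid="ignore"):
        out = np.where(counts > 0, risk / np.maximum(counts, 1), full)
    return out


def rsf_permutation_importance(rsf: RandomSurvivalForest, X, y_event, y_time,
                               n_repeats: int = 5, seed: int = 0,
                               oob: bool = True) -> np.ndarray:
    """C-index permutation importance for a survival forest.

    ``importance(f) = C(baseline) - mean_r C(feature f permuted)``, with the
    baseline risk aggregated over out-of-bag trees per sample by default.
    Features not used by any tree have exactly zero importance and are not
    recomputed.
    """
    X = np.asarray(X, float)
    y_event = np.asarray(y_event).astype(bool)
    y_time = np.asarray(y_time, float)
    n, p = X.shape
    P, used, W, X32 = _forest_tree_state(rsf, X, oob)
    base_risk = _aggregate_risk(P, W)
    a_idx, b_idx = _comparable_pairs(y_event, y_time)
    base_c = _cindex_from_pairs(base_risk, a_idx, b_idx)

    trees_by_feature: dict[int, list[int]] = {}
    for t, feats in enumerate(used):
        for f in feats:
            trees_by_feature.setdefault(int(f), []).append(t)

    rng = np.random.default_rng(seed % (2**31))
    counts = W.sum(axis=0)
    full_counts = counts > 0
    importance = np.zeros(p)
    risk_sum = (P * W).sum(axis=0)
    for f, trees in sorted(trees_by_feature.items()):
        drop = 0.0
        for _ in range(n_repeats):
            perm = rng.permutation(n)
            Xp = X32.copy()
            Xp[:, f] = X32[perm, f]
            new_sum = risk_sum.copy()
            for t in trees:
                est = rsf.estimators_[t]
                leaf = est.tree_.apply(Xp)
                pt = est.tree_.value[leaf][:, est.is_event_time_, 0].sum(1)
                new_sum += (pt - P[t]) * W[t]
            with np.errstate(invalid="ignore"):
                risk = np.where(full_counts, new_sum / np.maximum(counts, 1),
                                base_risk)
            drop += base_c - _cindex_from_pairs(risk, a_idx, b_idx)
        importance[f] = drop / n_repeats
    return importance


def permutation_importance(model, X, y_event, y_time, n_repeats: int = 5,
                           seed: int = 0, oob: bool = True) -> pd.Series:
    """Permutation importance (drop in Harrell's C) for any fitted learner.

    Uses the fast per-tree path for random survival forests and a generic
    predict-based path otherwise.  ``X`` may be a DataFrame (importances are
    labelled by column) or an array.
    """
    cols = list(X.columns) if isinstance(X, pd.DataFrame) else list(range(np.asarray(X).shape[1]))
    Xa = X.to_numpy(float) if isinstance(X, pd.DataFrame) else np.asarray(X, float)
    if isinstance(model, RandomSurvivalForest):
        imp = rsf_permutation_importance(model, Xa, y_event, y_time,
                                         n_repeats=n_repeats, seed=seed, oob=oob)
        return pd.Series(imp, index=cols)
    # generic path: full refit-free permute-and-predict
    rng = np.random.default_rng(seed % (2**31))
    a_idx, b_idx = _comparable_pairs(y_event, y_time)
    base = _cindex_from_pairs(np.asarray(model.predict(Xa), float), a_idx, b_idx)
    out = np.zeros(len(cols))
    n = Xa.shape[0]
    for j in range(len(cols)):
        drop = 0.0
        for _ in range(n_repeats):
            Xp = Xa.copy()
            Xp[:, j] = Xa[rng.permutation(n), j]
            drop += base - _cindex_from_pairs(np.asarray(model.predict(Xp), float),
                                              a_idx, b_idx)
        out[j] = drop / n_repeats
    return pd.Series(out, index=cols)


# ----------------------------------------------------------------------
# Stability selection
# ----------------------------------------------------------------------
@dataclass
class StabilityResult:
    """Selection counts over repeated forest fits and the final panel."""

    counts: pd.Series          # per feature, in [0, n_repeats]
    panel: list                # features with count >= min_count
    n_repeats: int
    top_k: int
    min_count: int
    importances: pd.DataFrame | None = None   # per-repeat importance tables


def stability_select(X: pd.DataFrame, y_event, y_time, n_repeats: int = 100,
                     top_k: int = 50, min_count: int = 50, seed: int = 0,
                     rsf_params: dict | None = None,
                     importance_repeats: int = 5, oob: bool = True,
                     keep_importances: bool = False) -> StabilityResult:
    """Permutation-importance stability selection over repeated forest fits.

    Fits ``n_repeats`` forests differing by RNG state, records each repeat's
    ``top_k`` features by permutation importance (ties at the cut are all
    included), and returns the features selected at least ``min_count``
    times.  Deterministic given the master seed.
    """
    if X.shape[1] < top_k:
        raise ValueError("feature pool smaller than top_k")
    if not np.asarray(y_event).astype(bool).any():
        raise ValueError("training data has no events")
    params = dict(rsf_params or {})
    params.setdefault("n_estimators", 500)
    params.setdefault("max_features", "sqrt")
    params.setdefault("min_samples_leaf", 3)
    Xa = X.to_numpy(float)
    y = to_surv(y_event, y_time)
    cols = np.asarray(X.columns)
    counts = np.zeros(X.shape[1], dtype=int)
    imps = [] if keep_importances else None
    master = np.random.default_rng(seed % (2**31))
    repeat_seeds = master.integers(0, 2**31 - 1, size=3 * n_repeats)
    for r in range(n_repeats):
        rsf = _make_learner("rsf", params, int(repeat_seeds[3 * r]))
        rsf.fit(Xa, y)
        imp = rsf_permutation_importance(
            rsf, Xa, y_event, y_time, n_repeats=importance_repeats,
            seed=int(repeat_seeds[3 * r + 1]), oob=oob,
        )
        order = np.argsort(-imp, kind="stable")
        cutoff = imp[order[top_k - 1]]
        if cutoff > 0:
            # positive importance ties at the cut are all included
            chosen = np.where(imp >= cutoff)[0]
        else:
            # degenerate cut (features the forest never separated on):
            # fill the remaining slots at random among the tied features
            above = np.where(imp > cutoff)[0]
            tied = np.where(imp == cutoff)[0]
            tie_rng = np.random.default_rng(int(repeat_seeds[3 * r + 2]))
            fill = tie_rng.choice(tied, size=top_k - len(above), replace=False)
            chosen = np.concatenate([above, fill])
        counts[chosen] += 1
        if keep_importances:
            imps.append(imp)
    count_s = pd.Series(counts, index=cols).sort_values(ascending=False, kind="stable")
    panel = [f for f in cols if count_s[f] >= min_count]
    if not panel:
        warnings.warn("stability selection produced an empty panel")
    return StabilityResult(
        counts=count_s, panel=panel, n_repeats=n_repeats, top_k=top_k,
        min_count=min_count,
        importances=pd.DataFrame(imps, columns=cols) if keep_importances else None,
    )


# ----------------------------------------------------------------------
# LASSO-Cox selection
# ----------------------------------------------------------------------
def _cox_loglik(lp, event, time):
    """Breslow log partial likelihood of risk scores lp."""
    order = np.argsort(-time, kind="stable")
    lp, event = lp[order], event[order]
    log_cum = np.logaddexp.accumulate(lp)
    # handle tied times: risk set includes all with time >= t_i
    t_sorted = time[order]
    # map each position to the last position sharing its time
    last = np.arange(len(lp))
    for i in range(len(lp) - 2, -1, -1):
        if t_sorted[i] == t_sorted[i + 1]:
            last[i] = last[i + 1]
    return float(np.sum((lp - log_cum[last])[event.astype(bool)]))


def lasso_cox_select(X: pd.DataFrame, y_event, y_time, k_folds: int = 3,
                     seed: int = 0, n_alphas: int = 50):
    """L1-penalised Cox path with the penalty chosen by k-fold
    cross-validated partial-likelihood deviance.

    Features should be standardized.  Returns
    ``(selected_features, coefs_at_alpha_min, alpha_min)``; the selection can
    be empty (with a warning) when the null model wins everywhere.
    """
    Xa = X.to_numpy(float)
    event = np.asarray(y_event).astype(bool)
    time = np.asarray(y_time, float)
    if not event.any():
        raise ValueError("no events in training data")
    y = to_surv(event, time)
    path = CoxnetSurvivalAnalysis(l1_ratio=1.0, n_alphas=n_alphas,
                                  alpha_min_ratio=0.05)
    path.fit(Xa, y)
    alphas = path.alphas_

    folds = _event_folds(event, k_folds, seed)
    dev = np.zeros((k_folds, len(alphas)))
    for f in range(k_folds):
        val = folds[f]
        trn = np.concatenate([folds[j] for j in range(k_folds) if j != f])
        m = CoxnetSurvivalAnalysis(l1_ratio=1.0, alphas=alphas, fit_baseline_model=False)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            m.fit(Xa[trn], y[trn])
        coefs = m.coef_  # (p, n_alphas_fit)
        for a in range(coefs.shape[1]):
            lp = Xa[val] @ coefs[:, a]
            dev[f, a] = -2.0 * _cox_loglik(lp, event[val], time[val])
    mean_dev = dev.mean(axis=0)
    a_min = int(np.argmin(mean_dev))
    alpha_min = float(alphas[a_min])
    coef = pd.Series(path.coef_[:, a_min], index=X.columns)
    selected = list(coef.index[coef != 0])
    if not selected:
        warnings.warn("LASSO selected no features at the CV-optimal penalty")
    return selected, coef, alpha_min


# ----------------------------------------------------------------------
# Evaluation and model building
# ----------------------------------------------------------------------
def evaluate_cindex(model, X, y_event, y_time) -> float:
    """Harrell C-index of a fitted model's risk score on (time, event).

    ``model`` may be a FittedModel, an sksurv estimator, or a precomputed
    risk array.
    """
    if isinstance(model, FittedModel):
        risk = model.predict_risk(X)
    elif hasattr(model, "predict"):
        risk = np.asarray(model.predict(np.asarray(X, float)), float)
    else:
        risk = np.asarray(model, float)
    return harrell_cindex(y_event, y_time, risk)


def standardizer(X_train: pd.DataFrame):
    """Train-set mean/sd pair; zero-variance columns get sd 1."""
    mean = X_train.mean()
    sd = X_train.std(ddof=0).replace(0.0, 1.0)
    return mean, sd


def build_model(name: str, X_train: pd.DataFrame, y_event, y_time,
                seed: int = 0, hyper_grid: dict | None = None,
                k_folds: int = 3, stability_kwargs: dict | None = None,
                standardize: bool = True) -> FittedModel:
    """Tune, select features and fit one of the five prognostic models.

    ``X_train`` is the model's feature pool (clinical, protein DEPs, or
    both).  Hyperparameters are tuned first by grid search with k-fold CV on
    the full pool, then the model's selector runs, then the final learner is
    refit on the selected panel with the best hyperparameters.
    """
    spec = model_spec(name, seed=seed, hyper_grid=hyper_grid)
    event = np.asarray(y_event).astype(bool)
    time = np.asarray(y_time, float)
    scaler = None
    Z = X_train.astype(float)
    if standardize:
        scaler = standardizer(Z)
        Z = (Z - scaler[0]) / scaler[1]

    best_params, cv_c, _ = tune_hyperparameters(
        spec.learner, spec.hyper_grid, Z.to_numpy(), event, time,
        k_folds=k_folds, seed=seed,
    )

    selection = None
    if spec.selector == "stability":
        kw = dict(stability_kwargs or {})
        kw.setdefault("rsf_params", best_params or None)
        selection = stability_select(Z, event, time, seed=seed, **kw)
        features = selection.panel
        if not features:  # degenerate pool: fall back to top-count features
            features = list(selection.counts.index[: min(10, Z.shape[1])])
    elif spec.selector == "lasso":
        selected, coef, alpha_min = lasso_cox_select(Z, event, time,
                                                     k_folds=k_folds, seed=seed)
        selection = {"coef": coef, "alpha_min": alpha_min}
        features = selected if selected else list(Z.columns)
    else:
        features = list(Z.columns)

    est = _make_learner(spec.learner, best_params, seed)
    est.fit(Z[features].to_numpy(), to_surv(event, time))
    return FittedModel(
        name=name, learner=spec.learner, features=list(features),
        estimator=est, params=best_params, scaler=scaler,
        selection=selection, cv_cindex=cv_c,
    )
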