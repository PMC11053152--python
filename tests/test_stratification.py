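"""Crank risk scores, thresholds, labels and stratification evaluation."""

import numpy as np
import pandas as pd
import pytest

from pptc_protrisk import models as M
from pptc_protrisk.stratification import (
    compute_crank,
    compute_threshold,
    evaluate_stratification,
    fisher_threshold,
    predict_survival_curve,
    stratify,
)

from test_models import survival_features


class TestComputeCrank:
    def test_certain_survival_gives_zero_risk(self):
        t = np.array([0.0, 10, 50, 100])
        assert compute_crank(t, np.ones(4)) == pytest.approx(0.0)

    def test_immediate_event_gives_full_horizon(self):
        t = np.array([0.0, 50, 100])
        s = np.array([1.0, 0.0, 0.0])
        # trapezoid between 0 and 50 contributes 25; force a step via dense grid
        t2 = np.array([0.0, 1e-9, 100.0])
        s2 = np.array([1.0, 0.0, 0.0])
        assert compute_crank(t2, s2) == pytest.approx(100.0, abs=1e-6)

    def test_step_curve_integrates_by_hand(self):
        # S = 1 until H/2, then 0: RMST = H/2 (grid contains the step)
        h = 80.0
        t = np.array([0.0, 40.0, 40.0 + 1e-9, 80.0])
        s = np.array([1.0, 1.0, 0.0, 0.0])
        assert compute_crank(t, s, horizon=h) == pytest.approx(h / 2, abs=1e-6)

    def test_grid_refinement_invariance_for_step_curves(self):
        h = 100.0
        coarse_t = np.array([0.0, 30.0, 30.0 + 1e-9, 100.0])
        coarse_s = np.array([1.0, 1.0, 0.4, 0.4])
        fine_t = np.linspace(0, 100, 2001)
        fine_s = np.where(fine_t <= 30.0, 1.0, 0.4)
        c1 = compute_crank(coarse_t, coarse_s, horizon=h)
        c2 = compute_crank(fine_t, fine_s, horizon=h)
        assert abs(c1 - c2) < 1e-3 * h

    def test_horizon_truncates_and_extends(self):
        t = np.array([0.0, 10.0])
        s = np.array([1.0, 0.5])
        # beyond the grid the curve extends flat at 0.5
        expected_rmst = 0.75 * 10 + 0.5 * 10
        assert compute_crank(t, s, horizon=20.0) == pytest.approx(20 - expected_rmst)

    def test_empty_grid_rejected(self):
        with pytest.raises(ValueError):
            compute_crank(np.array([]), np.array([]))


class TestThreshold:
    def test_hand_computed_midpoint(self):
        cranks = np.array([5.0, 7.0, 1.0, 3.0])
        events = np.array([1, 1, 0, 0])
        assert compute_threshold(cranks, events) == pytest.approx(4.0)

    def test_equal_group_means(self):
        cranks = np.array([2.0, 4.0, 2.0, 4.0])
        events = np.array([1, 1, 0, 0])
        assert compute_threshold(cranks, events) == pytest.approx(3.0)

    def test_shift_equivariance(self):
        rng = np.random.default_rng(0)
        cranks = rng.uniform(0, 50, 30)
        events = rng.binomial(1, 0.3, 30)
        base = compute_threshold(cranks, events)
        assert compute_threshold(cranks + 7.5, events) == pytest.approx(base + 7.5)

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            compute_threshold([1.0, 2.0], [1, 1])

    def test_fisher_boundary_falls_between_group_means(self):
        rng = np.random.default_rng(1)
        cranks = np.r_[rng.normal(10, 1, 20), rng.normal(2, 1, 60)]
        events = np.r_[np.ones(20), np.zeros(60)]
        fb = fisher_threshold(cranks, events)
        assert 2 < fb < 10


class TestStratify:
    def test_boundary_classified_high(self):
        labels = stratify([3.0, 2.9], threshold=3.0)
        assert list(labels) == ["high", "low"]

    def test_all_below_threshold(self):
        assert (stratify([1.0, 2.0], 5.0) == "low").all()

    def test_monotone_transform_invariance(self):
        rng = np.random.default_rng(2)
        cranks = rng.uniform(0, 20, 50)
        thr = 8.0
        base = stratify(cranks, thr)
        transformed = stratify(np.exp(cranks / 5), np.exp(thr / 5))
        assert (base == transformed).all()

    def test_nonfinite_threshold_rejected(self):
        with pytest.raises(ValueError):
            stratify([1.0], np.nan)


class TestEvaluateStratification:
    def _outcomes(self, events, times, ids=None):
        idx = ids if ids is not None else [f"P{i}" for i in range(len(events))]
        return pd.DataFrame({"event": events, "time": times}, index=idx)

    def test_perfect_labels(self):
        out = self._outcomes([1, 1, 0, 0], [10.0, 12, 80, 90])
        labels = ["high", "high", "low", "low"]
        strat = evaluate_stratification(labels, out, threshold=5.0)
        assert strat.accuracy == 1.0
        assert strat.fp == 0 and strat.fn == 0
        assert strat.tp == 2 and strat.tn == 2

    def test_confusion_counts(self):
        out = self._outcomes([1, 0, 1, 0, 0], [10.0, 20, 30, 40, 50])
        labels = ["high", "high", "low", "low", "low"]
        strat = evaluate_stratification(labels, out, threshold=0.0)
        assert (strat.tp, strat.fp, strat.tn, strat.fn) == (1, 1, 2, 1)
        assert strat.accuracy == pytest.approx(3 / 5)

    def test_single_class_partition_warns(self):
        out = self._outcomes([1, 0, 0], [5.0, 50, 60])
        with pytest.warns(UserWarning):
            strat = evaluate_stratification(["high"] * 3, out, threshold=0.0)
        assert strat.logrank["all"] is None

    def test_threshold_ignores_test_outcomes(self):
        # leak check: the threshold is a function of training cranks/events only
        rng = np.random.default_rng(3)
        cranks_train = rng.uniform(0, 10, 40)
        events_train = rng.binomial(1, 0.4, 40)
        thr = compute_threshold(cranks_train, events_train)
        shuffled_test_events = rng.permutation(rng.binomial(1, 0.4, 30))
        assert compute_threshold(cranks_train, events_train) == thr
        del shuffled_test_events


class TestPredictedCurves:
    def test_cox_hazard_monotonicity(self):
        X, event, time = survival_features(120, 3, 1, seed=20, beta=1.5)
        model = M.build_model("CliCox", X.rename(columns=dict(zip(
            X.columns, ["age", "TLNN", "ETE"]))), event, time, seed=0)
        Xr = X.rename(columns=dict(zip(X.columns, ["age", "TLNN", "ETE"])))
        times, S = predict_survival_curve(model, Xr)
        assert S.shape == (120, len(times))
        assert np.all(S <= 1.0 + 1e-12) and np.all(S >= -1e-12)
        assert np.all(np.diff(S, axis=1) <= 1e-9)
        # larger risk score => pointwise lower curve for a Cox model
        risk = model.predict_risk(Xr)
        i_hi, i_lo = int(np.argmax(risk)), int(np.argmin(risk))
        assert np.all(S[i_hi] <= S[i_lo] + 1e-12)

    def test_identical_patients_identical_curves(self):
        X, event, time = survival_features(80, 4, 1, seed=21)
        rsf = M.build_model(
            "ProtRsf", X, event, time, seed=0,
            hyper_grid={"n_estimators": [25]},
            stability_kwargs=dict(n_repeats=4, top_k=4, min_count=1),
        )
        pair = pd.concat([X.iloc[[0]], X.iloc[[0]]])
        times, S = predict_survival_curve(rsf, pair)
        assert np.allclose(S[0], S[1])

    def test_all_censored_training_rejected(self):
        # survival learners cannot estimate anything from a cohort with no
        # events; the failure is loud rather than silently flat
        X, _, time = survival_features(40, 3, 0, seed=22)
        rsf = M._make_learner("rsf", dict(n_estimators=25), 0)
        with pytest.raises(ValueError):
            rsf.fit(X.to_numpy(), M.to_surv(np.zeros(40, dtype=bool), time))

    def test_rare_event_training_gives_high_survival_curves(self):
        X, _, time = survival_features(40, 3, 0, seed=22)
        event = np.zeros(40, dtype=bool)
        event[np.argmax(time)] = True  # single late event
        rsf = M._make_learner("rsf", dict(n_estimators=25), 0)
        rsf.fit(X.to_numpy(), M.to_surv(event, time))
        fm = M.FittedModel("ProtRsf", "rsf", list(X.columns), rsf, {})
        times, S = predict_survival_curve(fm, X)
        # survival stays certain before the only observed event time
        assert np.allclose(S[:, times < time[event][0]], 1.0)
        assert S[:, -1].min() < 1.0
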