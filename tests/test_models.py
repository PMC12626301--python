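"""Single-event ISD models: Kaplan-Meier, Cox, MTLR, deep Cox, forest,
plus the median-survival-time reader used for risk scores."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from alsurv.containers import default_time_grid
from alsurv.models import (
    CoxPHModel,
    DeepCoxModel,
    KaplanMeierModel,
    MTLRModel,
    SurvivalForestModel,
    median_survival_time,
)
from alsurv.metrics import harrell_ci

from conftest import single_event_dataset

GRID = default_time_grid()


def sim_weibull_single_covariate(n, seed, beta=-0.5, shape=1.5, scale=300.0,
                                 censor_at=500):
    rng = np.random.default_rng(seed)
    x = rng.normal(size=(n, 1))
    lam = scale * np.exp(beta * x[:, 0])
    t = lam * rng.weibull(shape, n)
    c = rng.uniform(50, 600, n)
    obs = np.minimum(t, np.minimum(c, censor_at))
    d = (t <= np.minimum(c, censor_at)).astype(int)
    times = np.clip(np.ceil(obs), 1, censor_at).astype(int)
    return single_event_dataset(times, d, X=x)


class TestKaplanMeier:
    def test_empirical_survivor_without_censoring(self):
        ds = single_event_dataset([1, 2, 3, 4], [1, 1, 1, 1])
        m = KaplanMeierModel().fit(ds)
        assert m.km_.survival_at(2) == pytest.approx(0.5)

    def test_hand_product_limit_with_censoring(self):
        ds = single_event_dataset([1, 2, 3], [1, 0, 1])
        m = KaplanMeierModel().fit(ds)
        assert m.km_.survival_at(1) == pytest.approx(2 / 3)
        assert m.km_.survival_at(3) == pytest.approx(0.0)

    def test_all_censored_curve_stays_at_one(self):
        ds = single_event_dataset([5, 10, 15], [0, 0, 0])
        m = KaplanMeierModel().fit(ds)
        assert (m.predict_survival(np.zeros((2, 1)), GRID) == 1.0).all()

    def test_same_curve_for_every_patient(self):
        ds = sim_weibull_single_covariate(200, 0)
        curves = KaplanMeierModel().fit(ds).predict_survival(ds.X, GRID)
        assert (curves == curves[0]).all()

    def test_matches_lifelines(self):
        from lifelines import KaplanMeierFitter

        ds = sim_weibull_single_covariate(300, 1)
        m = KaplanMeierModel().fit(ds)
        kmf = KaplanMeierFitter().fit(ds.times[:, 0], ds.events[:, 0])
        ours = m.km_.curve_on_grid(GRID)
        theirs = kmf.survival_function_at_times(GRID).to_numpy()
        np.testing.assert_allclose(ours, theirs, atol=1e-10)


class TestCoxPH:
    def test_recovers_log_hazard_ratio_two_group_exponential(self):
        rng = np.random.default_rng(0)
        n = 5000
        x = rng.integers(0, 2, n).astype(float)
        t = rng.exponential(1.0 / (0.01 * np.exp(np.log(2) * x)))
        times = np.clip(np.ceil(t), 1, 10_000).astype(int)
        ds = single_event_dataset(times, np.ones(n, int), X=x[:, None])
        m = CoxPHModel().fit(ds)
        assert abs(m.coef_[0] - np.log(2)) < 0.1

    def test_zero_covariates_reproduce_baseline_curve(self):
        ds = sim_weibull_single_covariate(500, 2)
        m = CoxPHModel().fit(ds)
        curves = m.predict_survival(np.zeros((3, 1)), GRID)
        baseline = np.exp(
            -np.interp(GRID, np.concatenate(([0], m.baseline_times_)),
                       np.concatenate(([0], m.baseline_cumhaz_)))
        )
        # step interpolation: compare at the recorded baseline times
        at = m.baseline_times_.astype(int)
        np.testing.assert_allclose(curves[0, at], np.exp(-m.baseline_cumhaz_), rtol=1e-9)
        assert (curves[0] == curves[1]).all()

    def test_proportional_hazards_curves_never_cross(self):
        ds = sim_weibull_single_covariate(800, 3)
        m = CoxPHModel().fit(ds)
        curves = m.predict_survival(np.array([[-2.0], [2.0]]), GRID)
        diff = curves[0] - curves[1]
        inner = diff[(curves[0] < 1) & (curves[0] > 0)]
        assert (inner >= -1e-12).all() or (inner <= 1e-12).all()

    def test_matches_lifelines_on_tied_data(self):
        from lifelines import CoxPHFitter

        rng = np.random.default_rng(4)
        n = 400
        X = rng.normal(size=(n, 2))
        times = rng.integers(1, 8, n)
        events = rng.integers(0, 2, n)
        ds = single_event_dataset(times, events, X=X)
        ours = CoxPHModel().fit(ds).coef_
        df = pd.DataFrame({"x0": X[:, 0], "x1": X[:, 1], "t": times, "e": events})
        theirs = CoxPHFitter().fit(df, "t", "e").params_.to_numpy()
        np.testing.assert_allclose(ours, theirs, atol=1e-5)

    def test_no_events_rejected(self):
        ds = single_event_dataset([10, 20], [0, 0])
        with pytest.raises(ValueError):
            CoxPHModel().fit(ds)


class TestMTLR:
    def test_zero_weights_give_uniform_prior_survivor(self):
        ds = sim_weibull_single_covariate(300, 5)
        m = MTLRModel(n_bins=5)
        m.edges_ = np.array([100.0, 200.0, 300.0, 400.0, 500.0])
        m.theta_ = np.zeros((5, 1))
        m.bias_ = np.zeros(5)
        curves = m.predict_survival(np.zeros((1, 1)), GRID)
        # six equally likely outcomes -> survival at tau_j = 1 - (j+1)/6
        for j, tau in enumerate(m.edges_):
            assert curves[0, int(tau)] == pytest.approx(1 - (j + 1) / 6, abs=1e-9)

    def test_discriminates_informative_covariate(self):
        ds = sim_weibull_single_covariate(3000, 6)
        split = int(0.8 * ds.n)
        train = ds.subset(np.arange(split))
        test = ds.subset(np.arange(split, ds.n))
        m = MTLRModel().fit(train)
        curves = m.predict_survival(test.X, GRID)
        risks = -median_survival_time(curves, GRID)
        ci = harrell_ci(test.times[:, 0], test.events[:, 0], risks)
        assert ci > 0.6

    def test_curves_are_valid_isds(self):
        ds = sim_weibull_single_covariate(500, 7)
        m = MTLRModel().fit(ds)
        curves = m.predict_survival(ds.X[:100], GRID)
        assert np.allclose(curves[:, 0], 1.0)
        assert (np.diff(curves, axis=1) <= 1e-9).all()
        assert curves.min() >= 0 and curves.max() <= 1


class TestDeepCox:
    def test_close_to_linear_cox_on_linear_truth(self):
        ds = sim_weibull_single_covariate(2000, 8)
        split = int(0.7 * ds.n)
        vsplit = int(0.8 * ds.n)
        tr = ds.subset(np.arange(split))
        va = ds.subset(np.arange(split, vsplit))
        te = ds.subset(np.arange(vsplit, ds.n))
        cox_curves = CoxPHModel().fit(tr).predict_survival(te.X, GRID)
        deep = DeepCoxModel(seed=0).fit(tr, va)
        deep_curves = deep.predict_survival(te.X, GRID)
        t, d = te.times[:, 0], te.events[:, 0]
        ci_cox = harrell_ci(t, d, -median_survival_time(cox_curves, GRID))
        ci_deep = harrell_ci(t, d, -median_survival_time(deep_curves, GRID))
        assert abs(ci_cox - ci_deep) < 0.05

    def test_early_stopping_contract(self):
        ds = sim_weibull_single_covariate(600, 9)
        tr = ds.subset(np.arange(400))
        va = ds.subset(np.arange(400, 600))
        m = DeepCoxModel(seed=1, patience=10, max_epochs=100).fit(tr, va)
        if m.early_stopped_:
            assert m.epochs_run_ - m.best_epoch_ == m.patience

    def test_seeded_runs_reproduce_risk_scores(self):
        ds = sim_weibull_single_covariate(400, 10)
        tr = ds.subset(np.arange(300))
        va = ds.subset(np.arange(300, 400))
        r1 = DeepCoxModel(seed=7, max_epochs=20).fit(tr, va).predict_risk(ds.X[:50])
        r2 = DeepCoxModel(seed=7, max_epochs=20).fit(tr, va).predict_risk(ds.X[:50])
        np.testing.assert_array_equal(r1, r2)


class TestSurvivalForest:
    def test_chance_level_on_pure_noise(self):
        rng = np.random.default_rng(11)
        n = 1000
        X = rng.normal(size=(n, 3))
        t = np.clip(np.ceil(rng.exponential(200, n)), 1, 500).astype(int)
        d = rng.integers(0, 2, n)
        ds = single_event_dataset(t, d, X=X)
        tr = ds.subset(np.arange(700))
        te = ds.subset(np.arange(700, n))
        m = SurvivalForestModel(seed=0).fit(tr)
        risks = -median_survival_time(m.predict_survival(te.X, GRID), GRID)
        ci = harrell_ci(te.times[:, 0], te.events[:, 0], risks)
        assert 0.45 <= ci <= 0.55

    def test_captures_nonlinearity_that_defeats_distorted_linear_cox(self):
        rng = np.random.default_rng(12)
        n = 1500
        x = rng.normal(size=n)
        fast = np.abs(x) > 1  # event time depends on |x| threshold only
        t = np.where(fast, rng.exponential(60, n), rng.exponential(400, n))
        times = np.clip(np.ceil(t), 1, 500).astype(int)
        d = (t <= 500).astype(int)
        # linear model is handed a squared-distorted encoding of the signal
        X_forest = np.column_stack([x, x**2])
        ds = single_event_dataset(times, d, X=np.column_stack([x, np.sign(x)]))
        forest_ds = single_event_dataset(times, d, X=X_forest)
        tr_f = forest_ds.subset(np.arange(1000))
        te_f = forest_ds.subset(np.arange(1000, n))
        lin_ds = single_event_dataset(times, d, X=x[:, None])
        tr_l = lin_ds.subset(np.arange(1000))
        te_l = lin_ds.subset(np.arange(1000, n))
        fr = SurvivalForestModel(seed=1).fit(tr_f)
        ci_forest = harrell_ci(
            te_f.times[:, 0], te_f.events[:, 0],
            -median_survival_time(fr.predict_survival(te_f.X, GRID), GRID),
        )
        cx = CoxPHModel().fit(tr_l)
        ci_cox = harrell_ci(
            te_l.times[:, 0], te_l.events[:, 0],
            -median_survival_time(cx.predict_survival(te_l.X, GRID), GRID),
        )
        assert ci_forest > ci_cox

    def test_curves_are_valid_isds(self):
        ds = sim_weibull_single_covariate(300, 13)
        m = SurvivalForestModel(seed=2, n_trees=30).fit(ds)
        curves = m.predict_survival(ds.X[:50], GRID)
        assert (curves >= 0).all() and (curves <= 1).all()
        assert (np.diff(curves, axis=1) <= 1e-9).all()


class TestMedianSurvivalTime:
    def test_reads_crossing_time(self):
        grid = np.arange(0, 161, dtype=float)
        curve = np.clip(1 - grid / 160, 0, 1)  # crosses 0.5 at day 80
        assert median_survival_time(curve[None], grid)[0] == pytest.approx(80.0)

    def test_flat_curve_hits_cap(self):
        curve = np.ones_like(GRID)
        assert median_survival_time(curve[None], GRID)[0] == 1000.0

    def test_exponential_closed_form(self):
        curve = np.exp(-GRID / 100.0)
        med = median_survival_time(curve[None], GRID)[0]
        assert abs(med - 100 * np.log(2)) < 0.5

    def test_extrapolation_is_capped(self):
        curve = 1 - GRID / 5000.0  # S(500) = 0.9, crossing far beyond grid
        med = median_survival_time(curve[None], GRID)[0]
        assert med == 1000.0

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(st.lists(st.floats(0.0, 1.0), min_size=3, max_size=40))
    def test_any_monotone_curve_yields_finite_ordered_median(self, values):
        s = np.sort(np.asarray(values))[::-1]
        s = np.concatenate(([1.0], s))
        grid = np.arange(len(s), dtype=float)
        med = median_survival_time(s[None], grid, horizon=int(grid[-1]))[0]
        assert 0 <= med <= 2 * grid[-1]
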