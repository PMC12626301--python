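"""Censoring-aware metrics against independent brute-force oracles and
their analytic special cases."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from alsurv.metrics import (
    curves_at_own_times,
    d_calibration,
    harrell_ci,
    integrated_brier_score,
    brier_score,
    margin_mae,
    uno_ci,
)
from alsurv.nonparametric import KaplanMeier, censoring_km

import oracles


def random_instance(seed, n=6, horizon=100):
    rng = np.random.default_rng(seed)
    times = rng.integers(1, horizon, n).astype(float)
    events = rng.integers(0, 2, n)
    if events.sum() == 0:
        events[rng.integers(n)] = 1
    risks = rng.normal(size=n)
    grid = np.linspace(0, horizon, 21)
    curves = np.sort(rng.uniform(0, 1, (n, 21)))[:, ::-1]
    curves[:, 0] = 1.0
    return times, events, risks, grid, np.ascontiguousarray(curves)


class TestHarrell:
    def test_perfect_antiordering_gives_one(self):
        t = np.array([10, 20, 30, 40.0])
        assert harrell_ci(t, np.ones(4, int), -t) == 1.0

    def test_small_censored_instance_equals_enumeration(self):
        t = np.array([5, 8, 8, 12.0])
        d = np.array([1, 0, 1, 1])
        r = np.array([0.9, 0.4, 0.4, 0.1])
        assert harrell_ci(t, d, r) == pytest.approx(oracles.bf_harrell(t, d, r), abs=1e-15)

    def test_symmetry_under_risk_negation(self):
        rng = np.random.default_rng(0)
        t = rng.integers(1, 100, 50).astype(float)
        d = rng.integers(0, 2, 50)
        r = rng.normal(size=50)  # ties almost surely absent
        assert harrell_ci(t, d, r) + harrell_ci(t, d, -r) == pytest.approx(1.0)

    def test_permutation_invariance(self):
        t, d, r, *_ = random_instance(1, n=30)
        perm = np.random.default_rng(2).permutation(30)
        assert harrell_ci(t, d, r) == pytest.approx(harrell_ci(t[perm], d[perm], r[perm]))

    def test_no_comparable_pairs_raises(self):
        with pytest.raises(ValueError):
            harrell_ci([5.0, 5.0], [1, 1], [0.1, 0.2])


class TestUno:
    def test_equals_harrell_without_censoring(self):
        rng = np.random.default_rng(3)
        t = rng.integers(1, 200, 40).astype(float)
        d = np.ones(40, int)
        r = rng.normal(size=40)
        assert uno_ci(t, d, t, d, r, tau=500) == pytest.approx(harrell_ci(t, d, r))

    def test_small_instance_matches_manual_ipcw(self):
        train_t = np.array([3, 6, 10, 15, 20.0])
        train_d = np.array([1, 0, 1, 0, 1])
        t = np.array([4, 9, 14, 18, 25.0])
        d = np.array([1, 1, 0, 1, 0])
        r = np.array([2.0, 1.0, 0.5, -0.3, -1.0])
        ours = uno_ci(train_t, train_d, t, d, r, tau=500)
        ref = oracles.bf_uno(train_t, train_d, t, d, r, tau=500)
        assert ours == pytest.approx(ref, abs=1e-15)

    def test_ipcw_reduces_censoring_bias_at_chance_level(self):
        """With risk-dependent censoring, Harrell's CI drifts from 0.5 on
        outcome-independent risks while the IPCW-weighted version stays
        closer, on average over replicates."""
        h_bias = u_bias = 0.0
        reps = 10
        for s in range(reps):
            rng = np.random.default_rng(100 + s)
            n = 800
            risk = rng.normal(size=n)
            t_true = rng.exponential(100, n)
            # high-risk patients censored systematically earlier
            c = rng.exponential(np.where(risk > 0, 40, 400))
            t = np.ceil(np.minimum(t_true, c)).clip(1)
            d = (t_true <= c).astype(int)
            h_bias += abs(harrell_ci(t, d, risk) - 0.5)
            u_bias += abs(uno_ci(t, d, t, d, risk, tau=500) - 0.5)
        assert u_bias / reps < h_bias / reps


class TestBrier:
    def test_perfect_oracle_scores_zero(self):
        t = np.array([10, 20, 30.0])
        d = np.ones(3, int)
        grid = np.arange(0, 41, dtype=float)
        curves = (grid[None, :] < t[:, None]).astype(float)
        km = censoring_km(t, d)
        for at in (5.0, 15.0, 35.0):
            assert brier_score(curves, grid, t, d, km, at) == pytest.approx(0.0)

    def test_constant_half_prediction_scores_quarter(self):
        t = np.array([10, 20, 30, 40.0])
        d = np.ones(4, int)
        grid = np.arange(0, 51, dtype=float)
        curves = np.full((4, 51), 0.5)
        km = censoring_km(t, d)
        assert brier_score(curves, grid, t, d, km, 25.0) == pytest.approx(0.25)

    def test_censored_instance_matches_hand_ipcw(self):
        t = np.array([10, 25, 40, 60, 80, 95.0])
        d = np.array([1, 0, 1, 1, 0, 1])
        _, _, _, grid, curves = random_instance(7, n=6)
        km = censoring_km(t, d)
        ours = brier_score(curves, grid, t, d, km, 50.0)
        ref = oracles.bf_brier(curves, grid, t, d, t, d, 50.0)
        assert ours == pytest.approx(ref, abs=1e-15)

    def test_empty_grid_rejected(self):
        t = np.array([10.0])
        with pytest.raises(ValueError):
            integrated_brier_score(np.ones((1, 2)), np.array([0.0, 1.0]), t,
                                   np.array([1]), censoring_km(t, np.array([1])),
                                   eval_grid=np.array([]))


class TestMarginMAE:
    def test_equals_plain_mae_without_censoring(self):
        t = np.array([30, 60, 90.0])
        pred = np.array([40, 50, 100.0])
        km = KaplanMeier.fit(t, np.ones(3, int))
        assert margin_mae(pred, t, np.ones(3, int), km) == pytest.approx(
            np.abs(pred - t).mean()
        )

    def test_memoryless_margin_offset_is_constant(self):
        rng = np.random.default_rng(5)
        t = np.ceil(rng.exponential(100, 20000)).clip(1)
        km = KaplanMeier.fit(t, np.ones_like(t, dtype=int))
        offsets = km.margin_times(np.array([20.0, 80.0, 150.0])) - [20.0, 80.0, 150.0]
        # e(c) - c = mean residual life = 100 for an exponential; the KM
        # tail truncation and sampling noise allow a modest tolerance
        assert np.all(np.abs(offsets - 100.0) < 8.0)

    def test_oracle_margin_predictions_score_zero_on_all_censored(self):
        train_t = np.array([10, 20, 30, 50.0])
        train_d = np.array([1, 1, 0, 1])
        km = KaplanMeier.fit(train_t, train_d)
        c = np.array([12, 22.0])
        preds = km.margin_times(c)
        assert margin_mae(preds, c, np.zeros(2, int), km) == pytest.approx(0.0)

    def test_matches_brute_force_on_small_instance(self):
        train_t = np.array([5, 12, 20, 33, 47.0])
        train_d = np.array([1, 0, 1, 1, 0])
        t = np.array([7, 15, 40.0])
        d = np.array([1, 0, 0])
        pred = np.array([10, 20, 30.0])
        km = KaplanMeier.fit(train_t, train_d)
        ref = oracles.bf_margin_mae(pred, t, d, train_t, train_d)
        assert margin_mae(pred, t, d, km) == pytest.approx(ref, abs=1e-12)


class TestDCalibration:
    def test_exact_decile_midpoints_pass_with_zero_statistic(self):
        probs = np.tile(np.arange(0.05, 1.0, 0.1), 10)
        res = d_calibration(probs, np.ones_like(probs, dtype=int))
        assert res.statistic == pytest.approx(0.0, abs=1e-12)
        assert res.passed

    def test_true_model_calibrated_on_simulated_censored_data(self):
        passes = 0
        for s in range(20):
            rng = np.random.default_rng(200 + s)
            n = 2000
            scale = rng.uniform(80, 300, n)  # heterogeneous truth
            t_true = rng.exponential(scale)
            c = rng.exponential(400, n)
            t = np.minimum(t_true, c)
            d = (t_true <= c).astype(int)
            p_obs = np.exp(-t / scale)  # true S_i at the observed time
            passes += d_calibration(p_obs, d).passed
        assert passes >= 18

    def test_gross_miscalibration_detected(self):
        fails = 0
        for s in range(20):
            rng = np.random.default_rng(300 + s)
            n = 2000
            t_true = rng.exponential(150, n)
            c = rng.exponential(400, n)
            d = (t_true <= c).astype(int)
            p_obs = np.full(n, 0.99)
            fails += not d_calibration(p_obs, d).passed
        assert fails >= 18

    def test_masses_sum_to_sample_size(self):
        rng = np.random.default_rng(8)
        p = rng.uniform(0, 1, 137)
        d = rng.integers(0, 2, 137)
        res = d_calibration(p, d)
        assert res.observed.sum() == pytest.approx(1.0, abs=1e-9)

    def test_censored_mass_spread_matches_oracle(self):
        rng = np.random.default_rng(9)
        p = rng.uniform(0, 1, 25)
        d = rng.integers(0, 2, 25)
        ref = oracles.bf_dcal_statistic(p, d)
        assert d_calibration(p, d).statistic == pytest.approx(ref, abs=1e-10)


class TestOracleEquivalence:
    """Every metric equals its brute-force twin on tiny fixtures."""

    @pytest.mark.parametrize("seed", range(10))
    def test_all_metrics_match_brute_force(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(4, 9))
        t, d, r, grid, curves = random_instance(seed * 7 + 1, n=n)
        if d.sum() == 0 or not (t[d == 1][:, None] < t[None, :]).any():
            d[np.argmin(t)] = 1
        assert harrell_ci(t, d, r) == pytest.approx(oracles.bf_harrell(t, d, r), abs=1e-12)
        assert uno_ci(t, d, t, d, r, tau=200) == pytest.approx(
            oracles.bf_uno(t, d, t, d, r, tau=200), abs=1e-12
        )
        km_c = censoring_km(t, d)
        eval_grid = np.linspace(5, 95, 7)
        assert integrated_brier_score(curves, grid, t, d, km_c, eval_grid) == pytest.approx(
            oracles.bf_ibs(curves, grid, t, d, t, d, eval_grid), abs=1e-12
        )
        km_e = KaplanMeier.fit(t, d)
        pred = rng.uniform(1, 150, n)
        assert margin_mae(pred, t, d, km_e) == pytest.approx(
            oracles.bf_margin_mae(pred, t, d, t, d), abs=1e-12
        )
        p_obs = curves_at_own_times(curves, grid, t)
        assert d_calibration(p_obs, d).statistic == pytest.approx(
            oracles.bf_dcal_statistic(p_obs, d), abs=1e-12
        )

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(st.integers(0, 10_000))
    def test_harrell_equals_enumeration_on_random_instances(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(3, 9))
        t = rng.integers(1, 20, n).astype(float)
        d = rng.integers(0, 2, n)
        r = np.round(rng.normal(size=n), 1)  # induce occasional risk ties
        comp = (t[:, None] < t[None, :]) & (d[:, None] == 1)
        if not comp.any():
            return
        assert harrell_ci(t, d, r) == pytest.approx(oracles.bf_harrell(t, d, r), abs=1e-12)
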