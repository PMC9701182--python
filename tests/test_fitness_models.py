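"""Fastest-pace mining, FTP spans, VO2max, critical speed, prediction harness."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from marathonlab.fitness_models import (
    DegenerateFitError,
    FastestPaceTable,
    best_span_pace,
    build_weekly_matrix,
    cumulative_fastest,
    cv_fit,
    evaluate_prediction,
    fastest_paces,
    fp_features,
    ftp_features,
    mae_by_week,
    tlim_estimate,
    vo2_features,
    vo2max_estimate,
)

from conftest import constant_activity, series_from_paces


def brute_fastest(paces, w):
    """Brute-force minimum mean pace over all contiguous windows of length w."""
    return min(
        sum(paces[i : i + w]) / w for i in range(len(paces) - w + 1)
    )


def brute_best_span(times, target_s):
    """Brute-force fastest pace over spans of cumulative duration >= target."""
    best = math.inf
    n = len(times)
    for i in range(n):
        for j in range(i + 1, n + 1):
            dur = sum(times[i:j])
            if dur >= target_s:
                best = min(best, (dur / 60.0) / ((j - i) * 0.1))
    return best


class TestFastestPaces:
    def test_worked_example(self):
        table = fastest_paces(series_from_paces([4.0, 6.0, 4.0, 4.0]))
        assert table.get(100) == pytest.approx(4.0)
        assert table.get(200) == pytest.approx(4.0)
        assert table.get(300) == pytest.approx(14 / 3)
        assert table.get(400) == pytest.approx(4.5)

    def test_constant_pace_flat_table(self):
        table = fastest_paces(constant_activity(2000, 5.0))
        assert all(p == pytest.approx(5.0) for p in table.paces.values())

    def test_monotone_in_distance_for_fading_efforts(self):
        """For an effort that only slows over its course (the physical shape
        of a maximal effort), the fastest pace cannot improve with distance.
        Erratically paced interval sessions can violate this, which is why the
        table stores raw window minima rather than forcing monotonicity."""
        rng = np.random.default_rng(0)
        paces = np.sort(rng.uniform(3.5, 7.0, 60))
        table = fastest_paces(series_from_paces(paces))
        ds = sorted(table.paces)
        vals = [table.paces[d] for d in ds]
        assert all(a <= b + 1e-12 for a, b in zip(vals, vals[1:]))

    @given(m=st.integers(1, 40), seed=st.integers(0, 10_000))
    @settings(max_examples=100, deadline=None)
    def test_matches_brute_force(self, m, seed):
        rng = np.random.default_rng(seed)
        paces = rng.uniform(3.0, 8.0, m)
        table = fastest_paces(series_from_paces(paces))
        for w in range(1, m + 1):
            assert table.get(100 * w) == pytest.approx(brute_fastest(list(paces), w))


class TestCumulativeFastest:
    def test_running_min(self):
        t1 = FastestPaceTable({100: 5.0})
        t2 = FastestPaceTable({100: 4.5})
        cum = cumulative_fastest([t1, t2])
        assert cum[1].get(100) == 4.5

    def test_single_table_identity(self):
        t = FastestPaceTable({100: 5.0, 200: 5.2})
        assert cumulative_fastest([t])[0].paces == t.paces

    def test_elementwise_non_increasing(self):
        rng = np.random.default_rng(1)
        tables = [
            fastest_paces(series_from_paces(rng.uniform(3.5, 7.0, 30)))
            for _ in range(5)
        ]
        cum = cumulative_fastest(tables)
        for earlier, later in zip(cum, cum[1:]):
            for d, p in earlier.paces.items():
                assert later.paces[d] <= p


class TestFP:
    def test_feature_lookup(self):
        cum = cumulative_fastest([fastest_paces(constant_activity(5000, 4.0))])[-1]
        feats = fp_features(cum)
        assert feats["fp_5k"] == pytest.approx(4.0)
        assert math.isnan(feats["fp_10k"])

    def test_pace_monotone_across_distances_for_fading_efforts(self):
        rng = np.random.default_rng(2)
        cum = cumulative_fastest(
            [
                fastest_paces(series_from_paces(np.sort(rng.uniform(3.5, 7.0, 120))))
                for _ in range(3)
            ]
        )[-1]
        f = fp_features(cum)
        assert f["fp_1500m"] <= f["fp_5k"] <= f["fp_10k"]


class TestFTP:
    def test_constant_hour_activity(self):
        # 15 km at 4.0 min/km = 60 minutes
        feats = ftp_features([constant_activity(15000, 4.0)])
        assert all(v == pytest.approx(4.0) for v in feats.values())

    def test_short_activity_gives_missing(self):
        feats = ftp_features([constant_activity(8000, 5.0)])  # 40 min
        assert all(math.isnan(v) for v in feats.values())

    def test_ftp45_not_slower_than_ftp60(self):
        rng = np.random.default_rng(3)
        acts = [series_from_paces(rng.uniform(4.0, 6.5, 180)) for _ in range(3)]
        feats = ftp_features(acts)
        assert feats["ftp_45"] <= feats["ftp_60"]

    @given(m=st.integers(5, 30), seed=st.integers(0, 10_000))
    @settings(max_examples=60, deadline=None)
    def test_matches_brute_force(self, m, seed):
        rng = np.random.default_rng(seed)
        times = rng.uniform(20.0, 60.0, m)  # seconds per 100 m
        series = series_from_paces(times / 6.0)
        target_min = float(rng.uniform(1.0, times.sum() / 60.0))
        got = best_span_pace(series, target_min)
        expected = brute_best_span(list(times), target_min * 60.0)
        assert got == pytest.approx(expected)


class TestVO2max:
    def test_velocity_intercept(self):
        # oxygen-cost polynomial at v -> 0 approaches the -4.6 intercept
        frac_10 = (
            0.8
            + 0.1894393 * math.exp(-0.012778 * 10.0)
            + 0.2989558 * math.exp(-0.1932605 * 10.0)
        )
        assert vo2max_estimate(10.0, 1e-9) * frac_10 == pytest.approx(-4.6)

    def test_duration_fraction_limit(self):
        # the sustainable fraction at t -> 0 is the coefficient sum 1.2883951
        v = 250.0
        vo2 = -4.6 + 0.182258 * v + 0.000104 * v**2
        assert vo2max_estimate(1e-9, v) == pytest.approx(vo2 / 1.2883951)

    def test_frozen_worked_value(self):
        # independently evaluated: t=20 min, v=250 m/min
        assert vo2max_estimate(20.0, 250.0) == pytest.approx(49.806233428066335)

    def test_monotone_in_velocity_and_duration(self):
        v = np.linspace(51, 599, 80)
        est = [vo2max_estimate(30.0, vi) for vi in v]
        assert all(a < b for a, b in zip(est, est[1:]))
        t = np.linspace(5, 120, 40)
        frac = [vo2max_estimate(ti, 250.0) for ti in t]
        assert all(a < b for a, b in zip(frac, frac[1:]))  # smaller max(t) divisor

    def test_vo2_features_single_distance_missing(self):
        cum = FastestPaceTable({1500: 4.0}, scope="cumulative")
        feats = vo2_features(cum)
        assert math.isnan(feats["vo2_mean"]) and math.isnan(feats["vo2_std"])

    def test_constant_speed_std_reflects_curvature(self):
        """All distances at one speed: the SD comes from max(t) decay only."""
        pace = 5.0
        cum = FastestPaceTable(
            {d: pace for d in range(1500, 10001, 100)}, scope="cumulative"
        )
        feats = vo2_features(cum)
        direct = [
            vo2max_estimate((d / 1000) * pace, 1000.0 / pace)
            for d in range(1500, 10001, 100)
        ]
        assert feats["vo2_mean"] == pytest.approx(np.mean(direct))
        assert feats["vo2_std"] == pytest.approx(np.std(direct))
        assert feats["vo2_std"] > 0


class TestCriticalSpeed:
    def test_tlim_worked_examples(self):
        assert tlim_estimate(3000, 4.0) == 720.0
        assert tlim_estimate(1000, 1.0) == 60.0
        assert tlim_estimate(5000, 4.0) == 1200.0

    def test_exact_line_recovery(self):
        # paces chosen so that D = 200 + 4 * T exactly
        table = {}
        for d in (1500, 3000, 5000, 10000):
            t_s = (d - 200) / 4.0
            table[d] = (t_s / 60.0) / (d / 1000.0)
        cs, dp = cv_fit(FastestPaceTable(table, scope="cumulative"))
        assert cs == pytest.approx(4.0)
        assert dp == pytest.approx(200.0)

    def test_degenerate_point_set_rejected(self):
        with pytest.raises(DegenerateFitError):
            cv_fit(FastestPaceTable({3000: 4.0}, scope="cumulative"))


@pytest.fixture(scope="module")
def cb_matrix(small_dataset):
    return build_weekly_matrix(small_dataset.histories, "CB")


class TestPredictionHarness:
    def test_cb_row_has_eleven_model_features(self, cb_matrix):
        meta = {"runner_id", "week", "model", "sex", "age", "marathon_time"}
        assert len(set(cb_matrix.columns) - meta) == 11

    def test_inactive_week_carries_forward(self):
        from conftest import history_of

        sessions = [(45, 10000, 5.0), (44, 5000, 4.5), (20, 8000, 5.2)]
        h = history_of(sessions)
        matrix = build_weekly_matrix([h], "FP")
        w6 = matrix[matrix.week == 6].iloc[0]
        w5 = matrix[matrix.week == 5].iloc[0]
        assert w5["fp_5k"] == w6["fp_5k"]

    def test_oracle_regressor_zero_error(self, cb_matrix):
        """A regressor that reads the true time off its inputs scores MAE 0."""

        class Oracle:
            def fit(self, x, y):
                return self

            def predict(self, x):
                return x[:, -1]  # mt_leak is the last feature column

        matrix = cb_matrix.copy()
        matrix["mt_leak"] = matrix["marathon_time"]
        result = evaluate_prediction(matrix, regressor_factory=Oracle, n_folds=5, seed=0)
        assert mae_by_week(result).max() < 1e-9

    def test_constant_mean_regressor_closed_form(self, cb_matrix):
        from sklearn.dummy import DummyRegressor

        from marathonlab.fitness_models import runner_folds

        matrix = cb_matrix
        result = evaluate_prediction(
            matrix,
            regressor_factory=lambda: DummyRegressor(strategy="mean"),
            n_folds=5,
            seed=1,
        )
        folds = runner_folds(matrix["runner_id"].tolist(), 5, 1)
        week = int(matrix["week"].max())
        wk = matrix[matrix["week"] == week]
        test_ids = set(folds[0])
        train_mean = wk[~wk.runner_id.isin(test_ids)]["marathon_time"].mean()
        expected = (wk[wk.runner_id.isin(test_ids)]["marathon_time"] - train_mean).abs().mean()
        got = result[(result.week == week) & (result.fold == 0)]["mae"].iloc[0]
        assert got == pytest.approx(expected)

    def test_fold_assignment_deterministic(self, small_dataset):
        from marathonlab.fitness_models import runner_folds

        ids = [h.runner_id for h in small_dataset.histories]
        assert runner_folds(ids, 5, 3) == runner_folds(ids, 5, 3)

    def test_weekly_fastest_paces_improve_for_improving_runner(self):
        """An improving runner's weekly cumulative fastest paces cannot get
        slower, and their final critical-speed estimate reaches CS_true.
        (The week-by-week CS regression itself is not monotone: adding a new
        mined distance segment can shift the fit's leverage either way.)"""
        from marathonlab.synthetic_data import (
            SimulationConfig,
            simulate_population,
            simulate_training_log,
        )

        cfg = SimulationConfig(n_runners=1, seed=19, noise_sd=0.0)
        (profile,) = simulate_population(cfg)
        history = simulate_training_log(profile, cfg)
        matrix = build_weekly_matrix([history], "FP").sort_values(
            "week", ascending=False
        )
        for col in ("fp_1500m", "fp_5k", "fp_10k"):
            diffs = np.diff(matrix[col].to_numpy())
            assert (diffs <= 1e-12).all()  # pace only speeds up
        cv = build_weekly_matrix([history], "CV")
        final_cs = cv[cv.week == 0]["cs"].iloc[0]
        assert final_cs == pytest.approx(profile.CS_true, rel=1e-6)
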