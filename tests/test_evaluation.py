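"""Metrics against brute-force oracles, Shapley axioms, incidence CIs."""

import itertools

import numpy as np
import pandas as pd
import pytest

from heatspike import evaluation as ev
from heatspike.errors import InvalidArgumentError, SchemaError


class TestClipping:
    @pytest.mark.parametrize(
        "value, outcome, expected",
        [(-0.5, "all", 0.0), (120.0, "all", 104.0), (50.0, "admission_death", 48.0),
         (47.0, "admission_death", 47.0), (104.0, "all", 104.0)],
    )
    def test_clip_values(self, value, outcome, expected):
        assert ev.clip_predictions([value], outcome)[0] == expected

    def test_idempotent(self):
        rng = np.random.default_rng(0)
        x = rng.uniform(-50, 250, 200)
        once = ev.clip_predictions(x, "all")
        assert np.array_equal(once, ev.clip_predictions(once, "all"))

    def test_derive_caps_from_training(self):
        frames = pd.DataFrame({"count_all": [0, 3, 52]})
        assert ev.derive_caps(frames, "all") == (0.0, 104.0)

    def test_clipping_never_increases_rmse_when_obs_within_caps(self):
        rng = np.random.default_rng(1)
        obs = rng.integers(0, 104, 500).astype(float)
        pred = obs + rng.normal(0, 30, 500)
        clipped = ev.clip_predictions(pred, "all")
        assert ev.rmse(obs, clipped) <= ev.rmse(obs, pred)


class TestRMSE:
    def test_zero_when_equal(self):
        assert ev.rmse([1, 2, 3], [1, 2, 3]) == 0.0

    def test_hand_arithmetic(self):
        assert ev.rmse([0, 0], [3, 4]) == pytest.approx(np.sqrt(12.5))

    def test_paired_permutation_invariance(self):
        rng = np.random.default_rng(2)
        obs, pred = rng.normal(size=50), rng.normal(size=50)
        perm = rng.permutation(50)
        assert ev.rmse(obs, pred) == pytest.approx(ev.rmse(obs[perm], pred[perm]))

    def test_errors(self):
        with pytest.raises(InvalidArgumentError):
            ev.rmse([], [])
        with pytest.raises(InvalidArgumentError):
            ev.rmse([1, 2], [1])


class TestSpikeDaySelection:
    def test_hand_type7_quantile(self):
        daily = pd.Series(
            np.arange(1, 11, dtype=float),
            index=pd.date_range("2015-07-01", periods=10, freq="D"),
        )
        sel = ev.select_spike_days(daily, q=0.8)
        assert sel.thresholds[2015] == pytest.approx(8.2)
        assert [d.day for d in sel.days[2015]] == [9, 10]

    def test_all_equal_totals_select_every_day(self):
        daily = pd.Series(5.0, index=pd.date_range("2015-07-01", periods=8, freq="D"))
        sel = ev.select_spike_days(daily)
        assert len(sel.days[2015]) == 8

    def test_per_year_thresholds(self):
        idx = pd.date_range("2015-07-01", periods=10, freq="D").append(
            pd.date_range("2016-07-01", periods=10, freq="D")
        )
        daily = pd.Series(np.r_[np.arange(10.0), np.arange(10.0) * 10], index=idx)
        sel = ev.select_spike_days(daily)
        assert sel.thresholds[2016] == pytest.approx(10 * sel.thresholds[2015])

    def test_fractional_threshold_on_integer_totals(self):
        """Interpolating quantiles give fractional thresholds on integer data."""
        daily = pd.Series(
            [10, 20, 30, 41, 53, 56, 70],
            index=pd.date_range("2015-07-01", periods=7, freq="D"),
            dtype=float,
        )
        sel = ev.select_spike_days(daily)
        assert sel.thresholds[2015] != int(sel.thresholds[2015])

    def test_short_year_warns(self):
        daily = pd.Series([1.0, 2.0], index=pd.date_range("2015-07-01", periods=2))
        with pytest.warns(UserWarning):
            ev.select_spike_days(daily)


class TestSpikeMetrics:
    def _series(self, values, start="2015-07-01"):
        return pd.Series(values, index=pd.date_range(start, periods=len(values), freq="D"), dtype=float)

    def test_mape_hand_arithmetic(self):
        obs = self._series([50, 100])
        pred = self._series([45, 120])
        assert ev.spike_day_mape(obs, pred, obs.index) == pytest.approx(15.0)

    def test_mape_zero_when_perfect(self):
        obs = self._series([50, 100])
        assert ev.spike_day_mape(obs, obs, obs.index) == 0.0

    def test_mape_single_day(self):
        obs, pred = self._series([100]), self._series([80])
        assert ev.spike_day_mape(obs, pred, obs.index) == pytest.approx(20.0)

    def test_mape_zero_observed_error(self):
        obs = self._series([0, 100])
        with pytest.raises(InvalidArgumentError):
            ev.spike_day_mape(obs, obs, obs.index)

    def test_mape_empty_days_error(self):
        obs = self._series([10])
        with pytest.raises(InvalidArgumentError):
            ev.spike_day_mape(obs, obs, [])

    def test_tape_hand_arithmetic(self):
        obs = self._series([100, 50])
        pred = self._series([110, 55])
        assert ev.total_abs_pct_error(obs, pred, obs.index) == pytest.approx(10.0)

    def test_tape_cancellation_vs_mape(self):
        obs = self._series([100, 100])
        pred = self._series([80, 120])
        assert ev.total_abs_pct_error(obs, pred, obs.index) == 0.0
        assert ev.spike_day_mape(obs, pred, obs.index) == pytest.approx(20.0)

    def test_tape_underprediction(self):
        obs = self._series([100, 100])
        pred = self._series([50, 50])
        assert ev.total_abs_pct_error(obs, pred, obs.index) == pytest.approx(50.0)

    def test_tape_zero_denominator_error(self):
        obs = self._series([0.0])
        with pytest.raises(InvalidArgumentError):
            ev.total_abs_pct_error(obs, obs, obs.index)


class TestMetricOracles:
    def test_brute_force_equivalence_100_fixtures(self):
        """RMSE / spike-day MAPE / total abs pct error vs independent loops."""
        rng = np.random.default_rng(42)
        for _ in range(100):
            n = int(rng.integers(5, 40))
            obs = rng.uniform(1, 200, n)
            pred = rng.uniform(0, 250, n)
            idx = pd.date_range("2015-06-01", periods=n, freq="D")
            so, sp = pd.Series(obs, index=idx), pd.Series(pred, index=idx)
            k = int(rng.integers(1, n + 1))
            days = list(idx[rng.choice(n, size=k, replace=False)])

            acc = 0.0
            for i in range(n):
                acc += (obs[i] - pred[i]) ** 2
            assert ev.rmse(obs, pred) == pytest.approx((acc / n) ** 0.5, rel=1e-9)

            total = 0.0
            for d in days:
                total += abs(so[d] - sp[d]) / so[d]
            assert ev.spike_day_mape(so, sp, days) == pytest.approx(
                total / len(days) * 100, rel=1e-9
            )

            s_obs = sum(so[d] for d in days)
            s_pred = sum(sp[d] for d in days)
            assert ev.total_abs_pct_error(so, sp, days) == pytest.approx(
                abs(s_pred - s_obs) / s_obs * 100, rel=1e-9
            )


class TestShapley:
    def test_additive_model_exact(self):
        def f(X):
            return 2 * X["x1"] + 3 * X["x2"]

        rows = pd.DataFrame({"x1": [1.0], "x2": [1.0]})
        bg = pd.DataFrame({"x1": [0.0], "x2": [0.0]})
        table = ev.shap_attributions(f, rows, bg, mode="exact_permutation")
        assert table.values.iloc[0]["x1"] == pytest.approx(2.0)
        assert table.values.iloc[0]["x2"] == pytest.approx(3.0)
        assert table.baseline == pytest.approx(0.0)

    def test_dummy_feature_zero_attribution(self):
        def f(X):
            return 5 * X["x1"]

        rows = pd.DataFrame({"x1": [2.0], "dummy": [9.0]})
        bg = pd.DataFrame({"x1": np.zeros(4), "dummy": np.arange(4.0)})
        table = ev.shap_attributions(f, rows, bg, mode="exact_permutation")
        assert table.values.iloc[0]["dummy"] == pytest.approx(0.0, abs=1e-12)

    def test_interaction_matches_permutation_brute_force(self):
        def f(X):
            return X["a"] * X["b"] + 2 * X["a"]

        rows = pd.DataFrame({"a": [1.5], "b": [2.0]})
        bg = pd.DataFrame({"a": [0.0, 1.0], "b": [0.0, -1.0]})
        table = ev.shap_attributions(f, rows, bg, mode="exact_permutation")

        # brute force: average marginal contributions over both orderings
        feats = ["a", "b"]

        def v(subset):
            z = bg.copy()
            for c in subset:
                z[c] = rows.iloc[0][c]
            return float(np.mean(f(z)))

        phi = {c: 0.0 for c in feats}
        for order in itertools.permutations(feats):
            current = []
            prev = v(())
            for c in order:
                current.append(c)
                val = v(tuple(current))
                phi[c] += (val - prev) / 2
                prev = val
        for c in feats:
            assert table.values.iloc[0][c] == pytest.approx(phi[c], rel=1e-9)

    def test_local_accuracy(self):
        rng = np.random.default_rng(3)

        def f(X):
            return np.sin(X["a"]) + X["b"] ** 2 + X["a"] * X["c"]

        rows = pd.DataFrame(rng.normal(size=(3, 3)), columns=["a", "b", "c"])
        bg = pd.DataFrame(rng.normal(size=(8, 3)), columns=["a", "b", "c"])
        table = ev.shap_attributions(f, rows, bg, mode="exact_permutation")
        gap = table.local_accuracy_gap(f(rows).to_numpy())
        assert np.all(np.abs(gap) < 1e-9)

    def test_sampled_converges_to_exact(self):
        rng = np.random.default_rng(4)

        def f(X):
            return X["a"] * X["b"] + 0.5 * X["c"]

        rows = pd.DataFrame(rng.normal(size=(2, 3)), columns=["a", "b", "c"])
        bg = pd.DataFrame(rng.normal(size=(5, 3)), columns=["a", "b", "c"])
        exact = ev.shap_attributions(f, rows, bg, mode="exact_permutation")
        sampled = ev.shap_attributions(
            f, rows, bg, mode="sampled", seed=0, n_permutations=2000
        )
        scale = np.abs(exact.values.to_numpy()).mean()
        mad = np.abs(exact.values.to_numpy() - sampled.values.to_numpy()).mean()
        assert mad < 0.05 * scale

    def test_errors(self):
        rows = pd.DataFrame({"a": [1.0]})
        with pytest.raises(InvalidArgumentError):
            ev.shap_attributions(lambda X: X["a"], rows, rows.iloc[:0])
        wide = pd.DataFrame(np.zeros((1, 11)), columns=[f"f{i}" for i in range(11)])
        with pytest.raises(InvalidArgumentError):
            ev.shap_attributions(lambda X: X.sum(axis=1), wide, wide)


class TestIncidenceRateCI:
    def test_training_all_case_worked_example(self):
        """11,349 cases over the training denominator print as 37.5 (36.8-38.2)."""
        rate, lo, hi = ev.incidence_rate_ci(11349, 11349 / 37.5 * 1e5)
        assert round(rate, 1) == 37.5
        assert round(lo, 1) == 36.8
        assert round(hi, 1) == 38.2

    def test_testing_all_case_worked_example(self):
        rate, lo, hi = ev.incidence_rate_ci(7513, 7513 / 74.4 * 1e5)
        assert round(rate, 1) == 74.4
        assert round(lo, 1) == 72.7
        assert round(hi, 1) == 76.1

    def test_hand_arithmetic(self):
        rate, lo, hi = ev.incidence_rate_ci(100, 100_000)
        assert rate == pytest.approx(100.0)
        assert lo == pytest.approx(80.4, abs=0.05)
        assert hi == pytest.approx(119.6, abs=0.05)

    def test_exact_poisson_option(self):
        rate, lo, hi = ev.incidence_rate_ci(100, 100_000, method="exact")
        assert lo < rate < hi
        assert lo == pytest.approx(81.36, abs=0.05)  # Garwood limits for 100 events

    def test_zero_cases_error(self):
        with pytest.raises(InvalidArgumentError):
            ev.incidence_rate_ci(0, 1000)


class TestEvaluateModels:
    def test_perfect_predictions_zero_metrics(self, bundle_medium):
        frames = bundle_medium["frames"]
        report = ev.evaluate_model(frames, frames["count_all"].to_numpy(float))
        assert report.rmse_overall == 0.0
        assert report.spike_day_mape == 0.0
        assert report.total_abs_pct_error == 0.0

    def test_constant_zero_predictions(self, bundle_medium):
        frames = bundle_medium["frames"]
        report = ev.evaluate_model(frames, np.zeros(len(frames)))
        rms_obs = np.sqrt(np.mean(frames["count_all"].to_numpy(float) ** 2))
        assert report.rmse_overall == pytest.approx(rms_obs)

    def test_report_cardinality(self, bundle_medium):
        frames = bundle_medium["frames"]
        preds = {
            "m1": {"training": np.ones(len(frames)), "testing": np.ones(len(frames))},
            "m2": {"training": np.ones(len(frames))},
        }
        reports = ev.evaluate_models({"training": frames, "testing": frames}, preds)
        assert len(reports) == 3

    def test_clip_counts_recorded(self, bundle_medium):
        frames = bundle_medium["frames"]
        pred = np.full(len(frames), -1.0)
        pred[:5] = 200.0
        report = ev.evaluate_model(frames, pred)
        assert report.n_clipped_low == len(frames) - 5
        assert report.n_clipped_high == 5

    def test_length_mismatch_error(self, bundle_medium):
        with pytest.raises(SchemaError):
            ev.evaluate_model(bundle_medium["frames"], np.zeros(3))

    def test_daily_totals_use_heat_day_convention(self, bundle_medium):
        frames = bundle_medium["frames"]
        daily = ev.daily_totals(frames)
        one_day = frames[frames["frame_date"] == frames["frame_date"].iloc[0]]
        assert daily.iloc[0] == one_day["count_all"].sum()
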