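"""Count-model families, CV machinery, RFE, and the predict contract."""

import numpy as np
import pandas as pd
import pytest

from heatspike import evaluation as ev
from heatspike import feature_engineering as fe
from heatspike import model_suite as ms
from heatspike import synthetic_data as sd
from heatspike.errors import (
    FitError,
    GridSearchError,
    InvalidArgumentError,
    SchemaError,
)

RECOVERY_PREDICTORS = ["Ta_mean", "Ta_diff_max", "RH_mean", "SR_mean"]


def _linear_truth(seed):
    return sd.SyntheticTruth(
        temp_effect=(0.09, 0.0), knee_effect=0.0, spike_boost=0.0,
        night_effect=0.0, rainy_effect=0.0, post_rainy_effect=0.0,
        holiday_effect=0.0, age_effect=0.0, income_effect=0.0,
        sex_ratio_effect=0.0, seed=seed,
    )


def _simulate(n_cities, years, seed, truth=None, year_offsets=None):
    profiles = sd.generate_city_profiles(n_cities, seed=seed)
    rainy, holidays = sd.make_calendars(years, seed=seed + 1)
    sim = sd.simulate_hourly_weather(profiles, years, seed=seed + 2, year_offsets=year_offsets)
    frames = fe.build_frames(
        sim.hourly, rainy, holidays, profiles, heatwave_days=sim.heatwave_days
    )
    truth = truth or sd.SyntheticTruth(seed=seed + 3)
    return sd.simulate_heatstroke_counts(frames, truth), truth


class TestGLM:
    def test_coefficient_recovery_single_seed(self):
        """Linear truth at n > 20,000 frames: every slope within 3 SE."""
        frames, truth = _simulate(
            12, [2013, 2014, 2015, 2016, 2017, 2018, 2019], seed=40,
            truth=_linear_truth(41),
        )
        assert len(frames) >= 20_000
        model = ms.fit_glm_poisson(frames, RECOVERY_PREDICTORS)
        res = model._impl
        expected = {
            "Ta_mean": truth.temp_effect[0],
            "Ta_diff_max": truth.diff24_effect,
            "RH_mean": truth.humidity_effect,
            "SR_mean": truth.solar_effect,
        }
        for name, true_beta in expected.items():
            est, se = res.params[name], res.bse[name]
            assert abs(est - true_beta) < 3 * se, name

    def test_intercept_only_closed_form(self):
        """With offset 0, exp(intercept-hat) is exactly the sample mean."""
        rng = np.random.default_rng(0)
        frames = pd.DataFrame(
            {"count_all": rng.poisson(4.0, 500), "log_population_offset": 0.0}
        )
        model = ms.fit_glm_poisson(frames, [], offset=True)
        assert np.exp(model._impl.params["const"]) == pytest.approx(
            frames["count_all"].mean(), rel=1e-8
        )

    def test_offset_proportionality_exact(self, bundle_medium):
        frames = bundle_medium["frames"]
        model = ms.fit_glm_poisson(frames, RECOVERY_PREDICTORS)
        doubled = frames.copy()
        doubled["log_population_offset"] += np.log(2)
        ratio = ms.predict_counts(model, doubled) / ms.predict_counts(model, frames)
        assert np.allclose(ratio, 2.0, rtol=1e-12)

    def test_predictions_strictly_positive(self, bundle_medium):
        model = ms.fit_glm_poisson(bundle_medium["frames"], RECOVERY_PREDICTORS)
        assert (ms.predict_counts(model, bundle_medium["frames"]) > 0).all()

    def test_singular_design_error_names_columns(self, bundle_medium):
        frames = bundle_medium["frames"].copy()
        frames["dead"] = 1.0
        with pytest.raises(FitError, match="dead"):
            ms.fit_glm_poisson(frames, RECOVERY_PREDICTORS + ["dead"])


class TestGAM:
    def test_beats_linear_glm_on_quadratic_truth(self):
        truth = sd.SyntheticTruth(
            temp_effect=(0.09, 0.012), knee_effect=0.0, spike_boost=0.0,
            night_effect=0.0, rainy_effect=0.0, post_rainy_effect=0.0,
            holiday_effect=0.0, age_effect=0.0, income_effect=0.0,
            sex_ratio_effect=0.0, seed=61,
        )
        frames, _ = _simulate(6, [2015, 2016], seed=60, truth=truth)
        yr = frames["frame_date"].dt.year
        train, test = frames[yr == 2015], frames[yr == 2016]
        glm = ms.fit_glm_poisson(train, RECOVERY_PREDICTORS)
        gam = ms.fit_gam_poisson(train, RECOVERY_PREDICTORS)
        obs = test["count_all"].to_numpy(float)

        def poisson_deviance(mu):
            mu = np.clip(mu, 1e-9, None)
            with np.errstate(divide="ignore", invalid="ignore"):
                term = np.where(obs > 0, obs * np.log(obs / mu), 0.0)
            return 2 * np.sum(term - (obs - mu))

        assert poisson_deviance(ms.predict_counts(gam, test)) < poisson_deviance(
            ms.predict_counts(glm, test)
        )

    def test_edf_small_when_truth_linear(self):
        frames, _ = _simulate(6, [2015], seed=70, truth=_linear_truth(71))
        gam = ms.fit_gam_poisson(
            frames, RECOVERY_PREDICTORS, smooth_config={"alpha": "select", "terms": ["Ta_mean"]}
        )
        edf = ms.gam_smooth_edf(gam)
        assert edf["Ta_mean"] <= 2.5

    def test_zero_variance_predictor_dropped(self, bundle_medium):
        frames = bundle_medium["frames"].copy()
        frames["flat"] = 3.0
        with pytest.warns(UserWarning, match="zero-variance"):
            model = ms.fit_gam_poisson(frames, RECOVERY_PREDICTORS + ["flat"])
        assert "flat" not in model.selected_predictors

    def test_offset_proportionality(self, bundle_medium):
        frames = bundle_medium["frames"]
        gam = ms.fit_gam_poisson(frames, RECOVERY_PREDICTORS)
        doubled = frames.copy()
        doubled["log_population_offset"] += np.log(2)
        ratio = ms.predict_counts(gam, doubled) / ms.predict_counts(gam, frames)
        assert np.allclose(ratio, 2.0, rtol=1e-10)


class TestTrees:
    def test_capacity_on_step_function(self):
        rng = np.random.default_rng(0)
        n = 2000
        frames = pd.DataFrame(
            {
                "x": rng.uniform(0, 1, n),
                "population": 1.0,
            }
        )
        frames["count_all"] = np.where(frames["x"] > 0.5, 10.0, 0.0)
        for family in ("random_forest", "boosted_trees"):
            model = ms.fit_tree_regressor(frames, ["x"], family, seed=1)
            rmse = ev.rmse(frames["count_all"], ms.predict_counts(model, frames))
            assert rmse < 0.05 * frames["count_all"].std(), family

    def test_constant_target(self):
        frames = pd.DataFrame({"x": np.arange(50.0), "population": 1.0, "count_all": 7.0})
        model = ms.fit_tree_regressor(frames, ["x"], "random_forest", seed=0)
        assert np.allclose(ms.predict_counts(model, frames), 7.0)

    def test_seed_determinism(self, bundle_medium):
        frames = bundle_medium["frames"]
        a = ms.fit_tree_regressor(frames, RECOVERY_PREDICTORS, "boosted_trees", seed=5)
        b = ms.fit_tree_regressor(frames, RECOVERY_PREDICTORS, "boosted_trees", seed=5)
        assert np.array_equal(
            ms.predict_counts(a, frames), ms.predict_counts(b, frames)
        )

    def test_population_forced_into_predictors(self, bundle_medium):
        model = ms.fit_tree_regressor(
            bundle_medium["frames"], ["Ta_mean"], "boosted_trees", seed=0
        )
        assert "population" in model.selected_predictors
        assert not model.uses_offset

    def test_poisson_objective_nonnegative(self, bundle_medium):
        frames = bundle_medium["frames"]
        model = ms.fit_tree_regressor(frames, RECOVERY_PREDICTORS, "boosted_trees", seed=2)
        assert (ms.predict_counts(model, frames) >= 0).all()


class TestCV:
    def test_folds_partition_rows(self, bundle_medium):
        frames = bundle_medium["frames"]
        for assignment in ("random_rows", "blocked_by_time"):
            plan = ms.CVPlan(fold_assignment=assignment, seed=4)
            folds = plan.folds(frames)
            assert len(folds) == 5
            all_valid = np.concatenate([v for _, v in folds])
            assert sorted(all_valid) == list(range(len(frames)))
            for train_idx, valid_idx in folds:
                assert not set(train_idx) & set(valid_idx)

    def test_fold_metric_matches_hand_oracle(self):
        """Per-fold RMSE on a 20-row fixture against a hand loop."""
        rng = np.random.default_rng(3)
        frames = pd.DataFrame(
            {"count_all": rng.poisson(3, 20).astype(float), "log_population_offset": 0.0}
        )
        plan = ms.CVPlan(n_folds=4, seed=9)

        class MeanModel:
            def __init__(self, mean):
                self.mean = mean

            def predict(self, df):
                return np.full(len(df), self.mean)

        def factory(params, tr):
            return MeanModel(tr["count_all"].mean())

        _, table = ms.grid_search_cv(factory, frames, [{}], plan)
        hand = []
        for train_idx, valid_idx in plan.folds(frames):
            mu = frames.iloc[train_idx]["count_all"].mean()
            obs = frames.iloc[valid_idx]["count_all"].to_numpy()
            hand.append(np.sqrt(np.mean((obs - mu) ** 2)))
        assert table["score"].iloc[0] == pytest.approx(np.mean(hand), rel=1e-12)

    def test_singleton_grid(self, bundle_medium):
        frames = bundle_medium["frames"]
        factory = ms.tree_factory(RECOVERY_PREDICTORS, "boosted_trees", seed=0)
        best, table = ms.grid_search_cv(
            factory, frames.head(400), [{"n_estimators": 20}], ms.CVPlan(seed=1)
        )
        assert best == {"n_estimators": 20}
        assert len(table) == 1

    def test_tie_break_first_in_grid(self):
        frames = pd.DataFrame({"count_all": np.arange(20.0), "log_population_offset": 0.0})

        class Zero:
            def predict(self, df):
                return np.zeros(len(df))

        best, _ = ms.grid_search_cv(
            lambda p, tr: Zero(), frames, [{"tag": "first"}, {"tag": "second"}],
            ms.CVPlan(n_folds=4, seed=0),
        )
        assert best == {"tag": "first"}

    def test_all_failures_raise(self):
        frames = pd.DataFrame({"count_all": np.arange(20.0), "log_population_offset": 0.0})

        def broken(params, tr):
            raise ValueError("boom")

        with pytest.raises(GridSearchError):
            with pytest.warns(UserWarning):
                ms.grid_search_cv(broken, frames, [{}], ms.CVPlan(n_folds=4, seed=0))

    def test_true_model_selected_over_misspecified(self):
        """Grid {matching predictors, noise-only predictors}: the matching
        point wins CV RMSE."""
        frames, _ = _simulate(4, [2015], seed=90, truth=_linear_truth(91))
        rng = np.random.default_rng(1)
        frames["noise"] = rng.normal(size=len(frames))

        def factory(params, tr):
            return ms.fit_glm_poisson(tr, params["predictors"])

        best, _ = ms.grid_search_cv(
            factory,
            frames,
            [{"predictors": ["Ta_mean", "SR_mean"]}, {"predictors": ["noise"]}],
            ms.CVPlan(seed=2),
        )
        assert best["predictors"] == ["Ta_mean", "SR_mean"]


class TestRFE:
    def test_informative_predictor_retained(self):
        frames, _ = _simulate(6, [2015], seed=100, truth=_linear_truth(101))
        rng = np.random.default_rng(5)
        for k in range(4):
            frames[f"noise{k}"] = rng.normal(size=len(frames))
        selected, profile = ms.rfe_select(
            ms.rfe_glm_factory(),
            frames,
            ["Ta_mean", "noise0", "noise1", "noise2", "noise3"],
            ms.CVPlan(seed=6),
        )
        assert "Ta_mean" in selected
        assert len(profile) == 5

    def test_all_informative_full_set_possible(self):
        frames, _ = _simulate(6, [2015], seed=110, truth=_linear_truth(111))
        selected, _ = ms.rfe_select(
            ms.rfe_glm_factory(), frames, RECOVERY_PREDICTORS, ms.CVPlan(seed=7)
        )
        assert set(selected) <= set(RECOVERY_PREDICTORS)
        assert len(selected) >= 2

    def test_single_candidate_returned(self, bundle_medium):
        selected, _ = ms.rfe_select(
            ms.rfe_glm_factory(), bundle_medium["frames"], ["Ta_mean"], ms.CVPlan(seed=0)
        )
        assert selected == ["Ta_mean"]


class TestCitySpecific:
    def test_one_model_per_city(self, bundle_medium):
        models = ms.fit_city_specific(
            bundle_medium["frames"], "glm", min_rows=100
        )
        assert set(models) == set(bundle_medium["frames"]["city_id"].unique())
        for m in models.values():
            assert not (set(m.selected_predictors) & set(ms.CITY_PREDICTORS))

    def test_row_floor_skips_city(self, bundle_medium):
        frames = bundle_medium["frames"]
        small = frames.groupby("city_id").head(50)
        with pytest.warns(UserWarning, match="floor"):
            models = ms.fit_city_specific(small, "glm", min_rows=100)
        assert models == {}

    def test_constant_zero_city(self, bundle_medium):
        frames = bundle_medium["frames"].copy()
        city = frames["city_id"].iloc[0]
        frames.loc[frames["city_id"] == city, "count_all"] = 0
        models = ms.fit_city_specific(frames, "glm", min_rows=100)
        pred = ms.predict_counts(models[city], frames[frames["city_id"] == city])
        assert pred.max() < 0.01

    def test_pooled_within_10pct_on_homogeneous_cities(self, bundle_medium):
        frames = bundle_medium["frames"]
        pooled = ms.fit_glm_poisson(
            frames, [p for p in ms.WEATHER_PREDICTORS + ms.CALENDAR_PREDICTORS]
        )
        per_city = ms.fit_city_specific(frames, "glm", min_rows=100)
        obs = frames["count_all"].to_numpy(float)
        rmse_pooled = ev.rmse(obs, ms.predict_counts(pooled, frames))
        rmse_city = ev.rmse(obs, ms.predict_city_specific(per_city, frames))
        assert rmse_city <= 1.10 * rmse_pooled


class TestPredictContract:
    def test_missing_column_schema_error(self, bundle_medium):
        model = ms.fit_glm_poisson(bundle_medium["frames"], RECOVERY_PREDICTORS)
        with pytest.raises(SchemaError, match="Ta_mean"):
            ms.predict_counts(model, bundle_medium["frames"].drop(columns=["Ta_mean"]))

    def test_empty_frames(self, bundle_medium):
        model = ms.fit_glm_poisson(bundle_medium["frames"], RECOVERY_PREDICTORS)
        assert len(ms.predict_counts(model, bundle_medium["frames"].iloc[:0])) == 0

    @pytest.mark.parametrize("family", ["glm", "gam", "boosted_trees"])
    def test_save_load_round_trip(self, tmp_path, bundle_medium, family):
        frames = bundle_medium["frames"]
        if family == "glm":
            model = ms.fit_glm_poisson(frames, RECOVERY_PREDICTORS)
        elif family == "gam":
            model = ms.fit_gam_poisson(frames, RECOVERY_PREDICTORS)
        else:
            model = ms.fit_tree_regressor(frames, RECOVERY_PREDICTORS, family, seed=1)
        ms.save_model(model, tmp_path / family)
        again = ms.load_model(tmp_path / family)
        assert np.array_equal(
            ms.predict_counts(model, frames), ms.predict_counts(again, frames)
        )
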