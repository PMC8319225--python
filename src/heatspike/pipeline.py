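"""End-to-end orchestration: simulate → features → fit → spike-tune → hybrid → evaluate.

A run is described by a :class:`RunConfig` (YAML-loadable).  All stage seeds
are derived deterministically from the master seed, so identical config +
seed reproduces every intermediate and final artefact; metric reports are
byte-identical across reruns.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .errors import ConfigurationError, GapError, SchemaError
from . import evaluation as ev
from . import feature_engineering as fe
from . import model_suite as ms
from . import spike_ensemble as se
from . import synthetic_data as sd

logger = logging.getLogger(__name__)

STAGES = ("simulate", "features", "fit", "spike", "hybrid", "evaluate")


def stage_seed(master_seed: int, stage: str) -> int:
    """Deterministic per-stage seed below 2^31 derived from the master seed."""
    digest = hashlib.sha256(f"{master_seed}:{stage}".encode()).digest()
    return int.from_bytes(digest[:4], "big") % (2**31)


@dataclass
class RunConfig:
    """Configuration of one pipeline run (defaults match the study constants)."""

    outdir: str = "runs/run"
    seed: int = 0
    synthetic: bool = True
    n_cities: int = 16
    training_years: list[int] = field(default_factory=lambda: [2015, 2016, 2017])
    testing_year: int = 2018
    outcome: str = "all"
    # input CSV paths when synthetic is false
    weather_csv: str | None = None
    city_profiles_csv: str | None = None
    counts_csv: str | None = None
    rainy_csv: str | None = None
    holidays_csv: str | None = None
    # modelling options
    rfe: bool = False
    gam_alpha: float | str = 10.0
    tree_grids: dict = field(default_factory=lambda: {
        "random_forest": [{"n_estimators": 200, "min_samples_leaf": 2}],
        "boosted_trees": [{"n_estimators": 200, "max_depth": 4, "learning_rate": 0.1}],
    })
    city_specific: bool = True
    city_row_floor: int = 100
    cv_folds: int = 5
    # spike / hybrid options
    spike_enabled: bool = True
    spike_trigger_mape: float = 0.0  # run the spike stage when best MAPE exceeds this
    spike_percentile_grid: list[int] = field(default_factory=lambda: list(range(90, 99)))
    spike_n_grid: list[int] = field(default_factory=lambda: [100, 200])
    spike_bags: int = 10
    classifier_grid: list[dict] = field(default_factory=lambda: [{"n_estimators": 100, "max_depth": 3}])
    regressor_grid: list[dict] = field(default_factory=lambda: [{"n_estimators": 200, "max_depth": 4}])
    hybrid_lower_sum: float = 150.0
    hybrid_upper_sum: float = 300.0
    hybrid_reference_population: float | None = 1.0e7

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        payload = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = sorted(set(payload) - known)
        if unknown:
            raise ConfigurationError(f"unknown config keys: {unknown}")
        return cls(**payload)

    def validate(self) -> None:
        if self.testing_year in self.training_years:
            raise ConfigurationError(
                f"testing year {self.testing_year} overlaps the training years"
            )
        if self.outcome not in ("all", "admission_death"):
            raise ConfigurationError(f"unknown outcome {self.outcome!r}")
        if not self.synthetic:
            for key in ("weather_csv", "city_profiles_csv", "counts_csv", "rainy_csv", "holidays_csv"):
                path = getattr(self, key)
                if path is None or not Path(path).exists():
                    raise ConfigurationError(f"input file for {key} missing: {path}")

    def config_hash(self) -> str:
        blob = json.dumps(dataclasses.asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


def validate_inputs(paths: dict[str, str]) -> dict:
    """Schema report for a bundle of input CSVs; raises on violations.

    Checks column presence, hourly continuity of the weather table, severity
    labels of an optional registry table, and city-id referential integrity.
    """
    report = {"files": {}, "violations": []}
    required = {
        "weather": ["city_id", "timestamp", "Ta", "RH", "precip", "WS", "SR"],
        "city_profiles": ["city_id", "population_day", "population_night"],
        "rainy": ["year", "rainy_season_end"],
        "holidays": ["year", "date"],
    }
    tables = {}
    for key, cols in required.items():
        path = paths.get(key)
        if path is None:
            report["violations"].append(f"{key}: missing path")
            continue
        df = pd.read_csv(path)
        tables[key] = df
        missing = [c for c in cols if c not in df.columns]
        if missing:
            report["violations"].append(f"{key}: missing columns {missing}")
        report["files"][key] = {"rows": len(df)}
    if "weather" in tables and not report["violations"]:
        w = tables["weather"]
        w["timestamp"] = pd.to_datetime(w["timestamp"])
        try:
            fe.rolling_prev24_stats(w[["city_id", "timestamp", "Ta"]].assign(RH=0.0)[
                ["city_id", "timestamp", "Ta", "RH"]
            ])
        except GapError as exc:
            report["violations"].append(f"weather: {exc}")
        cities_w = set(w["city_id"])
        cities_p = set(tables["city_profiles"]["city_id"])
        orphan = sorted(cities_w - cities_p)
        if orphan:
            report["violations"].append(f"weather: cities without profile {orphan}")
    if "events" in paths:
        evd = pd.read_csv(paths["events"])
        bad = sorted(set(evd["severity"]) - set(sd.SEVERITIES))
        if bad:
            report["violations"].append(f"events: unknown severities {bad}")
    report["ok"] = not report["violations"]
    if not report["ok"]:
        raise SchemaError("; ".join(report["violations"]))
    return report


def _write_json(path: Path, payload) -> None:
    path.parent.mkdir(parents=True, exist_ok=True)
    path.write_text(json.dumps(payload, indent=2, sort_keys=True))


def run_pipeline(config: RunConfig) -> dict:
    """Execute all stages; returns a results dict and writes the run directory."""
    config.validate()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    years = sorted(config.training_years) + [config.testing_year]
    outcome = config.outcome
    outcome_col = ev.OUTCOME_COLUMNS[outcome]

    # --- simulate / load ---------------------------------------------------
    if config.synthetic:
        s = stage_seed(config.seed, "simulate")
        profiles = sd.generate_city_profiles(config.n_cities, seed=s)
        rainy, holidays = sd.make_calendars(years, seed=s + 1)
        sim = sd.simulate_hourly_weather(profiles, years, seed=s + 2)
        hourly, heatwave_days = sim.hourly, sim.heatwave_days
        prof_df = sd.profiles_frame(profiles)
        truth = sd.SyntheticTruth(seed=s + 3)
    else:
        hourly = pd.read_csv(config.weather_csv, parse_dates=["timestamp"])
        prof_df = pd.read_csv(config.city_profiles_csv)
        rainy = pd.read_csv(config.rainy_csv)
        holidays = pd.read_csv(config.holidays_csv)
        heatwave_days, truth = None, None

    # --- features ----------------------------------------------------------
    frames = fe.build_frames(hourly, rainy, holidays, prof_df, heatwave_days=heatwave_days)
    if config.synthetic:
        frames = sd.simulate_heatstroke_counts(frames, truth, heatwave_days=heatwave_days)
    else:
        counts = pd.read_csv(config.counts_csv, parse_dates=["frame_date"])
        key = ["city_id", "frame_date", "period"]
        frames = frames.drop(columns=["count_all", "count_admission_death"]).merge(
            counts[key + ["count_all", "count_admission_death"]], on=key, how="inner"
        )
    frames.to_csv(outdir / "frames.csv", index=False)
    year_of = frames["frame_date"].dt.year
    train = frames[year_of.isin(config.training_years)].reset_index(drop=True)
    test = frames[year_of == config.testing_year].reset_index(drop=True)
    splits = {"training": train, "testing": test}

    # --- fit the five families --------------------------------------------
    fit_seed = stage_seed(config.seed, "fit")
    cv = ms.CVPlan(n_folds=config.cv_folds, seed=fit_seed)
    predictors = ms.DEFAULT_PREDICTORS
    if config.rfe:
        predictors, rfe_table = ms.rfe_select(
            ms.rfe_glm_factory(outcome=outcome_col), train, predictors, cv,
            outcome=outcome_col,
        )
        rfe_table.to_csv(outdir / "rfe_profile.csv", index=False)

    models: dict[str, ms.FittedCountModel] = {}
    models["glm_wbgt_only"] = ms.fit_glm_poisson(
        train, ["WBGT_mean"], offset=True, outcome=outcome_col
    )
    models["glm"] = ms.fit_glm_poisson(train, predictors, offset=True, outcome=outcome_col)
    models["gam"] = ms.fit_gam_poisson(
        train, predictors, offset=True, outcome=outcome_col,
        smooth_config={"alpha": config.gam_alpha},
    )
    for family in ("random_forest", "boosted_trees"):
        grid = config.tree_grids.get(family, [{}])
        factory = ms.tree_factory(predictors, family, seed=fit_seed, outcome=outcome_col)
        if len(grid) == 1:
            best = grid[0]
        else:
            best, table = ms.grid_search_cv(factory, train, grid, cv, outcome=outcome_col)
            table.to_json(outdir / f"grid_{family}.json", orient="records")
        models[family] = ms.fit_tree_regressor(
            train, predictors, family, hyperparameters=best, seed=fit_seed,
            outcome=outcome_col,
        )

    predictions = {
        name: {split: ms.predict_counts(m, df) for split, df in splits.items()}
        for name, m in models.items()
    }
    reports = ev.evaluate_models(splits, predictions, outcome=outcome)

    # the best pooled family is chosen by 5-fold CV RMSE on the training
    # split (training-set RMSE would always crown the deepest tree model)
    factories = {
        "glm_wbgt_only": ms.glm_factory(["WBGT_mean"], outcome=outcome_col),
        "glm": ms.glm_factory(predictors, outcome=outcome_col),
        "gam": ms.gam_factory(
            predictors, outcome=outcome_col, smooth_config={"alpha": config.gam_alpha}
        ),
        "random_forest": ms.tree_factory(
            predictors, "random_forest", seed=fit_seed, outcome=outcome_col
        ),
        "boosted_trees": ms.tree_factory(
            predictors, "boosted_trees", seed=fit_seed, outcome=outcome_col
        ),
    }
    for name, model in models.items():
        point = model.hyperparameters if name in ms.TREE_FAMILIES else {}
        _, cv_table = ms.grid_search_cv(
            factories[name], train, [point], cv, outcome=outcome_col
        )
        model.cv_rmse = float(cv_table["score"].iloc[0])
    best_name = min(models, key=lambda n: models[n].cv_rmse)
    logger.info("best pooled family by CV RMSE: %s", best_name)

    # --- city-specific heterogeneity check ---------------------------------
    if config.city_specific:
        city_models = ms.fit_city_specific(
            train,
            models["gam"].family if best_name == "gam" else best_name,
            cv_plan=cv,
            outcome=outcome_col,
            min_rows=config.city_row_floor,
            seed=fit_seed,
            smooth_config={"alpha": config.gam_alpha, "df": 5},
        )
        city_pred = {
            split: ms.predict_city_specific(city_models, df) for split, df in splits.items()
        }
        covered = {s: ~np.isnan(p) for s, p in city_pred.items()}
        city_reports = [
            ev.evaluate_model(
                splits[s][covered[s]].reset_index(drop=True),
                city_pred[s][covered[s]],
                outcome=outcome,
                model_name="city_specific",
                split=s,
            )
            for s in splits
        ]
        reports.extend(city_reports)

    # --- spike stage --------------------------------------------------------
    hybrid_pred = None
    spike_cfg = None
    best_training_mape = next(
        r.spike_day_mape for r in reports if r.model == best_name and r.split == "training"
    )
    run_spike = config.spike_enabled or (
        best_training_mape is not None and best_training_mape > config.spike_trigger_mape
    )
    if run_spike:
        sseed = stage_seed(config.seed, "spike")
        base_cfg = se.SpikeConfig(n_bags=config.spike_bags, seed=sseed)
        spike_cfg, ensemble, audit = se.tune_spike_config(
            train,
            prof_df,
            percentile_grid=config.spike_percentile_grid,
            n_grid=config.spike_n_grid,
            cv_plan=ms.CVPlan(n_folds=config.cv_folds, seed=sseed),
            config=base_cfg,
            classifier_grid=config.classifier_grid,
            regressor_grid=config.regressor_grid,
            outcome=outcome,
        )
        audit.to_csv(outdir / "spike_tuning_audit.csv", index=False)
        ens_pred = {split: ensemble.predict(df) for split, df in splits.items()}
        predictions["undersampling_ensemble"] = ens_pred
        reports.extend(
            ev.evaluate_models(splits, {"undersampling_ensemble": ens_pred}, outcome=outcome)
        )

        # --- hybrid blend ---------------------------------------------------
        smooth_name = "gam"
        hybrid_cfg = se.HybridConfig(
            lower_sum=config.hybrid_lower_sum,
            upper_sum=config.hybrid_upper_sum,
            reference_population=config.hybrid_reference_population,
        )
        covered_pop = float(prof_df["population_night"].sum())
        hybrid_pred = {}
        for split, df in splits.items():
            res = se.blend_hybrid(
                predictions[smooth_name][split],
                ens_pred[split],
                df,
                hybrid_cfg,
                covered_population=covered_pop,
            )
            hybrid_pred[split] = res.predictions
            res.day_table.to_csv(outdir / f"hybrid_branches_{split}.csv", index=False)
        predictions["hybrid"] = hybrid_pred
        reports.extend(ev.evaluate_models(splits, {"hybrid": hybrid_pred}, outcome=outcome))

    # --- persist ------------------------------------------------------------
    for name, model in models.items():
        ms.save_model(model, outdir / "models" / name)
    pred_frame = []
    for name, per_split in predictions.items():
        for split, pred in per_split.items():
            df = splits[split][["city_id", "frame_date", "period", outcome_col]].copy()
            df["model"], df["split"], df["prediction"] = name, split, pred
            pred_frame.append(df)
    pd.concat(pred_frame, ignore_index=True).to_csv(outdir / "predictions.csv", index=False)

    metrics = {
        "outcome": outcome,
        "best_family": best_name,
        "spike_config": None
        if spike_cfg is None
        else {"percentile": spike_cfg.percentile, "undersample_n": spike_cfg.undersample_n},
        "reports": [r.to_dict() for r in reports],
    }
    _write_json(outdir / "metrics.json", metrics)
    ev.reports_frame(reports).to_csv(outdir / "metrics_summary.csv", index=False)
    import sklearn
    import statsmodels
    import xgboost

    manifest = {
        "package_version": __version__,
        "library_versions": {
            "numpy": np.__version__,
            "pandas": pd.__version__,
            "statsmodels": statsmodels.__version__,
            "scikit-learn": sklearn.__version__,
            "xgboost": xgboost.__version__,
        },
        "config": dataclasses.asdict(config),
        "config_hash": config.config_hash(),
        "master_seed": config.seed,
        "stage_seeds": {s: stage_seed(config.seed, s) for s in STAGES},
        "n_frames": {k: len(v) for k, v in splits.items()},
    }
    _write_json(outdir / "manifest.json", manifest)
    return {
        "frames": frames,
        "splits": splits,
        "models": models,
        "predictions": predictions,
        "reports": reports,
        "metrics": metrics,
        "outdir": outdir,
    }
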