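"""Under-sampling-and-bagging spike ensemble and the hybrid blend.

Rare heat-wave days dominate the public-health cost of forecast errors but
contribute few training rows, so a count regressor fit on all frames learns
the quiet majority and under-predicts spikes.  The procedure here rebalances
the training data in five steps:

1. seed sets — big-city rows (population > 500,000) whose count is at or
   above a chosen percentile (90–98) of big-city counts form the spike seed;
   a seeded random 10% of big-city zero-count rows forms the no-spike seed;
2. a boosted-tree classifier is trained on the two seeds (5-fold CV grid
   search by accuracy);
3. the classifier labels every big-city training row spike / no-spike; all
   rows of smaller cities are labelled no-spike a priori;
4. ten bags are fitted: each combines ALL spike rows with a seeded
   under-sample of 100 or 200 no-spike rows (without replacement within a
   bag) and trains a Poisson-objective boosted-tree regressor; the ensemble
   prediction is the arithmetic mean over bags;
5. the hybrid blend switches per heat day on the ensemble's predicted
   all-city daily total S: below the lower threshold the smooth baseline
   (GAM) is used, at or above the upper threshold the ensemble, in between
   their element-wise mean.

The 150/300 thresholds are absolute daily case counts appropriate for a
~10-million-person region; they scale linearly with the covered population
via ``HybridConfig.reference_population``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from xgboost import XGBClassifier

from .errors import ConfigurationError, FitError, InvalidArgumentError, SchemaError
from .evaluation import daily_totals, select_spike_days, spike_day_mape
from .model_suite import (
    CALENDAR_PREDICTORS,
    CITY_PREDICTORS,
    WEATHER_PREDICTORS,
    CVPlan,
    FittedCountModel,
    build_design,
    fit_tree_regressor,
    grid_search_cv,
    predict_counts,
    tree_factory,
)

logger = logging.getLogger(__name__)

#: predictors for the classifier and the bagged regressors: weather,
#: calendar, and city characteristics (population as an ordinary predictor).
SPIKE_PREDICTORS = WEATHER_PREDICTORS + CALENDAR_PREDICTORS + CITY_PREDICTORS + ["population"]

DEFAULT_CLASSIFIER_GRID = [
    {"n_estimators": n, "max_depth": d} for n in (100, 200) for d in (3, 5)
]
DEFAULT_REGRESSOR_GRID = [
    {"n_estimators": n, "max_depth": d} for n in (100, 200) for d in (3, 5)
]


@dataclass
class SpikeConfig:
    percentile: int = 95
    undersample_n: int = 100
    n_bags: int = 10
    zero_fraction: float = 0.10
    big_city_threshold: float = 500_000.0
    prob_threshold: float = 0.5
    seed: int = 0

    def __post_init__(self):
        if not 90 <= self.percentile <= 98:
            raise InvalidArgumentError(f"percentile must be in [90, 98], got {self.percentile}")
        if self.n_bags < 1:
            raise InvalidArgumentError("n_bags must be >= 1")


@dataclass
class SpikeEnsemble:
    classifier: object
    bag_models: list[FittedCountModel]
    config: SpikeConfig
    labels: pd.Series | None = None
    bag_row_ids: list[tuple] | None = None  # per bag: (spike index, no-spike index)

    def predict(self, frames: pd.DataFrame) -> np.ndarray:
        """Arithmetic mean of the bag predictions."""
        preds = np.stack([predict_counts(m, frames) for m in self.bag_models])
        return preds.mean(axis=0)

    def bag_predictions(self, frames: pd.DataFrame) -> np.ndarray:
        return np.stack([predict_counts(m, frames) for m in self.bag_models])


@dataclass
class HybridConfig:
    lower_sum: float = 150.0
    upper_sum: float = 300.0
    reference_population: float | None = None  # scale thresholds to pop/ref

    def __post_init__(self):
        if not 0 < self.lower_sum < self.upper_sum:
            raise InvalidArgumentError("need 0 < lower_sum < upper_sum")

    def scaled(self, covered_population: float) -> tuple[float, float]:
        if self.reference_population is None:
            return self.lower_sum, self.upper_sum
        s = covered_population / self.reference_population
        return self.lower_sum * s, self.upper_sum * s


def _big_city_ids(profiles: pd.DataFrame, threshold: float) -> list[str]:
    big = profiles[
        profiles[["population_day", "population_night"]].max(axis=1) > threshold
    ]
    return sorted(big["city_id"])


def build_spike_seed_sets(
    training_frames: pd.DataFrame,
    profiles: pd.DataFrame,
    config: SpikeConfig,
    outcome_col: str = "count_all",
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Spike seed rows and the sampled zero-count no-spike seed rows.

    The spike threshold is the interpolating ``config.percentile`` of the
    outcome over big-city training rows; spike rows are the big-city rows at
    or above it.  The zero seed is a seeded sample of round(zero_fraction ×
    n) of the big-city zero-count rows (minimum 1).  The sets are disjoint
    whenever the threshold is positive.
    """
    big_ids = _big_city_ids(profiles, config.big_city_threshold)
    if not big_ids:
        raise ConfigurationError(
            f"no city exceeds the big-city threshold {config.big_city_threshold:,.0f}"
        )
    big = training_frames[training_frames["city_id"].isin(big_ids)]
    counts = big[outcome_col].to_numpy(float)
    threshold = float(np.percentile(counts, config.percentile))  # linear interpolation
    spike_rows = big[big[outcome_col] >= threshold]
    zeros = big[big[outcome_col] == 0]
    k = max(1, int(round(config.zero_fraction * len(zeros))))
    rng = np.random.default_rng(config.seed)
    zero_sample = zeros.iloc[np.sort(rng.choice(len(zeros), size=min(k, len(zeros)), replace=False))]
    logger.info(
        "spike seed: percentile %d -> threshold %.2f, %d spike rows, %d zero rows sampled",
        config.percentile,
        threshold,
        len(spike_rows),
        len(zero_sample),
    )
    return spike_rows, zero_sample


class _ClassifierWrapper:
    """XGBoost binary classifier over the frame feature table."""

    def __init__(self, params: dict, seed: int):
        self.params = dict(params)
        self.seed = seed
        self.est = None
        self.columns = None

    def fit(self, frames: pd.DataFrame, labels: np.ndarray):
        X = build_design(frames, SPIKE_PREDICTORS)
        self.columns = list(X.columns)
        self.est = XGBClassifier(
            random_state=self.seed,
            n_jobs=1,
            tree_method="hist",
            verbosity=0,
            eval_metric="logloss",
            **self.params,
        )
        self.est.fit(X.to_numpy(float), labels.astype(int))
        return self

    def _design(self, frames):
        X = build_design(frames, SPIKE_PREDICTORS)
        return X.reindex(columns=self.columns, fill_value=0.0).to_numpy(float)

    def predict(self, frames: pd.DataFrame) -> np.ndarray:
        return self.est.predict(self._design(frames))

    def predict_proba(self, frames: pd.DataFrame) -> np.ndarray:
        return self.est.predict_proba(self._design(frames))[:, 1]


def fit_spike_classifier(
    spike_rows: pd.DataFrame,
    zero_sample_rows: pd.DataFrame,
    cv_plan: CVPlan,
    grid: list[dict] | None = None,
    seed: int = 0,
) -> _ClassifierWrapper:
    """Boosted-tree spike/no-spike classifier, grid-searched by CV accuracy."""
    if len(spike_rows) == 0 or len(zero_sample_rows) == 0:
        raise FitError("both classes must be non-empty to fit the spike classifier")
    train = pd.concat([spike_rows, zero_sample_rows], ignore_index=True)
    train = train.assign(_spike_label=[1] * len(spike_rows) + [0] * len(zero_sample_rows))
    grid = grid or DEFAULT_CLASSIFIER_GRID

    def factory(params, tr):
        clf = _ClassifierWrapper(params, seed)
        return clf.fit(tr, tr["_spike_label"].to_numpy())

    if len(grid) == 1:
        best = grid[0]
    else:
        n_folds = min(cv_plan.n_folds, len(train))
        plan = CVPlan(n_folds=n_folds, fold_assignment=cv_plan.fold_assignment, seed=cv_plan.seed)
        best, _ = grid_search_cv(
            factory, train, grid, plan, metric="accuracy", outcome="_spike_label"
        )
    clf = _ClassifierWrapper(best, seed)
    return clf.fit(train, train["_spike_label"].to_numpy())


def partition_training(
    classifier: _ClassifierWrapper,
    training_frames: pd.DataFrame,
    profiles: pd.DataFrame,
    prob_threshold: float = 0.5,
    big_city_threshold: float = 500_000.0,
) -> pd.Series:
    """Label every training row 'spike' or 'no_spike'.

    Big-city rows are labelled by the classifier probability against
    ``prob_threshold``; rows of cities at or below the population threshold
    are labelled no_spike a priori.
    """
    labels = pd.Series("no_spike", index=training_frames.index, name="spike_label")
    big_ids = _big_city_ids(profiles, big_city_threshold)
    mask = training_frames["city_id"].isin(big_ids)
    if mask.any():
        proba = classifier.predict_proba(training_frames.loc[mask])
        labels.loc[mask] = np.where(proba >= prob_threshold, "spike", "no_spike")
    return labels


def fit_undersampling_ensemble(
    labelled_frames: pd.DataFrame,
    labels: pd.Series,
    config: SpikeConfig,
    cv_plan: CVPlan,
    grid: list[dict] | None = None,
    outcome: str = "count_all",
    classifier: _ClassifierWrapper | None = None,
) -> SpikeEnsemble:
    """Fit the bagged under-sampling ensemble.

    Each of ``config.n_bags`` bags trains a Poisson-objective boosted-tree
    regressor on ALL spike-labelled rows plus a seeded sample (without
    replacement within the bag, independent across bags) of
    ``config.undersample_n`` no-spike rows.  Hyperparameters are grid-searched
    by 5-fold CV RMSE on the first bag and reused across bags.
    """
    spike = labelled_frames.loc[labels == "spike"]
    no_spike = labelled_frames.loc[labels == "no_spike"]
    if len(spike) == 0:
        raise FitError("spike cluster is empty; lower the percentile")
    if len(no_spike) < config.undersample_n:
        raise InvalidArgumentError(
            f"no-spike cluster has {len(no_spike)} rows < undersample_n="
            f"{config.undersample_n}; use a smaller undersample_n"
        )
    rng = np.random.default_rng(config.seed)
    grid = grid or DEFAULT_REGRESSOR_GRID
    bags = []
    bag_row_ids = []
    best_params = grid[0] if len(grid) == 1 else None
    for b in range(config.n_bags):
        sample_idx = np.sort(rng.choice(len(no_spike), size=config.undersample_n, replace=False))
        bag = pd.concat([spike, no_spike.iloc[sample_idx]], ignore_index=True)
        bag_row_ids.append((spike.index.to_numpy(), no_spike.index.to_numpy()[sample_idx]))
        if best_params is None:
            n_folds = min(cv_plan.n_folds, len(bag))
            plan = CVPlan(n_folds=n_folds, fold_assignment=cv_plan.fold_assignment, seed=cv_plan.seed)
            best_params, _ = grid_search_cv(
                tree_factory(SPIKE_PREDICTORS, "boosted_trees", seed=config.seed, outcome=outcome),
                bag,
                grid,
                plan,
                metric="rmse",
                outcome=outcome,
            )
        bags.append(
            fit_tree_regressor(
                bag,
                SPIKE_PREDICTORS,
                "boosted_trees",
                hyperparameters=best_params,
                seed=config.seed + b,
                outcome=outcome,
            )
        )
    return SpikeEnsemble(
        classifier=classifier,
        bag_models=bags,
        config=config,
        labels=labels,
        bag_row_ids=bag_row_ids,
    )


def fit_spike_pipeline(
    training_frames: pd.DataFrame,
    profiles: pd.DataFrame,
    config: SpikeConfig,
    cv_plan: CVPlan,
    classifier_grid: list[dict] | None = None,
    regressor_grid: list[dict] | None = None,
    outcome_col: str = "count_all",
) -> SpikeEnsemble:
    """Steps 1–4 in one call: seeds → classifier → partition → ensemble."""
    spike_rows, zero_rows = build_spike_seed_sets(
        training_frames, profiles, config, outcome_col=outcome_col
    )
    clf = fit_spike_classifier(
        spike_rows, zero_rows, cv_plan, grid=classifier_grid, seed=config.seed
    )
    labels = partition_training(
        clf,
        training_frames,
        profiles,
        prob_threshold=config.prob_threshold,
        big_city_threshold=config.big_city_threshold,
    )
    if (labels == "spike").sum() == 0:
        # the classifier found no spike rows in the full training data; fall
        # back to the seed rows so the ensemble remains well defined
        labels.loc[spike_rows.index] = "spike"
    return fit_undersampling_ensemble(
        training_frames,
        labels,
        config,
        cv_plan,
        grid=regressor_grid,
        outcome=outcome_col,
        classifier=clf,
    )


def tune_spike_config(
    training_frames: pd.DataFrame,
    profiles: pd.DataFrame,
    percentile_grid=range(90, 99),
    n_grid=(100, 200),
    cv_plan: CVPlan | None = None,
    config: SpikeConfig | None = None,
    classifier_grid: list[dict] | None = None,
    regressor_grid: list[dict] | None = None,
    outcome: str = "all",
) -> tuple[SpikeConfig, SpikeEnsemble, pd.DataFrame]:
    """Full factorial percentile × undersample_n, scored by training spike-day MAPE.

    Returns the least-MAPE configuration (ties to the smaller percentile,
    then smaller n), its fitted ensemble, and the audit table of all cells.
    """
    percentile_grid = list(percentile_grid)
    n_grid = list(n_grid)
    if not percentile_grid or not n_grid:
        raise InvalidArgumentError("grids must be non-empty")
    cv_plan = cv_plan or CVPlan()
    base = config or SpikeConfig()
    outcome_col = {"all": "count_all", "admission_death": "count_admission_death"}[outcome]
    obs_daily = daily_totals(training_frames, outcome=outcome)
    spike_days = select_spike_days(obs_daily).all_days()
    rows = []
    best = None
    for pct in percentile_grid:
        for n in n_grid:
            cfg = SpikeConfig(
                percentile=pct,
                undersample_n=n,
                n_bags=base.n_bags,
                zero_fraction=base.zero_fraction,
                big_city_threshold=base.big_city_threshold,
                prob_threshold=base.prob_threshold,
                seed=base.seed,
            )
            try:
                ens = fit_spike_pipeline(
                    training_frames,
                    profiles,
                    cfg,
                    cv_plan,
                    classifier_grid=classifier_grid,
                    regressor_grid=regressor_grid,
                    outcome_col=outcome_col,
                )
                pred_daily = daily_totals(training_frames, values=ens.predict(training_frames))
                mape = spike_day_mape(obs_daily, pred_daily, spike_days)
                rows.append({"percentile": pct, "undersample_n": n, "mape": mape, "failed": False})
                if best is None or mape < best[0]:
                    best = (mape, cfg, ens)
            except Exception as exc:  # noqa: BLE001 - cell-level failure is data
                logger.warning("spike-tune cell (%d, %d) failed: %s", pct, n, exc)
                rows.append({"percentile": pct, "undersample_n": n, "mape": np.nan, "failed": True})
    audit = pd.DataFrame(rows)
    if best is None:
        raise FitError("every spike-tuning cell failed")
    return best[1], best[2], audit


@dataclass
class HybridResult:
    predictions: np.ndarray
    day_table: pd.DataFrame  # per heat day: ensemble_sum, branch


def blend_hybrid(
    gam_pred,
    ensemble_pred,
    frames: pd.DataFrame,
    hybrid_config: HybridConfig | None = None,
    covered_population: float | None = None,
) -> HybridResult:
    """Per-heat-day switch between GAM, mean, and ensemble predictions.

    S(d) = Σ over all cities and both frames of the ensemble prediction on
    heat day d.  S < lower → GAM rows; lower ≤ S < upper → element-wise
    mean; S ≥ upper → ensemble rows.  Thresholds are scaled by
    covered_population / reference_population when a reference is set.
    """
    cfg = hybrid_config or HybridConfig()
    gam_pred = np.asarray(gam_pred, dtype=float)
    ensemble_pred = np.asarray(ensemble_pred, dtype=float)
    if gam_pred.shape != ensemble_pred.shape or len(gam_pred) != len(frames):
        raise SchemaError(
            f"misaligned vectors: gam {gam_pred.shape}, ensemble {ensemble_pred.shape}, "
            f"frames {len(frames)}"
        )
    lower, upper = cfg.scaled(covered_population) if covered_population else (
        cfg.lower_sum,
        cfg.upper_sum,
    )
    dates = pd.DatetimeIndex(frames["frame_date"])
    sums = pd.Series(ensemble_pred, index=dates).groupby(level=0).sum()
    branch = pd.Series(
        np.where(sums < lower, "gam", np.where(sums < upper, "mean", "ensemble")),
        index=sums.index,
    )
    row_branch = branch.loc[dates].to_numpy()
    hybrid = np.where(
        row_branch == "gam",
        gam_pred,
        np.where(row_branch == "mean", (gam_pred + ensemble_pred) / 2.0, ensemble_pred),
    )
    day_table = pd.DataFrame(
        {"ensemble_sum": sums, "branch": branch}
    ).rename_axis("frame_date").reset_index()
    return HybridResult(predictions=hybrid, day_table=day_table)
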