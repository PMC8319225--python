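"""Count-model families, cross-validated grid search, and RFE.

Five base families are supported, mirroring the three-step development
procedure:

* ``glm_wbgt_only`` — Poisson GLM with the frame-mean WBGT as the only
  predictor and a log-population offset (the classic baseline);
* ``glm`` — Poisson GLM, multivariable linear predictors, log-population
  offset;
* ``gam`` — penalized-spline Poisson additive model (statsmodels GLMGam with
  B-spline smooths on continuous predictors), log-population offset;
* ``random_forest`` — squared-error random forest with the period-matched
  population as an ordinary predictor (no offset);
* ``boosted_trees`` — gradient-boosted trees with a Poisson-deviance
  objective, population as a predictor (no offset).

Feature selection is recursive feature elimination driven by held-out-fold
permutation importance; hyperparameters come from an exhaustive 5-fold CV
grid search with least mean RMSE (highest accuracy for classifiers).
"""

from __future__ import annotations

import hashlib
import json
import logging
import pickle
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import statsmodels.api as sm
from sklearn.ensemble import RandomForestRegressor
from statsmodels.gam.api import BSplines, GLMGam
from xgboost import XGBRegressor

from .errors import FitError, GridSearchError, InvalidArgumentError, SchemaError

logger = logging.getLogger(__name__)

#: predictors used by the multivariable families, following the analysis'
#: predictor list: weather, temperature difference features, calendar, and
#: (for pooled models) city demographics.
WEATHER_PREDICTORS = [
    "precip_prev12h",
    "WS_mean",
    "Ta_mean",
    "RH_mean",
    "SR_mean",
    "Ta_diff_mean",
    "Ta_diff_max",
    "Ta_diff_min",
]
CALENDAR_PREDICTORS = ["period", "month", "rainy_season", "days_after_rainy_end", "holiday"]
CITY_PREDICTORS = [
    "median_age",
    "population_65plus",
    "men_women_ratio",
    "taxable_income",
    "green_area_pct",
]
DEFAULT_PREDICTORS = WEATHER_PREDICTORS + CALENDAR_PREDICTORS + CITY_PREDICTORS
#: continuous predictors given spline smooths in the GAM by default
# days_after_rainy_end stays parametric: a flexible smooth of a calendar
# index that is collinear with the seasonal temperature trend invites
# concurvity and misattributes the summer rise
DEFAULT_SMOOTH_TERMS = ["Ta_mean", "RH_mean", "SR_mean", "Ta_diff_max", "WS_mean"]

TREE_FAMILIES = ("random_forest", "boosted_trees")
GLM_FAMILIES = ("glm_wbgt_only", "glm", "gam")

DEFAULT_XGB_PARAMS = {
    "n_estimators": 200,
    "learning_rate": 0.1,
    "max_depth": 4,
    "subsample": 0.9,
    "min_child_weight": 1.0,
}
DEFAULT_RF_PARAMS = {"n_estimators": 300, "max_depth": None, "min_samples_leaf": 2}

#: small default grids (≤ 24 points per family)
DEFAULT_GRIDS = {
    "glm": [{}],
    "gam": [{"alpha": a} for a in (1.0, 10.0, 100.0)],
    "random_forest": [
        {"n_estimators": n, "min_samples_leaf": l} for n in (200, 400) for l in (1, 2, 5)
    ],
    "boosted_trees": [
        {"n_estimators": n, "max_depth": d, "learning_rate": lr}
        for n in (100, 200)
        for d in (3, 4, 6)
        for lr in (0.05, 0.1)
    ],
}


@dataclass
class CVPlan:
    """5-fold cross-validation plan.

    ``fold_assignment`` is ``"random_rows"`` (seeded row shuffle, the
    default) or ``"blocked_by_time"`` (contiguous blocks of the
    frame-date-sorted rows, which avoids temporal leakage but is not the
    common default for this design).
    """

    n_folds: int = 5
    fold_assignment: str = "random_rows"
    seed: int = 0

    def folds(self, frames: pd.DataFrame) -> list[tuple[np.ndarray, np.ndarray]]:
        n = len(frames)
        if self.n_folds < 2 or self.n_folds > n:
            raise InvalidArgumentError(
                f"n_folds={self.n_folds} invalid for {n} rows"
            )
        if self.fold_assignment == "random_rows":
            order = np.random.default_rng(self.seed).permutation(n)
        elif self.fold_assignment == "blocked_by_time":
            order = np.argsort(frames["frame_date"].to_numpy(), kind="stable")
        else:
            raise InvalidArgumentError(
                f"unknown fold_assignment {self.fold_assignment!r}"
            )
        pieces = np.array_split(order, self.n_folds)
        out = []
        for k in range(self.n_folds):
            valid = pieces[k]
            train = np.concatenate([pieces[j] for j in range(self.n_folds) if j != k])
            out.append((train, valid))
        return out


@dataclass
class FittedCountModel:
    """A trained count regressor with a uniform predict contract."""

    family: str
    selected_predictors: list[str]
    hyperparameters: dict
    uses_offset: bool
    outcome: str
    design_columns: list[str] = field(default_factory=list)
    cv_rmse: float | None = None
    training_fingerprint: str | None = None
    _impl: object = None
    _smoother_spec: dict | None = None

    def predict(self, frames: pd.DataFrame) -> np.ndarray:
        return predict_counts(self, frames)


def _fingerprint(frames: pd.DataFrame, predictors, outcome: str) -> str:
    h = hashlib.sha256()
    h.update(f"{len(frames)}|{sorted(predictors)}|{outcome}".encode())
    h.update(np.ascontiguousarray(frames[outcome].to_numpy(float)).tobytes())
    return h.hexdigest()[:16]


def build_design(frames: pd.DataFrame, predictors: list[str]) -> pd.DataFrame:
    """Numeric design matrix: booleans → 0/1, month → one-hot (June baseline),
    period → ``period_night`` indicator; continuous columns pass through."""
    missing = [p for p in predictors if p not in frames.columns]
    if missing:
        raise SchemaError(f"frames are missing predictor columns: {missing}")
    cols = {}
    for p in predictors:
        s = frames[p]
        if p == "month":
            for m in (7, 8, 9):
                cols[f"month_{m}"] = (s == m).astype(float)
        elif p == "period":
            cols["period_night"] = (s == "night").astype(float)
        elif s.dtype == bool:
            cols[p] = s.astype(float)
        else:
            cols[p] = pd.to_numeric(s, errors="raise").astype(float)
    return pd.DataFrame(cols, index=frames.index)


def _offset(frames: pd.DataFrame, use: bool) -> np.ndarray | None:
    return frames["log_population_offset"].to_numpy(float) if use else None


def _check_design(X: pd.DataFrame) -> None:
    zero_var = [c for c in X.columns if X[c].nunique() <= 1]
    arr = X.to_numpy(float)
    norms = np.linalg.norm(arr, axis=0)
    arr = arr / np.where(norms > 0, norms, 1.0)  # scale-free rank check
    if zero_var or np.linalg.matrix_rank(arr) < arr.shape[1]:
        raise FitError(
            "singular design matrix"
            + (f"; zero-variance columns: {zero_var}" if zero_var else "; collinear columns")
        )


# ---------------------------------------------------------------------------
# GLM / GAM
# ---------------------------------------------------------------------------

def fit_glm_poisson(
    frames: pd.DataFrame,
    predictors: list[str],
    offset: bool = True,
    outcome: str = "count_all",
) -> FittedCountModel:
    """Log-link Poisson GLM with optional log-population offset."""
    X = build_design(frames, predictors)
    Xc = sm.add_constant(X, has_constant="add")
    if len(frames) < 2 * (Xc.shape[1]):
        raise InvalidArgumentError(
            f"need >= {2 * Xc.shape[1]} rows for {Xc.shape[1]} parameters, got {len(frames)}"
        )
    if X.shape[1]:
        _check_design(Xc.drop(columns="const"))
    y = frames[outcome].to_numpy(float)
    glm = sm.GLM(y, Xc, family=sm.families.Poisson(), offset=_offset(frames, offset))
    try:
        res = glm.fit()
    except ValueError:
        # degenerate outcomes (e.g. all-zero counts) break the default
        # starting values; restart IRLS from zero coefficients
        res = glm.fit(start_params=np.zeros(Xc.shape[1]))
    except np.linalg.LinAlgError as exc:  # pragma: no cover - defensive
        raise FitError(f"GLM fit failed: {exc}") from exc
    family = "glm_wbgt_only" if predictors == ["WBGT_mean"] else "glm"
    return FittedCountModel(
        family=family,
        selected_predictors=list(predictors),
        hyperparameters={},
        uses_offset=offset,
        outcome=outcome,
        design_columns=list(Xc.columns),
        training_fingerprint=_fingerprint(frames, predictors, outcome),
        _impl=res,
    )


def fit_gam_poisson(
    frames: pd.DataFrame,
    predictors: list[str],
    offset: bool = True,
    smooth_config: dict | None = None,
    outcome: str = "count_all",
) -> FittedCountModel:
    """Penalized-B-spline Poisson additive model with log-population offset.

    ``smooth_config`` keys: ``terms`` (continuous predictors to smooth,
    default the weather terms present), ``df`` (basis size, default 6),
    ``degree`` (default 3), ``alpha`` (scalar penalty for every smooth,
    default 10.0, or ``"select"`` to pick the AIC-best value from
    ``alphas``).  Smooth bases shrink automatically when a predictor has too
    few unique values; zero-variance predictors are dropped with a warning.
    """
    cfg = dict(smooth_config or {})
    terms = [t for t in cfg.get("terms", DEFAULT_SMOOTH_TERMS) if t in predictors]
    df_basis = int(cfg.get("df", 6))
    degree = int(cfg.get("degree", 3))
    alpha = cfg.get("alpha", 10.0)
    alphas = cfg.get("alphas", (0.1, 1.0, 10.0, 100.0, 1000.0))

    predictors = list(predictors)
    for p in list(predictors):
        if frames[p].nunique() <= 1:
            warnings.warn(f"dropping zero-variance predictor {p!r}")
            predictors.remove(p)
            terms = [t for t in terms if t != p]
    linear = [p for p in predictors if p not in terms]

    smooth_dfs = []
    kept_terms = []
    for t in terms:
        nu = frames[t].nunique()
        d = df_basis
        if nu < df_basis + 2:
            d = max(degree + 1, nu - 1)
            warnings.warn(f"shrinking basis for {t!r} to df={d} ({nu} unique values)")
        if d <= degree:
            linear.append(t)
            continue
        kept_terms.append(t)
        smooth_dfs.append(d)
    terms = kept_terms

    y = frames[outcome].to_numpy(float)
    X_lin = sm.add_constant(build_design(frames, linear), has_constant="add")
    x_smooth = frames[terms].to_numpy(float)
    # extend the basis span beyond the training range so the smooths can
    # extrapolate into, e.g., a hotter held-out season; the curvature penalty
    # makes the data-free extension approximately linear
    bounds, knot_kwds = {}, []
    for t in terms:
        lo, hi = float(frames[t].min()), float(frames[t].max())
        margin = 0.15 * (hi - lo)
        bounds[t] = (lo - margin, hi + margin)
        knot_kwds.append({"lower_bound": lo - margin, "upper_bound": hi + margin})
    off = _offset(frames, offset)

    def _fit(alpha_value: float):
        smoother = BSplines(
            x_smooth,
            df=smooth_dfs,
            degree=[degree] * len(terms),
            include_intercept=False,
            knot_kwds=knot_kwds,
        )
        model = GLMGam(
            y,
            exog=X_lin,
            smoother=smoother,
            family=sm.families.Poisson(),
            offset=off,
            alpha=[float(alpha_value)] * len(terms),
        )
        return model, model.fit()

    if not terms:
        return fit_glm_poisson(frames, predictors, offset=offset, outcome=outcome)
    if alpha == "select":
        best = None
        for a in alphas:
            _, r = _fit(a)
            if best is None or r.aic < best[1]:
                best = (a, r.aic)
        alpha = best[0]
    model, res = _fit(float(alpha))
    return FittedCountModel(
        family="gam",
        selected_predictors=predictors,
        hyperparameters={"alpha": float(alpha), "df": smooth_dfs, "degree": degree},
        uses_offset=offset,
        outcome=outcome,
        design_columns=list(X_lin.columns),
        training_fingerprint=_fingerprint(frames, predictors, outcome),
        _impl=res,
        _smoother_spec={"terms": terms, "linear": linear, "bounds": bounds},
    )


def gam_smooth_edf(model: FittedCountModel) -> dict[str, float]:
    """Effective degrees of freedom per smooth term (basis-column sum)."""
    if model.family != "gam" or model._smoother_spec is None:
        raise InvalidArgumentError("edf is defined for fitted GAMs only")
    res = model._impl
    edf = np.asarray(res.edf)
    n_lin = len(model.design_columns)
    out = {}
    pos = n_lin
    smoother = res.model.smoother
    sizes = [s.dim_basis for s in smoother.smoothers]
    for name, size in zip(model._smoother_spec["terms"], sizes):
        out[name] = float(edf[pos : pos + size].sum())
        pos += size
    return out


# ---------------------------------------------------------------------------
# Tree families
# ---------------------------------------------------------------------------

def fit_tree_regressor(
    frames: pd.DataFrame,
    predictors: list[str],
    family: str,
    hyperparameters: dict | None = None,
    seed: int = 0,
    outcome: str = "count_all",
) -> FittedCountModel:
    """Random forest (squared error) or boosted trees (Poisson deviance).

    Tree families take no offset; the period-matched ``population`` column is
    appended as a predictor if not already listed.
    """
    if family not in TREE_FAMILIES:
        raise InvalidArgumentError(f"unknown tree family {family!r}")
    predictors = list(predictors)
    if "population" not in predictors:
        predictors.append("population")
    X = build_design(frames, predictors)
    y = frames[outcome].to_numpy(float)
    hp = dict(hyperparameters or {})
    if family == "random_forest":
        params = {**DEFAULT_RF_PARAMS, **hp}
        est = RandomForestRegressor(random_state=seed, n_jobs=1, **params)
    else:
        params = {**DEFAULT_XGB_PARAMS, **hp}
        est = XGBRegressor(
            objective="count:poisson",
            random_state=seed,
            n_jobs=1,
            tree_method="hist",
            verbosity=0,
            **params,
        )
    est.fit(X.to_numpy(float), y)
    return FittedCountModel(
        family=family,
        selected_predictors=predictors,
        hyperparameters=params,
        uses_offset=False,
        outcome=outcome,
        design_columns=list(X.columns),
        training_fingerprint=_fingerprint(frames, predictors, outcome),
        _impl=est,
    )


# ---------------------------------------------------------------------------
# Prediction
# ---------------------------------------------------------------------------

def predict_counts(model: FittedCountModel, frames: pd.DataFrame) -> np.ndarray:
    """Expected counts on the raw (unclipped) scale, length-matched to frames."""
    if len(frames) == 0:
        return np.empty(0)
    missing = [p for p in model.selected_predictors if p not in frames.columns]
    if missing:
        raise SchemaError(f"frames are missing predictor columns: {missing}")
    if model.family in TREE_FAMILIES:
        X = build_design(frames, model.selected_predictors)
        X = X.reindex(columns=model.design_columns, fill_value=0.0)
        pred = model._impl.predict(X.to_numpy(float))
        if model.family == "boosted_trees":
            pred = np.clip(pred, 0.0, None)
        return np.asarray(pred, dtype=float)
    off = _offset(frames, model.uses_offset)
    if model.family == "gam":
        spec = model._smoother_spec
        X_lin = sm.add_constant(build_design(frames, spec["linear"]), has_constant="add")
        X_lin = X_lin.reindex(columns=model.design_columns, fill_value=0.0)
        # B-spline bases are zero outside the knot span, so smooth inputs are
        # clipped to the training range and each smooth is extended linearly
        # beyond its boundary with the boundary slope (mgcv-style linear
        # extrapolation); without this a hotter held-out season would
        # collapse the fitted heat response.
        raw = np.column_stack([frames[t].to_numpy(float) for t in spec["terms"]])
        lo = np.array([spec["bounds"][t][0] for t in spec["terms"]])
        hi = np.array([spec["bounds"][t][1] for t in spec["terms"]])
        x_smooth = np.clip(raw, lo, hi)
        pred = model._impl.predict(
            exog=X_lin.to_numpy(float), exog_smooth=x_smooth, offset=off
        )
        overshoot_hi = np.clip(raw - hi, 0.0, None)
        overshoot_lo = np.clip(raw - lo, None, 0.0)
        if np.any(overshoot_hi > 0) or np.any(overshoot_lo < 0):
            correction = np.zeros(len(frames))
            ref_lin = X_lin.to_numpy(float)[:1]
            ref_smooth = x_smooth[:1].copy()
            for j, t in enumerate(spec["terms"]):
                for bound, overshoot in ((hi[j], overshoot_hi[:, j]), (lo[j], overshoot_lo[:, j])):
                    if not np.any(overshoot):
                        continue
                    delta = max(1e-6, 0.01 * (hi[j] - lo[j]))
                    inner = bound - delta if bound == hi[j] else bound + delta
                    a, b = ref_smooth.copy(), ref_smooth.copy()
                    a[0, j], b[0, j] = bound, inner
                    eta_a, eta_b = np.log(
                        model._impl.predict(exog=ref_lin, exog_smooth=a)
                    ), np.log(model._impl.predict(exog=ref_lin, exog_smooth=b))
                    slope = float(eta_a[0] - eta_b[0]) / (bound - inner)
                    correction += slope * overshoot
            pred = pred * np.exp(correction)
        return np.asarray(pred, dtype=float)
    X = sm.add_constant(
        build_design(frames, model.selected_predictors), has_constant="add"
    )
    X = X.reindex(columns=model.design_columns, fill_value=0.0)
    pred = model._impl.predict(X, offset=off)
    return np.asarray(pred, dtype=float)


# ---------------------------------------------------------------------------
# Persistence
# ---------------------------------------------------------------------------

def save_model(model: FittedCountModel, directory: str | Path) -> Path:
    """Persist a fitted model as meta.json + binary artefact."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    meta = {
        "format_version": 1,
        "family": model.family,
        "selected_predictors": model.selected_predictors,
        "hyperparameters": model.hyperparameters,
        "uses_offset": model.uses_offset,
        "outcome": model.outcome,
        "design_columns": model.design_columns,
        "cv_rmse": model.cv_rmse,
        "training_fingerprint": model.training_fingerprint,
    }
    (directory / "meta.json").write_text(json.dumps(meta, indent=2, sort_keys=True))
    with open(directory / "model.pkl", "wb") as fh:
        pickle.dump({"impl": model._impl, "smoother_spec": model._smoother_spec}, fh)
    return directory


def load_model(directory: str | Path) -> FittedCountModel:
    directory = Path(directory)
    meta = json.loads((directory / "meta.json").read_text())
    with open(directory / "model.pkl", "rb") as fh:
        blob = pickle.load(fh)
    meta.pop("format_version")
    return FittedCountModel(**meta, _impl=blob["impl"], _smoother_spec=blob["smoother_spec"])


# ---------------------------------------------------------------------------
# Cross-validated grid search
# ---------------------------------------------------------------------------

def _rmse(obs: np.ndarray, pred: np.ndarray) -> float:
    return float(np.sqrt(np.mean((np.asarray(obs, float) - np.asarray(pred, float)) ** 2)))


def grid_search_cv(
    model_factory,
    frames: pd.DataFrame,
    grid: list[dict],
    cv_plan: CVPlan,
    metric: str = "rmse",
    outcome: str = "count_all",
):
    """Exhaustive CV search over ``grid``.

    ``model_factory(params, train_frames)`` must return a fitted object with
    ``.predict(frames) -> array`` (expected counts, or class labels when
    ``metric == "accuracy"``).  Selects least mean RMSE / highest accuracy;
    ties go to the earlier grid point.  Grid points whose any fold fails are
    excluded with a warning; if all fail a GridSearchError is raised.
    """
    if not grid:
        raise InvalidArgumentError("grid must be non-empty")
    folds = cv_plan.folds(frames)
    rows = []
    for gi, params in enumerate(grid):
        fold_scores = []
        failed = False
        for train_idx, valid_idx in folds:
            tr = frames.iloc[train_idx]
            va = frames.iloc[valid_idx]
            try:
                fitted = model_factory(params, tr)
                pred = fitted.predict(va)
            except Exception as exc:  # noqa: BLE001 - grid points may fail legitimately
                warnings.warn(f"grid point {params} failed: {exc}")
                failed = True
                break
            if metric == "rmse":
                fold_scores.append(_rmse(va[outcome].to_numpy(float), pred))
            elif metric == "accuracy":
                fold_scores.append(
                    float(np.mean(np.asarray(pred) == va[outcome].to_numpy()))
                )
            else:
                raise InvalidArgumentError(f"unknown metric {metric!r}")
        rows.append(
            {
                "grid_index": gi,
                "params": params,
                "failed": failed,
                "score": np.nan if failed else float(np.mean(fold_scores)),
            }
        )
    table = pd.DataFrame(rows)
    ok = table[~table["failed"]]
    if ok.empty:
        raise GridSearchError("all grid points failed")
    if metric == "accuracy":
        best_idx = int(ok.loc[ok["score"].idxmax(), "grid_index"])
    else:
        best_idx = int(ok.loc[ok["score"].idxmin(), "grid_index"])
    best = grid[best_idx]
    return best, table


# ---------------------------------------------------------------------------
# Recursive feature elimination
# ---------------------------------------------------------------------------

def rfe_select(
    model_factory,
    frames: pd.DataFrame,
    candidate_predictors: list[str],
    cv_plan: CVPlan,
    outcome: str = "count_all",
):
    """RFE with held-out-fold permutation importance.

    ``model_factory(predictors, train_frames)`` returns a fitted object with
    ``.predict``.  Importance of a predictor is the mean increase in held-out
    RMSE when that column is permuted (seeded by ``cv_plan.seed``).  For
    k = 1..p the top-k subsets are scored by CV RMSE and the least-RMSE
    subset is returned together with the full k-vs-RMSE profile.
    """
    if len(candidate_predictors) < 1:
        raise InvalidArgumentError("need at least one candidate predictor")
    candidates = list(candidate_predictors)
    if len(candidates) == 1:
        return candidates, pd.DataFrame(
            [{"k": 1, "predictors": candidates, "cv_rmse": np.nan}]
        )
    folds = cv_plan.folds(frames)
    rng = np.random.default_rng(cv_plan.seed)
    importances = {p: [] for p in candidates}
    for train_idx, valid_idx in folds:
        tr, va = frames.iloc[train_idx], frames.iloc[valid_idx]
        fitted = model_factory(candidates, tr)
        base = _rmse(va[outcome].to_numpy(float), fitted.predict(va))
        for p in candidates:
            shuffled = va.copy()
            shuffled[p] = rng.permutation(shuffled[p].to_numpy())
            importances[p].append(
                _rmse(va[outcome].to_numpy(float), fitted.predict(shuffled)) - base
            )
    ranking = sorted(candidates, key=lambda p: -float(np.mean(importances[p])))
    profile = []
    for k in range(1, len(ranking) + 1):
        subset = ranking[:k]
        scores = []
        for train_idx, valid_idx in folds:
            tr, va = frames.iloc[train_idx], frames.iloc[valid_idx]
            fitted = model_factory(subset, tr)
            scores.append(_rmse(va[outcome].to_numpy(float), fitted.predict(va)))
        profile.append({"k": k, "predictors": subset, "cv_rmse": float(np.mean(scores))})
    table = pd.DataFrame(profile)
    best_k = int(table.loc[table["cv_rmse"].idxmin(), "k"])
    return list(table.loc[table["k"] == best_k, "predictors"].iloc[0]), table


# ---------------------------------------------------------------------------
# City-specific models
# ---------------------------------------------------------------------------

def fit_city_specific(
    frames: pd.DataFrame,
    family: str,
    cv_plan: CVPlan | None = None,
    predictors: list[str] | None = None,
    outcome: str = "count_all",
    min_rows: int = 100,
    seed: int = 0,
    smooth_config: dict | None = None,
) -> dict[str, FittedCountModel]:
    """One model per city, same family as the pooled best.

    City demographic features are excluded (within one city they are
    constant); the log-population offset is kept for GLM/GAM families.
    Cities with fewer than ``min_rows`` rows are skipped with a warning.
    """
    predictors = [
        p
        for p in (predictors or (WEATHER_PREDICTORS + CALENDAR_PREDICTORS))
        if p not in CITY_PREDICTORS
    ]
    out = {}
    for city_id, grp in frames.groupby("city_id", sort=True):
        if len(grp) < min_rows:
            warnings.warn(f"skipping {city_id}: {len(grp)} rows < floor {min_rows}")
            continue
        if family in ("glm", "glm_wbgt_only"):
            preds = ["WBGT_mean"] if family == "glm_wbgt_only" else predictors
            out[city_id] = fit_glm_poisson(grp, preds, offset=True, outcome=outcome)
        elif family == "gam":
            out[city_id] = fit_gam_poisson(
                grp, predictors, offset=True, outcome=outcome, smooth_config=smooth_config
            )
        elif family in TREE_FAMILIES:
            out[city_id] = fit_tree_regressor(
                grp, predictors, family, seed=seed, outcome=outcome
            )
        else:
            raise InvalidArgumentError(f"unknown family {family!r}")
    return out


def predict_city_specific(
    models: dict[str, FittedCountModel], frames: pd.DataFrame
) -> np.ndarray:
    """Pooled prediction vector from per-city models (NaN for unmodelled cities)."""
    pred = np.full(len(frames), np.nan)
    pos = frames.reset_index(drop=True)
    for city_id, model in models.items():
        mask = (pos["city_id"] == city_id).to_numpy()
        if mask.any():
            pred[mask] = predict_counts(model, pos.loc[mask])
    return pred


# ---------------------------------------------------------------------------
# Factory helpers (used by the pipeline and the spike ensemble)
# ---------------------------------------------------------------------------

def glm_factory(predictors, offset=True, outcome="count_all"):
    def factory(params, train_frames):
        return fit_glm_poisson(train_frames, predictors, offset=offset, outcome=outcome)

    return factory


def gam_factory(predictors, offset=True, outcome="count_all", smooth_config=None):
    def factory(params, train_frames):
        cfg = dict(smooth_config or {})
        cfg.update(params)
        return fit_gam_poisson(
            train_frames, predictors, offset=offset, outcome=outcome, smooth_config=cfg
        )

    return factory


def tree_factory(predictors, family, seed=0, outcome="count_all"):
    def factory(params, train_frames):
        return fit_tree_regressor(
            train_frames, predictors, family, hyperparameters=params, seed=seed,
            outcome=outcome,
        )

    return factory


def rfe_glm_factory(offset=True, outcome="count_all"):
    def factory(predictors, train_frames):
        return fit_glm_poisson(train_frames, predictors, offset=offset, outcome=outcome)

    return factory
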