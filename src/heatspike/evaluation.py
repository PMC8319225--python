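"""Evaluation suite: clipping, RMSE, spike-day metrics, attributions, rates.

Overall accuracy is RMSE per city per 12-h frame.  Spike-day accuracy works
on daily totals under the heat-day convention (the day frame of date D plus
the night frame starting date D): a spike day is a day whose observed
all-city total is at or above that year's 80th-percentile daily total
(linear-interpolation quantile — the thresholds this rule produces on
integer totals are fractional).  Spike-day MAPE averages |obs − pred|/obs
over spike days; the total absolute percentage error compares the sums over
all spike days of the period.  Predictions are clipped to [0, 104] for the
all-case outcome and [0, 48] for admission+death (twice the per-frame
training maxima) before any metric is computed.

Per-prediction feature attributions are Shapley values with background-set
marginalization: exact coalition enumeration for small feature sets, seeded
Monte-Carlo over permutations otherwise.
"""

from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .errors import InvalidArgumentError, SchemaError

CLIP_CAPS = {"all": 104.0, "admission_death": 48.0}
OUTCOME_COLUMNS = {"all": "count_all", "admission_death": "count_admission_death"}
SPIKE_QUANTILE = 0.80


def clip_predictions(pred, outcome: str = "all", caps: tuple[float, float] | None = None):
    """Clamp predictions to [0, cap] (104 all-case / 48 admission+death).

    ``caps=(low, high)`` overrides the outcome-based cap, e.g. with
    2 × the per-frame training maximum when auto-deriving.  Idempotent.
    """
    if caps is None:
        if outcome not in CLIP_CAPS:
            raise InvalidArgumentError(f"unknown outcome {outcome!r}")
        caps = (0.0, CLIP_CAPS[outcome])
    return np.clip(np.asarray(pred, dtype=float), caps[0], caps[1])


def derive_caps(training_frames: pd.DataFrame, outcome: str = "all") -> tuple[float, float]:
    """Caps as (0, 2 × max training count per city per 12 h)."""
    col = OUTCOME_COLUMNS[outcome]
    return (0.0, 2.0 * float(training_frames[col].max()))


def rmse(observed, predicted) -> float:
    """√(mean((obs − pred)²))."""
    obs = np.asarray(observed, dtype=float)
    pred = np.asarray(predicted, dtype=float)
    if obs.size == 0:
        raise InvalidArgumentError("rmse of empty vectors is undefined")
    if obs.shape != pred.shape:
        raise InvalidArgumentError(f"length mismatch: {obs.shape} vs {pred.shape}")
    return float(np.sqrt(np.mean((obs - pred) ** 2)))


def daily_totals(frames: pd.DataFrame, values=None, outcome: str = "all") -> pd.Series:
    """Sum per heat day across all cities and both frames.

    With ``values=None`` the observed outcome column is summed; otherwise
    ``values`` is a prediction vector aligned to ``frames``.
    """
    if values is None:
        v = frames[OUTCOME_COLUMNS[outcome]].to_numpy(float)
    else:
        v = np.asarray(values, dtype=float)
        if len(v) != len(frames):
            raise SchemaError(f"values length {len(v)} != frames length {len(frames)}")
    s = pd.Series(v, index=pd.DatetimeIndex(frames["frame_date"]))
    return s.groupby(level=0).sum().sort_index()


@dataclass
class SpikeDaySelection:
    days: dict[int, list]  # year -> sorted spike dates
    thresholds: dict[int, float]

    def all_days(self) -> list:
        return sorted(d for days in self.days.values() for d in days)


def select_spike_days(daily: pd.Series, q: float = SPIKE_QUANTILE) -> SpikeDaySelection:
    """Per-year spike days: total ≥ that year's interpolating q-quantile."""
    idx = pd.DatetimeIndex(daily.index)
    out_days, out_thr = {}, {}
    for year, grp in daily.groupby(idx.year):
        vals = grp.to_numpy(float)
        if len(vals) < 5:
            warnings.warn(f"year {year} has only {len(vals)} days; spike threshold unstable")
        thr = float(np.quantile(vals, q))  # linear interpolation (type 7)
        out_thr[int(year)] = thr
        out_days[int(year)] = sorted(pd.DatetimeIndex(grp.index[vals >= thr]))
    return SpikeDaySelection(days=out_days, thresholds=out_thr)


def spike_day_mape(obs_daily: pd.Series, pred_daily: pd.Series, spike_days) -> float:
    """Mean over spike days of |obs − pred| / obs × 100."""
    days = list(spike_days)
    if not days:
        raise InvalidArgumentError("spike_days must be non-empty")
    obs = obs_daily.loc[days].to_numpy(float)
    pred = pred_daily.loc[days].to_numpy(float)
    if np.any(obs <= 0):
        raise InvalidArgumentError("MAPE undefined: a spike day has observed total 0")
    return float(np.mean(np.abs(obs - pred) / obs) * 100.0)


def total_abs_pct_error(obs_daily: pd.Series, pred_daily: pd.Series, spike_days) -> float:
    """|Σ pred − Σ obs| / Σ obs × 100, sums over all spike days of the period."""
    days = list(spike_days)
    obs = float(obs_daily.loc[days].sum())
    pred = float(pred_daily.loc[days].sum())
    if obs <= 0:
        raise InvalidArgumentError("total absolute percentage error undefined: Σ obs = 0")
    return float(abs(pred - obs) / obs * 100.0)


# ---------------------------------------------------------------------------
# Shapley attributions
# ---------------------------------------------------------------------------

@dataclass
class AttributionTable:
    values: pd.DataFrame  # rows × features
    baseline: float

    def local_accuracy_gap(self, predictions) -> np.ndarray:
        return np.asarray(predictions, float) - self.baseline - self.values.sum(axis=1).to_numpy()


def shap_attributions(
    predict,
    rows: pd.DataFrame,
    background: pd.DataFrame,
    mode: str = "exact_permutation",
    seed: int | None = None,
    n_permutations: int = 2000,
) -> AttributionTable:
    """Shapley values of ``predict`` for each row, against a background set.

    The value of a coalition S is the mean prediction over background rows
    with the instance's features substituted on S.  ``exact_permutation``
    enumerates all coalitions (≤ 10 features); ``sampled`` is a seeded
    Monte-Carlo average of marginal contributions over random feature
    orderings.  The baseline is the mean prediction over the background set;
    per row the attributions sum to prediction − baseline (exactly in exact
    mode).
    """
    if len(background) == 0:
        raise InvalidArgumentError("background set must be non-empty")
    features = list(rows.columns)
    p = len(features)
    bg = background[features].to_numpy(float)
    X = rows[features].to_numpy(float)
    n = len(X)

    def coalition_value(subset: tuple[int, ...]) -> np.ndarray:
        """v(S) per instance: mean_b f(x_S ⊕ b_!S)."""
        vals = np.empty(n)
        for i in range(n):
            z = np.array(bg, copy=True)
            for j in subset:
                z[:, j] = X[i, j]
            vals[i] = float(np.mean(predict(pd.DataFrame(z, columns=features))))
        return vals

    baseline = float(np.mean(predict(pd.DataFrame(bg, columns=features))))
    phi = np.zeros((n, p))

    if mode == "exact_permutation":
        if p > 10:
            raise InvalidArgumentError(f"exact mode allows <= 10 features, got {p}")
        cache = {(): np.full(n, baseline)}
        for size in range(1, p + 1):
            for subset in itertools.combinations(range(p), size):
                cache[subset] = coalition_value(subset)
        fact = math.factorial
        for j in range(p):
            others = [k for k in range(p) if k != j]
            for size in range(0, p):
                w = fact(size) * fact(p - size - 1) / fact(p)
                for subset in itertools.combinations(others, size):
                    with_j = tuple(sorted(subset + (j,)))
                    phi[:, j] += w * (cache[with_j] - cache[subset])
    elif mode == "sampled":
        rng = np.random.default_rng(seed)
        counts = np.zeros(p)
        for _ in range(n_permutations):
            order = rng.permutation(p)
            prev = np.full(n, baseline)
            current: list[int] = []
            for j in order:
                current.append(j)
                val = coalition_value(tuple(sorted(current)))
                phi[:, j] += val - prev
                prev = val
            counts += 1
        phi /= counts
    else:
        raise InvalidArgumentError(f"unknown mode {mode!r}")
    return AttributionTable(
        values=pd.DataFrame(phi, index=rows.index, columns=features), baseline=baseline
    )


# ---------------------------------------------------------------------------
# Incidence rates
# ---------------------------------------------------------------------------

def incidence_rate_ci(
    cases: int, person_years_at_risk: float, method: str = "wald"
) -> tuple[float, float, float]:
    """Incidence rate per 100,000 with a 95% CI.

    ``wald`` (default): rate × (1 ± 1.96/√cases) — the normal approximation
    on the case count.  ``exact``: Garwood exact-Poisson limits via the
    chi-square distribution.
    """
    if cases < 1:
        raise InvalidArgumentError("CI undefined for zero cases")
    if person_years_at_risk <= 0:
        raise InvalidArgumentError("person_years_at_risk must be positive")
    rate = cases / person_years_at_risk * 1e5
    if method == "wald":
        half = 1.96 / math.sqrt(cases)
        return rate, rate * (1 - half), rate * (1 + half)
    if method == "exact":
        lo = stats.chi2.ppf(0.025, 2 * cases) / 2
        hi = stats.chi2.ppf(0.975, 2 * (cases + 1)) / 2
        return rate, lo / person_years_at_risk * 1e5, hi / person_years_at_risk * 1e5
    raise InvalidArgumentError(f"unknown method {method!r}")


# ---------------------------------------------------------------------------
# Report assembly
# ---------------------------------------------------------------------------

@dataclass
class EvaluationReport:
    model: str
    split: str
    outcome: str
    rmse_overall: float
    rmse_per_city: dict[str, float]
    spike_thresholds: dict[int, float]
    spike_days: dict[int, list]
    spike_day_mape: float | None
    total_abs_pct_error: float | None
    n_clipped_low: int
    n_clipped_high: int

    def to_dict(self) -> dict:
        d = {
            "model": self.model,
            "split": self.split,
            "outcome": self.outcome,
            "rmse_overall": self.rmse_overall,
            "rmse_per_city": dict(sorted(self.rmse_per_city.items())),
            "spike_thresholds": {str(k): v for k, v in sorted(self.spike_thresholds.items())},
            "spike_days": {
                str(k): [str(pd.Timestamp(d_).date()) for d_ in v]
                for k, v in sorted(self.spike_days.items())
            },
            "spike_day_mape": self.spike_day_mape,
            "total_abs_pct_error": self.total_abs_pct_error,
            "n_clipped_low": self.n_clipped_low,
            "n_clipped_high": self.n_clipped_high,
        }
        return d


def evaluate_model(
    frames: pd.DataFrame,
    predictions,
    outcome: str = "all",
    q: float = SPIKE_QUANTILE,
    model_name: str = "model",
    split: str = "testing",
    clip: bool = True,
) -> EvaluationReport:
    """Full report for one prediction vector on one split.

    Raw predictions are clipped first (with clipping counts recorded); all
    metrics are computed on the clipped vector.
    """
    pred = np.asarray(predictions, dtype=float)
    if len(pred) != len(frames):
        raise SchemaError(f"predictions length {len(pred)} != frames length {len(frames)}")
    n_low = n_high = 0
    if clip:
        caps = (0.0, CLIP_CAPS[outcome])
        n_low = int(np.sum(pred < caps[0]))
        n_high = int(np.sum(pred > caps[1]))
        pred = clip_predictions(pred, outcome)
    col = OUTCOME_COLUMNS[outcome]
    obs = frames[col].to_numpy(float)
    per_city = {
        str(city): rmse(grp[col].to_numpy(float), pred[idx])
        for city, grp, idx in (
            (c, g, (frames["city_id"] == c).to_numpy().nonzero()[0])
            for c, g in frames.groupby("city_id", sort=True)
        )
    }
    obs_daily = daily_totals(frames, outcome=outcome)
    pred_daily = daily_totals(frames, values=pred)
    selection = select_spike_days(obs_daily, q=q)
    days = selection.all_days()
    mape = spike_day_mape(obs_daily, pred_daily, days) if days else None
    tape = total_abs_pct_error(obs_daily, pred_daily, days) if days else None
    return EvaluationReport(
        model=model_name,
        split=split,
        outcome=outcome,
        rmse_overall=rmse(obs, pred),
        rmse_per_city=per_city,
        spike_thresholds=selection.thresholds,
        spike_days=selection.days,
        spike_day_mape=mape,
        total_abs_pct_error=tape,
        n_clipped_low=n_low,
        n_clipped_high=n_high,
    )


def evaluate_models(
    frames_by_split: dict[str, pd.DataFrame],
    predictions: dict[str, dict[str, np.ndarray]],
    outcome: str = "all",
    q: float = SPIKE_QUANTILE,
) -> list[EvaluationReport]:
    """Reports for every (model, split) pair; predictions[model][split]."""
    reports = []
    for model_name, per_split in predictions.items():
        for split, pred in per_split.items():
            reports.append(
                evaluate_model(
                    frames_by_split[split],
                    pred,
                    outcome=outcome,
                    q=q,
                    model_name=model_name,
                    split=split,
                )
            )
    return reports


def reports_frame(reports: list[EvaluationReport]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "model": r.model,
                "split": r.split,
                "outcome": r.outcome,
                "rmse": r.rmse_overall,
                "spike_day_mape": r.spike_day_mape,
                "total_abs_pct_error": r.total_abs_pct_error,
                "n_clipped_low": r.n_clipped_low,
                "n_clipped_high": r.n_clipped_high,
            }
            for r in reports
        ]
    )
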