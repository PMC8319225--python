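"""Hourly weather + calendars → per-city per-12-h model-ready feature rows.

The modelling unit is the 12-hour frame: one city over 06:00–17:59 ("day")
or 18:00–05:59 the next morning ("night"; labelled by the date of its 18:00
start).  The processing order mirrors the five steps the analysis uses:

1. grid-point weather is averaged (unweighted) to per-city per-hour series,
   with a coarse-grid fallback where a fine point is missing;
2. WBGT is computed per hour from the validated estimation polynomial;
3. previous-24-h mean/max/min are computed per city per hour (the window is
   the 24 hours strictly before the hour);
4. hourly values are summarized per frame (mean/max/min; precipitation is
   the 12-h sum);
5. difference features are the frame statistic minus the previous-24-h
   statistic evaluated at the frame's first hour, so consecutive hot days
   show up as near-zero or negative max-temperature differences.

Calendar variables (month, rainy season, days after the rainy-season end,
holidays) and city demographics are then attached, together with the
period-matched log-population offset.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .errors import (
    ConfigurationError,
    GapError,
    InvalidArgumentError,
    RecordValidationError,
    SchemaError,
)
from .synthetic_data import SEVERITIES, CityProfile, profiles_frame

logger = logging.getLogger(__name__)

WEATHER_VARS = ["Ta", "RH", "WS", "SR", "WBGT"]
#: variables that get frame-minus-previous-24-h difference features; only the
#: temperature differences enter the default predictor sets.
DIFF_VARS = ["Ta", "RH", "WBGT"]

DAY_START_HOUR = 6
NIGHT_START_HOUR = 18

# WBGT estimation polynomial (°C from Ta °C, RH %, SR kW/m², WS m/s)
_WBGT_TA = 0.735
_WBGT_RH = 0.0374
_WBGT_TARH = 0.00292
_WBGT_SR = 7.619
_WBGT_SR2 = -4.557
_WBGT_WS = -0.0572
_WBGT_CONST = -4.064


def estimate_wbgt(Ta, RH, SR, WS, validate: str = "raise"):
    """Estimate wet bulb globe temperature (°C).

    Evaluates the regression polynomial

        WBGT = 0.735·Ta + 0.0374·RH + 0.00292·Ta·RH + 7.619·SR
               − 4.557·SR² − 0.0572·WS − 4.064

    element-wise.  ``validate`` ∈ {"raise", "warn", "ignore"} controls what
    happens when RH is outside [0, 100] or SR/WS are negative.
    """
    Ta = np.asarray(Ta, dtype=float)
    RH = np.asarray(RH, dtype=float)
    SR = np.asarray(SR, dtype=float)
    WS = np.asarray(WS, dtype=float)
    bad = (RH < 0) | (RH > 100) | (SR < 0) | (WS < 0)
    if np.any(bad):
        msg = f"{int(np.sum(bad))} input(s) outside the WBGT domain (RH∈[0,100], SR≥0, WS≥0)"
        if validate == "raise":
            raise InvalidArgumentError(msg)
        if validate == "warn":
            logger.warning(msg)
    out = (
        _WBGT_TA * Ta
        + _WBGT_RH * RH
        + _WBGT_TARH * Ta * RH
        + _WBGT_SR * SR
        + _WBGT_SR2 * SR**2
        + _WBGT_WS * WS
        + _WBGT_CONST
    )
    return out if out.ndim else float(out)


# NWS/Rothfusz heat-index regression coefficients (°F)
_HI_C = (
    -42.379,
    2.04901523,
    10.14333127,
    -0.22475541,
    -6.83783e-3,
    -5.481717e-2,
    1.22874e-3,
    8.5282e-4,
    -1.99e-6,
)


def heat_index(Ta, RH):
    """Apparent temperature (°C) from ambient temperature and humidity.

    Rothfusz-style regression evaluated in Fahrenheit internally, with the
    standard low-/high-humidity adjustments and a pass-through below the
    regime where the adjustment applies (the ambient temperature is returned
    unchanged there).  Descriptive-statistics use only; never a model
    predictor.
    """
    Ta = np.asarray(Ta, dtype=float)
    RH = np.asarray(RH, dtype=float)
    Tf = Ta * 1.8 + 32.0
    simple = 0.5 * (Tf + 61.0 + (Tf - 68.0) * 1.2 + RH * 0.094)
    c1, c2, c3, c4, c5, c6, c7, c8, c9 = _HI_C
    full = (
        c1 + c2 * Tf + c3 * RH + c4 * Tf * RH + c5 * Tf**2 + c6 * RH**2
        + c7 * Tf**2 * RH + c8 * Tf * RH**2 + c9 * Tf**2 * RH**2
    )
    with np.errstate(invalid="ignore"):
        low_adj = ((13.0 - RH) / 4.0) * np.sqrt(
            np.clip((17.0 - np.abs(Tf - 95.0)) / 17.0, 0.0, None)
        )
        high_adj = ((RH - 85.0) / 10.0) * ((87.0 - Tf) / 5.0)
    full = np.where((RH < 13) & (Tf >= 80) & (Tf <= 112), full - low_adj, full)
    full = np.where((RH > 85) & (Tf >= 80) & (Tf <= 87), full + high_adj, full)
    hi_f = np.where(0.5 * (simple + Tf) < 80.0, Tf, full)
    out = (hi_f - 32.0) / 1.8
    return out if out.ndim else float(out)


def average_grid_to_city(
    grid_hourly: pd.DataFrame,
    mapping: pd.DataFrame,
    coarse_hourly: pd.DataFrame | None = None,
    cities=None,
) -> pd.DataFrame:
    """Unweighted mean of a city's grid points per variable per hour.

    ``grid_hourly`` has columns (grid_id, timestamp, Ta, RH, precip, WS, SR);
    ``mapping`` maps grid_id → city_id.  Missing (NaN) fine-grid values are
    substituted from ``coarse_hourly`` (keyed by city_id, timestamp) before
    averaging, mirroring the nearest-coarse-point fallback.
    """
    var_cols = [c for c in grid_hourly.columns if c not in ("grid_id", "timestamp")]
    mapped_cities = set(mapping["city_id"])
    if cities is not None:
        missing = sorted(set(cities) - mapped_cities)
        if missing:
            raise ConfigurationError(f"cities with zero mapped grid points: {missing}")
    merged = grid_hourly.merge(mapping, on="grid_id", how="left", validate="many_to_one")
    if merged["city_id"].isna().any():
        bad = sorted(merged.loc[merged["city_id"].isna(), "grid_id"].unique())
        raise ConfigurationError(f"grid points without a city mapping: {bad}")
    if coarse_hourly is not None:
        coarse = coarse_hourly.set_index(["city_id", "timestamp"])
        idx = pd.MultiIndex.from_frame(merged[["city_id", "timestamp"]])
        for v in var_cols:
            fallback = coarse[v].reindex(idx).to_numpy()
            col = merged[v].to_numpy(dtype=float)
            merged[v] = np.where(np.isnan(col), fallback, col)
    out = (
        merged.groupby(["city_id", "timestamp"], sort=True)[var_cols]
        .mean()
        .reset_index()
    )
    return out


def _check_contiguous(city_hourly: pd.DataFrame) -> None:
    missing = []
    for city_id, grp in city_hourly.groupby("city_id", sort=True):
        ts = pd.DatetimeIndex(grp["timestamp"]).sort_values()
        if ts.has_duplicates:
            dups = ts[ts.duplicated()]
            raise GapError(
                f"duplicate hours for {city_id}", [(city_id, t) for t in dups[:10]]
            )
        # gaps only checked within a season (contiguous June-September block)
        for _, yearly in grp.groupby(grp["timestamp"].dt.year):
            yts = pd.DatetimeIndex(yearly["timestamp"]).sort_values()
            expected = pd.date_range(yts[0], yts[-1], freq="h")
            gap = expected.difference(yts)
            missing.extend((city_id, t) for t in gap)
    if missing:
        raise GapError(
            f"{len(missing)} missing hour(s), first: {missing[:5]}", missing
        )


def rolling_prev24_stats(city_hourly: pd.DataFrame) -> pd.DataFrame:
    """Previous-24-h mean/max/min per city per hour per weather variable.

    For the row at hour *t* the window is hours [t−24h, t−1h].  Hours whose
    window is incomplete (the first 24 h of each season) carry NaN and
    ``prev24_complete`` False.  Gaps in the hourly series raise
    :class:`~heatspike.errors.GapError`.
    """
    _check_contiguous(city_hourly)
    df = city_hourly.sort_values(["city_id", "timestamp"]).reset_index(drop=True)
    var_cols = [v for v in WEATHER_VARS if v in df.columns]
    pieces = []
    for city_id, grp in df.groupby("city_id", sort=True):
        # one contiguous block per season: restart the window at season breaks
        out = grp[["city_id", "timestamp"]].copy()
        season = grp["timestamp"].dt.year
        for v in var_cols:
            shifted = grp.groupby(season)[v].shift(1)
            roll = shifted.groupby(season).rolling(24, min_periods=24)
            out[f"{v}_prev24_mean"] = roll.mean().reset_index(level=0, drop=True)
            out[f"{v}_prev24_max"] = roll.max().reset_index(level=0, drop=True)
            out[f"{v}_prev24_min"] = roll.min().reset_index(level=0, drop=True)
        pieces.append(out)
    result = pd.concat(pieces, ignore_index=True)
    first_var = var_cols[0]
    result["prev24_complete"] = result[f"{first_var}_prev24_mean"].notna()
    return result


def assign_frames(timestamps: pd.Series) -> pd.DataFrame:
    """Map each hourly timestamp to its (frame_date, period).

    Hours 06–17 belong to the day frame of their own date; hours 18–23 to the
    night frame starting that date; hours 00–05 to the night frame starting
    the previous date.
    """
    ts = pd.DatetimeIndex(timestamps)
    hour = ts.hour
    date = ts.normalize()
    frame_date = np.where(hour < DAY_START_HOUR, date - pd.Timedelta(days=1), date)
    period = np.where((hour >= DAY_START_HOUR) & (hour < NIGHT_START_HOUR), "day", "night")
    return pd.DataFrame({"frame_date": pd.DatetimeIndex(frame_date), "period": period})


def build_frames(
    city_hourly: pd.DataFrame,
    rainy: pd.DataFrame,
    holidays: pd.DataFrame,
    profiles: list[CityProfile] | pd.DataFrame,
    heatwave_days=None,
    drop_incomplete: bool = True,
) -> pd.DataFrame:
    """Build the per-city per-12-h feature table (counts left empty).

    Every hour belongs to exactly one frame.  Frames are dropped (with a
    logged count) when they have fewer than 12 hours (the trailing night
    frame of a season) or when the previous-24-h window before their first
    hour is incomplete (the first frames of a season), so all difference
    features on retained rows are well defined.
    """
    hourly = city_hourly.copy()
    hourly["WBGT"] = estimate_wbgt(
        hourly["Ta"], hourly["RH"], hourly["SR"], hourly["WS"], validate="warn"
    )
    fr = assign_frames(hourly["timestamp"])
    hourly = pd.concat([hourly.reset_index(drop=True), fr], axis=1)

    agg_spec = {}
    for v in WEATHER_VARS:
        agg_spec[f"{v}_mean"] = (v, "mean")
        agg_spec[f"{v}_max"] = (v, "max")
        agg_spec[f"{v}_min"] = (v, "min")
    agg_spec["precip_prev12h"] = ("precip", "sum")
    agg_spec["n_hours"] = ("Ta", "size")
    agg_spec["first_hour"] = ("timestamp", "min")
    frames = (
        hourly.groupby(["city_id", "frame_date", "period"], sort=True)
        .agg(**agg_spec)
        .reset_index()
    )

    # frame start = 06:00 (day) / 18:00 (night) of frame_date; the previous-24-h
    # statistics are those of the hour at the frame start.
    start_hour = np.where(frames["period"] == "day", DAY_START_HOUR, NIGHT_START_HOUR)
    frames["frame_start"] = frames["frame_date"] + pd.to_timedelta(start_hour, unit="h")
    prev = rolling_prev24_stats(hourly[["city_id", "timestamp"] + WEATHER_VARS])
    frames = frames.merge(
        prev.rename(columns={"timestamp": "frame_start"}),
        on=["city_id", "frame_start"],
        how="left",
    )
    frames["prev24_complete"] = frames["prev24_complete"].eq(True)
    for v in DIFF_VARS:
        for stat in ("mean", "max", "min"):
            frames[f"{v}_diff_{stat}"] = (
                frames[f"{v}_{stat}"] - frames[f"{v}_prev24_{stat}"]
            )

    n_total = len(frames)
    if drop_incomplete:
        keep = (frames["n_hours"] == 12) & frames["prev24_complete"]
        n_dropped = int((~keep).sum())
        if n_dropped:
            logger.info(
                "dropped %d/%d frames with incomplete hours or 24-h history",
                n_dropped,
                n_total,
            )
        frames = frames.loc[keep].reset_index(drop=True)

    # calendar features
    rainy_end = {
        int(r.year): pd.Timestamp(r.rainy_season_end) for r in rainy.itertuples()
    }
    years = frames["frame_date"].dt.year
    missing_years = sorted(set(years.unique()) - set(rainy_end))
    if missing_years:
        raise ConfigurationError(f"rainy-season calendar missing years: {missing_years}")
    ends = years.map(rainy_end)
    frames["month"] = frames["frame_date"].dt.month
    frames["rainy_season"] = frames["frame_date"] <= ends
    frames["days_after_rainy_end"] = (
        (frames["frame_date"] - ends).dt.days.clip(lower=0).astype(int)
    )
    holiday_set = {pd.Timestamp(d).date() for d in holidays["date"]}
    frames["holiday"] = [d.date() in holiday_set for d in frames["frame_date"]]

    # demographics + period-matched population offset
    prof = profiles if isinstance(profiles, pd.DataFrame) else profiles_frame(profiles)
    frames = frames.merge(prof, on="city_id", how="left", validate="many_to_one")
    if frames["population_day"].isna().any():
        bad = sorted(frames.loc[frames["population_day"].isna(), "city_id"].unique())
        raise ConfigurationError(f"cities without a profile: {bad}")
    frames["population"] = np.where(
        frames["period"] == "day", frames["population_day"], frames["population_night"]
    )
    frames["log_population_offset"] = np.log(frames["population"].astype(float))

    if heatwave_days is not None:
        days = {pd.Timestamp(d).date() for d in heatwave_days}
        frames["heatwave"] = [d.date() in days for d in frames["frame_date"]]

    frames["count_all"] = np.nan
    frames["count_admission_death"] = np.nan
    order = {"day": 0, "night": 1}
    frames = frames.sort_values(
        ["city_id", "frame_date", "period"], key=lambda s: s.map(order) if s.name == "period" else s
    ).reset_index(drop=True)
    return frames


def aggregate_registry(
    events: pd.DataFrame,
    frames: pd.DataFrame,
    on_unmatched: str = "error",
) -> pd.DataFrame:
    """Bin registry events into frames; fill count_all / count_admission_death.

    ``count_all`` counts every severity; ``count_admission_death`` counts
    moderate, severe, and death cases.  Events are assigned to the frame
    containing their timestamp (17:59 → day; 18:00 → night).  Events whose
    frame is not in ``frames`` raise (``on_unmatched="error"``) or are
    dropped with a log message (``"drop"``).
    """
    frames = frames.copy()
    frames["count_all"] = 0
    frames["count_admission_death"] = 0
    if len(events) == 0:
        return frames
    bad = ~events["severity"].isin(SEVERITIES)
    if bad.any():
        raise RecordValidationError(
            f"{int(bad.sum())} event(s) with unknown severity "
            f"{sorted(events.loc[bad, 'severity'].unique())}",
            bad_records=events.index[bad].tolist(),
        )
    ev = events.copy()
    fr = assign_frames(ev["timestamp"])
    ev = pd.concat([ev.reset_index(drop=True), fr], axis=1)
    ev["is_adm"] = ev["severity"].isin(["moderate", "severe", "death"])
    counts = (
        ev.groupby(["city_id", "frame_date", "period"])
        .agg(count_all=("severity", "size"), count_admission_death=("is_adm", "sum"))
        .reset_index()
    )
    key = ["city_id", "frame_date", "period"]
    merged = frames.drop(columns=["count_all", "count_admission_death"]).merge(
        counts, on=key, how="left"
    )
    merged["count_all"] = merged["count_all"].fillna(0).astype(int)
    merged["count_admission_death"] = merged["count_admission_death"].fillna(0).astype(int)
    n_assigned = int(merged["count_all"].sum())
    if n_assigned != len(ev):
        n_lost = len(ev) - n_assigned
        msg = f"{n_lost} event(s) fall outside the provided frames"
        if on_unmatched == "error":
            raise RecordValidationError(msg)
        logger.info(msg)
    return merged
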