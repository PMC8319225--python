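"""Shared fixtures: small synthetic bundles built once per session."""

import warnings

import pandas as pd
import pytest

from heatspike import feature_engineering as fe
from heatspike import synthetic_data as sd


@pytest.fixture(scope="session")
def profiles4():
    return sd.generate_city_profiles(4, seed=11)


@pytest.fixture(scope="session")
def calendars():
    return sd.make_calendars([2015, 2016, 2017], seed=5)


@pytest.fixture(scope="session")
def weather_small(profiles4):
    """2 cities, one season."""
    return sd.simulate_hourly_weather(profiles4[:2], [2015], seed=7)


@pytest.fixture(scope="session")
def frames_small(profiles4, calendars, weather_small):
    rainy, holidays = calendars
    return fe.build_frames(
        weather_small.hourly, rainy, holidays, profiles4[:2],
        heatwave_days=weather_small.heatwave_days,
    )


@pytest.fixture(scope="session")
def bundle_medium():
    """6 cities (≥1 big), 2 seasons, with counts — the model-fitting workhorse."""
    profiles = sd.generate_city_profiles(6, seed=2)
    rainy, holidays = sd.make_calendars([2015, 2016], seed=3)
    sim = sd.simulate_hourly_weather(profiles, [2015, 2016], seed=4)
    frames = fe.build_frames(
        sim.hourly, rainy, holidays, profiles, heatwave_days=sim.heatwave_days
    )
    truth = sd.SyntheticTruth(seed=9)
    frames = sd.simulate_heatstroke_counts(frames, truth)
    return {
        "profiles": profiles,
        "profiles_df": sd.profiles_frame(profiles),
        "frames": frames,
        "truth": truth,
        "heatwave_days": sim.heatwave_days,
    }


@pytest.fixture(autouse=True)
def _quiet_statsmodels():
    with warnings.catch_warnings():
        warnings.filterwarnings("ignore", module="statsmodels")
        warnings.filterwarnings("ignore", message=".*convergence.*")
        yield


def naive_frame_stats(hourly: pd.DataFrame) -> pd.DataFrame:
    """Independent per-frame loop oracle for mean/max/min and precip sums."""
    rows = []
    for (city, ts), grp in hourly.groupby(
        ["city_id", hourly["timestamp"].map(_frame_key)]
    ):
        row = {"city_id": city, "frame_date": ts[0], "period": ts[1], "n_hours": len(grp)}
        for v in ("Ta", "RH", "WS", "SR"):
            vals = grp[v].to_numpy(float)
            row[f"{v}_mean"] = vals.mean()
            row[f"{v}_max"] = vals.max()
            row[f"{v}_min"] = vals.min()
        row["precip_prev12h"] = grp["precip"].sum()
        rows.append(row)
    return pd.DataFrame(rows)


def _frame_key(ts):
    ts = pd.Timestamp(ts)
    if 6 <= ts.hour < 18:
        return (ts.normalize(), "day")
    if ts.hour >= 18:
        return (ts.normalize(), "night")
    return (ts.normalize() - pd.Timedelta(days=1), "night")
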