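"""Seeded synthetic inputs for the heatstroke-forecasting pipeline.

The real inputs of this analysis — an ambulance-transport heatstroke registry
and commercial gridded weather data — are not publicly available.  This module
generates statistically analogous inputs so that every downstream stage
(feature engineering, count models, spike ensemble, evaluation) can be
exercised and tested end to end:

* city profiles for a set of mid-sized to large cities (day/night population,
  demographics, green area), with the > 500,000-population "big city" rule;
* hourly weather per city for June 1 – September 30 of each requested year,
  with seasonal and diurnal temperature cycles, a shared regional anomaly,
  injected multi-day heat waves, humidity anticorrelated with temperature,
  daylight-only solar radiation, rain and wind;
* a rainy-season calendar (one end date per year) and a holiday calendar
  (weekends, fixed national holidays, and the Obon break of August 13–15);
* per-city per-12-h heatstroke counts drawn from a Poisson model whose
  log-rate is quadratic in mean temperature, depends on the consecutive-hot-day
  difference feature, humidity and solar radiation, carries a log-population
  offset, and receives an additive log-rate boost on heat-wave days (the
  "spike" mechanism the ensemble stage is built to capture).  The
  admission+death count is a binomial thinning of the all-case count.

Default magnitudes are calibrated so that a 16-city bundle reproduces the
study conditions: roughly 10 million total population, all-case incidence
near 37.5 per 100,000 per season, typical all-city daily totals of a few
dozen cases with heat-wave spikes several times larger, and weather marginals
inside the observed ranges (temperature ~10–36 °C, relative humidity 25–100%,
frame-mean solar radiation 0–0.7 kW/m²).
"""

from __future__ import annotations

import calendar as _calendar
import dataclasses
import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import InvalidArgumentError, SchemaError

SEASON_START = (6, 1)
SEASON_END = (9, 30)
SEASON_DAYS = 122
BIG_CITY_THRESHOLD = 500_000

WEATHER_COLUMNS = ["city_id", "timestamp", "Ta", "RH", "precip", "WS", "SR"]
SEVERITIES = ("mild", "moderate", "severe", "death")


@dataclass(frozen=True)
class CityProfile:
    """Static demographic and geographic attributes of one city."""

    city_id: str
    population_day: int
    population_night: int
    median_age: float
    population_65plus: int
    men_women_ratio: float  # men per 100 women
    taxable_income: float  # currency units per year
    green_area_pct: float

    @property
    def is_big_city(self) -> bool:
        return max(self.population_day, self.population_night) > BIG_CITY_THRESHOLD

    def population(self, period: str) -> int:
        return self.population_day if period == "day" else self.population_night


@dataclass
class SyntheticTruth:
    """Generating model for the per-frame Poisson counts.

    The log-rate is::

        eta = intercept
              + temp_effect[0] * (Ta_mean - temp_ref)
              + temp_effect[1] * (Ta_mean - temp_ref)**2
              + knee_effect * max(0, Ta_mean - temp_knee)
              + diff24_effect * Ta_diff_max
              + humidity_effect * (RH_mean - rh_ref)
              + solar_effect * SR_mean
              + spike_boost * 1[heat-wave day]
              + calendar terms (night, rainy season / post-rainy
                acclimatization decay, holiday)
              + demographic terms (median age, 65+ share, income, sex ratio)
              + log(population)

    and counts are Poisson(exp(eta)); the admission+death count is a
    Binomial(count, admission_fraction) thinning.  The hinge ("knee") term
    gives the J-shaped exposure-response curve characteristic of
    heat-related illness: risk is flat to mildly rising below the knee and
    climbs steeply above it.  The demographic terms give cities distinct
    baseline rates beyond their population size — older, lower-income cities
    with a larger 65+ share carry higher risk — mirroring the vulnerability
    gradients heat-illness registries show.
    """

    intercept: float = -14.45
    temp_effect: tuple[float, float] = (0.09, 0.003)
    temp_knee: float = 29.0
    knee_effect: float = 0.18
    diff24_effect: float = -0.04
    humidity_effect: float = 0.006
    solar_effect: float = 0.55
    spike_boost: float = 1.25
    admission_fraction: float = 0.29
    temp_ref: float = 26.0
    rh_ref: float = 70.0
    # calendar / behavioural effects
    night_effect: float = -0.35  # night frames: less outdoor exposure
    rainy_effect: float = -0.25  # during the rainy season (wet, cooler behaviour)
    post_rainy_effect: float = 0.25  # acclimatization bump right after the
    post_rainy_scale: float = 7.0  # rainy season ends, decaying over ~a week
    holiday_effect: float = 0.15  # more outdoor activity on holidays
    # per-city baseline effects (centered at typical city values)
    age_effect: float = 0.03  # per year of median age above 47
    senior_effect: float = 0.0  # per %-point of 65+ share above 27% (off by default:
    # the models see the raw 65+ count, so a share effect is unlearnable for them)
    income_effect: float = -0.25  # per million currency units above 3.6M
    sex_ratio_effect: float = -0.015  # per men-per-100-women above 92
    seed: int = 0

    def __post_init__(self):
        if not 0.0 <= self.admission_fraction < 1.0:
            raise InvalidArgumentError(
                f"admission_fraction must be in [0, 1), got {self.admission_fraction}"
            )

    def linear_predictor(self, frames: pd.DataFrame) -> np.ndarray:
        required = ["Ta_mean", "Ta_diff_max", "RH_mean", "SR_mean", "log_population_offset"]
        missing = [c for c in required if c not in frames.columns]
        if missing:
            raise SchemaError(f"frames are missing required feature columns: {missing}")
        ta = frames["Ta_mean"].to_numpy(float)
        t = ta - self.temp_ref
        eta = (
            self.intercept
            + self.temp_effect[0] * t
            + self.temp_effect[1] * t**2
            + self.knee_effect * np.clip(ta - self.temp_knee, 0.0, None)
            + self.diff24_effect * frames["Ta_diff_max"].to_numpy(float)
            + self.humidity_effect * (frames["RH_mean"].to_numpy(float) - self.rh_ref)
            + self.solar_effect * frames["SR_mean"].to_numpy(float)
            + frames["log_population_offset"].to_numpy(float)
        )
        if "period" in frames.columns:
            eta = eta + self.night_effect * (frames["period"] == "night").to_numpy(float)
        if "rainy_season" in frames.columns:
            rainy = frames["rainy_season"].to_numpy(bool)
            days_after = frames["days_after_rainy_end"].to_numpy(float)
            eta = eta + np.where(
                rainy,
                self.rainy_effect,
                self.post_rainy_effect * np.exp(-days_after / self.post_rainy_scale),
            )
        if "holiday" in frames.columns:
            eta = eta + self.holiday_effect * frames["holiday"].to_numpy(float)
        if "median_age" in frames.columns:
            senior_share = (
                frames["population_65plus"].to_numpy(float)
                / frames["population_night"].to_numpy(float)
                * 100.0
            )
            eta = eta + (
                self.age_effect * (frames["median_age"].to_numpy(float) - 47.0)
                + self.senior_effect * (senior_share - 27.0)
                + self.income_effect * (frames["taxable_income"].to_numpy(float) / 1e6 - 3.6)
                + self.sex_ratio_effect * (frames["men_women_ratio"].to_numpy(float) - 92.0)
            )
        if "heatwave" in frames.columns:
            eta = eta + self.spike_boost * frames["heatwave"].to_numpy(float)
        return eta

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self), indent=2, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "SyntheticTruth":
        payload = json.loads(text)
        payload["temp_effect"] = tuple(payload["temp_effect"])
        return cls(**payload)


@dataclass
class WeatherParams:
    """Tunable knobs of the hourly weather generator (units: °C, %, mm, m/s, kW/m²)."""

    base_temp: float = 22.5
    seasonal_amplitude: float = 6.5
    seasonal_peak_day: int = 68  # days after June 1 (≈ August 7)
    seasonal_width: float = 45.0
    diurnal_amplitude: float = 3.5
    regional_ar: float = 0.7
    regional_sd: float = 2.2
    city_noise_sd: float = 0.8
    n_heatwaves_per_year: tuple[int, int] = (3, 5)
    heatwave_length: tuple[int, int] = (3, 7)
    heatwave_bump: tuple[float, float] = (2.5, 5.0)
    rh_base: float = 78.0
    rh_slope: float = 2.2  # % per °C of temperature anomaly
    rh_sd: float = 6.0
    rain_day_prob: float = 0.30
    clear_sky_peak_sr: float = 0.95
    wind_shape: float = 2.2
    wind_scale: float = 1.2
    grid_noise_sd: float = 0.4
    # heat-wave designation (sustained-heat rule applied to the generated
    # series): a run of >= min_run consecutive days whose regional daily
    # maximum temperature is at or above detect_threshold
    heatwave_detect_threshold: float = 33.0
    heatwave_min_run: int = 3


@dataclass
class WeatherSim:
    """Hourly weather plus the injected heat-wave calendar."""

    hourly: pd.DataFrame
    heatwave_days: set  # set of datetime.date


def season_dates(year: int) -> pd.DatetimeIndex:
    return pd.date_range(f"{year}-06-01", f"{year}-09-30", freq="D")


def season_hours(year: int) -> pd.DatetimeIndex:
    return pd.date_range(f"{year}-06-01 00:00", periods=SEASON_DAYS * 24, freq="h")


# ---------------------------------------------------------------------------
# City profiles
# ---------------------------------------------------------------------------

def generate_city_profiles(n_cities: int, seed: int) -> list[CityProfile]:
    """Generate ``n_cities`` seeded city profiles.

    Populations are drawn from a two-component mixture (a ~30% share of
    large cities with 560k–3.5M night-time residents and a majority of
    50k–400k cities), so that a 16-city draw resembles the study region:
    around five cities above the 500,000 "big city" threshold and a total
    population near ten million.
    """
    if n_cities < 1:
        raise InvalidArgumentError(f"n_cities must be >= 1, got {n_cities}")
    rng = np.random.default_rng(seed)
    profiles = []
    n_big = int(round(0.3 * n_cities))
    if n_cities >= 5:
        n_big = max(1, n_big)
    big = np.zeros(n_cities, dtype=bool)
    big[rng.permutation(n_cities)[:n_big]] = True
    log_pop = np.where(
        big, rng.uniform(5.75, 6.55, n_cities), rng.uniform(4.70, 5.60, n_cities)
    )
    for i in range(n_cities):
        pop_night = int(round(10 ** log_pop[i]))
        pop_day = int(round(pop_night * rng.uniform(0.75, 1.45)))
        profiles.append(
            CityProfile(
                city_id=f"city{i:02d}",
                population_day=pop_day,
                population_night=pop_night,
                median_age=float(np.round(rng.uniform(42.0, 52.0), 1)),
                population_65plus=int(round(pop_night * rng.uniform(0.22, 0.33))),
                men_women_ratio=float(np.round(rng.uniform(85.0, 100.0), 1)),
                taxable_income=float(np.round(rng.uniform(2.8e6, 4.5e6), -3)),
                green_area_pct=float(np.round(rng.uniform(5.0, 60.0), 1)),
            )
        )
    return profiles


def profiles_frame(profiles: list[CityProfile]) -> pd.DataFrame:
    df = pd.DataFrame([dataclasses.asdict(p) for p in profiles])
    df["is_big_city"] = [p.is_big_city for p in profiles]
    return df


def profiles_from_frame(df: pd.DataFrame) -> list[CityProfile]:
    cols = [f.name for f in dataclasses.fields(CityProfile)]
    return [CityProfile(**{c: row[c] for c in cols}) for _, row in df.iterrows()]


# ---------------------------------------------------------------------------
# Calendars
# ---------------------------------------------------------------------------

def _nth_weekday(year: int, month: int, weekday: int, n: int):
    """Date of the n-th given weekday (Mon=0) of a month."""
    cal = _calendar.Calendar()
    days = [d for d in cal.itermonthdates(year, month) if d.month == month and d.weekday() == weekday]
    return days[n - 1]


def make_calendars(years: list[int], seed: int) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Rainy-season end dates and holiday calendar for each year.

    The rainy-season end is drawn uniformly between June 20 and July 31
    (the observed historical range for the study region).  Holidays are all
    Saturdays/Sundays of the season, Marine Day (3rd Monday of July),
    Mountain Day (Aug 11), Respect-for-the-Aged Day (3rd Monday of
    September), the autumnal equinox (taken as Sep 23), and the Obon break
    of August 13-15.
    """
    if not years:
        raise InvalidArgumentError("years must be non-empty")
    rng = np.random.default_rng(seed)
    rainy_rows, holiday_rows = [], []
    for year in sorted(years):
        end = pd.Timestamp(year=year, month=6, day=20) + pd.Timedelta(
            days=int(rng.integers(0, 42))
        )
        rainy_rows.append({"year": year, "rainy_season_end": end.date()})
        dates = set()
        for ts in season_dates(year):
            if ts.weekday() >= 5:
                dates.add(ts.date())
        dates.add(_nth_weekday(year, 7, 0, 3))   # Marine Day
        dates.add(pd.Timestamp(year, 8, 11).date())  # Mountain Day
        dates.add(_nth_weekday(year, 9, 0, 3))   # Respect-for-the-Aged Day
        dates.add(pd.Timestamp(year, 9, 23).date())  # autumnal equinox
        for day in (13, 14, 15):                 # Obon
            dates.add(pd.Timestamp(year, 8, day).date())
        for d in sorted(dates):
            holiday_rows.append({"year": year, "date": d})
    return pd.DataFrame(rainy_rows), pd.DataFrame(holiday_rows)


# ---------------------------------------------------------------------------
# Hourly weather
# ---------------------------------------------------------------------------

def simulate_hourly_weather(
    profiles: list[CityProfile],
    years: list[int],
    params: WeatherParams | None = None,
    seed: int = 0,
    inject_heatwaves: bool = True,
    year_offsets: dict[int, float] | None = None,
) -> WeatherSim:
    """Simulate per-city hourly weather for June 1 – Sep 30 of each year.

    Temperature = seasonal Gaussian bump + diurnal sinusoid + shared regional
    AR(1) daily anomaly + per-city hourly AR(1) noise + heat-wave bumps
    (3–7 consecutive days, shared across cities).  Relative humidity moves
    against the temperature anomaly; solar radiation follows a daylight
    half-sine scaled by a daily cloudiness factor (zero on 19:00–05:59);
    precipitation occurs on random wet days; wind is gamma-distributed.
    """
    if not profiles:
        raise InvalidArgumentError("profiles must be non-empty")
    if not years:
        raise InvalidArgumentError("years must be non-empty")
    p = params or WeatherParams()
    rng = np.random.default_rng(seed)
    hours_per_year = SEASON_DAYS * 24
    frames = []
    heatwave_days: set = set()
    s = np.arange(SEASON_DAYS)
    seasonal = p.base_temp + p.seasonal_amplitude * np.exp(
        -(((s - p.seasonal_peak_day) / p.seasonal_width) ** 2)
    )
    hour_of_day = np.tile(np.arange(24), SEASON_DAYS)
    diurnal = p.diurnal_amplitude * np.sin(2 * np.pi * (hour_of_day - 9) / 24)
    daylight = (hour_of_day >= 6) & (hour_of_day < 19)
    sr_shape = np.where(
        daylight, np.sin(np.pi * (hour_of_day - 5.5) / 13.5).clip(min=0.0), 0.0
    )
    city_offsets = rng.uniform(-1.0, 1.0, len(profiles))

    for year in sorted(years):
        ts = season_hours(year)
        # shared regional AR(1) daily anomaly
        eps = rng.normal(0.0, p.regional_sd * np.sqrt(1 - p.regional_ar**2), SEASON_DAYS)
        regional = np.empty(SEASON_DAYS)
        regional[0] = rng.normal(0.0, p.regional_sd)
        for d in range(1, SEASON_DAYS):
            regional[d] = p.regional_ar * regional[d - 1] + eps[d]
        # heat waves: contiguous bumps in July-August, shared regionally
        bump = np.zeros(SEASON_DAYS)
        if inject_heatwaves:
            n_waves = int(rng.integers(p.n_heatwaves_per_year[0], p.n_heatwaves_per_year[1] + 1))
            for _ in range(n_waves):
                length = int(rng.integers(p.heatwave_length[0], p.heatwave_length[1] + 1))
                start = int(rng.integers(35, SEASON_DAYS - 20 - length))  # July 6 – Sep 10
                amp = rng.uniform(*p.heatwave_bump)
                bump[start : start + length] = np.maximum(bump[start : start + length], amp)
        daily_temp = seasonal + regional + bump
        if year_offsets and year in year_offsets:
            # constant warming offset for this season, e.g. to emulate an
            # anomalously hot held-out validation year
            daily_temp = daily_temp + float(year_offsets[year])
        cloud = rng.uniform(0.25, 1.0, SEASON_DAYS)
        wet_day = rng.random(SEASON_DAYS) < p.rain_day_prob
        cloud = np.where(wet_day, cloud * 0.45, cloud)
        city_daily_max = np.empty((len(profiles), SEASON_DAYS))
        for ci, prof in enumerate(profiles):
            noise = rng.normal(0.0, p.city_noise_sd * np.sqrt(1 - 0.36), hours_per_year)
            ar = np.empty(hours_per_year)
            ar[0] = rng.normal(0.0, p.city_noise_sd)
            for h in range(1, hours_per_year):
                ar[h] = 0.6 * ar[h - 1] + noise[h]
            ta = np.repeat(daily_temp, 24) + diurnal + city_offsets[ci] + ar
            rh = (
                p.rh_base
                - p.rh_slope * (ta - np.repeat(seasonal, 24))
                + rng.normal(0.0, p.rh_sd, hours_per_year)
            ).clip(5.0, 100.0)
            sr = (
                p.clear_sky_peak_sr * sr_shape * np.repeat(cloud, 24)
                * rng.uniform(0.85, 1.0, hours_per_year)
            )
            wet_hour = np.repeat(wet_day, 24) & (rng.random(hours_per_year) < 0.30)
            precip = np.where(wet_hour, rng.exponential(2.0, hours_per_year), 0.0)
            ws = rng.gamma(p.wind_shape, p.wind_scale, hours_per_year)
            city_daily_max[ci] = ta.reshape(SEASON_DAYS, 24).max(axis=1)
            frames.append(
                pd.DataFrame(
                    {
                        "city_id": prof.city_id,
                        "timestamp": ts,
                        "Ta": np.round(ta, 3),
                        "RH": np.round(rh, 2),
                        "precip": np.round(precip, 2),
                        "WS": np.round(ws, 2),
                        "SR": np.round(sr, 4),
                    }
                )
            )
        # designate heat-wave days with the sustained-heat rule: a run of
        # >= heatwave_min_run consecutive days whose regional (city-mean)
        # daily maximum is at or above the detection threshold.  The rule is
        # a deterministic function of the generated weather, so the spike
        # mechanism tied to these days is learnable from the features.
        regional_max = city_daily_max.mean(axis=0)
        hot = regional_max >= p.heatwave_detect_threshold
        run = 0
        for d in range(SEASON_DAYS + 1):
            if d < SEASON_DAYS and hot[d]:
                run += 1
            else:
                if run >= p.heatwave_min_run:
                    for k in range(d - run, d):
                        heatwave_days.add(ts[24 * k].date())
                run = 0
    hourly = pd.concat(frames, ignore_index=True)
    return WeatherSim(hourly=hourly, heatwave_days=heatwave_days)


def make_grid_weather(
    city_hourly: pd.DataFrame,
    n_points: int = 4,
    seed: int = 0,
    noise_sd: float = 0.4,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Expand per-city weather into pseudo-grid-point weather.

    Emits ``n_points`` grid points per city whose values are the city series
    plus independent noise, together with the grid→city mapping table; used
    to exercise grid-to-city averaging.
    """
    rng = np.random.default_rng(seed)
    out, mapping = [], []
    for city_id, grp in city_hourly.groupby("city_id", sort=True):
        for k in range(n_points):
            gid = f"{city_id}_g{k}"
            mapping.append({"grid_id": gid, "city_id": city_id})
            g = grp.copy()
            g["grid_id"] = gid
            n = len(g)
            g["Ta"] = g["Ta"] + rng.normal(0, noise_sd, n)
            g["RH"] = (g["RH"] + rng.normal(0, 2.0, n)).clip(0, 100)
            g["WS"] = (g["WS"] + rng.normal(0, 0.2, n)).clip(lower=0)
            g["SR"] = np.where(g["SR"] > 0, (g["SR"] * rng.uniform(0.9, 1.1, n)), 0.0)
            out.append(g.drop(columns=["city_id"]))
    grid = pd.concat(out, ignore_index=True)[
        ["grid_id", "timestamp", "Ta", "RH", "precip", "WS", "SR"]
    ]
    return grid, pd.DataFrame(mapping)


# ---------------------------------------------------------------------------
# Counts
# ---------------------------------------------------------------------------

def simulate_heatstroke_counts(
    frames: pd.DataFrame,
    truth: SyntheticTruth,
    heatwave_days=None,
) -> pd.DataFrame:
    """Fill ``count_all`` and ``count_admission_death`` on a feature table.

    ``heatwave_days`` is an optional collection of dates; frames whose
    ``frame_date`` is in it receive the truth's additive ``spike_boost`` on
    the log scale (a ``heatwave`` column already present on ``frames`` is
    used the same way).  Counts are Poisson draws from the exponentiated
    linear predictor; the admission+death count is a binomial thinning.
    """
    frames = frames.copy()
    if heatwave_days is not None:
        days = {pd.Timestamp(d).date() for d in heatwave_days}
        frames["heatwave"] = [
            pd.Timestamp(d).date() in days for d in frames["frame_date"]
        ]
    eta = truth.linear_predictor(frames)
    mu = np.exp(eta)
    if not np.all(np.isfinite(mu)):
        raise InvalidArgumentError("non-finite expected counts; check truth coefficients")
    rng = np.random.default_rng(truth.seed)
    count_all = rng.poisson(mu)
    count_adm = rng.binomial(count_all, truth.admission_fraction)
    frames["count_all"] = count_all
    frames["count_admission_death"] = count_adm
    frames["true_mean"] = mu
    return frames


def expand_counts_to_events(frames: pd.DataFrame, seed: int = 0) -> pd.DataFrame:
    """Write one registry-style event row per simulated case.

    Each event gets a timestamp uniform within its frame's 12-hour window and
    a severity label consistent with the frame's admission+death count
    (admission+death cases split between moderate/severe/death; the rest
    mild).  Used to test the registry aggregator; the pipeline itself
    consumes frame-level counts.
    """
    rng = np.random.default_rng(seed)
    rows = []
    for rec in frames.itertuples(index=False):
        n_all = int(rec.count_all)
        if n_all == 0:
            continue
        n_adm = int(rec.count_admission_death)
        start_hour = 6 if rec.period == "day" else 18
        start = pd.Timestamp(rec.frame_date) + pd.Timedelta(hours=start_hour)
        offsets = rng.integers(0, 12 * 3600, n_all)
        severities = ["mild"] * (n_all - n_adm) + list(
            rng.choice(["moderate", "severe", "death"], size=n_adm, p=[0.75, 0.15, 0.10])
        )
        rng.shuffle(severities)
        for off, sev in zip(offsets, severities):
            rows.append(
                {
                    "city_id": rec.city_id,
                    "timestamp": start + pd.Timedelta(seconds=int(off)),
                    "severity": sev,
                }
            )
    return pd.DataFrame(rows, columns=["city_id", "timestamp", "severity"])


# ---------------------------------------------------------------------------
# Bundle writer
# ---------------------------------------------------------------------------

def write_bundle(
    outdir: str | Path,
    profiles: list[CityProfile],
    weather: WeatherSim,
    rainy: pd.DataFrame,
    holidays: pd.DataFrame,
    counts_frames: pd.DataFrame | None = None,
    truth: SyntheticTruth | None = None,
) -> dict:
    """Write the synthetic bundle as CSV files (+ JSON truth sidecar)."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {}
    profiles_frame(profiles).to_csv(outdir / "city_profiles.csv", index=False)
    paths["city_profiles"] = outdir / "city_profiles.csv"
    hourly = weather.hourly.copy()
    hourly["timestamp"] = hourly["timestamp"].dt.strftime("%Y-%m-%dT%H:%M:%S")
    hourly.to_csv(outdir / "weather_hourly.csv", index=False)
    paths["weather_hourly"] = outdir / "weather_hourly.csv"
    rainy.to_csv(outdir / "rainy_season.csv", index=False)
    paths["rainy_season"] = outdir / "rainy_season.csv"
    holidays.to_csv(outdir / "holidays.csv", index=False)
    paths["holidays"] = outdir / "holidays.csv"
    if counts_frames is not None:
        counts_frames.to_csv(outdir / "counts_frames.csv", index=False)
        paths["counts_frames"] = outdir / "counts_frames.csv"
    if truth is not None:
        (outdir / "truth.json").write_text(truth.to_json())
        paths["truth"] = outdir / "truth.json"
    pd.DataFrame(sorted(weather.heatwave_days), columns=["date"]).to_csv(
        outdir / "heatwave_days.csv", index=False
    )
    paths["heatwave_days"] = outdir / "heatwave_days.csv"
    return paths
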