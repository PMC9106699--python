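"""Synthetic daily weather / air-quality generator with known ground truth.

The generator emulates the statistical structure the matched-pair analysis
assumes for a mid-latitude city: an annual temperature cycle with AR(1)
day-to-day noise, a seasonally weighted circular mixture for wind direction
(one von Mises component centred in the North-East sector), gamma wind
speeds, bounded seasonal humidity, ordinal rainfall-duration categories, and
per-pollutant baselines driven by season, temperature and wind speed with
AR(1) persistence.  Each day carries both potential outcomes Y(0) and Y(1)
per pollutant; the observed concentration is Y(0) when winds blow from
elsewhere and Y(1) = Y(0) + τ when they blow from the North-East, so every
downstream stage can be checked against known effects.  An optional hidden
binary confounder multiplies the odds of a North-East draw by γ and shifts
both potential outcomes by δ.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field, replace
from typing import Mapping

import numpy as np
import pandas as pd
from scipy.signal import lfilter

from .datasets import NE_SECTOR, assign_treatment

_DAYS_PER_YEAR = 365.25

#: Fixed-date French public holidays (month, day).
FIXED_HOLIDAYS = ((1, 1), (5, 1), (5, 8), (7, 14), (8, 15), (11, 1), (11, 11), (12, 25))


def _seasonal(doy: np.ndarray, mean: float, amplitude: float, peak_day: float) -> np.ndarray:
    return mean + amplitude * np.cos(2.0 * np.pi * (doy - peak_day) / _DAYS_PER_YEAR)


def _ar1(innovations: np.ndarray, coef: float) -> np.ndarray:
    # x_t = coef * x_{t-1} + eps_t, x_0 started from the innovation alone
    return lfilter([1.0], [1.0, -coef], innovations)


@dataclass
class TemperatureModel:
    """Annual sinusoid plus AR(1) noise; °C."""
    mean: float = 12.5
    amplitude: float = 7.5
    peak_day: float = 200.0        # late July
    ar_coef: float = 0.7
    noise_sd: float = 2.4          # innovation sd


@dataclass
class WindDirectionModel:
    """Two-component von Mises mixture with a seasonally varying NE weight."""
    ne_center: float = 50.0        # degrees, middle of the 10°–90° sector
    ne_kappa: float = 6.0
    other_center: float = 235.0    # prevailing south-westerlies
    other_kappa: float = 1.2
    ne_weight_mean: float = 0.22
    ne_weight_amplitude: float = 0.08
    ne_weight_peak_day: float = 105.0   # NE flow most frequent in spring
    # continental NE flow is cooler and drier than the prevailing westerlies;
    # these shifts create the observed confounding that matching must remove
    ne_temperature_shift: float = -2.0  # °C on NE-component days
    ne_humidity_shift: float = -4.0     # percentage points on NE-component days


@dataclass
class WindSpeedModel:
    """Gamma-distributed daily mean wind speed; m/s."""
    shape: float = 4.0
    scale: float = 0.9


@dataclass
class HumidityModel:
    """Seasonal mean relative humidity with bounded Gaussian noise; %."""
    mean: float = 75.0
    amplitude: float = 9.0
    peak_day: float = 20.0         # winter maximum
    noise_sd: float = 8.0
    low: float = 25.0
    high: float = 100.0


@dataclass
class PollutantModel:
    """Linear baseline for one pollutant, µg/m³.

    Y(0) = intercept + seasonal cycle + temp_slope·T + wind_speed_slope·v
    + AR(1) noise; Y(1) = Y(0) + τ (optionally heterogeneous with sd
    ``tau_sd``).
    """
    intercept: float
    seasonal_amplitude: float
    seasonal_peak_day: float
    temp_slope: float
    wind_speed_slope: float
    ar_coef: float
    noise_sd: float
    tau: float = 0.0
    tau_sd: float = 0.0


@dataclass
class ConfounderModel:
    """Hidden binary confounder U: odds(NE draw) ×γ and outcomes +δ when U=1."""
    prevalence: float = 0.2
    gamma: float = 1.0
    delta: float = 0.0


def _default_pollutants() -> dict[str, PollutantModel]:
    # City-scale means near Paris background levels (NO2 ≈ 37, O3 ≈ 40,
    # PM10 ≈ 24, PM2.5 ≈ 14 µg/m³); winter peaks for combustion-related
    # pollutants, summer peak for ozone.
    return {
        "no2": PollutantModel(49.0, 6.0, 15.0, -0.40, -1.8, 0.40, 9.0, tau=0.0),
        "o3": PollutantModel(30.0, 10.0, 200.0, 0.60, 0.40, 0.30, 9.0, tau=0.0),
        "pm10": PollutantModel(33.0, 5.0, 15.0, -0.25, -1.5, 0.35, 8.0, tau=5.0),
        "pm25": PollutantModel(21.0, 4.0, 15.0, -0.20, -1.0, 0.35, 5.0, tau=2.5),
    }


@dataclass
class SyntheticConfig:
    """Full specification of one synthetic study."""
    n_days: int = 4018
    start: str = "2008-01-01"
    temperature: TemperatureModel = field(default_factory=TemperatureModel)
    wind_direction: WindDirectionModel = field(default_factory=WindDirectionModel)
    wind_speed: WindSpeedModel = field(default_factory=WindSpeedModel)
    humidity: HumidityModel = field(default_factory=HumidityModel)
    rainfall_probs: tuple = (0.40, 0.25, 0.20, 0.15)
    pollutants: dict = field(default_factory=_default_pollutants)
    sector: tuple = NE_SECTOR
    confounder: ConfounderModel = field(default_factory=ConfounderModel)

    def validate(self) -> None:
        if self.n_days < 30:
            raise ValueError("n_days must be at least 30")
        for name, sd in (("temperature.noise_sd", self.temperature.noise_sd),
                         ("humidity.noise_sd", self.humidity.noise_sd)):
            if sd < 0:
                raise ValueError(f"{name} must be >= 0")
        probs = np.asarray(self.rainfall_probs, dtype=float)
        if probs.size != 4 or np.any(probs < 0) or abs(probs.sum() - 1.0) > 1e-9:
            raise ValueError("rainfall_probs must be 4 nonnegative values summing to 1")
        wm = self.wind_direction
        wmin = wm.ne_weight_mean - wm.ne_weight_amplitude
        wmax = wm.ne_weight_mean + wm.ne_weight_amplitude
        if wmin < 0.0 or wmax > 1.0:
            raise ValueError("NE mixture weight must stay within [0, 1] over the year")
        for p, m in self.pollutants.items():
            if m.noise_sd < 0 or m.tau_sd < 0:
                raise ValueError(f"pollutant {p!r}: sd parameters must be >= 0")
        if self.confounder.gamma < 1.0:
            raise ValueError("confounder gamma must be >= 1")
        if not (0.0 <= self.confounder.prevalence <= 1.0):
            raise ValueError("confounder prevalence must lie in [0, 1]")


@dataclass
class SyntheticDataset:
    """Observed daily table plus the hidden truth behind it.

    ``observed`` is the analysis-facing table (never contains U or the
    counterfactual outcomes); ``truth`` holds Y(0), Y(1) and τ per pollutant
    and the confounder U, aligned row-by-row with ``observed``.
    """
    observed: pd.DataFrame
    truth: pd.DataFrame
    config: SyntheticConfig
    seed: int

    def true_tau_fs(self, pollutant: str, treated_rows) -> float:
        """Finite-sample average effect over the given treated row indices."""
        rows = np.asarray(treated_rows)
        y1 = self.truth.loc[rows, f"y1_{pollutant}"].to_numpy()
        y0 = self.truth.loc[rows, f"y0_{pollutant}"].to_numpy()
        return float(np.mean(y1 - y0))


def _streams(seed: int) -> dict[str, np.random.Generator]:
    names = ("temperature", "wind_component", "wind_angle_ne", "wind_angle_other",
             "wind_speed", "humidity", "rainfall", "confounder",
             "no2", "o3", "pm10", "pm25", "missing", "extra")
    children = np.random.SeedSequence(seed).spawn(len(names))
    return {n: np.random.default_rng(c) for n, c in zip(names, children)}


def _calendar(dates: pd.DatetimeIndex) -> pd.DataFrame:
    holiday = np.array([(d.month, d.day) in FIXED_HOLIDAYS for d in dates], dtype=int)
    weekend = (dates.dayofweek >= 5).astype(int)
    # bridge days: a working Monday/Friday adjacent to a public holiday
    prev_h = np.roll(holiday, 1); prev_h[0] = 0
    next_h = np.roll(holiday, -1); next_h[-1] = 0
    dow = dates.dayofweek
    bank = (((dow == 0) & (next_h == 1)) | ((dow == 4) & (prev_h == 1))) & (holiday == 0)
    return pd.DataFrame({"weekend": weekend, "holiday": holiday,
                         "bank_day": bank.astype(int)})


def generate_dataset(config: SyntheticConfig | None = None, seed: int = 0) -> SyntheticDataset:
    """Draw one synthetic study; reproducible given ``seed``.

    The treatment indicator is derived from the simulated wind direction via
    :func:`windmatch.datasets.assign_treatment`, never drawn directly, so the
    observed table obeys the same treatment-consistency invariant as real
    ingested data.
    """
    config = config or SyntheticConfig()
    config.validate()
    rng = _streams(seed)
    n = config.n_days
    dates = pd.date_range(config.start, periods=n, freq="D")
    doy = dates.dayofyear.to_numpy(dtype=float)

    tm = config.temperature
    temp = _seasonal(doy, tm.mean, tm.amplitude, tm.peak_day) + _ar1(
        rng["temperature"].normal(0.0, tm.noise_sd, n), tm.ar_coef)

    conf = config.confounder
    u = rng["confounder"].binomial(1, conf.prevalence, n)

    wm = config.wind_direction
    w_ne = np.clip(_seasonal(doy, wm.ne_weight_mean, wm.ne_weight_amplitude,
                             wm.ne_weight_peak_day), 0.01, 0.99)
    if conf.gamma != 1.0:
        odds = w_ne / (1.0 - w_ne)
        odds_u = odds * conf.gamma
        w_ne = np.where(u == 1, odds_u / (1.0 + odds_u), w_ne)
    is_ne = rng["wind_component"].random(n) < w_ne
    ang_ne = rng["wind_angle_ne"].vonmises(np.radians(wm.ne_center - 180.0),
                                           wm.ne_kappa, n)
    ang_other = rng["wind_angle_other"].vonmises(np.radians(wm.other_center - 180.0),
                                                 wm.other_kappa, n)
    wind_dir = (np.degrees(np.where(is_ne, ang_ne, ang_other)) + 180.0) % 360.0

    temp = temp + wm.ne_temperature_shift * is_ne

    ws = config.wind_speed
    wind_speed = rng["wind_speed"].gamma(ws.shape, ws.scale, n)

    hm = config.humidity
    humidity = np.clip(_seasonal(doy, hm.mean, hm.amplitude, hm.peak_day)
                       + wm.ne_humidity_shift * is_ne
                       + rng["humidity"].normal(0.0, hm.noise_sd, n), hm.low, hm.high)

    rain = rng["rainfall"].choice(np.array([1, 2, 3, 4]), size=n,
                                  p=np.asarray(config.rainfall_probs, dtype=float))

    w = assign_treatment(wind_dir, config.sector)

    cal = _calendar(dates)
    obs = pd.DataFrame({
        "date": dates, "w": w,
        "temperature": temp, "wind_speed": wind_speed,
        "wind_direction": wind_dir, "humidity": humidity,
        "rainfall_cat": rain.astype(int),
        "weekend": cal["weekend"].to_numpy(),
        "holiday": cal["holiday"].to_numpy(),
        "bank_day": cal["bank_day"].to_numpy(),
        "julian": np.arange(n, dtype=int),
        "month": dates.month, "year": dates.year,
    })

    truth = pd.DataFrame({"date": dates, "u": u})
    for name, pm in config.pollutants.items():
        eta = (pm.intercept + _seasonal(doy, 0.0, pm.seasonal_amplitude, pm.seasonal_peak_day)
               + pm.temp_slope * temp + pm.wind_speed_slope * wind_speed)
        noise = _ar1(rng[name].normal(0.0, pm.noise_sd, n), pm.ar_coef)
        y0 = eta + noise + conf.delta * u
        tau_i = np.full(n, pm.tau)
        if pm.tau_sd > 0:
            tau_i = tau_i + rng[name].normal(0.0, pm.tau_sd, n)
        y1 = y0 + tau_i
        obs[name] = np.where(w == 1, y1, y0)
        truth[f"y0_{name}"] = y0
        truth[f"y1_{name}"] = y1
        truth[f"tau_{name}"] = tau_i
    return SyntheticDataset(obs, truth, config, seed)


def inject_missingness(sds: SyntheticDataset, rates: Mapping[str, float],
                       seed: int = 0, mechanism: str = "mcar",
                       mar_slope: float = 0.8) -> SyntheticDataset:
    """Blank out observed pollutant/weather cells at the given per-variable rates.

    ``mechanism="mcar"`` masks completely at random; ``"mar_temperature"``
    makes the masking probability increase with the day's temperature
    (log-linear with slope ``mar_slope`` per standardised °C, rescaled to
    keep the marginal rate), for imputation stress tests.  The hidden truth
    table is untouched.
    """
    for var, rate in rates.items():
        if not (0.0 <= rate < 1.0):
            raise ValueError(f"rate for {var!r} must lie in [0, 1)")
    rng = np.random.default_rng(np.random.SeedSequence([seed, 909]))
    obs = sds.observed.copy()
    temp = obs["temperature"].to_numpy(dtype=float)
    z = (temp - temp.mean()) / max(temp.std(), 1e-12)
    for var, rate in rates.items():
        if rate == 0.0 or var not in obs.columns:
            continue
        n = len(obs)
        if mechanism == "mcar":
            p = np.full(n, rate)
        elif mechanism == "mar_temperature":
            wgt = np.exp(mar_slope * z)
            p = np.clip(rate * wgt / wgt.mean(), 0.0, 0.95)
        else:
            raise ValueError(f"unknown mechanism {mechanism!r}")
        mask = rng.random(n) < p
        obs.loc[mask, var] = np.nan
    return SyntheticDataset(obs, sds.truth, sds.config, sds.seed)


def generate_confounded_dataset(config: SyntheticConfig | None = None,
                                gamma_true: float = 2.0, delta: float = 0.0,
                                seed: int = 0) -> SyntheticDataset:
    """Generate a study with a hidden confounder of known strength.

    ``gamma_true`` multiplies each U=1 day's odds of a North-East mixture
    draw; ``delta`` shifts both potential outcomes of U=1 days.  With
    ``gamma_true=1`` and ``delta=0`` this reproduces
    :func:`generate_dataset` draw-for-draw.
    """
    if gamma_true < 1.0:
        raise ValueError("gamma_true must be >= 1")
    config = config or SyntheticConfig()
    conf = replace(config.confounder, gamma=gamma_true, delta=delta)
    return generate_dataset(dataclasses.replace(config, confounder=conf), seed)
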