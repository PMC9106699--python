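"""Daily air-quality data model.

One row per calendar day: pollutant concentrations (µg/m³), weather, calendar
indicators, and the North-East-wind treatment indicator ``w``.  The in-memory
container is a plain :class:`pandas.DataFrame` with a fixed column vocabulary;
helpers here handle CSV ingestion and validation, hourly→daily aggregation,
treatment assignment from wind direction, calendar-aware lag/lead columns, and
chained imputation of missing cells.
"""

from __future__ import annotations

import logging
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.base import clone
from sklearn.experimental import enable_iterative_imputer  # noqa: F401
from sklearn.impute import IterativeImputer
from sklearn.ensemble import RandomForestRegressor
from sklearn.linear_model import BayesianRidge, LinearRegression

logger = logging.getLogger(__name__)

#: Pollutants measured in µg/m³.
POLLUTANTS = ("no2", "o3", "pm10", "pm25")

#: Continuous weather covariates.
WEATHER_VARS = ("temperature", "wind_speed", "wind_direction", "humidity")

#: Binary calendar indicators.
CALENDAR_VARS = ("weekend", "holiday", "bank_day")

#: North-East sector of the wind rose, degrees, closed at both ends.
NE_SECTOR = (10.0, 90.0)

#: Columns that must be present in an ingested daily table.
REQUIRED_COLUMNS = ("date", "temperature", "wind_speed", "wind_direction", "humidity")

_IMPUTABLE = POLLUTANTS + ("temperature", "wind_speed", "wind_direction", "humidity", "rainfall_cat")


# ---------------------------------------------------------------------------
# treatment assignment
# ---------------------------------------------------------------------------

def assign_treatment(wind_direction, sector: tuple[float, float] = NE_SECTOR):
    """Treatment indicator: 1 iff the wind blows from the given sector.

    Parameters
    ----------
    wind_direction : scalar or array-like
        Direction the wind blows *from*, degrees on a 360° rose, 0° = North.
    sector : (low, high)
        Angular interval in degrees, endpoints included.  If ``low > high``
        the sector wraps through North.

    Missing directions propagate as NaN.
    """
    scalar = np.isscalar(wind_direction)
    wd = np.atleast_1d(np.asarray(wind_direction, dtype=float))
    valid = ~np.isnan(wd)
    if np.any((wd[valid] < 0.0) | (wd[valid] >= 360.0)):
        bad = wd[valid][(wd[valid] < 0.0) | (wd[valid] >= 360.0)]
        raise ValueError(f"wind direction must lie in [0, 360); got {bad[:5]}")
    lo, hi = float(sector[0]), float(sector[1])
    if lo <= hi:
        inside = (wd >= lo) & (wd <= hi)
    else:  # sector wrapping through 0°/360°
        inside = (wd >= lo) | (wd <= hi)
    if scalar:
        if not valid[0]:
            return float("nan")
        return int(inside[0])
    if valid.all():
        return inside.astype(int)
    return np.where(valid, inside.astype(float), np.nan)


# ---------------------------------------------------------------------------
# hourly -> daily aggregation
# ---------------------------------------------------------------------------

def aggregate_hourly_to_daily(hourly_values, trim_frac: float = 0.025,
                              max_missing: int = 3) -> float:
    """Trimmed-mean daily concentration from (possibly pooled) hourly readings.

    Missing readings are NaN.  If more than ``max_missing`` readings are
    missing the day is set to missing.  Otherwise the non-missing values are
    sorted and ``floor(n * trim_frac)`` values are dropped from *each* tail
    before averaging; with 24 hourly values and the 2.5% default nothing is
    trimmed, so trimming only bites when several stations' hours are pooled.
    """
    v = np.asarray(hourly_values, dtype=float)
    if v.size == 0:
        raise ValueError("hourly_values must be nonempty")
    if not (0.0 <= trim_frac < 0.5):
        raise ValueError("trim_frac must lie in [0, 0.5)")
    obs = v[~np.isnan(v)]
    n_missing = v.size - obs.size
    if n_missing > max_missing or obs.size == 0:
        return float("nan")
    k = int(np.floor(obs.size * trim_frac))
    obs = np.sort(obs)
    core = obs[k: obs.size - k] if k > 0 else obs
    return float(core.mean())


# ---------------------------------------------------------------------------
# lag / lead construction
# ---------------------------------------------------------------------------

def lag_name(var: str, offset: int) -> str:
    """Column name for ``var`` at a day offset: ``pm10_lag1``, ``pm10_lead1``."""
    if offset == 0:
        return var
    return f"{var}_lag{-offset}" if offset < 0 else f"{var}_lead{offset}"


def parse_lag_name(name: str):
    """Inverse of :func:`lag_name`; returns ``(base, offset)`` or ``None``."""
    for token, sign in (("_lag", -1), ("_lead", +1)):
        if token in name:
            base, _, tail = name.rpartition(token)
            if base and tail.isdigit():
                return base, sign * int(tail)
    return None


def add_lags_and_leads(df: pd.DataFrame, variables: Sequence[str],
                       offsets: Sequence[int]) -> pd.DataFrame:
    """Add calendar-aware lag/lead columns.

    A lag refers to the true previous calendar day: across a gap in the date
    index the lag is missing, never the prior row's value.  Boundary days get
    NaN for unavailable offsets.
    """
    unknown = [v for v in variables if v not in df.columns]
    if unknown:
        raise ValueError(f"unknown variables: {unknown}")
    out = df.copy()
    idx = pd.DatetimeIndex(pd.to_datetime(out["date"]))
    full = pd.date_range(idx.min(), idx.max(), freq="D")
    for var in variables:
        s = pd.Series(out[var].to_numpy(dtype=float), index=idx).reindex(full)
        for off in offsets:
            off = int(off)
            if off == 0:
                continue
            out[lag_name(var, off)] = s.shift(-off).reindex(idx).to_numpy()
    return out


# ---------------------------------------------------------------------------
# ingestion / validation
# ---------------------------------------------------------------------------

def rainfall_categories(duration, cutpoints=None) -> np.ndarray:
    """Map rainfall duration (minutes/day) to ordinal categories 1–4.

    Default cutpoints are the 25/50/75% quantiles of the observed durations,
    so the categories are data-driven quartile bins; pass explicit cutpoints
    to override.
    """
    d = np.asarray(duration, dtype=float)
    if cutpoints is None:
        cutpoints = np.nanquantile(d, [0.25, 0.5, 0.75])
    cutpoints = np.asarray(cutpoints, dtype=float)
    cat = np.searchsorted(cutpoints, d, side="right") + 1.0
    cat[np.isnan(d)] = np.nan
    return cat


def _check_ranges(df: pd.DataFrame) -> None:
    dates = pd.to_datetime(df["date"])
    for col, lo, hi, closed_hi in (("wind_direction", 0.0, 360.0, False),
                                   ("humidity", 0.0, 100.0, True)):
        if col not in df.columns:
            continue
        v = df[col].to_numpy(dtype=float)
        bad = (v < lo) | ((v > hi) if closed_hi else (v >= hi))
        bad &= ~np.isnan(v)
        if bad.any():
            i = int(np.flatnonzero(bad)[0])
            raise ValueError(
                f"row {i} (date {dates.iloc[i].date()}): {col}={v[i]} outside "
                f"[{lo}, {hi}{']' if closed_hi else ')'}")
    if "rainfall_cat" in df.columns:
        v = df["rainfall_cat"].to_numpy(dtype=float)
        bad = ~np.isin(v, (1.0, 2.0, 3.0, 4.0)) & ~np.isnan(v)
        if bad.any():
            i = int(np.flatnonzero(bad)[0])
            raise ValueError(f"row {i}: rainfall_cat={v[i]} not in {{1,2,3,4}}")


def validate_dataset(df: pd.DataFrame, sector: tuple[float, float] = NE_SECTOR) -> None:
    """Raise ``ValueError`` on any violated daily-table invariant."""
    dates = pd.to_datetime(df["date"])
    if dates.duplicated().any():
        dup = dates[dates.duplicated()].dt.date.tolist()
        raise ValueError(f"duplicate dates: {dup[:5]}")
    if not dates.is_monotonic_increasing:
        raise ValueError("dates must be strictly increasing")
    _check_ranges(df)
    if "w" in df.columns and "wind_direction" in df.columns:
        wd = df["wind_direction"].to_numpy(dtype=float)
        ok = np.isnan(wd)
        expect = assign_treatment(np.where(ok, 0.0, wd), sector)
        mism = (~ok) & (df["w"].to_numpy(dtype=float) != np.asarray(expect, dtype=float))
        if mism.any():
            i = int(np.flatnonzero(mism)[0])
            raise ValueError(f"row {i}: w inconsistent with wind_direction under sector {sector}")


def read_daily_dataset(path, schema: Mapping[str, str] | None = None,
                       sector: tuple[float, float] = NE_SECTOR) -> pd.DataFrame:
    """Read a one-row-per-day CSV into the validated daily table.

    ``schema`` maps raw CSV column names to the canonical names used here
    (``date, no2, o3, pm10, pm25, temperature, wind_speed, wind_direction,
    humidity, rainfall_cat, weekend, holiday, bank_day``).  Derived fields
    (``julian``, ``weekend``, ``month``, ``year``, and the treatment ``w``)
    are computed when absent.  Missing cells (empty or "NA") stay missing.
    """
    df = pd.read_csv(path, na_values=["NA"], float_precision="round_trip")
    if schema:
        df = df.rename(columns=dict(schema))
    missing_cols = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing_cols:
        raise ValueError(f"missing required columns: {missing_cols}")
    df["date"] = pd.to_datetime(df["date"])
    if df["date"].duplicated().any():
        dup = df.loc[df["date"].duplicated(), "date"].dt.date.tolist()
        raise ValueError(f"duplicate dates: {dup[:5]}")
    df = df.sort_values("date").reset_index(drop=True)
    _check_ranges(df)
    if "julian" not in df.columns:
        df["julian"] = (df["date"] - df["date"].iloc[0]).dt.days
    if "weekend" not in df.columns:
        df["weekend"] = (df["date"].dt.dayofweek >= 5).astype(int)
    df["month"] = df["date"].dt.month
    df["year"] = df["date"].dt.year
    for col in ("holiday", "bank_day"):
        if col not in df.columns:
            df[col] = 0
    if "w" not in df.columns:
        df["w"] = assign_treatment(df["wind_direction"].to_numpy(), sector)
    validate_dataset(df, sector)
    return df


def write_daily_dataset(df: pd.DataFrame, path) -> None:
    """Write the daily table back to CSV (dates as YYYY-MM-DD, NaN empty)."""
    df.to_csv(path, index=False, date_format="%Y-%m-%d")


# ---------------------------------------------------------------------------
# chained imputation
# ---------------------------------------------------------------------------

def _make_learner(spec, seed: int):
    if isinstance(spec, str):
        if spec == "forest":
            return RandomForestRegressor(n_estimators=30, min_samples_leaf=5,
                                         random_state=seed, n_jobs=1)
        if spec == "linear":
            return LinearRegression()
        if spec == "ridge":
            return BayesianRidge()
        raise ValueError(f"unknown learner spec {spec!r}")
    return clone(spec)


def impute_missing(df: pd.DataFrame, exclude: Iterable[str] = ("pm25",),
                   learner="forest", max_iter: int = 10, seed: int = 0,
                   tol: float = 1e-3) -> pd.DataFrame:
    """Chained (iterative) imputation of missing cells.

    Missing cells are initialised at column medians, then each incomplete
    variable is cycled over, fitting ``learner`` on observed rows and
    predicting the missing ones, until ``max_iter`` rounds or the mean
    absolute change of imputed cells falls below ``tol``.  Variables in
    ``exclude`` are left untouched and are not used as predictors (they may
    themselves be heavily missing).  Boolean ``imputed_<var>`` columns flag
    exactly the filled cells.  Deterministic given ``seed``.
    """
    exclude = set(exclude)
    targets = [c for c in _IMPUTABLE if c in df.columns and c not in exclude]
    for c in targets:
        if df[c].notna().sum() == 0:
            raise ValueError(f"variable {c!r} has zero observed values")
    predictors = [c for c in ("julian", "month", "weekend") if c in df.columns]
    cols = targets + predictors
    out = df.copy()
    was_missing = df[targets].isna()
    if was_missing.to_numpy().any():
        imputer = IterativeImputer(
            estimator=_make_learner(learner, seed),
            max_iter=max_iter, tol=tol, initial_strategy="median",
            random_state=seed, sample_posterior=False,
        )
        filled = imputer.fit_transform(df[cols].to_numpy(dtype=float))
        for j, c in enumerate(targets):
            out[c] = filled[:, j]
        if "rainfall_cat" in targets:
            out["rainfall_cat"] = np.clip(np.round(out["rainfall_cat"]), 1, 4)
        if "humidity" in targets:
            out["humidity"] = np.clip(out["humidity"], 0.0, 100.0)
        if "wind_direction" in targets:
            out["wind_direction"] = np.clip(out["wind_direction"], 0.0, 359.999)
    for c in targets + sorted(exclude & set(df.columns)):
        out[f"imputed_{c}"] = was_missing[c].to_numpy() if c in targets else False
    # treatment follows the (possibly imputed) wind direction
    if "w" in out.columns and "wind_direction" in out.columns:
        nan_w = out["w"].isna()
        if nan_w.any():
            out.loc[nan_w, "w"] = assign_treatment(
                out.loc[nan_w, "wind_direction"].to_numpy())
    return out


def evaluate_imputation(df: pd.DataFrame, mask_fraction: float, learner="forest",
                        seed: int = 0, variables: Sequence[str] | None = None,
                        exclude: Iterable[str] = ("pm25",),
                        max_iter: int = 10) -> pd.DataFrame:
    """Mask-and-impute benchmark of the chained imputer.

    For each target variable, ``mask_fraction`` of its *observed* cells are
    hidden at random, the dataset is re-imputed, and the mean absolute error
    between held-out and imputed values is reported next to the variable's
    observed mean.  Reproducible per seed.
    """
    if not (0.0 < mask_fraction < 1.0):
        raise ValueError("mask_fraction must lie in (0, 1)")
    exclude = set(exclude)
    if variables is None:
        variables = [c for c in _IMPUTABLE if c in df.columns and c not in exclude
                     and df[c].notna().any()]
    rng = np.random.default_rng(seed)
    work = df.copy()
    held: dict[str, pd.Series] = {}
    for var in variables:
        obs_idx = work.index[work[var].notna()].to_numpy()
        n_mask = max(1, int(round(mask_fraction * obs_idx.size)))
        chosen = rng.choice(obs_idx, size=n_mask, replace=False)
        held[var] = df.loc[chosen, var].copy()
        work.loc[chosen, var] = np.nan
    imputed = impute_missing(work, exclude=exclude, learner=learner,
                             max_iter=max_iter, seed=seed)
    rows = []
    for var in variables:
        truth = held[var]
        pred = imputed.loc[truth.index, var]
        rows.append({
            "variable": var,
            "n_masked": int(truth.size),
            "mae": float(np.abs(pred.to_numpy() - truth.to_numpy()).mean()),
            "observed_mean": float(df[var].mean()),
        })
    return pd.DataFrame(rows)
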