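"""Covariate balance diagnostics before vs after matching.

Continuous covariates are summarized by absolute standardized mean
differences (SMD), categorical ones by absolute percentage-point differences
in level shares.  The SMD denominator is the pooled pre-match standard
deviation, held fixed across stages so before/after values are directly
comparable; 0.1 is the conventional imbalance threshold.
"""

from __future__ import annotations

import warnings
from typing import Sequence

import numpy as np
import pandas as pd

from .matching import MatchedPairSet

#: Conventional SMD threshold above which a covariate is flagged imbalanced.
SMD_THRESHOLD = 0.1

DEFAULT_CONTINUOUS = ("temperature", "wind_speed", "humidity")
DEFAULT_CATEGORICAL = ("weekend", "holiday", "bank_day", "rainfall_cat")


def std_mean_diff(values_t, values_c, sd_ref: float) -> float:
    """Absolute standardized mean difference |mean_t − mean_c| / sd_ref."""
    t = np.asarray(values_t, dtype=float)
    c = np.asarray(values_c, dtype=float)
    if t.size == 0 or c.size == 0:
        raise ValueError("both samples must be nonempty")
    if not sd_ref > 0:
        raise ValueError("sd_ref must be > 0")
    return float(abs(np.nanmean(t) - np.nanmean(c)) / sd_ref)


def categorical_diff(values_t, values_c) -> pd.Series:
    """Per-level absolute share differences, in percentage points.

    Levels absent from one group count at share 0.  The mean over levels is
    available as ``result.mean()``.
    """
    t = pd.Series(values_t).dropna()
    c = pd.Series(values_c).dropna()
    if t.empty or c.empty:
        raise ValueError("both samples must be nonempty")
    levels = sorted(set(t.unique()) | set(c.unique()))
    share_t = t.value_counts(normalize=True).reindex(levels, fill_value=0.0)
    share_c = c.value_counts(normalize=True).reindex(levels, fill_value=0.0)
    return (share_t - share_c).abs() * 100.0


def _pooled_sd(values_t, values_c) -> float:
    """Classic pooled SD of the two pre-match groups, sqrt((s_t² + s_c²)/2)."""
    vt = np.var(np.asarray(values_t, dtype=float), ddof=1)
    vc = np.var(np.asarray(values_c, dtype=float), ddof=1)
    return float(np.sqrt((vt + vc) / 2.0))


def balance_table(df: pd.DataFrame, pairs: MatchedPairSet | None,
                  continuous: Sequence[str] = DEFAULT_CONTINUOUS,
                  categorical: Sequence[str] = DEFAULT_CATEGORICAL,
                  by_month: bool = False) -> pd.DataFrame:
    """Tidy balance table before vs after matching.

    "before" compares all treated days to all control days; "after" compares
    the matched treated to the matched controls.  ``by_month`` adds monthly
    strata of the *before* comparison (the view that motivates matching in
    the first place); the matched comparison is never stratified.
    """
    for cov in list(continuous) + list(categorical):
        if cov not in df.columns:
            raise ValueError(f"covariate {cov!r} not in dataset")
    w = df["w"].to_numpy(dtype=float)
    t_all = df[w == 1.0]
    c_all = df[w == 0.0]
    rows: list[dict] = []

    def add_continuous(stage, t_df, c_df, month=np.nan):
        for cov in continuous:
            sd_ref = _pooled_sd(t_all[cov].dropna(), c_all[cov].dropna())
            stat = std_mean_diff(t_df[cov].dropna(), c_df[cov].dropna(), sd_ref)
            rows.append({"covariate": cov, "type": "continuous", "stage": stage,
                         "level": np.nan, "month": month, "statistic": stat,
                         "flag_imbalanced": stat > SMD_THRESHOLD})

    def add_categorical(stage, t_df, c_df, month=np.nan):
        for cov in categorical:
            diffs = categorical_diff(t_df[cov], c_df[cov])
            for level, pp in diffs.items():
                rows.append({"covariate": cov, "type": "categorical", "stage": stage,
                             "level": level, "month": month, "statistic": float(pp),
                             "flag_imbalanced": np.nan})

    add_continuous("before", t_all, c_all)
    add_categorical("before", t_all, c_all)
    if by_month:
        for m in range(1, 13):
            t_m = t_all[t_all["month"] == m]
            c_m = c_all[c_all["month"] == m]
            if t_m.empty or c_m.empty:
                continue
            add_continuous("before", t_m, c_m, month=m)
    if pairs is not None and pairs.j > 0:
        t_m = df.loc[pairs.pairs["treated_index"]]
        c_m = df.loc[pairs.pairs["control_index"]]
        add_continuous("after", t_m, c_m)
        add_categorical("after", t_m, c_m)
    elif pairs is not None:
        warnings.warn("empty matched set: 'after' balance rows omitted")
    return pd.DataFrame(rows)


def balance_summary(table: pd.DataFrame) -> pd.DataFrame:
    """Stage-level means: mean continuous SMD and mean categorical pp difference."""
    whole = table[table["month"].isna()] if "month" in table.columns else table
    out = (whole.groupby(["stage", "type"])["statistic"].mean()
                .rename("mean_statistic").reset_index())
    return out
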