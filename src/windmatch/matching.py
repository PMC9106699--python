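"""Constrained pair matching without replacement.

Builds the hypothetical pairwise randomized experiment: each treated day
(North-East wind) is paired to a distinct control day that is admissible
under exact-match variables, covariate calipers and the date-gap rules, such
that the number of pairs is maximal and, among maximum matchings, the total
normalized covariate distance is minimal.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd
from scipy.optimize import linear_sum_assignment

from .datasets import add_lags_and_leads, parse_lag_name

logger = logging.getLogger(__name__)

#: Slack for closed caliper comparisons on floats.
_EPS = 1e-9


def _default_calipers() -> dict[str, float]:
    return {"temperature": 5.0, "wind_speed": 0.5, "humidity": 12.0, "pm10_lag1": 8.0}


@dataclass(frozen=True)
class MatchingConstraints:
    """Admissibility rules for a treated–control pair of days.

    ``min_date_gap`` encodes the no-interference (SUTVA) filter: pairs closer
    than 4 calendar days are excluded so that one day's wind regime cannot
    spill over into its counterpart.  ``max_date_gap`` keeps pairs within the
    same season.  ``exact_vars`` must be equal in the pair; ``calipers`` give
    the maximum absolute difference per continuous covariate (closed, ≤).
    Lagged variables use the ``<var>_lag1`` naming convention.
    """
    min_date_gap: int = 4
    max_date_gap: int = 60
    exact_vars: tuple[str, ...] = ("weekend", "holiday", "bank_day",
                                   "rainfall_cat", "w_lag1")
    calipers: Mapping[str, float] = field(default_factory=_default_calipers)
    lag_w_both_zero: bool = False   # stricter option: both units untreated the day before

    def __post_init__(self):
        if self.min_date_gap > self.max_date_gap:
            raise ValueError("min_date_gap must be <= max_date_gap")
        for var, width in self.calipers.items():
            if not width > 0:
                raise ValueError(f"caliper for {var!r} must be > 0")

    def needed_vars(self) -> tuple[str, ...]:
        return tuple(self.exact_vars) + tuple(self.calipers)


@dataclass
class MatchedPairSet:
    """Disjoint treated–control pairs with their distances.

    ``pairs`` columns: treated_index, control_index (row labels of the source
    table), treated_date, control_date, distance.
    """
    pairs: pd.DataFrame
    n_treated: int
    n_control: int
    n_treated_usable: int = 0
    n_control_usable: int = 0

    @property
    def j(self) -> int:
        return len(self.pairs)

    @property
    def matched_fraction(self) -> float:
        return self.j / self.n_treated if self.n_treated else 0.0

    @property
    def total_distance(self) -> float:
        return float(self.pairs["distance"].sum()) if self.j else 0.0

    def validate(self, df: pd.DataFrame, constraints: "MatchingConstraints") -> None:
        """Independently re-check every pair; raise on any violation."""
        used = pd.concat([self.pairs["treated_index"], self.pairs["control_index"]])
        if used.duplicated().any():
            raise AssertionError("pairs are not disjoint")
        for _, row in self.pairs.iterrows():
            t = df.loc[row["treated_index"]]
            c = df.loc[row["control_index"]]
            if not admissible(t, c, constraints):
                raise AssertionError(
                    f"inadmissible pair {row['treated_date']} / {row['control_date']}")

    def to_csv(self, path) -> None:
        self.pairs.to_csv(path, index=False, date_format="%Y-%m-%d")


def _date_gap_days(treated, control) -> int:
    return abs(int((pd.Timestamp(treated["date"]) - pd.Timestamp(control["date"])).days))


def admissible(treated, control, constraints: MatchingConstraints | None = None) -> bool:
    """True iff the (treated, control) rows may form a pair.

    A missing covariate needed by any constraint makes the pair inadmissible
    (logged), it is not an error.
    """
    constraints = constraints or MatchingConstraints()
    if int(treated["w"]) != 1 or int(control["w"]) != 0:
        raise ValueError("admissible() expects a treated (w=1) and a control (w=0) row")
    gap = _date_gap_days(treated, control)
    if not (constraints.min_date_gap <= gap <= constraints.max_date_gap):
        return False
    for var in constraints.exact_vars:
        a, b = treated[var], control[var]
        if pd.isna(a) or pd.isna(b):
            logger.debug("pair inadmissible: %s missing", var)
            return False
        if float(a) != float(b):
            return False
        if var == "w_lag1" and constraints.lag_w_both_zero and float(a) != 0.0:
            return False
    for var, width in constraints.calipers.items():
        a, b = treated[var], control[var]
        if pd.isna(a) or pd.isna(b):
            logger.debug("pair inadmissible: %s missing", var)
            return False
        if abs(float(a) - float(b)) > width + _EPS:
            return False
    return True


def pair_distance(treated, control, constraints: MatchingConstraints | None = None) -> float:
    """Normalized L1 distance between the two days of an admissible pair.

    Sum over caliper covariates of |difference| / caliper width, plus the
    date gap / max_date_gap; 0 iff all continuous covariates and the dates
    coincide.
    """
    constraints = constraints or MatchingConstraints()
    if not admissible(treated, control, constraints):
        raise ValueError("pair is not admissible")
    dist = _date_gap_days(treated, control) / constraints.max_date_gap
    for var, width in constraints.calipers.items():
        dist += abs(float(treated[var]) - float(control[var])) / width
    return float(dist)


def admissibility_matrices(df: pd.DataFrame,
                           constraints: MatchingConstraints):
    """Vectorized admissibility mask and distance matrix.

    Returns ``(treated_rows, control_rows, ok, dist)`` where ``treated_rows``
    / ``control_rows`` are the original row labels with all constraint
    covariates observed, ``ok[i, j]`` says whether the pair is admissible and
    ``dist`` holds the normalized L1 distance (valid where ``ok``).
    """
    needed = list(constraints.needed_vars())
    missing_cols = [v for v in needed if v not in df.columns]
    if missing_cols:
        raise ValueError(f"dataset lacks constraint columns: {missing_cols}")
    complete = df[needed].notna().all(axis=1)
    w = df["w"].to_numpy(dtype=float)
    t_mask = (w == 1.0) & complete.to_numpy()
    c_mask = (w == 0.0) & complete.to_numpy()
    treated_rows = df.index[t_mask].to_numpy()
    control_rows = df.index[c_mask].to_numpy()
    dt = pd.to_datetime(df.loc[treated_rows, "date"]).astype("int64").to_numpy() // 86_400_000_000_000
    dc = pd.to_datetime(df.loc[control_rows, "date"]).astype("int64").to_numpy() // 86_400_000_000_000
    gap = np.abs(dt[:, None] - dc[None, :])
    ok = (gap >= constraints.min_date_gap) & (gap <= constraints.max_date_gap)
    for var in constraints.exact_vars:
        vt = df.loc[treated_rows, var].to_numpy(dtype=float)
        vc = df.loc[control_rows, var].to_numpy(dtype=float)
        ok &= vt[:, None] == vc[None, :]
        if var == "w_lag1" and constraints.lag_w_both_zero:
            ok &= vt[:, None] == 0.0
    dist = gap / float(constraints.max_date_gap)
    for var, width in constraints.calipers.items():
        vt = df.loc[treated_rows, var].to_numpy(dtype=float)
        vc = df.loc[control_rows, var].to_numpy(dtype=float)
        diff = np.abs(vt[:, None] - vc[None, :])
        ok &= diff <= width + _EPS
        dist = dist + diff / width
    return treated_rows, control_rows, ok, dist


def _solve_assignment(ok: np.ndarray, dist: np.ndarray):
    """Max-cardinality, then min-total-distance bipartite matching.

    Solved as one rectangular assignment problem: each treated row may take a
    real admissible edge (cost = distance) or a private dummy column whose
    big-M cost exceeds any possible total distance, so the solver first
    maximizes the number of real edges and only then minimizes distance.
    Returns (row_positions, col_positions) of the chosen real edges.
    """
    n_t, n_c = ok.shape
    if n_t == 0 or n_c == 0 or not ok.any():
        return np.array([], dtype=int), np.array([], dtype=int)
    rows = np.flatnonzero(ok.any(axis=1))
    cols = np.flatnonzero(ok.any(axis=0))
    oks = ok[np.ix_(rows, cols)]
    dists = dist[np.ix_(rows, cols)]
    finite = dists[oks]
    big_m = float(finite.sum() + finite.max() + 1.0)
    t, c = oks.shape
    cost = np.full((t, c + t), big_m)
    real = np.where(oks, dists, 3.0 * big_m)
    cost[:, :c] = real
    ri, ci = linear_sum_assignment(cost)
    keep = (ci < c) & oks[ri, np.minimum(ci, c - 1)]
    return rows[ri[keep]], cols[ci[keep]]


def match_pairs(df: pd.DataFrame, constraints: MatchingConstraints | None = None,
                auto_lags: bool = True) -> MatchedPairSet:
    """Constrained optimal pair matching without replacement.

    Among all admissible treated–control edges, returns a matching of
    maximum cardinality; among maximum-cardinality matchings, total distance
    is minimal.  Deterministic: rows are processed in date order and the
    assignment solve is deterministic.  Lag columns referenced by the
    constraints (``w_lag1``, ``pm10_lag1``) are derived automatically from
    the base variables when absent.
    """
    constraints = constraints or MatchingConstraints()
    if auto_lags:
        lag_specs: dict[str, list[int]] = {}
        for var in constraints.needed_vars():
            if var in df.columns:
                continue
            parsed = parse_lag_name(var)
            if parsed and parsed[0] in df.columns:
                lag_specs.setdefault(parsed[0], []).append(parsed[1])
        for base, offs in lag_specs.items():
            df = add_lags_and_leads(df, [base], sorted(set(offs)))
    treated_rows, control_rows, ok, dist = admissibility_matrices(df, constraints)
    w = df["w"].to_numpy(dtype=float)
    n_treated = int((w == 1.0).sum())
    n_control = int((w == 0.0).sum())
    dropped_t = n_treated - treated_rows.size
    if dropped_t:
        logger.info("%d treated days dropped for missing constraint covariates", dropped_t)
    ti, ci = _solve_assignment(ok, dist)
    order = np.argsort(ti)
    ti, ci = ti[order], ci[order]
    pairs = pd.DataFrame({
        "treated_index": treated_rows[ti],
        "control_index": control_rows[ci],
        "treated_date": pd.to_datetime(df.loc[treated_rows[ti], "date"]).to_numpy(),
        "control_date": pd.to_datetime(df.loc[control_rows[ci], "date"]).to_numpy(),
        "distance": dist[ti, ci],
    })
    return MatchedPairSet(pairs, n_treated=n_treated, n_control=n_control,
                          n_treated_usable=int(treated_rows.size),
                          n_control_usable=int(control_rows.size))


def matching_summary(df: pd.DataFrame, pairs: MatchedPairSet,
                     covariates: tuple[str, ...] = ("temperature", "wind_speed",
                                                    "humidity")) -> dict:
    """Diagnostics: counts, matched fraction, covariate means matched vs initial."""
    rows = []
    matched_idx = pd.concat([pairs.pairs["treated_index"],
                             pairs.pairs["control_index"]]) if pairs.j else pd.Series(dtype=int)
    matched_idx = matched_idx[matched_idx.isin(df.index)]
    for cov in covariates:
        if cov not in df.columns:
            continue
        rows.append({
            "covariate": cov,
            "initial_mean": float(df[cov].mean()),
            "matched_mean": float(df.loc[matched_idx, cov].mean())
            if len(matched_idx) else float("nan"),
        })
    return {
        "n_treated": pairs.n_treated,
        "n_control": pairs.n_control,
        "j": pairs.j,
        "matched_fraction": round(pairs.matched_fraction, 3),
        "covariate_means": pd.DataFrame(rows),
    }
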