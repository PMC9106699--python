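"""Independent oracles and small-instance generators used across the suite."""

from __future__ import annotations

from functools import lru_cache

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from windmatch.matching import MatchingConstraints


def dp_match_oracle(ok: np.ndarray, dist: np.ndarray):
    """Exhaustive max-cardinality / min-total-distance matching.

    Bitmask dynamic program over controls (independent of the package's
    assignment-based solver).  Returns (cardinality, total_distance).
    """
    n_t, n_c = ok.shape
    ok_t = tuple(tuple(bool(v) for v in row) for row in ok)
    dist_t = tuple(tuple(float(v) for v in row) for row in dist)

    @lru_cache(maxsize=None)
    def go(i: int, used: int):
        if i == n_t:
            return (0, 0.0)
        best = go(i + 1, used)  # leave treated i unmatched
        for j in range(n_c):
            if ok_t[i][j] and not (used >> j) & 1:
                card, d = go(i + 1, used | (1 << j))
                cand = (card + 1, d + dist_t[i][j])
                if cand[0] > best[0] or (cand[0] == best[0] and cand[1] < best[1] - 1e-12):
                    best = cand
        return best

    result = go(0, 0)
    go.cache_clear()
    return result


def random_small_instance(rng: np.random.Generator):
    """A tiny daily table (≤ 8 treated, ≤ 10 controls) plus loosened constraints.

    Covariates are drawn so that admissibility is neither empty nor total;
    lagged variables are supplied directly as columns.
    """
    n_t = int(rng.integers(1, 9))
    n_c = int(rng.integers(1, 11))
    n = n_t + n_c
    days = rng.choice(np.arange(0, 120), size=n, replace=False)
    w = np.array([1] * n_t + [0] * n_c)
    df = pd.DataFrame({
        "date": pd.Timestamp("2015-01-01") + pd.to_timedelta(days, unit="D"),
        "w": w,
        "temperature": rng.uniform(5, 25, n),
        "wind_speed": rng.uniform(1, 6, n),
        "humidity": rng.uniform(40, 100, n),
        "pm10_lag1": rng.uniform(10, 40, n),
        "w_lag1": rng.integers(0, 2, n),
        "rainfall_cat": rng.integers(1, 3, n),
        "weekend": rng.integers(0, 2, n),
        "holiday": 0,
        "bank_day": 0,
    }).sort_values("date").reset_index(drop=True)
    constraints = MatchingConstraints(
        min_date_gap=int(rng.integers(1, 5)),
        max_date_gap=int(rng.integers(40, 90)),
        calipers={"temperature": float(rng.uniform(4, 12)),
                  "wind_speed": float(rng.uniform(1, 4)),
                  "humidity": float(rng.uniform(15, 40)),
                  "pm10_lag1": float(rng.uniform(8, 25))},
    )
    return df, constraints


def exact_greater_pvalue(diffs: np.ndarray, tau0: float) -> float:
    """Exact one-sided P(T >= t_obs) for the signed-rank statistic at Γ = 1.

    Full 2^J enumeration of sign assignments (equal probability 1/2 each),
    J ≤ ~16.  Zeros dropped, ties mid-ranked, matching the implementation's
    statistic definition.
    """
    a = np.asarray(diffs, dtype=float) - tau0
    a = a[a != 0.0]
    if a.size == 0:
        return 1.0
    r = rankdata(np.abs(a))
    t_obs = r[a > 0].sum()
    n = a.size
    signs = ((np.arange(2 ** n)[:, None] >> np.arange(n)) & 1).astype(float)
    t_all = signs @ r
    return float(np.mean(t_all >= t_obs - 1e-9))


def exact_signed_rank_interval(diffs: np.ndarray, alpha: float = 0.05,
                               tol: float = 0.005):
    """Invert the exact-distribution signed-rank test into a two-sided CI."""
    d = np.asarray(diffs, dtype=float)
    a2 = alpha / 2.0
    return _exact_interval_at(d, a2, tol)


def _exact_interval_at(d: np.ndarray, a2: float, tol: float):
    lo0, hi0 = d.min() - tol, d.max() + tol

    def bisect(pred, lo, hi):
        while hi - lo > tol:
            mid = 0.5 * (lo + hi)
            if pred(mid):
                hi = mid
            else:
                lo = mid
        return 0.5 * (lo + hi)

    if exact_greater_pvalue(d, lo0) > a2:
        low = float("-inf")
    else:
        low = bisect(lambda t0: exact_greater_pvalue(d, t0) > a2, lo0, hi0)
    if exact_greater_pvalue(-d, -hi0) > a2:
        high = float("inf")
    else:
        # bisection variable is -tau0, so it feeds straight into the mirror
        high = -bisect(lambda t: exact_greater_pvalue(-d, t) > a2, -hi0, -lo0)
    return low, high


def assert_interval_within_one_exact_step(d: np.ndarray, approx_interval,
                                          alpha: float = 0.05, tol: float = 0.03):
    """Check a normal-approximation interval against the exact 2^J inversion.

    The achievable exact p-values are multiples of 2^-J, so the inverted
    interval moves in discrete steps.  The approximation must lie inside the
    exact interval (it rejects at least as easily) but no more than one
    achievable-probability step inside it.
    """
    d = np.asarray(d, dtype=float)
    j = d.size
    a2 = alpha / 2.0
    # achievable one-sided tail probabilities of T for untied ranks 1..J
    counts = np.zeros(j * (j + 1) // 2 + 1)
    counts[0] = 1.0
    for r in range(1, j + 1):
        counts[r:] += counts[:-r].copy()
    tails = np.cumsum(counts[::-1])[::-1] / 2 ** j
    step = float(tails[tails > a2].min())         # smallest achievable p > a2
    outer_lo, outer_hi = _exact_interval_at(d, a2, 0.005)
    inner_lo, inner_hi = _exact_interval_at(d, step + 1e-9, 0.005)
    lo, hi = approx_interval
    assert outer_lo - tol <= lo <= inner_lo + tol, (lo, outer_lo, inner_lo)
    assert inner_hi - tol <= hi <= outer_hi + tol, (hi, inner_hi, outer_hi)
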