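"""Neymanian inference for the matched pairwise experiment.

Potential outcomes are treated as fixed; the treatment assignment within
pairs is the basis of inference.  The point estimate is the mean of the J
observed pair differences,

    tau_hat = (1/J) Σ_j (Y_t,j − Y_c,j),

its conservative variance estimate is

    var_hat = 1 / (J(J−1)) · Σ_j (d_j − tau_hat)²,

and confidence intervals use the Gaussian approximation with fixed
multipliers 1.96 (95%) and 2.576 (99%).  The variance estimator is
conservative in general and exactly unbiased under a constant additive
treatment effect.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .datasets import add_lags_and_leads, lag_name
from .matching import MatchedPairSet

logger = logging.getLogger(__name__)

Z95 = 1.96
Z99 = 2.576


@dataclass
class EffectEstimate:
    """Estimated effect for one outcome at one day offset."""
    outcome: str
    offset: int
    j: int
    tau_hat: float
    var_hat: float
    se: float
    ci95: tuple[float, float]
    ci99: tuple[float, float]
    relative_increase: float | None = None   # % of the matched control-arm mean

    def to_dict(self) -> dict:
        return {
            "outcome": self.outcome, "offset": self.offset, "j": self.j,
            "tau_hat": self.tau_hat, "var_hat": self.var_hat, "se": self.se,
            "ci95_low": self.ci95[0], "ci95_high": self.ci95[1],
            "ci99_low": self.ci99[0], "ci99_high": self.ci99[1],
            "relative_increase_pct": self.relative_increase,
        }


def _pair_values(df: pd.DataFrame, pairs: MatchedPairSet, outcome: str, offset: int):
    col = lag_name(outcome, offset)
    if col not in df.columns:
        df = add_lags_and_leads(df, [outcome], [offset])
    yt = df.loc[pairs.pairs["treated_index"], col].to_numpy(dtype=float)
    yc = df.loc[pairs.pairs["control_index"], col].to_numpy(dtype=float)
    keep = ~np.isnan(yt) & ~np.isnan(yc)
    return yt[keep], yc[keep], int((~keep).sum())


def pair_differences(df: pd.DataFrame, pairs: MatchedPairSet, outcome: str,
                     offset: int = 0) -> np.ndarray:
    """Observed pair differences d_j = Y(treated) − Y(control) at a day offset.

    Pairs with a missing member value are dropped listwise (count logged);
    offset −1 yields the previous-day, negative-control differences.
    """
    yt, yc, n_dropped = _pair_values(df, pairs, outcome, offset)
    if n_dropped:
        logger.info("%s offset %+d: %d pairs dropped for missing values",
                    outcome, offset, n_dropped)
    if yt.size == 0:
        raise ValueError(f"no complete pairs for {outcome} at offset {offset}")
    return yt - yc


def neyman_estimate(diffs, z95: float = Z95, z99: float = Z99,
                    outcome: str = "", offset: int = 0,
                    control_mean: float | None = None) -> EffectEstimate:
    """Point estimate, conservative variance and Gaussian CIs from pair differences."""
    d = np.asarray(diffs, dtype=float)
    j = d.size
    if j < 2:
        raise ValueError("need at least 2 pairs (variance undefined otherwise)")
    tau_hat = float(d.mean())
    var_hat = float(((d - tau_hat) ** 2).sum() / (j * (j - 1)))
    se = float(np.sqrt(var_hat))
    rel = None
    if control_mean is not None and control_mean != 0.0:
        rel = 100.0 * tau_hat / control_mean
    return EffectEstimate(
        outcome=outcome, offset=offset, j=j, tau_hat=tau_hat, var_hat=var_hat,
        se=se, ci95=(tau_hat - z95 * se, tau_hat + z95 * se),
        ci99=(tau_hat - z99 * se, tau_hat + z99 * se), relative_increase=rel)


def lead_lag_effects(df: pd.DataFrame, pairs: MatchedPairSet,
                     outcomes: Sequence[str],
                     offsets: Sequence[int] = (-1, 0, 1)) -> pd.DataFrame:
    """One Neyman estimate per outcome × day offset, as a tidy table.

    ``relative_increase_pct`` is measured against the matched control-arm
    mean at the same offset.
    """
    df = add_lags_and_leads(df, list(outcomes),
                            [o for o in offsets if o != 0])
    rows = []
    for outcome in outcomes:
        for offset in offsets:
            yt, yc, n_dropped = _pair_values(df, pairs, outcome, int(offset))
            if yt.size < 2:
                logger.warning("%s offset %+d skipped: fewer than 2 complete pairs",
                               outcome, offset)
                continue
            est = neyman_estimate(yt - yc, outcome=outcome, offset=int(offset),
                                  control_mean=float(yc.mean()))
            row = est.to_dict()
            row["n_dropped"] = n_dropped
            rows.append(row)
    return pd.DataFrame(rows)


@dataclass
class PrecisionComparison:
    """Pairwise vs completely randomized sampling-variance comparison."""
    outcome: str
    j: int
    var_pairwise: float
    se_pairwise: float
    var_complete: float
    se_complete: float

    @property
    def precision_ratio(self) -> float:
        """se_complete / se_pairwise; > 1 means pairing helped precision."""
        if self.se_pairwise == 0.0:
            return float("inf")
        return self.se_complete / self.se_pairwise


def complete_randomization_variance(df: pd.DataFrame, pairs: MatchedPairSet,
                                    outcome: str, offset: int = 0) -> PrecisionComparison:
    """Compare the pairwise variance estimate to the completely randomized one.

    The complete-randomization estimate is s_t²/J + s_c²/J with s² the sample
    variances of the matched treated and matched control outcome values.  If
    it exceeds the pairwise estimate, pairing similar days has improved
    precision over randomly splitting the matched sample.
    """
    yt, yc, _ = _pair_values(df, pairs, outcome, offset)
    j = yt.size
    if j < 2:
        raise ValueError("need at least 2 complete pairs")
    d = yt - yc
    tau_hat = d.mean()
    var_pairwise = float(((d - tau_hat) ** 2).sum() / (j * (j - 1)))
    var_complete = float(np.var(yt, ddof=1) / j + np.var(yc, ddof=1) / j)
    return PrecisionComparison(outcome=outcome, j=j,
                               var_pairwise=var_pairwise,
                               se_pairwise=float(np.sqrt(var_pairwise)),
                               var_complete=var_complete,
                               se_complete=float(np.sqrt(var_complete)))
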