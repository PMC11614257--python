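"""Mann-Kendall trend test and Sen's slope for short yearly series.

Used to test for monotone trend in yearly surveillance proportions (for
example the share of reviewed maternal deaths investigated by verbal
autopsy, i.e. identified at community level).  The Mann-Kendall score is

    S = sum_{i<j} sign(x_j - x_i),

its variance carries the standard tie-group correction

    var(S) = [n(n-1)(2n+5) - sum_t t(t-1)(2t+5)] / 18,

and the normal approximation applies the +/-1 continuity correction
(z = (S-1)/sqrt(var S) for S > 0, (S+1)/sqrt(var S) for S < 0, 0 at
S = 0).  Kendall's tau is reported as S divided by the n(n-1)/2 pair
count (tau-a).  Sen's slope is the median of all pairwise slopes
(x_j - x_i)/(year_j - year_i); its confidence interval uses the rank
method — ranks (N -+ z_{alpha/2} sqrt(var S))/2 among the N sorted
pairwise slopes, linearly interpolated between adjacent order statistics.

The module is unit-agnostic: slopes are in (value units) per year of
whatever scale the series is supplied on.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats

from .errors import MdsrEvalError

__all__ = ["YearlySeries", "TrendResult", "mann_kendall", "sen_slope", "MannKendallTrend"]


@dataclass(frozen=True)
class YearlySeries:
    """An ordered yearly series: strictly increasing years, one value each."""

    years: tuple[int, ...]
    values: tuple[float, ...]

    def __post_init__(self):
        if len(self.years) != len(self.values):
            raise MdsrEvalError("years and values must have equal length")
        if any(b <= a for a, b in zip(self.years, self.years[1:])):
            raise MdsrEvalError("years must be strictly increasing")

    def __len__(self) -> int:
        return len(self.years)


@dataclass(frozen=True)
class TrendResult:
    """Mann-Kendall statistic and Sen's slope with its confidence interval."""

    S: int
    var_S: float
    z: float
    p_value: float
    tau: float
    sen_slope: float
    slope_ci_low: float
    slope_ci_high: float
    alpha: float = 0.05


def _mk_score(values: np.ndarray) -> int:
    diff = np.sign(values[None, :] - values[:, None])
    return int(np.triu(diff, k=1).sum())


def _mk_variance(values: np.ndarray) -> float:
    n = values.size
    var = n * (n - 1) * (2 * n + 5)
    _, counts = np.unique(values, return_counts=True)
    for t in counts[counts > 1]:
        var -= t * (t - 1) * (2 * t + 5)
    return var / 18.0


def mann_kendall(
    series: YearlySeries, continuity: bool = True
) -> tuple[int, float, float, float, float]:
    """Mann-Kendall test: returns (S, var_S, z, two-sided p, tau)."""
    n = len(series)
    if n < 3:
        raise MdsrEvalError("Mann-Kendall requires at least 3 observations")
    values = np.asarray(series.values, dtype=float)
    s = _mk_score(values)
    var_s = _mk_variance(values)
    if var_s == 0:  # all values tied
        return s, 0.0, 0.0, 1.0, 0.0
    if continuity:
        if s > 0:
            z = (s - 1) / math.sqrt(var_s)
        elif s < 0:
            z = (s + 1) / math.sqrt(var_s)
        else:
            z = 0.0
    else:
        z = s / math.sqrt(var_s)
    p = 2.0 * stats.norm.sf(abs(z))
    tau = s / (n * (n - 1) / 2)
    return s, float(var_s), float(z), float(p), float(tau)


def _pairwise_slopes(series: YearlySeries) -> np.ndarray:
    years = np.asarray(series.years, dtype=float)
    values = np.asarray(series.values, dtype=float)
    n = years.size
    i, j = np.triu_indices(n, k=1)
    return (values[j] - values[i]) / (years[j] - years[i])


def sen_slope(series: YearlySeries, alpha: float = 0.05) -> tuple[float, float, float]:
    """Sen's slope and its rank-based confidence interval.

    The bounds are the pairwise slopes at ranks (N -+ C)/2 with
    C = z_{alpha/2} * sqrt(var S), linearly interpolated between adjacent
    order statistics (1-based ranks, clipped to [1, N]).
    """
    if len(series) < 3:
        raise MdsrEvalError("Sen's slope CI requires at least 3 observations")
    slopes = np.sort(_pairwise_slopes(series))
    n_slopes = slopes.size
    slope = float(np.median(slopes))
    var_s = _mk_variance(np.asarray(series.values, dtype=float))
    c = stats.norm.ppf(1 - alpha / 2) * math.sqrt(var_s)
    ranks = np.clip([(n_slopes - c) / 2.0, (n_slopes + c) / 2.0], 1, n_slopes)
    lo, hi = np.interp(ranks, np.arange(1, n_slopes + 1), slopes)
    return slope, float(lo), float(hi)


class MannKendallTrend:
    """Trend model for one yearly series.

    Examples
    --------
    >>> m = MannKendallTrend(range(2013, 2021), [3 + 2 * k for k in range(8)])
    >>> res = m.fit()
    >>> res.sen_slope
    2.0
    """

    def __init__(self, years: Sequence[int], values: Sequence[float]):
        self.series = YearlySeries(tuple(int(y) for y in years), tuple(float(v) for v in values))

    def fit(self, alpha: float = 0.05, continuity: bool = True) -> TrendResult:
        s, var_s, z, p, tau = mann_kendall(self.series, continuity=continuity)
        slope, lo, hi = sen_slope(self.series, alpha=alpha)
        return TrendResult(
            S=s,
            var_S=var_s,
            z=z,
            p_value=p,
            tau=tau,
            sen_slope=slope,
            slope_ci_low=lo,
            slope_ci_high=hi,
            alpha=alpha,
        )
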