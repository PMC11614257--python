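"""Group-comparison machinery for readiness scores.

The published comparison workflow is: check normality with Shapiro-Wilk,
then compare groups with independent-sample t-tests (two groups) or
one-way ANOVA (more), following a significant ANOVA with Bonferroni
post-hoc pairwise contrasts.  The normality gate is advisory (a warning,
not a hard stop) because the parametric tests are used throughout.

The t-test defaults to the classical pooled-variance form (with a Welch
switch) so that the two-group ANOVA identity F = t^2 holds exactly.
``compare_from_summaries`` is an approximate normal z-test from printed
mean/SE pairs, for checking published table rows when raw data are
unavailable.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass
from itertools import combinations
from typing import Mapping, Sequence

import numpy as np
from scipy import stats

from .errors import MdsrEvalError

logger = logging.getLogger("mdsreval")

__all__ = [
    "ComparisonResult",
    "shapiro_wilk_gate",
    "two_group_test",
    "one_way_anova",
    "bonferroni_pairwise",
    "compare_from_summaries",
]


@dataclass(frozen=True)
class ComparisonResult:
    """One contrast: difference, test statistic, p-values, significance."""

    contrast_label: str
    absolute_difference_pct: float
    test_statistic: float
    df: float | tuple[float, float]
    p_value: float
    adjusted_p_value: float | None = None
    significant: bool = False
    approximate: bool = False


def shapiro_wilk_gate(
    scores: Sequence[float], alpha: float = 0.05
) -> tuple[float, float, bool]:
    """Shapiro-Wilk normality check: (W, p, pass flag with pass = p >= alpha).

    Constant input has no defined W statistic and raises.
    """
    arr = np.asarray(scores, dtype=float)
    if arr.size < 3:
        raise MdsrEvalError("Shapiro-Wilk requires at least 3 observations")
    if np.ptp(arr) == 0:
        raise MdsrEvalError("Shapiro-Wilk undefined for constant data")
    w, p = stats.shapiro(arr)
    ok = p >= alpha
    if not ok:
        warnings.warn(
            f"Shapiro-Wilk rejects normality (W={w:.4f}, p={p:.2g}); "
            "parametric comparisons proceed but interpret with care",
            stacklevel=2,
        )
    return float(w), float(p), bool(ok)


def two_group_test(
    a: Sequence[float],
    b: Sequence[float],
    alpha: float = 0.05,
    label: str = "group1 vs group2",
    welch: bool = False,
) -> ComparisonResult:
    """Two-sided independent-sample t-test (pooled variance by default)."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise MdsrEvalError("each group needs at least 2 observations")
    t, p = stats.ttest_ind(a, b, equal_var=not welch)
    if math.isnan(t):  # both groups constant and equal
        t, p = 0.0, 1.0
    if welch:
        df = _welch_df(a, b)
    else:
        df = float(a.size + b.size - 2)
    return ComparisonResult(
        contrast_label=label,
        absolute_difference_pct=float(abs(a.mean() - b.mean())),
        test_statistic=float(t),
        df=df,
        p_value=float(p),
        significant=bool(p < alpha),
    )


def _welch_df(a: np.ndarray, b: np.ndarray) -> float:
    va, vb = a.var(ddof=1) / a.size, b.var(ddof=1) / b.size
    return float(
        (va + vb) ** 2 / (va**2 / (a.size - 1) + vb**2 / (b.size - 1))
    )


def one_way_anova(
    groups: Mapping[str, Sequence[float]],
) -> tuple[float, int, int, float]:
    """Classical one-way ANOVA: returns (F, df_between, df_within, p).

    All-identical observations yield F = 0, p = 1 (returned, not raised).
    """
    arrays = [np.asarray(v, dtype=float) for v in groups.values()]
    k = len(arrays)
    if k < 2:
        raise MdsrEvalError("ANOVA needs at least 2 groups")
    if any(a.size < 1 for a in arrays):
        raise MdsrEvalError("every group needs at least 1 observation")
    n = sum(a.size for a in arrays)
    if n <= k:
        raise MdsrEvalError("total observations must exceed the number of groups")
    df_b, df_w = k - 1, n - k
    pooled = np.concatenate(arrays)
    if np.ptp(pooled) == 0:
        return 0.0, df_b, df_w, 1.0
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # scipy warns on within-group constancy
        f, p = stats.f_oneway(*arrays)
    if math.isnan(f):  # zero within-group variance, nonzero between
        return math.inf, df_b, df_w, 0.0
    return float(f), df_b, df_w, float(p)


def bonferroni_pairwise(
    groups: Mapping[str, Sequence[float]],
    alpha: float = 0.05,
    override: bool = False,
    welch: bool = False,
) -> list[ComparisonResult]:
    """All pairwise pooled-t contrasts with Bonferroni adjustment.

    The adjustment family is every pair within the supplied grouping:
    adjusted_p = min(1, p * k(k-1)/2).  Refuses to run when the omnibus
    ANOVA is not significant at ``alpha`` unless ``override`` is set.
    Groups with fewer than 2 observations are skipped (a pairwise t-test
    is undefined for them) but still counted in the logged family size
    decision; the family size used for adjustment is the number of
    testable pairs.
    """
    _, _, _, p_anova = one_way_anova(groups)
    if p_anova >= alpha and not override:
        raise MdsrEvalError(
            f"omnibus ANOVA not significant (p={p_anova:.3g}); "
            "pass override=True to run post-hoc contrasts anyway"
        )
    testable = {k: v for k, v in groups.items() if len(v) >= 2}
    pairs = list(combinations(sorted(testable), 2))
    m = len(pairs)
    logger.info("bonferroni_pairwise: %d groups, family of %d comparisons", len(testable), m)
    out = []
    for ga, gb in pairs:
        base = two_group_test(
            testable[ga], testable[gb], alpha=alpha, label=f"{ga} vs {gb}", welch=welch
        )
        adj = min(1.0, base.p_value * m)
        out.append(
            ComparisonResult(
                contrast_label=base.contrast_label,
                absolute_difference_pct=base.absolute_difference_pct,
                test_statistic=base.test_statistic,
                df=base.df,
                p_value=base.p_value,
                adjusted_p_value=adj,
                significant=bool(adj < alpha),
            )
        )
    return out


def compare_from_summaries(
    mean1: float,
    se1: float,
    n1: int,
    mean2: float,
    se2: float,
    n2: int,
    alpha: float = 0.05,
    label: str = "group1 vs group2",
) -> ComparisonResult:
    """Approximate z-test from summary statistics (mean, SE, n) alone.

    z = (mean1 - mean2) / sqrt(se1^2 + se2^2) with a two-sided normal
    p-value.  Useful for checking published table rows when the raw
    per-facility scores are not available; flagged ``approximate``.
    """
    if se1 < 0 or se2 < 0:
        raise MdsrEvalError("standard errors must be non-negative")
    if n1 < 2 or n2 < 2:
        raise MdsrEvalError("each group needs n >= 2")
    denom = math.sqrt(se1**2 + se2**2)
    if denom == 0:
        raise MdsrEvalError("both standard errors are zero; z undefined")
    z = (mean1 - mean2) / denom
    p = 2.0 * stats.norm.sf(abs(z))
    return ComparisonResult(
        contrast_label=label,
        absolute_difference_pct=abs(mean1 - mean2),
        test_statistic=float(z),
        df=math.inf,
        p_value=float(p),
        significant=bool(p < alpha),
        approximate=True,
    )
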