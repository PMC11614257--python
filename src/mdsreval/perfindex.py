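"""The five MDSR performance indicators and their weighted composite.

From the six death-count aggregates of a region (expected deaths E(d),
identified d_i, notified d_n, reviewed d_r, and the community/facility
split of reviewed) the module computes, on the percent scale:

* ``Rn``   notification rate          = 100 * d_n / d_i
* ``CRn``  notification coverage rate = 100 * d_n / E(d)
* ``Rr``   review rate                = 100 * d_r / d_n
* ``CRr``  review coverage rate       = 100 * d_r / E(d)
* ``CRDp`` reviewed community share   = 100 * d_rc / d_r

Rn below 80% signals incomplete weekly notification; Rr above 100%
signals that committees review deaths that were never notified (so Rr is
deliberately not capped, in the composite either — regions can and do
exceed 100%).  The composite performance index (MDSRPI) is the weighted
sum of the five indicators (default weights 0.1/0.3/0.3/0.2/0.1 for
Rn/CRn/CRr/Rr/CRDp) and classifies as low (< 40), moderate ([40, 60])
or good (> 60) on the percent scale.

Zero denominators leave an indicator *undefined* (None plus a flag) —
never 0 and never infinity; the composite refuses to form until every
indicator is defined.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .datamodel import (
    DEFAULT_MDSRPI_WEIGHTS,
    PRINTED_EXPECTED_TOTAL,
    RegionCounts,
    load_ethiopia_panel,
)
from .errors import ConfigError, MdsrEvalError, UndefinedIndicatorError
from .readiness import display_round

__all__ = [
    "IndicatorSet",
    "MdsrpiResult",
    "compute_indicators",
    "aggregate_national",
    "compute_mdsrpi",
    "classify_mdsrpi",
    "PerformanceIndexModel",
    "PerformanceIndexResults",
]

INDICATOR_NAMES = ("Rn", "CRn", "Rr", "CRr", "CRDp")


@dataclass(frozen=True)
class IndicatorSet:
    """The five indicator rates (percent scale); None where undefined."""

    Rn: float | None
    CRn: float | None
    Rr: float | None
    CRr: float | None
    CRDp: float | None
    undefined: frozenset[str] = field(default_factory=frozenset)

    def as_dict(self) -> dict[str, float | None]:
        return {name: getattr(self, name) for name in INDICATOR_NAMES}


@dataclass(frozen=True)
class MdsrpiResult:
    """Weighted composite index and its performance class for one unit."""

    region: str
    indicators: IndicatorSet
    mdsrpi_pct: float
    performance_class: str


def _rate(num: int, den: int) -> float | None:
    return 100.0 * num / den if den > 0 else None


def compute_indicators(c: RegionCounts) -> IndicatorSet:
    """All five indicator rates for one region, unrounded."""
    values = {
        "Rn": _rate(c.notified, c.identified),
        "CRn": _rate(c.notified, c.expected),
        "Rr": _rate(c.reviewed, c.notified),
        "CRr": _rate(c.reviewed, c.expected),
        "CRDp": _rate(c.reviewed_community, c.reviewed),
    }
    undefined = frozenset(k for k, v in values.items() if v is None)
    return IndicatorSet(undefined=undefined, **values)


def aggregate_national(
    panel: Sequence[RegionCounts],
    expected_total: int | None = None,
) -> RegionCounts:
    """Componentwise sum of a count panel into one national row.

    ``expected_total`` overrides the summed expected-death count with a
    separately published national total (the packaged Ethiopian panel's
    regional values sum to 60639 while the published national total is
    60686; pass :data:`~mdsreval.datamodel.PRINTED_EXPECTED_TOTAL` to
    reproduce published national coverage rates).
    """
    if not panel:
        raise MdsrEvalError("empty count panel")
    sums = {
        col: sum(getattr(c, col) for c in panel)
        for col in (
            "expected",
            "identified",
            "notified",
            "reviewed",
            "reviewed_community",
            "reviewed_facility",
        )
    }
    if expected_total is not None:
        sums["expected"] = expected_total
    return RegionCounts(region="National", **sums)


def compute_mdsrpi(
    ind: IndicatorSet,
    weights: Mapping[str, float] | None = None,
    region: str = "",
) -> MdsrpiResult:
    """Weighted composite of the five indicators, on the percent scale."""
    weights = dict(weights) if weights is not None else dict(DEFAULT_MDSRPI_WEIGHTS)
    if set(weights) != set(INDICATOR_NAMES):
        raise ConfigError(f"weights must name exactly {INDICATOR_NAMES}")
    wsum = sum(weights.values())
    if abs(wsum - 1.0) > 1e-9:
        raise ConfigError(f"indicator weights must sum to 1, got {wsum}")
    if ind.undefined:
        raise UndefinedIndicatorError(sorted(ind.undefined))
    score = sum(weights[name] * getattr(ind, name) for name in INDICATOR_NAMES)
    return MdsrpiResult(
        region=region,
        indicators=ind,
        mdsrpi_pct=float(score),
        performance_class=classify_mdsrpi(score),
    )


def classify_mdsrpi(mdsrpi_pct: float) -> str:
    """low (< 40), moderate ([40, 60]), good (> 60) on the percent scale.

    The published thresholds are stated on the fraction scale (0.4/0.6);
    the moderate band is taken as the closed interval so the map is total.
    """
    if mdsrpi_pct < 0:
        raise MdsrEvalError(f"negative index score {mdsrpi_pct}")
    if mdsrpi_pct < 40.0:
        return "low"
    if mdsrpi_pct <= 60.0:
        return "moderate"
    return "good"


class PerformanceIndexModel:
    """Performance-index model over a region count panel.

    Parameters
    ----------
    panel
        One :class:`RegionCounts` per region.
    weights
        Indicator weights (default 0.1/0.3/0.3/0.2/0.1 for
        Rn/CRn/CRr/Rr/CRDp).
    expected_total
        Optional published national expected-deaths total used for the
        national row instead of the regional sum.

    Examples
    --------
    >>> model = PerformanceIndexModel.ethiopia()
    >>> res = model.fit()
    >>> round(res.national.mdsrpi_pct, 1)
    33.9
    """

    def __init__(
        self,
        panel: Iterable[RegionCounts],
        weights: Mapping[str, float] | None = None,
        expected_total: int | None = None,
    ):
        self.panel = list(panel)
        if not self.panel:
            raise MdsrEvalError("empty count panel")
        self.weights = dict(weights) if weights is not None else dict(DEFAULT_MDSRPI_WEIGHTS)
        self.expected_total = expected_total

    @classmethod
    def ethiopia(cls, use_printed_total_expected: bool = True) -> "PerformanceIndexModel":
        """Model over the packaged Ethiopian 2014-2020 panel."""
        return cls(
            load_ethiopia_panel(),
            expected_total=PRINTED_EXPECTED_TOTAL if use_printed_total_expected else None,
        )

    def fit(self) -> "PerformanceIndexResults":
        regional = [
            compute_mdsrpi(compute_indicators(c), self.weights, region=c.region)
            for c in self.panel
        ]
        nat_counts = aggregate_national(self.panel, self.expected_total)
        national = compute_mdsrpi(
            compute_indicators(nat_counts), self.weights, region=nat_counts.region
        )
        return PerformanceIndexResults(self, regional, national, nat_counts)


class PerformanceIndexResults:
    """Fitted per-region and national indicators, composite and classes."""

    def __init__(
        self,
        model: PerformanceIndexModel,
        regional: list[MdsrpiResult],
        national: MdsrpiResult,
        national_counts: RegionCounts,
    ):
        self.model = model
        self.regional = regional
        self.national = national
        self.national_counts = national_counts

    def by_region(self, region: str) -> MdsrpiResult:
        for r in self.regional:
            if r.region == region:
                return r
        raise KeyError(region)

    @property
    def table(self) -> pd.DataFrame:
        """Full-precision results, one row per region plus the national row."""
        rows = []
        for res, counts in [
            *zip(self.regional, self.model.panel),
            (self.national, self.national_counts),
        ]:
            rows.append(
                {
                    "region": res.region,
                    "expected": counts.expected,
                    "identified": counts.identified,
                    "notified": counts.notified,
                    "reviewed": counts.reviewed,
                    "reviewed_community": counts.reviewed_community,
                    "reviewed_facility": counts.reviewed_facility,
                    **res.indicators.as_dict(),
                    "MDSRPI": res.mdsrpi_pct,
                    "class": res.performance_class,
                }
            )
        return pd.DataFrame(rows)

    def display_table(self, decimals: int = 1) -> pd.DataFrame:
        """The same table with indicator columns display-rounded."""
        tab = self.table.copy()
        for col in (*INDICATOR_NAMES, "MDSRPI"):
            tab[col] = tab[col].map(lambda x: display_round(x, decimals))
        return tab

    def summary(self) -> str:
        tab = self.display_table()
        cols = ["region", "Rn", "CRn", "CRr", "Rr", "CRDp", "MDSRPI", "class"]
        return "MDSR performance index\n" + tab[cols].to_string(index=False)

    def to_markdown(self, decimals: int = 1) -> str:
        return self.display_table(decimals).to_markdown(index=False)
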