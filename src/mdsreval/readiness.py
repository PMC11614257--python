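"""Facility readiness scoring and functionality ratings.

Each of the four surveillance dimensions (structure, core function,
supportive function, system attributes) is scored as the percentage of
its yes/no items answered "yes".  The overall readiness composite is the
weighted sum of the four dimension percentages (equal 0.25 weights by
default, so it equals their arithmetic mean), and the composite — like
every dimension score — maps onto the five-band functionality rating
scale used for mid-term evaluations:

====================  =========================
score (%)             rating
====================  =========================
<= 20                 not functioning
(20, 50]              less functioning
(50, 75]              fairly functioning
(75, 90]              effectively functioning
(90, 100]             very effectively functioning
====================  =========================

The printed band labels ("21 to 50%", "51 to 75%", ...) leave fractional
scores like 50.4 unassigned; the half-open intervals above cover all of
[0, 100] and agree with the published band assignments at every printed
boundary value.

:class:`FacilityReadinessModel` is the statsmodels-style entry point:
build it from validated records (or a CSV), call :meth:`fit`, and the
returned :class:`ReadinessResults` carries per-facility scores, group
summaries with normal-approximation confidence intervals, and a
``summary()`` table.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .datamodel import (
    DIMENSIONS,
    DimensionSpec,
    EvaluationConfig,
    FacilityRecord,
    read_facility_table,
)
from .errors import ConfigError, MdsrEvalError, RecordValidationError

__all__ = [
    "DimensionScore",
    "ReadinessResult",
    "GroupSummary",
    "score_dimension",
    "overall_readiness",
    "classify_ephi",
    "summarize_group",
    "score_facility",
    "FacilityReadinessModel",
    "ReadinessResults",
    "EPHI_BANDS",
]

#: Upper bounds (inclusive) of the five functionality bands.
EPHI_BANDS: tuple[tuple[float, str], ...] = (
    (20.0, "not_functioning"),
    (50.0, "less_functioning"),
    (75.0, "fairly_functioning"),
    (90.0, "effectively_functioning"),
    (100.0, "very_effectively_functioning"),
)

#: 97.5th percentile of the standard normal; the published tables use
#: mean +/- 1.96 SE intervals rather than t quantiles.
Z_95 = 1.96


@dataclass(frozen=True)
class DimensionScore:
    """Score of one dimension for one facility."""

    dimension: str
    raw_total: int  # number of "yes" answers
    score_pct: float  # 100 * raw_total / item count
    weighted_pct: float  # weight * score_pct


@dataclass(frozen=True)
class ReadinessResult:
    """Per-facility readiness: four dimension scores, composite, rating."""

    facility_id: str
    dimension_scores: tuple[DimensionScore, ...]
    overall_pct: float
    rating: str
    subcategory_pct: Mapping[str, float] | None = None


@dataclass(frozen=True)
class GroupSummary:
    """Mean/SE/95% CI of a score within one stratifier group."""

    group_label: str
    n: int
    mean_pct: float
    se_pct: float | None
    ci_low_pct: float | None
    ci_high_pct: float | None


def score_dimension(record: FacilityRecord, spec: DimensionSpec) -> DimensionScore:
    """Percentage of the dimension's items answered yes; no imputation."""
    total = 0
    for item in spec.item_ids:
        if item not in record.responses:
            raise RecordValidationError(
                f"facility {record.facility_id!r} missing response for item {item!r}",
                field=item,
            )
        total += record.responses[item]
    pct = 100.0 * total / len(spec.item_ids)
    return DimensionScore(
        dimension=spec.name,
        raw_total=total,
        score_pct=pct,
        weighted_pct=spec.weight * pct,
    )


def overall_readiness(
    dim_scores: Sequence[DimensionScore],
    weights: Mapping[str, float] | None = None,
) -> float:
    """Weighted sum of the four dimension score percentages.

    With the default equal weights this is the arithmetic mean of the
    four dimension scores.  ``weights`` overrides the weights baked into
    the scores' ``weighted_pct``.
    """
    names = [s.dimension for s in dim_scores]
    if sorted(names) != sorted(DIMENSIONS):
        raise ConfigError(f"need one score per dimension, got {names}")
    if weights is None:
        return float(sum(s.weighted_pct for s in dim_scores))
    if set(weights) != set(DIMENSIONS):
        raise ConfigError("weights must name exactly the four dimensions")
    wsum = sum(weights.values())
    if abs(wsum - 1.0) > 1e-9:
        raise ConfigError(f"weights must sum to 1, got {wsum}")
    return float(sum(weights[s.dimension] * s.score_pct for s in dim_scores))


def classify_ephi(score_pct: float) -> str:
    """Map a percentage score onto the five functionality bands."""
    if not (0.0 <= score_pct <= 100.0):
        raise MdsrEvalError(f"score {score_pct} outside [0, 100]")
    for upper, label in EPHI_BANDS:
        if score_pct <= upper:
            return label
    raise AssertionError("unreachable: bands cover [0, 100]")


def summarize_group(
    scores: Sequence[float], group_label: str = ""
) -> GroupSummary:
    """Mean, standard error (sample SD / sqrt(n)) and 95% normal CI.

    With n < 2 the SE and CI are undefined and reported as None.
    """
    if len(scores) == 0:
        raise MdsrEvalError(f"empty group {group_label!r}")
    arr = np.asarray(scores, dtype=float)
    mean = float(arr.mean())
    if arr.size < 2:
        return GroupSummary(group_label, int(arr.size), mean, None, None, None)
    se = float(arr.std(ddof=1) / math.sqrt(arr.size))
    return GroupSummary(
        group_label,
        int(arr.size),
        mean,
        se,
        mean - Z_95 * se,
        mean + Z_95 * se,
    )


def score_facility(
    record: FacilityRecord, config: EvaluationConfig | None = None
) -> ReadinessResult:
    """Score all four dimensions and the composite for one facility."""
    config = config or EvaluationConfig()
    dim_scores = tuple(score_dimension(record, spec) for spec in config.dimension_specs)
    overall = overall_readiness(dim_scores)
    attr_spec = config.spec_for("attributes")
    sub_pct = {
        sub: 100.0 * sum(record.responses[i] for i in ids) / len(ids)
        for sub, ids in (attr_spec.subcategories or {}).items()
    }
    return ReadinessResult(
        facility_id=record.facility_id,
        dimension_scores=dim_scores,
        overall_pct=overall,
        rating=classify_ephi(overall),
        subcategory_pct=sub_pct,
    )


STRATIFIERS = (
    "region",
    "facility_level",
    "location",
    "region_type",
    "agro_zone",
    "years_implementing",
)


class FacilityReadinessModel:
    """Readiness-scoring model over a set of surveyed facilities.

    Parameters
    ----------
    records
        Validated facility records (typically already filtered to the
        MDSR-implementing subset).
    config
        Evaluation configuration; defaults cover the standard item
        layout with equal dimension weights.

    Examples
    --------
    >>> model = FacilityReadinessModel(records)
    >>> res = model.fit()
    >>> res.national("overall").mean_pct  # doctest: +SKIP
    44.9...
    """

    def __init__(
        self,
        records: Iterable[FacilityRecord],
        config: EvaluationConfig | None = None,
    ):
        self.records = list(records)
        if not self.records:
            raise MdsrEvalError("no facility records supplied")
        self.config = config or EvaluationConfig()

    @classmethod
    def from_csv(
        cls, path: str | Path, config: EvaluationConfig | None = None
    ) -> "FacilityReadinessModel":
        config = config or EvaluationConfig()
        return cls(read_facility_table(path, config), config)

    def fit(self) -> "ReadinessResults":
        results = [score_facility(r, self.config) for r in self.records]
        rows = []
        for rec, res in zip(self.records, results):
            row = {
                "facility_id": rec.facility_id,
                **{s: getattr(rec, s) for s in STRATIFIERS},
            }
            for ds in res.dimension_scores:
                row[ds.dimension] = ds.score_pct
            row["overall"] = res.overall_pct
            row["rating"] = res.rating
            for sub, pct in (res.subcategory_pct or {}).items():
                row[f"attr_{sub}"] = pct
            rows.append(row)
        frame = pd.DataFrame(rows)
        return ReadinessResults(self, results, frame)


class ReadinessResults:
    """Fitted readiness results: per-facility scores plus summaries."""

    def __init__(
        self,
        model: FacilityReadinessModel,
        per_facility: list[ReadinessResult],
        frame: pd.DataFrame,
    ):
        self.model = model
        self.per_facility = per_facility
        self.frame = frame

    @property
    def score_columns(self) -> tuple[str, ...]:
        return (*DIMENSIONS, "overall")

    def national(self, score: str = "overall") -> GroupSummary:
        """National mean/SE/CI for one score column."""
        return summarize_group(self.frame[score].tolist(), "national")

    def summarize_by(self, stratifier: str, score: str = "overall") -> pd.DataFrame:
        """Group summaries of one score by one stratifier.

        Returns a DataFrame with one row per group carrying n, mean, SE
        and the 95% CI, plus the functionality rating of the group mean.
        """
        if stratifier not in STRATIFIERS:
            raise MdsrEvalError(f"unknown stratifier {stratifier!r}")
        rows = []
        for label, sub in self.frame.groupby(stratifier, observed=True):
            gs = summarize_group(sub[score].tolist(), str(label))
            rows.append(
                {
                    "group": gs.group_label,
                    "n": gs.n,
                    "mean_pct": gs.mean_pct,
                    "se_pct": gs.se_pct,
                    "ci_low_pct": gs.ci_low_pct,
                    "ci_high_pct": gs.ci_high_pct,
                    "rating": classify_ephi(gs.mean_pct),
                }
            )
        return pd.DataFrame(rows)

    def summary(self) -> str:
        """Plain-text national summary table (one row per score)."""
        nd = self.model.config.rounding_decimals
        lines = [
            "Facility readiness summary",
            f"  facilities: {len(self.per_facility)}",
            f"{'score':<12}{'mean':>8}{'SE':>8}{'95% CI':>18}  rating",
        ]
        for col in self.score_columns:
            gs = self.national(col)
            ci = (
                f"[{display_round(gs.ci_low_pct, nd)} to {display_round(gs.ci_high_pct, nd)}]"
                if gs.ci_low_pct is not None
                else "NA"
            )
            lines.append(
                f"{col:<12}{display_round(gs.mean_pct, nd):>8}"
                f"{display_round(gs.se_pct, 2) if gs.se_pct is not None else 'NA':>8}"
                f"{ci:>18}  {classify_ephi(gs.mean_pct)}"
            )
        return "\n".join(lines)


def display_round(x: float, decimals: int = 1) -> float:
    """Round half away from zero, as published tables do.

    Python's built-in round() is banker's rounding; published one-decimal
    values use the conventional half-up rule (e.g. 44.925 -> 44.9 but
    33.95 -> 34.0).  Internal arithmetic is never rounded.
    """
    from decimal import ROUND_HALF_UP, Decimal

    q = Decimal(10) ** -decimals
    return float(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP))
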