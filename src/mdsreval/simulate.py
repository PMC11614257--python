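"""Synthetic survey and count-panel generator.

Generates facility survey tables, region count panels and yearly trend
series with the statistical structure the evaluation pipeline assumes,
so every stage can be exercised and calibrated without access to raw
survey data:

* item responses are exchangeable Bernoulli draws at a per-dimension
  yes-probability (optionally overridden per region or per item);
* a facility is MDSR-implementing (notified and reviewed >= 1 death in
  the year before the survey) with probability ``inclusion_prob``;
* panel counts form a thinning chain per region — identified ~
  Binomial(expected, p_identify), notified ~ Binomial(identified,
  p_notify), reviewed ~ Binomial(identified, p_review) — with reviewed
  drawn from *identified* rather than notified so that review rates
  above 100% (committees reviewing never-notified deaths) are reachable,
  as observed in practice;
* the trend series is linear in year plus Gaussian noise, clipped to
  [0, 100].

The ``ethiopia2020`` profile calibrates the generator to the published
national evaluation: the surveyed-cohort size (519 facilities, 77%
implementing), the regional and stratifier mixes, national dimension
mean scores (structure 51.7%, core 20.0%, supportive 38.4%, attributes
69.6%), and per-region panel probabilities derived from the national
2014-2020 count panel.  All randomness flows from the config seed.
"""

from __future__ import annotations

from typing import Mapping, Sequence

import numpy as np
from pydantic import BaseModel, ConfigDict, Field, model_validator

from .datamodel import (
    AGRO_ZONES,
    DIMENSIONS,
    EvaluationConfig,
    FacilityRecord,
    RegionCounts,
    load_ethiopia_panel,
)
from .design import pps_allocate
from .errors import ConfigError
from .trend import YearlySeries

__all__ = [
    "RegionMix",
    "PanelParams",
    "TrendParams",
    "SyntheticConfig",
    "gen_facility_survey",
    "gen_count_panel",
    "gen_trend_series",
    "ethiopia2020_config",
]


class RegionMix(BaseModel):
    """How facilities of one region are generated."""

    model_config = ConfigDict(frozen=True)

    name: str
    n_facilities: int = Field(ge=1)
    p_urban: float = Field(ge=0.0, le=1.0)
    level_probs: tuple[float, float, float]  # primary, secondary, tertiary
    region_type: str
    agro_probs: tuple[float, float, float, float, float]  # order of AGRO_ZONES
    p_ge2years: float = Field(ge=0.0, le=1.0)

    @model_validator(mode="after")
    def _check(self) -> "RegionMix":
        for name, probs in (("level_probs", self.level_probs), ("agro_probs", self.agro_probs)):
            if any(p < 0 for p in probs) or abs(sum(probs) - 1.0) > 1e-9:
                raise ConfigError(f"{name} must be non-negative and sum to 1")
        return self


class PanelParams(BaseModel):
    """Thinning-chain probabilities for one region's count panel."""

    model_config = ConfigDict(frozen=True)

    expected: int = Field(ge=1)
    p_identify: float = Field(ge=0.0, le=1.0)
    p_notify: float = Field(ge=0.0, le=1.0)
    p_review: float = Field(ge=0.0, le=1.0)
    p_community: float = Field(ge=0.0, le=1.0)


class TrendParams(BaseModel):
    model_config = ConfigDict(frozen=True)

    intercept: float = 100.0
    slope_per_year: float = -8.33
    noise_sd: float = Field(5.0, ge=0.0)


class SyntheticConfig(BaseModel):
    """Full generator configuration; reproducible from ``seed``."""

    model_config = ConfigDict(frozen=True)

    seed: int = 0
    regions: tuple[RegionMix, ...]
    dimension_probs: Mapping[str, float]
    region_dimension_probs: Mapping[str, Mapping[str, float]] = Field(default_factory=dict)
    item_probs: Mapping[str, float] = Field(default_factory=dict)
    inclusion_prob: float = Field(ge=0.0, le=1.0)
    panel_params: Mapping[str, PanelParams] = Field(default_factory=dict)
    years: tuple[int, int] = (2013, 2020)
    trend: TrendParams = Field(default_factory=TrendParams)

    @model_validator(mode="after")
    def _check(self) -> "SyntheticConfig":
        if set(self.dimension_probs) != set(DIMENSIONS):
            raise ConfigError("dimension_probs must name exactly the four dimensions")
        for mapping in (self.dimension_probs, self.item_probs, *self.region_dimension_probs.values()):
            for k, p in mapping.items():
                if not (0.0 <= p <= 1.0):
                    raise ConfigError(f"probability for {k!r} must be in [0, 1], got {p}")
        if self.years[1] < self.years[0]:
            raise ConfigError("empty year range")
        return self

    def item_prob(self, region: str, dimension: str, item: str) -> float:
        if item in self.item_probs:
            return self.item_probs[item]
        regional = self.region_dimension_probs.get(region, {})
        return regional.get(dimension, self.dimension_probs[dimension])


def _draw_activity(rng: np.random.Generator, implementing: bool) -> tuple[int, int]:
    """Last-year notified/reviewed counts; implementing means both >= 1."""
    if implementing:
        return int(1 + rng.poisson(1.0)), int(1 + rng.poisson(0.5))
    # non-implementing: either silent, or notifying without reviewing
    if rng.random() < 0.5:
        return 0, 0
    return int(1 + rng.poisson(1.0)), 0


def gen_facility_survey(
    config: SyntheticConfig, eval_config: EvaluationConfig | None = None
) -> list[FacilityRecord]:
    """Draw one synthetic facility survey table."""
    eval_config = eval_config or EvaluationConfig()
    rng = np.random.default_rng(config.seed)
    records: list[FacilityRecord] = []
    counter = 0
    for mix in config.regions:
        for _ in range(mix.n_facilities):
            counter += 1
            level = ("primary", "secondary", "tertiary")[
                rng.choice(3, p=np.asarray(mix.level_probs))
            ]
            responses = {}
            for spec in eval_config.dimension_specs:
                for item in spec.item_ids:
                    p = config.item_prob(mix.name, spec.name, item)
                    responses[item] = int(rng.random() < p)
            notified, reviewed = _draw_activity(
                rng, bool(rng.random() < config.inclusion_prob)
            )
            records.append(
                FacilityRecord(
                    facility_id=f"F{counter:05d}",
                    region=mix.name,
                    facility_level=level,
                    location="urban" if rng.random() < mix.p_urban else "rural",
                    region_type=mix.region_type,
                    agro_zone=AGRO_ZONES[rng.choice(5, p=np.asarray(mix.agro_probs))],
                    years_implementing="ge2" if rng.random() < mix.p_ge2years else "lt2",
                    notified_last_year=notified,
                    reviewed_last_year=reviewed,
                    responses=responses,
                )
            )
    return records


def gen_count_panel(config: SyntheticConfig) -> list[RegionCounts]:
    """Draw one synthetic region count panel via the thinning chain."""
    if not config.panel_params:
        raise ConfigError("panel_params is empty; nothing to generate")
    rng = np.random.default_rng(config.seed)
    panel = []
    for region, p in config.panel_params.items():
        identified = int(rng.binomial(p.expected, p.p_identify))
        notified = int(rng.binomial(identified, p.p_notify))
        reviewed = int(rng.binomial(identified, p.p_review))
        community = int(rng.binomial(reviewed, p.p_community))
        panel.append(
            RegionCounts(
                region=region,
                expected=p.expected,
                identified=identified,
                notified=notified,
                reviewed=reviewed,
                reviewed_community=community,
                reviewed_facility=reviewed - community,
            )
        )
    return panel


def gen_trend_series(config: SyntheticConfig) -> YearlySeries:
    """Linear-plus-noise yearly series, clipped to [0, 100]."""
    rng = np.random.default_rng(config.seed)
    y0, y1 = config.years
    years = tuple(range(y0, y1 + 1))
    t = config.trend
    values = []
    for year in years:
        v = t.intercept + t.slope_per_year * (year - y0)
        if t.noise_sd > 0:
            v += rng.normal(0.0, t.noise_sd)
        values.append(float(np.clip(v, 0.0, 100.0)))
    return YearlySeries(years, tuple(values))


# ---------------------------------------------------------------------------
# Calibrated national profile

#: Regional mix of the 400 MDSR-implementing facilities in the national
#: evaluation, used as PPS weights for the surveyed cohort.
_IMPLEMENTING_MIX: dict[str, int] = {
    "Addis Ababa": 17,
    "Afar": 2,
    "Amhara": 112,
    "Benishangul-Gumuz": 10,
    "Dire Dawa": 4,
    "Gambella": 4,
    "Harari": 2,
    "Oromia": 170,
    "SNNPR": 52,
    "Somali": 2,
    "Tigray": 25,
}

_REGION_TYPES: dict[str, str] = {
    "Addis Ababa": "city_administration",
    "Dire Dawa": "city_administration",
    "Harari": "city_administration",
    "Afar": "pastoralist",
    "Somali": "pastoralist",
    "Gambella": "pastoralist",
    "Benishangul-Gumuz": "pastoralist",
    "Amhara": "agrarian",
    "Oromia": "agrarian",
    "SNNPR": "agrarian",
    "Tigray": "agrarian",
}

#: National stratifier shares of the implementing cohort.
_LEVEL_PROBS = (0.8925, 0.0725, 0.035)
_AGRO_PROBS = (0.015, 0.1425, 0.5175, 0.3175, 0.0075)
_P_URBAN = 0.405
_P_GE2YEARS = 0.785

#: National dimension mean scores used as yes-probabilities.
_DIMENSION_PROBS = {
    "structure": 0.517,
    "core": 0.200,
    "supportive": 0.384,
    "attributes": 0.696,
}


def ethiopia2020_config(
    seed: int = 0,
    n_surveyed: int = 519,
    inclusion_prob: float = 400.0 / 519.0,
) -> SyntheticConfig:
    """Generator profile calibrated to the 2020 national evaluation.

    519 surveyed facilities allocated to regions by PPS over the
    implementing-cohort mix; stratifier mixes and dimension
    yes-probabilities set to the published national shares and mean
    scores; per-region panel probabilities derived from the packaged
    2014-2020 count panel (p_identify = identified/expected and so on,
    with p_review relative to identified).
    """
    alloc = pps_allocate(n_surveyed, _IMPLEMENTING_MIX)
    regions = tuple(
        RegionMix(
            name=r,
            n_facilities=max(1, k),
            p_urban=_P_URBAN,
            level_probs=_LEVEL_PROBS,
            region_type=_REGION_TYPES[r],
            agro_probs=_AGRO_PROBS,
            p_ge2years=_P_GE2YEARS,
        )
        for r, k in alloc.items()
    )
    panel_params = {
        c.region: PanelParams(
            expected=c.expected,
            p_identify=c.identified / c.expected,
            p_notify=c.notified / c.identified,
            p_review=c.reviewed / c.identified,
            p_community=c.reviewed_community / c.reviewed,
        )
        for c in load_ethiopia_panel()
    }
    return SyntheticConfig(
        seed=seed,
        regions=regions,
        dimension_probs=dict(_DIMENSION_PROBS),
        inclusion_prob=inclusion_prob,
        panel_params=panel_params,
        years=(2013, 2020),
        trend=TrendParams(intercept=100.0, slope_per_year=-8.33, noise_sd=5.0),
    )
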