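"""Shared data model and CSV I/O for the MDSR evaluation pipeline.

The pipeline consumes two table shapes:

* a **facility survey table** — one row per surveyed health facility with
  its stratifiers (region, level, location, ...) and the binary yes/no
  item responses for the four readiness dimensions (structure 7 items,
  core 11, supportive 10, attributes 26 in five subcategories);
* a **region count panel** — one row per region with the six death-count
  aggregates (expected, identified, notified, reviewed, and the
  community/facility split of reviewed) accumulated over the evaluation
  window.

Everything is validated on read; nothing is ever imputed.  Yes/no tokens
are accepted case-insensitively as ``yes/no/1/0/true/false`` and stored
as 0/1 integers.
"""

from __future__ import annotations

import csv
import hashlib
import json
import logging
from pathlib import Path
from typing import Iterable, Literal, Mapping

from pydantic import BaseModel, ConfigDict, Field, field_validator, model_validator

from .errors import ConfigError, ConsistencyError, RecordValidationError, SchemaError

logger = logging.getLogger("mdsreval")

#: The 11 first-level administrative units covered by the evaluation
#: (nine regions and two city administrations).
REGIONS: tuple[str, ...] = (
    "Addis Ababa",
    "Afar",
    "Amhara",
    "Benishangul-Gumuz",
    "Dire Dawa",
    "Gambella",
    "Harari",
    "Oromia",
    "SNNPR",
    "Somali",
    "Tigray",
)

FACILITY_LEVELS = ("primary", "secondary", "tertiary")
LOCATIONS = ("rural", "urban")
REGION_TYPES = ("agrarian", "pastoralist", "city_administration")
#: Agro-ecological zones by altitude: desert <500 m, lowland 500-1500 m,
#: midland 1500-2300 m, highland 2300-3200 m, upper highland >=3200 m.
AGRO_ZONES = ("desert", "lowland", "midland", "highland", "upper_highland")
YEARS_IMPLEMENTING = ("lt2", "ge2")

DIMENSIONS = ("structure", "core", "supportive", "attributes")

#: Attribute subcategories and their item counts (26 items in total).
ATTRIBUTE_SUBCATEGORIES: dict[str, int] = {
    "simplicity": 7,
    "flexibility": 2,
    "acceptability": 5,
    "usefulness": 8,
    "stability": 4,
}

_TRUE_TOKENS = {"yes", "1", "true"}
_FALSE_TOKENS = {"no", "0", "false"}


def parse_binary_token(token: str) -> int:
    """Normalize a yes/no survey token to 0/1; raise on anything else."""
    t = str(token).strip().lower()
    if t in _TRUE_TOKENS:
        return 1
    if t in _FALSE_TOKENS:
        return 0
    raise RecordValidationError(f"non-binary item value {token!r}")


class DimensionSpec(BaseModel):
    """One readiness dimension: its ordered item ids and composite weight."""

    model_config = ConfigDict(frozen=True)

    name: Literal["structure", "core", "supportive", "attributes"]
    item_ids: tuple[str, ...]
    subcategories: Mapping[str, tuple[str, ...]] | None = None
    weight: float = Field(0.25, ge=0.0, le=1.0)

    _EXPECTED_COUNTS = {"structure": 7, "core": 11, "supportive": 10, "attributes": 26}

    @model_validator(mode="after")
    def _check_counts(self) -> "DimensionSpec":
        expected = self._EXPECTED_COUNTS[self.name]
        if len(self.item_ids) != expected:
            raise ConfigError(
                f"dimension {self.name!r} must have {expected} items, "
                f"got {len(self.item_ids)}"
            )
        if len(set(self.item_ids)) != len(self.item_ids):
            raise ConfigError(f"duplicate item ids in dimension {self.name!r}")
        if self.name == "attributes":
            if self.subcategories is None:
                raise ConfigError("attributes dimension requires subcategories")
            for sub, n in ATTRIBUTE_SUBCATEGORIES.items():
                got = self.subcategories.get(sub, ())
                if len(got) != n:
                    raise ConfigError(
                        f"attributes subcategory {sub!r} must have {n} items, got {len(got)}"
                    )
            flat = [i for ids in self.subcategories.values() for i in ids]
            if sorted(flat) != sorted(self.item_ids):
                raise ConfigError("subcategories must partition the attribute items")
        elif self.subcategories is not None:
            raise ConfigError("only the attributes dimension has subcategories")
        return self


def default_dimension_specs() -> tuple[DimensionSpec, ...]:
    """The standard four-dimension item layout with equal 0.25 weights.

    Item identity is positional (``structure_1..7``, ``core_1..11``,
    ``supportive_1..10``, ``attr_<subcategory>_<k>``): the survey tool's
    item wording is not part of this package, only its scoring.
    """
    subcats = {
        sub: tuple(f"attr_{sub}_{k}" for k in range(1, n + 1))
        for sub, n in ATTRIBUTE_SUBCATEGORIES.items()
    }
    attr_items = tuple(i for ids in subcats.values() for i in ids)
    return (
        DimensionSpec(name="structure", item_ids=tuple(f"structure_{k}" for k in range(1, 8))),
        DimensionSpec(name="core", item_ids=tuple(f"core_{k}" for k in range(1, 12))),
        DimensionSpec(name="supportive", item_ids=tuple(f"supportive_{k}" for k in range(1, 11))),
        DimensionSpec(name="attributes", item_ids=attr_items, subcategories=subcats),
    )


#: Default composite weights for the five performance indicators.
#: Coverage rates carry 0.3 each (representativeness), the review rate
#: 0.2 (review-committee capacity), notification rate and community
#: proportion 0.1 each (completeness and the community loop).
DEFAULT_MDSRPI_WEIGHTS: dict[str, float] = {
    "Rn": 0.1,
    "CRn": 0.3,
    "CRr": 0.3,
    "Rr": 0.2,
    "CRDp": 0.1,
}


class EvaluationConfig(BaseModel):
    """Everything configurable about one evaluation run."""

    model_config = ConfigDict(frozen=True)

    dimension_specs: tuple[DimensionSpec, ...] = Field(default_factory=default_dimension_specs)
    mdsrpi_weights: Mapping[str, float] = Field(default_factory=lambda: dict(DEFAULT_MDSRPI_WEIGHTS))
    rounding_decimals: int = 1
    alpha: float = 0.05
    seed: int = 0

    @model_validator(mode="after")
    def _check(self) -> "EvaluationConfig":
        names = [s.name for s in self.dimension_specs]
        if sorted(names) != sorted(DIMENSIONS):
            raise ConfigError(f"need exactly the four dimensions, got {names}")
        wsum = sum(s.weight for s in self.dimension_specs)
        if abs(wsum - 1.0) > 1e-9:
            raise ConfigError(f"dimension weights must sum to 1, got {wsum}")
        if set(self.mdsrpi_weights) != set(DEFAULT_MDSRPI_WEIGHTS):
            raise ConfigError("mdsrpi_weights must name exactly Rn, CRn, CRr, Rr, CRDp")
        isum = sum(self.mdsrpi_weights.values())
        if abs(isum - 1.0) > 1e-9:
            raise ConfigError(f"mdsrpi weights must sum to 1, got {isum}")
        if not (0 < self.alpha < 1):
            raise ConfigError("alpha must be in (0, 1)")
        return self

    def spec_for(self, dimension: str) -> DimensionSpec:
        for s in self.dimension_specs:
            if s.name == dimension:
                return s
        raise KeyError(dimension)

    @property
    def item_ids(self) -> tuple[str, ...]:
        return tuple(i for s in self.dimension_specs for i in s.item_ids)

    def config_hash(self) -> str:
        """Stable short hash of the configuration, for run manifests/logs."""
        payload = json.dumps(self.model_dump(mode="json"), sort_keys=True)
        return hashlib.sha256(payload.encode()).hexdigest()[:12]

    @classmethod
    def from_yaml(cls, path: str | Path) -> "EvaluationConfig":
        import yaml

        with open(path, encoding="utf-8") as fh:
            raw = yaml.safe_load(fh) or {}
        return cls.model_validate(raw)


class FacilityRecord(BaseModel):
    """One surveyed facility: stratifiers plus binary item responses."""

    model_config = ConfigDict(frozen=True)

    facility_id: str
    region: str
    facility_level: Literal["primary", "secondary", "tertiary"]
    location: Literal["rural", "urban"]
    region_type: Literal["agrarian", "pastoralist", "city_administration"]
    agro_zone: Literal["desert", "lowland", "midland", "highland", "upper_highland"]
    years_implementing: Literal["lt2", "ge2"]
    notified_last_year: int = Field(ge=0)
    reviewed_last_year: int = Field(ge=0)
    responses: Mapping[str, int]

    @field_validator("region")
    @classmethod
    def _check_region(cls, v: str) -> str:
        if v not in REGIONS:
            raise ValueError(f"unknown region {v!r}; expected one of {REGIONS}")
        return v

    @field_validator("responses")
    @classmethod
    def _check_binary(cls, v: Mapping[str, int]) -> Mapping[str, int]:
        for item, val in v.items():
            if val not in (0, 1):
                raise ValueError(f"response for {item!r} must be 0/1, got {val!r}")
        return dict(v)

    @property
    def is_implementing(self) -> bool:
        """Notified and reviewed at least one maternal death in the year
        before the survey — the inclusion rule for the readiness analysis."""
        return self.notified_last_year >= 1 and self.reviewed_last_year >= 1


class RegionCounts(BaseModel):
    """The six death-count aggregates for one region over the window."""

    model_config = ConfigDict(frozen=True)

    region: str
    expected: int = Field(ge=0)
    identified: int = Field(ge=0)
    notified: int = Field(ge=0)
    reviewed: int = Field(ge=0)
    reviewed_community: int = Field(ge=0)
    reviewed_facility: int = Field(ge=0)

    @model_validator(mode="after")
    def _check_split(self) -> "RegionCounts":
        if self.reviewed_community + self.reviewed_facility != self.reviewed:
            raise ConsistencyError(
                f"region {self.region!r}: reviewed_community ({self.reviewed_community}) "
                f"+ reviewed_facility ({self.reviewed_facility}) != reviewed ({self.reviewed})"
            )
        return self


# ---------------------------------------------------------------------------
# CSV I/O

_STRATIFIER_COLUMNS = (
    "facility_id",
    "region",
    "facility_level",
    "location",
    "region_type",
    "agro_zone",
    "years_implementing",
    "notified_last_year",
    "reviewed_last_year",
)


def read_facility_table(
    path: str | Path, config: EvaluationConfig | None = None
) -> list[FacilityRecord]:
    """Read and validate a facility survey CSV.

    The header must carry every stratifier column and one column per item
    id of the active dimension specs.  Row order is preserved.
    """
    config = config or EvaluationConfig()
    items = config.item_ids
    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh)
        header = reader.fieldnames or []
        for col in (*_STRATIFIER_COLUMNS, *items):
            if col not in header:
                raise SchemaError(f"missing required column {col!r}")
        records: list[FacilityRecord] = []
        for idx, row in enumerate(reader):
            try:
                responses = {item: parse_binary_token(row[item]) for item in items}
                rec = FacilityRecord(
                    facility_id=row["facility_id"],
                    region=row["region"],
                    facility_level=row["facility_level"],
                    location=row["location"],
                    region_type=row["region_type"],
                    agro_zone=row["agro_zone"],
                    years_implementing=row["years_implementing"],
                    notified_last_year=int(row["notified_last_year"]),
                    reviewed_last_year=int(row["reviewed_last_year"]),
                    responses=responses,
                )
            except (RecordValidationError, ValueError) as exc:
                raise RecordValidationError(
                    f"row {idx}: {exc}", row=idx
                ) from exc
            records.append(rec)
    logger.info("read_facility_table: %d records from %s", len(records), path)
    return records


def write_facility_table(
    records: Iterable[FacilityRecord],
    path: str | Path,
    config: EvaluationConfig | None = None,
) -> None:
    """Write facility records back to CSV (lossless round-trip)."""
    config = config or EvaluationConfig()
    items = config.item_ids
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow([*_STRATIFIER_COLUMNS, *items])
        for rec in records:
            writer.writerow(
                [
                    rec.facility_id,
                    rec.region,
                    rec.facility_level,
                    rec.location,
                    rec.region_type,
                    rec.agro_zone,
                    rec.years_implementing,
                    rec.notified_last_year,
                    rec.reviewed_last_year,
                    *(rec.responses[i] for i in items),
                ]
            )


def filter_implementing(records: list[FacilityRecord]) -> list[FacilityRecord]:
    """Keep facilities that notified AND reviewed >= 1 death in the year
    before the survey.  Idempotent; logs kept/dropped counts."""
    kept = [r for r in records if r.is_implementing]
    logger.info(
        "filter_implementing: kept %d, dropped %d", len(kept), len(records) - len(kept)
    )
    return kept


_PANEL_COLUMNS = (
    "region",
    "expected",
    "identified",
    "notified",
    "reviewed",
    "reviewed_community",
    "reviewed_facility",
)


def read_count_panel(path: str | Path) -> list[RegionCounts]:
    """Read and validate a region count panel CSV."""
    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh)
        header = reader.fieldnames or []
        for col in _PANEL_COLUMNS:
            if col not in header:
                raise SchemaError(f"missing required column {col!r}")
        panel: list[RegionCounts] = []
        for idx, row in enumerate(reader):
            try:
                panel.append(
                    RegionCounts(
                        region=row["region"],
                        **{c: int(row[c]) for c in _PANEL_COLUMNS[1:]},
                    )
                )
            except ConsistencyError:
                raise
            except ValueError as exc:
                raise RecordValidationError(f"row {idx}: {exc}", row=idx) from exc
    logger.info("read_count_panel: %d regions from %s", len(panel), path)
    return panel


def write_count_panel(panel: Iterable[RegionCounts], path: str | Path) -> None:
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(_PANEL_COLUMNS)
        for c in panel:
            writer.writerow([c.region, *(getattr(c, col) for col in _PANEL_COLUMNS[1:])])


# ---------------------------------------------------------------------------
# Packaged national count panel (Ethiopia, 2014-2020)

#: The printed national total of expected maternal deaths.  The printed
#: per-region values sum to 60639; national computations use this printed
#: total by default, with a switch to recompute from the regional rows.
PRINTED_EXPECTED_TOTAL = 60686

_TABLE8_PATH = Path(__file__).parent / "data" / "ethiopia_region_counts_2014_2020.csv"


def load_ethiopia_panel() -> list[RegionCounts]:
    """The packaged Ethiopian national count panel, 2014-2020 (11 regions)."""
    return read_count_panel(_TABLE8_PATH)
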