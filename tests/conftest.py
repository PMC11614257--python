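import pytest

from mdsreval import EvaluationConfig, FacilityRecord


@pytest.fixture(scope="session")
def config() -> EvaluationConfig:
    return EvaluationConfig()


def make_record(
    config: EvaluationConfig,
    yes_counts: dict[str, int] | None = None,
    all_yes: bool = False,
    **overrides,
) -> FacilityRecord:
    """Build a record whose first ``yes_counts[dim]`` items of each
    dimension are yes (ordered item ids make this deterministic)."""
    yes_counts = yes_counts or {}
    responses = {}
    for spec in config.dimension_specs:
        k = len(spec.item_ids) if all_yes else yes_counts.get(spec.name, 0)
        for i, item in enumerate(spec.item_ids):
            responses[item] = 1 if i < k else 0
    defaults = dict(
        facility_id="F1",
        region="Oromia",
        facility_level="primary",
        location="rural",
        region_type="agrarian",
        agro_zone="midland",
        years_implementing="ge2",
        notified_last_year=1,
        reviewed_last_year=1,
        responses=responses,
    )
    defaults.update(overrides)
    return FacilityRecord(**defaults)


@pytest.fixture()
def record_factory(config):
    def _make(**kw):
        return make_record(config, **kw)

    return _make
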