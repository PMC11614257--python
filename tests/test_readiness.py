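"""Dimension scoring, the readiness composite, ratings and summaries."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from mdsreval import (
    FacilityReadinessModel,
    classify_ephi,
    overall_readiness,
    score_dimension,
    score_facility,
    summarize_group,
)
from mdsreval.errors import ConfigError, MdsrEvalError, RecordValidationError
from mdsreval.readiness import DimensionScore, display_round

from conftest import make_record


def _scores(vals):
    names = ["structure", "core", "supportive", "attributes"]
    return [DimensionScore(n, 0, v, 0.25 * v) for n, v in zip(names, vals)]


class TestScoreDimension:
    @pytest.mark.parametrize("dim,k,total,expected", [
        ("structure", 4, 7, 100 * 4 / 7),
        ("core", 0, 11, 0.0),
        ("supportive", 10, 10, 100.0),
        ("attributes", 26, 26, 100.0),
    ])
    def test_fraction_of_yes(self, config, dim, k, total, expected):
        rec = make_record(config, yes_counts={dim: k})
        ds = score_dimension(rec, config.spec_for(dim))
        assert ds.raw_total == k
        assert ds.score_pct == pytest.approx(expected)
        assert ds.weighted_pct == pytest.approx(0.25 * expected)

    def test_missing_item_raises_no_imputation(self, config, record_factory):
        rec = record_factory(all_yes=True)
        broken = rec.model_copy(
            update={"responses": {k: v for k, v in rec.responses.items()
                                  if k != "core_3"}}
        )
        with pytest.raises(RecordValidationError, match="core_3"):
            score_dimension(broken, config.spec_for("core"))


class TestOverallReadiness:
    def test_published_national_composite(self):
        """Equal-weight composite of the four national dimension means."""
        overall = overall_readiness(_scores([51.7, 20.0, 38.4, 69.6]))
        assert overall == pytest.approx(44.925)
        assert display_round(overall, 1) == 44.9

    def test_all_hundred(self):
        assert overall_readiness(_scores([100, 100, 100, 100])) == pytest.approx(100.0)

    def test_degenerate_weights(self):
        w = {"structure": 1.0, "core": 0.0, "supportive": 0.0, "attributes": 0.0}
        assert overall_readiness(_scores([80, 10, 20, 30]), w) == pytest.approx(80.0)

    def test_bad_weight_sum_rejected(self):
        w = {"structure": 0.5, "core": 0.5, "supportive": 0.5, "attributes": 0.5}
        with pytest.raises(ConfigError):
            overall_readiness(_scores([1, 2, 3, 4]), w)

    @given(st.lists(st.floats(0, 100), min_size=4, max_size=4))
    @settings(max_examples=50, deadline=None)
    def test_equal_weights_equal_mean(self, vals):
        assert overall_readiness(_scores(vals)) == pytest.approx(np.mean(vals))


class TestEphiBands:
    @pytest.mark.parametrize("score,label", [
        (0.0, "not_functioning"),
        (20.0, "not_functioning"),       # national core mean
        (38.4, "less_functioning"),      # national supportive mean
        (44.9, "less_functioning"),      # national overall
        (50.0, "less_functioning"),
        (50.4, "fairly_functioning"),    # fractional gap in printed bands
        (51.7, "fairly_functioning"),    # national structure mean
        (69.6, "fairly_functioning"),    # national attributes mean
        (75.0, "fairly_functioning"),
        (90.0, "effectively_functioning"),
        (90.1, "very_effectively_functioning"),
        (100.0, "very_effectively_functioning"),
    ])
    def test_band_map(self, score, label):
        assert classify_ephi(score) == label

    def test_out_of_domain(self):
        for bad in (-0.1, 100.1):
            with pytest.raises(MdsrEvalError):
                classify_ephi(bad)

    @given(st.floats(0, 100), st.floats(0, 100))
    @settings(max_examples=100, deadline=None)
    def test_monotone_total_step_function(self, a, b):
        order = ["not_functioning", "less_functioning", "fairly_functioning",
                 "effectively_functioning", "very_effectively_functioning"]
        ra, rb = order.index(classify_ephi(a)), order.index(classify_ephi(b))
        if a <= b:
            assert ra <= rb


class TestMonotonicity:
    @given(st.integers(0, 6), st.data())
    @settings(max_examples=30, deadline=None)
    def test_one_more_yes_never_decreases_scores(self, k, data):
        """Flipping one item from no to yes cannot lower any score."""
        from mdsreval import EvaluationConfig

        config = EvaluationConfig()
        counts = {
            d: data.draw(st.integers(0, n), label=d)
            for d, n in [("structure", 6), ("core", 11), ("supportive", 10),
                         ("attributes", 26)]
        }
        rec = make_record(config, yes_counts=counts)
        res = score_facility(rec, config)
        bumped = make_record(config, yes_counts={**counts, "structure": counts.get("structure", 0) + 1})
        res2 = score_facility(bumped, config)
        for d1, d2 in zip(res.dimension_scores, res2.dimension_scores):
            assert d2.score_pct >= d1.score_pct
        assert res2.overall_pct >= res.overall_pct


class TestSummarizeGroup:
    def test_published_national_interval(self):
        """mean 44.9, SE 0.52 -> 95% CI (43.9, 45.9) at one decimal."""
        mean, se = 44.9, 0.52
        lo, hi = mean - 1.96 * se, mean + 1.96 * se
        assert display_round(lo, 1) == 43.9
        assert display_round(hi, 1) == 45.9

    def test_single_observation_has_no_ci(self):
        gs = summarize_group([50.0], "solo")
        assert gs.mean_pct == 50.0
        assert gs.se_pct is None and gs.ci_low_pct is None

    def test_empty_group_raises(self):
        with pytest.raises(MdsrEvalError):
            summarize_group([], "none")

    def test_ci_symmetric_about_mean(self):
        rng = np.random.default_rng(3)
        gs = summarize_group(rng.uniform(0, 100, 40).tolist())
        assert gs.ci_high_pct - gs.mean_pct == pytest.approx(gs.mean_pct - gs.ci_low_pct)

    def test_monte_carlo_mean_recovery(self):
        """10,000 draws from a known normal: mean within 3 SE of truth."""
        rng = np.random.default_rng(42)
        draws = rng.normal(60.0, 12.0, 10_000)
        gs = summarize_group(draws.tolist())
        assert abs(gs.mean_pct - 60.0) < 3 * gs.se_pct


class TestModelResults:
    def test_fit_shapes_and_item_order_invariance(self, config, record_factory):
        recs = [
            make_record(config, yes_counts={"structure": 3, "core": 5,
                                            "supportive": 2, "attributes": 10},
                        facility_id=f"F{i}")
            for i in range(5)
        ]
        res = FacilityReadinessModel(recs, config).fit()
        assert len(res.frame) == 5
        assert set(res.score_columns) <= set(res.frame.columns)
        # overall equals the mean of the four dimension columns (equal weights)
        mean4 = res.frame[["structure", "core", "supportive", "attributes"]].mean(axis=1)
        assert np.allclose(res.frame["overall"], mean4)

    def test_summarize_by_stratifier(self, config):
        recs = [
            make_record(config, yes_counts={"structure": 3 + (i % 2)},
                        facility_id=f"F{i}",
                        location="urban" if i % 2 else "rural")
            for i in range(10)
        ]
        res = FacilityReadinessModel(recs, config).fit()
        tab = res.summarize_by("location", "structure")
        assert set(tab["group"]) == {"urban", "rural"}
        assert (tab["n"] == 5).all()

    def test_summary_text_mentions_rating(self, config, record_factory):
        res = FacilityReadinessModel([record_factory(all_yes=True)], config).fit()
        out = res.summary()
        assert "very_effectively_functioning" in out
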