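"""End-to-end evaluation pipeline and report rendering.

``run_full_evaluation`` wires the stages together — facility readiness
scoring with functionality ratings, group comparisons per stratifier,
the per-region and national performance index, and the yearly trend
test — and returns a :class:`ResultBundle` whose manifest records input
digests, the configuration hash and per-stage row counts.  Any stage
failure aborts with the stage name attached.

``render_report`` writes the bundle as CSV, JSON (full precision) or a
markdown report with one-decimal display rounding.
"""

from __future__ import annotations

import csv as _csv
import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass
from datetime import datetime, timezone
from pathlib import Path

import pandas as pd

from . import __version__
from .datamodel import (
    EvaluationConfig,
    filter_implementing,
    read_count_panel,
    read_facility_table,
)
from .errors import MdsrEvalError
from .groupstats import ComparisonResult, bonferroni_pairwise, two_group_test
from .perfindex import PerformanceIndexModel
from .readiness import STRATIFIERS, FacilityReadinessModel, display_round
from .trend import MannKendallTrend, TrendResult, YearlySeries

logger = logging.getLogger("mdsreval")

__all__ = ["RunManifest", "ResultBundle", "run_full_evaluation", "render_report", "read_yearly_series"]


@dataclass(frozen=True)
class RunManifest:
    timestamp: str
    config_hash: str
    input_digests: dict[str, str]
    version: str
    stage_rows: dict[str, int]


@dataclass
class ResultBundle:
    per_facility: pd.DataFrame
    group_summaries: dict[str, pd.DataFrame]  # stratifier -> summary table
    comparisons: dict[str, list[ComparisonResult]]
    index_table: pd.DataFrame
    trend: TrendResult | None
    manifest: RunManifest


def _digest(path: str | Path) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()[:16]


def read_yearly_series(path: str | Path) -> YearlySeries:
    """Read a 2-column (year, value) CSV into a yearly series."""
    years, values = [], []
    with open(path, newline="", encoding="utf-8") as fh:
        for row in _csv.DictReader(fh):
            years.append(int(row["year"]))
            values.append(float(row["value"]))
    return YearlySeries(tuple(years), tuple(values))


class StageError(MdsrEvalError):
    def __init__(self, stage: str, cause: Exception):
        self.stage = stage
        super().__init__(f"stage {stage!r} failed: {cause}")


def _stratifier_comparisons(
    frame: pd.DataFrame, stratifier: str, score: str, alpha: float
) -> list[ComparisonResult]:
    groups = {
        str(label): sub[score].tolist()
        for label, sub in frame.groupby(stratifier, observed=True)
    }
    testable = {k: v for k, v in groups.items() if len(v) >= 2}
    if len(testable) < 2:
        return []
    if len(testable) == 2:
        (la, va), (lb, vb) = sorted(testable.items())
        return [two_group_test(va, vb, alpha=alpha, label=f"{la} vs {lb}")]
    try:
        return bonferroni_pairwise(testable, alpha=alpha)
    except MdsrEvalError:  # omnibus ANOVA not significant
        return []


def run_full_evaluation(
    facility_csv: str | Path,
    panel_csv: str | Path | None = None,
    trend_csv: str | Path | None = None,
    config: EvaluationConfig | None = None,
    expected_total: int | None = None,
    apply_implementing_filter: bool = True,
) -> ResultBundle:
    """Run every pipeline stage on the supplied inputs."""
    config = config or EvaluationConfig()
    stage_rows: dict[str, int] = {}
    digests: dict[str, str] = {}

    try:
        records = read_facility_table(facility_csv, config)
        digests["facility_csv"] = _digest(facility_csv)
        stage_rows["facilities_read"] = len(records)
        if apply_implementing_filter:
            records = filter_implementing(records)
        stage_rows["facilities_analyzed"] = len(records)
        results = FacilityReadinessModel(records, config).fit()
    except Exception as exc:
        raise StageError("readiness", exc) from exc

    try:
        summaries = {s: results.summarize_by(s) for s in STRATIFIERS}
        comparisons = {
            s: _stratifier_comparisons(results.frame, s, "overall", config.alpha)
            for s in STRATIFIERS
        }
    except Exception as exc:
        raise StageError("compare", exc) from exc

    index_table = pd.DataFrame()
    if panel_csv is not None:
        try:
            panel = read_count_panel(panel_csv)
            digests["panel_csv"] = _digest(panel_csv)
            stage_rows["panel_regions"] = len(panel)
            index_table = PerformanceIndexModel(
                panel, config.mdsrpi_weights, expected_total
            ).fit().table
        except Exception as exc:
            raise StageError("mdsrpi", exc) from exc

    trend_result = None
    if trend_csv is not None:
        try:
            series = read_yearly_series(trend_csv)
            digests["trend_csv"] = _digest(trend_csv)
            stage_rows["trend_years"] = len(series)
            trend_result = MannKendallTrend(series.years, series.values).fit(
                alpha=config.alpha
            )
        except Exception as exc:
            raise StageError("trend", exc) from exc

    manifest = RunManifest(
        timestamp=datetime.now(timezone.utc).isoformat(),
        config_hash=config.config_hash(),
        input_digests=digests,
        version=__version__,
        stage_rows=stage_rows,
    )
    return ResultBundle(
        per_facility=results.frame,
        group_summaries=summaries,
        comparisons=comparisons,
        index_table=index_table,
        trend=trend_result,
        manifest=manifest,
    )


def _bundle_payload(bundle: ResultBundle) -> dict:
    return {
        "manifest": dataclasses.asdict(bundle.manifest),
        "per_facility": bundle.per_facility.to_dict(orient="records"),
        "group_summaries": {
            s: t.to_dict(orient="records") for s, t in bundle.group_summaries.items()
        },
        "comparisons": {
            s: [dataclasses.asdict(c) for c in cs] for s, cs in bundle.comparisons.items()
        },
        "index_table": bundle.index_table.to_dict(orient="records"),
        "trend": dataclasses.asdict(bundle.trend) if bundle.trend else None,
    }


def render_report(
    bundle: ResultBundle, out_dir: str | Path, format: str = "csv"
) -> list[Path]:
    """Write the bundle to ``out_dir``; returns the files written.

    ``json`` keeps full precision; ``csv``/``markdown`` display-round
    percentage columns to one decimal.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []

    if format == "json":
        path = out / "results.json"
        path.write_text(json.dumps(_bundle_payload(bundle), indent=2, default=str))
        written.append(path)
    elif format == "csv":
        pf = out / "per_facility.csv"
        bundle.per_facility.to_csv(pf, index=False)
        written.append(pf)
        for strat, table in bundle.group_summaries.items():
            p = out / f"summary_{strat}.csv"
            table.to_csv(p, index=False)
            written.append(p)
        if not bundle.index_table.empty:
            p = out / "performance_index.csv"
            rounded = bundle.index_table.copy()
            for col in rounded.select_dtypes("float").columns:
                rounded[col] = rounded[col].map(lambda x: display_round(x, 1))
            rounded.to_csv(p, index=False)
            written.append(p)
    elif format == "markdown":
        path = out / "report.md"
        parts = ["# MDSR evaluation report", ""]
        if not bundle.index_table.empty:
            rounded = bundle.index_table.copy()
            for col in rounded.select_dtypes("float").columns:
                rounded[col] = rounded[col].map(lambda x: display_round(x, 1))
            parts += ["## Performance indicators by region", "", rounded.to_markdown(index=False), ""]
        for strat, table in bundle.group_summaries.items():
            rounded = table.copy()
            for col in rounded.select_dtypes("float").columns:
                rounded[col] = rounded[col].map(lambda x: display_round(x, 1))
            parts += [f"## Readiness by {strat}", "", rounded.to_markdown(index=False), ""]
        if bundle.trend:
            t = bundle.trend
            parts += [
                "## Trend",
                "",
                f"Mann-Kendall S = {t.S}, z = {t.z:.3f}, p = {t.p_value:.4g}; "
                f"Sen's slope = {t.sen_slope:.3f} "
                f"(95% CI {t.slope_ci_low:.3f} to {t.slope_ci_high:.3f}) per year",
                "",
            ]
        path.write_text("\n".join(parts))
        written.append(path)
    else:
        raise MdsrEvalError(f"unknown report format {format!r}")

    manifest_path = out / "manifest.json"
    manifest_path.write_text(
        json.dumps(
            {**dataclasses.asdict(bundle.manifest), "files": [f.name for f in written]},
            indent=2,
        )
    )
    written.append(manifest_path)
    return written
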