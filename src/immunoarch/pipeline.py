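"""Per-slide and cohort orchestration.

``run_slide`` feeds one slide's coordinates independently to the two
analysis branches — moving-window point-process analysis and cluster
morphometrics — then summarizes intra-tumoral heterogeneity and, when
annotations are present, per-region outcome-candidate metrics.
``run_cohort`` aggregates slides into inter-tumoral QCoD tables and, when
outcomes are supplied, responder comparisons and RECIST trend tests.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import cluster_morphometrics as cm
from . import heterogeneity as het
from . import regions_outcomes as ro
from . import spatial_pointprocess as spp
from .core_io import OutcomeRecord, PointPattern, RegionMap, UndefinedMetricError, WindowGrid

logger = logging.getLogger("immunoarch.pipeline")


@dataclass
class RunConfig:
    """All pipeline thresholds in one serializable place (values echo the
    workflow defaults: 0.5 mm windows with 0.25 mm steps, alpha 0.05,
    minPts 30 / K 4, alpha-shape start 10 um, 250 um band half-width,
    50-cell floor for max cluster density)."""

    x_window: float = 500.0
    y_window: float = 500.0
    x_step: float = 250.0
    y_step: float = 250.0
    n_min: int = spp.DEFAULT_N_MIN
    csr_alpha: float = spp.DEFAULT_ALPHA
    ce_correction: str = "donnelly"
    min_pts: int = cm.DEFAULT_MIN_PTS
    k: int = cm.DEFAULT_K
    alpha_start: float = cm.DEFAULT_ALPHA_START
    ellipse_level: float = cm.DEFAULT_ELLIPSE_LEVEL
    band_halfwidth: float = ro.DEFAULT_BAND_HALFWIDTH
    min_cells: int = ro.DEFAULT_MIN_CELLS
    quartile_method: str = "linear"
    seed: int = 0

    @property
    def grid(self) -> WindowGrid:
        return WindowGrid(self.x_window, self.y_window, self.x_step, self.y_step)

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(dataclasses.asdict(self), fh)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            return cls(**(yaml.safe_load(fh) or {}))


@dataclass
class SlideResult:
    patient_id: str
    window_table: pd.DataFrame
    cluster_table: pd.DataFrame
    cluster_records: list
    summary: het.SlideSummary | None
    region_table: pd.DataFrame | None = None
    errors: list[str] = field(default_factory=list)


def run_slide(
    pp: PointPattern,
    regions: RegionMap | None = None,
    config: RunConfig | None = None,
    patient_id: str = "",
) -> SlideResult:
    """Full single-slide analysis; stage errors are recorded, not raised."""
    config = config or RunConfig()
    errors: list[str] = []
    window_table = pd.DataFrame()
    cluster_table = pd.DataFrame()
    records: list = []
    if pp.n == 0:
        logger.warning("slide %s has zero cells; emitting empty tables", patient_id)
        return SlideResult(patient_id, window_table, cluster_table, [], None,
                           errors=["zero cells"])
    try:
        window_results = spp.analyze_windows(
            pp, config.grid, alpha=config.csr_alpha, n_min=config.n_min,
            correction=config.ce_correction,
        )
        window_table = spp.windows_table(window_results)
    except Exception as exc:  # stage isolation: one branch failing must not kill the other
        errors.append(f"point-process branch: {exc}")
        logger.exception("slide %s point-process branch failed", patient_id)
    try:
        records, _ = cm.analyze_clusters(
            pp, min_pts=config.min_pts, k=config.k,
            alpha_start=config.alpha_start, level=config.ellipse_level,
        )
        cluster_table = cm.clusters_table(records)
    except Exception as exc:
        errors.append(f"morphometrics branch: {exc}")
        logger.exception("slide %s morphometrics branch failed", patient_id)

    summary = None
    try:
        summary = het.intra_tumoral(
            window_table if len(window_table) else None,
            cluster_table if len(cluster_table) else None,
            patient_id=patient_id, method=config.quartile_method,
        )
    except UndefinedMetricError as exc:
        errors.append(f"heterogeneity: {exc}")

    region_table = None
    if regions is not None and regions.polygons:
        try:
            ro.build_invasive_front(regions, band_halfwidth=config.band_halfwidth)
            region_table = ro.region_metric_table(
                pp, regions, records, patient_id=patient_id, min_cells=config.min_cells,
            )
        except Exception as exc:
            errors.append(f"regions: {exc}")
            logger.exception("slide %s region assignment failed", patient_id)
    return SlideResult(patient_id, window_table, cluster_table, records, summary,
                       region_table, errors)


#: per-region metrics tested against outcomes
OUTCOME_METRICS = ("avg_density_mm2", "max_cluster_density_mm2",
                   "n_circular", "n_elongated", "n_clusters")


@dataclass
class CohortResult:
    inter_qcod: pd.DataFrame
    heterogeneity: pd.DataFrame
    outcome_tests: pd.DataFrame | None = None
    unmatched_patients: list[str] = field(default_factory=list)


def run_cohort(
    slide_results: list[SlideResult],
    outcomes: list[OutcomeRecord] | None = None,
    config: RunConfig | None = None,
) -> CohortResult:
    """Aggregate slides: inter-tumoral QCoD and (optionally) outcome tests."""
    config = config or RunConfig()
    summaries = [s.summary for s in slide_results if s.summary is not None]
    if len(summaries) < 2:
        raise UndefinedMetricError("cohort analysis requires >= 2 analyzable slides")
    inter = het.inter_tumoral(summaries, method=config.quartile_method)
    het_table = het.heterogeneity_table(summaries, method=config.quartile_method)
    if outcomes is None:
        return CohortResult(inter, het_table)

    slide_ids = {s.patient_id for s in slide_results}
    matched = [o for o in outcomes if o.patient_id in slide_ids]
    unmatched = sorted({o.patient_id for o in outcomes} - slide_ids)
    if unmatched:
        logger.warning("outcome ids with no slide: %s", unmatched)
    flags = ro.group_responders(matched)

    region_tables = [s.region_table for s in slide_results if s.region_table is not None]
    rows = []
    if region_tables:
        all_regions = pd.concat(region_tables, ignore_index=True)
        for region in all_regions["region"].unique():
            sub = all_regions[all_regions["region"] == region]
            for metric in OUTCOME_METRICS:
                values = dict(zip(sub["patient_id"], sub[metric].astype(float)))
                try:
                    W, p = ro.compare_groups(values, flags)
                    rows.append({"metric": metric, "region": region,
                                 "test": "wilcoxon_rank_sum", "statistic": W, "p_value": p})
                except UndefinedMetricError as exc:
                    logger.info("%s / %s rank-sum skipped: %s", metric, region, exc)
                try:
                    groups = ro.recist_groups(values, matched)
                    J, p = ro.trend_test(groups, seed=config.seed)
                    rows.append({"metric": metric, "region": region,
                                 "test": "jonckheere_trend", "statistic": J, "p_value": p})
                except UndefinedMetricError as exc:
                    logger.info("%s / %s trend test skipped: %s", metric, region, exc)
    tests = pd.DataFrame(rows)
    return CohortResult(inter, het_table, tests, unmatched)
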