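"""Intra- and inter-tumoral heterogeneity via the quartile coefficient of
dispersion, QCoD = (Q3 - Q1) / (Q3 + Q1).

QCoD is scale-free and distribution-free, which suits metric arrays that
are skewed and vary over orders of magnitude across a slide.  Intra-tumoral
heterogeneity is the QCoD of a metric across windows (or clusters) within
one slide; each patient is then summarized by the per-metric median, and
inter-tumoral heterogeneity is the QCoD of those medians across patients.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core_io import UndefinedMetricError

logger = logging.getLogger("immunoarch.heterogeneity")

#: per-window metrics entering the point-process heterogeneity summary
WINDOW_METRICS = ("density_mm2", "mu", "mean_dist", "cluster_area_mm2")
#: per-cluster metrics entering the morphometric heterogeneity summary
CLUSTER_METRICS = (
    "density_mm2", "n", "A_alpha_mm2", "A_ellipse_mm2", "f_circ", "f_conv", "e",
)


@dataclass
class MetricDistribution:
    """Values of one metric with quartiles and QCoD."""

    metric_name: str
    values: np.ndarray
    Q1: float
    Q2: float
    Q3: float
    qcod: float


@dataclass
class SlideSummary:
    """Per-slide (per-patient) heterogeneity summary.

    ``distributions`` holds the intra-tumoral metric distributions;
    ``medians`` holds the per-metric median used as the patient's proxy
    value for inter-tumoral comparison.
    """

    patient_id: str
    distributions: dict[str, MetricDistribution] = field(default_factory=dict)
    medians: dict[str, float] = field(default_factory=dict)


def qcod(values, method: str = "linear") -> float:
    """Quartile coefficient of dispersion (Q3 - Q1)/(Q3 + Q1).

    Quartiles use linear interpolation between order statistics by default
    (numpy's ``method='linear'``, the common "type 7" convention); the
    convention is switchable because QCoD at small n is sensitive to it.
    """
    vals = np.asarray(values, dtype=float)
    vals = vals[np.isfinite(vals)]
    if vals.size < 2:
        raise UndefinedMetricError("QCoD requires at least 2 finite values")
    q1, q3 = np.percentile(vals, [25, 75], method=method)
    if q1 + q3 == 0:
        raise UndefinedMetricError("QCoD undefined: Q1 + Q3 = 0")
    return float((q3 - q1) / (q3 + q1))


def metric_distribution(name: str, values, method: str = "linear") -> MetricDistribution:
    vals = np.asarray(values, dtype=float)
    vals = vals[np.isfinite(vals)]
    if vals.size < 2:
        raise UndefinedMetricError(f"metric {name!r} has fewer than 2 finite values")
    q1, q2, q3 = np.percentile(vals, [25, 50, 75], method=method)
    return MetricDistribution(
        metric_name=name, values=vals, Q1=float(q1), Q2=float(q2), Q3=float(q3),
        qcod=qcod(vals, method=method),
    )


def intra_tumoral(
    window_table: pd.DataFrame | None,
    cluster_table: pd.DataFrame | None,
    patient_id: str = "",
    method: str = "linear",
) -> SlideSummary:
    """Per-slide QCoD for every window and cluster metric.

    Point-process metrics are taken only from windows with a converged
    Thomas fit (density uses all tested windows); cluster metrics only from
    non-degenerate clusters.  Metrics with fewer than 2 values are logged
    and omitted.
    """
    summary = SlideSummary(patient_id=patient_id)

    def add(prefix: str, name: str, values) -> None:
        try:
            dist = metric_distribution(f"{prefix}{name}", values, method=method)
        except UndefinedMetricError as exc:
            logger.info("slide %s: %s", patient_id, exc)
            return
        summary.distributions[dist.metric_name] = dist
        summary.medians[dist.metric_name] = dist.Q2

    if window_table is not None and len(window_table):
        fitted = window_table[window_table.get("converged", False) == True]  # noqa: E712
        for name in WINDOW_METRICS:
            source = window_table if name == "density_mm2" else fitted
            if name in source.columns:
                add("window_", name, source[name].to_numpy())
    if cluster_table is not None and len(cluster_table):
        good = cluster_table[cluster_table["excluded_reason"].isna()] \
            if "excluded_reason" in cluster_table.columns else cluster_table
        for name in CLUSTER_METRICS:
            if name in good.columns:
                add("cluster_", name, good[name].to_numpy())
    if not summary.distributions:
        raise UndefinedMetricError(f"slide {patient_id!r}: no metric has >= 2 values")
    return summary


def inter_tumoral(summaries: list[SlideSummary], method: str = "linear") -> pd.DataFrame:
    """QCoD of per-patient medians for each metric, across >= 2 slides."""
    if len(summaries) < 2:
        raise UndefinedMetricError("inter-tumoral QCoD requires at least 2 slides")
    metrics = sorted({m for s in summaries for m in s.medians})
    rows = []
    for m in metrics:
        medians = np.array([s.medians[m] for s in summaries if m in s.medians])
        if medians.size < 2:
            logger.info("metric %s present in < 2 slides; skipped", m)
            continue
        rows.append({"metric": m, "n_slides": medians.size, "qcod": qcod(medians, method=method)})
    return pd.DataFrame(rows)


def heterogeneity_table(
    summaries: list[SlideSummary], method: str = "linear"
) -> pd.DataFrame:
    """Tidy long table: patient_id, metric, level (intra/inter), qcod."""
    rows = [
        {"patient_id": s.patient_id, "metric": name, "level": "intra", "qcod": dist.qcod}
        for s in summaries
        for name, dist in s.distributions.items()
    ]
    if len(summaries) >= 2:
        inter = inter_tumoral(summaries, method=method)
        rows += [
            {"patient_id": "", "metric": r.metric, "level": "inter", "qcod": r.qcod}
            for r in inter.itertuples()
        ]
    return pd.DataFrame(rows)
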