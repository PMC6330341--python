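"""Tissue context, cluster phenotypes, and outcome association.

The invasive front is the band extending ``band_halfwidth`` (default 250
um) on both sides of the boundary where tumor meets non-tumor tissue.
Cells are labeled intratumoral / peritumoral / stromal by point-in-polygon
tests with the front taking precedence; clusters inherit a tissue
association from their member cells (any peritumoral cell -> invasive
front; else any intratumoral cell -> tumor; else normal).

Cluster phenotypes follow fixed shape-descriptor thresholds:

* circular  (lymphoid-follicle-like): e < 0.8 AND f_conv > 0.8 AND f_circ > 0.5
* elongated (invasive-front-like):    e > 0.9 OR  f_conv < 0.3 OR  f_circ < 0.3

Outcome grouping: MSI patients respond iff RECIST is CR or PR; for MSS
patients stable disease also counts as response.  Group comparisons use
the two-sided Wilcoxon rank-sum test (exact for small tie-free samples);
ordered RECIST trends use the Jonckheere-Terpstra test with a permutation
p-value.
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
import shapely
from scipy.stats import mannwhitneyu
from shapely.geometry import MultiPolygon

from .cluster_morphometrics import ClusterRecord, ShapeDescriptors
from .core_io import (
    OutcomeRecord,
    PointPattern,
    RegionMap,
    UndefinedMetricError,
    UM2_PER_MM2,
)

logger = logging.getLogger("immunoarch.regions")

DEFAULT_BAND_HALFWIDTH = 250.0  # um each side of the tumor edge
DEFAULT_MIN_CELLS = 50          # small-cluster exclusion for max density
#: RECIST categories in increasing order of response
RECIST_ORDER = ("PD", "SD", "PR", "CR")

CIRCULAR_RULE = {"e_max": 0.8, "f_conv_min": 0.8, "f_circ_min": 0.5}
ELONGATED_RULE = {"e_min": 0.9, "f_conv_max": 0.3, "f_circ_max": 0.3}


@dataclass
class ClusterPhenotype:
    is_circular: bool
    is_elongated: bool
    qualifies_density: bool


# ---------------------------------------------------------------------------
# tissue geometry
# ---------------------------------------------------------------------------


def build_invasive_front(
    regions: RegionMap, band_halfwidth: float = DEFAULT_BAND_HALFWIDTH
) -> RegionMap:
    """Derive the invasive-front band and return the updated RegionMap.

    The front is the part of the tumor boundary adjacent to non-tumor
    tissue, buffered by ``band_halfwidth`` on both sides and clipped to the
    annotated tissue.  Slides with no tumor or no tumor/non-tumor contact
    get an empty front (not an error).
    """
    tumor = regions.tumor
    normal = regions.normal
    if tumor.is_empty or normal.is_empty:
        regions.invasive_front = MultiPolygon([])
        return regions
    non_tumor = normal.difference(tumor)
    if non_tumor.is_empty:
        regions.invasive_front = MultiPolygon([])
        return regions
    # boundary segments of the tumor that touch non-tumor tissue
    shared_edge = tumor.boundary.intersection(non_tumor.buffer(1.0))
    if shared_edge.is_empty:
        regions.invasive_front = MultiPolygon([])
        return regions
    front = shared_edge.buffer(band_halfwidth).intersection(regions.tissue)
    regions.invasive_front = front
    return regions


def select_roi(regions: RegionMap) -> str:
    """Three-way ROI fallback: invasive front, else tumor, else normal."""
    if not regions.polygons:
        raise ValueError("slide has no annotated regions")
    if regions.has_invasive_front:
        label = "invasive_front"
    elif not regions.tumor.is_empty:
        label = "tumor"
    elif not regions.normal.is_empty:
        label = "normal"
    else:  # unreachable given label validation, kept for totality
        raise ValueError("no tumor or normal regions annotated")
    regions.roi_label = label
    return label


def roi_geometry(regions: RegionMap):
    """Geometry of the selected ROI (requires select_roi to have run)."""
    label = regions.roi_label or select_roi(regions)
    if label == "invasive_front":
        return regions.invasive_front
    return regions.union(label)


def assign_cells(pp: PointPattern, regions: RegionMap) -> tuple[np.ndarray, np.ndarray]:
    """Label each cell intratumoral / peritumoral / stromal.

    Membership in the invasive front takes precedence, making the three
    classes mutually exclusive; containment is boundary-inclusive.  Cells
    outside every annotated region are stromal with an out-of-annotation
    flag.  Returns ``(labels, out_of_annotation)`` arrays.
    """
    pts = shapely.points(pp.points)
    labels = np.full(pp.n, "stromal", dtype=object)
    out_of_annotation = np.ones(pp.n, dtype=bool)
    normal = regions.normal
    if not normal.is_empty:
        in_normal = shapely.covers(normal, pts)
        out_of_annotation &= ~in_normal
    tumor = regions.tumor
    if not tumor.is_empty:
        in_tumor = shapely.covers(tumor, pts)
        labels[in_tumor] = "intratumoral"
        out_of_annotation &= ~in_tumor
    if regions.has_invasive_front:
        in_front = shapely.covers(regions.invasive_front, pts)
        labels[in_front] = "peritumoral"
        out_of_annotation &= ~in_front
    return labels, out_of_annotation


def associate_clusters(
    clusters: Sequence[ClusterRecord], cell_labels: np.ndarray
) -> list[str]:
    """Tissue association per cluster from its member-cell labels.

    Any peritumoral member -> ``invasive_front``; else any intratumoral
    member -> ``tumor``; else ``normal``.
    """
    out = []
    for rec in clusters:
        member_labels = cell_labels[rec.member_idx]
        if np.any(member_labels == "peritumoral"):
            out.append("invasive_front")
        elif np.any(member_labels == "intratumoral"):
            out.append("tumor")
        else:
            out.append("normal")
    return out


# ---------------------------------------------------------------------------
# cluster phenotypes and per-region metrics
# ---------------------------------------------------------------------------


def classify_cluster(
    desc: ShapeDescriptors,
    min_cells: int = DEFAULT_MIN_CELLS,
    n: int | None = None,
    circular_rule: dict = CIRCULAR_RULE,
    elongated_rule: dict = ELONGATED_RULE,
) -> ClusterPhenotype:
    """Phenotype a cluster by its shape descriptors (see module docstring)."""
    if desc is None or desc.degenerate or not np.isfinite([desc.e, desc.f_conv, desc.f_circ]).all():
        return ClusterPhenotype(False, False, False)
    is_circular = (
        desc.e < circular_rule["e_max"]
        and desc.f_conv > circular_rule["f_conv_min"]
        and desc.f_circ > circular_rule["f_circ_min"]
    )
    is_elongated = (
        desc.e > elongated_rule["e_min"]
        or desc.f_conv < elongated_rule["f_conv_max"]
        or desc.f_circ < elongated_rule["f_circ_max"]
    )
    qualifies = n is None or n >= min_cells
    return ClusterPhenotype(is_circular, is_elongated, qualifies)


def max_cluster_density(
    clusters: Sequence[ClusterRecord], min_cells: int = DEFAULT_MIN_CELLS
) -> float:
    """Maximum within-cluster density (mm^-2) over clusters with >= min_cells.

    NaN (logged) when no cluster qualifies.
    """
    dens = [c.density_mm2 for c in clusters if c.n >= min_cells and np.isfinite(c.density_mm2)]
    if not dens:
        logger.info("no cluster with >= %d cells; max cluster density missing", min_cells)
        return float("nan")
    return float(max(dens))


def region_metric_table(
    pp: PointPattern,
    regions: RegionMap,
    clusters: Sequence[ClusterRecord],
    patient_id: str = "",
    min_cells: int = DEFAULT_MIN_CELLS,
) -> pd.DataFrame:
    """Per-region outcome-candidate metrics for one slide.

    For each region in {tumor, normal, invasive_front, ROI}: average cell
    density (cells in region / region area, mm^-2), maximum qualifying
    cluster density, counts of circular / elongated clusters, and the total
    cluster count.  Cluster-region membership follows the tissue
    association rule.
    """
    labels, _ = assign_cells(pp, regions)
    associations = associate_clusters(clusters, labels)
    select_roi(regions)
    geoms = {
        "tumor": regions.tumor,
        "normal": regions.normal,
        "invasive_front": regions.invasive_front,
    }
    cell_counts = {
        "tumor": int(np.sum(labels == "intratumoral")),
        "normal": int(np.sum(labels == "stromal")),
        "invasive_front": int(np.sum(labels == "peritumoral")),
    }
    rows = []
    region_names = ["tumor", "normal", "invasive_front", "ROI"]
    for name in region_names:
        key = regions.roi_label if name == "ROI" else name
        geom = geoms[key]
        if geom.is_empty:
            rows.append({"patient_id": patient_id, "region": name, "avg_density_mm2": float("nan"),
                         "max_cluster_density_mm2": float("nan"), "n_circular": 0,
                         "n_elongated": 0, "n_clusters": 0})
            continue
        in_region = [c for c, assoc in zip(clusters, associations) if assoc == key]
        n_circ = n_elong = 0
        for c in in_region:
            ph = classify_cluster(c.descriptors, min_cells=min_cells, n=c.n)
            n_circ += ph.is_circular
            n_elong += ph.is_elongated
        rows.append({
            "patient_id": patient_id,
            "region": name,
            "avg_density_mm2": cell_counts[key] / geom.area * UM2_PER_MM2,
            "max_cluster_density_mm2": max_cluster_density(in_region, min_cells=min_cells),
            "n_circular": n_circ,
            "n_elongated": n_elong,
            "n_clusters": len(in_region),
        })
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# outcome statistics
# ---------------------------------------------------------------------------


def is_responder(record: OutcomeRecord) -> bool:
    """MSI: CR/PR respond; MSS: CR/PR/SD respond."""
    if record.cohort == "MSI":
        return record.recist in ("CR", "PR")
    return record.recist in ("CR", "PR", "SD")


def group_responders(records: Sequence[OutcomeRecord]) -> dict[str, bool]:
    """Map patient_id -> responder flag."""
    return {r.patient_id: is_responder(r) for r in records}


def wilcoxon_rank_sum(
    x: np.ndarray, y: np.ndarray, exact_max_n: int = 20
) -> tuple[float, float]:
    """Two-sided Wilcoxon rank-sum test; returns (W, p).

    W is the rank sum of the first sample.  The exact null distribution is
    used for combined n <= ``exact_max_n`` without ties; otherwise the
    normal approximation with midrank tie correction and continuity
    correction.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) == 0 or len(y) == 0:
        raise UndefinedMetricError("both groups must be non-empty")
    n = len(x) + len(y)
    has_ties = len(np.unique(np.concatenate([x, y]))) < n
    method = "exact" if (n <= exact_max_n and not has_ties) else "asymptotic"
    res = mannwhitneyu(x, y, alternative="two-sided", method=method, use_continuity=True)
    W = float(res.statistic) + len(x) * (len(x) + 1) / 2.0  # U -> rank sum
    return W, float(res.pvalue)


def compare_groups(
    values: dict[str, float] | pd.Series,
    responder_flags: dict[str, bool],
) -> tuple[float, float]:
    """Responders vs non-responders on a per-patient metric.

    Missing (NaN) metric values are dropped.  Returns the responder-group
    rank sum and the two-sided p-value.
    """
    values = dict(values)
    resp, nonresp = [], []
    for pid, flag in responder_flags.items():
        v = values.get(pid, float("nan"))
        if not np.isfinite(v):
            continue
        (resp if flag else nonresp).append(v)
    if not resp or not nonresp:
        raise UndefinedMetricError("a group is empty after missing-value removal")
    return wilcoxon_rank_sum(np.array(resp), np.array(nonresp))


def _jt_statistic(groups: Sequence[np.ndarray]) -> float:
    """Jonckheere-Terpstra J: summed Mann-Whitney counts over ordered pairs,
    ties counted 1/2."""
    J = 0.0
    for i in range(len(groups)):
        for j in range(i + 1, len(groups)):
            xi = groups[i][:, None]
            yj = groups[j][None, :]
            J += float(np.sum(xi < yj) + 0.5 * np.sum(xi == yj))
    return J


def trend_test(
    values_by_group: Sequence[np.ndarray],
    n_perm: int = 10_000,
    seed: int | np.random.Generator = 0,
    exact_max_n: int = 8,
) -> tuple[float, float]:
    """Jonckheere-Terpstra trend test over ordered groups (e.g. PD<SD<PR<CR).

    One-sided for an increasing trend.  The p-value is exact (full
    enumeration of value permutations) for total n <= ``exact_max_n``, and
    a seeded Monte-Carlo permutation p with the add-one correction
    otherwise.  Empty groups are dropped; at least two non-empty groups are
    required.
    """
    groups = [np.asarray(g, dtype=float) for g in values_by_group]
    groups = [g[np.isfinite(g)] for g in groups]
    groups = [g for g in groups if g.size > 0]
    if len(groups) < 2:
        raise UndefinedMetricError("trend test requires >= 2 non-empty ordered groups")
    sizes = [len(g) for g in groups]
    pooled = np.concatenate(groups)
    J_obs = _jt_statistic(groups)

    def split(arr: np.ndarray) -> list[np.ndarray]:
        out, start = [], 0
        for s in sizes:
            out.append(arr[start:start + s])
            start += s
        return out

    if len(pooled) <= exact_max_n:
        count = total = 0
        for perm in itertools.permutations(pooled):
            total += 1
            if _jt_statistic(split(np.array(perm))) >= J_obs - 1e-12:
                count += 1
        return J_obs, count / total
    rng = np.random.default_rng(seed)
    count = 0
    arr = pooled.copy()
    for _ in range(n_perm):
        rng.shuffle(arr)
        if _jt_statistic(split(arr)) >= J_obs - 1e-12:
            count += 1
    return J_obs, (1 + count) / (n_perm + 1)


def recist_groups(
    values: dict[str, float], outcomes: Sequence[OutcomeRecord]
) -> list[np.ndarray]:
    """Per-patient metric values split into ordered RECIST groups (PD<SD<PR<CR)."""
    by_code: dict[str, list[float]] = {code: [] for code in RECIST_ORDER}
    for rec in outcomes:
        v = values.get(rec.patient_id, float("nan"))
        if np.isfinite(v):
            by_code[rec.recist].append(v)
    return [np.array(by_code[code]) for code in RECIST_ORDER]
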