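"""Cluster detection and morphometrics on whole-slide cell coordinates.

Clusters are detected with hierarchical density-based clustering (HDBSCAN:
mutual-reachability minimum spanning tree, excess-of-mass cluster
extraction; unassigned points are noise).  Each cluster's outline is the
alpha-shape obtained by escalating alpha from a starting radius until the
shape is a single connected region containing every member point.  From
the alpha-shape, convex hull and fitted covariance ellipse the module
computes the shape descriptors used to classify immuno-architecture:

* convexity    f_conv = A_alpha / A_conv
* circularity  f_circ = 4 pi A_alpha / P_alpha^2
* eccentricity e = sqrt(1 - lambda2/lambda1)

All lengths in micrometers; areas reported per-cluster in um^2 with mm^2 /
mm^-2 conversions in the tidy table.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
import shapely
from scipy.spatial import ConvexHull, Delaunay, QhullError
from scipy.stats import chi2
from shapely.geometry import MultiPoint, Polygon
from shapely.geometry.base import BaseGeometry
from sklearn.cluster import HDBSCAN

from .core_io import GeometryError, PointPattern, UM2_PER_MM2, points_covered_by

logger = logging.getLogger("immunoarch.morphometrics")

DEFAULT_MIN_PTS = 30     # minimum points per cluster
DEFAULT_K = 4            # core neighborhood range (k-th NN core distance)
DEFAULT_ALPHA_START = 10.0   # um
DEFAULT_ALPHA_FACTOR = 1.2   # geometric escalation factor
DEFAULT_ELLIPSE_LEVEL = 0.95


@dataclass
class ShapeDescriptors:
    """Shape descriptors of one cluster (ellipse at the given confidence level)."""

    f_conv: float
    f_circ: float
    lambda1: float
    lambda2: float
    a: float
    b: float
    e: float
    A_ellipse: float
    center: tuple[float, float]
    orientation: float  # radians of the major axis, in (-pi/2, pi/2]
    degenerate: bool = False


@dataclass
class ClusterRecord:
    """One detected cluster with alpha-shape geometry and descriptors."""

    cluster_id: int
    member_idx: np.ndarray
    n: int
    alpha: float
    shape: BaseGeometry | None = None
    A_alpha: float = float("nan")
    P_alpha: float = float("nan")
    A_conv: float = float("nan")
    descriptors: ShapeDescriptors | None = None
    excluded_reason: str | None = None

    @property
    def density_mm2(self) -> float:
        """Within-cluster cell density n / A_alpha in mm^-2."""
        return self.n / self.A_alpha * UM2_PER_MM2 if self.A_alpha > 0 else float("nan")


# ---------------------------------------------------------------------------
# detection
# ---------------------------------------------------------------------------


def detect_clusters(
    pp: PointPattern | np.ndarray,
    min_pts: int = DEFAULT_MIN_PTS,
    k: int = DEFAULT_K,
    min_membership: float = 0.5,
) -> tuple[list[np.ndarray], np.ndarray]:
    """HDBSCAN cluster memberships over Euclidean distances.

    ``min_pts`` is the minimum cluster size; ``k`` sets the core distance
    to the k-th nearest neighbor; extraction is by excess-of-mass
    stability.  Points whose soft-membership strength falls below
    ``min_membership`` are demoted to noise: such border points join a
    cluster only in the last moments before it dissolves, and because the
    downstream alpha-shape must contain every member, a single remote
    straggler would otherwise dominate a cluster's morphometry.  Returns
    (list of member index arrays, noise index array); clusters shrinking
    below ``min_pts`` after the trim are dissolved.  Patterns smaller than
    ``min_pts`` are all noise.
    """
    if min_pts < 2:
        raise ValueError("min_pts must be >= 2")
    if k < 1:
        raise ValueError("k must be >= 1")
    pts = pp.points if isinstance(pp, PointPattern) else np.asarray(pp, float).reshape(-1, 2)
    n = len(pts)
    if n < min_pts:
        return [], np.arange(n)
    model = HDBSCAN(min_cluster_size=min_pts, min_samples=k, copy=True).fit(pts)
    labels = model.labels_.copy()
    labels[model.probabilities_ < min_membership] = -1
    members = []
    for lab in sorted(set(labels) - {-1}):
        idx = np.where(labels == lab)[0]
        if len(idx) >= min_pts:
            members.append(idx)
        else:
            labels[idx] = -1
    return members, np.where(labels == -1)[0]


# ---------------------------------------------------------------------------
# alpha-shapes
# ---------------------------------------------------------------------------


def alpha_shape(points: np.ndarray, alpha: float) -> BaseGeometry:
    """Alpha-shape as the union of Delaunay triangles with circumradius <= alpha.

    Alpha is the circumradius parameter: boundary edges lie on circles of
    radius alpha.  The result may be empty, a polygon, or a multipolygon.
    """
    pts = np.asarray(points, dtype=float)
    if len(pts) < 3:
        raise GeometryError("alpha-shape requires at least 3 points")
    try:
        tri = Delaunay(pts)
    except QhullError as exc:
        raise GeometryError(f"degenerate point set: {exc}") from exc
    simplices = tri.simplices
    p0, p1, p2 = (pts[simplices[:, i]] for i in range(3))
    la = np.linalg.norm(p1 - p2, axis=1)
    lb = np.linalg.norm(p0 - p2, axis=1)
    lc = np.linalg.norm(p0 - p1, axis=1)
    area2 = np.abs(
        (p1[:, 0] - p0[:, 0]) * (p2[:, 1] - p0[:, 1])
        - (p2[:, 0] - p0[:, 0]) * (p1[:, 1] - p0[:, 1])
    )  # twice the triangle area
    with np.errstate(divide="ignore", invalid="ignore"):
        circumradius = la * lb * lc / (2.0 * area2)
    keep = np.where((area2 > 0) & (circumradius <= alpha))[0]
    if keep.size == 0:
        return Polygon()
    triangles = [Polygon(pts[simplices[t]]) for t in keep]
    return shapely.union_all(triangles)


def _alpha_ok(shape_geom: BaseGeometry, pts: np.ndarray) -> bool:
    """Single connected region covering every member point."""
    if shape_geom.is_empty or not isinstance(shape_geom, Polygon):
        return False
    return bool(np.all(points_covered_by(pts, shape_geom, tol=1e-9)))


def alpha_shape_escalate(
    points: np.ndarray,
    alpha_start: float = DEFAULT_ALPHA_START,
    factor: float = DEFAULT_ALPHA_FACTOR,
) -> tuple[float, Polygon, float, float]:
    """Escalate alpha geometrically until the shape is one connected region
    containing all points; refine once by bisection between the last
    failing and first passing alpha.

    Returns ``(alpha, polygon, area, perimeter)``; the perimeter includes
    hole boundaries (holes penalize circularity, as intended for a shape
    filter).  Termination is guaranteed: for alpha beyond the circumradius
    of every Delaunay triangle the shape is the triangulated convex hull.
    """
    pts = np.asarray(points, dtype=float)
    if len(pts) < 3:
        raise GeometryError("alpha-shape requires at least 3 points")
    if np.linalg.matrix_rank(pts - pts.mean(axis=0)) < 2:
        raise GeometryError("collinear points have no 2D alpha-shape")
    alpha = float(alpha_start)
    prev_fail = None
    # diameter bound: hull is reached well before alpha ~ diameter
    diam = float(np.max(pts.max(axis=0) - pts.min(axis=0))) * 2.0 + alpha_start
    shape_geom = alpha_shape(pts, alpha)
    while not _alpha_ok(shape_geom, pts):
        prev_fail = alpha
        alpha *= factor
        if alpha > 4 * diam:
            raise GeometryError("alpha escalation failed to produce a connected shape")
        shape_geom = alpha_shape(pts, alpha)
    if prev_fail is not None:
        # one bisection refinement between the bracketing alphas
        mid = 0.5 * (prev_fail + alpha)
        mid_geom = alpha_shape(pts, mid)
        if _alpha_ok(mid_geom, pts):
            alpha, shape_geom = mid, mid_geom
    return alpha, shape_geom, float(shape_geom.area), float(shape_geom.length)


# ---------------------------------------------------------------------------
# descriptors
# ---------------------------------------------------------------------------


def convexity(A_alpha: float, A_conv: float) -> float:
    """f_conv = A_alpha / A_conv in (0, 1]."""
    if A_conv <= 0:
        raise GeometryError("convex hull area must be > 0")
    if not 0 < A_alpha <= A_conv * (1 + 1e-9):
        raise ValueError("A_alpha must lie in (0, A_conv]")
    return min(A_alpha / A_conv, 1.0)


def circularity(A_alpha: float, P_alpha: float) -> float:
    """f_circ = 4 pi A / P^2, clipped to (0, 1] (isoperimetric bound)."""
    if P_alpha <= 0:
        raise GeometryError("perimeter must be > 0")
    val = 4.0 * math.pi * A_alpha / P_alpha**2
    if val > 1.0:
        logger.warning("circularity %.6f > 1 clipped to 1 (numerical)", val)
        val = 1.0
    return val


def fit_ellipse(points: np.ndarray, level: float = DEFAULT_ELLIPSE_LEVEL) -> ShapeDescriptors:
    """Confidence ellipse of the member-point covariance.

    Eigen-decomposes the sample covariance; semi-axes are
    a = sqrt(lambda1 * chi2_2(level)), b = sqrt(lambda2 * chi2_2(level));
    eccentricity e = sqrt(1 - lambda2/lambda1).  Collinear clusters give
    e = 1, zero area, flagged degenerate.  Convexity/circularity fields
    are NaN here and filled by :func:`summarize_cluster`.
    """
    pts = np.asarray(points, dtype=float)
    if len(pts) < 3:
        raise GeometryError("ellipse fit requires at least 3 points")
    cov = np.cov(pts.T, ddof=1)
    evals, evecs = np.linalg.eigh(cov)
    lam2, lam1 = float(max(evals[0], 0.0)), float(evals[1])
    scale = chi2.ppf(level, df=2)
    center = tuple(pts.mean(axis=0))
    major = evecs[:, 1]
    orientation = math.atan2(major[1], major[0])
    if orientation <= -math.pi / 2:
        orientation += math.pi
    elif orientation > math.pi / 2:
        orientation -= math.pi
    if lam1 <= 0 or lam2 / lam1 < 1e-12:
        return ShapeDescriptors(
            f_conv=float("nan"), f_circ=float("nan"),
            lambda1=lam1, lambda2=lam2, a=math.sqrt(max(lam1, 0) * scale), b=0.0,
            e=1.0, A_ellipse=0.0, center=center, orientation=orientation,
            degenerate=True,
        )
    a = math.sqrt(lam1 * scale)
    b = math.sqrt(lam2 * scale)
    e = math.sqrt(1.0 - lam2 / lam1)
    return ShapeDescriptors(
        f_conv=float("nan"), f_circ=float("nan"),
        lambda1=lam1, lambda2=lam2, a=a, b=b, e=e,
        A_ellipse=math.pi * a * b, center=center, orientation=orientation,
    )


def summarize_cluster(
    points: np.ndarray,
    cluster_id: int = 0,
    member_idx: np.ndarray | None = None,
    alpha_start: float = DEFAULT_ALPHA_START,
    level: float = DEFAULT_ELLIPSE_LEVEL,
) -> ClusterRecord:
    """Full morphometric record for one cluster's member points.

    Composes alpha-shape escalation, convex hull, shape descriptors and
    the confidence ellipse.  Degenerate geometry (fewer than 3 points,
    collinear members) yields a record excluded-with-reason rather than an
    exception, so slide-level summaries stay auditable.
    """
    pts = np.asarray(points, dtype=float)
    if member_idx is None:
        member_idx = np.arange(len(pts))
    rec = ClusterRecord(cluster_id=cluster_id, member_idx=member_idx, n=len(pts), alpha=float("nan"))
    try:
        alpha, shape_geom, A_alpha, P_alpha = alpha_shape_escalate(pts, alpha_start=alpha_start)
        hull = ConvexHull(pts)
        A_conv = float(hull.volume)  # 2D: volume is the area
        desc = fit_ellipse(pts, level=level)
        desc.f_conv = convexity(A_alpha, A_conv)
        desc.f_circ = circularity(A_alpha, P_alpha)
    except (GeometryError, QhullError) as exc:
        rec.excluded_reason = str(exc)
        logger.info("cluster %d excluded from morphometrics: %s", cluster_id, exc)
        return rec
    rec.alpha, rec.shape, rec.A_alpha, rec.P_alpha, rec.A_conv = alpha, shape_geom, A_alpha, P_alpha, A_conv
    rec.descriptors = desc
    return rec


def analyze_clusters(
    pp: PointPattern,
    min_pts: int = DEFAULT_MIN_PTS,
    k: int = DEFAULT_K,
    alpha_start: float = DEFAULT_ALPHA_START,
    level: float = DEFAULT_ELLIPSE_LEVEL,
) -> tuple[list[ClusterRecord], np.ndarray]:
    """Detect clusters on a slide and summarize each; returns (records, noise)."""
    members, noise = detect_clusters(pp, min_pts=min_pts, k=k)
    records = [
        summarize_cluster(pp.points[idx], cluster_id=cid, member_idx=idx,
                          alpha_start=alpha_start, level=level)
        for cid, idx in enumerate(members)
    ]
    return records, noise


def clusters_table(records: Sequence[ClusterRecord]) -> pd.DataFrame:
    """Tidy per-cluster table with areas in mm^2 and densities in mm^-2."""
    rows = []
    for rec in records:
        d = rec.descriptors
        rows.append({
            "cluster_id": rec.cluster_id,
            "n": rec.n,
            "alpha": rec.alpha,
            "A_alpha_mm2": rec.A_alpha / UM2_PER_MM2,
            "P_alpha_mm": rec.P_alpha / 1000.0,
            "A_conv_mm2": rec.A_conv / UM2_PER_MM2,
            "f_conv": d.f_conv if d else float("nan"),
            "f_circ": d.f_circ if d else float("nan"),
            "lambda1": d.lambda1 if d else float("nan"),
            "lambda2": d.lambda2 if d else float("nan"),
            "a": d.a if d else float("nan"),
            "b": d.b if d else float("nan"),
            "e": d.e if d else float("nan"),
            "A_ellipse_mm2": d.A_ellipse / UM2_PER_MM2 if d else float("nan"),
            "density_mm2": rec.density_mm2,
            "excluded_reason": rec.excluded_reason,
        })
    return pd.DataFrame(rows)
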