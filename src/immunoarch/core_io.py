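"""Shared data model, file I/O and unit conventions.

Coordinates are stored in micrometers internally.  Densities are reported
in cells per square millimeter (mm^-2), the unit pathologists use for TIL
densities; :data:`UM2_PER_MM2` is the single conversion constant used
everywhere.

File formats: cell tables are plain CSV with at least ``x`` and ``y``
columns; tissue annotations are GeoJSON FeatureCollections whose features
carry a ``label`` property that is either ``"tumor"`` or ``"normal"``;
per-patient outcomes are CSV with ``patient_id``, ``cohort`` (MSI/MSS) and
``recist`` (CR/PR/SD/PD) columns.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import shapely
from shapely.geometry import MultiPolygon, Polygon, box, mapping, shape
from shapely.geometry.base import BaseGeometry

logger = logging.getLogger("immunoarch")

#: micrometers^2 per millimeter^2 — multiply a um^-2 intensity by this to get mm^-2
UM2_PER_MM2 = 1.0e6

#: default scanner resolution, micrometers per pixel (20x equivalent)
DEFAULT_PIXEL_SIZE = 0.49

VALID_REGION_LABELS = ("tumor", "normal")
VALID_COHORTS = ("MSI", "MSS")
VALID_RECIST = ("CR", "PR", "SD", "PD")


class FormatError(ValueError):
    """Raised when an input file does not match the expected schema."""


class GeometryError(ValueError):
    """Raised for invalid or degenerate geometry."""


class UndefinedMetricError(ValueError):
    """Raised when a statistic is requested on inputs where it is undefined."""


def setup_logging(level: str = "INFO") -> None:
    """Configure the package logger (idempotent)."""
    root = logging.getLogger("immunoarch")
    if not root.handlers:
        handler = logging.StreamHandler()
        handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(name)s: %(message)s"))
        root.addHandler(handler)
    root.setLevel(level.upper())


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------


@dataclass
class PointPattern:
    """A planar point pattern: cell coordinates inside an observation window.

    Parameters
    ----------
    points:
        ``(n, 2)`` float array of x, y coordinates in micrometers.
    window:
        Observation region (shapely polygon) in micrometers.  Every point
        must lie inside or on the boundary of the window.
    """

    points: np.ndarray
    window: BaseGeometry

    def __post_init__(self) -> None:
        pts = np.asarray(self.points, dtype=float)
        if pts.size == 0:
            pts = pts.reshape(0, 2)
        if pts.ndim != 2 or pts.shape[1] != 2:
            raise ValueError(f"points must have shape (n, 2); got {pts.shape}")
        if not np.all(np.isfinite(pts)):
            bad = np.where(~np.isfinite(pts).all(axis=1))[0]
            raise ValueError(f"non-finite coordinates at rows {bad.tolist()}")
        self.points = pts
        if self.window is None or self.window.is_empty or self.window.area <= 0:
            raise GeometryError("observation window must have positive area")
        if len(pts) and not np.all(points_covered_by(pts, self.window, tol=1e-6)):
            raise GeometryError("some points fall outside the observation window")

    @property
    def n(self) -> int:
        return len(self.points)

    @property
    def area(self) -> float:
        """Window area in um^2."""
        return float(self.window.area)

    @property
    def intensity(self) -> float:
        """Empirical intensity in um^-2."""
        return self.n / self.area

    @property
    def density_mm2(self) -> float:
        """Empirical density in mm^-2."""
        return self.intensity * UM2_PER_MM2

    def subset(self, mask: np.ndarray, window: BaseGeometry | None = None) -> "PointPattern":
        return PointPattern(self.points[mask], window if window is not None else self.window)


@dataclass(frozen=True)
class WindowGrid:
    """Moving-window geometry: edge lengths and step sizes in micrometers.

    Defaults are 0.5 mm windows advanced in 0.25 mm steps (50% overlap)
    in both axes.
    """

    x_window: float = 500.0
    y_window: float = 500.0
    x_step: float = 250.0
    y_step: float = 250.0

    def __post_init__(self) -> None:
        for name in ("x_window", "y_window", "x_step", "y_step"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        if self.x_step > self.x_window or self.y_step > self.y_window:
            raise ValueError("step size must not exceed window size")


@dataclass
class RegionMap:
    """Labeled tumor/normal annotation polygons plus the derived invasive front.

    ``invasive_front`` is empty until computed by
    :func:`immunoarch.regions_outcomes.build_invasive_front`.
    """

    polygons: list[tuple[str, Polygon]] = field(default_factory=list)
    invasive_front: BaseGeometry = field(default_factory=lambda: MultiPolygon([]))
    roi_label: str | None = None

    def __post_init__(self) -> None:
        for i, (label, poly) in enumerate(self.polygons):
            if label not in VALID_REGION_LABELS:
                raise FormatError(
                    f"region {i}: label {label!r} not in {VALID_REGION_LABELS}"
                )
            if not poly.is_valid:
                raise GeometryError(f"region {i} ({label}): invalid polygon ({shapely.is_valid_reason(poly)})")

    def union(self, label: str) -> BaseGeometry:
        """Union of all polygons with the given label (may be empty)."""
        polys = [p for lab, p in self.polygons if lab == label]
        return shapely.union_all(polys) if polys else MultiPolygon([])

    @property
    def tumor(self) -> BaseGeometry:
        return self.union("tumor")

    @property
    def normal(self) -> BaseGeometry:
        return self.union("normal")

    @property
    def tissue(self) -> BaseGeometry:
        """Union of all annotated tissue."""
        return shapely.union_all([p for _, p in self.polygons]) if self.polygons else MultiPolygon([])

    @property
    def has_invasive_front(self) -> bool:
        return not self.invasive_front.is_empty


@dataclass(frozen=True)
class OutcomeRecord:
    """Per-patient treatment outcome: cohort (MSI/MSS) and RECIST category."""

    patient_id: str
    cohort: str
    recist: str

    def __post_init__(self) -> None:
        if self.cohort not in VALID_COHORTS:
            raise FormatError(f"unknown cohort {self.cohort!r} for patient {self.patient_id}")
        if self.recist not in VALID_RECIST:
            raise FormatError(f"unknown RECIST code {self.recist!r} for patient {self.patient_id}")


# ---------------------------------------------------------------------------
# geometry helpers
# ---------------------------------------------------------------------------


def points_covered_by(points: np.ndarray, geom: BaseGeometry, tol: float = 0.0) -> np.ndarray:
    """Boolean mask of points covered by ``geom`` (boundary inclusive).

    ``tol`` expands the geometry slightly to absorb floating-point jitter.
    """
    pts = shapely.points(np.asarray(points, dtype=float))
    target = geom.buffer(tol) if tol > 0 else geom
    return shapely.covers(target, pts)


def bounding_box_window(points: np.ndarray, pad: float = 0.0) -> Polygon:
    """Axis-aligned bounding box of a point set, optionally padded."""
    pts = np.asarray(points, dtype=float)
    if len(pts) == 0:
        raise GeometryError("cannot derive a window from an empty point set")
    (xmin, ymin), (xmax, ymax) = pts.min(axis=0), pts.max(axis=0)
    if xmax - xmin <= 0 or ymax - ymin <= 0:
        pad = max(pad, 1.0)  # degenerate extent: give the window measurable area
    return box(xmin - pad, ymin - pad, xmax + pad, ymax + pad)


def is_rectangle(window: BaseGeometry, rtol: float = 1e-9) -> bool:
    """True if the window is (numerically) its own axis-aligned envelope."""
    return bool(abs(window.area - window.envelope.area) <= rtol * max(window.envelope.area, 1.0))


# ---------------------------------------------------------------------------
# readers / writers
# ---------------------------------------------------------------------------


def read_cells(
    path: str | Path,
    units: str = "micron",
    pixel_size: float | None = None,
    window: BaseGeometry | None = None,
) -> PointPattern:
    """Read a cell-coordinate CSV into a :class:`PointPattern`.

    Parameters
    ----------
    units:
        ``"micron"`` (default) or ``"pixel"``.  Pixel coordinates are scaled
        by ``pixel_size`` (um/pixel), which is then required.
    window:
        Explicit observation window; defaults to the bounding box of the
        points (unpadded).
    """
    if units not in ("micron", "pixel"):
        raise FormatError(f"units must be 'micron' or 'pixel', got {units!r}")
    if units == "pixel" and (pixel_size is None or pixel_size <= 0):
        raise FormatError("pixel_size (um/pixel) is required when units='pixel'")
    df = pd.read_csv(path)
    missing = {"x", "y"} - set(df.columns)
    if missing:
        raise FormatError(f"{path}: missing required column(s) {sorted(missing)}")
    xy = df[["x", "y"]].to_numpy(dtype=float)
    bad = np.where(~np.isfinite(xy).all(axis=1))[0]
    if bad.size:
        raise FormatError(f"{path}: non-finite coordinate at row(s) {bad.tolist()}")
    if units == "pixel":
        xy = xy * float(pixel_size)
    if window is None:
        if len(xy) == 0:
            window = box(0.0, 0.0, 1.0, 1.0)  # placeholder; downstream ops reject n=0
        else:
            window = bounding_box_window(xy)
    return PointPattern(xy, window)


def write_cells(pp: PointPattern, path: str | Path) -> None:
    """Write a point pattern back to CSV (x, y in micrometers)."""
    pd.DataFrame(pp.points, columns=["x", "y"]).to_csv(path, index=False)


def read_regions(path: str | Path) -> RegionMap:
    """Read a tumor/normal GeoJSON FeatureCollection into a :class:`RegionMap`.

    Coordinates are interpreted in micrometers.  Every feature must carry a
    ``label`` property in {tumor, normal}; unknown labels and invalid
    polygons are hard errors naming the offending feature.
    """
    with open(path) as fh:
        gj = json.load(fh)
    if gj.get("type") != "FeatureCollection":
        raise FormatError(f"{path}: expected a GeoJSON FeatureCollection")
    polygons: list[tuple[str, Polygon]] = []
    for i, feat in enumerate(gj.get("features", [])):
        label = (feat.get("properties") or {}).get("label")
        if label not in VALID_REGION_LABELS:
            raise FormatError(f"{path}: feature {i} has label {label!r}, expected one of {VALID_REGION_LABELS}")
        geom = shape(feat["geometry"])
        geoms = list(geom.geoms) if isinstance(geom, MultiPolygon) else [geom]
        for g in geoms:
            if not isinstance(g, Polygon):
                raise GeometryError(f"{path}: feature {i} is not polygonal")
            if not g.is_valid:
                raise GeometryError(
                    f"{path}: feature {i} ({label}): {shapely.is_valid_reason(g)}"
                )
            polygons.append((label, g))
    return RegionMap(polygons=polygons)


def write_regions(regions: RegionMap, path: str | Path) -> None:
    """Write a RegionMap to GeoJSON (labels preserved; front not serialized)."""
    features = [
        {"type": "Feature", "properties": {"label": label}, "geometry": mapping(poly)}
        for label, poly in regions.polygons
    ]
    with open(path, "w") as fh:
        json.dump({"type": "FeatureCollection", "features": features}, fh)


def read_outcomes(path: str | Path) -> list[OutcomeRecord]:
    """Read the per-patient outcomes CSV (patient_id, cohort, recist)."""
    df = pd.read_csv(path, dtype=str)
    missing = {"patient_id", "cohort", "recist"} - set(df.columns)
    if missing:
        raise FormatError(f"{path}: missing required column(s) {sorted(missing)}")
    return [
        OutcomeRecord(row.patient_id, row.cohort.strip().upper(), row.recist.strip().upper())
        for row in df.itertuples()
    ]


def write_outcomes(records: Iterable[OutcomeRecord], path: str | Path) -> None:
    pd.DataFrame(
        [(r.patient_id, r.cohort, r.recist) for r in records],
        columns=["patient_id", "cohort", "recist"],
    ).to_csv(path, index=False)


def rectangle_window(xmin: float, ymin: float, xmax: float, ymax: float) -> Polygon:
    """Convenience constructor for an axis-aligned rectangular window."""
    return box(xmin, ymin, xmax, ymax)
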