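"""Virtual-slide generator: ground truth for every downstream stage.

A virtual slide consists of (a) a tumor polygon inside a normal-tissue
background, (b) region-conditional point processes — homogeneous Poisson or
Thomas cluster processes — for the diffuse CD8+ T-cell infiltrate, (c)
optional planted cluster archetypes (circular lymphoid-follicle-like disks
and elongated invasive-front-like strips), and (d) a detection-noise model
that thins true cells with a miss probability and adds uniform false
detections, emulating imperfect segmentation.

Thomas simulation follows the generative definition: Poisson parents at
intensity kappa in a window expanded by a 4*sigma guard (so clusters whose
parents fall just outside still contribute points), Poisson(mu) offspring
per parent, isotropic Gaussian offsets with standard deviation sigma,
clipped to the window.

All coordinates in micrometers; intensities in the scenario are given in
mm^-2 for readability and converted internally.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import shapely
import yaml
from shapely.geometry import Polygon, box
from shapely.geometry.base import BaseGeometry

from .core_io import (
    PointPattern,
    RegionMap,
    UM2_PER_MM2,
    write_cells,
    write_regions,
)


# ---------------------------------------------------------------------------
# elementary simulators
# ---------------------------------------------------------------------------


def _uniform_in(geom: BaseGeometry, n: int, rng: np.random.Generator) -> np.ndarray:
    """n points uniform in a geometry by bounding-box rejection."""
    if n == 0:
        return np.empty((0, 2))
    xmin, ymin, xmax, ymax = geom.bounds
    out = np.empty((0, 2))
    while len(out) < n:
        m = max(int((n - len(out)) * max(1.5, (xmax - xmin) * (ymax - ymin) / geom.area)), 16)
        cand = np.column_stack([rng.uniform(xmin, xmax, m), rng.uniform(ymin, ymax, m)])
        inside = shapely.covers(geom, shapely.points(cand))
        out = np.vstack([out, cand[inside]])
    return out[:n]


def simulate_poisson(
    window: BaseGeometry, intensity: float, rng: np.random.Generator
) -> np.ndarray:
    """Homogeneous Poisson process; ``intensity`` in um^-2."""
    n = rng.poisson(intensity * window.area)
    return _uniform_in(window, n, rng)


def simulate_thomas(
    window: BaseGeometry,
    kappa: float,
    mu: float,
    sigma: float,
    rng: np.random.Generator | int = 0,
    guard_factor: float = 4.0,
) -> PointPattern:
    """Simulate a Thomas cluster process in ``window``.

    ``kappa`` in um^-2, ``mu`` dimensionless, ``sigma`` in um.  Parents are
    simulated in the window's bounding box expanded by ``guard_factor *
    sigma`` to avoid edge deficits; offspring falling outside the window
    are discarded.
    """
    if min(kappa, mu, sigma) <= 0:
        raise ValueError("kappa, mu, sigma must be > 0")
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    xmin, ymin, xmax, ymax = window.bounds
    g = guard_factor * sigma
    exp_box = box(xmin - g, ymin - g, xmax + g, ymax + g)
    n_parents = rng.poisson(kappa * exp_box.area)
    parents = np.column_stack([
        rng.uniform(xmin - g, xmax + g, n_parents),
        rng.uniform(ymin - g, ymax + g, n_parents),
    ])
    counts = rng.poisson(mu, n_parents)
    centers = np.repeat(parents, counts, axis=0)
    pts = centers + rng.normal(0.0, sigma, size=centers.shape)
    inside = shapely.covers(window, shapely.points(pts)) if len(pts) else np.zeros(0, bool)
    return PointPattern(pts[inside], window)


def sample_disk(center: tuple[float, float], radius: float, n: int,
                rng: np.random.Generator) -> np.ndarray:
    """n points uniform in a disk."""
    r = radius * np.sqrt(rng.uniform(size=n))
    theta = rng.uniform(0, 2 * np.pi, n)
    return np.column_stack([center[0] + r * np.cos(theta), center[1] + r * np.sin(theta)])


def sample_disk_packed(
    center: tuple[float, float],
    radius: float,
    spacing: float,
    jitter: float,
    rng: np.random.Generator,
) -> np.ndarray:
    """Jittered hexagonal packing inside a disk (follicle archetype).

    Lymphoid follicles are tightly packed aggregates: cell centers repel at
    roughly one cell diameter, so their positions resemble a perturbed
    hexagonal lattice far more than a Poisson sample.  ``spacing`` is the
    lattice constant (~10 um, one lymphocyte diameter); ``jitter`` the
    Gaussian positional noise.
    """
    radius, spacing = float(radius), float(spacing)
    dx, dy = spacing, spacing * np.sqrt(3) / 2
    xs = np.arange(-radius, radius + dx, dx, dtype=float)
    ys = np.arange(-radius, radius + dy, dy, dtype=float)
    X, Y = np.meshgrid(xs, ys)
    X[::2] += dx / 2  # stagger alternate rows
    pts = np.column_stack([X.ravel(), Y.ravel()])
    pts = pts[np.hypot(pts[:, 0], pts[:, 1]) <= radius - spacing / 2]
    pts = pts + rng.normal(0.0, jitter, pts.shape)
    return pts + np.asarray(center, dtype=float)


def sample_strip(center: tuple[float, float], length: float, width: float,
                 angle: float, n: int, rng: np.random.Generator) -> np.ndarray:
    """n points uniform in a rotated rectangle (elongated archetype)."""
    local = np.column_stack([
        rng.uniform(-length / 2, length / 2, n),
        rng.uniform(-width / 2, width / 2, n),
    ])
    c, s = np.cos(angle), np.sin(angle)
    rot = local @ np.array([[c, s], [-s, c]])
    return rot + np.asarray(center)


def apply_detection_noise(
    points: np.ndarray,
    window: BaseGeometry,
    miss_rate: float,
    false_rate: float,
    rng: np.random.Generator,
    density_dependent_miss: bool = False,
    density_k: int = 10,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Thin true points and add uniform false detections.

    ``miss_rate`` q is the per-cell miss probability; ``false_rate`` is the
    false-detection intensity in um^-2.  With ``density_dependent_miss``
    the per-cell miss probability is scaled by the local k-NN density
    relative to its mean (capped at 1), emulating segmentation failure in
    very dense regions, while keeping the overall mean at q.

    Returns ``(observed, kept_mask, n_false)``-style triple: the observed
    coordinate array, the boolean keep mask over true points, and the
    false-point coordinates.
    """
    points = np.asarray(points, dtype=float)
    n = len(points)
    if density_dependent_miss and n > density_k:
        from scipy.spatial import cKDTree

        d, _ = cKDTree(points).query(points, k=density_k + 1)
        local = 1.0 / np.maximum(d[:, -1], 1e-9) ** 2
        probs = np.clip(miss_rate * local / local.mean(), 0.0, 1.0)
    else:
        probs = np.full(n, miss_rate)
    kept = rng.uniform(size=n) >= probs
    false_pts = simulate_poisson(window, false_rate, rng) if false_rate > 0 else np.empty((0, 2))
    observed = np.vstack([points[kept], false_pts])
    return observed, kept, false_pts


# ---------------------------------------------------------------------------
# slide scenarios
# ---------------------------------------------------------------------------


@dataclass
class SlideScenario:
    """Declarative description of one virtual slide.

    Defaults produce an 8 x 8 mm slide with a central 3 x 3 mm tumor whose
    infiltrate follows a Thomas process at the magnitudes seen in fitted
    clinical windows (kappa = 40 mm^-2, mu = 15, sigma = 25 um), sparse
    Poisson infiltrate in normal tissue, three follicle disks and two
    elongated strips, and detection noise at the segmentation operating
    point (25% misses, 12% false fraction).
    """

    slide_width: float = 8000.0
    slide_height: float = 8000.0
    tumor_size: float = 3000.0  # edge of the centered square tumor; 0 = no tumor
    # per-region diffuse processes: ("poisson", {"intensity_mm2": ...}) or
    # ("thomas", {"kappa_mm2": ..., "mu": ..., "sigma": ...})
    tumor_process: tuple[str, dict] = ("thomas", None)
    normal_process: tuple[str, dict] = ("poisson", None)
    n_follicles: int = 3
    follicle_radius: float = 150.0
    follicle_spacing: float = 10.0  # lattice constant, ~one lymphocyte diameter
    follicle_jitter: float = 2.0    # positional noise of packed cells
    n_strips: int = 2
    strip_length: float = 1500.0
    strip_width: float = 100.0
    strip_n: int = 400
    miss_rate: float = 0.25
    false_fraction: float = 0.12  # target FP/(TP+FP); converted to a rate
    false_rate_mm2: float | None = None  # overrides false_fraction if set
    density_dependent_miss: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if self.tumor_process[1] is None:
            self.tumor_process = (self.tumor_process[0], {"kappa_mm2": 40.0, "mu": 15.0, "sigma": 25.0})
        if self.normal_process[1] is None:
            self.normal_process = (self.normal_process[0], {"intensity_mm2": 50.0})
        if not 0 <= self.miss_rate < 1:
            raise ValueError("miss_rate must be in [0, 1)")
        if not 0 <= self.false_fraction < 1:
            raise ValueError("false_fraction must be in [0, 1)")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SlideScenario":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        for key in ("tumor_process", "normal_process"):
            if key in data and isinstance(data[key], list):
                data[key] = (data[key][0], data[key][1])
        return cls(**data)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["tumor_process"] = list(self.tumor_process)
        d["normal_process"] = list(self.normal_process)
        return d


def archetype_scenario(seed: int = 0) -> SlideScenario:
    """Scenario for cluster-archetype studies: three packed follicle disks
    and two elongated strips over a sparse (1 mm^-2) scattered stromal
    infiltrate, with detection noise off.  The background is thin enough
    that the planted archetypes are the only cell aggregates on the slide
    (the sparsest clinical slides carry on the order of a hundred cells)."""
    return SlideScenario(
        tumor_process=("poisson", {"intensity_mm2": 1.0}),
        normal_process=("poisson", {"intensity_mm2": 1.0}),
        miss_rate=0.0, false_fraction=0.0, seed=seed,
    )


def detection_noise_scenario(seed: int = 0) -> SlideScenario:
    """Scenario for detection-noise closure studies: a homogeneous
    moderate-density infiltrate (no tumor, no archetypes) with the default
    noise operating point (25% misses, 12% false fraction).  Homogeneity
    keeps point matching unambiguous so the recovered recall/precision
    reflect the noise model alone."""
    return SlideScenario(
        tumor_size=0.0,
        normal_process=("poisson", {"intensity_mm2": 150.0}),
        n_follicles=0, n_strips=0, seed=seed,
    )


@dataclass
class SlideSim:
    """Output of :func:`simulate_slide`: truth, observation, and provenance."""

    true_pattern: PointPattern
    observed_pattern: PointPattern
    regions: RegionMap
    provenance: np.ndarray        # per true point: tumor_bg / normal_bg / follicle_i / strip_i
    kept_mask: np.ndarray         # per true point: survived detection
    n_false: int
    manifest: dict = field(default_factory=dict)


def _run_process(spec: tuple[str, dict], geom: BaseGeometry, rng: np.random.Generator) -> np.ndarray:
    kind, params = spec
    if geom.is_empty or geom.area <= 0:
        return np.empty((0, 2))
    if kind == "poisson":
        return simulate_poisson(geom, params["intensity_mm2"] / UM2_PER_MM2, rng)
    if kind == "thomas":
        pp = simulate_thomas(
            geom,
            kappa=params["kappa_mm2"] / UM2_PER_MM2,
            mu=params["mu"],
            sigma=params["sigma"],
            rng=rng,
        )
        return pp.points
    raise ValueError(f"unknown process kind {kind!r}")


def simulate_slide(scenario: SlideScenario, seed: int | None = None) -> SlideSim:
    """Simulate a full virtual slide from a scenario (seeded, reproducible).

    Region processes are simulated region-conditionally; follicle disks are
    planted in normal tissue clear of the tumor, strips along the tumor
    boundary (or mid-slide when there is no tumor).  Detection noise then
    produces the observed pattern.  Archetypes that would not fit inside
    the slide raise immediately.
    """
    rng = np.random.default_rng(scenario.seed if seed is None else seed)
    W, H = scenario.slide_width, scenario.slide_height
    slide = box(0.0, 0.0, W, H)
    polygons: list[tuple[str, Polygon]] = []
    if scenario.tumor_size > 0:
        if scenario.tumor_size >= min(W, H):
            raise ValueError("tumor does not fit inside the slide")
        t0x, t0y = (W - scenario.tumor_size) / 2, (H - scenario.tumor_size) / 2
        tumor = box(t0x, t0y, t0x + scenario.tumor_size, t0y + scenario.tumor_size)
        normal = slide.difference(tumor)
        polygons = [("tumor", tumor), ("normal", normal)]
    else:
        tumor = Polygon()
        normal = slide
        polygons = [("normal", normal)]
    regions = RegionMap(polygons=polygons)

    chunks: list[np.ndarray] = []
    labels: list[str] = []

    def add(points: np.ndarray, label: str) -> None:
        chunks.append(points)
        labels.extend([label] * len(points))

    add(_run_process(scenario.tumor_process, tumor, rng), "tumor_bg")
    add(_run_process(scenario.normal_process, normal, rng), "normal_bg")

    # follicles: deterministic anchor positions in the normal margin
    margin = normal if not tumor.is_empty else slide
    clearance = scenario.follicle_radius * 1.5
    anchors = [
        (W * 0.15, H * 0.15), (W * 0.85, H * 0.15), (W * 0.15, H * 0.85),
        (W * 0.85, H * 0.85), (W * 0.5, H * 0.08), (W * 0.08, H * 0.5),
    ]
    if scenario.n_follicles > len(anchors):
        raise ValueError(f"at most {len(anchors)} follicles supported per slide")
    for i in range(scenario.n_follicles):
        cx, cy = anchors[i]
        disk = shapely.Point(cx, cy).buffer(clearance)
        if not margin.covers(disk) or not slide.covers(disk):
            raise ValueError(f"follicle {i} at ({cx:.0f}, {cy:.0f}) does not fit its region")
        add(sample_disk_packed((cx, cy), scenario.follicle_radius,
                               scenario.follicle_spacing, scenario.follicle_jitter, rng),
            f"follicle_{i}")

    # strips: along the tumor boundary (invasive-front-like) or mid-slide rows
    if scenario.n_strips > 0:
        if not tumor.is_empty:
            txmin, tymin, txmax, tymax = tumor.bounds
            strip_anchors = [
                ((txmin + txmax) / 2, tymin, 0.0),          # along bottom edge
                ((txmin + txmax) / 2, tymax, 0.0),          # along top edge
                (txmin, (tymin + tymax) / 2, np.pi / 2),    # along left edge
                (txmax, (tymin + tymax) / 2, np.pi / 2),    # along right edge
            ]
        else:
            strip_anchors = [
                (W * 0.5, H * 0.35, 0.0), (W * 0.5, H * 0.65, 0.0),
                (W * 0.35, H * 0.5, np.pi / 2), (W * 0.65, H * 0.5, np.pi / 2),
            ]
        if scenario.n_strips > len(strip_anchors):
            raise ValueError(f"at most {len(strip_anchors)} strips supported per slide")
        for i in range(scenario.n_strips):
            cx, cy, ang = strip_anchors[i]
            pts = sample_strip((cx, cy), scenario.strip_length, scenario.strip_width, ang, scenario.strip_n, rng)
            if not bool(np.all(shapely.covers(slide, shapely.points(pts)))):
                raise ValueError(f"strip {i} extends beyond the slide")
            add(pts, f"strip_{i}")

    true_pts = np.vstack([c for c in chunks if len(c)]) if any(len(c) for c in chunks) else np.empty((0, 2))
    provenance = np.array(labels, dtype=object)
    true_pattern = PointPattern(true_pts, slide)

    if scenario.false_rate_mm2 is not None:
        false_rate = scenario.false_rate_mm2 / UM2_PER_MM2
    elif scenario.false_fraction > 0 and len(true_pts):
        phi = scenario.false_fraction
        expected_false = phi / (1 - phi) * (1 - scenario.miss_rate) * len(true_pts)
        false_rate = expected_false / slide.area
    else:
        false_rate = 0.0
    observed, kept, false_pts = apply_detection_noise(
        true_pts, slide, scenario.miss_rate, false_rate, rng,
        density_dependent_miss=scenario.density_dependent_miss,
    )
    observed_pattern = PointPattern(observed, slide)

    manifest = {
        "scenario": scenario.to_dict(),
        "n_true": int(len(true_pts)),
        "n_observed": int(len(observed)),
        "n_missed": int((~kept).sum()),
        "n_false": int(len(false_pts)),
        "false_rate_um2": false_rate,
        "provenance_counts": {lab: int((provenance == lab).sum()) for lab in sorted(set(labels))},
    }
    return SlideSim(
        true_pattern=true_pattern,
        observed_pattern=observed_pattern,
        regions=regions,
        provenance=provenance,
        kept_mask=kept,
        n_false=len(false_pts),
        manifest=manifest,
    )


def write_slide(sim: SlideSim, out_dir: str | Path) -> None:
    """Write a simulated slide: true/observed CSVs, regions GeoJSON, manifest."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    write_cells(sim.true_pattern, out / "cells_true.csv")
    write_cells(sim.observed_pattern, out / "cells_observed.csv")
    write_regions(sim.regions, out / "regions.geojson")
    with open(out / "manifest.json", "w") as fh:
        json.dump(sim.manifest, fh, indent=2)
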