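"""Exact 2-D cross-section geometry for ablation prediction.

All quantities live in a frame-local Cartesian coordinate system in
millimetres, y-up, with polar angles measured counter-clockwise from the
+x axis.  Lumen contours are simple, counter-clockwise polygons; devices
(RA burr, imaging catheter, guidewire) are circles.  The three regions of
interest per frame are

* the *predicted* ablation region: a burr-sized circle centred at the
  imaging catheter (or the guidewire) intersected with the vessel wall,
  i.e. the part of the circle outside the pre-procedural lumen;
* the *actual* ablation region: tissue removed, post-lumen minus
  registered pre-lumen;
* their *overlap*.

Region booleans, areas, angular extents around the lumen centre and
minimum device clearances are all computed here on top of shapely.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Iterable, Literal, Sequence

import numpy as np
import shapely
from shapely.geometry import MultiPolygon, Point, Polygon
from shapely.ops import unary_union

__all__ = [
    "Point2D",
    "DeviceCircle",
    "CalciumArc",
    "GeometryError",
    "make_device_circle",
    "circle_polygon",
    "validate_contour",
    "predicted_region",
    "actual_region",
    "overlap_region",
    "region_area",
    "angular_extent",
    "min_clearance",
    "lumen_diameters",
    "CATHETER_DIAMETER_MM",
    "WIRE_DIAMETER_MM",
    "BURR_DIAMETERS_MM",
]

# Device dimensions (mm): monorail OFDI imaging catheter, 0.009-inch
# dedicated atherectomy guidewire, available burr sizes.
CATHETER_DIAMETER_MM = 0.9
WIRE_DIAMETER_MM = 0.229
BURR_DIAMETERS_MM = (1.25, 1.50, 1.75, 2.00, 2.15, 2.25)

#: area below which a region is considered empty (mm^2)
AREA_EPS = 1e-12


class GeometryError(ValueError):
    """Invalid geometric input (degenerate contour, bad diameter, ...)."""


@dataclass(frozen=True)
class Point2D:
    """A point in frame coordinates (mm)."""

    x: float
    y: float

    def __post_init__(self) -> None:
        if not (math.isfinite(self.x) and math.isfinite(self.y)):
            raise GeometryError(f"non-finite coordinates ({self.x}, {self.y})")

    def as_tuple(self) -> tuple[float, float]:
        return (self.x, self.y)


DeviceKind = Literal["burr", "catheter", "wire"]


@dataclass(frozen=True)
class DeviceCircle:
    """A circular device cross-section: burr, imaging catheter or guidewire."""

    center: Point2D
    diameter: float
    kind: DeviceKind = "burr"

    def __post_init__(self) -> None:
        if not (math.isfinite(self.diameter) and self.diameter > 0):
            raise GeometryError(f"diameter must be positive, got {self.diameter}")

    @property
    def radius(self) -> float:
        return self.diameter / 2.0

    def polygon(self, n_vertices: int = 360) -> Polygon:
        """Polygonal approximation with `n_vertices` equally spaced vertices.

        With the default 360 vertices the area deficit relative to the true
        circle is below 0.02 % (the inscribed-polygon factor
        ``n/(2*pi) * sin(2*pi/n)``).
        """
        return circle_polygon(self.center, self.radius, n_vertices)


@dataclass(frozen=True)
class CalciumArc:
    """An annotated calcium arc: angular span (degrees) and minimum depth."""

    start_deg: float
    end_deg: float
    min_depth_um: float = 0.0
    nodular: bool = False

    def __post_init__(self) -> None:
        if self.min_depth_um < 0:
            raise GeometryError("calcium depth must be >= 0")

    @property
    def span_deg(self) -> float:
        """Arc span in (0, 360]: ``(end - start) mod 360``, 360 if equal."""
        span = (self.end_deg - self.start_deg) % 360.0
        return 360.0 if span == 0.0 else span


def circle_polygon(center: Point2D | tuple[float, float], radius: float,
                   n_vertices: int = 360) -> Polygon:
    """Counter-clockwise regular polygon inscribed in a circle."""
    if radius <= 0:
        raise GeometryError(f"radius must be positive, got {radius}")
    if n_vertices < 3:
        raise GeometryError("need at least 3 vertices")
    cx, cy = (center.x, center.y) if isinstance(center, Point2D) else center
    theta = np.linspace(0.0, 2.0 * np.pi, n_vertices, endpoint=False)
    return Polygon(np.c_[cx + radius * np.cos(theta), cy + radius * np.sin(theta)])


def make_device_circle(center: Point2D, diameter: float,
                       kind: DeviceKind = "burr") -> DeviceCircle:
    """Construct a validated device circle."""
    return DeviceCircle(center=center, diameter=diameter, kind=kind)


def validate_contour(polygon: Polygon, *, reorient: bool = True) -> Polygon:
    """Check that a contour is a simple polygon; enforce CCW orientation.

    Raises :class:`GeometryError` for self-intersecting or degenerate
    contours.  Clockwise contours are re-oriented (the caller may log this).
    """
    if not isinstance(polygon, Polygon) or polygon.is_empty:
        raise GeometryError("contour must be a non-empty polygon")
    if len(polygon.exterior.coords) - 1 < 3:
        raise GeometryError("contour needs at least 3 vertices")
    if not polygon.is_valid:
        raise GeometryError("contour is not a simple polygon (self-intersection?)")
    if polygon.area < 1e-6:
        raise GeometryError(f"degenerate contour, area {polygon.area:.2e} mm^2")
    if not polygon.exterior.is_ccw:
        if not reorient:
            raise GeometryError("contour is clockwise")
        polygon = shapely.reverse(polygon)
    return polygon


def _as_region(geom) -> MultiPolygon:
    """Normalise any shapely output to a (possibly empty) MultiPolygon."""
    if geom.is_empty:
        return MultiPolygon([])
    if isinstance(geom, Polygon):
        return MultiPolygon([geom])
    if isinstance(geom, MultiPolygon):
        return geom
    # GeometryCollection from boolean ops: keep polygonal parts only
    polys = [g for g in getattr(geom, "geoms", []) if isinstance(g, Polygon)
             and g.area > AREA_EPS]
    return MultiPolygon(polys)


def predicted_region(burr: DeviceCircle, pre_lumen: Polygon,
                     n_vertices: int = 360) -> MultiPolygon:
    """Part of the burr circle lying in the vessel wall (outside the lumen).

    This is the predicted ablation region: the burr-sized circle minus the
    open interior of the pre-procedural lumen.  May be empty when the burr
    fits inside the lumen.
    """
    pre_lumen = validate_contour(pre_lumen)
    return _as_region(burr.polygon(n_vertices).difference(pre_lumen))


def actual_region(pre_lumen: Polygon, post_lumen: Polygon) -> MultiPolygon:
    """Tissue removed by ablation: post-lumen minus registered pre-lumen.

    Apparent lumen *loss* (pre minus post, e.g. tissue prolapse) is not part
    of the ablated region; obtain it separately with :func:`lumen_loss_region`.
    """
    pre_lumen = validate_contour(pre_lumen)
    post_lumen = validate_contour(post_lumen)
    return _as_region(post_lumen.difference(pre_lumen))


def lumen_loss_region(pre_lumen: Polygon, post_lumen: Polygon) -> MultiPolygon:
    """Diagnostic region: pre-lumen area lost after the procedure."""
    return _as_region(validate_contour(pre_lumen).difference(validate_contour(post_lumen)))


def overlap_region(predicted: MultiPolygon, actual: MultiPolygon) -> MultiPolygon:
    """Intersection of predicted and actual ablation regions."""
    return _as_region(shapely.intersection(predicted, actual))


def region_area(region) -> float:
    """Total area of a region (components minus holes), mm^2; >= 0."""
    return float(region.area)


def _edge_intervals(ring_coords: np.ndarray, cx: float, cy: float) -> np.ndarray:
    """Angular intervals (start, width), width <= 180 deg, subtended by edges."""
    x = ring_coords[:, 0] - cx
    y = ring_coords[:, 1] - cy
    ang = np.degrees(np.arctan2(y, x)) % 360.0
    a, b = ang[:-1], ang[1:]
    width = (b - a) % 360.0
    # each straight edge subtends the arc <= 180 deg between endpoint angles
    start = np.where(width <= 180.0, a, b)
    w = np.where(width <= 180.0, width, 360.0 - width)
    return np.c_[start, w]


def _merge_circular(intervals: np.ndarray) -> float:
    """Total measure (deg) of a union of circular intervals (start, width)."""
    if len(intervals) == 0:
        return 0.0
    if np.any(intervals[:, 1] >= 360.0):
        return 360.0
    # unwrap: split intervals crossing 360
    parts = []
    for s, w in intervals:
        s = s % 360.0
        if s + w <= 360.0:
            parts.append((s, s + w))
        else:
            parts.append((s, 360.0))
            parts.append((0.0, (s + w) - 360.0))
    parts.sort()
    total = 0.0
    cur_lo, cur_hi = parts[0]
    for lo, hi in parts[1:]:
        if lo > cur_hi:
            total += cur_hi - cur_lo
            cur_lo, cur_hi = lo, hi
        else:
            cur_hi = max(cur_hi, hi)
    total += cur_hi - cur_lo
    return min(total, 360.0)


def angular_extent(region, center: Point2D) -> float:
    """Angular measure (degrees) of a region as seen from `center`.

    The union of the angular intervals subtended at `center` by every
    component of the region, with 0/360 wrap-around merged; 0 for an empty
    region, at most 360.  Straight polygon edges subtend exact arcs, so no
    ray sampling is needed.  `center` (the lumen centroid) must not lie
    inside the region: ablation lives in the vessel wall.
    """
    region = _as_region(region) if not isinstance(region, MultiPolygon) else region
    if region.is_empty or region.area <= AREA_EPS:
        return 0.0
    pt = Point(center.x, center.y)
    if region.covers(pt):
        raise GeometryError("angle center lies inside the region")
    intervals = [
        _edge_intervals(np.asarray(poly.exterior.coords), center.x, center.y)
        for poly in region.geoms
    ]
    return _merge_circular(np.vstack(intervals))


def _shape_of(obj) -> tuple[object, float]:
    """(shapely boundary-owner, radius) for clearance computation."""
    if isinstance(obj, DeviceCircle):
        return Point(obj.center.x, obj.center.y), obj.radius
    if isinstance(obj, Polygon):
        return obj, 0.0
    raise GeometryError(f"unsupported shape {type(obj).__name__}")


def min_clearance(a: DeviceCircle | Polygon, b: DeviceCircle | Polygon) -> float:
    """Minimum surface-to-surface clearance between two shapes, mm.

    Circle-circle clearance is exact: centre distance minus both radii,
    clamped at zero (overlap or containment means contact).  For a circle
    against a lumen contour the relevant surface is the contour itself, so
    the clearance is the distance from the circle surface to the polygon
    boundary (zero if the circle crosses it) — this is the device-to-intima
    distance for a device sitting inside the lumen.  Symmetric in its
    arguments.
    """
    ga, ra = _shape_of(a)
    gb, rb = _shape_of(b)
    if isinstance(ga, Point) and isinstance(gb, Point):
        d = ga.distance(gb)
        return max(0.0, d - ra - rb)
    if isinstance(ga, Point) or isinstance(gb, Point):
        pt, r = (ga, ra) if isinstance(ga, Point) else (gb, rb)
        poly = gb if isinstance(ga, Point) else ga
        d_boundary = pt.distance(poly.exterior)
        return max(0.0, d_boundary - r)
    # polygon vs polygon: boundary-to-boundary, zero on overlap
    if ga.intersects(gb):
        return 0.0
    return float(ga.distance(gb))


def lumen_diameters(lumen: Polygon, step_deg: float = 1.0,
                    ) -> tuple[float, float, float]:
    """Minimum and mean lumen diameter (mm) plus lumen area (mm^2).

    Diameters are full chord lengths through the lumen centroid, sampled at
    `step_deg` steps over [0, 180).  For a non-convex contour a chord may
    exit and re-enter the lumen; the total in-lumen length is used.
    """
    lumen = validate_contour(lumen)
    centroid = lumen.centroid
    cx, cy = centroid.x, centroid.y
    minx, miny, maxx, maxy = lumen.bounds
    reach = 2.0 * max(maxx - minx, maxy - miny) + 1.0
    angles = np.arange(0.0, 180.0, step_deg)
    chords = np.empty(len(angles))
    n_reentrant = 0
    for i, deg in enumerate(angles):
        t = math.radians(deg)
        dx, dy = reach * math.cos(t), reach * math.sin(t)
        line = shapely.LineString([(cx - dx, cy - dy), (cx + dx, cy + dy)])
        seg = lumen.intersection(line)
        if seg.geom_type == "MultiLineString":
            n_reentrant += 1
        chords[i] = seg.length
    if n_reentrant:
        logging.getLogger(__name__).debug(
            "%d of %d chords exit and re-enter the lumen (non-convex contour)",
            n_reentrant, len(angles))
    return float(chords.min()), float(chords.mean()), float(lumen.area)
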