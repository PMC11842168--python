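"""Planar geometry primitives for lake-migration simulation.

All coordinates are Cartesian meters; no geographic CRS handling. Bearings
follow the navigation convention: degrees clockwise from grid north (+y),
normalized to [0, 360). Turning angles are signed degrees, positive
clockwise.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import shapely
from shapely.geometry import LineString, Point, Polygon

__all__ = [
    "CaptureRegion",
    "normalize_bearing",
    "bearing_to_unit",
    "point_in_polygon",
    "segment_crosses_region",
    "step_endpoint",
    "size_capture_region",
    "exposed_arc_length",
    "inward_normal_bearing",
    "validate_polygon",
    "InfeasibleGeometryError",
]


class InfeasibleGeometryError(ValueError):
    """No geometric solution satisfies the requested constraints."""


def normalize_bearing(degrees: float) -> float:
    """Wrap a bearing to [0, 360). Idempotent."""
    return float(degrees) % 360.0


def bearing_to_unit(bearing: float) -> tuple[float, float]:
    """Unit displacement (dx, dy) for a bearing in degrees clockwise from +y."""
    r = math.radians(bearing)
    return math.sin(r), math.cos(r)


def validate_polygon(poly: Polygon) -> Polygon:
    """Check structural validity: >=3 vertices, simple ring, positive area.

    Raises ``ValueError`` on failure; returns the polygon unchanged otherwise.
    """
    if not isinstance(poly, Polygon):
        raise ValueError(f"expected shapely Polygon, got {type(poly).__name__}")
    if poly.is_empty or len(poly.exterior.coords) < 4:  # ring repeats 1st vertex
        raise ValueError("polygon needs at least 3 distinct vertices")
    if not poly.is_valid:
        raise ValueError(f"invalid polygon: {shapely.is_valid_reason(poly)}")
    if poly.area <= 0:
        raise ValueError("polygon has non-positive area")
    return poly


def point_in_polygon(p: tuple[float, float], poly: Polygon) -> bool:
    """True iff ``p`` is strictly inside or on the boundary of ``poly``.

    Boundary points count as inside (closed-polygon convention), so a path
    vertex landing exactly on the shoreline does not escape the lake.
    """
    validate_polygon(poly)
    return bool(shapely.intersects_xy(poly, p[0], p[1]))


def step_endpoint(
    p: tuple[float, float], bearing: float, length: float
) -> tuple[float, float]:
    """Point at Euclidean distance ``length`` from ``p`` along ``bearing``."""
    if length <= 0:
        raise ValueError("step length must be positive")
    dx, dy = bearing_to_unit(bearing)
    return (p[0] + length * dx, p[1] + length * dy)


def segment_point_distance(
    ax: float, ay: float, bx: float, by: float, px: float, py: float
) -> float:
    """Minimum distance from point (px, py) to segment a-b."""
    vx, vy = bx - ax, by - ay
    wx, wy = px - ax, py - ay
    seg2 = vx * vx + vy * vy
    if seg2 == 0.0:
        return math.hypot(wx, wy)
    t = (wx * vx + wy * vy) / seg2
    if t < 0.0:
        t = 0.0
    elif t > 1.0:
        t = 1.0
    return math.hypot(wx - t * vx, wy - t * vy)


@dataclass(frozen=True)
class CaptureRegion:
    """Circular end-point region at the lake outlet.

    A migration succeeds when the path crosses into the disc. The disc
    straddles the shoreline; it is sized by ``exposed_perimeter`` — the arc
    length of its circle lying inside the lake — rather than by radius,
    because the outlet opening, not the disc, is the biologically meaningful
    width.
    """

    center: tuple[float, float]
    radius: float
    exposed_perimeter: float = field(default=float("nan"))

    def __post_init__(self) -> None:
        if not (self.radius > 0):
            raise ValueError("capture region radius must be positive")

    def crossed_by(self, a: tuple[float, float], b: tuple[float, float]) -> bool:
        """True iff segment a->b intersects the disc (entering counts even
        if the segment exits again)."""
        return (
            segment_point_distance(
                a[0], a[1], b[0], b[1], self.center[0], self.center[1]
            )
            <= self.radius
        )


def segment_crosses_region(
    a: tuple[float, float], b: tuple[float, float], region: CaptureRegion
) -> bool:
    """True iff segment a->b intersects the disc of ``region``."""
    return region.crossed_by(a, b)


def exposed_arc_length(
    poly: Polygon, center: tuple[float, float], radius: float, quad_segs: int = 256
) -> float:
    """Arc length of the circle of ``radius`` about ``center`` inside ``poly``."""
    circle = Point(center).buffer(radius, quad_segs=quad_segs)
    # polygonal circle underestimates arc length by factor sinc(pi/(2*quad_segs));
    # correct so the returned value approximates the true arc
    n = 4 * quad_segs
    chord_factor = n * math.sin(math.pi / n) / math.pi
    return float(circle.exterior.intersection(poly).length) / chord_factor


def size_capture_region(
    poly: Polygon,
    center: tuple[float, float],
    exposed_perimeter: float,
    rtol: float = 0.005,
) -> CaptureRegion:
    """Solve (bisection) for the disc radius whose in-lake arc has the target
    length.

    ``center`` must lie on the polygon boundary (within 1 m). The exposed arc
    is monotone non-decreasing in radius for the shoreline geometries used
    here, so bisection on radius converges; the result is validated to 1%.
    """
    validate_polygon(poly)
    if not (exposed_perimeter > 0):
        raise ValueError("exposed_perimeter must be positive")
    if poly.exterior.distance(Point(center)) > 1.0:
        raise ValueError("capture center must lie on the polygon boundary (within 1 m)")

    # on a locally straight shoreline the exposed arc is a half circle,
    # so r = P/pi is an excellent starting guess
    minx, miny, maxx, maxy = poly.bounds
    diameter = math.hypot(maxx - minx, maxy - miny)
    lo, hi = 0.0, exposed_perimeter / math.pi
    # grow hi until the arc exceeds the target (or geometry is infeasible)
    while exposed_arc_length(poly, center, hi) < exposed_perimeter:
        lo = hi
        hi *= 2.0
        if hi > diameter:
            raise InfeasibleGeometryError(
                f"no radius below the lake diameter ({diameter:.0f} m) exposes "
                f"{exposed_perimeter:.0f} m of arc"
            )
    for _ in range(60):
        mid = 0.5 * (lo + hi)
        if exposed_arc_length(poly, center, mid) < exposed_perimeter:
            lo = mid
        else:
            hi = mid
        if hi - lo <= rtol * 0.1 * hi:
            break
    radius = 0.5 * (lo + hi)
    achieved = exposed_arc_length(poly, center, radius)
    if abs(achieved - exposed_perimeter) > 0.01 * exposed_perimeter:
        raise InfeasibleGeometryError(
            f"bisection achieved arc {achieved:.1f} m, "
            f"target {exposed_perimeter:.1f} m"
        )
    return CaptureRegion(
        center=(float(center[0]), float(center[1])),
        radius=float(radius),
        exposed_perimeter=float(exposed_perimeter),
    )


def inward_normal_bearing(poly: Polygon, point: tuple[float, float]) -> float:
    """Bearing of the inward-pointing boundary normal at a boundary point.

    The tangent is estimated from the exterior ring by small arc offsets
    around the projection of ``point``; of the two normals, the one whose
    short probe lands inside the polygon is returned.
    """
    ring = poly.exterior
    s = ring.project(Point(point))
    eps = max(ring.length * 1e-4, 0.5)
    p0 = ring.interpolate((s - eps) % ring.length)
    p1 = ring.interpolate((s + eps) % ring.length)
    tx, ty = p1.x - p0.x, p1.y - p0.y
    norm = math.hypot(tx, ty)
    if norm == 0.0:
        raise ValueError("degenerate boundary tangent")
    tx, ty = tx / norm, ty / norm
    # two candidate normals, rotated +-90 degrees from the tangent
    for nx, ny in ((-ty, tx), (ty, -tx)):
        probe_len = 1.0
        for _ in range(20):
            probe = (point[0] + probe_len * nx, point[1] + probe_len * ny)
            if shapely.intersects_xy(poly, probe[0], probe[1]):
                return normalize_bearing(math.degrees(math.atan2(nx, ny)))
            probe_len *= 0.5
    raise InfeasibleGeometryError("could not determine inward normal")


def boundary_point_at_angle(
    poly: Polygon, angle_deg: float, origin: tuple[float, float] | None = None
) -> tuple[float, float]:
    """Boundary point hit by a ray from ``origin`` (default: centroid) at the
    given *math* angle (degrees counter-clockwise from +x).

    Used to place start/capture points at matched angular coordinates across
    basin shapes.
    """
    validate_polygon(poly)
    if origin is None:
        c = poly.centroid
        origin = (c.x, c.y)
    minx, miny, maxx, maxy = poly.bounds
    reach = 2.0 * math.hypot(maxx - minx, maxy - miny)
    r = math.radians(angle_deg)
    far = (origin[0] + reach * math.cos(r), origin[1] + reach * math.sin(r))
    hit = poly.exterior.intersection(LineString([origin, far]))
    if hit.is_empty:
        raise InfeasibleGeometryError(f"ray at {angle_deg} deg misses the boundary")
    pts = []
    for geom in getattr(hit, "geoms", [hit]):
        pts.extend(np.asarray(geom.coords))
    pts = np.asarray(pts)
    d = np.hypot(pts[:, 0] - origin[0], pts[:, 1] - origin[1])
    x, y = pts[np.argmax(d)]  # outermost crossing
    return (float(x), float(y))
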