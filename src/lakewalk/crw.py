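"""Correlated-random-walk engine for smolt migration inside a lake polygon.

Each path is a sequence of fixed-length steps. The heading of every step is
the previous heading plus a turning angle drawn from Normal(mu=0, sigma);
small sigma gives locally straight, globally wandering search paths. A
proposed step whose segment would leave the lake polygon is rejected and
redrawn with an inflated standard deviation

    sigma_eff = sigma * (1 + c * k**e)        (defaults c=0.1, e=2)

where k counts consecutive rejected proposals within the current step; k
resets to 0 once a step is accepted. A path terminates with

* ``success``          — the step reaches the capture disc at the outlet
                         (by default the step's endpoint lands in the disc —
                         the simulated fish checks its position once per
                         step — optionally any segment crossing; the test
                         precedes containment, so a proposal "colliding"
                         with the outlet region still succeeds);
* ``failure_cap``      — the step budget floor(max_path_length / L) is spent;
* ``failure_retries``  — no admissible heading found within the retry ceiling
                         (a guard absent from the underlying model; counted
                         separately and expected to be ~0).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import TYPE_CHECKING, Iterable, Sequence

import numpy as np
import shapely

from .geometry import CaptureRegion, bearing_to_unit, normalize_bearing

if TYPE_CHECKING:  # pragma: no cover
    from .basins import LakeBasin

__all__ = [
    "CRWParams",
    "Path",
    "draw_turn",
    "collision_sigma",
    "simulate_path",
    "simulate_ensemble",
]

SUCCESS = "success"
FAILURE_CAP = "failure_cap"
FAILURE_RETRIES = "failure_retries"


@dataclass(frozen=True)
class CRWParams:
    """Parameters of one correlated-random-walk condition.

    step_length
        Fixed distance (m) moved per step before a new turn is drawn.
    turn_sd
        Standard deviation (degrees) of the Gaussian turning-angle
        distribution; 0 degenerates to a straight path.
    turn_mean
        Mean turning angle (degrees); 0 for an unbiased walk.
    max_path_length
        Total path-length budget (m); the step budget is its floor-quotient
        by step_length, so every same-step-length path has the same maximum
        possible length.
    collision_coeff, collision_exponent
        Constants of the rejection-inflation rule sigma*(1 + c*k**e). The
        exponent is exposed because the rule is also used in the literature
        as sigma*(1 + c*k)**e.
    max_collision_retries
        Guard on redraws within one step.
    capture_mode
        ``"vertex"`` (default): success when a step's endpoint lands inside
        the capture disc, i.e. arrival is registered at the per-step
        position fixes. ``"segment"``: success when the step's segment
        crosses the disc at any point, even transiently. The vertex mode
        penalizes long steps, which can jump past a small outlet region
        between fixes.
    """

    step_length: float
    turn_sd: float
    turn_mean: float = 0.0
    max_path_length: float = 75_000.0
    collision_coeff: float = 0.1
    collision_exponent: float = 2.0
    max_collision_retries: int = 100
    capture_mode: str = "vertex"
    seed: int | None = None

    def __post_init__(self) -> None:
        if not (self.step_length > 0):
            raise ValueError("step_length must be positive")
        if self.turn_sd < 0:
            raise ValueError("turn_sd must be non-negative")
        if self.max_path_length < self.step_length:
            raise ValueError("max_path_length must be at least one step_length")
        if self.max_collision_retries < 1:
            raise ValueError("max_collision_retries must be >= 1")
        if self.capture_mode not in ("vertex", "segment"):
            raise ValueError("capture_mode must be 'vertex' or 'segment'")

    @property
    def max_steps(self) -> int:
        return int(self.max_path_length // self.step_length)


@dataclass
class Path:
    """One simulated migration path."""

    points: np.ndarray  # (n_steps + 1, 2)
    headings: np.ndarray  # (n_steps,) degrees in [0, 360)
    outcome: str
    n_steps: int
    distance: float  # n_steps * step_length, by construction
    n_collisions: int

    @property
    def succeeded(self) -> bool:
        return self.outcome == SUCCESS

    def turning_angles(self) -> np.ndarray:
        """Signed per-step turning angles (degrees), wrapped to (-180, 180]."""
        d = np.diff(self.headings)
        return (d + 180.0) % 360.0 - 180.0


def draw_turn(sigma_eff: float, rng: np.random.Generator, mu: float = 0.0) -> float:
    """One turning angle (signed degrees) from Normal(mu, sigma_eff)."""
    if sigma_eff < 0:
        raise ValueError("sigma_eff must be non-negative")
    if sigma_eff == 0.0:
        return float(mu)
    return float(rng.normal(mu, sigma_eff))


def collision_sigma(
    sigma: float, k: int, coeff: float = 0.1, exponent: float = 2.0
) -> float:
    """Inflated turning-angle SD after k rejected proposals: sigma*(1+c*k**e)."""
    if k < 0:
        raise ValueError("k must be non-negative")
    return sigma * (1.0 + coeff * float(k) ** exponent)


class _EdgeGrid:
    """Uniform spatial hash of a polygon's boundary edges.

    For a walker currently strictly inside the polygon, a proposed step
    stays inside iff its segment crosses no boundary edge; only edges whose
    bounding cells overlap the step need testing, which makes the check
    O(local edges) instead of O(perimeter).
    """

    def __init__(self, poly, cell: float | None = None):
        rings = [poly.exterior, *poly.interiors]
        segs: list[tuple[float, float, float, float]] = []
        for ring in rings:
            c = np.asarray(ring.coords)
            segs.extend(
                (c[i, 0], c[i, 1], c[i + 1, 0], c[i + 1, 1])
                for i in range(len(c) - 1)
            )
        self.segs = segs
        if cell is None:
            perim = sum(r.length for r in rings)
            cell = min(max(3.0 * perim / max(len(segs), 1), 50.0), 1000.0)
        self.cell = cell
        self.index: dict[tuple[int, int], list[int]] = {}
        for i, (x0, y0, x1, y1) in enumerate(segs):
            for key in self._keys(x0, y0, x1, y1):
                self.index.setdefault(key, []).append(i)

    def _keys(self, x0, y0, x1, y1):
        c = self.cell
        ix0, ix1 = sorted((int(x0 // c), int(x1 // c)))
        iy0, iy1 = sorted((int(y0 // c), int(y1 // c)))
        return [
            (ix, iy)
            for ix in range(ix0, ix1 + 1)
            for iy in range(iy0, iy1 + 1)
        ]

    def segment_clear(self, x0: float, y0: float, x1: float, y1: float) -> bool:
        """True iff segment (x0,y0)-(x1,y1) crosses no boundary edge."""
        segs = self.segs
        index = self.index
        seen: set[int] = set()
        dx, dy = x1 - x0, y1 - y0
        for key in self._keys(x0, y0, x1, y1):
            for i in index.get(key, ()):
                if i in seen:
                    continue
                seen.add(i)
                ax, ay, bx, by = segs[i]
                # orientation tests: the segments intersect iff the endpoints
                # of each straddle the other's supporting line
                d1 = dx * (ay - y0) - dy * (ax - x0)
                d2 = dx * (by - y0) - dy * (bx - x0)
                if (d1 > 0 and d2 > 0) or (d1 < 0 and d2 < 0):
                    continue
                ex, ey = bx - ax, by - ay
                d3 = ex * (y0 - ay) - ey * (x0 - ax)
                d4 = ex * (y1 - ay) - ey * (x1 - ax)
                if (d3 > 0 and d4 > 0) or (d3 < 0 and d4 < 0):
                    continue
                # collinear non-overlapping bboxes still count as clear
                if d1 == d2 == d3 == d4 == 0.0:
                    if max(min(ax, bx), min(x0, x1)) > min(max(ax, bx), max(x0, x1)):
                        continue
                    if max(min(ay, by), min(y0, y1)) > min(max(ay, by), max(y0, y1)):
                        continue
                return False
        return True


def _segment_checker(basin: "LakeBasin"):
    """Return segment_ok(x0, y0, x1, y1) testing that a step stays in-lake.

    Convex basins with an analytic containment predicate only need the
    endpoint test (a chord between interior points cannot leave a convex
    set). Arbitrary shorelines use the boundary edge grid: starting strictly
    inside, a step stays inside iff it crosses no boundary edge.
    """
    contains = basin.fast_contains
    if contains is not None and basin.convex:
        def segment_ok(x0, y0, x1, y1):
            return contains(x1, y1)
        return segment_ok
    grid = basin.metadata.get("_edge_grid")
    if not isinstance(grid, _EdgeGrid):
        grid = _EdgeGrid(basin.polygon)
        basin.metadata["_edge_grid"] = grid  # cached per basin
    return grid.segment_clear


def simulate_path(
    basin: "LakeBasin", params: CRWParams, rng: np.random.Generator
) -> Path:
    """Simulate one correlated random walk in ``basin``.

    The first step already applies a turn drawn around the basin's initial
    bearing (the bearing at which the inflowing river intercepts the lake),
    treating step 1 like every other step.
    """
    x, y = basin.start
    # the start sits on the shoreline: tolerate float rounding off the ring
    if not shapely.dwithin(basin.polygon, shapely.Point(x, y), 1e-6):
        raise ValueError("basin start point is outside the lake polygon")
    if basin.fast_contains is None or not basin.convex:
        # the edge-crossing test needs a strictly interior start; nudge a
        # river-mouth start off the shoreline along the inflow bearing
        if not shapely.contains_xy(basin.polygon, x, y):
            ux, uy = bearing_to_unit(basin.initial_bearing)
            for nudge in (1e-2, 1e-3, 1e-4, 1e-6):
                if shapely.contains_xy(basin.polygon, x + nudge * ux, y + nudge * uy):
                    x, y = x + nudge * ux, y + nudge * uy
                    break

    segment_ok = _segment_checker(basin)
    capture: CaptureRegion = basin.capture
    cx, cy = capture.center
    radius = capture.radius
    radius2 = radius * radius
    vertex_capture = params.capture_mode == "vertex"

    L = params.step_length
    sd = params.turn_sd
    mu = params.turn_mean
    coeff = params.collision_coeff
    expo = params.collision_exponent
    retries = params.max_collision_retries
    max_steps = params.max_steps
    heading = basin.initial_bearing

    normal = rng.normal
    sin = math.sin
    cos = math.cos
    hypot = math.hypot
    rad = math.pi / 180.0

    pts = np.empty((max_steps + 1, 2))
    pts[0] = (x, y)
    headings = np.empty(max_steps)
    n_collisions = 0
    outcome = FAILURE_CAP
    n = 0

    for n in range(1, max_steps + 1):
        accepted = False
        hit = False
        k = 0
        while True:
            sigma_eff = sd if k == 0 else sd * (1.0 + coeff * float(k) ** expo)
            h = heading + (mu if sigma_eff == 0.0 else normal(mu, sigma_eff))
            hr = h * rad
            nx = x + L * sin(hr)
            ny = y + L * cos(hr)
            # capture test first: colliding with the outlet region succeeds
            # even if the endpoint would leave the lake
            if vertex_capture:
                dxc, dyc = nx - cx, ny - cy
                if dxc * dxc + dyc * dyc <= radius2:
                    hit = True
                    break
            else:
                vx, vy = nx - x, ny - y
                wx, wy = cx - x, cy - y
                t = (wx * vx + wy * vy) / (L * L)
                if t < 0.0:
                    t = 0.0
                elif t > 1.0:
                    t = 1.0
                if hypot(wx - t * vx, wy - t * vy) <= radius:
                    hit = True
                    break
            if segment_ok(x, y, nx, ny):
                accepted = True
                break
            k += 1
            n_collisions += 1
            if k > retries:
                break
        if not (accepted or hit):
            outcome = FAILURE_RETRIES
            n -= 1
            break
        x, y = nx, ny
        heading = h % 360.0
        pts[n] = (x, y)
        headings[n - 1] = heading
        if hit:
            outcome = SUCCESS
            break
    # else: loop exhausted -> failure_cap, n == max_steps

    return Path(
        points=pts[: n + 1].copy(),
        headings=headings[:n].copy(),
        outcome=outcome,
        n_steps=n,
        distance=n * L,
        n_collisions=n_collisions,
    )


def path_rng(seed: int | Sequence[int], index: int) -> np.random.Generator:
    """Deterministic per-path substream: Generator seeded by (seed..., index).

    The scheme is a plain ``SeedSequence([*seed, index])``, so ensembles are
    bit-reproducible across machines and adding paths never perturbs earlier
    ones.
    """
    entropy = [seed] if isinstance(seed, (int, np.integer)) else list(seed)
    return np.random.default_rng(np.random.SeedSequence(entropy + [index]))


def simulate_ensemble(
    basin: "LakeBasin",
    params: CRWParams,
    n: int,
    seed: int | Sequence[int] | None = None,
) -> list[Path]:
    """Simulate ``n`` independent paths from per-path substreams of ``seed``."""
    if n < 1:
        raise ValueError("n must be >= 1")
    if seed is None:
        seed = params.seed
    if seed is None:
        raise ValueError("an ensemble seed is required (argument or CRWParams.seed)")
    return [simulate_path(basin, params, path_rng(seed, i)) for i in range(n)]
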