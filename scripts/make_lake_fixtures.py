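"""Regenerate the bundled synthetic stand-in shorelines for the five study
lakes (src/lakewalk/data/lakes/*_synthetic.geojson).

These polygons are constructed harmonic shapes, not digitized shorelines:
each emulates only the coarse aspect of the real lake (elongation, rough
placement of the inflow and outflow) and is area-normalized on load. Vertex
coordinates are meters, centroid near the origin.

Run from the repository root:  python scripts/make_lake_fixtures.py
"""

from __future__ import annotations

import json
import math
from pathlib import Path

import numpy as np
from shapely.geometry import Polygon

OUT = Path(__file__).resolve().parents[1] / "src" / "lakewalk" / "data" / "lakes"

# per-lake shape recipe: x/y stretch, harmonic irregularities (amplitude,
# order, phase deg), start/end placement as math angles (deg CCW from +x),
# target area km^2, and an optional widening of the southern half (Lomond's
# basin broadens toward the outflow end)
LAKES = {
    "Achonachie": dict(
        sx=2.6, sy=1.0, harmonics=[(0.10, 2, 35.0), (0.06, 3, 120.0)],
        start_deg=175.0, end_deg=5.0, area_km2=0.69, south_widen=0.0,
    ),
    "Meig": dict(
        sx=3.0, sy=1.0, harmonics=[(0.08, 2, 80.0), (0.05, 3, 200.0)],
        start_deg=182.0, end_deg=-4.0, area_km2=0.45, south_widen=0.0,
    ),
    "Garve": dict(
        sx=1.8, sy=1.0, harmonics=[(0.12, 2, 10.0), (0.05, 4, 60.0)],
        start_deg=168.0, end_deg=-10.0, area_km2=1.83, south_widen=0.0,
    ),
    "Lomond": dict(
        sx=1.0, sy=3.2, harmonics=[(0.10, 2, 150.0), (0.07, 3, 40.0)],
        start_deg=-62.0, end_deg=242.0, area_km2=71.0, south_widen=0.55,
    ),
    "Bassenthwaite": dict(
        sx=1.0, sy=2.8, harmonics=[(0.09, 2, 300.0), (0.05, 3, 15.0)],
        start_deg=88.0, end_deg=268.0, area_km2=5.1, south_widen=0.0,
    ),
}

N_VERTICES = 160


def build_outline(recipe: dict) -> np.ndarray:
    t = np.linspace(0.0, 2.0 * math.pi, N_VERTICES, endpoint=False)
    r = np.ones_like(t)
    for amp, order, phase in recipe["harmonics"]:
        r += amp * np.cos(order * t + math.radians(phase))
    x = recipe["sx"] * r * np.cos(t)
    y = recipe["sy"] * r * np.sin(t)
    if recipe["south_widen"]:
        ylo, yhi = y.min(), y.max()
        frac = (yhi - y) / (yhi - ylo)  # 0 at the north tip, 1 at the south
        x = x * (1.0 + recipe["south_widen"] * frac)
    scale = math.sqrt(recipe["area_km2"] * 1e6 / Polygon(np.c_[x, y]).area)
    return np.c_[x, y] * scale


def boundary_point(verts: np.ndarray, angle_deg: float) -> tuple[float, float]:
    """Outermost boundary vertex nearest the requested direction from the
    centroid (fixture points are snapped to the ring on load anyway)."""
    poly = Polygon(verts)
    c = poly.centroid
    ang = np.degrees(np.arctan2(verts[:, 1] - c.y, verts[:, 0] - c.x))
    d = np.abs((ang - angle_deg + 180.0) % 360.0 - 180.0)
    i = int(np.argmin(d))
    return (float(verts[i, 0]), float(verts[i, 1]))


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    for name, recipe in LAKES.items():
        verts = build_outline(recipe)
        poly = Polygon(verts)
        assert poly.is_valid, name
        start = boundary_point(verts, recipe["start_deg"])
        end = boundary_point(verts, recipe["end_deg"])
        ring = [[round(float(x), 1), round(float(y), 1)] for x, y in verts]
        ring.append(ring[0])
        gj = {
            "type": "FeatureCollection",
            "metadata": {
                "lake": name,
                "synthetic": True,
                "approximate": True,
                "note": (
                    "constructed stand-in shoreline; coarse aspect only, "
                    "area normalized on load"
                ),
                "crs": "planar meters, centroid origin",
            },
            "features": [
                {
                    "type": "Feature",
                    "properties": {"role": "lake"},
                    "geometry": {"type": "Polygon", "coordinates": [ring]},
                },
                {
                    "type": "Feature",
                    "properties": {"role": "start"},
                    "geometry": {
                        "type": "Point",
                        "coordinates": [round(start[0], 1), round(start[1], 1)],
                    },
                },
                {
                    "type": "Feature",
                    "properties": {"role": "capture_center"},
                    "geometry": {
                        "type": "Point",
                        "coordinates": [round(end[0], 1), round(end[1], 1)],
                    },
                },
            ],
        }
        path = OUT / f"{name.lower()}_synthetic.geojson"
        path.write_text(json.dumps(gj) + "\n")
        print(f"{name}: {path.name}  area={poly.area / 1e6:.2f} km^2")


if __name__ == "__main__":
    main()
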