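"""Serialization: GeoJSON basins and trajectories, WKT import, CSV tables,
and JSON run manifests.

Coordinates are planar meters throughout (no CRS metadata is attached).
GeoJSON floats are serialized with full precision so a written basin reads
back with bit-identical vertices.
"""

from __future__ import annotations

import hashlib
import json
import math
from dataclasses import asdict
from datetime import datetime, timezone
from importlib.metadata import version
from pathlib import Path as FsPath

import shapely
import shapely.wkt
from shapely.geometry import Polygon, mapping, shape

from .basins import LakeBasin
from .crw import Path
from .geometry import CaptureRegion, validate_polygon

__all__ = [
    "polygon_from_wkt",
    "polygon_to_wkt",
    "basin_to_geojson",
    "basin_from_geojson",
    "write_basin",
    "read_basin",
    "paths_to_geojson",
    "write_manifest",
]


def polygon_from_wkt(text: str) -> Polygon:
    """Parse a WKT POLYGON string (planar meters)."""
    geom = shapely.wkt.loads(text)
    if not isinstance(geom, Polygon):
        raise ValueError(f"expected POLYGON, got {geom.geom_type}")
    return validate_polygon(geom)


def polygon_to_wkt(poly: Polygon) -> str:
    return shapely.to_wkt(poly, rounding_precision=-1)


def basin_to_geojson(basin: LakeBasin) -> dict:
    """FeatureCollection with the lake polygon and the start/capture points.

    Capture radius and exposed perimeter, the initial bearing, and basin
    metadata travel in feature/collection properties, so the collection is a
    complete, self-contained basin description.
    """
    return {
        "type": "FeatureCollection",
        "metadata": {
            "name": basin.name,
            "area_km2": basin.area_km2,
            "start_end_km": basin.start_end_km,
            "convex": basin.convex,
            **basin.metadata,
        },
        "features": [
            {
                "type": "Feature",
                "properties": {"role": "lake"},
                "geometry": mapping(basin.polygon),
            },
            {
                "type": "Feature",
                "properties": {
                    "role": "start",
                    "initial_bearing_deg": basin.initial_bearing,
                },
                "geometry": {"type": "Point", "coordinates": list(basin.start)},
            },
            {
                "type": "Feature",
                "properties": {
                    "role": "capture_center",
                    "radius_m": basin.capture.radius,
                    "exposed_perimeter_m": basin.capture.exposed_perimeter,
                },
                "geometry": {
                    "type": "Point",
                    "coordinates": list(basin.capture.center),
                },
            },
        ],
    }


def basin_from_geojson(gj: dict) -> LakeBasin:
    """Rebuild a LakeBasin from its FeatureCollection form.

    The analytic containment fast path is not serialized; a basin read from
    disk uses polygon-based checks (convexity is re-derived from the
    geometry, so convex basins keep their cheap segment test).
    """
    feats = {f["properties"]["role"]: f for f in gj["features"]}
    poly = shape(feats["lake"]["geometry"])
    validate_polygon(poly)
    meta = dict(gj.get("metadata", {}))
    name = meta.pop("name", "basin")
    area_km2 = meta.pop("area_km2", poly.area / 1e6)
    start_end_km = meta.pop("start_end_km", math.nan)
    meta.pop("convex", None)
    start = tuple(feats["start"]["geometry"]["coordinates"])
    cap_props = feats["capture_center"]["properties"]
    capture = CaptureRegion(
        center=tuple(feats["capture_center"]["geometry"]["coordinates"]),
        radius=cap_props["radius_m"],
        exposed_perimeter=cap_props.get("exposed_perimeter_m", math.nan),
    )
    if math.isnan(start_end_km):
        start_end_km = math.dist(start, capture.center) / 1000.0
    convex = poly.convex_hull.area <= poly.area * (1.0 + 1e-9)
    return LakeBasin(
        name=name,
        polygon=poly,
        start=start,
        initial_bearing=feats["start"]["properties"]["initial_bearing_deg"],
        capture=capture,
        area_km2=area_km2,
        start_end_km=start_end_km,
        metadata=meta,
        fast_contains=None,
        convex=convex,
    )


def write_basin(basin: LakeBasin, path: str | FsPath) -> None:
    FsPath(path).write_text(json.dumps(basin_to_geojson(basin)) + "\n")


def read_basin(path: str | FsPath) -> LakeBasin:
    return basin_from_geojson(json.loads(FsPath(path).read_text()))


def paths_to_geojson(paths: list[Path], properties: dict | None = None) -> dict:
    """LineString FeatureCollection of full trajectories (one per path)."""
    features = []
    for i, p in enumerate(paths):
        props = {
            "path_id": i,
            "outcome": p.outcome,
            "n_steps": p.n_steps,
            "distance_m": p.distance,
            "n_collisions": p.n_collisions,
        }
        if properties:
            props.update(properties)
        features.append(
            {
                "type": "Feature",
                "properties": props,
                "geometry": {
                    "type": "LineString",
                    "coordinates": p.points.tolist(),
                },
            }
        )
    return {"type": "FeatureCollection", "features": features}


def _file_checksum(path: FsPath) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()[:16]


def write_manifest(
    out_dir: str | FsPath,
    seed: int,
    config: dict,
    outputs: list[str] | None = None,
) -> FsPath:
    """Record seed, configuration and output checksums for a run, so every
    result table is traceable to the exact inputs that produced it."""
    out = FsPath(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    try:
        pkg_version = version("lakewalk")
    except Exception:  # not installed (e.g. run from a checkout)
        pkg_version = "unknown"
    manifest = {
        "created_utc": datetime.now(timezone.utc).isoformat(timespec="seconds"),
        "package": {"name": "lakewalk", "version": pkg_version},
        "seed": seed,
        "config": config,
        "config_sha256": hashlib.sha256(
            json.dumps(config, sort_keys=True, default=str).encode()
        ).hexdigest()[:16],
        "outputs": {
            name: _file_checksum(out / name)
            for name in (outputs or [])
            if (out / name).exists()
        },
    }
    path = out / "manifest.json"
    path.write_text(json.dumps(manifest, indent=2, default=str) + "\n")
    return path
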