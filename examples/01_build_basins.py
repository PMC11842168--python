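"""Build the four hypothetical study basins and inspect their geometry.

The basins share the published constraints: a circular (25.0 km^2),
elliptical (22.1 km^2) and rounded-rectangular (27.8 km^2) lake, the last
in two variants that differ only in where migration starts and ends —
laterally on one long shore (5.5 km apart, like the curved basins) or at
the two ends (11.3 km apart). Every basin has a 440-m-circumference
end-point disc at the outlet.

Run:  python examples/01_build_basins.py
"""

from pathlib import Path

from lakewalk import hypothetical_basins
from lakewalk.io import write_basin

out = Path("scratch/basins")
out.mkdir(parents=True, exist_ok=True)

print(f"{'basin':22s} {'area km^2':>9s} {'start-end km':>12s} "
      f"{'capture r m':>11s} {'bearing deg':>11s}")
for basin in hypothetical_basins():
    print(
        f"{basin.name:22s} {basin.polygon.area / 1e6:9.2f} "
        f"{basin.start_end_km:12.2f} {basin.capture.radius:11.1f} "
        f"{basin.initial_bearing:11.1f}"
    )
    write_basin(basin, out / f"{basin.name}.geojson")

print(f"\nGeoJSON written to {out}/. The bearing is the inward shoreline")
print("normal at the start — the direction the inflowing river points into")
print("the lake; every simulated path launches around it.")
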