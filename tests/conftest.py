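"""Shared fixtures: study basins, an open-water test basin, and small
pre-run simulation grids reused across test modules."""

from __future__ import annotations

import numpy as np
import pytest
from shapely.geometry import Polygon

from lakewalk import (
    CRWParams,
    CaptureRegion,
    LakeBasin,
    hypothetical_basins,
    hypothetical_design,
    run_grid,
)


@pytest.fixture(scope="session")
def basins():
    """The four study basins, keyed by name."""
    return {b.name: b for b in hypothetical_basins()}


@pytest.fixture(scope="session")
def circular_basin(basins):
    return basins["circular"]


def make_open_water(side: float = 2e7) -> LakeBasin:
    """A huge square 'lake' whose walls and capture region are unreachable:
    collision-free open water for parameter-recovery and straight-line tests."""
    h = side / 2.0
    poly = Polygon([(-h, -h), (h, -h), (h, h), (-h, h)])
    return LakeBasin(
        name="open_water",
        polygon=poly,
        start=(0.0, 0.0),
        initial_bearing=0.0,
        capture=CaptureRegion(center=(0.0, h), radius=1.0, exposed_perimeter=2 * np.pi),
        area_km2=side * side / 1e6,
        start_end_km=h / 1000.0,
        metadata={"purpose": "test"},
        fast_contains=lambda x, y: -h <= x <= h and -h <= y <= h,
        convex=True,
    )


@pytest.fixture(scope="session")
def open_water():
    return make_open_water()


def make_corridor(length: float = 2000.0, width: float = 400.0) -> LakeBasin:
    """A straight corridor with the capture disc dead ahead at ``length`` m
    from the start: the sigma=0 walk reaches it in exactly length/L steps."""
    hw = width / 2.0
    poly = Polygon([(-hw, -50.0), (hw, -50.0), (hw, length + 50.0), (-hw, length + 50.0)])
    return LakeBasin(
        name="corridor",
        polygon=poly,
        start=(0.0, 0.0),
        initial_bearing=0.0,  # due north, straight at the capture disc
        capture=CaptureRegion(center=(0.0, length), radius=10.0, exposed_perimeter=20 * np.pi),
        area_km2=poly.area / 1e6,
        start_end_km=length / 1000.0,
        metadata={"purpose": "test"},
        convex=True,
    )


@pytest.fixture()
def corridor():
    return make_corridor()


@pytest.fixture(scope="session")
def smoke_grid():
    """A reduced hypothetical grid (30 paths/cell) with per-path records,
    shared by experiment-level and statistics tests."""
    design = hypothetical_design(seed=7, n_per_cell=30)
    cells, paths = run_grid(design, return_paths=True)
    return design, cells, paths
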