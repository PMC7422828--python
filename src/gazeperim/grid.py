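"""The modified 24-2 visual-field test grid.

A standard 24-2 perimetric lattice places 54 points at odd multiples of 3
degrees (6 degree spacing) over the central field, with two extra nasal
points at 27 degrees.  Remote eye-trackers have poor vertical range, so the
top and bottom rows (y = +/-21) are omitted here, leaving 46 locations:
44 test points plus the two blind-spot points at (15, +/-3) (right-eye
format), which sit over the optic nerve head and act as an internal
validity check.

Locations carry a growth-pattern stage: stage-1 "seed" points at
(+/-9, +/-9) are tested first, and each later stage contains points
adjacent (one 6-degree lattice step) to an earlier stage, so completed
estimates can seed the priors of their neighbours.  Blind-spot points are
stage 0 and are tested throughout, outside the growth pattern.

Coordinates are visual-field degrees, x positive rightward, y positive
upward; right-eye format is the internal convention (a left-eye grid is
the x-mirror image).
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "GridLocation",
    "TestGrid",
    "build_grid",
    "growth_pattern",
    "mirror_grid",
    "to_right_eye_format",
    "aggregate_regions",
    "grid_to_frame",
    "grid_from_frame",
]

ROLE_TEST = "test"
ROLE_BLIND_SPOT = "blind_spot"

#: lattice step between neighbouring grid points, degrees
LATTICE_STEP_DEG = 6.0


@dataclass(frozen=True)
class GridLocation:
    x: float  # visual-field degrees, positive = right
    y: float  # visual-field degrees, positive = up
    role: str = ROLE_TEST
    group: int = 1  # growth-pattern stage; 0 = blind spot (tested throughout)

    @property
    def eccentricity(self) -> float:
        return float(np.hypot(self.x, self.y))

    @property
    def key(self) -> tuple[float, float]:
        return (self.x, self.y)


@dataclass(frozen=True)
class TestGrid:
    locations: tuple[GridLocation, ...]
    eye: str = "right"

    def __post_init__(self) -> None:
        if self.eye not in ("left", "right"):
            raise ValueError(f"eye must be 'left' or 'right', got {self.eye!r}")

    def __len__(self) -> int:
        return len(self.locations)

    def __iter__(self):
        return iter(self.locations)

    @property
    def test_locations(self) -> tuple[GridLocation, ...]:
        return tuple(l for l in self.locations if l.role == ROLE_TEST)

    @property
    def blind_spot_locations(self) -> tuple[GridLocation, ...]:
        return tuple(l for l in self.locations if l.role == ROLE_BLIND_SPOT)

    def location_at(self, x: float, y: float) -> GridLocation:
        for l in self.locations:
            if l.x == x and l.y == y:
                return l
        raise KeyError(f"no grid location at ({x}, {y})")

    def index_of(self, location: GridLocation) -> int:
        return self.locations.index(location)


def _right_eye_coordinates() -> list[tuple[float, float]]:
    """54-point 24-2 lattice minus the y=+/-21 rows, right-eye format."""
    coords: list[tuple[float, float]] = []
    for y in (15.0, 9.0, 3.0, -3.0, -9.0, -15.0):
        if abs(y) == 15.0:
            xs = [-15.0, -9.0, -3.0, 3.0, 9.0, 15.0]
        elif abs(y) == 9.0:
            xs = [-21.0, -15.0, -9.0, -3.0, 3.0, 9.0, 15.0, 21.0]
        else:  # |y| == 3: eight lattice points plus the nasal extension
            xs = [-27.0, -21.0, -15.0, -9.0, -3.0, 3.0, 9.0, 15.0, 21.0]
        coords.extend((x, y) for x in xs)
    return coords


#: blind-spot points in right-eye format (temporal field, over the disc)
BLIND_SPOT_RIGHT = ((15.0, 3.0), (15.0, -3.0))

#: growth-pattern seed points, one per quadrant
SEED_POINTS = ((9.0, 9.0), (-9.0, 9.0), (9.0, -9.0), (-9.0, -9.0))


def build_grid(eye: str = "right",
               stages: Sequence[Iterable[tuple[float, float]]] | None = None) -> TestGrid:
    """Build the 46-location modified 24-2 grid for one eye.

    Parameters
    ----------
    eye:
        ``"right"`` or ``"left"``; the left-eye grid is the x-mirror of the
        right-eye grid.
    stages:
        Optional explicit growth-pattern grouping (sequence of coordinate
        collections, right-eye format, stage 1 first).  Defaults to
        breadth-first expansion from the four quadrant seeds.
    """
    coords = _right_eye_coordinates()
    blind = set(BLIND_SPOT_RIGHT)
    locs = [
        GridLocation(x, y, ROLE_BLIND_SPOT if (x, y) in blind else ROLE_TEST, 0)
        for (x, y) in coords
    ]
    stage_map = _assign_stages(locs, stages)
    locs = [replace(l, group=stage_map.get(l.key, 0)) for l in locs]
    grid = TestGrid(tuple(locs), eye="right")
    if eye == "left":
        grid = mirror_grid(grid)
    elif eye != "right":
        raise ValueError(f"eye must be 'left' or 'right', got {eye!r}")
    return grid


def _assign_stages(locs: Sequence[GridLocation],
                   stages: Sequence[Iterable[tuple[float, float]]] | None,
                   ) -> dict[tuple[float, float], int]:
    test_keys = [l.key for l in locs if l.role == ROLE_TEST]
    if stages is not None:
        out: dict[tuple[float, float], int] = {}
        for k, stage in enumerate(stages, start=1):
            for xy in stage:
                xy = (float(xy[0]), float(xy[1]))
                if xy not in test_keys:
                    raise ValueError(f"growth-pattern stage references unknown location {xy}")
                if xy in out:
                    raise ValueError(f"location {xy} appears in more than one stage")
                out[xy] = k
        missing = set(test_keys) - set(out)
        if missing:
            raise ValueError(f"growth pattern does not cover locations: {sorted(missing)}")
        return out
    # default: breadth-first 6-degree-neighbour expansion from quadrant seeds
    out = {xy: 1 for xy in SEED_POINTS}
    stage = 1
    remaining = set(test_keys) - set(out)
    while remaining:
        frontier = {
            xy for xy in remaining
            if any(_is_neighbor(xy, done) for done in out)
        }
        if not frontier:
            raise ValueError(
                f"locations unreachable from growth-pattern seeds: {sorted(remaining)}")
        stage += 1
        for xy in frontier:
            out[xy] = stage
        remaining -= frontier
    return out


def _is_neighbor(a: tuple[float, float], b: tuple[float, float],
                 step: float = LATTICE_STEP_DEG) -> bool:
    """One lattice step: Chebyshev distance <= 6 degrees (and not identical)."""
    dx, dy = abs(a[0] - b[0]), abs(a[1] - b[1])
    return max(dx, dy) <= step and (dx, dy) != (0.0, 0.0)


def neighbors_of(location: GridLocation, grid: TestGrid,
                 step: float = LATTICE_STEP_DEG) -> tuple[GridLocation, ...]:
    """Grid locations within one lattice step of ``location``."""
    return tuple(
        l for l in grid
        if l.key != location.key and _is_neighbor(location.key, l.key, step)
    )


def growth_pattern(grid: TestGrid) -> list[tuple[GridLocation, ...]]:
    """Ordered growth-pattern stages (test locations only, stage 1 first)."""
    stages: dict[int, list[GridLocation]] = {}
    for l in grid:
        if l.role != ROLE_TEST:
            continue
        stages.setdefault(l.group, []).append(l)
    return [tuple(stages[k]) for k in sorted(stages)]


def mirror_grid(grid: TestGrid) -> TestGrid:
    """Flip a grid to the other eye's format (x -> -x)."""
    locs = tuple(replace(l, x=-l.x) for l in grid.locations)
    return TestGrid(locs, eye="left" if grid.eye == "right" else "right")


def to_right_eye_format(grid: TestGrid, values: np.ndarray | None = None):
    """Return a right-eye-format view of a grid (and aligned values).

    For a left-eye grid, coordinates are x-mirrored; values keep their
    pairing with locations and are returned unchanged in order.  For a
    right-eye grid this is the identity.
    """
    out_grid = mirror_grid(grid) if grid.eye == "left" else grid
    if values is None:
        return out_grid
    return out_grid, np.asarray(values)


def aggregate_regions(values, grid: TestGrid,
                      region_map: Mapping[str, Iterable[tuple[float, float]]],
                      ) -> dict[str, float]:
    """Mean of pointwise values over named sets of grid locations.

    ``values`` is aligned with ``grid.locations``.  Locations absent from
    every region are ignored; a region referencing a coordinate not in the
    grid raises ``KeyError``.
    """
    values = np.asarray(values, dtype=float)
    if values.shape[0] != len(grid):
        raise ValueError("values must align with grid locations")
    index = {l.key: i for i, l in enumerate(grid)}
    out: dict[str, float] = {}
    for name, members in region_map.items():
        idx = []
        for xy in members:
            xy = (float(xy[0]), float(xy[1]))
            if xy not in index:
                raise KeyError(f"region {name!r} references unknown location {xy}")
            idx.append(index[xy])
        out[name] = float(np.mean(values[idx]))
    return out


def grid_to_frame(grid: TestGrid) -> pd.DataFrame:
    """Grid as a DataFrame (columns x_deg, y_deg, role, group)."""
    return pd.DataFrame(
        {
            "x_deg": [l.x for l in grid],
            "y_deg": [l.y for l in grid],
            "role": [l.role for l in grid],
            "group": [l.group for l in grid],
        }
    )


def grid_from_frame(frame: pd.DataFrame, eye: str = "right") -> TestGrid:
    locs = tuple(
        GridLocation(float(r.x_deg), float(r.y_deg), str(r.role), int(r.group))
        for r in frame.itertuples()
    )
    return TestGrid(locs, eye=eye)
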