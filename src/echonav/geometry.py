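"""Coordinate conventions, search-region polygons and step-group generation.

Positions are integer pixel coordinates on the body-camera image plane,
origin at the top-left corner with ``y`` increasing downward (image
convention; the camera looks down on a supine patient). Consequently
NORTH — toward the patient's head — is ``(0, -step)`` and WEST — toward
the patient's anatomical right — is ``(-step, 0)``.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum
from typing import Iterable, NamedTuple

import shapely
from shapely.geometry import Polygon

__all__ = [
    "GridPosition",
    "Direction",
    "SearchRegion",
    "InvalidRegionError",
    "point_in_region",
    "step_group",
]


class InvalidRegionError(ValueError):
    """Raised for degenerate or out-of-canvas search regions."""


class GridPosition(NamedTuple):
    """Integer pixel coordinate; the unit of probe placement."""

    x: int
    y: int

    def offset(self, dx: int, dy: int) -> "GridPosition":
        return GridPosition(self.x + dx, self.y + dy)


class Direction(Enum):
    """The four cardinal probe-movement directions, in fixed priority order."""

    NORTH = (0, -1)
    SOUTH = (0, 1)
    EAST = (1, 0)
    WEST = (-1, 0)

    @property
    def dx(self) -> int:
        return self.value[0]

    @property
    def dy(self) -> int:
        return self.value[1]


#: Fixed candidate order used everywhere a step group is enumerated.
STEP_ORDER = (Direction.NORTH, Direction.SOUTH, Direction.EAST, Direction.WEST)


@dataclass(frozen=True)
class SearchRegion:
    """Operator-calibrated 4-vertex polygon restricting probe traversal.

    The polygon is formed by connecting the four vertices in order; it must
    be simple (non-self-intersecting), have strictly positive area and lie
    entirely on the camera canvas.
    """

    vertices: tuple[GridPosition, GridPosition, GridPosition, GridPosition]
    canvas_width: int
    canvas_height: int

    def __post_init__(self) -> None:
        verts = tuple(GridPosition(int(x), int(y)) for x, y in self.vertices)
        if len(verts) != 4:
            raise InvalidRegionError(f"a search region needs exactly 4 vertices, got {len(verts)}")
        object.__setattr__(self, "vertices", verts)
        for v in verts:
            if not (0 <= v.x < self.canvas_width and 0 <= v.y < self.canvas_height):
                raise InvalidRegionError(f"vertex {v} lies outside the {self.canvas_width}x{self.canvas_height} canvas")
        poly = Polygon(verts)
        if not poly.is_valid or poly.area <= 0:
            raise InvalidRegionError("region polygon is degenerate (self-intersecting or zero area)")
        object.__setattr__(self, "_polygon", poly)

    @property
    def polygon(self) -> Polygon:
        return self._polygon  # type: ignore[attr-defined]

    def bounds(self) -> tuple[int, int, int, int]:
        """Integer (min_x, min_y, max_x, max_y) bounding box of the polygon."""
        minx, miny, maxx, maxy = self.polygon.bounds
        return int(minx), int(miny), int(maxx), int(maxy)

    def contains(self, p: GridPosition) -> bool:
        """True iff ``p`` is inside or on the boundary of the polygon."""
        return bool(shapely.intersects_xy(self.polygon, p.x, p.y))

    def contains_many(self, xs: Iterable[int], ys: Iterable[int]):
        """Vectorised boundary-inclusive membership test."""
        return shapely.intersects_xy(self.polygon, xs, ys)

    @classmethod
    def from_vertex_list(cls, vertices, canvas_width: int, canvas_height: int) -> "SearchRegion":
        verts = tuple(GridPosition(int(x), int(y)) for x, y in vertices)
        return cls(verts, canvas_width, canvas_height)  # type: ignore[arg-type]


def point_in_region(p: GridPosition, r: SearchRegion) -> bool:
    """Boundary-inclusive point-in-polygon test for the search region."""
    return r.contains(p)


def step_group(p: GridPosition, step: int, r: SearchRegion) -> list[GridPosition]:
    """Candidate neighbour positions one step N, S, E and W of ``p``.

    Candidates falling outside the search region are dropped (not clamped);
    the surviving ones keep the fixed N, S, E, W order. The returned list
    may be empty when ``step`` overshoots the region on all four sides.
    """
    if step < 1:
        raise ValueError(f"step must be >= 1, got {step}")
    candidates = [p.offset(d.dx * step, d.dy * step) for d in STEP_ORDER]
    xs = [c.x for c in candidates]
    ys = [c.y for c in candidates]
    inside = r.contains_many(xs, ys)
    return [c for c, ok in zip(candidates, inside) if ok]
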