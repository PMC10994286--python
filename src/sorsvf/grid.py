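"""Geometry of the 24-2 perimetric test pattern.

The 24-2 pattern tests 54 locations spanning roughly the central 24 degrees
of the visual field (extended to 27 degrees nasally), on a 6-degree square
lattice offset 3 degrees from both axes.  All coordinates are expressed in
degrees of visual angle in right-eye (OD) convention: temporal = +x,
superior = +y.  Left-eye fields are mirrored into this convention before
analysis (see :mod:`sorsvf.fields`).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

QUADRANTS = ("superotemporal", "superonasal", "inferotemporal", "inferonasal")

#: lattice half-spacing in degrees; locations sit at odd multiples of 3
GRID_STEP = 6


@dataclass(frozen=True)
class GridSpec:
    """Coordinate map, quadrant labels and adjacency for a test pattern.

    Attributes
    ----------
    locations : tuple of (int, int)
        Ordered (x, y) coordinates in degrees, OD convention.  The order is
        fixed: sorted by descending y, then ascending x (superior rows
        first, temporal-positive x increasing within a row).
    """

    locations: tuple[tuple[int, int], ...]
    blind_spot: frozenset[int] = field(default_factory=frozenset)

    @property
    def n_locations(self) -> int:
        return len(self.locations)

    def index_of(self, x: int, y: int) -> int:
        """Index of the location at (x, y); raises KeyError if absent."""
        try:
            return self.locations.index((x, y))
        except ValueError:
            raise KeyError(f"no test location at ({x}, {y})") from None

    def quadrant_of(self, index: int) -> str:
        x, y = self.locations[index]
        if x == 0 or y == 0:
            raise ValueError(f"location {index} lies on an axis")
        if y > 0:
            return "superotemporal" if x > 0 else "superonasal"
        return "inferotemporal" if x > 0 else "inferonasal"

    def neighbors_of(self, index: int) -> tuple[int, ...]:
        """Indices at 6-degree axis-aligned offsets from ``index``."""
        x, y = self.locations[index]
        out = []
        for dx, dy in ((GRID_STEP, 0), (-GRID_STEP, 0), (0, GRID_STEP), (0, -GRID_STEP)):
            try:
                out.append(self.index_of(x + dx, y + dy))
            except KeyError:
                pass
        return tuple(out)

    def coordinates(self) -> np.ndarray:
        """(n, 2) float array of the location coordinates."""
        return np.asarray(self.locations, dtype=float)

    def quadrant_centers(self) -> dict[str, int]:
        """Index of the (±9, ±9) center of each quadrant."""
        centers = {}
        for sx, sy in ((9, 9), (-9, 9), (9, -9), (-9, -9)):
            i = self.index_of(sx, sy)
            centers[self.quadrant_of(i)] = i
        return centers

    def to_json(self) -> str:
        return json.dumps(
            {
                "locations": [list(p) for p in self.locations],
                "blind_spot": sorted(self.blind_spot),
            }
        )

    @classmethod
    def from_json(cls, text: str) -> "GridSpec":
        d = json.loads(text)
        return cls(
            locations=tuple(tuple(p) for p in d["locations"]),
            blind_spot=frozenset(d["blind_spot"]),
        )


def build_24_2_grid() -> GridSpec:
    """Construct the canonical 54-location 24-2 grid.

    The layout is every (x, y) with \\|x\\|, \\|y\\| in {3, 9, 15, 21} and
    \\|x\\| + \\|y\\| <= 30 (52 points), plus the two nasal-extension points at
    (-27, +/-3).  The physiologic blind spot projects to (+15, +/-3) in OD
    convention; those two indices are flagged and excluded from mean
    deviation (but not from reconstruction or RMSE).
    """
    pts = []
    vals = (3, 9, 15, 21)
    for x in [v * s for v in vals for s in (1, -1)]:
        for y in [v * s for v in vals for s in (1, -1)]:
            if abs(x) + abs(y) <= 30:
                pts.append((x, y))
    pts.extend([(-27, 3), (-27, -3)])
    pts.sort(key=lambda p: (-p[1], p[0]))
    locations = tuple(pts)
    blind = frozenset(locations.index(p) for p in ((15, 3), (15, -3)))
    return GridSpec(locations=locations, blind_spot=blind)
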