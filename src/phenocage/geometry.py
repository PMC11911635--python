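"""Arena geometries, named zones and the light cycle.

Coordinates are arena-local centimetres: origin at the lower-left corner
for rectangular arenas, at the centre for circular ones.  Zone membership
is decided on the point position; boundary samples count as inside
(closed zones).  The one exception is :class:`QuadrantZone`, whose
half-open convention guarantees that the four quadrants of a circular
arena partition it exactly (every sample belongs to exactly one
quadrant).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "Zone",
    "RectZone",
    "DiscZone",
    "QuadrantZone",
    "ArenaGeometry",
    "LightCycle",
    "open_field_arena",
    "phenotyper_arena",
    "barnes_arena",
    "water_maze_arena",
    "quadrant_partition",
]


class GeometryError(ValueError):
    """Raised for invalid zone or arena definitions."""


@dataclass(frozen=True)
class RectZone:
    """Axis-aligned rectangle [x0, x1] x [y0, y1], closed."""

    x0: float
    y0: float
    x1: float
    y1: float

    def __post_init__(self) -> None:
        if not (self.x1 > self.x0 and self.y1 > self.y0):
            raise GeometryError("rectangle must have positive extent")

    def contains(self, x, y):
        x = np.asarray(x, dtype=float)
        y = np.asarray(y, dtype=float)
        return (x >= self.x0) & (x <= self.x1) & (y >= self.y0) & (y <= self.y1)

    def translated(self, dx: float, dy: float) -> "RectZone":
        return RectZone(self.x0 + dx, self.y0 + dy, self.x1 + dx, self.y1 + dy)

    @property
    def center(self) -> tuple[float, float]:
        return ((self.x0 + self.x1) / 2.0, (self.y0 + self.y1) / 2.0)


@dataclass(frozen=True)
class DiscZone:
    """Closed disc of given radius around (cx, cy)."""

    cx: float
    cy: float
    radius: float

    def __post_init__(self) -> None:
        if self.radius <= 0:
            raise GeometryError("disc radius must be positive")

    def contains(self, x, y):
        x = np.asarray(x, dtype=float)
        y = np.asarray(y, dtype=float)
        return (x - self.cx) ** 2 + (y - self.cy) ** 2 <= self.radius**2

    def translated(self, dx: float, dy: float) -> "DiscZone":
        return DiscZone(self.cx + dx, self.cy + dy, self.radius)

    @property
    def center(self) -> tuple[float, float]:
        return (self.cx, self.cy)


# Compass quadrants of a disc.  Half-open on the centre lines so the four
# quadrants tile the disc without overlap: "east" means x >= cx, "north"
# means y >= cy.
_QUADRANT_SIGNS = {
    "NE": (True, True),
    "NW": (False, True),
    "SW": (False, False),
    "SE": (True, False),
}


@dataclass(frozen=True)
class QuadrantZone:
    """One compass quadrant (NE/NW/SW/SE) of a disc centred at (cx, cy)."""

    cx: float
    cy: float
    radius: float
    quadrant: str

    def __post_init__(self) -> None:
        if self.quadrant not in _QUADRANT_SIGNS:
            raise GeometryError(f"unknown quadrant {self.quadrant!r}")
        if self.radius <= 0:
            raise GeometryError("disc radius must be positive")

    def contains(self, x, y):
        x = np.asarray(x, dtype=float)
        y = np.asarray(y, dtype=float)
        east, north = _QUADRANT_SIGNS[self.quadrant]
        in_disc = (x - self.cx) ** 2 + (y - self.cy) ** 2 <= self.radius**2
        ew = (x >= self.cx) if east else (x < self.cx)
        ns = (y >= self.cy) if north else (y < self.cy)
        return in_disc & ew & ns

    def translated(self, dx: float, dy: float) -> "QuadrantZone":
        return QuadrantZone(self.cx + dx, self.cy + dy, self.radius, self.quadrant)

    @property
    def center(self) -> tuple[float, float]:
        east, north = _QUADRANT_SIGNS[self.quadrant]
        r = self.radius / 2.0
        return (self.cx + (r if east else -r), self.cy + (r if north else -r))


Zone = RectZone | DiscZone | QuadrantZone


def quadrant_partition(cx: float, cy: float, radius: float) -> dict[str, QuadrantZone]:
    """The four compass quadrants of a disc, tiling it exactly."""
    return {q: QuadrantZone(cx, cy, radius, q) for q in ("NW", "NE", "SE", "SW")}


@dataclass
class ArenaGeometry:
    """An arena with named zones.

    ``kind`` is one of open_field, barnes, water_maze, phenotyper,
    three_chamber, t_maze, darklight.  ``bounds`` is the outer shape the
    animal can occupy; every named zone must lie within it.
    """

    kind: str
    bounds: Zone
    zones: dict[str, Zone] = field(default_factory=dict)

    KINDS = frozenset(
        {
            "open_field",
            "barnes",
            "water_maze",
            "phenotyper",
            "three_chamber",
            "t_maze",
            "darklight",
        }
    )

    def __post_init__(self) -> None:
        if self.kind not in self.KINDS:
            raise GeometryError(f"unknown arena kind {self.kind!r}")

    def contains(self, x, y):
        return self.bounds.contains(x, y)

    def zone(self, name: str) -> Zone:
        try:
            return self.zones[name]
        except KeyError:
            raise GeometryError(f"arena has no zone named {name!r}") from None


def open_field_arena(size: float = 50.0, inner: float = 40.0) -> ArenaGeometry:
    """50x50 cm open field with a centred 40x40 cm inner zone.

    The outer zone is the remaining border strip; membership is derived as
    "not inner" so inner/outer partition the box.
    """
    m = (size - inner) / 2.0
    return ArenaGeometry(
        kind="open_field",
        bounds=RectZone(0, 0, size, size),
        zones={"inner": RectZone(m, m, size - m, size - m)},
    )


def phenotyper_arena(size: float = 30.0, shelter: RectZone | None = None) -> ArenaGeometry:
    """30x30 cm automated home cage with a 10x10 cm corner shelter."""
    if shelter is None:
        shelter = RectZone(0.0, size - 10.0, 10.0, size)
    return ArenaGeometry(
        kind="phenotyper",
        bounds=RectZone(0, 0, size, size),
        zones={"shelter": shelter},
    )


def barnes_arena(diameter: float = 120.0, n_holes: int = 12, hole_diameter: float = 10.5,
                 hole_inset: float = 12.0) -> ArenaGeometry:
    """Circular Barnes platform with equally spaced hole zones.

    Holes are discs of ``hole_diameter`` placed ``hole_inset`` cm in from
    the circumference, named hole_01 .. hole_12 counter-clockwise from
    the +x axis.
    """
    r = diameter / 2.0
    ring = r - hole_inset
    zones: dict[str, Zone] = {}
    for i in range(n_holes):
        th = 2.0 * np.pi * i / n_holes
        zones[f"hole_{i + 1:02d}"] = DiscZone(
            ring * np.cos(th), ring * np.sin(th), hole_diameter / 2.0
        )
    return ArenaGeometry(kind="barnes", bounds=DiscZone(0, 0, r), zones=zones)


def water_maze_arena(diameter: float = 120.0, platform_diameter: float = 11.0,
                     platform_from_edge: float = 27.0,
                     platform_quadrant: str = "NE") -> ArenaGeometry:
    """120 cm pool, 11 cm platform ~27 cm from the edge, four quadrants."""
    r = diameter / 2.0
    ring = r - platform_from_edge
    east, north = _QUADRANT_SIGNS[platform_quadrant]
    # platform on the quadrant's diagonal
    d = ring / np.sqrt(2.0)
    px = d if east else -d
    py = d if north else -d
    zones: dict[str, Zone] = dict(quadrant_partition(0.0, 0.0, r))
    zones["platform"] = DiscZone(px, py, platform_diameter / 2.0)
    return ArenaGeometry(kind="water_maze", bounds=DiscZone(0, 0, r), zones=zones)


@dataclass(frozen=True)
class LightCycle:
    """12h:12h light/dark cycle anchored to the recording clock.

    ``lights_on``/``lights_off`` are clock hours (default 07:00-19:00).
    ``start_clock`` is the clock hour at trace time 0; home-cage
    monitoring conventionally starts at dark onset, so the default puts
    t=0 at lights-off and dark phase 1 first.
    """

    lights_on: float = 7.0
    lights_off: float = 19.0
    start_clock: float = 19.0

    def __post_init__(self) -> None:
        if not (0 <= self.lights_on < 24 and 0 <= self.lights_off < 24):
            raise GeometryError("clock hours must lie in [0, 24)")
        if abs((self.lights_off - self.lights_on) % 24.0 - 12.0) > 1e-9:
            raise GeometryError("light cycle must be 12h:12h (two switches per 24 h)")

    def clock_hour(self, t_s):
        """Clock hour in [0, 24) at trace time ``t_s`` seconds."""
        return (self.start_clock + np.asarray(t_s, dtype=float) / 3600.0) % 24.0

    def phase(self, t_s):
        """'light' or 'dark' at trace time ``t_s`` (vectorised)."""
        h = self.clock_hour(t_s)
        on, off = self.lights_on, self.lights_off
        if on < off:
            is_light = (h >= on) & (h < off)
        else:
            is_light = (h >= on) | (h < off)
        return np.where(is_light, "light", "dark")

    def phase_edges(self, duration_s: float) -> list[tuple[float, float, str]]:
        """(start, end, phase) intervals covering [0, duration_s]."""
        edges = [0.0]
        # next switch after time t: switches happen when clock hits on/off
        t = 0.0
        while t < duration_s:
            h = float(self.clock_hour(t))
            deltas = [(self.lights_on - h) % 24.0, (self.lights_off - h) % 24.0]
            step = min(d for d in deltas if d > 1e-9) * 3600.0
            t = t + step
            if t < duration_s:
                edges.append(t)
        edges.append(duration_s)
        out = []
        for a, b in zip(edges[:-1], edges[1:]):
            if b - a > 1e-9:
                out.append((a, b, str(self.phase(a + 1e-6))))
        return out
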