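"""Two-level substrate topography for patterned neuronal cultures.

A culture is a disk of radius ``culture_radius`` (mm).  Part of the substrate
may be covered by raised PDMS regions of height ``h`` (mm); the rest is flat
glass at height 0.  Three standard conditions are supported:

* ``control`` — flat substrate, no obstacles;
* ``tracks``  — parallel raised stripes (0.2 mm PDMS separated by 0.3 mm
  glass gaps by default, i.e. 40% coverage);
* ``squares`` — randomly placed, non-overlapping raised squares covering a
  target fraction of the disk (25% by default).

Raised regions deflect growing axons or let them cross a border with a
small, height- and direction-dependent probability (see
:data:`AXON_CROSSING_TABLE`).  All geometry is exact (segment/rectangle
intersection); no rasterisation is used.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
import json
import math

import numpy as np

__all__ = [
    "Direction",
    "ObstacleMap",
    "BorderEvent",
    "AXON_CROSSING_TABLE",
    "ACTIVITY_CROSSING_TABLE",
    "crossing_probability",
    "make_control",
    "make_tracks",
    "make_squares",
    "make_half_pdms",
    "height_at",
    "classify_segment",
]

#: geometric tolerance (mm) for on-border points
EPS = 1e-9

#: max attempts when packing random squares
MAX_SQUARE_ATTEMPTS = 100_000


class Direction(str, Enum):
    """Direction of a border crossing relative to the raised regions."""

    BOTTOM_TO_TOP = "bottom_to_top"  # glass -> PDMS
    TOP_TO_BOTTOM = "top_to_bottom"  # PDMS -> glass


# Calibrated probabilities that a single axon segment hitting a PDMS border
# at >= 30 degrees crosses it, per obstacle height h (mm) and direction.
# Heights beyond 0.7 mm are impassable.
AXON_CROSSING_TABLE = {
    0.0: (1.0, 1.0),
    0.1: (0.45e-3, 3.3e-3),
    0.4: (0.25e-3, 3.3e-3),
    0.6: (0.02e-3, 0.50e-3),
    0.7: (0.0, 0.0),
}

# Experimentally measured fractions of activity bursts that successfully
# propagate across a glass/PDMS border (the calibration targets for the
# axon-crossing probabilities above).
ACTIVITY_CROSSING_TABLE = {
    0.0: (1.0, 1.0),
    0.1: (0.60, 0.85),
    0.4: (0.15, 0.90),
    0.6: (0.05, 0.30),
    0.7: (0.0, 0.0),
}


def crossing_probability(h: float, direction: Direction,
                         table: dict | None = None) -> float:
    """Axon border-crossing probability for obstacle height ``h`` (mm).

    Values between tabulated heights are linearly interpolated; heights
    above the largest tabulated height are impassable (probability 0).
    ``h = 0`` always gives probability 1 in both directions.
    """
    if h < 0:
        raise ValueError("obstacle height must be >= 0")
    tab = AXON_CROSSING_TABLE if table is None else table
    col = 0 if direction == Direction.BOTTOM_TO_TOP else 1
    hs = sorted(tab)
    ps = [tab[x][col] for x in hs]
    if h >= hs[-1]:
        return ps[-1]
    return float(np.interp(h, hs, ps))


@dataclass(frozen=True)
class BorderEvent:
    """First intersection of a directed segment with a region border."""

    point: tuple  # (x, y) mm
    tangent_angle: float  # border tangent direction, radians
    incidence_angle: float  # angle between segment and border, radians in [0, pi/2]
    direction: Direction


@dataclass
class ObstacleMap:
    """Substrate height field: a disk with raised axis-aligned rectangles.

    ``rects`` is an (M, 4) array of ``(x0, y0, x1, y1)`` rectangles raised to
    height ``height``; they must not overlap.  ``crossing_probs`` maps
    ``Direction`` to the per-segment axon crossing probability at this
    height and may be overridden (e.g. during calibration).
    """

    condition: str
    culture_radius: float
    height: float
    rects: np.ndarray  # (M, 4) as x0, y0, x1, y1
    crossing_probs: dict = field(default_factory=dict)
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.culture_radius <= 0:
            raise ValueError("culture_radius must be positive")
        if self.height < 0:
            raise ValueError("height must be >= 0")
        self.rects = np.asarray(self.rects, dtype=float).reshape(-1, 4)
        if not self.crossing_probs:
            self.crossing_probs = {
                d: crossing_probability(self.height, d) for d in Direction
            }

    # -- queries ---------------------------------------------------------
    def height_at(self, point) -> float:
        return height_at(self, point)

    def classify_segment(self, p0, p1):
        return classify_segment(self, p0, p1)

    def covered_fraction(self, n_samples: int = 200_000, rng=None) -> float:
        """Monte-Carlo fraction of the culture disk covered by raised PDMS."""
        if len(self.rects) == 0:
            return 0.0
        rng = np.random.default_rng(0 if rng is None else rng)
        r = self.culture_radius
        pts = rng.uniform(-r, r, size=(int(n_samples * 4 / math.pi * 1.1), 2))
        pts = pts[np.hypot(pts[:, 0], pts[:, 1]) <= r][:n_samples]
        return float(np.mean(_inside_any_rect(self.rects, pts)))

    def crossing_probability(self, direction: Direction) -> float:
        return self.crossing_probs[Direction(direction)]

    # -- serialization ---------------------------------------------------
    def to_json(self) -> str:
        return json.dumps(
            {
                "condition": self.condition,
                "culture_radius_mm": self.culture_radius,
                "h_mm": self.height,
                "rects": self.rects.tolist(),
                "crossing_probs": {d.value: p for d, p in self.crossing_probs.items()},
                "meta": self.meta,
            }
        )

    @classmethod
    def from_json(cls, text: str) -> "ObstacleMap":
        d = json.loads(text)
        return cls(
            condition=d["condition"],
            culture_radius=d["culture_radius_mm"],
            height=d["h_mm"],
            rects=np.asarray(d["rects"], dtype=float).reshape(-1, 4),
            crossing_probs={Direction(k): v for k, v in d["crossing_probs"].items()},
            meta=d.get("meta", {}),
        )


def _inside_any_rect(rects: np.ndarray, pts: np.ndarray) -> np.ndarray:
    """Boolean mask: is each point strictly inside any rectangle."""
    pts = np.atleast_2d(pts)
    inside = np.zeros(len(pts), dtype=bool)
    for x0, y0, x1, y1 in rects:
        inside |= (
            (pts[:, 0] > x0) & (pts[:, 0] < x1) & (pts[:, 1] > y0) & (pts[:, 1] < y1)
        )
    return inside


# ---------------------------------------------------------------------------
# constructors
# ---------------------------------------------------------------------------

def make_control(culture_radius: float) -> ObstacleMap:
    """Flat substrate: no obstacles, height 0 everywhere."""
    if culture_radius <= 0:
        raise ValueError("culture_radius must be positive")
    return ObstacleMap(
        condition="control",
        culture_radius=float(culture_radius),
        height=0.0,
        rects=np.empty((0, 4)),
    )


def make_tracks(
    culture_radius: float,
    pdms_width: float = 0.2,
    gap_width: float = 0.3,
    h: float = 0.1,
    phase: float | None = None,
) -> ObstacleMap:
    """Parallel vertical raised stripes (constant-x bands) across the disk.

    Stripes of width ``pdms_width`` repeat with period ``pdms_width +
    gap_width``.  The default geometry (0.2 mm stripes, 0.3 mm gaps) covers
    40% of the substrate.  The first stripe starts at ``x = -culture_radius``
    unless ``phase`` shifts it.
    """
    if pdms_width <= 0 or gap_width <= 0:
        raise ValueError("stripe widths must be positive")
    if h < 0:
        raise ValueError("h must be >= 0")
    r = float(culture_radius)
    if r <= 0:
        raise ValueError("culture_radius must be positive")
    period = pdms_width + gap_width
    x = -r + (0.0 if phase is None else phase % period)
    rects = []
    while x < r:
        rects.append((x, -r, min(x + pdms_width, r), r))
        x += period
    return ObstacleMap(
        condition="tracks",
        culture_radius=r,
        height=float(h),
        rects=np.asarray(rects),
        meta={"pdms_width": pdms_width, "gap_width": gap_width, "period": period},
    )


def make_squares(
    culture_radius: float,
    coverage: float = 0.25,
    side: float = 0.3,
    h: float = 0.1,
    rng=None,
) -> ObstacleMap:
    """Randomly placed non-overlapping raised squares covering ``coverage``.

    Squares of side ``side`` mm are dart-thrown (rejection sampling of
    overlaps) with centers inside the disk until the covered disk fraction
    first reaches ``coverage``.
    """
    if not (0 < coverage < 1):
        raise ValueError("coverage must be in (0, 1)")
    if side <= 0:
        raise ValueError("side must be positive")
    r = float(culture_radius)
    if r <= 0:
        raise ValueError("culture_radius must be positive")
    rng = np.random.default_rng(rng)
    disk_area = math.pi * r * r
    rects: list[tuple] = []
    covered = 0.0
    attempts = 0
    half = side / 2.0
    while covered / disk_area < coverage:
        attempts += 1
        if attempts > MAX_SQUARE_ATTEMPTS:
            raise RuntimeError(
                f"could not reach coverage {coverage} after {MAX_SQUARE_ATTEMPTS} "
                "placement attempts (packing limit)"
            )
        # uniform center in disk
        cx, cy = rng.uniform(-r, r, size=2)
        if math.hypot(cx, cy) > r:
            continue
        x0, y0, x1, y1 = cx - half, cy - half, cx + half, cy + half
        overlap = any(
            x0 < ox1 and x1 > ox0 and y0 < oy1 and y1 > oy0
            for ox0, oy0, ox1, oy1 in rects
        )
        if overlap:
            continue
        rects.append((x0, y0, x1, y1))
        covered += _square_disk_overlap_area(x0, y0, x1, y1, r)
    return ObstacleMap(
        condition="squares",
        culture_radius=r,
        height=float(h),
        rects=np.asarray(rects),
        meta={"coverage_target": coverage, "side": side,
              "coverage_achieved": covered / disk_area},
    )


def _square_disk_overlap_area(x0, y0, x1, y1, r) -> float:
    """Exact area of rect [x0,x1]x[y0,y1] intersected with the r-disk."""
    from shapely.geometry import Point, box

    return box(x0, y0, x1, y1).intersection(Point(0, 0).buffer(r, 256)).area


def make_half_pdms(culture_radius: float, h: float,
                   crossing_probs: dict | None = None) -> ObstacleMap:
    """Half-glass / half-PDMS calibration substrate.

    The half-plane ``x > 0`` of the culture disk is raised to height ``h``;
    the other half stays at glass level.  This reproduces the geometry used
    to calibrate axon border-crossing probabilities against measured
    activity-propagation fractions.
    """
    r = float(culture_radius)
    if r <= 0:
        raise ValueError("culture_radius must be positive")
    m = ObstacleMap(
        condition="half",
        culture_radius=r,
        height=float(h),
        rects=np.array([[0.0, -r, r, r]]),
    )
    if crossing_probs is not None:
        m.crossing_probs = {Direction(k): float(v) for k, v in crossing_probs.items()}
    return m


# ---------------------------------------------------------------------------
# geometric queries
# ---------------------------------------------------------------------------

def height_at(map: ObstacleMap, point) -> float:
    """Substrate height (mm) at ``point``; raises if outside the disk."""
    x, y = float(point[0]), float(point[1])
    if math.hypot(x, y) > map.culture_radius + EPS:
        raise ValueError(f"point {point} outside culture disk")
    if len(map.rects) and _inside_any_rect(map.rects, np.array([[x, y]]))[0]:
        return map.height
    return 0.0


def _segment_rect_crossings(p0, p1, rect):
    """Parameters t in (EPS, 1] where segment p0->p1 crosses rect's border.

    Returns list of (t, tangent_angle).  Vertical edges have tangent pi/2,
    horizontal edges tangent 0.
    """
    x0, y0, x1, y1 = rect
    px, py = p0
    dx, dy = p1[0] - p0[0], p1[1] - p0[1]
    out = []
    # vertical edges x = x0, x1 with y in [y0, y1]
    if abs(dx) > 0:
        for xe in (x0, x1):
            t = (xe - px) / dx
            if EPS < t <= 1.0:
                y = py + t * dy
                if y0 - EPS <= y <= y1 + EPS:
                    out.append((t, math.pi / 2))
    if abs(dy) > 0:
        for ye in (y0, y1):
            t = (ye - py) / dy
            if EPS < t <= 1.0:
                x = px + t * dx
                if x0 - EPS <= x <= x1 + EPS:
                    out.append((t, 0.0))
    return out


def classify_segment(map: ObstacleMap, p0, p1):
    """First border event along the directed segment ``p0 -> p1``.

    Returns ``None`` if no raised-region border is crossed, else a
    :class:`BorderEvent` carrying the crossing point, the border tangent,
    the incidence angle (in [0, pi/2]) and the crossing direction, judged
    from the substrate level at ``p0``.
    """
    p0 = (float(p0[0]), float(p0[1]))
    p1 = (float(p1[0]), float(p1[1]))
    dx, dy = p1[0] - p0[0], p1[1] - p0[1]
    seg_len = math.hypot(dx, dy)
    if seg_len < EPS:
        raise ValueError("degenerate zero-length segment")
    if len(map.rects) == 0:
        return None
    best = None
    for rect in map.rects:
        for t, tangent in _segment_rect_crossings(p0, p1, rect):
            if best is None or t < best[0]:
                best = (t, tangent)
    if best is None:
        return None
    t, tangent = best
    heading = math.atan2(dy, dx)
    inc = abs(((heading - tangent) + math.pi / 2) % math.pi - math.pi / 2)
    start_h = height_at(map, p0)
    direction = Direction.BOTTOM_TO_TOP if start_h == 0 else Direction.TOP_TO_BOTTOM
    return BorderEvent(
        point=(p0[0] + t * dx, p0[1] + t * dy),
        tangent_angle=tangent,
        incidence_angle=inc,
        direction=direction,
    )
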