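"""Structural network generation for spatially patterned neuronal cultures.

Somas are placed as non-overlapping disks uniformly over the culture,
axons grow as random polylines (short segments with Gaussian heading
noise) that are deflected by raised-substrate borders or cross them with a
small probability, and a directed synaptic network is formed wherever an
axon passes through another neuron's dendritic disk.

Conventions
-----------
The structural adjacency matrix ``S`` follows the convention
``S[i, j] = 1`` meaning a connection ``j -> i`` (row = postsynaptic,
column = presynaptic).  Weights ``W`` share the sparsity of ``S`` and hold
uniform (0, 1) synaptic efficacies; the sign of a connection is carried by
the presynaptic neuron's type (excitatory/inhibitory), not by ``W``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
import math

import numpy as np
import scipy.sparse as sp

from .topography import Direction, ObstacleMap, classify_segment

__all__ = [
    "Culture",
    "StructuralNetwork",
    "place_somas",
    "assign_types",
    "sample_axon_length",
    "sample_dendrite_radius",
    "grow_axon",
    "build_adjacency",
    "grow_network",
]

# default physical parameters (mm unless noted)
SOMA_RADIUS = 0.0075          # 7.5 um
SEGMENT_LENGTH = 0.010        # axon growth step, 10 um
HEADING_SIGMA = 0.1           # radians, per-segment heading noise
DENDRITE_MEAN = 0.150         # mean dendritic-tree radius
DENDRITE_SD = 0.020
DENDRITE_FLOOR = 0.001        # 1 um truncation floor
DEFLECTION_ANGLE = math.radians(30.0)  # below this, axons follow the border
EXCITATORY, INHIBITORY = 0, 1


@dataclass
class Culture:
    """Grown culture: somas, neuron types, dendritic disks and axons."""

    positions: np.ndarray          # (N, 2) mm
    types: np.ndarray              # (N,) int8; 0 = excitatory, 1 = inhibitory
    soma_radius: float
    dendrite_radii: np.ndarray     # (N,) mm
    axons: list                    # N polylines, each (n_vertices, 2)
    axon_lengths: np.ndarray       # (N,) consumed length incl. crossing penalties
    axon_levels: list = None       # N arrays: substrate height at each vertex
    soma_levels: np.ndarray = None  # (N,) substrate height under each soma
    meta: dict = field(default_factory=dict)

    @property
    def n_neurons(self) -> int:
        return len(self.positions)


@dataclass
class StructuralNetwork:
    """Directed structural connectivity of a grown culture.

    ``S[i, j] = 1`` encodes a synapse from neuron ``j`` onto neuron ``i``.
    """

    S: sp.csr_matrix               # (N, N) binary, row = post, col = pre
    W: sp.csr_matrix               # same sparsity, weights in (0, 1)
    types: np.ndarray
    positions: np.ndarray
    meta: dict = field(default_factory=dict)

    @property
    def n_neurons(self) -> int:
        return self.S.shape[0]

    @property
    def n_edges(self) -> int:
        return int(self.S.nnz)

    def in_degrees(self) -> np.ndarray:
        return np.asarray(self.S.sum(axis=1)).ravel()

    def out_degrees(self) -> np.ndarray:
        return np.asarray(self.S.sum(axis=0)).ravel()


# ---------------------------------------------------------------------------
# sampling primitives
# ---------------------------------------------------------------------------

def place_somas(density: float, culture_radius: float,
                soma_radius: float = SOMA_RADIUS, rng=None,
                n_neurons: int | None = None) -> np.ndarray:
    """Uniform non-overlapping soma positions on the culture disk.

    Exactly ``N = floor(density * pi * r^2)`` somas are placed by dart
    throwing with a neighbour grid; somas are hard disks of radius
    ``soma_radius`` that may not overlap.  ``n_neurons`` overrides the
    density-derived count.
    """
    r = float(culture_radius)
    if r <= 0:
        raise ValueError("culture_radius must be positive")
    n = int(n_neurons) if n_neurons is not None else int(density * math.pi * r * r)
    if n < 1:
        raise ValueError("parameters yield zero neurons")
    rng = np.random.default_rng(rng)
    min_d = 2.0 * soma_radius
    cell = max(min_d, 1e-6)
    grid: dict = {}
    pts = np.empty((n, 2))
    placed = 0
    attempts = 0
    max_attempts = 200 * n + 10_000
    while placed < n:
        attempts += 1
        if attempts > max_attempts:
            raise RuntimeError(
                f"soma packing failed: placed {placed}/{n} after {attempts} attempts"
            )
        x, y = rng.uniform(-r, r, size=2)
        if x * x + y * y > r * r:
            continue
        ci, cj = int(x // cell), int(y // cell)
        ok = True
        for di in (-1, 0, 1):
            for dj in (-1, 0, 1):
                for k in grid.get((ci + di, cj + dj), ()):
                    ddx, ddy = pts[k, 0] - x, pts[k, 1] - y
                    if ddx * ddx + ddy * ddy < min_d * min_d:
                        ok = False
                        break
                if not ok:
                    break
            if not ok:
                break
        if not ok:
            continue
        pts[placed] = (x, y)
        grid.setdefault((ci, cj), []).append(placed)
        placed += 1
    return pts


def assign_types(n: int, inhibitory_fraction: float = 0.2, rng=None) -> np.ndarray:
    """Random neuron types with exactly ``round(n * fraction)`` inhibitory."""
    if not (0.0 <= inhibitory_fraction <= 1.0):
        raise ValueError("inhibitory_fraction must be in [0, 1]")
    rng = np.random.default_rng(rng)
    n_inh = int(round(n * inhibitory_fraction))
    types = np.zeros(n, dtype=np.int8)
    types[:n_inh] = INHIBITORY
    rng.shuffle(types)
    return types


def sample_axon_length(mean_length: float, rng=None, size=None):
    """Rayleigh axon length with mean ``mean_length`` (scale = mean*sqrt(2/pi))."""
    if mean_length <= 0:
        raise ValueError("mean_length must be positive")
    rng = np.random.default_rng(rng)
    scale = mean_length * math.sqrt(2.0 / math.pi)
    return rng.rayleigh(scale=scale, size=size)


def sample_dendrite_radius(rng=None, size=None, mean: float = DENDRITE_MEAN,
                           sd: float = DENDRITE_SD):
    """Gaussian dendritic-tree radius, truncated at a small positive floor."""
    rng = np.random.default_rng(rng)
    r = rng.normal(mean, sd, size=size)
    return np.maximum(r, DENDRITE_FLOOR)


# ---------------------------------------------------------------------------
# axon growth
# ---------------------------------------------------------------------------

def _tangent_heading(tangent_angle: float, heading: float, jitter: float) -> float:
    """Border-parallel heading closest to ``heading``, plus jitter."""
    a, b = tangent_angle, tangent_angle + math.pi
    da = abs((heading - a + math.pi) % (2 * math.pi) - math.pi)
    db = abs((heading - b + math.pi) % (2 * math.pi) - math.pi)
    return (a if da <= db else b) + jitter


def grow_axon(start, map: ObstacleMap, target_length: float, rng=None,
              segment_length: float = SEGMENT_LENGTH,
              heading_sigma: float = HEADING_SIGMA):
    """Grow one axon polyline from ``start`` on the substrate ``map``.

    The axon's intrinsic growth direction performs a Gaussian random walk
    (sd ``heading_sigma`` per step) and segments of ``segment_length`` are
    laid along it.  When the intended segment meets a raised-region border
    at an incidence angle of 30 degrees or more, it crosses with the map's
    per-direction probability (a successful crossing charges
    ``segment_length + h`` to the consumed length); otherwise — shallow
    incidence or a failed crossing roll — the placed segment is replaced
    by one parallel to the border (plus heading-scale jitter).  Deflection
    clips only the placed segment: the intrinsic direction keeps its
    random walk, so an axon pointing into a wall slides along it,
    re-attempting the crossing at every step until its direction diffuses
    away — this is what makes the tiny per-step crossing probabilities
    effective at the culture scale.  Segments that would exit the culture
    disk are deflected parallel to the rim.  Growth stops once the
    consumed length reaches ``target_length``.

    Returns ``(polyline, consumed_length, levels)`` where ``polyline`` is
    an ``(n_vertices, 2)`` array starting at ``start`` and ``levels`` the
    substrate height under each vertex (0 on glass, ``h`` on PDMS).
    """
    x, y = float(start[0]), float(start[1])
    r = map.culture_radius
    if math.hypot(x, y) > r:
        raise ValueError("axon start outside culture disk")
    if target_length < 0:
        raise ValueError("target_length must be >= 0")
    rng = np.random.default_rng(rng)
    from .topography import height_at
    if map.height == 0.0 and len(map.rects):
        # a zero-height pattern has no walls: grow as on a flat substrate
        from dataclasses import replace as _dc_replace
        map = _dc_replace(map, rects=np.empty((0, 4)))
    verts = [(x, y)]
    levels = [height_at(map, (x, y))]
    consumed = 0.0
    heading = rng.uniform(0.0, 2.0 * math.pi)
    dl = segment_length
    h = map.height
    first = True

    def place_parallel(tangent, jitter_scale=1.0):
        """Try to lay a border-parallel segment; returns endpoint or None."""
        for attempt in range(4):
            jitter = rng.normal(0.0, heading_sigma) * jitter_scale \
                if attempt < 3 else 0.0
            th = _tangent_heading(tangent, heading, jitter)
            px = x + dl * math.cos(th)
            py = y + dl * math.sin(th)
            if px * px + py * py > r * r:
                continue
            ev = classify_segment(map, (x, y), (px, py))
            if ev is None:
                return px, py
            if attempt == 3:
                # corner: truncate just short of the border
                tx = (ev.point[0] - x) * 0.9 + x
                ty = (ev.point[1] - y) * 0.9 + y
                if math.hypot(tx - x, ty - y) > 0.05 * dl:
                    return tx, ty
        return None

    while consumed < target_length - 1e-12:
        if not first:
            heading += rng.normal(0.0, heading_sigma)
        first = False
        nx = x + dl * math.cos(heading)
        ny = y + dl * math.sin(heading)
        moved = False
        if nx * nx + ny * ny > r * r:
            # culture rim: impassable wall, follow it
            rim_tangent = math.atan2(y, x) + math.pi / 2
            res = place_parallel(rim_tangent)
            if res is not None:
                x, y = res
                moved = True
            consumed += dl
        else:
            event = classify_segment(map, (x, y), (nx, ny))
            if event is None:
                x, y = nx, ny
                consumed += dl
                moved = True
            elif (event.incidence_angle >= DEFLECTION_ANGLE
                    and rng.random() < map.crossing_probs[event.direction]):
                # crossing a wall of height h costs extra length
                x, y = nx, ny
                consumed += dl + h
                moved = True
            else:
                res = place_parallel(event.tangent_angle)
                if res is not None:
                    x, y = res
                    moved = True
                # charge the step even when stuck in a corner so growth
                # terminates rather than looping forever
                consumed += dl
        if moved:
            verts.append((x, y))
            levels.append(height_at(map, (x, y)))
    return np.asarray(verts), consumed, np.asarray(levels)


# ---------------------------------------------------------------------------
# connectivity
# ---------------------------------------------------------------------------

def _segment_disk_dist2(polyline: np.ndarray, centers: np.ndarray,
                        seg_mask: np.ndarray | None = None,
                        per_segment: bool = False) -> np.ndarray:
    """Squared distance from each center to the (masked) polyline.

    With ``per_segment`` the full (segments, centers) distance matrix is
    returned instead of the minimum over segments.
    """
    if len(polyline) < 2:
        if seg_mask is not None and not seg_mask.any():
            out = np.full(len(centers), np.inf)
            return out[None, :] if per_segment else out
        diff = centers - polyline[0]
        out = (diff * diff).sum(-1)
        return out[None, :] if per_segment else out
    a = polyline[:-1]
    d = polyline[1:] - polyline[:-1]
    if seg_mask is not None:
        if not seg_mask.any():
            out = np.full(len(centers), np.inf)
            return out[None, :] if per_segment else out
        a, d = a[seg_mask], d[seg_mask]
    a = a[:, None, :]                      # (S, 1, 2)
    d = d[:, None, :]
    len2 = np.maximum((d * d).sum(-1), 1e-18)
    ap = centers[None, :, :] - a           # (S, N, 2)
    t = np.clip((ap * d).sum(-1) / len2, 0.0, 1.0)
    closest = a + t[..., None] * d
    dist2 = ((centers[None, :, :] - closest) ** 2).sum(-1)
    return dist2 if per_segment else dist2.min(axis=0)


def _count_episodes(inside: np.ndarray) -> np.ndarray:
    """Crossing episodes per center: runs of consecutive in-disk segments."""
    starts = inside.copy()
    starts[1:] &= ~inside[:-1]
    return starts.sum(axis=0)


def _segments_hit_disks(polyline: np.ndarray, centers: np.ndarray,
                        radii: np.ndarray, seg_levels=None,
                        center_levels=None) -> np.ndarray:
    """Boolean mask over ``centers``: does the polyline pass within ``radii``.

    When levels are given, only polyline segments lying on a center's own
    substrate level may make contact with it.
    """
    if seg_levels is None or center_levels is None:
        return _segment_disk_dist2(polyline, centers) <= radii * radii
    hit = np.zeros(len(centers), dtype=bool)
    for lev in np.unique(center_levels):
        sel = center_levels == lev
        d2 = _segment_disk_dist2(polyline, centers[sel], seg_levels == lev)
        hit[sel] = d2 <= radii[sel] * radii[sel]
    return hit


def _grow_all_axons(positions: np.ndarray, lengths: np.ndarray,
                    map: ObstacleMap, rng,
                    segment_length: float = SEGMENT_LENGTH,
                    heading_sigma: float = HEADING_SIGMA):
    """Grow every axon with the compiled batch kernel."""
    from ._growth_core import grow_axons_batch

    rng = np.random.default_rng(rng)
    n = len(positions)
    cap = int(np.sum(lengths / segment_length)) + 16 * n
    verts = np.empty((cap, 2))
    levels = np.empty(cap)
    offsets = np.empty(n + 1, dtype=np.int64)
    consumed = np.empty(n)
    seed = int(rng.integers(0, 2**31 - 1))
    # a zero-height pattern has no walls: grow as on a flat substrate
    rects = map.rects if map.height > 0.0 else np.empty((0, 4))
    bad = grow_axons_batch(
        np.ascontiguousarray(positions, dtype=float),
        np.ascontiguousarray(lengths, dtype=float),
        np.ascontiguousarray(rects, dtype=float),
        map.height,
        map.crossing_probs[Direction.BOTTOM_TO_TOP],
        map.crossing_probs[Direction.TOP_TO_BOTTOM],
        map.culture_radius, segment_length, heading_sigma,
        DEFLECTION_ANGLE, seed, verts, levels, offsets, consumed)
    if bad:
        raise RuntimeError(f"axon vertex buffer overflow for {bad} axons")
    axons = [verts[offsets[i]:offsets[i + 1]].copy() for i in range(n)]
    axon_levels = [levels[offsets[i]:offsets[i + 1]].copy() for i in range(n)]
    return axons, axon_levels, consumed


def build_adjacency(culture: Culture, alpha: float = 0.5, rng=None,
                    respect_levels: bool = True,
                    alpha_mode: str = "per_event") -> StructuralNetwork:
    """Directed structural network from grown axons and dendritic disks.

    A synapse ``i -> j`` may form wherever the axon of ``i`` crosses the
    dendritic disk of ``j``.  With ``alpha_mode="per_event"`` (default)
    each crossing episode — a maximal run of consecutive axon segments
    inside the disk — is an independent Bernoulli(``alpha``) opportunity,
    so a pair crossed ``m`` times connects with probability
    ``1 - (1-alpha)^m``; ``"per_pair"`` uses a single trial per ordered
    pair regardless of the number of crossings.  Created edges get
    independent U(0, 1) weights and are stored as ``S[j, i] = 1``.

    With ``respect_levels`` (default), a contact only counts if the axon
    passes the disk while at or below the target soma's substrate level:
    dendritic arbors cannot climb a PDMS wall, so an axon on top of an
    obstacle is out of reach of a bottom-level dendrite, but arbors of
    raised somas may spill down over the edge and intercept axons running
    below — the same descent/ascent asymmetry the obstacle-crossing
    probabilities encode for axons.
    """
    rng = np.random.default_rng(rng)
    n = culture.n_neurons
    pos = culture.positions
    radii = culture.dendrite_radii
    use_levels = (respect_levels and culture.axon_levels is not None
                  and culture.soma_levels is not None
                  and np.ptp(culture.soma_levels) > 0)
    if alpha_mode not in ("per_event", "per_pair"):
        raise ValueError("alpha_mode must be 'per_event' or 'per_pair'")
    rows, cols = [], []  # row = post j, col = pre i
    for i in range(n):
        poly = culture.axons[i]
        episodes = np.zeros(n, dtype=np.int64)
        if use_levels:
            lv = culture.axon_levels[i]
            # a crossing segment touches both sides; judge by its lower end
            seg_lo = np.minimum(lv[:-1], lv[1:]) if len(lv) > 1 else lv
            for lev in np.unique(culture.soma_levels):
                sel = culture.soma_levels == lev
                mask = seg_lo <= lev + 1e-12
                d2 = _segment_disk_dist2(poly, pos[sel], mask, per_segment=True)
                inside = d2 <= (radii[sel] * radii[sel])[None, :]
                episodes[sel] = _count_episodes(inside)
        else:
            d2 = _segment_disk_dist2(poly, pos, per_segment=True)
            episodes = _count_episodes(d2 <= (radii * radii)[None, :])
        episodes[i] = 0
        cand = np.flatnonzero(episodes)
        if alpha >= 1.0:
            keep = cand
        elif alpha <= 0.0:
            keep = cand[:0]
        elif alpha_mode == "per_event":
            p = 1.0 - (1.0 - alpha) ** episodes[cand]
            keep = cand[rng.random(len(cand)) < p]
        else:
            keep = cand[rng.random(len(cand)) < alpha]
        rows.append(keep)
        cols.append(np.full(len(keep), i, dtype=np.int64))
    rows = np.concatenate(rows) if rows else np.empty(0, dtype=np.int64)
    cols = np.concatenate(cols) if cols else np.empty(0, dtype=np.int64)
    data = np.ones(len(rows), dtype=np.int8)
    S = sp.csr_matrix((data, (rows, cols)), shape=(n, n))
    S.sum_duplicates()
    S.data[:] = 1
    W = S.astype(float).copy()
    W.data = rng.uniform(0.0, 1.0, size=W.nnz)
    # uniform draws are in [0, 1); nudge exact zeros into the open interval
    W.data[W.data == 0.0] = 1e-12
    return StructuralNetwork(
        S=S, W=W, types=culture.types, positions=pos,
        meta=dict(culture.meta, alpha=alpha),
    )


def grow_network(
    map: ObstacleMap,
    density: float = 400.0,
    mean_axon_length: float = 1.0,
    rng=None,
    inhibitory_fraction: float = 0.2,
    alpha: float = 0.5,
    soma_radius: float = SOMA_RADIUS,
    n_neurons: int | None = None,
) -> tuple[Culture, StructuralNetwork]:
    """End-to-end network growth on a substrate.

    Places somas at ``density`` neurons/mm^2, assigns 80/20
    excitatory/inhibitory types, grows one axon per neuron with
    Rayleigh-distributed target lengths of mean ``mean_axon_length`` and
    builds the directed adjacency with connection probability ``alpha``.
    """
    rng = np.random.default_rng(rng)
    pos = place_somas(density, map.culture_radius, soma_radius, rng,
                      n_neurons=n_neurons)
    n = len(pos)
    types = assign_types(n, inhibitory_fraction, rng)
    lengths = sample_axon_length(mean_axon_length, rng, size=n)
    radii = sample_dendrite_radius(rng, size=n)
    axons, axon_levels, consumed = _grow_all_axons(pos, lengths, map, rng)
    from .topography import height_at
    soma_levels = np.array([height_at(map, p) for p in pos])
    culture = Culture(
        positions=pos, types=types, soma_radius=soma_radius,
        dendrite_radii=radii, axons=axons, axon_lengths=consumed,
        axon_levels=axon_levels, soma_levels=soma_levels,
        meta={
            "condition": map.condition, "density": density,
            "mean_axon_length": mean_axon_length, "h": map.height,
            "culture_radius": map.culture_radius,
        },
    )
    return culture, build_adjacency(culture, alpha, rng)
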