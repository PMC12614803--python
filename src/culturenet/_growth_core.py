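"""Compiled batch axon-growth kernel.

Numba implementation of the axon growth rules (random-walk heading,
border deflection/crossing, rim following) for whole cultures at once;
semantics match :func:`culturenet.growth.grow_axon`.
"""

from __future__ import annotations

import numpy as np

try:
    from numba import njit
except ImportError:  # pragma: no cover
    def njit(*a, **k):
        def wrap(f):
            return f
        return wrap if not (a and callable(a[0])) else a[0]

EPS = 1e-9


@njit(cache=True)
def _inside_any(rects, x, y):  # pragma: no cover - compiled
    for m in range(rects.shape[0]):
        if rects[m, 0] < x < rects[m, 2] and rects[m, 1] < y < rects[m, 3]:
            return True
    return False


@njit(cache=True)
def _first_crossing(rects, px, py, dx, dy):  # pragma: no cover - compiled
    """First border crossing along (px,py)+t*(dx,dy), t in (EPS, 1].

    Returns (t, vertical) with t > 1 when nothing is crossed; ``vertical``
    is True when the crossed edge is a constant-x border.
    """
    best_t = 2.0
    vertical = False
    for m in range(rects.shape[0]):
        x0, y0, x1, y1 = rects[m, 0], rects[m, 1], rects[m, 2], rects[m, 3]
        if dx != 0.0:
            for xe in (x0, x1):
                t = (xe - px) / dx
                if EPS < t <= 1.0 and t < best_t:
                    yy = py + t * dy
                    if y0 - EPS <= yy <= y1 + EPS:
                        best_t = t
                        vertical = True
        if dy != 0.0:
            for ye in (y0, y1):
                t = (ye - py) / dy
                if EPS < t <= 1.0 and t < best_t:
                    xx = px + t * dx
                    if x0 - EPS <= xx <= x1 + EPS:
                        best_t = t
                        vertical = False
    return best_t, vertical


@njit(cache=True)
def _incidence(heading, tangent):  # pragma: no cover - compiled
    d = (heading - tangent + np.pi / 2) % np.pi - np.pi / 2
    return abs(d)


@njit(cache=True)
def _tangent_near(tangent, heading, jitter):  # pragma: no cover - compiled
    a = tangent
    b = tangent + np.pi
    da = abs((heading - a + np.pi) % (2 * np.pi) - np.pi)
    db = abs((heading - b + np.pi) % (2 * np.pi) - np.pi)
    if da <= db:
        return a + jitter
    return b + jitter


@njit(cache=True)
def grow_axons_batch(starts, targets, rects, h, p_bt, p_tb, radius,
                     dl, sigma_phi, deflect_angle, seed,
                     verts, levels, offsets, consumed):
    # pragma: no cover - compiled
    """Grow all axons; fills flat vertex/level arrays via ``offsets``.

    ``verts`` is (capacity, 2); per-axon vertex ranges are
    ``offsets[i]:offsets[i+1]`` (set here).  Returns the number of axons
    whose buffers would have overflowed (0 on success).
    """
    np.random.seed(seed)
    n = starts.shape[0]
    pos = 0
    bad = 0
    cap = verts.shape[0]
    for i in range(n):
        offsets[i] = pos
        x = starts[i, 0]
        y = starts[i, 1]
        target = targets[i]
        if pos >= cap:
            bad += 1
            continue
        verts[pos, 0] = x
        verts[pos, 1] = y
        levels[pos] = h if _inside_any(rects, x, y) else 0.0
        pos += 1
        used = 0.0
        heading = np.random.uniform(0.0, 2.0 * np.pi)
        first = True
        max_steps = int(target / dl) + 8
        step_count = 0
        while used < target - 1e-12 and step_count < max_steps:
            step_count += 1
            if not first:
                heading += np.random.normal(0.0, sigma_phi)
            first = False
            dx = dl * np.cos(heading)
            dy = dl * np.sin(heading)
            nx = x + dx
            ny = y + dy
            moved = False
            if nx * nx + ny * ny > radius * radius:
                rim_t = np.arctan2(y, x) + np.pi / 2
                for attempt in range(4):
                    jit = np.random.normal(0.0, sigma_phi) if attempt < 3 else 0.0
                    th = _tangent_near(rim_t, heading, jit)
                    px = x + dl * np.cos(th)
                    py = y + dl * np.sin(th)
                    if px * px + py * py > radius * radius:
                        continue
                    t2, _ = _first_crossing(rects, x, y, px - x, py - y)
                    if t2 > 1.0:
                        x = px
                        y = py
                        moved = True
                        break
                    if attempt == 3 and t2 > 0.05:
                        # corner: truncate just short of the border
                        x = x + 0.9 * t2 * (px - x)
                        y = y + 0.9 * t2 * (py - y)
                        moved = True
                used += dl
            else:
                t, vert = _first_crossing(rects, x, y, dx, dy)
                if t > 1.0:
                    x = nx
                    y = ny
                    used += dl
                    moved = True
                else:
                    tangent = np.pi / 2 if vert else 0.0
                    inc = _incidence(heading, tangent)
                    on_top = levels[pos - 1] > 0.0
                    p_cross = p_tb if on_top else p_bt
                    if inc >= deflect_angle and np.random.random() < p_cross:
                        x = nx
                        y = ny
                        used += dl + h
                        moved = True
                    else:
                        for attempt in range(4):
                            jit = (np.random.normal(0.0, sigma_phi)
                                   if attempt < 3 else 0.0)
                            th = _tangent_near(tangent, heading, jit)
                            px = x + dl * np.cos(th)
                            py = y + dl * np.sin(th)
                            if px * px + py * py > radius * radius:
                                continue
                            t2, _ = _first_crossing(rects, x, y, px - x, py - y)
                            if t2 > 1.0:
                                x = px
                                y = py
                                moved = True
                                break
                            if attempt == 3 and t2 > 0.05:
                                x = x + 0.9 * t2 * (px - x)
                                y = y + 0.9 * t2 * (py - y)
                                moved = True
                        used += dl
            if moved:
                if pos >= cap:
                    bad += 1
                    break
                verts[pos, 0] = x
                verts[pos, 1] = y
                levels[pos] = h if _inside_any(rects, x, y) else 0.0
                pos += 1
        consumed[i] = used
    offsets[n] = pos
    return bad
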