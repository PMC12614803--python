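"""Activity measures: population activity, bursts, richness and fronts.

The central object is the population activity

    PA(t) = (1/N) |{ i : some spike of i falls within tau_win/2 of t }|

evaluated on a strided time grid.  Network bursts are above-threshold
local maxima of PA(t); their peak heights Gamma (the co-activation sizes)
feed the dynamical-richness statistic Theta, and the first-spike times of
burst participants yield initiation points and front propagation
velocities.  The module also implements the half-glass/half-PDMS
calibration loop that fits axon border-crossing probabilities to target
activity-propagation fractions.
"""

from __future__ import annotations

from dataclasses import dataclass, field
import math

import numpy as np
from scipy.signal import find_peaks

from . import growth
from .dynamics import DynamicsParams, SpikeTrain, simulate
from .topography import Direction, make_half_pdms

__all__ = [
    "Burst",
    "ActivitySummary",
    "population_activity",
    "detect_bursts",
    "dynamical_richness",
    "front_initiation",
    "front_velocity",
    "burst_table",
    "crossing_fraction",
    "calibrate_crossing_probabilities",
]

PA_WINDOW = 200.0      # ms, sliding co-activation window
PA_STRIDE = 10.0       # ms, evaluation stride of the PA trace
PA_THRESHOLD = 0.1     # minimum PA peak height to accept a burst
MIN_SEPARATION = 500.0  # ms, peaks closer than this merge into one burst
K_INIT = 5             # earliest spikers defining the initiation centroid


@dataclass
class Burst:
    """One network burst: an above-threshold excursion of PA(t)."""

    t_peak: float                 # ms, position of the PA maximum
    size: float                   # Gamma, peak PA in [0, 1]
    t_start: float                # ms, excursion start
    t_end: float                  # ms, excursion end
    participants: np.ndarray      # neuron ids spiking during the excursion
    first_spike_times: np.ndarray  # ms, first spike of each participant


@dataclass
class ActivitySummary:
    times: np.ndarray
    pa: np.ndarray
    bursts: list
    window: float = PA_WINDOW
    threshold: float = PA_THRESHOLD
    meta: dict = field(default_factory=dict)

    @property
    def peak_sizes(self) -> np.ndarray:
        return np.array([b.size for b in self.bursts])


def population_activity(spikes: SpikeTrain, window: float = PA_WINDOW,
                        stride: float = PA_STRIDE):
    """PA trace: fraction of neurons with a spike within ``window``/2 of t.

    Returns ``(times, pa)`` with ``times`` spanning [0, duration] at
    ``stride`` ms.
    """
    if window <= 0 or stride <= 0:
        raise ValueError("window and stride must be positive")
    n_centers = int(math.floor(spikes.duration / stride)) + 1
    times = np.arange(n_centers) * stride
    if spikes.n_spikes == 0:
        return times, np.zeros(n_centers)
    half = window / 2.0
    lo = spikes.times - half
    hi = spikes.times + half
    k_lo = np.maximum(np.floor(lo / stride).astype(np.int64) + 1, 0)
    k_hi = np.minimum(np.ceil(hi / stride).astype(np.int64) - 1, n_centers - 1)
    lengths = np.maximum(k_hi - k_lo + 1, 0)
    keep = lengths > 0
    k_lo, lengths, ids = k_lo[keep], lengths[keep], spikes.ids[keep]
    # expand each spike into the grid indices it activates, then dedupe
    # (neuron, grid-index) pairs so a neuron counts once per center
    offsets = np.repeat(np.cumsum(lengths) - lengths, lengths)
    ks = np.arange(lengths.sum()) - offsets + np.repeat(k_lo, lengths)
    keys = np.unique(np.repeat(ids, lengths) * n_centers + ks)
    counts = np.bincount((keys % n_centers).astype(np.int64), minlength=n_centers)
    return times, counts / spikes.n_neurons


def detect_bursts(times: np.ndarray, pa: np.ndarray, spikes: SpikeTrain = None,
                  threshold: float = PA_THRESHOLD,
                  min_separation: float = MIN_SEPARATION,
                  window: float = PA_WINDOW) -> list:
    """Network bursts as merged above-threshold local maxima of PA(t).

    Peaks closer than ``min_separation`` are merged keeping the higher
    one.  If ``spikes`` is given, each burst carries its participant set:
    neurons spiking within the above-threshold excursion (padded by half
    the PA window) and their first spike times.
    """
    if not (0.0 < threshold < 1.0):
        raise ValueError("threshold must be in (0, 1)")
    if len(pa) < 3:
        return []
    stride = times[1] - times[0]
    idx, _ = find_peaks(pa, height=threshold)
    if len(idx) == 0:
        return []
    # merge close peaks, keeping the higher
    merged = [idx[0]]
    for i in idx[1:]:
        if times[i] - times[merged[-1]] < min_separation:
            if pa[i] > pa[merged[-1]]:
                merged[-1] = i
        else:
            merged.append(i)
    per_neuron = spikes.per_neuron() if spikes is not None else None
    bursts = []
    above = pa >= threshold
    for i in merged:
        a = i
        while a > 0 and above[a - 1]:
            a -= 1
        b = i
        while b < len(pa) - 1 and above[b + 1]:
            b += 1
        t0 = times[a] - window / 2.0
        t1 = times[b] + window / 2.0
        participants = np.empty(0, dtype=np.int64)
        firsts = np.empty(0)
        if per_neuron is not None:
            p_list, f_list = [], []
            for nid, st in enumerate(per_neuron):
                j = np.searchsorted(st, t0, side="left")
                if j < len(st) and st[j] <= t1:
                    p_list.append(nid)
                    f_list.append(st[j])
            participants = np.array(p_list, dtype=np.int64)
            firsts = np.array(f_list)
        bursts.append(Burst(
            t_peak=float(times[i]), size=float(pa[i]),
            t_start=float(times[a]), t_end=float(times[b]),
            participants=participants, first_spike_times=firsts,
        ))
    return bursts


def analyze_activity(spikes: SpikeTrain, window: float = PA_WINDOW,
                     stride: float = PA_STRIDE, threshold: float = PA_THRESHOLD,
                     min_separation: float = MIN_SEPARATION) -> ActivitySummary:
    """PA trace plus detected bursts in one call."""
    times, pa = population_activity(spikes, window, stride)
    bursts = detect_bursts(times, pa, spikes, threshold, min_separation, window)
    return ActivitySummary(times=times, pa=pa, bursts=bursts,
                           window=window, threshold=threshold)


def dynamical_richness(peak_sizes, m: int = 10) -> float:
    """Theta: closeness of the burst-size histogram to uniform on [0, 1].

    Theta = 1 - m/(2(m-1)) * sum_i |p_i - 1/m| over an ``m``-bin histogram
    of the PA peak sizes Gamma.  0 means all bursts land in one bin (rigid,
    all-or-none dynamics); 1 means all co-activation sizes are equally
    represented.  Returns NaN for an empty peak list.
    """
    if m < 2:
        raise ValueError("m must be >= 2")
    g = np.asarray(peak_sizes, dtype=float)
    if g.size == 0:
        return float("nan")
    if np.any((g < 0) | (g > 1)):
        raise ValueError("peak sizes must lie in [0, 1]")
    bins = np.minimum((g * m).astype(int), m - 1)
    p = np.bincount(bins, minlength=m) / g.size
    return float(1.0 - m / (2.0 * (m - 1)) * np.abs(p - 1.0 / m).sum())


def _front_mask(burst: Burst, min_halfwidth: float = 25.0) -> np.ndarray:
    """Participants belonging to the coherent front passage.

    Bursts are preceded by a slow ignition phase in which scattered
    neurons fire long before the propagating front launches; these early
    outliers would corrupt both the initiation centroid and the velocity
    fit.  The front is isolated with a robust time window: first-spike
    times within 3 scaled MADs of the median (never narrower than
    ``min_halfwidth`` ms).
    """
    t = burst.first_spike_times
    if len(t) == 0:
        return np.zeros(0, dtype=bool)
    med = np.median(t)
    mad = np.median(np.abs(t - med))
    half = max(3.0 * 1.4826 * mad, min_halfwidth)
    return np.abs(t - med) <= half


def front_initiation(burst: Burst, positions: np.ndarray,
                     k_init: int = K_INIT):
    """Centroid of the earliest ``k_init`` front spikers of the burst.

    Returns None when the burst has fewer than ``k_init`` participants.
    Pre-front stragglers are excluded (see :func:`_front_mask`).
    """
    keep = _front_mask(burst)
    if keep.sum() < k_init:
        return None
    t = burst.first_spike_times[keep]
    order = np.argsort(t, kind="stable")[:k_init]
    return positions[burst.participants[keep][order]].mean(axis=0)


def front_velocity(burst: Burst, positions: np.ndarray, map=None,
                   k_init: int = K_INIT, trim: tuple = (5.0, 95.0),
                   min_extent: float = 0.05) -> float:
    """Front speed (mm/s) from first-spike times vs distance to initiation.

    Distances are Euclidean, except on a tracks substrate where only the
    stripe-perpendicular coordinate (x, for vertical stripes) is used,
    since the measured front moves transversally across tracks.  A least
    squares fit of distance on time is made on participants whose
    first-spike time lies within the ``trim`` percentiles (discarding
    outlier late spikers); degenerate bursts (tiny spatial or temporal
    extent, or a non-positive slope) give NaN.
    """
    init = front_initiation(burst, positions, k_init)
    if init is None:
        return float("nan")
    keep = _front_mask(burst)
    pos = positions[burst.participants[keep]]
    if map is not None and getattr(map, "condition", None) == "tracks":
        dist = np.abs(pos[:, 0] - init[0])
    else:
        dist = np.hypot(pos[:, 0] - init[0], pos[:, 1] - init[1])
    t = burst.first_spike_times[keep]
    t = t - t.min()
    lo, hi = np.percentile(t, trim)
    keep = (t >= lo) & (t <= hi)
    t, dist = t[keep], dist[keep]
    if len(t) < 4 or np.ptp(t) < 1e-6 or np.ptp(dist) < min_extent:
        return float("nan")
    # a propagating front must actually order firing times by distance;
    # near-simultaneous multi-site ignitions produce weakly ordered
    # time-distance clouds (r^2 well below the ~0.5 of clean fronts)
    # whose inverted slope is meaningless
    r = np.corrcoef(dist, t)[0, 1]
    if not np.isfinite(r) or r * r < 0.3 or r <= 0:
        return float("nan")
    # regress time on distance (positions are exact, spike times jittered;
    # the reverse fit would be attenuated by the firing-time noise)
    slope = np.polyfit(dist, t, 1)[0]  # ms per mm
    if not np.isfinite(slope) or slope <= 1e-9:
        return float("nan")
    return float(1000.0 / slope)


def burst_table(spikes: SpikeTrain, positions: np.ndarray, map=None,
                **kwargs):
    """Per-burst summary rows (peak time, size, initiation, velocity)."""
    import pandas as pd

    summary = analyze_activity(spikes)
    rows = []
    for b in summary.bursts:
        init = front_initiation(b, positions, kwargs.get("k_init", K_INIT))
        rows.append({
            "t_peak_ms": b.t_peak,
            "size_frac": b.size,
            "n_participants": len(b.participants),
            "x_init_mm": np.nan if init is None else init[0],
            "y_init_mm": np.nan if init is None else init[1],
            "velocity_mm_s": front_velocity(b, positions, map, **kwargs),
        })
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# half-culture calibration of axon crossing probabilities
# ---------------------------------------------------------------------------

def crossing_fraction(spikes: SpikeTrain, positions: np.ndarray, map,
                      participation: float = 0.2, k_init: int = K_INIT):
    """Activity-propagation fractions across a half-glass/half-PDMS border.

    Each burst is attributed to the side (glass x<0, PDMS x>0) of its
    initiation point; it counts as crossing when at least ``participation``
    of the far side's neurons take part.  Returns
    ``(frac_bottom_to_top, frac_top_to_bottom, n_bottom, n_top)`` with NaN
    fractions where no burst originated on a side.
    """
    if getattr(map, "condition", None) != "half":
        raise ValueError("crossing_fraction needs the half-PDMS calibration map")
    summary = analyze_activity(spikes)
    n_bottom = int(np.sum(positions[:, 0] < 0))
    n_top = len(positions) - n_bottom
    counts = {Direction.BOTTOM_TO_TOP: [0, 0], Direction.TOP_TO_BOTTOM: [0, 0]}
    for b in summary.bursts:
        init = front_initiation(b, positions, k_init)
        if init is None:
            continue
        origin_bottom = init[0] < 0
        far_mask = positions[b.participants, 0] >= 0 if origin_bottom else \
            positions[b.participants, 0] < 0
        far_total = n_top if origin_bottom else n_bottom
        d = Direction.BOTTOM_TO_TOP if origin_bottom else Direction.TOP_TO_BOTTOM
        counts[d][1] += 1
        if far_total > 0 and far_mask.sum() / far_total >= participation:
            counts[d][0] += 1
    def frac(c):
        return c[0] / c[1] if c[1] else float("nan")
    return (frac(counts[Direction.BOTTOM_TO_TOP]),
            frac(counts[Direction.TOP_TO_BOTTOM]),
            counts[Direction.BOTTOM_TO_TOP][1],
            counts[Direction.TOP_TO_BOTTOM][1])


def _simulate_half(p_bt, p_tb, h, rng, *, culture_radius, density,
                   mean_axon_length, duration, sigma, n_reps,
                   participation):
    """Pooled crossing fractions for one candidate probability pair."""
    tot = {Direction.BOTTOM_TO_TOP: [0, 0], Direction.TOP_TO_BOTTOM: [0, 0]}
    params = DynamicsParams(sigma=sigma)
    for _ in range(n_reps):
        m = make_half_pdms(culture_radius, h, crossing_probs={
            Direction.BOTTOM_TO_TOP: p_bt, Direction.TOP_TO_BOTTOM: p_tb})
        culture, net = growth.grow_network(
            m, density=density, mean_axon_length=mean_axon_length, rng=rng)
        spikes = simulate(net, params, duration, rng=rng)
        fbt, ftb, nb, nt = crossing_fraction(
            spikes, culture.positions, m, participation)
        if nb:
            tot[Direction.BOTTOM_TO_TOP][0] += fbt * nb
            tot[Direction.BOTTOM_TO_TOP][1] += nb
        if nt:
            tot[Direction.TOP_TO_BOTTOM][0] += ftb * nt
            tot[Direction.TOP_TO_BOTTOM][1] += nt
    def frac(c):
        return c[0] / c[1] if c[1] else float("nan")
    return frac(tot[Direction.BOTTOM_TO_TOP]), frac(tot[Direction.TOP_TO_BOTTOM])


def calibrate_crossing_probabilities(
    targets: tuple, h: float, rng=None, tolerance: float = 0.05,
    max_iter: int = 8, p_init: tuple | None = None,
    culture_radius: float = 1.0, density: float = 400.0,
    mean_axon_length: float = 1.0, duration: float = 120_000.0,
    sigma: float = 2.0, n_reps: int = 1, participation: float = 0.2,
    p_bounds: tuple = (1e-6, 1.0), simulator=None,
):
    """Fit per-direction axon crossing probabilities to activity targets.

    ``targets = (frac_bottom_to_top, frac_top_to_bottom)`` are the desired
    fractions of bursts that successfully propagate across the glass/PDMS
    border of a half-and-half culture of obstacle height ``h``.  Each
    direction's probability is adjusted by bisection on a log scale until
    the simulated propagation fraction matches its target within
    ``tolerance`` (the activity fractions respond monotonically to the
    axon probabilities).  Returns ``(probs, trail)`` where ``probs`` is the
    fitted pair and ``trail`` the audit list of evaluated candidates.

    Degenerate targets short-circuit: a target of 1 (or 0) maps directly
    to probability 1 (or 0) without simulation.

    ``simulator`` may replace the grow-and-simulate evaluation with any
    callable ``f(p_bt, p_tb, h, rng, **kwargs) -> (frac_bt, frac_tb)``,
    e.g. for calibration sensitivity studies.
    """
    rng = np.random.default_rng(rng)
    t_bt, t_tb = targets
    for t in (t_bt, t_tb):
        if not (0.0 <= t <= 1.0):
            raise ValueError("target fractions must be in [0, 1]")
    fixed = {}
    if t_bt >= 1.0 - 1e-12:
        fixed[0] = 1.0
    elif t_bt <= 1e-12:
        fixed[0] = 0.0
    if t_tb >= 1.0 - 1e-12:
        fixed[1] = 1.0
    elif t_tb <= 1e-12:
        fixed[1] = 0.0
    if len(fixed) == 2:
        return (fixed[0], fixed[1]), []

    lo = [math.log10(p_bounds[0])] * 2
    hi = [math.log10(p_bounds[1])] * 2
    if p_init is None:
        p = [math.sqrt(p_bounds[0] * p_bounds[1])] * 2
    else:
        p = [max(p_bounds[0], min(p_bounds[1], x)) for x in p_init]
    for d, val in fixed.items():
        p[d] = val
    trail = []
    sim_kwargs = dict(
        culture_radius=culture_radius, density=density,
        mean_axon_length=mean_axon_length, duration=duration, sigma=sigma,
        n_reps=n_reps, participation=participation)
    evaluate = _simulate_half if simulator is None else simulator
    converged = {d: (d in fixed) for d in (0, 1)}
    for it in range(max_iter):
        f = evaluate(p[0], p[1], h, rng, **sim_kwargs)
        trail.append({"iter": it, "p_bottom_to_top": p[0],
                      "p_top_to_bottom": p[1],
                      "frac_bottom_to_top": f[0], "frac_top_to_bottom": f[1]})
        targets_ = (t_bt, t_tb)
        for d in (0, 1):
            if converged[d]:
                continue
            if not math.isnan(f[d]) and abs(f[d] - targets_[d]) <= tolerance:
                converged[d] = True
                continue
            lp = math.log10(p[d])
            if math.isnan(f[d]) or f[d] < targets_[d]:
                lo[d] = lp
            else:
                hi[d] = lp
            p[d] = 10 ** ((lo[d] + hi[d]) / 2.0)
        if all(converged.values()):
            return (p[0], p[1]), trail
    raise RuntimeError(
        f"crossing-probability calibration did not converge in {max_iter} "
        f"iterations; trail: {trail}")
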