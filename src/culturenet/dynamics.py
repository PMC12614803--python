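"""Spiking dynamics of cultured networks.

Each neuron follows the Izhikevich quadratic integrate-and-fire model with
adaptation,

    dv/dt = 0.04 v^2 + 5 v + 140 - u + sum_j w_ij p_j + sigma eta_i(t)
    du/dt = eps (b v - u)

with a spike emitted when ``v > v_c`` followed by the resets ``v <- v_0``,
``u <- u + delta_u``.  Synaptic transmission uses an
instantaneous-rise/exponential-decay potential ``p`` per presynaptic
neuron (sign set by its type) and a depression variable ``q`` that is
depleted multiplicatively at each spike and recovers slowly:

    tau_p dp/dt = -p,      spike: p <- p + delta_p q
    tau_q dq/dt = 1 - q,   spike: q <- (1 - delta_q) q

Integration is fixed-step Euler-Maruyama for (v, u) — noise increment
``sigma * sqrt(dt) * N(0,1)`` per neuron per step — while the linear p and
q dynamics use their exact exponential decay over each step.  The
postsynaptic drive ``sum_j w_ij p_j`` is maintained incrementally (split
into excitatory and inhibitory components, each with its own decay
factor), which makes the cost per step O(N) plus O(out-degree) per spike.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
import math

import numpy as np
import scipy.sparse as sp

try:
    from numba import njit

    _HAVE_NUMBA = True
except ImportError:  # pragma: no cover - numba is a hard dependency in practice
    _HAVE_NUMBA = False

    def njit(*a, **k):
        def wrap(f):
            return f
        return wrap if not (a and callable(a[0])) else a[0]

__all__ = ["DynamicsParams", "SpikeTrain", "step", "simulate"]


@dataclass
class DynamicsParams:
    """Parameters of the neuron and synapse dynamics (ms, mV units)."""

    sigma: float = 2.0        # noise intensity (amplitude of sigma*sqrt(dt)*N(0,1))
    eps: float = 0.02         # adaptation rate, 1/ms
    b: float = 0.2            # adaptation voltage sensitivity
    v_c: float = 30.0         # spike threshold, mV
    v_0: float = -65.0        # reset potential, mV
    delta_u: float = 6.5      # adaptation increment at spike
    tau_pE: float = 10.0      # excitatory synaptic decay, ms
    delta_pE: float = 3.0     # max excitatory postsynaptic potential, mV
    tau_pI: float = 10.0      # inhibitory synaptic decay, ms
    delta_pI: float = -6.0    # max inhibitory postsynaptic potential, mV
    tau_q: float = 1000.0     # synaptic depression recovery, ms
    delta_q: float = 0.8      # vesicle-pool depletion fraction per spike
    dt: float = 0.1           # integration step, ms
    noise_as_variance: bool = False  # if True use sqrt(sigma*dt) increments

    def __post_init__(self):
        if self.dt <= 0:
            raise ValueError("dt must be positive")
        if not (0.0 < self.delta_q < 1.0):
            raise ValueError("delta_q must be in (0, 1)")
        if min(self.tau_pE, self.tau_pI, self.tau_q) <= 0:
            raise ValueError("all timescales must be positive")
        if self.delta_pE < 0 or self.delta_pI > 0:
            raise ValueError("delta_pE must be >= 0 and delta_pI <= 0")

    def noise_amplitude(self) -> float:
        """Per-step noise increment standard deviation."""
        if self.noise_as_variance:
            return math.sqrt(self.sigma * self.dt)
        return self.sigma * math.sqrt(self.dt)

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class SpikeTrain:
    """Spike events of one simulation run, sorted by time."""

    ids: np.ndarray       # (K,) neuron indices
    times: np.ndarray     # (K,) spike times, ms
    duration: float       # ms
    n_neurons: int
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        self.ids = np.asarray(self.ids, dtype=np.int64)
        self.times = np.asarray(self.times, dtype=float)
        if len(self.ids) != len(self.times):
            raise ValueError("ids and times must have equal length")
        if len(self.times) and (np.any(np.diff(self.times) < 0)):
            order = np.argsort(self.times, kind="stable")
            self.ids, self.times = self.ids[order], self.times[order]

    @property
    def n_spikes(self) -> int:
        return len(self.times)

    def spikes_of(self, neuron: int) -> np.ndarray:
        return self.times[self.ids == neuron]

    def per_neuron(self) -> list:
        """Spike times split per neuron (list of arrays, length n_neurons)."""
        order = np.argsort(self.ids, kind="stable")
        ids, times = self.ids[order], self.times[order]
        bounds = np.searchsorted(ids, np.arange(self.n_neurons + 1))
        return [times[bounds[i]:bounds[i + 1]] for i in range(self.n_neurons)]


# ---------------------------------------------------------------------------
# single reference step (used directly by tests and the slow path)
# ---------------------------------------------------------------------------

def step(state: dict, W, types, params: DynamicsParams, rng=None):
    """One Euler-Maruyama step of the full network; returns spike indices.

    ``state`` holds per-neuron vectors ``v, u, p, q`` and is updated in
    place.  ``W`` is the (N, N) weight matrix with row = postsynaptic.
    This is the readable reference implementation; :func:`simulate` runs an
    equivalent compiled loop.
    """
    rng = np.random.default_rng(rng)
    v, u, p, q = state["v"], state["u"], state["p"], state["q"]
    if not np.all(np.isfinite(v)):
        raise FloatingPointError(
            "membrane potential diverged; reduce dt (integration error)")
    dt = params.dt
    drive = np.asarray(W @ p).ravel()
    noise = params.noise_amplitude() * rng.standard_normal(len(v))
    dv = dt * (0.04 * v * v + 5.0 * v + 140.0 - u + drive) + noise
    du = dt * params.eps * (params.b * v - u)
    v += dv
    u += du
    # exact exponential decay of the linear synapse/depression dynamics
    tau_p = np.where(types == 0, params.tau_pE, params.tau_pI)
    p *= np.exp(-dt / tau_p)
    q[:] = 1.0 + (q - 1.0) * math.exp(-dt / params.tau_q)
    spiked = np.flatnonzero(v > params.v_c)
    if len(spiked):
        v[spiked] = params.v_0
        u[spiked] += params.delta_u
        delta_p = np.where(types[spiked] == 0, params.delta_pE, params.delta_pI)
        p[spiked] += delta_p * q[spiked]
        q[spiked] *= 1.0 - params.delta_q
    if np.any(np.abs(v) > 1e7):
        raise FloatingPointError(
            "membrane potential diverged; reduce dt (integration error)")
    return spiked


def initial_state(n: int, params: DynamicsParams) -> dict:
    """Resting-state initial conditions: v=v_0, u=b*v_0, p=0, q=1."""
    return {
        "v": np.full(n, params.v_0),
        "u": np.full(n, params.b * params.v_0),
        "p": np.zeros(n),
        "q": np.ones(n),
    }


# ---------------------------------------------------------------------------
# compiled simulation loop
# ---------------------------------------------------------------------------

@njit(cache=True, fastmath=True)
def _run_core(out_indptr, out_indices, out_weights, is_inh,
              n_steps, dt, noise_amp, eps, b, v_c, v_0, delta_u,
              f_pE, f_pI, delta_pE, delta_pI, f_q, delta_q,
              seed, spike_ids, spike_steps,
              v, u, p, q):  # pragma: no cover - compiled
    np.random.seed(seed)
    n = len(is_inh)
    i_exc = np.zeros(n)
    i_inh = np.zeros(n)
    # incremental postsynaptic drive, split by presynaptic type
    for j in range(n):
        if p[j] != 0.0:
            for e in range(out_indptr[j], out_indptr[j + 1]):
                if is_inh[j]:
                    i_inh[out_indices[e]] += out_weights[e] * p[j]
                else:
                    i_exc[out_indices[e]] += out_weights[e] * p[j]
    # branch-free per-neuron synaptic constants
    f_p = np.where(is_inh, f_pI, f_pE)
    delta_p = np.where(is_inh, delta_pI, delta_pE)
    spiked = np.empty(n, np.int64)
    cap = len(spike_ids)
    k = 0
    overflow = False
    diverged = False
    for s in range(n_steps):
        noise = np.random.standard_normal(n)
        for i in range(n):
            vi = v[i]
            dv = dt * (0.04 * vi * vi + 5.0 * vi + 140.0 - u[i]
                       + i_exc[i] + i_inh[i]) + noise_amp * noise[i]
            u[i] += dt * eps * (b * vi - u[i])
            v[i] = vi + dv
            p[i] *= f_p[i]
            q[i] = 1.0 + (q[i] - 1.0) * f_q
            i_exc[i] *= f_pE
            i_inh[i] *= f_pI
        # detect spikes with a simple scan; handle them in a short second
        # loop (keeping buffer writes and early exits out of the hot scan
        # lets the compiler vectorize the integration sweep)
        ns = 0
        for i in range(n):
            if v[i] > v_c:
                spiked[ns] = i
                ns += 1
            elif not (v[i] > -1e7):
                diverged = True
        if diverged:
            return -2
        for m in range(ns):
            i = spiked[m]
            if k < cap:
                spike_ids[k] = i
                spike_steps[k] = s + 1
                k += 1
            else:
                overflow = True
            v[i] = v_0
            u[i] += delta_u
            dp = delta_p[i] * q[i]
            p[i] += dp
            if is_inh[i]:
                for e in range(out_indptr[i], out_indptr[i + 1]):
                    i_inh[out_indices[e]] += out_weights[e] * dp
            else:
                for e in range(out_indptr[i], out_indptr[i + 1]):
                    i_exc[out_indices[e]] += out_weights[e] * dp
            q[i] *= 1.0 - delta_q
        if overflow:
            return -1
    return k


def simulate(network, params: DynamicsParams, duration: float, rng=None,
             init: dict | None = None) -> SpikeTrain:
    """Simulate the network for ``duration`` ms and return its spike train.

    ``network`` is a :class:`~culturenet.growth.StructuralNetwork` (or any
    object with ``W`` — row = postsynaptic — and ``types``).  Identical
    (network, params, seed) triples produce identical spike trains.
    Initial conditions default to the resting state (v = v_0, u = b v_0,
    p = 0, q = 1); ``init`` may override any of the four state vectors.
    """
    if duration <= 0:
        raise ValueError("duration must be positive")
    rng = np.random.default_rng(rng)
    seed = int(rng.integers(0, 2**31 - 1))
    W = network.W if sp.issparse(network.W) else sp.csr_matrix(network.W)
    types = np.asarray(network.types, dtype=np.int8)
    n = W.shape[0]
    # outgoing view: row j of W^T lists postsynaptic targets of neuron j
    out = W.T.tocsr()
    out.sort_indices()
    n_steps = int(round(duration / params.dt))
    dt = params.dt
    state = initial_state(n, params)
    if init:
        for key, val in init.items():
            state[key] = np.asarray(val, dtype=float).copy()
    cap = max(100_000, int(n * duration / 1000.0 * 30))
    for _ in range(6):
        spike_ids = np.empty(cap, dtype=np.int64)
        spike_steps = np.empty(cap, dtype=np.int64)
        k = _run_core(
            out.indptr, out.indices, out.data.astype(np.float64),
            types == 1, n_steps, dt, params.noise_amplitude(), params.eps,
            params.b, params.v_c, params.v_0, params.delta_u,
            math.exp(-dt / params.tau_pE), math.exp(-dt / params.tau_pI),
            params.delta_pE, params.delta_pI,
            math.exp(-dt / params.tau_q), params.delta_q,
            seed, spike_ids, spike_steps,
            state["v"].copy(), state["u"].copy(),
            state["p"].copy(), state["q"].copy(),
        )
        if k == -2:
            raise FloatingPointError(
                "membrane potential diverged; reduce dt (integration error)")
        if k >= 0:
            break
        cap *= 4
    else:  # pragma: no cover
        raise RuntimeError("spike buffer kept overflowing")
    return SpikeTrain(
        ids=spike_ids[:k].copy(),
        times=spike_steps[:k] * dt,
        duration=float(duration),
        n_neurons=n,
        meta={"seed": seed, "params": params.to_dict()},
    )


def simulate_reference(network, params: DynamicsParams, duration: float,
                       rng=None, init: dict | None = None) -> SpikeTrain:
    """Plain-numpy simulation using :func:`step`; slow, for cross-checks."""
    if duration <= 0:
        raise ValueError("duration must be positive")
    rng = np.random.default_rng(rng)
    W = network.W
    if sp.issparse(W):
        W = W.toarray()
    types = np.asarray(network.types)
    n = W.shape[0]
    state = initial_state(n, params)
    if init:
        for key, val in init.items():
            state[key] = np.asarray(val, dtype=float).copy()
    n_steps = int(round(duration / params.dt))
    ids, times = [], []
    for s in range(n_steps):
        spiked = step(state, W, types, params, rng)
        t = (s + 1) * params.dt
        for i in spiked:
            ids.append(i)
            times.append(t)
    return SpikeTrain(ids=np.array(ids, dtype=np.int64),
                      times=np.array(times), duration=float(duration),
                      n_neurons=n)
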