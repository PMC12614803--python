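# Methods

`culturenet` simulates the growth and spontaneous activity of dissociated
neuronal cultures plated on substrates with two-level PDMS topography, and
provides the analysis stack used to characterize such cultures: burst
statistics, dynamical richness, activity-front propagation, graph measures
of the structural network, and effective-connectivity reconstruction by
Generalised Transfer Entropy (GTE).

## Substrate model

A culture is a disk of radius `r` (default 1.5 mm).  Raised PDMS regions of
height `h` partition the surface into two levels; three standard conditions
are built in:

- **control** — flat, no obstacles;
- **tracks** — parallel raised stripes, 0.2 mm PDMS separated by 0.3 mm
  glass gaps (40% coverage, period 0.5 mm).  Stripes run vertically; all
  results are rotation-invariant;
- **squares** — randomly placed, non-overlapping raised squares covering
  25% of the disk, side 0.3 mm by default (the experimental side length is
  not fixed by the literature; `side` is a constructor argument).  Note a
  geometric consequence of the contact rules below: with 0.3 mm sides and
  ~0.15 mm dendritic reach, every raised soma is within reach of the
  surrounding surface, so square modules are only weakly isolated in this
  model.

Axon crossing probabilities per border attempt, `P(h, direction)`, follow
the calibrated table (1 at h=0; e.g. 0.45e-3 / 3.3e-3 for
bottom→top / top→bottom at h=0.1; 0 above h=0.7), linearly interpolated in
`h` between tabulated heights.  A half-glass/half-PDMS geometry
(`make_half_pdms`) reproduces the calibration setup, and
`metrics.calibrate_crossing_probabilities` re-fits the probabilities to
target activity-crossing fractions by bisection on a log scale (tolerance
0.05 by default on the activity fraction).

## Network growth

Somas (radius 7.5 µm, hard disks) are placed uniformly at density
ρ = 400 /mm² (N = ⌊ρπr²⌋; 2827 at r = 1.5 mm), 80% excitatory / 20%
inhibitory.  Each neuron grows one axon: segments of Δℓ = 10 µm whose
intrinsic direction performs a Gaussian random walk (σ_φ = 0.1 rad per
segment), up to a Rayleigh-distributed total length with mean ⟨ℓ⟩
(default 1 mm).  Dendritic trees are disks of Gaussian radius
150 ± 20 µm (truncated at 1 µm).

Obstacle borders interact with growth as follows.  If the intended segment
meets a border at incidence < 30°, it is replaced by a border-parallel
segment (plus heading-scale jitter).  At steeper incidence the axon
crosses with probability `P(h, d)` — a successful crossing costs Δℓ + h of
growth length — and is deflected parallel otherwise.  Two implementation
points are deliberate and load-bearing:

1. **Heading memory is intrinsic.**  Deflection clips the *placed*
   segment only; the growth direction keeps its own random walk.  An axon
   pointing into a wall therefore slides along it and re-attempts the
   crossing at every step until its direction diffuses away.  If instead
   the heading were reset to the placed (parallel) direction, a deflected
   axon would approach the wall only at vanishing incidence and
   effectively never attempt to cross again, making the calibrated
   10⁻³-scale probabilities inert at any culture size.
2. **The culture rim is a wall**: segments that would exit the disk are
   deflected parallel to the rim, so axon length is not silently lost at
   the boundary.

A synapse i→j may form wherever axon *i* passes through the dendritic disk
of *j*.  Each *crossing episode* (maximal run of consecutive segments
inside the disk) is an independent Bernoulli(α = 0.5) opportunity, so a
pair crossed *m* times connects with probability 1 − (1−α)^m; a
single-trial-per-pair variant is available (`alpha_mode="per_pair"`).
Contacts respect the topography asymmetrically: they require the axon
segment to lie **at or below** the target soma's level.  Dendritic arbors
of raised somas can spill down over an edge and intercept axons running
below, but arbors cannot climb a wall — the same descent/ascent asymmetry
the crossing-probability table encodes for axons.  This rule was selected
against the reported phenomenology: symmetric unclipped disks abolish
track modularity (39% of tracks edges cross channel borders and dynamics
are globally synchronous), while symmetric strict clipping starves the
channels (mean in-degree ~32 vs ~62 in control) and leaves them silent at
the operating noise level.  With the asymmetric rule, tracks networks at
h = 0.1, ⟨ℓ⟩ = 1 mm have mean in-degree ≈ 45–50, >95% of connections
within channels, connection angles peaked at ±π/2, and module-resolved
bursting.  `respect_levels=False` restores unclipped disks.

Edges are directed and stored with the convention `S[i, j] = 1 ⇔ j → i`
(row = postsynaptic).  Weights are i.i.d. U(0,1); the sign of a
connection is carried by the presynaptic neuron's type, not by `W`.

A zero-height pattern has no walls: growth on an `h = 0` substrate ignores
the pattern entirely, so tracks at h = 0 reduce exactly to control.

## Neuron and synapse dynamics

Each neuron follows the Izhikevich quadratic integrate-and-fire model with
adaptation,

    dv/dt = 0.04 v² + 5 v + 140 − u + Σ_j w_ij p_j + σ η(t)
    du/dt = ε (b v − u),            ε = 0.02 /ms, b = 0.2

with spike threshold v_c = 30 mV and resets v ← −65, u ← u + 6.5.
Synapses have instantaneous rise and exponential decay
(τ_p = 10 ms; release amplitude δ_pE = +3 mV, δ_pI = −6 mV) and
short-term depression: a resource q ∈ (0,1] multiplies each release, is
depleted by the factor (1 − δ_q) = 0.2 at every presynaptic spike and
recovers with τ_q = 1 s.  These parameter values place the flat culture in
the canonical regime of dissociated cultures: a quiescent network
punctuated by all-or-none network bursts terminated by synaptic
depression.

Integration is fixed-step Euler–Maruyama for (v, u) with dt = 0.1 ms;
the per-step noise increment is σ·√dt·N(0,1) (σ in mV/√ms, i.e. σ² in
mV²/ms; the alternative reading with increment √(σ·dt) is available via
`noise_as_variance=True`).  The linear p and q dynamics are advanced with
their exact exponential decay factors.  Spikes are detected after each
full step (resolution dt) and resets applied then; the postsynaptic drive
Σ w_ij p_j is maintained incrementally, split into excitatory and
inhibitory components, making the cost per step O(N) plus O(out-degree)
per spike.  Initial conditions are the resting state (v = −65, u = b·v,
p = 0, q = 1); there are no transmission delays.  The compiled core and
the plain-numpy reference stepper produce identical event streams on
deterministic fixtures, and halving dt moves first-spike times of a
deterministic chain fixture by well under 1 ms.

At the operating point (σ = 2.0, ⟨ℓ⟩ = 1 mm, h = 0.1 mm, 600 s):
control cultures burst all-or-none (peak population activity ≈ 0.98)
with fronts near 200 mm/s; tracks cultures produce module-resolved
bursts of widely varying size (Θ ≈ 0.5) whose transverse fronts travel
at ~20 mm/s; squares are intermediate.  Burst counts rise steeply with σ
and the culture fragments into asynchronous firing near σ ≈ 2.75.

## Activity measures

- **Population activity** PA(t): fraction of neurons with ≥1 spike in a
  τ_win = 200 ms window centred on t, evaluated every 10 ms.
- **Network bursts**: strict local maxima of PA(t) above 0.1; peaks
  closer than 500 ms merge (keeping the higher).  A burst's participants
  are the neurons spiking during its above-threshold excursion (padded by
  τ_win/2), each with its first spike time.
- **Dynamical richness** Θ = 1 − m/(2(m−1)) Σᵢ |pᵢ − 1/m| over an
  m-bin histogram (m = 10 by default) of burst peak sizes Γ ∈ [0,1]:
  0 when all bursts have one size, 1 when all sizes are equally
  represented.  Undefined (NaN) without bursts.
- **Fronts.**  Bursts ignite via a slow build-up phase in which scattered
  neurons fire long before the coherent front launches.  The front is
  therefore isolated with a robust window (first-spike times within 3
  scaled MADs of the median, floor ±25 ms) before any spatial analysis.
  The initiation point is the centroid of the 5 earliest front spikers.
  The velocity is obtained by regressing first-spike *time on distance*
  from the initiation point (5–95% time-trimmed) and inverting the slope;
  regressing distance on time would be attenuated by firing-time jitter,
  which at 200 mm/s rivals the culture traversal time.  A validity cut
  requires the fit to explain at least 30% of the first-spike-time
  variance: clean propagating fronts sit near r² ≈ 0.5, while
  near-simultaneous multi-site ignitions (which are not fronts) fall well
  below and would otherwise contribute arbitrarily large inverted slopes.
  Such bursts yield NaN and are excluded from velocity summaries.  On
  tracks substrates the distance uses only the stripe-perpendicular
  coordinate, matching how transverse front speeds are measured.
  Synthetic planted waves from 1 to 1000 mm/s are recovered within 5%.
- **Activity crossing** (half-glass/half-PDMS): each burst is attributed
  to the side of its initiation point; it counts as crossing when ≥20% of
  the far side's neurons participate.  The 20% quorum is an
  operationalization (config-exposed); the calibration loop is agnostic
  to it since it compares simulated and target fractions under the same
  criterion.

## Graph measures

Scalar measures are computed on the symmetrized binary graph (edge if
either direction exists), per the undirected 2m convention of modularity:
global efficiency (mean of 1/d over ordered pairs; disconnected pairs
contribute 0), Newman modularity Q of a partition, mean local clustering
(degree < 2 contributes 0), and Louvain community detection (best of 10
seeded restarts).  Null models are directed Erdős–Rényi graphs matched to
the observed mean in-degree, summarized as mean ± sd over draws.
In-degree, connection-length and connection-angle summaries use the
directed matrix and soma-to-soma geometry.

## Effective connectivity (GTE)

Spike trains are binarized at 10 ms.  For an ordered pair, transfer
entropy is estimated with plug-in histograms at Markov order k = 2 with
the same-bin source term included ("instant feedback"), in bits.  No bias
correction is applied; at the default 10 ms bins and ≥2×10⁴ samples the
plug-in bias (~10⁻³ bits) is far below the signal scale but is the reason
raw TE values should only be compared within a recording.  Each pair's TE
is z-scored against the pooled distribution of all inputs to its target
and all outputs of its source (the pair's own entry excluded; flag to
include), and thresholded at z ≥ 2 into a binary effective matrix.
Reconstruction quality against the known structural matrix is summarized
by the ROC AUC over off-diagonal entries (the structural convention is
transposed to source→target internally).  A conditioning variant that
drops high-activity bins (`exclude_high_activity`) is available and off
by default.

## Problem sizes and scaling

The model's reference operating conditions (`FULL` profile: r = 1.5 mm,
N ≈ 2800, 600 s, 10 replicates) are where the headline behaviours hold;
the package also defines a `DESK` profile (r = 0.75 mm, N ≈ 700, shorter
runs) for interactive work.  Quantities differ in how they scale down:

- Front velocities and burst shapes are size-intrinsic and stable from
  r ≈ 1.0 mm.
- Burst *rates* fall roughly with N (nucleation is noise-driven), so
  reduced runs need proportionally longer durations to collect the same
  number of bursts; tracks channels nucleate per channel and are the most
  size-sensitive condition.
- Activity-crossing fractions depend on the absolute number of
  border-crossing axons and hence on border length; they are measured at
  r = 1.5 mm.
- GTE cost grows as N²·T; the acceptance script estimates it on a random
  subset of 800 neurons of a full culture, which leaves the AUC estimate
  unbiased (the truth matrix is subset identically).

The acceptance script (`scripts/acceptance.py`) states the exact reduced
sizes it uses; the test suite uses smaller fixtures still.  What passing
tests show is that the implemented rules reproduce the model's reported
regime structure and quantitative anchors at these sizes; they do not
validate the model against new biological data, and the synthetic
cultures lack dendritic arborization, axon branching and bundling,
plasticity, apoptosis and astrocytes.

## Numerical choices and edge cases

- Geometry is exact segment/rectangle intersection with a 10⁻⁹ mm border
  tolerance; no rasterization.
- Square placement is rejection sampling with a 10⁵-attempt cap
  (`RuntimeError` on unreachable coverage); placement is reproducible
  from the seed.
- Soma packing uses dart throwing on a neighbour grid with an attempt cap.
- Axon growth at corners: if a border-parallel placement keeps crossing
  after jittered retries, the segment is truncated just short of the
  border; growth length is charged regardless so termination is
  guaranteed.
- All randomness flows from `numpy.random.Generator` seeds; the compiled
  simulation core derives a single integer seed per run from the caller's
  generator, so identical (network, parameters, seed) triples give
  identical spike trains.
- Degenerate inputs return missing values rather than raising where the
  quantity is genuinely undefined: Θ of an empty peak list, velocity of a
  spatially degenerate burst, crossing fractions with no bursts on a side.

## Known limitations

- The two-level topography supports axis-aligned rectangles only.
- The 30° deflection threshold, the 20% crossing quorum, Θ's bin count,
  and the burst-merge separation are field conventions or
  operationalizations, all exposed as parameters.
- The noise convention (amplitude vs variance reading of σ) is a genuine
  ambiguity of the model family; the default reproduces the documented
  operating regimes, and the alternative is one flag away.
- At strongly reduced sizes (r ≤ 0.75 mm) tracks cultures may produce no
  bursts in short runs; analyses then return empty tables rather than
  failing.
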