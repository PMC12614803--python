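"""Calibrate axon border-crossing probabilities against activity targets.

The per-segment probability that an axon scales a PDMS wall cannot be
measured directly; it is fitted so that simulated activity on a
half-glass/half-PDMS culture crosses the border at the experimentally
measured per-burst rates.  This demo runs the log-scale bisection loop at
a very small scale (short runs, small culture), so the fitted values are
coarse — the point is the machinery: each iteration grows a culture,
simulates it, classifies burst origins and measures crossing fractions.
"""

from culturenet.metrics import calibrate_crossing_probabilities

# degenerate targets resolve without simulation
probs, trail = calibrate_crossing_probabilities((1.0, 1.0), h=0.0)
print(f"h=0 targets (1, 1) -> probabilities {probs} ({len(trail)} sims)")

try:
    probs, trail = calibrate_crossing_probabilities(
        (0.6, 0.85), h=0.1, rng=0,
        culture_radius=0.75, duration=90_000.0, n_reps=1,
        tolerance=0.35, max_iter=4)
    print(f"h=0.1 coarse fit -> P(bottom->top)={probs[0]:.2e}, "
          f"P(top->bottom)={probs[1]:.2e}")
except RuntimeError as err:
    # at this tiny scale the loop may run out of iterations; the audit
    # trail in the message still shows the search closing in
    print(f"calibration did not converge at demo scale: {err}")
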