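"""Simulate spontaneous activity and detect network bursts.

Grows a small flat (control) culture, runs 120 s of Izhikevich dynamics
with synaptic depression at noise sigma = 2.0, and summarizes the
population activity.  On a flat substrate the culture is bistable:
near-silence interrupted by all-or-none network bursts in which almost
every neuron fires (peak sizes near 1), which is why the dynamical
richness Theta is close to 0.
"""

import numpy as np

import culturenet as cn
from culturenet.metrics import analyze_activity, dynamical_richness

culture, network = cn.grow_network(cn.make_control(0.75), rng=1)
spikes = cn.simulate(network, cn.DynamicsParams(sigma=2.0), 120_000.0, rng=2)
print(f"{culture.n_neurons} neurons, {spikes.n_spikes} spikes in 120 s "
      f"({spikes.n_spikes / culture.n_neurons / 120:.2f} Hz per neuron)")

summary = analyze_activity(spikes)
sizes = summary.peak_sizes
print(f"{len(sizes)} network bursts; peak sizes "
      f"{np.round(np.sort(sizes), 2)}")
if len(sizes):
    theta = dynamical_richness(sizes, m=10)
    print(f"dynamical richness Theta = {theta:.2f} "
          "(0 = rigid all-or-none bursting, 1 = all sizes equally likely)")
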