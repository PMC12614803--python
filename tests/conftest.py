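"""Shared fixtures: small cultures grown once per test session."""

import numpy as np
import pytest

import culturenet as cn


@pytest.fixture(scope="session")
def small_control():
    """Small flat culture (r = 0.5 mm, ~314 neurons) with its network."""
    culture, net = cn.grow_network(cn.make_control(0.5), rng=10)
    return culture, net


@pytest.fixture(scope="session")
def small_tracks():
    """Small tracks culture (r = 0.75 mm, h = 0.1) with its network."""
    m = cn.make_tracks(0.75, h=0.1)
    culture, net = cn.grow_network(m, rng=11)
    return m, culture, net


@pytest.fixture(scope="session")
def small_squares():
    m = cn.make_squares(0.75, h=0.1, rng=12)
    culture, net = cn.grow_network(m, rng=13)
    return m, culture, net


def make_spike_train(ids, times, duration, n_neurons):
    return cn.SpikeTrain(ids=np.asarray(ids), times=np.asarray(times, float),
                         duration=duration, n_neurons=n_neurons)
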