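"""Activity metrics: PA windows, burst detection, richness and fronts."""

import numpy as np
import pytest

import culturenet.metrics as M
from culturenet.topography import make_half_pdms, make_tracks

from conftest import make_spike_train


class TestPopulationActivity:
    def test_all_fire_at_zero(self):
        st = make_spike_train([0, 1, 2, 3], [0, 0, 0, 0], 1000.0, 4)
        times, pa = M.population_activity(st)
        assert pa[0] == 1.0

    def test_empty_train(self):
        st = make_spike_train([], [], 1000.0, 4)
        _, pa = M.population_activity(st)
        assert np.all(pa == 0)

    def test_window_membership_example(self):
        """Neurons 0 and 1 fall in the 200 ms window centred at 150 ms."""
        st = make_spike_train([0, 1, 2], [100.0, 150.0, 290.0], 1000.0, 4)
        times, pa = M.population_activity(st, window=200.0, stride=10.0)
        assert pa[list(times).index(150.0)] == 0.5

    def test_brute_force_recount(self):
        """Windowed-set definition equals a direct per-centre recount."""
        rng = np.random.default_rng(0)
        for _ in range(10):
            n, k = 6, 40
            ids = rng.integers(0, n, k)
            ts = np.sort(rng.uniform(0, 2000, k))
            st = make_spike_train(ids, ts, 2000.0, n)
            times, pa = M.population_activity(st, window=200.0, stride=10.0)
            for c in rng.choice(len(times), 25, replace=False):
                t = times[c]
                active = {i for i, s in zip(ids, ts) if abs(s - t) < 100.0}
                assert pa[c] == pytest.approx(len(active) / n)

    def test_invalid_window(self):
        st = make_spike_train([], [], 100.0, 1)
        with pytest.raises(ValueError):
            M.population_activity(st, window=0.0)


def _pa_bursts(pa, stride=10.0, **kw):
    times = np.arange(len(pa)) * stride
    return M.detect_bursts(times, np.asarray(pa, float), **kw)


class TestDetectBursts:
    def test_flat_subthreshold(self):
        assert _pa_bursts([0.05] * 100) == []

    def test_single_peak(self):
        pa = np.zeros(100)
        pa[40:61] = np.concatenate([np.linspace(0, 0.8, 11),
                                    np.linspace(0.8, 0, 11)[1:]])
        bursts = _pa_bursts(pa)
        assert len(bursts) == 1
        assert bursts[0].size == pytest.approx(0.8)

    def test_close_peaks_merge(self):
        pa = np.zeros(200)
        pa[50] = 0.5
        pa[49] = pa[51] = 0.2
        pa[55] = 0.7  # 50 ms later
        pa[54] = pa[56] = 0.2
        bursts = _pa_bursts(pa, min_separation=200.0)
        assert len(bursts) == 1
        assert bursts[0].size == pytest.approx(0.7)

    def test_distant_peaks_kept(self):
        pa = np.zeros(300)
        for c in (50, 150, 250):
            pa[c] = 0.5
            pa[c - 1] = pa[c + 1] = 0.2
        assert len(_pa_bursts(pa, min_separation=500.0)) == 3

    def test_threshold_validation(self):
        with pytest.raises(ValueError):
            _pa_bursts([0.5] * 10, threshold=1.5)


class TestDynamicalRichness:
    def test_single_bin_is_zero(self):
        assert M.dynamical_richness([0.42] * 30, m=10) == pytest.approx(0.0)

    def test_uniform_is_one(self):
        peaks = (np.arange(10) + 0.5) / 10
        assert M.dynamical_richness(peaks, m=10) == pytest.approx(1.0)

    def test_two_bins_split(self):
        assert M.dynamical_richness([0.25, 0.75], m=2) == pytest.approx(1.0)

    def test_order_and_duplication_invariance(self):
        rng = np.random.default_rng(1)
        peaks = rng.uniform(0, 1, 40)
        theta = M.dynamical_richness(peaks, m=10)
        assert M.dynamical_richness(peaks[::-1], m=10) == pytest.approx(theta)
        assert M.dynamical_richness(np.tile(peaks, 2), m=10) == \
            pytest.approx(theta)

    def test_empty_is_nan(self):
        assert np.isnan(M.dynamical_richness([], m=10))

    def test_bounds(self):
        rng = np.random.default_rng(2)
        for _ in range(20):
            th = M.dynamical_richness(rng.uniform(0, 1, 15), m=10)
            assert 0.0 <= th <= 1.0


def _planar_wave_burst(v_mm_s, n=400, seed=0, origin=(0.3, -0.2),
                       radial=True):
    """Synthetic burst: first-spike times from a wave at speed v."""
    rng = np.random.default_rng(seed)
    pos = rng.uniform(-1.5, 1.5, (n, 2))
    d = np.hypot(pos[:, 0] - origin[0], pos[:, 1] - origin[1]) if radial \
        else np.abs(pos[:, 0] - origin[0])
    t = 1000.0 * d / v_mm_s  # ms
    burst = M.Burst(t_peak=float(np.median(t)), size=1.0, t_start=0.0,
                    t_end=float(t.max()), participants=np.arange(n),
                    first_spike_times=t)
    return burst, pos


class TestFronts:
    def test_initiation_at_wave_origin(self):
        burst, pos = _planar_wave_burst(100.0)
        init = M.front_initiation(burst, pos)
        assert np.hypot(init[0] - 0.3, init[1] + 0.2) < 0.1

    def test_initiation_requires_quorum(self):
        burst, pos = _planar_wave_burst(100.0, n=3)
        assert M.front_initiation(burst, pos, k_init=5) is None

    @pytest.mark.parametrize("speed", [1.0, 10.0, 100.0, 1000.0])
    def test_velocity_recovery_over_two_decades(self, speed):
        burst, pos = _planar_wave_burst(speed)
        v = M.front_velocity(burst, pos)
        assert v == pytest.approx(speed, rel=0.05)

    def test_simultaneous_activation_is_missing(self):
        burst, pos = _planar_wave_burst(100.0)
        burst.first_spike_times = np.zeros_like(burst.first_spike_times)
        assert np.isnan(M.front_velocity(burst, pos))

    def test_tracks_uses_transverse_coordinate(self):
        m = make_tracks(1.5, h=0.1)
        burst, pos = _planar_wave_burst(50.0, radial=False, origin=(0.0, 0.0))
        v = M.front_velocity(burst, pos, map=m)
        assert v == pytest.approx(50.0, rel=0.05)


class TestCrossingFraction:
    def _train_for(self, pos, active_mask, t0=1000.0):
        ids = np.flatnonzero(active_mask)
        # earliest spikers clustered so the initiation point is well defined
        order = np.argsort(pos[ids, 0] * np.sign(pos[ids, 0].mean()))
        times = t0 + np.linspace(0, 80, len(ids))
        return make_spike_train(ids[order], times, 3000.0, len(pos))

    def test_confined_burst_does_not_cross(self):
        m = make_half_pdms(1.0, 0.1)
        rng = np.random.default_rng(0)
        pos = rng.uniform(-1, 1, (200, 2)) * 0.7
        left = pos[:, 0] < 0
        st = self._train_for(pos, left)
        fbt, ftb, nb, nt = M.crossing_fraction(st, pos, m)
        assert nb == 1 and fbt == 0.0

    def test_full_culture_burst_crosses(self):
        m = make_half_pdms(1.0, 0.1)
        rng = np.random.default_rng(1)
        pos = rng.uniform(-1, 1, (200, 2)) * 0.7
        ids = np.argsort(pos[:, 0])  # wave from left: initiation on glass
        times = 1000.0 + np.linspace(0, 80, len(ids))
        st = make_spike_train(ids, times, 3000.0, len(pos))
        fbt, ftb, nb, nt = M.crossing_fraction(st, pos, m)
        assert nb == 1 and fbt == 1.0

    def test_requires_half_map(self):
        st = make_spike_train([], [], 100.0, 3)
        with pytest.raises(ValueError):
            M.crossing_fraction(st, np.zeros((3, 2)), make_tracks(1.0))


class TestCalibration:
    def test_trivial_targets_short_circuit(self):
        probs, trail = M.calibrate_crossing_probabilities((1.0, 1.0), h=0.0)
        assert probs == (1.0, 1.0) and trail == []
        probs, _ = M.calibrate_crossing_probabilities((0.0, 0.0), h=0.8)
        assert probs == (0.0, 0.0)

    def test_invalid_targets(self):
        with pytest.raises(ValueError):
            M.calibrate_crossing_probabilities((1.2, 0.5), h=0.1)
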