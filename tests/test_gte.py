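"""Transfer-entropy estimation, z-scoring and ROC scoring."""

import numpy as np
import pytest

from culturenet import gte
from conftest import make_spike_train


class TestBinarize:
    def test_bin_index(self):
        st = make_spike_train([0], [25.0], 100.0, 2)
        b = gte.binarize(st, bin_ms=10.0)
        assert b.shape == (2, 10)
        assert b[0, 2] == 1 and b.sum() == 1

    def test_multiple_spikes_saturate(self):
        st = make_spike_train([0, 0, 0], [11.0, 13.0, 19.0], 100.0, 1)
        b = gte.binarize(st, bin_ms=10.0)
        assert b[0, 1] == 1 and b.sum() == 1

    def test_bin_count(self):
        st = make_spike_train([], [], 600_000.0, 1)
        assert gte.binarize(st, 10.0).shape[1] == 60_000


class TestGtePair:
    def test_independent_series_near_zero(self):
        rng = np.random.default_rng(0)
        a = (rng.random(60_000) < 0.1).astype(np.uint8)
        b = (rng.random(60_000) < 0.1).astype(np.uint8)
        assert gte.gte_pair(a, b, k=2, instant_feedback=True) < 0.001

    def test_shifted_copy_carries_one_bit(self):
        rng = np.random.default_rng(1)
        src = (rng.random(60_000) < 0.5).astype(np.uint8)
        dst = np.roll(src, 1)
        te = gte.gte_pair(src, dst, k=1, instant_feedback=False)
        assert te == pytest.approx(1.0, abs=0.01)

    def test_instant_feedback_captures_same_bin(self):
        rng = np.random.default_rng(2)
        src = (rng.random(60_000) < 0.5).astype(np.uint8)
        te_on = gte.gte_pair(src, src.copy(), k=1, instant_feedback=True)
        te_off = gte.gte_pair(src, src.copy(), k=1, instant_feedback=False)
        assert te_on == pytest.approx(1.0, abs=0.01)
        assert te_off < 0.01

    def test_constant_series(self):
        z = np.zeros(1000, dtype=np.uint8)
        assert gte.gte_pair(z, z) == 0.0

    def test_nonnegative_up_to_estimator_noise(self):
        rng = np.random.default_rng(3)
        for _ in range(10):
            a = (rng.random(5000) < 0.2).astype(np.uint8)
            b = (rng.random(5000) < 0.2).astype(np.uint8)
            assert gte.gte_pair(a, b) > -1e-12

    def test_series_length_validation(self):
        with pytest.raises(ValueError):
            gte.gte_pair(np.zeros(3, np.uint8), np.zeros(3, np.uint8), k=2)


class TestGteMatrix:
    def test_matches_pairwise_calls(self):
        rng = np.random.default_rng(4)
        b = (rng.random((4, 3000)) < 0.2).astype(np.uint8)
        te = gte.gte_matrix(b, k=2, instant_feedback=True)
        for i in range(4):
            assert te[i, i] == 0.0
            for j in range(4):
                if i != j:
                    assert te[i, j] == pytest.approx(
                        gte.gte_pair(b[i], b[j]), abs=1e-12)

    def test_directed_chain_dominates(self):
        rng = np.random.default_rng(5)
        src = (rng.random(30_000) < 0.3).astype(np.uint8)
        mid = np.roll(src, 1)
        noise = (rng.random(30_000) < 0.3).astype(np.uint8)
        te = gte.gte_matrix(np.vstack([src, mid, noise]), k=1,
                            instant_feedback=False)
        assert te[0, 1] > te[1, 0]
        assert te[0, 1] > te[0, 2]


class TestZScore:
    def test_uniform_te_gives_zero(self):
        te = np.full((5, 5), 0.3)
        np.fill_diagonal(te, 0)
        assert np.allclose(gte.zscore_matrix(te), 0.0)

    def test_brute_force_pooling_oracle(self):
        rng = np.random.default_rng(6)
        te = rng.random((6, 6))
        np.fill_diagonal(te, 0)
        z = gte.zscore_matrix(te)
        for i in range(6):
            for j in range(6):
                if i == j:
                    continue
                pool = [te[x, j] for x in range(6) if x != j and (x, j) != (i, j)]
                pool += [te[i, y] for y in range(6) if y != i and (i, y) != (i, j)]
                mu, sd = np.mean(pool), np.std(pool)
                assert z[i, j] == pytest.approx((te[i, j] - mu) / sd, rel=1e-9)

    def test_dominant_entry_has_max_z(self):
        te = np.full((6, 6), 0.1)
        np.fill_diagonal(te, 0)
        te[2, 4] = 5.0
        z = gte.zscore_matrix(te)
        assert z[2, 4] == z.max()

    def test_small_matrix_rejected(self):
        with pytest.raises(ValueError):
            gte.zscore_matrix(np.zeros((2, 2)))


class TestThreshold:
    def test_extreme_thresholds(self):
        rng = np.random.default_rng(7)
        z = rng.normal(0, 1, (5, 5))
        assert gte.threshold(z, np.inf).sum() == 0
        assert gte.threshold(z, -np.inf).sum() == 20  # all off-diagonal

    def test_cutoff_inclusive(self):
        z = np.zeros((3, 3))
        z[0, 1] = 2.0
        z[1, 2] = 1.99
        e = gte.threshold(z, 2.0)
        assert e[0, 1] == 1 and e[1, 2] == 0


class TestRocAuc:
    def _truth(self, n, density, seed):
        rng = np.random.default_rng(seed)
        t = (rng.random((n, n)) < density).astype(int)
        np.fill_diagonal(t, 0)
        return t

    def test_perfect_scores(self):
        t = self._truth(8, 0.3, 0)
        scores = t.T + 1e-6 * np.random.default_rng(1).random((8, 8))
        _, _, auc = gte.roc_auc(scores, t)
        assert auc == 1.0

    def test_random_scores_near_half(self):
        rng = np.random.default_rng(2)
        aucs = []
        for s in range(20):
            t = self._truth(12, 0.3, 100 + s)
            _, _, auc = gte.roc_auc(rng.random((12, 12)), t)
            aucs.append(auc)
        assert np.mean(aucs) == pytest.approx(0.5, abs=0.05)

    def test_equals_rank_statistic(self):
        """AUC equals the Mann-Whitney U statistic normalized by n1*n0."""
        rng = np.random.default_rng(3)
        for s in range(10):
            n = 6
            t = self._truth(n, 0.4, 200 + s)
            if t.sum() == 0 or t.sum() == n * (n - 1):
                continue
            scores = rng.random((n, n))
            _, _, auc = gte.roc_auc(scores, t)
            mask = ~np.eye(n, dtype=bool)
            y = t.T[mask]
            x = scores[mask]
            pos, neg = x[y == 1], x[y == 0]
            u = sum((pos[:, None] > neg[None, :]).sum()
                    for _ in [0]) + 0.5 * (pos[:, None] == neg[None, :]).sum()
            assert auc == pytest.approx(u / (len(pos) * len(neg)), rel=1e-9)

    def test_degenerate_truth_raises(self):
        with pytest.raises(ValueError):
            gte.roc_auc(np.random.default_rng(0).random((4, 4)),
                        np.zeros((4, 4)))


class TestReconstructPipeline:
    def test_shifted_pair_network(self):
        """Reconstruction recovers a planted feed-forward motif."""
        rng = np.random.default_rng(8)
        n, t_len = 6, 20_000
        base = (rng.random((n, t_len)) < 0.15).astype(np.uint8)
        # neuron 1 echoes neuron 0 one bin later on top of its own noise
        base[1] |= np.roll(base[0], 1)
        st_duration = t_len * 10.0
        ids, times = [], []
        for i in range(n):
            for b in np.flatnonzero(base[i]):
                ids.append(i)
                times.append(b * 10.0 + 5.0)
        st = make_spike_train(ids, times, st_duration, n)
        eff = gte.reconstruct(st, bin_ms=10.0, k=2, z_th=2.0)
        assert eff.z[0, 1] == eff.z.max()
        assert eff.E[0, 1] == 1
        assert np.all(np.diag(eff.E) == 0)
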