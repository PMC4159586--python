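import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from sklearn.metrics import adjusted_rand_score

import scnmap as sm
from scnmap.cluster import (
    KMedoids,
    cosine_distance,
    cosine_distance_matrix,
    gap_select_k,
    kmedoids,
    rank_and_trim,
    window_stability,
)
from scnmap.io import SeriesMatrix


def make_series(X, dt=0.5):
    n = X.shape[0]
    coords = np.column_stack([np.arange(n), np.zeros(n, dtype=int)])
    return SeriesMatrix(X, coords, np.ones(n, dtype=bool), dt_hours=dt)


class TestCosineDistance:
    def test_identical_is_zero(self):
        u = np.array([3.0, 1.0, 4.0])
        assert cosine_distance(u, u) == pytest.approx(0.0, abs=1e-15)

    def test_orthogonal_is_one(self):
        assert cosine_distance([1.0, 0.0], [0.0, 1.0]) == pytest.approx(1.0)

    def test_zero_norm_rejected(self):
        with pytest.raises(ValueError, match="zero-norm"):
            cosine_distance([0.0, 0.0], [1.0, 2.0])

    @settings(max_examples=100, deadline=None, derandomize=True)
    @given(st.integers(0, 2 ** 31 - 1),
           st.floats(0.01, 100.0), st.floats(0.01, 100.0))
    def test_rescaling_invariance(self, seed, alpha, beta):
        rng = np.random.default_rng(seed)
        u = rng.normal(size=12)
        v = rng.normal(size=12)
        d0 = cosine_distance(u, v)
        d1 = cosine_distance(alpha * u, beta * v)
        assert d1 == pytest.approx(d0, abs=1e-12)


class TestKMedoids:
    def test_orthogonal_prototypes_recovered(self):
        k, reps = 4, 6
        X = np.repeat(np.eye(k), reps, axis=0)
        est = KMedoids(n_clusters=k, random_state=0).fit(X)
        truth = np.repeat(np.arange(k), reps)
        assert adjusted_rand_score(truth, est.labels_) == 1.0
        assert est.inertia_ == pytest.approx(0.0, abs=1e-12)

    def test_per_series_rescaling_leaves_labels(self):
        rng = np.random.default_rng(1)
        t = np.arange(60) * 0.5
        X = np.vstack([
            10 + 5 * np.cos(2 * np.pi * (t - p) / 24) + rng.normal(0, .2, 60)
            for p in (0, 0, 0, 12, 12, 12, 6, 6, 6)
        ])
        a = KMedoids(n_clusters=3, random_state=3).fit(X).labels_
        scales = rng.uniform(0.1, 10, size=(9, 1))
        b = KMedoids(n_clusters=3, random_state=3).fit(X * scales).labels_
        assert adjusted_rand_score(a, b) == 1.0

    def test_deterministic_given_seed(self):
        rng = np.random.default_rng(5)
        X = rng.uniform(1, 2, (40, 30))
        a = KMedoids(n_clusters=4, random_state=9).fit(X)
        b = KMedoids(n_clusters=4, random_state=9).fit(X)
        assert np.array_equal(a.labels_, b.labels_)
        assert np.array_equal(a.medoid_indices_, b.medoid_indices_)

    def test_medoids_belong_to_their_cluster(self):
        rng = np.random.default_rng(8)
        X = rng.uniform(1, 2, (50, 20))
        est = KMedoids(n_clusters=5, random_state=2).fit(X)
        for j, m in enumerate(est.medoid_indices_):
            assert est.labels_[m] == j

    def test_small_instance_matches_exhaustive_search(self):
        """k = 2 on <= 12 points: restarts attain the global optimum."""
        rng = np.random.default_rng(0)
        for trial in range(10):
            X = rng.uniform(0.1, 1.0, size=(10, 8))
            D = cosine_distance_matrix(X)
            best = min(
                D[:, [i, j]].min(axis=1).sum()
                for i, j in itertools.combinations(range(10), 2)
            )
            est = KMedoids(n_clusters=2, n_init=20, random_state=trial).fit(X)
            assert est.inertia_ == pytest.approx(best, rel=1e-9)

    def test_k_larger_than_n_rejected(self):
        with pytest.raises(ValueError, match="exceeds"):
            KMedoids(n_clusters=5).fit(np.ones((3, 4)) + np.eye(3, 4))

    def test_planted_wt_partition_recovered(self, wt_series):
        series, truth = wt_series
        result = kmedoids(series, 5, seed=1)
        valid = result.labels >= 0
        assert adjusted_rand_score(truth[valid], result.labels[valid]) >= 0.9


class TestGapStatistic:
    def test_two_antiphase_bundles(self):
        rng = np.random.default_rng(3)
        t = np.arange(120) * 0.5
        a = 50 + 40 * np.cos(2 * np.pi * t / 24) + rng.normal(0, 2, (30, 120))
        b = 50 + 40 * np.cos(2 * np.pi * (t - 12) / 24) + rng.normal(0, 2, (30, 120))
        curve = gap_select_k(make_series(np.vstack([a, b])), k_max=6, B=20,
                             seed=0)
        assert curve.chosen_k == 2

    def test_single_bundle_chooses_one(self):
        rng = np.random.default_rng(3)
        t = np.arange(120) * 0.5
        a = 50 + 40 * np.cos(2 * np.pi * t / 24) + rng.normal(0, 2, (30, 120))
        assert gap_select_k(make_series(a), k_max=6, B=20, seed=0).chosen_k == 1

    def test_identical_series_chooses_one(self):
        X = np.tile(np.linspace(1, 2, 50), (20, 1))
        assert gap_select_k(make_series(X), k_max=4, B=10, seed=0).chosen_k == 1

    def test_reference_count_floor(self):
        with pytest.raises(ValueError, match="reference"):
            gap_select_k(make_series(np.random.default_rng(0).uniform(
                1, 2, (20, 10))), k_max=3, B=5, seed=0)


class TestRankAndTrim:
    def _result(self, amplitudes):
        t = np.arange(96) * 0.5
        phases = np.linspace(0, 16, len(amplitudes), endpoint=False)
        X = np.vstack([
            50 + a * np.cos(2 * np.pi * (t - p) / 24)
            for a, p in zip(amplitudes, phases)
        ])
        X = np.repeat(X, 3, axis=0)
        return kmedoids(make_series(X), len(amplitudes), seed=0)

    def test_keeps_highest_amplitude_in_order(self):
        result = self._result([10.0, 5.0, 1.0])
        trimmed = rank_and_trim(result, top_n=2)
        amps = trimmed.amplitudes()
        assert trimmed.k == 2
        assert amps[0] > amps[1]
        assert amps[0] == pytest.approx(result.amplitudes().max())
        assert np.sum(trimmed.labels == -1) == 3

    def test_tie_break_is_stable_by_cluster_id(self):
        result = self._result([5.0, 5.0, 5.0])
        trimmed = rank_and_trim(result, top_n=3)
        assert np.array_equal(trimmed.amplitude_rank, [0, 1, 2])

    def test_too_few_clusters_warns_and_keeps_all(self):
        result = self._result([10.0, 5.0])
        with pytest.warns(UserWarning, match="keeps all"):
            trimmed = rank_and_trim(result, top_n=6)
        assert trimmed.k == 2

    def test_wt_scatter_cluster_is_trimmed(self, wt_series):
        """The lowest-amplitude cluster is dropped by the top-n rule."""
        series, _ = wt_series
        result = kmedoids(series, 5, seed=1)
        trimmed = rank_and_trim(result, top_n=4)
        dropped = result.amplitude_rank[-1]
        assert np.all(trimmed.labels[result.labels == dropped] == -1)


class TestWindowStability:
    def test_duplicated_windows_agree_exactly(self):
        rng = np.random.default_rng(6)
        t = np.arange(60) * 0.5
        X = np.vstack([
            20 + 10 * np.cos(2 * np.pi * (t - p) / 24) + rng.normal(0, .5, 60)
            for p in (0,) * 10 + (12,) * 10
        ])
        tiled = make_series(np.hstack([X, X]))
        aris = window_stability(tiled, 2, 2, seed=0)
        assert np.allclose(aris, 1.0)

    def test_noise_windows_disagree(self):
        rng = np.random.default_rng(0)
        X = rng.normal(100, 5, (150, 120))
        aris = window_stability(make_series(X), 2, 5, seed=1)
        assert np.all(np.abs(aris) < 0.2)

    def test_wt_windows_stable(self, wt_series):
        series, _ = wt_series
        aris = window_stability(series, 2, 5, seed=1)
        assert np.all(aris >= 0.8)

    def test_short_window_rejected(self):
        X = np.random.default_rng(0).uniform(1, 2, (10, 5))
        with pytest.raises(ValueError, match="2 frames"):
            window_stability(make_series(X), 4, 2, seed=0)
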