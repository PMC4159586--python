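import itertools

import numpy as np
import pytest

import scnmap as sm
from scnmap.graph import (
    SimilarityGraph,
    build_graph,
    circular_corr,
    circular_mean,
    clockface,
    clockhand_summary,
    cluster_contiguity,
    correlation_distance,
    correlation_distance_matrix,
    embedding_coherence,
    laplacian_spectrum,
    ncut_value,
    scree_select_l,
    spatial_coherence,
    spectral_analysis,
    spectral_cluster,
    spectral_embedding,
)
from scnmap.io import SeriesMatrix


def brute_min_ncut(W):
    n = W.shape[0]
    best = np.inf
    for bits in range(1, 2 ** (n - 1)):
        lab = np.array([(bits >> i) & 1 for i in range(n)])
        best = min(best, ncut_value(W, lab))
    return best


def graph_from_weights(W):
    n = W.shape[0]
    return SimilarityGraph(nodes=np.arange(n), distance=np.zeros((n, n)),
                           weights=W, sigma=1.0)


class TestCorrelationDistance:
    def test_anchor_values(self):
        t = np.linspace(0, 4 * np.pi, 64)
        u = np.sin(t)
        assert correlation_distance(u, -u) == pytest.approx(1.0)
        assert correlation_distance(u, u) == pytest.approx(0.0)
        # exactly orthogonal residuals: r = 0 -> sqrt(2)/2
        v = np.cos(t)
        v = v - v.mean()
        u0 = u - u.mean()
        v = v - (u0 @ v) / (u0 @ u0) * u0
        assert correlation_distance(u0, v) == pytest.approx(
            np.sqrt(2) / 2, abs=1e-12)

    def test_constant_series_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            correlation_distance(np.ones(10), np.arange(10.0))

    def test_location_invariance(self):
        rng = np.random.default_rng(0)
        u, v = rng.normal(size=(2, 40))
        assert correlation_distance(u + 100, v - 7) == pytest.approx(
            correlation_distance(u, v), abs=1e-12)


class TestBuildGraph:
    def test_kernel_anchors(self):
        # d = 0 -> W = 1 for any sigma
        assert np.exp(-0.0) == 1.0
        d = np.sqrt(2) / 2
        w_narrow = np.exp(-d ** 2 / (2 * 0.3 ** 2))
        w_wide = np.exp(-d ** 2 / (2 * 0.95 ** 2))
        assert w_narrow == pytest.approx(0.0622, abs=1e-3)  # suppressed
        assert w_wide == pytest.approx(0.758, abs=1e-3)     # retained

    def test_graph_matrix_properties(self):
        rng = np.random.default_rng(1)
        X = rng.normal(10, 2, (20, 50))
        g = build_graph(X, sigma=0.95)
        assert np.allclose(g.weights, g.weights.T)
        assert np.allclose(np.diag(g.weights), 1.0)
        assert g.weights.min() > 0
        assert g.distance.min() >= 0 and g.distance.max() <= 1

    def test_constant_rows_dropped(self):
        X = np.vstack([np.ones(30), np.random.default_rng(0).normal(size=(5, 30))])
        coords = np.column_stack([np.arange(6), np.zeros(6, int)])
        series = SeriesMatrix(X, coords, np.ones(6, bool), dt_hours=0.5)
        with pytest.warns(UserWarning, match="constant"):
            g = build_graph(series)
        assert g.n_nodes == 5 and 0 not in g.nodes

    def test_bad_sigma_rejected(self):
        with pytest.raises(ValueError, match="sigma"):
            build_graph(np.random.default_rng(0).normal(size=(4, 10)), sigma=0)


class TestLaplacian:
    def test_complete_graph_closed_form(self):
        n = 7
        W = np.ones((n, n)) - np.eye(n)
        ev, _ = laplacian_spectrum(W)
        assert ev[0] == pytest.approx(0.0, abs=1e-10)
        assert np.allclose(ev[1:], n / (n - 1))

    def test_disconnected_cliques_zero_multiplicity_two(self):
        W = np.zeros((8, 8))
        W[:4, :4] = 1.0
        W[4:, 4:] = 1.0
        ev, _ = laplacian_spectrum(W)
        assert np.sum(ev < 1e-10) == 2

    def test_eigenvalue_range(self):
        rng = np.random.default_rng(2)
        X = rng.normal(10, 3, (30, 40))
        g = build_graph(X)
        ev, _ = laplacian_spectrum(g)
        assert ev[0] == pytest.approx(0.0, abs=1e-8)
        assert ev.min() >= -1e-10 and ev.max() <= 2 + 1e-10

    def test_asymmetric_rejected(self):
        W = np.eye(3)
        W[0, 1] = 0.5
        with pytest.raises(ValueError, match="symmetric"):
            laplacian_spectrum(W)


class TestNcut:
    def test_disconnected_components_zero(self):
        W = np.zeros((6, 6))
        W[:3, :3] = 1.0
        W[3:, 3:] = 1.0
        labels = np.array([0, 0, 0, 1, 1, 1])
        assert ncut_value(W, labels) == 0.0

    def test_single_cluster_zero(self):
        W = np.ones((5, 5))
        assert ncut_value(W, np.zeros(5)) == 0.0

    def test_barbell_matches_enumeration(self):
        W = np.zeros((6, 6))
        for i, j in itertools.combinations(range(3), 2):
            W[i, j] = W[j, i] = 1.0
            W[i + 3, j + 3] = W[j + 3, i + 3] = 1.0
        W[2, 3] = W[3, 2] = 0.1
        np.fill_diagonal(W, 1.0)
        labels = np.array([0, 0, 0, 1, 1, 1])
        # independent hand computation: cut = 0.1 both ways
        deg = W.sum(axis=1)
        expected = 0.1 / deg[:3].sum() + 0.1 / deg[3:].sum()
        assert ncut_value(W, labels) == pytest.approx(expected, rel=1e-12)
        assert brute_min_ncut(W) == pytest.approx(expected, rel=1e-12)

    def test_empty_cluster_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            ncut_value(np.ones((3, 3)), np.array([0, 0, 0]), n_clusters=2)


class TestSpectralCluster:
    def test_two_cliques_recovered_optimally(self):
        W = np.full((10, 10), 0.01)
        W[:5, :5] = 1.0
        W[5:, 5:] = 1.0
        W[4, 5] = W[5, 4] = 0.1
        np.fill_diagonal(W, 1.0)
        labels = spectral_cluster(graph_from_weights(W), k=2, l=2, seed=0)
        assert len(set(labels[:5])) == 1 and len(set(labels[5:])) == 1
        assert labels[0] != labels[5]
        assert ncut_value(W, labels) == pytest.approx(brute_min_ncut(W))

    def test_random_graph_oracle_agreement(self):
        rng = np.random.default_rng(0)
        hits = 0
        for trial in range(30):
            n = int(rng.integers(5, 11))
            A = rng.uniform(0, 1, (n, n))
            W = (A + A.T) / 2
            np.fill_diagonal(W, 1.0)
            labels = spectral_cluster(graph_from_weights(W), k=2, seed=trial)
            hits += np.isclose(ncut_value(W, labels), brute_min_ncut(W),
                               rtol=1e-9)
        assert hits >= 28

    def test_wt_partition_matches_planted_regions(self, wt_series):
        from sklearn.metrics import adjusted_rand_score

        series, truth = wt_series
        emb = spectral_analysis(series, sigma=0.95, k=5, l=2, seed=1)
        ari = adjusted_rand_score(truth[emb.node_indices], emb.labels)
        assert ari >= 0.85

    def test_k_exceeding_nodes_rejected(self):
        W = np.eye(3) + 0.1
        with pytest.raises(ValueError, match="exceeds"):
            spectral_cluster(graph_from_weights(W), k=5, seed=0)


class TestScree:
    def test_obvious_gap(self):
        ev = np.array([0.0, 0.01, 0.02, 0.5, 0.52, 0.55, 0.6])
        assert scree_select_l(ev) == 2

    def test_no_gap_defaults_with_warning(self):
        # a flat plateau of eigenvalues offers no discernible gap
        ev = np.concatenate([[0.0], 0.5 + 0.01 * np.arange(12)])
        with pytest.warns(UserWarning, match="defaulting"):
            assert scree_select_l(ev) == 2

    @pytest.mark.filterwarnings("ignore::UserWarning")
    def test_wt_embedding_dimension_is_two(self, wt_series):
        # at sigma = 0.95 the dense kernel compresses the spectrum near 1;
        # whether through a detected gap or the documented fallback, the
        # embedding dimension resolves to 2
        series, _ = wt_series
        g = build_graph(series)
        ev, _ = laplacian_spectrum(g)
        assert scree_select_l(ev) == 2


class TestEmbeddingCoherence:
    def test_circle_rho_near_one(self):
        th = 2 * np.pi * np.arange(100) / 100
        pts = np.c_[np.cos(th), np.sin(th)]
        _, rho_mean, rho = embedding_coherence(pts)
        assert rho_mean >= 0.95
        assert rho.max() <= 1.0

    def test_uniform_disk_mean_two_thirds(self):
        rng = np.random.default_rng(42)
        r = np.sqrt(rng.uniform(0, 1, 2000))
        th = rng.uniform(0, 2 * np.pi, 2000)
        pts = np.c_[r * np.cos(th), r * np.sin(th)]
        _, rho_mean, _ = embedding_coherence(pts)
        assert rho_mean == pytest.approx(2 / 3, abs=0.05)

    def test_coincident_points_rejected(self):
        with pytest.raises(ValueError, match="diameter"):
            embedding_coherence(np.ones((5, 2)))


class TestCircularStats:
    def test_circular_mean_wraps(self):
        assert circular_mean(np.array([0.1, 2 * np.pi - 0.1])) == pytest.approx(
            0.0, abs=1e-12)

    def test_corr_exact_rotation_and_reflection(self):
        rng = np.random.default_rng(0)
        a = rng.uniform(0, 2 * np.pi, 500)
        assert circular_corr(a, np.mod(a + 1.0, 2 * np.pi)) == pytest.approx(1.0)
        assert circular_corr(a, np.mod(-a + 2.0, 2 * np.pi)) == pytest.approx(-1.0)

    def test_corr_independent_near_zero(self):
        rng = np.random.default_rng(1)
        a = rng.uniform(0, 2 * np.pi, 2000)
        b = rng.uniform(0, 2 * np.pi, 2000)
        assert abs(circular_corr(a, b)) < 0.1


class TestClockFace:
    def test_single_phase_movie_peak_sets_span_all_nodes(self):
        rng = np.random.default_rng(0)
        t = np.arange(200) * 0.5
        X = 50 + 30 * np.cos(2 * np.pi * t / 24) + rng.normal(0, 0.1, (12, 200))
        coords = np.column_stack([np.arange(12), np.zeros(12, int)])
        series = SeriesMatrix(X, coords, np.ones(12, bool), dt_hours=0.5)
        emb = spectral_analysis(series, k=2, l=2, seed=0)
        trace = clockface(emb, series)
        defined = trace.defined()
        assert defined.any()
        # every node peaks within a couple of frames of the shared phase
        peak_frames = trace.frame_times[trace.n_peak_nodes > 0] % 24
        assert np.all((peak_frames < 2.0) | (peak_frames > 22.0))

    def test_non_oscillating_tissue_empty_trace(self):
        rng = np.random.default_rng(3)
        X = np.cumsum(np.abs(rng.normal(1, 0.001, (8, 120))), axis=1)
        coords = np.column_stack([np.arange(8), np.zeros(8, int)])
        series = SeriesMatrix(X, coords, np.ones(8, bool), dt_hours=0.5)
        emb = spectral_analysis(series, k=2, l=2, seed=0)
        with pytest.warns(UserWarning, match="non-oscillating"):
            trace = clockface(emb, series)
        assert not trace.defined().any()
        summary = clockhand_summary(trace)
        assert np.isnan(summary["monotonicity"])


class TestInvariance:
    def test_permutation_consistency(self):
        rng = np.random.default_rng(4)
        X = rng.normal(10, 2, (15, 60))
        g1 = build_graph(X)
        perm = rng.permutation(15)
        g2 = build_graph(X[perm])
        assert np.allclose(g2.weights, g1.weights[np.ix_(perm, perm)])

    def test_constant_shift_leaves_graph_unchanged(self):
        rng = np.random.default_rng(5)
        X = rng.normal(10, 2, (10, 50))
        g1 = build_graph(X)
        g2 = build_graph(X + 123.4)
        assert np.allclose(g1.distance, g2.distance, atol=1e-12)
        assert np.allclose(g1.weights, g2.weights, atol=1e-12)

    def test_embedding_sign_fixed(self):
        rng = np.random.default_rng(6)
        X = rng.normal(10, 2, (12, 40))
        c1, _ = spectral_embedding(build_graph(X), l=2)
        c2, _ = spectral_embedding(build_graph(X), l=2)
        assert np.allclose(c1, c2)


class TestSpatialReadouts:
    def test_compact_vs_scattered(self):
        rng = np.random.default_rng(0)
        coords = np.array([(r, c) for r in range(10) for c in range(10)])
        compact = (coords[:, 0] >= 5).astype(int)
        scattered = rng.integers(0, 2, 100)
        assert spatial_coherence(compact, coords) < \
            spatial_coherence(scattered, coords)
        assert cluster_contiguity(compact, coords, (10, 10)) == 1.0
        assert cluster_contiguity(scattered, coords, (10, 10)) < 0.8
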