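"""Similarity-network spectral clustering, embedding, and clock faces.

Each in-mask superpixel is a node; the Pearson correlation r between two
brightness time series is turned into the distance

    d(u, v) = sqrt((1 - r(u, v)) / 2)        (d in [0, 1])

so perfectly correlated series sit at distance 0, uncorrelated ones at
sqrt(2)/2 and anticorrelated ones at 1.  A Gaussian kernel
W_ij = exp(-d_ij^2 / (2 sigma^2)) converts distances to edge weights; at
the default sigma = 0.95 even uncorrelated pairs retain substantial
weight, preserving the full richness of the correlation structure,
whereas sigma around 0.3 suppresses everything beyond r = 0.

Clustering solves the relaxed N-cut problem: the symmetric normalized
Laplacian L = I - D^(-1/2) W D^(-1/2) is diagonalised, nodes are mapped
by the first l eigenvectors past the trivial one (D^(-1/2)-scaled), and
the embedded points are partitioned by seeded k-means.  The 2-D
embedding acts as a 24-h clock face: the circular mean direction of the
nodes peaking at each frame traces the "clock hand", and the histogram
of center-distances (normalized by half the embedding diameter)
measures how ring-like — i.e. how spatiotemporally coherent — the
tissue is.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import linalg, ndimage
from sklearn.base import BaseEstimator, ClusterMixin
from sklearn.cluster import KMeans
from sklearn.utils import check_array

from .io import SeriesMatrix
from .preprocess import batch_peaks

__all__ = [
    "correlation_distance",
    "correlation_distance_matrix",
    "build_graph",
    "SimilarityGraph",
    "laplacian_spectrum",
    "spectral_embedding",
    "SpectralClockMap",
    "spectral_cluster",
    "spectral_analysis",
    "ncut_value",
    "scree_select_l",
    "EmbeddingResult",
    "ClockFaceTrace",
    "clockface",
    "clockhand_summary",
    "embedding_coherence",
    "circular_mean",
    "circular_corr",
    "spatial_coherence",
    "cluster_contiguity",
]


# ---------------------------------------------------------------------------
# Distances and the similarity graph
# ---------------------------------------------------------------------------

def correlation_distance(u: np.ndarray, v: np.ndarray) -> float:
    """sqrt((1 - pearson(u, v)) / 2); 0 at r=1, sqrt(2)/2 at r=0, 1 at r=-1."""
    u = np.asarray(u, dtype=float)
    v = np.asarray(v, dtype=float)
    su, sv = u.std(), v.std()
    if su == 0 or sv == 0:
        raise ValueError("correlation distance undefined for constant series")
    r = float(np.corrcoef(u, v)[0, 1])
    return float(np.sqrt(max(1.0 - r, 0.0) / 2.0))


def correlation_distance_matrix(X: np.ndarray) -> np.ndarray:
    """Pairwise correlation distances of the rows of X."""
    X = np.asarray(X, dtype=float)
    if np.any(X.std(axis=1) == 0):
        raise ValueError("constant rows present; remove degenerate series")
    r = np.corrcoef(X)
    np.clip(r, -1.0, 1.0, out=r)
    d = np.sqrt((1.0 - r) / 2.0)
    np.fill_diagonal(d, 0.0)
    return d


@dataclass
class SimilarityGraph:
    """Dense correlation-similarity network over valid superpixels."""

    nodes: np.ndarray          # indices into the originating SeriesMatrix
    distance: np.ndarray       # pairwise d in [0, 1]
    weights: np.ndarray        # W_ij = exp(-d^2 / (2 sigma^2)), W_ii = 1
    sigma: float

    @property
    def n_nodes(self) -> int:
        return self.nodes.size


def build_graph(series, sigma: float = 0.95) -> SimilarityGraph:
    """Dense similarity graph from a SeriesMatrix or raw series array.

    Constant (zero-variance) in-mask series have no defined correlation
    and are excluded from the node set with a warning.
    """
    if sigma <= 0:
        raise ValueError("sigma must be positive")
    if isinstance(series, SeriesMatrix):
        variances = series.series.std(axis=1)
        valid = series.in_mask & (variances > 0)
        n_dropped = int((series.in_mask & (variances == 0)).sum())
        if n_dropped:
            warnings.warn(f"{n_dropped} constant in-mask series excluded "
                          "from the similarity graph")
        nodes = np.flatnonzero(valid)
        X = series.series[valid]
    else:
        X = np.atleast_2d(np.asarray(series, dtype=float))
        nodes = np.arange(X.shape[0])
    if X.shape[0] < 2:
        raise ValueError("need at least 2 valid nodes")
    d = correlation_distance_matrix(X)
    W = np.exp(-(d ** 2) / (2.0 * sigma ** 2))
    return SimilarityGraph(nodes=nodes, distance=d, weights=W, sigma=sigma)


# ---------------------------------------------------------------------------
# Laplacian, embedding, N-cut
# ---------------------------------------------------------------------------

def laplacian_spectrum(W: np.ndarray | SimilarityGraph
                       ) -> tuple[np.ndarray, np.ndarray]:
    """Eigenpairs of the symmetric normalized Laplacian, ascending.

    L = I - D^(-1/2) W D^(-1/2), the relaxation of the N-cut objective.
    The smallest eigenvalue is 0 (within 1e-8) and all eigenvalues lie
    in [0, 2].
    """
    if isinstance(W, SimilarityGraph):
        W = W.weights
    W = np.asarray(W, dtype=float)
    if not np.allclose(W, W.T):
        raise ValueError("weight matrix must be symmetric")
    deg = W.sum(axis=1)
    if np.any(deg <= 0):
        raise ValueError("every node needs positive degree")
    inv_sqrt = 1.0 / np.sqrt(deg)
    L = np.eye(W.shape[0]) - inv_sqrt[:, None] * W * inv_sqrt[None, :]
    L = (L + L.T) / 2.0
    eigenvalues, eigenvectors = linalg.eigh(L)
    return eigenvalues, eigenvectors


def spectral_embedding(W: np.ndarray | SimilarityGraph, l: int = 2
                       ) -> tuple[np.ndarray, np.ndarray]:
    """Coordinates from the first l nontrivial Laplacian eigenvectors.

    Eigenvectors are D^(-1/2)-scaled (undoing the symmetrization, which
    makes the trivial eigenvector constant) and the trivial one is
    dropped.  Returns ``(coordinates, eigenvalues)``.
    """
    if isinstance(W, SimilarityGraph):
        W = W.weights
    eigenvalues, eigenvectors = laplacian_spectrum(W)
    deg = np.asarray(W, dtype=float).sum(axis=1)
    scaled = eigenvectors / np.sqrt(deg)[:, None]
    coords = scaled[:, 1:1 + l]
    # fix an arbitrary sign per eigenvector for reproducibility
    for j in range(coords.shape[1]):
        col = coords[:, j]
        pivot = np.argmax(np.abs(col))
        if col[pivot] < 0:
            coords[:, j] = -col
    return coords, eigenvalues


def ncut_value(W: np.ndarray | SimilarityGraph, labels: np.ndarray,
               n_clusters: int | None = None) -> float:
    """Normalized-cut objective: sum over clusters of cut(C)/vol(C).

    When ``n_clusters`` is given, every id in range(n_clusters) must be
    populated; an empty cluster is rejected (the objective is undefined
    for it).
    """
    if isinstance(W, SimilarityGraph):
        W = W.weights
    W = np.asarray(W, dtype=float)
    labels = np.asarray(labels)
    ids = np.unique(labels) if n_clusters is None else np.arange(n_clusters)
    total = 0.0
    deg = W.sum(axis=1)
    for c in ids:
        members = labels == c
        if not members.any():
            raise ValueError(f"cluster {c} is empty: N-cut undefined")
        vol = deg[members].sum()
        cut = W[np.ix_(members, ~members)].sum()
        total += cut / vol if vol > 0 else 0.0
    return float(total)


def scree_select_l(eigenvalues: np.ndarray, zero_tol: float = 1e-8,
                   min_gap_ratio: float = 1.5, default: int = 2) -> int:
    """Embedding dimension from the scree of nonzero eigenvalues.

    l is the number of nonzero eigenvalues preceding the largest
    relative gap among the first min(10, n/2) of them.  Without a clear
    gap (largest ratio < ``min_gap_ratio``) the default of 2 is returned
    with a warning — two dimensions are also what the clock-face readout
    requires.
    """
    ev = np.asarray(eigenvalues, dtype=float)
    nonzero = ev[ev > zero_tol]
    if nonzero.size < 4:
        raise ValueError("need at least 4 nonzero eigenvalues")
    m = int(min(10, max(2, ev.size // 2), nonzero.size))
    head = nonzero[:m]
    ratios = head[1:] / head[:-1]
    if ratios.max() < min_gap_ratio:
        warnings.warn("no discernible eigenvalue gap; defaulting to l = "
                      f"{default}")
        return default
    return int(np.argmax(ratios) + 1)


# ---------------------------------------------------------------------------
# The estimator
# ---------------------------------------------------------------------------

class SpectralClockMap(ClusterMixin, BaseEstimator):
    """Relaxed-N-cut spectral clustering with a 2-D phase embedding.

    Parameters
    ----------
    n_clusters : int
        Number of clusters k (5 by default).
    n_components : int
        Embedding dimension l (2 by default: the clock face).
    sigma : float
        Gaussian kernel scale on the correlation distance (0.95 keeps
        weight on weakly and anti-correlated pairs).
    random_state : int or None
        Seeds the k-means discretization.

    Attributes
    ----------
    labels_ : cluster id per sample.
    embedding_ : (n, n_components) spectral coordinates.
    eigenvalues_ : ascending normalized-Laplacian spectrum.
    affinity_ : the kernel matrix W.
    distance_ : the correlation-distance matrix.
    """

    def __init__(self, n_clusters: int = 5, n_components: int = 2,
                 sigma: float = 0.95, random_state=None, n_init: int = 10):
        self.n_clusters = n_clusters
        self.n_components = n_components
        self.sigma = sigma
        self.random_state = random_state
        self.n_init = n_init

    def fit(self, X, y=None):
        """Build the graph from rows of X, embed, and partition."""
        X = check_array(X, dtype=float)
        graph = build_graph(X, sigma=self.sigma)
        self._fit_graph(graph)
        return self

    def _fit_graph(self, graph: SimilarityGraph):
        n = graph.n_nodes
        k = self.n_clusters
        if k > n:
            raise ValueError(f"n_clusters={k} exceeds n_nodes={n}")
        if k < 2:
            raise ValueError("n_clusters must be >= 2")
        coords, eigenvalues = spectral_embedding(graph, l=self.n_components)
        km = KMeans(n_clusters=k, n_init=self.n_init,
                    random_state=self.random_state)
        labels = km.fit_predict(coords)
        if k == 2:
            labels = self._refine_bipartition(graph.weights, coords, labels)
        self.graph_ = graph
        self.affinity_ = graph.weights
        self.distance_ = graph.distance
        self.embedding_ = coords
        self.eigenvalues_ = eigenvalues
        self.labels_ = labels
        return self

    @staticmethod
    def _refine_bipartition(W, coords, km_labels):
        """Discretize a 2-way relaxation: best of k-means and threshold
        sweeps along each embedding coordinate, then greedy single-node
        moves until the N-cut stops improving."""
        candidates = []
        if len(np.unique(km_labels)) == 2:
            candidates.append(km_labels)
        for j in range(coords.shape[1]):
            order = np.argsort(coords[:, j], kind="stable")
            candidates.append(_best_sweep_cut(W, order))
        scores = [ncut_value(W, lab) for lab in candidates]
        best = candidates[int(np.argmin(scores))]
        return _local_search_bipartition(W, best)

    def fit_predict(self, X, y=None):
        return self.fit(X).labels_


def _best_sweep_cut(W: np.ndarray, order: np.ndarray) -> np.ndarray:
    """Best-N-cut threshold bipartition along a node ordering.

    Nodes cross from side B to side A one at a time in the given order;
    cut weight and volumes are updated incrementally, so the whole sweep
    costs O(n^2).
    """
    n = order.size
    d = W.sum(axis=1)
    total = d.sum()
    Wx = np.zeros(n)        # (W @ indicator of A)_i
    vol_a = 0.0
    cut = 0.0
    best_score, best_cut_pos = np.inf, 1
    for pos, i in enumerate(order[:-1]):
        # node i joins A: edges to current A leave the cut, the rest join
        cut += d[i] - 2.0 * Wx[i] - W[i, i]
        vol_a += d[i]
        Wx += W[:, i]
        vol_b = total - vol_a
        if vol_a > 0 and vol_b > 0:
            score = cut / vol_a + cut / vol_b
            if score < best_score:
                best_score, best_cut_pos = score, pos + 1
    labels = np.ones(n, dtype=int)
    labels[order[:best_cut_pos]] = 0
    return labels


def _local_search_bipartition(W: np.ndarray, labels: np.ndarray,
                              max_passes: int = 50) -> np.ndarray:
    """Greedy N-cut descent by single-node moves between the two sides.

    Move deltas are evaluated in O(n) via running cut/volume updates;
    the objective strictly decreases at every accepted move, so the
    search terminates.
    """
    labels = np.asarray(labels, dtype=int).copy()
    n = labels.size
    d = W.sum(axis=1)
    x = labels == 0
    Wx = W @ x
    vol_a = d[x].sum()
    vol_b = d.sum() - vol_a
    cut = vol_a - Wx[x].sum()
    current = cut / vol_a + cut / vol_b if vol_a > 0 and vol_b > 0 else np.inf

    for _ in range(max_passes):
        # candidate cut/volumes after moving each node, vectorized;
        # (W @ (1-x))_i = d_i - Wx_i, so both directions share one form
        in_a = x
        Wy = d - Wx
        new_cut = np.where(
            in_a,
            cut + 2 * Wx - d - np.diag(W),   # A -> B
            cut + 2 * Wy - d - np.diag(W),   # B -> A
        )
        new_vol_a = np.where(in_a, vol_a - d, vol_a + d)
        new_vol_b = np.where(in_a, vol_b + d, vol_b - d)
        n_a = int(in_a.sum())
        # a move may not empty either side
        feasible = np.where(in_a, n_a > 1, n - n_a > 1)
        with np.errstate(divide="ignore", invalid="ignore"):
            scores = np.where(
                feasible & (new_vol_a > 0) & (new_vol_b > 0),
                new_cut / new_vol_a + new_cut / new_vol_b,
                np.inf,
            )
        i = int(np.argmin(scores))
        if scores[i] >= current - 1e-12:
            break
        # apply the move
        if x[i]:
            x[i] = False
            Wx -= W[:, i]
            vol_a -= d[i]
            vol_b += d[i]
        else:
            x[i] = True
            Wx += W[:, i]
            vol_a += d[i]
            vol_b -= d[i]
        cut = vol_a - Wx[x].sum()
        current = scores[i]
    out = np.ones(n, dtype=int)
    out[x] = 0
    return out


def spectral_cluster(graph: SimilarityGraph, k: int = 5, l: int = 2,
                     seed: int = 0) -> np.ndarray:
    """Partition a similarity graph by the relaxed N-cut (see estimator)."""
    est = SpectralClockMap(n_clusters=k, n_components=l, random_state=seed)
    est._fit_graph(graph)
    return est.labels_


# ---------------------------------------------------------------------------
# Clock face and coherence readouts
# ---------------------------------------------------------------------------

@dataclass
class EmbeddingResult:
    """Spectral embedding plus per-node labels and coherence statistics."""

    node_indices: np.ndarray   # indices into the originating SeriesMatrix
    coordinates: np.ndarray    # n x l
    eigenvalues: np.ndarray
    labels: np.ndarray         # spectral cluster id per node
    center: np.ndarray
    rho: np.ndarray            # normalized center distances, clipped to [0,1]
    rho_mean: float
    rho_histogram: np.ndarray  # 20 bins on [0, 1]


@dataclass
class ClockFaceTrace:
    """Per-frame clock-hand direction of the peaking superpixels."""

    frame_times: np.ndarray
    theta: np.ndarray          # radians in [0, 2pi); NaN where no node peaks
    n_peak_nodes: np.ndarray
    peak_sets: list
    node_angles: np.ndarray | None = None  # embedding angle per node

    def defined(self) -> np.ndarray:
        return ~np.isnan(self.theta)

    def peak_events(self) -> tuple[np.ndarray, np.ndarray]:
        """(node_angle, peak_time_hours) for every (node, peak) event."""
        if self.node_angles is None:
            raise ValueError("trace carries no node angles")
        angles, times = [], []
        for t, nodes in zip(self.frame_times, self.peak_sets):
            angles.extend(self.node_angles[nodes])
            times.extend([t] * len(nodes))
        return np.asarray(angles), np.asarray(times)


def circular_mean(angles: np.ndarray) -> float:
    """Mean direction of a set of angles, in [0, 2pi)."""
    angles = np.asarray(angles, dtype=float)
    return float(np.mod(
        np.arctan2(np.sin(angles).mean(), np.cos(angles).mean()), 2 * np.pi
    ))


def circular_corr(alpha: np.ndarray, beta: np.ndarray) -> float:
    """Fisher-Lee circular-circular correlation.

    rho = sum_{i<j} sin(a_i - a_j) sin(b_i - b_j) normalized by the
    corresponding root sums of squares.  Rotation- and
    reflection-equivariant, and — unlike mean-deviation estimators — well
    defined when the marginals are nearly uniform on the circle (no
    circular mean enters).  Evaluated in O(n) via product-to-sum
    identities.
    """
    a = np.asarray(alpha, dtype=float)
    b = np.asarray(beta, dtype=float)
    if a.size != b.size or a.size < 2:
        raise ValueError("need two equal-length angle arrays")
    # sum_{ij} sin(ai-aj) sin(bi-bj) = 2 (a1*a2 - a3*a4)
    a1 = (np.cos(a) * np.cos(b)).sum()
    a2 = (np.sin(a) * np.sin(b)).sum()
    a3 = (np.cos(a) * np.sin(b)).sum()
    a4 = (np.sin(a) * np.cos(b)).sum()
    num = 2.0 * (a1 * a2 - a3 * a4)

    def pair_sin_sq(x: np.ndarray) -> float:
        # sum_{ij} sin^2(xi - xj) = (n^2 - |sum exp(2i x)|^2) / 2
        n = x.size
        return (n ** 2 - np.cos(2 * x).sum() ** 2
                - np.sin(2 * x).sum() ** 2) / 2.0

    denom = np.sqrt(pair_sin_sq(a) * pair_sin_sq(b))
    if denom == 0:
        return 0.0
    return float(num / denom)


def embedding_coherence(coordinates: np.ndarray, n_bins: int = 20
                        ) -> tuple[np.ndarray, float, np.ndarray]:
    """Histogram and mean of normalized center distances.

    rho_i = |x_i - center| / (diameter / 2) with the center of mass as
    center and the maximum pairwise distance as diameter; values are
    clipped at 1 (the center of mass of an asymmetric cloud can sit
    slightly more than half a diameter from its farthest point).  A
    ring-like embedding concentrates rho near 1; a filled disk spreads
    it (uniform disk: mean 2/3).

    Returns ``(histogram, rho_mean, rho)``.
    """
    X = np.asarray(coordinates, dtype=float)
    if X.shape[0] < 2:
        raise ValueError("need at least 2 embedded points")
    center = X.mean(axis=0)
    diffs = X[:, None, :] - X[None, :, :]
    diameter = np.sqrt((diffs ** 2).sum(axis=2)).max()
    if diameter == 0:
        raise ValueError("all embedded points coincide (zero diameter)")
    rho = np.linalg.norm(X - center, axis=1) / (diameter / 2.0)
    rho = np.clip(rho, 0.0, 1.0)
    hist, _ = np.histogram(rho, bins=n_bins, range=(0.0, 1.0))
    return hist, float(rho.mean()), rho


def spectral_analysis(series: SeriesMatrix, sigma: float = 0.95,
                      k: int = 5, l: int = 2, seed: int = 0
                      ) -> EmbeddingResult:
    """Full graph -> embedding -> clusters -> coherence pass."""
    graph = build_graph(series, sigma=sigma)
    est = SpectralClockMap(n_clusters=k, n_components=l, random_state=seed)
    est._fit_graph(graph)
    hist, rho_mean, rho = embedding_coherence(est.embedding_)
    return EmbeddingResult(
        node_indices=graph.nodes,
        coordinates=est.embedding_,
        eigenvalues=est.eigenvalues_,
        labels=est.labels_,
        center=est.embedding_.mean(axis=0),
        rho=rho,
        rho_mean=rho_mean,
        rho_histogram=hist,
    )


def clockface(embedding: EmbeddingResult, series: SeriesMatrix,
              dt_hours: float | None = None,
              window_hours: float = 15.0) -> ClockFaceTrace:
    """Clock-hand direction of the peaking nodes, frame by frame.

    A node belongs to frame t's peak set when its own series has a local
    maximum (15-h moving window) at t.  The hand angle is the circular
    mean of the peak-set nodes' atan2 angles around the embedding's
    center of mass; frames with an empty peak set get NaN (the hand is
    undefined, as in non-oscillating tissue).
    """
    if embedding.coordinates.shape[1] != 2:
        raise ValueError("clock face requires a 2-D embedding")
    dt = series.dt_hours if dt_hours is None else dt_hours
    T = series.n_frames
    center = embedding.center
    rel = embedding.coordinates - center
    node_angles = np.mod(np.arctan2(rel[:, 1], rel[:, 0]), 2 * np.pi)

    peak_mask = batch_peaks(series.series[embedding.node_indices], dt,
                            window_hours)
    peak_sets = [np.flatnonzero(peak_mask[:, t]) for t in range(T)]

    theta = np.full(T, np.nan)
    counts = np.zeros(T, dtype=int)
    for t in range(T):
        if peak_sets[t].size:
            theta[t] = circular_mean(node_angles[peak_sets[t]])
            counts[t] = peak_sets[t].size
    if counts.sum() == 0:
        warnings.warn("no peaking superpixels at any frame: clock hand "
                      "undefined (non-oscillating tissue)")
    return ClockFaceTrace(
        frame_times=np.arange(T) * dt,
        theta=theta,
        n_peak_nodes=counts,
        peak_sets=[np.asarray(s, dtype=int) for s in peak_sets],
        node_angles=node_angles,
    )


def clockhand_summary(trace: ClockFaceTrace,
                      period_hours: float = 24.0) -> dict:
    """Monotonicity and rotation statistics of the clock hand.

    Returns a dict with:

    ``monotonicity``
        |net angular progression| / total absolute progression of the
        unwrapped hand angle over defined frames (1 = perfectly
        monotone, near 0 = back-and-forth bouncing).
    ``circ_corr``
        Circular-circular correlation magnitude between embedding angle
        and time of day mapped to the circle (2*pi*(t mod P)/P), paired
        at the (node, peak) event level so every peaking superpixel
        contributes one observation; falls back to the per-frame hand
        angle when the trace carries no node angles.
    ``turns_per_period``
        |least-squares slope of the unwrapped angle| * P / (2*pi): how
        many full turns the hand makes per circadian period.
    ``n_defined``
        Number of frames with a defined hand angle.
    """
    mask = trace.defined()
    t = trace.frame_times[mask]
    th = trace.theta[mask]
    if th.size < 3:
        return {"monotonicity": np.nan, "circ_corr": np.nan,
                "turns_per_period": np.nan, "n_defined": int(th.size)}
    unwrapped = np.unwrap(th)
    steps = np.diff(unwrapped)
    total = np.abs(steps).sum()
    monotonicity = float(np.abs(steps.sum()) / total) if total > 0 else 1.0
    if trace.node_angles is not None:
        ev_angle, ev_time = trace.peak_events()
        ev_day = 2 * np.pi * np.mod(ev_time, period_hours) / period_hours
        corr = abs(circular_corr(ev_angle, ev_day))
    else:
        day_angle = 2 * np.pi * np.mod(t, period_hours) / period_hours
        corr = abs(circular_corr(th, day_angle))
    slope = np.polyfit(t, unwrapped, 1)[0]
    turns = float(abs(slope) * period_hours / (2 * np.pi))
    return {"monotonicity": monotonicity, "circ_corr": corr,
            "turns_per_period": turns, "n_defined": int(th.size)}


# ---------------------------------------------------------------------------
# Spatial readouts of a partition
# ---------------------------------------------------------------------------

def spatial_coherence(labels: np.ndarray, coords: np.ndarray) -> float:
    """Within-cluster grid-distance ratio; < 1 means spatially compact.

    Mean over clusters (weighted by size) of the mean pairwise grid
    distance within the cluster, divided by the mean pairwise distance
    over all labeled nodes.  Contiguous clusters occupying ~1/k of the
    tissue give values well below 1; spatially scrambled clusters give
    values near 1.
    """
    labels = np.asarray(labels)
    coords = np.asarray(coords, dtype=float)
    valid = labels >= 0
    labels, coords = labels[valid], coords[valid]

    def mean_pairwise(P: np.ndarray) -> float:
        if P.shape[0] < 2:
            return 0.0
        diffs = P[:, None, :] - P[None, :, :]
        d = np.sqrt((diffs ** 2).sum(axis=2))
        n = P.shape[0]
        return float(d.sum() / (n * (n - 1)))

    overall = mean_pairwise(coords)
    if overall == 0:
        raise ValueError("degenerate coordinates")
    num, denom = 0.0, 0
    for c in np.unique(labels):
        members = coords[labels == c]
        num += mean_pairwise(members) * members.shape[0]
        denom += members.shape[0]
    return (num / denom) / overall


def cluster_contiguity(labels: np.ndarray, coords: np.ndarray,
                       grid_shape: tuple[int, int]) -> float:
    """Mean fraction of each cluster lying in its largest 4-connected patch.

    1.0 means every cluster is a single contiguous region of the grid;
    spatially scrambled partitions (many isolated superpixels per
    cluster) score near 0.  Averaged over clusters, weighted by size.
    """
    labels = np.asarray(labels)
    coords = np.asarray(coords, dtype=int)
    ids = [c for c in np.unique(labels) if c >= 0]
    if not ids:
        return np.nan
    frac_sum, total = 0.0, 0
    for c in ids:
        img = np.zeros(grid_shape, dtype=bool)
        pts = coords[labels == c]
        img[pts[:, 0], pts[:, 1]] = True
        comp, n_comp = ndimage.label(img)
        sizes = np.bincount(comp.ravel())[1:]
        frac_sum += sizes.max() / sizes.sum() * pts.shape[0]
        total += pts.shape[0]
    return float(frac_sum / total)
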