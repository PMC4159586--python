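"""k-medoids clustering of brightness time series under cosine distance.

Cosine distance D(u, v) = 1 - u.v/(|u||v|) is invariant under positive
rescaling of either series, so differences in basal brightness have no
effect on the partition — only the shape of the time series matters.
The number of clusters is selected with the gap statistic (within-cluster
dispersion compared against uniform reference data), clusters are
summarised by their mean series and ranked by amplitude (max - min), and
a windowed re-clustering check quantifies the stability of the partition
over time.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from sklearn.base import BaseEstimator, ClusterMixin
from sklearn.metrics import adjusted_rand_score
from sklearn.utils import check_array, check_random_state

from .io import SeriesMatrix

__all__ = [
    "cosine_distance",
    "cosine_distance_matrix",
    "KMedoids",
    "kmedoids",
    "gap_select_k",
    "rank_and_trim",
    "window_stability",
    "ClusterResult",
    "GapCurve",
]


def cosine_distance(u: np.ndarray, v: np.ndarray) -> float:
    """1 - cos(angle) between two series; in [0, 2].

    Rejects zero-norm inputs, for which the distance is undefined.
    """
    u = np.asarray(u, dtype=float)
    v = np.asarray(v, dtype=float)
    nu, nv = np.linalg.norm(u), np.linalg.norm(v)
    if nu == 0 or nv == 0:
        raise ValueError("cosine distance undefined for zero-norm series")
    return float(1.0 - (u @ v) / (nu * nv))


def cosine_distance_matrix(X: np.ndarray) -> np.ndarray:
    """Pairwise cosine distances of the rows of X (all rows nonzero)."""
    X = np.asarray(X, dtype=float)
    norms = np.linalg.norm(X, axis=1)
    if np.any(norms == 0):
        raise ValueError("zero-norm rows present; remove degenerate series")
    U = X / norms[:, None]
    D = 1.0 - U @ U.T
    np.clip(D, 0.0, 2.0, out=D)
    np.fill_diagonal(D, 0.0)
    return D


class KMedoids(ClusterMixin, BaseEstimator):
    """Alternating k-medoids under cosine distance.

    Parameters
    ----------
    n_clusters : int
        Number of clusters k.
    n_init : int
        Independent k-medoids++-style restarts; the run with the lowest
        total within-cluster distance is kept.
    max_iter : int
        Iteration cap for the assignment/update alternation.
    random_state : int, RandomState or None
        Seeds the initialization, making the fit deterministic.
    swap_max_n : int
        Below this sample count each restart is finished with a PAM-style
        swap phase (greedy medoid/non-medoid exchanges), which reliably
        reaches the global optimum on small instances; on large series
        matrices the alternating scheme alone is used for speed.

    Attributes
    ----------
    labels_ : ndarray of shape (n,)
        Cluster id per sample.
    medoid_indices_ : ndarray of shape (k,)
        Row indices of the representative series.
    cluster_centers_ : ndarray of shape (k, T)
        The medoid series themselves.
    inertia_ : float
        Total within-cluster cosine distance to the medoids.
    """

    def __init__(self, n_clusters: int = 5, n_init: int = 10,
                 max_iter: int = 100, random_state=None,
                 swap_max_n: int = 300):
        self.n_clusters = n_clusters
        self.n_init = n_init
        self.max_iter = max_iter
        self.random_state = random_state
        self.swap_max_n = swap_max_n

    # -- internals ---------------------------------------------------------

    @staticmethod
    def _init_medoids(D: np.ndarray, k: int, rng) -> np.ndarray:
        """k-medoids++ seeding: spread initial medoids by squared distance."""
        n = D.shape[0]
        medoids = [int(rng.integers(n))]
        for _ in range(1, k):
            closest = D[:, medoids].min(axis=1)
            weights = closest ** 2
            total = weights.sum()
            if total <= 0:
                # all remaining points coincide with a medoid
                choices = np.setdiff1d(np.arange(n), medoids)
                medoids.append(int(rng.choice(choices)))
                continue
            medoids.append(int(rng.choice(n, p=weights / total)))
        return np.asarray(medoids)

    @staticmethod
    def _run(D: np.ndarray, medoids: np.ndarray, max_iter: int):
        n, k = D.shape[0], medoids.size
        labels = np.argmin(D[:, medoids], axis=1)
        prev_cost = np.inf
        for _ in range(max_iter):
            # medoid update: member minimizing summed within-cluster distance
            for j in range(k):
                members = np.flatnonzero(labels == j)
                if members.size == 0:
                    # re-seed an empty cluster at the worst-assigned point
                    worst = np.argmax(D[np.arange(n), medoids[labels]])
                    medoids[j] = worst
                    labels[worst] = j
                    members = np.array([worst])
                sub = D[np.ix_(members, members)]
                medoids[j] = members[int(np.argmin(sub.sum(axis=0)))]
            new_labels = np.argmin(D[:, medoids], axis=1)
            cost = D[np.arange(n), medoids[new_labels]].sum()
            # the alternation never increases the objective
            assert cost <= prev_cost + 1e-9, "k-medoids objective increased"
            if np.array_equal(new_labels, labels) and cost == prev_cost:
                break
            labels = new_labels
            prev_cost = cost
        cost = D[np.arange(n), medoids[labels]].sum()
        return labels, medoids, cost

    @staticmethod
    def _swap_phase(D: np.ndarray, medoids: np.ndarray, max_sweeps: int = 20):
        """Greedy PAM swaps: exchange a medoid for a non-medoid whenever
        that lowers the total assignment cost; stop at a local optimum."""
        n, k = D.shape[0], medoids.size
        medoids = medoids.copy()
        cost = D[:, medoids].min(axis=1).sum()
        for _ in range(max_sweeps):
            improved = False
            for j in range(k):
                others = np.delete(medoids, j)
                d_rest = (D[:, others].min(axis=1) if others.size
                          else np.full(n, np.inf))
                # cost of every candidate replacement, vectorized
                cand_cost = np.minimum(d_rest[:, None], D).sum(axis=0)
                cand_cost[medoids] = np.inf  # keep medoids distinct
                best = int(np.argmin(cand_cost))
                if cand_cost[best] < cost - 1e-12:
                    medoids[j] = best
                    cost = cand_cost[best]
                    improved = True
            if not improved:
                break
        labels = np.argmin(D[:, medoids], axis=1)
        return labels, medoids, cost

    def _fit_precomputed(self, D: np.ndarray):
        n = D.shape[0]
        k = self.n_clusters
        if k < 1:
            raise ValueError("n_clusters must be >= 1")
        if k > n:
            raise ValueError(f"n_clusters={k} exceeds n_samples={n}")
        rng = np.random.default_rng(
            check_random_state(self.random_state).randint(2 ** 31)
        )
        best = None
        for _ in range(max(1, self.n_init)):
            medoids = self._init_medoids(D, k, rng)
            labels, medoids, cost = self._run(D, medoids.copy(), self.max_iter)
            if n <= self.swap_max_n:
                labels, medoids, cost = self._swap_phase(D, medoids)
            if best is None or cost < best[2]:
                best = (labels, medoids, cost)
        self.labels_, self.medoid_indices_, self.inertia_ = best
        return self

    # -- sklearn surface ---------------------------------------------------

    def fit(self, X, y=None):
        """Cluster the rows of X (n_series x n_frames)."""
        X = check_array(X, dtype=float)
        D = cosine_distance_matrix(X)
        self._fit_precomputed(D)
        self.cluster_centers_ = X[self.medoid_indices_]
        return self

    def fit_predict(self, X, y=None):
        return self.fit(X).labels_

    def predict(self, X):
        X = check_array(X, dtype=float)
        norms = np.linalg.norm(X, axis=1)
        if np.any(norms == 0):
            raise ValueError("zero-norm rows cannot be assigned")
        U = X / norms[:, None]
        C = self.cluster_centers_
        C = C / np.linalg.norm(C, axis=1)[:, None]
        return np.argmin(1.0 - U @ C.T, axis=1)


@dataclass
class ClusterResult:
    """A k-medoids partition of the in-mask superpixels.

    ``labels`` has one entry per superpixel of the originating
    SeriesMatrix; excluded superpixels (masked out, degenerate, or
    trimmed by amplitude rank) carry the label -1.
    """

    labels: np.ndarray
    medoid_indices: np.ndarray
    k: int
    mean_series: np.ndarray
    amplitude_rank: np.ndarray
    inertia: float = np.nan
    gap_curve: "GapCurve | None" = None

    def amplitudes(self) -> np.ndarray:
        """Peak-to-trough amplitude (max - min) of each cluster mean."""
        return self.mean_series.max(axis=1) - self.mean_series.min(axis=1)

    def label_map(self, grid_shape: tuple[int, int],
                  coords: np.ndarray) -> np.ndarray:
        """Cluster-id image (1-based; 0 = background/excluded)."""
        img = np.zeros(grid_shape, dtype=np.int32)
        valid = self.labels >= 0
        img[coords[valid, 0], coords[valid, 1]] = self.labels[valid] + 1
        return img


@dataclass
class GapCurve:
    """Gap statistic over candidate k, with the selection rule baked in."""

    candidate_k: np.ndarray
    gap: np.ndarray
    se: np.ndarray
    chosen_k: int
    reference_count: int

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame({
            "k": self.candidate_k, "gap": self.gap, "se": self.se,
        })


def _valid_rows(series: SeriesMatrix) -> np.ndarray:
    """In-mask rows with nonzero norm (cosine distance is defined)."""
    norms = np.linalg.norm(series.series, axis=1)
    valid = series.in_mask & (norms > 0)
    n_degenerate = int((series.in_mask & (norms == 0)).sum())
    if n_degenerate:
        warnings.warn(
            f"{n_degenerate} zero-norm in-mask series excluded from clustering"
        )
    return valid


def _result_from_labels(series: SeriesMatrix, valid: np.ndarray,
                        labels_valid: np.ndarray, medoids_valid: np.ndarray,
                        inertia: float) -> ClusterResult:
    k = int(labels_valid.max()) + 1
    labels = np.full(series.n_series, -1, dtype=int)
    labels[valid] = labels_valid
    valid_idx = np.flatnonzero(valid)
    mean_series = np.vstack([
        series.series[valid_idx[labels_valid == j]].mean(axis=0)
        for j in range(k)
    ])
    amplitude = mean_series.max(axis=1) - mean_series.min(axis=1)
    rank = np.argsort(-amplitude, kind="stable")
    return ClusterResult(
        labels=labels,
        medoid_indices=valid_idx[medoids_valid],
        k=k,
        mean_series=mean_series,
        amplitude_rank=rank,
        inertia=inertia,
    )


def kmedoids(series: SeriesMatrix, k: int, seed: int = 0,
             n_init: int = 10) -> ClusterResult:
    """Cluster the in-mask series of a SeriesMatrix into k groups."""
    valid = _valid_rows(series)
    X = series.series[valid]
    est = KMedoids(n_clusters=k, n_init=n_init, random_state=seed).fit(X)
    return _result_from_labels(series, valid, est.labels_,
                               est.medoid_indices_, est.inertia_)


def _log_wk(D: np.ndarray, labels: np.ndarray, k: int) -> float:
    """log of the pooled within-cluster dispersion W_k.

    W_k = sum over clusters of (sum of pairwise distances) / (2 * size),
    where the pairwise sum counts both orders of each pair.
    """
    total = 0.0
    for j in range(k):
        members = np.flatnonzero(labels == j)
        if members.size < 2:
            continue
        sub = D[np.ix_(members, members)]
        total += sub.sum() / (2.0 * members.size)
    return float(np.log(max(total, 1e-300)))


def gap_select_k(series: SeriesMatrix, k_max: int = 8, B: int = 50,
                 seed: int = 0, n_init: int = 10,
                 ref_n_init: int = 1) -> GapCurve:
    """Choose the number of clusters with the gap statistic.

    For each k in 1..k_max the log within-cluster cosine dispersion of
    the data is compared with that of ``B`` reference datasets drawn
    uniformly over each feature's observed range.  gap(k) is the mean
    reference log-dispersion minus the observed one, and the chosen k is
    the smallest k with gap(k) >= gap(k+1) - se(k+1).
    """
    if B < 10:
        raise ValueError("need at least 10 reference datasets")
    valid = _valid_rows(series)
    X = series.series[valid]
    n, T = X.shape
    if k_max < 2 or n < k_max:
        raise ValueError("need k_max >= 2 and at least k_max valid series")

    D = cosine_distance_matrix(X)
    ks = np.arange(1, k_max + 1)

    def dispersion_curve(Dm: np.ndarray, seed_: int, inits: int) -> np.ndarray:
        out = np.empty(ks.size)
        for i, k in enumerate(ks):
            if k == 1:
                labels = np.zeros(Dm.shape[0], dtype=int)
            else:
                est = KMedoids(n_clusters=int(k), n_init=inits,
                               random_state=seed_ + int(k))
                est._fit_precomputed(Dm)
                labels = est.labels_
            out[i] = _log_wk(Dm, labels, int(k))
        return out

    log_w = dispersion_curve(D, seed, n_init)

    rng = np.random.default_rng(seed)
    lo = X.min(axis=0)
    hi = X.max(axis=0)
    log_w_ref = np.empty((B, ks.size))
    for b in range(B):
        ref = rng.uniform(lo, hi, size=(n, T))
        Dref = cosine_distance_matrix(ref)
        log_w_ref[b] = dispersion_curve(Dref, seed + 1000 + b, ref_n_init)

    gap = log_w_ref.mean(axis=0) - log_w
    se = log_w_ref.std(axis=0, ddof=0) * np.sqrt(1.0 + 1.0 / B)

    chosen = int(ks[-1])
    if np.ptp(log_w) < 1e-12 and np.isclose(np.exp(log_w[0]), 0.0):
        chosen = 1
    else:
        for i in range(ks.size - 1):
            if gap[i] >= gap[i + 1] - se[i + 1]:
                chosen = int(ks[i])
                break
    return GapCurve(ks, gap, se, chosen, B)


def rank_and_trim(result: ClusterResult, top_n: int = 6) -> ClusterResult:
    """Keep only the ``top_n`` highest-amplitude clusters.

    Light scatters broadly in neural tissue; low-amplitude clusters are
    dominated by scattered signal, so analysis is restricted to the five
    or six highest-amplitude clusters.  Retained clusters are relabeled
    0..top_n-1 in descending amplitude order (ties broken by original
    cluster id); everything else becomes background (-1).
    """
    if result.k < top_n:
        warnings.warn(
            f"only {result.k} clusters available; top_n={top_n} keeps all"
        )
        top_n = result.k
    keep = result.amplitude_rank[:top_n]
    relabel = {int(old): new for new, old in enumerate(keep)}
    labels = np.array([relabel.get(int(l), -1) for l in result.labels])
    return ClusterResult(
        labels=labels,
        medoid_indices=result.medoid_indices[keep],
        k=top_n,
        mean_series=result.mean_series[keep],
        amplitude_rank=np.arange(top_n),
        inertia=result.inertia,
        gap_curve=result.gap_curve,
    )


def window_stability(series: SeriesMatrix, window_count: int, k: int,
                     seed: int = 0, n_init: int = 10) -> np.ndarray:
    """Pairwise ARI between clusterings of contiguous time windows.

    The time axis is split into ``window_count`` equal contiguous
    windows, each clustered independently at the same k; the adjusted
    Rand index (invariant to label permutation) quantifies agreement.
    """
    T = series.n_frames
    width = T // window_count
    if width < 2:
        raise ValueError("windows must span at least 2 frames")
    labelings = []
    for w in range(window_count):
        sub = SeriesMatrix(
            series.series[:, w * width:(w + 1) * width],
            series.coords, series.in_mask,
            dt_hours=series.dt_hours,
            superpixel_size_px=series.superpixel_size_px,
            grid_shape=series.grid_shape,
        )
        labelings.append(kmedoids(sub, k, seed=seed, n_init=n_init).labels)
    aris = []
    for i in range(window_count):
        for j in range(i + 1, window_count):
            both = (labelings[i] >= 0) & (labelings[j] >= 0)
            aris.append(adjusted_rand_score(
                labelings[i][both], labelings[j][both]
            ))
    return np.asarray(aris)
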