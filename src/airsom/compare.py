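"""Reference clusterers and projections used to benchmark the SOM.

A SOM day-typing is expected to produce partitions comparable to
conventional clustering: Lloyd's k-means (the closest relative — a SOM with
no neighborhood coupling is an online k-means) and Ward's minimum-variance
agglomeration. ``agreement`` scores two labelings after optimally matching
their class identities, and ``sammon_map`` provides the nonlinear
projection used to visualize distortions between class profiles.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.optimize import linear_sum_assignment
from scipy.spatial.distance import cdist

from .selection import classical_mds

__all__ = [
    "KMeansResult",
    "kmeans",
    "MergeTree",
    "ward_clustering",
    "sammon_map",
    "agreement",
]


@dataclass
class KMeansResult:
    labels: np.ndarray
    centroids: np.ndarray
    within_ss: float


def _lloyd(Z: np.ndarray, k: int, rng: np.random.Generator, max_iter: int = 300):
    n = Z.shape[0]
    centroids = Z[rng.choice(n, size=k, replace=False)].copy()
    labels = np.full(n, -1)
    for _ in range(max_iter):
        d2 = cdist(Z, centroids, metric="sqeuclidean")
        new_labels = np.argmin(d2, axis=1)
        # empty-cluster repair: reseed from the point farthest from its centroid
        for c in range(k):
            if not np.any(new_labels == c):
                far = int(np.argmax(d2[np.arange(n), new_labels]))
                centroids[c] = Z[far]
                new_labels[far] = c
        if np.array_equal(new_labels, labels):
            break
        labels = new_labels
        for c in range(k):
            centroids[c] = Z[labels == c].mean(axis=0)
    within = float(np.sum((Z - centroids[labels]) ** 2))
    return labels, centroids, within


def kmeans(
    Z: np.ndarray, k: int, n_restarts: int = 10, seed: int = 0
) -> KMeansResult:
    """Lloyd's k-means, best of ``n_restarts`` by within-cluster sum of squares.

    Initialization samples k distinct data rows — the same policy the SOM
    uses — so SOM-vs-k-means comparisons are like for like.
    """
    Z = np.asarray(Z, dtype=float)
    if Z.shape[0] < k:
        raise ValueError(f"more clusters ({k}) than observations ({Z.shape[0]})")
    if n_restarts < 1:
        raise ValueError("n_restarts must be >= 1")
    best = None
    for r in range(n_restarts):
        ss = np.random.SeedSequence(entropy=seed, spawn_key=(r,))
        rng = np.random.default_rng(ss)
        labels, centroids, within = _lloyd(Z, k, rng)
        if best is None or within < best.within_ss:
            best = KMeansResult(labels=labels, centroids=centroids, within_ss=within)
    return best


@dataclass
class MergeTree:
    """An agglomeration history: n-1 merges over n leaves.

    ``linkage`` is in scipy's standard format (cluster-a, cluster-b, height,
    size). Heights follow the Ward.D2 convention (merge costs on the
    distance scale) and are non-decreasing.
    """

    linkage: np.ndarray
    leaf_labels: list

    @property
    def n_leaves(self) -> int:
        return self.linkage.shape[0] + 1

    @property
    def heights(self) -> np.ndarray:
        return self.linkage[:, 2]

    def cut(self, k: int) -> np.ndarray:
        """Labels (1..k) from cutting the tree into k clusters."""
        return fcluster(self.linkage, t=k, criterion="maxclust")


def ward_clustering(Z: np.ndarray, k: int, leaf_labels=None):
    """Ward's minimum-variance agglomerative clustering cut at k clusters.

    Uses the Lance–Williams recurrence on Euclidean distances with Ward's
    objective (the Ward.D2 convention, where merge heights live on the
    distance scale; note R's hclust historically shipped a "ward.D" variant
    that skips squaring — that is not what is computed here).
    """
    Z = np.asarray(Z, dtype=float)
    n = Z.shape[0]
    if n < k:
        raise ValueError(f"more clusters ({k}) than observations ({n})")
    link = linkage(Z, method="ward")
    tree = MergeTree(
        linkage=link,
        leaf_labels=list(leaf_labels) if leaf_labels is not None else list(range(n)),
    )
    return tree.cut(k), tree


def _sammon_stress(D: np.ndarray, Y: np.ndarray, iu) -> float:
    d = cdist(Y, Y)[iu]
    delta = D[iu]
    return float(np.sum((delta - d) ** 2 / delta) / np.sum(delta))


def sammon_map(
    D: np.ndarray,
    dims: int = 2,
    max_iter: int = 500,
    tol: float = 1e-9,
    seed: int = 0,
    jitter: float = 0.0,
):
    """Sammon's nonlinear projection of a distance matrix.

    Minimizes the Sammon stress
    E = (1/sum delta_ij) * sum (delta_ij - d_ij)^2 / delta_ij
    (sums over i<j) by gradient descent with step halving, starting from the
    classical MDS embedding. The 1/delta weighting emphasizes small
    distances, so local neighborhoods are preserved at the expense of large
    ones. Stress never increases across accepted iterations.

    Duplicate points (zero off-diagonal distances) are rejected unless
    ``jitter > 0``, in which case seeded uniform noise of that magnitude is
    added to the offending distances.
    """
    D = np.asarray(D, dtype=float).copy()
    n = D.shape[0]
    iu = np.triu_indices(n, k=1)
    if np.any(D[iu] <= 0):
        if jitter <= 0:
            raise ValueError(
                "duplicate points (zero off-diagonal distance); pass jitter > 0"
            )
        rng = np.random.default_rng(seed)
        bad = D[iu] <= 0
        vals = D[iu]
        vals[bad] = jitter * (0.5 + rng.random(bad.sum()))
        D[iu] = vals
        D.T[iu] = vals
    if n == 1:
        return np.zeros((1, dims)), 0.0

    Y = classical_mds(D, dims)
    if n == 2:  # 1-D line reproduces any single distance exactly
        return Y, _sammon_stress(D, Y, iu)
    c = np.sum(D[iu])
    stress = _sammon_stress(D, Y, iu)
    step = 0.3
    for _ in range(max_iter):
        d = cdist(Y, Y)
        np.fill_diagonal(d, 1.0)
        delta = D.copy()
        np.fill_diagonal(delta, 1.0)
        # gradient of E wrt Y
        w = (delta - d) / (delta * d)
        np.fill_diagonal(w, 0.0)
        grad = (-2.0 / c) * ((w.sum(axis=1))[:, None] * Y - w @ Y)
        gnorm = np.sqrt(np.sum(grad**2))
        if gnorm < tol:
            break
        improved = False
        for _ in range(30):
            Y_new = Y - step * grad
            s_new = _sammon_stress(D, Y_new, iu)
            if s_new < stress:
                improved = True
                break
            step /= 2
        if not improved:
            break
        Y, stress = Y_new, s_new
        step *= 1.5
        if gnorm * step < tol:
            break
    return Y, stress


def agreement(labels_a, labels_b, method: str = "optimal") -> float:
    """Percent of observations on which two labelings directly agree
    after one-to-one matching of their class identities.

    Builds the confusion matrix (padded square when class counts differ)
    and matches classes to maximize total matched observations — by the
    Hungarian algorithm (``method="optimal"``, default) or greedily picking
    the largest remaining cell (``method="greedy"``, for sensitivity).
    Returns 100 * matched / n; 100 iff the labelings are identical up to
    renaming.
    """
    a = np.asarray(labels_a)
    b = np.asarray(labels_b)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("labelings must be 1-D and the same length")
    if a.size == 0:
        raise ValueError("labelings are empty")
    ua, ia = np.unique(a, return_inverse=True)
    ub, ib = np.unique(b, return_inverse=True)
    m = max(ua.size, ub.size)
    C = np.zeros((m, m))
    np.add.at(C, (ia, ib), 1)
    if method == "optimal":
        r, cidx = linear_sum_assignment(-C)
        matched = C[r, cidx].sum()
    elif method == "greedy":
        work = C.copy()
        matched = 0.0
        for _ in range(m):
            i, j = np.unravel_index(np.argmax(work), work.shape)
            matched += work[i, j]
            work[i, :] = -1
            work[:, j] = -1
    else:
        raise ValueError("method must be 'optimal' or 'greedy'")
    return float(100.0 * matched / a.size)
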