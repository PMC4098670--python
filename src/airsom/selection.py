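"""Choosing the number of day types (map size).

Three complementary views are provided: a classical MDS embedding for
visual exploration of grouping structure, the Calinski–Harabasz variance
ratio as a cluster-count statistic, and an adjusted-R² scan measuring how
much of each raw pollutant's variance a labeling explains (one-way ANOVA on
class indicators). ``size_scan`` runs all of these for SOM solutions over a
range of k; the report surfaces the CH-maximal k and candidate elbows in
the pooled adjusted R², but deliberately does not decree a "right" k —
cluster-count selection on data without sharp group boundaries is a
judgment call and the statistics here are decision aids.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .data import IntegrityError, PollutantMatrix
from .som import SOMGrid, TrainingSchedule, train_with_restarts

__all__ = [
    "classical_mds",
    "ch_index",
    "adjusted_r2_scan",
    "R2Summary",
    "grid_shape_for_k",
    "expected_class_size",
    "size_scan",
    "SelectionReport",
]


def classical_mds(D: np.ndarray, dims: int = 2) -> np.ndarray:
    """Classical (Torgerson) multidimensional scaling.

    Double-centers the squared distance matrix, eigendecomposes, and returns
    the top ``dims`` principal coordinates (deterministic up to sign, with
    output dimensions in order of non-increasing variance). For distances
    that admit an exact Euclidean embedding in ``dims`` dimensions the
    pairwise distances are reproduced exactly.
    """
    D = np.asarray(D, dtype=float)
    if D.ndim != 2 or D.shape[0] != D.shape[1]:
        raise ValueError("D must be square")
    if not np.allclose(D, D.T, atol=1e-8):
        raise ValueError("D must be symmetric")
    n = D.shape[0]
    J = np.eye(n) - np.ones((n, n)) / n
    B = -0.5 * J @ (D**2) @ J
    B = (B + B.T) / 2
    eigval, eigvec = np.linalg.eigh(B)
    order = np.argsort(eigval)[::-1][:dims]
    lam = np.clip(eigval[order], 0.0, None)
    return eigvec[:, order] * np.sqrt(lam)


def _group_stats(Z: np.ndarray, labels: np.ndarray):
    classes, inverse, counts = np.unique(labels, return_inverse=True, return_counts=True)
    sums = np.zeros((classes.size, Z.shape[1]))
    np.add.at(sums, inverse, Z)
    means = sums / counts[:, None]
    return classes, inverse, counts, means


def ch_index(Z: np.ndarray, labels: np.ndarray) -> float:
    """Calinski–Harabasz variance-ratio index of a labeling.

    CH = (SS_B / (k-1)) / (SS_W / (n-k)) where SS_B is the between-class and
    SS_W the within-class sum of squared deviations. Larger is better.
    Perfect separation (SS_W = 0) returns ``inf``.
    """
    Z = np.asarray(Z, dtype=float)
    labels = np.asarray(labels)
    n = Z.shape[0]
    classes, inverse, counts, means = _group_stats(Z, labels)
    k = classes.size
    if k < 2:
        raise ValueError("CH index needs at least 2 realized classes")
    if k >= n:
        raise ValueError("CH index needs k < n (no all-singleton labelings)")
    grand = Z.mean(axis=0)
    ss_b = float(np.sum(counts[:, None] * (means - grand) ** 2))
    ss_w = float(np.sum((Z - means[inverse]) ** 2))
    if ss_w == 0:
        return math.inf
    return (ss_b / (k - 1)) / (ss_w / (n - k))


@dataclass(frozen=True)
class R2Summary:
    """Per-pollutant adjusted R² of a labeling plus pooled summaries."""

    by_pollutant: pd.Series
    mean: float
    min: float
    max: float


def adjusted_r2_scan(Z_raw, labels: np.ndarray) -> R2Summary:
    """Variance in each raw pollutant explained by a class labeling.

    Fits the one-way ANOVA model (predict each pollutant from class
    indicators, i.e. class means), giving R²_j = 1 - SSE_j/SST_j per
    pollutant, then applies the degrees-of-freedom correction
    adj R² = 1 - (1-R²)(n-1)/(n-k) with k the realized class count.
    """
    if isinstance(Z_raw, PollutantMatrix):
        values, names = Z_raw.values, Z_raw.columns
    else:
        values = np.asarray(Z_raw, dtype=float)
        names = [f"x{j}" for j in range(values.shape[1])]
    if np.isnan(values).any():
        raise IntegrityError("adjusted_r2_scan requires complete data")
    labels = np.asarray(labels)
    n = values.shape[0]
    classes, inverse, counts, means = _group_stats(values, labels)
    k = classes.size
    if k < 2:
        raise ValueError("need at least 2 realized classes")
    if k >= n:
        raise ValueError("degenerate dof: realized classes equal observations")
    sst = np.sum((values - values.mean(axis=0)) ** 2, axis=0)
    if np.any(sst == 0):
        j = int(np.flatnonzero(sst == 0)[0])
        raise IntegrityError(f"pollutant {names[j]!r} has zero variance")
    sse = np.sum((values - means[inverse]) ** 2, axis=0)
    r2 = 1 - sse / sst
    adj = 1 - (1 - r2) * (n - 1) / (n - k)
    series = pd.Series(adj, index=list(names), name="adjusted_r2")
    return R2Summary(
        by_pollutant=series,
        mean=float(series.mean()),
        min=float(series.min()),
        max=float(series.max()),
    )


def grid_shape_for_k(k: int) -> tuple[int, int]:
    """Most-square factor pair (X, Y) with X*Y = k and X >= Y; primes give (k, 1)."""
    if k < 1:
        raise ValueError("k must be >= 1")
    for y in range(int(math.isqrt(k)), 0, -1):
        if k % y == 0:
            return (k // y, y)
    raise AssertionError("unreachable")


def expected_class_size(n: int, k: int) -> int:
    """Expected per-class sample size (whole days) under a balanced k-way split."""
    if k < 1 or n < 1:
        raise ValueError("n and k must be positive")
    return n // k


@dataclass
class SelectionReport:
    """Per-k diagnostics from a map-size scan.

    ``table`` holds one row per k: grid shape, CH index (on the standardized
    training data), quantization error, and the pooled adjusted-R² summary
    on the raw pollutant scale. ``r2_by_pollutant`` keeps the full per-
    pollutant detail. ``chosen_k`` is left to the user; ``ch_best_k`` and
    ``r2_elbow_candidates`` flag the CH maximum and the k values whose
    pooled-R² gain over the previous k is above the median gain.
    """

    table: pd.DataFrame
    r2_by_pollutant: pd.DataFrame
    chosen_k: int | None = None

    @property
    def ch_best_k(self) -> int:
        return int(self.table.loc[self.table["ch"].idxmax(), "k"])

    @property
    def r2_elbow_candidates(self) -> list[int]:
        gains = self.table.set_index("k")["r2_mean"].diff().dropna()
        if gains.empty:
            return []
        return [int(k) for k, g in gains.items() if g > gains.median()]

    @property
    def r2_monotone_violations(self) -> int:
        """Count of k-steps where pooled adjusted R² decreased (sampling noise)."""
        gains = self.table["r2_mean"].diff().dropna()
        return int((gains < 0).sum())


def size_scan(
    Z_std: np.ndarray,
    Z_raw,
    k_min: int = 2,
    k_max: int = 30,
    schedule: TrainingSchedule | None = None,
    n_restarts: int = 10,
    seed: int = 0,
    topology: str = "rectangular",
) -> SelectionReport:
    """Train SOMs for each k in [k_min, k_max] and score each solution.

    Each k uses its most-square grid shape and an independent restart set
    (seeds derived from ``seed`` and k). CH is computed on the standardized
    training matrix, adjusted R² on the raw pollutant values.
    """
    Z_std = np.asarray(Z_std, dtype=float)
    n = Z_std.shape[0]
    if not (2 <= k_min <= k_max):
        raise ValueError("need 2 <= k_min <= k_max")
    if k_max >= n:
        raise ValueError("k_max must be below the number of training days")
    base = schedule or TrainingSchedule()
    rows = []
    per_pollutant = {}
    for k in range(k_min, k_max + 1):
        x, y = grid_shape_for_k(k)
        grid = SOMGrid(x=x, y=y, topology=topology)
        sched = replace(base, seed=int(np.random.SeedSequence((seed, k)).generate_state(1)[0] % 2**31))
        model = train_with_restarts(Z_std, grid, sched, n_restarts=n_restarts)
        r2 = adjusted_r2_scan(Z_raw, model.assignments)
        per_pollutant[k] = r2.by_pollutant
        rows.append(
            {
                "k": k,
                "x": x,
                "y": y,
                "ch": ch_index(Z_std, model.assignments),
                "qe": model.qe,
                "r2_mean": r2.mean,
                "r2_min": r2.min,
                "r2_max": r2.max,
            }
        )
    return SelectionReport(
        table=pd.DataFrame(rows),
        r2_by_pollutant=pd.DataFrame(per_pollutant).T.rename_axis("k"),
    )
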