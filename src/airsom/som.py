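"""Sequential Kohonen self-organizing map for day-type classification.

The SOM places ``k = X * Y`` class profiles ("codebook" vectors, one per map
node) on a small planar grid and trains them online: at each iteration one
day is drawn at random, its best matching unit (BMU) is found by Euclidean
distance, and every codebook within a shrinking planar neighborhood of the
BMU is pulled toward the presented day by a decaying learning rate. The
neighborhood coupling is what organizes the map — grid-adjacent nodes end
up with similar profiles, so the trained grid reads as an ordered layout of
day types rather than an unordered set of clusters.

Defaults follow common practice for classification-oriented SOMs: the
learning rate decays linearly from 0.05 to 0.01 over the full run, the
bubble neighborhood radius starts at the 2/3-quantile of node-to-node
distances and shrinks linearly to 1.0 over the first third of iterations
(then holds, leaving BMU-only fine tuning on a unit-spaced grid), and the
iteration count defaults to 500 per node.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
from scipy.spatial.distance import cdist

from .data import (
    IntegrityError,
    PollutantMatrix,
    SchemaError,
    StandardizationParams,
    apply_standardization,
)

__all__ = [
    "SOMGrid",
    "TrainingSchedule",
    "SOMModel",
    "build_grid",
    "dissimilarity",
    "initialize_codebooks",
    "find_bmu",
    "update_step",
    "train",
    "quantization_error",
    "train_with_restarts",
    "modal_qe_choice",
    "assign",
    "save_model",
    "load_model",
    "UNLABELED",
]

#: Label used by :func:`assign` for rows with no observed entries.
UNLABELED = -1

_TOPOLOGIES = ("rectangular", "hexagonal")


@dataclass(frozen=True)
class SOMGrid:
    """An X-columns by Y-rows node lattice with planar coordinates.

    Nodes are ordered row-major with node 0 at grid position (1, 1), the
    bottom-left corner. ``labels[m]`` gives the 1-based (x, y) position of
    node ``m``. Rectangular grids place node (x, y) at planar (x, y) with
    unit spacing; hexagonal grids offset even rows by +0.5 in x and space
    rows by sqrt(3)/2.
    """

    x: int
    y: int
    topology: str = "rectangular"

    def __post_init__(self) -> None:
        if self.x < 1 or self.y < 1:
            raise ValueError("grid dimensions must be positive")
        if self.topology not in _TOPOLOGIES:
            raise ValueError(f"topology must be one of {_TOPOLOGIES}")

    @property
    def k(self) -> int:
        return self.x * self.y

    @property
    def labels(self) -> list[tuple[int, int]]:
        return [(m % self.x + 1, m // self.x + 1) for m in range(self.k)]

    @property
    def coords(self) -> np.ndarray:
        """k x 2 planar node coordinates."""
        xy = np.array(self.labels, dtype=float)
        if self.topology == "hexagonal":
            xy[:, 0] += 0.5 * (xy[:, 1] % 2 == 0)
            xy[:, 1] *= math.sqrt(3) / 2
        return xy

    def distances(self) -> np.ndarray:
        """k x k symmetric planar node-to-node distance matrix."""
        return cdist(self.coords, self.coords)

    def adjacency(self, tol: float = 1e-9) -> np.ndarray:
        """Boolean k x k matrix of nearest-neighbor node pairs."""
        d = self.distances()
        off = d[~np.eye(self.k, dtype=bool)]
        if off.size == 0:
            return np.zeros((self.k, self.k), dtype=bool)
        return (d > 0) & (d <= off.min() + tol)


def build_grid(x: int, y: int, topology: str = "rectangular") -> SOMGrid:
    """Construct the output map lattice (see :class:`SOMGrid`)."""
    return SOMGrid(x=x, y=y, topology=topology)


def dissimilarity(a, b, observed_mask=None) -> float:
    """Euclidean distance between two day profiles.

    With a boolean ``observed_mask`` (True = observed in both vectors) the
    distance is computed over the observed dimensions only and rescaled by
    sqrt(p / p_observed), which keeps magnitudes comparable between complete
    and incomplete days and makes the masked distance an unbiased estimate
    of the full distance when coordinates are exchangeable.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("profiles must have equal length")
    p = a.shape[-1]
    if observed_mask is None:
        return float(np.sqrt(np.sum((a - b) ** 2)))
    observed_mask = np.asarray(observed_mask, dtype=bool)
    p_obs = int(observed_mask.sum())
    if p_obs == 0:
        raise ValueError("no observed dimensions")
    diff = a[observed_mask] - b[observed_mask]
    return float(np.sqrt(np.sum(diff**2) * p / p_obs))


def _default_radius_start(grid: SOMGrid) -> float:
    """Radius covering 2/3 of the distinct node-to-node distances."""
    d = grid.distances()
    uniq = np.unique(d[d > 0])
    if uniq.size == 0:  # single-node grid
        return 1.0
    idx = max(0, math.ceil(2 * uniq.size / 3) - 1)
    return float(uniq[idx])


@dataclass(frozen=True)
class TrainingSchedule:
    """Iteration count, learning-rate decay, neighborhood decay and seed.

    ``t_total=None`` resolves to 500 iterations per node. ``radius_start=None``
    resolves to the 2/3-quantile of the grid's node-to-node distances. The
    radius decays linearly from ``radius_start`` to ``radius_end`` over the
    first ``radius_fraction`` of iterations and is held constant after; alpha
    decays linearly over the whole run.
    """

    t_total: int | None = None
    alpha_start: float = 0.05
    alpha_end: float = 0.01
    radius_start: float | None = None
    radius_end: float = 1.0
    radius_fraction: float = 1 / 3
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0 < self.alpha_end <= self.alpha_start < 1):
            raise ValueError("need 0 < alpha_end <= alpha_start < 1")
        if self.radius_end <= 0:
            raise ValueError("radius_end must be positive")
        if self.radius_start is not None and self.radius_start < self.radius_end:
            raise ValueError("radius_start must be >= radius_end")
        if not (0 < self.radius_fraction <= 1):
            raise ValueError("radius_fraction must be in (0, 1]")
        if self.t_total is not None and self.t_total < 1:
            raise ValueError("t_total must be positive")

    def resolve(self, grid: SOMGrid) -> "TrainingSchedule":
        """Fill grid-dependent defaults into concrete values."""
        t_total = self.t_total if self.t_total is not None else 500 * grid.k
        radius_start = (
            self.radius_start
            if self.radius_start is not None
            else max(_default_radius_start(grid), self.radius_end)
        )
        return replace(self, t_total=t_total, radius_start=radius_start)

    def alpha(self, t: int) -> float:
        """Learning rate at iteration t (0-based), linear decay over T."""
        return self.alpha_start + (self.alpha_end - self.alpha_start) * t / self.t_total

    def radius(self, t: int) -> float:
        """Neighborhood radius at iteration t: linear to radius_end, then held."""
        t_decay = self.radius_fraction * self.t_total
        if t >= t_decay:
            return self.radius_end
        frac = t / t_decay
        return self.radius_start + (self.radius_end - self.radius_start) * frac


@dataclass
class SOMModel:
    """A trained map: codebooks, day assignments and fit diagnostics.

    ``qe`` is the quantization error — the mean Euclidean distance between
    training days and their assigned codebook — the standard map-fit
    diagnostic. ``restart_qes`` logs the QE of every restart when the model
    came from :func:`train_with_restarts`.
    """

    grid: SOMGrid
    codebooks: np.ndarray
    assignments: np.ndarray
    qe: float
    schedule: TrainingSchedule
    standardization: StandardizationParams | None = None
    columns: tuple[str, ...] = field(default=())
    restart_qes: list[float] = field(default_factory=list)

    @property
    def k(self) -> int:
        return self.grid.k


def initialize_codebooks(Z: np.ndarray, grid: SOMGrid, seed: int) -> np.ndarray:
    """Seed codebooks with k distinct days sampled from the training matrix."""
    Z = np.asarray(Z, dtype=float)
    n = Z.shape[0]
    if n < grid.k:
        raise IntegrityError(f"more nodes ({grid.k}) than training days ({n})")
    rng = np.random.default_rng(seed)
    rows = rng.choice(n, size=grid.k, replace=False)
    return Z[rows].copy()


def find_bmu(z: np.ndarray, codebooks: np.ndarray) -> int:
    """Index of the codebook nearest to z; ties go to the lowest node id."""
    codebooks = np.asarray(codebooks, dtype=float)
    if codebooks.size == 0:
        raise ValueError("codebooks are empty")
    d2 = np.sum((codebooks - np.asarray(z, dtype=float)) ** 2, axis=1)
    return int(np.argmin(d2))


def update_step(
    codebooks: np.ndarray,
    z: np.ndarray,
    bmu: int,
    alpha: float,
    radius: float,
    grid: SOMGrid,
) -> np.ndarray:
    """One Kohonen update: pull the BMU's bubble neighborhood toward z.

    Every node with planar grid distance strictly less than ``radius`` from
    the BMU moves by ``alpha * (z - w)``; the strict inequality means a held
    radius of 1.0 on a unit-spaced grid updates the BMU alone.
    """
    if not (0 < alpha < 1):
        raise ValueError("alpha must be in (0, 1)")
    if radius <= 0:
        raise ValueError("radius must be positive")
    out = np.asarray(codebooks, dtype=float).copy()
    inside = grid.distances()[bmu] < radius
    out[inside] += alpha * (np.asarray(z, dtype=float) - out[inside])
    return out


def _check_training_input(Z: np.ndarray, grid: SOMGrid) -> np.ndarray:
    Z = np.asarray(Z, dtype=float)
    if Z.ndim != 2:
        raise ValueError("training matrix must be 2-D")
    if np.isnan(Z).any():
        raise IntegrityError("training matrix must be complete-case")
    if Z.shape[0] < grid.k:
        raise IntegrityError(f"more nodes ({grid.k}) than training days ({Z.shape[0]})")
    return Z


def train(
    Z: np.ndarray,
    grid: SOMGrid,
    schedule: TrainingSchedule | None = None,
    standardization: StandardizationParams | None = None,
    columns=(),
) -> SOMModel:
    """Train one SOM by sequential (online) learning.

    At each of T iterations a training row is drawn uniformly with
    replacement, its BMU found, and the bubble neighborhood updated. Final
    assignments are recomputed over all rows after training, and the
    quantization error is the mean day-to-assigned-codebook distance. The
    whole run is reproducible from ``schedule.seed``.
    """
    Z = _check_training_input(Z, grid)
    schedule = (schedule or TrainingSchedule()).resolve(grid)
    rng = np.random.default_rng(schedule.seed)
    codebooks = initialize_codebooks(Z, grid, seed=int(rng.integers(2**31)))

    T = schedule.t_total
    order = rng.integers(0, Z.shape[0], size=T)
    grid_d = grid.distances()
    alpha_step = (schedule.alpha_end - schedule.alpha_start) / T
    t_decay = schedule.radius_fraction * T
    for t in range(T):
        z = Z[order[t]]
        d2 = np.einsum("kp,kp->k", codebooks - z, codebooks - z)
        bmu = int(np.argmin(d2))
        alpha = schedule.alpha_start + alpha_step * t
        if t >= t_decay:
            radius = schedule.radius_end
        else:
            radius = schedule.radius_start + (
                schedule.radius_end - schedule.radius_start
            ) * (t / t_decay)
        inside = grid_d[bmu] < radius
        codebooks[inside] += alpha * (z - codebooks[inside])

    d = cdist(Z, codebooks)
    assignments = np.argmin(d, axis=1)
    qe = float(d[np.arange(Z.shape[0]), assignments].mean())
    return SOMModel(
        grid=grid,
        codebooks=codebooks,
        assignments=assignments,
        qe=qe,
        schedule=schedule,
        standardization=standardization,
        columns=tuple(columns),
    )


def quantization_error(Z: np.ndarray, model: SOMModel) -> float:
    """Mean Euclidean distance between days and their assigned codebooks."""
    Z = np.asarray(Z, dtype=float)
    assigned = model.codebooks[model.assignments]
    return float(np.sqrt(np.sum((Z - assigned) ** 2, axis=1)).mean())


def derive_restart_seed(seed: int, restart: int) -> int:
    """Deterministic per-restart seed from the top-level seed."""
    ss = np.random.SeedSequence(entropy=seed, spawn_key=(restart,))
    return int(ss.generate_state(1)[0] % 2**31)


def train_with_restarts(
    Z: np.ndarray,
    grid: SOMGrid,
    schedule: TrainingSchedule | None = None,
    n_restarts: int = 10,
    standardization: StandardizationParams | None = None,
    columns=(),
) -> SOMModel:
    """Train several independently initialized maps and keep a typical one.

    Each restart gets a distinct seed derived from ``schedule.seed``. The
    quantization errors are rounded to 3 decimals (on the standardized
    scale) and the returned model is one whose rounded QE is the modal
    value — the "most frequent QE" rule — with ties broken by the lowest
    unrounded QE. All restart QEs are recorded on the returned model.
    """
    if n_restarts < 1:
        raise ValueError("n_restarts must be >= 1")
    schedule = (schedule or TrainingSchedule()).resolve(grid)
    models = []
    for r in range(n_restarts):
        sub = replace(schedule, seed=derive_restart_seed(schedule.seed, r))
        models.append(
            train(Z, grid, sub, standardization=standardization, columns=columns)
        )
    qes = [m.qe for m in models]
    best = models[modal_qe_choice(qes)]
    best.restart_qes = [float(q) for q in qes]
    return best


def modal_qe_choice(qes, ndigits: int = 3) -> int:
    """Index of the restart implementing the "most frequent QE" rule.

    QEs are binned by rounding to ``ndigits`` decimals; the winner comes
    from the bin with the most restarts, ties broken by the lowest
    unrounded QE (when all rounded QEs are distinct this degenerates to
    plain QE minimization).
    """
    qes = np.asarray(qes, dtype=float)
    rounded = np.round(qes, ndigits)
    values, counts = np.unique(rounded, return_counts=True)
    modal_bins = values[counts == counts.max()]
    candidates = np.flatnonzero(np.isin(rounded, modal_bins))
    return int(candidates[np.argmin(qes[candidates])])


def assign(Z_new: PollutantMatrix, model: SOMModel) -> np.ndarray:
    """Project (possibly incomplete) days onto a trained map.

    Applies the stored standardization, then finds each row's BMU; rows
    with missing entries use the rescaled masked distance, and rows with no
    observed entries get :data:`UNLABELED`.
    """
    if model.standardization is None:
        raise SchemaError("model has no stored standardization parameters")
    if model.columns and tuple(Z_new.columns) != model.columns:
        raise SchemaError(
            f"columns {Z_new.columns} do not match model fit {list(model.columns)}"
        )
    S = apply_standardization(Z_new, model.standardization).values
    labels = np.full(S.shape[0], UNLABELED, dtype=int)
    observed = ~np.isnan(S)
    complete = observed.all(axis=1)
    if complete.any():
        labels[complete] = np.argmin(cdist(S[complete], model.codebooks), axis=1)
    for i in np.flatnonzero(~complete):
        mask = observed[i]
        if not mask.any():
            continue
        diff = model.codebooks[:, mask] - S[i, mask]
        labels[i] = int(np.argmin(np.einsum("kj,kj->k", diff, diff)))
    return labels


def save_model(model: SOMModel, path) -> None:
    """Serialize a model to JSON text sufficient for bit-exact reload."""
    std = model.standardization
    doc = {
        "grid": {"x": model.grid.x, "y": model.grid.y, "topology": model.grid.topology},
        "codebooks": model.codebooks.tolist(),
        "assignments": model.assignments.tolist(),
        "qe": model.qe,
        "schedule": {
            "t_total": model.schedule.t_total,
            "alpha_start": model.schedule.alpha_start,
            "alpha_end": model.schedule.alpha_end,
            "radius_start": model.schedule.radius_start,
            "radius_end": model.schedule.radius_end,
            "radius_fraction": model.schedule.radius_fraction,
            "seed": model.schedule.seed,
        },
        "standardization": None
        if std is None
        else {
            "means": std.means.tolist(),
            "sds": std.sds.tolist(),
            "columns": list(std.columns),
        },
        "columns": list(model.columns),
        "restart_qes": model.restart_qes,
    }
    Path(path).write_text(json.dumps(doc, indent=1))


def load_model(path) -> SOMModel:
    """Reload a model written by :func:`save_model`."""
    doc = json.loads(Path(path).read_text())
    std = doc["standardization"]
    return SOMModel(
        grid=SOMGrid(**doc["grid"]),
        codebooks=np.array(doc["codebooks"], dtype=float),
        assignments=np.array(doc["assignments"], dtype=int),
        qe=float(doc["qe"]),
        schedule=TrainingSchedule(**doc["schedule"]),
        standardization=None
        if std is None
        else StandardizationParams(
            means=std["means"], sds=std["sds"], columns=std["columns"]
        ),
        columns=tuple(doc["columns"]),
        restart_qes=[float(q) for q in doc["restart_qes"]],
    )
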