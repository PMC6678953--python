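"""Batch self-organizing map over the binary disease-indicator space.

The SOM provides an ordered low-dimensional representation of the record
population: each node of a rectangular lattice carries a codebook vector
in indicator space, trained by the deterministic batch rule

    m_i  <-  sum_j h(d(c_j, i), sigma_t) * x_j  /  sum_j h(d(c_j, i), sigma_t)

where ``c_j`` is the best-matching unit (BMU) of sample row ``x_j``,
``d`` the Euclidean distance between node coordinates on the grid, and
``h(d, sigma) = exp(-d^2 / (2 sigma^2))`` a Gaussian neighborhood whose
radius shrinks linearly from ``sigma_start`` to ``sigma_end`` across
epochs. In the zero-radius limit one batch epoch reduces exactly to one
Lloyd (k-means) centroid update with k = number of nodes.

Training runs on a seeded random sample; mapping (BMU lookup) then runs
over the entire data set, which is what makes cluster analysis of tens
of millions of records tractable.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml
from scipy.spatial.distance import cdist

__all__ = [
    "SomGrid",
    "TrainingSchedule",
    "SomModel",
    "NodeAssignment",
    "default_grid",
    "init_codebook",
    "find_bmu",
    "train_batch",
    "map_records",
    "quantization_error",
    "component_plane",
    "save_model",
    "load_model",
]


@dataclass(frozen=True)
class SomGrid:
    """Rectangular lattice; nodes indexed row-major, 0-based."""

    n_rows: int
    n_cols: int

    def __post_init__(self) -> None:
        if self.n_rows < 1 or self.n_cols < 1:
            raise ValueError("grid must have at least one row and one column")

    @property
    def n_nodes(self) -> int:
        return self.n_rows * self.n_cols

    @property
    def coordinates(self) -> np.ndarray:
        """(n_nodes, 2) array of (row, col) integer coordinates."""
        rows, cols = np.divmod(np.arange(self.n_nodes), self.n_cols)
        return np.column_stack([rows, cols])

    def grid_distances(self) -> np.ndarray:
        """Pairwise Euclidean distances between node coordinates."""
        xy = self.coordinates.astype(float)
        return cdist(xy, xy)


@dataclass(frozen=True)
class TrainingSchedule:
    """Neighborhood and sampling schedule for batch training.

    ``sigma_start``/``sigma_end`` are Gaussian radii in grid-distance
    units, interpolated linearly over ``n_epochs``. ``sample_size`` caps
    the number of records used for training (seeded sampling without
    replacement); mapping afterwards always uses all records.
    """

    n_epochs: int = 30
    sigma_start: float = 5.0
    sigma_end: float = 0.5
    sample_size: int = 200_000
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_epochs < 1:
            raise ValueError("n_epochs must be >= 1")
        if not (self.sigma_start >= self.sigma_end > 0):
            raise ValueError("need sigma_start >= sigma_end > 0")
        if self.sample_size < 1:
            raise ValueError("sample_size must be >= 1")

    def sigma_at(self, epoch: int) -> float:
        """Radius used during 0-based *epoch* (linear interpolation)."""
        if self.n_epochs == 1:
            return self.sigma_end
        t = epoch / (self.n_epochs - 1)
        return self.sigma_start + t * (self.sigma_end - self.sigma_start)


@dataclass
class SomModel:
    """A trained map: grid geometry, per-node codebook, training metadata."""

    grid: SomGrid
    codebook: np.ndarray  # (n_nodes, n_features)
    schedule: TrainingSchedule | None = None
    training_qe_trace: np.ndarray | None = None  # length n_epochs + 1

    def __post_init__(self) -> None:
        self.codebook = np.asarray(self.codebook, dtype=float)
        if self.codebook.shape[0] != self.grid.n_nodes:
            raise ValueError("codebook must hold one vector per node")
        if not np.isfinite(self.codebook).all():
            raise ValueError("codebook entries must be finite")

    @property
    def n_features(self) -> int:
        return self.codebook.shape[1]


@dataclass
class NodeAssignment:
    """Best-matching unit of every record plus per-node tallies."""

    bmu: np.ndarray  # (n_records,) node indices
    node_counts: np.ndarray  # (n_nodes,)

    def __post_init__(self) -> None:
        if self.node_counts.sum() != len(self.bmu):
            raise ValueError("node_counts must sum to the record count")


def default_grid(matrix: np.ndarray, n_nodes: int = 1000) -> SomGrid:
    """Grid of about *n_nodes* nodes with aspect ratio set by the data.

    The rows:cols ratio follows the ratio of the standard deviations
    along the first two principal axes, clamped to [1, 4] — the
    conventional way to let the map mirror the data's dominant spread.
    """
    X = np.asarray(matrix, dtype=float)
    ratio = 1.0
    if X.shape[0] > 1 and X.shape[1] > 1:
        Xc = X - X.mean(axis=0)
        s = np.linalg.svd(Xc, compute_uv=False)
        if len(s) > 1 and s[1] > 0:
            ratio = float(np.clip(s[0] / s[1], 1.0, 4.0))
    n_cols = max(1, int(round(np.sqrt(n_nodes / ratio))))
    n_rows = max(1, int(round(n_nodes / n_cols)))
    if n_rows < n_cols:
        n_rows, n_cols = n_cols, n_rows
    return SomGrid(n_rows=n_rows, n_cols=n_cols)


def init_codebook(
    matrix: np.ndarray,
    grid: SomGrid,
    method: str = "pca_plane",
    seed: int = 0,
) -> np.ndarray:
    """Initial codebook: PCA-plane (linear) or seeded sample of rows.

    ``pca_plane`` lays the codebook out linearly on the plane of the
    data's first two principal axes, centered on the data mean, with the
    grid axes spanning one standard deviation each way along the
    corresponding axis. Zero-variance data fall back to a mean-centered
    zero plane with a warning.
    """
    X = np.asarray(matrix, dtype=float)
    if X.shape[0] == 0:
        raise ValueError("cannot initialize a codebook from an empty matrix")
    if method == "random":
        rng = np.random.default_rng(seed)
        idx = rng.integers(0, X.shape[0], size=grid.n_nodes)
        return X[idx].copy()
    if method != "pca_plane":
        raise ValueError(f"unknown initialization method {method!r}")

    mean = X.mean(axis=0)
    Xc = X - mean
    # coordinates scaled to [-1, 1] along each grid axis (0 for singleton axes)
    coords = grid.coordinates.astype(float)
    span = np.array([max(grid.n_rows - 1, 1), max(grid.n_cols - 1, 1)], dtype=float)
    unit = np.where(
        [grid.n_rows > 1, grid.n_cols > 1],
        2.0 * coords / span - 1.0,
        0.0,
    )

    U, s, Vt = np.linalg.svd(Xc, full_matrices=False)
    n = X.shape[0]
    sds = s / np.sqrt(max(n - 1, 1))
    axes = np.zeros((2, X.shape[1]))
    scale = np.zeros(2)
    for k in range(min(2, len(s))):
        if sds[k] > 1e-12:
            axes[k] = Vt[k]
            scale[k] = sds[k]
    if scale[0] == 0.0:
        warnings.warn("zero-variance data: PCA-plane init degenerates to the mean plane")
    # the longer grid axis follows the first principal axis
    pc_row = 0 if grid.n_rows >= grid.n_cols else 1
    pc_col = 1 - pc_row
    return (
        mean
        + unit[:, [0]] * scale[pc_row] * axes[pc_row]
        + unit[:, [1]] * scale[pc_col] * axes[pc_col]
    )


def find_bmu(model: SomModel, x: np.ndarray) -> int:
    """Index of the node whose codebook vector is nearest to *x*
    (squared Euclidean; ties go to the lowest node index)."""
    x = np.asarray(x, dtype=float)
    if x.shape != (model.n_features,):
        raise ValueError(
            f"vector has dimension {x.shape}, codebook expects ({model.n_features},)"
        )
    d2 = ((model.codebook - x) ** 2).sum(axis=1)
    return int(np.argmin(d2))


def _bmu_all(codebook: np.ndarray, X: np.ndarray) -> np.ndarray:
    """Vectorized BMU lookup for every row of X (argmin = lowest-index tie-break)."""
    d2 = cdist(X, codebook, metric="sqeuclidean")
    return d2.argmin(axis=1)


def train_batch(
    matrix: np.ndarray,
    grid: SomGrid,
    schedule: TrainingSchedule | None = None,
    init: str = "pca_plane",
) -> SomModel:
    """Train a batch SOM on a seeded sample of *matrix*.

    Every epoch assigns BMUs for all sample rows, then replaces each
    node's vector by the Gaussian-kernel-weighted mean of the sample
    (a convex combination, so codebook entries stay within the sample's
    column ranges; binary indicators stay in [0, 1]). Nodes receiving
    zero kernel mass keep their previous vector. The quantization-error
    trace has one entry for the initial codebook plus one per epoch.
    """
    X = np.asarray(matrix, dtype=float)
    if X.shape[0] == 0:
        raise ValueError("cannot train on an empty sample")
    schedule = schedule or TrainingSchedule()
    if X.shape[0] > schedule.sample_size:
        rng = np.random.default_rng(schedule.seed)
        idx = rng.choice(X.shape[0], size=schedule.sample_size, replace=False)
        X = X[idx]
    if X.shape[0] < grid.n_nodes:
        warnings.warn(
            f"training sample ({X.shape[0]} rows) smaller than the grid "
            f"({grid.n_nodes} nodes); many nodes will stay at initialization"
        )

    codebook = init_codebook(X, grid, method=init, seed=schedule.seed)
    D2 = grid.grid_distances() ** 2  # (nodes, nodes)

    qe_trace = []
    bmu = _bmu_all(codebook, X)
    qe_trace.append(_qe(codebook, X, bmu))
    for epoch in range(schedule.n_epochs):
        sigma = schedule.sigma_at(epoch)
        H = np.exp(-D2 / (2.0 * sigma * sigma))  # (nodes, nodes)
        K = H[:, bmu]  # kernel weight of node i for sample j
        mass = K.sum(axis=1)
        numer = K @ X
        alive = mass > 0.0
        codebook = codebook.copy()
        codebook[alive] = numer[alive] / mass[alive, None]
        bmu = _bmu_all(codebook, X)
        qe_trace.append(_qe(codebook, X, bmu))

    return SomModel(
        grid=grid,
        codebook=codebook,
        schedule=schedule,
        training_qe_trace=np.asarray(qe_trace),
    )


def map_records(model: SomModel, matrix: np.ndarray) -> NodeAssignment:
    """BMU of every row of *matrix* (typically the full data, not just
    the training sample), plus per-node record counts."""
    X = np.asarray(matrix, dtype=float)
    if X.size and X.shape[1] != model.n_features:
        raise ValueError(
            f"matrix has {X.shape[1]} columns, codebook expects {model.n_features}"
        )
    if X.shape[0] == 0:
        return NodeAssignment(
            bmu=np.empty(0, dtype=int),
            node_counts=np.zeros(model.grid.n_nodes, dtype=int),
        )
    bmu = _bmu_all(model.codebook, X)
    counts = np.bincount(bmu, minlength=model.grid.n_nodes)
    return NodeAssignment(bmu=bmu, node_counts=counts)


def _qe(codebook: np.ndarray, X: np.ndarray, bmu: np.ndarray) -> float:
    return float(np.sqrt(((X - codebook[bmu]) ** 2).sum(axis=1)).mean())


def quantization_error(
    model: SomModel, matrix: np.ndarray, assignment: NodeAssignment | None = None
) -> float:
    """Mean Euclidean distance of records to their BMU codebook vectors."""
    X = np.asarray(matrix, dtype=float)
    if assignment is None:
        assignment = map_records(model, matrix)
    return _qe(model.codebook, X, assignment.bmu)


def component_plane(
    model: SomModel,
    assignment: NodeAssignment,
    values: np.ndarray,
) -> tuple[np.ndarray, np.ndarray]:
    """Per-node mean of a record attribute (NaN = missing, excluded from
    both numerator and denominator).

    Returns ``(plane, n)`` as (n_rows, n_cols) grids; nodes with no
    non-missing records get plane = NaN and n = 0. For a binary
    attribute the plane is the per-node fraction in [0, 1].
    """
    values = np.asarray(values, dtype=float)
    if values.shape[0] != len(assignment.bmu):
        raise ValueError("values must align one-to-one with mapped records")
    ok = ~np.isnan(values)
    n_nodes = model.grid.n_nodes
    counts = np.bincount(assignment.bmu[ok], minlength=n_nodes)
    sums = np.bincount(assignment.bmu[ok], weights=values[ok], minlength=n_nodes)
    with np.errstate(invalid="ignore"):
        plane = np.where(counts > 0, sums / np.maximum(counts, 1), np.nan)
    shape = (model.grid.n_rows, model.grid.n_cols)
    return plane.reshape(shape), counts.reshape(shape)


def save_model(model: SomModel, header_path: str | Path, codebook_path: str | Path) -> None:
    """Persist a model as YAML header (grid, schedule) + CSV codebook."""
    sched = model.schedule
    header = {
        "grid": {"n_rows": model.grid.n_rows, "n_cols": model.grid.n_cols},
        "schedule": None
        if sched is None
        else {
            "n_epochs": sched.n_epochs,
            "sigma_start": sched.sigma_start,
            "sigma_end": sched.sigma_end,
            "sample_size": sched.sample_size,
            "seed": sched.seed,
        },
    }
    with open(header_path, "w") as fh:
        yaml.safe_dump(header, fh)
    n_feat = model.n_features
    cols = ",".join(f"f{j}" for j in range(n_feat))
    np.savetxt(
        codebook_path,
        np.column_stack([np.arange(model.grid.n_nodes), model.codebook]),
        delimiter=",",
        header="node_id," + cols,
        comments="",
        fmt=["%d"] + ["%.17g"] * n_feat,
    )


def load_model(header_path: str | Path, codebook_path: str | Path) -> SomModel:
    with open(header_path) as fh:
        header = yaml.safe_load(fh)
    grid = SomGrid(**header["grid"])
    sched = TrainingSchedule(**header["schedule"]) if header.get("schedule") else None
    table = np.loadtxt(codebook_path, delimiter=",", skiprows=1, ndmin=2)
    return SomModel(grid=grid, codebook=table[:, 1:], schedule=sched)
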