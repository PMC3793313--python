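"""Principal feature analysis (PFA) voxel selection.

PFA selects original features (voxels) rather than projecting onto
components.  The pipeline:

1. Build the voxel dependency matrix (covariance or correlation of the
   voxel rows of the data matrix) and eigendecompose it.
2. Keep the first ``q`` eigenvectors; the *rows* of the resulting
   ``n x q`` matrix are the projections of the voxels onto component
   space.  Highly correlated voxels get nearly identical rows.
3. Cluster the rows with k-means under cosine distance and retain, per
   cluster, the single voxel whose row lies closest to the cluster
   center — one representative per group of mutually redundant voxels.
4. Rank the representatives by the magnitude of their loading on the
   leading eigenvector and truncate, discarding noise-derived clusters.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .io import VoxelTimeSeries

__all__ = [
    "DependencyDecomposition",
    "ProjectionRows",
    "ClusterModel",
    "SelectedFeatures",
    "PFAConfig",
    "compute_dependency_matrix",
    "eigendecompose",
    "choose_q",
    "projection_rows",
    "cosine_distance",
    "kmeans_cosine",
    "kmeans_objective",
    "select_cluster_representatives",
    "rank_by_leading_eigenvector",
    "pfa_select",
]

_SYM_RTOL = 1e-9


@dataclass
class DependencyDecomposition:
    """Symmetric dependency matrix with its sorted eigendecomposition.

    ``eigenvectors[:, i]`` is the unit-norm eigenvector paired with
    ``eigenvalues[i]``; eigenvalues are sorted non-increasing.  The sign
    of each eigenvector is fixed so that its largest-magnitude entry is
    nonnegative (first such entry on ties).
    """

    sigma: np.ndarray
    eigenvalues: np.ndarray
    eigenvectors: np.ndarray

    @property
    def n(self) -> int:
        return self.sigma.shape[0]

    @property
    def leading_eigenvector(self) -> np.ndarray:
        return self.eigenvectors[:, 0]


@dataclass
class ProjectionRows:
    """The n row-vectors of the truncated eigenvector matrix.

    ``rows[i]`` is the projection of voxel i onto the leading ``q``
    components; ``retained_variance`` is the fraction of total spectrum
    mass carried by those components.
    """

    q: int
    rows: np.ndarray
    retained_variance: float

    @property
    def n(self) -> int:
        return self.rows.shape[0]


@dataclass
class ClusterModel:
    """Converged cosine k-means clustering of projection rows."""

    k: int
    assignment: np.ndarray
    centers: np.ndarray
    n_iterations: int
    seed: int
    converged: bool = True


@dataclass
class SelectedFeatures:
    """Ordered voxel indices with per-voxel selection scores."""

    indices: np.ndarray
    scores: np.ndarray
    method: str
    category: str | None = None
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.indices = np.asarray(self.indices, dtype=int)
        self.scores = np.asarray(self.scores, dtype=float)
        if self.indices.shape != self.scores.shape:
            raise ValueError("indices and scores must be aligned")
        if len(set(self.indices.tolist())) != self.indices.size:
            raise ValueError("selected indices must be distinct")

    def __len__(self) -> int:
        return self.indices.size


def compute_dependency_matrix(ts, mode: str = "correlation") -> np.ndarray:
    """Voxel-by-voxel covariance or correlation matrix.

    Covariance uses divisor ``L - 1`` over observations; correlation is
    the covariance of per-voxel standardized rows.  Raises if a voxel
    has zero variance in correlation mode.
    """
    Y = ts.values if isinstance(ts, VoxelTimeSeries) else np.asarray(ts, dtype=float)
    if Y.ndim != 2 or Y.shape[1] < 2:
        raise ValueError("need a 2-D matrix with at least 2 observations")
    if mode not in ("covariance", "correlation"):
        raise ValueError(f"unknown mode {mode!r}")
    if mode == "correlation":
        sd = Y.std(axis=1, ddof=1)
        dead = np.flatnonzero(sd == 0)
        if dead.size:
            raise ValueError(
                f"zero-variance voxel(s) {dead.tolist()} cannot enter correlation mode"
            )
        Y = (Y - Y.mean(axis=1, keepdims=True)) / sd[:, None]
    sigma = np.cov(Y, ddof=1)
    sigma = np.atleast_2d(sigma)
    return 0.5 * (sigma + sigma.T)  # kill round-off asymmetry


def _fix_signs(vectors: np.ndarray) -> np.ndarray:
    """Make each column's largest-magnitude entry nonnegative (first on ties)."""
    out = vectors.copy()
    for j in range(out.shape[1]):
        col = out[:, j]
        i = int(np.argmax(np.abs(col)))  # argmax takes the first maximum
        if col[i] < 0:
            out[:, j] = -col
    return out


def eigendecompose(sigma: np.ndarray) -> DependencyDecomposition:
    """Full symmetric eigendecomposition, eigenvalues sorted descending."""
    sigma = np.asarray(sigma, dtype=float)
    if sigma.ndim != 2 or sigma.shape[0] != sigma.shape[1]:
        raise ValueError("sigma must be square")
    scale = max(np.abs(sigma).max(), 1.0)
    if np.abs(sigma - sigma.T).max() > _SYM_RTOL * scale:
        raise ValueError("sigma is not symmetric within tolerance")
    sigma = 0.5 * (sigma + sigma.T)
    evals, evecs = np.linalg.eigh(sigma)
    order = np.argsort(evals)[::-1]
    evals = evals[order]
    evecs = _fix_signs(evecs[:, order])
    return DependencyDecomposition(sigma=sigma, eigenvalues=evals, eigenvectors=evecs)


def choose_q(eigenvalues: np.ndarray, variance_fraction: float) -> int:
    """Smallest q whose leading eigenvalues carry >= the given fraction."""
    if not 0.0 < variance_fraction <= 1.0:
        raise ValueError("variance_fraction must be in (0, 1]")
    lam = np.clip(np.asarray(eigenvalues, dtype=float), 0.0, None)
    total = lam.sum()
    if total <= 0:
        raise ValueError("all-zero spectrum: cannot choose q")
    cum = np.cumsum(lam) / total
    # tolerance guards fraction=1.0 against round-off shortfall
    q = int(np.searchsorted(cum, variance_fraction - 1e-12)) + 1
    return min(q, int(np.max(np.flatnonzero(lam > 0))) + 1)


def projection_rows(decomposition: DependencyDecomposition, q: int) -> ProjectionRows:
    """Rows of the first-q eigenvector matrix: one q-vector per voxel."""
    n = decomposition.n
    if not 1 <= q <= n:
        raise ValueError(f"q must be in [1, {n}]")
    lam = np.clip(decomposition.eigenvalues, 0.0, None)
    retained = float(lam[:q].sum() / lam.sum()) if lam.sum() > 0 else 0.0
    return ProjectionRows(q=q, rows=decomposition.eigenvectors[:, :q].copy(),
                          retained_variance=retained)


def cosine_distance(u: np.ndarray, v: np.ndarray) -> float:
    """1 - cos(angle between u and v); lies in [0, 2]."""
    u = np.asarray(u, dtype=float)
    v = np.asarray(v, dtype=float)
    nu, nv = np.linalg.norm(u), np.linalg.norm(v)
    if nu == 0 or nv == 0:
        raise ValueError("cosine distance undefined for zero-norm vector")
    return float(np.clip(1.0 - float(u @ v) / (nu * nv), 0.0, 2.0))


def _cosine_distances(rows_unit: np.ndarray, centers: np.ndarray) -> np.ndarray:
    """Pairwise cosine distance from unit rows (zero rows allowed) to unit centers."""
    return np.clip(1.0 - rows_unit @ centers.T, 0.0, 2.0)


def _normalize(X: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    norms = np.linalg.norm(X, axis=1)
    out = np.zeros_like(X)
    nz = norms > 0
    out[nz] = X[nz] / norms[nz, None]
    return out, norms


def kmeans_cosine(rows, k: int, seed: int = 0, max_iter: int = 300) -> ClusterModel:
    """Lloyd's k-means under cosine distance.

    Initial centers are k distinct rows drawn without replacement by the
    seeded generator.  Each iteration assigns rows to the nearest center
    (ties -> lowest center id), then recomputes each center as the member
    mean renormalized to unit length.  Stops at an assignment fixed
    point or after ``max_iter`` iterations.  An empty cluster is
    repaired by moving in the row farthest from its own center.

    Rows with zero norm have no direction; they sit at distance 1 from
    every center and land in the lowest-id cluster.
    """
    X = np.asarray(rows.rows if isinstance(rows, ProjectionRows) else rows, dtype=float)
    if X.ndim != 2:
        raise ValueError("rows must be 2-D")
    n = X.shape[0]
    if k <= 0:
        raise ValueError("k must be positive")
    if max_iter < 1:
        raise ValueError("max_iter must be >= 1")
    Xu, norms = _normalize(X)
    candidates = np.flatnonzero(norms > 0)
    if k > candidates.size:
        raise ValueError(f"k={k} exceeds the {candidates.size} rows with nonzero norm")

    rng = np.random.default_rng(seed)
    init = candidates[rng.choice(candidates.size, size=k, replace=False)]
    centers = Xu[init].copy()

    assignment = np.full(n, -1, dtype=int)
    n_iter = 0
    converged = False
    for n_iter in range(1, max_iter + 1):
        dist = _cosine_distances(Xu, centers)
        new_assignment = np.argmin(dist, axis=1)  # first minimum -> lowest id

        # repair empty clusters: pull in the row farthest from its own center
        for c in range(k):
            if not np.any(new_assignment == c):
                own = dist[np.arange(n), new_assignment]
                # forbid stealing from singleton clusters or seeding with a zero row
                sizes = np.bincount(new_assignment, minlength=k)
                movable = (sizes[new_assignment] > 1) & (norms > 0)
                if not movable.any():
                    break
                own = np.where(movable, own, -np.inf)
                far = int(np.argmax(own))
                new_assignment[far] = c
                centers[c] = Xu[far]
                dist = _cosine_distances(Xu, centers)

        if np.array_equal(new_assignment, assignment):
            converged = True
            break
        assignment = new_assignment

        for c in range(k):
            members = np.flatnonzero(assignment == c)
            if members.size == 0:
                continue
            mean = X[members].mean(axis=0)
            norm = np.linalg.norm(mean)
            if norm > 0:
                centers[c] = mean / norm
            # zero mean (perfect cancellation): keep the previous center

    return ClusterModel(k=k, assignment=assignment, centers=centers,
                        n_iterations=n_iter, seed=seed, converged=converged)


def kmeans_objective(model: ClusterModel, rows) -> float:
    """Total within-cluster cosine distance (zero-norm rows count 1 each)."""
    X = np.asarray(rows.rows if isinstance(rows, ProjectionRows) else rows, dtype=float)
    Xu, _ = _normalize(X)
    dist = _cosine_distances(Xu, model.centers)
    return float(dist[np.arange(X.shape[0]), model.assignment].sum())


def select_cluster_representatives(model: ClusterModel, rows) -> SelectedFeatures:
    """One voxel per cluster: the member closest to the cluster center.

    Ties go to the lowest voxel index; output is ordered by cluster id.
    """
    X = np.asarray(rows.rows if isinstance(rows, ProjectionRows) else rows, dtype=float)
    Xu, _ = _normalize(X)
    dist = _cosine_distances(Xu, model.centers)
    indices, scores = [], []
    for c in range(model.k):
        members = np.flatnonzero(model.assignment == c)
        if members.size == 0:
            raise ValueError(f"cluster {c} is empty; model is invalid")
        d = dist[members, c]
        best = members[int(np.argmin(d))]  # argmin -> first = lowest index
        indices.append(int(best))
        scores.append(float(d.min()))
    return SelectedFeatures(indices=np.array(indices), scores=np.array(scores),
                            method="pfa-representatives")


def rank_by_leading_eigenvector(
    selected: SelectedFeatures, decomposition: DependencyDecomposition
) -> SelectedFeatures:
    """Re-rank selected voxels by |loading| on the leading eigenvector.

    The noise filter: clusters made of pure-noise voxels contribute
    representatives with near-zero leading-eigenvector loadings, which a
    subsequent truncation discards.  No removal happens here.
    """
    e1 = np.abs(decomposition.leading_eigenvector)
    idx = selected.indices
    if idx.size and (idx.min() < 0 or idx.max() >= e1.size):
        raise ValueError("selected index out of range for the decomposition")
    scores = e1[idx]
    order = np.lexsort((idx, -scores))
    return SelectedFeatures(indices=idx[order], scores=scores[order],
                            method="pfa", category=selected.category,
                            provenance=selected.provenance)


@dataclass
class PFAConfig:
    """Knobs of the PFA pipeline.

    ``oversample_factor`` controls k relative to the requested feature
    count: clustering into more clusters than features wanted gives the
    leading-eigenvector filter something to remove.  1.0 reproduces the
    unfiltered variant.
    """

    mode: str = "correlation"
    variance_fraction: float = 0.9
    oversample_factor: float = 1.2
    seed: int = 0
    max_iter: int = 300
    n_restarts: int = 10

    def __post_init__(self) -> None:
        if self.oversample_factor < 1.0:
            raise ValueError("oversample_factor must be >= 1.0")
        if self.n_restarts < 1:
            raise ValueError("n_restarts must be >= 1")


def pfa_select(ts, n_features: int, config: PFAConfig | None = None) -> SelectedFeatures:
    """Run the full PFA pipeline and return the top ``n_features`` voxels.

    Multi-restart k-means keeps the restart with the lowest total
    within-cluster cosine distance; all randomness derives from
    ``config.seed``.
    """
    config = config or PFAConfig()
    Y = ts.values if isinstance(ts, VoxelTimeSeries) else np.asarray(ts, dtype=float)
    n = Y.shape[0]
    if not 1 <= n_features <= n:
        raise ValueError(f"n_features must be in [1, {n}]")

    sigma = compute_dependency_matrix(ts, mode=config.mode)
    decomp = eigendecompose(sigma)
    q = choose_q(decomp.eigenvalues, config.variance_fraction)
    rows = projection_rows(decomp, q)

    k = min(n, math.ceil(config.oversample_factor * n_features))
    child_seeds = np.random.SeedSequence(config.seed).generate_state(config.n_restarts)
    best_model, best_obj = None, np.inf
    for s in child_seeds:
        model = kmeans_cosine(rows, k=k, seed=int(s), max_iter=config.max_iter)
        obj = kmeans_objective(model, rows)
        if obj < best_obj - 1e-15:
            best_model, best_obj = model, obj

    reps = select_cluster_representatives(best_model, rows)
    ranked = rank_by_leading_eigenvector(reps, decomp)
    out = SelectedFeatures(
        indices=ranked.indices[:n_features],
        scores=ranked.scores[:n_features],
        method="pfa",
        provenance={
            "q": q,
            "retained_variance": rows.retained_variance,
            "k": k,
            "n_iterations": best_model.n_iterations,
            "objective": best_obj,
            "mode": config.mode,
            "seed": config.seed,
        },
    )
    return out
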