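"""Hybrid density clustering: k-means compression, DBSCAN on centroids,
label propagation.

The expensive part of DBSCAN is its O(n^2) neighbourhood computation.  The
hybrid algorithm first compresses the dataset into k << n representative
centroids by minimising intra-cluster variance (Lloyd iterations from a
k-means++-style seeding), then runs DBSCAN on the centroids alone —
O(nk + k^2) overall — and finally hands each original point the density
label of its centroid.  Both primitives are implemented here from first
principles with explicit core/border/noise typing, because the typing (not
just the partition) drives the border-retention reduction pipeline.

All distances are Euclidean (L2).  Neighbourhood counts include the query
point itself, so a point with ``min_pts - 1`` genuine neighbours plus
itself is core when ``min_pts`` of them fall within ``eps``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.distance import cdist

from .datasets import PointSet

__all__ = [
    "DensityParams",
    "CentroidModel",
    "DbscanResult",
    "ClusteringOutcome",
    "kmeans_fit",
    "dbscan_fit",
    "classify_point_types",
    "propagate_labels",
    "km_dbscan",
    "majority_centroid_labels",
]

CORE, BORDER, NOISE = "core", "border", "noise"


@dataclass(frozen=True)
class DensityParams:
    """DBSCAN neighbourhood radius ``eps`` (feature-space distance units)
    and minimum neighbourhood size ``min_pts`` (self included)."""

    eps: float
    min_pts: int

    def __post_init__(self) -> None:
        if self.eps <= 0:
            raise ValueError(f"eps must be positive, got {self.eps}")
        if self.min_pts < 1:
            raise ValueError(f"min_pts must be >= 1, got {self.min_pts}")


@dataclass
class CentroidModel:
    """Fitted k-means state: centroids mu_i, the point->centroid assignment
    defining the clusters C_i, and the final intra-cluster variance."""

    centroids: np.ndarray
    assignment: np.ndarray
    inertia: float
    k: int
    seed: int


@dataclass
class DbscanResult:
    """Density clustering of m points.

    ``labels``: -1 for noise, 0..C-1 for clusters.  ``point_type`` holds the
    {core, border, noise} typing; ``neighbor_counts`` the |N_eps| counts
    (self included) that produced it.
    """

    labels: np.ndarray
    point_type: np.ndarray
    neighbor_counts: np.ndarray

    @property
    def n_clusters(self) -> int:
        return int(self.labels.max() + 1) if self.labels.size else 0


@dataclass
class ClusteringOutcome:
    """Full hybrid run: per-point labels plus the centroid-level evidence."""

    point_labels: np.ndarray
    centroid_result: DbscanResult
    model: CentroidModel
    params: DensityParams


def _as_points(X) -> np.ndarray:
    pts = X.points if isinstance(X, PointSet) else np.asarray(X, dtype=float)
    if pts.ndim != 2:
        raise ValueError("expected a 2-D point matrix")
    if not np.all(np.isfinite(pts)):
        raise ValueError("points must be finite")
    return pts


def _kmeanspp_init(pts: np.ndarray, k: int, rng: np.random.Generator) -> np.ndarray:
    """k-means++ seeding: first centre uniform, then D^2-weighted draws."""
    n = pts.shape[0]
    centers = np.empty((k, pts.shape[1]))
    centers[0] = pts[rng.integers(n)]
    d2 = np.sum((pts - centers[0]) ** 2, axis=1)
    for j in range(1, k):
        total = d2.sum()
        if total <= 0:  # all remaining points coincide with chosen centres
            centers[j:] = centers[0]
            break
        centers[j] = pts[rng.choice(n, p=d2 / total)]
        d2 = np.minimum(d2, np.sum((pts - centers[j]) ** 2, axis=1))
    return centers


def kmeans_fit(
    X,
    k: int,
    seed: int = 0,
    max_iter: int = 300,
    tol: float = 1e-4,
) -> CentroidModel:
    """Lloyd's algorithm from k-means++ seeding.

    Iterates assign/update until the largest centroid displacement drops
    below ``tol`` or ``max_iter`` is reached.  An emptied cluster is
    re-seeded at the point currently farthest from its own centroid, which
    keeps every centroid owning at least one point.  The inertia (summed
    squared distance of points to their centroid) is non-increasing across
    iterations, a property the test suite asserts.
    """
    pts = _as_points(X)
    n = pts.shape[0]
    if not 1 <= k <= n:
        raise ValueError(f"k must satisfy 1 <= k <= n={n}, got {k}")
    rng = np.random.default_rng(seed)
    centers = _kmeanspp_init(pts, k, rng)

    assignment = np.zeros(n, dtype=int)
    for _ in range(max_iter):
        dists = cdist(pts, centers)
        assignment = np.argmin(dists, axis=1)
        new_centers = centers.copy()
        for j in range(k):
            members = assignment == j
            if members.any():
                new_centers[j] = pts[members].mean(axis=0)
            else:
                # re-seed dead centroid at the worst-fit point
                worst = np.argmax(dists[np.arange(n), assignment])
                new_centers[j] = pts[worst]
                assignment[worst] = j
        shift = np.max(np.linalg.norm(new_centers - centers, axis=1))
        centers = new_centers
        if shift < tol:
            break
    dists = cdist(pts, centers)
    assignment = np.argmin(dists, axis=1)
    inertia = float(np.sum((pts - centers[assignment]) ** 2))
    return CentroidModel(centers, assignment, inertia, k, seed)


def classify_point_types(X, params: DensityParams) -> np.ndarray:
    """Exhaustive {core, border, noise} typing of every point.

    Core: at least ``min_pts`` points (self included) within ``eps``.
    Border: non-core with at least one core point within ``eps``.
    Noise: everything else.
    """
    pts = _as_points(X)
    within = cdist(pts, pts) <= params.eps
    counts = within.sum(axis=1)
    core = counts >= params.min_pts
    border = ~core & (within & core[None, :]).any(axis=1)
    types = np.full(pts.shape[0], NOISE, dtype=object)
    types[core] = CORE
    types[border] = BORDER
    return types.astype("U6")


def dbscan_fit(X, params: DensityParams) -> DbscanResult:
    """DBSCAN by explicit core-graph connected components.

    Clusters are the connected components of the graph on core points with
    edges between core pairs within ``eps``; components are numbered by
    their lowest core-point index, so the labelling is deterministic in the
    row order of the input.  Each border point takes the label of its
    lowest-index core neighbour (the documented tie-break when cores from
    two clusters are both within reach).  Noise keeps label -1.
    """
    pts = _as_points(X)
    m = pts.shape[0]
    within = cdist(pts, pts) <= params.eps
    counts = within.sum(axis=1)
    core = counts >= params.min_pts

    labels = np.full(m, -1, dtype=int)
    types = np.full(m, NOISE, dtype="U6")

    core_idx = np.flatnonzero(core)
    if core_idx.size:
        from scipy.sparse import csr_matrix
        from scipy.sparse.csgraph import connected_components

        adj = csr_matrix(within[np.ix_(core_idx, core_idx)])
        _, comp = connected_components(adj, directed=False)
        # renumber components by first (lowest) core index for determinism
        order: dict[int, int] = {}
        for c in comp:
            if c not in order:
                order[c] = len(order)
        labels[core_idx] = [order[c] for c in comp]
        types[core_idx] = CORE

        non_core = np.flatnonzero(~core)
        if non_core.size:
            reach = within[np.ix_(non_core, core_idx)]
            has_core = reach.any(axis=1)
            first_core = np.argmax(reach, axis=1)  # lowest-index core neighbour
            border_rows = non_core[has_core]
            labels[border_rows] = labels[core_idx[first_core[has_core]]]
            types[border_rows] = BORDER

    return DbscanResult(labels, types, counts.astype(int))


def propagate_labels(model: CentroidModel, centroid_labels: np.ndarray) -> np.ndarray:
    """Give each original point the density label of its centroid.

    Points whose centroid was typed noise (label -1) inherit -1.
    """
    centroid_labels = np.asarray(centroid_labels, dtype=int)
    if centroid_labels.shape != (model.k,):
        raise ValueError(
            f"centroid_labels must have length k={model.k}, "
            f"got {centroid_labels.shape}"
        )
    return centroid_labels[model.assignment]


def majority_centroid_labels(model: CentroidModel, point_labels: np.ndarray) -> np.ndarray:
    """Label each centroid by majority vote of its members' labels.

    Used to carry ground-truth class labels up to the centroid level, e.g.
    for grid-tuning density parameters against known structure.  Ties break
    toward the smallest label value.
    """
    point_labels = np.asarray(point_labels, dtype=int)
    if point_labels.shape != model.assignment.shape:
        raise ValueError("point_labels must have one entry per point")
    out = np.empty(model.k, dtype=int)
    for j in range(model.k):
        members = point_labels[model.assignment == j]
        values, counts = np.unique(members, return_counts=True)
        out[j] = values[np.argmax(counts)]
    return out


def km_dbscan(
    X,
    k: int,
    params: DensityParams,
    seed: int = 0,
    noise_to_nearest: bool = False,
) -> ClusteringOutcome:
    """The hybrid pipeline: compress, density-cluster the centroids, propagate.

    With ``noise_to_nearest=True`` points assigned to a noise centroid are
    re-attached to the nearest non-noise centroid instead of keeping -1.
    Deterministic given ``seed``.
    """
    pts = _as_points(X)
    model = kmeans_fit(pts, k, seed=seed)
    result = dbscan_fit(model.centroids, params)
    centroid_labels = result.labels.copy()
    if noise_to_nearest and (centroid_labels == -1).any():
        clustered = np.flatnonzero(centroid_labels != -1)
        if clustered.size:
            noisy = np.flatnonzero(centroid_labels == -1)
            d = cdist(model.centroids[noisy], model.centroids[clustered])
            centroid_labels[noisy] = centroid_labels[clustered[np.argmin(d, axis=1)]]
    point_labels = propagate_labels(model, centroid_labels)
    return ClusteringOutcome(point_labels, result, model, params)
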