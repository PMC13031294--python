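"""Border-retention instance selection for training-set reduction.

Each class is processed independently: compress the class to k_i centroids
(k_i given directly or as ceil(alpha * |X_i|)), type each centroid as
core/border/noise by exhaustive neighbourhood counting, and retain the
border centroids — the condensed stand-ins for the samples near the class
periphery, where decision boundaries live.  Core centroids (deep inside the
class) and noise centroids (outliers) are dropped.  Because centroids are
synthetic points, the retained set is mapped back to real training rows:
the default ``nearest_member`` policy keeps, for each border centroid, the
closest point among those assigned to it (a medoid-like representative);
``all_members`` keeps every point assigned to a border centroid.

Two ablation policies bracket the hybrid: ``kmeans_only`` skips density
typing and keeps one nearest member per centroid, and ``dbscan_only`` skips
compression and keeps the border points of DBSCAN run on the raw class.

An optional embedding front-end (PCA or UMAP, delegated to scikit-learn and
umap-learn) maps the data to d' dimensions before clustering; selection
indices always refer to original rows, so the reduced set can be used in
the original space.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from math import ceil

import numpy as np
from scipy.spatial.distance import cdist

from .clustering import (
    BORDER,
    CORE,
    NOISE,
    DensityParams,
    classify_point_types,
    dbscan_fit,
    kmeans_fit,
)
from .datasets import PointSet

__all__ = [
    "ReductionSpec",
    "ReductionResult",
    "ClassStats",
    "POLICIES",
    "embed",
    "reduce_class",
    "reduce_dataset",
    "tune_density_params",
]

POLICIES = ("nearest_member", "all_members", "kmeans_only", "dbscan_only")


@dataclass
class ReductionSpec:
    """Per-class configuration for one reduction run.

    Exactly one of ``per_class_k`` (explicit class -> k map) or ``alpha``
    (k_i = ceil(alpha * |X_i|)) sets the centroid counts.  Density
    parameters may be given per class or once as a default for every class.
    """

    per_class_k: dict | None = None
    alpha: float | None = None
    per_class_density: dict | None = None
    default_density: DensityParams | None = None
    embed_method: str = "none"
    embed_dims: int | None = None
    policy: str = "nearest_member"
    standardize: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if (self.per_class_k is None) == (self.alpha is None):
            raise ValueError("set exactly one of per_class_k or alpha")
        if self.alpha is not None and not 0 < self.alpha <= 1:
            raise ValueError(f"alpha must lie in (0, 1], got {self.alpha}")
        if self.policy not in POLICIES:
            raise ValueError(f"unknown policy {self.policy!r}; choose from {POLICIES}")
        if self.embed_method not in ("none", "pca", "umap"):
            raise ValueError(f"unknown embed method {self.embed_method!r}")
        if self.embed_method != "none" and self.embed_dims is None:
            raise ValueError("embed_dims required when embedding is enabled")

    def k_for(self, label: int, n_class: int) -> int:
        if self.alpha is not None:
            return ceil(self.alpha * n_class)
        try:
            return int(self.per_class_k[label])
        except KeyError:
            raise ValueError(f"no k configured for class {label}") from None

    def density_for(self, label: int) -> DensityParams:
        if self.per_class_density is not None and label in self.per_class_density:
            return self.per_class_density[label]
        if self.default_density is not None:
            return self.default_density
        raise ValueError(f"no density parameters configured for class {label}")


@dataclass
class ClassStats:
    """Bookkeeping for one class: sizes, centroid typing, selection count."""

    n_class: int
    k_class: int
    n_core: int
    n_border: int
    n_noise: int
    n_selected: int


@dataclass
class ReductionResult:
    """Selected original row ids plus per-class accounting and Eq.-style ratio."""

    selected_indices: np.ndarray
    per_class_stats: dict[int, ClassStats]
    reduction_ratio: float
    n_original: int

    def stats_dict(self) -> dict:
        return {
            int(c): vars(s).copy() for c, s in sorted(self.per_class_stats.items())
        }


def embed(X: PointSet, method: str, d_prime: int, seed: int = 0) -> PointSet:
    """Project to d' < d dimensions with PCA or UMAP, preserving row order.

    Row i of the output corresponds to row i of the input, so selections in
    the embedded space index the original table directly.
    """
    if method not in ("pca", "umap"):
        raise ValueError(f"unknown embed method {method!r}")
    if d_prime >= X.d:
        raise ValueError(f"d_prime must be < d={X.d}, got {d_prime}")
    if d_prime < 1:
        raise ValueError("d_prime must be >= 1")
    if method == "pca":
        from sklearn.decomposition import PCA

        emb = PCA(n_components=d_prime, random_state=seed).fit_transform(X.points)
    else:
        try:
            from umap import UMAP
        except ImportError as exc:  # pragma: no cover
            raise ImportError("umap-learn is required for method='umap'") from exc
        emb = UMAP(
            n_components=d_prime, random_state=seed, n_jobs=1
        ).fit_transform(X.points)
    return PointSet(np.asarray(emb, dtype=float), X.labels)


def _nearest_member(points: np.ndarray, members: np.ndarray, center: np.ndarray) -> int:
    """Local index of the member closest to center; ties -> lowest index."""
    d = np.linalg.norm(points[members] - center, axis=1)
    return int(members[np.argmin(d)])


def reduce_class(
    X_c: PointSet,
    k_c: int,
    params: DensityParams,
    policy: str = "nearest_member",
    seed: int = 0,
) -> tuple[np.ndarray, ClassStats]:
    """Reduce one class; returns local row indices (into X_c) and stats.

    ``k_c`` larger than the class is clamped with a warning so batch runs
    survive tiny classes.  An empty selection (no border centroids) is
    legal but warned about, never silent.
    """
    if policy not in POLICIES:
        raise ValueError(f"unknown policy {policy!r}")
    n_c = X_c.n
    if k_c < 1:
        raise ValueError(f"k must be >= 1, got {k_c}")
    if k_c > n_c:
        warnings.warn(
            f"k={k_c} exceeds class size {n_c}; clamping to {n_c}", stacklevel=2
        )
        k_c = n_c

    if policy == "dbscan_only":
        types = classify_point_types(X_c.points, params)
        selected = np.flatnonzero(types == BORDER)
        stats = ClassStats(
            n_class=n_c,
            k_class=n_c,
            n_core=int((types == CORE).sum()),
            n_border=int((types == BORDER).sum()),
            n_noise=int((types == NOISE).sum()),
            n_selected=selected.size,
        )
        if selected.size == 0:
            warnings.warn("no border points found; empty selection", stacklevel=2)
        return selected, stats

    model = kmeans_fit(X_c.points, k_c, seed=seed)

    if policy == "kmeans_only":
        # no density typing: every centroid is retained, one real member each
        picked = sorted(
            {
                _nearest_member(
                    X_c.points,
                    np.flatnonzero(model.assignment == j),
                    model.centroids[j],
                )
                for j in range(k_c)
            }
        )
        stats = ClassStats(n_c, k_c, 0, k_c, 0, len(picked))
        return np.asarray(picked, dtype=int), stats

    types = classify_point_types(model.centroids, params)
    border_centroids = np.flatnonzero(types == BORDER)
    if policy == "nearest_member":
        picked = sorted(
            {
                _nearest_member(
                    X_c.points,
                    np.flatnonzero(model.assignment == j),
                    model.centroids[j],
                )
                for j in border_centroids
            }
        )
        selected = np.asarray(picked, dtype=int)
    else:  # all_members
        selected = np.flatnonzero(np.isin(model.assignment, border_centroids))

    stats = ClassStats(
        n_class=n_c,
        k_class=k_c,
        n_core=int((types == CORE).sum()),
        n_border=border_centroids.size,
        n_noise=int((types == NOISE).sum()),
        n_selected=selected.size,
    )
    if selected.size == 0:
        warnings.warn(
            f"no border centroids for this class (eps={params.eps}, "
            f"min_pts={params.min_pts}); empty selection",
            stacklevel=2,
        )
    return selected, stats


def reduce_dataset(X: PointSet, spec: ReductionSpec) -> ReductionResult:
    """Run the per-class reduction over a labeled dataset.

    Classes never mix: each class subset is compressed, typed, and selected
    independently, and the per-class selections are translated back to
    original row ids and unioned.  The reported ratio is exactly
    |selected| / n.
    """
    if X.labels is None:
        raise ValueError("reduce_dataset requires class labels")
    work = X
    if spec.standardize:
        mu = work.points.mean(axis=0)
        sd = work.points.std(axis=0)
        sd[sd == 0] = 1.0
        work = PointSet((work.points - mu) / sd, work.labels)
    if spec.embed_method != "none":
        work = embed(work, spec.embed_method, spec.embed_dims, seed=spec.seed)

    selected_all: list[np.ndarray] = []
    per_class: dict[int, ClassStats] = {}
    for label in np.unique(work.labels):
        rows = np.flatnonzero(work.labels == label)
        X_c = work.subset(rows)
        k_c = spec.k_for(int(label), X_c.n)
        params = spec.density_for(int(label))
        local, stats = reduce_class(X_c, k_c, params, spec.policy, seed=spec.seed)
        selected_all.append(rows[local])
        per_class[int(label)] = stats

    selected = np.unique(np.concatenate(selected_all)) if selected_all else np.array([], int)
    if selected.size == 0:
        warnings.warn("reduction selected no rows at all", stacklevel=2)
    return ReductionResult(
        selected_indices=selected,
        per_class_stats=per_class,
        reduction_ratio=selected.size / X.n,
        n_original=X.n,
    )


def tune_density_params(
    centroids: PointSet,
    eps_grid,
    min_pts_grid,
    objective: str = "ari_vs_labels",
    target: float | None = None,
) -> DensityParams:
    """Exhaustive (eps, min_pts) grid search at the centroid level.

    ``ari_vs_labels`` maximises adjusted Rand index of the centroid DBSCAN
    labels against ``centroids.labels``; ``border_fraction_target`` picks
    the cell whose border fraction is closest to ``target``.  Ties break
    toward smaller eps, then smaller min_pts, so the result is independent
    of grid ordering.
    """
    from .metrics import adjusted_rand_index

    eps_grid = sorted(float(e) for e in eps_grid)
    min_pts_grid = sorted(int(m) for m in min_pts_grid)
    if not eps_grid or not min_pts_grid:
        raise ValueError("parameter grid must be non-empty")
    if objective not in ("ari_vs_labels", "border_fraction_target"):
        raise ValueError(f"unknown objective {objective!r}")
    if objective == "ari_vs_labels" and centroids.labels is None:
        raise ValueError("ari_vs_labels objective requires labels")
    if objective == "border_fraction_target" and target is None:
        raise ValueError("border_fraction_target objective requires a target")

    best: tuple[float, DensityParams] | None = None
    for eps in eps_grid:
        for min_pts in min_pts_grid:
            params = DensityParams(eps, min_pts)
            if objective == "ari_vs_labels":
                result = dbscan_fit(centroids.points, params)
                score = adjusted_rand_index(result.labels, centroids.labels)
            else:
                types = classify_point_types(centroids.points, params)
                frac = (types == BORDER).sum() / centroids.n
                score = -abs(frac - target)
            # strict > keeps the first (smallest eps, then min_pts) maximiser
            if best is None or score > best[0]:
                best = (score, params)
    return best[1]
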