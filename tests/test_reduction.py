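"""Reduction pipeline: per-class selection, policies, embedding, tuning."""

import warnings

import numpy as np
import pytest

from kmdbscan import (
    DensityParams,
    PointSet,
    ReductionSpec,
    embed,
    kmeans_fit,
    reduce_class,
    reduce_dataset,
    tune_density_params,
)
from kmdbscan.clustering import classify_point_types
from kmdbscan.reduction import POLICIES

SEGMENT = PointSet(np.linspace(0.0, 9.9, 100)[:, None])


def test_segment_border_centroids_are_the_extremes():
    """Uniform 1-D segment, k=10: only the two end centroids lack full
    neighbourhoods, so they alone are typed border and selected."""
    model = kmeans_fit(SEGMENT.points, 10, seed=0)
    order = np.argsort(model.centroids[:, 0])
    spacing = np.diff(np.sort(model.centroids[:, 0])).max()
    params = DensityParams(eps=1.1 * spacing, min_pts=3)
    selected, stats = reduce_class(SEGMENT, 10, params, "nearest_member", seed=0)
    assert stats.n_border == 2 and stats.n_core == 8 and stats.n_noise == 0
    assert stats.n_selected == len(selected) == 2
    # the naive count on the 10 centroids says exactly the extremes are border
    types = classify_point_types(model.centroids, params)
    assert set(np.flatnonzero(types == "border")) == {order[0], order[-1]}
    # selected points are real rows near the segment ends
    ends = SEGMENT.points[selected, 0]
    assert ends.min() < 1.0 and ends.max() > 8.9


def test_empty_selection_limits_warn():
    model_params_unsat = DensityParams(eps=0.5, min_pts=11)  # min_pts > k
    with pytest.warns(UserWarning, match="empty selection"):
        selected, stats = reduce_class(SEGMENT, 10, model_params_unsat, seed=0)
    assert selected.size == 0 and stats.n_noise == 10
    # eps beyond the centroid-cloud diameter: everything core, nothing border
    with pytest.warns(UserWarning, match="empty selection"):
        selected, stats = reduce_class(
            SEGMENT, 10, DensityParams(eps=100.0, min_pts=3), seed=0
        )
    assert selected.size == 0 and stats.n_core == 10 and stats.n_border == 0


def test_k_larger_than_class_clamps_with_warning():
    tiny = PointSet(np.arange(5.0)[:, None])
    with pytest.warns(UserWarning, match="clamping"):
        selected, stats = reduce_class(
            tiny, 12, DensityParams(eps=1.5, min_pts=2), seed=0
        )
    assert stats.k_class == 5


@pytest.mark.parametrize("policy", POLICIES)
def test_policy_selections_are_original_rows(two_blobs, policy):
    spec = ReductionSpec(
        per_class_k={0: 20, 1: 20},
        default_density=DensityParams(eps=0.9, min_pts=4),
        policy=policy,
        seed=0,
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        result = reduce_dataset(two_blobs, spec)
    sel = result.selected_indices
    assert np.array_equal(sel, np.unique(sel))  # sorted, unique
    assert sel.size == 0 or (sel.min() >= 0 and sel.max() < two_blobs.n)
    # Eq.-style ratio is an exact recount
    assert result.reduction_ratio == sel.size / two_blobs.n
    # class purity: per-class counts partition the selection
    per_class = {
        c: (two_blobs.labels[sel] == c).sum() for c in (0, 1)
    }
    assert sum(per_class.values()) == sel.size
    for c, stats in result.per_class_stats.items():
        assert stats.n_selected == per_class[c]
        assert stats.n_core + stats.n_border + stats.n_noise == stats.k_class


def test_nearest_member_subset_of_all_members(two_blobs):
    def run(policy):
        spec = ReductionSpec(
            per_class_k={0: 30, 1: 30},
            default_density=DensityParams(eps=0.7, min_pts=3),
            policy=policy,
            seed=0,
        )
        return set(reduce_dataset(two_blobs, spec).selected_indices)

    near, all_m = run("nearest_member"), run("all_members")
    assert len(near) <= len(all_m)
    assert near <= all_m


def test_selected_points_concentrate_on_class_periphery(moons):
    spec = ReductionSpec(
        per_class_k={0: 80, 1: 80},
        default_density=DensityParams(eps=0.15, min_pts=3),
        policy="all_members",
        seed=0,
    )
    result = reduce_dataset(moons, spec)
    sel = result.selected_indices
    for c in (0, 1):
        cls_rows = np.flatnonzero(moons.labels == c)
        center = moons.points[cls_rows].mean(axis=0)
        all_d = np.linalg.norm(moons.points[cls_rows] - center, axis=1).mean()
        sel_rows = sel[moons.labels[sel] == c]
        sel_d = np.linalg.norm(moons.points[sel_rows] - center, axis=1).mean()
        assert sel_d > all_d


def test_alpha_entry_point_sets_per_class_k(two_blobs):
    spec = ReductionSpec(
        alpha=0.02,
        default_density=DensityParams(eps=0.9, min_pts=4),
        seed=0,
    )
    result = reduce_dataset(two_blobs, spec)
    for stats in result.per_class_stats.values():
        assert stats.k_class == int(np.ceil(0.02 * stats.n_class))


def test_reduce_dataset_determinism_and_missing_labels(two_blobs):
    spec = ReductionSpec(
        per_class_k={0: 20, 1: 20},
        default_density=DensityParams(eps=0.9, min_pts=4),
        seed=5,
    )
    a = reduce_dataset(two_blobs, spec)
    b = reduce_dataset(two_blobs, spec)
    assert np.array_equal(a.selected_indices, b.selected_indices)
    with pytest.raises(ValueError):
        reduce_dataset(PointSet(two_blobs.points), spec)


def test_spec_validation():
    good = dict(default_density=DensityParams(1.0, 3))
    with pytest.raises(ValueError):
        ReductionSpec(**good)  # neither k nor alpha
    with pytest.raises(ValueError):
        ReductionSpec(alpha=0.1, per_class_k={0: 5}, **good)
    with pytest.raises(ValueError):
        ReductionSpec(alpha=1.5, **good)
    with pytest.raises(ValueError):
        ReductionSpec(alpha=0.1, policy="bogus", **good)
    with pytest.raises(ValueError):
        ReductionSpec(alpha=0.1, embed_method="pca", **good)  # no dims
    spec = ReductionSpec(alpha=0.1, **good)
    assert spec.density_for(3) == DensityParams(1.0, 3)  # default applies
    spec2 = ReductionSpec(per_class_k={0: 5})
    with pytest.raises(ValueError):
        spec2.density_for(0)
    with pytest.raises(ValueError):
        spec2.k_for(1, 10)


# ---------------------------------------------------------------- embedding


def test_pca_embed_recovers_planted_subspace():
    rng = np.random.default_rng(0)
    basis = np.linalg.qr(rng.normal(size=(6, 2)))[0]
    low = rng.normal(size=(300, 2)) * [4.0, 1.5]
    X = PointSet(low @ basis.T)
    emb = embed(X, "pca", 2, seed=0)
    assert emb.points.shape == (300, 2)
    # exact 2-D subspace: pairwise distances are preserved by PCA to 2 dims
    from scipy.spatial.distance import pdist

    assert np.allclose(pdist(emb.points), pdist(X.points), atol=1e-8)
    # first component variance equals the top sample-covariance eigenvalue
    eigvals = np.linalg.eigvalsh(np.cov(X.points, rowvar=False))
    assert np.var(emb.points[:, 0], ddof=1) == pytest.approx(eigvals[-1])


def test_embed_row_order_and_errors():
    rng = np.random.default_rng(1)
    X = PointSet(rng.normal(size=(50, 4)), labels=np.arange(50) % 2)
    emb = embed(X, "pca", 2, seed=0)
    assert emb.n == 50 and emb.d == 2
    assert np.array_equal(emb.labels, X.labels)
    with pytest.raises(ValueError):
        embed(X, "pca", 4, seed=0)
    with pytest.raises(ValueError):
        embed(X, "isomap", 2, seed=0)


# ---------------------------------------------------------------- tuning


def test_tuning_single_cell_and_exhaustive_oracle(mixture):
    model = kmeans_fit(mixture.points, 50, seed=0)
    from kmdbscan import dbscan_fit, majority_centroid_labels, adjusted_rand_index

    cl = majority_centroid_labels(model, mixture.labels)
    centroids = PointSet(model.centroids, cl)
    only = tune_density_params(centroids, [1.0], [3])
    assert (only.eps, only.min_pts) == (1.0, 3)

    eps_grid = [0.8, 1.1, 1.4, 1.7]
    mp_grid = [2, 4]
    best = tune_density_params(centroids, eps_grid, mp_grid)
    scores = {
        (e, m): adjusted_rand_index(
            dbscan_fit(model.centroids, DensityParams(e, m)).labels, cl
        )
        for e in eps_grid
        for m in mp_grid
    }
    assert scores[(best.eps, best.min_pts)] == max(scores.values())


def test_tuning_tie_break_and_border_target():
    # four collinear centroids, two labels perfectly separated at eps < 2
    pts = np.array([[0.0], [1.0], [10.0], [11.0]])
    centroids = PointSet(pts, [0, 0, 1, 1])
    best = tune_density_params(centroids, [1.5, 1.6], [1, 2])
    assert (best.eps, best.min_pts) == (1.5, 1)  # ties -> smaller eps, min_pts
    target = tune_density_params(
        centroids, [1.5], [3], objective="border_fraction_target", target=0.0
    )
    assert target.eps == 1.5
    with pytest.raises(ValueError):
        tune_density_params(centroids, [], [3])
    with pytest.raises(ValueError):
        tune_density_params(PointSet(pts), [1.0], [3])  # no labels
    with pytest.raises(ValueError):
        tune_density_params(centroids, [1.0], [3], objective="border_fraction_target")
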