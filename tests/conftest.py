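"""Shared fixtures and independent brute-force oracles.

The oracles here deliberately avoid the package's own code paths: the naive
DBSCAN works by explicit O(m^2) loops and breadth-first search, the ARI
oracle counts item pairs directly, and the k-means oracle enumerates every
partition.  They exist to validate the real implementations on small
instances.
"""

from __future__ import annotations

from itertools import combinations, product

import numpy as np
import pytest

from kmdbscan.datasets import (
    PointSet,
    make_concentric_rings,
    make_gaussian_mixture,
    make_two_moons,
)

# ---------------------------------------------------------------- oracles


def naive_dbscan(points: np.ndarray, eps: float, min_pts: int):
    """Reference DBSCAN: explicit loops, BFS over the core graph.

    Returns (labels, types) with the same conventions as the package:
    clusters numbered by lowest core index, borders attached to their
    lowest-index core neighbour, noise -1.
    """
    points = np.asarray(points, dtype=float)
    m = len(points)
    dist = np.zeros((m, m))
    for i in range(m):
        for j in range(m):
            dist[i, j] = np.sqrt(np.sum((points[i] - points[j]) ** 2))
    neighbors = [set(np.flatnonzero(dist[i] <= eps)) for i in range(m)]
    core = [len(neighbors[i]) >= min_pts for i in range(m)]

    labels = [-1] * m
    types = ["noise"] * m
    next_label = 0
    for i in range(m):
        if core[i] and labels[i] == -1:
            # BFS through core points reachable via eps-edges
            queue, seen = [i], {i}
            while queue:
                u = queue.pop(0)
                labels[u] = next_label
                types[u] = "core"
                for v in sorted(neighbors[u]):
                    if core[v] and v not in seen:
                        seen.add(v)
                        queue.append(v)
            next_label += 1
    for i in range(m):
        if not core[i]:
            core_nb = sorted(v for v in neighbors[i] if core[v])
            if core_nb:
                labels[i] = labels[core_nb[0]]
                types[i] = "border"
    return np.array(labels), np.array(types)


def pair_counting_ari(a, b) -> float:
    """ARI by direct enumeration of item pairs (same/different in each)."""
    a, b = np.asarray(a), np.asarray(b)
    n = len(a)
    together_a = together_b = together_both = 0
    for i, j in combinations(range(n), 2):
        sa, sb = a[i] == a[j], b[i] == b[j]
        together_a += sa
        together_b += sb
        together_both += sa and sb
    total = n * (n - 1) // 2
    expected = together_a * together_b / total
    max_index = (together_a + together_b) / 2
    if max_index == expected:
        return 1.0
    return (together_both - expected) / (max_index - expected)


def best_kmeans_partition(points: np.ndarray, k: int):
    """Globally optimal k-means by enumerating every assignment (tiny n only)."""
    points = np.asarray(points, dtype=float)
    if points.ndim == 1:
        points = points[:, None]
    n = len(points)
    best = (np.inf, None, None)
    for assign in product(range(k), repeat=n):
        assign = np.array(assign)
        if len(set(assign)) < k:
            continue
        centers = np.array([points[assign == j].mean(axis=0) for j in range(k)])
        inertia = float(np.sum((points - centers[assign]) ** 2))
        if inertia < best[0]:
            best = (inertia, assign, centers)
    return best


# ---------------------------------------------------------------- fixtures


@pytest.fixture(scope="session")
def moons():
    return make_two_moons(3000, 0.1, seed=0)


@pytest.fixture(scope="session")
def rings():
    return make_concentric_rings(4600, seed=0)


@pytest.fixture(scope="session")
def mixture():
    return make_gaussian_mixture(1500, seed=0)


@pytest.fixture(scope="session")
def two_blobs():
    """Two well-separated isotropic Gaussian blobs with class labels."""
    rng = np.random.default_rng(0)
    pts = np.vstack(
        [rng.normal((0, 0), 1, (1000, 2)), rng.normal((5, 0), 1, (1000, 2))]
    )
    return PointSet(pts, np.repeat([0, 1], 1000))


def random_instance(rng: np.random.Generator):
    """A small clumpy point set for oracle-equivalence sweeps."""
    m = int(rng.integers(5, 61))
    d = int(rng.integers(1, 4))
    n_clumps = int(rng.integers(1, 4))
    centers = rng.uniform(-5, 5, size=(n_clumps, d))
    pts = centers[rng.integers(n_clumps, size=m)] + rng.normal(0, 0.6, size=(m, d))
    eps = float(rng.uniform(0.3, 1.5))
    min_pts = int(rng.integers(1, 6))
    return pts, eps, min_pts
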