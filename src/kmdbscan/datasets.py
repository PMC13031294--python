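"""Seeded synthetic benchmark generators.

Three desk-scale geometries exercise the clusterer and the reduction
pipeline: two interleaved half-moons (non-convex, interleaved clusters),
concentric rings (non-overlapping, non-linearly-separable clusters), and a
Gaussian mixture with partially overlapping components.  Every generator
returns a :class:`PointSet` carrying ground-truth labels so adjusted Rand
index can be evaluated downstream, and all randomness flows through a single
``numpy.random.Generator`` derived from the explicit ``seed`` argument.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "PointSet",
    "make_two_moons",
    "make_concentric_rings",
    "make_gaussian_mixture",
]


@dataclass
class PointSet:
    """An ``n x d`` matrix of finite points with optional integer labels.

    Row identity is positional: row ``i`` keeps the id ``i`` through every
    operation in this package, so selections can always be mapped back to the
    original table.
    """

    points: np.ndarray
    labels: np.ndarray | None = field(default=None)

    def __post_init__(self) -> None:
        self.points = np.asarray(self.points, dtype=float)
        if self.points.ndim != 2:
            raise ValueError("points must be a 2-D array (n x d)")
        if self.points.shape[0] < 1 or self.points.shape[1] < 1:
            raise ValueError("need n >= 1 points and d >= 1 features")
        if not np.all(np.isfinite(self.points)):
            raise ValueError("points must be finite")
        if self.labels is not None:
            self.labels = np.asarray(self.labels, dtype=int)
            if self.labels.shape != (self.points.shape[0],):
                raise ValueError(
                    f"labels must have length n={self.points.shape[0]}, "
                    f"got shape {self.labels.shape}"
                )

    @property
    def n(self) -> int:
        return self.points.shape[0]

    @property
    def d(self) -> int:
        return self.points.shape[1]

    def subset(self, idx: np.ndarray) -> "PointSet":
        """Row subset keeping label alignment; ``idx`` are row positions."""
        idx = np.asarray(idx, dtype=int)
        labels = None if self.labels is None else self.labels[idx]
        return PointSet(self.points[idx], labels)


def _split_counts(n: int, weights: np.ndarray) -> np.ndarray:
    """Largest-remainder apportionment of n into len(weights) integer counts."""
    exact = n * weights
    counts = np.floor(exact).astype(int)
    remainder = exact - counts
    short = n - counts.sum()
    # hand the leftover units to the largest fractional parts (stable order)
    for i in np.argsort(-remainder, kind="stable")[:short]:
        counts[i] += 1
    return counts


def make_two_moons(n: int = 3000, noise_sd: float = 0.1, seed: int = 0) -> PointSet:
    """Two interleaved unit-radius half-circle arcs with Gaussian noise.

    The first moon is the upper half of the unit circle centred at the
    origin; the second is the lower half reflected and shifted by
    ``(1, 0.5)`` so the arcs interleave.  ``n`` points are split as evenly
    as possible between the arcs and isotropic Gaussian noise of standard
    deviation ``noise_sd`` is added to both coordinates.
    """
    if n < 2:
        raise ValueError(f"need n >= 2, got {n}")
    if noise_sd < 0:
        raise ValueError(f"noise_sd must be non-negative, got {noise_sd}")
    rng = np.random.default_rng(seed)
    n0 = n // 2 + n % 2
    n1 = n - n0
    t0 = rng.uniform(0.0, np.pi, size=n0)
    t1 = rng.uniform(0.0, np.pi, size=n1)
    outer = np.column_stack([np.cos(t0), np.sin(t0)])
    inner = np.column_stack([1.0 - np.cos(t1), 0.5 - np.sin(t1)])
    pts = np.vstack([outer, inner])
    if noise_sd > 0:
        pts = pts + rng.normal(0.0, noise_sd, size=pts.shape)
    labels = np.concatenate([np.zeros(n0, dtype=int), np.ones(n1, dtype=int)])
    return PointSet(pts, labels)


def make_concentric_rings(
    n: int = 4600,
    radii: tuple[float, ...] = (1.0, 3.0),
    noise_sd: float = 0.05,
    seed: int = 0,
) -> PointSet:
    """Concentric rings: uniform angles, radial Gaussian jitter, one label per ring.

    Points are apportioned across rings proportionally to ring radius
    (approximating uniform linear density along each circle).  A radial gap
    below ``4 * noise_sd`` risks the rings' noise tails touching, which
    triggers a warning.
    """
    radii_arr = np.asarray(sorted(set(float(r) for r in radii)), dtype=float)
    if radii_arr.size < 2:
        raise ValueError("need at least 2 distinct radii")
    if np.any(radii_arr <= 0):
        raise ValueError("radii must be positive")
    if noise_sd < 0:
        raise ValueError(f"noise_sd must be non-negative, got {noise_sd}")
    min_gap = np.min(np.diff(radii_arr))
    if noise_sd > 0 and min_gap <= 4.0 * noise_sd:
        warnings.warn(
            f"radial gap {min_gap:.3g} <= 4*noise_sd={4 * noise_sd:.3g}: "
            "rings may overlap radially",
            stacklevel=2,
        )
    rng = np.random.default_rng(seed)
    weights = radii_arr / radii_arr.sum()
    counts = _split_counts(n, weights)
    chunks, labels = [], []
    for ring, (r, n_r) in enumerate(zip(radii_arr, counts)):
        theta = rng.uniform(0.0, 2.0 * np.pi, size=n_r)
        rho = r + (rng.normal(0.0, noise_sd, size=n_r) if noise_sd > 0 else 0.0)
        chunks.append(np.column_stack([rho * np.cos(theta), rho * np.sin(theta)]))
        labels.append(np.full(n_r, ring, dtype=int))
    return PointSet(np.vstack(chunks), np.concatenate(labels))


_DEFAULT_MIXTURE_MEANS = ((0.0, 0.0), (5.5, 0.0), (2.75, 4.7631))


def make_gaussian_mixture(
    n: int = 1500,
    means: tuple = _DEFAULT_MIXTURE_MEANS,
    sds: tuple[float, ...] = (1.0, 1.0, 1.0),
    weights: tuple[float, ...] | None = None,
    seed: int = 0,
) -> PointSet:
    """Isotropic Gaussian mixture with component index as the label.

    Defaults give three components on an equilateral triangle with means
    5.5 standard deviations apart, so the tails overlap partially (a small
    fraction of points falls between components) — the hardest of the three
    synthetic regimes.  Per-component counts are the largest-remainder
    rounding of ``n * w_i`` so they always sum to ``n``.
    """
    means_arr = np.atleast_2d(np.asarray(means, dtype=float))
    sds_arr = np.asarray(sds, dtype=float)
    m = means_arr.shape[0]
    if sds_arr.shape != (m,):
        raise ValueError(f"means and sds lengths differ: {m} vs {sds_arr.shape}")
    if np.any(sds_arr <= 0):
        raise ValueError("sds must be positive")
    if weights is None:
        w = np.full(m, 1.0 / m)
    else:
        w = np.asarray(weights, dtype=float)
        if w.shape != (m,):
            raise ValueError(f"weights length {w.shape} != number of components {m}")
        if np.any(w < 0) or not np.isclose(w.sum(), 1.0):
            raise ValueError("weights must be non-negative and sum to 1")
    rng = np.random.default_rng(seed)
    counts = _split_counts(n, w)
    chunks, labels = [], []
    for i, (mu, sd, n_i) in enumerate(zip(means_arr, sds_arr, counts)):
        chunks.append(mu + rng.normal(0.0, sd, size=(n_i, means_arr.shape[1])))
        labels.append(np.full(n_i, i, dtype=int))
    return PointSet(np.vstack(chunks), np.concatenate(labels))
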