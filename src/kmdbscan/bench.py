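"""Benchmark harness.

Reproducible desk-scale experiment protocols: the clustering benchmark
(plain DBSCAN on the full data versus the hybrid, averaged over seeds), the
parameter-sensitivity grid, and the reduction experiment (downstream
classifier trained on the full set versus each reduction policy).

Timing uses a monotonic process clock wrapped around the clustering or
training call only; timing fields are informational and excluded from any
determinism comparison.
"""

from __future__ import annotations

import time
import warnings
from dataclasses import dataclass, field
from statistics import mean, stdev

import numpy as np

from .clustering import (
    DensityParams,
    dbscan_fit,
    km_dbscan,
    kmeans_fit,
    majority_centroid_labels,
    propagate_labels,
)
from .datasets import (
    PointSet,
    make_concentric_rings,
    make_gaussian_mixture,
    make_two_moons,
)
from .io import load_table
from .metrics import adjusted_rand_index
from .reduction import (
    POLICIES,
    ReductionSpec,
    reduce_dataset,
    tune_density_params,
)

__all__ = [
    "BenchConfig",
    "make_dataset",
    "moons_benchmark_config",
    "rings_benchmark_config",
    "run_clustering_benchmark",
    "run_sensitivity_grid",
    "run_reduction_experiment",
]

_SHAPES = {
    "moons": make_two_moons,
    "rings": make_concentric_rings,
    "mixture": make_gaussian_mixture,
}


@dataclass
class BenchConfig:
    """One benchmark run: dataset source, algorithm parameters, seed protocol.

    ``dataset`` is either ``{"shape": "moons"|"rings"|"mixture", ...generator
    kwargs}`` or ``{"path": file, "label_col": name}``.  ``eps``/``min_pts``
    parameterise DBSCAN at the centroid level; ``full_eps``/``full_min_pts``
    parameterise the full-data DBSCAN baseline (defaulting to the centroid
    values when omitted).
    """

    dataset: dict
    k: int = 100
    eps: float = 0.5
    min_pts: int = 3
    full_eps: float | None = None
    full_min_pts: int | None = None
    seeds: list[int] = field(default_factory=lambda: [0, 1, 2, 3, 4])
    tune_eps_grid: list[float] | None = None
    tune_min_pts_grid: list[int] | None = None
    reduction: dict | None = None
    downstream: dict = field(default_factory=lambda: {"name": "svm"})
    test_size: float = 0.25

    def validate(self) -> None:
        if not isinstance(self.dataset, dict):
            raise ValueError("dataset must be a mapping")
        if "shape" in self.dataset:
            if self.dataset["shape"] not in _SHAPES:
                raise ValueError(
                    f"dataset.shape must be one of {sorted(_SHAPES)}, "
                    f"got {self.dataset['shape']!r}"
                )
        elif "path" not in self.dataset:
            raise ValueError("dataset needs either 'shape' or 'path'")
        if self.k < 1:
            raise ValueError(f"k must be >= 1, got {self.k}")
        if self.eps <= 0:
            raise ValueError(f"eps must be positive, got {self.eps}")
        if self.min_pts < 1:
            raise ValueError(f"min_pts must be >= 1, got {self.min_pts}")
        if not self.seeds:
            raise ValueError("need at least one seed")
        if not 0 < self.test_size < 1:
            raise ValueError(f"test_size must lie in (0, 1), got {self.test_size}")
        if (self.tune_eps_grid is None) != (self.tune_min_pts_grid is None):
            raise ValueError("tune_eps_grid and tune_min_pts_grid go together")


def moons_benchmark_config(seeds=None) -> BenchConfig:
    """Stock two-moons protocol: n=3000, noise sd 0.1, k=100, per-seed
    centroid-level grid tuning of (eps, min_pts)."""
    return BenchConfig(
        dataset={"shape": "moons", "n": 3000, "noise_sd": 0.1},
        k=100,
        full_eps=0.1,
        full_min_pts=4,
        seeds=list(seeds) if seeds is not None else [0, 1, 2, 3, 4],
        tune_eps_grid=[round(0.16 + 0.02 * i, 2) for i in range(9)],
        tune_min_pts_grid=[3, 4, 5],
    )


def rings_benchmark_config(seeds=None) -> BenchConfig:
    """Stock concentric-rings protocol: n=4600, radii (1, 3), k=100,
    per-seed centroid-level grid tuning of (eps, min_pts)."""
    return BenchConfig(
        dataset={"shape": "rings", "n": 4600},
        k=100,
        full_eps=0.2,
        full_min_pts=5,
        seeds=list(seeds) if seeds is not None else [0, 1, 2, 3, 4],
        tune_eps_grid=[round(0.3 + 0.1 * i, 2) for i in range(8)],
        tune_min_pts_grid=[3, 4, 5],
    )


def make_dataset(spec: dict, seed: int) -> PointSet:
    """Materialise the dataset a config refers to, for one seed."""
    spec = dict(spec)
    if "path" in spec:
        return load_table(spec["path"], spec.get("label_col"))
    shape = spec.pop("shape")
    spec.pop("seed", None)
    return _SHAPES[shape](seed=seed, **spec)


def _agg(values: list[float]) -> dict:
    return {
        "mean": mean(values),
        "sd": stdev(values) if len(values) > 1 else 0.0,
    }


def run_clustering_benchmark(config: BenchConfig) -> dict:
    """Plain DBSCAN versus the hybrid, one run per seed, aggregated.

    Reports per seed the full-data DBSCAN ARI, the hybrid ARI, both
    runtimes and their ratio; the clustering-level reduction ratio is the
    k/n compression factor.  Aggregates are mean +/- sd over seeds.
    """
    config.validate()
    full_params = DensityParams(
        config.full_eps if config.full_eps is not None else config.eps,
        config.full_min_pts if config.full_min_pts is not None else config.min_pts,
    )
    km_params = DensityParams(config.eps, config.min_pts)

    runs = []
    for seed in config.seeds:
        X = make_dataset(config.dataset, seed)
        if X.labels is None:
            raise ValueError("clustering benchmark requires ground-truth labels")
        t0 = time.perf_counter()
        full = dbscan_fit(X.points, full_params)
        t_full = time.perf_counter() - t0
        if config.tune_eps_grid is not None:
            # per-seed grid tuning at the centroid level against the
            # majority-vote class labels of the centroids
            model = kmeans_fit(X.points, config.k, seed=seed)
            cent_labels = majority_centroid_labels(model, X.labels)
            params_used = tune_density_params(
                PointSet(model.centroids, cent_labels),
                config.tune_eps_grid,
                config.tune_min_pts_grid,
            )
            t0 = time.perf_counter()
            cent_result = dbscan_fit(model.centroids, params_used)
            labels = propagate_labels(model, cent_result.labels)
            t_km = time.perf_counter() - t0
            noise_centroids = int((cent_result.labels == -1).sum())
        else:
            params_used = km_params
            t0 = time.perf_counter()
            outcome = km_dbscan(X.points, config.k, km_params, seed=seed)
            t_km = time.perf_counter() - t0
            labels = outcome.point_labels
            noise_centroids = int((outcome.centroid_result.labels == -1).sum())
        runs.append(
            {
                "seed": seed,
                "n": X.n,
                "eps": params_used.eps,
                "min_pts": params_used.min_pts,
                "ari_dbscan": adjusted_rand_index(full.labels, X.labels),
                "ari_km_dbscan": adjusted_rand_index(labels, X.labels),
                "time_dbscan_s": t_full,
                "time_km_dbscan_s": t_km,
                "speedup": t_full / t_km if t_km > 0 else float("inf"),
                "noise_centroids": noise_centroids,
            }
        )
    report = {
        "protocol": "clustering",
        "params": {
            "k": config.k,
            "eps": km_params.eps,
            "min_pts": km_params.min_pts,
            "full_eps": full_params.eps,
            "full_min_pts": full_params.min_pts,
            "seeds": list(config.seeds),
        },
        "reduction_ratio_kn": config.k / runs[0]["n"],
        "runs": runs,
        "ari_dbscan": _agg([r["ari_dbscan"] for r in runs]),
        "ari_km_dbscan": _agg([r["ari_km_dbscan"] for r in runs]),
        "time_km_dbscan_s": _agg([r["time_km_dbscan_s"] for r in runs]),
    }
    return report


def run_sensitivity_grid(config: BenchConfig, grid: list[dict]) -> list[dict]:
    """Evaluate every (method, eps, min_pts[, k]) cell on the config dataset.

    Each grid entry is ``{"method": "dbscan"|"km_dbscan", "eps": ..,
    "min_pts": .., "k": ..}`` (k ignored for plain DBSCAN); one result row
    per cell with the ARI and runtime.  The dataset is generated once with
    the first configured seed, so the table isolates parameter effects.
    """
    config.validate()
    if not grid:
        raise ValueError("grid must be non-empty")
    seed = config.seeds[0]
    X = make_dataset(config.dataset, seed)
    if X.labels is None:
        raise ValueError("sensitivity grid requires ground-truth labels")
    rows = []
    for cell in grid:
        method = cell.get("method", "km_dbscan")
        params = DensityParams(cell["eps"], cell["min_pts"])
        t0 = time.perf_counter()
        if method == "dbscan":
            labels = dbscan_fit(X.points, params).labels
            k_used = None
        elif method == "km_dbscan":
            k_used = cell.get("k", config.k)
            labels = km_dbscan(X.points, k_used, params, seed=seed).point_labels
        else:
            raise ValueError(f"unknown method {method!r}")
        elapsed = time.perf_counter() - t0
        rows.append(
            {
                "method": method,
                "eps": params.eps,
                "min_pts": params.min_pts,
                "k": k_used,
                "ari": adjusted_rand_index(labels, X.labels),
                "time_s": elapsed,
            }
        )
    return rows


def _make_classifier(downstream: dict, seed: int):
    name = downstream.get("name", "svm")
    params = {k: v for k, v in downstream.items() if k != "name"}
    if name == "svm":
        from sklearn.svm import SVC

        return SVC(random_state=seed, **params)
    if name == "mlp":
        from sklearn.neural_network import MLPClassifier

        return MLPClassifier(random_state=seed, **params)
    raise ValueError(f"unknown downstream classifier {name!r}")


def _fit_score(clf, X_train, y_train, X_test, y_test) -> tuple[float, float, int | None]:
    t0 = time.perf_counter()
    clf.fit(X_train, y_train)
    elapsed = time.perf_counter() - t0
    acc = float(clf.score(X_test, y_test))
    n_sv = int(clf.n_support_.sum()) if hasattr(clf, "n_support_") else None
    return acc, elapsed, n_sv


def _reduction_spec(raw: dict, policy: str, seed: int) -> ReductionSpec:
    """Build a ReductionSpec from a plain config mapping.

    Density parameters may appear flat (``eps``/``min_pts`` for every class)
    or per class under ``per_class_density`` as ``{label: {eps, min_pts}}``.
    """
    raw = dict(raw)
    eps = raw.pop("eps", None)
    min_pts = raw.pop("min_pts", None)
    if eps is not None:
        raw["default_density"] = DensityParams(eps, min_pts if min_pts else 3)
    pcd = raw.get("per_class_density")
    if pcd is not None:
        raw["per_class_density"] = {
            int(c): p if isinstance(p, DensityParams)
            else DensityParams(p["eps"], p["min_pts"])
            for c, p in pcd.items()
        }
    if "per_class_k" in raw and raw["per_class_k"] is not None:
        raw["per_class_k"] = {int(c): int(v) for c, v in raw["per_class_k"].items()}
    return ReductionSpec(**{**raw, "policy": policy, "seed": seed})


def run_reduction_experiment(config: BenchConfig, policies=None) -> dict:
    """Downstream accuracy of full-data training versus each reduction policy.

    Splits the dataset, trains the configured classifier on the full
    training rows, then for each policy reduces the training rows and
    retrains, reporting accuracy, accuracy delta, reduction ratio,
    training-time speedup and (for the SVM adapter) support-vector counts.
    A policy whose selection comes back empty is recorded as failed and the
    run continues.
    """
    from sklearn.model_selection import train_test_split

    config.validate()
    if config.reduction is None:
        raise ValueError("config.reduction is required for reduction experiments")
    if policies is None:
        policies = ["nearest_member", "kmeans_only", "dbscan_only"]
    for p in policies:
        if p not in POLICIES:
            raise ValueError(f"unknown policy {p!r}")

    seed = config.seeds[0]
    X = make_dataset(config.dataset, seed)
    if X.labels is None:
        raise ValueError("reduction experiment requires class labels")
    idx_train, idx_test = train_test_split(
        np.arange(X.n),
        test_size=config.test_size,
        random_state=seed,
        stratify=X.labels,
    )
    train, test = X.subset(idx_train), X.subset(idx_test)

    acc_full, t_full, sv_full = _fit_score(
        _make_classifier(config.downstream, seed),
        train.points, train.labels, test.points, test.labels,
    )
    report = {
        "protocol": "reduction",
        "n_train": train.n,
        "n_test": test.n,
        "full": {"accuracy": acc_full, "train_time_s": t_full, "n_sv": sv_full},
        "policies": {},
    }
    for policy in policies:
        spec = _reduction_spec(config.reduction, policy, seed)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            result = reduce_dataset(train, spec)
        if result.selected_indices.size == 0:
            report["policies"][policy] = {"failed": "empty selection"}
            continue
        red = train.subset(result.selected_indices)
        if np.unique(red.labels).size < 2:
            report["policies"][policy] = {"failed": "single-class selection"}
            continue
        acc, t_red, sv_red = _fit_score(
            _make_classifier(config.downstream, seed),
            red.points, red.labels, test.points, test.labels,
        )
        report["policies"][policy] = {
            "accuracy": acc,
            "accuracy_delta": acc - acc_full,
            "reduction_ratio": result.reduction_ratio,
            "train_time_s": t_red,
            "speedup": t_full / t_red if t_red > 0 else float("inf"),
            "n_sv": sv_red,
            "per_class": result.stats_dict(),
        }
    return report
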