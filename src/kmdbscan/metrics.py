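"""Evaluation metrics as pure functions.

Accuracy, adjusted Rand index (chance-corrected partition agreement via the
contingency table), reduction ratio N'/N, speedup T_original/T_reduced,
support-vector reduction ratio, and the carbon-emission product
energy (kWh) x intensity (gCO2/kWh).  The ARI here is an independent
implementation; the test suite cross-checks it against both a brute-force
pair-counting oracle and scikit-learn.

Noise convention: a clustering label of -1 is treated as one extra ordinary
cluster by default; pass ``drop_noise=True`` to exclude those rows before
computing agreement.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict
import json

import numpy as np

__all__ = [
    "MetricReport",
    "accuracy",
    "adjusted_rand_index",
    "reduction_ratio",
    "speedup",
    "sv_reduction_ratio",
    "carbon_emissions",
]


def accuracy(tp: int, tn: int, fp: int, fn: int) -> float:
    """(TP + TN) / (TP + TN + FP + FN)."""
    counts = (tp, tn, fp, fn)
    if any(c < 0 for c in counts):
        raise ValueError("confusion counts must be non-negative")
    total = sum(counts)
    if total < 1:
        raise ValueError("confusion counts are all zero")
    return (tp + tn) / total


def adjusted_rand_index(a, b, drop_noise: bool = False) -> float:
    """Chance-corrected agreement between two labelings of the same items.

    Computed from the contingency table n_ij with margins a_i, b_j:
    (sum C(n_ij,2) - E) / (mean of margin pair sums - E), where
    E = sum C(a_i,2) * sum C(b_j,2) / C(n,2).  Invariant under relabeling of
    either argument and symmetric; 1 for identical partitions, about 0 for
    independent ones.
    """
    a = np.asarray(a).ravel()
    b = np.asarray(b).ravel()
    if a.shape != b.shape:
        raise ValueError(f"label vectors differ in length: {a.size} vs {b.size}")
    if a.size < 2:
        raise ValueError("need at least 2 items")
    if drop_noise:
        keep = (a != -1) & (b != -1)
        a, b = a[keep], b[keep]
        if a.size < 2:
            raise ValueError("fewer than 2 items remain after dropping noise")
    n = a.size
    _, ai_inv = np.unique(a, return_inverse=True)
    _, bj_inv = np.unique(b, return_inverse=True)
    table = np.zeros((ai_inv.max() + 1, bj_inv.max() + 1), dtype=np.int64)
    np.add.at(table, (ai_inv, bj_inv), 1)

    def comb2(x):
        return x * (x - 1) // 2

    sum_ij = comb2(table).sum()
    sum_a = comb2(table.sum(axis=1)).sum()
    sum_b = comb2(table.sum(axis=0)).sum()
    total = comb2(n)
    expected = sum_a * sum_b / total
    max_index = (sum_a + sum_b) / 2.0
    if max_index == expected:  # both partitions trivial -> define as 1
        return 1.0
    return float((sum_ij - expected) / (max_index - expected))


def reduction_ratio(n_reduced: int, n_original: int) -> float:
    """Fraction of rows retained after reduction, N'/N."""
    if n_original < 1:
        raise ValueError("original size must be >= 1")
    if not 0 <= n_reduced <= n_original:
        raise ValueError(
            f"reduced size must lie in [0, {n_original}], got {n_reduced}"
        )
    return n_reduced / n_original

def speedup(t_original: float, t_reduced: float) -> float:
    """T_original / T_reduced; both in seconds, both strictly positive."""
    if t_original <= 0 or t_reduced <= 0:
        raise ValueError("times must be positive")
    return t_original / t_reduced


def sv_reduction_ratio(svs_reduced: int, svs_full: int) -> float:
    """Support vectors of the reduced-data model over those of the full model."""
    if svs_full < 1 or svs_reduced < 1:
        raise ValueError("support-vector counts must be >= 1")
    return svs_reduced / svs_full


def carbon_emissions(energy_kwh: float, intensity_g_per_kwh: float) -> float:
    """Grams CO2-eq = energy consumed (kWh) x carbon intensity (gCO2/kWh)."""
    if energy_kwh < 0 or intensity_g_per_kwh < 0:
        raise ValueError("energy and intensity must be non-negative")
    return energy_kwh * intensity_g_per_kwh


@dataclass
class MetricReport:
    """Bundle of evaluation numbers plus the raw inputs they came from.

    Ratios are held at full precision; table-style rounding happens only in
    :meth:`to_json`.
    """

    accuracy: float | None = None
    ari: float | None = None
    reduction_ratio: float | None = None
    speedup: float | None = None
    sv_reduction_ratio: float | None = None
    carbon_g: float | None = None
    inputs: dict | None = None

    def to_dict(self) -> dict:
        return {k: v for k, v in asdict(self).items() if v is not None}

    def to_json(self, ndigits: int = 4) -> str:
        out = {}
        for k, v in self.to_dict().items():
            out[k] = round(v, ndigits) if isinstance(v, float) else v
        return json.dumps(out, indent=2)
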