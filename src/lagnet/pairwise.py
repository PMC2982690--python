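"""Pairwise relevance metrics: correlation, mutual information, associativity.

Every unordered gene pair is scored on two orthogonal axes — a linear one
(Pearson product-moment correlation with its two-sided t significance) and
a nonlinear one (binned mutual information in bits).  The associativity
measure (AM) projects the weighted pair (MI, |r|) onto a 2-D plane and takes
the Euclidean magnitude as a single regulatory-strength score; the angle
alpha records how the evidence splits between the two axes.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from itertools import combinations
from typing import Iterable, Sequence

import numpy as np
from scipy import stats as _sps

from .io import ExpressionProfile

__all__ = [
    "PairStats",
    "MetricCentroids",
    "pearson_with_pvalue",
    "mutual_information",
    "associativity_measure",
    "all_pair_stats",
    "centroids",
    "default_bins",
    "stats_to_frame",
]


@dataclass(frozen=True)
class PairStats:
    """Relevance metrics for one unordered gene pair (gene_a < gene_b)."""

    gene_a: str
    gene_b: str
    mi_bits: float
    pearson_r: float
    p_value: float
    am: float
    alpha: float

    def __post_init__(self) -> None:
        if not self.gene_a < self.gene_b:
            raise ValueError("gene_a must sort lexicographically before gene_b")
        if self.mi_bits < 0:
            raise ValueError("mutual information cannot be negative")
        if abs(self.pearson_r) > 1 + 1e-12:
            raise ValueError("|pearson_r| must be <= 1")
        if not 0.0 <= self.p_value <= 1.0:
            raise ValueError("p_value must lie in [0, 1]")

    @property
    def pair(self) -> tuple[str, str]:
        return (self.gene_a, self.gene_b)


@dataclass(frozen=True)
class MetricCentroids:
    """Means of MI and |r| over all pair candidates; the PGHC starting point."""

    mi_centroid: float
    cor_centroid: float

    def __post_init__(self) -> None:
        if not (math.isfinite(self.mi_centroid) and math.isfinite(self.cor_centroid)):
            raise ValueError("centroids must be finite")
        if self.mi_centroid < 0 or self.cor_centroid < 0:
            raise ValueError("centroids must be non-negative")


def pearson_with_pvalue(x: Sequence[float], y: Sequence[float]) -> tuple[float, float]:
    """Pearson r = cov(x, y) / (sigma_x sigma_y) with its two-sided p-value.

    The significance is the exact t transform of r with n - 2 degrees of
    freedom under the null of no correlation.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-D series of equal length")
    if x.size < 3:
        raise ValueError("need at least 3 samples for a correlation p-value")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("correlation is undefined for a constant series")
    res = _sps.pearsonr(x, y)
    return float(res.statistic), float(res.pvalue)


def mutual_information(
    x: Sequence[float],
    y: Sequence[float],
    bins: int,
    base: float = 2.0,
) -> float:
    """Mutual information of two series over an equal-width joint histogram.

    I = sum_{cells} p(x,y) * log_base[ p(x,y) / (p1(x) p2(y)) ], with empty
    cells contributing zero.  Base 2 gives bits.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-D series of equal length")
    if x.size < 3:
        raise ValueError("need at least 3 samples")
    if bins < 2:
        raise ValueError("bins must be >= 2")
    joint, _, _ = np.histogram2d(x, y, bins=bins)
    n = joint.sum()
    pxy = joint / n
    px = pxy.sum(axis=1)
    py = pxy.sum(axis=0)
    nz = pxy > 0
    outer = np.outer(px, py)
    mi = float(np.sum(pxy[nz] * np.log(pxy[nz] / outer[nz]))) / math.log(base)
    # clip the tiny negative round-off the cell sum can produce
    return max(mi, 0.0)


def associativity_measure(
    mi: float, cor: float, w1: float, w2: float
) -> tuple[float, float]:
    """Project weighted (MI, |r|) onto orthogonal axes; return (am, alpha).

    am is the Euclidean magnitude sqrt((w1 MI)^2 + (w2 |r|)^2); alpha is the
    angle of the vector from the MI axis, in [0, pi/2].  The zero vector has
    alpha = 0 by convention.
    """
    if mi < 0:
        raise ValueError("mutual information cannot be negative")
    if w1 <= 0 or w2 <= 0:
        raise ValueError("weights must be positive")
    u = w1 * mi
    v = w2 * abs(cor)
    am = math.hypot(u, v)
    alpha = 0.0 if am == 0 else math.atan2(v, u)
    return am, alpha


def default_bins(n_samples: int) -> int:
    """Default joint-histogram bin count: floor(sqrt(T)), at least 2.

    A 2-D histogram has bins^2 cells; capping that near the sample count T
    keeps the finite-sample bias of the MI estimate (about (bins-1)^2 /
    (2 T ln 2) bits) below the dependence signal a short series can carry.
    One-dimensional rules such as Sturges (ceil(1 + log2 T), 5 at T = 14)
    put more cells than samples in the joint histogram and drown the
    estimate in bias; they remain available through the ``bins`` argument.
    """
    if n_samples < 2:
        raise ValueError("need at least two samples")
    return max(2, math.isqrt(n_samples))


def all_pair_stats(
    profile: ExpressionProfile,
    bins: int | None = None,
    weights: tuple[float, float] | str = "centroid",
) -> list[PairStats]:
    """Score all n(n-1)/2 unordered gene pairs of a profile.

    With ``weights="centroid"`` the AM weights are 1/centroid per axis, so
    both axes have mean 1 across the pair universe before projection.
    """
    if profile.n_genes < 2:
        raise ValueError("pairwise analysis needs at least two genes")
    if bins is None:
        bins = default_bins(profile.n_time_points)

    raw: list[tuple[str, str, float, float, float]] = []
    for ga, gb in combinations(sorted(profile.gene_ids), 2):
        xa = profile.series(ga)
        xb = profile.series(gb)
        r, p = pearson_with_pvalue(xa, xb)
        mi = mutual_information(xa, xb, bins=bins)
        raw.append((ga, gb, mi, r, p))

    if weights == "centroid":
        mi_c = float(np.mean([t[2] for t in raw]))
        cor_c = float(np.mean([abs(t[3]) for t in raw]))
        if mi_c == 0 or cor_c == 0:
            raise ValueError("centroid weights undefined: a metric centroid is zero")
        w1, w2 = 1.0 / mi_c, 1.0 / cor_c
    else:
        w1, w2 = weights
        if w1 <= 0 or w2 <= 0:
            raise ValueError("weights must be positive")

    out = []
    for ga, gb, mi, r, p in raw:
        am, alpha = associativity_measure(mi, r, w1, w2)
        out.append(PairStats(ga, gb, mi, r, p, am, alpha))
    return out


def centroids(stats: Iterable[PairStats]) -> MetricCentroids:
    """Arithmetic means of MI and |r| across a pair collection."""
    stats = list(stats)
    if not stats:
        raise ValueError("cannot take centroids of an empty collection")
    return MetricCentroids(
        float(np.mean([s.mi_bits for s in stats])),
        float(np.mean([abs(s.pearson_r) for s in stats])),
    )


def stats_to_frame(stats: Iterable[PairStats]):
    """Pair statistics as a DataFrame (the exportable pair-stats table)."""
    import pandas as pd

    return pd.DataFrame(
        [
            {
                "gene_a": s.gene_a,
                "gene_b": s.gene_b,
                "mi_bits": s.mi_bits,
                "pearson_r": s.pearson_r,
                "p_value": s.p_value,
                "am": s.am,
                "alpha": s.alpha,
            }
            for s in stats
        ]
    )
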