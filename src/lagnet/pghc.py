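"""Pairwise Gene Hierarchy Criterion: threshold partitioning of pair candidates.

Pairs are split three ways by (MI, |r|, p):

* APGs (authentic): MI and |r| clear their thresholds AND p is significant.
* QPGs (questionable): exactly one of the two evidence routes holds —
  MI clears but the correlation+significance pair does not, or vice versa.
* UPGs (unauthentic): neither route holds.

The supervised loop starts both thresholds at the metric centroids and walks
them down (undersized APGs, refilling from the QPG pool) or up (oversized)
in fixed increments until the APG fraction lands in a target band.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

from .pairwise import PairStats

__all__ = [
    "Thresholds",
    "Partition",
    "classify_once",
    "pghc_iterate",
    "rank_qpgs",
    "adapt_p_threshold",
    "P_LADDER",
    "DEFAULT_BAND",
]

#: p-value threshold ladder used when a dataset is significance-starved
P_LADDER = (0.05, 0.1, 0.2, 0.3, 0.4, 0.5, 0.6, 0.7, 0.8, 0.9, 1.0)

#: default target APG fraction band
DEFAULT_BAND = (0.30, 0.45)


@dataclass(frozen=True)
class Thresholds:
    """PGHC thresholds: MI (bits), |correlation|, p-value, and increments."""

    mi_th: float
    cc_th: float
    p_th: float = 0.05
    delta_mi: float = 0.005
    delta_cc: float = 0.005

    def __post_init__(self) -> None:
        if self.mi_th < 0:
            raise ValueError("mi_th must be >= 0")
        if not 0.0 <= self.cc_th <= 1.0:
            raise ValueError("cc_th must lie in [0, 1]")
        if not 0.0 < self.p_th <= 1.0:
            raise ValueError("p_th must lie in (0, 1]")
        if self.delta_mi <= 0 or self.delta_cc <= 0:
            raise ValueError("increments must be positive")


@dataclass(frozen=True)
class Partition:
    """APG/QPG/UPG assignment together with the thresholds that produced it."""

    apgs: frozenset[tuple[str, str]]
    qpgs: frozenset[tuple[str, str]]
    upgs: frozenset[tuple[str, str]]
    thresholds_used: Thresholds
    iterations: int = 0
    status: str = "classified"  # classified | converged | bounded | capped
    trace: tuple[tuple[int, float, float, int], ...] = ()

    def __post_init__(self) -> None:
        if self.apgs & self.qpgs or self.apgs & self.upgs or self.qpgs & self.upgs:
            raise ValueError("partition groups must be pairwise disjoint")

    @property
    def n_pairs(self) -> int:
        return len(self.apgs) + len(self.qpgs) + len(self.upgs)

    @property
    def apg_fraction(self) -> float:
        return len(self.apgs) / self.n_pairs

    @property
    def converged(self) -> bool:
        return self.status in {"classified", "converged"}


def _route_mi(s: PairStats, th: Thresholds) -> bool:
    return s.mi_bits >= th.mi_th


def _route_cp(s: PairStats, th: Thresholds) -> bool:
    return abs(s.pearson_r) >= th.cc_th and s.p_value <= th.p_th


def classify_once(stats: Iterable[PairStats], th: Thresholds) -> Partition:
    """Single three-way classification at fixed thresholds."""
    stats = list(stats)
    if not stats:
        raise ValueError("cannot classify an empty pair collection")
    apg, qpg, upg = set(), set(), set()
    for s in stats:
        mi_ok, cp_ok = _route_mi(s, th), _route_cp(s, th)
        if mi_ok and cp_ok:
            apg.add(s.pair)
        elif mi_ok or cp_ok:
            qpg.add(s.pair)
        else:
            upg.add(s.pair)
    return Partition(frozenset(apg), frozenset(qpg), frozenset(upg), th)


def pghc_iterate(
    stats: Iterable[PairStats],
    init: Thresholds,
    target_fraction: tuple[float, float] = DEFAULT_BAND,
    max_iterations: int = 10_000,
) -> Partition:
    """Walk (mi_th, cc_th) from the initial point until the APG fraction
    lands in ``target_fraction``.

    Undersized APGs with a non-empty QPG pool lower both thresholds by their
    increments; oversized APGs raise both.  The walk stops in the band, when
    the thresholds pin against their domain ([0, inf) x [0, 1]), when the
    adjustment direction reverses (the band is narrower than one step), or
    at the iteration cap.  The returned partition is the best one visited
    (smallest distance of the APG fraction to the band), so a capped or
    bounded run still yields a usable answer, flagged by ``status``.
    """
    stats = list(stats)
    lo, hi = target_fraction
    if not 0.0 < lo < hi <= 1.0:
        raise ValueError("target_fraction must satisfy 0 < lo < hi <= 1")
    if max_iterations < 1:
        raise ValueError("max_iterations must be >= 1")

    def band_distance(frac: float) -> float:
        if frac < lo:
            return lo - frac
        if frac > hi:
            return frac - hi
        return 0.0

    th = init
    best: Partition | None = None
    best_dist = float("inf")
    trace: list[tuple[int, float, float, int]] = []
    last_move = 0  # -1 lowered, +1 raised
    status = "capped"
    iterations = 0

    for iterations in range(max_iterations + 1):
        part = classify_once(stats, th)
        frac = part.apg_fraction
        trace.append((iterations, th.mi_th, th.cc_th, len(part.apgs)))
        dist = band_distance(frac)
        if dist < best_dist:
            best, best_dist = part, dist

        if lo <= frac <= hi:
            status = "converged" if iterations else "classified"
            best = part
            break
        if frac < lo:
            if not part.qpgs:
                status = "bounded"
                break
            if last_move == +1:
                status = "bounded"  # band straddled: one step overshoots it
                break
            new_th = replace(
                th,
                mi_th=max(th.mi_th - th.delta_mi, 0.0),
                cc_th=max(th.cc_th - th.delta_cc, 0.0),
            )
            last_move = -1
        else:  # oversized
            if last_move == -1:
                status = "bounded"
                break
            new_th = replace(
                th,
                mi_th=th.mi_th + th.delta_mi,
                cc_th=min(th.cc_th + th.delta_cc, 1.0),
            )
            last_move = +1
        if new_th.mi_th == th.mi_th and new_th.cc_th == th.cc_th:
            status = "bounded"  # pinned at the domain boundary
            break
        th = new_th
    assert best is not None
    return replace(best, iterations=iterations, status=status, trace=tuple(trace))


def rank_qpgs(stats: Iterable[PairStats]) -> list[tuple[str, str]]:
    """Order questionable pairs for promotion: strongest associativity first.

    Descending AM, ties by ascending p-value, then lexicographic pair id;
    a stable total order.
    """
    return [
        s.pair
        for s in sorted(stats, key=lambda s: (-s.am, s.p_value, s.pair))
    ]


def adapt_p_threshold(
    stats: Iterable[PairStats], min_candidate_fraction: float
) -> float:
    """Smallest ladder rung admitting at least the requested pair fraction.

    Significance-starved series (few pairs with p <= 0.05) cannot seed a
    network; the threshold is lifted along a fixed ladder until enough of
    the pair universe is eligible.  1.0 always satisfies.
    """
    stats = list(stats)
    if not stats:
        raise ValueError("cannot adapt the p threshold on an empty collection")
    if not 0.0 < min_candidate_fraction < 1.0:
        raise ValueError("min_candidate_fraction must lie in (0, 1)")
    n = len(stats)
    for rung in P_LADDER:
        if sum(s.p_value <= rung for s in stats) / n >= min_candidate_fraction:
            return rung
    return 1.0
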