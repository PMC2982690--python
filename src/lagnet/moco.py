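"""Multiobjective combinatorial-optimization wrapper around PGHC.

The network-inference problem is treated as a constrained combinatorial
search: maximise the feasible APG group (reach the target band first) and
then the UPG group, subject to group arithmetic (non-negative sizes summing
to n(n-1)/2), gain constraints carried by the spectral stage, and acquired
biological knowledge — edges the analyst forces in or forbids.  The search
itself is the deterministic PGHC threshold walk; knowledge is applied to
its terminal partition with exact set arithmetic.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

from .pairwise import PairStats
from .pghc import DEFAULT_BAND, Partition, Thresholds, pghc_iterate

__all__ = [
    "KnowledgeConstraints",
    "ConstraintRecord",
    "MocoResult",
    "solve",
    "check_constraints",
    "read_knowledge_file",
]


def _unordered(pair: tuple[str, str]) -> tuple[str, str]:
    a, b = pair
    return (a, b) if a < b else (b, a)


@dataclass(frozen=True)
class KnowledgeConstraints:
    """Acquired-knowledge constraints: forced edges, forbidden pairs, gain cut.

    ``forced_edges`` are directed (source, target); ``forbidden_edges`` are
    unordered.  The two sets must be disjoint on the underlying unordered
    pairs.
    """

    forced_edges: frozenset[tuple[str, str]] = frozenset()
    forbidden_edges: frozenset[tuple[str, str]] = frozenset()
    gain_threshold: float = 0.3

    def __post_init__(self) -> None:
        object.__setattr__(self, "forced_edges", frozenset(self.forced_edges))
        object.__setattr__(
            self,
            "forbidden_edges",
            frozenset(_unordered(p) for p in self.forbidden_edges),
        )
        if self.gain_threshold < 0:
            raise ValueError("gain threshold must be non-negative")
        forced_u = {_unordered(e) for e in self.forced_edges}
        clash = forced_u & self.forbidden_edges
        if clash:
            raise ValueError(f"pairs both forced and forbidden: {sorted(clash)}")

    @property
    def forced_pairs(self) -> frozenset[tuple[str, str]]:
        return frozenset(_unordered(e) for e in self.forced_edges)

    @property
    def empty(self) -> bool:
        return not self.forced_edges and not self.forbidden_edges


@dataclass(frozen=True)
class ConstraintRecord:
    name: str
    passed: bool
    detail: str = ""


@dataclass(frozen=True)
class MocoResult:
    """Terminal partition with knowledge applied, plus objective bookkeeping."""

    partition: Partition
    objective_values: tuple[int, int]  # (apg_size, upg_size)
    constraint_report: tuple[ConstraintRecord, ...]
    forced_flags: frozenset[tuple[str, str]] = frozenset()  # provenance: knowledge

    @property
    def satisfied(self) -> bool:
        return all(r.passed for r in self.constraint_report)


def solve(
    stats: Iterable[PairStats],
    init: Thresholds,
    knowledge: KnowledgeConstraints | None = None,
    band: tuple[float, float] = DEFAULT_BAND,
    max_iterations: int = 10_000,
) -> MocoResult:
    """Run the PGHC walk, then impose knowledge constraints exactly.

    Forbidden pairs admitted by the thresholds are demoted from APGs to
    UPGs; forced pairs are promoted into APGs regardless of thresholds and
    flagged with knowledge provenance.  With empty knowledge the result is
    identical to the bare PGHC iteration.
    """
    stats = list(stats)
    knowledge = knowledge or KnowledgeConstraints()
    universe = {s.pair for s in stats}

    for edge in sorted(knowledge.forced_edges):
        if _unordered(edge) not in universe:
            raise KeyError(f"forced pair {edge} is not in the pair universe")

    part = pghc_iterate(stats, init, band, max_iterations)
    apg, qpg, upg = set(part.apgs), set(part.qpgs), set(part.upgs)

    demoted = knowledge.forbidden_edges & apg
    apg -= demoted
    upg |= demoted

    promoted = set()
    for pair in knowledge.forced_pairs:
        if pair not in apg:
            qpg.discard(pair)
            upg.discard(pair)
            apg.add(pair)
        promoted.add(pair)

    final = replace(
        part,
        apgs=frozenset(apg),
        qpgs=frozenset(qpg),
        upgs=frozenset(upg),
    )
    result = MocoResult(
        partition=final,
        objective_values=(len(apg), len(upg)),
        constraint_report=(),
        forced_flags=frozenset(promoted),
    )
    return replace_report(result, check_constraints(result, knowledge))


def replace_report(
    result: MocoResult, report: Sequence[ConstraintRecord]
) -> MocoResult:
    return MocoResult(
        partition=result.partition,
        objective_values=result.objective_values,
        constraint_report=tuple(report),
        forced_flags=result.forced_flags,
    )


def check_constraints(
    result: MocoResult, knowledge: KnowledgeConstraints
) -> list[ConstraintRecord]:
    """Audit a result against group arithmetic and knowledge constraints."""
    part = result.partition
    records = [
        ConstraintRecord(
            "non_negative_group_sizes",
            len(part.apgs) >= 0 and len(part.qpgs) >= 0 and len(part.upgs) >= 0,
        ),
        ConstraintRecord(
            "fixed_pair_total",
            len(part.apgs) + len(part.qpgs) + len(part.upgs) == part.n_pairs,
            f"total={part.n_pairs}",
        ),
        ConstraintRecord(
            "groups_disjoint",
            not (part.apgs & part.qpgs or part.apgs & part.upgs or part.qpgs & part.upgs),
        ),
    ]
    bad_forbidden = knowledge.forbidden_edges & part.apgs
    records.append(
        ConstraintRecord(
            "forbidden_absent_from_apgs",
            not bad_forbidden,
            f"violations={sorted(bad_forbidden)}" if bad_forbidden else "",
        )
    )
    missing_forced = knowledge.forced_pairs - part.apgs
    records.append(
        ConstraintRecord(
            "forced_present_in_apgs",
            not missing_forced,
            f"missing={sorted(missing_forced)}" if missing_forced else "",
        )
    )
    return records


def read_knowledge_file(
    path: str | Path, gain_threshold: float = 0.3
) -> KnowledgeConstraints:
    """Parse a directive file: lines of ``force|forbid <gene_a> <gene_b>``.

    Delimiter is any run of tabs/commas/whitespace; ``#`` starts a comment.
    ``force`` lines are directed source -> target.
    """
    import re

    forced, forbidden = set(), set()
    for ln, line in enumerate(Path(path).read_text().splitlines(), start=1):
        line = line.split("#", 1)[0].strip()
        if not line:
            continue
        fields = re.split(r"[,\t\s]+", line)
        if len(fields) != 3:
            raise ValueError(f"{path}:{ln}: expected 'force|forbid gene_a gene_b'")
        directive, a, b = fields
        if directive == "force":
            forced.add((a, b))
        elif directive == "forbid":
            forbidden.add((a, b))
        else:
            raise ValueError(f"{path}:{ln}: unknown directive {directive!r}")
    return KnowledgeConstraints(
        frozenset(forced), frozenset(forbidden), gain_threshold
    )
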