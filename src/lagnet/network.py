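"""Assembly and export of the directed regulatory network.

Edges come from the authentic pair group: a pair whose phase call is
``lagging`` (b lags a) is drawn a -> b, a ``leading`` call is drawn b -> a,
and an ``undirected`` call keeps the association as a bilateral link.  All
input genes stay in the node set, so genes that end up in no authentic pair
appear as isolates — a biologically meaningful outcome, not an error.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

from .pairwise import PairStats
from .pghc import Partition
from .spectral import PhaseCall

__all__ = [
    "DirectedEdge",
    "UndirectedEdge",
    "RegulatoryNetwork",
    "build_network",
    "degree_summary",
    "export_network",
    "read_edge_table",
]


@dataclass(frozen=True)
class DirectedEdge:
    source: str
    target: str
    am: float
    phase_rad: float | None
    gain: float | None
    provenance: str = "threshold"  # threshold | knowledge


@dataclass(frozen=True)
class UndirectedEdge:
    gene_a: str
    gene_b: str
    am: float
    provenance: str = "threshold"

    def __post_init__(self) -> None:
        if not self.gene_a < self.gene_b:
            raise ValueError("gene_a must sort before gene_b")


@dataclass(frozen=True)
class RegulatoryNetwork:
    nodes: frozenset[str]
    directed_edges: frozenset[DirectedEdge]
    undirected_edges: frozenset[UndirectedEdge]

    def __post_init__(self) -> None:
        seen: set[tuple[str, str]] = set()
        for e in self.directed_edges:
            if e.source == e.target:
                raise ValueError(f"self-edge on {e.source!r}")
            if e.source not in self.nodes or e.target not in self.nodes:
                raise ValueError(f"edge endpoint outside the node set: {e}")
            key = tuple(sorted((e.source, e.target)))
            if key in seen:
                raise ValueError(f"duplicate edge on pair {key}")
            seen.add(key)
        for e in self.undirected_edges:
            if e.gene_a not in self.nodes or e.gene_b not in self.nodes:
                raise ValueError(f"edge endpoint outside the node set: {e}")
            key = (e.gene_a, e.gene_b)
            if key in seen:
                raise ValueError(f"duplicate edge on pair {key}")
            seen.add(key)

    @property
    def n_edges(self) -> int:
        return len(self.directed_edges) + len(self.undirected_edges)

    def to_networkx(self):
        """MultiDiGraph-free view: a networkx DiGraph with undirected links
        stored as edges tagged ``directed=False`` in both orders' canonical
        (gene_a, gene_b) order."""
        import networkx as nx

        g = nx.DiGraph()
        g.add_nodes_from(sorted(self.nodes))
        for e in sorted(self.directed_edges, key=lambda e: (e.source, e.target)):
            g.add_edge(
                e.source,
                e.target,
                directed=True,
                am=e.am,
                phase_rad=e.phase_rad if e.phase_rad is not None else float("nan"),
                gain=e.gain if e.gain is not None else float("nan"),
                provenance=e.provenance,
            )
        for e in sorted(self.undirected_edges, key=lambda e: (e.gene_a, e.gene_b)):
            g.add_edge(
                e.gene_a,
                e.gene_b,
                directed=False,
                am=e.am,
                phase_rad=float("nan"),
                gain=float("nan"),
                provenance=e.provenance,
            )
        return g


def build_network(
    partition: Partition,
    calls: Mapping[tuple[str, str], PhaseCall],
    stats: Iterable[PairStats],
    all_genes: Sequence[str],
    forced_edges: Iterable[tuple[str, str]] = (),
    forced_flags: Iterable[tuple[str, str]] = (),
) -> RegulatoryNetwork:
    """Turn the authentic pair group plus per-pair phase calls into a network.

    ``forced_edges`` supply directions for knowledge-forced pairs (flagged
    in ``forced_flags``); such pairs keep their forced orientation and carry
    ``provenance="knowledge"``.
    """
    by_pair = {s.pair: s for s in stats}
    forced_dir = {tuple(sorted(e)): e for e in forced_edges}
    flagged = {tuple(sorted(p)) for p in forced_flags} | set(forced_dir)

    directed: set[DirectedEdge] = set()
    undirected: set[UndirectedEdge] = set()
    for pair in sorted(partition.apgs):
        a, b = pair
        am = by_pair[pair].am if pair in by_pair else float("nan")
        provenance = "knowledge" if pair in flagged else "threshold"
        if pair in forced_dir:
            src, tgt = forced_dir[pair]
            call = calls.get(pair)
            directed.add(
                DirectedEdge(
                    src,
                    tgt,
                    am,
                    call.phase_rad if call else None,
                    call.gain_at_dominant if call else None,
                    provenance,
                )
            )
            continue
        if pair not in calls:
            raise KeyError(f"authentic pair {pair} has no phase call")
        call = calls[pair]
        if call.direction == "lagging":  # b lags a: a is upstream
            directed.add(
                DirectedEdge(a, b, am, call.phase_rad, call.gain_at_dominant, provenance)
            )
        elif call.direction == "leading":  # b leads a: b is upstream
            directed.add(
                DirectedEdge(b, a, am, call.phase_rad, call.gain_at_dominant, provenance)
            )
        else:
            undirected.add(UndirectedEdge(a, b, am, provenance))

    return RegulatoryNetwork(
        frozenset(all_genes), frozenset(directed), frozenset(undirected)
    )


def degree_summary(network: RegulatoryNetwork):
    """Per-node (in, out, undirected) degrees and the mean total degree.

    Returns ``(DataFrame indexed by node, mean_total_degree)``.
    """
    import pandas as pd

    nodes = sorted(network.nodes)
    deg = {n: {"in_degree": 0, "out_degree": 0, "undirected_degree": 0} for n in nodes}
    for e in network.directed_edges:
        deg[e.target]["in_degree"] += 1
        deg[e.source]["out_degree"] += 1
    for e in network.undirected_edges:
        deg[e.gene_a]["undirected_degree"] += 1
        deg[e.gene_b]["undirected_degree"] += 1
    df = pd.DataFrame.from_dict(deg, orient="index")
    df.index.name = "gene"
    df["total_degree"] = df.sum(axis=1)
    mean_total = float(df["total_degree"].mean()) if len(df) else 0.0
    return df, mean_total


def _edge_rows(network: RegulatoryNetwork):
    rows = []
    for e in sorted(network.directed_edges, key=lambda e: (e.source, e.target)):
        rows.append((e.source, e.target, 1, e.am, e.phase_rad, e.gain, e.provenance))
    for e in sorted(network.undirected_edges, key=lambda e: (e.gene_a, e.gene_b)):
        rows.append((e.gene_a, e.gene_b, 0, e.am, None, None, e.provenance))
    return rows


def export_network(
    network: RegulatoryNetwork, path: str | Path, format: str = "edge-table"
) -> None:
    """Write a network as SIF, GraphML, or a delimited edge table.

    The edge table round-trips exactly through :func:`read_edge_table`;
    SIF tags directed links ``activates-lead`` and bilateral ones
    ``associates``; GraphML carries am/phase/gain as edge attributes.
    """
    path = Path(path)
    if format == "sif":
        with path.open("w") as fh:
            for src, tgt, d, *_ in _edge_rows(network):
                tag = "activates-lead" if d else "associates"
                fh.write(f"{src}\t{tag}\t{tgt}\n")
            linked = {g for e in network.directed_edges for g in (e.source, e.target)}
            linked |= {
                g for e in network.undirected_edges for g in (e.gene_a, e.gene_b)
            }
            for node in sorted(network.nodes - linked):
                fh.write(f"{node}\n")
    elif format == "graphml":
        import networkx as nx

        nx.write_graphml(network.to_networkx(), path)
    elif format == "edge-table":
        with path.open("w") as fh:
            fh.write("source\ttarget\tdirected\tam\tphase_rad\tgain\tprovenance\n")
            for src, tgt, d, am, phase, gain, prov in _edge_rows(network):
                fh.write(
                    "\t".join(
                        [
                            src,
                            tgt,
                            str(d),
                            repr(am),
                            "" if phase is None else repr(phase),
                            "" if gain is None else repr(gain),
                            prov,
                        ]
                    )
                    + "\n"
                )
            for node in sorted(network.nodes):
                fh.write(f"#node\t{node}\n")
    else:
        raise ValueError(f"unknown network format {format!r}")


def read_edge_table(path: str | Path) -> RegulatoryNetwork:
    """Re-import an edge table written by :func:`export_network`."""
    lines = Path(path).read_text().splitlines()
    if not lines or not lines[0].startswith("source\t"):
        raise ValueError(f"{path}: not an edge table")
    directed: set[DirectedEdge] = set()
    undirected: set[UndirectedEdge] = set()
    nodes: set[str] = set()
    for line in lines[1:]:
        if not line.strip():
            continue
        if line.startswith("#node\t"):
            nodes.add(line.split("\t", 1)[1])
            continue
        src, tgt, d, am, phase, gain, prov = line.split("\t")
        if d == "1":
            directed.add(
                DirectedEdge(
                    src,
                    tgt,
                    float(am),
                    float(phase) if phase else None,
                    float(gain) if gain else None,
                    prov,
                )
            )
        else:
            undirected.add(UndirectedEdge(src, tgt, float(am), prov))
    nodes |= {g for e in directed for g in (e.source, e.target)}
    nodes |= {g for e in undirected for g in (e.gene_a, e.gene_b)}
    return RegulatoryNetwork(frozenset(nodes), frozenset(directed), frozenset(undirected))
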