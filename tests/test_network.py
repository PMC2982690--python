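import numpy as np
import pytest

from lagnet.network import (
    DirectedEdge,
    RegulatoryNetwork,
    UndirectedEdge,
    build_network,
    degree_summary,
    export_network,
    read_edge_table,
)
from lagnet.pairwise import PairStats
from lagnet.pghc import Partition, Thresholds
from lagnet.spectral import PhaseCall


def make_partition(apgs, qpgs=(), upgs=()):
    return Partition(
        frozenset(apgs), frozenset(qpgs), frozenset(upgs), Thresholds(0.5, 0.5)
    )


def make_stats(pairs):
    return [PairStats(a, b, 0.8, 0.6, 0.01, 1.0, 0.6) for a, b in pairs]


def lag_call(phase=-0.8):
    return PhaseCall("lagging", 0.125, phase, 1.2, 0.95)


def lead_call(phase=0.8):
    return PhaseCall("leading", 0.125, phase, 1.2, 0.95)


def und_call():
    return PhaseCall("undirected", 0.125, 0.01, 1.2, 0.95)


class TestBuildNetwork:
    def test_empty_apgs_gives_isolated_nodes(self):
        net = build_network(make_partition([]), {}, [], ["a", "b", "c"])
        assert net.nodes == {"a", "b", "c"}
        assert net.n_edges == 0

    def test_gene_in_no_pair_stays_as_isolate(self):
        pairs = [("a", "b")]
        net = build_network(
            make_partition(pairs), {("a", "b"): lag_call()}, make_stats(pairs),
            ["a", "b", "loner"],
        )
        assert "loner" in net.nodes
        deg, _ = degree_summary(net)
        assert deg.loc["loner", "total_degree"] == 0

    def test_lagging_call_orients_first_to_second(self):
        pairs = [("a", "b")]
        net = build_network(
            make_partition(pairs), {("a", "b"): lag_call()}, make_stats(pairs), ["a", "b"]
        )
        (edge,) = net.directed_edges
        assert (edge.source, edge.target) == ("a", "b")

    def test_leading_call_orients_second_to_first(self):
        pairs = [("a", "b")]
        net = build_network(
            make_partition(pairs), {("a", "b"): lead_call()}, make_stats(pairs), ["a", "b"]
        )
        (edge,) = net.directed_edges
        assert (edge.source, edge.target) == ("b", "a")

    def test_edge_count_and_handshake_lemma(self):
        rng = np.random.default_rng(30)
        genes = [f"n{i}" for i in range(8)]
        from itertools import combinations

        pairs = [p for p in combinations(genes, 2) if rng.random() < 0.4]
        calls = {}
        for p in pairs:
            calls[p] = [lag_call(), lead_call(), und_call()][int(rng.integers(3))]
        net = build_network(make_partition(pairs), calls, make_stats(pairs), genes)
        assert net.n_edges == len(pairs)
        deg, _ = degree_summary(net)
        assert deg["in_degree"].sum() == len(net.directed_edges)
        assert deg["out_degree"].sum() == len(net.directed_edges)
        assert deg["undirected_degree"].sum() == 2 * len(net.undirected_edges)
        assert deg["total_degree"].sum() == 2 * net.n_edges

    def test_reversing_all_calls_reverses_all_directed_edges(self):
        pairs = [("a", "b"), ("c", "d"), ("e", "f")]
        calls = {pairs[0]: lag_call(), pairs[1]: lead_call(), pairs[2]: und_call()}
        flipped = {
            p: PhaseCall(
                {"lagging": "leading", "leading": "lagging"}.get(c.direction, c.direction),
                c.dominant_frequency,
                -c.phase_rad,
                c.gain_at_dominant,
                c.coherence_at_dominant,
            )
            for p, c in calls.items()
        }
        genes = sorted({g for p in pairs for g in p})
        a = build_network(make_partition(pairs), calls, make_stats(pairs), genes)
        b = build_network(make_partition(pairs), flipped, make_stats(pairs), genes)
        assert {(e.source, e.target) for e in b.directed_edges} == {
            (e.target, e.source) for e in a.directed_edges
        }
        assert a.undirected_edges == b.undirected_edges

    def test_missing_call_is_an_error(self):
        pairs = [("a", "b")]
        with pytest.raises(KeyError, match="phase call"):
            build_network(make_partition(pairs), {}, make_stats(pairs), ["a", "b"])

    def test_forced_edge_keeps_its_direction_and_provenance(self):
        pairs = [("a", "b")]
        net = build_network(
            make_partition(pairs),
            {},
            make_stats(pairs),
            ["a", "b"],
            forced_edges=[("b", "a")],
            forced_flags=[("a", "b")],
        )
        (edge,) = net.directed_edges
        assert (edge.source, edge.target) == ("b", "a")
        assert edge.provenance == "knowledge"


class TestNetworkInvariants:
    def test_self_edge_rejected(self):
        with pytest.raises(ValueError, match="self-edge"):
            RegulatoryNetwork(
                frozenset(["a"]),
                frozenset([DirectedEdge("a", "a", 1.0, None, None)]),
                frozenset(),
            )

    def test_duplicate_unordered_pair_rejected(self):
        with pytest.raises(ValueError, match="duplicate"):
            RegulatoryNetwork(
                frozenset(["a", "b"]),
                frozenset([DirectedEdge("a", "b", 1.0, None, None)]),
                frozenset([UndirectedEdge("a", "b", 1.0)]),
            )


class TestExport:
    @pytest.fixture
    def network(self):
        return RegulatoryNetwork(
            frozenset(["a", "b", "c", "iso"]),
            frozenset([DirectedEdge("a", "b", 1.25, -0.8, 1.5)]),
            frozenset([UndirectedEdge("b", "c", 0.75)]),
        )

    def test_empty_network_documents(self, tmp_path):
        net = RegulatoryNetwork(frozenset(["x"]), frozenset(), frozenset())
        for fmt, name in [("sif", "n.sif"), ("graphml", "n.graphml"), ("edge-table", "n.tsv")]:
            export_network(net, tmp_path / name, fmt)
            assert (tmp_path / name).exists()

    def test_single_directed_edge_sif_line(self, tmp_path, network):
        p = tmp_path / "n.sif"
        export_network(network, p, "sif")
        lines = p.read_text().splitlines()
        assert "a\tactivates-lead\tb" in lines
        assert "b\tassociates\tc" in lines
        assert "iso" in lines  # isolate listed bare

    def test_edge_table_round_trip_byte_identical(self, tmp_path, network):
        p1, p2 = tmp_path / "a.tsv", tmp_path / "b.tsv"
        export_network(network, p1, "edge-table")
        again = read_edge_table(p1)
        assert again == network
        export_network(again, p2, "edge-table")
        assert p1.read_text() == p2.read_text()

    def test_graphml_carries_edge_attributes(self, tmp_path, network):
        import networkx as nx

        p = tmp_path / "n.graphml"
        export_network(network, p, "graphml")
        g = nx.read_graphml(p)
        assert g.edges["a", "b"]["am"] == pytest.approx(1.25)
        assert g.edges["a", "b"]["phase_rad"] == pytest.approx(-0.8)

    def test_unknown_format_rejected(self, tmp_path, network):
        with pytest.raises(ValueError, match="format"):
            export_network(network, tmp_path / "x", "dot")
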