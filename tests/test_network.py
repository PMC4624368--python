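"""Network construction, conductance, and nucleus selection."""

import math

import networkx as nx
import numpy as np
import pytest

from seqsimnet.config import PipelineConfig
from seqsimnet.network import (
    build_network,
    connected_components,
    domain_conductance,
    export_graphml,
    select_nuclei,
)
from seqsimnet.similarity import SimilarityHit
from ._oracles import conductance_by_edge_count, union_find_components


def _hit(q, s, pident=90.0, aln=100, qend=100, send=100, evalue=1e-30, bitscore=100.0,
         qstart=1, sstart=1):
    return SimilarityHit(q, s, pident, aln, qstart=qstart, qend=qend,
                         sstart=sstart, send=send, evalue=evalue, bitscore=bitscore)


def _labeled_graph(edges, origin):
    g = nx.Graph()
    g.add_nodes_from(origin)
    g.add_edges_from(edges)
    for n, o in origin.items():
        g.nodes[n]["origin"] = o
    return g


class TestBuildNetwork:
    LENGTHS = {"a": 100, "b": 100, "c": 100, "d": 100, "e": 100, "f": 100}
    ORIGINS = {k: "Bacteria" for k in LENGTHS}

    def test_identical_pair_gets_full_identity_edge(self):
        net = build_network([_hit("a", "b", pident=100.0, evalue=1e-50)],
                            self.LENGTHS, self.ORIGINS)
        assert net.number_of_edges() == 1
        assert net.edges["a", "b"]["adjusted_identity"] == 100.0

    def test_fragment_coverage_blocks_edge(self):
        # strong identity but the subject is covered over only 40 % of its length
        hit = _hit("a", "b", pident=90.0, aln=40, qend=40, send=40)
        net = build_network([hit], self.LENGTHS, self.ORIGINS)
        assert net.number_of_edges() == 0

    def test_evalue_and_identity_filters(self):
        weak_e = _hit("a", "b", evalue=1e-4)
        weak_id = _hit("c", "d", pident=25.0)
        net = build_network([weak_e, weak_id], self.LENGTHS, self.ORIGINS)
        assert net.number_of_edges() == 0

    def test_planted_family_with_isolated_fragment(self):
        members = ["a", "b", "c", "d", "e"]
        hits = [_hit(u, v) for i, u in enumerate(members) for v in members[i + 1:]]
        hits.append(_hit("a", "f", pident=95.0, aln=40, qend=40, send=40))
        lengths = dict(self.LENGTHS, f=40)
        net = build_network(hits, lengths, self.ORIGINS,
                            include_singletons=["f"])
        comp = connected_components(net)
        # oracle: direct per-pair threshold check says the 10 family edges all
        # qualify and the fragment hit fails coverage on the query side
        assert {n for n, c in comp.items() if c == comp["a"]} == set(members)
        assert net.degree["f"] == 0

    def test_unknown_id_rejected(self):
        with pytest.raises(KeyError):
            build_network([_hit("a", "zz")], self.LENGTHS, self.ORIGINS)

    def test_best_directional_hit_decides(self):
        # weak a->b direction would fail, strong b->a direction qualifies
        weak = _hit("a", "b", pident=20.0, bitscore=10.0)
        strong = _hit("b", "a", pident=90.0, bitscore=120.0)
        net = build_network([weak, strong], self.LENGTHS, self.ORIGINS)
        assert net.has_edge("a", "b")


class TestConnectedComponents:
    def test_edgeless_graph(self):
        g = nx.Graph()
        g.add_nodes_from("abc")
        assert sorted(connected_components(g).values()) == [0, 1, 2]

    def test_path_plus_isolate(self):
        g = nx.Graph([("a", "b"), ("b", "c")])
        g.add_node("d")
        comp = connected_components(g)
        assert comp["a"] == comp["b"] == comp["c"] != comp["d"]

    def test_random_graph_matches_union_find(self):
        rng = np.random.default_rng(23)
        g = nx.gnp_random_graph(50, 0.05, seed=7)
        comp = connected_components(g)
        assert comp == union_find_components(list(g.nodes), list(g.edges))


class TestDomainConductance:
    def test_triangle_with_pendant(self):
        origin = {"a1": "Archaea", "a2": "Archaea", "a3": "Archaea", "b1": "Bacteria"}
        g = _labeled_graph([("a1", "a2"), ("a2", "a3"), ("a1", "a3"), ("a3", "b1")], origin)
        assert domain_conductance(g, g.nodes, "Archaea") == pytest.approx(1 / 3)
        assert domain_conductance(g, g.nodes, "Bacteria") == math.inf

    def test_bridged_k4s(self):
        origin = {f"a{i}": "Archaea" for i in range(4)}
        origin.update({f"b{i}": "Bacteria" for i in range(4)})
        edges = [(f"a{i}", f"a{j}") for i in range(4) for j in range(i + 1, 4)]
        edges += [(f"b{i}", f"b{j}") for i in range(4) for j in range(i + 1, 4)]
        edges.append(("a0", "b0"))
        g = _labeled_graph(edges, origin)
        assert domain_conductance(g, g.nodes, "Archaea") == pytest.approx(1 / 6)
        assert domain_conductance(g, g.nodes, "Bacteria") == pytest.approx(1 / 6)

    def test_single_domain_component_is_zero(self):
        origin = {"a1": "Archaea", "a2": "Archaea", "a3": "Archaea"}
        g = _labeled_graph([("a1", "a2"), ("a2", "a3")], origin)
        assert domain_conductance(g, g.nodes, "Archaea") == 0.0
        # a domain absent from the component has neither kind of edge
        assert domain_conductance(g, g.nodes, "Bacteria") == 0.0

    def test_matches_bruteforce_on_random_labeled_graphs(self):
        rng = np.random.default_rng(29)
        domains = ["Archaea", "Bacteria", "Eukaryote", "Environment"]
        for _ in range(30):
            n = int(rng.integers(2, 13))
            g = nx.gnp_random_graph(n, float(rng.uniform(0.1, 0.7)),
                                    seed=int(rng.integers(1 << 30)))
            origin = {v: domains[rng.integers(4)] for v in g.nodes}
            nx.set_node_attributes(g, origin, "origin")
            for comp in nx.connected_components(g):
                sub_edges = list(g.subgraph(comp).edges)
                for d in domains:
                    assert domain_conductance(g, comp, d) == \
                        conductance_by_edge_count(sub_edges, origin, d)

    def test_edge_addition_monotonicity(self):
        origin = {"a1": "Archaea", "a2": "Archaea", "b1": "Bacteria", "b2": "Bacteria"}
        g = _labeled_graph([("a1", "a2"), ("b1", "b2"), ("a1", "b1")], origin)
        before = domain_conductance(g, g.nodes, "Archaea")
        g.add_edge("a2", "b2")  # inter-domain: never decreases
        assert domain_conductance(g, g.nodes, "Archaea") >= before
        g2 = _labeled_graph([("a1", "a2"), ("b1", "b2"), ("a1", "b1")], origin)
        g2.add_node("a3")
        g2.nodes["a3"]["origin"] = "Archaea"
        before = domain_conductance(g2, g2.nodes, "Archaea")
        g2.add_edge("a2", "a3")  # intra-domain: never increases
        assert domain_conductance(g2, g2.nodes, "Archaea") <= before


class TestSelectNuclei:
    def test_bridged_k4s_pass(self):
        origin = {f"a{i}": "Archaea" for i in range(4)}
        origin.update({f"b{i}": "Bacteria" for i in range(4)})
        edges = [(f"a{i}", f"a{j}") for i in range(4) for j in range(i + 1, 4)]
        edges += [(f"b{i}", f"b{j}") for i in range(4) for j in range(i + 1, 4)]
        edges.append(("a0", "b0"))
        nuclei = select_nuclei(_labeled_graph(edges, origin))
        assert len(nuclei) == 1 and nuclei[0].passes

    def test_pendant_domain_fails(self):
        origin = {"a1": "Archaea", "a2": "Archaea", "a3": "Archaea", "b1": "Bacteria"}
        g = _labeled_graph([("a1", "a2"), ("a2", "a3"), ("a1", "a3"), ("a3", "b1")], origin)
        (nuc,) = select_nuclei(g)
        assert not nuc.passes
        assert nuc.conductance["Bacteria"] == math.inf

    def test_single_domain_component_fails(self):
        origin = {"b1": "Bacteria", "b2": "Bacteria"}
        (nuc,) = select_nuclei(_labeled_graph([("b1", "b2")], origin))
        assert not nuc.passes


class TestEdgeFilterMonotonicity:
    def _random_hits(self, rng, n=30):
        hits, lengths, origins = [], {}, {}
        for i in range(n):
            lengths[f"s{i}"] = 100
            origins[f"s{i}"] = "Bacteria"
        for _ in range(120):
            i, j = rng.integers(n, size=2)
            if i == j:
                continue
            span = int(rng.integers(30, 101))
            hits.append(_hit(f"s{i}", f"s{j}", pident=float(rng.uniform(10, 100)),
                             aln=span, qend=span, send=span,
                             evalue=float(rng.uniform(0, 1e-4))))
        return hits, lengths, origins

    def test_stricter_thresholds_shrink_edge_set(self):
        rng = np.random.default_rng(31)
        hits, lengths, origins = self._random_hits(rng)
        base = build_network(hits, lengths, origins, PipelineConfig())
        for kwargs in ({"min_adjusted_identity": 45.0},
                       {"min_mutual_coverage": 0.9},
                       {"min_adjusted_identity": 60.0, "min_mutual_coverage": 0.95}):
            strict = build_network(hits, lengths, origins,
                                   PipelineConfig(**kwargs))
            assert set(strict.edges) <= set(base.edges)


class TestGraphmlExport:
    def test_round_trip_counts_and_attributes(self, tmp_path):
        origin = {"a": "Archaea", "b": "Bacteria"}
        g = _labeled_graph([("a", "b")], origin)
        path = tmp_path / "net.graphml"
        export_graphml(g, path, annotations={"a": {"cpr_identity": 42.5}})
        back = nx.read_graphml(str(path))
        assert back.number_of_nodes() == 2 and back.number_of_edges() == 1
        assert back.nodes["a"]["cpr_identity"] == pytest.approx(42.5)
        assert back.nodes["b"]["origin"] == "Bacteria"
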