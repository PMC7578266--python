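import itertools

import networkx as nx
import numpy as np
import pandas as pd
import pytest

from osteoblast.chip_io import PeptideAnnotation
from osteoblast.diffphos import DifferentialRecord, Direction
from osteoblast.network_compare import (
    EdgeListError,
    Ppin,
    SiteKinasePrediction,
    build_ppin,
    centrality_metrics,
    compare_networks,
    export_networkin_input,
    read_predictions,
    top_decile,
)


# --- independent brute-force centrality oracle -----------------------

def brute_force_centralities(nodes, edges):
    """Exhaustive path-enumeration oracle for graphs of a few nodes."""
    nodes = list(nodes)
    adj = {n: set() for n in nodes}
    for u, v in edges:
        adj[u].add(v)
        adj[v].add(u)

    def all_simple_paths(s, t):
        stack = [(s, [s])]
        while stack:
            cur, path = stack.pop()
            if cur == t:
                yield path
                continue
            for nxt in adj[cur]:
                if nxt not in path:
                    stack.append((nxt, path + [nxt]))

    n = len(nodes)
    dist = {}
    sigma = {}  # pair -> (count of shortest paths, interior-node counts)
    for s, t in itertools.combinations(nodes, 2):
        paths = list(all_simple_paths(s, t))
        if not paths:
            continue
        d = min(len(p) - 1 for p in paths)
        shortest = [p for p in paths if len(p) - 1 == d]
        dist[(s, t)] = d
        interior = {}
        for p in shortest:
            for v in p[1:-1]:
                interior[v] = interior.get(v, 0) + 1
        sigma[(s, t)] = (len(shortest), interior)

    degree = {v: float(len(adj[v])) for v in nodes}

    betweenness = {v: 0.0 for v in nodes}
    for (s, t), (count, interior) in sigma.items():
        for v, c in interior.items():
            betweenness[v] += c / count
    if n > 2:
        norm = (n - 1) * (n - 2) / 2.0
        betweenness = {v: b / norm for v, b in betweenness.items()}

    closeness = {}
    for v in nodes:
        total, reachable = 0, 0
        for s, t in dist:
            if v == s or v == t:
                total += dist[(s, t)]
                reachable += 1
        closeness[v] = reachable / total if total > 0 else 0.0

    return degree, betweenness, closeness


def ppin_from_edges(edges, nodes=None):
    g = nx.Graph()
    if nodes:
        g.add_nodes_from(nodes)
    g.add_edges_from(edges)
    return centrality_metrics(Ppin(graph=g))


class TestBuildPpin:
    def test_dedupe_and_self_loop_removal(self):
        df = pd.DataFrame({"a": ["A", "B", "A"], "b": ["B", "A", "A"]})
        ppin = build_ppin(df)
        assert ppin.nodes == {"A", "B"}
        assert ppin.edges == {frozenset(("A", "B"))}

    def test_empty_edge_list(self):
        ppin = build_ppin(pd.DataFrame({"a": [], "b": []}))
        assert ppin.n_nodes == 0 and ppin.n_edges == 0

    def test_triangle(self):
        df = pd.DataFrame({"a": ["A", "B", "A"], "b": ["B", "C", "C"]})
        ppin = build_ppin(df)
        assert ppin.n_nodes == 3 and ppin.n_edges == 3

    def test_whitelist_restriction(self):
        df = pd.DataFrame({"a": ["A", "B", "C"], "b": ["B", "C", "D"]})
        ppin = build_ppin(df, node_whitelist={"A", "B", "C"})
        assert ppin.nodes == {"A", "B", "C"}
        assert ppin.n_edges == 2

    def test_malformed_row_reports_line(self):
        df = pd.DataFrame({"a": ["A", ""], "b": ["B", "C"]})
        with pytest.raises(EdgeListError, match="line 3"):
            build_ppin(df)

    def test_from_tsv_file(self, tmp_path):
        p = tmp_path / "edges.tsv"
        p.write_text("node1\tnode2\tcombined_score\nA\tB\t0.9\nB\tC\t0.5\n")
        ppin = build_ppin(p)
        assert ppin.nodes == {"A", "B", "C"}
        assert ppin.n_edges == 2

    def test_degree_sum_equals_twice_edges(self):
        rng = np.random.default_rng(4)
        names = [f"N{i}" for i in range(15)]
        edges = {
            tuple(sorted(rng.choice(names, 2, replace=False))) for _ in range(30)
        }
        ppin = ppin_from_edges(edges)
        assert sum(ppin.metrics["degree"].values()) == 2 * ppin.n_edges


class TestCentralityMetrics:
    def test_path_graph(self):
        ppin = ppin_from_edges([("A", "B"), ("B", "C")])
        assert ppin.metrics["degree"]["B"] == 2.0
        assert ppin.metrics["betweenness"]["B"] == pytest.approx(1.0)
        assert ppin.metrics["betweenness"]["A"] == 0.0

    def test_complete_graph_zero_betweenness(self):
        ppin = ppin_from_edges(itertools.combinations("ABCD", 2))
        assert all(b == 0.0 for b in ppin.metrics["betweenness"].values())

    def test_star_center_max_closeness(self):
        ppin = ppin_from_edges([("c", "l1"), ("c", "l2"), ("c", "l3")])
        closeness = ppin.metrics["closeness"]
        assert closeness["c"] == max(closeness.values())
        assert closeness["c"] == pytest.approx(1.0)  # adjacent to all

    def test_against_brute_force_random_graphs(self):
        rng = np.random.default_rng(17)
        for _ in range(50):
            n = int(rng.integers(2, 7))
            nodes = [f"v{i}" for i in range(n)]
            edges = [
                pair for pair in itertools.combinations(nodes, 2)
                if rng.random() < 0.5
            ]
            ppin = ppin_from_edges(edges, nodes=nodes)
            deg, bet, clo = brute_force_centralities(nodes, edges)
            for v in nodes:
                assert ppin.metrics["degree"][v] == deg[v]
                assert ppin.metrics["betweenness"][v] == pytest.approx(bet[v], abs=1e-12)
                assert ppin.metrics["closeness"][v] == pytest.approx(clo[v], abs=1e-12)

    def test_disconnected_graph_closeness_within_component(self):
        # two components: edge A-B and triangle C-D-E
        ppin = ppin_from_edges([("A", "B"), ("C", "D"), ("D", "E"), ("C", "E")])
        assert ppin.metrics["closeness"]["A"] == pytest.approx(1.0)
        assert ppin.metrics["closeness"]["C"] == pytest.approx(1.0)


class TestTopDecile:
    def _ppin_with_metric(self, values):
        g = nx.Graph()
        g.add_nodes_from(values)
        ppin = Ppin(graph=g)
        ppin.metrics["degree"] = dict(values)
        return ppin

    def test_ten_distinct_values_single_winner(self):
        values = {f"n{i}": float(i) for i in range(1, 11)}
        ppin = self._ppin_with_metric(values)
        assert top_decile(ppin, "degree") == {"n10"}

    def test_all_equal_returns_everything(self):
        values = {f"n{i}": 3.0 for i in range(8)}
        ppin = self._ppin_with_metric(values)
        assert top_decile(ppin, "degree") == set(values)

    def test_empty_graph(self):
        ppin = Ppin(graph=nx.Graph())
        ppin.metrics["degree"] = {}
        assert top_decile(ppin, "degree") == set()

    def test_unknown_metric(self):
        ppin = self._ppin_with_metric({"a": 1.0})
        with pytest.raises(KeyError, match="not computed"):
            top_decile(ppin, "pagerank")

    def test_ties_at_threshold_included(self):
        values = {f"n{i}": float(i) for i in range(1, 10)}
        values["extra"] = 9.0  # duplicates the max
        ppin = self._ppin_with_metric(values)
        selected = top_decile(ppin, "degree")
        assert {"n9", "extra"} <= selected


class TestCompareNetworks:
    def test_identical_graphs(self):
        a = ppin_from_edges([("A", "B"), ("B", "C")])
        b = ppin_from_edges([("A", "B"), ("B", "C")])
        only_a, shared, only_b = compare_networks(a, b)
        assert only_a == only_b == set()
        assert shared == {"A", "B", "C"}

    def test_disjoint_graphs(self):
        a = ppin_from_edges([("A", "B")])
        b = ppin_from_edges([("X", "Y")])
        only_a, shared, only_b = compare_networks(a, b)
        assert shared == set()
        assert only_a == {"A", "B"} and only_b == {"X", "Y"}

    def test_partition_property(self):
        rng = np.random.default_rng(3)
        names = [f"P{i}" for i in range(12)]
        def rand_edges():
            return [
                pair for pair in itertools.combinations(names, 2)
                if rng.random() < 0.2
            ]
        a, b = ppin_from_edges(rand_edges()), ppin_from_edges(rand_edges())
        only_a, shared, only_b = compare_networks(a, b)
        assert only_a & shared == only_a & only_b == shared & only_b == set()
        assert only_a | shared | only_b == a.nodes | b.nodes

    def test_metric_based_comparison(self):
        a = ppin_from_edges([("hub", x) for x in "ABCDEF"])
        b = ppin_from_edges([("hub", x) for x in "ABC"] + [("A", "B")])
        only_a, shared, only_b = compare_networks(a, b, metric="betweenness")
        assert "hub" in shared


class TestPredictorInterface:
    def _record(self, spot_id, positions, accession="P00001", p=0.01, fc=0.5):
        ann = PeptideAnnotation(
            spot_id=spot_id, sequence="AAAAAAYAAAAAA", symbol=spot_id.split("_")[0],
            phospho_positions=positions, uniprot_accession=accession,
        )
        direction = Direction.DOWN if p < 0.05 and fc < 1 else Direction.NS
        return DifferentialRecord(spot_id, p, fc, direction, ann)

    def test_one_row_per_site(self):
        rec = self._record("FAK2_572_584", (573, 579, 580))
        table = export_networkin_input([rec])
        assert len(table) == 3
        assert list(table["position"]) == [573, 579, 580]
        assert set(table["substrate"]) == {"P00001"}

    def test_empty_records(self):
        assert len(export_networkin_input([])) == 0

    def test_ns_records_excluded(self):
        rec = self._record("AAA_1_13", (5,), p=0.9)
        assert len(export_networkin_input([rec])) == 0

    def test_missing_accession_skipped(self):
        rec = self._record("AAA_1_13", (5,), accession="")
        assert len(export_networkin_input([rec])) == 0

    def test_read_predictions_round_trip(self, tmp_path):
        p = tmp_path / "pred.tsv"
        p.write_text(
            "substrate\tposition\tkinase\tscore\n"
            "PXN\t31\tSRC\t5.2\nPXN\t33\tFYN\t2.1\n"
        )
        preds = read_predictions(p)
        assert preds[0] == SiteKinasePrediction("PXN", 31, "SRC", 5.2)
        assert len(preds) == 2

    def test_prediction_validation(self):
        with pytest.raises(ValueError):
            SiteKinasePrediction("X", 0, "K")
        with pytest.raises(ValueError):
            SiteKinasePrediction("X", 1, "K", score=-1.0)
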