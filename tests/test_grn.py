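"""Network construction and census: edge conditions, sign rules, FFL and DOR
enumeration against brute-force oracles, comparison, and export round trips."""

from itertools import combinations, permutations

import networkx as nx
import numpy as np
import pandas as pd
import pytest

from germnet import activity, grn
from germnet.errors import InputError

from conftest import make_expression


def tiny_model_and_expr(target_profile, activity_profile=None):
    """Two-motif model where gene TfB's profile is controlled explicitly."""
    samples = [f"s_{d}_1" for d in range(6)]
    a = (np.array([0.0, 0.3, 0.8, 1.2, 1.4, 1.5])
         if activity_profile is None else np.asarray(activity_profile))
    b = np.array([1.0, 0.2, 0.9, 0.1, 0.8, 0.3])
    model = activity.ActivityModel(
        A=pd.DataFrame([a, b], index=["MA", "MB"], columns=samples),
        c=pd.Series(0.0, index=samples),
        residual_var=pd.Series(0.0, index=samples),
        pvalues=pd.Series(0.001, index=["MA", "MB"]),
        selected=["MA", "MB"])
    rpm = pd.DataFrame(
        [2.0 ** (4 + a) - 1.0, 2.0 ** np.asarray(target_profile) - 1.0],
        index=["TfA", "TfB"], columns=samples)
    expr = make_expression(rpm)
    return model, expr, samples


def make_sites(rows, genes=("TfA", "TfB"), motifs=("MA", "MB")):
    from germnet.motifscan import SiteCountMatrix
    return SiteCountMatrix(pd.DataFrame(rows, index=list(genes),
                                        columns=list(motifs)))


TF_MAP = {"MA": ["TfA"], "MB": ["TfB"]}


class TestInferEdges:
    def test_no_site_blocks_perfect_correlation(self):
        a = np.array([0.0, 0.3, 0.8, 1.2, 1.4, 1.5])
        model, expr, _ = tiny_model_and_expr(4 + a)  # TfB copies MA exactly
        sites = make_sites([[0, 0], [0, 0]])
        net = grn.infer_edges(model, expr, sites, TF_MAP)
        assert net.edges == []

    def test_correlation_at_threshold_excluded(self):
        # construct a profile with Pearson r to MA of exactly 0.8
        a = np.array([0.0, 0.3, 0.8, 1.2, 1.4, 1.5])
        az = (a - a.mean()) / np.linalg.norm(a - a.mean())
        perp = np.array([1.0, -1, 1, -1, 1, -1])
        perp = perp - perp.mean() - az * (az @ (perp - perp.mean()))
        perp /= np.linalg.norm(perp)
        target = 5 + 0.8 * az + 0.6 * perp
        model, expr, _ = tiny_model_and_expr(target)
        sites = make_sites([[0, 0], [1, 0]])
        r = np.corrcoef(model.A.loc["MA"],
                        expr.log2_expr.loc["TfB"])[0, 1]
        assert r == pytest.approx(0.8, abs=1e-9)
        net = grn.infer_edges(model, expr, sites, TF_MAP, threshold=0.8)
        assert net.edges == []  # strictly greater than required
        net2 = grn.infer_edges(model, expr, sites, TF_MAP, threshold=0.79)
        assert net2.edges == [("MA", "MB")]

    def test_sign_follows_correlation(self):
        a = np.array([0.0, 0.3, 0.8, 1.2, 1.4, 1.5])
        model, expr, _ = tiny_model_and_expr(6 - a)  # anticorrelated
        sites = make_sites([[0, 0], [2, 0]])
        net = grn.infer_edges(model, expr, sites, TF_MAP)
        d = net.graph.edges["MA", "MB"]
        assert d["sign"] == "inhibitory" and d["weight"] < -0.99
        assert d["sites"] == 2

    def test_self_edges_excluded_by_default(self):
        a = np.array([0.0, 0.3, 0.8, 1.2, 1.4, 1.5])
        model, expr, _ = tiny_model_and_expr(4 + a)
        sites = make_sites([[3, 0], [0, 0]])  # TfA promoter has MA sites
        assert grn.infer_edges(model, expr, sites, TF_MAP).edges == []
        allowed = grn.infer_edges(model, expr, sites, TF_MAP, allow_self=True)
        assert allowed.edges == [("MA", "MA")]

    def test_scenario_recovery_with_signs(self, scenario, scenario_network):
        _, _, net = scenario_network
        predicted = {(u, scenario.tf_gene_map[v][0],
                      1 if d["sign"] == "inductive" else -1)
                     for u, v, d in net.graph.edges(data=True)}
        truth = set(scenario.truth.true_edges)
        tp = len(predicted & truth)
        assert tp / max(len(predicted), 1) >= 0.9   # precision
        assert tp / len(truth) >= 0.9               # recall
        for u, gene, sign in predicted & truth:
            assert sign == dict(((r, t), s) for r, t, s in truth)[(u, gene)]

    def test_threshold_monotonicity(self, scenario, scenario_network):
        expr, model, net08 = scenario_network
        net09 = grn.infer_edges(model, expr, scenario.sites,
                                scenario.tf_gene_map, threshold=0.9)
        assert set(net09.edges) <= set(net08.edges)

    def test_sign_matches_weight_on_all_edges(self, scenario_network):
        _, _, net = scenario_network
        for _, _, d in net.graph.edges(data=True):
            assert d["sign"] == ("inductive" if d["weight"] > 0
                                 else "inhibitory")


def graph_from_edges(edges):
    g = nx.DiGraph()
    g.add_edges_from(edges)
    for u, v in g.edges:
        g.edges[u, v].update(sign="inductive", weight=0.9, sites=1)
    return grn.Network(g)


def brute_force_ffl(net):
    nodes = list(net.graph.nodes)
    out = []
    for a, b, c in permutations(nodes, 3):
        if (net.graph.has_edge(a, b) and net.graph.has_edge(b, c)
                and net.graph.has_edge(a, c)):
            out.append((a, b, c))
    return sorted(out)


class TestFFL:
    def test_single_loop(self):
        net = graph_from_edges([("a", "b"), ("b", "c"), ("a", "c")])
        assert grn.count_ffl(net) == [("a", "b", "c")]

    def test_two_node_graph_has_none(self):
        assert grn.count_ffl(graph_from_edges([("a", "b")])) == []

    def test_matches_cubic_enumeration_on_random_graphs(self):
        rng = np.random.default_rng(20)
        for trial in range(20):
            n = int(rng.integers(4, 9))
            p = float(rng.uniform(0.15, 0.5))
            edges = [(f"n{i}", f"n{j}") for i in range(n) for j in range(n)
                     if i != j and rng.random() < p]
            net = graph_from_edges(edges) if edges else graph_from_edges([("x", "y")])
            assert grn.count_ffl(net) == brute_force_ffl(net)

    def test_signs_reported_for_coherence(self):
        net = graph_from_edges([("a", "b"), ("b", "c"), ("a", "c")])
        net.graph.edges["a", "b"]["sign"] = "inhibitory"
        assert grn.ffl_signs(net, ("a", "b", "c")) == (
            "inhibitory", "inductive", "inductive")


def brute_force_dors(net, min_regs=2, min_shared=3):
    regs = [n for n in net.graph.nodes if net.graph.out_degree(n) > 0]
    satisfying = {}
    for r in range(min_regs, len(regs) + 1):
        for group in combinations(regs, r):
            shared = set.intersection(
                *(set(net.graph.successors(x)) for x in group))
            if len(shared) >= min_shared:
                satisfying[frozenset(group)] = frozenset(shared)
    maximal = [(g, s) for g, s in satisfying.items()
               if not any(g < other for other in satisfying)]
    return sorted(maximal, key=lambda t: (-len(t[0]), -len(t[1]),
                                          sorted(t[0]), sorted(t[1])))


class TestDOR:
    def test_two_regulators_three_shared_targets(self):
        edges = [(r, t) for r in ("r1", "r2") for t in ("t1", "t2", "t3")]
        dors = grn.find_dors(graph_from_edges(edges))
        assert dors == [(frozenset({"r1", "r2"}),
                         frozenset({"t1", "t2", "t3"}))]

    def test_star_graph_has_no_dor(self):
        edges = [("hub", t) for t in ("t1", "t2", "t3", "t4")]
        assert grn.find_dors(graph_from_edges(edges)) == []

    def test_matches_exhaustive_search_on_fixtures(self):
        rng = np.random.default_rng(30)
        for trial in range(15):
            edges = [(f"r{i}", f"t{j}") for i in range(5) for j in range(5)
                     if rng.random() < 0.5]
            if not edges:
                continue
            net = graph_from_edges(edges)
            assert grn.find_dors(net) == brute_force_dors(net)


class TestCompare:
    def test_identical_networks(self):
        net = graph_from_edges([("a", "b"), ("b", "c")])
        cmp = grn.compare_networks(net, net)
        assert cmp["n_shared_nodes"] == 3
        assert cmp["unique_nodes_a"] == cmp["unique_nodes_b"] == []
        assert cmp["shared_edges"] == [("a", "b"), ("b", "c")]

    def test_disjoint_networks(self):
        cmp = grn.compare_networks(graph_from_edges([("a", "b")]),
                                   graph_from_edges([("x", "y")]))
        assert cmp["n_shared_nodes"] == 0
        assert cmp["shared_edges"] == []

    def test_roles(self):
        net = graph_from_edges([("a", "b"), ("b", "c")])
        cmp = grn.compare_networks(net, net)
        assert cmp["roles_a"] == {"a": "input", "b": "input+target",
                                  "c": "target"}


class TestExport:
    def test_empty_network_sif(self, tmp_path):
        net = grn.Network(nx.DiGraph())
        path = tmp_path / "empty.sif"
        grn.export_network(net, path, "sif")
        assert path.read_text() == ""

    def test_sif_line_count_equals_edges(self, tmp_path, scenario_network):
        _, _, net = scenario_network
        path = tmp_path / "net.sif"
        grn.export_network(net, path, "sif")
        lines = [l for l in path.read_text().splitlines() if l]
        assert len(lines) == len(net.edges)
        assert all(len(l.split("\t")) == 3 for l in lines)

    def test_graphml_round_trip(self, tmp_path, scenario_network):
        _, _, net = scenario_network
        path = tmp_path / "net.graphml"
        grn.export_network(net, path, "graphml")
        back = grn.read_graphml(path)
        assert back.nodes == net.nodes
        assert back.edges == net.edges
        for u, v in net.edges:
            orig, copy = net.graph.edges[u, v], back.graph.edges[u, v]
            assert copy["sign"] == orig["sign"]
            assert copy["weight"] == pytest.approx(orig["weight"])

    def test_unknown_format_lists_supported(self, tmp_path):
        net = grn.Network(nx.DiGraph())
        with pytest.raises(InputError, match="sif"):
            grn.export_network(net, tmp_path / "x", "dot")

    def test_deterministic_bytes(self, tmp_path, scenario_network):
        _, _, net = scenario_network
        p1, p2 = tmp_path / "a.graphml", tmp_path / "b.graphml"
        grn.export_network(net, p1, "graphml")
        grn.export_network(net, p2, "graphml")
        assert p1.read_bytes() == p2.read_bytes()


def test_ffl_edges_exist_in_network(scenario_network):
    _, _, net = scenario_network
    for a, b, c in grn.count_ffl(net):
        assert net.graph.has_edge(a, b)
        assert net.graph.has_edge(b, c)
        assert net.graph.has_edge(a, c)
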