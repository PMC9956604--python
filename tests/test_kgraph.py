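"""Knowledge-graph ingestion, MCL clustering, module graph and enrichment."""

import math

import networkx as nx
import numpy as np
import pandas as pd
import pytest
from scipy import stats

from ivambn.kgraph import (GraphValidationError, KnowledgeGraph,
                           ModulePartition, assign_modules, clustering_metrics,
                           derive_module_graph, enrich_modules,
                           filter_causal_gene_graph, load_graph,
                           markov_cluster, rank_algorithms, read_gmt)
from ivambn.synthdata import make_toy_knowledge_graph

from conftest import two_cliques_graph


# ---------------------------------------------------------------------------
# independent MCL oracle: plain matrix iteration, no pruning tricks

def mcl_oracle_partition(g: KnowledgeGraph, inflation: float = 2.0,
                         expansion: int = 2) -> set[frozenset]:
    und = g.undirected_simple()
    order = sorted(und.nodes())
    m = nx.to_numpy_array(und, nodelist=order) + np.eye(len(order))
    m /= m.sum(axis=0, keepdims=True)
    for _ in range(200):
        new = np.linalg.matrix_power(m, expansion) ** inflation
        new[new < 1e-5] = 0.0
        s = new.sum(axis=0, keepdims=True)
        s[s == 0] = 1.0
        new /= s
        if np.max(np.abs(new - m)) < 1e-8:
            m = new
            break
        m = new
    # cluster = rows of attractors; merge overlaps via a union graph
    un = nx.Graph()
    un.add_nodes_from(range(len(order)))
    for i in range(len(order)):
        if m[i, i] > 1e-12:
            for j in np.nonzero(m[i, :] > 1e-12)[0]:
                un.add_edge(i, j)
    return {frozenset(order[i] for i in comp)
            for comp in nx.connected_components(un)}


def partition_as_sets(p: ModulePartition) -> set[frozenset]:
    return {frozenset(genes) for genes in p.modules().values()}


# ---------------------------------------------------------------------------
# loading

def _write_graph(tmp_path, edge_rows, type_rows):
    ep = tmp_path / "edges.tsv"
    tp = tmp_path / "types.tsv"
    ep.write_text("src\trelation\tdst\n"
                  + "".join("\t".join(r) + "\n" for r in edge_rows))
    tp.write_text("node\tntype\n"
                  + "".join("\t".join(r) + "\n" for r in type_rows))
    return str(ep), str(tp)


class TestLoadGraph:
    def test_two_edge_roundtrip(self, tmp_path):
        ep, tp = _write_graph(tmp_path,
                              [("A", "increases", "B"), ("B", "decreases", "C")],
                              [("A", "gene"), ("B", "gene"), ("C", "gene")])
        g = load_graph(ep, tp)
        assert g.n_nodes == 3 and g.n_edges == 2
        assert ("A", "increases", "B") in g.edges

    def test_undeclared_node_rejected(self, tmp_path):
        ep, tp = _write_graph(tmp_path, [("A", "increases", "X")],
                              [("A", "gene")])
        with pytest.raises(GraphValidationError, match="X"):
            load_graph(ep, tp)

    def test_duplicate_edges_deduplicated(self, tmp_path):
        rows = [("A", "increases", "B"), ("A", "increases", "B"),
                ("B", "regulates", "A")]
        ep, tp = _write_graph(tmp_path, rows, [("A", "gene"), ("B", "gene")])
        g = load_graph(ep, tp)
        # oracle: set-based line reader
        assert g.n_edges == len(set(rows))
        assert g.n_nodes == len({n for r in rows for n in (r[0], r[2])})

    def test_malformed_row_names_line(self, tmp_path):
        ep = tmp_path / "edges.tsv"
        ep.write_text("src\trelation\tdst\nA\tincreases\tB\nA\tbroken\n")
        tp = tmp_path / "types.tsv"
        tp.write_text("node\tntype\nA\tgene\nB\tgene\n")
        with pytest.raises(GraphValidationError, match=":3"):
            load_graph(str(ep), str(tp))

    def test_unknown_relation_becomes_other(self, tmp_path):
        ep, tp = _write_graph(tmp_path, [("A", "binds", "B")],
                              [("A", "gene"), ("B", "gene")])
        g = load_graph(ep, tp)
        assert g.edges == [("A", "other", "B")]


class TestFilterCausal:
    def test_chain_plus_process_node(self):
        nodes = {c: "gene" for c in "ABCDE"}
        nodes["proc"] = "process"
        edges = [(a, "increases", b) for a, b in zip("ABCD", "BCDE")]
        edges.append(("proc", "association", "A"))
        g = KnowledgeGraph(nodes=nodes, edges=edges)
        f = filter_causal_gene_graph(g)
        assert set(f.nodes) == set("ABCDE")
        assert f.n_edges == 4

    def test_largest_component_kept(self):
        nodes = {c: "gene" for c in "ABCDEF"}
        edges = [("A", "increases", "B"), ("B", "increases", "C"),
                 ("C", "increases", "D"), ("E", "increases", "F")]
        f = filter_causal_gene_graph(KnowledgeGraph(nodes=nodes, edges=edges))
        assert set(f.nodes) == set("ABCD")

    def test_counts_match_bruteforce(self, rng):
        g, _ = make_toy_knowledge_graph(2, 4, bridges=1, noise_edges=3, seed=5)
        # add association edges and a process node
        nodes = dict(g.nodes)
        nodes["p1"] = "process"
        edges = list(g.edges) + [("p1", "association", "C0G0"),
                                 ("C0G1", "association", "C1G1")]
        mixed = KnowledgeGraph(nodes=nodes, edges=edges)
        f = filter_causal_gene_graph(mixed)
        # independent brute-force filter over the edge list
        causal = {(s, r, d) for s, r, d in edges
                  if r in {"increases", "decreases", "regulates"}
                  and nodes[s] in {"gene", "protein", "rna"}
                  and nodes[d] in {"gene", "protein", "rna"}}
        und = nx.Graph((s, d) for s, _, d in causal)
        comp = max(nx.connected_components(und), key=len)
        expect_edges = {e for e in causal if e[0] in comp and e[2] in comp}
        assert set(f.nodes) == comp
        assert set(f.edges) == expect_edges

    def test_idempotent(self, bridged_cliques):
        once = filter_causal_gene_graph(bridged_cliques)
        twice = filter_causal_gene_graph(once)
        assert set(once.edges) == set(twice.edges)
        assert once.nodes == twice.nodes

    def test_empty_result_is_error(self):
        g = KnowledgeGraph(nodes={"p": "process", "q": "process"},
                           edges=[("p", "association", "q")])
        with pytest.raises(GraphValidationError):
            filter_causal_gene_graph(g)


class TestMarkovCluster:
    @pytest.mark.parametrize("graph,expected_k", [
        (two_cliques_graph(4, 4), 2),
        (two_cliques_graph(5, 5), 2),
    ])
    def test_two_cliques_split_at_bridge(self, graph, expected_k):
        p = markov_cluster(graph, inflation=2.0)
        mods = partition_as_sets(p)
        assert len(mods) == expected_k
        assert mods == mcl_oracle_partition(graph)

    def test_single_triangle_one_cluster(self):
        nodes = {c: "gene" for c in "ABC"}
        edges = [("A", "increases", "B"), ("B", "increases", "C"),
                 ("A", "increases", "C")]
        p = markov_cluster(KnowledgeGraph(nodes=nodes, edges=edges))
        assert len(p.modules()) == 1

    def test_ring_of_three_cliques(self):
        g, truth = make_toy_knowledge_graph(3, 5, bridges=1, seed=2)
        p = markov_cluster(g)
        assert partition_as_sets(p) == mcl_oracle_partition(g)
        assert partition_as_sets(p) == partition_as_sets(truth)

    def test_relabeling_invariance_and_determinism(self, bridged_cliques):
        p1 = markov_cluster(bridged_cliques)
        p2 = markov_cluster(bridged_cliques)
        assert p1.assignment == p2.assignment
        ren = {n: f"z_{n}" for n in bridged_cliques.nodes}
        relabeled = KnowledgeGraph(
            nodes={ren[n]: t for n, t in bridged_cliques.nodes.items()},
            edges=[(ren[s], r, ren[d]) for s, r, d in bridged_cliques.edges])
        p3 = markov_cluster(relabeled)
        orig = {frozenset(ren[g] for g in c) for c in partition_as_sets(p1)}
        assert orig == partition_as_sets(p3)

    def test_inflation_must_exceed_one(self, bridged_cliques):
        with pytest.raises(ValueError):
            markov_cluster(bridged_cliques, inflation=1.0)


class TestAssignModules:
    def _graph_with_loose_gene(self, extra_edges):
        g = two_cliques_graph(3, 3)
        nodes = dict(g.nodes)
        nodes["X"] = "gene"
        edges = list(g.edges) + extra_edges
        return KnowledgeGraph(nodes=nodes, edges=edges)

    def test_gene_adjacent_to_one_cluster_merges(self):
        g = self._graph_with_loose_gene([("X", "increases", "A0")])
        base = markov_cluster(two_cliques_graph(3, 3))
        base.assignment["X"] = max(base.assignment.values()) + 1
        out = assign_modules(base, g)
        cluster_of_a0 = out.assignment["A0"]
        assert out.assignment["X"] == cluster_of_a0

    def test_gene_bridging_two_clusters_stays_singleton(self):
        g = self._graph_with_loose_gene([("X", "increases", "A0"),
                                         ("X", "increases", "B0")])
        base = markov_cluster(two_cliques_graph(3, 3))
        base.assignment["X"] = max(base.assignment.values()) + 1
        out = assign_modules(base, g)
        assert [out.assignment["X"]] == [m for m, genes in out.modules().items()
                                         if genes == ["X"]]
        assert out.assignment["X"] in out.singletons

    def test_fully_clustered_partition_unchanged(self, bridged_cliques):
        p = markov_cluster(bridged_cliques)
        out = assign_modules(p, bridged_cliques)
        assert partition_as_sets(out) == partition_as_sets(p)


# ---------------------------------------------------------------------------
# metrics

def metrics_oracle(genes: set, g: KnowledgeGraph) -> dict:
    """Exhaustive edge counting straight from the formulas."""
    und = g.undirected_simple()
    n_total = und.number_of_nodes()
    m_total = und.number_of_edges()
    n_s = len(genes)
    m_s = sum(1 for u, v in und.edges() if u in genes and v in genes)
    c_s = sum(1 for u, v in und.edges() if (u in genes) != (v in genes))
    cond = c_s / (2 * m_s + c_s) if (2 * m_s + c_s) else 0.0
    return {
        "internal_density": 0.0 if n_s == 1 else m_s / (n_s * (n_s - 1) / 2),
        "edges_inside": m_s,
        "average_degree": 2 * m_s / n_s,
        "expansion": c_s / n_s,
        "cut_ratio": c_s / (n_s * (n_total - n_s)) if n_s < n_total else 0.0,
        "conductance": cond,
        "norm_cut": cond + (c_s / (2 * (m_total - m_s) + c_s)
                            if 2 * (m_total - m_s) + c_s else 0.0),
    }


class TestClusteringMetrics:
    def test_isolated_clique(self):
        g = two_cliques_graph(3, 3)
        nodes = dict(g.nodes)
        edges = [e for e in g.edges if not (e[0] == "A0" and e[2] == "B0")]
        g2 = KnowledgeGraph(nodes=nodes, edges=edges)
        p = ModulePartition(assignment={n: (0 if n.startswith("A") else 1)
                                        for n in nodes})
        rep = clustering_metrics(p, g2)
        assert rep.loc[0, "internal_density"] == 1.0
        assert rep.loc[0, "expansion"] == 0.0
        assert rep.loc[0, "conductance"] == 0.0

    def test_hand_computed_four_clique(self):
        # 4-clique cluster with 2 boundary edges inside a 10-node graph
        nodes = {f"n{i}": "gene" for i in range(10)}
        edges = [(f"n{i}", "increases", f"n{j}")
                 for i in range(4) for j in range(i + 1, 4)]
        edges += [("n3", "increases", "n4"), ("n0", "increases", "n5"),
                  ("n4", "increases", "n5"), ("n6", "increases", "n7"),
                  ("n8", "increases", "n9"), ("n5", "increases", "n6")]
        g = KnowledgeGraph(nodes=nodes, edges=edges)
        assignment = {f"n{i}": 0 if i < 4 else 1 for i in range(10)}
        rep = clustering_metrics(ModulePartition(assignment=assignment), g)
        # cluster 0: n=4, m=6, c=2, N=10, M=12
        assert rep.loc[0, "internal_density"] == 1.0
        assert rep.loc[0, "edges_inside"] == 6
        assert rep.loc[0, "average_degree"] == 3.0
        assert rep.loc[0, "expansion"] == 0.5
        assert rep.loc[0, "cut_ratio"] == 2 / 24
        assert rep.loc[0, "conductance"] == 2 / 14
        assert rep.loc[0, "norm_cut"] == pytest.approx(2 / 14 + 2 / 14)

    def test_random_graphs_match_oracle(self, rng):
        for _ in range(20):
            n = int(rng.integers(4, 13))
            und = nx.gnp_random_graph(n, 0.4, seed=int(rng.integers(1 << 30)))
            nodes = {f"g{i}": "gene" for i in range(n)}
            edges = [(f"g{u}", "increases", f"g{v}") for u, v in und.edges()]
            g = KnowledgeGraph(nodes=nodes, edges=edges)
            assignment = {f"g{i}": int(rng.integers(0, 3)) for i in range(n)}
            p = ModulePartition(assignment=assignment)
            rep = clustering_metrics(p, g)
            for mod, genes in p.modules().items():
                oracle = metrics_oracle(set(genes), g)
                for k, v in oracle.items():
                    assert rep.loc[mod, k] == pytest.approx(v), (k, mod)

    def test_average_ranks_with_dominating_algorithm(self):
        good = pd.DataFrame([{
            "internal_density": 1.0, "edges_inside": 6, "average_degree": 3.0,
            "expansion": 0.1, "cut_ratio": 0.01, "conductance": 0.05,
            "norm_cut": 0.08}])
        bad = pd.DataFrame([{
            "internal_density": 0.3, "edges_inside": 2, "average_degree": 1.0,
            "expansion": 0.9, "cut_ratio": 0.2, "conductance": 0.6,
            "norm_cut": 0.9}])
        ranks = rank_algorithms({"good": good, "bad": bad})
        assert ranks["good"] == 1.0 and ranks["bad"] == 2.0


class TestModuleGraph:
    def _kg(self, edges, genes):
        return KnowledgeGraph(nodes={g: "gene" for g in genes},
                              edges=[(a, "increases", b) for a, b in edges])

    def test_direct_edge(self):
        g = self._kg([("a", "b")], ["a", "b"])
        p = ModulePartition(assignment={"a": 0, "b": 1})
        mg = derive_module_graph(p, g)
        assert mg.edges == [(0, 1)]

    def test_interior_node_outside_pair_blocks_edge(self):
        g = self._kg([("a", "x"), ("x", "b")], ["a", "x", "b"])
        p = ModulePartition(assignment={"a": 0, "b": 1, "x": 2})
        mg = derive_module_graph(p, g)
        assert (0, 1) not in mg.graph.edges()
        assert (0, 2) in mg.graph.edges() and (2, 1) in mg.graph.edges()

    def test_two_cycle_broken_by_support(self):
        # M0 -> M1 via three gene edges, M1 -> M0 via one
        edges = [("a1", "b1"), ("a2", "b2"), ("a3", "b3"), ("b1", "a1")]
        genes = ["a1", "a2", "a3", "b1", "b2", "b3"]
        g = self._kg(edges, genes)
        p = ModulePartition(assignment={g_: (0 if g_.startswith("a") else 1)
                                        for g_ in genes})
        mg = derive_module_graph(p, g)
        assert (0, 1) in mg.graph.edges()
        assert (1, 0) not in mg.graph.edges()
        assert (1, 0) in mg.removed_edges

    def test_acyclic_and_subset_invariant(self, rng):
        for _ in range(10):
            n = int(rng.integers(6, 12))
            dg = nx.gnp_random_graph(n, 0.3, directed=True,
                                     seed=int(rng.integers(1 << 30)))
            nodes = {f"g{i}": "gene" for i in range(n)}
            edges = [(f"g{u}", "increases", f"g{v}") for u, v in dg.edges()
                     if u != v]
            if not edges:
                continue
            g = KnowledgeGraph(nodes=nodes, edges=edges)
            p = ModulePartition(assignment={f"g{i}": int(rng.integers(0, 4))
                                            for i in range(n)})
            mg = derive_module_graph(p, g)
            assert nx.is_directed_acyclic_graph(mg.graph)
            list(nx.topological_sort(mg.graph))
            assert set(mg.graph.edges()) <= set(mg.provenance)


class TestEnrichment:
    def test_exact_copy_of_gene_set(self):
        universe = {f"g{i}" for i in range(100)}
        module = {f"g{i}" for i in range(10)}
        p = ModulePartition(assignment={g: 0 for g in module})
        res = enrich_modules(p, {"S": set(module)}, universe=universe)
        expect = 1 / math.comb(100, 10)
        assert res["p"].iloc[0] == pytest.approx(expect, rel=1e-9)
        assert res["p_adj"].iloc[0] == pytest.approx(expect, rel=1e-9)

    def test_zero_overlap_falls_back_to_gene_symbols(self):
        universe = {f"g{i}" for i in range(20)}
        p = ModulePartition(assignment={"g0": 0, "g1": 0})
        enrich_modules(p, {"S": {"g10", "g11"}}, universe=universe)
        assert p.module_labels[0] == "g0/g1"

    def test_closed_form_tail(self):
        # k=3, n=5, K=10, N=50
        universe = {f"g{i}" for i in range(50)}
        module = {"g0", "g1", "g2", "g40", "g41"}
        gene_set = {f"g{i}" for i in range(10)}
        p = ModulePartition(assignment={g: 0 for g in module})
        res = enrich_modules(p, {"S": gene_set}, universe=universe)
        expect = sum(math.comb(10, i) * math.comb(40, 5 - i)
                     for i in range(3, 6)) / math.comb(50, 5)
        assert res["p"].iloc[0] == pytest.approx(expect, rel=1e-12)

    def test_bh_monotone_and_dominates_raw(self, rng):
        universe = {f"g{i}" for i in range(60)}
        assignment = {}
        for m in range(4):
            for i in range(5):
                assignment[f"g{m * 5 + i}"] = m
        p = ModulePartition(assignment=assignment)
        sets = {f"S{j}": set(rng.choice(sorted(universe), size=8,
                                        replace=False)) for j in range(5)}
        res = enrich_modules(p, sets, universe=universe)
        assert (res["p_adj"] >= res["p"] - 1e-15).all()
        srt = res.sort_values("p")
        assert srt["p_adj"].is_monotonic_increasing

    def test_gmt_reader(self, tmp_path):
        gmt = tmp_path / "s.gmt"
        gmt.write_text("SET1\tdesc\tg1\tg2\nSET2\tdesc\tg3\n")
        sets = read_gmt(str(gmt))
        assert sets == {"SET1": {"g1", "g2"}, "SET2": {"g3"}}
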