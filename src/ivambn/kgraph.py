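"""Knowledge-graph ingestion, Markov clustering, module graph and enrichment.

A curated cause-and-effect graph over genes, proteins, biological processes
and pathologies is reduced to its causal gene backbone, clustered into
modules with the Markov Cluster algorithm (MCL), and condensed into an
acyclic *module graph* that later constrains Bayesian-network structure
learning.  Modules are annotated by hypergeometric over-representation of
user-supplied gene sets (GMT).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

logger = logging.getLogger(__name__)

NODE_TYPES = {"gene", "protein", "rna", "process", "pathology", "chemical", "other"}
RELATIONS = {"increases", "decreases", "regulates", "association",
             "hasComponent", "isA", "other"}
CAUSAL_RELATIONS = {"increases", "decreases", "regulates"}
GENE_LIKE = {"gene", "protein", "rna"}


class GraphValidationError(ValueError):
    """Raised when an edge list or node-type table violates the contract."""


@dataclass
class KnowledgeGraph:
    """Typed directed multigraph of biological entities and causal relations.

    ``nodes`` maps node id to its entity type; ``edges`` is a list of
    (source, relation, target) triples.  Parallel edges are allowed only
    with distinct relations.
    """

    nodes: dict[str, str]
    edges: list[tuple[str, str, str]]

    def __post_init__(self) -> None:
        for nid, ntype in self.nodes.items():
            if ntype not in NODE_TYPES:
                raise GraphValidationError(f"unknown node type {ntype!r} for {nid!r}")
        seen: set[tuple[str, str, str]] = set()
        for src, rel, dst in self.edges:
            if src not in self.nodes or dst not in self.nodes:
                raise GraphValidationError(
                    f"edge ({src!r}, {rel!r}, {dst!r}) references undeclared node")
            if rel not in RELATIONS:
                raise GraphValidationError(f"unknown relation {rel!r}")
            if (src, rel, dst) in seen:
                raise GraphValidationError(
                    f"duplicate edge ({src!r}, {rel!r}, {dst!r})")
            seen.add((src, rel, dst))

    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    def to_networkx(self) -> nx.MultiDiGraph:
        g = nx.MultiDiGraph()
        for nid, ntype in self.nodes.items():
            g.add_node(nid, ntype=ntype)
        for src, rel, dst in self.edges:
            g.add_edge(src, dst, relation=rel)
        return g

    def directed_simple(self) -> nx.DiGraph:
        """Directed simple-graph view (parallel relations collapsed)."""
        g = nx.DiGraph()
        g.add_nodes_from(self.nodes)
        g.add_edges_from((s, d) for s, _, d in self.edges)
        return g

    def undirected_simple(self) -> nx.Graph:
        g = nx.Graph()
        g.add_nodes_from(self.nodes)
        g.add_edges_from((s, d) for s, _, d in self.edges if s != d)
        return g


@dataclass
class ModulePartition:
    """Assignment of genes to modules plus bookkeeping for singletons."""

    assignment: dict[str, int]
    singletons: set[int] = field(default_factory=set)
    module_labels: dict[int, str] = field(default_factory=dict)

    def modules(self) -> dict[int, list[str]]:
        out: dict[int, list[str]] = {}
        for gene, mod in self.assignment.items():
            out.setdefault(mod, []).append(gene)
        return {m: sorted(v) for m, v in sorted(out.items())}

    def to_frame(self) -> pd.DataFrame:
        rows = sorted(self.assignment.items())
        return pd.DataFrame(rows, columns=["gene", "module"])


@dataclass
class ModuleGraph:
    """Acyclic directed graph over modules with path-support provenance."""

    graph: nx.DiGraph
    provenance: dict[tuple[int, int], int]
    removed_edges: list[tuple[int, int]] = field(default_factory=list)

    @property
    def edges(self) -> list[tuple[int, int]]:
        return sorted(self.graph.edges())

    def to_frame(self) -> pd.DataFrame:
        rows = [(u, v, self.provenance.get((u, v), 0)) for u, v in self.edges]
        return pd.DataFrame(rows, columns=["from", "to", "support"])


# ---------------------------------------------------------------------------
# I/O

def load_graph(edges_path: str, types_path: str) -> KnowledgeGraph:
    """Read a 3-column (src, relation, dst) TSV plus a node-type TSV.

    Unknown relations are mapped to ``other`` with a warning; exactly
    duplicated edges are dropped with a log line.  An edge endpoint absent
    from the node-type table is a validation error.
    """
    types = pd.read_csv(types_path, sep="\t")
    if types.shape[1] < 2:
        raise GraphValidationError("node-type table needs (node, ntype) columns")
    nodes: dict[str, str] = {}
    for _, row in types.iterrows():
        nid, ntype = str(row.iloc[0]), str(row.iloc[1])
        if ntype not in NODE_TYPES:
            logger.warning("node %s: unknown type %r mapped to 'other'", nid, ntype)
            ntype = "other"
        nodes[nid] = ntype

    edges: list[tuple[str, str, str]] = []
    seen: set[tuple[str, str, str]] = set()
    n_dup = 0
    with open(edges_path) as fh:
        header = fh.readline()
        if len(header.rstrip("\n").split("\t")) != 3:
            raise GraphValidationError(
                f"{edges_path}: header must have 3 tab-separated columns")
        for lineno, line in enumerate(fh, start=2):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) != 3:
                raise GraphValidationError(
                    f"{edges_path}:{lineno}: expected 3 columns, got {len(parts)}")
            src, rel, dst = parts
            if rel not in RELATIONS:
                logger.warning("%s:%d: unknown relation %r mapped to 'other'",
                               edges_path, lineno, rel)
                rel = "other"
            if src not in nodes or dst not in nodes:
                missing = src if src not in nodes else dst
                raise GraphValidationError(
                    f"{edges_path}:{lineno}: node {missing!r} not in type table")
            triple = (src, rel, dst)
            if triple in seen:
                n_dup += 1
                continue
            seen.add(triple)
            edges.append(triple)
    if n_dup:
        logger.info("deduplicated %d identical edges", n_dup)
    return KnowledgeGraph(nodes=nodes, edges=edges)


def write_partition(p: ModulePartition, path: str) -> None:
    p.to_frame().to_csv(path, sep="\t", index=False)


def write_module_graph(mg: ModuleGraph, path: str) -> None:
    mg.to_frame().to_csv(path, sep="\t", index=False)


def read_gmt(path: str) -> dict[str, set[str]]:
    """Read gene sets from GMT (name, description, genes...)."""
    sets: dict[str, set[str]] = {}
    with open(path) as fh:
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 3:
                continue
            sets[parts[0]] = {g for g in parts[2:] if g}
    return sets


# ---------------------------------------------------------------------------
# Filtering

def filter_causal_gene_graph(g: KnowledgeGraph) -> KnowledgeGraph:
    """Restrict to causal relations between gene-like entities.

    Keeps nodes of type gene/protein/rna (collapsed onto one gene node per
    symbol) and edges labelled increases/decreases/regulates, then restricts
    to the largest weakly connected component.
    """
    if not g.nodes:
        raise GraphValidationError("empty input graph")
    kept_nodes = {nid: "gene" for nid, t in g.nodes.items() if t in GENE_LIKE}
    kept_edges = [(s, r, d) for s, r, d in g.edges
                  if r in CAUSAL_RELATIONS and s in kept_nodes and d in kept_nodes]
    # collapsing gene/protein/rna onto symbols may create exact duplicates
    kept_edges = sorted(set(kept_edges), key=kept_edges.index)
    if not kept_nodes or not kept_edges:
        raise GraphValidationError("no causal gene graph remains after filtering")
    sub = KnowledgeGraph(nodes=kept_nodes, edges=kept_edges)
    comps = list(nx.weakly_connected_components(sub.directed_simple()))
    largest = max(comps, key=lambda c: (len(c), sorted(c)))
    nodes = {n: "gene" for n in largest}
    edges = [(s, r, d) for s, r, d in kept_edges if s in largest and d in largest]
    return KnowledgeGraph(nodes=nodes, edges=edges)


# ---------------------------------------------------------------------------
# Markov clustering

class MCLConvergenceError(RuntimeError):
    pass


def _mcl_matrix(adj: np.ndarray, inflation: float, expansion: int,
                prune_tol: float, max_iter: int, conv_tol: float = 1e-8
                ) -> np.ndarray:
    """Iterate expand-inflate-prune on a column-stochastic flow matrix."""
    m = adj.astype(float).copy()
    np.fill_diagonal(m, m.diagonal() + 1.0)  # self loops
    m /= m.sum(axis=0, keepdims=True)
    for _ in range(max_iter):
        new = np.linalg.matrix_power(m, expansion)
        new = np.power(new, inflation)
        new[new < prune_tol] = 0.0
        colsum = new.sum(axis=0, keepdims=True)
        colsum[colsum == 0] = 1.0
        new /= colsum
        resid = np.max(np.abs(new - m))
        m = new
        if resid < conv_tol:
            return m
    raise MCLConvergenceError(
        f"MCL did not converge in {max_iter} iterations (residual {resid:.3g})")


def _clusters_from_flow(m: np.ndarray) -> list[set[int]]:
    """Attractor-based cluster extraction; overlapping attractor rows merge."""
    n = m.shape[0]
    attractors = [i for i in range(n) if m[i, i] > 1e-12]
    raw = [set(np.nonzero(m[i, :] > 1e-12)[0]) for i in attractors]
    # merge overlapping attractor systems
    merged: list[set[int]] = []
    for cl in raw:
        hit = [k for k, ex in enumerate(merged) if ex & cl]
        if not hit:
            merged.append(set(cl))
        else:
            base = merged[hit[0]]
            base |= cl
            for k in reversed(hit[1:]):
                base |= merged.pop(k)
    covered = set().union(*merged) if merged else set()
    for i in range(n):  # nodes pruned away entirely become their own cluster
        if i not in covered:
            merged.append({i})
    return merged


def markov_cluster(g: KnowledgeGraph, inflation: float = 2.0,
                   expansion: int = 2, prune_tol: float = 1e-5,
                   max_iter: int = 200) -> ModulePartition:
    """Cluster the undirected view of ``g`` with the Markov Cluster algorithm.

    Deterministic given inputs: the flow matrix is iterated
    (expand -> inflate -> prune -> renormalise) to idempotency and clusters
    are read off the attractor rows.  Module ids are dense integers ordered
    by (cluster size desc, lexicographically smallest member).
    """
    if inflation <= 1:
        raise ValueError("inflation must be > 1")
    und = g.undirected_simple()
    order = sorted(und.nodes())
    adj = nx.to_numpy_array(und, nodelist=order)
    flow = _mcl_matrix(adj, inflation, expansion, prune_tol, max_iter)
    clusters = _clusters_from_flow(flow)
    named = [sorted(order[i] for i in cl) for cl in clusters]
    named.sort(key=lambda cl: (-len(cl), cl[0]))
    assignment = {gene: mid for mid, cl in enumerate(named) for gene in cl}
    singles = {mid for mid, cl in enumerate(named) if len(cl) == 1}
    return ModulePartition(assignment=assignment, singletons=singles)


def assign_modules(p: ModulePartition, g: KnowledgeGraph) -> ModulePartition:
    """Resolve unclustered (singleton-cluster) genes against the clusters.

    A gene outside any multi-gene cluster joins a cluster if it is adjacent
    (undirected) to exactly one; genes adjacent to several clusters, or to
    none, stay as single-gene modules.  Module ids are re-densified.
    """
    und = g.undirected_simple()
    modules = p.modules()
    multi = {m: genes for m, genes in modules.items() if len(genes) > 1}
    gene2cluster = {gene: m for m, genes in multi.items() for gene in genes}
    loose = sorted(gene for m, genes in modules.items()
                   if len(genes) == 1 for gene in genes)
    new_assignment = dict(gene2cluster)
    pending_singletons: list[str] = []
    for gene in loose:
        neigh_clusters = {gene2cluster[nb] for nb in und.neighbors(gene)
                          if nb in gene2cluster}
        if len(neigh_clusters) == 1:
            new_assignment[gene] = next(iter(neigh_clusters))
        else:
            pending_singletons.append(gene)
    # densify: multi-gene clusters first (size desc), then singleton genes
    groups: dict[int, list[str]] = {}
    for gene, m in new_assignment.items():
        groups.setdefault(m, []).append(gene)
    ordered = sorted(groups.values(), key=lambda cl: (-len(cl), sorted(cl)[0]))
    final: dict[str, int] = {}
    for mid, cl in enumerate(ordered):
        for gene in cl:
            final[gene] = mid
    singles: set[int] = set()
    next_id = len(ordered)
    for gene in pending_singletons:
        final[gene] = next_id
        singles.add(next_id)
        next_id += 1
    singles |= {mid for mid, cl in enumerate(ordered) if len(cl) == 1}
    labels = {mid: cl[0] for mid, cl in enumerate(ordered) if len(cl) == 1}
    labels.update({final[gene]: gene for gene in pending_singletons})
    return ModulePartition(assignment=final, singletons=singles,
                           module_labels=labels)


# ---------------------------------------------------------------------------
# Clustering quality metrics

METRIC_DIRECTION = {  # +1: larger is better, -1: smaller is better
    "internal_density": 1, "edges_inside": 1, "average_degree": 1,
    "expansion": -1, "cut_ratio": -1, "conductance": -1, "norm_cut": -1,
}


def clustering_metrics(p: ModulePartition, g: KnowledgeGraph) -> pd.DataFrame:
    """Per-cluster quality metrics on the undirected simple view.

    For a cluster S with n_S nodes, m_S internal edges and c_S boundary
    edges in a graph of N nodes and M edges:
    density m/(n(n-1)/2), edges_inside m, average_degree 2m/n,
    expansion c/n, cut_ratio c/(n(N-n)), conductance c/(2m+c),
    norm_cut conductance + c/(2(M-m)+c).  Singleton clusters get density 0
    and are flagged.
    """
    und = g.undirected_simple()
    n_total = und.number_of_nodes()
    m_total = und.number_of_edges()
    rows = []
    for mod, genes in p.modules().items():
        s = set(genes)
        n_s = len(s)
        m_s = sum(1 for u, v in und.edges() if u in s and v in s)
        c_s = sum(1 for u, v in und.edges() if (u in s) != (v in s))
        singleton = n_s == 1
        density = 0.0 if singleton else m_s / (n_s * (n_s - 1) / 2)
        rows.append({
            "module": mod, "n_nodes": n_s, "singleton": singleton,
            "internal_density": density,
            "edges_inside": m_s,
            "average_degree": 2 * m_s / n_s,
            "expansion": c_s / n_s,
            "cut_ratio": c_s / (n_s * (n_total - n_s)) if n_s < n_total else 0.0,
            "conductance": c_s / (2 * m_s + c_s) if (2 * m_s + c_s) else 0.0,
            "norm_cut": ((c_s / (2 * m_s + c_s) if (2 * m_s + c_s) else 0.0)
                         + (c_s / (2 * (m_total - m_s) + c_s)
                            if (2 * (m_total - m_s) + c_s) else 0.0)),
        })
    return pd.DataFrame(rows).set_index("module")


def rank_algorithms(reports: dict[str, pd.DataFrame]) -> pd.Series:
    """Average rank of clustering algorithms across the seven metrics.

    Each algorithm is summarised by its mean metric value over clusters;
    algorithms are ranked per metric in the metric's preferred direction
    (rank 1 best) and ranks are averaged.
    """
    summary = pd.DataFrame({
        name: rep[list(METRIC_DIRECTION)].mean() for name, rep in reports.items()
    }).T
    ranks = pd.DataFrame(index=summary.index, columns=summary.columns, dtype=float)
    for metric, direction in METRIC_DIRECTION.items():
        ranks[metric] = summary[metric].rank(ascending=(direction < 0))
    return ranks.mean(axis=1).sort_values()


# ---------------------------------------------------------------------------
# Module graph

def derive_module_graph(p: ModulePartition, g: KnowledgeGraph,
                        path_cutoff: int = 6) -> ModuleGraph:
    """Condense the gene graph onto modules, then enforce acyclicity.

    An edge M1 -> M2 is created iff some gene of M1 reaches some gene of M2
    by a directed path whose interior nodes all lie within M1 union M2.
    Edge support counts the simple such paths (length-capped by
    ``path_cutoff``).  Cycles are broken by repeatedly removing the cycle
    edge with least support, ties by lexicographic (M1, M2).
    """
    dg = g.directed_simple()
    modules = p.modules()
    mod_ids = sorted(modules)
    support: dict[tuple[int, int], int] = {}
    for m1 in mod_ids:
        for m2 in mod_ids:
            if m1 == m2:
                continue
            pairset = set(modules[m1]) | set(modules[m2])
            sub = dg.subgraph(pairset)
            count = 0
            for a in modules[m1]:
                for b in modules[m2]:
                    for _ in nx.all_simple_paths(sub, a, b, cutoff=path_cutoff):
                        count += 1
            if count:
                support[(m1, m2)] = count
    mg = nx.DiGraph()
    mg.add_nodes_from(mod_ids)
    mg.add_edges_from(support)
    removed: list[tuple[int, int]] = []
    while not nx.is_directed_acyclic_graph(mg):
        cycle = nx.find_cycle(mg)
        edge = min(((u, v) for u, v, *_ in cycle),
                   key=lambda e: (support[e], e))
        mg.remove_edge(*edge)
        removed.append(edge)
        logger.info("module-graph cycle broken: removed %s (support %d)",
                    edge, support[edge])
    return ModuleGraph(graph=mg, provenance=support, removed_edges=removed)


# ---------------------------------------------------------------------------
# Enrichment

def enrich_modules(p: ModulePartition, gene_sets: dict[str, set[str]],
                   universe: set[str] | None = None,
                   alpha: float = 0.05) -> pd.DataFrame:
    """Hypergeometric over-representation of gene sets per module.

    p = P(X >= k) with X ~ Hypergeom(N, K, n): N universe size, K set size
    within universe, n module size, k overlap.  Benjamini-Hochberg across
    all (module, set) tests.  The most significant adjusted-significant set
    names the module; modules with no significant set keep gene-symbol
    labels.
    """
    modules = p.modules()
    if universe is None:
        universe = set(p.assignment)
    n_u = len(universe)
    rows = []
    for mod, genes in modules.items():
        mod_genes = set(genes) & universe
        if set(genes) - universe:
            raise ValueError(f"module {mod} has genes outside the universe")
        for name in sorted(gene_sets):
            set_genes = gene_sets[name] & universe
            k = len(mod_genes & set_genes)
            rows.append({
                "module": mod, "gene_set": name, "k": k,
                "n": len(mod_genes), "K": len(set_genes), "N": n_u,
                "p": float(stats.hypergeom.sf(k - 1, n_u, len(set_genes),
                                              len(mod_genes))),
            })
    res = pd.DataFrame(rows)
    if len(res):
        res["p_adj"] = multipletests(res["p"], method="fdr_bh")[1]
    labels: dict[int, str] = {}
    for mod, genes in modules.items():
        sub = res[(res["module"] == mod) & (res["p_adj"] < alpha) & (res["k"] > 0)]
        if len(sub):
            best = sub.sort_values(["p_adj", "p", "gene_set"]).iloc[0]
            labels[mod] = str(best["gene_set"])
        else:
            labels[mod] = "/".join(genes)
    p.module_labels.update(labels)
    return res
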