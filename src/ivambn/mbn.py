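"""Modular Bayesian network: constrained structure learning and inference.

Module activity scores (continuous) and raw demographic/phenotype features
(continuous or discrete) become nodes of a hybrid Bayesian network whose
joint density factorises into node-local conditionals: conditional linear
Gaussians for continuous nodes (one regression per discrete-parent
configuration) and multinomial tables for discrete nodes.  Discrete nodes
may never be children of Gaussian ones.

Structure is learned by a first-ascent greedy hill climber on the BIC score
(loglik - d/2 * log n) under logical constraints (whitelist / blacklist /
initial graph) derived from the knowledge-graph module graph; edge
confidence comes from bootstrap resampling, external validity from a
node-label permutation test of the held-out log-likelihood.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

Edge = tuple[str, str]


@dataclass
class ConstraintSet:
    """Whitelist / blacklist / initial-graph constraints for structure search."""

    whitelist: set[Edge] = field(default_factory=set)
    blacklist: set[Edge] = field(default_factory=set)
    initial_graph: set[Edge] = field(default_factory=set)
    strategy: str = "data_driven"

    def __post_init__(self) -> None:
        if self.whitelist & self.blacklist:
            raise ValueError("whitelist and blacklist overlap")
        g = nx.DiGraph(sorted(self.whitelist | self.initial_graph))
        if not nx.is_directed_acyclic_graph(g):
            raise ValueError("whitelist plus initial graph contains a cycle")


@dataclass
class MbnModel:
    """Fitted hybrid Bayesian network: DAG + node-local distributions."""

    graph: nx.DiGraph
    kinds: dict[str, str]                      # node -> gaussian | discrete
    params: dict[str, dict] = field(default_factory=dict)

    @property
    def nodes(self) -> list[str]:
        return sorted(self.graph.nodes())

    @property
    def edges(self) -> set[Edge]:
        return set(self.graph.edges())

    def copy_structure(self) -> nx.DiGraph:
        return self.graph.copy()


@dataclass
class BootstrapResult:
    """Per-edge bootstrap support: strength (pair) and direction fractions."""

    table: pd.DataFrame   # columns: from, to, strength, direction
    B: int


# ---------------------------------------------------------------------------
# Constraints

DEMOGRAPHIC_ROLES = {"demographic", "age"}


def build_constraints(module_graph_edges, roles: dict[str, str],
                      strategy: str, sub_option: str = "both") -> ConstraintSet:
    """Translate logical rules plus a knowledge strategy into constraints.

    Roles: "demographic" (incl. "age"), "phenotype", "module".  Rules:
    demographic nodes admit no incoming edges (sources; age included),
    the phenotype node admits no outgoing edges.  Strategies:
    data_driven (logical blacklist only), knowledge_informed (module-graph
    edges used as initial graph and/or whitelist, per ``sub_option`` in
    {"init", "whitelist", "both"}), knowledge_driven (all module-module
    edges outside the module graph are blacklisted as well).
    """
    if strategy not in {"data_driven", "knowledge_informed", "knowledge_driven"}:
        raise ValueError(f"unknown strategy {strategy!r}")
    nodes = sorted(roles)
    mg_edges = {(str(u), str(v)) for u, v in module_graph_edges}
    blacklist: set[Edge] = set()
    for u in nodes:
        for v in nodes:
            if u == v:
                continue
            if roles[v] in DEMOGRAPHIC_ROLES:
                blacklist.add((u, v))          # demographics are sources
            if roles[u] == "phenotype":
                blacklist.add((u, v))          # phenotype is a sink
    if strategy == "knowledge_driven":
        for u in nodes:
            for v in nodes:
                if u == v or (u, v) in mg_edges:
                    continue
                if roles[u] == "module" and roles[v] == "module":
                    blacklist.add((u, v))
    whitelist: set[Edge] = set()
    initial: set[Edge] = set()
    if strategy == "knowledge_informed":
        if sub_option not in {"init", "whitelist", "both"}:
            raise ValueError(f"unknown sub_option {sub_option!r}")
        if sub_option in {"init", "both"}:
            initial = set(mg_edges)
        if sub_option in {"whitelist", "both"}:
            whitelist = set(mg_edges)
    elif strategy == "knowledge_driven":
        initial = set(mg_edges)
    if whitelist & blacklist:
        raise ValueError("module-graph edges conflict with logical blacklist")
    return ConstraintSet(whitelist=whitelist, blacklist=blacklist,
                         initial_graph=initial, strategy=strategy)


# ---------------------------------------------------------------------------
# Node-local scoring

class _NodeScorer:
    """Cached BIC node scores over one dataset."""

    def __init__(self, data: pd.DataFrame, kinds: dict[str, str]):
        self.kinds = kinds
        self.n = len(data)
        self.cont: dict[str, np.ndarray] = {}
        self.disc_codes: dict[str, np.ndarray] = {}
        self.disc_levels: dict[str, list] = {}
        for col in data.columns:
            if kinds[col] == "gaussian":
                self.cont[col] = data[col].to_numpy(dtype=float)
            else:
                codes, uniq = pd.factorize(data[col], sort=True)
                self.disc_codes[col] = codes
                self.disc_levels[col] = list(uniq)
        self.cache: dict[tuple, tuple[float, float]] = {}

    def _strata(self, dparents: tuple[str, ...]) -> list[np.ndarray]:
        if not dparents:
            return [np.arange(self.n)]
        key = np.zeros(self.n, dtype=np.int64)
        for dp in dparents:
            key = key * (max(self.disc_codes[dp]) + 1) + self.disc_codes[dp]
        out = []
        for val in np.unique(key):
            out.append(np.nonzero(key == val)[0])
        return out

    def loglik_dof(self, node: str, parents: tuple[str, ...]):
        """(max log-likelihood, parameter count) of node given parents."""
        key = (node, parents)
        if key in self.cache:
            return self.cache[key]
        cparents = tuple(p for p in parents if self.kinds[p] == "gaussian")
        dparents = tuple(p for p in parents if self.kinds[p] == "discrete")
        if self.kinds[node] == "gaussian":
            y_all = self.cont[node]
            ll = 0.0
            dof = 0.0
            for idx in self._strata(dparents):
                y = y_all[idx]
                ns = len(y)
                p = len(cparents)
                if ns < p + 2:
                    self.cache[key] = (-np.inf, np.inf)
                    return self.cache[key]
                if p:
                    x = np.column_stack([np.ones(ns)]
                                        + [self.cont[c][idx] for c in cparents])
                    beta, *_ = np.linalg.lstsq(x, y, rcond=None)
                    resid = y - x @ beta
                else:
                    resid = y - y.mean()
                var = max(float(resid @ resid) / ns, 1e-12)
                ll += -0.5 * ns * (math.log(2 * math.pi * var) + 1.0)
                dof += p + 2
        else:
            codes = self.disc_codes[node]
            n_levels = len(self.disc_levels[node])
            ll = 0.0
            for idx in self._strata(dparents):
                sub = codes[idx]
                counts = np.bincount(sub, minlength=n_levels).astype(float)
                tot = counts.sum()
                nz = counts > 0
                ll += float((counts[nz] * np.log(counts[nz] / tot)).sum())
            n_configs = 1
            for dp in dparents:
                n_configs *= len(self.disc_levels[dp])
            dof = (n_levels - 1) * n_configs
        self.cache[key] = (ll, float(dof))
        return self.cache[key]

    def bic(self, node: str, parents: tuple[str, ...]) -> float:
        ll, dof = self.loglik_dof(node, parents)
        if not np.isfinite(ll):
            return -np.inf
        return ll - 0.5 * dof * math.log(self.n)


def _edge_allowed(u: str, v: str, kinds: dict[str, str],
                  blacklist: set[Edge]) -> bool:
    if (u, v) in blacklist:
        return False
    # no discrete child of a Gaussian parent
    if kinds[u] == "gaussian" and kinds[v] == "discrete":
        return False
    return True


def _hill_climb_structure(data: pd.DataFrame, kinds: dict[str, str],
                          constraints: ConstraintSet | None = None,
                          scorer: _NodeScorer | None = None,
                          max_iter: int = 10_000) -> nx.DiGraph:
    """First-ascent greedy BIC hill climb; deterministic.

    Moves (add / delete / reverse) are evaluated over ordered node pairs in
    lexicographic order and the first strictly improving move is applied.
    """
    constraints = constraints or ConstraintSet()
    scorer = scorer or _NodeScorer(data, kinds)
    nodes = sorted(data.columns)
    g = nx.DiGraph()
    g.add_nodes_from(nodes)
    for u, v in sorted(constraints.initial_graph | constraints.whitelist):
        if not _edge_allowed(u, v, kinds, constraints.blacklist):
            raise ValueError(f"constrained edge {(u, v)} violates logical rules")
        g.add_edge(u, v)
    if not nx.is_directed_acyclic_graph(g):
        raise ValueError("initial graph is cyclic")

    def parents(node, graph):
        return tuple(sorted(graph.predecessors(node)))

    pairs = [(u, v) for u in nodes for v in nodes if u != v]
    for _ in range(max_iter):
        improved = False
        for u, v in pairs:
            if not g.has_edge(u, v):
                # add u -> v
                if not _edge_allowed(u, v, kinds, constraints.blacklist):
                    continue
                if g.has_edge(v, u) or nx.has_path(g, v, u):
                    continue
                old = scorer.bic(v, parents(v, g))
                new = scorer.bic(v, tuple(sorted(set(parents(v, g)) | {u})))
                if new > old + 1e-9:
                    g.add_edge(u, v)
                    improved = True
                    break
            else:
                # delete u -> v
                if (u, v) not in constraints.whitelist:
                    old = scorer.bic(v, parents(v, g))
                    new = scorer.bic(v, tuple(sorted(set(parents(v, g)) - {u})))
                    if new > old + 1e-9:
                        g.remove_edge(u, v)
                        improved = True
                        break
                # reverse u -> v
                if ((u, v) not in constraints.whitelist
                        and _edge_allowed(v, u, kinds, constraints.blacklist)):
                    g.remove_edge(u, v)
                    cyclic = nx.has_path(g, u, v)
                    if not cyclic:
                        old = (scorer.bic(v, tuple(sorted(set(parents(v, g)) | {u})))
                               + scorer.bic(u, parents(u, g)))
                        new = (scorer.bic(v, parents(v, g))
                               + scorer.bic(u, tuple(sorted(set(parents(u, g)) | {v}))))
                        if new > old + 1e-9:
                            g.add_edge(v, u)
                            improved = True
                            break
                    g.add_edge(u, v)
        if not improved:
            return g
    raise RuntimeError("hill climb did not converge (no admissible fixed point)")


def hill_climb_bic(data: pd.DataFrame, kinds: dict[str, str],
                   constraints: ConstraintSet | None = None,
                   restarts: int = 1, seed: int = 0) -> MbnModel:
    """Greedy BIC structure learning followed by parameter fitting.

    With ``restarts`` > 1, additional runs start from the initial graph
    perturbed by random admissible edges; the best-scoring structure wins.
    """
    constraints = constraints or ConstraintSet()
    scorer = _NodeScorer(data, kinds)
    rng = np.random.default_rng(seed)
    nodes = sorted(data.columns)

    def total_bic(g):
        return sum(scorer.bic(v, tuple(sorted(g.predecessors(v)))) for v in nodes)

    best_g = _hill_climb_structure(data, kinds, constraints, scorer)
    best_score = total_bic(best_g)
    for _ in range(max(restarts - 1, 0)):
        extra = ConstraintSet(whitelist=set(constraints.whitelist),
                              blacklist=set(constraints.blacklist),
                              initial_graph=set(constraints.initial_graph),
                              strategy=constraints.strategy)
        probe = nx.DiGraph(sorted(extra.initial_graph | extra.whitelist))
        probe.add_nodes_from(nodes)
        candidates = [(u, v) for u in nodes for v in nodes if u != v
                      and _edge_allowed(u, v, kinds, extra.blacklist)]
        rng.shuffle(candidates)
        for u, v in candidates[:len(nodes)]:
            if not probe.has_edge(u, v) and not nx.has_path(probe, v, u):
                probe.add_edge(u, v)
        extra.initial_graph = set(probe.edges())
        try:
            g = _hill_climb_structure(data, kinds, extra, scorer)
        except ValueError:
            continue
        sc = total_bic(g)
        if sc > best_score + 1e-9:
            best_g, best_score = g, sc
    return fit_parameters(best_g, data, kinds)


# ---------------------------------------------------------------------------
# Parameters and likelihood

def fit_parameters(g: nx.DiGraph, data: pd.DataFrame,
                   kinds: dict[str, str]) -> MbnModel:
    """Maximum-likelihood local distributions for a fixed DAG.

    Gaussian nodes: OLS on continuous parents, one fit per discrete-parent
    configuration (plus a pooled fallback).  Discrete nodes: CPT by relative
    frequency; configurations never observed get a uniform (add-one) row.
    """
    if not nx.is_directed_acyclic_graph(g):
        raise ValueError("graph must be acyclic")
    params: dict[str, dict] = {}
    n = len(data)
    for node in sorted(g.nodes()):
        parents = sorted(g.predecessors(node))
        cparents = [p for p in parents if kinds[p] == "gaussian"]
        dparents = [p for p in parents if kinds[p] == "discrete"]
        if kinds[node] == "gaussian":
            y_all = data[node].to_numpy(dtype=float)
            strata: dict[tuple, dict] = {}
            groups = (data.groupby(dparents, sort=True).groups.items()
                      if dparents else [((), data.index)])
            for cfg, idx in groups:
                cfg = cfg if isinstance(cfg, tuple) else (cfg,)
                sub = data.loc[idx]
                y = sub[node].to_numpy(dtype=float)
                ns = len(y)
                if ns < len(cparents) + 2:
                    raise ValueError(
                        f"node {node!r}, stratum {cfg}: {ns} samples for "
                        f"{len(cparents)} parents — tighten constraints")
                if cparents:
                    x = np.column_stack([np.ones(ns)]
                                        + [sub[c].to_numpy(dtype=float)
                                           for c in cparents])
                    beta, *_ = np.linalg.lstsq(x, y, rcond=None)
                    resid = y - x @ beta
                    intercept, coefs = float(beta[0]), beta[1:].copy()
                else:
                    intercept, coefs = float(y.mean()), np.zeros(0)
                    resid = y - intercept
                sd = max(float(np.sqrt((resid @ resid) / ns)), 1e-9)
                strata[cfg] = {"intercept": intercept, "coefs": coefs, "sd": sd}
            pooled_resid = y_all - y_all.mean()
            params[node] = {
                "type": "gaussian",
                "continuous_parents": cparents,
                "discrete_parents": dparents,
                "strata": strata,
                "pooled": {"intercept": float(y_all.mean()), "coefs": np.zeros(0),
                           "sd": max(float(np.sqrt((pooled_resid @ pooled_resid)
                                                   / n)), 1e-9)},
            }
        else:
            if cparents:
                raise ValueError(
                    f"discrete node {node!r} cannot have Gaussian parents")
            levels = sorted(pd.unique(data[node]).tolist())
            cpt: dict[tuple, np.ndarray] = {}
            groups = (data.groupby(dparents, sort=True).groups.items()
                      if dparents else [((), data.index)])
            for cfg, idx in groups:
                cfg = cfg if isinstance(cfg, tuple) else (cfg,)
                vals = data.loc[idx, node]
                counts = np.array([float((vals == lv).sum()) for lv in levels])
                cpt[cfg] = counts / counts.sum()
            params[node] = {"type": "discrete", "parents": dparents,
                            "levels": levels, "cpt": cpt}
    return MbnModel(graph=g.copy(), kinds=dict(kinds), params=params)


def _gaussian_row_params(p: dict, cfg: tuple):
    if cfg in p["strata"]:
        return p["strata"][cfg]
    logger.warning("unseen discrete configuration %s: pooled fallback", cfg)
    return p["pooled"]


def node_loglik(model: MbnModel, data: pd.DataFrame) -> dict[str, float]:
    """Plug-in log-likelihood contribution of every node."""
    out: dict[str, float] = {}
    for node in model.nodes:
        p = model.params[node]
        if p["type"] == "gaussian":
            y = data[node].to_numpy(dtype=float)
            dparents = p["discrete_parents"]
            cparents = p["continuous_parents"]
            total = 0.0
            groups = (data.groupby(dparents, sort=True).groups.items()
                      if dparents else [((), data.index)])
            for cfg, idx in groups:
                cfg = cfg if isinstance(cfg, tuple) else (cfg,)
                sp = _gaussian_row_params(p, cfg)
                sub = data.loc[idx]
                mean = sp["intercept"] * np.ones(len(sub))
                coefs = sp["coefs"]
                use_parents = cparents if len(coefs) else []
                for c, b in zip(use_parents, coefs):
                    mean += b * sub[c].to_numpy(dtype=float)
                resid = sub[node].to_numpy(dtype=float) - mean
                sd = sp["sd"]
                total += float((-0.5 * math.log(2 * math.pi * sd * sd)
                                - resid ** 2 / (2 * sd * sd)).sum())
            out[node] = total
        else:
            levels = p["levels"]
            lvl_index = {lv: i for i, lv in enumerate(levels)}
            dparents = p["parents"]
            total = 0.0
            groups = (data.groupby(dparents, sort=True).groups.items()
                      if dparents else [((), data.index)])
            for cfg, idx in groups:
                cfg = cfg if isinstance(cfg, tuple) else (cfg,)
                probs = p["cpt"].get(cfg)
                vals = data.loc[idx, node]
                counts = np.zeros(len(levels))
                n_unseen = 0
                for v in vals:
                    if v in lvl_index:
                        counts[lvl_index[v]] += 1
                    else:
                        n_unseen += 1
                if probs is None:
                    probs = np.full(len(levels), 1.0 / len(levels))
                if n_unseen or (counts[probs <= 0].sum() > 0):
                    logger.warning("node %s: unseen level/config smoothed", node)
                    smoothed = (probs * len(idx) + 1.0) / (len(idx) + len(levels) + 1)
                    total += float((counts * np.log(smoothed)).sum())
                    total += n_unseen * math.log(1.0 / (len(idx) + len(levels) + 1))
                else:
                    nz = counts > 0
                    total += float((counts[nz] * np.log(probs[nz])).sum())
            out[node] = total
    return out


def model_loglik(model: MbnModel, data: pd.DataFrame) -> float:
    """Total plug-in log-likelihood: the exact sum of node contributions."""
    return float(sum(node_loglik(model, data).values()))


# ---------------------------------------------------------------------------
# Bootstrap confidence

def bootstrap_structure(data: pd.DataFrame, kinds: dict[str, str],
                        constraints: ConstraintSet | None = None,
                        B: int = 1000, threshold: float = 0.4,
                        seed: int = 0) -> tuple[BootstrapResult, MbnModel]:
    """Bootstrap edge confidence plus the thresholded consensus network.

    ``B`` resamples of the rows (with replacement) are each re-learned;
    strength of an edge is the fraction of networks containing it in either
    direction, direction the fraction oriented that way among those.  The
    consensus keeps pairs with strength >= threshold at the majority
    orientation and breaks any remaining cycles by dropping the
    lowest-strength cycle edge (ties lexicographic).
    """
    if B < 1:
        raise ValueError("B must be >= 1")
    constraints = constraints or ConstraintSet()
    rng = np.random.default_rng(seed)
    n = len(data)
    dir_counts: dict[Edge, int] = {}
    for _ in range(B):
        idx = rng.integers(0, n, n)
        boot = data.iloc[idx].reset_index(drop=True)
        try:
            g = _hill_climb_structure(boot, kinds, constraints)
        except ValueError:
            continue
        for e in g.edges():
            dir_counts[e] = dir_counts.get(e, 0) + 1
    pairs = sorted({tuple(sorted(e)) for e in dir_counts})
    rows = []
    strength_of: dict[Edge, float] = {}
    consensus_edges: list[tuple[float, Edge]] = []
    for u, v in pairs:
        n_uv = dir_counts.get((u, v), 0)
        n_vu = dir_counts.get((v, u), 0)
        strength = (n_uv + n_vu) / B
        for a, b, cnt in [(u, v, n_uv), (v, u, n_vu)]:
            direction = cnt / (n_uv + n_vu) if (n_uv + n_vu) else 0.0
            rows.append({"from": a, "to": b, "strength": strength,
                         "direction": direction})
            strength_of[(a, b)] = strength
        if strength >= threshold:
            winner = (u, v) if n_uv >= n_vu else (v, u)
            consensus_edges.append((strength, winner))
    cg = nx.DiGraph()
    cg.add_nodes_from(sorted(data.columns))
    for _, e in consensus_edges:
        cg.add_edge(*e)
    while not nx.is_directed_acyclic_graph(cg):
        cycle = nx.find_cycle(cg)
        drop = min(((u, v) for u, v, *_ in cycle),
                   key=lambda e: (strength_of[e], e))
        cg.remove_edge(*drop)
        logger.info("consensus cycle broken: removed %s", drop)
    table = pd.DataFrame(rows, columns=["from", "to", "strength", "direction"])
    consensus = fit_parameters(cg, data, kinds)
    return BootstrapResult(table=table, B=B), consensus


# ---------------------------------------------------------------------------
# Permutation test & overlap

def permutation_test_loglik(model: MbnModel, train: pd.DataFrame,
                            test: pd.DataFrame, P: int = 1000, seed: int = 0,
                            classes: dict[str, str] | None = None) -> dict:
    """Empirical p for the held-out log-likelihood against permuted networks.

    Node labels of the DAG are permuted within classes (default: within node
    kind, which preserves the logical constraints), parameters are refitted
    on ``train`` and scored on ``test``.  p = (1 + #{perm >= true}) / (P + 1).
    """
    classes = classes or dict(model.kinds)
    groups: dict[str, list[str]] = {}
    for node in model.nodes:
        groups.setdefault(classes[node], []).append(node)
    n_perms_possible = 1.0
    for g in groups.values():
        n_perms_possible *= math.factorial(len(g))
    rng = np.random.default_rng(seed)
    true_model = fit_parameters(model.graph, train, model.kinds)
    true_ll = model_loglik(true_model, test)
    if n_perms_possible - 1 <= P:
        # small permutation group: enumerate it exactly (identity excluded)
        from itertools import permutations, product
        keys = sorted(groups)
        mappings = []
        for combo in product(*(permutations(groups[k]) for k in keys)):
            mapping = {}
            for k, permed in zip(keys, combo):
                mapping.update(dict(zip(groups[k], permed)))
            if any(a != b for a, b in mapping.items()):
                mappings.append(mapping)
        if len(mappings) < P:
            logger.info("only %d distinct permutations; reducing P from %d",
                        len(mappings), P)
        P = len(mappings)
    else:
        mappings = []
        for _ in range(P):
            mapping = {}
            for g in groups.values():
                perm = rng.permutation(len(g))
                for i, node in enumerate(g):
                    mapping[node] = g[perm[i]]
            mappings.append(mapping)
    perm_lls = []
    for mapping in mappings:
        pg = nx.relabel_nodes(model.graph, mapping)
        pm = fit_parameters(pg, train, model.kinds)
        perm_lls.append(model_loglik(pm, test))
    perm_lls = np.asarray(perm_lls)
    p = (1 + int((perm_lls >= true_ll).sum())) / (P + 1)
    return {"p": p, "true_loglik": true_ll, "perm_logliks": perm_lls, "P": P}


def graph_overlap_test(g_a, g_b, universe) -> dict:
    """Edge overlap of two graphs with a hypergeometric upper-tail p.

    Computed both directed and on the skeleton.  Overlap fraction is the
    Jaccard index |A & B| / |A | B|; the p-value is the upper tail of the
    hypergeometric for |A & B| given |A|, |B| and the admissible universe.
    """
    a, b = set(g_a), set(g_b)
    uni = set(universe)
    if not uni:
        raise ValueError("empty edge universe")
    if not a <= uni or not b <= uni:
        raise ValueError("edge sets must be subsets of the universe")

    def _one(a_s, b_s, n_u):
        k = len(a_s & b_s)
        union = len(a_s | b_s)
        frac = k / union if union else 1.0
        p = float(stats.hypergeom.sf(k - 1, n_u, len(b_s), len(a_s)))
        return k, frac, p

    k_d, f_d, p_d = _one(a, b, len(uni))
    sk_a = {frozenset(e) for e in a}
    sk_b = {frozenset(e) for e in b}
    sk_u = {frozenset(e) for e in uni}
    k_s, f_s, p_s = _one(sk_a, sk_b, len(sk_u))
    return {"k_directed": k_d, "overlap_directed": f_d, "p_directed": p_d,
            "k_skeleton": k_s, "overlap_skeleton": f_s, "p_skeleton": p_s}


def structural_hamming_distance(edges_a, edges_b) -> int:
    """SHD between two directed graphs over the same node set."""
    a, b = set(edges_a), set(edges_b)
    pairs = {frozenset(e) for e in a | b}
    shd = 0
    for pair in pairs:
        u, v = sorted(pair)
        in_a = ((u, v) in a, (v, u) in a)
        in_b = ((u, v) in b, (v, u) in b)
        if in_a != in_b:
            shd += 1
    return shd
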