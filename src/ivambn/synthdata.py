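"""Synthetic fixtures with the statistical shape the model assumes.

Generates (i) planted-community knowledge graphs for the clustering stage
and (ii) mixed-type patient cohorts: latent module activities following a
linear-Gaussian DAG, gene features as noisy loadings of their module score,
ordinal clinical scores produced through the same thermometer link the
decoder uses, demographics, completely-at-random missingness and additive
batch offsets.  A fixed-seed ``worked_example`` miniature exercises the full
pipeline and doubles as the golden reproducibility fixture.

Cohort defaults mirror the training data the method targets: about 200
subjects, gene modules of a handful of genes plus singletons, an MMSE-like
0-30 score and a Braak-like 1-6 stage, sex/APOE/age/education demographics.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd

from . import kgraph as kg
from . import mbn as mbn_mod
from . import simulate as sim
from .hivae import ModalitySpec, fit_hivae
from .kgraph import KnowledgeGraph, ModulePartition

CAUSAL = ["increases", "decreases", "regulates"]


def make_toy_knowledge_graph(k_clusters: int, clique_size: int,
                             bridges: int = 1, noise_edges: int = 0,
                             seed: int = 0
                             ) -> tuple[KnowledgeGraph, ModulePartition]:
    """Planted causal communities: k cliques chained by bridge edges.

    Returns the graph and the ground-truth partition.  Within a clique every
    unordered gene pair gets one causal edge with random orientation and
    relation; ``bridges`` edges connect each consecutive clique pair;
    ``noise_edges`` extra random causal edges are sprinkled on top.
    """
    if k_clusters < 2:
        raise ValueError("need at least 2 clusters")
    rng = np.random.default_rng(seed)
    nodes: dict[str, str] = {}
    clusters: list[list[str]] = []
    for c in range(k_clusters):
        genes = [f"C{c}G{i}" for i in range(clique_size)]
        clusters.append(genes)
        for g in genes:
            nodes[g] = "gene"
    edges: set[tuple[str, str, str]] = set()
    for genes in clusters:
        for i in range(len(genes)):
            for j in range(i + 1, len(genes)):
                a, b = genes[i], genes[j]
                if rng.random() < 0.5:
                    a, b = b, a
                edges.add((a, CAUSAL[rng.integers(len(CAUSAL))], b))
    for c in range(k_clusters - 1):
        for _ in range(bridges):
            a = clusters[c][rng.integers(clique_size)]
            b = clusters[c + 1][rng.integers(clique_size)]
            edges.add((a, CAUSAL[rng.integers(len(CAUSAL))], b))
    names = sorted(nodes)
    tries = 0
    added = 0
    while added < noise_edges and tries < 100 * max(noise_edges, 1):
        tries += 1
        a, b = (names[i] for i in rng.integers(len(names), size=2))
        if a == b:
            continue
        e = (a, CAUSAL[rng.integers(len(CAUSAL))], b)
        if e not in edges:
            edges.add(e)
            added += 1
    truth = ModulePartition(assignment={
        g: c for c, genes in enumerate(clusters) for g in genes})
    return KnowledgeGraph(nodes=nodes, edges=sorted(edges)), truth


# ---------------------------------------------------------------------------
# Cohort generator

@dataclass
class OrdinalScore:
    """Ordinal clinical score generated through the thermometer link.

    category = 1 + #{theta_r < weight * latent + logistic noise}, mapped
    onto ``levels``.
    """

    name: str
    levels: list
    thresholds: list[float]
    weight: float
    parent: str = "phenotype"

    def __post_init__(self) -> None:
        if len(self.thresholds) != len(self.levels) - 1:
            raise ValueError(f"{self.name}: need |levels|-1 thresholds")
        if np.any(np.diff(self.thresholds) <= 0):
            raise ValueError(f"{self.name}: thresholds must increase")


@dataclass
class SyntheticScenario:
    """Ground-truth generative model of one synthetic cohort."""

    n_subjects: int = 200
    module_sizes: dict[str, int] = field(default_factory=lambda: {
        "CD33": 1, "M1": 4, "M2": 3, "M3": 3, "M4": 2})
    dag_edges: dict[tuple[str, str], float] = field(default_factory=dict)
    noise_sd: dict[str, float] = field(default_factory=dict)
    loading_noise_sd: float = 0.3
    ordinal_scores: list[OrdinalScore] = field(default_factory=list)
    demographics: dict[str, dict] = field(default_factory=lambda: {
        "age": {"kind": "normal", "mean": 88.0, "sd": 3.4},
        "education": {"kind": "normal", "mean": 16.0, "sd": 3.0},
        "sex": {"kind": "categorical", "levels": ["f", "m"], "probs": [0.7, 0.3]},
        "APOE": {"kind": "categorical", "levels": [0, 1], "probs": [0.62, 0.38]},
    })
    missingness: float = 0.0
    batch_offsets: dict[str, float] = field(default_factory=dict)
    # MCL granularity used when clustering the scenario's knowledge graph:
    # fine enough that a gene bridging two modules stays unclustered
    mcl_inflation: float = 4.0
    seed: int = 0

    def latent_nodes(self) -> list[str]:
        nodes = set(self.module_sizes) | {"phenotype"}
        for u, v in self.dag_edges:
            nodes.update([u, v])
        return sorted(nodes - set(self.demographics))

    def validate(self) -> None:
        g = nx.DiGraph(list(self.dag_edges))
        if not nx.is_directed_acyclic_graph(g):
            raise ValueError("scenario DAG is cyclic")
        for u, v in self.dag_edges:
            if u == "phenotype":
                raise ValueError("phenotype must be a sink")
            if v in self.demographics:
                raise ValueError("demographics must be sources")
        if not 0 <= self.missingness < 1:
            raise ValueError("missingness must be in [0, 1)")


def feature_names(sc: SyntheticScenario, module: str) -> list[str]:
    size = sc.module_sizes[module]
    if size == 1:
        return [module]
    return [f"{module}_g{i}" for i in range(size)]


def simulate_cohort(sc: SyntheticScenario) -> tuple[pd.DataFrame, dict]:
    """Sample a subject table plus all ground-truth parameters.

    Latent module activities follow the linear-Gaussian DAG (coefficients
    of continuous demographic parents act on their standardised values);
    features are unit loadings of their module score plus Gaussian noise;
    ordinal scores threshold a weighted latent with logistic noise.
    """
    sc.validate()
    rng = np.random.default_rng(sc.seed)
    n = sc.n_subjects
    data = pd.DataFrame(index=range(n))
    standardized: dict[str, np.ndarray] = {}
    for name in sorted(sc.demographics):
        spec = sc.demographics[name]
        if spec["kind"] == "normal":
            vals = spec["mean"] + spec["sd"] * rng.standard_normal(n)
            data[name] = vals
            standardized[name] = (vals - spec["mean"]) / spec["sd"]
        else:
            probs = np.asarray(spec["probs"], dtype=float)
            idx = rng.choice(len(probs), size=n, p=probs / probs.sum())
            data[name] = [spec["levels"][i] for i in idx]

    dag = nx.DiGraph()
    dag.add_nodes_from(sc.latent_nodes())
    dag.add_edges_from(sc.dag_edges)
    scores = pd.DataFrame(index=range(n))
    for node in nx.lexicographical_topological_sort(dag):
        if node in sc.demographics:
            continue
        mean = np.zeros(n)
        for parent in dag.predecessors(node):
            beta = sc.dag_edges[(parent, node)]
            pv = (standardized[parent] if parent in standardized
                  else scores[parent].to_numpy())
            mean = mean + beta * pv
        sd = sc.noise_sd.get(node, 1.0)
        scores[node] = mean + sd * rng.standard_normal(n)

    for module in sorted(sc.module_sizes):
        for feat in feature_names(sc, module):
            data[feat] = (scores[module].to_numpy()
                          + sc.loading_noise_sd * rng.standard_normal(n))

    for osc in sc.ordinal_scores:
        h = osc.weight * scores[osc.parent].to_numpy()
        noise = rng.logistic(size=n)
        theta = np.asarray(osc.thresholds)
        cat = (theta[None, :] < (h + noise)[:, None]).sum(axis=1)
        data[osc.name] = [osc.levels[c] for c in cat]

    feature_cols = [f for m in sc.module_sizes for f in feature_names(sc, m)
                    if sc.module_sizes[m] > 1]
    if sc.missingness > 0 and feature_cols:
        mask = rng.random((n, len(feature_cols))) < sc.missingness
        block = data[feature_cols].to_numpy(dtype=float)
        block[mask] = np.nan
        data[feature_cols] = block

    if sc.batch_offsets:
        batches = sorted(sc.batch_offsets)
        assign = np.array(batches)[np.arange(n) % len(batches)]
        data["batch"] = assign
        gene_cols = [f for m in sc.module_sizes for f in feature_names(sc, m)]
        for b in batches:
            rows = assign == b
            data.loc[rows, gene_cols] += sc.batch_offsets[b]

    truth = {"scores": scores, "dag_edges": dict(sc.dag_edges),
             "noise_sd": dict(sc.noise_sd), "scenario": sc}
    return data, truth


# ---------------------------------------------------------------------------
# The worked example: a fixed-seed miniature of the whole pipeline

def default_scenario(seed: int = 7) -> SyntheticScenario:
    """The study-shaped default: 200 subjects, 6 modules, planted CD33 path.

    CD33 feeds two gene cascades whose final modules suppress the phenotype
    latent, so a CD33 down-expression is planted to *raise* the MMSE-like
    score and *lower* the Braak-like stage.
    """
    mmse_levels = list(range(0, 31))
    braak_levels = list(range(1, 7))
    return SyntheticScenario(
        n_subjects=200,
        module_sizes={"CD33": 1, "M1": 4, "M2": 3, "M3": 3, "M4": 2},
        dag_edges={
            ("age", "CD33"): 0.4,
            ("CD33", "M1"): 0.8,
            ("M1", "M2"): 0.7,
            ("CD33", "M3"): 0.6,
            ("M3", "M4"): 0.5,
            ("M2", "phenotype"): -0.6,
            ("M3", "phenotype"): -0.4,
            ("education", "M4"): 0.5,
            ("M4", "phenotype"): 0.3,
        },
        noise_sd={"CD33": 1.0, "M1": 0.6, "M2": 0.6, "M3": 0.6, "M4": 0.8,
                  "phenotype": 0.5},
        ordinal_scores=[
            OrdinalScore(name="MMSE", levels=mmse_levels,
                         thresholds=list(np.linspace(-2.8, 2.8, 30)),
                         weight=2.0),
            OrdinalScore(name="Braak", levels=braak_levels,
                         thresholds=list(np.linspace(-1.6, 1.6, 5)),
                         weight=-2.0),
        ],
        missingness=0.05,
        seed=seed,
    )


def _scenario_knowledge_graph(sc: SyntheticScenario, seed: int
                              ) -> KnowledgeGraph:
    """Gene-level causal graph consistent with the scenario's module DAG."""
    rng = np.random.default_rng(seed)
    nodes: dict[str, str] = {}
    edges: set[tuple[str, str, str]] = set()
    for module in sorted(sc.module_sizes):
        feats = feature_names(sc, module)
        for f in feats:
            nodes[f] = "gene"
        for i in range(len(feats)):
            for j in range(i + 1, len(feats)):
                a, b = feats[i], feats[j]
                if rng.random() < 0.5:
                    a, b = b, a
                edges.add((a, CAUSAL[rng.integers(len(CAUSAL))], b))
    for (u, v) in sorted(sc.dag_edges):
        if u in sc.module_sizes and v in sc.module_sizes:
            src = feature_names(sc, u)
            dst = feature_names(sc, v)
            edges.add((src[0], "increases", dst[0]))
            if len(src) == 1 and len(dst) > 1:
                # balance a singleton gene's attachments so clustering can
                # recognise it as bridging rather than belonging
                edges.add((src[0], "increases", dst[1]))
    return KnowledgeGraph(nodes=nodes, edges=sorted(edges))


def _match_modules(partition: ModulePartition, sc: SyntheticScenario
                   ) -> dict[int, str]:
    """Map learned module ids onto scenario module names by membership."""
    gene2true = {f: m for m in sc.module_sizes for f in feature_names(sc, m)}
    mapping: dict[int, str] = {}
    for mid, genes in partition.modules().items():
        votes = pd.Series([gene2true[g] for g in genes if g in gene2true])
        mapping[mid] = votes.mode().iloc[0] if len(votes) else f"module{mid}"
    return mapping


def worked_example(out_dir: str | Path | None = None, seed: int = 7,
                   hivae_epochs: int = 150, bootstrap_b: int = 30) -> dict:
    """Run the full pipeline shape on the fixed default scenario.

    Knowledge graph -> clustering -> module graph -> per-module HI-VAEs ->
    constrained bootstrap structure learning -> consensus network -> 9-fold
    CD33 down-expression -> effect tests and gene-set score test.  With
    ``out_dir`` the key outputs are written as deterministic text files.
    """
    sc = default_scenario(seed=seed)
    data, truth = simulate_cohort(sc)

    graph = _scenario_knowledge_graph(sc, seed=seed + 1)
    filtered = kg.filter_causal_gene_graph(graph)
    partition = kg.assign_modules(
        kg.markov_cluster(filtered, inflation=sc.mcl_inflation), filtered)
    module_graph = kg.derive_module_graph(partition, filtered)
    name_of = _match_modules(partition, sc)
    named_edges = {(name_of[u], name_of[v]) for u, v in module_graph.edges}

    gene_sets = {f"SET_{m}": set(feature_names(sc, m))
                 for m in sc.module_sizes if sc.module_sizes[m] > 1}
    enrichment = kg.enrich_modules(partition, gene_sets)

    # per-module HI-VAEs (singletons stay raw identity nodes)
    codecs: dict[str, sim.IdentityCodec | sim.HivaeCodec] = {}
    scores = pd.DataFrame(index=data.index)
    for i, module in enumerate(sorted(sc.module_sizes)):
        feats = feature_names(sc, module)
        if len(feats) == 1:
            codecs[module] = sim.IdentityCodec(feats[0])
        else:
            specs = [ModalitySpec(name=f, kind="real") for f in feats]
            model = fit_hivae(data[feats],
                              specs, {"seed": seed + 10 + i,
                                      "epochs": hivae_epochs})
            codecs[module] = sim.HivaeCodec(model)
        scores[module] = codecs[module].encode(data)
    pheno_specs = [ModalitySpec(name=o.name, kind="ordinal", levels=o.levels)
                   for o in sc.ordinal_scores]
    pheno_model = fit_hivae(data[[o.name for o in sc.ordinal_scores]],
                            pheno_specs, {"seed": seed + 99,
                                          "epochs": hivae_epochs})
    codecs["phenotype"] = sim.HivaeCodec(pheno_model)
    scores["phenotype"] = codecs["phenotype"].encode(data)

    node_frame = scores.copy()
    for demo in sorted(sc.demographics):
        node_frame[demo] = data[demo]
    kinds = {c: "gaussian" for c in scores.columns}
    kinds.update({"age": "gaussian", "education": "gaussian",
                  "sex": "discrete", "APOE": "discrete"})
    roles = {c: "module" for c in scores.columns}
    roles.update({"age": "age", "education": "demographic",
                  "sex": "demographic", "APOE": "demographic",
                  "phenotype": "phenotype"})
    constraints = mbn_mod.build_constraints(
        sorted(e for e in named_edges if e[0] != e[1]), roles,
        strategy="knowledge_informed")
    boot, consensus = mbn_mod.bootstrap_structure(
        node_frame, kinds, constraints, B=bootstrap_b, threshold=0.4,
        seed=seed + 500)

    ivambn = sim.IvambnModel(mbn=consensus, codecs=codecs)
    spec = sim.PerturbationSpec(target="CD33", fold=9.0, direction="down")
    result = sim.perturb(ivambn, data, spec, seed=seed + 900)
    effects = sim.perturbation_effect_tests(result.baseline_features,
                                            result.perturbed_features)

    gene_cols = [f for m in sc.module_sizes for f in feature_names(sc, m)]
    expr = pd.concat([result.baseline_features[gene_cols],
                      result.perturbed_features[gene_cols]])
    expr = expr.fillna(expr.mean())
    cond = ["baseline"] * len(data) + ["perturbed"] * len(data)
    geneset = sim.gene_set_score_test(
        expr.reset_index(drop=True), cond,
        {m: feature_names(sc, m) for m in sc.module_sizes},
        perms=1000, seed=seed + 1300)

    pheno_shift = {}
    for o in sc.ordinal_scores:
        base = pd.to_numeric(result.baseline_features[o.name])
        pert = pd.to_numeric(result.perturbed_features[o.name])
        pheno_shift[o.name] = float(pert.mean() - base.mean())

    bundle = {
        "scenario": sc, "data": data, "truth": truth,
        "partition": partition, "module_graph": module_graph,
        "module_names": name_of, "enrichment": enrichment,
        "scores": node_frame, "constraints": constraints,
        "bootstrap": boot, "consensus": consensus, "ivambn": ivambn,
        "perturbation": result, "effects": effects, "geneset": geneset,
        "phenotype_shift": pheno_shift, "seed": seed,
    }
    if out_dir is not None:
        write_golden(bundle, out_dir)
    return bundle


def write_golden(bundle: dict, out_dir: str | Path) -> None:
    """Write the deterministic text outputs of a worked-example run."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    fmt = "%.10g"
    bundle["partition"].to_frame().to_csv(out / "modules.tsv", sep="\t",
                                          index=False)
    bundle["module_graph"].to_frame().to_csv(out / "module_graph.tsv",
                                             sep="\t", index=False)
    edges = pd.DataFrame(sorted(bundle["consensus"].edges),
                         columns=["from", "to"])
    edges.to_csv(out / "consensus_edges.tsv", sep="\t", index=False)
    bundle["bootstrap"].table.to_csv(out / "bootstrap.tsv", sep="\t",
                                     index=False, float_format=fmt)
    bundle["effects"].to_csv(out / "effects.csv", index=False, float_format=fmt)
    bundle["geneset"].to_csv(out / "geneset.csv", index=False, float_format=fmt)
    with open(out / "summary.json", "w") as fh:
        json.dump({"phenotype_shift": bundle["phenotype_shift"],
                   "seed": bundle["seed"]}, fh, indent=2, sort_keys=True)
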