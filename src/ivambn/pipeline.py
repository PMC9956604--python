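"""End-to-end orchestration with config, manifest and per-stage resume.

A run directory is built in stages — synth (optional) -> kgraph -> hivae ->
mbn -> simulate — each a pure function of its inputs, the config and the
seeds recorded in the manifest.  Completed stages whose output hashes match
the manifest are skipped on rerun, which keeps long bootstrap runs
resumable; rerunning with the same seeds reproduces identical hashes.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import kgraph as kg, mbn as mbn_mod, simulate as sim
from .hivae import HivaeModel, ModalitySpec, fit_hivae
from .synthdata import (SyntheticScenario, _scenario_knowledge_graph,
                        default_scenario, feature_names, simulate_cohort)

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Validated configuration of one pipeline run."""

    out_dir: str
    seed: int = 7
    scenario: str | None = "default"      # None: inputs supplied as files
    edges: str | None = None
    types: str | None = None
    gmt: str | None = None
    data: str | None = None
    model_spec: str | None = None
    inflation: float = 4.0   # matches the default scenario's granularity
    strategy: str = "knowledge_informed"
    sub_option: str = "both"
    hivae_epochs: int = 150
    bootstrap_b: int = 30
    threshold: float = 0.4
    perturbation: dict = field(default_factory=lambda: {
        "target": "CD33", "fold": 9.0, "direction": "down"})
    geneset_perms: int = 1000

    @classmethod
    def from_yaml(cls, path: str) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        cfg = cls(**raw)
        cfg.validate()
        return cfg

    def validate(self) -> None:
        if self.scenario is None:
            for key in ("edges", "types", "data", "model_spec"):
                val = getattr(self, key)
                if val is None:
                    raise ValueError(f"file-driven run needs {key!r}")
                if not Path(val).exists():
                    raise FileNotFoundError(f"{key}: {val} does not exist")


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


class _Manifest:
    def __init__(self, out: Path):
        from . import __version__
        self.path = out / "manifest.json"
        self.data: dict = {"version": __version__, "stages": {}}
        if self.path.exists():
            self.data = json.loads(self.path.read_text())

    def stage_done(self, name: str, out: Path) -> bool:
        st = self.data["stages"].get(name)
        if not st:
            return False
        for rel, digest in st["outputs"].items():
            f = out / rel
            if not f.exists() or _sha256(f) != digest:
                return False
        return True

    def record(self, name: str, out: Path, files: list[str], seed: int) -> None:
        self.data["stages"][name] = {
            "seed": seed,
            "outputs": {rel: _sha256(out / rel) for rel in files},
        }
        self.path.write_text(json.dumps(self.data, indent=2, sort_keys=True))


# ---------------------------------------------------------------------------
# model spec (which features form which module, node kinds and roles)

def write_model_spec(sc: SyntheticScenario, path: Path) -> None:
    modules: dict = {}
    for m in sorted(sc.module_sizes):
        feats = feature_names(sc, m)
        if len(feats) == 1:
            continue
        modules[m] = {"features": {f: "real" for f in feats}, "role": "module"}
    modules["phenotype"] = {
        "features": {o.name: {"kind": "ordinal", "levels": list(o.levels)}
                     for o in sc.ordinal_scores},
        "role": "phenotype"}
    raw_nodes: dict = {}
    for m in sorted(sc.module_sizes):
        if sc.module_sizes[m] == 1:
            raw_nodes[m] = {"kind": "gaussian", "role": "module"}
    for d, spec in sorted(sc.demographics.items()):
        raw_nodes[d] = {"kind": "gaussian" if spec["kind"] == "normal"
                        else "discrete",
                        "role": "age" if d == "age" else "demographic"}
    with open(path, "w") as fh:
        yaml.safe_dump({"modules": modules, "raw_nodes": raw_nodes}, fh,
                       sort_keys=True)


def _parse_feature(name: str, spec) -> ModalitySpec:
    if isinstance(spec, str):
        return ModalitySpec(name=name, kind=spec)
    return ModalitySpec(name=name, kind=spec["kind"],
                        levels=spec.get("levels"), R=spec.get("R"))


def load_model_spec(path: Path) -> dict:
    with open(path) as fh:
        return yaml.safe_load(fh)


# ---------------------------------------------------------------------------
# stages

def _stage_synth(cfg: RunConfig, out: Path) -> list[str]:
    sc = default_scenario(seed=cfg.seed) if cfg.scenario == "default" else None
    if sc is None:
        with open(cfg.scenario) as fh:
            raw = yaml.safe_load(fh)
        raw["seed"] = raw.get("seed", cfg.seed)
        sc = SyntheticScenario(**raw)
    data, _ = simulate_cohort(sc)
    data.to_csv(out / "data.csv", index=False, float_format="%.10g")
    graph = _scenario_knowledge_graph(sc, seed=cfg.seed + 1)
    pd.DataFrame(graph.edges, columns=["src", "relation", "dst"]).to_csv(
        out / "edges.tsv", sep="\t", index=False)
    pd.DataFrame(sorted(graph.nodes.items()), columns=["node", "ntype"]).to_csv(
        out / "types.tsv", sep="\t", index=False)
    with open(out / "sets.gmt", "w") as fh:
        for m in sorted(sc.module_sizes):
            if sc.module_sizes[m] > 1:
                fh.write("\t".join([f"SET_{m}", "synthetic"]
                                   + feature_names(sc, m)) + "\n")
    write_model_spec(sc, out / "model.yaml")
    return ["data.csv", "edges.tsv", "types.tsv", "sets.gmt", "model.yaml"]


def _stage_kgraph(cfg: RunConfig, out: Path, edges: str, types: str,
                  gmt: str | None, spec: dict) -> list[str]:
    graph = kg.load_graph(edges, types)
    filtered = kg.filter_causal_gene_graph(graph)
    partition = kg.assign_modules(
        kg.markov_cluster(filtered, inflation=cfg.inflation), filtered)
    module_graph = kg.derive_module_graph(partition, filtered)
    kg.write_partition(partition, out / "modules.tsv")
    kg.write_module_graph(module_graph, out / "module_graph.tsv")
    files = ["modules.tsv", "module_graph.tsv"]
    if gmt:
        enrich = kg.enrich_modules(partition, kg.read_gmt(gmt))
        enrich.to_csv(out / "enrichment.csv", index=False, float_format="%.10g")
        files.append("enrichment.csv")
    # map learned module ids onto declared module names by feature majority
    feat2module = {}
    for m, mspec in spec["modules"].items():
        for f in mspec["features"]:
            feat2module[f] = m
    for node, nspec in spec.get("raw_nodes", {}).items():
        if nspec.get("role") == "module":
            feat2module[node] = node
    name_rows = []
    for mid, genes in partition.modules().items():
        votes = pd.Series([feat2module[g] for g in genes if g in feat2module])
        name = votes.mode().iloc[0] if len(votes) else f"module{mid}"
        name_rows.append({"module": mid, "name": name})
    names = pd.DataFrame(name_rows).set_index("module")["name"]
    mg_named = sorted({(names[u], names[v]) for u, v in module_graph.edges
                       if names[u] != names[v]})
    pd.DataFrame(mg_named, columns=["from", "to"]).to_csv(
        out / "module_graph_named.tsv", sep="\t", index=False)
    files.append("module_graph_named.tsv")
    return files


def _build_codecs(spec: dict, data: pd.DataFrame, out: Path, seed: int,
                  epochs: int, fit: bool = True) -> dict:
    codecs: dict = {}
    ckpt = out / "checkpoints"
    ckpt.mkdir(exist_ok=True)
    for i, (module, mspec) in enumerate(sorted(spec["modules"].items())):
        specs = [_parse_feature(f, s) for f, s in sorted(mspec["features"].items())]
        path = ckpt / f"{module}.npz"
        if fit:
            model = fit_hivae(data[[s.name for s in specs]], specs,
                              {"seed": seed + 10 + i, "epochs": epochs})
            model.save(path)
        else:
            model = HivaeModel.load(path)
        codecs[module] = sim.HivaeCodec(model)
    for node, nspec in spec.get("raw_nodes", {}).items():
        if nspec.get("role") == "module" and nspec["kind"] == "gaussian":
            codecs[node] = sim.IdentityCodec(node)
    return codecs


def _node_tables(spec: dict, data: pd.DataFrame, codecs: dict):
    scores = pd.DataFrame(index=data.index)
    kinds: dict[str, str] = {}
    roles: dict[str, str] = {}
    for module, mspec in sorted(spec["modules"].items()):
        scores[module] = codecs[module].encode(data)
        kinds[module] = "gaussian"
        roles[module] = mspec.get("role", "module")
    for node, nspec in sorted(spec.get("raw_nodes", {}).items()):
        scores[node] = (data[node] if nspec["kind"] == "discrete"
                        else data[node].astype(float))
        kinds[node] = nspec["kind"]
        roles[node] = nspec.get("role", "module")
        if node in codecs:
            scores[node] = codecs[node].encode(data)
    return scores, kinds, roles


def _stage_mbn(cfg: RunConfig, out: Path, scores, kinds, roles) -> list[str]:
    mg = pd.read_csv(out / "module_graph_named.tsv", sep="\t")
    mg_edges = [(r["from"], r["to"]) for _, r in mg.iterrows()
                if r["from"] in roles and r["to"] in roles]
    constraints = mbn_mod.build_constraints(mg_edges, roles, cfg.strategy,
                                            sub_option=cfg.sub_option)
    boot, consensus = mbn_mod.bootstrap_structure(
        scores, kinds, constraints, B=cfg.bootstrap_b,
        threshold=cfg.threshold, seed=cfg.seed + 500)
    boot.table.to_csv(out / "bootstrap.tsv", sep="\t", index=False,
                      float_format="%.10g")
    pd.DataFrame(sorted(consensus.edges), columns=["from", "to"]).to_csv(
        out / "consensus_edges.tsv", sep="\t", index=False)
    return ["bootstrap.tsv", "consensus_edges.tsv"]


def _stage_simulate(cfg: RunConfig, out: Path, spec: dict, data, scores,
                    kinds, codecs) -> list[str]:
    import networkx as nx
    edges = pd.read_csv(out / "consensus_edges.tsv", sep="\t")
    g = nx.DiGraph()
    g.add_nodes_from(scores.columns)
    g.add_edges_from([(r["from"], r["to"]) for _, r in edges.iterrows()])
    consensus = mbn_mod.fit_parameters(g, scores, kinds)
    ivambn = sim.IvambnModel(mbn=consensus, codecs=codecs)
    pspec = sim.PerturbationSpec(**cfg.perturbation)
    result = sim.perturb(ivambn, data, pspec, seed=cfg.seed + 900)
    effects = sim.perturbation_effect_tests(result.baseline_features,
                                            result.perturbed_features)
    effects.to_csv(out / "effects.csv", index=False, float_format="%.10g")
    gene_sets = {m: sorted(mspec["features"])
                 for m, mspec in spec["modules"].items()
                 if mspec.get("role", "module") == "module"}
    gene_cols = sorted({f for fs in gene_sets.values() for f in fs})
    expr = pd.concat([result.baseline_features[gene_cols],
                      result.perturbed_features[gene_cols]])
    expr = expr.fillna(expr.mean()).reset_index(drop=True)
    cond = ["baseline"] * len(data) + ["perturbed"] * len(data)
    geneset = sim.gene_set_score_test(expr, cond, gene_sets,
                                      perms=cfg.geneset_perms,
                                      seed=cfg.seed + 1300)
    geneset.to_csv(out / "geneset.csv", index=False, float_format="%.10g")
    pheno_feats = [f for m, mspec in spec["modules"].items()
                   if mspec.get("role") == "phenotype"
                   for f in sorted(mspec["features"])]
    shift = {f: float(pd.to_numeric(result.perturbed_features[f]).mean()
                      - pd.to_numeric(result.baseline_features[f]).mean())
             for f in pheno_feats}
    with open(out / "summary.json", "w") as fh:
        json.dump({"phenotype_shift": shift, "seed": cfg.seed,
                   "target": pspec.target}, fh, indent=2, sort_keys=True)
    return ["effects.csv", "geneset.csv", "summary.json"]


def run_pipeline(cfg: RunConfig) -> Path:
    """Execute all stages into ``cfg.out_dir``; resume completed stages."""
    cfg.validate()
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = _Manifest(out)

    if cfg.scenario is not None:
        if not manifest.stage_done("synth", out):
            files = _stage_synth(cfg, out)
            manifest.record("synth", out, files, cfg.seed)
        edges, types, gmt = (str(out / "edges.tsv"), str(out / "types.tsv"),
                             str(out / "sets.gmt"))
        data_path, spec_path = out / "data.csv", out / "model.yaml"
    else:
        edges, types, gmt = cfg.edges, cfg.types, cfg.gmt
        data_path, spec_path = Path(cfg.data), Path(cfg.model_spec)

    spec = load_model_spec(spec_path)
    data = pd.read_csv(data_path)

    if not manifest.stage_done("kgraph", out):
        files = _stage_kgraph(cfg, out, edges, types, gmt, spec)
        manifest.record("kgraph", out, files, cfg.seed)

    hivae_done = manifest.stage_done("hivae", out) and all(
        (out / "checkpoints" / f"{m}.npz").exists()
        for m in spec["modules"])
    codecs = _build_codecs(spec, data, out, cfg.seed, cfg.hivae_epochs,
                           fit=not hivae_done)
    scores, kinds, roles = _node_tables(spec, data, codecs)
    if not hivae_done:
        scores.to_csv(out / "scores.csv", index=False, float_format="%.10g")
        # checkpoints are binary runtime artifacts; the manifest tracks the
        # deterministic text outputs (npz archives embed zip timestamps)
        manifest.record("hivae", out, ["scores.csv"], cfg.seed)

    if not manifest.stage_done("mbn", out):
        files = _stage_mbn(cfg, out, scores, kinds, roles)
        manifest.record("mbn", out, files, cfg.seed)

    if not manifest.stage_done("simulate", out):
        files = _stage_simulate(cfg, out, spec, data, scores, kinds, codecs)
        manifest.record("simulate", out, files, cfg.seed)
    logger.info("pipeline complete: %s", out)
    return out
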