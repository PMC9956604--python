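"""Generative use of the fitted model: sampling, prediction, interventions.

The fitted network over module scores is a generative model: ancestral
sampling in topological order produces synthetic subjects whose module
scores are decoded back to feature space through the per-module
autoencoders.  A counterfactual perturbation (e.g. a 9-fold down-expression
of one gene) shifts the target feature, re-encodes its module, *mutilates*
the network by deleting the module node's incoming edges (the
do-intervention), resamples all descendants, and decodes — non-descendants
are copied from baseline so that every downstream difference is causal.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .hivae import HivaeModel
from .mbn import MbnModel

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# Codecs: map between one module's features and its scalar activity score

class IdentityCodec:
    """Codec for a single raw continuous feature (singleton gene module)."""

    def __init__(self, feature: str):
        self.features = [feature]

    def encode(self, df: pd.DataFrame) -> np.ndarray:
        return df[self.features[0]].to_numpy(dtype=float)

    def decode(self, scores, rng=None, mode: str = "mean") -> pd.DataFrame:
        return pd.DataFrame({self.features[0]: np.asarray(scores, dtype=float)})


class HivaeCodec:
    """Codec backed by a trained HI-VAE with a scalar latent."""

    def __init__(self, model: HivaeModel):
        if model.latent_dim != 1:
            raise ValueError("MBN integration expects latent_dim == 1")
        self.model = model
        self.features = model.feature_names

    def encode(self, df: pd.DataFrame) -> np.ndarray:
        return self.model.encode(df)[:, 0]

    def decode(self, scores, rng=None, mode: str = "sample") -> pd.DataFrame:
        return self.model.decode(np.asarray(scores, dtype=float)[:, None],
                                 rng=rng, mode=mode)


@dataclass
class IvambnModel:
    """Fitted network plus the codec of every module node.

    Nodes without a codec are raw features (demographics, discrete
    variables) whose node values are the feature values themselves.
    """

    mbn: MbnModel
    codecs: dict[str, IdentityCodec | HivaeCodec] = field(default_factory=dict)

    def encode_data(self, data: pd.DataFrame) -> pd.DataFrame:
        """Node-value table: codec scores for modules, raw columns otherwise."""
        cols: dict[str, np.ndarray | pd.Series] = {}
        for node in self.mbn.nodes:
            if node in self.codecs:
                cols[node] = self.codecs[node].encode(data)
            else:
                cols[node] = data[node].to_numpy()
        return pd.DataFrame(cols, index=data.index)

    def node_of_feature(self, feature: str) -> str:
        for node, codec in self.codecs.items():
            if feature in codec.features:
                return node
        if feature in self.mbn.graph.nodes:
            return feature
        raise KeyError(f"feature {feature!r} not in any module or node")


@dataclass
class PerturbationSpec:
    """A fold-change intervention on one feature.

    ``fold`` > 1; ``direction`` up/down; the shift is +/- log2(fold) divided
    by the control standard deviation (1 on the abnormality scale).
    """

    target: str
    fold: float = 9.0
    direction: str = "down"
    scale: str = "abnormality"
    sd_ctrl: float = 1.0

    def __post_init__(self) -> None:
        if self.fold <= 1:
            raise ValueError("fold must be > 1")
        if self.direction not in {"up", "down"}:
            raise ValueError("direction must be 'up' or 'down'")
        if self.scale not in {"abnormality", "log2cpm"}:
            raise ValueError("scale must be 'abnormality' or 'log2cpm'")

    @property
    def shift(self) -> float:
        delta = np.log2(self.fold)
        if self.scale == "abnormality":
            delta /= self.sd_ctrl
        return -delta if self.direction == "down" else delta


@dataclass
class SimulationResult:
    """Matched baseline / perturbed tables of scores and decoded features."""

    baseline_scores: pd.DataFrame
    baseline_features: pd.DataFrame
    perturbed_scores: pd.DataFrame
    perturbed_features: pd.DataFrame
    seed: int | None = None
    target_node: str | None = None


# ---------------------------------------------------------------------------
# Ancestral sampling

def _sample_node(model: MbnModel, node: str, current: pd.DataFrame,
                 rng: np.random.Generator) -> np.ndarray | list:
    """Draw node values from its local conditional given ``current``."""
    p = model.params[node]
    n = len(current)
    if p["type"] == "gaussian":
        dparents = p["discrete_parents"]
        cparents = p["continuous_parents"]
        out = np.empty(n)
        if dparents:
            groups = current.groupby(dparents, sort=True).indices.items()
        else:
            groups = [((), np.arange(n))]
        for cfg, idx in groups:
            cfg = cfg if isinstance(cfg, tuple) else (cfg,)
            sp = p["strata"].get(cfg, p["pooled"])
            mean = np.full(len(idx), sp["intercept"])
            coefs = sp["coefs"]
            use_parents = cparents if len(coefs) else []
            for c, b in zip(use_parents, coefs):
                mean += b * current[c].to_numpy(dtype=float)[idx]
            out[idx] = mean + sp["sd"] * rng.standard_normal(len(idx))
        return out
    levels = p["levels"]
    dparents = p["parents"]
    out_idx = np.empty(n, dtype=int)
    if dparents:
        groups = current.groupby(dparents, sort=True).indices.items()
    else:
        groups = [((), np.arange(n))]
    for cfg, idx in groups:
        cfg = cfg if isinstance(cfg, tuple) else (cfg,)
        probs = p["cpt"].get(cfg, np.full(len(levels), 1.0 / len(levels)))
        cum = np.cumsum(probs)
        u = rng.random(len(idx))
        out_idx[idx] = (u[:, None] > cum[None, :]).sum(axis=1)
    return [levels[i] for i in out_idx]


def ancestral_sample(model: IvambnModel | MbnModel, n: int, seed: int = 0,
                     codecs: dict | None = None,
                     decode_mode: str = "sample") -> SimulationResult:
    """Sample ``n`` synthetic subjects from the generative model.

    Nodes are drawn in topological order from their local conditionals;
    module scores are decoded into features through the codecs (a draw from
    each feature likelihood by default).
    """
    if isinstance(model, MbnModel):
        model = IvambnModel(mbn=model, codecs=codecs or {})
    g = model.mbn.graph
    if not nx.is_directed_acyclic_graph(g):
        raise ValueError("model graph contains a cycle")
    rng = np.random.default_rng(seed)
    order = list(nx.lexicographical_topological_sort(g))
    current = pd.DataFrame(index=range(n))
    for node in order:
        current[node] = _sample_node(model.mbn, node, current, rng)
    feats: list[pd.DataFrame] = []
    for node in model.mbn.nodes:
        if node in model.codecs:
            df = model.codecs[node].decode(
                current[node].to_numpy(dtype=float), rng=rng, mode=decode_mode)
            df.index = current.index
            feats.append(df)
        else:
            feats.append(current[[node]])
    features = pd.concat(feats, axis=1)
    return SimulationResult(baseline_scores=current, baseline_features=features,
                            perturbed_scores=current, perturbed_features=features,
                            seed=seed)


# ---------------------------------------------------------------------------
# Model-fit evaluation

def _kl_hist(real: np.ndarray, synth: np.ndarray, bins: int = 20) -> float:
    lo = min(real.min(), synth.min())
    hi = max(real.max(), synth.max())
    if hi == lo:
        hi = lo + 1.0
    edges = np.linspace(lo, hi, bins + 1)
    cr = np.histogram(real, bins=edges)[0] + 1.0      # pseudo-count 1
    cs = np.histogram(synth, bins=edges)[0] + 1.0
    p = cr / cr.sum()
    q = cs / cs.sum()
    return float((p * np.log(p / q)).sum())


def evaluate_fit(real: pd.DataFrame, synth: pd.DataFrame,
                 bins: int = 20) -> dict:
    """Marginal KL divergences, summary statistics and correlation distance.

    Continuous variables use ``bins``-bin histograms with pseudo-count 1;
    discrete variables use plug-in category frequencies.  The correlation
    term is the Frobenius distance between the correlation matrices of the
    shared numeric columns.
    """
    kl: dict[str, float] = {}
    rows = []
    shared = [c for c in real.columns if c in synth.columns]
    for c in real.columns:
        if c not in synth.columns:
            logger.info("evaluate_fit: %s absent in synthetic table, skipped", c)
    numeric = [c for c in shared
               if pd.api.types.is_float_dtype(real[c])
               and pd.api.types.is_float_dtype(synth[c])]
    for c in shared:
        r = real[c].dropna()
        s = synth[c].dropna()
        if c in numeric:
            kl[c] = _kl_hist(r.to_numpy(dtype=float), s.to_numpy(dtype=float),
                             bins=bins)
            rows.append({"variable": c, "real_mean": r.mean(), "synth_mean": s.mean(),
                         "real_sd": r.std(), "synth_sd": s.std()})
        else:
            cats = sorted(set(r) | set(s), key=str)
            p = np.array([max((r == cat).mean(), 1e-12) for cat in cats])
            q = np.array([max((s == cat).mean(), 1e-12) for cat in cats])
            kl[c] = float((p * np.log(p / q)).sum())
            rows.append({"variable": c, "real_mean": np.nan, "synth_mean": np.nan,
                         "real_sd": np.nan, "synth_sd": np.nan})
    corr_dist = np.nan
    if len(numeric) >= 2:
        cr = real[numeric].corr().to_numpy()
        cs = synth[numeric].corr().to_numpy()
        corr_dist = float(np.linalg.norm(cr - cs, "fro"))
    return {"kl": pd.Series(kl), "summary": pd.DataFrame(rows),
            "corr_frobenius": corr_dist}


# ---------------------------------------------------------------------------
# Conditional prediction

def _linear_system(model: MbnModel, cfg_row: pd.Series | None):
    """Joint-Gaussian (mu, Sigma) over continuous nodes implied by the CLG.

    ``cfg_row`` supplies the discrete-parent configuration (None when the
    network has no discrete nodes).
    """
    cont = [v for v in model.nodes if model.kinds[v] == "gaussian"]
    k = len(cont)
    pos = {v: i for i, v in enumerate(cont)}
    b = np.zeros((k, k))
    mu0 = np.zeros(k)
    d = np.zeros(k)
    for v in cont:
        p = model.params[v]
        cfg = (tuple(cfg_row[dp] for dp in p["discrete_parents"])
               if p["discrete_parents"] else ())
        sp = p["strata"].get(cfg, p["pooled"])
        mu0[pos[v]] = sp["intercept"]
        d[pos[v]] = sp["sd"] ** 2
        coefs = sp["coefs"]
        use_parents = p["continuous_parents"] if len(coefs) else []
        for c, beta in zip(use_parents, coefs):
            b[pos[v], pos[c]] = beta
    a = np.linalg.inv(np.eye(k) - b)
    mean = a @ mu0
    cov = a @ np.diag(d) @ a.T
    return cont, mean, cov


def predict_module_score(model: MbnModel, observed: pd.DataFrame, target: str,
                         truth: pd.Series | np.ndarray | None = None) -> dict:
    """Conditional mean of a continuous node given the other observed nodes.

    The fitted conditional-linear-Gaussian system implies a joint Gaussian
    over continuous nodes (per discrete configuration); the target is
    conditioned on all observed continuous nodes by standard Gaussian
    conditioning.  When ``truth`` is supplied the Pearson r and its
    Fisher-z 95% CI are reported.
    """
    if target in observed.columns:
        raise ValueError(f"target {target!r} must not be observed in the input")
    if model.kinds.get(target) != "gaussian":
        raise ValueError(f"target {target!r} is not a continuous node")
    disc_cols = [c for c in observed.columns if model.kinds.get(c) == "discrete"]
    preds = np.empty(len(observed))
    groups = (observed.groupby(disc_cols, sort=True).indices.items()
              if disc_cols else [((), np.arange(len(observed)))])
    for cfg, idx in groups:
        cfg_row = (pd.Series(cfg if isinstance(cfg, tuple) else (cfg,),
                             index=disc_cols) if disc_cols else None)
        cont, mean, cov = _linear_system(model, cfg_row)
        obs_nodes = [c for c in cont if c in observed.columns]
        ti = cont.index(target)
        oi = [cont.index(c) for c in obs_nodes]
        if not oi:
            preds[idx] = mean[ti]
            continue
        sig_oo = cov[np.ix_(oi, oi)]
        sig_to = cov[ti, oi]
        w = np.linalg.solve(sig_oo, sig_to)
        x_o = observed.iloc[idx][obs_nodes].to_numpy(dtype=float)
        preds[idx] = mean[ti] + (x_o - mean[oi]) @ w
    out = {"predicted": pd.Series(preds, index=observed.index, name=target)}
    if truth is not None:
        t = np.asarray(truth, dtype=float)
        r = float(np.corrcoef(t, preds)[0, 1])
        n = len(t)
        z = np.arctanh(r)
        half = 1.959963984540054 / np.sqrt(n - 3)
        out.update({"r": r, "ci": (float(np.tanh(z - half)),
                                   float(np.tanh(z + half)))})
    return out


# ---------------------------------------------------------------------------
# Counterfactual perturbation

def perturb(model: IvambnModel, data: pd.DataFrame, spec: PerturbationSpec,
            seed: int = 0, decode_mode: str = "sample") -> SimulationResult:
    """Simulate a fold-change intervention on one feature.

    The target feature is shifted by the spec's log2-fold delta in every
    sample; its module is re-encoded (identity for singleton nodes), the
    module node's incoming edges are deleted (mutilation) and all
    descendants are resampled in topological order conditioning on the
    intervened values.  Non-descendants keep their baseline values.
    """
    rng = np.random.default_rng(seed)
    node = model.node_of_feature(spec.target)
    baseline_scores = model.encode_data(data)
    delta = spec.shift

    shifted = data[spec.target].to_numpy(dtype=float) + delta
    if node in model.codecs and len(model.codecs[node].features) > 1:
        codec = model.codecs[node]
        module_df = data[codec.features].copy()
        module_df[spec.target] = shifted
        intervened = codec.encode(module_df)
        intervened_features = module_df
    else:
        intervened = shifted
        intervened_features = pd.DataFrame({spec.target: shifted},
                                           index=data.index)

    g = model.mbn.graph
    descendants = nx.descendants(g, node)
    if not descendants:
        logger.warning("target node %s has no descendants: only the target "
                       "itself changes", node)
    mutilated = g.copy()
    mutilated.remove_edges_from(list(g.in_edges(node)))

    scores = baseline_scores.copy()
    scores[node] = intervened
    for v in nx.lexicographical_topological_sort(mutilated):
        if v in descendants:
            scores[v] = _sample_node(model.mbn, v, scores, rng)

    features = data.copy()
    for col in intervened_features.columns:
        features[col] = intervened_features[col]
    for v in sorted(descendants):
        if v in model.codecs:
            dec = model.codecs[v].decode(scores[v].to_numpy(dtype=float),
                                         rng=rng, mode=decode_mode)
            dec.index = features.index
            for col in dec.columns:
                features[col] = dec[col]
        elif v in features.columns:
            features[v] = scores[v]
    return SimulationResult(
        baseline_scores=baseline_scores, baseline_features=data.copy(),
        perturbed_scores=scores, perturbed_features=features,
        seed=seed, target_node=node)


# ---------------------------------------------------------------------------
# Downstream statistics

def perturbation_effect_tests(baseline: pd.DataFrame,
                              perturbed: pd.DataFrame) -> pd.DataFrame:
    """Per-feature regression of value on the condition indicator.

    Equivalent to the pooled two-sample t-test; ordinal scores are treated
    as numeric.  Returns (feature, estimate, p, q) with Benjamini-Hochberg
    q-values; constant features get NA with a note.
    """
    rows = []
    for col in baseline.columns:
        if col not in perturbed.columns:
            continue
        x = pd.to_numeric(baseline[col], errors="coerce").dropna()
        y = pd.to_numeric(perturbed[col], errors="coerce").dropna()
        if not len(x) or not len(y):
            rows.append({"feature": col, "estimate": np.nan, "p": np.nan,
                         "note": "non-numeric"})
            continue
        est = float(y.mean() - x.mean())
        pooled = np.concatenate([x, y])
        if pooled.std(ddof=0) == 0:
            rows.append({"feature": col, "estimate": est, "p": np.nan,
                         "note": "constant"})
            continue
        t, p = stats.ttest_ind(y, x, equal_var=True)
        rows.append({"feature": col, "estimate": est, "p": float(p), "note": ""})
    table = pd.DataFrame(rows)
    table["q"] = np.nan
    ok = table["p"].notna()
    if ok.any():
        table.loc[ok, "q"] = multipletests(table.loc[ok, "p"], method="fdr_bh")[1]
    return table


def gene_set_score_test(expr: pd.DataFrame, condition, sets: dict[str, list],
                        perms: int = 10_000, seed: int = 0) -> pd.DataFrame:
    """Global score test of gene sets against a two-group condition.

    For set S with column-standardised expression X_S (n x m_S) and centred
    condition indicator y:  Q_S = || X_S' y ||^2 / (m_S * sigma^2) with
    sigma^2 = Var(y).  The null is the permutation distribution of the
    condition labels (add-one corrected); BH across sets.
    """
    cond = pd.Series(condition).to_numpy()
    levels = sorted(pd.unique(cond), key=str)
    if len(levels) != 2:
        raise ValueError("condition must have exactly two levels")
    for lv in levels:
        if (cond == lv).sum() < 2:
            raise ValueError("need >= 2 samples per condition")
    y = (cond == levels[1]).astype(float)
    y -= y.mean()
    sigma2 = float((y ** 2).mean())
    rng = np.random.default_rng(seed)
    n = len(y)
    yp = np.stack([y[rng.permutation(n)] for _ in range(perms)], axis=1)

    rows = []
    for name in sorted(sets):
        genes = [g for g in sets[name] if g in expr.columns]
        if not genes:
            rows.append({"gene_set": name, "n_genes": 0, "Q": np.nan,
                         "p": np.nan, "note": "no measured genes"})
            continue
        x = expr[genes].to_numpy(dtype=float)
        x = x - x.mean(axis=0)
        sd = x.std(axis=0)
        sd[sd == 0] = 1.0
        x = x / sd
        m = x.shape[1]
        q_obs = float(((x.T @ y) ** 2).sum()) / (m * sigma2)
        q_perm = ((x.T @ yp) ** 2).sum(axis=0) / (m * sigma2)
        p = (1 + int((q_perm >= q_obs - 1e-12).sum())) / (perms + 1)
        rows.append({"gene_set": name, "n_genes": m, "Q": q_obs, "p": p,
                     "note": ""})
    table = pd.DataFrame(rows)
    table["q"] = np.nan
    ok = table["p"].notna()
    if ok.any():
        table.loc[ok, "q"] = multipletests(table.loc[ok, "p"], method="fdr_bh")[1]
    return table


def target_screen(model: IvambnModel, data: pd.DataFrame, phenotype_node: str,
                  fold: float = 9.0, seed: int = 0,
                  candidate_features: list[str] | None = None) -> pd.DataFrame:
    """Simulate up- and down-regulation of every phenotype-ancestor gene.

    Only genes whose module node is an ancestor of the phenotype node can
    affect the phenotype; others are excluded with a reason.  Reported per
    (gene, direction): the mean change of each phenotype feature (numeric)
    between perturbed and baseline.
    """
    g = model.mbn.graph
    if phenotype_node not in g.nodes:
        raise ValueError(f"phenotype node {phenotype_node!r} not in the graph")
    ancestors = nx.ancestors(g, phenotype_node)
    if not ancestors:
        logger.warning("phenotype node has no ancestors: empty screen")
    pheno_feats = (model.codecs[phenotype_node].features
                   if phenotype_node in model.codecs else [phenotype_node])
    if candidate_features is None:
        candidate_features = []
        for node in sorted(g.nodes()):
            if node == phenotype_node or model.mbn.kinds[node] != "gaussian":
                continue
            feats = (model.codecs[node].features if node in model.codecs
                     else [node])
            candidate_features.extend(f for f in feats if f in data.columns)
    rows = []
    for i, feat in enumerate(sorted(set(candidate_features))):
        node = model.node_of_feature(feat)
        if node == phenotype_node:
            continue
        if node not in ancestors:
            rows.append({"target": feat, "direction": "excluded",
                         "reason": "module not an ancestor of phenotype",
                         **{f"d_{pf}": np.nan for pf in pheno_feats}})
            continue
        for direction in ("down", "up"):
            spec = PerturbationSpec(target=feat, fold=fold, direction=direction)
            res = perturb(model, data, spec, seed=seed + i)
            deltas = {}
            for pf in pheno_feats:
                base = pd.to_numeric(res.baseline_features[pf], errors="coerce")
                pert = pd.to_numeric(res.perturbed_features[pf], errors="coerce")
                deltas[f"d_{pf}"] = float(pert.mean() - base.mean())
            rows.append({"target": feat, "direction": direction, "reason": "",
                         **deltas})
    return pd.DataFrame(rows)
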