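"""Expression preprocessing: logCPM, abnormality scores, batch adjustment.

Raw gene counts are normalised to log counts per million, case samples are
standardised against healthy controls of the same study (abnormality
scores), and residual cross-study batch effects are removed with a
parametric empirical-Bayes location/scale adjustment.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)


@dataclass
class AbnormalityMatrix:
    """Gene x case-sample abnormality scores plus control provenance."""

    scores: pd.DataFrame            # genes x case samples
    control_mean: pd.Series
    control_sd: pd.Series
    dropped_genes: list[str] = field(default_factory=list)


def logcpm(counts: pd.DataFrame, pseudocount: float = 0.5) -> pd.DataFrame:
    """log2 counts-per-million: log2((c + pc) / (lib + pc*G) * 1e6).

    ``counts`` is genes x samples with non-negative integer entries.
    """
    if (counts.to_numpy() < 0).any():
        raise ValueError("counts must be non-negative")
    lib = counts.sum(axis=0)
    if (lib <= 0).any():
        bad = list(lib.index[lib <= 0])
        raise ValueError(f"all-zero samples: {bad}")
    g = counts.shape[0]
    denom = lib + pseudocount * g
    return np.log2((counts + pseudocount).div(denom, axis=1) * 1e6)


def abnormality_scores(x: pd.DataFrame, meta: pd.DataFrame,
                       study_col: str = "batch",
                       diagnosis_col: str = "diagnosis") -> AbnormalityMatrix:
    """Standardise case samples against controls, within study.

    For every case sample and gene: (x - mean_control) / sd_control, with
    control statistics computed within the sample's study stratum.  Genes
    with zero control variance in any stratum are dropped with a warning.
    """
    meta = meta.loc[x.columns]
    dropped: set[str] = set()
    blocks: list[pd.DataFrame] = []
    means: list[pd.Series] = []
    sds: list[pd.Series] = []
    for study, idx in meta.groupby(study_col, sort=True).groups.items():
        sub_meta = meta.loc[idx]
        controls = sub_meta.index[sub_meta[diagnosis_col] == "control"]
        cases = sub_meta.index[sub_meta[diagnosis_col] == "case"]
        if len(controls) < 2:
            raise ValueError(f"study {study!r}: need >= 2 control samples")
        mu = x[controls].mean(axis=1)
        sd = x[controls].std(axis=1, ddof=1)
        zero = sd.index[sd == 0]
        dropped.update(zero)
        if len(cases):
            blocks.append(x[cases].sub(mu, axis=0).div(sd.replace(0, np.nan),
                                                       axis=0))
        means.append(mu.rename(str(study)))
        sds.append(sd.rename(str(study)))
    if dropped:
        logger.warning("dropping %d genes with zero control variance", len(dropped))
    scores = pd.concat(blocks, axis=1) if blocks else pd.DataFrame(index=x.index)
    scores = scores.drop(index=sorted(dropped))
    return AbnormalityMatrix(
        scores=scores,
        control_mean=pd.concat(means, axis=1).mean(axis=1).drop(sorted(dropped)),
        control_sd=pd.concat(sds, axis=1).mean(axis=1).drop(sorted(dropped)),
        dropped_genes=sorted(dropped),
    )


def _combat_adjust(values: np.ndarray, batches: np.ndarray,
                   max_iter: int = 100, tol: float = 1e-6) -> np.ndarray:
    """Parametric empirical-Bayes location/scale batch adjustment.

    ``values`` is genes x samples.  Per gene, data are standardised against
    the grand mean and pooled variance; per-batch location (gamma) and scale
    (delta^2) estimates are shrunk toward cross-gene priors (normal prior on
    gamma, inverse-gamma on delta^2, moments-matched) by iterating the
    posterior-mean equations, then removed.
    """
    levels = sorted(set(batches))
    n_genes, n_samples = values.shape
    design = np.stack([(batches == b).astype(float) for b in levels], axis=1)
    n_per = design.sum(axis=0)
    # gene-wise grand mean weighted by batch (standard practice: per-batch
    # means averaged with batch sizes) and pooled variance
    batch_means = values @ design / n_per          # genes x batches
    grand_mean = batch_means @ (n_per / n_samples)
    # pooled variance from residuals around each sample's own batch mean,
    # so batch location offsets do not inflate the scale
    fitted = batch_means @ design.T
    pooled_var = ((values - fitted) ** 2).mean(axis=1)
    pooled_var[pooled_var == 0] = 1e-12
    z = (values - grand_mean[:, None]) / np.sqrt(pooled_var)[:, None]

    gamma_hat = z @ design / n_per                  # genes x batches
    delta_hat = np.stack([z[:, batches == b].var(axis=1, ddof=1)
                          for b in levels], axis=1)
    delta_hat[delta_hat == 0] = 1e-12

    gamma_bar = gamma_hat.mean(axis=0)              # per batch
    tau2 = gamma_hat.var(axis=0, ddof=1)
    # inverse-gamma prior on delta^2, method of moments
    v = delta_hat.mean(axis=0)
    s2 = delta_hat.var(axis=0, ddof=1)
    lam = (v ** 2 + 2 * s2) / np.maximum(s2, 1e-12)
    theta = (v ** 3 + v * s2) / np.maximum(s2, 1e-12)

    gamma_star = gamma_hat.copy()
    delta_star = delta_hat.copy()
    for j, b in enumerate(levels):
        zb = z[:, batches == b]
        n_b = zb.shape[1]
        g_new = gamma_hat[:, j]
        d_new = delta_hat[:, j]
        for _ in range(max_iter):
            g_old, d_old = g_new, d_new
            g_new = (n_b * tau2[j] * gamma_hat[:, j] + d_old * gamma_bar[j]) / (
                n_b * tau2[j] + d_old)
            ss = ((zb - g_new[:, None]) ** 2).sum(axis=1)
            d_new = (theta[j] + 0.5 * ss) / (n_b / 2 + lam[j] - 1)
            if (np.max(np.abs(g_new - g_old)) < tol
                    and np.max(np.abs(d_new - d_old)) < tol):
                break
        gamma_star[:, j] = g_new
        delta_star[:, j] = np.maximum(d_new, 1e-12)

    adjusted = z.copy()
    for j, b in enumerate(levels):
        cols = batches == b
        adjusted[:, cols] = (z[:, cols] - gamma_star[:, j][:, None]) / np.sqrt(
            delta_star[:, j])[:, None]
    return adjusted * np.sqrt(pooled_var)[:, None] + grand_mean[:, None]


def batch_adjust(a: AbnormalityMatrix | pd.DataFrame,
                 batch_labels: pd.Series) -> pd.DataFrame:
    """Remove batch-specific location and scale from abnormality scores.

    Empirical-Bayes shrinkage pulls per-gene batch effects toward a
    cross-gene prior before removal; the grand structure (gene means,
    pooled scale) is preserved.  Single-batch input is returned unchanged.
    """
    scores = a.scores if isinstance(a, AbnormalityMatrix) else a
    batches = batch_labels.loc[scores.columns].astype(str).to_numpy()
    levels, counts = np.unique(batches, return_counts=True)
    if len(levels) < 2:
        logger.info("single batch: batch_adjust is the identity")
        return scores.copy()
    if (counts < 2).any():
        raise ValueError("each batch needs >= 2 samples")
    adj = _combat_adjust(scores.to_numpy(dtype=float), batches)
    return pd.DataFrame(adj, index=scores.index, columns=scores.columns)
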