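"""Heterogeneous Incomplete Variational Autoencoder (HI-VAE) per module.

Each module of features (continuous abnormality scores, ordinal clinical
scores, categorical demographics) is embedded into a low-dimensional latent
"module activity score" by a VAE whose decoder factorises over feature
likelihoods:

* real features      — Gaussian with learned mean head and log-variance,
* ordinal features   — thermometer likelihood: cumulative probabilities are
                       sigmoids of ordered thresholds minus a latent score,
* categorical        — softmax over levels.

Missing entries are handled by masking the reconstruction term of the ELBO
(the "Incomplete" contract) and by mean-imputation in normalised space on
the encoder input.  The latent prior is a Gaussian mixture with K
components (uniform weights); K = 1 recovers the standard normal prior and
the classical analytic regulariser

    1/2 sum_j (1 + log sigma_j^2 - mu_j^2 - sigma_j^2).

The implementation uses hand-derived gradients (linear encoder and decoder
heads) and an Adam optimiser; training is deterministic given the seed.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from itertools import product

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

_LOGSIG_CLIP = 5.0


@dataclass
class ModalitySpec:
    """Declares how one feature enters the model.

    kind "real": continuous Gaussian.  kind "ordinal": R ordered categories,
    ``levels`` lists their values in order (defaults to 1..R).  kind
    "categorical": unordered ``levels``.
    """

    name: str
    kind: str  # real | ordinal | categorical
    R: int | None = None
    levels: list | None = None

    def __post_init__(self) -> None:
        if self.kind not in {"real", "ordinal", "categorical"}:
            raise ValueError(f"unknown modality kind {self.kind!r}")
        if self.kind == "ordinal":
            if self.levels is not None and self.R is None:
                self.R = len(self.levels)
            if self.R is None or self.R < 2:
                raise ValueError(f"{self.name}: ordinal needs R >= 2")
            if self.levels is None:
                self.levels = list(range(1, self.R + 1))
            if len(self.levels) != self.R:
                raise ValueError(f"{self.name}: |levels| must equal R")
        if self.kind == "categorical":
            if not self.levels or len(self.levels) < 2:
                raise ValueError(f"{self.name}: categorical needs >= 2 levels")

    def to_dict(self) -> dict:
        return {"name": self.name, "kind": self.kind, "R": self.R,
                "levels": self.levels}

    @classmethod
    def from_dict(cls, d: dict) -> "ModalitySpec":
        return cls(name=d["name"], kind=d["kind"], R=d.get("R"),
                   levels=d.get("levels"))


def _sigmoid(x: np.ndarray) -> np.ndarray:
    out = np.empty_like(x, dtype=float)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


def _softplus(x: np.ndarray) -> np.ndarray:
    return np.logaddexp(0.0, x)


def thermometer_logprobs(h, theta) -> np.ndarray:
    """Log-probabilities of the R ordinal categories under the thermometer link.

    P(x <= r) = sigmoid(theta_r - h) for r = 1..R-1, with P(x <= 0) = 0 and
    P(x <= R) = 1; category probabilities are consecutive differences.
    ``h`` may be a scalar or an (n,) array; returns (R,) or (n, R) logs.
    """
    theta = np.asarray(theta, dtype=float)
    if theta.ndim != 1 or len(theta) < 1:
        raise ValueError("theta must be a 1-D array of length R-1 >= 1")
    if np.any(np.diff(theta) <= 0):
        raise ValueError("thermometer thresholds must be strictly increasing")
    h_arr = np.atleast_1d(np.asarray(h, dtype=float))
    cdf_inner = _sigmoid(theta[None, :] - h_arr[:, None])      # (n, R-1)
    n = len(h_arr)
    cdf = np.concatenate([np.zeros((n, 1)), cdf_inner, np.ones((n, 1))], axis=1)
    probs = np.diff(cdf, axis=1)
    logp = np.log(np.clip(probs, 1e-300, None))
    return logp[0] if np.isscalar(h) or np.ndim(h) == 0 else logp


# ---------------------------------------------------------------------------
# Model container

@dataclass
class HivaeModel:
    """Trained HI-VAE for one module: parameters plus input normalisation."""

    specs: list[ModalitySpec]
    latent_dim: int
    K: int
    params: dict[str, np.ndarray]
    norm_mean: dict[str, float]
    norm_sd: dict[str, float]
    loss_history: list[float] = field(default_factory=list)

    # -- layout ------------------------------------------------------------
    @property
    def feature_names(self) -> list[str]:
        return [s.name for s in self.specs]

    def _input_dim(self) -> int:
        d = 0
        for s in self.specs:
            d += len(s.levels) if s.kind == "categorical" else 1
        return d

    def ordinal_thresholds(self, name: str) -> np.ndarray:
        """Monotone thresholds theta_1..theta_{R-1} for an ordinal feature."""
        t1 = self.params[f"dec|{name}|theta1"]
        deltas = self.params[f"dec|{name}|deltas"]
        if len(deltas):
            return np.concatenate([[t1[0]], t1[0] + np.cumsum(_softplus(deltas))])
        return np.array([t1[0]])

    # -- data preparation ----------------------------------------------------
    def _prepare(self, data: pd.DataFrame):
        """Normalised zero-imputed encoder input + per-feature targets/masks."""
        n = len(data)
        cols = []
        targets: dict[str, np.ndarray] = {}
        masks: dict[str, np.ndarray] = {}
        for s in self.specs:
            raw = data[s.name] if s.name in data else pd.Series(np.nan, index=data.index)
            if s.kind == "real":
                vals = raw.to_numpy(dtype=float)
                mask = np.isfinite(vals)
                xn = (np.where(mask, vals, 0.0) - self.norm_mean[s.name] * mask
                      ) / self.norm_sd[s.name]
                xn = np.where(mask, xn, 0.0)
                cols.append(xn[:, None])
                targets[s.name] = xn
                masks[s.name] = mask
            elif s.kind == "ordinal":
                level_to_r = {lv: r + 1 for r, lv in enumerate(s.levels)}
                vals = raw.map(level_to_r).to_numpy(dtype=float)
                mask = np.isfinite(vals)
                idx = np.where(mask, vals, 1).astype(int)
                xn = (np.where(mask, vals, 0.0) - self.norm_mean[s.name] * mask
                      ) / self.norm_sd[s.name]
                xn = np.where(mask, xn, 0.0)
                cols.append(xn[:, None])
                targets[s.name] = idx
                masks[s.name] = mask
            else:
                level_to_c = {lv: c for c, lv in enumerate(s.levels)}
                vals = raw.map(level_to_c)
                mask = vals.notna().to_numpy()
                idx = vals.fillna(0).to_numpy(dtype=int)
                onehot = np.zeros((n, len(s.levels)))
                onehot[np.arange(n)[mask], idx[mask]] = 1.0
                cols.append(onehot)
                targets[s.name] = idx
                masks[s.name] = mask
        xt = np.concatenate(cols, axis=1) if cols else np.zeros((n, 0))
        return xt, targets, masks

    # -- core forward/backward ----------------------------------------------
    def _encode_arrays(self, xt: np.ndarray):
        mu = xt @ self.params["enc_Wmu"] + self.params["enc_bmu"]
        logsig = np.clip(xt @ self.params["enc_Wsig"] + self.params["enc_bsig"],
                         -_LOGSIG_CLIP, _LOGSIG_CLIP)
        return mu, logsig

    def _responsibilities(self, mu: np.ndarray) -> np.ndarray:
        """Closed-form categorical posterior over mixture components."""
        means = self.params["prior_means"]                       # (K, Dz)
        d2 = ((mu[:, None, :] - means[None, :, :]) ** 2).sum(axis=2)
        logits = -0.5 * d2
        logits -= logits.max(axis=1, keepdims=True)
        r = np.exp(logits)
        return r / r.sum(axis=1, keepdims=True)

    def _component_weights(self, z: np.ndarray) -> np.ndarray:
        """p(s | z) under the mixture prior (unit component covariance)."""
        means = self.params["prior_means"]
        logits = -0.5 * ((z[:, None, :] - means[None, :, :]) ** 2).sum(axis=2)
        logits -= logits.max(axis=1, keepdims=True)
        r = np.exp(logits)
        return r / r.sum(axis=1, keepdims=True)

    def _decoder_loglik(self, z: np.ndarray, targets, masks, grads=None):
        """Masked log p(x_obs | z) per sample; optionally accumulates grads.

        Decoder biases are component-conditional: each head's intercept is
        the p(s|z)-weighted mixture of K per-component biases (for K = 1
        this is an ordinary intercept).  Returns (loglik (n,), dz (n, Dz));
        when ``grads`` is given, decoder parameter gradients of the summed
        loglik are added in place.
        """
        n = z.shape[0]
        ll = np.zeros(n)
        dz = np.zeros_like(z)
        r_z = self._component_weights(z)                     # (n, K)
        g_comp = np.zeros((n, self.K))   # d loglik / d (component weight)
        for s in self.specs:
            m = masks[s.name].astype(float)
            if s.kind == "real":
                w = self.params[f"dec|{s.name}|w"]
                b = self.params[f"dec|{s.name}|b"]            # (K,)
                rho = self.params[f"dec|{s.name}|rho"][0]
                mean = z @ w + r_z @ b
                resid = targets[s.name] - mean
                ll += m * (-0.5 * (np.log(2 * np.pi) + rho
                                   + resid ** 2 * np.exp(-rho)))
                dmean = m * resid * np.exp(-rho)
                dz += dmean[:, None] * w[None, :]
                g_comp += dmean[:, None] * b[None, :]
                if grads is not None:
                    grads[f"dec|{s.name}|w"] += z.T @ dmean
                    grads[f"dec|{s.name}|b"] += r_z.T @ dmean
                    grads[f"dec|{s.name}|rho"] += np.array([
                        (m * (-0.5 + 0.5 * resid ** 2 * np.exp(-rho))).sum()])
            elif s.kind == "ordinal":
                w = self.params[f"dec|{s.name}|w"]
                b = self.params[f"dec|{s.name}|b"]            # (K,)
                theta = self.ordinal_thresholds(s.name)
                h = z @ w + r_z @ b
                r_obs = targets[s.name]                           # 1..R
                a = theta[None, :] - h[:, None]                   # (n, R-1)
                sig = _sigmoid(a)
                sigp = sig * (1.0 - sig)
                cdf = np.concatenate([np.zeros((n, 1)), sig, np.ones((n, 1))],
                                     axis=1)
                probs = np.clip(np.diff(cdf, axis=1), 1e-12, None)
                p_obs = probs[np.arange(n), r_obs - 1]
                ll += m * np.log(p_obs)
                # d log p / dh = -(S'(a_r) - S'(a_{r-1})) / p
                sigp_pad = np.concatenate(
                    [np.zeros((n, 1)), sigp, np.zeros((n, 1))], axis=1)
                su = sigp_pad[np.arange(n), r_obs]                # S'(a_r)
                sl = sigp_pad[np.arange(n), r_obs - 1]            # S'(a_{r-1})
                dh = m * (-(su - sl)) / p_obs
                dz += dh[:, None] * w[None, :]
                g_comp += dh[:, None] * b[None, :]
                if grads is not None:
                    grads[f"dec|{s.name}|w"] += z.T @ dh
                    grads[f"dec|{s.name}|b"] += r_z.T @ dh
                    # theta gradients: +S'(a_r)/p at t=r, -S'(a_{r-1})/p at t=r-1
                    g_theta = np.zeros(len(theta))
                    coef_u = m * su / p_obs
                    coef_l = -m * sl / p_obs
                    for t in range(1, len(theta) + 1):
                        g_theta[t - 1] += coef_u[r_obs == t].sum()
                        g_theta[t - 1] += coef_l[r_obs - 1 == t].sum()
                    grads[f"dec|{s.name}|theta1"] += np.array([g_theta.sum()])
                    deltas = self.params[f"dec|{s.name}|deltas"]
                    if len(deltas):
                        # theta_t depends on delta_u for u <= t (2-indexed)
                        tail = np.cumsum(g_theta[::-1])[::-1]     # sum_{t>=u}
                        grads[f"dec|{s.name}|deltas"] += (
                            _sigmoid(deltas) * tail[1:])
            else:
                W = self.params[f"dec|{s.name}|W"]
                b = self.params[f"dec|{s.name}|b"]            # (K, C)
                logits = z @ W + r_z @ b
                logits -= logits.max(axis=1, keepdims=True)
                lse = np.log(np.exp(logits).sum(axis=1))
                c_obs = targets[s.name]
                ll += m * (logits[np.arange(n), c_obs] - lse)
                soft = np.exp(logits) / np.exp(logits).sum(axis=1, keepdims=True)
                dlogits = -soft
                dlogits[np.arange(n), c_obs] += 1.0
                dlogits *= m[:, None]
                dz += dlogits @ W.T
                g_comp += dlogits @ b.T
                if grads is not None:
                    grads[f"dec|{s.name}|W"] += z.T @ dlogits
                    grads[f"dec|{s.name}|b"] += r_z.T @ dlogits
        if self.K > 1:
            # gradient through the component weights r(z):
            # dr_k/dz = r_k (m_k - sum_l r_l m_l)
            means = self.params["prior_means"]                # (K, Dz)
            mbar = r_z @ means                                # (n, Dz)
            rg = r_z * g_comp                                 # (n, K)
            dz += np.einsum("nk,kj->nj", rg, means) - rg.sum(axis=1)[:, None] * mbar
            if grads is not None:
                u = rg.sum(axis=1)                            # sum_k r_k g_k
                coef = r_z * (g_comp - u[:, None])            # (n, K)
                grads["prior_means"] += (
                    np.einsum("nk,nj->kj", coef, z)
                    - coef.sum(axis=0)[:, None] * means)
        return ll, dz

    def _elbo_batch(self, xt, targets, masks, eps, grads=None):
        """Mean per-sample ELBO of a batch; fills ``grads`` if provided.

        eps has shape (L, n, Dz): L Monte-Carlo draws of the latent noise.
        """
        n = xt.shape[0]
        L = eps.shape[0]
        mu, logsig = self._encode_arrays(xt)
        sig = np.exp(logsig)
        resp = self._responsibilities(mu)                         # (n, K)
        means = self.params["prior_means"]

        # regulariser: -sum_k r_k KL(q(z|x) || N(m_k, I)) - KL(r || uniform)
        kl_comp = 0.5 * (
            (sig ** 2).sum(axis=1)[:, None]
            + ((mu[:, None, :] - means[None, :, :]) ** 2).sum(axis=2)
            - self.latent_dim
            - 2 * logsig.sum(axis=1)[:, None])                    # (n, K)
        kl_z = (resp * kl_comp).sum(axis=1)
        kl_s = (resp * np.log(np.clip(resp * self.K, 1e-12, None))).sum(axis=1)
        reg = -(kl_z + kl_s)

        recon = np.zeros(n)
        dmu = np.zeros_like(mu)
        dlogsig = np.zeros_like(logsig)
        dec_grads = ({k: np.zeros_like(v) for k, v in self.params.items()}
                     if grads is not None else None)
        for li in range(L):
            z = mu + sig * eps[li]
            ll, dz = self._decoder_loglik(z, targets, masks, grads=dec_grads)
            recon += ll / L
            dmu += dz / L
            dlogsig += dz * sig * eps[li] / L
        if grads is not None:
            for k, g in dec_grads.items():
                grads[k] += g / L
            # regulariser gradients (responsibilities treated as constants)
            dmu += -(resp[:, :, None] * (mu[:, None, :] - means[None, :, :])
                     ).sum(axis=1)
            dlogsig += 1.0 - sig ** 2
            if self.K > 1:
                grads["prior_means"] += np.einsum(
                    "nk,nkj->kj", resp, mu[:, None, :] - means[None, :, :])
            grads["enc_Wmu"] += xt.T @ dmu
            grads["enc_bmu"] += dmu.sum(axis=0)
            inrange = np.abs(xt @ self.params["enc_Wsig"]
                             + self.params["enc_bsig"]) < _LOGSIG_CLIP
            dlogsig = dlogsig * inrange
            grads["enc_Wsig"] += xt.T @ dlogsig
            grads["enc_bsig"] += dlogsig.sum(axis=0)
        return float((reg + recon).mean()), float(recon.mean())

    # -- public API ----------------------------------------------------------
    def encode(self, data: pd.DataFrame) -> np.ndarray:
        """Posterior means mu(x), shape (n, latent_dim)."""
        xt, _, _ = self._prepare(data)
        mu, _ = self._encode_arrays(xt)
        return mu

    def encode_sd(self, data: pd.DataFrame) -> np.ndarray:
        xt, _, _ = self._prepare(data)
        _, logsig = self._encode_arrays(xt)
        return np.exp(logsig)

    def sample_posterior(self, data: pd.DataFrame,
                         rng: np.random.Generator) -> np.ndarray:
        """Draw z = mu(x) + sigma(x) * eps from the approximate posterior."""
        xt, _, _ = self._prepare(data)
        mu, logsig = self._encode_arrays(xt)
        return mu + np.exp(logsig) * rng.standard_normal(mu.shape)

    def decode(self, scores: np.ndarray, rng: np.random.Generator | None = None,
               mode: str = "mean") -> pd.DataFrame:
        """Map latent scores to feature space.

        mode "mean": expected value for real features, modal category for
        ordinal/categorical.  mode "sample": a draw from each feature
        likelihood (requires ``rng``).
        """
        if mode not in {"mean", "sample"}:
            raise ValueError("mode must be 'mean' or 'sample'")
        if mode == "sample" and rng is None:
            raise ValueError("mode='sample' requires rng")
        z = np.atleast_2d(np.asarray(scores, dtype=float))
        if z.shape[1] != self.latent_dim:
            z = z.reshape(-1, self.latent_dim)
        n = z.shape[0]
        r_z = self._component_weights(z)
        out: dict[str, np.ndarray | list] = {}
        for s in self.specs:
            if s.kind == "real":
                w = self.params[f"dec|{s.name}|w"]
                b = self.params[f"dec|{s.name}|b"]
                rho = self.params[f"dec|{s.name}|rho"][0]
                mean_n = z @ w + r_z @ b
                if mode == "sample":
                    mean_n = mean_n + np.exp(rho / 2) * rng.standard_normal(n)
                out[s.name] = mean_n * self.norm_sd[s.name] + self.norm_mean[s.name]
            elif s.kind == "ordinal":
                w = self.params[f"dec|{s.name}|w"]
                b = self.params[f"dec|{s.name}|b"]
                h = z @ w + r_z @ b
                logp = thermometer_logprobs(h, self.ordinal_thresholds(s.name))
                if mode == "mean":
                    idx = np.argmax(logp, axis=1)
                else:
                    cum = np.cumsum(np.exp(logp), axis=1)
                    u = rng.random(n)
                    idx = (u[:, None] > cum).sum(axis=1)
                out[s.name] = [s.levels[i] for i in idx]
            else:
                W = self.params[f"dec|{s.name}|W"]
                b = self.params[f"dec|{s.name}|b"]
                logits = z @ W + r_z @ b
                if mode == "mean":
                    idx = np.argmax(logits, axis=1)
                else:
                    logits = logits - logits.max(axis=1, keepdims=True)
                    probs = np.exp(logits)
                    probs /= probs.sum(axis=1, keepdims=True)
                    cum = np.cumsum(probs, axis=1)
                    u = rng.random(n)
                    idx = (u[:, None] > cum).sum(axis=1)
                out[s.name] = [s.levels[i] for i in idx]
        return pd.DataFrame(out)

    # -- persistence -----------------------------------------------------------
    def save(self, path: str) -> None:
        """Single portable archive: JSON metadata + parameter tensors (npz)."""
        meta = {
            "specs": [s.to_dict() for s in self.specs],
            "latent_dim": self.latent_dim, "K": self.K,
            "norm_mean": self.norm_mean, "norm_sd": self.norm_sd,
        }
        np.savez(path, __meta__=np.frombuffer(
            json.dumps(meta).encode(), dtype=np.uint8), **self.params)

    @classmethod
    def load(cls, path: str) -> "HivaeModel":
        with np.load(path) as arc:
            meta = json.loads(bytes(arc["__meta__"]).decode())
            params = {k: arc[k] for k in arc.files if k != "__meta__"}
        return cls(specs=[ModalitySpec.from_dict(d) for d in meta["specs"]],
                   latent_dim=meta["latent_dim"], K=meta["K"], params=params,
                   norm_mean=meta["norm_mean"], norm_sd=meta["norm_sd"])


# ---------------------------------------------------------------------------
# Functional operations

def elbo(x: pd.DataFrame, mask: pd.DataFrame | None, model: HivaeModel,
         L: int = 1, rng: np.random.Generator | None = None,
         return_parts: bool = False):
    """Evidence lower bound, averaged over samples.

    The reconstruction term (1/L) sum_l log p(x_obs | z^(l)) covers only
    observed entries; a fully missing sample contributes the regulariser
    alone.  ``mask`` (True = observed) overrides the NaN pattern of ``x``.
    """
    if L < 1:
        raise ValueError("L must be >= 1")
    rng = rng or np.random.default_rng(0)
    xt, targets, masks = model._prepare(x)
    if mask is not None:
        for s in model.specs:
            masks[s.name] = masks[s.name] & mask[s.name].to_numpy()
    eps = rng.standard_normal((L, len(x), model.latent_dim))
    total, recon = model._elbo_batch(xt, targets, masks, eps)
    if return_parts:
        return total, total - recon, recon
    return total


def _init_params(specs, d_in, d_z, K, rng) -> dict[str, np.ndarray]:
    p: dict[str, np.ndarray] = {
        "enc_Wmu": 0.1 * rng.standard_normal((d_in, d_z)),
        "enc_bmu": np.zeros(d_z),
        "enc_Wsig": 0.01 * rng.standard_normal((d_in, d_z)),
        "enc_bsig": np.full(d_z, -1.0),
        "prior_means": (np.zeros((K, d_z)) if K == 1
                        else 0.5 * rng.standard_normal((K, d_z))),
    }
    for s in specs:
        if s.kind == "real":
            # inputs are standardised, so unit loadings with small decoder
            # noise start near the high-fidelity end of the (loading, noise)
            # trade-off, which the ELBO alone leaves under-determined for
            # few-feature modules
            p[f"dec|{s.name}|w"] = (np.ones(d_z) + 0.1 * rng.standard_normal(d_z)
                                    ) / np.sqrt(d_z)
            p[f"dec|{s.name}|b"] = np.zeros(K)
            p[f"dec|{s.name}|rho"] = np.full(1, -3.0)
        elif s.kind == "ordinal":
            p[f"dec|{s.name}|w"] = 0.1 * rng.standard_normal(d_z)
            p[f"dec|{s.name}|b"] = np.zeros(K)
            # initial thresholds: equally spaced quantile-ish grid
            p[f"dec|{s.name}|theta1"] = np.array([-1.0])
            p[f"dec|{s.name}|deltas"] = np.full(
                max(s.R - 2, 0), np.log(np.expm1(2.0 / max(s.R - 1, 1))))
        else:
            c = len(s.levels)
            p[f"dec|{s.name}|W"] = 0.1 * rng.standard_normal((d_z, c))
            p[f"dec|{s.name}|b"] = np.zeros((K, c))
    return p


_FROZEN_K1 = {"prior_means"}


def fit_hivae(data: pd.DataFrame, specs: list[ModalitySpec],
              hyper: dict | None = None) -> HivaeModel:
    """Train a HI-VAE on one module slice by Adam ascent on the masked ELBO.

    ``hyper`` keys (defaults): lr 0.01, minibatch 32, D_z 1, K 1,
    epochs 500, patience 50, seed 0.  Deterministic given the seed.
    """
    hyper = dict(hyper or {})
    lr = hyper.get("lr", 0.01)
    minibatch = hyper.get("minibatch", 32)
    d_z = hyper.get("D_z", 1)
    K = hyper.get("K", 1)
    epochs = hyper.get("epochs", 500)
    patience = hyper.get("patience", 50)
    seed = hyper.get("seed", 0)
    if len(specs) < 1:
        raise ValueError("need at least one feature spec")
    if len(data) < 10:
        raise ValueError("need at least 10 samples to fit a HI-VAE")

    # normalisation statistics from observed training entries
    norm_mean: dict[str, float] = {}
    norm_sd: dict[str, float] = {}
    for s in specs:
        if s.kind == "categorical":
            continue
        if s.kind == "real":
            vals = data[s.name].to_numpy(dtype=float)
        else:
            level_to_r = {lv: r + 1 for r, lv in enumerate(s.levels)}
            vals = data[s.name].map(level_to_r).to_numpy(dtype=float)
        obs = vals[np.isfinite(vals)]
        mu = float(obs.mean()) if len(obs) else 0.0
        sd = float(obs.std(ddof=0)) if len(obs) else 1.0
        norm_mean[s.name] = mu
        norm_sd[s.name] = sd if sd > 0 else 1.0

    rng = np.random.default_rng(seed)
    model = HivaeModel(specs=specs, latent_dim=d_z, K=K, params={},
                       norm_mean=norm_mean, norm_sd=norm_sd)
    model.params = _init_params(specs, model._input_dim(), d_z, K, rng)
    xt_all, targets_all, masks_all = model._prepare(data)
    n = len(data)

    mom1 = {k: np.zeros_like(v) for k, v in model.params.items()}
    mom2 = {k: np.zeros_like(v) for k, v in model.params.items()}
    t_step = 0
    best = -np.inf
    best_params = None
    stall = 0
    for epoch in range(epochs):
        perm = rng.permutation(n)
        ep_elbo = 0.0
        n_batches = 0
        for start in range(0, n, minibatch):
            idx = perm[start:start + minibatch]
            xt = xt_all[idx]
            targets = {k: v[idx] for k, v in targets_all.items()}
            masks = {k: v[idx] for k, v in masks_all.items()}
            eps = rng.standard_normal((1, len(idx), d_z))
            grads = {k: np.zeros_like(v) for k, v in model.params.items()}
            val, _ = model._elbo_batch(xt, targets, masks, eps, grads=grads)
            if not np.isfinite(val):
                raise RuntimeError(
                    f"HI-VAE training diverged at epoch {epoch} (ELBO={val})")
            ep_elbo += val
            n_batches += 1
            t_step += 1
            for k in model.params:
                if K == 1 and k in _FROZEN_K1:
                    continue
                g = grads[k] / len(idx)            # mean-per-sample gradient
                mom1[k] = 0.9 * mom1[k] + 0.1 * g
                mom2[k] = 0.999 * mom2[k] + 0.001 * g ** 2
                m_hat = mom1[k] / (1 - 0.9 ** t_step)
                v_hat = mom2[k] / (1 - 0.999 ** t_step)
                model.params[k] = model.params[k] + lr * m_hat / (
                    np.sqrt(v_hat) + 1e-8)
        ep_elbo /= max(n_batches, 1)
        model.loss_history.append(ep_elbo)
        if ep_elbo > best + 1e-6:
            best = ep_elbo
            best_params = {k: v.copy() for k, v in model.params.items()}
            stall = 0
        else:
            stall += 1
            if stall >= patience:
                logger.info("early stop at epoch %d (best ELBO %.4f)", epoch, best)
                break
    if best_params is not None:
        model.params = best_params
    return model


def encode(data: pd.DataFrame, model: HivaeModel) -> pd.DataFrame:
    """Posterior-mean module scores with the sample index of ``data``."""
    mu = model.encode(data)
    cols = [f"z{j}" for j in range(model.latent_dim)]
    return pd.DataFrame(mu, index=data.index, columns=cols)


def decode(scores, model: HivaeModel, rng: np.random.Generator | None = None,
           mode: str = "mean") -> pd.DataFrame:
    return model.decode(np.asarray(scores, dtype=float), rng=rng, mode=mode)


def sample_posterior(data: pd.DataFrame, model: HivaeModel,
                     rng: np.random.Generator) -> np.ndarray:
    return model.sample_posterior(data, rng)


def reconstruction_loglik(model: HivaeModel, data: pd.DataFrame,
                          L: int = 10, rng: np.random.Generator | None = None
                          ) -> float:
    """Held-out objective: (1/L) sum_l log p(x_obs | z^(l)), mean per sample."""
    rng = rng or np.random.default_rng(0)
    xt, targets, masks = model._prepare(data)
    eps = rng.standard_normal((L, len(data), model.latent_dim))
    _, recon = model._elbo_batch(xt, targets, masks, eps)
    return recon


def grid_search_cv(data: pd.DataFrame, specs: list[ModalitySpec],
                   grid: dict[str, list] | list[dict], folds: int = 3,
                   seed: int = 0) -> tuple[dict, pd.DataFrame]:
    """Seeded k-fold CV over a hyperparameter grid.

    The selection objective is the held-out reconstruction term; the full
    CV table is returned alongside the winning hyperparameter dict.
    """
    if isinstance(grid, dict):
        keys = sorted(grid)
        combos = [dict(zip(keys, vals)) for vals in product(*(grid[k] for k in keys))]
    else:
        combos = [dict(c) for c in grid]
    if not combos:
        raise ValueError("empty hyperparameter grid")
    n = len(data)
    if n < folds:
        raise ValueError(f"need at least {folds} samples for {folds}-fold CV")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n)
    fold_of = np.zeros(n, dtype=int)
    for f in range(folds):
        fold_of[perm[f::folds]] = f
    rows = []
    for combo in combos:
        scores = []
        for f in range(folds):
            train = data.iloc[fold_of != f]
            test = data.iloc[fold_of == f]
            # same training seed per fold across combos: paired comparison
            hyper = {**combo, "seed": seed + f}
            m = fit_hivae(train, specs, hyper)
            scores.append(reconstruction_loglik(
                m, test, L=10, rng=np.random.default_rng(seed + 77 + f)))
        rows.append({**combo, "cv_reconstruction": float(np.mean(scores))})
    table = pd.DataFrame(rows)
    best_idx = int(table["cv_reconstruction"].idxmax())
    best = {k: combos[best_idx][k] for k in combos[best_idx]}
    return best, table
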