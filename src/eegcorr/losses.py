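"""Training objective: KL alignment + reconstruction + soft-CCA.

The total loss for one clip is

    L = L_CCA + L_kl + L_dec,          L_CCA = L_inv + lambda * L_dco

where

* ``L_inv``  — squared Frobenius distance between the two views'
  normalized embeddings (views of a normal clip should agree);
* ``L_dco``  — squared Frobenius distance of each view's embedding
  correlation matrix from the identity (prevents collapse);
* ``L_kl``   — KL divergence of both per-node Gaussian posteriors from
  the standard-normal prior, in closed form;
* ``L_dec``  — Frobenius norms of the attribute and structure
  reconstruction errors.

Embedding normalization subtracts the column mean, divides by the column
standard deviation and by sqrt(N), so ``Z'^T Z'`` is the column
correlation matrix and the decorrelation target ``I`` is on the right
scale.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import _autodiff as ad
from ._autodiff import Tensor
from .graphs import EPS, EEGGraph, normalize_adjacency
from .model import (
    ModelParams,
    GaussianPosterior,
    _params_to_tensors,
    decode_attributes_t,
    decode_structure_t,
    encode_t,
    init_params,
    sample_t,
)

__all__ = [
    "LossConfig",
    "LossBreakdown",
    "kl_loss",
    "recon_loss",
    "normalize_embeddings",
    "invariance_loss",
    "decorrelation_loss",
    "total_loss",
    "clip_loss",
    "train",
]


@dataclass(frozen=True)
class LossConfig:
    """Objective weights.  ``lambda_dco`` trades decorrelation against
    invariance inside the CCA term; the prior is fixed at N(0, I).

    The KL term is down-weighted by default (beta-style): with full
    weight it dominates the objective and collapses both posteriors onto
    the prior, leaving the embeddings uninformative and the detector
    blind.  ``w_kl = 0.01`` keeps the alignment regularization active
    without crushing the signal.
    """

    lambda_dco: float = 0.1
    w_cca: float = 1.0
    w_kl: float = 0.01
    w_dec: float = 1.0

    def __post_init__(self):
        if self.lambda_dco < 0:
            raise ValueError("lambda_dco must be >= 0")


@dataclass(frozen=True)
class LossBreakdown:
    L_inv: float
    L_dco: float
    L_CCA: float
    L_kl: float
    L_dec: float
    L_total: float

    def as_dict(self) -> dict:
        return {
            "L_inv": self.L_inv,
            "L_dco": self.L_dco,
            "L_CCA": self.L_CCA,
            "L_kl": self.L_kl,
            "L_dec": self.L_dec,
            "L_total": self.L_total,
        }


# ---------------------------------------------------------------------
# tensor-level loss terms
# ---------------------------------------------------------------------

def kl_t(mu: Tensor, log_var: Tensor) -> Tensor:
    """Closed-form KL(N(mu, diag(exp(log_var))) || N(0, I)), summed over
    nodes and latent dimensions."""
    return ((mu * mu + ad.exp(log_var) - 1.0 - log_var) * 0.5).sum()


def normalize_t(Z: Tensor) -> Tensor:
    N = Z.shape[0]
    centered = Z - Z.mean(axis=0, keepdims=True)
    sd = ad.sqrt((centered * centered).mean(axis=0, keepdims=True) + EPS)
    return centered / sd * (1.0 / np.sqrt(N))


def invariance_t(Zst_n: Tensor, Zse_n: Tensor) -> Tensor:
    diff = Zst_n - Zse_n
    return (diff * diff).sum()


def decorrelation_t(Z_n: Tensor) -> Tensor:
    G = Z_n.T @ Z_n - ad.constant(np.eye(Z_n.shape[1]))
    return (G * G).sum()


def frobenius_t(Delta: Tensor) -> Tensor:
    # sqrt guarded away from 0 where the norm is non-differentiable
    return ad.sqrt((Delta * Delta).sum() + EPS**2)


# ---------------------------------------------------------------------
# ndarray API
# ---------------------------------------------------------------------

def kl_loss(post_st: GaussianPosterior, post_se: GaussianPosterior = None) -> float:
    """KL of the posterior(s) from the standard-normal prior.

    With two posteriors (structural and semantic) the two divergences are
    summed; the result is minimized to pull both views to the prior.
    """
    total = kl_t(ad.constant(post_st.mu), ad.constant(post_st.log_var)).data
    if post_se is not None:
        total = total + kl_t(ad.constant(post_se.mu), ad.constant(post_se.log_var)).data
    return float(total)


def recon_loss(X, X_hat, A, A_hat) -> float:
    """||X - X_hat||_F + ||A - A_hat||_F (unsquared norms)."""
    X, X_hat = np.asarray(X, dtype=float), np.asarray(X_hat, dtype=float)
    A, A_hat = np.asarray(A, dtype=float), np.asarray(A_hat, dtype=float)
    if X.shape != X_hat.shape:
        raise ValueError(f"attribute shapes differ: {X.shape} vs {X_hat.shape}")
    if A.shape != A_hat.shape:
        raise ValueError(f"structure shapes differ: {A.shape} vs {A_hat.shape}")
    return float(np.linalg.norm(X - X_hat) + np.linalg.norm(A - A_hat))


def normalize_embeddings(Z) -> np.ndarray:
    """Column-standardize and scale by 1/sqrt(N) so Z'^T Z' is the column
    correlation matrix; zero-variance columns are floored at EPS."""
    Z = np.asarray(Z, dtype=float)
    if Z.shape[0] < 2:
        raise ValueError("need at least 2 rows to normalize embeddings")
    return normalize_t(ad.constant(Z)).data


def invariance_loss(Zst_n, Zse_n) -> float:
    """Squared Frobenius distance between the two normalized views."""
    Zst_n, Zse_n = np.asarray(Zst_n, dtype=float), np.asarray(Zse_n, dtype=float)
    if Zst_n.shape != Zse_n.shape:
        raise ValueError(f"shape mismatch {Zst_n.shape} vs {Zse_n.shape}")
    return float(((Zst_n - Zse_n) ** 2).sum())


def decorrelation_loss(Z_n) -> float:
    """||Z'^T Z' - I||_F^2 for one view (caller sums both views)."""
    Z_n = np.asarray(Z_n, dtype=float)
    return float(decorrelation_t(ad.constant(Z_n)).data)


def total_loss(
    L_inv: float, L_dco: float, L_kl: float, L_dec: float, cfg: LossConfig = LossConfig()
) -> LossBreakdown:
    """Assemble the breakdown: L_CCA = L_inv + lambda*L_dco and
    L_total = w_cca*L_CCA + w_kl*L_kl + w_dec*L_dec."""
    L_CCA = L_inv + cfg.lambda_dco * L_dco
    L_total = cfg.w_cca * L_CCA + cfg.w_kl * L_kl + cfg.w_dec * L_dec
    return LossBreakdown(
        float(L_inv), float(L_dco), float(L_CCA), float(L_kl), float(L_dec), float(L_total)
    )


# ---------------------------------------------------------------------
# per-clip objective and training loop
# ---------------------------------------------------------------------

def clip_loss(
    params_t: dict,
    X: np.ndarray,
    A_norm: np.ndarray,
    A_raw: np.ndarray,
    cfg: LossConfig,
    eta_st: np.ndarray,
    eta_se: np.ndarray,
    activation: str = "relu",
    n_decoder_layers: int = 2,
):
    """Differentiable total loss for one (G, G') pair.

    ``eta_st``/``eta_se`` are the reparameterization noises (pass zeros
    to evaluate at the posterior means).  Returns the scalar loss tensor
    plus the numeric breakdown.
    """
    X_t = ad.constant(X)
    A_t = ad.constant(A_norm)
    mu_st, lv_st = encode_t(X_t, A_t, params_t, activation)
    mu_se, lv_se = encode_t(X_t, None, params_t, activation)

    Z_st = sample_t(mu_st, lv_st, eta_st)
    Z_se = sample_t(mu_se, lv_se, eta_se)
    Zst_n = normalize_t(Z_st)
    Zse_n = normalize_t(Z_se)

    L_inv = invariance_t(Zst_n, Zse_n)
    L_dco = decorrelation_t(Zst_n) + decorrelation_t(Zse_n)
    L_kl = kl_t(mu_st, lv_st) + kl_t(mu_se, lv_se)

    Z_f = Z_st + Z_se
    X_hat = decode_attributes_t(Z_f, params_t, n_decoder_layers, activation)
    A_hat = decode_structure_t(Z_f)
    L_dec = frobenius_t(X_t - X_hat) + frobenius_t(ad.constant(A_raw) - A_hat)

    L_CCA = L_inv + cfg.lambda_dco * L_dco
    L = cfg.w_cca * L_CCA + cfg.w_kl * L_kl + cfg.w_dec * L_dec
    breakdown = LossBreakdown(
        float(L_inv.data), float(L_dco.data), float(L_CCA.data),
        float(L_kl.data), float(L_dec.data), float(L.data),
    )
    return L, breakdown


class _Adam:
    """Adam optimizer over a dict of named arrays."""

    def __init__(self, arrays: dict, lr: float = 1e-3, beta1=0.9, beta2=0.999, eps=1e-8):
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.m = {k: np.zeros_like(v) for k, v in arrays.items()}
        self.v = {k: np.zeros_like(v) for k, v in arrays.items()}
        self.t = 0

    def step(self, arrays: dict, grads: dict):
        self.t += 1
        b1t = 1 - self.b1**self.t
        b2t = 1 - self.b2**self.t
        for k, g in grads.items():
            self.m[k] = self.b1 * self.m[k] + (1 - self.b1) * g
            self.v[k] = self.b2 * self.v[k] + (1 - self.b2) * g**2
            arrays[k] -= self.lr * (self.m[k] / b1t) / (np.sqrt(self.v[k] / b2t) + self.eps)


def _check_finite(breakdown: LossBreakdown):
    for name, val in breakdown.as_dict().items():
        if not np.isfinite(val):
            raise FloatingPointError(f"training diverged: {name} is {val}")


def train(
    dataset,
    cfg: LossConfig = LossConfig(),
    seed: int = 0,
    epochs: int = 200,
    lr: float = 1e-3,
    params: ModelParams = None,
    hidden_dim: int = 64,
    latent_dim: int = 32,
    decoder_hidden: int = 64,
    sample_during_training: bool = True,
    callback=None,
):
    """Fit the encoder/decoder on normal clips by gradient descent.

    ``dataset`` is a sequence of EEG graphs (the identity-graph pair of
    each is implied) or of explicit ``(G, G_identity)`` pairs.  One clip
    is one full-batch optimization step.  Deterministic given ``seed``.

    Returns ``(params, history)`` with one :class:`LossBreakdown` per
    epoch (mean over clips).
    """
    pairs = []
    for item in dataset:
        g = item[0] if isinstance(item, tuple) else item
        if not isinstance(g, EEGGraph):
            raise TypeError("dataset items must be EEGGraph (or (G, G') pairs)")
        pairs.append(g)
    if not pairs:
        raise ValueError("dataset is empty")
    N = pairs[0].n_channels
    D = pairs[0].X.n_features
    if any(g.n_channels != N or g.X.n_features != D for g in pairs):
        raise ValueError("all graphs must share channel and feature counts")

    rng = np.random.default_rng(seed)
    if params is None:
        params = init_params(
            D, h=hidden_dim, d=latent_dim, decoder_hidden=decoder_hidden,
            seed=int(rng.integers(2**31)),
        )
    else:
        params = params.copy()
    d = params.dims["d"]
    L_dec_layers = params.dims["L"]

    # pre-normalize adjacencies once; keep the raw A as the recon target
    prepared = []
    for g in pairs:
        A_norm = g.A.A if g.A.params.get("normalized") else normalize_adjacency(g.A).A
        prepared.append((g.X.X, A_norm, g.A.A))

    arrays = params.arrays()
    opt = _Adam(arrays, lr=lr)
    history = []
    for epoch in range(epochs):
        acc = np.zeros(6)
        for X, A_norm, A_raw in prepared:
            if sample_during_training:
                eta_st = rng.standard_normal((N, d))
                eta_se = rng.standard_normal((N, d))
            else:
                eta_st = eta_se = np.zeros((N, d))
            params_t = {k: Tensor(v, requires_grad=True) for k, v in arrays.items()}
            L, breakdown = clip_loss(
                params_t, X, A_norm, A_raw, cfg, eta_st, eta_se,
                params.activation, L_dec_layers,
            )
            _check_finite(breakdown)
            if lr != 0.0:
                L.backward()
                grads = {k: t.grad for k, t in params_t.items() if t.grad is not None}
                opt.step(arrays, grads)
            acc += np.array(list(breakdown.as_dict().values()))
        mean = acc / len(prepared)
        history.append(LossBreakdown(*mean))
        if callback is not None:
            callback(epoch, history[-1])
    return params, history
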