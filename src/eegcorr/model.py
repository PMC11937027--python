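"""Weight-sharing variational graph encoder and fusion decoder.

Two views of the same clip are encoded with ONE set of weights:

* structural view — the EEG graph ``{A, X}``; each channel aggregates
  its neighbors through the normalized adjacency;
* semantic view — the identity graph ``{I, X}``; each channel sees only
  its own features ("identity aggregation").

Each view yields a per-node diagonal Gaussian posterior.  Embeddings are
drawn by the reparameterization trick, fused by elementwise sum, and
decoded back to node attributes (an MLP) and to the graph structure (a
logistic-squashed Gram matrix).

Public functions operate on NumPy arrays; the ``*_t`` twins operate on
autodiff tensors and are what the training loop differentiates through.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import _autodiff as ad
from ._autodiff import Tensor
from .graphs import EEGGraph

__all__ = [
    "ModelParams",
    "GaussianPosterior",
    "EmbeddingSet",
    "Reconstruction",
    "init_params",
    "gcn_layer",
    "encode",
    "sample_embedding",
    "fuse",
    "decode_attributes",
    "decode_structure",
]

_ACTIVATIONS = {
    "relu": ad.relu,
    "identity": lambda x: x,
    "sigmoid": ad.sigmoid,
}


@dataclass
class ModelParams:
    """All learnable weights; the variational heads serve BOTH views.

    ``W1`` maps D features to the hidden width h, ``W_mu``/``W_logvar``
    map h to the latent width d, and the decoder MLP maps d back to D.
    """

    W1: np.ndarray
    W_mu: np.ndarray
    W_logvar: np.ndarray
    dec_W: list
    dec_b: list
    activation: str = "relu"

    def __post_init__(self):
        if self.activation not in _ACTIVATIONS:
            raise ValueError(f"unknown activation {self.activation!r}")
        for arr in self.arrays().values():
            if not np.all(np.isfinite(arr)):
                raise ValueError("model parameters contain non-finite entries")

    @property
    def dims(self) -> dict:
        return {
            "D": self.W1.shape[0],
            "h": self.W1.shape[1],
            "d": self.W_mu.shape[1],
            "L": len(self.dec_W),
        }

    def arrays(self) -> dict:
        """Flat name -> ndarray view of every learnable array."""
        out = {"W1": self.W1, "W_mu": self.W_mu, "W_logvar": self.W_logvar}
        for i, (W, b) in enumerate(zip(self.dec_W, self.dec_b)):
            out[f"dec_W{i}"] = W
            out[f"dec_b{i}"] = b
        return out

    def copy(self) -> "ModelParams":
        return ModelParams(
            self.W1.copy(),
            self.W_mu.copy(),
            self.W_logvar.copy(),
            [W.copy() for W in self.dec_W],
            [b.copy() for b in self.dec_b],
            self.activation,
        )

    def to_dict(self) -> dict:
        return {
            "activation": self.activation,
            "W1": self.W1.tolist(),
            "W_mu": self.W_mu.tolist(),
            "W_logvar": self.W_logvar.tolist(),
            "dec_W": [W.tolist() for W in self.dec_W],
            "dec_b": [b.tolist() for b in self.dec_b],
        }

    @classmethod
    def from_dict(cls, doc: dict) -> "ModelParams":
        return cls(
            np.array(doc["W1"], dtype=float),
            np.array(doc["W_mu"], dtype=float),
            np.array(doc["W_logvar"], dtype=float),
            [np.array(W, dtype=float) for W in doc["dec_W"]],
            [np.array(b, dtype=float) for b in doc["dec_b"]],
            doc.get("activation", "relu"),
        )


@dataclass(frozen=True)
class GaussianPosterior:
    """Per-node diagonal Gaussian q(z_i) = N(mu_i, diag(exp(log_var_i)))."""

    mu: np.ndarray
    log_var: np.ndarray
    view: str = "structural"

    def __post_init__(self):
        mu = np.asarray(self.mu, dtype=float)
        lv = np.asarray(self.log_var, dtype=float)
        if mu.shape != lv.shape:
            raise ValueError("mu and log_var must have equal shapes")
        if not (np.all(np.isfinite(mu)) and np.all(np.isfinite(lv))):
            raise ValueError("posterior contains non-finite entries")
        object.__setattr__(self, "mu", mu)
        object.__setattr__(self, "log_var", lv)


@dataclass(frozen=True)
class EmbeddingSet:
    """Sampled (or mean) embeddings of both views, their normalized forms,
    and the fusion Z_f = Z_st + Z_se."""

    Z_st: np.ndarray
    Z_se: np.ndarray
    Z_st_norm: np.ndarray
    Z_se_norm: np.ndarray
    Z_f: np.ndarray = field(default=None)

    def __post_init__(self):
        if self.Z_f is None:
            object.__setattr__(self, "Z_f", self.Z_st + self.Z_se)


@dataclass(frozen=True)
class Reconstruction:
    """Decoder outputs: node attributes X_hat and structure A_hat."""

    X_hat: np.ndarray
    A_hat: np.ndarray


# ---------------------------------------------------------------------
# tensor-level forward pass (differentiated by the training loop)
# ---------------------------------------------------------------------

def gcn_layer_t(X: Tensor, A_norm, W: Tensor, phi: str = "relu") -> Tensor:
    """One graph-convolution layer phi(A_norm @ X @ W); A_norm=None means
    the identity graph (no aggregation)."""
    act = _ACTIVATIONS[phi]
    pre = X @ W if A_norm is None else A_norm @ (X @ W)
    return act(pre)


def encode_t(X: Tensor, A_norm, p: dict, activation: str):
    """Shared-weight encoder: returns (mu, log_var) tensors for one view."""
    H = gcn_layer_t(X, A_norm, p["W1"], activation)
    mu = gcn_layer_t(H, A_norm, p["W_mu"], "identity")
    log_var = gcn_layer_t(H, A_norm, p["W_logvar"], "identity")
    return mu, log_var


def sample_t(mu: Tensor, log_var: Tensor, eta: np.ndarray) -> Tensor:
    """Reparameterized draw z = mu + exp(log_var/2) * eta."""
    return mu + ad.exp(log_var * 0.5) * ad.constant(eta)


def decode_attributes_t(Z_f: Tensor, p: dict, n_layers: int, activation: str) -> Tensor:
    out = Z_f
    for l in range(n_layers):
        out = out @ p[f"dec_W{l}"] + p[f"dec_b{l}"]
        if l < n_layers - 1:  # hidden layers activated, final layer linear
            out = _ACTIVATIONS[activation](out)
    return out


def decode_structure_t(Z_f: Tensor) -> Tensor:
    return ad.sigmoid(Z_f @ Z_f.T)


# ---------------------------------------------------------------------
# ndarray API
# ---------------------------------------------------------------------

def init_params(
    D: int,
    h: int = 64,
    d: int = 32,
    decoder_hidden: int = 64,
    n_decoder_layers: int = 2,
    activation: str = "relu",
    seed: int = 0,
) -> ModelParams:
    """Glorot-uniform initialization, deterministic in ``seed``."""
    rng = np.random.default_rng(seed)

    def glorot(n_in, n_out):
        limit = np.sqrt(6.0 / (n_in + n_out))
        return rng.uniform(-limit, limit, size=(n_in, n_out))

    widths = [d] + [decoder_hidden] * (n_decoder_layers - 1) + [D]
    dec_W = [glorot(widths[i], widths[i + 1]) for i in range(n_decoder_layers)]
    dec_b = [np.zeros(widths[i + 1]) for i in range(n_decoder_layers)]
    return ModelParams(glorot(D, h), glorot(h, d), glorot(h, d), dec_W, dec_b, activation)


def _params_to_tensors(params: ModelParams, requires_grad: bool = False) -> dict:
    return {k: Tensor(v, requires_grad=requires_grad) for k, v in params.arrays().items()}


def gcn_layer(X, A_norm, W, phi: str = "relu") -> np.ndarray:
    """phi(A_norm @ X @ W) on plain arrays; pass A_norm=None for the
    identity graph."""
    X = np.asarray(X, dtype=float)
    W = np.asarray(W, dtype=float)
    if X.shape[1] != W.shape[0]:
        raise ValueError(f"feature dim {X.shape[1]} != weight rows {W.shape[0]}")
    if A_norm is not None:
        A_norm = np.asarray(A_norm, dtype=float)
        if A_norm.shape[1] != X.shape[0]:
            raise ValueError("adjacency and feature row counts differ")
    out = gcn_layer_t(
        ad.constant(X),
        None if A_norm is None else ad.constant(A_norm),
        ad.constant(W),
        phi,
    )
    return out.data


def encode(graph: EEGGraph, params: ModelParams, *, normalized: bool = None) -> GaussianPosterior:
    """Posterior for one view of a clip.

    An adjacency equal to the identity matrix gives the semantic view
    (no aggregation), anything else the structural view; the check is on
    the matrix itself so corrupted identity-built graphs still aggregate
    their injected edges.  ``graph.A`` must already be GCN-normalized
    (see :func:`eegcorr.graphs.normalize_adjacency`).
    """
    is_identity = np.array_equal(graph.A.A, np.eye(graph.n_channels))
    A = None if is_identity else graph.A.A
    p = _params_to_tensors(params)
    mu_t, lv_t = encode_t(ad.constant(graph.X.X), None if A is None else ad.constant(A), p, params.activation)
    if not (np.all(np.isfinite(mu_t.data)) and np.all(np.isfinite(lv_t.data))):
        raise FloatingPointError("encoder produced non-finite posterior (divergence)")
    return GaussianPosterior(mu_t.data, lv_t.data, "semantic" if is_identity else "structural")


def sample_embedding(post: GaussianPosterior, seed: int) -> np.ndarray:
    """Reparameterized sample, deterministic given ``seed``."""
    rng = np.random.default_rng(seed)
    eta = rng.standard_normal(post.mu.shape)
    return post.mu + np.exp(post.log_var / 2.0) * eta


def fuse(Z_st: np.ndarray, Z_se: np.ndarray) -> np.ndarray:
    """Fusion embedding Z_f = Z_st + Z_se."""
    Z_st = np.asarray(Z_st, dtype=float)
    Z_se = np.asarray(Z_se, dtype=float)
    if Z_st.shape != Z_se.shape:
        raise ValueError(f"shape mismatch {Z_st.shape} vs {Z_se.shape}")
    return Z_st + Z_se


def decode_attributes(Z_f: np.ndarray, params: ModelParams) -> np.ndarray:
    p = _params_to_tensors(params)
    return decode_attributes_t(
        ad.constant(np.asarray(Z_f, dtype=float)), p, len(params.dec_W), params.activation
    ).data


def decode_structure(Z_f: np.ndarray) -> np.ndarray:
    """A_hat = logistic(Z_f Z_f^T), symmetric with entries in (0, 1)."""
    return decode_structure_t(ad.constant(np.asarray(Z_f, dtype=float))).data
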