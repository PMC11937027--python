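"""EEG graph construction.

A clip is turned into an attributed graph ``G = {A, X}``: ``A`` encodes
inter-channel connectivity (one of five builders below) and ``X`` holds
per-channel features.  A sixth, the identity graph ``G' = {I, X}``,
carries no inter-channel edges and is the "semantic" view of the
weight-sharing encoder.

Builders
--------
dist
    Gaussian kernel of inter-electrode Euclidean distance, truncated at a
    distance threshold ``k`` (0.9 on unit-sphere coordinates).
corr
    Normalized lag-zero cross-correlation of channel features; only the
    three strongest edges per node are kept.
rand
    All off-diagonal entries 0.5 (every pair equally connected).
full
    All entries 1.
dtf
    Correlation of a pair normalized by the summed squared correlations
    of the source channel with all third channels, on the same top-3
    neighborhood as ``corr``.
identity
    The identity matrix: no relationships between channels.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field

import numpy as np

from .clips import EEGClip
from .layout import ElectrodeLayout

__all__ = [
    "FeatureMatrix",
    "AdjacencyMatrix",
    "EEGGraph",
    "extract_features",
    "build_dist_graph",
    "build_corr_graph",
    "build_rand_graph",
    "build_full_graph",
    "build_dtf_graph",
    "build_identity_graph",
    "build_graph",
    "normalize_adjacency",
    "graph_to_json",
    "graph_from_json",
    "matrix_to_csv",
    "EPS",
    "GRAPH_KINDS",
    "TOP_K_NEIGHBORS",
]

logger = logging.getLogger(__name__)

EPS = 1e-8
TOP_K_NEIGHBORS = 3
GRAPH_KINDS = ("dist", "corr", "rand", "full", "dtf", "identity")


@dataclass(frozen=True)
class FeatureMatrix:
    """N x D per-channel feature matrix with finite entries."""

    X: np.ndarray

    def __post_init__(self):
        X = np.asarray(self.X, dtype=float)
        if X.ndim != 2:
            raise ValueError("feature matrix must be 2-D (channels x features)")
        if not np.all(np.isfinite(X)):
            raise ValueError("feature matrix contains non-finite entries")
        object.__setattr__(self, "X", X)

    @property
    def n_channels(self) -> int:
        return self.X.shape[0]

    @property
    def n_features(self) -> int:
        return self.X.shape[1]


@dataclass(frozen=True)
class AdjacencyMatrix:
    """N x N adjacency with its builder kind and parameters."""

    A: np.ndarray
    kind: str
    params: dict = field(default_factory=dict)

    def __post_init__(self):
        A = np.asarray(self.A, dtype=float)
        if A.ndim != 2 or A.shape[0] != A.shape[1]:
            raise ValueError("adjacency must be square")
        if not np.all(np.isfinite(A)):
            raise ValueError("adjacency contains non-finite entries")
        object.__setattr__(self, "A", A)
        object.__setattr__(self, "params", dict(self.params))

    @property
    def n_channels(self) -> int:
        return self.A.shape[0]


@dataclass(frozen=True)
class EEGGraph:
    """Attributed graph {A, X} for one clip."""

    A: AdjacencyMatrix
    X: FeatureMatrix

    def __post_init__(self):
        if self.A.n_channels != self.X.n_channels:
            raise ValueError(
                f"adjacency has {self.A.n_channels} nodes but features have "
                f"{self.X.n_channels} rows"
            )

    @property
    def n_channels(self) -> int:
        return self.X.n_channels

    def with_features(self, X: FeatureMatrix) -> "EEGGraph":
        return EEGGraph(self.A, X)


def _zscore_rows(M: np.ndarray) -> np.ndarray:
    mean = M.mean(axis=1, keepdims=True)
    sd = M.std(axis=1, keepdims=True)
    degenerate = sd < EPS
    if np.any(degenerate):
        warnings.warn(
            "zero-variance channel(s) in feature z-scoring; variance floored",
            RuntimeWarning,
            stacklevel=3,
        )
        sd = np.where(degenerate, EPS, sd)
    return (M - mean) / sd


def extract_features(clip: EEGClip, mode: str = "spectral", D: int = 64) -> FeatureMatrix:
    """Per-channel feature vectors from a clip.

    ``spectral`` (default): log-magnitude of the first ``D`` frequency
    bins of each channel's discrete Fourier transform, row z-scored.
    ``raw``: uniform downsampling of the time series to ``D`` samples,
    row z-scored.
    """
    if mode == "spectral":
        if D > clip.n_samples // 2:
            raise ValueError("spectral mode requires D <= samples/2")
        spectrum = np.fft.rfft(clip.signal, axis=1)
        mag = np.abs(spectrum[:, :D])
        feats = np.log(mag + EPS)
    elif mode == "raw":
        if D > clip.n_samples:
            raise ValueError("raw mode requires D <= samples")
        idx = np.linspace(0, clip.n_samples - 1, D).round().astype(int)
        feats = clip.signal[:, idx]
    else:
        raise ValueError(f"unknown feature mode {mode!r}")
    return FeatureMatrix(_zscore_rows(feats))


def build_dist_graph(
    layout: ElectrodeLayout, tau: float = 1.0, k: float = 0.9
) -> AdjacencyMatrix:
    """Distance graph: a_ij = exp(-||v_i - v_j||^2 / tau) within radius k.

    Pairs farther apart than ``k`` get weight 0, which sparsifies the
    graph; the diagonal is exp(0) = 1.
    """
    if tau <= 0:
        raise ValueError("tau must be positive")
    if layout.n_channels < 2:
        raise ValueError("need at least 2 electrodes")
    dist = layout.pairwise_distances()
    A = np.where(dist <= k, np.exp(-(dist**2) / tau), 0.0)
    return AdjacencyMatrix(A, "dist", {"tau": tau, "k": k})


def _centered_rows(X: np.ndarray) -> np.ndarray:
    return X - X.mean(axis=1, keepdims=True)


def _pairwise_correlation(X: np.ndarray) -> np.ndarray:
    """Lag-zero mean-centered cross-correlation matrix (unnormalized)."""
    C = _centered_rows(X)
    return C @ C.T


def _normalized_correlation(X: np.ndarray) -> np.ndarray:
    """corr(X_i, X_j) / (||X_i|| ||X_j||) on mean-centered rows: Pearson r."""
    C = _centered_rows(X)
    norms = np.maximum(np.linalg.norm(C, axis=1), EPS)
    return (C @ C.T) / np.outer(norms, norms)


def _topk_neighbor_mask(weights: np.ndarray, k: int = TOP_K_NEIGHBORS) -> np.ndarray:
    """Per-row boolean mask of the k largest |weights| off the diagonal.

    Ties broken toward the lower channel index so outputs are
    deterministic; rows of graphs with N-1 <= k keep everything.
    """
    N = weights.shape[0]
    mask = np.zeros((N, N), dtype=bool)
    for i in range(N):
        others = [j for j in range(N) if j != i]
        # stable sort on (-|w|, j): largest magnitude first, low index wins ties
        order = sorted(others, key=lambda j: (-abs(weights[i, j]), j))
        for j in order[:k]:
            mask[i, j] = True
    return mask


def build_corr_graph(X: FeatureMatrix) -> AdjacencyMatrix:
    """Functional-connectivity graph from normalized cross-correlation.

    Edge weight is the normalized lag-zero correlation of the two
    channels' feature rows; each node keeps only its three strongest
    edges (by absolute correlation) to avoid an overly connected graph.
    """
    N = X.n_channels
    W = _normalized_correlation(X.X)
    np.fill_diagonal(W, 0.0)
    if N <= TOP_K_NEIGHBORS:
        logger.warning(
            "corr graph with N=%d <= %d: keeping all off-diagonal edges", N, TOP_K_NEIGHBORS
        )
        return AdjacencyMatrix(W, "corr", {"top_k": TOP_K_NEIGHBORS})
    mask = _topk_neighbor_mask(W)
    return AdjacencyMatrix(np.where(mask, W, 0.0), "corr", {"top_k": TOP_K_NEIGHBORS})


def build_rand_graph(N: int) -> AdjacencyMatrix:
    """Uniform graph: every pair connected with weight 0.5, diagonal 1."""
    if N < 1:
        raise ValueError("need at least 1 channel")
    A = np.full((N, N), 0.5)
    np.fill_diagonal(A, 1.0)
    return AdjacencyMatrix(A, "rand", {})


def build_full_graph(N: int) -> AdjacencyMatrix:
    """Complete graph with all weights 1."""
    if N < 1:
        raise ValueError("need at least 1 channel")
    return AdjacencyMatrix(np.ones((N, N)), "full", {})


def build_dtf_graph(X: FeatureMatrix) -> AdjacencyMatrix:
    """Directed-influence graph normalizing pair correlation by the rest.

    a_ij = corr(X_i, X_j) / sum_{m != i,j} corr(X_i, X_m)^2 on the same
    top-3 neighborhood as the correlation graph; rows are directed.
    """
    N = X.n_channels
    if N < 3:
        raise ValueError("DTF graph requires >= 3 channels")
    C = _pairwise_correlation(X.X)
    rank_w = _normalized_correlation(X.X)
    np.fill_diagonal(rank_w, 0.0)
    A = np.zeros((N, N))
    sq = C**2
    for i in range(N):
        for j in range(N):
            if i == j:
                continue
            denom = sq[i].sum() - sq[i, i] - sq[i, j]
            A[i, j] = C[i, j] / max(denom, EPS)
    if N - 1 > TOP_K_NEIGHBORS:
        mask = _topk_neighbor_mask(rank_w)
        A = np.where(mask, A, 0.0)
    return AdjacencyMatrix(A, "dtf", {"top_k": TOP_K_NEIGHBORS})


def build_identity_graph(N: int) -> AdjacencyMatrix:
    """Identity matrix: no relationships between channels."""
    if N < 1:
        raise ValueError("need at least 1 channel")
    return AdjacencyMatrix(np.eye(N), "identity", {})


def build_graph(
    kind: str,
    X: FeatureMatrix,
    layout: ElectrodeLayout | None = None,
    tau: float = 1.0,
    k: float = 0.9,
) -> EEGGraph:
    """Dispatch on graph kind and pair the adjacency with the features."""
    N = X.n_channels
    if kind == "dist":
        if layout is None:
            raise ValueError("dist graph requires an electrode layout")
        A = build_dist_graph(layout, tau=tau, k=k)
    elif kind == "corr":
        A = build_corr_graph(X)
    elif kind == "rand":
        A = build_rand_graph(N)
    elif kind == "full":
        A = build_full_graph(N)
    elif kind == "dtf":
        A = build_dtf_graph(X)
    elif kind == "identity":
        A = build_identity_graph(N)
    else:
        raise ValueError(f"unknown graph kind {kind!r}; expected one of {GRAPH_KINDS}")
    return EEGGraph(A, X)


def normalize_adjacency(A: AdjacencyMatrix, add_self_loops: bool = True) -> AdjacencyMatrix:
    """Symmetric GCN normalization D^{-1/2} (A [+ I]) D^{-1/2}.

    Self-loops are added by default so sparse graphs cannot have
    zero-degree rows; an identity matrix is its own normalization and is
    returned unchanged (the check is on the matrix, not the kind tag,
    since corruption can add edges to an identity-built graph).
    """
    if np.array_equal(A.A, np.eye(A.n_channels)):
        return A
    M = A.A + np.eye(A.n_channels) if add_self_loops else A.A.copy()
    deg = M.sum(axis=1)
    if np.any(deg <= 0):
        bad = int(np.argmin(deg))
        raise ValueError(
            f"non-positive degree ({deg[bad]:.3g}) at node {bad}; "
            "cannot normalize without self-loops" if not add_self_loops
            else f"non-positive degree ({deg[bad]:.3g}) at node {bad}"
        )
    d_inv_sqrt = 1.0 / np.sqrt(deg)
    M = d_inv_sqrt[:, None] * M * d_inv_sqrt[None, :]
    params = dict(A.params, normalized=True, self_loops=add_self_loops)
    return AdjacencyMatrix(M, A.kind, params)


def graph_to_json(graph: EEGGraph, labels=None) -> str:
    """Serialize a graph as a single JSON document {kind, params, labels, A, X}."""
    doc = {
        "kind": graph.A.kind,
        "params": graph.A.params,
        "labels": list(labels) if labels is not None else None,
        "A": graph.A.A.tolist(),
        "X": graph.X.X.tolist(),
    }
    return json.dumps(doc)


def matrix_to_csv(M: np.ndarray, labels, path):
    """Write an adjacency or feature matrix as CSV with channel-label
    header (adjacency also gets a label index column)."""
    import pandas as pd

    M = np.asarray(M, dtype=float)
    labels = list(labels)
    if M.shape[0] != len(labels):
        raise ValueError(f"{len(labels)} labels for {M.shape[0]} rows")
    square = M.shape[0] == M.shape[1]
    df = pd.DataFrame(M, columns=labels if square else None, index=labels)
    df.to_csv(path, float_format="%.12g", index_label="channel")


def graph_from_json(text: str) -> EEGGraph:
    doc = json.loads(text)
    return EEGGraph(
        AdjacencyMatrix(np.array(doc["A"], dtype=float), doc["kind"], doc.get("params", {})),
        FeatureMatrix(np.array(doc["X"], dtype=float)),
    )
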