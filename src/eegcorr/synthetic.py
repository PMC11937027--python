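"""Synthetic multichannel clips and the corruption benchmark.

Real seizure corpora are access-controlled, so the pipeline is exercised
on surrogate data: each channel is a mixing-weighted sum of a few
band-limited stochastic latent sources plus white sensor noise.
Channels that load on the same sources are correlated, which makes the
correlation- and influence-based graph builders non-trivial.

The benchmark mirrors the anomalous-channel protocol: average every 35
normal clips without overlap, then corrupt at most one node per averaged
clip with small probability, applying BOTH corruptions to it —
structural (connect it to every other node) and contextual (replace its
feature vector with that of the Euclidean-farthest node).  A detector
trained on pure normal clips is then asked to find the corrupted nodes.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
from scipy import signal as sp_signal

from .clips import EEGClip
from .graphs import AdjacencyMatrix, EEGGraph, FeatureMatrix, build_graph, extract_features
from .layout import STANDARD_1020_CHANNELS, standard_1020_layout

__all__ = [
    "GeneratorSpec",
    "BenchmarkSet",
    "default_mixing",
    "generate_normal_clip",
    "average_clips",
    "inject_anomaly",
    "make_benchmark",
    "save_benchmark",
    "load_benchmark",
]

DEFAULT_WINDOW = 35
DEFAULT_P_INJECT = 0.03


@dataclass(frozen=True)
class GeneratorSpec:
    """Parameters of the normal-clip generator.

    Defaults emulate a 19-channel 10-20 recording: 12-second clips at
    250 Hz, four rhythmic cortical sources band-limited to 1-30 Hz, and
    moderate white sensor noise.
    """

    N: int = 19
    fs: float = 250.0
    duration: float = 12.0
    n_sources: int = 4
    mixing: np.ndarray = None
    noise_sd: float = 0.1
    band: tuple = (1.0, 30.0)
    mixing_seed: int = 0

    def __post_init__(self):
        if self.n_sources < 1:
            raise ValueError("need at least one latent source")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if self.mixing is not None:
            M = np.asarray(self.mixing, dtype=float)
            if M.shape != (self.N, self.n_sources):
                raise ValueError(
                    f"mixing must be ({self.N}, {self.n_sources}), got {M.shape}"
                )
            object.__setattr__(self, "mixing", M)

    @property
    def n_samples(self) -> int:
        return int(round(self.fs * self.duration))

    def resolved_mixing(self) -> np.ndarray:
        if self.mixing is not None:
            return self.mixing
        return default_mixing(self.N, self.n_sources, self.mixing_seed)

    def to_dict(self) -> dict:
        return {
            "N": self.N,
            "fs": self.fs,
            "duration": self.duration,
            "n_sources": self.n_sources,
            "mixing": None if self.mixing is None else self.mixing.tolist(),
            "noise_sd": self.noise_sd,
            "band": list(self.band),
            "mixing_seed": self.mixing_seed,
        }

    @classmethod
    def from_dict(cls, doc: dict) -> "GeneratorSpec":
        doc = dict(doc)
        if doc.get("mixing") is not None:
            doc["mixing"] = np.array(doc["mixing"], dtype=float)
        doc["band"] = tuple(doc.get("band", (1.0, 30.0)))
        return cls(**doc)


def default_mixing(N: int, n_sources: int, seed: int = 0) -> np.ndarray:
    """Spatially smooth source loadings.

    Each source is anchored at a random point on the scalp sphere and
    loads on each electrode with a Gaussian falloff in Euclidean
    distance, mimicking volume conduction; nearby electrodes therefore
    share sources and are correlated.
    """
    rng = np.random.default_rng(seed)
    if N == len(STANDARD_1020_CHANNELS):
        coords = standard_1020_layout().coords
    else:
        coords = rng.standard_normal((N, 3))
        coords /= np.linalg.norm(coords, axis=1, keepdims=True)
    centers = rng.standard_normal((n_sources, 3))
    centers /= np.linalg.norm(centers, axis=1, keepdims=True)
    d2 = ((coords[:, None, :] - centers[None, :, :]) ** 2).sum(axis=-1)
    return np.exp(-d2 / 0.8)


def _bandlimited_sources(spec: GeneratorSpec, rng: np.random.Generator) -> np.ndarray:
    """Unit-variance band-limited noise sources, one per row."""
    raw = rng.standard_normal((spec.n_sources, spec.n_samples))
    lo, hi = spec.band
    nyq = spec.fs / 2.0
    sos = sp_signal.butter(4, [lo / nyq, hi / nyq], btype="band", output="sos")
    src = sp_signal.sosfiltfilt(sos, raw, axis=1)
    sd = src.std(axis=1, keepdims=True)
    return src / np.maximum(sd, 1e-12)


def generate_normal_clip(spec: GeneratorSpec, seed: int) -> EEGClip:
    """One normal clip: mixing @ sources + white noise, deterministic in
    ``seed``.  Amplitudes are scaled to a plausible microvolt range."""
    rng = np.random.default_rng(seed)
    sources = _bandlimited_sources(spec, rng)
    mixing = spec.resolved_mixing()
    sig = mixing @ sources
    if spec.noise_sd > 0:
        sig = sig + spec.noise_sd * rng.standard_normal(sig.shape)
    labels = (
        STANDARD_1020_CHANNELS
        if spec.N == len(STANDARD_1020_CHANNELS)
        else tuple(f"CH{i}" for i in range(spec.N))
    )
    return EEGClip(30.0 * sig, spec.fs, labels)


def average_clips(features, window: int = DEFAULT_WINDOW) -> list:
    """Average consecutive disjoint blocks of ``window`` feature matrices
    elementwise; a trailing partial block is dropped."""
    features = list(features)
    if window < 1:
        raise ValueError("window must be >= 1")
    if len(features) < window:
        raise ValueError(f"need at least {window} clips, got {len(features)}")
    out = []
    for b in range(len(features) // window):
        block = features[b * window : (b + 1) * window]
        out.append(FeatureMatrix(np.mean([f.X for f in block], axis=0)))
    return out


def inject_anomaly(graph: EEGGraph, p_inject: float, seed: int):
    """Corrupt at most one node of a graph, with probability ``p_inject``.

    The corrupted node gets both treatments: its adjacency row and
    column are set to 1 against every other node (structural), and its
    feature row is replaced by the feature row of the node at the
    largest Euclidean distance from it (contextual).

    Returns ``(graph, node_labels)``; labels mark the corrupted node.
    """
    if graph.n_channels < 2:
        raise ValueError("need at least 2 nodes to inject an anomaly")
    if not 0 <= p_inject <= 1:
        raise ValueError("p_inject must be in [0, 1]")
    rng = np.random.default_rng(seed)
    N = graph.n_channels
    labels = np.zeros(N, dtype=int)
    if rng.random() >= p_inject:
        return graph, labels
    node = int(rng.integers(N))
    labels[node] = 1

    A = graph.A.A.copy()
    mask = np.arange(N) != node
    A[node, mask] = 1.0
    A[mask, node] = 1.0

    X = graph.X.X.copy()
    dists = np.linalg.norm(X - X[node], axis=1)
    farthest = int(np.argmax(dists))
    X[node] = X[farthest]

    params = dict(graph.A.params, injected_node=node, swap_source=farthest)
    return EEGGraph(AdjacencyMatrix(A, graph.A.kind, params), FeatureMatrix(X)), labels


@dataclass(frozen=True)
class BenchmarkSet:
    """Averaged clips with injected anomalies and their ground truth."""

    graphs: list
    features: list
    node_labels: np.ndarray
    clip_labels: np.ndarray
    params: dict = field(default_factory=dict)
    seed: int = 0

    def __post_init__(self):
        nl = np.asarray(self.node_labels, dtype=int)
        cl = np.asarray(self.clip_labels, dtype=int)
        if nl.shape[0] != len(self.graphs) or cl.shape[0] != len(self.graphs):
            raise ValueError("label/clip count mismatch")
        if np.any(nl.sum(axis=1) > 1):
            raise ValueError("at most one corrupted node per clip")
        if not np.array_equal(cl, (nl.sum(axis=1) > 0).astype(int)):
            raise ValueError("clip label must be the OR of its node labels")
        object.__setattr__(self, "node_labels", nl)
        object.__setattr__(self, "clip_labels", cl)

    @property
    def n_clips(self) -> int:
        return len(self.graphs)


def make_benchmark(
    spec: GeneratorSpec = GeneratorSpec(),
    n_clips: int = 350,
    window: int = DEFAULT_WINDOW,
    p_inject: float = DEFAULT_P_INJECT,
    seed: int = 0,
    graph_kind: str = "corr",
    feature_mode: str = "spectral",
    D: int = 64,
    tau: float = 1.0,
    k: float = 0.9,
) -> BenchmarkSet:
    """Full benchmark protocol: generate -> featurize -> average ->
    build graphs -> inject.

    All randomness flows from one seeded stream, so a fixed seed gives a
    byte-identical benchmark.
    """
    if n_clips < window:
        raise ValueError("n_clips must be >= window")
    rng = np.random.default_rng(seed)
    clip_seeds = rng.integers(2**31, size=n_clips)
    feats = [
        extract_features(generate_normal_clip(spec, int(s)), feature_mode, D)
        for s in clip_seeds
    ]
    averaged = average_clips(feats, window)
    layout = standard_1020_layout() if spec.N == len(STANDARD_1020_CHANNELS) else None

    graphs, node_labels = [], []
    inject_seeds = rng.integers(2**31, size=len(averaged))
    for fm, s in zip(averaged, inject_seeds):
        g = build_graph(graph_kind, fm, layout=layout, tau=tau, k=k)
        g, labels = inject_anomaly(g, p_inject, int(s))
        graphs.append(g)
        node_labels.append(labels)
    node_labels = np.array(node_labels, dtype=int)
    clip_labels = (node_labels.sum(axis=1) > 0).astype(int)
    params = {
        "spec": spec.to_dict(),
        "n_clips": n_clips,
        "window": window,
        "p_inject": p_inject,
        "graph_kind": graph_kind,
        "feature_mode": feature_mode,
        "D": D,
        "tau": tau,
        "k": k,
    }
    return BenchmarkSet(graphs, averaged, node_labels, clip_labels, params, seed)


# ---------------------------------------------------------------------
# directory serialization (CSV matrices + JSON manifest)
# ---------------------------------------------------------------------

def save_benchmark(bench: BenchmarkSet, outdir):
    """Write features/adjacencies as per-clip CSVs plus a JSON manifest."""
    from pathlib import Path

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    for i, g in enumerate(bench.graphs):
        np.savetxt(outdir / f"clip{i:04d}_X.csv", g.X.X, delimiter=",", fmt="%.17g")
        np.savetxt(outdir / f"clip{i:04d}_A.csv", g.A.A, delimiter=",", fmt="%.17g")
    manifest = {
        "n_clips": bench.n_clips,
        "graph_kind": bench.graphs[0].A.kind if bench.graphs else None,
        "node_labels": bench.node_labels.tolist(),
        "clip_labels": bench.clip_labels.tolist(),
        "params": bench.params,
        "seed": bench.seed,
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))


def load_benchmark(indir) -> BenchmarkSet:
    from pathlib import Path

    indir = Path(indir)
    manifest = json.loads((indir / "manifest.json").read_text())
    kind = manifest.get("graph_kind") or "corr"
    graphs, features = [], []
    for i in range(manifest["n_clips"]):
        X = np.loadtxt(indir / f"clip{i:04d}_X.csv", delimiter=",", ndmin=2)
        A = np.loadtxt(indir / f"clip{i:04d}_A.csv", delimiter=",", ndmin=2)
        fm = FeatureMatrix(X)
        features.append(fm)
        graphs.append(EEGGraph(AdjacencyMatrix(A, kind, {}), fm))
    return BenchmarkSet(
        graphs,
        features,
        np.array(manifest["node_labels"], dtype=int),
        np.array(manifest["clip_labels"], dtype=int),
        manifest.get("params", {}),
        manifest.get("seed", 0),
    )
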