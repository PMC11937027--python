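"""Model/Results interface for the graph-correlation anomaly detector.

:class:`GraphCorrelationModel` is built from a collection of per-clip
EEG graphs (one graph per clip, all sharing the montage) and fitted on
normal data only.  :meth:`GraphCorrelationModel.fit` returns a
:class:`GraphCorrelationResults` carrying the trained parameters, the
per-epoch loss history, and the scoring/evaluation methods.

Example
-------
>>> bench = make_benchmark(p_inject=0.0, n_clips=70, seed=7)
>>> model = GraphCorrelationModel(bench.graphs)
>>> res = model.fit(epochs=50, seed=7)
>>> scores = res.score(bench.graphs)       # per-clip + per-channel scores
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .graphs import EEGGraph, build_identity_graph, normalize_adjacency
from .layout import STANDARD_1020_CHANNELS
from .losses import LossConfig, train
from .model import EmbeddingSet, ModelParams, encode, fuse, sample_embedding
from .losses import normalize_embeddings
from .scoring import AnomalyScores, EvalReport, clip_score, evaluate, node_scores

__all__ = ["GraphCorrelationModel", "GraphCorrelationResults"]


class GraphCorrelationModel:
    """Unsupervised channel-anomaly model over per-clip EEG graphs.

    Parameters
    ----------
    graphs : sequence of EEGGraph
        Training clips, assumed normal; all must share the channel count
        and feature dimension.
    loss_config : LossConfig, optional
        Objective weights (decorrelation trade-off etc.).
    hidden_dim, latent_dim, decoder_hidden : int
        Encoder hidden width h, latent width d, decoder hidden width.
    channel_labels : sequence of str, optional
        Montage names used in score tables; defaults to the 10-20
        montage when the channel count matches, else CH0..CHn.
    """

    def __init__(
        self,
        graphs,
        loss_config: LossConfig = None,
        hidden_dim: int = 64,
        latent_dim: int = 32,
        decoder_hidden: int = 64,
        channel_labels=None,
    ):
        graphs = list(graphs)
        if not graphs:
            raise ValueError("need at least one training graph")
        if not all(isinstance(g, EEGGraph) for g in graphs):
            raise TypeError("graphs must be EEGGraph instances")
        N = graphs[0].n_channels
        D = graphs[0].X.n_features
        for g in graphs:
            if g.n_channels != N or g.X.n_features != D:
                raise ValueError("all graphs must share channel/feature counts")
        self.graphs = graphs
        self.n_channels = N
        self.n_features = D
        self.loss_config = loss_config or LossConfig()
        self.hidden_dim = hidden_dim
        self.latent_dim = latent_dim
        self.decoder_hidden = decoder_hidden
        if channel_labels is None:
            channel_labels = (
                STANDARD_1020_CHANNELS
                if N == len(STANDARD_1020_CHANNELS)
                else tuple(f"CH{i}" for i in range(N))
            )
        self.channel_labels = tuple(channel_labels)

    @classmethod
    def from_clips(
        cls,
        clips,
        graph_kind: str = "corr",
        feature_mode: str = "spectral",
        D: int = 64,
        layout=None,
        **kwargs,
    ) -> "GraphCorrelationModel":
        """Build per-clip graphs from raw clips, then the model."""
        from .graphs import build_graph, extract_features
        from .layout import standard_1020_layout

        clips = list(clips)
        if layout is None and clips and clips[0].n_channels == len(STANDARD_1020_CHANNELS):
            layout = standard_1020_layout()
        graphs = [
            build_graph(graph_kind, extract_features(c, feature_mode, D), layout=layout)
            for c in clips
        ]
        labels = clips[0].channel_labels if clips else None
        return cls(graphs, channel_labels=labels, **kwargs)

    def fit(
        self, epochs: int = 200, lr: float = 1e-3, seed: int = 0, callback=None
    ) -> "GraphCorrelationResults":
        """Train by full-batch-per-clip gradient descent; deterministic
        given ``seed``."""
        params, history = train(
            self.graphs,
            cfg=self.loss_config,
            seed=seed,
            epochs=epochs,
            lr=lr,
            hidden_dim=self.hidden_dim,
            latent_dim=self.latent_dim,
            decoder_hidden=self.decoder_hidden,
            callback=callback,
        )
        return GraphCorrelationResults(self, params, history, seed=seed, epochs=epochs, lr=lr)


class GraphCorrelationResults:
    """Fitted detector: trained weights, loss history, scoring."""

    def __init__(self, model, params: ModelParams, history, seed: int, epochs: int, lr: float):
        self.model = model
        self.params = params
        self.history = list(history)
        self.seed = seed
        self.epochs = epochs
        self.lr = lr

    # -- diagnostics --------------------------------------------------
    def history_frame(self) -> pd.DataFrame:
        """Per-epoch loss breakdown as a DataFrame."""
        df = pd.DataFrame([h.as_dict() for h in self.history])
        df.insert(0, "epoch", np.arange(len(df)))
        return df

    def summary(self) -> str:
        """Plain-text summary in the spirit of statsmodels results."""
        first = self.history[0].as_dict() if self.history else {}
        last = self.history[-1].as_dict() if self.history else {}
        dims = self.params.dims
        kind = self.model.graphs[0].A.kind if self.model.graphs else "n/a"
        lines = [
            "Graph Correlation Anomaly Detector",
            "=" * 54,
            f"clips (training):      {len(self.model.graphs)}",
            f"channels / features:   {self.model.n_channels} / {self.model.n_features}",
            f"graph kind:            {kind}",
            f"dims (D, h, d, L):     ({dims['D']}, {dims['h']}, {dims['d']}, {dims['L']})",
            f"lambda (decorrelation): {self.model.loss_config.lambda_dco}",
            f"epochs / lr / seed:    {self.epochs} / {self.lr} / {self.seed}",
            "-" * 54,
            f"{'term':<10}{'epoch 0':>14}{'final':>14}",
        ]
        for key in ("L_inv", "L_dco", "L_kl", "L_dec", "L_total"):
            lines.append(f"{key:<10}{first.get(key, float('nan')):>14.4f}{last.get(key, float('nan')):>14.4f}")
        lines.append("=" * 54)
        return "\n".join(lines)

    # -- embedding and scoring ---------------------------------------
    def embed(self, graph: EEGGraph, sample_seed: int = None) -> EmbeddingSet:
        """Both views' embeddings for one clip.

        Posterior means by default (deterministic scores); pass
        ``sample_seed`` to draw reparameterized samples instead.
        """
        A_norm = graph.A if graph.A.params.get("normalized") else normalize_adjacency(graph.A)
        g_struct = EEGGraph(A_norm, graph.X)
        g_sem = EEGGraph(build_identity_graph(graph.n_channels), graph.X)
        post_st = encode(g_struct, self.params)
        post_se = encode(g_sem, self.params)
        if sample_seed is None:
            Z_st, Z_se = post_st.mu, post_se.mu
        else:
            Z_st = sample_embedding(post_st, sample_seed)
            Z_se = sample_embedding(post_se, sample_seed + 1)
        return EmbeddingSet(
            Z_st, Z_se, normalize_embeddings(Z_st), normalize_embeddings(Z_se), fuse(Z_st, Z_se)
        )

    def node_scores(self, graph: EEGGraph) -> np.ndarray:
        """Per-channel anomaly scores for one clip (posterior means)."""
        emb = self.embed(graph)
        return node_scores(emb.Z_st_norm, emb.Z_se_norm)

    def score(self, graphs, aggregation: str = "mean") -> pd.DataFrame:
        """Score a batch of clips.

        Returns one row per clip: ``clip_score`` plus one column per
        channel label.
        """
        graphs = list(graphs)
        rows = []
        for g in graphs:
            s = self.node_scores(g)
            rows.append([clip_score(s, aggregation), *s])
        labels = self.model.channel_labels
        if graphs and len(labels) != graphs[0].n_channels:
            labels = tuple(f"CH{i}" for i in range(graphs[0].n_channels))
        return pd.DataFrame(rows, columns=["clip_score", *labels])

    def anomaly_scores(self, graph: EEGGraph, aggregation: str = "mean") -> AnomalyScores:
        s = self.node_scores(graph)
        return AnomalyScores(s, clip_score(s, aggregation), aggregation)

    def evaluate_nodes(self, graphs, node_labels, threshold=None, q: float = 0.95) -> EvalReport:
        """Node-level detection metrics over a labeled benchmark."""
        scores = np.concatenate([self.node_scores(g) for g in graphs])
        labels = np.asarray(node_labels, dtype=int).ravel()
        return evaluate(scores, labels, threshold=threshold, q=q)

    def evaluate_clips(
        self, graphs, clip_labels, aggregation: str = "mean", threshold=None, q: float = 0.95
    ) -> EvalReport:
        """Clip-level detection metrics (aggregated channel scores)."""
        scores = np.array([clip_score(self.node_scores(g), aggregation) for g in graphs])
        return evaluate(scores, np.asarray(clip_labels, dtype=int), threshold=threshold, q=q)

    # -- persistence --------------------------------------------------
    def save(self, path):
        """Single-JSON checkpoint; loading reproduces forward passes
        bit-for-bit (floats round-trip exactly through JSON repr)."""
        doc = {
            "format": "eegcorr-checkpoint-v1",
            "params": self.params.to_dict(),
            "loss_config": {
                "lambda_dco": self.model.loss_config.lambda_dco,
                "w_cca": self.model.loss_config.w_cca,
                "w_kl": self.model.loss_config.w_kl,
                "w_dec": self.model.loss_config.w_dec,
            },
            "n_channels": self.model.n_channels,
            "n_features": self.model.n_features,
            "channel_labels": list(self.model.channel_labels),
            "training": {"epochs": self.epochs, "lr": self.lr, "seed": self.seed},
            "history": [h.as_dict() for h in self.history],
        }
        with open(path, "w") as fh:
            json.dump(doc, fh)

    @classmethod
    def load(cls, path) -> "GraphCorrelationResults":
        from .losses import LossBreakdown

        with open(path) as fh:
            doc = json.load(fh)
        params = ModelParams.from_dict(doc["params"])
        cfg = LossConfig(**doc["loss_config"])
        model = _CheckpointModel(
            doc["n_channels"], doc["n_features"], cfg, tuple(doc["channel_labels"])
        )
        history = [LossBreakdown(**h) for h in doc.get("history", [])]
        tr = doc.get("training", {})
        return cls(model, params, history, tr.get("seed", 0), tr.get("epochs", 0), tr.get("lr", 0.0))


@dataclass
class _CheckpointModel:
    """Stand-in model carrying only what scoring needs after load."""

    n_channels: int
    n_features: int
    loss_config: LossConfig
    channel_labels: tuple

    @property
    def graphs(self):
        return []
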