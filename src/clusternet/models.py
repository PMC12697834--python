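"""LocNet and ClusterNet.

ClusterNet classifies one hierarchical graph: four message-passing layers
with PointTransformer-style vector-attention convolutions over the cluster
nodes and their kNN edges, a global elementwise-maximum pooling over cluster
features, and a final linear layer producing per-class log probabilities.

Cluster input features are either the 8 handcrafted features (HCF mode) or an
8-dimensional embedding of each cluster's member localizations computed by
LocNet (LCF mode), a per-cluster point-set network (PointTransformer blocks
over the member localizations, max-pooled, sigmoid-squashed to (0, 1)).
In LCF mode LocNet and ClusterNet form a single network trained end to end.

The attention convolution: for edge j -> i with features x and positions p,

    delta_ij = theta(p_j - p_i)                       (learned position code)
    e_ij     = gamma(q(x_i) - k(x_j) + delta_ij)      (per-channel logits)
    a_ij     = softmax over j in N(i) of e_ij
    y_i      = sum_j a_ij * (v(x_j) + delta_ij)

where q, k, v are linear maps and theta, gamma are two-layer MLPs. Only
relative positions enter, so the layer is translation invariant; rotation
robustness is learned from augmentation, not built in.

Exact hidden widths are configurable; the defaults below are the package's
own CPU-friendly choices.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import cdist

from . import engine as eg
from .engine import LayerNorm, Linear, Module, SegIdx, Tensor
from .exceptions import ConfigError, PreconditionError
from .graphs import HierarchicalGraph


@dataclass(frozen=True)
class ModelConfig:
    n_classes: int = 7
    mode: str = "HCF"  # {"HCF", "LCF"}
    embed_dim: int = 8  # LocNet output / HCF input width
    n_message_layers: int = 4
    hidden_dim: int = 64
    locnet_hidden: int = 16
    locnet_blocks: int = 2
    locnet_k: int = 8  # attention neighbourhood inside a cluster
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_classes < 2:
            raise ConfigError("n_classes must be >= 2")
        if self.mode not in ("HCF", "LCF"):
            raise ConfigError(f"unknown mode {self.mode!r}")
        if min(self.embed_dim, self.n_message_layers, self.hidden_dim) < 1:
            raise ConfigError("dimensions must be positive")


@dataclass
class ClassPrediction:
    """Forward-pass outputs for a batch of graphs, with the intermediate
    features the explainability stage consumes."""

    log_probs: np.ndarray  # (G, n_classes)
    predicted_class: np.ndarray  # (G,) argmax, ties -> lowest index
    graph_feature: np.ndarray  # (G, hidden) pooled
    cluster_features_post_mp: np.ndarray  # (M, hidden) after last MP layer
    locnet_features: np.ndarray | None  # (M, embed_dim) LCF only
    graph_ids: np.ndarray  # (M,) graph index per cluster row


# ---------------------------------------------------------------------------
# batching


def loc_knn_edges(graph: HierarchicalGraph, k: int) -> np.ndarray:
    """(2, E) [src; dst] kNN edges (+self) among each cluster's member
    localizations, in graph-local localization indices. Cached on the graph;
    rigid motions preserve the result, so rotated copies may share it."""
    cache = graph.__dict__.setdefault("_locknn_cache", {})
    if k in cache:
        return cache[k]
    src_all, dst_all = [], []
    for cid in range(graph.n_clusters):
        members = np.flatnonzero(graph.loc_cluster == cid)
        pts = graph.loc_pos[members]
        m = len(members)
        d = cdist(pts, pts)
        np.fill_diagonal(d, np.inf)
        k_eff = min(k, m - 1)
        if k_eff > 0:
            nbrs = np.argsort(d, axis=1, kind="stable")[:, :k_eff]
            src_all.append(members[nbrs.ravel()])
            dst_all.append(np.repeat(members, k_eff))
        src_all.append(members)  # self edges
        dst_all.append(members)
    edges = np.vstack([np.concatenate(src_all), np.concatenate(dst_all)])
    cache[k] = edges
    return edges


class GraphBatch:
    """Several hierarchical graphs stacked into flat arrays with offsets."""

    def __init__(self, graphs: list[HierarchicalGraph], cfg: ModelConfig,
                 class_to_index: dict[str, int] | None = None):
        if not graphs:
            raise PreconditionError("empty batch")
        c_pos, c_feat, g_ids = [], [], []
        e_src, e_dst = [], []
        l_pos, l_cluster, le_src, le_dst = [], [], [], []
        c_off = 0
        l_off = 0
        for gi, g in enumerate(graphs):
            if g.n_clusters < 1:
                raise PreconditionError("graph without cluster nodes")
            c_pos.append(g.cluster_pos)
            g_ids.append(np.full(g.n_clusters, gi, np.int64))
            e_src.append(g.edges[0] + c_off)
            e_dst.append(g.edges[1] + c_off)
            if cfg.mode == "HCF":
                if g.cluster_features is None:
                    raise PreconditionError("HCF mode needs cluster features on every graph")
                c_feat.append(g.cluster_features)
            else:
                l_pos.append(g.loc_pos)
                l_cluster.append(g.loc_cluster + c_off)
                le = loc_knn_edges(g, cfg.locnet_k)
                le_src.append(le[0] + l_off)
                le_dst.append(le[1] + l_off)
                l_off += len(g.loc_pos)
            c_off += g.n_clusters
        self.n_graphs = len(graphs)
        self.n_clusters = c_off
        self.cluster_pos = np.concatenate(c_pos).astype(np.float32)
        self.graph_ids = np.concatenate(g_ids)
        # SegIdx wrappers precompute sort metadata for the hot segment ops
        self.graph_ids_seg = SegIdx(self.graph_ids)
        self.edge_src = SegIdx(np.concatenate(e_src))
        self.edge_dst = SegIdx(np.concatenate(e_dst))
        self.cluster_features = np.concatenate(c_feat).astype(np.float32) if c_feat else None
        if cfg.mode == "LCF":
            self.loc_pos = np.concatenate(l_pos).astype(np.float32)
            self.loc_cluster = SegIdx(np.concatenate(l_cluster))
            self.loc_edge_src = SegIdx(np.concatenate(le_src))
            self.loc_edge_dst = SegIdx(np.concatenate(le_dst))
        labels = [g.label for g in graphs]
        if class_to_index is not None and all(lb is not None for lb in labels):
            self.targets = np.array([class_to_index[lb] for lb in labels], np.int64)
        else:
            self.targets = None


# ---------------------------------------------------------------------------
# layers


class PointTransformerConv(Module):
    """Vector attention over graph neighbourhoods with a learned
    relative-position encoding added to both logits and values.

    The position MLP receives the relative vector together with its norm;
    the norm is rotation invariant, which speeds up learning of
    rotation-robust geometry at small sample sizes, while the raw relative
    vector keeps the layer's full positional expressiveness.
    """

    def __init__(self, d_in: int, d_out: int, rng: np.random.Generator):
        self.lin_q = Linear(d_in, d_out, rng)
        self.lin_k = Linear(d_in, d_out, rng)
        self.lin_v = Linear(d_in, d_out, rng)
        self.pos1 = Linear(3, d_out, rng)
        self.pos2 = Linear(d_out, d_out, rng)
        self.attn1 = Linear(d_out, d_out, rng)
        self.attn2 = Linear(d_out, d_out, rng)

    def __call__(self, x: Tensor, pos: np.ndarray, src, dst, n_nodes: int) -> Tensor:
        if x.data.shape[0] != n_nodes:
            raise ConfigError("feature/node count mismatch")
        src = src if isinstance(src, SegIdx) else SegIdx(np.asarray(src))
        dst = dst if isinstance(dst, SegIdx) else SegIdx(np.asarray(dst))
        rel_np = pos[src.idx] - pos[dst.idx]
        rel = np.column_stack([rel_np, np.linalg.norm(rel_np, axis=1)]).astype(np.float32)
        params = {
            "wq": self.lin_q.weight, "bq": self.lin_q.bias,
            "wk": self.lin_k.weight, "bk": self.lin_k.bias,
            "wv": self.lin_v.weight, "bv": self.lin_v.bias,
            "wp1": self.pos1.weight, "bp1": self.pos1.bias,
            "wp2": self.pos2.weight, "bp2": self.pos2.bias,
            "wa1": self.attn1.weight, "ba1": self.attn1.bias,
            "wa2": self.attn2.weight, "ba2": self.attn2.bias,
        }
        return eg.fused_point_attention(x, params, rel, src, dst, n_nodes)


class LocNet(Module):
    """Per-cluster point-set embedding network.

    Member localizations carry no input features; a constant scalar is lifted
    to the hidden width and geometry enters purely through the convolution's
    relative-position encodings (keeping the network translation invariant).
    Max pooling over members makes the embedding permutation invariant, and
    a final sigmoid squashes it into (0, 1).
    """

    def __init__(self, cfg: ModelConfig, rng: np.random.Generator):
        h = cfg.locnet_hidden
        self.lift = Linear(1, h, rng)
        self.convs = [PointTransformerConv(h, h, rng) for _ in range(cfg.locnet_blocks)]
        self.norms = [LayerNorm(h) for _ in range(cfg.locnet_blocks)]
        self.out = Linear(h, cfg.embed_dim, rng)

    def __call__(self, loc_pos: np.ndarray, loc_cluster: np.ndarray,
                 edge_src: np.ndarray, edge_dst: np.ndarray, n_clusters: int) -> Tensor:
        n = loc_pos.shape[0]
        x = eg.relu(self.lift(Tensor(np.ones((n, 1), np.float32))))
        for conv, norm in zip(self.convs, self.norms):
            x = eg.relu(norm(conv(x, loc_pos, edge_src, edge_dst, n))) + x
        pooled = eg.segment_max(x, loc_cluster, n_clusters)
        return eg.sigmoid(self.out(pooled))


class ClusterNet(Module):
    """The graph classifier (see module docstring)."""

    def __init__(self, cfg: ModelConfig):
        self.cfg = cfg
        rng = np.random.default_rng(cfg.seed)
        self.locnet = LocNet(cfg, rng) if cfg.mode == "LCF" else None
        self.in_proj = Linear(cfg.embed_dim, cfg.hidden_dim, rng)
        self.convs = [
            PointTransformerConv(cfg.hidden_dim, cfg.hidden_dim, rng)
            for _ in range(cfg.n_message_layers)
        ]
        self.norms = [LayerNorm(cfg.hidden_dim) for _ in range(cfg.n_message_layers)]
        self.head = Linear(cfg.hidden_dim, cfg.n_classes, rng)

    def forward_batch(self, batch: GraphBatch) -> tuple[Tensor, dict]:
        """Log-probabilities for every graph in the batch, plus the
        intermediate tensors (for loss, hooks and explanation)."""
        if self.cfg.mode == "LCF":
            h = self.locnet(batch.loc_pos, batch.loc_cluster,
                            batch.loc_edge_src, batch.loc_edge_dst, batch.n_clusters)
        else:
            if batch.cluster_features is None:
                raise PreconditionError("HCF forward without cluster features")
            h = Tensor(batch.cluster_features)
        x = eg.relu(self.in_proj(h))
        for conv, norm in zip(self.convs, self.norms):
            x = eg.relu(norm(conv(x, batch.cluster_pos, batch.edge_src,
                                  batch.edge_dst, batch.n_clusters))) + x
        pooled = eg.segment_max(x, batch.graph_ids_seg, batch.n_graphs)
        log_probs = eg.log_softmax(self.head(pooled))
        hooks = {"locnet": h if self.cfg.mode == "LCF" else None,
                 "post_mp": x, "pooled": pooled}
        return log_probs, hooks

    def predict(self, graphs: list[HierarchicalGraph]) -> ClassPrediction:
        """Inference-mode forward pass over a list of graphs."""
        batch = GraphBatch(graphs, self.cfg)
        log_probs, hooks = self.forward_batch(batch)
        lp = log_probs.data.astype(np.float64)
        return ClassPrediction(
            log_probs=lp,
            predicted_class=lp.argmax(axis=1),
            graph_feature=hooks["pooled"].data.copy(),
            cluster_features_post_mp=hooks["post_mp"].data.copy(),
            locnet_features=None if hooks["locnet"] is None else hooks["locnet"].data.copy(),
            graph_ids=batch.graph_ids.copy(),
        )

    def predict_proba(self, graph: HierarchicalGraph) -> np.ndarray:
        """Class probabilities for a single graph."""
        return np.exp(self.predict([graph]).log_probs[0])


CHECKPOINT_VERSION = 1


def save_model(model: ClusterNet, path, class_to_index: dict[str, int] | None = None):
    """Write parameters as an ``.npz`` archive with a JSON config sidecar."""
    import json
    from dataclasses import asdict
    from pathlib import Path

    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    arrays = {f"param_{i}": a for i, a in enumerate(model.state_arrays())}
    np.savez(path, **arrays)
    sidecar = {
        "checkpoint_version": CHECKPOINT_VERSION,
        "model_config": asdict(model.cfg),
        "class_to_index": class_to_index,
    }
    path.with_suffix(".json").write_text(json.dumps(sidecar, indent=2))
    return path


def load_model(path) -> tuple[ClusterNet, dict[str, int] | None]:
    """Load a checkpoint written by :func:`save_model`."""
    import json
    from pathlib import Path

    path = Path(path)
    sidecar = json.loads(path.with_suffix(".json").read_text())
    if sidecar.get("checkpoint_version") != CHECKPOINT_VERSION:
        raise ConfigError(f"unsupported checkpoint version in {path}")
    cfg = ModelConfig(**sidecar["model_config"])
    model = ClusterNet(cfg)
    with np.load(path) as npz:
        arrays = [npz[f"param_{i}"] for i in range(len(npz.files))]
    model.load_state_arrays(arrays)
    return model, sidecar.get("class_to_index")
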