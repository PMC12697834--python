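"""Explainability: layer-wise feature embedding and important-subgraph search.

Two complementary views of a trained classifier:

* UMAP embeddings of features at four levels — handcrafted cluster features,
  LocNet cluster embeddings, cluster features after the last message-passing
  layer, and pooled whole-graph features — show how class separation builds
  up as the receptive field grows from single clusters to the whole graph.

* SubgraphX searches for the connected subset of cluster nodes most
  responsible for a graph's classification, via Monte-Carlo tree search with
  a sampled-Shapley value function. Positive/negative fidelity quantify how
  necessary/sufficient the found subgraph is: with p = probability of the
  full graph's predicted class,

      Fid+ = p(full graph) - p(graph minus subgraph)     (necessity)
      Fid- = p(full graph) - p(subgraph alone)           (sufficiency)

  Best performance is Fid+ -> 1 and Fid- -> 0. Node removal deletes the node
  and its incident edges; the remaining nodes keep their original normalized
  positions (re-normalizing would confound occlusion with geometry change).
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass

import networkx as nx
import numpy as np

from .exceptions import PreconditionError
from .graphs import HierarchicalGraph


# ---------------------------------------------------------------------------
# feature extraction + UMAP

LEVELS = ("hcf", "locnet", "post_mp4", "whole_graph")


@dataclass
class EmbeddingSet:
    level: str
    raw: np.ndarray  # (n_rows, d), normalized
    parent_ids: list[str]  # source ROI per row
    gt: list[str | None]
    pred: np.ndarray  # predicted class index per row
    embedded: np.ndarray | None = None  # (n_rows, 2) after umap_embed


def _normalize(raw: np.ndarray, reference_rows: np.ndarray, mode: str) -> np.ndarray:
    """Center and scale each feature by statistics of the reference rows.

    ``mode="variance"`` divides by the per-feature variance (the literal
    convention this pipeline uses by default); ``mode="std"`` is ordinary
    z-scoring. Constant features are left centered.
    """
    ref = raw[reference_rows]
    mean = ref.mean(axis=0)
    var = ref.var(axis=0)
    scale = var if mode == "variance" else np.sqrt(var)
    scale = np.where(scale > 0, scale, 1.0)
    return (raw - mean) / scale


def extract_features(
    model,
    graphs: list[HierarchicalGraph],
    level: str,
    reference: np.ndarray | None = None,
    normalization: str = "variance",
) -> EmbeddingSet:
    """Raw feature rows at one level, normalized over a reference subset.

    ``reference`` is a boolean mask over ``graphs`` marking the rows whose
    statistics define the normalization (e.g. everything but a reserved test
    set); default: all graphs. Cluster-level rows inherit their graph's mask.
    """
    if level not in LEVELS:
        raise PreconditionError(f"level must be one of {LEVELS}")
    if level != "hcf" and model is None:
        raise PreconditionError(f"level {level!r} requires a trained model")
    if reference is None:
        reference = np.ones(len(graphs), bool)
    reference = np.asarray(reference, bool)

    if level == "hcf":
        rows, parent, gt, row_graph = [], [], [], []
        for gi, g in enumerate(graphs):
            if g.cluster_features is None:
                raise PreconditionError("hcf level needs cluster features")
            rows.append(g.cluster_features)
            parent += [g.source_id] * g.n_clusters
            gt += [g.label] * g.n_clusters
            row_graph += [gi] * g.n_clusters
        raw = np.vstack(rows)
        row_graph = np.array(row_graph)
        if model is not None:
            pred_graph = model.predict(graphs).predicted_class
        else:
            pred_graph = np.full(len(graphs), -1)
        pred = pred_graph[row_graph]
    else:
        prediction = model.predict(graphs)
        if level == "whole_graph":
            raw = prediction.graph_feature
            parent = [g.source_id for g in graphs]
            gt = [g.label for g in graphs]
            pred = prediction.predicted_class
            row_graph = np.arange(len(graphs))
        else:
            raw = (
                prediction.locnet_features
                if level == "locnet"
                else prediction.cluster_features_post_mp
            )
            if raw is None:
                raise PreconditionError("locnet level requires an LCF model")
            row_graph = prediction.graph_ids
            parent = [graphs[gi].source_id for gi in row_graph]
            gt = [graphs[gi].label for gi in row_graph]
            pred = prediction.predicted_class[row_graph]

    normalized = _normalize(np.asarray(raw, float), reference[row_graph], normalization)
    return EmbeddingSet(level=level, raw=normalized, parent_ids=parent, gt=gt, pred=pred)


def umap_embed(
    features: np.ndarray, n_neighbors: int = 20, min_dist: float = 0.5, seed: int = 0
) -> np.ndarray:
    """Seeded 2D UMAP of a feature matrix."""
    features = np.asarray(features, float)
    if features.shape[0] < n_neighbors + 1:
        raise PreconditionError(
            f"UMAP with {n_neighbors} neighbors needs >= {n_neighbors + 1} rows"
        )
    import umap  # deferred: heavy import

    reducer = umap.UMAP(
        n_components=2, n_neighbors=n_neighbors, min_dist=min_dist, random_state=seed
    )
    return np.asarray(reducer.fit_transform(features), float)


# ---------------------------------------------------------------------------
# occlusion and fidelity


def induce_subgraph(graph: HierarchicalGraph, nodes) -> HierarchicalGraph:
    """Cluster-node-induced subgraph: selected nodes keep their original
    positions and features; only edges with both ends selected survive;
    member localizations follow their cluster. Original node indices are
    kept on the result as ``node_ids``."""
    nodes = np.array(sorted(set(int(n) for n in nodes)), np.int64)
    if nodes.size == 0 or nodes.min() < 0 or nodes.max() >= graph.n_clusters:
        raise PreconditionError("subgraph nodes must be a non-empty subset of cluster nodes")
    remap = -np.ones(graph.n_clusters, np.int64)
    remap[nodes] = np.arange(nodes.size)
    e_mask = np.isin(graph.edges[0], nodes) & np.isin(graph.edges[1], nodes)
    edges = remap[graph.edges[:, e_mask]]
    l_mask = np.isin(graph.loc_cluster, nodes)
    # carry over any original ids from a previous induction
    parent_ids = graph.__dict__.get("node_ids")
    sub = HierarchicalGraph(
        loc_pos=graph.loc_pos[l_mask],
        loc_cluster=remap[graph.loc_cluster[l_mask]],
        cluster_pos=graph.cluster_pos[nodes],
        cluster_features=None if graph.cluster_features is None else graph.cluster_features[nodes],
        edges=edges,
        label=graph.label,
        source_id=graph.source_id,
    )
    sub.__dict__["node_ids"] = nodes if parent_ids is None else np.asarray(parent_ids)[nodes]
    return sub


def _proba_many(model, graphs: list, n_classes: int) -> np.ndarray:
    """Class probabilities for a list of graphs; ``None`` entries (empty
    occlusions) get the uninformative uniform distribution."""
    real = [g for g in graphs if g is not None]
    if real:
        if hasattr(model, "predict"):
            probs_real = np.exp(model.predict(real).log_probs)
        else:
            probs_real = np.array([model.predict_proba(g) for g in real])
    out = np.full((len(graphs), n_classes), 1.0 / n_classes)
    j = 0
    for i, g in enumerate(graphs):
        if g is not None:
            out[i] = probs_real[j]
            j += 1
    return out


@dataclass
class FidelityReport:
    fid_plus: float | None  # None when the complement is empty
    fid_minus: float | None  # None when the subgraph is empty
    subgraph_nodes: np.ndarray
    predicted_class: int
    p_full: float


def fidelity(model, graph: HierarchicalGraph, subgraph_nodes) -> FidelityReport:
    """Fid+/Fid- of a candidate subgraph, anchored on the model's predicted
    class for the full graph (not the ground truth)."""
    nodes = sorted(set(int(n) for n in subgraph_nodes))
    if any(n < 0 or n >= graph.n_clusters for n in nodes):
        raise PreconditionError("subgraph nodes outside the graph")
    p_all = model.predict_proba(graph)
    cls = int(np.argmax(p_all))
    p_full = float(p_all[cls])

    complement = sorted(set(range(graph.n_clusters)) - set(nodes))
    fid_plus = None
    if complement:
        fid_plus = p_full - float(model.predict_proba(induce_subgraph(graph, complement))[cls])
    fid_minus = None
    if nodes:
        fid_minus = p_full - float(model.predict_proba(induce_subgraph(graph, nodes))[cls])
    return FidelityReport(
        fid_plus=fid_plus,
        fid_minus=fid_minus,
        subgraph_nodes=np.array(nodes, np.int64),
        predicted_class=cls,
        p_full=p_full,
    )


# ---------------------------------------------------------------------------
# SubgraphX


@dataclass(frozen=True)
class ExplainConfig:
    max_subgraph_nodes: int = 8
    rollouts: int = 100
    shapley_samples: int = 100
    l_hop: int = 2  # coalition neighbourhood radius around the candidate
    exploration: float = 5.0  # UCT exploration constant
    seed: int = 0

    def __post_init__(self) -> None:
        if self.max_subgraph_nodes < 1 or self.rollouts < 1 or self.shapley_samples < 1:
            raise PreconditionError("invalid explanation configuration")


def _cluster_nx(graph: HierarchicalGraph) -> nx.Graph:
    g = nx.Graph()
    g.add_nodes_from(range(graph.n_clusters))
    src, dst = graph.edges
    g.add_edges_from((int(a), int(b)) for a, b in zip(src, dst) if a != b)
    return g


def _subset_seed(master: int, subset: frozenset) -> int:
    digest = hashlib.sha256((str(master) + str(sorted(subset))).encode()).digest()
    return int.from_bytes(digest[:4], "little")


class _ShapleyScorer:
    """Monte-Carlo Shapley-style contribution of a node subset to the
    predicted-class probability.

    Coalitions are sampled from the subset's L-hop neighbourhood; the score
    is the mean of p(S u C) - p(C) over sampled coalitions C. The estimate
    for a given subset is a deterministic function of (subset, seed), so
    repeated queries agree and scores are comparable across candidates.
    """

    def __init__(self, model, graph: HierarchicalGraph, nxg: nx.Graph,
                 target_class: int, cfg: ExplainConfig, n_classes: int):
        self.model = model
        self.graph = graph
        self.nxg = nxg
        self.cls = target_class
        self.cfg = cfg
        self.n_classes = n_classes
        self.cache: dict[frozenset, float] = {}

    def __call__(self, subset: frozenset) -> float:
        if subset in self.cache:
            return self.cache[subset]
        rng = np.random.default_rng(_subset_seed(self.cfg.seed, subset))
        hood = set(subset)
        for _ in range(self.cfg.l_hop):
            hood |= {nb for n in hood for nb in self.nxg.neighbors(n)}
        pool = sorted(hood - set(subset))
        with_s, without_s = [], []
        for _ in range(self.cfg.shapley_samples):
            coalition = [n for n in pool if rng.random() < 0.5]
            with_s.append(sorted(coalition) + sorted(subset))
            without_s.append(sorted(coalition))
        graphs = [induce_subgraph(self.graph, s) if s else None for s in with_s + without_s]
        probs = _proba_many(self.model, graphs, self.n_classes)[:, self.cls]
        k = len(with_s)
        score = float(np.mean(probs[:k] - probs[k:]))
        self.cache[subset] = score
        return score


@dataclass
class _TreeNode:
    subset: frozenset
    children: list | None = None
    visits: int = 0
    total_reward: float = 0.0


def _prunable_children(subset: frozenset, nxg: nx.Graph) -> list[frozenset]:
    """Subsets obtained by removing one node while staying connected."""
    children = []
    for v in sorted(subset):
        rest = subset - {v}
        if rest and nx.is_connected(nxg.subgraph(rest)):
            children.append(rest)
    return children


def subgraphx_search(
    model, graph: HierarchicalGraph, cfg: ExplainConfig = ExplainConfig()
) -> tuple[np.ndarray, FidelityReport]:
    """Find the most important connected subgraph of <= ``max_subgraph_nodes``
    cluster nodes via Monte-Carlo tree search.

    The tree's root is the full node set (per connected component; the best
    component's result is returned). Each action prunes one node while
    preserving connectivity; every visited subset small enough to be a
    candidate is scored with the sampled-Shapley value, and the best-scoring
    candidate found within ``rollouts`` rollouts wins. Deterministic given
    ``cfg.seed``.
    """
    if graph.n_clusters < 2:
        raise PreconditionError("need >= 2 cluster nodes to search")
    p_all = model.predict_proba(graph)
    target_class = int(np.argmax(p_all))
    n_classes = p_all.shape[0]
    nxg = _cluster_nx(graph)
    scorer = _ShapleyScorer(model, graph, nxg, target_class, cfg, n_classes)

    best_subset: frozenset | None = None
    best_score = -np.inf
    for component in nx.connected_components(nxg):
        root = _TreeNode(frozenset(component))
        nodes_index: dict[frozenset, _TreeNode] = {root.subset: root}

        def consider(subset: frozenset) -> None:
            nonlocal best_subset, best_score
            if len(subset) <= cfg.max_subgraph_nodes:
                score = scorer(subset)
                if score > best_score or (
                    score == best_score
                    and best_subset is not None
                    and sorted(subset) < sorted(best_subset)
                ):
                    best_subset, best_score = subset, score

        consider(root.subset)
        for _ in range(cfg.rollouts):
            path = [root]
            node = root
            while len(node.subset) > 1:
                if node.children is None:
                    node.children = [
                        nodes_index.setdefault(cs, _TreeNode(cs))
                        for cs in _prunable_children(node.subset, nxg)
                    ]
                if not node.children:
                    break
                unvisited = [c for c in node.children if c.visits == 0]
                if unvisited:
                    node = min(unvisited, key=lambda c: sorted(c.subset))
                else:
                    log_n = np.log(node.visits + 1)
                    node = max(
                        node.children,
                        key=lambda c: (
                            c.total_reward / c.visits
                            + cfg.exploration * np.sqrt(log_n / c.visits),
                            [-i for i in sorted(c.subset)],
                        ),
                    )
                path.append(node)
            # score every candidate-sized subset on the path; the rollout's
            # reward is the best score seen, steering the tree toward
            # regions holding good candidates
            reward = -np.inf
            for n in path:
                if len(n.subset) <= cfg.max_subgraph_nodes:
                    consider(n.subset)
                    reward = max(reward, scorer(n.subset))
            if not np.isfinite(reward):
                reward = 0.0
            for n in path:
                n.visits += 1
                n.total_reward += reward

    assert best_subset is not None
    nodes = np.array(sorted(best_subset), np.int64)
    return nodes, fidelity(model, graph, nodes)
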