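"""Shared fixtures: synthetic datasets and a small trained classifier."""

from __future__ import annotations

import numpy as np
import pytest

import clusternet as cn
from clusternet.features import features_for_clusters
from clusternet.graphs import HierarchicalGraph, _knn_edges, build_graph
from clusternet.models import ModelConfig
from clusternet.preprocess import ClusteringConfig, cluster
from clusternet.train import TrainConfig, train

FOUR_CLASSES = ["grid", "digit1", "digit3", "letterO"]


@pytest.fixture
def rng():
    return np.random.default_rng(42)


def make_graphs(n_per_class: int, seed: int, with_features: bool = True,
                classes=tuple(FOUR_CLASSES)):
    """Synthetic ROIs clustered with k-means (k=12) and turned into graphs."""
    library = cn.make_default_templates().subset(list(classes))
    tables = cn.sample_dataset(library, n_per_class, cn.SimulationParams(seed=seed))
    graphs = []
    for t in tables:
        cs = cluster(t, ClusteringConfig(seed=0))
        feats = features_for_clusters(cs) if with_features else None
        graphs.append(build_graph(cs, features=feats))
    return graphs


def random_cluster_graph(rng: np.random.Generator, n_clusters: int,
                         n_neighbors: int = 3) -> HierarchicalGraph:
    """Small random cluster-level graph (features in [0,1], positions in
    [-1,1]) for explainability tests; localization level left trivial."""
    pos = rng.uniform(-1, 1, size=(n_clusters, 2))
    feats = rng.uniform(0, 1, size=(n_clusters, 8))
    edges = _knn_edges(pos, n_neighbors)
    loc_pos = np.repeat(pos, 3, axis=0) + 0.01 * rng.standard_normal((3 * n_clusters, 2))
    loc_cluster = np.repeat(np.arange(n_clusters), 3)
    return HierarchicalGraph(
        loc_pos=loc_pos, loc_cluster=loc_cluster, cluster_pos=pos,
        cluster_features=feats, edges=edges, label="a", source_id=f"rand{n_clusters}",
    )


@pytest.fixture(scope="session")
def tiny_hcf_run():
    """A small but genuinely trained HCF classifier on 4-class data.

    Returns (model, class_to_index, train_graphs, test_graphs, result).
    """
    graphs = make_graphs(n_per_class=40, seed=11)
    labels = [g.label for g in graphs]
    folds = cn.make_splits(labels, cn.SplitPlan(), seed=1)
    fold = folds[0]
    tr = [graphs[i] for i in fold.train]
    va = [graphs[i] for i in fold.val]
    te = [graphs[i] for i in fold.test]
    from clusternet.train import prepare_hcf_graphs

    prepare_hcf_graphs(tr, va, te)
    cfg = ModelConfig(n_classes=4, mode="HCF", hidden_dim=32, seed=0)
    result = train(cfg, tr, va, TrainConfig(epochs=40, batch_size=16, seed=0))
    return result.model, result.class_to_index, tr, te, result
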