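"""Fidelity identities, SubgraphX search against brute force, UMAP."""

import itertools

import networkx as nx
import numpy as np
import pytest

from clusternet.exceptions import PreconditionError
from clusternet.explain import (ExplainConfig, _ShapleyScorer, _cluster_nx,
                                extract_features, fidelity, induce_subgraph,
                                subgraphx_search, umap_embed)
from conftest import random_cluster_graph


class ConstantModel:
    def __init__(self, probs=(0.25, 0.75)):
        self.probs = np.asarray(probs, float)

    def predict_proba(self, graph):
        return self.probs


class DecisiveNodeModel:
    """Output depends only on whether original node 3 (with a high first
    feature) is present — a rule-based oracle for the search."""

    def __init__(self, node=3, threshold=0.5):
        self.node, self.threshold = node, threshold

    def predict_proba(self, graph):
        ids = graph.__dict__.get("node_ids", np.arange(graph.n_clusters))
        present = self.node in set(int(i) for i in ids)
        if present:
            pos = list(int(i) for i in ids).index(self.node)
            present = graph.cluster_features[pos, 0] > self.threshold
        return np.array([0.1, 0.9]) if present else np.array([0.9, 0.1])


def _decisive_graph(rng, n):
    g = random_cluster_graph(rng, n)
    g.cluster_features[3, 0] = 0.95  # make node 3 decisive
    return g


class TestInduceSubgraph:
    def test_keeps_positions_features_and_induced_edges(self):
        g = random_cluster_graph(np.random.default_rng(0), 7)
        sub = induce_subgraph(g, [1, 3, 5])
        np.testing.assert_array_equal(sub.cluster_pos, g.cluster_pos[[1, 3, 5]])
        np.testing.assert_array_equal(sub.cluster_features,
                                      g.cluster_features[[1, 3, 5]])
        np.testing.assert_array_equal(sub.__dict__["node_ids"], [1, 3, 5])
        # every surviving edge existed with both ends selected
        orig = {tuple(e) for e in g.edges.T}
        remap = {0: 1, 1: 3, 2: 5}
        for a, b in sub.edges.T:
            assert (remap[int(a)], remap[int(b)]) in orig
        # member localizations follow their cluster
        assert set(np.unique(sub.loc_cluster)) <= {0, 1, 2}

    def test_invalid_nodes_rejected(self):
        g = random_cluster_graph(np.random.default_rng(1), 4)
        with pytest.raises(PreconditionError):
            induce_subgraph(g, [9])
        with pytest.raises(PreconditionError):
            induce_subgraph(g, [])


class TestFidelity:
    def test_full_graph_subgraph_gives_exactly_zero_fid_minus(self, tiny_hcf_run):
        model, _, _, test_graphs, _ = tiny_hcf_run
        g = test_graphs[0]
        report = fidelity(model, g, list(range(g.n_clusters)))
        assert report.fid_minus == 0.0
        assert report.fid_plus is None  # empty complement: undefined

    def test_constant_model_has_zero_fidelities(self):
        g = random_cluster_graph(np.random.default_rng(2), 8)
        report = fidelity(ConstantModel(), g, [0, 1, 2])
        assert report.fid_plus == 0.0
        assert report.fid_minus == 0.0

    def test_anchored_on_predicted_class(self):
        g = _decisive_graph(np.random.default_rng(3), 8)
        model = DecisiveNodeModel()
        report = fidelity(model, g, [3])
        assert report.predicted_class == 1
        # removing node 3 flips the prediction: necessity 0.9 - 0.1
        assert report.fid_plus == pytest.approx(0.8)
        # the subgraph alone suffices: Fid- = 0
        assert report.fid_minus == pytest.approx(0.0)


def _enumerate_connected_subsets(nxg, max_nodes):
    nodes = sorted(nxg.nodes)
    for r in range(1, max_nodes + 1):
        for combo in itertools.combinations(nodes, r):
            sg = nxg.subgraph(combo)
            if nx.is_connected(sg):
                yield frozenset(combo)


class TestSubgraphX:
    CFG = ExplainConfig(max_subgraph_nodes=4, rollouts=60, shapley_samples=20,
                        seed=0)

    def test_finds_decisive_node(self):
        rng = np.random.default_rng(4)
        for trial in range(10):
            g = _decisive_graph(rng, int(rng.integers(6, 10)))
            nodes, report = subgraphx_search(DecisiveNodeModel(), g, self.CFG)
            assert 3 in nodes.tolist()
            assert report.fid_minus == pytest.approx(0.0, abs=1e-12)

    def test_matches_exhaustive_enumeration(self):
        rng = np.random.default_rng(5)
        hits = 0
        trials = 10
        for _ in range(trials):
            g = _decisive_graph(rng, 8)
            model = DecisiveNodeModel()
            nodes, _ = subgraphx_search(model, g, self.CFG)
            nxg = _cluster_nx(g)
            p = model.predict_proba(g)
            scorer = _ShapleyScorer(model, g, nxg, int(np.argmax(p)), self.CFG,
                                    len(p))
            best = max(scorer(s) for s in
                       _enumerate_connected_subsets(nxg, self.CFG.max_subgraph_nodes))
            if scorer(frozenset(int(i) for i in nodes)) == pytest.approx(best):
                hits += 1
        assert hits >= 0.9 * trials

    def test_seed_determinism(self):
        g = _decisive_graph(np.random.default_rng(6), 9)
        n1, _ = subgraphx_search(DecisiveNodeModel(), g, self.CFG)
        n2, _ = subgraphx_search(DecisiveNodeModel(), g, self.CFG)
        np.testing.assert_array_equal(n1, n2)

    def test_returned_subgraph_beats_random_subsets(self):
        # monotone sanity: Fid- of the found subgraph below that of random
        # same-size subgraphs on average
        rng = np.random.default_rng(7)
        found, rand = [], []
        for _ in range(20):
            g = _decisive_graph(rng, 8)
            model = DecisiveNodeModel()
            nodes, report = subgraphx_search(model, g, self.CFG)
            found.append(report.fid_minus)
            pick = rng.choice(8, size=len(nodes), replace=False)
            rand.append(fidelity(model, g, pick.tolist()).fid_minus)
        assert np.mean(found) < np.mean(rand)


class TestExtractFeatures:
    def test_hcf_level_shape_and_centering(self, tiny_hcf_run):
        model, _, train_graphs, test_graphs, _ = tiny_hcf_run
        graphs = train_graphs + test_graphs
        reference = np.array([True] * len(train_graphs) + [False] * len(test_graphs))
        emb = extract_features(model, graphs, "hcf", reference=reference)
        n_rows = sum(g.n_clusters for g in graphs)
        assert emb.raw.shape == (n_rows, 8)
        ref_rows = emb.raw[np.concatenate(
            [np.full(g.n_clusters, reference[i]) for i, g in enumerate(graphs)])]
        np.testing.assert_allclose(ref_rows.mean(axis=0), 0.0, atol=1e-9)

    def test_whole_graph_level_one_row_per_graph(self, tiny_hcf_run):
        model, _, _, test_graphs, _ = tiny_hcf_run
        emb = extract_features(model, test_graphs, "whole_graph")
        assert emb.raw.shape[0] == len(test_graphs)
        assert len(emb.parent_ids) == len(test_graphs)

    def test_model_required_for_deep_levels(self, tiny_hcf_run):
        _, _, _, test_graphs, _ = tiny_hcf_run
        with pytest.raises(PreconditionError):
            extract_features(None, test_graphs, "post_mp4")


class TestUmap:
    def test_embeds_to_2d_deterministically(self):
        rng = np.random.default_rng(8)
        feats = rng.standard_normal((60, 8))
        a = umap_embed(feats, n_neighbors=10, seed=1)
        b = umap_embed(feats, n_neighbors=10, seed=1)
        assert a.shape == (60, 2)
        np.testing.assert_allclose(a, b)

    def test_separated_blobs_stay_separated(self):
        rng = np.random.default_rng(9)
        blob1 = rng.standard_normal((50, 6))
        blob2 = rng.standard_normal((50, 6)) + 30.0
        coords = umap_embed(np.vstack([blob1, blob2]), n_neighbors=10, seed=0)
        c1, c2 = coords[:50].mean(axis=0), coords[50:].mean(axis=0)
        gap = np.linalg.norm(c1 - c2)
        r1 = np.percentile(np.linalg.norm(coords[:50] - c1, axis=1), 95)
        r2 = np.percentile(np.linalg.norm(coords[50:] - c2, axis=1), 95)
        assert gap > max(r1, r2)

    def test_too_few_rows_rejected(self):
        with pytest.raises(PreconditionError):
            umap_embed(np.zeros((5, 3)), n_neighbors=20)
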