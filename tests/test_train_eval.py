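"""Splits, sampling, augmentation, the training loop and metrics."""

import numpy as np
import pytest

from clusternet.exceptions import PreconditionError
from clusternet.models import ClassPrediction
from clusternet.train import (SplitPlan, augment_rotation, evaluate,
                              make_splits, sampler_weights)
from conftest import random_cluster_graph


class TestSplits:
    def test_stratified_fold_sizes(self):
        labels = np.repeat(["a", "b", "c", "d"], 25)
        folds = make_splits(labels, SplitPlan(), seed=0)
        assert len(folds) == 5
        for fold in folds:
            test_labels = labels[fold.test]
            for cls in "abcd":
                assert np.sum(test_labels == cls) == 5  # 20% of 25
            # 64 / 16 / 20 partition, disjoint
            assert len(fold.train) == 64 and len(fold.val) == 16
            all_idx = np.concatenate([fold.train, fold.val, fold.test])
            assert len(np.unique(all_idx)) == 100

    def test_test_folds_disjoint(self):
        labels = np.repeat(["a", "b"], 30)
        folds = make_splits(labels, SplitPlan(), seed=1)
        seen = set()
        for fold in folds:
            assert not seen & set(fold.test.tolist())
            seen |= set(fold.test.tolist())
        assert seen == set(range(60))

    def test_seed_determinism(self):
        labels = np.repeat(["a", "b", "c"], 20)
        f1 = make_splits(labels, SplitPlan(), seed=7)
        f2 = make_splits(labels, SplitPlan(), seed=7)
        for a, b in zip(f1, f2):
            np.testing.assert_array_equal(a.train, b.train)
            np.testing.assert_array_equal(a.test, b.test)

    def test_grouped_mode_keeps_patients_whole(self):
        rng = np.random.default_rng(0)
        groups = np.repeat(np.arange(12), rng.integers(2, 8, 12))
        labels = np.where(rng.random(len(groups)) < 0.3, "resp", "no_resp")
        folds = make_splits(labels, SplitPlan(mode="grouped_cv"), seed=0,
                            groups=groups)
        for g in np.unique(groups):
            member_folds = {
                f for f, fold in enumerate(folds)
                if set(np.flatnonzero(groups == g)) & set(fold.test.tolist())
            }
            assert len(member_folds) == 1
        # validation also keeps groups whole
        fold = folds[0]
        val_groups = set(groups[fold.val].tolist())
        train_groups = set(groups[fold.train].tolist())
        assert not val_groups & train_groups

    def test_fewer_groups_than_folds_rejected(self):
        with pytest.raises(PreconditionError):
            make_splits(["a", "b", "a"], SplitPlan(mode="grouped_cv"),
                        seed=0, groups=[1, 1, 2])


class TestSamplerWeights:
    def test_inverse_class_frequency(self):
        labels = ["A"] * 100 + ["B"] * 300
        w = sampler_weights(labels)
        assert w[0] == pytest.approx(3 * w[100])

    def test_balanced_classes_uniform(self):
        w = sampler_weights(["A"] * 50 + ["B"] * 50)
        assert np.allclose(w, w[0])

    def test_expected_draws_equalized(self):
        labels = np.array(["A"] * 100 + ["B"] * 300)
        w = sampler_weights(labels)
        rng = np.random.default_rng(0)
        draws = rng.choice(labels, size=10_000, replace=True, p=w / w.sum())
        n_a = np.sum(draws == "A")
        se = np.sqrt(10_000 * 0.5 * 0.5)
        assert abs(n_a - 5000) < 3 * se


class TestAugmentation:
    def test_rotation_is_isometry_on_both_levels(self):
        g = random_cluster_graph(np.random.default_rng(0), 8)
        out = augment_rotation(g, seed=3)

        def pdist(p):
            return np.linalg.norm(p[:, None] - p[None], axis=2)

        np.testing.assert_allclose(pdist(out.cluster_pos), pdist(g.cluster_pos),
                                   atol=1e-9)
        np.testing.assert_allclose(pdist(out.loc_pos), pdist(g.loc_pos), atol=1e-9)

    def test_features_and_topology_untouched(self):
        g = random_cluster_graph(np.random.default_rng(1), 6)
        out = augment_rotation(g, seed=5)
        np.testing.assert_array_equal(out.cluster_features, g.cluster_features)
        np.testing.assert_array_equal(out.edges, g.edges)
        np.testing.assert_array_equal(out.loc_cluster, g.loc_cluster)


class _FakeModel:
    """Fixed predictions, for testing the metric arithmetic in isolation."""

    def __init__(self, log_probs):
        self._lp = np.asarray(log_probs, float)

    def predict(self, graphs):
        lp = self._lp[: len(graphs)]
        return ClassPrediction(
            log_probs=lp, predicted_class=lp.argmax(axis=1),
            graph_feature=np.zeros((len(graphs), 1)),
            cluster_features_post_mp=np.zeros((1, 1)),
            locnet_features=None, graph_ids=np.zeros(1, int),
        )


def _graphs_with_labels(labels):
    rng = np.random.default_rng(0)
    out = []
    for lb in labels:
        g = random_cluster_graph(rng, 4)
        g.label = lb
        out.append(g)
    return out


class TestEvaluate:
    def test_balanced_accuracy_is_mean_recall(self):
        # class a: 2/2 correct; class b: 1/2 correct -> balanced acc 0.75
        graphs = _graphs_with_labels(["a", "a", "b", "b"])
        logp = np.log(np.array([[0.9, 0.1], [0.8, 0.2], [0.3, 0.7], [0.6, 0.4]]))
        report = evaluate(_FakeModel(logp), graphs, {"a": 0, "b": 1})
        assert report.recalls["a"] == 1.0
        assert report.recalls["b"] == 0.5
        assert report.balanced_accuracy == pytest.approx(0.75)
        np.testing.assert_array_equal(report.confusion, [[2, 0], [1, 1]])

    def test_perfect_separation_gives_auroc_one(self):
        graphs = _graphs_with_labels(["a", "a", "b", "b"])
        logp = np.log(np.array([[0.9, 0.1], [0.8, 0.2], [0.2, 0.8], [0.1, 0.9]]))
        report = evaluate(_FakeModel(logp), graphs, {"a": 0, "b": 1})
        assert report.auroc["a"] == 1.0 and report.auroc["b"] == 1.0

    def test_constant_scores_give_auroc_half(self):
        graphs = _graphs_with_labels(["a", "a", "b", "b"])
        logp = np.log(np.full((4, 2), 0.5))
        report = evaluate(_FakeModel(logp), graphs, {"a": 0, "b": 1})
        assert report.auroc["a"] == pytest.approx(0.5)

    def test_absent_class_recall_is_nan_with_warning(self):
        graphs = _graphs_with_labels(["a", "a"])
        logp = np.log(np.array([[0.9, 0.1], [0.8, 0.2]]))
        with pytest.warns(UserWarning):
            report = evaluate(_FakeModel(logp), graphs, {"a": 0, "b": 1})
        assert np.isnan(report.recalls["b"])
        assert report.balanced_accuracy == 1.0


class TestTrainingLoop:
    def test_checkpoint_has_minimum_validation_loss(self, tiny_hcf_run):
        _, _, _, _, result = tiny_hcf_run
        val_losses = [e["val_loss"] for e in result.log]
        assert result.best_val_loss == pytest.approx(min(val_losses))
        assert result.log[result.best_epoch]["val_loss"] == pytest.approx(
            result.best_val_loss)

    def test_small_model_learns_something(self, tiny_hcf_run):
        model, c2i, _, test_graphs, _ = tiny_hcf_run
        report = evaluate(model, test_graphs, c2i)
        assert report.balanced_accuracy > 0.5  # well above 4-class chance

    def test_rotation_robustness_is_learned(self, tiny_hcf_run):
        # the architecture is not rotation invariant; augmentation during
        # training should make accuracy on rotated test graphs track the
        # unrotated accuracy closely
        from clusternet.train import augment_rotation

        model, c2i, _, test_graphs, _ = tiny_hcf_run
        acc = evaluate(model, test_graphs, c2i).balanced_accuracy
        rng = np.random.default_rng(99)
        rotated = [augment_rotation(g, rng) for g in test_graphs]
        acc_rot = evaluate(model, rotated, c2i).balanced_accuracy
        assert abs(acc - acc_rot) <= 0.05

    def test_scaler_fitted_on_training_data_only(self, tiny_hcf_run):
        # provenance tag on the fitted object guards against leakage
        from clusternet.graphs import fit_scaler, stack_features

        _, _, train_graphs, _, _ = tiny_hcf_run
        scaler = fit_scaler(stack_features(train_graphs))
        assert scaler.fitted_on == "train"
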