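"""Data partitions, class-balanced sampling, augmentation, training loop and
evaluation metrics.

Training follows the standard recipe for this model family: Adam (lr 1e-3,
weight decay 1e-4), negative log-likelihood on log-softmax outputs, a
weighted random sampler equalizing expected class frequencies, random
in-plane rotations as augmentation, and selection of the checkpoint with the
lowest validation loss over all epochs (no early stopping). Evaluation never
applies augmentation.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
from sklearn.metrics import confusion_matrix as sk_confusion
from sklearn.metrics import roc_auc_score

from .engine import Adam, nll_loss
from .exceptions import PreconditionError
from .graphs import HierarchicalGraph, fit_scaler, rescale_graph_features, stack_features
from .models import ClusterNet, GraphBatch, ModelConfig

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# partitions


@dataclass(frozen=True)
class SplitPlan:
    """Cross-validation layout.

    ``stratified_cv``: 5 folds; each fold's test set is a disjoint 20% with
    per-class proportions matching the whole; the remaining 80% is split
    64%/16% (of the whole) into train/validation, again stratified.
    ``grouped_cv``: groups (e.g. patients) are never split across folds, and
    folds approximate the global class ratio as closely as the groups allow.
    """

    mode: str = "stratified_cv"
    n_folds: int = 5
    val_fraction: float = 0.2  # of the non-test portion

    def __post_init__(self) -> None:
        if self.mode not in ("stratified_cv", "grouped_cv"):
            raise PreconditionError(f"unknown split mode {self.mode!r}")
        if self.n_folds < 2:
            raise PreconditionError("need >= 2 folds")


@dataclass(frozen=True)
class Fold:
    train: np.ndarray
    val: np.ndarray
    test: np.ndarray


def _stratified_folds(labels: np.ndarray, n_folds: int, rng: np.random.Generator) -> list[np.ndarray]:
    """Disjoint test folds with per-class proportions preserved."""
    folds: list[list[int]] = [[] for _ in range(n_folds)]
    for cls in np.unique(labels):
        idx = np.flatnonzero(labels == cls)
        rng.shuffle(idx)
        for f, chunk in enumerate(np.array_split(idx, n_folds)):
            folds[f].extend(chunk.tolist())
    return [np.sort(np.array(f, np.int64)) for f in folds]


def _greedy_group_folds(labels, groups, n_folds, rng):
    """Assign whole groups to folds, greedily balancing size and class ratio."""
    uniq_groups = np.unique(groups)
    if len(uniq_groups) < n_folds:
        raise PreconditionError("fewer groups than folds")
    classes = np.unique(labels)
    overall = np.array([(labels == c).mean() for c in classes])
    # largest groups first: easier to balance the remainder
    sizes = {g: int(np.sum(groups == g)) for g in uniq_groups}
    order = sorted(uniq_groups, key=lambda g: (-sizes[g], str(g)))
    fold_members: list[list[int]] = [[] for _ in range(n_folds)]
    fold_counts = np.zeros((n_folds, len(classes)))
    target = len(labels) / n_folds
    for g in order:
        g_idx = np.flatnonzero(groups == g)
        g_counts = np.array([(labels[g_idx] == c).sum() for c in classes])
        best, best_cost = 0, np.inf
        for f in range(n_folds):
            new = fold_counts[f] + g_counts
            n_new = new.sum()
            ratio = new / n_new
            cost = np.abs(ratio - overall).sum() + abs(n_new - target) / target
            if cost < best_cost:
                best, best_cost = f, cost
        fold_members[best].extend(g_idx.tolist())
        fold_counts[best] += g_counts
    return [np.sort(np.array(f, np.int64)) for f in fold_members]


def make_splits(
    labels: list | np.ndarray,
    plan: SplitPlan = SplitPlan(),
    seed: int = 0,
    groups: list | np.ndarray | None = None,
) -> list[Fold]:
    """Deterministic cross-validation folds (see :class:`SplitPlan`)."""
    labels = np.asarray(labels)
    rng = np.random.default_rng(seed)
    if plan.mode == "grouped_cv":
        if groups is None:
            raise PreconditionError("grouped_cv needs a group key per item")
        groups = np.asarray(groups)
        test_folds = _greedy_group_folds(labels, groups, plan.n_folds, rng)
    else:
        test_folds = _stratified_folds(labels, plan.n_folds, rng)

    folds = []
    for f in range(plan.n_folds):
        test = test_folds[f]
        rest = np.sort(np.concatenate([test_folds[i] for i in range(plan.n_folds) if i != f]))
        if plan.mode == "grouped_cv":
            # validation keeps whole groups together and chases the class ratio
            sub = _greedy_group_folds(
                labels[rest], groups[rest], max(2, round(1 / plan.val_fraction)), rng
            )
            val = rest[sub[0]]
        else:
            val_parts = []
            for cls in np.unique(labels):
                idx = rest[labels[rest] == cls]
                shuffled = idx.copy()
                rng.shuffle(shuffled)
                n_val = int(round(plan.val_fraction * len(idx)))
                val_parts.append(shuffled[:n_val])
            val = np.sort(np.concatenate(val_parts))
        train = np.setdiff1d(rest, val)
        folds.append(Fold(train=train, val=val, test=test))
    return folds


def sampler_weights(labels: list | np.ndarray) -> np.ndarray:
    """Inverse-class-frequency weight per item: under sampling with
    replacement the expected class frequencies are equal."""
    labels = np.asarray(labels)
    classes, counts = np.unique(labels, return_counts=True)
    if len(classes) < 2:
        raise PreconditionError("need >= 2 classes for weighted sampling")
    freq = dict(zip(classes.tolist(), counts.tolist()))
    return np.array([1.0 / freq[lb] for lb in labels.tolist()])


def augment_rotation(graph: HierarchicalGraph, seed: int | np.random.Generator) -> HierarchicalGraph:
    """Rotate all node positions by one uniform angle about the origin of the
    normalized frame; features and topology untouched."""
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    theta = rng.uniform(0.0, 2.0 * np.pi)
    c, s = np.cos(theta), np.sin(theta)
    rot = np.array([[c, -s], [s, c]])
    out = graph.copy()
    out.loc_pos = graph.loc_pos @ rot.T
    out.cluster_pos = graph.cluster_pos @ rot.T
    # member kNN structure is rotation invariant; share the cache
    if "_locknn_cache" in graph.__dict__:
        out.__dict__["_locknn_cache"] = graph.__dict__["_locknn_cache"]
    return out


# ---------------------------------------------------------------------------
# training


@dataclass(frozen=True)
class TrainConfig:
    epochs: int = 100
    lr: float = 1e-3
    weight_decay: float = 1e-4
    batch_size: int = 128  # 8 suits small (cell-scale) datasets
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.epochs, self.batch_size) < 1 or self.lr <= 0:
            raise PreconditionError("invalid training configuration")


@dataclass
class TrainResult:
    model: ClusterNet
    class_to_index: dict[str, int]
    log: list[dict] = field(default_factory=list)  # per-epoch train/val loss
    best_epoch: int = -1
    best_val_loss: float = np.inf


def _epoch_loss(model: ClusterNet, graphs, class_to_index, batch_size) -> float:
    """Mean NLL over a dataset, no augmentation, no gradient use."""
    total, n = 0.0, 0
    for start in range(0, len(graphs), batch_size):
        chunk = graphs[start:start + batch_size]
        batch = GraphBatch(chunk, model.cfg, class_to_index)
        log_probs, _ = model.forward_batch(batch)
        total += float(nll_loss(log_probs, batch.targets).data) * len(chunk)
        n += len(chunk)
    return total / n


def train(
    model_cfg: ModelConfig,
    train_graphs: list[HierarchicalGraph],
    val_graphs: list[HierarchicalGraph],
    cfg: TrainConfig = TrainConfig(),
    class_names: list[str] | None = None,
) -> TrainResult:
    """Train ClusterNet with weighted sampling and rotation augmentation,
    returning the checkpoint with minimum validation loss.

    Raises on NaN loss (divergence) with a diagnostic.
    """
    if not train_graphs or not val_graphs:
        raise PreconditionError("train and validation sets must be non-empty")
    if class_names is None:
        class_names = sorted({g.label for g in train_graphs + val_graphs})
    class_to_index = {c: i for i, c in enumerate(class_names)}

    model = ClusterNet(model_cfg)
    opt = Adam(model.parameters(), lr=cfg.lr, weight_decay=cfg.weight_decay)
    rng = np.random.default_rng(cfg.seed)
    labels = [g.label for g in train_graphs]
    weights = sampler_weights(labels)
    probs = weights / weights.sum()

    result = TrainResult(model=model, class_to_index=class_to_index)
    best_state = model.state_arrays()
    n_train = len(train_graphs)
    for epoch in range(cfg.epochs):
        order = rng.choice(n_train, size=n_train, replace=True, p=probs)
        epoch_train_loss, seen = 0.0, 0
        for start in range(0, n_train, cfg.batch_size):
            idx = order[start:start + cfg.batch_size]
            chunk = [augment_rotation(train_graphs[i], rng) for i in idx]
            batch = GraphBatch(chunk, model_cfg, class_to_index)
            log_probs, _ = model.forward_batch(batch)
            loss = nll_loss(log_probs, batch.targets)
            if not np.isfinite(loss.data):
                raise FloatingPointError(
                    f"training diverged (loss={float(loss.data)}) at epoch {epoch}"
                )
            model.zero_grad()
            loss.backward()
            opt.step()
            epoch_train_loss += float(loss.data) * len(idx)
            seen += len(idx)
        val_loss = _epoch_loss(model, val_graphs, class_to_index, cfg.batch_size)
        result.log.append(
            {"epoch": epoch, "train_loss": epoch_train_loss / seen, "val_loss": val_loss}
        )
        if val_loss < result.best_val_loss:
            result.best_val_loss = val_loss
            result.best_epoch = epoch
            best_state = model.state_arrays()
    model.load_state_arrays(best_state)
    return result


# ---------------------------------------------------------------------------
# evaluation


@dataclass
class MetricsReport:
    class_names: list[str]
    recalls: dict[str, float]  # NaN for a class absent from the test set
    balanced_accuracy: float
    auroc: dict[str, float]  # one-vs-rest per class
    macro_auroc: float
    confusion: np.ndarray  # rows: ground truth, cols: prediction


def evaluate(
    model: ClusterNet,
    test_graphs: list[HierarchicalGraph],
    class_to_index: dict[str, int],
) -> MetricsReport:
    """Recall per class, balanced accuracy (mean recall), one-vs-rest AUROC
    and the confusion matrix on a labeled test set; no augmentation."""
    if not test_graphs:
        raise PreconditionError("empty test set")
    class_names = sorted(class_to_index, key=class_to_index.get)
    y_true = np.array([class_to_index[g.label] for g in test_graphs])
    pred = model.predict(test_graphs)
    y_pred = pred.predicted_class
    probas = np.exp(pred.log_probs)

    recalls: dict[str, float] = {}
    for name in class_names:
        c = class_to_index[name]
        mask = y_true == c
        if not mask.any():
            warnings.warn(f"class {name!r} absent from test set; recall undefined")
            recalls[name] = float("nan")
        else:
            recalls[name] = float(np.mean(y_pred[mask] == c))
    present = [r for r in recalls.values() if np.isfinite(r)]
    balanced_accuracy = float(np.mean(present))

    auroc: dict[str, float] = {}
    for name in class_names:
        c = class_to_index[name]
        mask = y_true == c
        if mask.all() or not mask.any():
            auroc[name] = float("nan")
        else:
            auroc[name] = float(roc_auc_score(mask.astype(int), probas[:, c]))
    finite = [a for a in auroc.values() if np.isfinite(a)]
    macro_auroc = float(np.mean(finite)) if finite else float("nan")

    confusion = sk_confusion(y_true, y_pred, labels=list(range(len(class_names))))
    return MetricsReport(
        class_names=class_names,
        recalls=recalls,
        balanced_accuracy=balanced_accuracy,
        auroc=auroc,
        macro_auroc=macro_auroc,
        confusion=confusion,
    )


def prepare_hcf_graphs(train_graphs, *other_sets):
    """Fit the feature scaler on the training graphs only and apply it to all
    sets in place (leak-free normalization helper)."""
    scaler = fit_scaler(stack_features(train_graphs))
    rescale_graph_features(train_graphs, scaler)
    for graphs in other_sets:
        rescale_graph_features(list(graphs), scaler)
    return scaler
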