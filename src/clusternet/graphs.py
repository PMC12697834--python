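"""Hierarchical graph construction from clustered localizations.

Each ROI/cell becomes one graph with two node levels: localization nodes
(position only, no features, each belonging to exactly one cluster node) and
cluster nodes (position = centroid of members, optionally the 8 handcrafted
features). Undirected edges connect each cluster node to itself (self-loop)
and to its five nearest neighbouring cluster nodes.

Positions are normalized per graph to [-1, 1] preserving aspect ratio::

    x -> 2 (x - min x) / max(x_range, y_range) - 1   (same divisor for y)

Cluster features are min-max normalized to [0, 1] with statistics fitted on
the training set only; out-of-range values at test time are clamped.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .exceptions import DegenerateSampleError, PreconditionError
from .features import FEATURE_NAMES
from .preprocess import ClusterSet

logger = logging.getLogger(__name__)

N_NEIGHBORS_DEFAULT = 5


@dataclass
class HierarchicalGraph:
    """Localization + cluster nodes of one ROI, normalized coordinates.

    ``edges`` is a (2, E) int array over cluster-node indices, symmetric and
    including one self-loop per cluster node. ``loc_cluster`` maps each
    localization node to its parent cluster node index (membership is stored
    as a pooling index, not as explicit edges).
    """

    loc_pos: np.ndarray  # (N, 2) in [-1, 1]
    loc_cluster: np.ndarray  # (N,) int
    cluster_pos: np.ndarray  # (M, 2) in [-1, 1]
    cluster_features: np.ndarray | None  # (M, 8) in [0, 1] or None
    edges: np.ndarray  # (2, E) int, symmetric, self-loops included
    label: str | None = None
    source_id: str | None = None

    @property
    def n_clusters(self) -> int:
        return int(self.cluster_pos.shape[0])

    def copy(self) -> "HierarchicalGraph":
        return HierarchicalGraph(
            loc_pos=self.loc_pos.copy(),
            loc_cluster=self.loc_cluster.copy(),
            cluster_pos=self.cluster_pos.copy(),
            cluster_features=None if self.cluster_features is None else self.cluster_features.copy(),
            edges=self.edges.copy(),
            label=self.label,
            source_id=self.source_id,
        )


def normalize_positions(positions: np.ndarray) -> np.ndarray:
    """Map nm coordinates into [-1, 1] with a shared divisor for x and y,
    so the point pattern's aspect ratio is preserved."""
    positions = np.asarray(positions, float)
    if positions.ndim != 2 or positions.shape[1] != 2 or positions.shape[0] < 1:
        raise PreconditionError("positions must be a non-empty (n, 2) array")
    mins = positions.min(axis=0)
    ranges = positions.max(axis=0) - mins
    divisor = float(ranges.max())
    if divisor <= 0.0:
        raise DegenerateSampleError("all positions identical; cannot normalize")
    return 2.0 * (positions - mins) / divisor - 1.0


@dataclass(frozen=True)
class FeatureScaler:
    """Per-feature min/max measured over a training set of clusters.

    ``fitted_on`` records the provenance of the statistics so that leakage
    (fitting on validation/test data) is detectable downstream.
    """

    mins: np.ndarray
    maxs: np.ndarray
    fitted_on: str = "train"

    def __post_init__(self) -> None:
        if np.any(self.maxs < self.mins):
            raise PreconditionError("scaler max < min")


def fit_scaler(feature_matrix: np.ndarray, fitted_on: str = "train") -> FeatureScaler:
    """Fit min-max statistics on training clusters ((n, 8) array)."""
    feature_matrix = np.asarray(feature_matrix, float)
    if feature_matrix.ndim != 2 or feature_matrix.shape[0] < 1:
        raise PreconditionError("need a non-empty (n, n_features) matrix")
    return FeatureScaler(
        mins=feature_matrix.min(axis=0), maxs=feature_matrix.max(axis=0), fitted_on=fitted_on
    )


def apply_scaler(h: np.ndarray, scaler: FeatureScaler) -> np.ndarray:
    """h -> (h - min) / (max - min), clamped to [0, 1].

    Training values land in [0, 1] by construction; unseen test values can
    exceed the range, so the output is clamped to keep the model's input
    domain fixed. A constant feature (max == min) maps to 0 with a warning.
    """
    h = np.asarray(h, float)
    span = scaler.maxs - scaler.mins
    degenerate = span <= 0
    if np.any(degenerate):
        logger.warning("constant feature(s) %s map to 0", np.flatnonzero(degenerate).tolist())
    safe_span = np.where(degenerate, 1.0, span)
    scaled = (h - scaler.mins) / safe_span
    scaled = np.where(degenerate, 0.0, scaled)
    return np.clip(scaled, 0.0, 1.0)


def _knn_edges(positions: np.ndarray, k: int) -> np.ndarray:
    """Symmetrized kNN edges + self-loops over cluster positions.

    Neighbours are ranked by Euclidean distance with ties broken by lowest
    index; the undirected edge (i, j) exists when i lists j or j lists i.
    """
    m = positions.shape[0]
    pairs = {(i, i) for i in range(m)}  # self-loops
    if m > 1:
        d = np.linalg.norm(positions[:, None, :] - positions[None, :, :], axis=2)
        np.fill_diagonal(d, np.inf)
        k_eff = min(k, m - 1)
        # lexicographic (distance, index) ranking makes ties deterministic
        order = np.lexsort((np.tile(np.arange(m), (m, 1)), d), axis=1)
        for i in range(m):
            for j in order[i, :k_eff]:
                pairs.add((i, int(j)))
                pairs.add((int(j), i))
    edges = np.array(sorted(pairs), dtype=np.int64).T
    return edges.reshape(2, -1)


def build_graph(
    clusters: ClusterSet,
    features: dict | None = None,
    n_neighbors: int = N_NEIGHBORS_DEFAULT,
    scaler: FeatureScaler | None = None,
) -> HierarchicalGraph:
    """Assemble the hierarchical graph of one ROI/cell.

    Parameters
    ----------
    clusters : filtered cluster partition of the ROI.
    features : optional ``{cluster_id: ClusterFeatureVector}`` (handcrafted
        mode). When given and ``scaler`` is set, features are min-max
        normalized; otherwise they are attached raw (fit the scaler over the
        training set and re-apply via :func:`rescale_graph_features`).
    n_neighbors : cluster-node neighbours per node before symmetrization.
    """
    ids = clusters.surviving_ids
    if not ids:
        raise PreconditionError("empty ClusterSet")
    member_points = [clusters.points_of(cid) for cid in ids]
    loc_pos_nm = np.concatenate(member_points)
    loc_cluster = np.concatenate(
        [np.full(len(pts), i, dtype=np.int64) for i, pts in enumerate(member_points)]
    )
    cluster_pos_nm = np.array([pts.mean(axis=0) for pts in member_points])

    # one joint normalization over the parent graph (loc + cluster nodes);
    # centroids are convex combinations of members, so the extrema come from
    # the localization nodes either way
    all_norm = normalize_positions(np.vstack([loc_pos_nm, cluster_pos_nm]))
    loc_pos = all_norm[: len(loc_pos_nm)]
    cluster_pos = all_norm[len(loc_pos_nm):]

    feat_matrix = None
    if features is not None:
        feat_matrix = np.array([features[cid].as_array() for cid in ids], float)
        if feat_matrix.shape[1] != len(FEATURE_NAMES):
            raise PreconditionError("expected 8 features per cluster")
        if scaler is not None:
            feat_matrix = apply_scaler(feat_matrix, scaler)

    edges = _knn_edges(cluster_pos, n_neighbors)
    return HierarchicalGraph(
        loc_pos=loc_pos,
        loc_cluster=loc_cluster,
        cluster_pos=cluster_pos,
        cluster_features=feat_matrix,
        edges=edges,
        label=clusters.parent.gt_label,
        source_id=clusters.parent.source_id,
    )


def rescale_graph_features(graphs: list[HierarchicalGraph], scaler: FeatureScaler) -> None:
    """In-place min-max normalization of raw cluster features on each graph."""
    for g in graphs:
        if g.cluster_features is not None:
            g.cluster_features = apply_scaler(g.cluster_features, scaler)


def stack_features(graphs: list[HierarchicalGraph]) -> np.ndarray:
    """All cluster feature rows of a list of graphs, for scaler fitting."""
    mats = [g.cluster_features for g in graphs if g.cluster_features is not None]
    if not mats:
        raise PreconditionError("graphs carry no cluster features")
    return np.vstack(mats)
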