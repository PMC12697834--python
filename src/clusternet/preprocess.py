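"""Quality filtering, temporal grouping, cell assignment and clustering.

The dSTORM-style preprocessing chain runs quality filter -> temporal
grouping -> cell assignment -> cell filter -> clustering; DNA-origami-style
ROIs skip straight to clustering. All distance parameters are nm.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from shapely.geometry import LineString, Point, Polygon
from sklearn.cluster import DBSCAN, KMeans

from .exceptions import EmptyResultError, PreconditionError
from .io import LocalizationTable

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class QualityThresholds:
    """Per-localization quality cuts; the defaults follow common dSTORM QC:
    very bright detections (multi-emitter events), PSF widths far from the
    diffraction limit, poor PSF fits and imprecise localizations are removed.
    """

    max_photons: float = 30_000.0
    psf_sigma_min: float = 75.0  # nm
    psf_sigma_max: float = 200.0  # nm
    psf_pvalue_max: float = 0.01
    precision_max: float = 25.0  # nm

    def __post_init__(self) -> None:
        if self.psf_sigma_min >= self.psf_sigma_max:
            raise PreconditionError("psf_sigma_min must be < psf_sigma_max")
        if min(self.max_photons, self.psf_sigma_min, self.psf_pvalue_max, self.precision_max) <= 0:
            raise PreconditionError("all thresholds must be > 0")


@dataclass(frozen=True)
class GroupingParams:
    """Temporal grouping of blinking events: localizations within ``radius``
    and at most ``max_frame_gap`` frames apart are chained into one track;
    tracks spanning more than ``max_lifetime`` frames are discarded outright
    (long-lived emitters are likely artifacts)."""

    radius: float = 60.0  # nm
    max_frame_gap: int = 2
    max_lifetime: int = 5  # frames spanned, inclusive

    def __post_init__(self) -> None:
        if self.radius <= 0 or self.max_frame_gap <= 0 or self.max_lifetime <= 0:
            raise PreconditionError("grouping parameters must be > 0")


@dataclass(frozen=True)
class ClusteringConfig:
    method: str = "kmeans"  # {"kmeans", "dbscan"}
    k: int = 12
    eps: float = 50.0  # nm, dbscan
    min_pts: int = 3  # dbscan
    min_cluster_size: int = 3  # clusters with <=2 localizations are discarded
    seed: int = 0

    def __post_init__(self) -> None:
        if self.method not in ("kmeans", "dbscan"):
            raise PreconditionError(f"unknown clustering method {self.method!r}")
        if self.k < 1 or self.eps <= 0 or self.min_pts < 1:
            raise PreconditionError("invalid clustering parameters")
        if self.min_cluster_size < 3:
            # the convex hull and PCA both need >=3 points per cluster
            raise PreconditionError("min_cluster_size must be >= 3")


@dataclass
class ClusterSet:
    """Partition of a localization table into filtered clusters.

    ``assignment`` holds one cluster id per localization; ``-1`` marks DBSCAN
    noise; ids not in ``surviving_ids`` were removed by the small-cluster
    filter.
    """

    parent: LocalizationTable
    assignment: np.ndarray
    surviving_ids: list[int] = field(default_factory=list)

    def points_of(self, cluster_id: int) -> np.ndarray:
        return self.parent.xy[self.assignment == cluster_id]

    def sizes(self) -> dict[int, int]:
        return {cid: int(np.sum(self.assignment == cid)) for cid in self.surviving_ids}


_THRESHOLD_RULES = (
    # (column, predicate keeping a row)
    ("photons", lambda col, thr: col <= thr.max_photons),
    ("psf_sigma", lambda col, thr: (col >= thr.psf_sigma_min) & (col <= thr.psf_sigma_max)),
    ("psf_pvalue", lambda col, thr: col <= thr.psf_pvalue_max),
    ("precision", lambda col, thr: col <= thr.precision_max),
)


def filter_localizations(
    table: LocalizationTable, thr: QualityThresholds = QualityThresholds()
) -> LocalizationTable:
    """Apply the quality cuts; thresholds on absent columns are skipped with
    a warning. Raises :class:`EmptyResultError` if nothing survives."""
    keep = np.ones(len(table), bool)
    for column, rule in _THRESHOLD_RULES:
        if column in table.data.columns:
            keep &= rule(table.data[column].to_numpy(float), thr)
        else:
            logger.warning("quality column %r absent; threshold skipped", column)
    if not keep.any():
        raise EmptyResultError("quality filter removed every localization")
    return table.replace(table.data[keep])


def temporal_group(
    table: LocalizationTable, gp: GroupingParams = GroupingParams()
) -> LocalizationTable:
    """Merge blinking events into single localizations.

    Greedy transitive chaining in frame order: a track is extended by the
    nearest not-yet-assigned localization within ``radius`` of the track's
    last member and within ``max_frame_gap`` frames of it. A finished track
    spanning <= ``max_lifetime`` frames is replaced by one localization at the
    members' mean position carrying the first frame number; longer tracks are
    dropped entirely.
    """
    if "frame" not in table.data.columns:
        raise PreconditionError("temporal grouping needs a frame column")
    df = table.data.sort_values("frame", kind="stable").reset_index(drop=True)
    xy = df[["x", "y"]].to_numpy(float)
    frames = df["frame"].to_numpy(int)
    n = len(df)
    assigned = np.zeros(n, bool)
    out_rows = []
    for i in range(n):
        if assigned[i]:
            continue
        track = [i]
        assigned[i] = True
        last = i
        while True:
            cand = np.flatnonzero(
                (~assigned)
                & (frames > frames[last])
                & (frames <= frames[last] + gp.max_frame_gap)
            )
            if cand.size == 0:
                break
            dists = np.hypot(xy[cand, 0] - xy[last, 0], xy[cand, 1] - xy[last, 1])
            j = np.argmin(dists)
            if dists[j] > gp.radius:
                break
            last = int(cand[j])
            track.append(last)
            assigned[last] = True
        lifetime = frames[track[-1]] - frames[track[0]] + 1
        if lifetime > gp.max_lifetime:
            continue  # long-lived track removed entirely
        mean_pos = xy[track].mean(axis=0)
        row = df.iloc[track[0]].copy()
        row["x"], row["y"] = mean_pos
        row["frame"] = frames[track[0]]
        out_rows.append(row)
    if not out_rows:
        return table.replace(df.iloc[0:0])
    return table.replace(pd.DataFrame(out_rows))


def assign_cells(
    table: LocalizationTable,
    cell_regions: list[Polygon],
    membrane_regions: list[LineString] | None = None,
    membrane_width: float = 100.0,
) -> list[LocalizationTable]:
    """Split a FOV into per-cell tables using pre-made cell polygons (nm).

    Each retained localization is labeled ``membrane`` (within
    ``membrane_width``/2 of a membrane polyline) or ``interior`` in a new
    ``region`` column. Localizations outside every cell are dropped. Cells may
    come out empty; :func:`filter_cells` removes those later.
    """
    if not cell_regions:
        raise PreconditionError("no cell regions provided")
    membrane_regions = membrane_regions or []
    half_width = membrane_width / 2.0
    xy = table.xy
    out = []
    for ci, poly in enumerate(cell_regions):
        inside = np.array([poly.covers(Point(p)) for p in xy])
        df = table.data[inside].reset_index(drop=True)
        if len(df):
            pts = df[["x", "y"]].to_numpy(float)
            is_membrane = np.zeros(len(df), bool)
            for line in membrane_regions:
                d = np.array([line.distance(Point(p)) for p in pts])
                is_membrane |= d <= half_width
            df = df.assign(region=np.where(is_membrane, "membrane", "interior"))
        else:
            df = df.assign(region=pd.Series(dtype=str))
        cell = LocalizationTable(
            df,
            gt_label=table.gt_label,
            source_id=f"{table.source_id or 'fov'}_cell{ci:03d}",
            extra_metadata=dict(table.extra_metadata),
        )
        out.append(cell)
    return out


def cells_from_label_mask(mask: np.ndarray, nm_per_pixel: float) -> list[Polygon]:
    """Convert a label-mask image (0 = background, one integer label per
    cell) into cell polygons in nm, for :func:`assign_cells`."""
    from skimage import measure  # deferred: image stack only needed here

    if mask.ndim != 2:
        raise PreconditionError("label mask must be a 2D integer image")
    polygons = []
    for lab in np.unique(mask):
        if lab == 0:
            continue
        contours = measure.find_contours(mask == lab, 0.5)
        if not contours:
            continue
        longest = max(contours, key=len)
        # contours are (row, col); image rows map to y, cols to x
        poly = Polygon(np.column_stack([longest[:, 1], longest[:, 0]]) * nm_per_pixel)
        if not poly.is_valid:
            poly = poly.buffer(0)
        polygons.append(poly)
    return polygons


def filter_cells(cells: list[LocalizationTable]) -> list[LocalizationTable]:
    """Keep cells with >=500 localizations, >=5 membrane and >=5 interior."""
    survivors = []
    for cell in cells:
        if "region" not in cell.data.columns:
            raise PreconditionError("cells must carry membrane/interior labels")
        n = len(cell)
        n_mem = int((cell.data["region"] == "membrane").sum())
        n_int = int((cell.data["region"] == "interior").sum())
        if n >= 500 and n_mem >= 5 and n_int >= 5:
            survivors.append(cell)
    return survivors


def cluster(table: LocalizationTable, cfg: ClusteringConfig = ClusteringConfig()) -> ClusterSet:
    """Partition an ROI/cell into clusters and drop tiny ones.

    k-means (k-means++ init, 10 restarts, seeded) yields exactly ``k``
    clusters before filtering; DBSCAN yields density clusters with noise
    excluded. Clusters smaller than ``min_cluster_size`` (default: two or
    fewer localizations) are then discarded so that the convex hull and
    principal components exist downstream.
    """
    xy = table.xy
    # canonical row order makes the partition invariant to input row order
    # (k-means++ init draws depend on row order otherwise)
    order = np.lexsort((xy[:, 1], xy[:, 0]))
    inverse = np.argsort(order)
    xy_sorted = xy[order]
    if cfg.method == "kmeans":
        if len(xy) < cfg.k:
            raise PreconditionError(f"k-means needs >= k={cfg.k} localizations, got {len(xy)}")
        km = KMeans(n_clusters=cfg.k, n_init=10, random_state=cfg.seed)
        labels = km.fit_predict(xy_sorted)[inverse]
    else:
        if len(xy) < 1:
            raise PreconditionError("empty table")
        labels = DBSCAN(eps=cfg.eps, min_samples=cfg.min_pts).fit_predict(xy_sorted)[inverse]
    surviving = [
        int(cid)
        for cid in np.unique(labels)
        if cid != -1 and np.sum(labels == cid) >= cfg.min_cluster_size
    ]
    if not surviving:
        raise EmptyResultError("no cluster survived the small-cluster filter")
    return ClusterSet(parent=table, assignment=labels, surviving_ids=surviving)
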