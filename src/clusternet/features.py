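"""Handcrafted per-cluster shape features.

Eight features summarize each cluster of localizations:

=========  ==========================================================
count      number of localizations
rg2        radius of gyration squared: mean squared distance of the
           localizations from their centroid (nm^2)
perimeter  perimeter of the convex hull (nm)
linearity  (l0 - l1) / l0, PCA eigenvalue ratio (dimensionless)
planarity  l1 / l0; in 2D the third eigenvalue l2 = 0, so
           linearity + planarity = 1 and one of the pair is redundant
           (kept anyway — nothing is lost by the redundancy)
length     2.35 * sqrt(l0): FWHM along the major axis, using the
           literal constant 2.35 (nm)
area       2.35^2 * sqrt(l0 * l1) (nm^2)
density    count / area (nm^-2)
=========  ==========================================================

l0 >= l1 are the eigenvalues of the sample covariance matrix of the cluster's
coordinates. The covariance uses the n-1 denominator by default (standard PCA
convention); pass ``ddof=0`` for the population variance instead.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial import ConvexHull, QhullError

from .exceptions import DegenerateSampleError, PreconditionError

FWHM_FACTOR = 2.35  # FWHM of a Gaussian ~ 2.35 sigma; used literally

FEATURE_NAMES = (
    "count",
    "rg2",
    "perimeter",
    "linearity",
    "planarity",
    "length",
    "area",
    "density",
)


@dataclass(frozen=True)
class PCAResult:
    """Variances along the principal components of a 2D cluster (nm^2).

    ``lambda2`` is identically 0 for 2D data and carried for the 3D
    extension path.
    """

    lambda0: float
    lambda1: float
    lambda2: float = 0.0


@dataclass(frozen=True)
class ClusterFeatureVector:
    count: int
    rg2: float
    perimeter: float
    linearity: float
    planarity: float
    length: float
    area: float
    density: float

    def as_array(self) -> np.ndarray:
        return np.array([getattr(self, name) for name in FEATURE_NAMES], float)


def pca_variances(points: np.ndarray, ddof: int = 1) -> PCAResult:
    """Eigenvalues of the coordinate covariance matrix, sorted descending."""
    points = np.asarray(points, float)
    if points.ndim != 2 or points.shape[1] != 2:
        raise PreconditionError("points must be an (n, 2) array")
    if points.shape[0] < 3:
        raise PreconditionError("PCA needs >=3 points")
    if np.allclose(points, points[0]):
        raise DegenerateSampleError("all points identical; PCA undefined")
    cov = np.cov(points.T, ddof=ddof)
    eigvals = np.linalg.eigvalsh(cov)[::-1]
    eigvals = np.clip(eigvals, 0.0, None)  # guard tiny negative fp residue
    return PCAResult(lambda0=float(eigvals[0]), lambda1=float(eigvals[1]))


def hull_perimeter(points: np.ndarray) -> float:
    """Convex-hull perimeter in nm (triangle perimeter for 3 points)."""
    points = np.asarray(points, float)
    try:
        hull = ConvexHull(points)
    except QhullError as exc:
        raise DegenerateSampleError(f"degenerate hull: {exc}") from exc
    # in 2D, Qhull's "volume" is the area and "area" is the perimeter
    return float(hull.area)


def compute_features(points: np.ndarray, ddof: int = 1) -> ClusterFeatureVector:
    """All eight features for one cluster of >=3 non-collinear points."""
    points = np.asarray(points, float)
    pca = pca_variances(points, ddof=ddof)
    if pca.lambda1 <= 0.0 or pca.lambda0 <= 0.0:
        # collinear clusters have zero area, so density is undefined;
        # upstream small-cluster filtering makes this rare in practice
        raise DegenerateSampleError("collinear cluster: zero area, density undefined")
    centroid = points.mean(axis=0)
    rg2 = float(np.mean(np.sum((points - centroid) ** 2, axis=1)))
    perimeter = hull_perimeter(points)
    linearity = (pca.lambda0 - pca.lambda1) / pca.lambda0
    planarity = pca.lambda1 / pca.lambda0
    length = FWHM_FACTOR * np.sqrt(pca.lambda0)
    area = FWHM_FACTOR**2 * np.sqrt(pca.lambda0 * pca.lambda1)
    count = points.shape[0]
    return ClusterFeatureVector(
        count=count,
        rg2=rg2,
        perimeter=perimeter,
        linearity=float(linearity),
        planarity=float(planarity),
        length=float(length),
        area=float(area),
        density=float(count / area),
    )


def features_for_clusters(cluster_set, ddof: int = 1) -> dict[int, ClusterFeatureVector]:
    """Feature vectors keyed by surviving cluster id of a ClusterSet."""
    return {
        cid: compute_features(cluster_set.points_of(cid), ddof=ddof)
        for cid in cluster_set.surviving_ids
    }
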