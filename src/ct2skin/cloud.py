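"""Point-cloud reconstruction from validated slice contours.

Validated contour points are projected into world millimetres using only the
volume geometry (per-axis spacing, origin, slice index) — no interpolation or
meshing, so every cloud point corresponds to a traced boundary position in an
original slice.  The axial cloud, which is the least artifact-prone view, then
supplies an axis-aligned bounding box used to clip the sagittal and coronal
clouds before the three are fused.  Fusion is geometric union followed by a
second voxel downsampling pass, and two outlier filters (radius-based density,
then statistical distance-to-neighbours) remove any residual stray points.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.spatial import cKDTree

from .contours import Contour
from .volume import PlanarSlice

__all__ = [
    "PointCloud",
    "BoundingBox3D",
    "OutlierParams",
    "contour_to_world",
    "axial_bounding_box",
    "clip_to_box",
    "voxel_downsample",
    "merge_triplanar",
    "remove_outliers",
]


@dataclass(frozen=True)
class PointCloud:
    """Unordered set of 3D world points in millimetres."""

    points: np.ndarray  # (N, 3) float64
    source_plane: str = "unknown"

    def __post_init__(self) -> None:
        pts = np.asarray(self.points, dtype=np.float64).reshape(-1, 3)
        if pts.size and not np.all(np.isfinite(pts)):
            raise ValueError("point cloud contains non-finite coordinates")
        object.__setattr__(self, "points", pts)

    def __len__(self) -> int:
        return len(self.points)

    def with_points(self, points: np.ndarray) -> "PointCloud":
        return PointCloud(points=points, source_plane=self.source_plane)


@dataclass(frozen=True)
class BoundingBox3D:
    min_xyz: tuple[float, float, float]
    max_xyz: tuple[float, float, float]

    def __post_init__(self) -> None:
        lo, hi = np.asarray(self.min_xyz, float), np.asarray(self.max_xyz, float)
        if np.any(lo > hi):
            raise ValueError(f"box min {self.min_xyz} exceeds max {self.max_xyz}")


@dataclass(frozen=True)
class OutlierParams:
    """Parameters of the two-stage outlier removal.

    ``radius_mm``/``min_neighbors`` drive the density pass (a point must have
    at least ``min_neighbors`` other points within ``radius_mm``);
    ``stat_k``/``stat_std_ratio`` drive the statistical pass (mean distance to
    the ``stat_k`` nearest neighbours must not exceed the global mean plus
    ``stat_std_ratio`` standard deviations).
    """

    radius_mm: float = 2.0
    min_neighbors: int = 4
    stat_k: int = 20
    stat_std_ratio: float = 2.0

    def __post_init__(self) -> None:
        if min(self.radius_mm, self.min_neighbors, self.stat_k, self.stat_std_ratio) <= 0:
            raise ValueError("all outlier parameters must be positive")


def contour_to_world(contour: Contour, sl: PlanarSlice) -> PointCloud:
    """Project a validated slice contour into world coordinates.

    Each (row, col) point maps through the slice's recorded axis permutation
    (including the z-flip that keeps sagittal/coronal images upright), per-axis
    spacing and origin; the slice index supplies the third coordinate.  The
    mapping is affine and exactly invertible, so clouds from all three
    orientations land in the same axial world frame by construction.
    """
    pts = contour.points
    xyz = sl.rowcol_to_world(pts[:, 0], pts[:, 1])
    return PointCloud(points=xyz, source_plane=sl.orientation)


def axial_bounding_box(axial_cloud: PointCloud) -> BoundingBox3D:
    """Componentwise min/max of the axial cloud — the acceptance gate for
    sagittal/coronal points."""
    if len(axial_cloud) == 0:
        raise ValueError("cannot compute a bounding box of an empty cloud")
    lo = axial_cloud.points.min(axis=0)
    hi = axial_cloud.points.max(axis=0)
    return BoundingBox3D(min_xyz=tuple(lo), max_xyz=tuple(hi))


def clip_to_box(cloud: PointCloud, box: BoundingBox3D) -> PointCloud:
    """Retain exactly the points inside the closed box (idempotent)."""
    if len(cloud) == 0:
        return cloud
    lo = np.asarray(box.min_xyz)
    hi = np.asarray(box.max_xyz)
    keep = np.all((cloud.points >= lo) & (cloud.points <= hi), axis=1)
    return cloud.with_points(cloud.points[keep])


def voxel_downsample(cloud: PointCloud, voxel_mm: float) -> PointCloud:
    """Replace each occupied voxel-grid cell with the centroid of its points.

    The grid has edge ``voxel_mm`` and is anchored at the cloud's componentwise
    minimum, making the result deterministic.  Points are grouped by
    ``floor((p - min) / voxel)``; the output is sorted by cell index and is
    independent of input point order (set semantics).
    """
    if voxel_mm <= 0:
        raise ValueError("voxel_mm must be > 0")
    pts = cloud.points
    if len(pts) == 0:
        return cloud
    # canonical ordering removes any dependence on input order, including in
    # floating-point summation
    order = np.lexsort((pts[:, 2], pts[:, 1], pts[:, 0]))
    pts = pts[order]
    anchor = pts.min(axis=0)
    cells = np.floor((pts - anchor) / voxel_mm).astype(np.int64)
    _, inverse, counts = np.unique(cells, axis=0, return_inverse=True, return_counts=True)
    sums = np.zeros((len(counts), 3), dtype=np.float64)
    np.add.at(sums, inverse, pts)
    centroids = sums / counts[:, None]
    return cloud.with_points(centroids)


def merge_triplanar(
    axial: PointCloud,
    sagittal: PointCloud,
    coronal: PointCloud,
    voxel_mm: float = 1.0,
) -> PointCloud:
    """Fuse the three uniplanar clouds by geometric addition (set union) and a
    second voxel-downsampling pass at ``voxel_mm``."""
    merged = np.vstack([axial.points, sagittal.points, coronal.points])
    return voxel_downsample(PointCloud(points=merged, source_plane="merged"), voxel_mm)


def remove_outliers(cloud: PointCloud, params: OutlierParams = OutlierParams()) -> PointCloud:
    """Two-stage outlier removal: density (radius) pass, then statistical pass.

    Pass 1 drops points with fewer than ``min_neighbors`` other points inside
    ``radius_mm``.  Pass 2 recomputes k-NN mean distances on the survivors and
    drops points beyond ``mean + stat_std_ratio * std``.  Clouds too small for
    the statistical pass (``<= stat_k`` points) are returned unchanged with a
    warning.
    """
    n = len(cloud)
    if n <= params.stat_k:
        warnings.warn(
            f"cloud of {n} points is too small for outlier removal (stat_k={params.stat_k}); "
            "returning it unchanged",
            stacklevel=2,
        )
        return cloud

    tree = cKDTree(cloud.points)
    counts = tree.query_ball_point(cloud.points, r=params.radius_mm, return_length=True)
    keep = counts - 1 >= params.min_neighbors  # exclude the point itself
    pts = cloud.points[keep]

    if len(pts) <= params.stat_k:
        return cloud.with_points(pts)
    tree = cKDTree(pts)
    dists, _ = tree.query(pts, k=params.stat_k + 1)
    mean_d = dists[:, 1:].mean(axis=1)  # column 0 is the point itself
    cutoff = mean_d.mean() + params.stat_std_ratio * mean_d.std()
    return cloud.with_points(pts[mean_d <= cutoff])
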