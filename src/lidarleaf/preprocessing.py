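"""Point-cloud cleanup and leaf segmentation.

The raw 360-degree cloud contains the room, the pot and the stem besides
the leaves.  The pipeline removes the background by bounding box, removes
sparse noise by voxel point-density thresholding, strips pot and stem by a
cylindrical/height filter, and finally segments the remaining points into
individual leaves with k-means (k supplied by the operator as the leaf
count).  Every step is a pure function of its inputs: no points are ever
created, and per-point labels (when present) travel with their points.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from sklearn.cluster import KMeans

from .scan_geometry import PointCloud, ValidationError

logger = logging.getLogger("lidarleaf")


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass
class VoxelGrid:
    """Points binned into cubic cells of side ``voxel_size`` mm.

    ``counts`` maps an integer (i, j, k) cell index to its point count,
    ``membership`` to the indices of the contained points in the source
    cloud.  A point p falls in cell floor((p - origin) / voxel_size).
    """

    origin: np.ndarray
    voxel_size: float
    counts: dict[tuple[int, int, int], int]
    membership: dict[tuple[int, int, int], np.ndarray]
    source: PointCloud

    def occupied(self) -> int:
        return len(self.counts)


@dataclass
class SegmentationResult:
    """Per-point leaf labels in {1..k}; ``removed`` lists discarded indices
    (filled by the pipeline driver, empty when segmenting directly)."""

    leaf_labels: np.ndarray
    k: int
    removed: np.ndarray = field(
        default_factory=lambda: np.empty(0, dtype=int))


# ---------------------------------------------------------------------------
# Operations
# ---------------------------------------------------------------------------

def remove_background(cloud: PointCloud, bounds) -> PointCloud:
    """Retain exactly the points inside the closed axis-aligned box.

    ``bounds`` is ((xmin, ymin, zmin), (xmax, ymax, zmax)) in mm.
    """
    lo = np.asarray(bounds[0], dtype=float)
    hi = np.asarray(bounds[1], dtype=float)
    if not np.all(lo < hi):
        raise ValidationError("box bounds must satisfy min < max per axis")
    inside = np.all((cloud.points >= lo) & (cloud.points <= hi), axis=1)
    if len(cloud) and not inside.any():
        logger.warning("background removal discarded every point")
    return cloud.select(inside)


def voxelize(cloud: PointCloud, voxel_size: float) -> VoxelGrid:
    """Bin the cloud into cubic voxels, origin at the floored min corner."""
    if not (voxel_size > 0):
        raise ValidationError("voxel_size must be positive")
    if len(cloud) == 0:
        return VoxelGrid(np.zeros(3), voxel_size, {}, {}, cloud)
    origin = np.floor(cloud.points.min(axis=0))
    idx = np.floor((cloud.points - origin) / voxel_size).astype(int)
    order = np.lexsort((idx[:, 2], idx[:, 1], idx[:, 0]))
    sorted_idx = idx[order]
    uniq, starts, counts = np.unique(sorted_idx, axis=0,
                                     return_index=True, return_counts=True)
    counts_map: dict[tuple[int, int, int], int] = {}
    members: dict[tuple[int, int, int], np.ndarray] = {}
    for cell, start, cnt in zip(uniq, starts, counts):
        key = tuple(int(c) for c in cell)
        counts_map[key] = int(cnt)
        members[key] = np.sort(order[start:start + cnt])
    return VoxelGrid(origin, voxel_size, counts_map, members, cloud)


def density_filter(grid: VoxelGrid, min_points: int) -> PointCloud:
    """Keep the points of voxels holding at least ``min_points`` points.

    Sparse returns (stray reflections, mixed-pixel edges) occupy
    low-density voxels and are dropped; original point order is preserved.
    """
    if min_points < 1:
        raise ValidationError("min_points must be >= 1")
    keep = [grid.membership[key] for key, cnt in grid.counts.items()
            if cnt >= min_points]
    if not keep:
        return PointCloud.empty()
    indices = np.sort(np.concatenate(keep))
    return grid.source.select(indices)


def remove_pot_and_stem(cloud: PointCloud, stem_radius: float,
                        pot_top_z: float,
                        stem_radius_top: float | None = None,
                        stem_top_z: float | None = None) -> PointCloud:
    """Drop points within ``stem_radius`` mm of the rotation axis and all
    points at or below ``pot_top_z``.

    By default the radial cutoff is constant with height (matching the
    instrument's processing; this slightly clips top leaves and under-clips
    bottom ones on tapered stems).  Passing ``stem_radius_top`` and
    ``stem_top_z`` enables an optional linear taper of the cutoff between
    ``pot_top_z`` and ``stem_top_z``.
    """
    if not (stem_radius > 0):
        raise ValidationError("stem_radius must be positive")
    r = np.hypot(cloud.points[:, 0], cloud.points[:, 1])
    z = cloud.points[:, 2]
    if stem_radius_top is not None and stem_top_z is not None:
        f = np.clip((z - pot_top_z) / max(stem_top_z - pot_top_z, 1e-9),
                    0.0, 1.0)
        cutoff = stem_radius + f * (stem_radius_top - stem_radius)
    else:
        cutoff = stem_radius
    keep = (r > cutoff) & (z > pot_top_z)
    return cloud.select(keep)


def segment_leaves(cloud: PointCloud, k: int, seed: int = 0
                   ) -> SegmentationResult:
    """K-means segmentation of the leaf cloud into ``k`` clusters.

    Uses k-means++ with 10 restarts on the raw mm coordinates; labels are
    remapped so cluster 1 has the lowest centroid (leaves numbered bottom
    to top, mirroring the sequential labelling of the instrument's output).
    """
    if k < 1:
        raise ValidationError("k must be >= 1")
    if len(cloud) < k:
        raise ValidationError(
            f"cannot split {len(cloud)} points into {k} clusters")
    km = KMeans(n_clusters=k, init="k-means++", n_init=10,
                random_state=int(seed) % (2 ** 31))
    raw = km.fit_predict(cloud.points)
    order = np.argsort(km.cluster_centers_[:, 2], kind="stable")
    remap = np.empty(k, dtype=int)
    remap[order] = np.arange(1, k + 1)
    return SegmentationResult(leaf_labels=remap[raw], k=k)
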