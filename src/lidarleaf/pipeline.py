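"""End-to-end pipeline driver: raw records to traits, with a run manifest.

Stages: conversion (when the input is raw polar records), background
removal, voxel density filtering, pot/stem removal, k-means leaf
segmentation, per-leaf surface reconstruction, trait extraction.  Each run
writes intermediate clouds, per-leaf meshes, a trait report and a manifest
recording the configuration, input digest and per-stage point counts; a
run is a pure function of (input, configuration, seed).
"""

from __future__ import annotations

import hashlib
import logging
import time
from dataclasses import asdict, dataclass, field, fields
from pathlib import Path

import numpy as np

from . import io as lio
from .preprocessing import (
    SegmentationResult,
    density_filter,
    remove_background,
    remove_pot_and_stem,
    segment_leaves,
    voxelize,
)
from scipy.spatial import cKDTree

from .reconstruction import LeafMesh, reconstruct_leaf
from .scan_geometry import (
    PointCloud,
    PolarScan,
    ScanConfig,
    ValidationError,
    convert_scan,
)
from .traits import PlantTraits, extract_traits

logger = logging.getLogger("lidarleaf")

__version__ = "0.1.0"


class PipelineError(RuntimeError):
    """A stage failed; ``stage`` names it."""

    def __init__(self, stage: str, message: str) -> None:
        super().__init__(f"stage {stage!r} failed: {message}")
        self.stage = stage


@dataclass
class PipelineConfig:
    """Every knob of a processing run, with documented defaults.

    Lengths in mm, angles in radians (scan) / degrees where noted.
    """

    scan: ScanConfig = field(default_factory=ScanConfig)
    # preprocessing
    bounds_min: tuple[float, float, float] = (-600.0, -600.0, 1.0)
    bounds_max: tuple[float, float, float] = (600.0, 600.0, 2000.0)
    voxel_size: float = 10.0
    min_points: int = 2
    stem_radius: float = 30.0
    stem_radius_top: float | None = None  # optional taper, off by default
    stem_top_z: float | None = None
    pot_top_z: float = 125.0
    k: int = 8
    seed: int = 0
    # reconstruction
    bandwidth_fraction: float = 0.3
    frame_mode: str = "pca"
    max_edge_factor: float = 3.0
    max_neighbors: int = 1000
    max_support_points: int | None = 3000
    refine_segmentation: bool = True
    refine_max_distance: float = 12.0  # mm, reassignment gate
    # traits
    proximal_fraction: float = 0.2
    # output
    output_dir: str | None = None

    def __post_init__(self) -> None:
        if not (self.voxel_size > 0 and self.min_points >= 1
                and self.stem_radius > 0 and self.k >= 1):
            raise ValidationError("pipeline parameters out of range")
        if not (0 < self.bandwidth_fraction <= 1
                and 0 < self.proximal_fraction <= 1):
            raise ValidationError("fractions must lie in (0, 1]")
        if self.frame_mode not in ("pca", "xy-plane"):
            raise ValidationError(f"unknown frame_mode {self.frame_mode!r}")

    @classmethod
    def from_dict(cls, data: dict) -> "PipelineConfig":
        """Build from a flat mapping; unknown keys are rejected."""
        data = dict(data)
        scan_keys = {k: data.pop(k) for k in list(data)
                     if k in ScanConfig.__dataclass_fields__
                     or (k.endswith("_deg")
                         and k[:-4] in ScanConfig.__dataclass_fields__)}
        valid = {f.name for f in fields(cls)} - {"scan"}
        unknown = set(data) - valid
        if unknown:
            raise ValidationError(f"unknown config keys: {sorted(unknown)}")
        for key in ("bounds_min", "bounds_max"):
            if key in data:
                data[key] = tuple(float(v) for v in data[key])
        return cls(scan=lio.scan_config_from_dict(scan_keys), **data)

    def to_dict(self) -> dict:
        doc = asdict(self)
        doc["scan"] = asdict(self.scan)
        return doc


@dataclass
class RunManifest:
    """Reproducibility record written alongside every run's outputs."""

    config: dict
    input_digest: str | None
    package_version: str
    seed: int
    stage_counts: dict[str, int] = field(default_factory=dict)
    stage_seconds: dict[str, float] = field(default_factory=dict)

    def write(self, path) -> None:
        lio.write_json(path, asdict(self))


def _cluster_core(pts: np.ndarray, cell: float, link_cells: float
                  ) -> np.ndarray:
    """Boolean mask of the largest spatially connected body of a cluster.

    Points are voxelized at ``cell`` mm and voxels within
    ``link_cells * cell`` of each other are linked, so small occlusion
    holes in a blade do not break it apart while distinct blades (tens of
    mm apart) stay separate.
    """
    from scipy.sparse import coo_matrix
    from scipy.sparse.csgraph import connected_components

    idx = np.floor(pts / cell).astype(np.int64)
    voxels, inverse = np.unique(idx, axis=0, return_inverse=True)
    centers = (voxels + 0.5) * cell
    pairs = cKDTree(centers).query_pairs(link_cells * cell,
                                         output_type="ndarray")
    n = len(voxels)
    if len(pairs):
        graph = coo_matrix(
            (np.ones(len(pairs)), (pairs[:, 0], pairs[:, 1])), shape=(n, n))
    else:
        graph = coo_matrix((n, n))
    _, comp = connected_components(graph, directed=False)
    counts = np.bincount(comp)
    return comp[inverse] == np.argmax(counts)


def refine_leaf_labels(points: np.ndarray, labels: np.ndarray,
                       config: PipelineConfig) -> np.ndarray:
    """One spatial-coherence reassignment pass after k-means.

    K-means partitions space into convex cells, so a cluster often holds
    one blade plus a sparse swath sliced off a neighboring blade, and the
    swath poisons that cluster's surface fit while its area goes missing
    from its own leaf.  Each cluster is therefore reduced to its core —
    the largest spatially connected body, which is the blade itself —
    and every point is re-labelled by its nearest core (points farther
    than ``refine_max_distance`` mm from every core are dropped as
    unattributable).
    """
    k = int(labels.max())
    cores: list[np.ndarray] = []
    owners: list[np.ndarray] = []
    for leaf_id in range(1, k + 1):
        pts = points[labels == leaf_id]
        if len(pts) < 12:
            continue
        mask = _cluster_core(pts, cell=10.0, link_cells=2.9)
        cores.append(pts[mask])
        owners.append(np.full(int(mask.sum()), leaf_id, dtype=int))
    if not cores:
        return labels
    bank = np.concatenate(cores)
    owner = np.concatenate(owners)
    dist, idx = cKDTree(bank).query(points, workers=-1)
    new_labels = np.where(dist <= config.refine_max_distance,
                          owner[idx], 0)
    # a leaf may not collapse below the fitting floor of 12 points
    for leaf_id in range(1, k + 1):
        if (new_labels == leaf_id).sum() < 12:
            new_labels[labels == leaf_id] = leaf_id
    return new_labels


def _load_input(source, config: PipelineConfig):
    """Resolve the input into a PointCloud (converting raw records)."""
    if isinstance(source, PointCloud):
        return source, None
    if isinstance(source, PolarScan):
        return convert_scan(source, config.scan), None
    path = Path(source)
    digest = hashlib.sha256(path.read_bytes()).hexdigest()
    with path.open() as fh:
        first = fh.readline().strip()
    if first == lio.RAW_HEADER:
        scan = lio.read_raw_scan(path, config.scan)
        return convert_scan(scan, config.scan), digest
    return lio.read_point_cloud(path), digest


def run_pipeline(source, config: PipelineConfig
                 ) -> tuple[PlantTraits, list[LeafMesh], RunManifest]:
    """Execute conversion, preprocessing, reconstruction and trait
    extraction; optionally write all artifacts to ``config.output_dir``.

    ``source`` may be a path (raw scan file or point-cloud CSV/XYZ/PLY), a
    :class:`PolarScan` or a :class:`PointCloud`.
    """
    manifest = RunManifest(config=config.to_dict(), input_digest=None,
                           package_version=__version__, seed=config.seed)
    out = Path(config.output_dir) if config.output_dir else None
    if out is not None:
        out.mkdir(parents=True, exist_ok=True)

    def stage(name, func, *args, **kwargs):
        t0 = time.perf_counter()
        try:
            result = func(*args, **kwargs)
        except Exception as exc:
            if out is not None:
                manifest.write(out / "manifest.json")
            raise PipelineError(name, str(exc)) from exc
        manifest.stage_seconds[name] = round(time.perf_counter() - t0, 4)
        return result

    cloud, digest = stage("load", _load_input, source, config)
    manifest.input_digest = digest
    manifest.stage_counts["input"] = len(cloud)
    logger.info("input: %d points", len(cloud))

    cloud = stage("background_removal", remove_background, cloud,
                  (config.bounds_min, config.bounds_max))
    manifest.stage_counts["background_removal"] = len(cloud)
    logger.info("after background removal: %d points", len(cloud))

    grid = stage("voxelization", voxelize, cloud, config.voxel_size)
    cloud = stage("density_filter", density_filter, grid, config.min_points)
    manifest.stage_counts["density_filter"] = len(cloud)
    logger.info("after density filter: %d points", len(cloud))

    cloud = stage("pot_stem_removal", remove_pot_and_stem, cloud,
                  config.stem_radius, config.pot_top_z,
                  stem_radius_top=config.stem_radius_top,
                  stem_top_z=config.stem_top_z)
    manifest.stage_counts["pot_stem_removal"] = len(cloud)
    logger.info("after pot/stem removal: %d points", len(cloud))
    if out is not None:
        lio.write_point_cloud(out / "cloud_clean.csv", cloud)

    seg: SegmentationResult = stage("segmentation", segment_leaves, cloud,
                                    config.k, config.seed)
    leaf_labels = seg.leaf_labels
    if config.refine_segmentation:
        leaf_labels = stage("segmentation_refinement", refine_leaf_labels,
                            cloud.points, leaf_labels, config)
        manifest.stage_counts["segmentation_refinement"] = int(
            (leaf_labels > 0).sum())
    labeled = PointCloud(cloud.points, leaf_labels)
    if out is not None:
        lio.write_point_cloud(out / "cloud_segmented.csv", labeled)

    meshes: list[LeafMesh] = []
    for leaf_id in range(1, config.k + 1):
        pts = cloud.points[leaf_labels == leaf_id]
        mesh = stage(f"reconstruction_leaf_{leaf_id}", reconstruct_leaf, pts,
                     bandwidth_fraction=config.bandwidth_fraction,
                     frame_mode=config.frame_mode,
                     max_edge_factor=config.max_edge_factor,
                     max_neighbors=config.max_neighbors,
                     max_support_points=config.max_support_points,
                     seed=config.seed, leaf_id=leaf_id)
        meshes.append(mesh)
        logger.info("leaf %d: %d points -> %d triangles", leaf_id,
                    len(pts), mesh.triangles.shape[0])
        if out is not None:
            lio.write_mesh(out / f"leaf_{leaf_id:02d}.ply", mesh)
            lio.write_mesh(out / f"leaf_{leaf_id:02d}.obj", mesh)
    manifest.stage_counts["triangles"] = int(
        sum(m.triangles.shape[0] for m in meshes))

    plant_traits = stage("traits", extract_traits, meshes,
                         proximal_fraction=config.proximal_fraction)
    if out is not None:
        lio.write_plant_mesh(out / "plant.ply", meshes)
        lio.write_json(out / "traits.json", plant_traits.to_dict())
        manifest.write(out / "manifest.json")
    return plant_traits, meshes, manifest
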