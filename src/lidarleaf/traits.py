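"""Morphological trait extraction from leaf meshes, plus validation stats.

Traits: per-leaf area (sum of triangle areas), plant total area, leaf
inclination angle at the node (angle of the proximal blade direction to
the horizontal, 0 = horizontal, 90 = vertical) and the leaf angular
distribution (LAD): per-triangle facet elevation angles binned in
10-degree classes over [0, 90], each triangle weighted by its share of the
total leaf area.  Validation compares paired estimates and references via
the squared Pearson correlation and the mean absolute error.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .reconstruction import LeafMesh
from .scan_geometry import ValidationError

logger = logging.getLogger("lidarleaf")

LAD_BIN_EDGES = np.arange(0.0, 100.0, 10.0)  # [0,10), ..., [80,90]


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass
class PlantTraits:
    """Per-leaf and whole-plant traits of one reconstructed plant."""

    per_leaf_area: np.ndarray          # mm^2, indexed by leaf_id order
    total_area: float                  # mm^2
    per_leaf_inclination: np.ndarray   # degrees
    angular_distribution: np.ndarray   # 9 fractions

    def __post_init__(self) -> None:
        self.per_leaf_area = np.asarray(self.per_leaf_area, dtype=float)
        self.per_leaf_inclination = np.asarray(
            self.per_leaf_inclination, dtype=float)
        self.angular_distribution = np.asarray(
            self.angular_distribution, dtype=float)
        if abs(self.total_area - self.per_leaf_area.sum()) > 1e-9 * max(
                1.0, abs(self.total_area)):
            raise ValidationError("total_area must equal sum of leaf areas")
        if self.total_area > 0:
            if np.any(self.angular_distribution < 0) or abs(
                    self.angular_distribution.sum() - 1.0) > 1e-9:
                raise ValidationError(
                    "angular distribution must be non-negative and sum to 1")

    def to_dict(self) -> dict:
        return {
            "per_leaf_area_mm2": self.per_leaf_area.tolist(),
            "total_area_mm2": self.total_area,
            "per_leaf_inclination_deg": self.per_leaf_inclination.tolist(),
            "lad": self.angular_distribution.tolist(),
        }


@dataclass
class ValidationReport:
    """Agreement between paired estimates and reference measurements."""

    r_squared: float | None
    mae: float
    mae_percent_of_mean: float
    n: int

    def to_dict(self) -> dict:
        return {"r_squared": self.r_squared, "mae": self.mae,
                "mae_percent_of_mean": self.mae_percent_of_mean, "n": self.n}


# ---------------------------------------------------------------------------
# Operations
# ---------------------------------------------------------------------------

def leaf_area(mesh: LeafMesh) -> float:
    """Leaf area (mm^2) = sum of the areas of the mesh triangles."""
    return float(mesh.triangle_areas.sum())


def total_leaf_area(meshes: Sequence[LeafMesh]) -> float:
    """Plant total leaf area (mm^2); 0 for an empty plant."""
    return float(sum(leaf_area(m) for m in meshes))


def leaf_inclination_angle(mesh: LeafMesh, stem_axis_point=(0.0, 0.0),
                           proximal_fraction: float = 0.2) -> float:
    """Inclination (degrees in [0, 90]) of the blade where it leaves the stem.

    The vertex nearest the stem axis serves as the attachment proxy; the
    principal direction of the vertices within ``proximal_fraction`` of the
    leaf's span from it is compared with the horizontal plane.  If fewer
    than 3 vertices fall in the proximal region the fraction is widened to
    0.5 before giving up.
    """
    if not (0 < proximal_fraction <= 1):
        raise ValidationError("proximal_fraction must be in (0, 1]")
    if mesh.vertices.shape[0] < 3:
        raise ValidationError("mesh has too few vertices")
    axis = np.asarray(stem_axis_point, dtype=float)
    radial = np.hypot(mesh.vertices[:, 0] - axis[0],
                      mesh.vertices[:, 1] - axis[1])
    attach = mesh.vertices[np.argmin(radial)]
    dist = np.linalg.norm(mesh.vertices - attach, axis=1)
    span = float(dist.max())
    if span <= 0:
        raise ValidationError("degenerate mesh: zero span")
    for frac in (proximal_fraction, 0.5):
        sel = dist <= frac * span
        if sel.sum() >= 3:
            break
    else:
        raise ValidationError("too few proximal vertices")
    prox = mesh.vertices[sel]
    _, _, vt = np.linalg.svd(prox - prox.mean(axis=0), full_matrices=False)
    direction = vt[0]
    horiz = float(np.hypot(direction[0], direction[1]))
    return float(np.degrees(np.arctan2(abs(direction[2]), horiz)))


def angular_distribution(meshes: Sequence[LeafMesh]) -> np.ndarray:
    """Area-fraction LAD over 10-degree facet-angle bins [0,10) ... [80,90].

    Facet angle alpha = arccos(|n_z|): a horizontal facet (normal straight
    up) scores 0, a vertical facet 90.  Using |n_z| makes the result
    immune to normal orientation flips.
    """
    total = total_leaf_area(meshes)
    if not (total > 0):
        raise ValidationError("total area must be positive")
    mass = np.zeros(9)
    for mesh in meshes:
        nz = np.abs(mesh.triangle_unit_normals[:, 2])
        alpha = np.degrees(np.arccos(np.clip(nz, 0.0, 1.0)))
        bins = np.minimum((alpha // 10).astype(int), 8)
        np.add.at(mass, bins, mesh.triangle_areas)
    return mass / total


def extract_traits(meshes: Sequence[LeafMesh], stem_axis_point=(0.0, 0.0),
                   proximal_fraction: float = 0.2) -> PlantTraits:
    """All four traits of one plant from its per-leaf meshes."""
    areas = np.array([leaf_area(m) for m in meshes])
    incl = np.array([
        leaf_inclination_angle(m, stem_axis_point, proximal_fraction)
        for m in meshes])
    lad = angular_distribution(meshes) if areas.sum() > 0 else np.zeros(9)
    return PlantTraits(per_leaf_area=areas, total_area=float(areas.sum()),
                       per_leaf_inclination=incl, angular_distribution=lad)


def mean_angular_distribution(per_plant_lads: Sequence[np.ndarray]
                              ) -> tuple[np.ndarray, np.ndarray]:
    """Average LAD across plants and its standard deviation per bin."""
    stack = np.vstack(per_plant_lads)
    return stack.mean(axis=0), stack.std(axis=0, ddof=1 if len(stack) > 1
                                         else 0)


def validate(estimates, references, r2_mode: str = "pearson"
             ) -> ValidationReport:
    """Paired validation statistics.

    ``r2_mode="pearson"`` (default) reports the squared Pearson correlation
    of the pairs; ``"identity"`` reports 1 - SSE/SST about the identity
    line instead.  R^2 is reported as missing (None) when either vector has
    zero variance.
    """
    est = np.asarray(estimates, dtype=float).ravel()
    ref = np.asarray(references, dtype=float).ravel()
    if est.size != ref.size or est.size < 2:
        raise ValidationError("need equal-length paired vectors, n >= 2")
    mae = float(np.mean(np.abs(est - ref)))
    mean_ref = float(np.mean(ref))
    mae_pct = 100.0 * mae / mean_ref if mean_ref != 0 else float("nan")
    if est.std() == 0 or ref.std() == 0:
        r2 = None
    elif r2_mode == "pearson":
        r2 = float(np.corrcoef(est, ref)[0, 1] ** 2)
    elif r2_mode == "identity":
        sst = float(np.sum((ref - mean_ref) ** 2))
        r2 = 1.0 - float(np.sum((est - ref) ** 2)) / sst
    else:
        raise ValidationError(f"unknown r2_mode {r2_mode!r}")
    return ValidationReport(r_squared=r2, mae=mae,
                            mae_percent_of_mean=mae_pct, n=int(est.size))
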