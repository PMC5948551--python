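"""Leaf surface reconstruction: local-quadratic LOWESS fit and Delaunay mesh.

Each segmented leaf cloud is expressed in a leaf-local orthonormal frame
(u, v, w).  The height w is modelled as a smooth function of (u, v) by
LOWESS: at every evaluation location the nearest fraction of support
points is fitted with a full quadratic

    w = a0 + a1 u + a2 v + a3 u^2 + a4 u v + a5 v^2

under tricube distance weights, and the fitted value at the location is
kept.  The (u, v) support coordinates are Delaunay-triangulated, boundary
triangles with over-long edges are pruned (plain Delaunay fills the convex
hull and would overestimate concave blades), each vertex is elevated to
its fitted height, and the triangles are mapped back to world coordinates
with per-triangle areas and unit normals.

By default the frame is the PCA frame of the leaf points (w along the
smallest-variance axis), which stays well-posed for steep erectophile
leaves; ``frame_mode="xy-plane"`` reproduces fitting and triangulating in
the world XY plane instead.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.spatial import Delaunay, cKDTree

from .scan_geometry import PointCloud, ValidationError

logger = logging.getLogger("lidarleaf")


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass
class LeafSurfaceFit:
    """LOWESS height model of one leaf in its local frame.

    ``axes`` rows are the unit vectors (u, v, w); ``support_uvw`` holds the
    leaf's points expressed in that frame.
    """

    origin: np.ndarray
    axes: np.ndarray           # (3, 3) orthonormal, rows u, v, w
    support_uvw: np.ndarray    # (n, 3)
    bandwidth_fraction: float
    max_neighbors: int = 1000
    _tree: cKDTree | None = None

    def __post_init__(self) -> None:
        gram = self.axes @ self.axes.T
        if not np.allclose(gram, np.eye(3), atol=1e-9):
            raise ValidationError("frame axes must be orthonormal")
        if not (0 < self.bandwidth_fraction <= 1):
            raise ValidationError("bandwidth_fraction must be in (0, 1]")
        if self._tree is None:
            self._tree = cKDTree(self.support_uvw[:, :2])

    @property
    def n_support(self) -> int:
        return int(self.support_uvw.shape[0])

    def neighborhood_size(self) -> int:
        k = int(np.ceil(self.bandwidth_fraction * self.n_support))
        return int(np.clip(k, min(12, self.n_support),
                           min(self.max_neighbors, self.n_support)))

    def to_world(self, uvw: np.ndarray) -> np.ndarray:
        return self.origin + np.asarray(uvw) @ self.axes

    def to_frame(self, xyz: np.ndarray) -> np.ndarray:
        return (np.asarray(xyz) - self.origin) @ self.axes.T

    def __call__(self, uv: np.ndarray) -> np.ndarray:
        """Fitted height w at each (u, v) location, shape (m,)."""
        uv = np.atleast_2d(np.asarray(uv, dtype=float))
        k = self.neighborhood_size()
        dist, idx = self._tree.query(uv, k=k, workers=-1)
        dist = np.atleast_2d(dist)
        idx = np.atleast_2d(idx)
        out = np.empty(uv.shape[0])
        for i in range(uv.shape[0]):
            out[i] = self._fit_one(uv[i], dist[i], idx[i])
        return out

    def _fit_one(self, uv0, dist, idx) -> float:
        pts = self.support_uvw[idx]
        dmax = dist[-1]
        if dmax <= 0:
            w = np.ones_like(dist)
        else:
            w = (1.0 - np.minimum(dist / dmax, 1.0) ** 3) ** 3
            w = np.maximum(w, 1e-6)  # keep the farthest point from vanishing
        du = pts[:, 0] - uv0[0]
        dv = pts[:, 1] - uv0[1]
        sw = np.sqrt(w)
        design = np.column_stack([np.ones_like(du), du, dv,
                                  du * du, du * dv, dv * dv])
        coef, _, rank, _ = np.linalg.lstsq(design * sw[:, None],
                                           pts[:, 2] * sw, rcond=None)
        if rank == 6:
            return float(coef[0])
        logger.debug("degenerate quadratic neighborhood, falling back")
        coef, _, rank, _ = np.linalg.lstsq(design[:, :3] * sw[:, None],
                                           pts[:, 2] * sw, rcond=None)
        if rank == 3:
            return float(coef[0])
        return float(np.average(pts[:, 2], weights=w))


@dataclass
class LeafMesh:
    """Triangulated leaf surface with per-triangle areas and unit normals."""

    vertices: np.ndarray              # (n, 3) mm, world frame
    triangles: np.ndarray             # (m, 3) int
    triangle_areas: np.ndarray        # (m,) mm^2
    triangle_unit_normals: np.ndarray  # (m, 3)
    leaf_id: int = 0

    def __post_init__(self) -> None:
        m = self.triangles.shape[0]
        if m and self.triangles.max() >= self.vertices.shape[0]:
            raise ValidationError("triangle references invalid vertex")
        if m and not np.all(self.triangle_areas > 0):
            raise ValidationError("triangle areas must be positive")
        if m and not np.allclose(
                np.linalg.norm(self.triangle_unit_normals, axis=1), 1.0,
                atol=1e-9):
            raise ValidationError("normals must be unit length")

    @property
    def area(self) -> float:
        return float(self.triangle_areas.sum())


# ---------------------------------------------------------------------------
# Operations
# ---------------------------------------------------------------------------

def _pca_frame(points: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Centroid origin; axes = principal directions, w = least variance.

    Signs are fixed deterministically: w points towards +Z (ties +X), u
    towards its largest-magnitude world component, v = w x u.
    """
    origin = points.mean(axis=0)
    _, _, vt = np.linalg.svd(points - origin, full_matrices=False)
    u, v, w = vt[0], vt[1], vt[2]
    if w[2] < 0 or (w[2] == 0 and w[0] < 0):
        w = -w
    if u[np.argmax(np.abs(u))] < 0:
        u = -u
    v = np.cross(w, u)
    return origin, np.vstack([u, v, w])


def grid_thin(coords: np.ndarray, target_n: int) -> np.ndarray:
    """Indices of an evenly spaced subset of about ``target_n`` points.

    One representative — the point nearest its cell center — is kept per
    grid cell; the cell size is found by bisection so the occupied-cell
    count lands near the target.  Deterministic.  Works in any dimension;
    leaf support thinning applies it to the (u, v) plane coordinates so
    that the ranging-noise thickness of the cloud cannot stack several
    near-coincident picks onto one surface location.
    """
    coords = np.asarray(coords, dtype=float)
    n = coords.shape[0]
    if n <= target_n:
        return np.arange(n)
    lo_corner = coords.min(axis=0)
    span = float(np.max(coords.max(axis=0) - lo_corner))
    lo_c, hi_c = span * 1e-4, span
    pick = np.arange(n)[:target_n]
    for _ in range(24):
        cell = 0.5 * (lo_c + hi_c)
        idx = np.floor((coords - lo_corner) / cell).astype(np.int64)
        cells, inverse = np.unique(idx, axis=0, return_inverse=True)
        if cells.shape[0] > target_n:
            lo_c = cell  # cells too small
            continue
        hi_c = cell
        centers = lo_corner + (idx + 0.5) * cell
        dist = np.linalg.norm(coords - centers, axis=1)
        order = np.lexsort((dist, inverse))
        first_of_cell = np.concatenate(
            [[True], inverse[order][1:] != inverse[order][:-1]])
        pick = order[first_of_cell]
        if cells.shape[0] >= 0.95 * target_n:
            break
    return np.sort(pick)


def fit_leaf_surface(points: PointCloud | np.ndarray,
                     bandwidth_fraction: float = 0.3,
                     frame_mode: str = "pca",
                     max_neighbors: int = 1000,
                     max_support_points: int | None = None,
                     robust_iterations: int = 1,
                     seed: int = 0) -> LeafSurfaceFit:
    """Fit the LOWESS height model to one leaf's points.

    ``max_neighbors`` caps the neighborhood size at high point densities so
    the fit stays local (and tractable) on full-resolution scans;
    ``max_support_points`` thins the support to an even grid in the leaf
    plane (see :func:`grid_thin`), collapsing the near-duplicate coverage
    that overlapping sweeps of the 360-degree scan produce.

    ``robust_iterations`` applies the usual LOWESS robustifying pass:
    support points whose height residual exceeds 6 scaled MADs are
    discarded and the fit repeated.  This rejects the stray patches of a
    neighboring leaf that imperfect k-means segmentation leaves in a
    cluster, which would otherwise drag the local quadratics between two
    surface sheets.
    """
    xyz = points.points if isinstance(points, PointCloud) else np.asarray(
        points, dtype=float)
    if xyz.shape[0] < 12:
        raise ValidationError(
            "need at least 12 points to fit local quadratics")
    if frame_mode == "pca":
        origin, axes = _pca_frame(xyz)
    elif frame_mode == "xy-plane":
        origin, axes = np.zeros(3), np.eye(3)
    else:
        raise ValidationError(f"unknown frame_mode {frame_mode!r}")
    support = (xyz - origin) @ axes.T
    if max_support_points is not None and len(support) > max_support_points:
        support = support[grid_thin(support[:, :2], max_support_points)]
    fit = LeafSurfaceFit(origin=origin, axes=axes, support_uvw=support,
                         bandwidth_fraction=bandwidth_fraction,
                         max_neighbors=max_neighbors)
    for _ in range(robust_iterations):
        resid = fit.support_uvw[:, 2] - fit(fit.support_uvw[:, :2])
        med = np.median(resid)
        mad = 1.4826 * np.median(np.abs(resid - med))
        if mad <= 0:
            break
        keep = np.abs(resid - med) <= 6.0 * mad
        if keep.all() or keep.sum() < 12:
            break
        logger.debug("robust pass dropped %d support points",
                     int((~keep).sum()))
        fit = LeafSurfaceFit(origin=origin, axes=axes,
                             support_uvw=fit.support_uvw[keep],
                             bandwidth_fraction=bandwidth_fraction,
                             max_neighbors=max_neighbors)
    return fit


def _envelope_prune(uv: np.ndarray, simplices: np.ndarray,
                    max_edge_factor: float) -> np.ndarray:
    """Remove convex-hull fill triangles outside the blade's outline.

    Plain Delaunay triangulates the convex hull of the support, bridging
    concave parts of the outline (the tapered base and tip of a blade, a
    notch of a test shape).  A grass blade is a ribbon along its first
    principal axis, so its outline is recovered as the per-slice extent of
    the support along v: the u range is cut into bins, the observed
    [min(v), max(v)] envelope (linearly interpolated across empty bins) is
    widened by ``max_edge_factor/6`` of the median triangulation edge, and
    triangles whose centroid leaves the envelope are dropped.  Interior
    triangles always survive, however long their edges: inside the blade a
    long edge marks an occlusion shadow that the smooth fitted surface
    should span, not a geometry error.
    """
    edge_len = np.linalg.norm(
        uv[simplices] - uv[np.roll(simplices, -1, axis=1)], axis=2)
    med_edge = float(np.median(edge_len))
    margin = max_edge_factor / 6.0 * med_edge
    u, v = uv[:, 0], uv[:, 1]
    span = float(u.max() - u.min())
    if span <= 0:
        return simplices
    n_bins = int(np.clip(len(uv) // 25, 1, max(1, int(span / (2 * med_edge))
                                               or 1)))
    edges_u = np.linspace(u.min(), u.max(), n_bins + 1)
    which = np.clip(np.searchsorted(edges_u, u, side="right") - 1,
                    0, n_bins - 1)
    lo = np.full(n_bins, np.inf)
    hi = np.full(n_bins, -np.inf)
    np.minimum.at(lo, which, v)
    np.maximum.at(hi, which, v)
    centers = 0.5 * (edges_u[:-1] + edges_u[1:])
    valid = np.isfinite(lo)
    lo_f = np.interp(centers, centers[valid], lo[valid])
    hi_f = np.interp(centers, centers[valid], hi[valid])
    cent = uv[simplices].mean(axis=1)
    cb = np.clip(np.searchsorted(edges_u, cent[:, 0], side="right") - 1,
                 0, n_bins - 1)
    inside = ((cent[:, 1] >= lo_f[cb] - margin)
              & (cent[:, 1] <= hi_f[cb] + margin))
    return simplices[inside]


def triangulate_leaf(fit: LeafSurfaceFit, max_edge_factor: float = 3.0,
                     leaf_id: int = 0) -> LeafMesh:
    """Delaunay-triangulate the support (u, v), trim convex-hull fill
    outside the blade outline, elevate vertices to the fitted surface and
    return the world-frame mesh.

    See :func:`_envelope_prune` for the pruning rule.  Normals are
    oriented with non-negative world-Z component (ties: +X).
    """
    uv = fit.support_uvw[:, :2]
    if uv.shape[0] < 3:
        raise ValidationError("need at least 3 support points")
    try:
        tri = Delaunay(uv)
    except Exception as exc:  # qhull failure on degenerate input
        raise ValidationError(f"triangulation failed: {exc}") from exc
    simplices = tri.simplices
    if simplices.shape[0] == 0:
        raise ValidationError("all support points are collinear")

    simplices = _envelope_prune(uv, simplices, max_edge_factor)
    if simplices.shape[0] == 0:
        raise ValidationError("outline pruning removed every triangle")

    heights = fit(uv)
    verts_world = fit.to_world(
        np.column_stack([uv, heights]))
    a = verts_world[simplices[:, 0]]
    b = verts_world[simplices[:, 1]]
    c = verts_world[simplices[:, 2]]
    cross = np.cross(b - a, c - a)
    norm = np.linalg.norm(cross, axis=1)
    ok = norm > 1e-12
    simplices, cross, norm = simplices[ok], cross[ok], norm[ok]
    areas = 0.5 * norm
    normals = cross / norm[:, None]
    flip = (normals[:, 2] < 0) | ((normals[:, 2] == 0) & (normals[:, 0] < 0))
    normals[flip] *= -1.0
    return LeafMesh(vertices=verts_world, triangles=simplices,
                    triangle_areas=areas, triangle_unit_normals=normals,
                    leaf_id=leaf_id)


def mesh_from_arrays(vertices: np.ndarray, triangles: np.ndarray,
                     leaf_id: int = 0) -> LeafMesh:
    """Build a :class:`LeafMesh` from raw vertex/triangle arrays, computing
    areas and consistently oriented unit normals (Z >= 0, ties +X);
    zero-area triangles are dropped."""
    vertices = np.asarray(vertices, dtype=float).reshape(-1, 3)
    triangles = np.asarray(triangles, dtype=int).reshape(-1, 3)
    a, b, c = (vertices[triangles[:, i]] for i in range(3))
    cross = np.cross(b - a, c - a)
    norm = np.linalg.norm(cross, axis=1)
    ok = norm > 1e-12
    triangles, cross, norm = triangles[ok], cross[ok], norm[ok]
    normals = cross / norm[:, None]
    flip = (normals[:, 2] < 0) | ((normals[:, 2] == 0) & (normals[:, 0] < 0))
    normals[flip] *= -1.0
    return LeafMesh(vertices=vertices, triangles=triangles,
                    triangle_areas=0.5 * norm, triangle_unit_normals=normals,
                    leaf_id=leaf_id)


def reconstruct_leaf(points: PointCloud | np.ndarray,
                     bandwidth_fraction: float = 0.3,
                     frame_mode: str = "pca",
                     max_edge_factor: float = 3.0,
                     max_neighbors: int = 1000,
                     max_support_points: int | None = None,
                     seed: int = 0, leaf_id: int = 0) -> LeafMesh:
    """Convenience wrapper: fit then triangulate one leaf."""
    fit = fit_leaf_surface(points, bandwidth_fraction=bandwidth_fraction,
                           frame_mode=frame_mode, max_neighbors=max_neighbors,
                           max_support_points=max_support_points, seed=seed)
    return triangulate_leaf(fit, max_edge_factor=max_edge_factor,
                            leaf_id=leaf_id)
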