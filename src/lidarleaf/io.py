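"""File formats: raw scan records, point clouds (CSV/XYZ/PLY), meshes, config.

The raw scan file is plain text, one return per line::

    #lidarleaf-raw v1
    # sweep_index sample_index range_mm theta_rad [phi_rad]
    0 12 1043.2 -0.1534
    ...

The stage angle column is optional; when absent it is derived from the
sweep index via the scan configuration (continuous rotation).  Point
clouds round-trip through CSV (header ``X,Y,Z[,label]``), whitespace XYZ
and ASCII PLY at 6 decimal places (1 nm); meshes are written as ASCII PLY
or Wavefront OBJ via trimesh and read back from either.
"""

from __future__ import annotations

import json
import math
import tomllib
from pathlib import Path

import numpy as np
import pandas as pd
import trimesh

from .reconstruction import LeafMesh, mesh_from_arrays
from .scan_geometry import (
    PointCloud,
    PolarScan,
    ScanConfig,
    ValidationError,
    assign_stage_angle,
)

RAW_HEADER = "#lidarleaf-raw v1"
FLOAT_FMT = "%.6f"


class ParseError(ValidationError):
    """Malformed input file; message names the offending line."""


# ---------------------------------------------------------------------------
# Raw scan records
# ---------------------------------------------------------------------------

def write_raw_scan(path, scan: PolarScan, include_phi: bool = True) -> None:
    path = Path(path)
    cols = [scan.sweep_index, scan.sample_index, scan.range_R,
            scan.beam_angle_theta]
    fmts = ["%d", "%d", FLOAT_FMT, "%.9f"]
    if include_phi:
        cols.append(scan.stage_angle_phi)
        fmts.append("%.9f")
    with path.open("w") as fh:
        fh.write(RAW_HEADER + "\n")
        np.savetxt(fh, np.column_stack(cols), fmt=fmts)


def read_raw_scan(path, config: ScanConfig | None = None) -> PolarScan:
    """Parse a raw scan file; ``config`` supplies the stage angle when the
    file has no phi column."""
    path = Path(path)
    with path.open() as fh:
        first = fh.readline().rstrip("\n")
        if first.strip() != RAW_HEADER:
            raise ParseError(
                f"{path.name}:1: expected header {RAW_HEADER!r}, "
                f"got {first[:40]!r}")
        rows = []
        ncol = None
        for lineno, line in enumerate(fh, start=2):
            stripped = line.strip()
            if not stripped or stripped.startswith("#"):
                continue
            parts = stripped.split()
            if len(parts) not in (4, 5):
                raise ParseError(
                    f"{path.name}:{lineno}: expected 4 or 5 columns, "
                    f"got {len(parts)}")
            if ncol is None:
                ncol = len(parts)
            elif len(parts) != ncol:
                raise ParseError(
                    f"{path.name}:{lineno}: inconsistent column count")
            try:
                rows.append([float(p) for p in parts])
            except ValueError as exc:
                raise ParseError(
                    f"{path.name}:{lineno}: {exc}") from None
    if not rows:
        z = np.empty(0)
        return PolarScan(z, z, z)
    arr = np.asarray(rows)
    sweep = arr[:, 0].astype(int)
    if ncol == 5:
        phi = arr[:, 4]
    else:
        if config is None:
            raise ValidationError(
                "file has no phi column; a scan configuration is required")
        phi = np.array([assign_stage_angle(int(s), config) for s in
                        np.unique(sweep)])
        phi = phi[np.searchsorted(np.unique(sweep), sweep)]
    return PolarScan(arr[:, 2], arr[:, 3], phi, sweep, arr[:, 1].astype(int))


# ---------------------------------------------------------------------------
# Point clouds
# ---------------------------------------------------------------------------

def write_point_cloud(path, cloud: PointCloud) -> None:
    path = Path(path)
    suffix = path.suffix.lower()
    if suffix == ".csv":
        cols = {"X": cloud.points[:, 0], "Y": cloud.points[:, 1],
                "Z": cloud.points[:, 2]}
        if cloud.labels is not None:
            cols["label"] = cloud.labels
        pd.DataFrame(cols).to_csv(path, index=False, float_format=FLOAT_FMT)
    elif suffix == ".xyz":
        np.savetxt(path, cloud.points, fmt=FLOAT_FMT)
    elif suffix == ".ply":
        with path.open("w") as fh:
            fh.write("ply\nformat ascii 1.0\n"
                     f"element vertex {len(cloud)}\n"
                     "property float x\nproperty float y\nproperty float z\n"
                     "end_header\n")
            np.savetxt(fh, cloud.points, fmt=FLOAT_FMT)
    else:
        raise ValidationError(f"unsupported point-cloud format {suffix!r}")


def read_point_cloud(path) -> PointCloud:
    path = Path(path)
    suffix = path.suffix.lower()
    if suffix == ".csv":
        try:
            df = pd.read_csv(path)
        except Exception as exc:
            raise ParseError(f"{path.name}: {exc}") from exc
        cols = [c.upper() for c in df.columns]
        if cols[:3] != ["X", "Y", "Z"]:
            raise ParseError(
                f"{path.name}:1: expected header X,Y,Z[,label]")
        labels = df.iloc[:, 3].to_numpy(dtype=int) if (
            len(df.columns) > 3 and df.columns[3].lower() == "label"
        ) else None
        return PointCloud(df.iloc[:, :3].to_numpy(dtype=float), labels)
    if suffix == ".xyz":
        pts = np.loadtxt(path, ndmin=2)
        if pts.size == 0:
            return PointCloud.empty()
        if pts.shape[1] < 3:
            raise ParseError(f"{path.name}: expected 3 columns")
        return PointCloud(pts[:, :3])
    if suffix == ".ply":
        loaded = trimesh.load(path, process=False)
        if isinstance(loaded, trimesh.Scene):  # e.g. zero-vertex file
            geoms = list(loaded.geometry.values())
            if not geoms:
                return PointCloud.empty()
            verts = np.concatenate(
                [np.asarray(g.vertices, dtype=float) for g in geoms])
        else:
            verts = np.asarray(loaded.vertices, dtype=float)
        return PointCloud(verts) if len(verts) else PointCloud.empty()
    raise ValidationError(f"unsupported point-cloud format {suffix!r}")


# ---------------------------------------------------------------------------
# Meshes
# ---------------------------------------------------------------------------

def write_mesh(path, mesh: LeafMesh) -> None:
    """Write a leaf mesh as ASCII PLY or Wavefront OBJ (by extension)."""
    path = Path(path)
    tm = trimesh.Trimesh(vertices=mesh.vertices, faces=mesh.triangles,
                         process=False)
    suffix = path.suffix.lower()
    if suffix == ".ply":
        path.write_bytes(trimesh.exchange.ply.export_ply(
            tm, encoding="ascii"))
    elif suffix == ".obj":
        path.write_text(trimesh.exchange.obj.export_obj(tm))
    else:
        raise ValidationError(f"unsupported mesh format {suffix!r}")


def write_plant_mesh(path, meshes) -> None:
    """Concatenate per-leaf meshes into one plant file."""
    tm = trimesh.util.concatenate([
        trimesh.Trimesh(vertices=m.vertices, faces=m.triangles,
                        process=False) for m in meshes])
    write_mesh_trimesh(path, tm)


def write_mesh_trimesh(path, tm: "trimesh.Trimesh") -> None:
    path = Path(path)
    suffix = path.suffix.lower()
    if suffix == ".ply":
        path.write_bytes(trimesh.exchange.ply.export_ply(
            tm, encoding="ascii"))
    elif suffix == ".obj":
        path.write_text(trimesh.exchange.obj.export_obj(tm))
    else:
        raise ValidationError(f"unsupported mesh format {suffix!r}")


def read_mesh(path, leaf_id: int = 0) -> LeafMesh:
    loaded = trimesh.load(Path(path), process=False)
    if not hasattr(loaded, "faces") or len(loaded.faces) == 0:
        raise ParseError(f"{Path(path).name}: no faces found")
    return mesh_from_arrays(np.asarray(loaded.vertices),
                            np.asarray(loaded.faces), leaf_id=leaf_id)


# ---------------------------------------------------------------------------
# Configuration and JSON reports
# ---------------------------------------------------------------------------

_SCAN_ANGLE_FIELDS = {"beam_angular_interval", "start_angle", "stop_angle"}


def scan_config_from_dict(data: dict) -> ScanConfig:
    """Build a :class:`ScanConfig` from flat keys; a ``_deg`` suffix on an
    angle field accepts degrees."""
    kwargs: dict[str, float] = {}
    valid = set(ScanConfig.__dataclass_fields__)
    for key, value in data.items():
        if key.endswith("_deg") and key[:-4] in _SCAN_ANGLE_FIELDS:
            kwargs[key[:-4]] = math.radians(float(value))
        elif key in valid:
            kwargs[key] = float(value)
        else:
            raise ValidationError(f"unknown scan config key {key!r}")
    return ScanConfig(**kwargs)


def read_scan_config(path) -> ScanConfig:
    with Path(path).open("rb") as fh:
        data = tomllib.load(fh)
    return scan_config_from_dict(data)


def write_ground_truth(path, truth) -> None:
    doc = {
        "per_leaf_area_mm2": np.asarray(truth.per_leaf_area).tolist(),
        "total_area_mm2": float(truth.total_area),
        "per_leaf_inclination_deg": np.asarray(
            truth.per_leaf_inclination).tolist(),
        "lad": np.asarray(truth.angular_distribution).tolist(),
    }
    Path(path).write_text(json.dumps(doc, indent=2, sort_keys=True) + "\n")


def write_json(path, obj) -> None:
    Path(path).write_text(json.dumps(obj, indent=2, sort_keys=True) + "\n")
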