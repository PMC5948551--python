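"""Instrument coordinate system and polar-to-Cartesian conversion.

The instrument is a side-looking 2-D LiDAR profiler facing a precision
rotation stage.  The vertical scanning plane of the LiDAR passing through
the stage center at stage angle ``phi = 0`` is the XZ plane; the stage
center is the origin and Z points up.  A return at range ``R`` (mm), beam
elevation ``theta`` (rad, 0 = horizontal, positive = upward) and stage
angle ``phi`` (rad) maps to

    X = (D - R cos(theta)) cos(phi)
    Y = (D - R cos(theta)) sin(phi)
    Z = h + R sin(theta)

where ``D`` is the horizontal LiDAR-to-stage-center distance and ``h`` the
LiDAR height above the stage plane.  All lengths are millimetres, all
angles radians; the CLI accepts degrees and converts at the boundary.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Iterable, Iterator

import numpy as np

logger = logging.getLogger("lidarleaf")

TWO_PI = 2.0 * math.pi


class ValidationError(ValueError):
    """Raised when an input violates a documented precondition."""


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ScanConfig:
    """Geometry and timing of one turntable-LiDAR acquisition.

    Parameters
    ----------
    lidar_distance_D : float
        Horizontal distance from the LiDAR to the rotation-stage center, mm.
    lidar_height_h : float
        Height of the LiDAR scan origin above the stage plane, mm.
    scan_frequency : float
        Vertical sweep rate of the LiDAR, Hz (the instrument runs at 25 Hz).
    beam_angular_interval : float
        Elevation step between consecutive beams within a sweep, rad
        (0.0029 rad at 25 Hz).
    start_angle, stop_angle : float
        Elevation swath limits, rad, each in (-pi/2, pi/2).
    rotation_speed : float
        Stage rotation speed, degrees/s (3 deg/s in routine use).
    scan_start_time : float
        Offset between stage motion start and first sweep, s.
    """

    lidar_distance_D: float = 1200.0
    lidar_height_h: float = 400.0
    scan_frequency: float = 25.0
    beam_angular_interval: float = 0.0029
    start_angle: float = -0.5
    stop_angle: float = 0.7
    rotation_speed: float = 3.0
    scan_start_time: float = 0.0

    def __post_init__(self) -> None:
        if not (self.lidar_distance_D > 0):
            raise ValidationError("lidar_distance_D must be positive")
        if not (self.scan_frequency > 0):
            raise ValidationError("scan_frequency must be positive")
        if not (self.rotation_speed > 0):
            raise ValidationError("rotation_speed must be positive")
        if not (self.beam_angular_interval > 0):
            raise ValidationError("beam_angular_interval must be positive")
        if not (self.start_angle < self.stop_angle):
            raise ValidationError("start_angle must be < stop_angle")
        half_pi = math.pi / 2
        if not (-half_pi < self.start_angle and self.stop_angle < half_pi):
            raise ValidationError("swath angles must lie within (-pi/2, pi/2)")

    @property
    def rotation_speed_rad(self) -> float:
        """Stage speed in rad/s."""
        return math.radians(self.rotation_speed)

    def beam_angles(self) -> np.ndarray:
        """Elevation grid of one sweep, start to stop inclusive."""
        n = int(math.floor((self.stop_angle - self.start_angle)
                           / self.beam_angular_interval + 1e-9)) + 1
        return self.start_angle + self.beam_angular_interval * np.arange(n)


@dataclass(frozen=True)
class PolarRecord:
    """One LiDAR return: range plus beam and stage angles."""

    range_R: float
    beam_angle_theta: float
    stage_angle_phi: float
    sweep_index: int = 0
    sample_index: int = 0

    def __post_init__(self) -> None:
        vals = (self.range_R, self.beam_angle_theta, self.stage_angle_phi)
        if not all(math.isfinite(v) for v in vals):
            raise ValidationError("polar record fields must be finite")
        if self.range_R < 0:
            raise ValidationError("range_R must be non-negative")


class PolarScan:
    """Column-oriented batch of :class:`PolarRecord` (one full acquisition)."""

    def __init__(self, range_R, beam_angle_theta, stage_angle_phi,
                 sweep_index=None, sample_index=None) -> None:
        self.range_R = np.asarray(range_R, dtype=float)
        self.beam_angle_theta = np.asarray(beam_angle_theta, dtype=float)
        self.stage_angle_phi = np.mod(
            np.asarray(stage_angle_phi, dtype=float), TWO_PI)
        n = self.range_R.size
        if self.beam_angle_theta.size != n or self.stage_angle_phi.size != n:
            raise ValidationError("polar scan columns must have equal length")
        if not (np.all(np.isfinite(self.range_R))
                and np.all(np.isfinite(self.beam_angle_theta))
                and np.all(np.isfinite(self.stage_angle_phi))):
            raise ValidationError("polar scan columns must be finite")
        if n and self.range_R.min() < 0:
            raise ValidationError("range_R must be non-negative")
        self.sweep_index = (np.zeros(n, dtype=int) if sweep_index is None
                            else np.asarray(sweep_index, dtype=int))
        self.sample_index = (np.zeros(n, dtype=int) if sample_index is None
                             else np.asarray(sample_index, dtype=int))

    def __len__(self) -> int:
        return int(self.range_R.size)

    def __iter__(self) -> Iterator[PolarRecord]:
        for i in range(len(self)):
            yield PolarRecord(float(self.range_R[i]),
                              float(self.beam_angle_theta[i]),
                              float(self.stage_angle_phi[i]),
                              int(self.sweep_index[i]),
                              int(self.sample_index[i]))

    @classmethod
    def from_records(cls, records: Iterable[PolarRecord]) -> "PolarScan":
        recs = list(records)
        return cls([r.range_R for r in recs],
                   [r.beam_angle_theta for r in recs],
                   [r.stage_angle_phi for r in recs],
                   [r.sweep_index for r in recs],
                   [r.sample_index for r in recs])


@dataclass
class PointCloud:
    """Unordered 3-D points (mm) in the stage-centered frame, optional labels."""

    points: np.ndarray
    labels: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.points = np.asarray(self.points, dtype=float).reshape(-1, 3)
        if self.labels is not None:
            self.labels = np.asarray(self.labels, dtype=int).ravel()
            if self.labels.size != self.points.shape[0]:
                raise ValidationError(
                    "label count must equal point count")

    def __len__(self) -> int:
        return int(self.points.shape[0])

    @classmethod
    def empty(cls) -> "PointCloud":
        return cls(np.empty((0, 3)))

    def select(self, mask_or_indices) -> "PointCloud":
        """Subset cloud, carrying labels along."""
        pts = self.points[mask_or_indices]
        lab = None if self.labels is None else self.labels[mask_or_indices]
        return PointCloud(pts, lab)


# ---------------------------------------------------------------------------
# Operations
# ---------------------------------------------------------------------------

def polar_to_cartesian(record: PolarRecord, config: ScanConfig):
    """Convert one polar return to a Cartesian point (X, Y, Z) in mm."""
    D, h = config.lidar_distance_D, config.lidar_height_h
    r, th, ph = record.range_R, record.beam_angle_theta, record.stage_angle_phi
    radial = D - r * math.cos(th)
    return (radial * math.cos(ph), radial * math.sin(ph),
            h + r * math.sin(th))


def assign_stage_angle(sweep_index: int, config: ScanConfig) -> float:
    """Stage angle phi (rad, in [0, 2pi)) at the start of a given sweep.

    The stage rotates continuously; phi accumulates from the scan start time
    at the configured speed, one sweep every ``1/scan_frequency`` seconds.
    """
    if sweep_index < 0:
        raise ValidationError("sweep_index must be non-negative")
    t = sweep_index / config.scan_frequency + config.scan_start_time
    return math.fmod(config.rotation_speed_rad * t, TWO_PI)


def radial_resolution(config: ScanConfig) -> float:
    """Azimuthal angle swept by the stage between consecutive sweeps, rad."""
    return config.rotation_speed_rad / config.scan_frequency


def vertical_sampling_spacing(config: ScanConfig, target_range: float) -> float:
    """Arc spacing (mm) between adjacent beams at a given range (mm).

    Small-angle arc length: beam interval times range, e.g. 0.0029 rad at
    1000 mm gives 2.9 mm between adjacent returns on a surface.
    """
    if not (target_range > 0):
        raise ValidationError("target_range must be positive")
    return config.beam_angular_interval * target_range


def full_rotation_duration(config: ScanConfig) -> float:
    """Seconds for one complete 360-degree stage rotation."""
    return 360.0 / config.rotation_speed


def convert_scan(records, config: ScanConfig) -> PointCloud:
    """Convert a batch of polar records into an unlabeled point cloud.

    ``records`` may be a :class:`PolarScan` (vectorized path) or any iterable
    of :class:`PolarRecord`.  Order is preserved, one point per record.
    """
    if not isinstance(records, PolarScan):
        records = PolarScan.from_records(records)
    if len(records) == 0:
        return PointCloud.empty()
    D, h = config.lidar_distance_D, config.lidar_height_h
    radial = D - records.range_R * np.cos(records.beam_angle_theta)
    x = radial * np.cos(records.stage_angle_phi)
    y = radial * np.sin(records.stage_angle_phi)
    z = h + records.range_R * np.sin(records.beam_angle_theta)
    return PointCloud(np.column_stack([x, y, z]))
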