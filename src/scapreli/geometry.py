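"""Scapula coordinate systems and 3D scapular orientation.

The ISB scapula frame is built from the AA/IA/TS triplet: Z runs from AA to
TS (medially for a right-convention scapula), X is the unit normal of the
AA-IA-TS plane pointing anteriorly, and Y = Z x X points superiorly.  For
each scapula, an *average* frame built from the mean landmarks re-expresses
every digitization in a common coordinate system, so dispersion across
observers and measures can be compared.  Because no thorax landmarks are
available in shoulder CT volumes, the average frame is placed at a fixed
published resting scapulothoracic orientation (41.1 deg protraction,
5.4 deg medial rotation, 13.5 deg anterior tilt); per-measure frames are
then decomposed against that thorax frame with a mobile-axis YXZ Euler
sequence into e1 (retraction/protraction), e2 (lateral/medial rotation) and
e3 (internal/external rotation).
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Iterable

import numpy as np

from .exceptions import DegenerateGeometryError, GimbalLockError, ValidationError
from .landmark_io import (
    CoordinateSpace,
    LandmarkTriplet,
    MeasurementRecord,
    as_point,
)

ORTHONORMALITY_TOL = 1e-9
DEFAULT_AREA_EPSILON = 1.0  # mm^2; smaller triangles are digitization failures
DEFAULT_GIMBAL_TOL = 1e-9


@dataclass(frozen=True)
class Frame:
    """Proper rotation + origin; columns of R are the X, Y, Z axis vectors."""

    R: np.ndarray
    origin: np.ndarray

    def __post_init__(self) -> None:
        R = np.asarray(self.R, dtype=float)
        if R.shape != (3, 3):
            raise ValueError(f"R must be 3x3, got {R.shape}")
        object.__setattr__(self, "R", R)
        object.__setattr__(self, "origin", as_point(self.origin, "origin"))
        if np.max(np.abs(R.T @ R - np.eye(3))) > ORTHONORMALITY_TOL * 10:
            raise ValidationError("frame axes are not orthonormal")
        if abs(np.linalg.det(R) - 1.0) > 1e-8:
            raise ValidationError(f"frame is not a proper rotation (det={np.linalg.det(R)})")

    @property
    def x_axis(self) -> np.ndarray:
        return self.R[:, 0]

    @property
    def y_axis(self) -> np.ndarray:
        return self.R[:, 1]

    @property
    def z_axis(self) -> np.ndarray:
        return self.R[:, 2]

    def to_local(self, p: np.ndarray) -> np.ndarray:
        """World -> frame coordinates: R^T (p - origin)."""
        return self.R.T @ (np.asarray(p, dtype=float) - self.origin)

    def to_world(self, p: np.ndarray) -> np.ndarray:
        return self.R @ np.asarray(p, dtype=float) + self.origin


@dataclass(frozen=True)
class ThoraxPose:
    """Resting scapulothoracic orientation (degrees)."""

    protraction_deg: float = 41.1
    medial_rotation_deg: float = 5.4
    anterior_tilt_deg: float = 13.5

    def __post_init__(self) -> None:
        for v in (self.protraction_deg, self.medial_rotation_deg, self.anterior_tilt_deg):
            if not -180.0 < v <= 180.0:
                raise ValueError(f"pose angle {v} outside (-180, 180]")


DEFAULT_THORAX_POSE = ThoraxPose()


@dataclass(frozen=True)
class OrientationAngles:
    """YXZ Euler triplet, degrees.

    e1 retraction/protraction, e2 lateral/medial rotation, e3
    internal/external rotation (the field's conventional labels; the third
    thorax-pose component is conventionally called anterior tilt).
    """

    e1_deg: float
    e2_deg: float
    e3_deg: float

    def as_array(self) -> np.ndarray:
        return np.array([self.e1_deg, self.e2_deg, self.e3_deg])


MeanLandmarks = LandmarkTriplet  # mean AA/IA/TS across observers and measures


def mean_landmarks(records: Iterable[MeasurementRecord]) -> MeanLandmarks:
    """Per-landmark arithmetic mean across all records of one scapula."""
    records = list(records)
    if not records:
        raise ValueError("mean_landmarks needs at least one record")
    spaces = {r.coordinate_space for r in records}
    if len(spaces) != 1:
        raise ValidationError(f"records mix coordinate spaces: {sorted(s.value for s in spaces)}")
    stacks = np.stack([r.landmarks.as_array() for r in records])  # (n, 3 landmarks, 3)
    mAA, mIA, mTS = stacks.mean(axis=0)
    return LandmarkTriplet(mAA, mIA, mTS)


def build_scapula_frame(
    triplet: LandmarkTriplet, area_epsilon: float = DEFAULT_AREA_EPSILON
) -> Frame:
    """ISB scapula frame from an AA/IA/TS triplet (right-side convention).

    Z = unit(TS - AA) (pointing medially); X = unit normal of the landmark
    plane pointing anteriorly, realized as unit(cross(TS - AA, IA - AA));
    Y = Z x X (pointing superiorly).  Origin at AA.  The canonical template
    (AA at origin, TS on +Z, IA in the Y-Z plane with negative Y) maps to
    the identity rotation.
    """
    if triplet.triangle_area() <= area_epsilon:
        raise DegenerateGeometryError(
            f"AA/IA/TS triangle area {triplet.triangle_area():.3g} mm^2 "
            f"<= epsilon {area_epsilon} mm^2"
        )
    z = triplet.TS - triplet.AA
    z = z / np.linalg.norm(z)
    x = np.cross(triplet.TS - triplet.AA, triplet.IA - triplet.AA)
    x = x / np.linalg.norm(x)
    y = np.cross(z, x)
    R = np.column_stack([x, y, z])
    # re-orthogonalize against accumulated rounding before the strict check
    u, _, vt = np.linalg.svd(R)
    return Frame(u @ vt, triplet.AA)


def to_average_cs(record: MeasurementRecord, avg_frame: Frame) -> MeasurementRecord:
    """Re-express an imaging-space record in the average scapula frame."""
    if record.coordinate_space != CoordinateSpace.IMAGING:
        raise ValidationError(f"expected imaging-space record, got {record.coordinate_space}")
    moved = record.landmarks.transformed(avg_frame.to_local)
    return replace(record, landmarks=moved, coordinate_space=CoordinateSpace.AVERAGE_SCAPULA)


def from_average_cs(record: MeasurementRecord, avg_frame: Frame) -> MeasurementRecord:
    """Inverse of :func:`to_average_cs` (round trip exact to 1e-9 mm)."""
    if record.coordinate_space != CoordinateSpace.AVERAGE_SCAPULA:
        raise ValidationError("expected average-scapula-space record")
    moved = record.landmarks.transformed(avg_frame.to_world)
    return replace(record, landmarks=moved, coordinate_space=CoordinateSpace.IMAGING)


def _rot_x(a: float) -> np.ndarray:
    c, s = np.cos(a), np.sin(a)
    return np.array([[1, 0, 0], [0, c, -s], [0, s, c]])


def _rot_y(a: float) -> np.ndarray:
    c, s = np.cos(a), np.sin(a)
    return np.array([[c, 0, s], [0, 1, 0], [-s, 0, c]])


def _rot_z(a: float) -> np.ndarray:
    c, s = np.cos(a), np.sin(a)
    return np.array([[c, -s, 0], [s, c, 0], [0, 0, 1]])


def euler_yxz_compose(angles: OrientationAngles) -> Frame:
    """Mobile-axis Y -> X' -> Z'' rotation: R = Ry(e1) Rx(e2) Rz(e3)."""
    e1, e2, e3 = np.deg2rad(angles.as_array())
    return Frame(_rot_y(e1) @ _rot_x(e2) @ _rot_z(e3), np.zeros(3))


def euler_yxz_extract(frame: Frame, gimbal_tol: float = DEFAULT_GIMBAL_TOL) -> OrientationAngles:
    """Decompose a proper rotation into mobile-axis YXZ angles (degrees).

    For R = Ry(e1) Rx(e2) Rz(e3): R[1,2] = -sin(e2), R[0,2]/R[2,2] carry e1
    and R[1,0]/R[1,1] carry e3.  Near |e2| = 90 deg the decomposition is
    singular; that raises :class:`GimbalLockError` rather than returning an
    arbitrary e1/e3 split.
    """
    R = frame.R
    s2 = -R[1, 2]
    if abs(s2) >= 1.0 - gimbal_tol:
        raise GimbalLockError(
            f"YXZ extraction singular: |R[1,2]| = {abs(R[1, 2]):.12f} within "
            f"{gimbal_tol} of 1 (e2 -> +/-90 deg)"
        )
    e2 = np.arcsin(s2)
    e1 = np.arctan2(R[0, 2], R[2, 2])
    e3 = np.arctan2(R[1, 0], R[1, 1])
    return OrientationAngles(*np.rad2deg([e1, e2, e3]))


def thorax_rotation(pose: ThoraxPose = DEFAULT_THORAX_POSE) -> Frame:
    """Rotation from the average scapula frame to the thorax frame.

    The three successive rotations (protraction, medial rotation, anterior
    tilt) compose in the same mobile-axis YXZ sequence used for extraction;
    positive pose values map identically onto the signed (e1, e2, e3).
    """
    return euler_yxz_compose(
        OrientationAngles(pose.protraction_deg, pose.medial_rotation_deg, pose.anterior_tilt_deg)
    )


def apply_thorax_rotation(record: MeasurementRecord, r_acs_tcs: Frame) -> MeasurementRecord:
    """Rotate average-scapula coordinates into the thorax frame: p -> R p."""
    if record.coordinate_space != CoordinateSpace.AVERAGE_SCAPULA:
        raise ValidationError(f"expected average-scapula record, got {record.coordinate_space}")
    moved = record.landmarks.transformed(lambda p: r_acs_tcs.R @ p)
    return replace(record, landmarks=moved, coordinate_space=CoordinateSpace.THORAX)


def scapular_orientation(
    record: MeasurementRecord,
    area_epsilon: float = DEFAULT_AREA_EPSILON,
    gimbal_tol: float = DEFAULT_GIMBAL_TOL,
) -> OrientationAngles:
    """Orientation of one digitization's scapula frame in the thorax frame.

    The record must already be in thorax space (mean landmarks -> average
    frame -> thorax rotation applied); the per-measure frame built from its
    triplet *is* the scapula-to-thorax rotation, decomposed via YXZ.
    """
    if record.coordinate_space != CoordinateSpace.THORAX:
        raise ValidationError(f"expected thorax-space record, got {record.coordinate_space}")
    frame = build_scapula_frame(record.landmarks, area_epsilon=area_epsilon)
    return euler_yxz_extract(frame, gimbal_tol=gimbal_tol)
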