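"""Deterministic landmark positioning strategies on annotated edge polylines.

Two of the three ISB landmarks have operational rules that can be executed
on a digitized bone-edge curve: the acromial angle (AA) is the first angle
greater than 45 degrees walking along the lateral edge of the acromion, and
the inferior angle (IA) is the most distal point along the medial edge of
the scapula.  The trigonum spinae rule ("apex of the root triangle") has no
comparable curve-level definition and is not automated; synthetic datasets
carry TS ground truth directly.

These operators serve as executable ground truth for the synthetic data
module and let acromion morphologies with no clear angle (curved
transitions) be represented as explicit detection failures.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from enum import Enum

import numpy as np

from .exceptions import LandmarkNotFoundError

MIN_SEGMENT_LENGTH = 1e-6  # mm


class PolylineRole(str, Enum):
    LATERAL_ACROMION_EDGE = "lateral_acromion_edge"
    MEDIAL_EDGE = "medial_edge"


class AmbiguousAngleWarning(UserWarning):
    """More than one vertex exceeds the AA threshold (multi-angle acromion)."""


@dataclass(frozen=True)
class EdgePolyline:
    """Ordered bone-edge curve; vertex 0 is the anatomical start.

    For the acromion edge that is the anterior tip; for the medial edge the
    superior end.
    """

    vertices: np.ndarray  # (n, 3) mm
    role: PolylineRole

    def __post_init__(self) -> None:
        v = np.asarray(self.vertices, dtype=float)
        if v.ndim != 2 or v.shape[1] != 3 or v.shape[0] < 3:
            raise ValueError(f"polyline needs >= 3 points of dim 3, got shape {v.shape}")
        if not np.all(np.isfinite(v)):
            raise ValueError("polyline has non-finite vertices")
        seg = np.linalg.norm(np.diff(v, axis=0), axis=1)
        if np.any(seg <= MIN_SEGMENT_LENGTH):
            raise ValueError("consecutive polyline vertices coincide")
        object.__setattr__(self, "vertices", v)
        object.__setattr__(self, "role", PolylineRole(self.role))


def turning_angles(polyline: EdgePolyline) -> np.ndarray:
    """Turning angle (deg) at each interior vertex.

    180 deg minus the interior angle between the incoming and outgoing
    segments; a straight continuation scores 0.  Unsigned, isometry
    invariant.
    """
    v = polyline.vertices
    d = np.diff(v, axis=0)
    d = d / np.linalg.norm(d, axis=1, keepdims=True)
    cosang = np.clip(np.sum(d[:-1] * d[1:], axis=1), -1.0, 1.0)
    return np.rad2deg(np.arccos(cosang))


def detect_AA(polyline: EdgePolyline, threshold_deg: float = 45.0) -> np.ndarray:
    """First interior vertex whose turning angle strictly exceeds the threshold.

    Walks from vertex 0 (the anterior tip of the lateral acromion edge).
    Raises :class:`LandmarkNotFoundError` when no angle exceeds the
    threshold -- the curved-transition morphology with no clear angle.
    Warns with :class:`AmbiguousAngleWarning` when several vertices exceed
    it (multi-angle morphology); the first is still returned.
    """
    if polyline.role != PolylineRole.LATERAL_ACROMION_EDGE:
        raise ValueError(f"detect_AA needs a lateral_acromion_edge polyline, got {polyline.role}")
    angles = turning_angles(polyline)
    exceed = np.flatnonzero(angles > threshold_deg)
    if exceed.size == 0:
        raise LandmarkNotFoundError(
            f"no turning angle exceeds {threshold_deg} deg "
            f"(max {angles.max():.2f} deg): no clear acromial angle"
        )
    if exceed.size > 1:
        warnings.warn(
            f"{exceed.size} vertices exceed the {threshold_deg} deg threshold; "
            "returning the first",
            AmbiguousAngleWarning,
            stacklevel=2,
        )
    return polyline.vertices[exceed[0] + 1]  # interior vertex i has angle index i-1


def detect_IA(polyline: EdgePolyline, distal_direction: np.ndarray) -> np.ndarray:
    """Most distal vertex of the medial edge along ``distal_direction``.

    Ties (equal projections) resolve to the lowest vertex index.
    """
    if polyline.role != PolylineRole.MEDIAL_EDGE:
        raise ValueError(f"detect_IA needs a medial_edge polyline, got {polyline.role}")
    d = np.asarray(distal_direction, dtype=float)
    n = np.linalg.norm(d)
    if not np.isfinite(n) or abs(n - 1.0) > 1e-6:
        raise ValueError("distal_direction must be a unit vector")
    proj = polyline.vertices @ d
    return polyline.vertices[int(np.argmax(proj))]
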