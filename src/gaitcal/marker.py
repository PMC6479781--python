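"""Marker-based (reference system) lower-limb joint kinematics.

Segment frames follow the anatomical basis of :mod:`gaitcal.geometry`
(x lateral-right, y anterior, z superior).  Joint angles use the mobile
Euler sequence flexion -> adduction -> internal rotation; knee flexion and
ankle flexion are the sagittal terms of the same decomposition with
clinical signs (knee flexion positive; ankle positive = toe-down rotation
relative to the static standing posture, see README).

Medial knee/ankle markers may be absent during gait: they are then
reconstructed as segment-fixed points from the thigh/shank cluster markers
using a rigid (Kabsch) fit against the static calibration trial.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import NamedTuple, Optional

import numpy as np

from .errors import DegenerateGeometryError, InputError, MissingLandmarkError
from .geometry import decompose_xyz, kabsch, unit, wrap_angle
from .prep import DOF_NAMES, AngleSeries, LandmarkSeries

_COLLINEAR_TOL = 1e-10


@dataclass
class SegmentFrame:
    """Origin plus right-handed orthonormal axes for one body segment."""

    origin: np.ndarray
    x: np.ndarray
    y: np.ndarray
    z: np.ndarray

    def __post_init__(self):
        self.origin = np.asarray(self.origin, dtype=float)
        self.x = np.asarray(self.x, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        self.z = np.asarray(self.z, dtype=float)
        R = self.matrix
        if not np.allclose(R.T @ R, np.eye(3), atol=1e-9):
            raise InputError("segment axes must be orthonormal")
        if np.linalg.det(R) < 0:
            raise InputError("segment axes must be right-handed")

    @property
    def matrix(self) -> np.ndarray:
        """Axes as columns, expressed in the lab frame."""
        return np.column_stack([self.x, self.y, self.z])

    @classmethod
    def from_matrix(cls, origin: np.ndarray, R: np.ndarray) -> "SegmentFrame":
        return cls(origin, R[:, 0], R[:, 1], R[:, 2])


@dataclass
class HipCenterModel:
    """Hip joint center as fractions of the inter-ASIS distance.

    Offsets are applied along the pelvis x (lateral, sign flipped for the
    left side), y (anterior) and z (superior) axes from the pelvis origin.
    Defaults follow the Bell-style regression commonly used in gait labs;
    the model is configuration, never hard-coded downstream.
    """

    lateral: float = 0.36
    anterior: float = -0.19
    superior: float = -0.30

    def __post_init__(self):
        for v in (self.lateral, self.anterior, self.superior):
            if not np.isfinite(v):
                raise InputError("hip center offsets must be finite")


class EulerAngles(NamedTuple):
    flexion: float
    adduction: float
    rotation: float
    gimbal: bool


# ---------------------------------------------------------------------------
# segment frames
# ---------------------------------------------------------------------------

def pelvis_frame_marker(asis_l, asis_r, sacrum) -> SegmentFrame:
    """Pelvis frame from the two ASIS markers and the sacrum.

    Origin: midpoint between the mid-ASIS point and the sacrum.  x runs
    from the mid-ASIS point toward the right ASIS; z is the superior
    normal of the ASIS-sacrum plane; y = z cross x (anterior).
    """
    asis_l = np.asarray(asis_l, dtype=float)
    asis_r = np.asarray(asis_r, dtype=float)
    sacrum = np.asarray(sacrum, dtype=float)
    mid_asis = 0.5 * (asis_l + asis_r)
    origin = 0.5 * (mid_asis + sacrum)
    dx = asis_r - mid_asis
    dsac = sacrum - mid_asis
    n = np.cross(dsac, dx)
    scale = max(np.linalg.norm(dx), np.linalg.norm(dsac))
    if np.linalg.norm(n) < _COLLINEAR_TOL * max(scale, 1.0) ** 2:
        raise DegenerateGeometryError(
            "ASIS and sacrum markers are collinear; pelvis frame undefined")
    x = unit(dx)
    z = unit(n)
    y = np.cross(z, x)
    return SegmentFrame(origin, x, y, z)


def hip_joint_center(frame: SegmentFrame, inter_asis: float,
                     model: HipCenterModel, side: str = "right") -> np.ndarray:
    """Hip joint center from the pelvis frame and inter-ASIS distance."""
    if side not in ("right", "left"):
        raise InputError("side must be 'right' or 'left'")
    if inter_asis <= 0:
        raise InputError("inter-ASIS distance must be positive")
    lat = model.lateral if side == "right" else -model.lateral
    return (frame.origin
            + inter_asis * (lat * frame.x
                            + model.anterior * frame.y
                            + model.superior * frame.z))


def thigh_frame_marker(knee_lat, knee_med, hip_center) -> SegmentFrame:
    """Thigh frame: origin mid-knee, z toward the hip center, y anterior
    normal of the (hip, lateral knee, medial knee) plane."""
    knee_lat = np.asarray(knee_lat, dtype=float)
    knee_med = np.asarray(knee_med, dtype=float)
    hip_center = np.asarray(hip_center, dtype=float)
    origin = 0.5 * (knee_lat + knee_med)
    zv = hip_center - origin
    lat = knee_lat - knee_med
    n = np.cross(zv, lat)
    if np.linalg.norm(n) < _COLLINEAR_TOL:
        raise DegenerateGeometryError(
            "hip center and knee markers are collinear; thigh frame undefined")
    z = unit(zv)
    y = unit(n)
    x = np.cross(y, z)
    return SegmentFrame(origin, x, y, z)


def shank_frame_marker(ankle_lat, ankle_med, thigh_origin) -> SegmentFrame:
    """Shank frame: origin mid-ankle, z toward the thigh origin."""
    ankle_lat = np.asarray(ankle_lat, dtype=float)
    ankle_med = np.asarray(ankle_med, dtype=float)
    thigh_origin = np.asarray(thigh_origin, dtype=float)
    origin = 0.5 * (ankle_lat + ankle_med)
    zv = thigh_origin - origin
    lat = ankle_lat - ankle_med
    n = np.cross(zv, lat)
    if np.linalg.norm(n) < _COLLINEAR_TOL:
        raise DegenerateGeometryError(
            "thigh origin and ankle markers are collinear; shank frame undefined")
    z = unit(zv)
    y = unit(n)
    x = np.cross(y, z)
    return SegmentFrame(origin, x, y, z)


def foot_frame_marker(toe, heel, shank_origin) -> SegmentFrame:
    """Foot frame: origin at the 2nd metatarsal marker, long (y) axis toward
    the shank origin, x the lateral normal of the (heel, toe, shank-origin)
    plane, z = x cross y."""
    toe = np.asarray(toe, dtype=float)
    heel = np.asarray(heel, dtype=float)
    shank_origin = np.asarray(shank_origin, dtype=float)
    yv = shank_origin - toe
    hv = heel - toe
    n = np.cross(yv, hv)
    if np.linalg.norm(n) < _COLLINEAR_TOL:
        raise DegenerateGeometryError(
            "heel, toe and shank origin are collinear; foot frame undefined")
    y = unit(yv)
    x = unit(n)
    z = np.cross(x, y)
    return SegmentFrame(toe, x, y, z)


# ---------------------------------------------------------------------------
# Euler decomposition
# ---------------------------------------------------------------------------

def euler_joint_angles(proximal: SegmentFrame, distal: SegmentFrame) -> EulerAngles:
    """Mobile-axis flexion/adduction/rotation decomposition.

    Decomposes ``R = proximal.T @ distal`` as ``Rx(flexion) @ Ry(adduction)
    @ Rz(rotation)`` (degrees).  Gimbal proximity (|adduction| > 89 deg) is
    flagged, never raised.
    """
    R = proximal.matrix.T @ distal.matrix
    a, b, c, gimbal = decompose_xyz(R)
    return EulerAngles(float(a), float(b), float(c), bool(gimbal))


# ---------------------------------------------------------------------------
# full pipeline
# ---------------------------------------------------------------------------

_GAIT_REQUIRED = ("sacrum", "l_asis", "r_asis", "r_heel", "r_toe")
_STATIC_REQUIRED = _GAIT_REQUIRED + (
    "r_knee_lat", "r_knee_med", "r_ankle_lat", "r_ankle_med")
_THIGH_CLUSTER = tuple(f"r_thigh_{i}" for i in range(1, 5))
_SHANK_CLUSTER = tuple(f"r_shank_{i}" for i in range(1, 5))


def _static_mean(static: LandmarkSeries, name: str) -> np.ndarray:
    return static.landmarks[name].mean(axis=0)


def _reconstruct_from_cluster(static: LandmarkSeries, gait: LandmarkSeries,
                              cluster: tuple, targets: tuple) -> dict:
    """Rigid-fit cluster markers frame-by-frame and carry target markers
    along as cluster-fixed points calibrated in the static trial."""
    present = [m for m in cluster if m in gait.landmarks]
    if len(present) < 3:
        raise MissingLandmarkError(
            " / ".join(m for m in cluster if m not in gait.landmarks),
            gait.dialect)
    static.require(present)
    ref = np.stack([_static_mean(static, m) for m in present])     # (m, 3)
    tgt_static = np.stack([_static_mean(static, m) for m in targets])
    n = gait.n_frames
    out = {name: np.empty((n, 3)) for name in targets}
    clouds = np.stack([gait.landmarks[m] for m in present], axis=1)  # (n, m, 3)
    for i in range(n):
        R, t = kabsch(ref, clouds[i])
        moved = tgt_static @ R.T + t
        for j, name in enumerate(targets):
            out[name][i] = moved[j]
    return out


def compute_marker_angles(series: LandmarkSeries, static: LandmarkSeries,
                          model: Optional[HipCenterModel] = None) -> AngleSeries:
    """Five-DOF right-limb joint angles from a prepared marker series.

    ``series`` should already be uniformly sampled (and filtered if
    desired); this function performs no signal conditioning.  Medial and
    lateral knee/ankle markers are taken from the trial when present and
    otherwise reconstructed from the cluster markers via the static trial.
    The ankle channel is referenced to the static standing posture.
    """
    if series.dialect != "marker" or static.dialect != "marker":
        raise InputError("compute_marker_angles expects marker-dialect series")
    model = model or HipCenterModel()
    series.require(_GAIT_REQUIRED)
    static.require(_STATIC_REQUIRED)

    lm = dict(series.landmarks)
    if "r_knee_lat" not in lm or "r_knee_med" not in lm:
        lm.update(_reconstruct_from_cluster(
            static, series, _THIGH_CLUSTER, ("r_knee_lat", "r_knee_med")))
    if "r_ankle_lat" not in lm or "r_ankle_med" not in lm:
        lm.update(_reconstruct_from_cluster(
            static, series, _SHANK_CLUSTER, ("r_ankle_lat", "r_ankle_med")))

    ankle_offset = _static_ankle_offset(static, model)

    n = series.n_frames
    values = np.empty((n, 5))
    for i in range(n):
        values[i] = _frame_angles(
            {k: v[i] for k, v in lm.items()}, model, ankle_offset)
    return AngleSeries(series.time, values, DOF_NAMES)


def _frame_angles(p: dict, model: HipCenterModel, ankle_offset: float) -> np.ndarray:
    pelvis = pelvis_frame_marker(p["l_asis"], p["r_asis"], p["sacrum"])
    inter_asis = float(np.linalg.norm(p["r_asis"] - p["l_asis"]))
    hip = hip_joint_center(pelvis, inter_asis, model, "right")
    thigh = thigh_frame_marker(p["r_knee_lat"], p["r_knee_med"], hip)
    shank = shank_frame_marker(p["r_ankle_lat"], p["r_ankle_med"], thigh.origin)
    foot = foot_frame_marker(p["r_toe"], p["r_heel"], shank.origin)
    hip_ang = euler_joint_angles(pelvis, thigh)
    knee_ang = euler_joint_angles(thigh, shank)
    foot_ang = euler_joint_angles(shank, foot)
    return np.array([
        hip_ang.flexion,
        hip_ang.adduction,
        hip_ang.rotation,
        -knee_ang.flexion,
        wrap_angle(ankle_offset - foot_ang.flexion),
    ])


def _static_ankle_offset(static: LandmarkSeries, model: HipCenterModel) -> float:
    """Sagittal shank-to-foot Euler angle in the static standing posture."""
    p = {name: _static_mean(static, name) for name in _STATIC_REQUIRED}
    pelvis = pelvis_frame_marker(p["l_asis"], p["r_asis"], p["sacrum"])
    inter_asis = float(np.linalg.norm(p["r_asis"] - p["l_asis"]))
    hip = hip_joint_center(pelvis, inter_asis, model, "right")
    thigh = thigh_frame_marker(p["r_knee_lat"], p["r_knee_med"], hip)
    shank = shank_frame_marker(p["r_ankle_lat"], p["r_ankle_med"], thigh.origin)
    foot = foot_frame_marker(p["r_toe"], p["r_heel"], shank.origin)
    return euler_joint_angles(shank, foot).flexion
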