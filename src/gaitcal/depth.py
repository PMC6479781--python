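"""Depth-sensor (skeleton landmark) lower-limb joint kinematics.

The reduced landmark set supports a pelvis frame, a thigh frame, hip Euler
angles and scalar vector-angles at the knee and ankle.  The thigh frame
needs the ankle landmark because only two thigh-fixed landmarks exist; it
degenerates when hip, knee and ankle are exactly collinear, in which case
the previous frame's plane normal is carried forward.
"""

from __future__ import annotations

from typing import Optional

import numpy as np

from .errors import DegenerateGeometryError, InputError
from .geometry import angle_between, decompose_xyz, unit
from .marker import EulerAngles, SegmentFrame
from .prep import DOF_NAMES, AngleSeries, LandmarkSeries

_DEGENERATE_SIN = 1e-8


def pelvis_frame_kinect(spine_base, spine_mid, hip_l, hip_r) -> SegmentFrame:
    """Pelvis frame from spine and hip landmarks.

    Origin at the spine base; y superior along spine base -> spine mid;
    x = y cross (hip left -> hip right), re-normalized; z = x cross y.
    In an upright pose x is anterior and z points to the subject's right.
    """
    spine_base = np.asarray(spine_base, dtype=float)
    spine_mid = np.asarray(spine_mid, dtype=float)
    hip_l = np.asarray(hip_l, dtype=float)
    hip_r = np.asarray(hip_r, dtype=float)
    if np.linalg.norm(spine_mid - spine_base) < 1e-12:
        raise DegenerateGeometryError("spine mid coincides with spine base")
    y = unit(spine_mid - spine_base)
    lat = unit(hip_r - hip_l)
    xv = np.cross(y, lat)
    if np.linalg.norm(xv) < _DEGENERATE_SIN:
        raise DegenerateGeometryError(
            "spine axis is parallel to the hip line; pelvis frame undefined")
    x = unit(xv)
    z = np.cross(x, y)
    return SegmentFrame(spine_base, x, y, z)


def thigh_frame_kinect(hip_r, knee_r, ankle_r,
                       prev_z: Optional[np.ndarray] = None) -> SegmentFrame:
    """Right thigh frame from hip, knee and ankle landmarks.

    Origin at the knee; y along knee -> hip; z = y cross (ankle -> knee)
    normalized; x = y cross z.  With a straight leg (collinear landmarks)
    the plane normal is undefined: ``prev_z`` from the previous frame is
    carried forward when given, otherwise the degeneracy raises.
    """
    hip_r = np.asarray(hip_r, dtype=float)
    knee_r = np.asarray(knee_r, dtype=float)
    ankle_r = np.asarray(ankle_r, dtype=float)
    y = unit(hip_r - knee_r)
    zv = np.cross(y, knee_r - ankle_r)
    nz = np.linalg.norm(zv)
    if nz < _DEGENERATE_SIN * np.linalg.norm(knee_r - ankle_r):
        if prev_z is None:
            raise DegenerateGeometryError(
                "hip, knee and ankle are collinear and no previous frame "
                "is available")
        zv = prev_z - np.dot(prev_z, y) * y
        if np.linalg.norm(zv) < _DEGENERATE_SIN:
            raise DegenerateGeometryError(
                "carried-forward thigh axis is parallel to the segment")
    z = unit(zv)
    x = np.cross(y, z)
    return SegmentFrame(knee_r, x, y, z)


def _to_anatomical(frame: SegmentFrame, segment: str) -> np.ndarray:
    """Re-map a depth-sensor frame onto the anatomical basis
    (x right, y anterior, z superior) used by the Euler machinery."""
    if segment == "pelvis":
        return np.column_stack([frame.z, frame.x, frame.y])
    if segment == "thigh":
        return np.column_stack([-frame.z, -frame.x, frame.y])
    raise InputError(f"unknown segment {segment!r}")


def hip_angles_kinect(pelvis: SegmentFrame, thigh: SegmentFrame) -> EulerAngles:
    """Hip Euler angles (flexion, adduction, rotation) in degrees.

    Uses the identical mobile-axis decomposition as the marker pipeline
    after re-mapping both depth-sensor frames onto the shared anatomical
    basis, so both systems agree exactly on identical segment poses.
    """
    P = _to_anatomical(pelvis, "pelvis")
    T = _to_anatomical(thigh, "thigh")
    a, b, c, gimbal = decompose_xyz(P.T @ T)
    return EulerAngles(float(a), float(b), float(c), bool(gimbal))


def knee_angle_kinect(hip_r, knee_r, ankle_r) -> float:
    """Knee flexion as the supplement of the hip->knee / knee->ankle angle.

    0 deg for a perfectly straight leg, increasing with flexion.
    """
    hip_r = np.asarray(hip_r, dtype=float)
    knee_r = np.asarray(knee_r, dtype=float)
    ankle_r = np.asarray(ankle_r, dtype=float)
    return float(180.0 - angle_between(hip_r - knee_r, ankle_r - knee_r))


def ankle_angle_kinect(knee_r, ankle_r, foot_r) -> float:
    """Ankle angle: (ankle->knee vs ankle->foot angle) minus 90 deg.

    0 deg when the foot vector is perpendicular to the shank.  With the
    package's axis conventions positive values correspond to a toe-down
    (plantar-directed) rotation; the same signed quantity is produced by
    the marker pipeline, so the two systems are directly comparable.
    """
    knee_r = np.asarray(knee_r, dtype=float)
    ankle_r = np.asarray(ankle_r, dtype=float)
    foot_r = np.asarray(foot_r, dtype=float)
    return float(angle_between(knee_r - ankle_r, foot_r - ankle_r) - 90.0)


_REQUIRED = ("spine_base", "spine_mid", "hip_l", "hip_r",
             "knee_r", "ankle_r", "foot_r")


def compute_kinect_angles(series: LandmarkSeries) -> AngleSeries:
    """Five-DOF right-limb angles from a prepared depth-sensor series.

    The series must be uniformly resampled (and filtered if desired)
    beforehand.  Thigh-frame degeneracies fall back to the previous
    frame's plane normal; a degenerate first frame raises.
    """
    if series.dialect != "depth":
        raise InputError("compute_kinect_angles expects a depth-dialect series")
    series.require(_REQUIRED)
    t = series.time
    if t.size >= 2:
        dt = np.diff(t)
        if not np.allclose(dt, dt[0], rtol=1e-6, atol=1e-9):
            raise InputError(
                "nonuniform sampling: call resample_uniform before computing "
                "depth-sensor angles")
    lm = series.landmarks
    n = series.n_frames
    values = np.empty((n, 5))
    prev_z = None
    for i in range(n):
        pelvis = pelvis_frame_kinect(lm["spine_base"][i], lm["spine_mid"][i],
                                     lm["hip_l"][i], lm["hip_r"][i])
        thigh = thigh_frame_kinect(lm["hip_r"][i], lm["knee_r"][i],
                                   lm["ankle_r"][i], prev_z=prev_z)
        prev_z = thigh.z
        hip = hip_angles_kinect(pelvis, thigh)
        values[i, 0] = hip.flexion
        values[i, 1] = hip.adduction
        values[i, 2] = hip.rotation
        values[i, 3] = knee_angle_kinect(lm["hip_r"][i], lm["knee_r"][i],
                                         lm["ankle_r"][i])
        values[i, 4] = ankle_angle_kinect(lm["knee_r"][i], lm["ankle_r"][i],
                                          lm["foot_r"][i])
    return AngleSeries(t, values, DOF_NAMES)
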