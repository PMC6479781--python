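"""Synthetic gait generator for both measurement streams.

Ground-truth joint-angle profiles are truncated Fourier series in cycle
fraction.  Marker and depth-sensor landmark trajectories are produced by a
forward kinematic chain built from the very frame definitions the analysis
modules use, so on noiseless data the analysis pipelines invert the
generator exactly (up to interpolation error).

The default profiles are cosine-only (even in cycle fraction), which pins
the peak anterior foot excursion - the initial-contact detector's signal -
exactly at the cycle boundary.

The depth stream applies a per-DOF affine (optionally cubic) distortion to
the true angles before landmark synthesis, then adds landmark noise,
timestamp jitter and frame dropout.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Dict, Optional, Tuple

import numpy as np
from scipy.interpolate import CubicSpline

from .errors import ConfigurationError
from .geometry import NEUTRAL_AXES, compose_xyz, rot_x
from .marker import HipCenterModel, hip_joint_center, pelvis_frame_marker
from .prep import DOF_NAMES, LandmarkSeries


@dataclass(frozen=True)
class FourierSeries:
    """Truncated Fourier series a0 + sum_k (a_k cos(2 pi k phi) + b_k sin(...))."""

    a0: float = 0.0
    cos: Tuple[float, ...] = ()
    sin: Tuple[float, ...] = ()

    def __post_init__(self):
        if len(self.cos) > 4 or len(self.sin) > 4:
            raise ConfigurationError("Fourier order is limited to 4")

    def __call__(self, phi: np.ndarray) -> np.ndarray:
        phi = np.asarray(phi, dtype=float)
        out = np.full(phi.shape, self.a0)
        for k, a in enumerate(self.cos, start=1):
            out = out + a * np.cos(2.0 * np.pi * k * phi)
        for k, b in enumerate(self.sin, start=1):
            out = out + b * np.sin(2.0 * np.pi * k * phi)
        return out


def default_profiles() -> Dict[str, FourierSeries]:
    """Qualitatively gait-like default angle profiles (degrees).

    Hip flexion peaks (~35 deg) at initial contact and extends to ~5 deg
    mid-cycle; knee moves 5-55 deg; the remaining DOFs are small.
    """
    return {
        "hip_flexion": FourierSeries(20.0, (15.0,)),
        "hip_adduction": FourierSeries(2.0, (4.0, -1.0)),
        "hip_rotation": FourierSeries(0.0, (-3.0, 2.0)),
        "knee_flexion": FourierSeries(30.0, (-25.0,)),
        "ankle_flexion": FourierSeries(-2.0, (6.0, -3.0)),
    }


@dataclass
class GaitProfileConfig:
    """Everything needed to synthesize one subject's gait trials."""

    cadence: float = 112.0              # steps/min; stride period = 120/cadence
    n_cycles: int = 3
    profiles: Dict[str, FourierSeries] = field(default_factory=default_profiles)
    pelvis_width: float = 0.24          # inter-ASIS distance, m
    thigh_length: float = 0.40
    shank_length: float = 0.38
    foot_length: float = 0.15
    seed: int = 0
    walking_speed: float = 1.0          # m/s, pelvis advance (cosmetic)
    pelvis_height: float = 0.85
    sample_rate: float = 100.0
    pad_cycles: float = 0.25            # lead-in/out so every IC is interior
    hip_model: HipCenterModel = field(default_factory=HipCenterModel)

    def __post_init__(self):
        if self.cadence <= 0:
            raise ConfigurationError("cadence must be positive")
        if self.n_cycles < 1:
            raise ConfigurationError("n_cycles must be >= 1")
        for name in ("pelvis_width", "thigh_length", "shank_length",
                     "foot_length"):
            if getattr(self, name) <= 0:
                raise ConfigurationError(f"{name} must be positive")
        missing = [d for d in DOF_NAMES if d not in self.profiles]
        if missing:
            raise ConfigurationError(f"profiles missing DOFs: {missing}")

    @property
    def stride_period(self) -> float:
        return 120.0 / self.cadence


@dataclass
class DistortionConfig:
    """Systematic + stochastic corruption of the depth-sensor stream.

    ``gains`` / ``offsets`` / ``cubic`` apply per DOF to the true angles
    (deg): ``g * x + o + c * x**3``.  ``noise_sd`` is isotropic landmark
    position noise (m); ``jitter_sd`` perturbs the nominally uniform
    timestamps (s, clipped to keep time strictly increasing); ``dropout``
    drops frames independently.
    """

    gains: Tuple[float, ...] = (1.0,) * 5
    offsets: Tuple[float, ...] = (0.0,) * 5
    cubic: Tuple[float, ...] = (0.0,) * 5
    noise_sd: float = 0.0
    jitter_sd: float = 0.0
    rate: float = 30.0
    dropout: float = 0.0

    def __post_init__(self):
        for name in ("gains", "offsets", "cubic"):
            v = np.asarray(getattr(self, name), dtype=float)
            if v.shape != (5,) or not np.all(np.isfinite(v)):
                raise ConfigurationError(f"{name} must be 5 finite values")
        if np.any(np.asarray(self.gains) == 0.0):
            raise ConfigurationError("gains must be nonzero")
        if self.noise_sd < 0 or self.jitter_sd < 0:
            raise ConfigurationError("noise SDs must be >= 0")
        if not 0.0 <= self.dropout < 1.0:
            raise ConfigurationError("dropout must be in [0, 1)")
        if self.rate <= 0:
            raise ConfigurationError("rate must be positive")

    def apply(self, angles: np.ndarray) -> np.ndarray:
        g = np.asarray(self.gains)
        o = np.asarray(self.offsets)
        c = np.asarray(self.cubic)
        return g * angles + o + c * angles ** 3


@dataclass
class TrueAngles:
    """Ground-truth five-DOF right-limb angle trajectories."""

    time: np.ndarray
    values: np.ndarray                   # (N, 5), degrees, DOF_NAMES order
    ic_times: np.ndarray                 # initial contacts, s

    def __post_init__(self):
        self.time = np.asarray(self.time, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        self.ic_times = np.asarray(self.ic_times, dtype=float)
        if not np.all(np.diff(self.time) > 0):
            raise ConfigurationError("time must be strictly increasing")
        if self.values.shape != (self.time.size, 5):
            raise ConfigurationError("values must be (n_samples, 5)")
        if (self.ic_times.min() < self.time[0] - 1e-9
                or self.ic_times.max() > self.time[-1] + 1e-9):
            raise ConfigurationError("IC times must lie within the trial")


def generate_true_angles(cfg: GaitProfileConfig) -> TrueAngles:
    """Sample the configured angle profiles at the marker rate.

    Initial contacts sit at exact cycle boundaries; the trial is padded by
    ``pad_cycles`` strides on both sides so every contact is interior.
    """
    T = cfg.stride_period
    duration = (cfg.n_cycles + 2.0 * cfg.pad_cycles) * T
    dt = 1.0 / cfg.sample_rate
    time = np.arange(int(np.floor(duration / dt + 1e-9)) + 1) * dt
    phi = time / T - cfg.pad_cycles
    values = np.column_stack([cfg.profiles[d](phi) for d in DOF_NAMES])
    ic = cfg.pad_cycles * T + np.arange(cfg.n_cycles + 1) * T
    return TrueAngles(time, values, ic)


# ---------------------------------------------------------------------------
# forward kinematic chain
# ---------------------------------------------------------------------------

# marker placements local to the designed pelvis frame (m)
_MID_ASIS_ANT = 0.09
_SACRUM_POST = 0.12
_SPINE_MID_UP = 0.25
_KNEE_HALF_WIDTH = 0.05
_ANKLE_HALF_WIDTH = 0.04
_FOOT_DROP = 0.05
_HEEL_BACK = 0.06

# thigh / shank cluster marker positions local to the segment frame,
# relative to the distal joint center, as fractions of segment length
_CLUSTER_LOCAL = np.array([
    [0.060, 0.040, 0.45],
    [0.070, -0.020, 0.40],
    [0.050, 0.050, 0.33],
    [0.080, 0.000, 0.25],
])


def _pelvis_points(cfg: GaitProfileConfig, time: np.ndarray):
    """Pelvis-fixed marker positions plus the analysis pelvis frame."""
    xp, yp, zp = NEUTRAL_AXES[:, 0], NEUTRAL_AXES[:, 1], NEUTRAL_AXES[:, 2]
    O = (cfg.walking_speed * time)[:, None] * np.array([1.0, 0.0, 0.0]) \
        + cfg.pelvis_height * np.array([0.0, 1.0, 0.0])
    mid_asis = O + _MID_ASIS_ANT * yp
    pts = {
        "r_asis": mid_asis + 0.5 * cfg.pelvis_width * xp,
        "l_asis": mid_asis - 0.5 * cfg.pelvis_width * xp,
        "sacrum": O - _SACRUM_POST * yp,
    }
    # analysis pelvis origin (midpoint of mid-ASIS and sacrum); axes are the
    # neutral anatomical axes by construction of the coplanar marker layout
    origin = 0.5 * (mid_asis + pts["sacrum"])
    return pts, origin


def _hip_centers(cfg: GaitProfileConfig, origin: np.ndarray):
    frame_proto = pelvis_frame_marker(
        [-0.5 * cfg.pelvis_width, _MID_ASIS_ANT, 0.0],
        [0.5 * cfg.pelvis_width, _MID_ASIS_ANT, 0.0],
        [0.0, -_SACRUM_POST, 0.0])
    # offsets of the hip centers from the pelvis origin, in pelvis axes
    local = {}
    for side in ("right", "left"):
        p = hip_joint_center(frame_proto, cfg.pelvis_width, cfg.hip_model, side)
        local[side] = (p - frame_proto.origin) @ frame_proto.matrix
    out = {}
    for side in ("right", "left"):
        lx, ly, lz = local[side]
        out[side] = (origin + lx * NEUTRAL_AXES[:, 0]
                     + ly * NEUTRAL_AXES[:, 1] + lz * NEUTRAL_AXES[:, 2])
    return out


def _right_leg_chain(cfg: GaitProfileConfig, hip_r: np.ndarray,
                     angles: np.ndarray):
    """Joint centers and segment orientation matrices for the right leg.

    ``angles`` is (N, 5) in DOF_NAMES order.  Returns dict of points and
    the (N, 3, 3) thigh/shank/foot orientations.
    """
    hf, ha, hr, knee, ankle = (angles[:, i] for i in range(5))
    T = NEUTRAL_AXES @ compose_xyz(hf, ha, hr)
    K = hip_r - cfg.thigh_length * T[..., :, 2]
    S = T @ rot_x(-knee)
    A = K - cfg.shank_length * S[..., :, 2]
    F = S @ rot_x(-ankle)
    return {"knee": K, "ankle": A, "thigh": T, "shank": S, "foot": F}


def _marker_set(cfg: GaitProfileConfig, time: np.ndarray,
                angles: np.ndarray) -> Dict[str, np.ndarray]:
    pts, origin = _pelvis_points(cfg, time)
    hips = _hip_centers(cfg, origin)
    chain = _right_leg_chain(cfg, hips["right"], angles)
    T, S, F = chain["thigh"], chain["shank"], chain["foot"]
    K, A = chain["knee"], chain["ankle"]
    pts["r_knee_lat"] = K + _KNEE_HALF_WIDTH * T[..., :, 0]
    pts["r_knee_med"] = K - _KNEE_HALF_WIDTH * T[..., :, 0]
    pts["r_ankle_lat"] = A + _ANKLE_HALF_WIDTH * S[..., :, 0]
    pts["r_ankle_med"] = A - _ANKLE_HALF_WIDTH * S[..., :, 0]
    pts["r_toe"] = (A + cfg.foot_length * F[..., :, 1]
                    - _FOOT_DROP * F[..., :, 2])
    pts["r_heel"] = (A - _HEEL_BACK * F[..., :, 1]
                     - _FOOT_DROP * F[..., :, 2])
    for i, local in enumerate(_CLUSTER_LOCAL, start=1):
        lx, ly, lz = local
        pts[f"r_thigh_{i}"] = (K + lx * T[..., :, 0] + ly * T[..., :, 1]
                               + lz * cfg.thigh_length * T[..., :, 2])
        pts[f"r_shank_{i}"] = (A + lx * S[..., :, 0] + ly * S[..., :, 1]
                               + lz * cfg.shank_length * S[..., :, 2])
    return pts


def forward_markers(angles: TrueAngles, cfg: GaitProfileConfig,
                    noise_sd: float = 0.0) -> LandmarkSeries:
    """Marker-dialect landmark trajectories at the marker sampling rate.

    Noiseless output is exactly invertible by
    :func:`gaitcal.marker.compute_marker_angles`.
    """
    if noise_sd < 0:
        raise ConfigurationError("noise_sd must be >= 0")
    pts = _marker_set(cfg, angles.time, angles.values)
    if noise_sd > 0:
        rng = np.random.default_rng([cfg.seed, 1])
        for name in sorted(pts):
            pts[name] = pts[name] + rng.normal(0.0, noise_sd, pts[name].shape)
    return LandmarkSeries("marker", angles.time.copy(), pts,
                          nominal_rate=cfg.sample_rate)


def forward_markers_static(cfg: GaitProfileConfig, duration: float = 0.5,
                           noise_sd: float = 0.0) -> LandmarkSeries:
    """Static calibration trial: neutral standing pose, all angles zero."""
    n = max(int(round(duration * cfg.sample_rate)), 4)
    time = np.arange(n) / cfg.sample_rate
    static_cfg = replace(cfg, walking_speed=0.0)
    pts = _marker_set(static_cfg, time, np.zeros((n, 5)))
    if noise_sd > 0:
        rng = np.random.default_rng([cfg.seed, 2])
        for name in sorted(pts):
            pts[name] = pts[name] + rng.normal(0.0, noise_sd, pts[name].shape)
    return LandmarkSeries("marker", time, pts, nominal_rate=cfg.sample_rate)


def forward_kinect(angles: TrueAngles, cfg: GaitProfileConfig,
                   dist: DistortionConfig) -> LandmarkSeries:
    """Depth-dialect landmark trajectories at a jittered ~``dist.rate`` Hz.

    True angles are interpolated to the depth timestamps, distorted per
    DOF, and pushed through the same forward chain; landmark noise and
    frame dropout are then applied.  Deterministic given ``cfg.seed``.
    """
    rng = np.random.default_rng([cfg.seed, 3])
    t0, t1 = angles.time[0], angles.time[-1]
    n_nom = int(np.floor((t1 - t0) * dist.rate + 1e-9)) + 1
    t = t0 + np.arange(n_nom) / dist.rate
    if dist.jitter_sd > 0:
        jit = rng.normal(0.0, dist.jitter_sd, n_nom)
        lim = 0.45 / dist.rate
        t = t + np.clip(jit, -lim, lim)
        t = np.clip(t, t0, t1)
    keep = np.ones(n_nom, dtype=bool)
    if dist.dropout > 0:
        keep = rng.random(n_nom) >= dist.dropout
        if keep.sum() < 2:
            keep[:2] = True
    t = t[keep]

    true_at_t = CubicSpline(angles.time, angles.values, axis=0)(t)
    distorted = dist.apply(true_at_t)

    _, origin = _pelvis_points(cfg, t)
    hips = _hip_centers(cfg, origin)
    chain = _right_leg_chain(cfg, hips["right"], distorted)
    S, A = chain["shank"], chain["ankle"]
    foot_dir = (S @ rot_x(-distorted[:, 4]))[..., :, 1]
    pts = {
        "spine_base": origin,
        "spine_mid": origin + _SPINE_MID_UP * NEUTRAL_AXES[:, 2],
        "hip_r": hips["right"],
        "hip_l": hips["left"],
        "knee_r": chain["knee"],
        "ankle_r": A,
        "foot_r": A + cfg.foot_length * foot_dir,
    }
    if dist.noise_sd > 0:
        for name in sorted(pts):
            pts[name] = pts[name] + rng.normal(0.0, dist.noise_sd,
                                               pts[name].shape)
    return LandmarkSeries("depth", t, pts, nominal_rate=dist.rate)


def vary_profile(cfg: GaitProfileConfig, rng: np.random.Generator,
                 amp_scale: float = 0.15, offset_sd: float = 2.0,
                 seed: Optional[int] = None) -> GaitProfileConfig:
    """Perturb a subject's Fourier profile (cosine terms only, preserving
    the even symmetry that anchors initial contact at the cycle boundary)."""
    profiles = {}
    for name, fs in cfg.profiles.items():
        cos = tuple(a * (1.0 + rng.uniform(-amp_scale, amp_scale))
                    for a in fs.cos)
        a0 = fs.a0 + rng.normal(0.0, offset_sd)
        profiles[name] = FourierSeries(a0, cos, fs.sin)
    return replace(cfg, profiles=profiles,
                   seed=cfg.seed if seed is None else seed)
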