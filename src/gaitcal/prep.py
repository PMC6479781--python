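"""Shared time-series types plus resampling, filtering and cycle normalization.

All positions are meters in the lab frame (+X walking direction, +Y up,
+Z right), angles are degrees, time is seconds.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import numpy as np
from scipy.interpolate import CubicSpline
from scipy.signal import butter, filtfilt

from .errors import InputError

#: canonical joint-angle channel order used everywhere downstream
DOF_NAMES: Tuple[str, ...] = (
    "hip_flexion",
    "hip_adduction",
    "hip_rotation",
    "knee_flexion",
    "ankle_flexion",
)

MARKER_DIALECT = "marker"
DEPTH_DIALECT = "depth"

#: canonical marker-based vocabulary (modified Cleveland set, right limb)
MARKER_NAMES = frozenset(
    ["sacrum", "l_asis", "r_asis",
     "r_knee_lat", "r_knee_med", "r_ankle_lat", "r_ankle_med",
     "r_heel", "r_toe"]
    + [f"r_thigh_{i}" for i in range(1, 5)]
    + [f"r_shank_{i}" for i in range(1, 5)]
)

#: canonical depth-sensor vocabulary (subset of the 25-landmark skeleton)
DEPTH_NAMES = frozenset([
    "spine_base", "spine_mid", "spine_shoulder", "head", "neck",
    "hip_l", "hip_r", "knee_l", "knee_r",
    "ankle_l", "ankle_r", "foot_l", "foot_r",
])

_VOCABULARY = {MARKER_DIALECT: MARKER_NAMES, DEPTH_DIALECT: DEPTH_NAMES}


@dataclass
class LandmarkSeries:
    """Timestamped named 3D point trajectories from either measurement system.

    ``landmarks`` maps canonical names to (N, 3) position arrays sharing
    ``time`` (strictly increasing, possibly nonuniform for the depth
    dialect).
    """

    dialect: str
    time: np.ndarray
    landmarks: Dict[str, np.ndarray]
    nominal_rate: float

    def __post_init__(self):
        self.time = np.asarray(self.time, dtype=float)
        if self.dialect not in _VOCABULARY:
            raise InputError(f"unknown dialect {self.dialect!r}")
        if self.time.ndim != 1:
            raise InputError("time must be one-dimensional")
        if self.time.size >= 2 and not np.all(np.diff(self.time) > 0):
            raise InputError("time stamps must be strictly increasing")
        vocab = _VOCABULARY[self.dialect]
        n = self.time.size
        for name in list(self.landmarks):
            if name not in vocab:
                raise InputError(
                    f"landmark {name!r} not in the {self.dialect} vocabulary")
            arr = np.asarray(self.landmarks[name], dtype=float)
            if arr.shape != (n, 3):
                raise InputError(
                    f"landmark {name!r} has shape {arr.shape}, "
                    f"expected {(n, 3)}")
            if not np.all(np.isfinite(arr)):
                raise InputError(f"landmark {name!r} contains non-finite values")
            self.landmarks[name] = arr

    @property
    def n_frames(self) -> int:
        return self.time.size

    @property
    def names(self) -> List[str]:
        return sorted(self.landmarks)

    def require(self, names: Iterable[str]) -> None:
        for name in names:
            if name not in self.landmarks:
                from .errors import MissingLandmarkError

                raise MissingLandmarkError(name, self.dialect)

    def copy(self) -> "LandmarkSeries":
        return LandmarkSeries(
            dialect=self.dialect,
            time=self.time.copy(),
            landmarks={k: v.copy() for k, v in self.landmarks.items()},
            nominal_rate=self.nominal_rate,
        )


@dataclass
class AngleSeries:
    """Uniformly sampled joint-angle trajectories (degrees)."""

    time: np.ndarray
    values: np.ndarray          # (N, D)
    dof_names: Tuple[str, ...] = DOF_NAMES

    def __post_init__(self):
        self.time = np.asarray(self.time, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        self.dof_names = tuple(self.dof_names)
        if self.values.ndim != 2 or self.values.shape[0] != self.time.size:
            raise InputError("values must be (n_samples, n_dof)")
        if self.values.shape[1] != len(self.dof_names):
            raise InputError("dof_names length does not match values")
        if not np.all(np.isfinite(self.values)):
            raise InputError("angle values must be finite")
        if self.time.size >= 2:
            dt = np.diff(self.time)
            if not np.all(dt > 0):
                raise InputError("time must be strictly increasing")
            if not np.allclose(dt, dt[0], rtol=1e-6, atol=1e-9):
                raise InputError("AngleSeries requires a uniform time step")

    @property
    def rate(self) -> float:
        if self.time.size < 2:
            raise InputError("need at least two samples to infer a rate")
        return 1.0 / (self.time[1] - self.time[0])

    def slice_time(self, t0: float, t1: float) -> "AngleSeries":
        m = (self.time >= t0) & (self.time <= t1)
        return AngleSeries(self.time[m], self.values[m], self.dof_names)


def _uniform_grid(t0: float, t1: float, rate: float) -> np.ndarray:
    n = int(np.floor((t1 - t0) * rate + 1e-9)) + 1
    return t0 + np.arange(n) / rate


def resample_uniform(series: LandmarkSeries, rate: float,
                     max_gap: Optional[float] = 0.2) -> LandmarkSeries:
    """Resample a landmark series onto a uniform grid at ``rate`` Hz.

    Cubic interpolation per coordinate over [t0, tN].  Gaps (missing
    frames) longer than ``max_gap`` seconds invalidate the segment and
    raise; pass ``max_gap=None`` to disable the check.
    """
    if series.n_frames < 2:
        raise InputError("resampling needs at least 2 frames")
    if rate <= 0:
        raise InputError("rate must be positive")
    t = series.time
    if max_gap is not None:
        worst = np.max(np.diff(t))
        nominal_dt = 1.0 / series.nominal_rate
        if worst > max(max_gap, 2.0 * nominal_dt):
            raise InputError(
                f"gap of {worst:.3f}s exceeds the {max_gap:.3f}s fill limit; "
                "trial segment is invalid")
    grid = _uniform_grid(t[0], t[-1], rate)
    out: Dict[str, np.ndarray] = {}
    for name, pos in series.landmarks.items():
        out[name] = CubicSpline(t, pos, axis=0)(grid)
    return LandmarkSeries(series.dialect, grid, out, nominal_rate=rate)


def butterworth_lowpass(signal, cutoff: float = 6.0, order: int = 4):
    """Zero-phase low-pass Butterworth filter (forward-backward pass).

    Accepts an :class:`AngleSeries` or a :class:`LandmarkSeries` and
    returns the same type.  The design order is applied in each direction,
    so the effective attenuation is that of a 2 x ``order`` filter; DC is
    preserved exactly.  Input must be uniformly sampled -- resample first.
    """
    if isinstance(signal, AngleSeries):
        rate = signal.rate
        _check_filter(rate, cutoff)
        b, a = butter(order, cutoff / (rate / 2.0))
        vals = filtfilt(b, a, signal.values, axis=0)
        return AngleSeries(signal.time, vals, signal.dof_names)
    if isinstance(signal, LandmarkSeries):
        t = signal.time
        if t.size < 2:
            raise InputError("filtering needs at least 2 frames")
        dt = np.diff(t)
        if not np.allclose(dt, dt[0], rtol=1e-6, atol=1e-9):
            raise InputError(
                "nonuniform sampling: call resample_uniform before filtering")
        rate = 1.0 / dt[0]
        _check_filter(rate, cutoff)
        b, a = butter(order, cutoff / (rate / 2.0))
        out = {name: filtfilt(b, a, pos, axis=0)
               for name, pos in signal.landmarks.items()}
        return LandmarkSeries(signal.dialect, t.copy(), out, signal.nominal_rate)
    raise InputError(f"cannot filter object of type {type(signal).__name__}")


def _check_filter(rate: float, cutoff: float) -> None:
    if rate <= 2.0 * cutoff:
        raise InputError(
            f"sampling rate {rate:.1f} Hz must exceed twice the "
            f"{cutoff:.1f} Hz cutoff")


@dataclass
class AngleCycle:
    """One gait cycle of joint angles on the closed 0..100% grid (101 rows)."""

    values: np.ndarray                      # (101, D), degrees
    dof_names: Tuple[str, ...] = DOF_NAMES
    trial_id: Optional[str] = None
    day: Optional[int] = None

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        self.dof_names = tuple(self.dof_names)
        if self.values.ndim != 2 or self.values.shape[0] != 101:
            raise InputError("an AngleCycle holds exactly 101 rows")
        if self.values.shape[1] != len(self.dof_names):
            raise InputError("dof_names length does not match values")
        if not np.all(np.isfinite(self.values)):
            raise InputError("cycle values must be finite")


def normalize_cycle(segment: AngleSeries, trial_id: Optional[str] = None,
                    day: Optional[int] = None) -> AngleCycle:
    """Map one cycle's angle segment onto the closed 0..100% grid.

    Cubic interpolation on cycle fraction; rows 0 and 100 equal the
    segment's endpoint values exactly.
    """
    if segment.time.size < 4:
        raise InputError("cycle segment needs at least 4 samples")
    frac = (segment.time - segment.time[0]) / (segment.time[-1] - segment.time[0])
    grid = np.linspace(0.0, 1.0, 101)
    out = CubicSpline(frac, segment.values, axis=0)(grid)
    out[0] = segment.values[0]
    out[-1] = segment.values[-1]
    return AngleCycle(out, segment.dof_names, trial_id=trial_id, day=day)


def average_cycles(cycles: Sequence[AngleCycle]) -> Tuple[AngleCycle, np.ndarray]:
    """Pointwise mean cycle and SD across cycles (SD is 0 for one cycle)."""
    if len(cycles) == 0:
        raise InputError("average_cycles needs at least one cycle")
    names = cycles[0].dof_names
    if any(c.dof_names != names for c in cycles):
        raise InputError("cycles must share the same DOF set")
    stack = np.stack([c.values for c in cycles])
    mean = stack.mean(axis=0)
    sd = stack.std(axis=0, ddof=1) if stack.shape[0] > 1 else np.zeros_like(mean)
    return AngleCycle(mean, names, trial_id=cycles[0].trial_id,
                      day=cycles[0].day), sd
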