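"""Initial-contact detection, cycle segmentation and discrete parameters.

Initial contacts are detected coordinate-style (Zeni-like): local maxima
of the foot landmark's anterior displacement relative to the pelvis
center.  The rule is threshold-free; the minimum peak spacing is half the
stride estimate taken from the signal's dominant period.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Optional, Sequence, Tuple

import numpy as np
from scipy.interpolate import CubicSpline
from scipy.signal import find_peaks

from .errors import InputError, MissingLandmarkError
from .prep import AngleCycle, AngleSeries, LandmarkSeries, resample_uniform

# AngleCycle is re-exported here as part of this module's public surface
__all__ = [
    "AngleCycle", "DiscreteParams", "detect_initial_contacts",
    "segment_and_normalize", "extract_discrete_params", "pair_events",
]

_FOOT_PREFERENCE = {
    "marker": ("r_toe", "r_heel"),
    "depth": ("foot_r", "ankle_r"),
}
_PELVIS_PREFERENCE = {
    "marker": (("l_asis", "r_asis"), ("sacrum",)),
    "depth": (("spine_base",),),
}


@dataclass
class DiscreteParams:
    """Per-DOF max, min, ROM and angle at initial contact for one cycle."""

    dof_names: Tuple[str, ...]
    maximum: np.ndarray
    minimum: np.ndarray
    rom: np.ndarray
    initial_contact: np.ndarray

    def __post_init__(self):
        for name in ("maximum", "minimum", "rom", "initial_contact"):
            setattr(self, name, np.asarray(getattr(self, name), dtype=float))
        if np.any(self.rom < -1e-12):
            raise InputError("ROM must be non-negative")


def _event_signal(series: LandmarkSeries, side: str):
    if side != "right":
        raise InputError("only right-limb event detection is implemented")
    foot_name = next((n for n in _FOOT_PREFERENCE[series.dialect]
                      if n in series.landmarks), None)
    if foot_name is None:
        raise MissingLandmarkError(
            " or ".join(_FOOT_PREFERENCE[series.dialect]), series.dialect)
    pelvis = None
    for group in _PELVIS_PREFERENCE[series.dialect]:
        if all(n in series.landmarks for n in group):
            pelvis = np.mean([series.landmarks[n] for n in group], axis=0)
            break
    if pelvis is None:
        raise MissingLandmarkError("pelvis-center landmarks", series.dialect)
    # anterior (lab +X) displacement of the foot relative to the pelvis
    return series.landmarks[foot_name][:, 0] - pelvis[:, 0]


def _dominant_period(signal: np.ndarray, dt: float) -> float:
    """Dominant period via the power spectrum (ignoring near-DC bins)."""
    x = signal - signal.mean()
    freqs = np.fft.rfftfreq(x.size, dt)
    power = np.abs(np.fft.rfft(x)) ** 2
    valid = freqs > 0.2          # gait strides are slower than 5 Hz
    if not np.any(valid) or np.all(power[valid] <= 0):
        raise InputError("signal too short to estimate a stride period")
    f = freqs[valid][np.argmax(power[valid])]
    return 1.0 / f


def detect_initial_contacts(series: LandmarkSeries,
                            side: str = "right") -> np.ndarray:
    """Initial-contact event times for the chosen limb.

    Deterministic; raises :class:`InputError` when fewer than one full
    cycle (two contacts) can be found, e.g. for a standing trial.
    """
    if series.n_frames < 8:
        raise InputError("too few frames for event detection")
    work = series
    dts = np.diff(series.time)
    if not np.allclose(dts, dts[0], rtol=1e-6, atol=1e-9):
        work = resample_uniform(series, series.nominal_rate)
    s = _event_signal(work, side)
    dt = work.time[1] - work.time[0]
    if np.ptp(s) < 1e-4:
        raise InputError("no gait cycles detected (stationary trial)")
    period = _dominant_period(s, dt)
    distance = max(int(round(0.5 * period / dt)), 1)
    peaks, _ = find_peaks(s, distance=distance, prominence=0.05 * np.ptp(s))
    if peaks.size < 2:
        raise InputError("fewer than one full gait cycle detected")
    return work.time[peaks]


def segment_and_normalize(angles: AngleSeries, events: Sequence[float],
                          trial_id: Optional[str] = None,
                          day: Optional[int] = None) -> List[AngleCycle]:
    """One time-normalized cycle per consecutive event pair.

    Each DOF is interpolated (cubic) from the full series onto the
    101-point grid between the two events, so cycle endpoints equal the
    angle values at the event times.
    """
    events = np.asarray(events, dtype=float)
    if events.size < 2:
        raise InputError("need at least two events to cut a cycle")
    if np.any(np.diff(events) <= 0):
        raise InputError("event times must be strictly increasing")
    t0, t1 = angles.time[0], angles.time[-1]
    if events[0] < t0 - 1e-9 or events[-1] > t1 + 1e-9:
        raise InputError("events fall outside the angle series")
    spline = CubicSpline(angles.time, angles.values, axis=0)
    cycles = []
    for e0, e1 in zip(events[:-1], events[1:]):
        grid = np.linspace(e0, e1, 101)
        cycles.append(AngleCycle(spline(grid), angles.dof_names,
                                 trial_id=trial_id, day=day))
    return cycles


def extract_discrete_params(cycle: AngleCycle) -> DiscreteParams:
    """Per-DOF maximum, minimum, ROM and value at initial contact (0%)."""
    vmax = cycle.values.max(axis=0)
    vmin = cycle.values.min(axis=0)
    return DiscreteParams(cycle.dof_names, vmax, vmin, vmax - vmin,
                          cycle.values[0].copy())


def pair_events(events_a: np.ndarray, events_b: np.ndarray,
                tol: Optional[float] = None) -> List[Tuple[int, int]]:
    """Match two systems' event lists by temporal proximity.

    Robust to a missed event on either side.  ``tol`` defaults to half
    the median stride of the first list.
    """
    events_a = np.asarray(events_a, dtype=float)
    events_b = np.asarray(events_b, dtype=float)
    if tol is None:
        if events_a.size < 2:
            raise InputError("cannot infer pairing tolerance from one event")
        tol = 0.5 * float(np.median(np.diff(events_a)))
    pairs = []
    used = set()
    for i, ta in enumerate(events_a):
        j = int(np.argmin(np.abs(events_b - ta))) if events_b.size else -1
        if j >= 0 and j not in used and abs(events_b[j] - ta) <= tol:
            pairs.append((i, j))
            used.add(j)
    return pairs
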