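"""File readers/writers, configuration and the end-to-end pipeline.

Canonical internal units are meters, degrees and seconds; conversions
happen at the I/O boundary.  Marker trajectories use TRC or wide CSV;
depth-sensor landmarks use wide CSV (mandatory per-frame timestamps,
nonuniform allowed) or JSON.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence

import numpy as np
import pandas as pd
import yaml

from .calibrate import (GaitTensor, apply_linear_calibration,
                        apply_lstm_calibrator, build_gait_tensor,
                        fit_linear_calibration, train_lstm_calibrator)
from .depth import compute_kinect_angles
from .errors import InputError, MissingLandmarkError
from .events import detect_initial_contacts, pair_events, segment_and_normalize
from .marker import HipCenterModel, compute_marker_angles
from .prep import (DEPTH_DIALECT, MARKER_DIALECT, LandmarkSeries,
                   butterworth_lowpass, resample_uniform)
from .stats import reliability_report, validity_report

log = logging.getLogger("gaitcal")

_UNIT_SCALE = {"m": 1.0, "mm": 0.001, "cm": 0.01}


def _apply_mapping(names: Sequence[str], mapping: Optional[Dict[str, str]]):
    mapping = mapping or {}
    return [mapping.get(n, n) for n in names]


# ---------------------------------------------------------------------------
# TRC (marker dialect)
# ---------------------------------------------------------------------------

def write_trc(series: LandmarkSeries, path, units: str = "m") -> None:
    """Write a marker series as a TRC file (tab separated, text)."""
    if units not in _UNIT_SCALE:
        raise InputError(f"unknown units {units!r}")
    scale = 1.0 / _UNIT_SCALE[units]
    names = series.names
    n = series.n_frames
    rate = series.nominal_rate
    path = Path(path)
    with path.open("w") as fh:
        fh.write(f"PathFileType\t4\t(X/Y/Z)\t{path.name}\n")
        fh.write("DataRate\tCameraRate\tNumFrames\tNumMarkers\tUnits\t"
                 "OrigDataRate\tOrigDataStartFrame\tOrigNumFrames\n")
        fh.write(f"{rate:g}\t{rate:g}\t{n}\t{len(names)}\t{units}\t"
                 f"{rate:g}\t1\t{n}\n")
        fh.write("Frame#\tTime\t" + "\t\t\t".join(names) + "\t\t\t\n")
        fh.write("\t\t" + "\t".join(
            f"X{i}\tY{i}\tZ{i}" for i in range(1, len(names) + 1)) + "\n")
        fh.write("\n")
        for i in range(n):
            row = [str(i + 1), repr(float(series.time[i]))]
            for name in names:
                row.extend(repr(float(v * scale))
                           for v in series.landmarks[name][i])
            fh.write("\t".join(row) + "\n")


def read_trc(path, mapping: Optional[Dict[str, str]] = None) -> LandmarkSeries:
    """Read a TRC marker file; positions converted to meters."""
    path = Path(path)
    lines = path.read_text().splitlines()
    if len(lines) < 6:
        raise InputError(f"{path}: truncated TRC file")
    header_keys = lines[1].split("\t")
    header_vals = lines[2].split("\t")
    header = dict(zip(header_keys, header_vals))
    units = header.get("Units", "").strip()
    if units not in _UNIT_SCALE:
        raise InputError(f"{path}: unknown or missing units {units!r}")
    scale = _UNIT_SCALE[units]
    rate = float(header.get("DataRate", 0) or 0)
    raw_names = [n for n in lines[3].split("\t")[2:] if n.strip()]
    names = _apply_mapping(raw_names, mapping)
    data_lines = [ln for ln in lines[5:] if ln.strip()]
    times = []
    cols = {name: [] for name in names}
    for ln in data_lines:
        parts = ln.split("\t")
        if len(parts) < 2 + 3 * len(names):
            raise InputError(f"{path}: short data row")
        times.append(float(parts[1]))
        for j, name in enumerate(names):
            xyz = parts[2 + 3 * j: 5 + 3 * j]
            cols[name].append([float(v) * scale for v in xyz])
    from .prep import MARKER_NAMES

    landmarks = {}
    for name, vals in cols.items():
        if name in MARKER_NAMES:
            landmarks[name] = np.asarray(vals)
        else:
            log.debug("ignoring unknown marker %r", name)
    return LandmarkSeries(MARKER_DIALECT, np.asarray(times), landmarks,
                          nominal_rate=rate or 100.0)


# ---------------------------------------------------------------------------
# wide CSV / JSON (both dialects)
# ---------------------------------------------------------------------------

def write_landmark_csv(series: LandmarkSeries, path) -> None:
    """Wide CSV: a ``time`` column plus ``<name>_x/_y/_z`` columns (meters)."""
    data = {"time": series.time}
    for name in series.names:
        arr = series.landmarks[name]
        for k, suffix in enumerate("xyz"):
            data[f"{name}_{suffix}"] = arr[:, k]
    pd.DataFrame(data).to_csv(path, index=False, float_format="%.17g")


def read_landmark_csv(path, dialect: str = DEPTH_DIALECT,
                      mapping: Optional[Dict[str, str]] = None,
                      nominal_rate: Optional[float] = None) -> LandmarkSeries:
    """Read a wide-CSV landmark file with a mandatory ``time`` column."""
    df = pd.read_csv(path)
    if "time" not in df.columns:
        raise InputError(f"{path}: missing mandatory 'time' column")
    t = df["time"].to_numpy(dtype=float)
    if t.size >= 2 and np.any(np.diff(t) <= 0):
        raise InputError(f"{path}: timestamps must be strictly increasing "
                         "(duplicates or reversals found)")
    mapping = mapping or {}
    groups: Dict[str, list] = {}
    for col in df.columns:
        if col == "time" or not col[-2:] in ("_x", "_y", "_z"):
            continue
        base, suffix = col[:-2], col[-1]
        groups.setdefault(mapping.get(base, base), [None] * 3)[
            "xyz".index(suffix)] = col
    landmarks = {}
    from .prep import _VOCABULARY

    vocab = _VOCABULARY[dialect]
    for name, colnames in groups.items():
        if any(c is None for c in colnames):
            raise InputError(f"{path}: incomplete x/y/z triplet for {name!r}")
        if name not in vocab:
            log.debug("ignoring unknown landmark %r", name)
            continue
        landmarks[name] = df[colnames].to_numpy(dtype=float)
    if nominal_rate is None:
        nominal_rate = float((t.size - 1) / (t[-1] - t[0])) if t.size > 1 else 0.0
    return LandmarkSeries(dialect, t, landmarks, nominal_rate=nominal_rate)


def write_landmark_json(series: LandmarkSeries, path) -> None:
    payload = {"dialect": series.dialect,
               "nominal_rate": series.nominal_rate,
               "time": series.time.tolist(),
               "landmarks": {n: series.landmarks[n].tolist()
                             for n in series.names}}
    with open(path, "w") as fh:
        json.dump(payload, fh)


def read_landmark_json(path,
                       mapping: Optional[Dict[str, str]] = None) -> LandmarkSeries:
    with open(path) as fh:
        d = json.load(fh)
    mapping = mapping or {}
    landmarks = {mapping.get(n, n): np.asarray(v)
                 for n, v in d["landmarks"].items()}
    return LandmarkSeries(d["dialect"], np.asarray(d["time"]), landmarks,
                          nominal_rate=float(d["nominal_rate"]))


def save_tensor(tensor: GaitTensor, path) -> None:
    with open(path, "w") as fh:
        json.dump(tensor.to_dict(), fh)


def load_tensor(path) -> GaitTensor:
    with open(path) as fh:
        return GaitTensor.from_dict(json.load(fh))


def read_marker_file(path, mapping: Optional[Dict[str, str]] = None
                     ) -> LandmarkSeries:
    """Read a marker trajectory file (TRC by extension, else wide CSV)."""
    return _read_marker_any(path, mapping)


def read_landmark_file(path, mapping: Optional[Dict[str, str]] = None
                       ) -> LandmarkSeries:
    """Read a depth-sensor landmark file (JSON by extension, else CSV)."""
    if str(path).endswith(".json"):
        return read_landmark_json(path, mapping)
    return read_landmark_csv(path, DEPTH_DIALECT, mapping)


def load_config(path) -> dict:
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict):
        raise InputError(f"{path}: configuration must be a mapping")
    return cfg


# ---------------------------------------------------------------------------
# manifest + pipeline
# ---------------------------------------------------------------------------

@dataclass
class TrialManifest:
    """One trial's file set and metadata."""

    subject: str
    day: int
    trial: str
    marker_file: Optional[str] = None
    depth_file: Optional[str] = None
    static_file: Optional[str] = None
    mapping: Dict[str, str] = field(default_factory=dict)

    def __post_init__(self):
        if self.day not in (1, 2):
            raise InputError(f"day must be 1 or 2, got {self.day}")


def load_manifest(path) -> dict:
    d = load_config(path)
    if "trials" not in d:
        raise InputError(f"{path}: manifest needs a 'trials' list")
    base = Path(path).parent
    trials = []
    for td in d["trials"]:
        t = TrialManifest(subject=str(td["subject"]), day=int(td["day"]),
                          trial=str(td["trial"]),
                          marker_file=td.get("marker_file"),
                          depth_file=td.get("depth_file"),
                          static_file=td.get("static_file"),
                          mapping=td.get("mapping", {}))
        for attr in ("marker_file", "depth_file", "static_file"):
            val = getattr(t, attr)
            if val is not None:
                p = (base / val) if not Path(val).is_absolute() else Path(val)
                if not p.exists():
                    raise InputError(f"manifest references missing file {p}")
                setattr(t, attr, str(p))
        trials.append(t)
    d["trials"] = trials
    return d


def _read_marker_any(path, mapping):
    if str(path).endswith(".trc"):
        return read_trc(path, mapping)
    return read_landmark_csv(path, MARKER_DIALECT, mapping, nominal_rate=100.0)


def _trial_cycles(trial: TrialManifest, config: dict):
    """Paired (depth, marker) cycles for one trial; marker side optional."""
    cutoff = config.get("filter", {}).get("cutoff", 6.0)
    order = config.get("filter", {}).get("order", 4)
    rate = config.get("resample_rate", 100.0)
    hip = HipCenterModel(**config.get("hip_center", {}))

    out = {"subject": trial.subject, "day": trial.day, "trial": trial.trial}
    depth = read_landmark_csv(trial.depth_file, DEPTH_DIALECT, trial.mapping)
    depth_u = butterworth_lowpass(resample_uniform(depth, rate), cutoff, order)
    depth_angles = compute_kinect_angles(depth_u)
    depth_events = detect_initial_contacts(depth_u)
    tid = f"{trial.subject}-d{trial.day}-{trial.trial}"
    out["depth_cycles"] = segment_and_normalize(
        depth_angles, depth_events, trial_id=tid, day=trial.day)

    if trial.marker_file is not None:
        if trial.static_file is None:
            raise InputError(
                f"trial {tid}: marker processing requires a static trial")
        markers = _read_marker_any(trial.marker_file, trial.mapping)
        static = _read_marker_any(trial.static_file, trial.mapping)
        markers_f = butterworth_lowpass(markers, cutoff, order)
        marker_angles = compute_marker_angles(markers_f, static, hip)
        marker_events = detect_initial_contacts(markers_f)
        pairs = pair_events(marker_events, depth_events)
        # keep only cycles whose two bounding events matched in both systems
        pair_map = dict(pairs)
        kept_m, kept_d = [], []
        for i in range(len(marker_events) - 1):
            if i in pair_map and (i + 1) in pair_map \
                    and pair_map[i + 1] == pair_map[i] + 1:
                kept_m.append(i)
                kept_d.append(pair_map[i])
        m_cycles = segment_and_normalize(marker_angles, marker_events,
                                         trial_id=tid, day=trial.day)
        out["marker_cycles"] = [m_cycles[i] for i in kept_m]
        out["depth_cycles"] = [out["depth_cycles"][j] for j in kept_d]
    return out


def run_pipeline(manifest, out_dir) -> dict:
    """End-to-end run: kinematics, events, calibration, agreement reports.

    ``manifest`` is a path to a YAML manifest or an already-loaded dict.
    Writes deterministic JSON artifacts under ``out_dir`` and returns the
    collected results.  Rerunning with the same seed reproduces the
    reports byte for byte.
    """
    if not isinstance(manifest, dict):
        manifest = load_manifest(manifest)
    config = manifest.get("config", {})
    seed = int(manifest.get("seed", 0))
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    results = []
    for trial in manifest["trials"]:
        log.info("processing trial %s day %s %s",
                 trial.subject, trial.day, trial.trial)
        try:
            results.append(_trial_cycles(trial, config))
        except (InputError, MissingLandmarkError) as exc:
            raise InputError(
                f"trial {trial.subject}/{trial.trial} (day {trial.day}): "
                f"{exc}") from exc

    def collect(day, key):
        cycles, subjects = [], []
        for r in results:
            if r["day"] == day and key in r:
                for c in r[key]:
                    cycles.append(c)
                    subjects.append(r["subject"])
        return cycles, subjects

    d1_depth, d1_subj = collect(1, "depth_cycles")
    d1_marker, d1_msubj = collect(1, "marker_cycles")
    artifacts: dict = {}

    if d1_marker:
        g1 = build_gait_tensor(d1_depth, "depth", d1_subj)
        g2 = build_gait_tensor(d1_marker, "reference", d1_msubj)
        calib_subject = manifest.get("calibration_subject")
        if calib_subject is not None:
            fit_idx = [i for i, s in enumerate(g1.subjects)
                       if s == calib_subject]
            eval_idx = [i for i, s in enumerate(g1.subjects)
                        if s != calib_subject]
            if not fit_idx or not eval_idx:
                raise InputError(
                    f"calibration subject {calib_subject!r} must exist and "
                    "leave evaluation subjects")
        else:
            fit_idx = eval_idx = list(range(g1.n))
        sub = lambda g, idx: GaitTensor(
            g.values[idx], [g.trial_ids[i] for i in idx],
            [g.subjects[i] for i in idx], g.system)
        lstm_cfg = config.get("lstm", {})
        linear = fit_linear_calibration(sub(g1, fit_idx), sub(g2, fit_idx))
        lstm = train_lstm_calibrator(
            sub(g1, fit_idx), sub(g2, fit_idx),
            epochs=int(lstm_cfg.get("epochs", 300)),
            hidden=int(lstm_cfg.get("hidden", 100)),
            learning_rate=float(lstm_cfg.get("learning_rate", 0.006)),
            seed=seed)
        g1_eval, g2_eval = sub(g1, eval_idx), sub(g2, eval_idx)
        systems = {"depth": g1_eval,
                   "linear": apply_linear_calibration(linear, g1_eval),
                   "lstm": apply_lstm_calibrator(lstm, g1_eval)}
        validity = validity_report(g2_eval, systems,
                                   config.get("cmc_mode", "system-pair"))
        validity.to_json(out_dir / "validity.json")
        with open(out_dir / "linear_calibration.json", "w") as fh:
            json.dump(linear.to_dict(), fh, indent=2, sort_keys=True)
        lstm.save(out_dir / "lstm_calibration.json")
        save_tensor(g1, out_dir / "tensor_depth_day1.json")
        save_tensor(g2, out_dir / "tensor_reference_day1.json")
        artifacts["validity"] = validity

    d2_depth, d2_subj = collect(2, "depth_cycles")
    if d2_depth:
        gd1 = build_gait_tensor(d1_depth, "depth", d1_subj)
        gd2 = build_gait_tensor(d2_depth, "depth", d2_subj)
        reliability = reliability_report(gd1, gd2)
        reliability.to_json(out_dir / "reliability.json")
        save_tensor(gd2, out_dir / "tensor_depth_day2.json")
        artifacts["reliability"] = reliability
    else:
        log.warning("manifest has no day-2 trials; reliability section omitted")
    return artifacts
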