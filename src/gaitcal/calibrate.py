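"""Calibration of depth-sensor kinematics against the reference system.

Two methods operate on stacked gait tensors (n trials x 101 steps x 5
DOFs): per-DOF ordinary least squares over all pooled time points, and a
two-layer LSTM sequence model (100 cells per layer, full-batch gradient
descent, learning rate 0.006) mapping whole depth-sensor cycles onto
reference cycles.  Angles are z-scored per DOF around the network (the
stated learning rate is only meaningful on scaled data) and mapped back to
degrees on output.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from . import _lstm
from .errors import DivergenceError, InputError, NumericalError
from .prep import DOF_NAMES, AngleCycle


@dataclass
class GaitTensor:
    """n x 101 x 5 stack of normalized gait cycles for one system."""

    values: np.ndarray
    trial_ids: Tuple[str, ...] = ()
    subjects: Tuple[str, ...] = ()
    system: str = ""

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 3 or self.values.shape[1:] != (101, 5):
            raise InputError(
                f"gait tensor must be (n, 101, 5); got {self.values.shape}")
        if not np.all(np.isfinite(self.values)):
            raise InputError("gait tensor must be finite")
        self.trial_ids = tuple(self.trial_ids) or tuple(
            f"trial_{i}" for i in range(self.n))
        self.subjects = tuple(self.subjects) or (("",) * self.n)
        if len(self.trial_ids) != self.n or len(self.subjects) != self.n:
            raise InputError("metadata length must match the trial dimension")

    @property
    def n(self) -> int:
        return self.values.shape[0]

    def to_dict(self) -> dict:
        return {"system": self.system,
                "trial_ids": list(self.trial_ids),
                "subjects": list(self.subjects),
                "dof_names": list(DOF_NAMES),
                "values": self.values.tolist()}

    @classmethod
    def from_dict(cls, d: dict) -> "GaitTensor":
        return cls(np.asarray(d["values"], dtype=float),
                   tuple(d.get("trial_ids", ())),
                   tuple(d.get("subjects", ())),
                   d.get("system", ""))


def build_gait_tensor(cycles: Sequence[AngleCycle], system: str = "",
                      subjects: Optional[Sequence[str]] = None) -> GaitTensor:
    """Stack cycles (in order) into a gait tensor."""
    if len(cycles) == 0:
        raise InputError("cannot build a gait tensor from zero cycles")
    names = cycles[0].dof_names
    if any(c.dof_names != names for c in cycles):
        raise InputError("cycles have mixed DOF sets")
    if names != DOF_NAMES:
        raise InputError(f"expected DOF order {DOF_NAMES}, got {names}")
    values = np.stack([c.values for c in cycles])
    ids = tuple(c.trial_id or f"trial_{i}" for i, c in enumerate(cycles))
    subj = tuple(subjects) if subjects is not None else ("",) * len(cycles)
    return GaitTensor(values, ids, subj, system)


# ---------------------------------------------------------------------------
# linear regression calibration
# ---------------------------------------------------------------------------

@dataclass
class LinearCalibration:
    """Per-DOF affine map reference ~ slope * depth + intercept."""

    slopes: np.ndarray
    intercepts: np.ndarray
    r_squared: np.ndarray
    n_points: int

    def __post_init__(self):
        self.slopes = np.asarray(self.slopes, dtype=float)
        self.intercepts = np.asarray(self.intercepts, dtype=float)
        self.r_squared = np.asarray(self.r_squared, dtype=float)
        if self.slopes.shape != (5,) or self.intercepts.shape != (5,):
            raise InputError("linear calibration needs 5 slope/intercept pairs")
        if not np.all(np.isfinite(self.slopes)):
            raise NumericalError("non-finite calibration slopes")

    def to_dict(self) -> dict:
        return {"kind": "linear",
                "dof_names": list(DOF_NAMES),
                "slopes": self.slopes.tolist(),
                "intercepts": self.intercepts.tolist(),
                "r_squared": self.r_squared.tolist(),
                "n_points": self.n_points}

    @classmethod
    def from_dict(cls, d: dict) -> "LinearCalibration":
        return cls(np.asarray(d["slopes"]), np.asarray(d["intercepts"]),
                   np.asarray(d.get("r_squared", [np.nan] * 5)),
                   int(d.get("n_points", 0)))


def fit_linear_calibration(g1: GaitTensor, g2: GaitTensor) -> LinearCalibration:
    """OLS of the reference (g2) on the depth-sensor stream (g1), per DOF,
    over all pooled trial/time points."""
    if g1.values.shape != g2.values.shape:
        raise InputError("paired tensors must have identical shapes")
    x = g1.values.reshape(-1, 5)
    y = g2.values.reshape(-1, 5)
    slopes = np.empty(5)
    intercepts = np.empty(5)
    r2 = np.empty(5)
    for d in range(5):
        xd, yd = x[:, d], y[:, d]
        vx = xd.var()
        if vx < 1e-14:
            raise NumericalError(
                f"degenerate (constant) predictor for DOF {DOF_NAMES[d]!r}")
        slopes[d] = np.cov(xd, yd, bias=True)[0, 1] / vx
        intercepts[d] = yd.mean() - slopes[d] * xd.mean()
        resid = yd - (slopes[d] * xd + intercepts[d])
        vy = yd.var()
        r2[d] = 1.0 - resid.var() / vy if vy > 0 else 1.0
    return LinearCalibration(slopes, intercepts, r2, x.shape[0])


def apply_linear_calibration(model: LinearCalibration,
                             g1: GaitTensor) -> GaitTensor:
    values = model.slopes * g1.values + model.intercepts
    return GaitTensor(values, g1.trial_ids, g1.subjects,
                      system=f"{g1.system}+linear" if g1.system else "linear")


# ---------------------------------------------------------------------------
# LSTM calibration
# ---------------------------------------------------------------------------

@dataclass
class LSTMCalibrator:
    """Trained two-layer LSTM sequence calibrator.

    The architecture (layers, cell count) is fixed at construction; only
    the weights are mutated by training.  ``loss_history`` is the
    full-batch MSE (standardized units) per epoch.
    """

    params: Dict[str, np.ndarray]
    x_mean: np.ndarray
    x_std: np.ndarray
    y_mean: np.ndarray
    y_std: np.ndarray
    hidden: int
    n_layers: int = 2
    seed: int = 0
    learning_rate: float = 0.006
    loss_history: List[float] = field(default_factory=list)

    def predict(self, g1: GaitTensor) -> GaitTensor:
        X = (g1.values - self.x_mean) / self.x_std
        Y, _ = _lstm.forward(self.params, X, self.n_layers)
        values = Y * self.y_std + self.y_mean
        return GaitTensor(values, g1.trial_ids, g1.subjects,
                          system=f"{g1.system}+lstm" if g1.system else "lstm")

    def save(self, path) -> None:
        payload = {
            "kind": "lstm",
            "hidden": self.hidden,
            "n_layers": self.n_layers,
            "seed": self.seed,
            "learning_rate": self.learning_rate,
            "x_mean": self.x_mean.tolist(), "x_std": self.x_std.tolist(),
            "y_mean": self.y_mean.tolist(), "y_std": self.y_std.tolist(),
            "loss_history": self.loss_history,
            "params": {k: v.tolist() for k, v in self.params.items()},
        }
        with open(path, "w") as fh:
            json.dump(payload, fh)

    @classmethod
    def load(cls, path) -> "LSTMCalibrator":
        with open(path) as fh:
            d = json.load(fh)
        return cls(params={k: np.asarray(v) for k, v in d["params"].items()},
                   x_mean=np.asarray(d["x_mean"]), x_std=np.asarray(d["x_std"]),
                   y_mean=np.asarray(d["y_mean"]), y_std=np.asarray(d["y_std"]),
                   hidden=int(d["hidden"]), n_layers=int(d["n_layers"]),
                   seed=int(d["seed"]),
                   learning_rate=float(d["learning_rate"]),
                   loss_history=list(d["loss_history"]))


def train_lstm_calibrator(g1: GaitTensor, g2: GaitTensor,
                          epochs: int = 500, seed: int = 0,
                          hidden: int = 100, learning_rate: float = 0.006,
                          clip_norm: float = 5.0,
                          early_stop_tol: float = 1e-6,
                          early_stop_window: int = 20,
                          dtype=np.float32) -> LSTMCalibrator:
    """Train the sequence calibrator with full-batch gradient descent.

    Minimizes the MSE between predicted and reference sequences over all
    trials, time steps and DOFs.  Deterministic given ``seed``.  A
    non-finite loss raises :class:`DivergenceError`.  Training runs in
    ``dtype`` (float32 by default, roughly twice as fast on CPU); the
    stored weights are promoted back to float64.
    """
    if g1.values.shape != g2.values.shape:
        raise InputError("paired tensors must have identical shapes")
    if g1.n < 1:
        raise InputError("need at least one trial to train")
    x_mean = g1.values.reshape(-1, 5).mean(axis=0)
    x_std = g1.values.reshape(-1, 5).std(axis=0)
    y_mean = g2.values.reshape(-1, 5).mean(axis=0)
    y_std = g2.values.reshape(-1, 5).std(axis=0)
    x_std = np.where(x_std < 1e-9, 1.0, x_std)
    y_std = np.where(y_std < 1e-9, 1.0, y_std)
    X = ((g1.values - x_mean) / x_std).astype(dtype)
    Y = ((g2.values - y_mean) / y_std).astype(dtype)

    rng = np.random.default_rng(seed)
    params = {k: v.astype(dtype)
              for k, v in _lstm.init_params(rng, 5, hidden, 5).items()}
    history: List[float] = []
    for epoch in range(epochs):
        pred, state = _lstm.forward(params, X)
        err = pred - Y
        loss = float(np.mean(err * err))
        if not np.isfinite(loss):
            raise DivergenceError(
                f"loss became non-finite at epoch {epoch}; "
                "lower the learning rate")
        history.append(loss)
        if (len(history) > early_stop_window
                and abs(history[-1 - early_stop_window] - loss)
                <= early_stop_tol * max(loss, 1e-12)):
            break
        dY = 2.0 * err / err.size
        grads = _lstm.backward(params, X, dY, state)
        _lstm.clip_global_norm(grads, clip_norm)
        for k in params:
            params[k] = params[k] - dtype(learning_rate) * grads[k]
    params = {k: v.astype(np.float64) for k, v in params.items()}
    return LSTMCalibrator(params=params, x_mean=x_mean, x_std=x_std,
                          y_mean=y_mean, y_std=y_std, hidden=hidden,
                          seed=seed, learning_rate=learning_rate,
                          loss_history=history)


def apply_lstm_calibrator(model: LSTMCalibrator, g1: GaitTensor) -> GaitTensor:
    """Map each depth-sensor cycle through the trained network."""
    return model.predict(g1)
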