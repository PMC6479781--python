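# gaitcal

Lower-limb gait kinematics from two measurement streams — a marker-based
optical system (modified Cleveland marker set, 100 Hz) and a depth-sensor
skeleton stream (10 of the 25 standard landmarks, fluctuating ~30 Hz) —
plus calibration of the markerless stream against the reference and the
measurement-agreement statistics used in concurrent-validity /
inter-day-reliability studies.

Because no real recordings ship with the package, a synthetic gait
generator produces ground-truth joint-angle profiles and forward-kinematic
landmark trajectories for **both** streams, with a configurable distortion
model (per-DOF affine + optional cubic error, landmark noise, timestamp
jitter, frame dropout) for the depth stream. On noiseless data the
analysis pipelines invert the generator exactly, which anchors the test
suite.

## What's inside

| module | contents |
| --- | --- |
| `gaitcal.synthetic` | Fourier-series angle profiles, forward kinematics for both dialects, distortion model |
| `gaitcal.prep` | `LandmarkSeries` / `AngleSeries` / `AngleCycle`, cubic resampling, zero-phase 4th-order Butterworth low-pass (6 Hz default), 101-point cycle normalization, cycle averaging |
| `gaitcal.marker` | segment frames (pelvis/thigh/shank/foot), Bell-style hip-joint-center model, mobile-axis Euler sequence (flexion → adduction → rotation), cluster-based reconstruction of removed medial/lateral markers from a static calibration trial |
| `gaitcal.depth` | depth-sensor pelvis/thigh frames, hip Euler angles via the shared decomposition, unsigned vector angles for knee and ankle |
| `gaitcal.events` | coordinate-based initial-contact detection, cycle segmentation, discrete parameters (max/min/ROM/angle at initial contact) |
| `gaitcal.calibrate` | `GaitTensor` (n×101×5), per-DOF linear regression calibration, two-layer LSTM sequence calibrator (100 cells/layer, full-batch gradient descent, lr 0.006; pure numpy incl. BPTT) |
| `gaitcal.stats` | RMSE, Kadaba CMC with the `"<0.001"` sentinel for negative radicands, Shapiro–Wilk-gated Pearson/Spearman correlation, Bland–Altman 95% LoA, ICC(2,k) with McGraw–Wong F-based CI, SEM = SD·√(1−ICC), interpretation bands, validity/reliability report assembly |
| `gaitcal.io` / `gaitcal.cli` | TRC + wide-CSV/JSON readers and writers, YAML config/manifest, end-to-end pipeline, `gaitcal` CLI |

Conventions: meters / degrees / seconds; lab frame +X walking direction,
+Y up, +Z subject's right; DOF order `hip_flexion, hip_adduction,
hip_rotation, knee_flexion, ankle_flexion`. The ankle channel is the
depth-sensor vector-angle convention (`angle(shank, foot) − 90°`; positive
is a toe-down rotation) and the marker pipeline reports the same signed
quantity referenced to the static standing posture, so the two systems are
directly comparable.

## CLI

```bash
gaitcal simulate --config sim.yml --out data/ --seed 1   # synthetic cohort (TRC + CSV + manifest)
gaitcal kinematics marker --input trial.trc --static static.trc --out angles.csv
gaitcal kinematics kinect --input trial_depth.csv --out angles.csv
gaitcal events --input trial.trc --dialect marker
gaitcal calibrate fit-linear --g1 depth.json --g2 ref.json --out linear.json
gaitcal calibrate fit-lstm   --g1 depth.json --g2 ref.json --out lstm.json --epochs 1200
gaitcal calibrate apply --model linear.json --g1 depth.json --out calibrated.json
gaitcal validity --reference ref.json --system depth depth.json --out validity.json
gaitcal reliability --day1 d1.json --day2 d2.json --out reliability.json
gaitcal report --manifest data/manifest.yml --out results/   # full pipeline
```

Exit codes: 0 success, 2 input error, 3 numerical failure. Gait tensors
travel as JSON; reports are deterministic JSON (byte-identical across
reruns with the same seed).

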