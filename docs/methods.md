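# Methods

This note records the models, conventions and numerical choices behind
`wristpose`, in the order data flows through the package.

## Synthetic cohort model

**What it emulates.** Bench-top occupational tasks (assembly, checkout
scanning, typing) performed standing, recorded at 100 Hz, with a
scripted range-of-motion sweep in FE, RU and PS before and after each
task. The full factorial design is P participants × 2 sessions × 2
repetitions × 3 tasks; default task durations (assembly 155 s, checkout
130 s, typing 175 s, each jittered ±10% per recording) were chosen so a
10-participant cohort yields on the order of 1.8×10⁴ windows per
participant, the scale typical of such recordings.

**Angle trajectories.** Each channel is a band-limited dwell process
(white noise low-passed at 0.3 Hz, scaled to a task-specific SD about a
task-specific mean) plus, for FE, occasional smooth Gaussian excursions
(Poisson arrivals, amplitude ≈ 40–50°, mostly toward flexion). A final
4 Hz zero-phase smoothing pass keeps everything band-limited below the
5 Hz label filter. Physiological clamps: |FE| ≤ 90°, |RU| ≤ 45°,
|PS| ≤ 100°. Task profile parameters were set once so that the pooled
FE window-label histogram of a default cohort places ≈ 0.90 of its mass
in the two dominant bins (15°≥θ>−15° and −15°≥θ>−45°), the imbalance
characteristic of natural bench work; the acceptance script recomputes
this number.

**Sign conventions.** Flexion positive, radial deviation positive,
pronation positive, with segment axes x distal / y radial / z dorsal.
The field does not agree on these signs, so they are pinned here and a
`sign_flip_fe`/`sign_flip_ru` switch exports the opposite convention.

**Sensor model.** Hand orientation = forearm orientation composed with
intrinsic x–y–z rotations by (θ_PS, θ_FE, θ_RU). The forearm follows a
slow orientation random walk (default 8° SD, <0.2 Hz) and a slow
position walk (3 cm SD, <0.8 Hz) so that wrist-sensor channels carry
information and accelerometers are not pure inclinometers. Gyroscopes
report exact analytic body rates of each segment (Euler-rate formula),
expressed in the sensor frame; accelerometers report specific force:
gravity (9.81 m/s²) plus the sensor point's linear acceleration from
twice-differentiated lever-arm positions, in the sensor frame. Mounting
misalignment is a fixed small rotation per sensor (default 5° SD per
axis), drawn once per participant and held across all their recordings —
modelling visual-only sensor placement. White noise: 1 deg/s gyro,
0.15 m/s² accelerometer. A validation helper exposes the simulated
orientations so tests can confirm that quaternion finite-differencing of
the hand orientation reproduces the gyro channels to <1 deg/s.

**Not modelled:** magnetometers (6-DOF sensors only), soft-tissue
artifact, marker occlusion, task apparatus geometry.

## Preprocessing

Angles are filtered at 5 Hz and inertial channels at 6 Hz with a
forward–backward Butterworth filter; the order is 4 before the
bidirectional pass (unstated in the source convention; 4th order is the
usual choice in IMU biomechanics), giving an effective 8th-order
magnitude response with zero phase. Windows are 12 channels × 100
samples with a 90-sample overlap (stride 10 ⇒ 10 windows/s); windows
never span recording boundaries. The label is the mean of samples
45..54 (0-based) of the filtered angle channels — the symmetric center
10 of an even-length window. Binning is upper-edge-inclusive
(45° ⇒ second bin, −45° ⇒ bottom bin); the RU inequalities overlap at
exactly +10°, which is resolved in favour of the radial bin (θ≥10°
wins). Min/max normalization to [0, 1] is fitted per channel on the
training partition only and applied with clipping elsewhere; a
degenerate constant channel maps to 0 with a warning. Range-of-motion
sweeps are part of the exported recordings and are included in
windowing by default (`include_rom_sweeps`), since the source procedure
records them and never states they were excluded.

## Resampling

Per recording: round the target-channel window labels to the nearest
degree (halves away from zero — pinned for reproducibility), draw one
window uniformly per occupied 1° bin, then draw uniformly with
replacement from those representatives until exactly 250 examples exist
(3000 per participant). Drawing step 3 from the representatives rather
than from all windows of occupied bins keeps the output approximately
flat across the range of motion; the alternative would partially
restore the raw imbalance and is available behind a switch. If occupied
bins ever exceed the quota the representatives are uniformly
subsampled. Separate balanced sets are built for the FE and RU models,
because flattening one channel's histogram does not flatten the
other's.

## Classifier and training

Architecture (valid padding throughout): 12×100×1 → conv 3×3, 32
filters → maxpool 2×2 → conv 3×3, 64 filters → maxpool 2×2 (floor
semantics, odd edges cropped) → flatten (1×23×64 = 1472) → dense 4096,
ReLU, dropout 0.80 → dense n_classes, softmax. Implemented in a compact
seeded numpy engine (im2col convolutions, inverted dropout, Adam);
float32 throughout; He-normal initialization from an explicit seed, so
builds and training runs are bit-reproducible single-threaded.

Training: categorical cross-entropy, Adam at base learning rate 1e-3
(optimizer, rate and batch size 64 are unstated in the source
convention and pinned in config), 10% validation split taken from the
seeded shuffle, early stopping on validation loss with min-delta 0,
patience 10, hard limit 500 epochs; the reported weights are those of
the best validation epoch, not the last. Refinement: same loss on the
held-out wearer's balanced session-1 windows, learning rate 1e-4 (10×
lower, enforced), patience 1, hard limit 50 epochs. Guards reject
refinement data from any other wearer or from session 2.

## Evaluation

Leave-one-subject-out with refinement: per fold, normalization and the
network are fitted on the balanced windows of all other participants,
refined on the test participant's session 1, and tested on **all raw
(un-resampled) windows of session 2** — session 1 is consumed by
refinement, so testing on it would be biased. A hash-based audit proves
no test window appears in any training or refinement set. Metrics:
accuracy, Cohen's κ = (p_o − p_e)/(1 − p_e) (κ := 1 in the degenerate
p_e = 1 case), Landis–Koch labels (Poor <0, Slight ≤0.20, Fair ≤0.40,
Moderate ≤0.60, Substantial ≤0.80, Almost Perfect ≤1), contingency
tables with true class on rows (cumulative = counts summed across folds
before row normalization; empty rows become NaN with a warning and are
excluded from within-k averaging), within-k-bin rates, and fold means ±
standard error (sample SD/√n_folds).

## Problem sizes used by the test suite

The suite exercises the full pipeline at desk scale: structural checks
use 1–10 participants at 6–12 s per task; the parameter-recovery run
uses a low-noise, zero-misalignment 3-participant cohort at 60 s per
task with an 8-epoch initial budget and 3-epoch refinement at batch
128, which reaches mean FE κ ≈ 0.64 (well above the 0.4 "Moderate"
threshold asserted) with a label-shuffled control at κ ≈ 0. The
refinement-benefit check uses two wearers with 15°-SD mounting
rotations and asserts the median paired κ improvement across 5 seeds is
non-negative (observed ≈ +0.08). Generator calibration pools ≈ 2×10⁵
FE window labels from a default 10-participant cohort.

## Known limitations

- The synthetic cohort shares its kinematic family across wearers;
  inter-subject variability is limited to seeds, mounting rotations and
  trajectory realizations, so LOSO generalization here is easier than
  across real humans. Passing tests demonstrate pipeline correctness
  and recoverability, not field accuracy.
- The sensor model has no soft-tissue artifact, no drift, and exact
  gravity magnitude, all of which flatter accelerometer-based posture
  cues.
- Single-threaded determinism is exact; under multi-threaded BLAS,
  floating-point reduction order may vary across runs.
- PS is simulated and recorded but never classified (only FE and RU
  have bin schemes).
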