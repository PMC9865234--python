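# wristpose

Binned wrist-posture estimation from two wearable inertial sensors.

## The problem

Ergonomic assessment tools (Strain Index, RULA, REBA) grade exposure to
awkward wrist postures from *binned* joint angles, and today those bins
are mostly assigned by a human watching video frame by frame.
`wristpose` implements an automated alternative: two uncalibrated 6-DOF
IMUs — one on the hand dorsum, one on the distal forearm — feed a small
convolutional network that classifies each second of movement into the
standard postural bins for flexion/extension (FE, 5 classes:
θ>45°, 45°≥θ>15°, 15°≥θ>−15°, −15°≥θ>−45°, −45°≥θ) and radial/ulnar
deviation (RU, 3 classes: θ≥10°, 10°>θ>−10°, −10°≥θ). No
sensor-to-segment calibration is assumed beyond approximate visual
mounting; the network learns the mapping, and a short per-wearer
refinement pass absorbs individual mounting differences.

Because participant recordings of this kind are access-restricted, the
package ships a forward-kinematic synthetic-cohort generator that
emulates the experimental design (P participants × 2 sessions × 2
repetitions × 3 bench tasks, 100 Hz, range-of-motion sweeps bracketing
each task) so every stage of the pipeline can be exercised and audited
offline.

## Pipeline

1. **simulate** (`wristpose.cohort`) — smooth task-specific wrist-angle
   trajectories drive a rigid-body sensor model (gravity + linear
   acceleration + noise in misaligned sensor frames) to produce paired
   ground-truth angles and the 12-channel inertial stream.
2. **preprocess** (`wristpose.preprocess`) — zero-lag Butterworth
   low-pass (5 Hz angles, 6 Hz inertial), per-channel min/max
   normalization fitted on the training partition, restructuring into
   12×100 windows with 90-sample overlap (10 windows/s); each window is
   labelled with the mean of its 10 central angle samples and binned.
3. **resample** (`wristpose.resample`) — per recording, one window per
   occupied 1° bin of the target angle, then draws with replacement to
   250 examples (3000 per participant), flattening the class imbalance.
4. **train** (`wristpose.model`) — the classifier: conv 3×3×32 → pool
   2×2 → conv 3×3×64 → pool 2×2 → dense 4096 (dropout 0.8) → softmax,
   trained with cross-entropy and Adam; early stopping with patience 10
   (limit 500 epochs), then per-wearer refinement at a 10× lower
   learning rate with patience 1 (limit 50 epochs).
5. **evaluate** (`wristpose.evaluate`) — leave-one-subject-out
   cross-validation: refine on the held-out wearer's first session,
   test on all raw windows of their second session; report accuracy,
   Cohen's κ with Landis–Koch label, row-normalized contingency tables
   and within-1-bin rates, with standard errors across folds.

## Worked example

```python
import numpy as np
from wristpose import SimConfig, generate_cohort, loso_evaluate
from wristpose.model import TrainConfig, PhaseConfig

sim = SimConfig(seed=11, gyro_noise_sd=0.2, acc_noise_sd=0.05,
                misalignment_sd_deg=0.0,
                duration_s={t: 60.0 for t in ("assembly", "checkout", "typing")},
                duration_jitter=0.0)
recordings = generate_cohort(3, sim)          # 36 recordings
cfg = TrainConfig(seed=5, batch_size=128,
                  initial=PhaseConfig(10, 8, 1e-3),
                  refine=PhaseConfig(1, 3, 1e-4))
report = loso_evaluate(recordings, cfg, targets=("fe",))
print(report.summary_text())
```

Output from this exact run:

```
target fe:
  accuracy 0.800 +/- 0.010 (SE), kappa 0.636 +/- 0.014 (Substantial)
  ...
```

i.e. on a low-noise three-wearer cohort the LOSO+refinement pipeline
recovers the 5-class FE bin of 80% of one-second windows, κ = 0.64
("Substantial" chance-corrected agreement); a label-shuffled control
sits at κ ≈ 0. The same flow is available from the shell:

```bash
wristpose run-all --config config.yaml --output runs/demo --seed 11
```

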