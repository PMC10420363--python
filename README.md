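# gaitevents

Automatic detection of gait events — **initial contact (IC)**, the instant a
foot touches the ground, and **foot off (FO)**, the instant it leaves — from
3-D motion-capture marker trajectories of the left/right heel, toe and ankle.

Clinical 3-D gait analysis needs these two events to segment gait cycles and
compute spatiotemporal and kinematic variables.  Force plates give
gold-standard event times but cover only a few steps per walkway; manual
annotation is slow and subjective; classic velocity-threshold rules depend on
thresholds that break down across pathologies (forefoot strikers, foot drag,
short strides).  This package provides:

- **Recurrent frame classifiers** — one independent stacked bi-directional
  LSTM per event type.  Input is a per-trial `T x 36` tensor (six markers x
  (position, velocity) x (AP, ML, V) axes), each channel min-max normalized
  to `[0.1, 1.1]` per trial.  Output per frame is a 3-way softmax
  P(no event / left event / right event); events are read off the
  probability curves by thresholded peak picking (threshold 0.01).
  Training uses sample-weighted categorical cross-entropy (event frames
  weighted 10:1 by default) with Adam, zero-padding + masking for batching,
  and random 25–125-frame crop buffers around the annotated events.
  The network is implemented directly on numpy (full BPTT; gradients are
  verified against numerical differentiation in the test suite).
- **A velocity-threshold baseline** (modified Ghoussayni-style): IC from
  heel sagittal-speed minima gated by walking speed `v`, FO from ascending
  crossings of toe sagittal speed through `1.9 v`, with threshold grid
  search on training data.
- **A synthetic gait simulator** that generates trials with exact
  construction-defined IC/FO ground truth: per-foot stance/swing phase
  schedules, heel-first / forefoot-first / midfoot strike patterns, stride
  jitter, foot-drag (reduced swing clearance) and Gaussian marker noise.
  All learning and evaluation behaviour is testable end-to-end without any
  clinical data.
- **Evaluation & statistics**: tolerance-window event matching (TP within
  ±4 frames, FP within ±50 frames, else FN; at 150 Hz one frame = 6.7 ms),
  MAE with bootstrap 95% CI, detection rate TP/(TP+FP+FN), cumulative
  detection curves, paired Wilcoxon signed-rank comparison with Bonferroni
  correction and effect size r = |Z|/√N, and a seed-sensitivity harness.
- **I/O**: C3D read/write (Intel/float subset), a portable HDF5 fixture
  format, patient-stratified train/val/test splitting with zero-shot
  holdout classes, and a `gaitevents` CLI
  (`simulate / train / detect / heuristic-detect / evaluate / run`).

## Worked example

Simulate a small noise-free heel-strike cohort and evaluate the baseline
detector's IC accuracy against the built-in ground truth:

```python
import numpy as np
from dataclasses import replace
from gaitevents import PRESET_PROFILES, CohortSpec, simulate_cohort, EventType
from gaitevents.heuristic import detect_events_heuristic
from gaitevents.evaluation import (
    MatchResult, match_trial, detection_rate, temporal_error_summary,
)

profile = replace(PRESET_PROFILES["HC-heel"], noise_sd_mm=0.0, duration_s=8.0)
cohort = simulate_cohort(CohortSpec(profiles=((profile, 5, 2),), seed=0))

results = []
for trial in cohort.trials:
    preds = [e for e in detect_events_heuristic(trial) if e.etype == EventType.IC]
    results.append(match_trial(preds, trial, EventType.IC))
combined = MatchResult.combine(results)

mae, lo, hi, n = temporal_error_summary(combined, seed=0)
print(f"IC detection rate: {detection_rate(combined):.1%}")
print(f"IC MAE: {mae:.2f} ms (95% CI {lo:.2f}-{hi:.2f}, n={n})")
```

prints

```
IC detection rate: 100.0%
IC MAE: 4.50 ms (95% CI 3.96-5.00, n=148)
```

i.e. on clean heel-strike gait every of the 148 ground-truth ICs is matched
within the ±4-frame tolerance window, with a mean absolute timing error
under one frame (6.7 ms).  On forefoot-striking profiles the same baseline
fails (the heel lands ~60 ms after the true contact), which is precisely
the regime where the trained recurrent detector keeps its accuracy — run
`gaitevents run --config <experiment.json> --out report/` for the full
model-vs-baseline comparison.

## Layout

- `src/gaitevents/gait_core.py` — domain types, C3D/HDF5 I/O, stratified splits
- `src/gaitevents/synthetic_gait.py` — parametric gait simulator + presets
- `src/gaitevents/features.py` — feature tensors, labels, batching, resampling
- `src/gaitevents/detector.py` — BiLSTM classifier, training, grid search
- `src/gaitevents/postprocess.py` — probability peaks → discrete events
- `src/gaitevents/heuristic.py` — velocity-threshold baseline
- `src/gaitevents/evaluation.py` — matching, metrics, statistics
- `src/gaitevents/pipeline.py`, `cli.py` — end-to-end experiments and CLI
- `docs/methods.md` — model, simulator and evaluation details
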