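# Methods

## Problem and data model

A trial is one straight-walkway recording: six marker trajectories
(left/right heel, toe, ankle) as `T x 3` matrices in mm with axis order
(AP, ML, V) — anterior-posterior, medio-lateral, vertical — at a sampling
rate `fs` (nominally 150 Hz), plus annotated gait events.  Events are
`(type IC|FO, side L|R, frame, source)` with 0-based integer frames; any
sub-frame ground truth (e.g. force plates sampling faster than the
cameras) is rounded to the nearest camera frame, since all metrics are
expressed in whole frames / multiples of 1000/fs ms.  Walking direction is
+AP by default; every speed-based quantity is direction-agnostic
(magnitudes or absolute means), so −AP walks are accepted.

## Recurrent detector

Two independent models, one per event type; a single joint model is
deliberately out of scope (joint training is known to degrade detection of
the first/last events of a trial).

*Features.* Per trial: positions of the six markers and their first
derivatives — central differences, second-order one-sided at the
boundaries, in mm/s — stacked in a fixed channel order
(marker-major, position before velocity, axes AP/ML/V) to 36 channels.
Derivatives are computed on raw trajectories first; every channel is then
min-max normalized **per trial** to `[0.1, 1.1]` (constant channels map to
0.1).  Per-trial normalization is what lets one model absorb differences
in laboratory size and setup.  Training/validation trials are cropped to
their annotated events plus independent random buffers of 25–125 frames on
each side, then right-zero-padded per batch; a mask marks real frames.

*Targets and loss.* Per frame a 3-class target (0 none, 1 left, 2 right),
single-frame labels without widening; class imbalance is handled by sample
weights (event frames weighted `w`, default 10, non-event 1, padded 0).
The loss is the weighted mean categorical cross-entropy over positive-
weight frames.

*Architecture.* Masked input → `n_layers` bi-directional LSTM layers of
`hidden_units` each (forward and backward passes skip masked frames by
carrying their state), dropout after each layer (training only) → per-frame
dense 3-way softmax.  Defaults follow the grid-search optimum of the
reference clinical setup: 3 layers, 200 units, dropout 0.4, weights 1:10;
the grid space is {1,2,3} layers x {50..350 step 50} units x
{0.2,0.4,0.6} dropout x {10,100,500,1000} weights (252 combinations).
The network is length-agnostic: inference runs on arbitrary-length trials.

*Implementation.* Forward pass, full backpropagation-through-time and Adam
are written directly on numpy; gradients are validated against central
finite differences (relative error < 1e-5) and the masking contract
(arbitrary right-padding changes loss and unmasked predictions by < 1e-6)
is asserted in the test suite.  Training settings the architecture search
does not fix — learning rate 3e-3, batch size 16, epochs (default 20),
gradient-norm clipping at 5 — are package defaults, not reference values.
The parameters of the best-validation-loss epoch are retained.

*Grid search selection.* Candidates are ranked by validation detection
rate at the ±4-frame window, with MAE as tie-breaker — the two metrics the
evaluation protocol defines, in robustness-first order.

## Peak post-processing

For each side channel independently: local maxima strictly above the 0.01
probability threshold are candidates (plateaus count once, at their first
frame); among candidates, the subset maximizing total probability mass
subject to a minimum separation (default 25 frames at 150 Hz ≈ 167 ms,
scaled by fs/150 — well below any physiological same-side inter-event
interval) is selected by an exact dynamic program.  The DP is verified
against brute-force subset enumeration.  At reduced training scale the
0.01 threshold lets low-confidence cross-talk bumps through; matching
reports them as *spurious* without affecting the counts (below).

## Velocity-threshold baseline

Walking speed `v` is the absolute mean AP velocity of the mid-ankle point
(the method is given no markers beyond the six it already uses).  Marker
sagittal speed is `sqrt(v_AP² + v_V²)` in m/s, with the velocity
components moving-average smoothed (default 5 frames at 150 Hz) *before*
taking the magnitude — smoothing the magnitude itself would rectify marker
noise into a positive speed floor near the thresholds.

- **IC**: the fitted threshold is 0 m/s, which a non-negative speed cannot
  cross; the operational rule is therefore descending entries of heel
  sagittal speed into the region below `max(th_ic, 0.2 v)`, deduplicated
  by keeping the entry with the deeper following minimum.
- **FO**: ascending crossings of toe sagittal speed through
  `th_fo_factor · v` (fitted factor 1.9), earlier crossing kept on
  conflicts.

`fit_thresholds` grid-searches `(th_ic, th_fo_factor)` on training data,
ranking by mean absolute error of matched events plus a penalty
proportional to the miss rate, so a degenerate threshold that detects
almost nothing cannot win; ties break toward smaller thresholds.  Whether
`v` should be per trial or per subject is unspecified upstream; per trial
is used.

## Synthetic gait simulator

Each foot follows a cyclic schedule: cycle duration `120/cadence` s,
stance fraction of it in ground contact, feet anti-phased, stride length
`speed x cycle` with per-cycle lognormal-free multiplicative jitter
(`step_length_cv`).  During stance a marker is ground-fixed (AP and V
exactly constant before noise); during swing it advances one stride along
a C¹ profile whose velocity ramps up over a `rise` fraction and down over
a `fall` fraction of the swing, with a `sin²` vertical clearance arc.

Two shape constants encode the event-adjacent signatures real detectors
rely on: the toe accelerates sharply at push-off (rise 0.05 of swing) — the
signature a `1.9 v` toe-speed threshold detects within the tolerance
window — and the heel decelerates sharply into landing (fall 0.10).
Strike pattern shifts the contact order: heel strikers ground the heel
first and the toe `heel_toe_offset_ms` later; forefoot strikers the
reverse; midfoot simultaneously.  IC ground truth is the first sampled
contact frame of the strike-leading marker, FO the first frame after the
toe's last contact — both derived from the same sampled schedule that
generates the trajectories, so truth is exact by construction.
Foot drag scales down swing toe clearance (fully dragging at severity 1).
Ground offsets (heel 25, toe 15, ankle 70 mm) and foot length (150 mm) are
geometry constants, not anatomical claims.  Additive white Gaussian noise
models residual (already-filtered) marker error.

Preset personas (`HC-heel`, `MD-baseline`, `ICP-forefoot`,
`DF-forefoot-drag`, `CF-short-stride`) are kinematic caricatures of a
clinical cohort's strike-pattern structure — self-selected speeds of
0.7–1.2 m/s, cadences 105–130 steps/min, 1–1.5 mm marker noise, forefoot
offsets of −60 to −70 ms — chosen once as plausible magnitudes; they are
test personas, not clinical models.  Cohort simulation adds ±4% per-subject
speed/cadence jitter so subjects are distinguishable.

**What the simulator does not emulate** — soft-tissue artefact, marker
occlusion and gap-filling, turning, walking aids, kinematic-chain
consistency between markers, within-trial fatigue — means that passing
tests demonstrate the correctness and relative ordering of the methods on
data with the constructed event signatures, not clinical-grade absolute
accuracy.

## Evaluation protocol

Matching is per (event type, side) stream: each ground-truth event may
match one prediction within ±50 frames; a match within ±4 frames is a TP,
a farther match an FP, an unmatched truth event an FN.  The assignment is
the optimal one-to-one matching (maximum cardinality, then minimum total
absolute error, Hungarian algorithm), verified against exhaustive
enumeration.  Predictions left unmatched are reported separately as
spurious and excluded from the three counts (the window-based reading of
the protocol); a config flag can count them as FPs instead.

- Temporal error: MAE in ms over matched events (TP and FP; FNs excluded
  — matched-but-late events belong in the error distribution), with a
  seeded nonparametric bootstrap 95% CI of the mean (2000 resamples;
  normal approximation switchable).
- Detection rate: TP/(TP+FP+FN).  Cumulative detection curves report the
  matched fraction within w = 0..4 frames.
- Method comparison: Shapiro–Wilk normality p-values (informational),
  two-sided Wilcoxon signed-rank on paired per-event absolute errors
  (normal approximation without continuity correction; pairs are truth
  events matched by both methods), Bonferroni correction by the number of
  comparisons (default 3), effect size r = |Z|/√N with N the
  nonzero-difference pairs.
- Seed sensitivity: retraining a fixed configuration under k seeds and
  reporting the per-seed MAE spread isolates the effect of initialization
  and batch order.

## Problem sizes

The shipped experiments run on one CPU: learnability uses ~340 trials of
4 s (two personas, 2 mm noise), a patient-level 60/10/30 split, and
reduced detectors (1 bi-directional layer, 32 units, 10 epochs); baseline
recovery uses 20 clean 12-s heel-strike trials (≥10 cycles each); the
zero-shot experiment holds the drag persona fully out of training.  These
sizes were chosen as the smallest at which the methods' qualitative
ordering is stable across seeds.

## Known limitations

- The "modified" variant of the velocity-threshold method is a documented
  reconstruction (the exact clinical modifications are unpublished); its
  IC rule and gate factor 0.2 are package choices.
- C3D support covers the modern Intel/float subset only.
- The numpy detector is CPU-oriented; desk-scale configurations train in
  minutes, the full 252-point grid at clinical scale would not.
- Bootstrap CIs assume independent matched events; within-trial
  correlation is ignored, as in the underlying protocol.
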