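"""Feature tensors and per-frame targets for the recurrent detectors.

The network input is a T x 36 matrix per trial: the 3-D positions of the six
foot/ankle markers and their first derivatives, each channel min-max
normalized per trial to [0.1, 1.1].  Targets are per-frame 3-class labels
(0 = no event, 1 = left, 2 = right) for one event type, with sample weights
compensating the event/non-event imbalance.

Derivatives are computed on raw mm trajectories before normalization and
then normalized as independent channels; normalization statistics are per
trial, which is what lets the same model absorb lab-scale differences.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .gait_core import MARKER_NAMES, EventType, GaitEvent, Side, Source, Trial

__all__ = [
    "AXES",
    "FeatureTensor",
    "LabelSequence",
    "Batch",
    "compute_velocity",
    "assemble_features",
    "normalize",
    "normalize_tensor",
    "crop_with_buffer",
    "make_labels",
    "make_sample_weights",
    "pad_batch",
    "resample_trial",
    "make_training_batches",
]

AXES = ("AP", "ML", "V")

#: Fixed channel ordering: marker-major, then position before velocity, then axis.
CHANNEL_NAMES: tuple[str, ...] = tuple(
    f"{marker}.{kind}.{axis}"
    for marker in MARKER_NAMES
    for kind in ("pos", "vel")
    for axis in AXES
)
N_CHANNELS = len(CHANNEL_NAMES)  # 36


@dataclass
class FeatureTensor:
    """Per-trial T x 36 input matrix with a frame-validity mask."""

    values: np.ndarray
    mask: np.ndarray
    channel_names: tuple[str, ...]
    fs: float
    trial_id: str

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.values.ndim != 2 or self.values.shape[1] != N_CHANNELS:
            raise ValueError(f"values must be T x {N_CHANNELS}, got {self.values.shape}")
        if self.mask.shape != (self.values.shape[0],):
            raise ValueError("mask length must match frame count")


@dataclass
class LabelSequence:
    """Per-frame 3-class targets for one event type, plus sample weights."""

    etype: EventType
    classes: np.ndarray   # length T, values in {0 none, 1 left, 2 right}
    weights: np.ndarray   # length T, >= 0; 0 on padded frames

    def __post_init__(self) -> None:
        self.etype = EventType(self.etype)
        self.classes = np.asarray(self.classes, dtype=int)
        self.weights = np.asarray(self.weights, dtype=float)
        if self.classes.shape != self.weights.shape:
            raise ValueError("classes and weights must have the same length")
        if not np.isin(self.classes, (0, 1, 2)).all():
            raise ValueError("classes must be in {0, 1, 2}")
        if (self.weights < 0).any():
            raise ValueError("weights must be non-negative")


@dataclass
class Batch:
    """Right-zero-padded training batch."""

    values: np.ndarray    # B x Tmax x 36
    mask: np.ndarray      # B x Tmax bool
    classes: np.ndarray   # B x Tmax int
    weights: np.ndarray   # B x Tmax float
    trial_ids: tuple[str, ...] = ()


def compute_velocity(positions: np.ndarray, fs: float) -> np.ndarray:
    """First derivative in mm/s: central differences, one-sided at the ends."""
    positions = np.asarray(positions, dtype=float)
    if positions.shape[0] < 2:
        raise ValueError("need at least 2 frames to differentiate")
    edge_order = 2 if positions.shape[0] >= 3 else 1
    return np.gradient(positions, axis=0, edge_order=edge_order) * fs


def assemble_features(trial: Trial) -> FeatureTensor:
    """Stack marker positions and velocities into the 36-channel input."""
    missing = [m for m in MARKER_NAMES if m not in trial.markers]
    if missing:
        raise ValueError(f"missing marker {missing[0]}")
    cols = []
    for marker in MARKER_NAMES:
        pos = np.asarray(trial.markers[marker], dtype=float)
        cols.append(pos)
        cols.append(compute_velocity(pos, trial.fs))
    values = np.concatenate(cols, axis=1)
    return FeatureTensor(
        values=values,
        mask=np.ones(values.shape[0], dtype=bool),
        channel_names=CHANNEL_NAMES,
        fs=trial.fs,
        trial_id=trial.trial_id,
    )


def normalize(values: np.ndarray, mask: np.ndarray | None = None) -> np.ndarray:
    """Per-channel min-max scaling of unmasked frames to [0.1, 1.1].

    Constant channels map to all-0.1; masked frames stay 0.
    """
    values = np.asarray(values, dtype=float)
    if not np.isfinite(values).all():
        raise ValueError("non-finite values in input")
    if mask is None:
        mask = np.ones(values.shape[0], dtype=bool)
    mask = np.asarray(mask, dtype=bool)
    if mask.sum() < 2:
        raise ValueError("need at least 2 unmasked frames to normalize")
    sub = values[mask]
    lo = sub.min(axis=0)
    span = sub.max(axis=0) - lo
    out = np.zeros_like(values)
    with np.errstate(invalid="ignore", divide="ignore"):
        scaled = (values - lo) / span
    scaled[:, span == 0] = 0.0
    out[mask] = 0.1 + scaled[mask]
    return out


def normalize_tensor(tensor: FeatureTensor) -> FeatureTensor:
    return FeatureTensor(
        values=normalize(tensor.values, tensor.mask),
        mask=tensor.mask.copy(),
        channel_names=tensor.channel_names,
        fs=tensor.fs,
        trial_id=tensor.trial_id,
    )


def crop_with_buffer(
    trial: Trial,
    rng: np.random.Generator,
    min_buf: int = 25,
    max_buf: int = 125,
) -> Trial:
    """Crop a trial to its TRUTH events plus random frame buffers.

    The buffers before the first and after the last event are drawn
    independently and uniformly from {min_buf, ..., max_buf}; the crop is
    clamped to the recording.  Events are re-indexed to the cropped frames.
    """
    truth = trial.events_of(source=Source.TRUTH)
    if not truth:
        raise ValueError(f"trial {trial.trial_id} has no TRUTH events to crop around")
    b1 = int(rng.integers(min_buf, max_buf + 1))
    b2 = int(rng.integers(min_buf, max_buf + 1))
    first, last = truth[0].frame, truth[-1].frame
    start = max(0, first - b1)
    end = min(trial.n_frames, last + b2 + 1)
    markers = {k: v[start:end] for k, v in trial.markers.items()}
    events = [
        GaitEvent(e.etype, e.side, e.frame - start, e.source)
        for e in trial.events
        if start <= e.frame < end
    ]
    return Trial(
        trial_id=trial.trial_id,
        subject_id=trial.subject_id,
        pathology=trial.pathology,
        fs=trial.fs,
        markers=markers,
        events=events,
    )


def make_labels(trial: Trial, etype: EventType) -> LabelSequence:
    """Single-frame 3-class targets: 1 at left events, 2 at right events."""
    etype = EventType(etype)
    classes = np.zeros(trial.n_frames, dtype=int)
    for ev in trial.events_of(etype=etype, source=Source.TRUTH):
        classes[ev.frame] = 1 if ev.side is Side.L else 2
    return LabelSequence(etype=etype, classes=classes, weights=np.ones(trial.n_frames))


def make_sample_weights(labels: LabelSequence, ratio: float = 10.0) -> np.ndarray:
    """Weights: event frames ``ratio``, non-event frames 1, padded frames 0."""
    if ratio < 1:
        raise ValueError(f"event weight ratio must be >= 1, got {ratio}")
    weights = np.where(labels.classes > 0, float(ratio), 1.0)
    weights[labels.weights == 0] = 0.0
    return weights


def pad_batch(tensors: list[FeatureTensor], labels: list[LabelSequence]) -> Batch:
    """Right-zero-pad to the longest trial; masks mark real frames."""
    if not tensors or len(tensors) != len(labels):
        raise ValueError("need equal nonempty lists of tensors and labels")
    names = tensors[0].channel_names
    for ft in tensors[1:]:
        if ft.channel_names != names:
            raise ValueError("channel-order mismatch between tensors")
    for ft, lab in zip(tensors, labels):
        if len(lab.classes) != ft.values.shape[0]:
            raise ValueError("label length does not match tensor length")
    tmax = max(ft.values.shape[0] for ft in tensors)
    B = len(tensors)
    values = np.zeros((B, tmax, N_CHANNELS))
    mask = np.zeros((B, tmax), dtype=bool)
    classes = np.zeros((B, tmax), dtype=int)
    weights = np.zeros((B, tmax))
    for i, (ft, lab) in enumerate(zip(tensors, labels)):
        T = ft.values.shape[0]
        values[i, :T] = ft.values
        mask[i, :T] = ft.mask
        classes[i, :T] = lab.classes
        weights[i, :T] = lab.weights
        weights[i, :T][~ft.mask] = 0.0
    return Batch(values, mask, classes, weights, tuple(ft.trial_id for ft in tensors))


def resample_trial(trial: Trial, new_fs: float) -> Trial:
    """Linearly interpolate trajectories onto a new sampling grid.

    Event frames are mapped by time and rounded to the nearest new frame.
    Supports cross-laboratory frequency-mismatch experiments (e.g. 150 Hz
    model applied to 100 Hz captures).
    """
    if new_fs <= 0:
        raise ValueError("new_fs must be positive")
    T = trial.n_frames
    new_T = int(round(T * new_fs / trial.fs))
    if new_T < 2:
        raise ValueError("resampling would leave fewer than 2 frames")
    t_old = np.arange(T) / trial.fs
    t_new = np.arange(new_T) / new_fs
    markers = {}
    for name, pos in trial.markers.items():
        markers[name] = np.column_stack(
            [np.interp(t_new, t_old, pos[:, j]) for j in range(3)]
        )
    events = []
    for e in trial.events:
        frame = int(round(e.frame / trial.fs * new_fs))
        if 0 <= frame < new_T:
            events.append(GaitEvent(e.etype, e.side, frame, e.source))
    return Trial(
        trial_id=trial.trial_id,
        subject_id=trial.subject_id,
        pathology=trial.pathology,
        fs=new_fs,
        markers=markers,
        events=events,
    )


def make_training_batches(
    trials: list[Trial],
    etype: EventType,
    weight_ratio: float = 10.0,
    rng: np.random.Generator | None = None,
    batch_size: int = 16,
    crop: bool = True,
    min_buf: int = 25,
    max_buf: int = 125,
) -> list[Batch]:
    """Full preparation pipeline: crop -> features -> normalize -> label -> pad.

    Convenience used by the training CLI, grid search and tests.
    """
    rng = rng or np.random.default_rng(0)
    tensors, labels = [], []
    for trial in trials:
        tr = crop_with_buffer(trial, rng, min_buf, max_buf) if crop else trial
        ft = normalize_tensor(assemble_features(tr))
        lab = make_labels(tr, etype)
        lab = LabelSequence(etype, lab.classes, make_sample_weights(lab, weight_ratio))
        tensors.append(ft)
        labels.append(lab)
    batches = []
    for i in range(0, len(tensors), batch_size):
        batches.append(pad_batch(tensors[i : i + batch_size], labels[i : i + batch_size]))
    return batches
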