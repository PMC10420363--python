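"""Core domain types for marker-based gait analysis.

A :class:`Trial` holds the 3-D trajectories (mm) of the six foot/ankle
markers of one straight-walkway recording, its sampling rate, and the
annotated gait events.  Coordinates use the axis order (AP, ML, V):
anterior-posterior (walking direction), medio-lateral, vertical.  Event
frames are 0-based integer indices at the trial's sampling rate.

The module also provides C3D and HDF5 fixture I/O and patient-stratified
dataset partitioning.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, replace
from enum import Enum
from typing import Iterable, Mapping, Sequence

import numpy as np

__all__ = [
    "MARKER_NAMES",
    "EventType",
    "Side",
    "Source",
    "Split",
    "GaitEvent",
    "Trial",
    "Dataset",
    "split_dataset",
    "read_c3d",
    "write_trial_c3d",
    "read_fixture",
    "write_fixture",
    "load_alias_config",
]

#: Canonical marker names, in the fixed order used throughout the package.
MARKER_NAMES = ("L_HEEL", "L_TOE", "L_ANKLE", "R_HEEL", "R_TOE", "R_ANKLE")


class EventType(str, Enum):
    IC = "IC"  # initial contact: foot first touches the ground
    FO = "FO"  # foot off: foot leaves the ground


class Side(str, Enum):
    L = "L"
    R = "R"


class Source(str, Enum):
    TRUTH = "TRUTH"          # ground truth (force plate / construction)
    MODEL = "MODEL"          # recurrent network detector
    HEURISTIC = "HEURISTIC"  # velocity-threshold baseline


class Split(str, Enum):
    TRAIN = "TRAIN"
    VAL = "VAL"
    TEST = "TEST"


@dataclass(frozen=True)
class GaitEvent:
    """A single gait event at an integer frame index."""

    etype: EventType
    side: Side
    frame: int
    source: Source = Source.TRUTH

    def __post_init__(self) -> None:
        object.__setattr__(self, "etype", EventType(self.etype))
        object.__setattr__(self, "side", Side(self.side))
        object.__setattr__(self, "source", Source(self.source))
        if self.frame < 0 or int(self.frame) != self.frame:
            raise ValueError(f"event frame must be a non-negative integer, got {self.frame!r}")
        object.__setattr__(self, "frame", int(self.frame))


@dataclass
class Trial:
    """One walking recording: six marker trajectories plus annotated events.

    markers maps each name in :data:`MARKER_NAMES` to a T x 3 array in mm,
    axis order (AP, ML, V).  All trajectories share the frame count T >= 2.
    """

    trial_id: str
    subject_id: str
    pathology: str
    fs: float
    markers: dict[str, np.ndarray]
    events: list[GaitEvent] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.markers = {k: np.asarray(v, dtype=float) for k, v in self.markers.items()}
        self.events = sorted(self.events, key=lambda e: (e.frame, e.etype.value, e.side.value))
        self.validate()

    def validate(self) -> None:
        if not self.fs > 0:
            raise ValueError(f"sampling rate must be positive, got {self.fs}")
        missing = [m for m in MARKER_NAMES if m not in self.markers]
        if missing:
            raise ValueError(f"missing marker {missing[0]}")
        lengths = {m: self.markers[m].shape for m in MARKER_NAMES}
        shapes = set(lengths.values())
        if len(shapes) != 1:
            raise ValueError(f"marker trajectories disagree in shape: {lengths}")
        (shape,) = shapes
        if len(shape) != 2 or shape[1] != 3 or shape[0] < 2:
            raise ValueError(f"marker trajectories must be Tx3 with T >= 2, got shape {shape}")
        T = shape[0]
        seen: set[tuple] = set()
        for ev in self.events:
            if not 0 <= ev.frame < T:
                raise ValueError(f"event frame {ev.frame} outside [0, {T})")
            key = (ev.etype, ev.side, ev.frame)
            if key in seen:
                raise ValueError(f"duplicate event {key}")
            seen.add(key)

    @property
    def n_frames(self) -> int:
        return self.markers[MARKER_NAMES[0]].shape[0]

    @property
    def duration_s(self) -> float:
        return self.n_frames / self.fs

    def events_of(
        self,
        etype: EventType | None = None,
        side: Side | None = None,
        source: Source | None = None,
    ) -> list[GaitEvent]:
        """Events filtered by type/side/source, sorted by frame."""
        out = []
        for ev in self.events:
            if etype is not None and ev.etype != EventType(etype):
                continue
            if side is not None and ev.side != Side(side):
                continue
            if source is not None and ev.source != Source(source):
                continue
            out.append(ev)
        return out

    def copy(self) -> "Trial":
        return Trial(
            trial_id=self.trial_id,
            subject_id=self.subject_id,
            pathology=self.pathology,
            fs=self.fs,
            markers={k: v.copy() for k, v in self.markers.items()},
            events=list(self.events),
        )


@dataclass
class Dataset:
    """A collection of trials with an optional patient-stratified partition."""

    trials: list[Trial]
    partition: dict[str, Split] | None = None

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        ids = [t.trial_id for t in self.trials]
        if len(set(ids)) != len(ids):
            raise ValueError("trial_ids are not unique")
        if self.partition is not None:
            self.partition = {k: Split(v) for k, v in self.partition.items()}
            missing = [i for i in ids if i not in self.partition]
            if missing:
                raise ValueError(f"partition missing trials: {missing[:3]}")
            by_subject: dict[str, set[Split]] = {}
            for t in self.trials:
                by_subject.setdefault(t.subject_id, set()).add(self.partition[t.trial_id])
            bad = {s: p for s, p in by_subject.items() if len(p) > 1}
            if bad:
                raise ValueError(f"subjects span multiple partitions: {sorted(bad)[:3]}")

    def subjects(self) -> list[str]:
        return sorted({t.subject_id for t in self.trials})

    def trials_in(self, split: Split) -> list[Trial]:
        if self.partition is None:
            raise ValueError("dataset has no partition")
        split = Split(split)
        return [t for t in self.trials if self.partition[t.trial_id] == split]


def _largest_remainder(n: int, fractions: Sequence[float]) -> list[int]:
    exact = [n * f for f in fractions]
    base = [math.floor(e) for e in exact]
    left = n - sum(base)
    order = sorted(range(len(fractions)), key=lambda i: exact[i] - base[i], reverse=True)
    for i in order[:left]:
        base[i] += 1
    return base


def split_dataset(
    dataset: Dataset,
    fractions: tuple[float, float, float] = (0.6, 0.1, 0.3),
    holdout_classes: Iterable[str] = (),
    seed: int = 0,
) -> Dataset:
    """Assign subjects to TRAIN/VAL/TEST, stratified at the patient level.

    Subjects (never individual trials) are randomly allocated per pathology
    class with largest-remainder rounding of the requested fractions, so a
    subject's trials always share one partition.  Classes in
    ``holdout_classes`` go entirely to TEST (zero-shot evaluation classes).
    Deterministic for a given seed.
    """
    if len(fractions) != 3 or any(not 0 < f < 1 for f in fractions):
        raise ValueError(f"fractions must be three values in (0, 1), got {fractions}")
    if abs(sum(fractions) - 1.0) > 1e-9:
        raise ValueError(f"fractions must sum to 1, got {sum(fractions)}")
    holdout = {str(c) for c in holdout_classes}

    subj_path: dict[str, str] = {}
    for t in dataset.trials:
        prev = subj_path.setdefault(t.subject_id, t.pathology)
        if prev != t.pathology:
            raise ValueError(f"subject {t.subject_id} has inconsistent pathology labels")

    rng = np.random.default_rng(seed)
    partition: dict[str, Split] = {}
    splits = (Split.TRAIN, Split.VAL, Split.TEST)
    by_class: dict[str, list[str]] = {}
    for s, p in sorted(subj_path.items()):
        by_class.setdefault(p, []).append(s)

    assign: dict[str, Split] = {}
    for pathology in sorted(by_class):
        subjects = by_class[pathology]
        if pathology in holdout:
            for s in subjects:
                assign[s] = Split.TEST
            continue
        if len(subjects) < 3:
            raise ValueError(
                f"pathology {pathology!r} has only {len(subjects)} subject(s); "
                "too few to fill train/val/test — consider adding it to holdout_classes"
            )
        counts = _largest_remainder(len(subjects), fractions)
        perm = rng.permutation(len(subjects))
        shuffled = [subjects[i] for i in perm]
        idx = 0
        for split, c in zip(splits, counts):
            for s in shuffled[idx : idx + c]:
                assign[s] = split
            idx += c

    for t in dataset.trials:
        partition[t.trial_id] = assign[t.subject_id]
    return Dataset(trials=dataset.trials, partition=partition)


# ---------------------------------------------------------------------------
# C3D I/O

_DEFAULT_ALIASES: dict[str, tuple[str, ...]] = {name: (name,) for name in MARKER_NAMES}

_EVENT_LABELS = {EventType.IC: "Foot Strike", EventType.FO: "Foot Off"}
_EVENT_CONTEXTS = {Side.L: "Left", Side.R: "Right"}


def load_alias_config(path) -> dict[str, tuple[str, ...]]:
    """Load a marker-label alias table from JSON: {canonical: [labels...]}."""
    with open(path) as fh:
        raw = json.load(fh)
    table = dict(_DEFAULT_ALIASES)
    for canonical, labels in raw.items():
        if canonical not in MARKER_NAMES:
            raise ValueError(f"unknown canonical marker {canonical!r}")
        table[canonical] = tuple([canonical, *labels])
    return table


def read_c3d(path, aliases: Mapping[str, tuple[str, ...]] | None = None,
             subject_id: str = "", pathology: str = "UNKNOWN") -> Trial:
    """Read a C3D motion-capture file into a :class:`Trial`.

    Marker labels are resolved through the alias table; coordinates are
    converted to mm, event annotations become TRUTH gait events (nearest
    frame at the file's point rate), frames are 0-based.
    """
    from . import c3d

    rec = c3d.read_c3d(path)
    table = dict(_DEFAULT_ALIASES)
    if aliases:
        table.update({k: tuple(v) for k, v in aliases.items()})

    scale = 1000.0 if rec.units.strip().lower() in ("m", "meter", "metres", "meters") else 1.0
    label_to_idx = {lab.strip(): i for i, lab in enumerate(rec.labels)}
    markers: dict[str, np.ndarray] = {}
    for canonical in MARKER_NAMES:
        idx = None
        for alias in table[canonical]:
            if alias in label_to_idx:
                idx = label_to_idx[alias]
                break
        if idx is None:
            raise ValueError(f"missing marker {canonical}")
        markers[canonical] = rec.points[:, idx, :] * scale

    rev_label = {v: k for k, v in _EVENT_LABELS.items()}
    rev_ctx = {v: k for k, v in _EVENT_CONTEXTS.items()}
    events = []
    for label, context, time_s in rec.events:
        etype = rev_label.get(label.strip())
        side = rev_ctx.get(context.strip())
        if etype is None or side is None:
            continue
        frame = int(round(time_s * rec.rate))
        if 0 <= frame < rec.points.shape[0]:
            events.append(GaitEvent(etype, side, frame, Source.TRUTH))

    import os

    trial_id = os.path.splitext(os.path.basename(str(path)))[0]
    return Trial(
        trial_id=trial_id,
        subject_id=subject_id or trial_id,
        pathology=pathology,
        fs=rec.rate,
        markers=markers,
        events=events,
    )


def write_trial_c3d(trial: Trial, path) -> None:
    """Write a trial to a C3D file readable by :func:`read_c3d` (units mm)."""
    from . import c3d

    points = np.stack([trial.markers[m] for m in MARKER_NAMES], axis=1)
    if not np.isfinite(points).all():
        raise ValueError("marker trajectories contain non-finite coordinates")
    events = [
        (_EVENT_LABELS[ev.etype], _EVENT_CONTEXTS[ev.side], ev.frame / trial.fs)
        for ev in trial.events
    ]
    c3d.write_c3d(path, points, list(MARKER_NAMES), trial.fs, events, units="mm")


# ---------------------------------------------------------------------------
# HDF5 fixture I/O

_FIXTURE_SCHEMA = "gaitevents-fixture"
_FIXTURE_VERSION = 1

_EVENT_DTYPE = np.dtype(
    [("etype", "S2"), ("side", "S1"), ("frame", "<i8"), ("source", "S9")]
)


def write_fixture(dataset: Dataset, path) -> None:
    """Write a dataset to the portable HDF5 fixture format.

    Layout: /trials/<id>/markers/<name> (Tx3 float64), /trials/<id>/events
    (structured: etype, side, frame, source), trial metadata as attributes,
    and optionally /partition (trial_id, split) pairs.
    """
    import h5py

    with h5py.File(path, "w") as fh:
        fh.attrs["schema"] = _FIXTURE_SCHEMA
        fh.attrs["schema_version"] = _FIXTURE_VERSION
        tg = fh.create_group("trials")
        for t in dataset.trials:
            g = tg.create_group(t.trial_id)
            g.attrs["subject_id"] = t.subject_id
            g.attrs["pathology"] = t.pathology
            g.attrs["fs"] = float(t.fs)
            mg = g.create_group("markers")
            for name in MARKER_NAMES:
                mg.create_dataset(name, data=t.markers[name])
            ev = np.array(
                [
                    (e.etype.value.encode(), e.side.value.encode(), e.frame, e.source.value.encode())
                    for e in t.events
                ],
                dtype=_EVENT_DTYPE,
            )
            g.create_dataset("events", data=ev)
        if dataset.partition is not None:
            pg = fh.create_group("partition")
            ids = sorted(dataset.partition)
            pg.create_dataset("trial_id", data=np.array(ids, dtype="S"))
            pg.create_dataset(
                "split", data=np.array([dataset.partition[i].value for i in ids], dtype="S")
            )


def read_fixture(path) -> Dataset:
    """Read a dataset written by :func:`write_fixture`."""
    import h5py

    with h5py.File(path, "r") as fh:
        schema = fh.attrs.get("schema")
        version = fh.attrs.get("schema_version")
        if schema != _FIXTURE_SCHEMA or version != _FIXTURE_VERSION:
            raise ValueError(
                f"fixture schema mismatch: found {schema!r} v{version!r}, "
                f"expected {_FIXTURE_SCHEMA!r} v{_FIXTURE_VERSION}"
            )
        trials = []
        for tid in sorted(fh["trials"]):
            g = fh["trials"][tid]
            markers = {name: np.asarray(g["markers"][name]) for name in g["markers"]}
            events = [
                GaitEvent(
                    EventType(row["etype"].decode()),
                    Side(row["side"].decode()),
                    int(row["frame"]),
                    Source(row["source"].decode()),
                )
                for row in np.asarray(g["events"])
            ]
            trials.append(
                Trial(
                    trial_id=tid,
                    subject_id=str(g.attrs["subject_id"]),
                    pathology=str(g.attrs["pathology"]),
                    fs=float(g.attrs["fs"]),
                    markers=markers,
                    events=events,
                )
            )
        partition = None
        if "partition" in fh:
            ids = [b.decode() for b in fh["partition"]["trial_id"]]
            sps = [b.decode() for b in fh["partition"]["split"]]
            partition = {i: Split(s) for i, s in zip(ids, sps)}
    return Dataset(trials=trials, partition=partition)
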