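"""Velocity-threshold baseline (modified Ghoussayni-style detector).

IC is detected where the heel marker's sagittal-plane speed drops to a
local minimum below a walking-speed-proportional gate (the fitted IC
threshold of 0 m/s cannot be crossed by a non-negative speed, so the gate
``max(th_ic, ic_gate_factor * v)`` makes the criterion operational); FO is
detected at ascending crossings of the toe speed through
``th_fo_factor * v`` with the fitted factor 1.9.  ``v`` is the trial's
walking speed, estimated from the mid-ankle anterior-posterior drift.
Thresholds can be re-fitted on a training set by grid search.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace

import numpy as np
from scipy.ndimage import uniform_filter1d

from .gait_core import Dataset, EventType, GaitEvent, Side, Source, Trial

__all__ = [
    "HeuristicConfig",
    "TrialKinematics",
    "walking_speed",
    "sagittal_speed",
    "detect_events_heuristic",
    "fit_thresholds",
]


@dataclass(frozen=True)
class HeuristicConfig:
    th_ic: float = 0.0            # m/s; fitted operating point 0
    th_fo_factor: float = 1.9     # FO threshold = th_fo_factor * walking speed
    ic_gate_factor: float = 0.2   # v-proportional gate making th_ic = 0 operational
    min_separation: int = 25      # frames at 150 Hz, scaled by fs/150
    smoothing: int = 5            # moving-average window, frames at 150 Hz

    def __post_init__(self) -> None:
        if self.th_ic < 0:
            raise ValueError("th_ic must be >= 0")
        if self.th_fo_factor <= 0:
            raise ValueError("th_fo_factor must be > 0")
        if self.min_separation < 1 or self.smoothing < 1:
            raise ValueError("min_separation and smoothing must be >= 1")


@dataclass
class TrialKinematics:
    """Walking speed and per-foot heel/toe sagittal speed traces (m/s)."""

    v: float
    heel_speed: dict[str, np.ndarray]
    toe_speed: dict[str, np.ndarray]


def walking_speed(trial: Trial) -> float:
    """Trial walking speed: |mean AP velocity| of the mid-ankle point, m/s.

    Direction-agnostic, so trials walked in -AP give the same value.
    """
    mid = 0.5 * (trial.markers["L_ANKLE"][:, 0] + trial.markers["R_ANKLE"][:, 0])
    disp_mm = mid[-1] - mid[0]
    return abs(disp_mm) / (trial.n_frames - 1) * trial.fs / 1000.0


def sagittal_speed(positions: np.ndarray, fs: float, smoothing: int = 5) -> np.ndarray:
    """Sagittal-plane marker speed sqrt(v_AP^2 + v_V^2) in m/s.

    The velocity components are moving-average smoothed before taking the
    magnitude (smoothing the magnitude itself would rectify marker noise
    into a positive speed floor near the detection gates).  Invariant to
    medio-lateral motion by construction.
    """
    positions = np.asarray(positions, dtype=float)
    if positions.shape[0] < 2:
        raise ValueError("need at least 2 frames")
    vel = np.gradient(positions, axis=0) * fs  # mm/s
    win = max(1, int(round(smoothing * fs / 150.0)))
    vel = uniform_filter1d(vel, size=win, axis=0, mode="nearest")
    return np.hypot(vel[:, 0], vel[:, 2]) / 1000.0


def trial_kinematics(trial: Trial, config: HeuristicConfig | None = None) -> TrialKinematics:
    config = config or HeuristicConfig()
    heel = {}
    toe = {}
    for side in ("L", "R"):
        heel[side] = sagittal_speed(trial.markers[f"{side}_HEEL"], trial.fs, config.smoothing)
        toe[side] = sagittal_speed(trial.markers[f"{side}_TOE"], trial.fs, config.smoothing)
    return TrialKinematics(v=walking_speed(trial), heel_speed=heel, toe_speed=toe)


def _dedup(candidates: list[tuple[int, float]], min_sep: int) -> list[int]:
    """Keep candidates at least min_sep apart, preferring smaller rank value."""
    kept: list[int] = []
    for frame, _ in sorted(candidates, key=lambda c: (c[1], c[0])):
        if all(abs(frame - k) >= min_sep for k in kept):
            kept.append(frame)
    return sorted(kept)


def detect_events_heuristic(
    trial: Trial, config: HeuristicConfig | None = None
) -> list[GaitEvent]:
    """Detect IC and FO events per foot from heel/toe sagittal speeds."""
    config = config or HeuristicConfig()
    kin = trial_kinematics(trial, config)
    min_sep = max(1, int(round(config.min_separation * trial.fs / 150.0)))
    events: list[GaitEvent] = []
    if kin.v <= 1e-6:
        warnings.warn(
            f"trial {trial.trial_id}: walking speed ~0, speed-proportional "
            "thresholds undefined; no events detected",
            stacklevel=2,
        )
        return events
    ic_gate = max(config.th_ic, config.ic_gate_factor * kin.v)
    th_fo = config.th_fo_factor * kin.v
    for side in (Side.L, Side.R):
        hs = kin.heel_speed[side.value]
        # IC: descending entry into the below-gate region; rank by the depth
        # of the following minimum so the deeper minimum wins deduplication.
        entries = np.flatnonzero((hs[1:] < ic_gate) & (hs[:-1] >= ic_gate)) + 1
        candidates = []
        for f in entries:
            end = f
            while end < len(hs) and hs[end] < ic_gate:
                end += 1
            candidates.append((int(f), float(hs[f:end].min())))
        for frame in _dedup(candidates, min_sep):
            events.append(GaitEvent(EventType.IC, side, frame, Source.HEURISTIC))
        # FO: ascending crossing of the toe speed through th_fo; earlier
        # crossing wins deduplication.
        ts = kin.toe_speed[side.value]
        crossings = np.flatnonzero((ts[1:] >= th_fo) & (ts[:-1] < th_fo)) + 1
        for frame in _dedup([(int(f), float(f)) for f in crossings], min_sep):
            events.append(GaitEvent(EventType.FO, side, frame, Source.HEURISTIC))
    return sorted(events, key=lambda e: (e.frame, e.etype.value, e.side.value))


def fit_thresholds(
    train: Dataset | list[Trial],
    th_ic_grid=(0.0, 0.05, 0.1, 0.2),
    th_fo_factor_grid=(1.3, 1.5, 1.7, 1.9, 2.1, 2.3),
    base_config: HeuristicConfig | None = None,
) -> HeuristicConfig:
    """Grid-search thresholds minimizing mean absolute temporal error on the
    training set; ties break toward smaller thresholds."""
    from . import evaluation

    trials = train.trials if isinstance(train, Dataset) else list(train)
    if not th_ic_grid or not th_fo_factor_grid:
        raise ValueError("threshold grids must be nonempty")
    base = base_config or HeuristicConfig()
    best_cfg, best_mae = None, np.inf
    for th_ic in sorted(th_ic_grid):
        for th_fo in sorted(th_fo_factor_grid):
            cfg = replace(base, th_ic=float(th_ic), th_fo_factor=float(th_fo))
            results = []
            for trial in trials:
                preds = detect_events_heuristic(trial, cfg)
                for etype in (EventType.IC, EventType.FO):
                    results.append(
                        evaluation.match_trial(
                            [e for e in preds if e.etype == etype], trial, etype
                        )
                    )
            combined = evaluation.MatchResult.combine(results)
            if combined.n_matched == 0:
                continue
            mae = evaluation.temporal_error_summary(combined, n_boot=0)[0]
            # penalize undetected events so degenerate thresholds cannot win
            mae += 1000.0 * combined.n_fn / max(1, len(combined.matches))
            if mae < best_mae - 1e-12:
                best_cfg, best_mae = cfg, mae
    if best_cfg is None:
        raise ValueError("no threshold combination produced any matched events")
    return best_cfg
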