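"""Parametric synthetic-gait simulator with construction-defined ground truth.

Each foot follows a cyclic stance/swing phase schedule: during stance the
foot markers are fixed to the ground (constant AP and vertical position up
to measurement noise); during swing each marker travels one stride along a
smooth C1 arc with a vertical clearance bump.  The two feet are anti-phased.
Initial contact (IC) is the first stance frame of the strike-leading marker
(heel for heel strikers, toe for forefoot strikers), foot off (FO) the first
frame after the toe's last stance frame — both derived directly from the
sampled contact schedule, so every trial carries exact TRUTH events.

The swing arc is not a biomechanical model: only the event-adjacent
kinematic signatures matter (near-zero marker speed in stance, a sharp toe
acceleration at push-off, heel deceleration into landing, reduced toe
clearance under foot drag).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from enum import Enum

import numpy as np

from .gait_core import (
    MARKER_NAMES,
    Dataset,
    EventType,
    GaitEvent,
    Side,
    Source,
    Trial,
)

__all__ = [
    "StrikePattern",
    "GaitProfile",
    "CohortSpec",
    "simulate_trial",
    "simulate_cohort",
    "PRESET_PROFILES",
]


class StrikePattern(str, Enum):
    HEEL = "HEEL"
    FOREFOOT = "FOREFOOT"
    MIDFOOT = "MIDFOOT"


# Marker geometry constants (mm).  Ground offsets are config constants, not
# anatomical claims; ankle rides above the heel with a fixed offset.
HEEL_GROUND_MM = 25.0
TOE_GROUND_MM = 15.0
ANKLE_OFFSET_MM = (30.0, 0.0, 45.0)   # ankle = heel + offset (V total 70 mm)
FOOT_LENGTH_MM = 150.0
HEEL_CLEARANCE_MM = 120.0
TOE_CLEARANCE_MM = 40.0
ML_HALF_WIDTH_MM = 60.0               # lateral offset of each foot from midline
HEEL_RISE_FRACTION = 0.25             # heel lifts this fraction of stance before FO
# Swing velocity shaping (fractions of swing spent accelerating / decelerating).
# The toe leaves the ground with a sharp push-off (short rise), the heel lands
# with a sharp deceleration (short fall) — the signatures velocity-threshold
# event detection relies on.
HEEL_SWING_SHAPE = (0.45, 0.10)
TOE_SWING_SHAPE = (0.05, 0.45)
_T0_S = 0.3                           # first left-foot IC (s)


@dataclass(frozen=True)
class GaitProfile:
    """Parameters of one synthetic walking persona."""

    name: str
    walking_speed: float = 1.2        # m/s
    cadence: float = 112.0            # steps/min (both feet)
    stance_fraction: float = 0.62     # fraction of the gait cycle in stance
    step_length_cv: float = 0.02      # per-cycle stride-length jitter (CV)
    strike_pattern: StrikePattern = StrikePattern.HEEL
    heel_toe_offset_ms: float = 60.0  # >0: heel contacts first; <0: toe first
    drag_severity: float = 0.0        # in [0,1]; scales down swing toe clearance
    noise_sd_mm: float = 1.0          # additive white Gaussian marker noise
    duration_s: float = 5.0
    fs: float = 150.0

    def __post_init__(self) -> None:
        object.__setattr__(self, "strike_pattern", StrikePattern(self.strike_pattern))
        if self.walking_speed <= 0 or self.cadence <= 0 or self.duration_s <= 0 or self.fs <= 0:
            raise ValueError("walking_speed, cadence, duration_s and fs must be positive")
        if not 0.4 < self.stance_fraction < 0.8:
            raise ValueError(f"stance_fraction must be in (0.4, 0.8), got {self.stance_fraction}")
        if self.step_length_cv < 0 or self.noise_sd_mm < 0:
            raise ValueError("step_length_cv and noise_sd_mm must be >= 0")
        if not 0 <= self.drag_severity <= 1:
            raise ValueError(f"drag_severity must be in [0, 1], got {self.drag_severity}")
        if self.strike_pattern is StrikePattern.HEEL and self.heel_toe_offset_ms < 0:
            raise ValueError("HEEL strike requires heel_toe_offset_ms >= 0")
        if self.strike_pattern is StrikePattern.FOREFOOT and self.heel_toe_offset_ms > 0:
            raise ValueError("FOREFOOT strike requires heel_toe_offset_ms <= 0")

    @property
    def cycle_s(self) -> float:
        return 120.0 / self.cadence

    @property
    def stride_m(self) -> float:
        return self.walking_speed * self.cycle_s


@dataclass(frozen=True)
class CohortSpec:
    """A cohort: (profile, n_subjects, trials_per_subject) groups plus a seed."""

    profiles: tuple[tuple[GaitProfile, int, int], ...]
    seed: int = 0

    def __post_init__(self) -> None:
        names = [p.name for p, _, _ in self.profiles]
        if len(set(names)) != len(names):
            raise ValueError(f"duplicate profile names in cohort spec: {names}")
        for p, n_sub, n_tr in self.profiles:
            if n_sub < 1 or n_tr < 1:
                raise ValueError("n_subjects and trials_per_subject must be >= 1")


def _swing_shape(tau: np.ndarray, rise: float, fall: float) -> np.ndarray:
    """Normalized C1 swing displacement: 0 -> 1 with zero end velocities.

    Velocity ramps up as sin^2 over the first ``rise`` fraction of the swing,
    cruises, then ramps down over the last ``fall`` fraction.
    """
    tau = np.clip(tau, 0.0, 1.0)
    c = 1.0 - rise / 2.0 - fall / 2.0
    out = np.empty_like(tau)
    lo = tau <= rise
    hi = tau >= 1.0 - fall
    mid = ~lo & ~hi
    out[lo] = tau[lo] / 2.0 - (rise / (2 * np.pi)) * np.sin(np.pi * tau[lo] / rise)
    out[mid] = rise / 2.0 + (tau[mid] - rise)
    w = 1.0 - tau[hi]
    out[hi] = (rise / 2.0 + (1.0 - fall - rise) + fall / 2.0
               - w / 2.0 + (fall / (2 * np.pi)) * np.sin(np.pi * w / fall))
    return out / c


def _marker_track(
    t: np.ndarray,
    downs: np.ndarray,
    ups: np.ndarray,
    anchors_mm: np.ndarray,
    ground_mm: float,
    clearance_mm: float,
    shape: tuple[float, float],
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Sample one marker's AP and V tracks plus its ground-contact indicator.

    downs/ups are the stance entry/exit times of consecutive cycles
    (downs[0] <= 0 covers the initial condition, ups[-1] = +inf the tail);
    anchors_mm the stance AP positions.
    """
    k = np.searchsorted(downs, t, side="right") - 1
    k = np.clip(k, 0, len(downs) - 1)
    in_stance = t < ups[k]
    ap = anchors_mm[k].astype(float).copy()
    v = np.full_like(t, ground_mm)
    sw = ~in_stance
    if sw.any():
        ks = k[sw]
        tau = (t[sw] - ups[ks]) / (downs[ks + 1] - ups[ks])
        ap[sw] = anchors_mm[ks] + (anchors_mm[ks + 1] - anchors_mm[ks]) * _swing_shape(
            tau, *shape
        )
        v[sw] = ground_mm + clearance_mm * np.sin(np.pi * np.clip(tau, 0, 1)) ** 2
    return ap, v, in_stance


def simulate_trial(profile: GaitProfile, subject_id: str, trial_id: str, seed: int) -> Trial:
    """Simulate one trial; deterministic for a given (profile, seed)."""
    p = profile
    fs, cycle = p.fs, p.cycle_s
    stance_s = p.stance_fraction * cycle
    if p.duration_s < _T0_S + 2 * cycle:
        raise ValueError(
            f"duration {p.duration_s:.2f}s holds fewer than 2 full gait cycles "
            f"(cycle {cycle:.2f}s)"
        )
    T = int(round(p.duration_s * fs))
    t = np.arange(T) / fs
    rng = np.random.default_rng(seed)

    offset_s = p.heel_toe_offset_ms / 1000.0
    n_cycles = int(math.ceil(p.duration_s / cycle)) + 2
    markers: dict[str, np.ndarray] = {}
    events: list[GaitEvent] = []

    for side, t0, x0_m in (
        (Side.L, _T0_S, 0.0),
        (Side.R, _T0_S + cycle / 2.0, p.stride_m / 2.0),
    ):
        # nominal foot IC/FO times for cycles -1 .. n_cycles
        ks = np.arange(-1, n_cycles + 1)
        ic_t = t0 + ks * cycle
        fo_t = ic_t + stance_s
        strides = p.stride_m * np.maximum(
            0.1, 1.0 + p.step_length_cv * rng.standard_normal(len(ks) + 1)
        )
        anchors_m = x0_m - p.stride_m + np.concatenate(([0.0], np.cumsum(strides)))[: len(ks)]
        anchors_mm = anchors_m * 1000.0

        if p.strike_pattern is StrikePattern.FOREFOOT:
            heel_down, toe_down = ic_t - offset_s, ic_t
        else:  # HEEL or MIDFOOT (offset 0 for MIDFOOT-style simultaneous contact)
            heel_down, toe_down = ic_t, ic_t + offset_s
        heel_up = fo_t - HEEL_RISE_FRACTION * stance_s
        toe_up = fo_t.copy()

        toe_clear = TOE_CLEARANCE_MM * (1.0 - p.drag_severity)
        heel_clear = HEEL_CLEARANCE_MM * (1.0 - 0.5 * p.drag_severity)
        inf = np.array([np.inf])
        heel_ap, heel_v, _ = _marker_track(
            t, heel_down, np.concatenate((heel_up[:-1], inf)), anchors_mm,
            HEEL_GROUND_MM, heel_clear, HEEL_SWING_SHAPE,
        )
        toe_ap, toe_v, toe_contact = _marker_track(
            t, toe_down, np.concatenate((toe_up[:-1], inf)), anchors_mm + FOOT_LENGTH_MM,
            TOE_GROUND_MM, toe_clear, TOE_SWING_SHAPE,
        )
        lead_down = toe_down if p.strike_pattern is StrikePattern.FOREFOOT else heel_down
        lead_up = toe_up if p.strike_pattern is StrikePattern.FOREFOOT else heel_up
        k = np.clip(np.searchsorted(lead_down, t, side="right") - 1, 0, len(lead_down) - 1)
        lead_contact = t < np.concatenate((lead_up[:-1], inf))[k]

        ml = ML_HALF_WIDTH_MM if side is Side.L else -ML_HALF_WIDTH_MM
        prefix = side.value
        markers[f"{prefix}_HEEL"] = np.column_stack((heel_ap, np.full(T, ml), heel_v))
        markers[f"{prefix}_TOE"] = np.column_stack((toe_ap, np.full(T, ml), toe_v))
        markers[f"{prefix}_ANKLE"] = markers[f"{prefix}_HEEL"] + np.asarray(ANKLE_OFFSET_MM)

        ic_frames = np.flatnonzero(lead_contact[1:] & ~lead_contact[:-1]) + 1
        fo_frames = np.flatnonzero(~toe_contact[1:] & toe_contact[:-1]) + 1
        events.extend(GaitEvent(EventType.IC, side, int(f), Source.TRUTH) for f in ic_frames)
        events.extend(GaitEvent(EventType.FO, side, int(f), Source.TRUTH) for f in fo_frames)

    if p.noise_sd_mm > 0:
        for name in MARKER_NAMES:
            markers[name] = markers[name] + rng.normal(0.0, p.noise_sd_mm, size=(T, 3))

    return Trial(
        trial_id=trial_id,
        subject_id=subject_id,
        pathology=f"SYNTH-{p.name}",
        fs=fs,
        markers=markers,
        events=events,
    )


def simulate_cohort(spec: CohortSpec) -> Dataset:
    """Simulate a cohort: per-subject jitter of speed/cadence, deterministic seed."""
    trials = []
    for pi, (profile, n_subjects, trials_per_subject) in enumerate(spec.profiles):
        for si in range(n_subjects):
            ss = np.random.SeedSequence((spec.seed, pi, si))
            sub_rng = np.random.default_rng(ss)
            jitter = 1.0 + 0.04 * sub_rng.standard_normal(2)
            jitter = np.clip(jitter, 0.85, 1.15)
            subject_profile = replace(
                profile,
                walking_speed=profile.walking_speed * float(jitter[0]),
                cadence=profile.cadence * float(jitter[1]),
            )
            subject_id = f"{profile.name}-S{si:03d}"
            trial_seeds = ss.generate_state(trials_per_subject + 1)[1:] % (2**31)
            for ti in range(trials_per_subject):
                trials.append(
                    simulate_trial(
                        subject_profile,
                        subject_id=subject_id,
                        trial_id=f"{subject_id}-T{ti:02d}",
                        seed=int(trial_seeds[ti]),
                    )
                )
    return Dataset(trials=trials)


#: Test personas loosely mirroring a clinical cohort's strike patterns; they
#: are kinematic caricatures, not clinical models.
PRESET_PROFILES: dict[str, GaitProfile] = {
    "HC-heel": GaitProfile(
        name="HC-heel", walking_speed=1.2, cadence=112, stance_fraction=0.62,
        step_length_cv=0.02, strike_pattern=StrikePattern.HEEL, heel_toe_offset_ms=60,
        drag_severity=0.0, noise_sd_mm=1.0,
    ),
    "MD-baseline": GaitProfile(
        name="MD-baseline", walking_speed=1.1, cadence=115, stance_fraction=0.61,
        step_length_cv=0.03, strike_pattern=StrikePattern.HEEL, heel_toe_offset_ms=50,
        drag_severity=0.0, noise_sd_mm=1.0,
    ),
    "ICP-forefoot": GaitProfile(
        name="ICP-forefoot", walking_speed=0.9, cadence=120, stance_fraction=0.60,
        step_length_cv=0.05, strike_pattern=StrikePattern.FOREFOOT, heel_toe_offset_ms=-60,
        drag_severity=0.2, noise_sd_mm=1.5,
    ),
    "DF-forefoot-drag": GaitProfile(
        name="DF-forefoot-drag", walking_speed=0.8, cadence=105, stance_fraction=0.58,
        step_length_cv=0.06, strike_pattern=StrikePattern.FOREFOOT, heel_toe_offset_ms=-70,
        drag_severity=0.7, noise_sd_mm=1.5,
    ),
    "CF-short-stride": GaitProfile(
        name="CF-short-stride", walking_speed=0.7, cadence=130, stance_fraction=0.63,
        step_length_cv=0.06, strike_pattern=StrikePattern.MIDFOOT, heel_toe_offset_ms=0,
        drag_severity=0.1, noise_sd_mm=1.5,
    ),
}
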