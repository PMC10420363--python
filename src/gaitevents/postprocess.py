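"""Convert per-frame class probabilities into discrete gait events.

Peak detection on the left/right probability channels with the 0.01
threshold, plus duplicate-peak suppression: among local maxima above the
threshold, the subset maximizing total probability mass subject to a
minimum per-class frame separation is kept (exact dynamic program).
Plateau ties break to the lowest frame index.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .gait_core import EventType, GaitEvent, Side, Source, Trial

__all__ = [
    "PostprocessConfig",
    "detect_events",
    "detect_events_for_trial",
    "local_peaks",
]


@dataclass(frozen=True)
class PostprocessConfig:
    """threshold: minimum peak probability; min_separation: frames at 150 Hz
    between same-class events (scaled by fs/150 at detection time)."""

    threshold: float = 0.01
    min_separation: int = 25

    def __post_init__(self) -> None:
        if not 0 < self.threshold < 1:
            raise ValueError(f"threshold must be in (0, 1), got {self.threshold}")
        if self.min_separation < 1:
            raise ValueError("min_separation must be >= 1")


def local_peaks(x: np.ndarray, threshold: float) -> list[int]:
    """Indices of local maxima strictly above ``threshold``.

    A plateau is a single peak reported at its first frame; an endpoint
    counts as a peak when its interior neighbour is lower.
    """
    x = np.asarray(x, dtype=float)
    T = len(x)
    peaks = []
    i = 0
    while i < T:
        j = i
        while j + 1 < T and x[j + 1] == x[i]:
            j += 1
        left_lower = i == 0 or x[i - 1] < x[i]
        right_lower = j == T - 1 or x[j + 1] < x[i]
        if left_lower and right_lower and x[i] > threshold and not (i == 0 and j == T - 1):
            peaks.append(i)
        i = j + 1
    return peaks


def _select_peaks(frames: list[int], heights: list[float], min_sep: int) -> list[int]:
    """Max-total-probability subset of peaks with pairwise separation >= min_sep."""
    n = len(frames)
    if n == 0:
        return []
    best = np.zeros(n)
    prev = np.full(n, -1)
    for i in range(n):
        b, p = 0.0, -1
        for j in range(i):
            if frames[i] - frames[j] >= min_sep and best[j] > b:
                b, p = best[j], j
        best[i] = heights[i] + b
        prev[i] = p
    end = int(np.argmax(best))
    out = []
    while end >= 0:
        out.append(frames[end])
        end = prev[end]
    return out[::-1]


def detect_events(
    probs: np.ndarray,
    etype: EventType,
    config: PostprocessConfig | None = None,
    fs: float = 150.0,
) -> list[GaitEvent]:
    """Detect events of one type from a T x 3 row-stochastic probability matrix."""
    config = config or PostprocessConfig()
    probs = np.asarray(probs, dtype=float)
    if probs.ndim != 2 or probs.shape[1] != 3:
        raise ValueError(f"probs must be T x 3, got {probs.shape}")
    if not np.allclose(probs.sum(axis=1), 1.0, atol=1e-4):
        raise ValueError("probability rows must sum to 1")
    min_sep = max(1, int(round(config.min_separation * fs / 150.0)))
    events = []
    for cls, side in ((1, Side.L), (2, Side.R)):
        col = probs[:, cls]
        frames = local_peaks(col, config.threshold)
        kept = _select_peaks(frames, [float(col[f]) for f in frames], min_sep)
        events.extend(GaitEvent(etype, side, f, Source.MODEL) for f in kept)
    return sorted(events, key=lambda e: (e.frame, e.side.value))


def detect_events_for_trial(model, trial: Trial, config: PostprocessConfig | None = None):
    """Full inference path: features -> normalize -> predict -> peak detection."""
    from .detector import predict_probabilities
    from .features import assemble_features, normalize_tensor

    tensor = normalize_tensor(assemble_features(trial))
    probs = predict_probabilities(model, tensor)
    return detect_events(probs, model.config.etype, config, fs=trial.fs)
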