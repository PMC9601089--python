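"""Clip-level view prediction from per-frame pleural probabilities.

A lung-ultrasound (LUS) clip is a short video; a frame classifier emits,
for every frame, the probability ``p`` that the frame shows a *pleural*
view (the positive class; *parenchymal* is the negative class).  A single
clip-level call is produced by (1) smoothing the frame series with a
moving average of width ``w`` and (2) calling the clip pleural when at
least ``tau`` consecutive smoothed values meet or exceed a classification
threshold ``t``.  The contiguity requirement makes the rule robust to the
curtain sign — a respiratory artifact in which individual frames of a
pleural clip transiently resemble parenchymal frames.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from typing import Optional, Sequence

import numpy as np

__all__ = [
    "ViewLabel",
    "FrameProbSeries",
    "ClipHyperparams",
    "ClipPrediction",
    "moving_average",
    "longest_run_at_or_above",
    "classify_clip",
    "frame_class",
]


class ViewLabel(str, Enum):
    """The two LUS views. Pleural is the positive class by convention."""

    PARENCHYMAL = "parenchymal"
    PLEURAL = "pleural"

    def __str__(self) -> str:  # stable for CSV round trips
        return self.value


@dataclass(frozen=True)
class FrameProbSeries:
    """One clip's ordered per-frame pleural probabilities.

    Parameters
    ----------
    clip_id, patient_id : str
        Identifiers; multiple clips may share a patient.
    probs : sequence of float
        Per-frame probability of the pleural view, in acquisition order.
    true_label : ViewLabel, optional
        Expert-annotated view of the whole clip, when known.
    """

    clip_id: str
    patient_id: str
    probs: tuple = field(repr=False)
    true_label: Optional[ViewLabel] = None

    def __post_init__(self) -> None:
        arr = np.asarray(self.probs, dtype=float)
        if arr.ndim != 1 or arr.size == 0:
            raise ValueError(f"clip {self.clip_id!r}: probs must be a non-empty 1-d sequence")
        if np.any(~np.isfinite(arr)) or arr.min() < 0.0 or arr.max() > 1.0:
            raise ValueError(f"clip {self.clip_id!r}: probabilities must lie in [0, 1]")
        object.__setattr__(self, "probs", tuple(float(p) for p in arr))

    def __len__(self) -> int:
        return len(self.probs)


@dataclass(frozen=True)
class ClipHyperparams:
    """The (tau, t, w) triple governing clip-level prediction.

    tau : minimum number of consecutive qualifying smoothed frames.
    t   : classification threshold applied to smoothed probabilities.
    w   : moving-average window width, in frames.
    """

    tau: int
    t: float
    w: int

    def __post_init__(self) -> None:
        if int(self.tau) != self.tau or self.tau < 1:
            raise ValueError(f"tau must be a positive integer, got {self.tau}")
        if int(self.w) != self.w or self.w < 1:
            raise ValueError(f"w must be a positive integer, got {self.w}")
        if not 0.0 <= self.t <= 1.0:
            raise ValueError(f"t must lie in [0, 1], got {self.t}")
        object.__setattr__(self, "tau", int(self.tau))
        object.__setattr__(self, "w", int(self.w))
        object.__setattr__(self, "t", float(self.t))


@dataclass(frozen=True)
class ClipPrediction:
    """Result of applying the clip rule to one probability series."""

    clip_id: str
    predicted: ViewLabel
    smoothed: tuple
    longest_qualifying_run: int
    mean_raw_prob: float
    patient_id: str = ""
    true_label: Optional[ViewLabel] = None


def moving_average(probs: Sequence[float], w: int) -> np.ndarray:
    """Moving average over every fully contained window of ``w`` frames.

    Returns an array of length ``len(probs) - w + 1``.  No padding is
    applied at the boundaries; when ``w`` exceeds the series length the
    single global mean is returned.
    """
    arr = np.asarray(probs, dtype=float)
    if arr.ndim != 1 or arr.size == 0:
        raise ValueError("probs must be a non-empty 1-d sequence")
    if int(w) != w or w < 1:
        raise ValueError(f"window width w must be a positive integer, got {w}")
    w = int(w)
    if w >= arr.size:
        return np.array([arr.mean()])
    windows = np.lib.stride_tricks.sliding_window_view(arr, w)
    return windows.mean(axis=1)


def longest_run_at_or_above(values: Sequence[float], t: float) -> int:
    """Length of the longest run of consecutive values ``>= t``."""
    mask = np.asarray(values, dtype=float) >= t
    if not mask.any():
        return 0
    # run lengths via cumulative count reset at gaps
    padded = np.concatenate(([False], mask, [False]))
    edges = np.flatnonzero(np.diff(padded.astype(np.int8)))
    starts, stops = edges[::2], edges[1::2]
    return int((stops - starts).max())


def classify_clip(series: FrameProbSeries, hp: ClipHyperparams) -> ClipPrediction:
    """Apply moving-average smoothing then the contiguous-threshold rule.

    The clip is predicted pleural iff the smoothed series contains at
    least ``hp.tau`` consecutive values each ``>= hp.t``; otherwise
    parenchymal.  A smoothed series shorter than ``tau`` can never
    qualify, so such clips default to parenchymal.
    """
    smoothed = moving_average(series.probs, hp.w)
    run = longest_run_at_or_above(smoothed, hp.t)
    predicted = ViewLabel.PLEURAL if run >= hp.tau else ViewLabel.PARENCHYMAL
    return ClipPrediction(
        clip_id=series.clip_id,
        predicted=predicted,
        smoothed=tuple(float(v) for v in smoothed),
        longest_qualifying_run=run,
        mean_raw_prob=float(np.mean(series.probs)),
        patient_id=series.patient_id,
        true_label=series.true_label,
    )


def frame_class(p: float) -> ViewLabel:
    """Single-frame decision: pleural iff ``p >= 0.5``."""
    if not 0.0 <= p <= 1.0:
        raise ValueError(f"frame probability must lie in [0, 1], got {p}")
    return ViewLabel.PLEURAL if p >= 0.5 else ViewLabel.PARENCHYMAL
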