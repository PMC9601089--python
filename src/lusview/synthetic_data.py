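"""Synthetic frame-probability series and annotation event logs.

Real inputs to this toolkit are per-frame pleural probabilities emitted
by a frame classifier, and timed label/skip/discard events exported from
an annotation platform.  Neither can be shipped, so this module
generates both with the statistical structure the clip rule is designed
around:

* parenchymal clips — a sustained low probability baseline plus noise;
* plain pleural clips — a sustained high baseline plus noise;
* curtain-sign pleural clips — a square-wave oscillation between the
  pleural baseline and a low excursion, emulating aerated lung sliding
  over abdominal organs with each breath;
* probe-movement clips — a single mid-clip switch between the two
  baselines, labelled by the longer segment.

Event logs draw per-action durations from a normal truncated at zero,
with configurable means (skipping an irrelevant clip is the fast action
the triage workflow tries to eliminate).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, List, Sequence, Tuple, Union

import numpy as np

from .annotation_efficiency import AnnotationAction, AnnotationEvent, SprintKind
from .clip_aggregation import FrameProbSeries, ViewLabel

__all__ = [
    "SeriesGenConfig",
    "EventGenConfig",
    "generate_series_dataset",
    "generate_event_log",
    "make_sprint_mix",
]

DISCARD = "discard"

ClipLabel = Tuple[str, Union[ViewLabel, str]]


@dataclass(frozen=True)
class SeriesGenConfig:
    """Configuration of the probability-series generator.

    Baselines default to well separated values (0.1 vs 0.9) with small
    Gaussian noise, the regime in which a competent frame classifier
    operates.  Clip lengths default to 100-350 frames (a few seconds of
    ultrasound at typical frame rates); the curtain-sign period defaults
    to 60 frames, roughly one respiratory excursion.  Patients receive
    a Poisson-distributed number of clips so the patient-grouped fold
    machinery is exercised.
    """

    n_clips: int = 200
    pleural_fraction: float = 0.5
    clip_length_range: Tuple[int, int] = (100, 350)
    parenchymal_mean: float = 0.1
    pleural_mean: float = 0.9
    noise_sd: float = 0.05
    curtain_fraction: float = 0.3
    curtain_period_frames: int = 60
    curtain_low: float = 0.2
    probe_switch_fraction: float = 0.05
    clips_per_patient_mean: float = 2.4
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_clips < 1:
            raise ValueError("n_clips must be positive")
        lo, hi = self.clip_length_range
        if lo < 1 or hi < lo:
            raise ValueError(f"invalid clip_length_range {self.clip_length_range}")
        for name in (
            "pleural_fraction", "parenchymal_mean", "pleural_mean",
            "curtain_fraction", "curtain_low", "probe_switch_fraction",
        ):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1], got {v}")
        if self.parenchymal_mean >= self.pleural_mean:
            raise ValueError("parenchymal_mean must be below pleural_mean")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")
        if self.curtain_period_frames < 1:
            raise ValueError("curtain_period_frames must be positive")
        if self.clips_per_patient_mean < 1:
            raise ValueError("clips_per_patient_mean must be at least 1")


@dataclass(frozen=True)
class EventGenConfig:
    """Configuration of the annotation event-log generator.

    Defaults describe a four-person team annotating 195-clip sprints,
    with mean action durations of 20 s to label, 8.5 s to skip and 10 s
    to discard a clip.
    """

    n_annotators: int = 4
    clips_per_sprint: int = 195
    mean_label_s: float = 20.0
    mean_skip_s: float = 8.5
    mean_discard_s: float = 10.0
    duration_sd_s: float = 2.5
    discard_fraction: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_annotators < 1 or self.clips_per_sprint < 1:
            raise ValueError("n_annotators and clips_per_sprint must be positive")
        for name in ("mean_label_s", "mean_skip_s", "mean_discard_s"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.duration_sd_s < 0:
            raise ValueError("duration_sd_s must be non-negative")
        if not 0.0 <= self.discard_fraction <= 1.0:
            raise ValueError("discard_fraction must lie in [0, 1]")


def _assign_patients(n_clips: int, mean_clips: float, rng: np.random.Generator) -> List[str]:
    """Patient id per clip; counts per patient ~ 1 + Poisson(mean - 1)."""
    ids: List[str] = []
    patient = 0
    while len(ids) < n_clips:
        count = 1 + int(rng.poisson(mean_clips - 1.0))
        ids.extend([f"pat{patient:04d}"] * count)
        patient += 1
    return ids[:n_clips]


def generate_series_dataset(config: SeriesGenConfig) -> List[FrameProbSeries]:
    """Generate labelled frame-probability series. Deterministic per seed."""
    rng = np.random.default_rng(config.seed)
    patients = _assign_patients(config.n_clips, config.clips_per_patient_mean, rng)
    lo, hi = config.clip_length_range
    half_period = max(1, config.curtain_period_frames // 2)

    dataset: List[FrameProbSeries] = []
    for i in range(config.n_clips):
        length = int(rng.integers(lo, hi + 1))
        frames = np.arange(length)
        if rng.random() < config.probe_switch_fraction:
            # one change point; truth follows the longer segment
            cut = int(rng.integers(1, length)) if length > 1 else 1
            first_pleural = bool(rng.random() < 0.5)
            lo_base, hi_base = config.parenchymal_mean, config.pleural_mean
            first, second = (hi_base, lo_base) if first_pleural else (lo_base, hi_base)
            base = np.where(frames < cut, first, second)
            major_first = cut >= length - cut  # tie -> first segment
            pleural_major = first_pleural if major_first else not first_pleural
            label = ViewLabel.PLEURAL if pleural_major else ViewLabel.PARENCHYMAL
        elif rng.random() < config.pleural_fraction:
            label = ViewLabel.PLEURAL
            if rng.random() < config.curtain_fraction:
                phase = (frames // half_period) % 2
                base = np.where(phase == 0, config.pleural_mean, config.curtain_low)
            else:
                base = np.full(length, config.pleural_mean)
        else:
            label = ViewLabel.PARENCHYMAL
            base = np.full(length, config.parenchymal_mean)
        probs = base + rng.normal(0.0, config.noise_sd, size=length)
        np.clip(probs, 0.0, 1.0, out=probs)
        dataset.append(
            FrameProbSeries(
                clip_id=f"clip{i:05d}",
                patient_id=patients[i],
                probs=tuple(probs),
                true_label=label,
            )
        )
    return dataset


def make_sprint_mix(
    n_parenchymal: int, n_pleural: int, n_discard: int, prefix: str = "clip"
) -> List[ClipLabel]:
    """Convenience clip-label list with the given class mix."""
    labels: List[ClipLabel] = []
    labels += [(f"{prefix}-par{i:04d}", ViewLabel.PARENCHYMAL) for i in range(n_parenchymal)]
    labels += [(f"{prefix}-ple{i:04d}", ViewLabel.PLEURAL) for i in range(n_pleural)]
    labels += [(f"{prefix}-dis{i:04d}", DISCARD) for i in range(n_discard)]
    return labels


_ACTION_FOR_LABEL = {
    ViewLabel.PARENCHYMAL: AnnotationAction.LABEL_PARENCHYMAL,
    ViewLabel.PLEURAL: AnnotationAction.SKIP_PLEURAL,
    DISCARD: AnnotationAction.DISCARD,
}


def generate_event_log(
    clip_labels: Iterable[ClipLabel],
    config: EventGenConfig,
    sprint_kind: SprintKind = SprintKind.CONTROL,
) -> List[AnnotationEvent]:
    """Generate timed annotation events for a parenchymal-specific task.

    Parenchymal clips receive label events, pleural clips skip events
    and flagged clips discard events; when ``config.discard_fraction``
    is positive, unflagged clips are additionally discarded at that
    rate.  Clips are shuffled then dealt to annotators in consecutive
    sprints of ``clips_per_sprint``.  Durations are normal with the
    configured per-action mean, truncated at zero.  Deterministic per
    seed.
    """
    clip_labels = list(clip_labels)
    if not clip_labels:
        raise ValueError("no clips supplied")
    rng = np.random.default_rng(config.seed)
    order = rng.permutation(len(clip_labels))

    mean_for = {
        AnnotationAction.LABEL_PARENCHYMAL: config.mean_label_s,
        AnnotationAction.SKIP_PLEURAL: config.mean_skip_s,
        AnnotationAction.DISCARD: config.mean_discard_s,
    }
    events: List[AnnotationEvent] = []
    for pos, idx in enumerate(order):
        clip_id, label = clip_labels[idx]
        if label not in _ACTION_FOR_LABEL:
            raise ValueError(f"clip {clip_id!r}: unrecognised label {label!r}")
        action = _ACTION_FOR_LABEL[label]
        if action is not AnnotationAction.DISCARD and config.discard_fraction > 0:
            if rng.random() < config.discard_fraction:
                action = AnnotationAction.DISCARD
        duration = max(0.0, rng.normal(mean_for[action], config.duration_sd_s))
        annotator = (pos // config.clips_per_sprint) % config.n_annotators
        sprint_round = pos // (config.clips_per_sprint * config.n_annotators)
        events.append(
            AnnotationEvent(
                clip_id=clip_id,
                annotator_id=f"ann{annotator:02d}",
                sprint_id=f"{sprint_kind.value}-r{sprint_round}-ann{annotator:02d}",
                sprint_kind=sprint_kind,
                action=action,
                duration_s=duration,
            )
        )
    return events
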