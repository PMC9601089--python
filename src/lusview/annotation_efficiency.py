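"""Annotation-throughput metrics from timed event logs.

Each annotation event is one timed action by one annotator on one clip:
labelling a task-relevant (parenchymal) clip, skipping a task-irrelevant
(pleural) clip, or discarding an unusable clip.  Rates are computed per
annotator within each sprint kind (control vs. auto-partitioned), with
active sprint time taken as the sum of recorded event durations.
Discards count toward time but toward neither the label nor the skip
rate.  Sprint kinds are compared with a one-sided paired t-test, and
per-clip skip cost extrapolates to larger databases.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from typing import Dict, Iterable, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "SprintKind",
    "AnnotationAction",
    "AnnotationEvent",
    "EfficiencyReport",
    "ExtrapolationSpec",
    "sprint_metrics",
    "paired_one_sided_t",
    "extrapolate_savings",
    "sprint_time_saved",
    "METRIC_DIRECTIONS",
]

SECONDS_PER_DAY = 86_400.0


class SprintKind(str, Enum):
    CONTROL = "control"
    AUTO_PARTITIONED = "auto_partitioned"

    def __str__(self) -> str:
        return self.value


class AnnotationAction(str, Enum):
    LABEL_PARENCHYMAL = "label_parenchymal"
    SKIP_PLEURAL = "skip_pleural"
    DISCARD = "discard"

    def __str__(self) -> str:
        return self.value


@dataclass(frozen=True)
class AnnotationEvent:
    """One timed label/skip/discard action."""

    clip_id: str
    annotator_id: str
    sprint_id: str
    sprint_kind: SprintKind
    action: AnnotationAction
    duration_s: float

    def __post_init__(self) -> None:
        if self.duration_s < 0:
            raise ValueError(
                f"event on clip {self.clip_id!r}: duration must be non-negative"
            )


# Directions in which each metric is expected to improve under
# auto-partitioning: more relevant labels per hour, fewer skips, less
# time spent skipping.
METRIC_DIRECTIONS: Dict[str, str] = {
    "labels_per_hour": "greater",       # auto > control
    "skips_per_hour": "less",           # auto < control
    "skip_time_min": "less",
}


@dataclass(frozen=True)
class EfficiencyReport:
    """Per-annotator rates plus cross-annotator summaries.

    per_annotator : one row per annotator x sprint_kind with
        labels_per_hour, skips_per_hour, skip_time_min and total_hours.
    summary : mean and sd (n-1 denominator) of each metric per sprint kind.
    paired_tests : metric -> (t statistic, one-sided p, direction), present
        when both sprint kinds cover the same annotators.
    """

    per_annotator: pd.DataFrame
    summary: pd.DataFrame
    paired_tests: Dict[str, Tuple[float, float, str]] = field(default_factory=dict)


def sprint_metrics(events: Iterable[AnnotationEvent]) -> EfficiencyReport:
    """Throughput metrics per annotator and sprint kind.

    labels_per_hour = label-event count / total active hours;
    skips_per_hour likewise; skip_time_min = summed skip durations.
    Raises if any annotator x sprint-kind cell has zero total time.
    """
    events = list(events)
    if not events:
        raise ValueError("no annotation events supplied")
    df = pd.DataFrame(
        {
            "annotator_id": [e.annotator_id for e in events],
            "sprint_kind": [e.sprint_kind.value for e in events],
            "action": [e.action.value for e in events],
            "duration_s": [e.duration_s for e in events],
        }
    )
    rows = []
    for (annotator, kind), grp in df.groupby(["annotator_id", "sprint_kind"], sort=True):
        total_s = grp["duration_s"].sum()
        if total_s <= 0:
            raise ValueError(
                f"annotator {annotator!r} has zero total time in sprint kind {kind!r}"
            )
        hours = total_s / 3600.0
        labels = (grp["action"] == AnnotationAction.LABEL_PARENCHYMAL.value).sum()
        skip_mask = grp["action"] == AnnotationAction.SKIP_PLEURAL.value
        rows.append(
            {
                "annotator_id": annotator,
                "sprint_kind": kind,
                "n_events": len(grp),
                "total_hours": hours,
                "labels_per_hour": labels / hours,
                "skips_per_hour": int(skip_mask.sum()) / hours,
                "skip_time_min": grp.loc[skip_mask, "duration_s"].sum() / 60.0,
            }
        )
    per_annotator = pd.DataFrame(rows)

    metrics = ["labels_per_hour", "skips_per_hour", "skip_time_min"]
    summary = (
        per_annotator.groupby("sprint_kind")[metrics]
        .agg(["mean", "std"])
        .reset_index()
    )

    paired_tests: Dict[str, Tuple[float, float, str]] = {}
    kinds = set(per_annotator["sprint_kind"])
    if {SprintKind.CONTROL.value, SprintKind.AUTO_PARTITIONED.value} <= kinds:
        wide = per_annotator.pivot(
            index="annotator_id", columns="sprint_kind", values=metrics
        ).dropna()
        if len(wide) >= 2:
            for metric in metrics:
                auto = wide[(metric, SprintKind.AUTO_PARTITIONED.value)].to_numpy()
                control = wide[(metric, SprintKind.CONTROL.value)].to_numpy()
                direction = METRIC_DIRECTIONS[metric]
                # test on auto - control differences in the stated direction
                t, p = paired_one_sided_t(auto - control, direction)
                paired_tests[metric] = (t, p, direction)
    return EfficiencyReport(
        per_annotator=per_annotator, summary=summary, paired_tests=paired_tests
    )


def paired_one_sided_t(
    differences: Sequence[float], direction: str
) -> Tuple[float, float]:
    """One-sided paired t-test on a vector of paired differences.

    t = mean(d) / (sd(d) / sqrt(n)) with n-1 degrees of freedom; the
    p-value is one-sided in the requested direction ("greater": mean
    difference > 0; "less": mean difference < 0).  An all-zero vector is
    the exact null: t = 0, p = 0.5.
    """
    if direction not in ("greater", "less"):
        raise ValueError(f"direction must be 'greater' or 'less', got {direction!r}")
    d = np.asarray(differences, dtype=float)
    if d.size < 2:
        raise ValueError("need at least 2 paired differences")
    if np.all(d == 0.0):
        return 0.0, 0.5
    sd = d.std(ddof=1)
    if sd == 0.0:
        raise ValueError("differences are constant and nonzero: t is undefined")
    t = d.mean() / (sd / np.sqrt(d.size))
    df = d.size - 1
    p = stats.t.sf(t, df) if direction == "greater" else stats.t.cdf(t, df)
    return float(t), float(p)


@dataclass(frozen=True)
class ExtrapolationSpec:
    """Inputs for projecting skip-time savings to a larger database.

    mean_skip_s : average seconds to skip one irrelevant clip.
    frac_irrelevant_control : irrelevant-clip fraction without partitioning.
    frac_irrelevant_auto : irrelevant-clip fraction after auto-partitioning.
    n_clips : database size to extrapolate over.
    """

    mean_skip_s: float
    frac_irrelevant_control: float
    frac_irrelevant_auto: float
    n_clips: int

    def __post_init__(self) -> None:
        if self.mean_skip_s < 0:
            raise ValueError("mean_skip_s must be non-negative")
        for name in ("frac_irrelevant_control", "frac_irrelevant_auto"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1], got {v}")
        if self.n_clips < 1:
            raise ValueError("n_clips must be a positive integer")
        if self.frac_irrelevant_auto > self.frac_irrelevant_control:
            import warnings

            warnings.warn(
                "auto-partitioned irrelevant fraction exceeds control: "
                "the partitioner is not reducing irrelevant clips",
                stacklevel=2,
            )


def extrapolate_savings(spec: ExtrapolationSpec) -> Tuple[float, float]:
    """Projected skip-time saved over ``n_clips``, as (seconds, days)."""
    seconds = (
        spec.mean_skip_s
        * (spec.frac_irrelevant_control - spec.frac_irrelevant_auto)
        * spec.n_clips
    )
    return seconds, seconds / SECONDS_PER_DAY


def sprint_time_saved(
    control_skip_min: Sequence[float] | float,
    auto_skip_min: Sequence[float] | float,
    n_annotators: int | None = None,
) -> float:
    """Total minutes of skip time saved across annotators.

    With per-annotator sequences, sums the pairwise (control - auto)
    differences.  In summary mode, pass scalar means and
    ``n_annotators``: the mean difference is multiplied by the team size.
    """
    if np.isscalar(control_skip_min) != np.isscalar(auto_skip_min):
        raise ValueError("mix of scalar and per-annotator inputs")
    if np.isscalar(control_skip_min):
        if n_annotators is None or n_annotators < 1:
            raise ValueError("summary mode requires a positive n_annotators")
        return float((control_skip_min - auto_skip_min) * n_annotators)
    control = np.asarray(control_skip_min, dtype=float)
    auto = np.asarray(auto_skip_min, dtype=float)
    if control.shape != auto.shape:
        raise ValueError(
            f"paired inputs differ in length: {control.shape} vs {auto.shape}"
        )
    return float(np.sum(control - auto))
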