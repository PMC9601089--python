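"""Confidence-based dataset partitioning for annotation sprints.

After running the clip classifier over an unannotated pool, clips
predicted as the task-relevant view with a confidently low (or high)
mean frame probability are selected, and a seeded random subset is
drawn to form a fixed-size annotation sprint.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from typing import List, Sequence

import numpy as np

from .clip_aggregation import ClipPrediction, ViewLabel

__all__ = [
    "PartitionCriteria",
    "PartitionManifest",
    "filter_by_criteria",
    "sample_partition",
]


@dataclass(frozen=True)
class PartitionCriteria:
    """Selection rule for one target view.

    For a parenchymal target, a clip qualifies when predicted
    parenchymal with mean raw pleural probability strictly below
    ``avg_prob_threshold``.  For a pleural target the mirrored rule
    applies: mean probability strictly above ``1 - avg_prob_threshold``.
    """

    target_view: ViewLabel = ViewLabel.PARENCHYMAL
    avg_prob_threshold: float = 0.3

    def __post_init__(self) -> None:
        if not 0.0 <= self.avg_prob_threshold <= 1.0:
            raise ValueError(
                f"avg_prob_threshold must lie in [0, 1], got {self.avg_prob_threshold}"
            )

    def matches(self, prediction: ClipPrediction) -> bool:
        if prediction.predicted is not self.target_view:
            return False
        if self.target_view is ViewLabel.PARENCHYMAL:
            return prediction.mean_raw_prob < self.avg_prob_threshold
        return prediction.mean_raw_prob > 1.0 - self.avg_prob_threshold


@dataclass(frozen=True)
class PartitionManifest:
    """Record of one partition draw: who was selected, under what rule."""

    selected_clip_ids: tuple
    criteria: PartitionCriteria
    n_candidates: int
    n_selected: int
    seed: int

    def __post_init__(self) -> None:
        if self.n_selected != len(self.selected_clip_ids):
            raise ValueError("n_selected does not match the selected clip list")
        if self.n_selected > self.n_candidates:
            raise ValueError("cannot select more clips than candidates")

    def to_json(self) -> str:
        return json.dumps(
            {
                "criteria": {
                    "target_view": self.criteria.target_view.value,
                    "avg_prob_threshold": self.criteria.avg_prob_threshold,
                },
                "seed": self.seed,
                "n_candidates": self.n_candidates,
                "n_selected": self.n_selected,
                "selected_clip_ids": list(self.selected_clip_ids),
            },
            indent=2,
        )

    @classmethod
    def from_json(cls, text: str) -> "PartitionManifest":
        d = json.loads(text)
        return cls(
            selected_clip_ids=tuple(d["selected_clip_ids"]),
            criteria=PartitionCriteria(
                target_view=ViewLabel(d["criteria"]["target_view"]),
                avg_prob_threshold=d["criteria"]["avg_prob_threshold"],
            ),
            n_candidates=d["n_candidates"],
            n_selected=d["n_selected"],
            seed=d["seed"],
        )


def filter_by_criteria(
    predictions: Sequence[ClipPrediction], criteria: PartitionCriteria
) -> List[ClipPrediction]:
    """Clips matching the criteria, in their original order."""
    return [p for p in predictions if criteria.matches(p)]


def sample_partition(
    candidates: Sequence[ClipPrediction],
    n: int,
    seed: int,
    criteria: PartitionCriteria | None = None,
) -> PartitionManifest:
    """Draw ``n`` candidates uniformly without replacement.

    Selected clips keep their order within ``candidates``.  The manifest
    records the seed and counts so the draw is exactly reproducible.
    """
    if n < 0:
        raise ValueError(f"n must be non-negative, got {n}")
    if n > len(candidates):
        raise ValueError(f"cannot select {n} clips from {len(candidates)} candidates")
    if criteria is None:
        criteria = PartitionCriteria()
    rng = np.random.default_rng(seed)
    idx = np.sort(rng.choice(len(candidates), size=n, replace=False))
    return PartitionManifest(
        selected_clip_ids=tuple(candidates[i].clip_id for i in idx),
        criteria=criteria,
        n_candidates=len(candidates),
        n_selected=n,
        seed=seed,
    )
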