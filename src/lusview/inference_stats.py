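"""Cochran sample-size estimation and Wald confidence intervals.

When a holdout set is annotated to audit classifier (or annotator)
accuracy, the number of clips needed to pin a proportion ``A`` down to
within a margin ``M`` at confidence ``alpha`` is given by Cochran's
formula

    n = Z^2 * A * (1 - A) / M^2

with ``Z`` the two-sided standard-normal quantile for ``alpha``.  The
matching interval for an observed accuracy on ``n`` samples is the Wald
interval ``a +/- Z * sqrt(a * (1 - a) / n)``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from scipy import stats

__all__ = ["SampleSizeSpec", "AccuracyInterval", "cochran_n", "accuracy_ci", "z_value"]


def z_value(alpha: float) -> float:
    """Two-sided standard-normal quantile for confidence level ``alpha``."""
    if not 0.0 < alpha < 1.0:
        raise ValueError(f"confidence level must lie in (0, 1), got {alpha}")
    return float(stats.norm.ppf(0.5 + alpha / 2.0))


@dataclass(frozen=True)
class SampleSizeSpec:
    """Inputs to Cochran's formula.

    alpha : confidence level (e.g. 0.95).
    margin : half-width M of the target interval, on the proportion scale.
    assumed_accuracy : the anticipated proportion A.
    """

    alpha: float
    margin: float
    assumed_accuracy: float

    def __post_init__(self) -> None:
        if not 0.0 < self.alpha < 1.0:
            raise ValueError(f"alpha must lie in (0, 1), got {self.alpha}")
        if not 0.0 < self.margin < 1.0:
            raise ValueError(f"margin must lie in (0, 1), got {self.margin}")
        if not 0.0 < self.assumed_accuracy < 1.0:
            raise ValueError(
                f"assumed_accuracy must lie in (0, 1), got {self.assumed_accuracy}"
            )

    @property
    def z(self) -> float:
        return z_value(self.alpha)


@dataclass(frozen=True)
class AccuracyInterval:
    """A symmetric Wald interval for an observed accuracy, clamped to [0, 1]."""

    point: float
    margin: float
    n: int
    alpha: float

    @property
    def lower(self) -> float:
        return max(0.0, self.point - self.margin)

    @property
    def upper(self) -> float:
        return min(1.0, self.point + self.margin)

    def to_dict(self) -> dict:
        return {
            "point": self.point,
            "margin": self.margin,
            "lower": self.lower,
            "upper": self.upper,
            "n": self.n,
            "alpha": self.alpha,
        }


def cochran_n(spec: SampleSizeSpec) -> int:
    """Sample size ``ceil(Z^2 * A * (1-A) / M^2)``.

    The ceiling guarantees the realised margin never exceeds the target.
    """
    a = spec.assumed_accuracy
    raw = spec.z**2 * a * (1.0 - a) / spec.margin**2
    return int(math.ceil(raw))


def accuracy_ci(observed_accuracy: float, n: int, alpha: float) -> AccuracyInterval:
    """Wald interval for an accuracy observed on ``n`` samples."""
    if not 0.0 <= observed_accuracy <= 1.0:
        raise ValueError(f"observed accuracy must lie in [0, 1], got {observed_accuracy}")
    if n < 1:
        raise ValueError(f"n must be a positive integer, got {n}")
    margin = z_value(alpha) * math.sqrt(observed_accuracy * (1.0 - observed_accuracy) / n)
    return AccuracyInterval(point=observed_accuracy, margin=margin, n=int(n), alpha=alpha)
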