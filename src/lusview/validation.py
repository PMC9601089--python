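"""Patient-grouped cross-validation, hyperparameter grid search and metrics.

Folds are split by patient identifier so that no patient contributes
clips to both sides of any split — the leakage guard required when
several clips share a patient.  The grid search evaluates every
(tau, t, w) combination by clip-level accuracy on each fold's validation
clips and selects the combination maximising the unweighted mean of the
per-fold accuracies.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Iterable, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats

from .clip_aggregation import (
    ClipHyperparams,
    FrameProbSeries,
    ViewLabel,
    longest_run_at_or_above,
    moving_average,
)

__all__ = [
    "FoldAssignment",
    "GridSpec",
    "GridSearchResult",
    "MetricsReport",
    "assign_folds",
    "grid_search",
    "compute_metrics",
    "auc_rank",
]


@dataclass(frozen=True)
class FoldAssignment:
    """Mapping from patient_id to a fold index in ``[0, k)``."""

    folds: Mapping[str, int]
    k: int

    def __post_init__(self) -> None:
        if self.k < 2:
            raise ValueError(f"k must be at least 2, got {self.k}")
        bad = {p: f for p, f in self.folds.items() if not 0 <= f < self.k}
        if bad:
            raise ValueError(f"fold indices out of range [0, {self.k}): {bad}")

    def patients_in_fold(self, fold: int) -> set:
        return {p for p, f in self.folds.items() if f == fold}


@dataclass(frozen=True)
class GridSpec:
    """Hyperparameter grid. Defaults span the full search space:
    tau, w in {1..40} and t in {0.1, ..., 0.9} (14,400 combinations)."""

    tau_values: tuple = tuple(range(1, 41))
    w_values: tuple = tuple(range(1, 41))
    t_values: tuple = tuple(i / 10 for i in range(1, 10))

    def __post_init__(self) -> None:
        if not (self.tau_values and self.w_values and self.t_values):
            raise ValueError("grid value sets must be non-empty")
        object.__setattr__(self, "tau_values", tuple(sorted(int(v) for v in set(self.tau_values))))
        object.__setattr__(self, "w_values", tuple(sorted(int(v) for v in set(self.w_values))))
        object.__setattr__(self, "t_values", tuple(sorted(float(v) for v in set(self.t_values))))
        if min(self.tau_values) < 1 or min(self.w_values) < 1:
            raise ValueError("tau and w values must be positive integers")
        if min(self.t_values) < 0 or max(self.t_values) > 1:
            raise ValueError("t values must lie in [0, 1]")

    @property
    def n_combinations(self) -> int:
        return len(self.tau_values) * len(self.w_values) * len(self.t_values)


@dataclass(frozen=True)
class GridSearchResult:
    """Best hyperparameters plus the full accuracy table.

    ``table`` maps (tau, t, w) to mean validation accuracy across folds;
    ``fold_table`` additionally holds per-fold accuracies.
    """

    best: ClipHyperparams
    table: Dict[Tuple[int, float, int], float]
    fold_table: Dict[Tuple[int, float, int], tuple] = field(default_factory=dict)

    @property
    def best_accuracy(self) -> float:
        return self.table[(self.best.tau, self.best.t, self.best.w)]

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for (tau, t, w), acc in sorted(self.table.items()):
            row = {"tau": tau, "t": t, "w": w, "mean_val_accuracy": acc}
            for i, a in enumerate(self.fold_table.get((tau, t, w), ())):
                row[f"fold_{i}_accuracy"] = a
            rows.append(row)
        return pd.DataFrame(rows)


@dataclass(frozen=True)
class MetricsReport:
    """Confusion counts and derived rates with pleural as positive.

    Ratios whose denominator is zero are reported as ``None`` rather
    than coerced to zero.  ``auc`` applies at frame level only.
    """

    level: str
    tp: int
    fp: int
    tn: int
    fn: int
    auc: Optional[float] = None

    @property
    def n(self) -> int:
        return self.tp + self.fp + self.tn + self.fn

    @property
    def accuracy(self) -> Optional[float]:
        return (self.tp + self.tn) / self.n if self.n else None

    @property
    def npv(self) -> Optional[float]:
        denom = self.tn + self.fn
        return self.tn / denom if denom else None

    @property
    def ppv(self) -> Optional[float]:
        denom = self.tp + self.fp
        return self.tp / denom if denom else None

    def to_dict(self) -> dict:
        return {
            "level": self.level,
            "tp": self.tp, "fp": self.fp, "tn": self.tn, "fn": self.fn,
            "accuracy": self.accuracy, "npv": self.npv, "ppv": self.ppv,
            "auc": self.auc,
        }


def assign_folds(
    patient_ids: Iterable[str],
    clip_counts: Mapping[str, int],
    k: int,
    seed: int,
) -> FoldAssignment:
    """Assign patients to ``k`` folds, balancing total clip counts.

    Patients are taken in decreasing clip-count order (seeded shuffle
    breaks ties among equal counts) and each is placed in the currently
    lightest fold.  Deterministic for a given seed; no patient spans
    folds by construction.
    """
    patients = sorted(set(patient_ids))
    if k < 2:
        raise ValueError(f"k must be at least 2, got {k}")
    if len(patients) < k:
        raise ValueError(f"need at least k={k} patients, got {len(patients)}")
    rng = np.random.default_rng(seed)
    order = list(rng.permutation(patients))
    order.sort(key=lambda p: -clip_counts.get(p, 1))  # stable: ties keep shuffled order
    loads = np.zeros(k, dtype=int)
    folds: Dict[str, int] = {}
    for p in order:
        f = int(np.argmin(loads))  # ties -> lowest fold index
        folds[p] = f
        loads[f] += clip_counts.get(p, 1)
    return FoldAssignment(folds=folds, k=k)


def _qualifying_runs(
    dataset: Sequence[FrameProbSeries], grid: GridSpec
) -> np.ndarray:
    """Longest qualifying run per (clip, w, t); shared by all tau values."""
    runs = np.empty((len(dataset), len(grid.w_values), len(grid.t_values)), dtype=np.int64)
    for ci, series in enumerate(dataset):
        for wi, w in enumerate(grid.w_values):
            smoothed = moving_average(series.probs, w)
            for ti, t in enumerate(grid.t_values):
                runs[ci, wi, ti] = longest_run_at_or_above(smoothed, t)
    return runs


def grid_search(
    dataset: Sequence[FrameProbSeries],
    folds: FoldAssignment,
    grid: GridSpec,
) -> GridSearchResult:
    """Exhaustive (tau, t, w) search maximising mean validation accuracy.

    For every combination, clip-level accuracy is computed on each
    fold's validation clips and averaged across folds with equal fold
    weight.  Ties on mean accuracy are broken deterministically toward
    the smallest w, then smallest tau, then t nearest 0.5 (preferring
    the less restrictive, better-conditioned rule), then smallest t.

    The clip rule only scores pre-computed probabilities, so no model is
    refit per fold; the training side of each split is untouched.
    """
    dataset = sorted(dataset, key=lambda s: s.clip_id)
    if not dataset:
        raise ValueError("dataset is empty")
    unlabelled = [s.clip_id for s in dataset if s.true_label is None]
    if unlabelled:
        raise ValueError(f"clips without a true label: {unlabelled}")
    missing = {s.patient_id for s in dataset} - set(folds.folds)
    if missing:
        raise ValueError(f"patients missing from fold assignment: {sorted(missing)}")

    runs = _qualifying_runs(dataset, grid)  # (clip, w, t)
    truth = np.array([s.true_label is ViewLabel.PLEURAL for s in dataset])
    fold_of_clip = np.array([folds.folds[s.patient_id] for s in dataset])
    taus = np.asarray(grid.tau_values)

    # pred[clip, w, t, tau] = run >= tau, evaluated lazily per fold
    fold_accs = np.empty(
        (folds.k, len(grid.w_values), len(grid.t_values), len(taus)), dtype=float
    )
    fold_sizes = np.empty(folds.k, dtype=int)
    for f in range(folds.k):
        in_fold = fold_of_clip == f
        fold_sizes[f] = in_fold.sum()
        if fold_sizes[f] == 0:
            fold_accs[f] = np.nan
            continue
        pred = runs[in_fold][:, :, :, None] >= taus[None, None, None, :]
        correct = pred == truth[in_fold][:, None, None, None]
        fold_accs[f] = correct.mean(axis=0)
    # unweighted mean over non-empty folds
    mean_acc = np.nanmean(fold_accs, axis=0)  # (w, t, tau)

    table: Dict[Tuple[int, float, int], float] = {}
    fold_table: Dict[Tuple[int, float, int], tuple] = {}
    for wi, w in enumerate(grid.w_values):
        for ti, t in enumerate(grid.t_values):
            for ki, tau in enumerate(grid.tau_values):
                key = (int(tau), float(t), int(w))
                table[key] = float(mean_acc[wi, ti, ki])
                fold_table[key] = tuple(
                    float(fold_accs[f, wi, ti, ki])
                    for f in range(folds.k)
                    if fold_sizes[f] > 0
                )
    best_key = min(
        table,
        key=lambda k: (-table[k], k[2], k[0], abs(k[1] - 0.5), k[1]),
    )
    best = ClipHyperparams(tau=best_key[0], t=best_key[1], w=best_key[2])
    return GridSearchResult(best=best, table=table, fold_table=fold_table)


def compute_metrics(
    pairs: Iterable[Tuple[ViewLabel, ViewLabel]],
    level: str = "clip",
    auc: Optional[float] = None,
) -> MetricsReport:
    """Confusion counts and accuracy/NPV/PPV from (true, predicted) pairs."""
    pairs = list(pairs)
    if not pairs:
        raise ValueError("no (true, predicted) pairs supplied")
    tp = fp = tn = fn = 0
    for true, pred in pairs:
        if pred is ViewLabel.PLEURAL:
            if true is ViewLabel.PLEURAL:
                tp += 1
            else:
                fp += 1
        else:
            if true is ViewLabel.PARENCHYMAL:
                tn += 1
            else:
                fn += 1
    return MetricsReport(level=level, tp=tp, fp=fp, tn=tn, fn=fn, auc=auc)


def auc_rank(scores_pos: Sequence[float], scores_neg: Sequence[float]) -> float:
    """ROC AUC as the tie-aware Mann-Whitney probability.

    The probability that a randomly drawn positive score exceeds a
    randomly drawn negative score, with ties counted half.
    """
    pos = np.asarray(scores_pos, dtype=float)
    neg = np.asarray(scores_neg, dtype=float)
    if pos.size == 0 or neg.size == 0:
        raise ValueError("both score collections must be non-empty")
    u = stats.mannwhitneyu(pos, neg, alternative="two-sided").statistic
    return float(u / (pos.size * neg.size))
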