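"""Tests for patient-grouped folds, grid search and metric computation."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from lusview import (
    ClipHyperparams,
    FrameProbSeries,
    GridSpec,
    ViewLabel,
    assign_folds,
    auc_rank,
    classify_clip,
    compute_metrics,
    grid_search,
)
from conftest import oracle_classify


class TestAssignFolds:
    def test_one_patient_per_fold_when_counts_match(self):
        patients = [f"p{i}" for i in range(10)]
        fa = assign_folds(patients, {p: 1 for p in patients}, k=10, seed=0)
        assert sorted(fa.folds.values()) == list(range(10))

    def test_deterministic_for_fixed_seed(self):
        patients = [f"p{i}" for i in range(25)]
        counts = {p: (i % 5) + 1 for i, p in enumerate(patients)}
        a = assign_folds(patients, counts, k=5, seed=7)
        b = assign_folds(patients, counts, k=5, seed=7)
        assert a.folds == b.folds

    def test_greedy_balances_clip_totals(self):
        # one heavy patient: the greedy rule parks it alone-ish while the
        # light patients fill the other fold
        patients = [f"p{i}" for i in range(20)]
        counts = {p: 1 for p in patients}
        counts["p0"] = 10
        fa = assign_folds(patients, counts, k=2, seed=0)
        loads = [sum(counts[p] for p in fa.patients_in_fold(f)) for f in range(2)]
        heavy_fold = fa.folds["p0"]
        assert len(fa.patients_in_fold(heavy_fold)) < len(fa.patients_in_fold(1 - heavy_fold))
        assert abs(loads[0] - loads[1]) <= 1  # within one greedy step

    def test_fewer_patients_than_folds_rejected(self):
        with pytest.raises(ValueError):
            assign_folds(["a", "b"], {"a": 1, "b": 1}, k=3, seed=0)

    @given(n=st.integers(10, 40), k=st.integers(2, 10), seed=st.integers(0, 10))
    @settings(deadline=None, derandomize=True, max_examples=50)
    def test_partition_is_total_and_disjoint(self, n, k, seed):
        """Every patient lands in exactly one fold; folds tile the cohort."""
        patients = [f"p{i}" for i in range(n)]
        counts = {p: (hash(p) % 4) + 1 for p in patients}
        fa = assign_folds(patients, counts, k=k, seed=seed)
        assert set(fa.folds) == set(patients)
        per_fold = [fa.patients_in_fold(f) for f in range(k)]
        assert all(a.isdisjoint(b) for a, b in itertools.combinations(per_fold, 2))
        assert set().union(*per_fold) == set(patients)
        assert all(per_fold)  # each fold non-empty when n >= k


def _mini_dataset():
    """Six patients, one clip each, separable at t in (0.3, 0.8]."""
    clips = []
    for i in range(3):
        clips.append(FrameProbSeries(f"ple{i}", f"A{i}", (0.8,) * 8, ViewLabel.PLEURAL))
        clips.append(FrameProbSeries(f"par{i}", f"B{i}", (0.3,) * 8, ViewLabel.PARENCHYMAL))
    return clips


class TestGridSearch:
    def test_singleton_grid_returns_that_combination(self, separable_dataset):
        counts = {}
        for s in separable_dataset:
            counts[s.patient_id] = counts.get(s.patient_id, 0) + 1
        folds = assign_folds(counts, counts, k=3, seed=0)
        grid = GridSpec(tau_values=(2,), w_values=(3,), t_values=(0.5,))
        res = grid_search(separable_dataset, folds, grid)
        assert (res.best.tau, res.best.t, res.best.w) == (2, 0.5, 3)
        assert len(res.table) == 1

    def test_separable_dataset_wide_band_attains_perfect_accuracy(self, separable_dataset):
        counts = {}
        for s in separable_dataset:
            counts[s.patient_id] = counts.get(s.patient_id, 0) + 1
        folds = assign_folds(counts, counts, k=3, seed=0)
        grid = GridSpec(tau_values=(1, 4, 8), w_values=(1, 3), t_values=(0.5, 0.7, 0.9))
        res = grid_search(separable_dataset, folds, grid)
        assert res.best_accuracy == 1.0
        # every combination with t separating the classes and a feasible
        # contiguity demand is perfect: tau <= 10 - w + 1
        for (tau, t, w), acc in res.table.items():
            if 0.4 < t <= 0.95 and tau <= 10 - w + 1:
                assert acc == 1.0, (tau, t, w)

    def test_argmax_matches_exhaustive_reevaluation(self):
        dataset = _mini_dataset()
        counts = {s.patient_id: 1 for s in dataset}
        folds = assign_folds(counts, counts, k=3, seed=1)
        grid = GridSpec(tau_values=(1, 2, 4), w_values=(1, 2, 5), t_values=(0.2, 0.5, 0.9))
        res = grid_search(dataset, folds, grid)

        # independent re-evaluation straight from the brute-force clip oracle
        best_acc = -1.0
        for tau, t, w in itertools.product(grid.tau_values, grid.t_values, grid.w_values):
            fold_accs = []
            for f in range(folds.k):
                val = [s for s in dataset if folds.folds[s.patient_id] == f]
                if not val:
                    continue
                hits = [oracle_classify(s.probs, tau, t, w) is s.true_label for s in val]
                fold_accs.append(np.mean(hits))
            acc = float(np.mean(fold_accs))
            assert acc == pytest.approx(res.table[(tau, t, w)])
            best_acc = max(best_acc, acc)
        assert res.best_accuracy == pytest.approx(best_acc)

    def test_dataset_order_does_not_change_result(self, separable_dataset):
        counts = {}
        for s in separable_dataset:
            counts[s.patient_id] = counts.get(s.patient_id, 0) + 1
        folds = assign_folds(counts, counts, k=3, seed=0)
        grid = GridSpec(tau_values=(1, 5), w_values=(1, 4), t_values=(0.3, 0.7))
        res_fwd = grid_search(separable_dataset, folds, grid)
        res_rev = grid_search(list(reversed(separable_dataset)), folds, grid)
        assert res_fwd.best == res_rev.best
        assert res_fwd.table == res_rev.table

    def test_unlabelled_clip_rejected(self):
        clips = [FrameProbSeries("c", "p0", (0.5,) * 4, None),
                 FrameProbSeries("d", "p1", (0.5,) * 4, ViewLabel.PLEURAL)]
        counts = {"p0": 1, "p1": 1}
        folds = assign_folds(counts, counts, k=2, seed=0)
        with pytest.raises(ValueError, match="true label"):
            grid_search(clips, folds, GridSpec(tau_values=(1,), w_values=(1,), t_values=(0.5,)))

    def test_tie_break_prefers_small_w_then_tau(self):
        # all-constant clips: many combinations tie at the same accuracy
        dataset = _mini_dataset()
        counts = {s.patient_id: 1 for s in dataset}
        folds = assign_folds(counts, counts, k=2, seed=0)
        grid = GridSpec(tau_values=(1, 2, 3), w_values=(1, 2, 3), t_values=(0.5,))
        res = grid_search(dataset, folds, grid)
        # every combination here is perfect; the tie-break picks w=1, tau=1
        assert res.best == ClipHyperparams(tau=1, t=0.5, w=1)


class TestComputeMetrics:
    def test_forced_confusion_arithmetic(self):
        pairs = (
            [(ViewLabel.PLEURAL, ViewLabel.PLEURAL)] * 3
            + [(ViewLabel.PARENCHYMAL, ViewLabel.PLEURAL)] * 1
            + [(ViewLabel.PARENCHYMAL, ViewLabel.PARENCHYMAL)] * 4
            + [(ViewLabel.PLEURAL, ViewLabel.PARENCHYMAL)] * 2
        )
        rep = compute_metrics(pairs)
        assert (rep.tp, rep.fp, rep.tn, rep.fn) == (3, 1, 4, 2)
        assert rep.accuracy == pytest.approx(0.7)
        assert rep.ppv == pytest.approx(0.75)
        assert rep.npv == pytest.approx(2 / 3)
        assert rep.n == len(pairs)

    def test_all_correct_gives_unit_accuracy(self):
        pairs = [(ViewLabel.PLEURAL, ViewLabel.PLEURAL),
                 (ViewLabel.PARENCHYMAL, ViewLabel.PARENCHYMAL)]
        assert compute_metrics(pairs).accuracy == 1.0

    def test_undefined_ratios_are_none_not_zero(self):
        pairs = [(ViewLabel.PARENCHYMAL, ViewLabel.PARENCHYMAL)]
        rep = compute_metrics(pairs)
        assert rep.ppv is None
        assert rep.npv == 1.0

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            compute_metrics([])

    @given(
        tp=st.integers(0, 20), fp=st.integers(0, 20),
        tn=st.integers(0, 20), fn=st.integers(0, 20),
    )
    @settings(deadline=None, derandomize=True, max_examples=50)
    def test_counts_conserved(self, tp, fp, tn, fn):
        if tp + fp + tn + fn == 0:
            return
        pairs = (
            [(ViewLabel.PLEURAL, ViewLabel.PLEURAL)] * tp
            + [(ViewLabel.PARENCHYMAL, ViewLabel.PLEURAL)] * fp
            + [(ViewLabel.PARENCHYMAL, ViewLabel.PARENCHYMAL)] * tn
            + [(ViewLabel.PLEURAL, ViewLabel.PARENCHYMAL)] * fn
        )
        rep = compute_metrics(pairs)
        assert (rep.tp, rep.fp, rep.tn, rep.fn) == (tp, fp, tn, fn)


class TestAucRank:
    @pytest.mark.parametrize(
        "pos, neg, expected",
        [
            ([0.9, 0.8], [0.1, 0.2], 1.0),
            ([0.5], [0.5], 0.5),
            ([0.8, 0.4], [0.6, 0.2], 0.75),
        ],
    )
    def test_known_values(self, pos, neg, expected):
        assert auc_rank(pos, neg) == pytest.approx(expected)

    def test_empty_side_rejected(self):
        with pytest.raises(ValueError):
            auc_rank([], [0.5])

    def test_matches_sklearn_roc_auc(self):
        from sklearn.metrics import roc_auc_score

        rng = np.random.default_rng(3)
        pos = rng.beta(5, 2, size=60)
        neg = rng.beta(2, 5, size=45)
        y = np.r_[np.ones(60), np.zeros(45)]
        assert auc_rank(pos, neg) == pytest.approx(roc_auc_score(y, np.r_[pos, neg]))

    @given(
        pos=st.lists(st.floats(0.01, 0.99), min_size=1, max_size=20),
        neg=st.lists(st.floats(0.01, 0.99), min_size=1, max_size=20),
    )
    @settings(deadline=None, derandomize=True, max_examples=60)
    def test_invariant_under_monotone_transform(self, pos, neg):
        base = auc_rank(pos, neg)
        logit = lambda p: np.log(p) - np.log1p(-p)
        assert auc_rank(logit(np.array(pos)), logit(np.array(neg))) == pytest.approx(base)
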