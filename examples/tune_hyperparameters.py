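"""Tune (tau, t, w) with a patient-grouped cross-validated grid search.

Folds are split by patient so a patient's clips never straddle the
train/validation boundary, then every hyperparameter combination is
scored by mean validation accuracy across folds.
"""

from lusview import GridSpec, SeriesGenConfig, assign_folds, generate_series_dataset, grid_search

dataset = generate_series_dataset(
    SeriesGenConfig(n_clips=80, noise_sd=0.05, probe_switch_fraction=0.0, seed=11)
)
counts: dict[str, int] = {}
for s in dataset:
    counts[s.patient_id] = counts.get(s.patient_id, 0) + 1

folds = assign_folds(counts.keys(), counts, k=5, seed=0)
grid = GridSpec(tau_values=range(1, 11), w_values=range(1, 11))  # t defaults to 0.1..0.9
result = grid_search(dataset, folds, grid)

best = result.best
print(f"{len(dataset)} clips from {len(counts)} patients, {grid.n_combinations} combinations")
print(f"best (tau={best.tau}, t={best.t}, w={best.w}) "
      f"with mean validation accuracy {result.best_accuracy:.3f}")
print("Ties are broken toward the smallest w, then tau, then t nearest 0.5;")
print("on this well-separated panel many combinations reach accuracy 1.0, so the")
print("tie-break returns the least restrictive perfectly separating rule.")
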