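"""Classify synthetic clips with the deployed (tau=7, t=0.7, w=17) rule.

Generates a small labelled panel of frame-probability series — including
curtain-sign pleural clips whose probability oscillates with breathing —
and shows how smoothing plus the contiguity requirement turns noisy
frame scores into stable clip-level view calls.
"""

from lusview import (
    ClipHyperparams,
    SeriesGenConfig,
    ViewLabel,
    classify_clip,
    generate_series_dataset,
)

dataset = generate_series_dataset(SeriesGenConfig(n_clips=12, curtain_fraction=0.6, seed=3))
hp = ClipHyperparams(tau=7, t=0.7, w=17)

correct = 0
print(f"clip      true          predicted     run  mean_p")
for series in dataset:
    pred = classify_clip(series, hp)
    correct += pred.predicted is series.true_label
    print(f"{series.clip_id}  {series.true_label.value:<12}  {pred.predicted.value:<12}"
          f"  {pred.longest_qualifying_run:3d}  {pred.mean_raw_prob:.3f}")
print(f"\n{correct}/{len(dataset)} correct. 'run' is the longest stretch of smoothed")
print("probabilities >= 0.7; a clip is called pleural when the run reaches tau=7,")
print("so curtain-sign oscillations (high mean_p, interrupted runs) still classify")
print("correctly while parenchymal clips (run 0) never do.")
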