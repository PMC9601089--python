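# Methods

## The clip prediction rule

A frame classifier emits, for each frame of a lung-ultrasound clip, the
probability *p* of the pleural view (positive class; parenchymal is
negative, and a single frame is called pleural when *p* ≥ 0.5). The clip
rule converts the ordered series *p₁ … pₙ* into one clip-level call:

1. **Smoothing.** A moving average of width *w* over fully contained
   windows yields *n − w + 1* values. No boundary padding is used, so
   every smoothed value is a genuine mean of *w* observed frames; when
   *w* ≥ *n* the output degenerates to the single global mean. Because
   only the presence of a qualifying run matters, trailing and centered
   window conventions give identical clip decisions; the implementation
   indexes windows by their left edge.
2. **Contiguous threshold.** The clip is pleural iff some τ consecutive
   smoothed values are each ≥ *t*. Values exactly equal to *t* qualify
   ("meet or exceed"); the boundary is tested explicitly. If the
   smoothed series is shorter than τ the clip defaults to parenchymal —
   the conservative reading, since the required run cannot exist.

The rationale is the asymmetry of LUS artifacts: pleural clips often
contain parenchymal-looking frames (the curtain sign moves aerated lung
across the window once per breath) but parenchymal clips rarely produce
sustained pleural-looking runs. Requiring τ *consecutive* smoothed
exceedances therefore discriminates better than any per-frame vote.

`mean_raw_prob`, used by the partitioning criterion, is the mean of the
**raw** series, not the smoothed one: the smoothed series merely reorders
information for the run test, while the partition filter is defined on
the classifier's average output.

## Cross-validation and grid search

Folds are assigned to **patients**, not clips: a patient with several
clips must fall entirely inside one fold or validation scores leak.
Assignment is greedy — patients in decreasing clip-count order, each to
the currently lightest fold, with a seeded shuffle breaking count ties —
which balances fold sizes to within one patient's clips while remaining
fully deterministic.

The grid search scores every (τ, t, w) by clip-level accuracy on each
fold's validation clips and averages **with equal fold weight** (the
unweighted mean of per-fold accuracies; fold sizes differ by at most a
few clips under the greedy balancing, so the distinction is minor but is
fixed deterministically). No model is refit per fold — probabilities are
pre-computed inputs — so the search is a pure evaluation and the full
14,400-point default grid is feasible. Internally the longest qualifying
run is computed once per (clip, w, t) and compared against every τ,
collapsing the τ axis to an integer comparison.

Ties on mean accuracy (common on separable data) break toward the
smallest *w*, then the smallest τ, then *t* nearest 0.5, then the
smaller *t* — preferring the least restrictive and best-conditioned of
the equally accurate rules. The *t* grid is generated as the nearest
floats to 0.1 … 0.9 directly (i/10), not by accumulation, so grid keys
are exact and reproducible.

Metrics use pleural = positive: NPV = TN/(TN+FN) is the fraction of
parenchymal-predicted clips that are truly parenchymal — the quantity an
annotator consuming a parenchymal-partitioned dataset experiences.
Undefined ratios (empty denominator) are reported as absent, never as
zero. Frame-level AUC is the tie-aware Mann–Whitney estimator
U/(n₊·n₋), which is invariant to monotone transforms of the scores and
is cross-checked against an independent ROC implementation in the tests.

## Partitioning

For a parenchymal-specific task, a clip enters the candidate pool iff it
is predicted parenchymal **and** its mean raw probability is strictly
below 0.3. The threshold sits well under the optimal classification
threshold (t = 0.7), trading pool size for purity: the filter discards
correctly-predicted-but-uncertain clips to suppress false negatives in
the delivered sprint. The pleural-target mirror rule (mean probability
strictly above 1 − threshold) is a symmetric extension of the same idea.
Sprint sampling is uniform without replacement from the candidates with
an explicit recorded seed; the manifest stores criteria, seed and counts
so any draw re-validates and reproduces exactly.

## Holdout sizing and intervals

Cochran's formula n = Z²A(1−A)/M² sizes a holdout audit: A is the
assumed accuracy, M the target margin, Z the two-sided normal quantile
for the confidence level (computed exactly, ≈ 1.959964 at 95%, not the
rounded 1.96). The result is **ceiled** to the next integer so the
realised margin never exceeds the target. The interval for an observed
accuracy is the matching Wald form a ± Z·√(a(1−a)/n), clamped to [0, 1].
Wilson or Clopper–Pearson intervals are deliberately not offered: the
toolkit mirrors the Cochran/Wald pairing so sizing and interval are
mutually consistent.

## Efficiency accounting

Event logs record one timed action per clip: label (relevant
parenchymal), skip (irrelevant pleural) or discard (quality failure).
Per annotator and sprint kind, rates divide action counts by the **sum
of recorded event durations** — platform idle time is unobservable in
this schema, so "active time" is the denominator throughout. Discards
count toward time but toward neither rate. Cross-annotator summaries use
the n−1 standard deviation.

Sprint kinds are compared with a one-sided paired t-test on
per-annotator differences, t = d̄/(s_d/√n) with n−1 degrees of freedom
against the exact t reference distribution; the caller declares the
direction (labels/hour expected greater under auto-partitioning;
skips/hour and skip time greater under control). An all-zero difference
vector is the exact null (t = 0, p = 0.5); a constant nonzero vector has
no defined t and is rejected.

Two complementary savings figures exist and are both provided without
reconciliation: `sprint_time_saved` (per-annotator or summary-mode
difference in skip minutes — team totals of the realised sprints) and
`extrapolate_savings` (mean skip seconds × reduction in the irrelevant
fraction × database size), which projects to datasets not yet annotated.
They answer different questions and coincide only approximately.

## Synthetic data

The series generator emulates the probability dynamics the rule is
designed around, at the series level only (no pixels; the frame
classifier is outside this package):

- parenchymal clips: constant baseline 0.1 + Gaussian noise (sd 0.05),
  clamped to [0, 1];
- plain pleural clips: baseline 0.9 + noise;
- curtain-sign pleural clips (30% of pleural by default): a **square
  wave** alternating between the pleural baseline and a low excursion
  (0.2) with a 60-frame period, roughly one respiratory cycle at typical
  frame rates. A square wave is the harshest waveform for the
  smoothing/contiguity logic — maximal within-clip variance and abrupt
  run breaks — so it stresses exactly what the rule must survive;
- probe-movement clips (5%): one change point between the two baselines,
  labelled by the longer segment, reproducing the acquisition error mode
  in which the operator crosses views mid-clip.

Clip lengths are uniform on 100–350 frames (a few seconds of
ultrasound); patients receive 1 + Poisson(1.4) clips so the mean clips
per patient ≈ 2.4 and the fold machinery is genuinely exercised.
Everything is driven by one `numpy` generator seed.

The event-log generator assigns label/skip/discard events from clip
labels, deals clips into per-annotator sprints (default four annotators,
195 clips each) and draws durations from a normal truncated at zero.
The mean skip duration defaults to 8.5 s; mean label (20 s) and discard
(10 s) durations and the 2.5 s sd are the package's calibration, chosen
once so that realistic sprint mixes produce label rates on the order of
120 (control) vs 175 (auto-partitioned) per hour. With mean/sd ≈ 3.4 the
zero-truncation bias is negligible relative to Monte-Carlo error.

**What passing on synthetic data does and does not show.** The generator
produces well-separated baselines with stationary noise; real frame
classifiers drift within clips, err systematically on hard anatomy and
emit correlated noise. Tests on generated data therefore validate the
*machinery* — rule correctness against a brute-force oracle, leak-free
folds, exact maximisation, seeded reproducibility, metric arithmetic —
not clinical performance, which depends on the upstream classifier.

## Problem sizes and numerical choices

The test suite runs grid searches on grids restricted to τ, w ≤ 10 over
panels of 60–80 clips, and oracle sweeps over hundreds of random series
of length ≤ 30 — sizes at which independent brute-force re-evaluation is
feasible and exact, which is the point of the checks. The full 40×40×9
grid is supported and used the same code path. Floating-point CSV round
trips use `repr` on write and round-trip-precision parsing on read, so
manifests and event logs are bit-exact through the file layer.

## Known limitations

- The pluggable probability source is a contract, not an integration: no
  DICOM/video decoding or neural-network inference is included.
- Annotator learning and sprint-order effects are recorded (sprint ids)
  but not modelled or tested for.
- The Wald interval misbehaves near accuracy 0 or 1 at small n; the
  clamping guards the bounds but no continuity correction is applied.
- Fold balancing is by clip count only; class balance within folds is
  not enforced.
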