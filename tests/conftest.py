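import numpy as np
import pytest

from lusview import FrameProbSeries, ViewLabel


def naive_moving_average(probs, w):
    """Loop-based reference moving average over fully contained windows."""
    n = len(probs)
    if w >= n:
        return [sum(probs) / n]
    return [sum(probs[i : i + w]) / w for i in range(n - w + 1)]


def oracle_classify(probs, tau, t, w):
    """Brute-force clip rule: enumerate every window of tau smoothed values."""
    smoothed = naive_moving_average(probs, w)
    for i in range(len(smoothed) - tau + 1):
        if all(v >= t for v in smoothed[i : i + tau]):
            return ViewLabel.PLEURAL
    return ViewLabel.PARENCHYMAL


@pytest.fixture(scope="session")
def separable_dataset():
    """Hand-built clips whose classes a wide hyperparameter band separates.

    Pleural clips contain a run of 10 frames at 0.95 inside a 0.2
    background; parenchymal clips never exceed 0.4.  Any (tau, t, w)
    with t in (0.4, 0.95] and tau <= 10 - w + 1 scores accuracy 1.0.
    """
    rng = np.random.default_rng(42)
    clips = []
    for i in range(30):
        length = int(rng.integers(25, 60))
        start = int(rng.integers(0, length - 10))
        probs = np.full(length, 0.2)
        probs[start : start + 10] = 0.95
        clips.append(
            FrameProbSeries(
                clip_id=f"ple{i:03d}",
                patient_id=f"pat{i % 12:03d}",
                probs=tuple(probs),
                true_label=ViewLabel.PLEURAL,
            )
        )
    for i in range(30):
        length = int(rng.integers(25, 60))
        probs = rng.uniform(0.0, 0.4, size=length)
        clips.append(
            FrameProbSeries(
                clip_id=f"par{i:03d}",
                patient_id=f"pat{12 + i % 12:03d}",
                probs=tuple(probs),
                true_label=ViewLabel.PARENCHYMAL,
            )
        )
    return clips
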