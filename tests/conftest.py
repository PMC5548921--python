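import numpy as np
import pandas as pd
import pytest

from tastecells import calcium


def oracle_responded(time_s, ratio_au, threshold, max_gap_s, min_duration_s):
    """Brute-force response rule: scan every sample pair (i, j) and accept if
    all samples in between are strictly above threshold, no gap exceeds
    max_gap_s, and t_j - t_i >= min_duration_s. Independent of the
    production run detector."""
    t = np.asarray(time_s)
    r = np.asarray(ratio_au)
    n = t.size
    for i in range(n):
        if not r[i] > threshold:
            continue
        for j in range(i, n):
            if not r[j] > threshold:
                break
            if j > i and t[j] - t[j - 1] > max_gap_s:
                break
            if t[j] - t[i] >= min_duration_s:
                return True
    return False


def random_trace(rng, n_min=30, n_max=80):
    """Random irregular trace over ~[0, 600] s with a stimulus at 150 s and
    an occasional step of random height/length after it."""
    n = int(rng.integers(n_min, n_max))
    gaps = rng.uniform(1.0, 12.0, size=n)
    t = np.cumsum(gaps)
    t = t / t[-1] * 600.0
    r = rng.normal(1.0, 0.05, size=n)
    onset = 150.0
    if rng.random() < 0.7:
        height = rng.uniform(0.0, 1.0)
        start = onset + rng.uniform(0.0, 100.0)
        length = rng.uniform(2.0, 120.0)
        r = r + height * ((t >= start) & (t <= start + length))
    return calcium.CalciumTrace(f"r{rng.integers(1e6)}", t, r), calcium.StimulusEvent(onset, 4.0)


@pytest.fixture
def rng():
    return np.random.default_rng(20260921)
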