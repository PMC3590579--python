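"""Shared fixtures and the independent brute-force sample-entropy oracle.

The oracle is written as a literal transcription of the definition — plain
Python loops over every template pair — and is kept deliberately free of the
vectorized implementation's machinery so the two can disagree.
"""

import math

import numpy as np
import pytest


def brute_force_sample_entropy(x, m, r):
    """O(N²) reference sample entropy: count matching template pairs directly.

    Templates of length m and m+1 both start at i = 0..N-m-1 so the
    conditional probability is formed over the same pair population;
    self-matches (i == j) are excluded; distance is the Chebyshev max-norm.
    Returns NaN when no m-templates match, +inf when none extend to m+1.
    """
    x = [float(v) for v in x]
    n = len(x)
    nt = n - m
    b = 0
    a = 0
    for i in range(nt):
        for j in range(i + 1, nt):
            d = 0.0
            for k in range(m):
                d = max(d, abs(x[i + k] - x[j + k]))
            if d <= r:
                b += 1
                if max(d, abs(x[i + m] - x[j + m])) <= r:
                    a += 1
    if b == 0:
        return math.nan
    if a == 0:
        return math.inf
    return -math.log(a / b)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def short_protocol():
    """A 60/30/60-second protocol for fast beat-detection tests."""
    from pulsemei import ProtocolSpec

    return ProtocolSpec(baseline_s=60.0, occlusion_s=30.0, hyperemia_s=60.0)
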