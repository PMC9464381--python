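import numpy as np
import pytest


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def naive_expected_detections(risks, screened, dp, sensitivity=1.0, mode="cascade"):
    """Triple-loop reference for the expected-detection accounting.

    For every patient k and occurrence interval i (mass at t = i + 0.5,
    0-based), walk the patient's exams at times j + 1 >= i + 1 in order; the
    q-th such exam contributes sensitivity * (1-sensitivity)**q * dp**delay
    (cascade) or, in flat mode, only the first exam contributes sensitivity *
    dp**delay.
    """
    risks = np.asarray(risks, float)
    screened = np.asarray(screened).astype(bool)
    N, n = risks.shape
    total = 0.0
    for k in range(N):
        for i in range(n):
            q = 0
            for j in range(i, n):
                if screened[k, j]:
                    delay = (j + 1) - (i + 0.5)
                    if mode == "cascade":
                        total += risks[k, i] * sensitivity * (1 - sensitivity) ** q * dp ** delay
                    elif q == 0:
                        total += risks[k, i] * sensitivity * dp ** delay
                    q += 1
    return total


def naive_max_detections(risks, dp, sensitivity=1.0, mode="cascade"):
    full = np.ones_like(np.asarray(risks, float), dtype=bool)
    return naive_expected_detections(risks, full, dp, sensitivity, mode)
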