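import numpy as np
import pytest

from regremodel.motifs import PWM


@pytest.fixture(scope="session")
def sharp_pwm() -> PWM:
    """Length-10 non-palindromic matrix with a well-separated threshold."""
    p = np.full((10, 4), 0.02)
    p[np.arange(10), [0, 1, 2, 3, 0, 0, 3, 2, 1, 0]] = 0.94  # ACGTAATGCA
    return PWM("sharp", p, 8.0)


@pytest.fixture(scope="session")
def uniform_pwm() -> PWM:
    return PWM("uniform", np.full((6, 4), 0.25), 0.0)


def naive_pwm_score(pwm: PWM, seq: str, floor: float = 1e-3) -> float:
    """Independent per-position loop oracle for the log-odds score."""
    import math

    idx = {"A": 0, "C": 1, "G": 2, "T": 3}
    total = 0.0
    for i, base in enumerate(seq.upper()):
        p = max(float(pwm.probabilities[i, idx[base]]), floor)
        total += math.log(p / 0.25)
    return total
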