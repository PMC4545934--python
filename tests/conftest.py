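import numpy as np
import pytest

from pwmscale import (
    BACKGROUND_PRESETS,
    PFM,
    build_pwm,
    exact_distribution,
)


@pytest.fixture
def uniform_bg():
    return BACKGROUND_PRESETS["uniform"]


@pytest.fixture
def single_a_column_pfm():
    """One column with counts (A=8, C=0, G=0, T=0)."""
    return PFM(counts=np.array([[8.0], [0.0], [0.0], [0.0]]), n_sequences=8,
               motif_id="A1")


@pytest.fixture
def a6_pfm():
    """Six identical (A=8,0,0,0) columns: the worked-example motif."""
    counts = np.zeros((4, 6))
    counts[0] = 8.0
    return PFM(counts=counts, n_sequences=8, motif_id="A6")


@pytest.fixture
def a6_pwm(a6_pfm, uniform_bg):
    return build_pwm(a6_pfm, uniform_bg)


@pytest.fixture
def a6_exact(a6_pwm):
    return exact_distribution(a6_pwm)


def enumerated_landscape(pwm, background):
    """Brute-force oracle: score and probability of all 4^L k-mers."""
    scores = np.zeros(1)
    probs = np.ones(1)
    for k in range(pwm.length):
        scores = (scores[:, None] + pwm.weights[None, :, k]).ravel()
        probs = (probs[:, None] * background.freqs[None, :]).ravel()
    return scores, probs


def enumerated_top_quantile(scores, probs, q):
    """Nearest-rank top-q score from an enumerated landscape."""
    order = np.argsort(scores)[::-1]
    tail = np.cumsum(probs[order])
    idx = int(np.searchsorted(tail, q - 1e-12, side="left"))
    return float(scores[order][min(idx, len(order) - 1)])
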