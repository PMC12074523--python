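import math

import numpy as np
import pytest

from fmsflow import (
    BandTone,
    CohortModel,
    OscillationSpec,
    ProtocolSpec,
    ResponseSpec,
    generate_trace,
)
from fmsflow.constants import control_group_model, cvd_dm2_group_model

#: Tone amplitude whose mean square x 1e6 equals the worked-example VM of 11.6.
VM_11P6_AMPLITUDE = math.sqrt(2.0 * 11.6e-6)


@pytest.fixture
def protocol():
    return ProtocolSpec()


@pytest.fixture
def myogenic_only_osc():
    return OscillationSpec(tones=(BandTone("myogenic", 0.1, VM_11P6_AMPLITUDE),))


@pytest.fixture
def flat_response():
    return ResponseSpec(ir_max=0.0, hr_max=0.0)


@pytest.fixture
def clean_myogenic_trace(protocol, myogenic_only_osc, flat_response):
    """Noise-free, envelope-free trace with a single 0.1 Hz myogenic tone."""
    return generate_trace(protocol, myogenic_only_osc, flat_response, noise_sd=0.0, seed=11)


@pytest.fixture
def control_model():
    return control_group_model()


@pytest.fixture
def patient_model():
    return cvd_dm2_group_model()


@pytest.fixture
def control_cohort_100k(control_model):
    from fmsflow import generate_cohort

    return generate_cohort(CohortModel(groups=((control_model, 100_000),), seed=2024))


def brute_force_dft_band_power(x: np.ndarray, fs: float, lo: float, hi: float) -> float:
    """Independent oracle: direct DFT sum over bins in (lo, hi].

    One-sided mean-square contribution of each positive-frequency bin is
    2*|X_k|^2/N^2 (N even, k < N/2), matching the Parseval convention of the
    periodogram route without going through scipy.
    """
    n = x.size
    freqs = np.arange(n // 2 + 1) * fs / n
    power = 0.0
    for k, f in enumerate(freqs):
        if lo < f <= hi:
            xk = np.sum(x * np.exp(-2j * np.pi * k * np.arange(n) / n))
            scale = 1.0 if k in (0, n // 2) and n % 2 == 0 else 2.0
            power += scale * abs(xk) ** 2 / n**2
    return power


def pairwise_rank_auc(scores: np.ndarray, labels: np.ndarray) -> float:
    """Independent oracle: P(score_pos > score_neg) + 0.5 P(tie)."""
    pos = scores[labels.astype(bool)]
    neg = scores[~labels.astype(bool)]
    wins = 0.0
    for p in pos:
        wins += np.sum(p > neg) + 0.5 * np.sum(p == neg)
    return wins / (len(pos) * len(neg))
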