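import numpy as np
import pytest

from rettphys import Trace


@pytest.fixture
def psc_kernel():
    """Analytic double-exponential PSC kernel at 2 kHz, unit peak."""
    fs = 2000.0
    t = np.arange(0, 0.06, 1 / fs)
    k = np.exp(-t / 0.010) - np.exp(-t / 0.002)
    return k / k.max(), fs


@pytest.fixture
def planted_event_trace(psc_kernel):
    """Factory: clean trace with events of a given amplitude (in noise-SD
    units with sigma = 1 pA) planted every 2 s; returns (trace, times)."""
    kernel, fs = psc_kernel

    def make(amp_sigma: float, n_events: int = 5, noise_sd: float = 0.0,
             seed: int = 0, polarity: str = "negative"):
        duration = 2.0 * n_events + 2.0
        n = int(duration * fs)
        sig = np.zeros(n)
        times = 1.0 + 2.0 * np.arange(n_events)
        for t0 in times:
            k = int(t0 * fs)
            sig[k:k + kernel.size] += amp_sigma * kernel
        if noise_sd > 0:
            sig = sig + np.random.default_rng(seed).normal(0, noise_sd, n)
        if polarity == "negative":
            sig = -sig
        return Trace(sig, 1 / fs), times

    return make
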