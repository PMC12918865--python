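import numpy as np
import pytest

from synquant.synthetic import psc_kernel
from synquant.traceio import Trace

SAMPLING_RATE = 20_000.0


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def make_trace_with_events(
    event_times_s,
    amplitudes_pa,
    taus_ms,
    duration_s,
    rms_noise=0.0,
    tau_rise_ms=0.5,
    sampling_rate=SAMPLING_RATE,
    seed=0,
):
    """Deterministic trace with events at exact sample-aligned times."""
    n = int(round(duration_s * sampling_rate))
    t_ms = np.arange(n) / sampling_rate * 1000.0
    y = np.zeros(n)
    for t0, a, tau in zip(event_times_s, amplitudes_pa, taus_ms):
        y += a * psc_kernel(t_ms - t0 * 1000.0, tau_rise_ms, tau)
    if rms_noise > 0:
        y += np.random.default_rng(seed).normal(0, rms_noise, n)
    return Trace(sampling_rate, -y, polarity="inward")
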