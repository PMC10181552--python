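import numpy as np
import pytest

from eegtiming import EpochSet, MarkerStream, SampledStream


@pytest.fixture
def grid_stream():
    """A 250 Hz stream sampled exactly on the k/rate grid, 10 s long."""
    rate = 250.0
    ts = np.arange(int(10 * rate)) / rate
    data = np.zeros_like(ts)
    return SampledStream(
        raw_timestamps=ts, data=data, nominal_rate=rate, corrected_timestamps=ts.copy()
    )


@pytest.fixture
def chunked_stream():
    """A 125 Hz stream delivered in 60-sample chunks with clustered stamps."""
    rate, chunk, n_chunks = 125.0, 60, 10
    n = chunk * n_chunks
    true = np.arange(n) / rate
    raw = np.empty(n)
    for c in range(n_chunks):
        delivery = true[(c + 1) * chunk - 1] + 0.02
        raw[c * chunk : (c + 1) * chunk] = delivery + np.arange(chunk) * 2e-4
    return SampledStream(raw_timestamps=raw, data=np.zeros(n), nominal_rate=rate)


def make_step_epochs(
    latencies_ms, rate=500.0, amplitude=10.0, window=(-0.2, 0.8)
) -> EpochSet:
    """Epochs that step from 0 to `amplitude` at the given per-trial latency."""
    n = int(round((window[1] - window[0]) * rate))
    rel = window[0] + np.arange(n) / rate
    trials = np.zeros((len(latencies_ms), n))
    for i, lat in enumerate(latencies_ms):
        trials[i, rel >= lat / 1000.0 - 1e-9] = amplitude
    return EpochSet(
        rel_times=rel,
        trials=trials,
        trial_t0=np.arange(len(latencies_ms), dtype=float),
        nominal_rate=rate,
    )


@pytest.fixture
def step_epochs_factory():
    return make_step_epochs


@pytest.fixture
def markers_every_100ms():
    ts = 1.0 + np.arange(20) * 0.1
    return MarkerStream(timestamps=ts)
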