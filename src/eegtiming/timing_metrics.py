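"""Timing-oracle analysis: epoching, half-maximum onset latencies, lag/jitter.

The timing benchmark records a periodic square-wave stimulus on one channel
together with a marker stream carrying the intended stimulus times. For each
marker the signal is epoched, the onset is located as the first post-marker
sample exceeding half the maximum of the trial-averaged response, and the
per-trial marker-to-onset latencies are summarized as *lag* (their mean, a
constant offset removable by timestamp shifting) and *jitter* (their sample
standard deviation, the irreducible timing noise that smears ERP averages).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .stream_model import EpochSet, MarkerStream, SampledStream, TimingResult

__all__ = [
    "OnsetParams",
    "extract_epochs",
    "detect_latencies",
    "correct_lag",
    "summarize_runs",
    "RunSetSummary",
]


@dataclass(frozen=True)
class OnsetParams:
    """Epoch window and baseline bounds in seconds relative to the marker."""

    window_start: float = -0.2
    window_end: float = 0.8
    baseline_end: float = 0.0

    def __post_init__(self) -> None:
        if not (self.window_start < self.baseline_end <= 0.0 < self.window_end):
            raise ValueError("require window_start < baseline_end <= 0 < window_end")


def extract_epochs(
    stream: SampledStream,
    markers: MarkerStream,
    params: OnsetParams | None = None,
    channel: int = 0,
) -> EpochSet:
    """Cut fixed-length trial windows around each marker.

    Each trial consists of the ``round(span * rate)`` consecutive samples
    starting at the first sample whose corrected timestamp is >=
    ``t0 + window_start``; trials are aligned on a shared relative-time grid
    spaced at one nominal interval over the half-open window
    ``[window_start, window_end)``. Markers whose window is not fully covered
    by the recording are dropped and counted in ``n_dropped``.
    """
    params = params or OnsetParams()
    if stream.corrected_timestamps is None:
        raise ValueError("stream has no corrected timestamps; dejitter first")
    ts = stream.corrected_timestamps
    rate = stream.nominal_rate
    n_len = int(round((params.window_end - params.window_start) * rate))
    rel_times = params.window_start + np.arange(n_len) / rate

    sig = stream.data[:, channel]
    rows: list[np.ndarray] = []
    t0s: list[float] = []
    dropped = 0
    # Samples can land exactly on the window edge (marker clock commensurate
    # with the sample grid); a nanosecond guard keeps the half-open boundary
    # decision independent of floating-point summation order.
    tie_eps = 1e-9
    dt = 1.0 / rate
    for t0 in markers.timestamps:
        i0 = int(np.searchsorted(ts, t0 + params.window_start - tie_eps, side="left"))
        if (
            i0 + n_len > ts.shape[0]
            or ts[i0] > t0 + params.window_start + dt  # pre-window not covered
        ):
            dropped += 1
            continue
        rows.append(sig[i0 : i0 + n_len])
        t0s.append(float(t0))
    if not rows:
        raise ValueError("no epochs: no marker window lies within the recording")
    return EpochSet(
        rel_times=rel_times,
        trials=np.vstack(rows),
        trial_t0=np.array(t0s),
        nominal_rate=rate,
        n_dropped=dropped,
    )


def detect_latencies(
    epochs: EpochSet, params: OnsetParams | None = None
) -> TimingResult:
    """Half-maximum onset latencies and their lag/jitter summary.

    Each trial is baseline-corrected by subtracting its pre-stimulus mean
    (``[window_start, baseline_end)``). The detection threshold is half the
    post-stimulus maximum of the trial-averaged waveform; a trial's latency is
    the relative time, in ms, of its first post-stimulus sample exceeding that
    threshold. Trials that never cross are NaN and excluded from the mean
    (lag) and sample SD (jitter). Latencies are reported at sample resolution,
    with no sub-sample interpolation.
    """
    params = params or OnsetParams()
    if epochs.n_trials < 2:
        raise ValueError("need at least 2 trials")
    rel = epochs.rel_times
    base_mask = rel < params.baseline_end
    post_mask = rel >= 0.0

    baseline = epochs.trials[:, base_mask].mean(axis=1, keepdims=True)
    corrected = epochs.trials - baseline
    average = corrected.mean(axis=0)
    peak = float(average[post_mask].max())
    if peak <= 0:
        raise ValueError("no response detected: nonpositive post-stimulus peak")
    threshold = 0.5 * peak

    post = corrected[:, post_mask]
    rel_post_ms = rel[post_mask] * 1000.0
    above = post > threshold
    first = np.argmax(above, axis=1)
    crossed = above.any(axis=1)
    latencies = np.where(crossed, rel_post_ms[first], np.nan)
    return TimingResult.from_latencies(latencies)


def correct_lag(stream: SampledStream, lag_ms: float) -> SampledStream:
    """Shift corrected timestamps earlier by a measured lag (milliseconds).

    Subtracting the run's mean marker-to-onset latency aligns the signal time
    base with the stimulus clock; sample values are untouched.
    """
    if stream.corrected_timestamps is None:
        raise ValueError("stream has no corrected timestamps; dejitter first")
    return stream.with_corrected(stream.corrected_timestamps - lag_ms / 1000.0)


@dataclass(frozen=True)
class RunSetSummary:
    """Across-run summary for one recording configuration (plain, unweighted)."""

    mean_lag_ms: float
    mean_jitter_ms: float
    lag_sd_ms: float
    jitter_sd_ms: float
    n_runs: int


def summarize_runs(results: list[TimingResult]) -> RunSetSummary:
    """Unweighted mean and across-run SD of lag and jitter over runs.

    Runs are not weighted by trial count. With a single run the across-run
    SDs are reported as 0.
    """
    if not results:
        raise ValueError("no runs")
    lags = np.array([r.lag_ms for r in results])
    jitters = np.array([r.jitter_ms for r in results])
    sd = lambda x: float(np.std(x, ddof=1)) if x.size > 1 else 0.0  # noqa: E731
    return RunSetSummary(
        mean_lag_ms=float(lags.mean()),
        mean_jitter_ms=float(jitters.mean()),
        lag_sd_ms=sd(lags),
        jitter_sd_ms=sd(jitters),
        n_runs=len(results),
    )
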