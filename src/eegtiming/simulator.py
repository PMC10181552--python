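"""Seedable generator emulating the square-wave timing-test rig and transport.

The physical benchmark plays a 10 Hz train of 5 ms square pulses into one
amplifier channel while the stimulus software emits a marker at each intended
playback time. Between stimulus and recorded sample sit (a) a constant
hardware/audio path delay plus per-trial onset jitter, (b) the amplifier's
front-end and ADC, and (c) a transport that may buffer samples into chunks
before delivery, stamping every sample in a chunk at (roughly) the chunk's
reception time.

This module reproduces that chain with known ground truth so the dejittering
algorithms and timing metrics can be validated end to end:

* markers on the stimulus clock, pulses on the signal clock after a constant
  lag plus optional Gaussian onset jitter;
* samples on an exact ``k / rate`` grid; each sample value is the mean of the
  continuous pulse train over the preceding sample period (a one-sample
  boxcar standing in for the amplifier's anti-alias front-end) plus white
  Gaussian noise;
* chunked delivery with sizes drawn from a configurable distribution
  (defaults: {59,60,61} at 125 Hz, {119,120,121} at 250 Hz — a ~0.48 s buffer
  interval), occasional truncated "short" chunks, delivery at the generation
  time of the chunk's last sample plus a transport delay, and near-identical
  within-chunk raw timestamps;
* or per-sample delivery with zero-mean stamping noise
  (:func:`simulate_clean_recording`), the behavior of an unbuffered link.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .stream_model import MarkerStream, SampledStream

__all__ = ["SimConfig", "GroundTruth", "simulate_recording", "simulate_clean_recording"]


def default_chunk_sizes(rate: float, buffer_interval: float = 0.48) -> tuple[int, ...]:
    """Chunk-size support for a buffered link accumulating ~buffer_interval s."""
    m = int(round(rate * buffer_interval))
    return (m - 1, m, m + 1)


@dataclass(frozen=True)
class SimConfig:
    """Full description of one simulated timing-test recording.

    Times are seconds, amplitudes microvolts. ``duration`` is the length of
    the stimulus block (so ``duration * pulse_rate`` markers are emitted);
    the recording itself starts ``marker_lead`` seconds earlier and extends
    one second past the last marker so every trial window is covered.
    """

    rate: float = 125.0
    duration: float = 40.0
    pulse_rate: float = 10.0
    pulse_width: float = 0.005
    pulse_amplitude: float = 1000.0
    noise_sd: float = 1.0
    hardware_lag: float = 0.025
    onset_jitter_sd: float = 0.0
    chunk_size_choices: Optional[Sequence[int]] = None
    chunk_size_probs: Optional[Sequence[float]] = None
    short_chunk_prob: float = 0.02
    short_chunk_fraction: float = 0.25
    transport_delay: float = 0.02
    intra_chunk_stamp_spacing: float = 0.0002
    stamp_noise_sd: float = 0.0005
    # Lead-in long enough that the chunk stream reaches its steady state
    # before trials start (the corrected time base settles once the first
    # maximum-size chunk has arrived; ~30 chunks make a miss vanishingly
    # unlikely). The 0.3 ms fraction is a constant stimulus-clock offset:
    # real stimulus and amplifier clocks are never commensurate, so markers
    # never coincide exactly with sample instants.
    marker_lead: float = 15.0003
    seed: int = 0

    def __post_init__(self) -> None:
        if self.rate <= 0 or self.duration <= 0 or self.pulse_rate <= 0:
            raise ValueError("rates and duration must be positive")
        if self.pulse_width >= 1.0 / self.pulse_rate:
            raise ValueError("overlapping pulses: pulse_width >= 1/pulse_rate")
        if not (0.0 <= self.short_chunk_prob <= 1.0):
            raise ValueError("short_chunk_prob must be in [0, 1]")
        if self.chunk_size_choices is not None and any(
            s < 1 for s in self.chunk_size_choices
        ):
            raise ValueError("chunk sizes must be >= 1")

    @property
    def sizes(self) -> tuple[int, ...]:
        if self.chunk_size_choices is not None:
            return tuple(int(s) for s in self.chunk_size_choices)
        return default_chunk_sizes(self.rate)


@dataclass
class GroundTruth:
    """What the simulator actually did — the oracle for every downstream test."""

    true_sample_times: np.ndarray
    true_onset_times: np.ndarray
    emitted_chunk_sizes: list[int] = field(default_factory=list)
    injected_lag: float = 0.0
    injected_jitter_sd: float = 0.0


def _pulse_train_boxcar(
    sample_times: np.ndarray,
    onsets: np.ndarray,
    width: float,
    amplitude: float,
    dt: float,
) -> np.ndarray:
    """Mean of the pulse train over each sample's preceding period (t-dt, t].

    Integrating over the sample period models the amplifier's anti-alias
    front-end; without it a pulse narrower than the sample interval could fall
    entirely between samples and vanish.
    """
    values = np.zeros_like(sample_times)
    t0 = sample_times[0]
    for on in onsets:
        k_first = int(np.ceil((on - t0) / dt - 1e-12))  # first window ending > on
        k_last = int(np.floor((on + width - t0) / dt + 1.0 - 1e-12))
        k_first = max(k_first, 0)
        k_last = min(k_last, sample_times.shape[0] - 1)
        if k_last < k_first:
            continue
        ks = np.arange(k_first, k_last + 1)
        win_end = sample_times[ks]
        overlap = np.minimum(win_end, on + width) - np.maximum(win_end - dt, on)
        np.clip(overlap, 0.0, None, out=overlap)
        values[ks] += amplitude * overlap / dt
    return values


def _signal_and_markers(
    config: SimConfig, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    n_markers = int(round(config.duration * config.pulse_rate))
    marker_times = config.marker_lead + np.arange(n_markers) / config.pulse_rate

    delays = np.full(n_markers, config.hardware_lag)
    if config.onset_jitter_sd > 0:
        delays = delays + rng.normal(0.0, config.onset_jitter_sd, n_markers)
    np.clip(delays, 0.0, None, out=delays)  # a pulse can never precede its marker
    onsets = marker_times + delays

    # 1.5 s tail: covers the last trial's +0.8 s window even after the
    # transport drops an unfilled final buffer (~0.48 s of samples).
    total = config.marker_lead + n_markers / config.pulse_rate + 1.5
    n_samples = int(round(total * config.rate))
    dt = 1.0 / config.rate
    true_times = np.arange(n_samples) * dt

    values = _pulse_train_boxcar(
        true_times, onsets, config.pulse_width, config.pulse_amplitude, dt
    )
    if config.noise_sd > 0:
        values = values + rng.normal(0.0, config.noise_sd, n_samples)
    return true_times, values, marker_times, onsets


def _draw_chunk_sizes(
    config: SimConfig, n_samples: int, rng: np.random.Generator
) -> list[int]:
    sizes = np.asarray(config.sizes)
    probs = None
    if config.chunk_size_probs is not None:
        probs = np.asarray(config.chunk_size_probs, dtype=float)
        probs = probs / probs.sum()
    out: list[int] = []
    remaining = n_samples
    while remaining > 0:
        size = int(rng.choice(sizes, p=probs))
        if config.short_chunk_prob > 0 and rng.random() < config.short_chunk_prob:
            size = max(1, int(round(size * config.short_chunk_fraction)))
        if size > remaining:
            # Samples still sitting in the transport buffer when the
            # recording stops never reach the file; the unfilled final
            # buffer is dropped (unless nothing was delivered at all).
            if out:
                break
            size = remaining
        out.append(size)
        remaining -= size
    return out


def simulate_recording(
    config: SimConfig,
) -> tuple[SampledStream, MarkerStream, GroundTruth]:
    """Simulate one chunk-buffered timing-test recording.

    Samples are grouped into chunks drawn from the configured size
    distribution (with occasional truncated short chunks); each chunk is
    delivered at the generation time of its last sample plus the transport
    delay, and the raw timestamps of its samples are the delivery time plus a
    small constant per-sample stamping spacing. Identical seeds give
    bit-identical output.
    """
    rng = np.random.default_rng(config.seed)
    true_times, values, marker_times, onsets = _signal_and_markers(config, rng)
    n_samples = true_times.shape[0]

    chunk_sizes = _draw_chunk_sizes(config, n_samples, rng)
    n_delivered = sum(chunk_sizes)
    true_times = true_times[:n_delivered]
    values = values[:n_delivered]
    raw = np.empty(n_delivered)
    start = 0
    for size in chunk_sizes:
        end = start + size  # exclusive
        delivery = true_times[end - 1] + config.transport_delay
        raw[start:end] = delivery + np.arange(size) * config.intra_chunk_stamp_spacing
        start = end

    stream = SampledStream(
        raw_timestamps=raw,
        data=values,
        nominal_rate=config.rate,
        channel_labels=["signal"],
    )
    markers = MarkerStream(
        timestamps=marker_times, labels=["pulse"] * marker_times.shape[0]
    )
    truth = GroundTruth(
        true_sample_times=true_times,
        true_onset_times=onsets,
        emitted_chunk_sizes=chunk_sizes,
        injected_lag=config.hardware_lag,
        injected_jitter_sd=config.onset_jitter_sd,
    )
    return stream, markers, truth


def simulate_clean_recording(
    config: SimConfig,
) -> tuple[SampledStream, MarkerStream, GroundTruth]:
    """Simulate an unbuffered link: every sample delivered individually.

    Raw timestamps are the true sample times plus the constant transport
    delay plus zero-mean Gaussian stamping noise of SD
    ``config.stamp_noise_sd`` — the regime the conventional per-segment
    linear dejitter is designed for.
    """
    rng = np.random.default_rng(config.seed)
    true_times, values, marker_times, onsets = _signal_and_markers(config, rng)
    n_samples = true_times.shape[0]

    raw = true_times + config.transport_delay
    if config.stamp_noise_sd > 0:
        raw = raw + rng.normal(0.0, config.stamp_noise_sd, n_samples)

    stream = SampledStream(
        raw_timestamps=raw,
        data=values,
        nominal_rate=config.rate,
        channel_labels=["signal"],
    )
    markers = MarkerStream(
        timestamps=marker_times, labels=["pulse"] * marker_times.shape[0]
    )
    truth = GroundTruth(
        true_sample_times=true_times,
        true_onset_times=onsets,
        emitted_chunk_sizes=[1] * n_samples,
        injected_lag=config.hardware_lag,
        injected_jitter_sd=config.onset_jitter_sd,
    )
    return stream, markers, truth
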