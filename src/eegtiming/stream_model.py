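"""Core in-memory containers for sampled streams, markers, chunks and results.

Timestamps are double-precision seconds on the recorder's clock (the XDF
convention); all public timing metrics are reported in milliseconds.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np

__all__ = [
    "SampledStream",
    "MarkerStream",
    "Chunk",
    "ChunkMap",
    "EpochSet",
    "TimingResult",
    "validate",
    "nominal_interval_ms",
]


def nominal_interval_ms(rate: float) -> float:
    """Nominal sample interval in milliseconds for a sampling rate in Hz.

    E.g. 8 ms at 125 Hz, 4 ms at 250 Hz, 2 ms at 500 Hz.
    """
    if rate <= 0:
        raise ValueError("nonpositive rate")
    return 1000.0 / rate


@dataclass
class SampledStream:
    """One amplifier channel group with raw and optionally corrected timestamps.

    Parameters
    ----------
    raw_timestamps
        Per-sample reception timestamps in seconds. With buffered transports
        these cluster at chunk reception times and are only monotone between
        transport bursts.
    data
        Sample values in microvolts, shape ``(n_samples, n_channels)``.
    nominal_rate
        Sampling rate in Hz from the stream metadata. Never re-estimated
        from the timestamps.
    corrected_timestamps
        Dejittered timestamps in seconds, strictly increasing, or ``None``
        if no correction has been applied yet.
    """

    raw_timestamps: np.ndarray
    data: np.ndarray
    nominal_rate: float
    corrected_timestamps: Optional[np.ndarray] = None
    channel_labels: Sequence[str] = field(default_factory=list)
    name: str = "EEG"

    def __post_init__(self) -> None:
        self.raw_timestamps = np.asarray(self.raw_timestamps, dtype=np.float64)
        self.data = np.asarray(self.data, dtype=np.float64)
        if self.data.ndim == 1:
            self.data = self.data[:, None]
        if self.corrected_timestamps is not None:
            self.corrected_timestamps = np.asarray(
                self.corrected_timestamps, dtype=np.float64
            )
        if not self.channel_labels:
            self.channel_labels = [f"ch{i}" for i in range(self.data.shape[1])]

    @property
    def n_samples(self) -> int:
        return self.raw_timestamps.shape[0]

    @property
    def n_channels(self) -> int:
        return self.data.shape[1]

    @property
    def nominal_interval(self) -> float:
        """Nominal sample interval in seconds (1 / nominal_rate)."""
        return 1.0 / self.nominal_rate

    @property
    def timestamps(self) -> np.ndarray:
        """Corrected timestamps if present, else raw."""
        if self.corrected_timestamps is not None:
            return self.corrected_timestamps
        return self.raw_timestamps

    def with_corrected(self, corrected: np.ndarray) -> "SampledStream":
        """Return a copy of this stream carrying the given corrected timestamps."""
        return replace(self, corrected_timestamps=np.asarray(corrected, np.float64))


@dataclass
class MarkerStream:
    """Stimulus event markers; each marker timestamp is the trial's t0."""

    timestamps: np.ndarray
    labels: Sequence[str] = field(default_factory=list)
    name: str = "Markers"

    def __post_init__(self) -> None:
        self.timestamps = np.asarray(self.timestamps, dtype=np.float64)
        if not self.labels:
            self.labels = ["marker"] * self.timestamps.shape[0]

    @property
    def n_markers(self) -> int:
        return self.timestamps.shape[0]


@dataclass
class Chunk:
    """One transmission chunk: inclusive index range plus reception metadata."""

    start: int
    end: int  # inclusive
    reception_timestamp: float
    short: bool = False
    shifted: bool = False
    shift_s: float = 0.0

    @property
    def n_samples(self) -> int:
        return self.end - self.start + 1

    @property
    def regular(self) -> bool:
        return not (self.short or self.shifted)


@dataclass
class ChunkMap:
    """Ordered partition of a stream's samples into transmission chunks."""

    chunks: list[Chunk]

    @property
    def n_chunks(self) -> int:
        return len(self.chunks)

    @property
    def sizes(self) -> np.ndarray:
        return np.array([c.n_samples for c in self.chunks], dtype=int)

    def __iter__(self):
        return iter(self.chunks)

    def __len__(self) -> int:
        return len(self.chunks)

    def __getitem__(self, i: int) -> Chunk:
        return self.chunks[i]

    def check_partition(self, n_samples: int) -> None:
        """Raise if the chunks do not partition [0, n_samples-1] in order."""
        expect = 0
        for c in self.chunks:
            if c.start != expect:
                raise ValueError(f"chunk gap/overlap at index {c.start}")
            if c.end < c.start:
                raise ValueError("empty chunk")
            expect = c.end + 1
        if expect != n_samples:
            raise ValueError("chunks do not cover all samples")


@dataclass
class EpochSet:
    """Per-trial signal windows aligned on time relative to the marker.

    ``rel_times`` runs over the half-open epoch window (default [-0.2, 0.8) s)
    with spacing exactly one nominal sample interval; ``trials`` has shape
    (n_trials, len(rel_times)).
    """

    rel_times: np.ndarray
    trials: np.ndarray
    trial_t0: np.ndarray
    nominal_rate: float
    n_dropped: int = 0

    def __post_init__(self) -> None:
        self.rel_times = np.asarray(self.rel_times, dtype=np.float64)
        self.trials = np.atleast_2d(np.asarray(self.trials, dtype=np.float64))
        self.trial_t0 = np.asarray(self.trial_t0, dtype=np.float64)

    @property
    def n_trials(self) -> int:
        return self.trials.shape[0]


@dataclass
class TimingResult:
    """Single-trial latencies plus their lag (mean) and jitter (sample SD).

    Latencies are in milliseconds relative to the marker; trials whose signal
    never crosses the half-maximum threshold are NaN and excluded from the
    lag/jitter summaries.
    """

    latencies_ms: np.ndarray
    lag_ms: float
    jitter_ms: float
    n_trials_used: int

    def __post_init__(self) -> None:
        self.latencies_ms = np.asarray(self.latencies_ms, dtype=np.float64)

    @classmethod
    def from_latencies(cls, latencies_ms: np.ndarray) -> "TimingResult":
        """Build a result from per-trial latencies (NaN marks missing trials)."""
        lat = np.asarray(latencies_ms, dtype=np.float64)
        ok = lat[~np.isnan(lat)]
        if ok.size == 0:
            return cls(lat, float("nan"), float("nan"), 0)
        lag = float(np.mean(ok))
        jitter = float(np.std(ok, ddof=1)) if ok.size > 1 else 0.0
        return cls(lat, lag, jitter, int(ok.size))


def validate(stream: SampledStream) -> list[str]:
    """Check a stream's structural invariants; return human-readable violations.

    Reports rather than raises, and never mutates the stream.
    """
    problems: list[str] = []
    if stream.data.shape[0] != stream.raw_timestamps.shape[0]:
        problems.append(
            "length mismatch: "
            f"{stream.data.shape[0]} samples vs {stream.raw_timestamps.shape[0]} timestamps"
        )
    if not stream.nominal_rate > 0:
        problems.append(f"nonpositive rate: {stream.nominal_rate}")
    ct = stream.corrected_timestamps
    if ct is not None:
        if ct.shape[0] != stream.raw_timestamps.shape[0]:
            problems.append("corrected timestamp count differs from raw")
        if ct.shape[0] > 1 and not np.all(np.diff(ct) > 0):
            problems.append("corrected timestamps not strictly increasing")
    return problems
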