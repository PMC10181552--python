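"""Timestamp correction for sampled streams.

Two methods are provided:

* :func:`regular_dejitter` — the conventional XDF-importer approach: split the
  recording into gap-free segments and replace each segment's timestamps with
  an ordinary-least-squares line fitted against sample index. Appropriate when
  every sample is delivered (and timestamped) individually, so stamping noise
  is zero-mean around the true sample clock.

* :func:`chunk_dejitter` — a local correction for buffered transports that
  deliver samples in bursts ("chunks") whose raw timestamps cluster at the
  chunk reception time. Each chunk's timestamps are extrapolated forward from
  its reception timestamp at the nominal rate; occasional short chunks whose
  extrapolation overlaps the previous chunk are shifted right into place.

A global line fit is systematically wrong for chunked streams because chunk
sizes vary by a sample or two, so the reception times do not fall on a single
line with per-sample slope; the chunk method trusts each reception timestamp
locally instead.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .stream_model import Chunk, ChunkMap, SampledStream

__all__ = [
    "ChunkDejitterParams",
    "detect_chunks",
    "regular_dejitter",
    "chunk_dejitter",
]


@dataclass(frozen=True)
class ChunkDejitterParams:
    """Tuning knobs for chunk detection and short-chunk repair.

    boundary_factor
        A new chunk starts wherever the raw inter-sample gap exceeds
        ``boundary_factor / nominal_rate``. Within-chunk stamping intervals
        are orders of magnitude below one nominal interval while inter-chunk
        gaps are tens of intervals, so the default factor of 2 separates the
        two regimes with a wide margin.
    overlap_tolerance
        Slack in seconds before an extrapolated chunk counting as overlapping
        its predecessor. 0 means any non-positive gap triggers a shift.
    """

    boundary_factor: float = 2.0
    overlap_tolerance: float = 0.0

    def __post_init__(self) -> None:
        if not self.boundary_factor > 1:
            raise ValueError("boundary_factor must be > 1")
        if self.overlap_tolerance < 0:
            raise ValueError("overlap_tolerance must be >= 0")


def detect_chunks(
    stream: SampledStream, params: ChunkDejitterParams | None = None
) -> ChunkMap:
    """Partition a stream's samples into transmission chunks.

    A chunk boundary is declared before sample ``i`` iff
    ``raw[i] - raw[i-1] > boundary_factor / nominal_rate``. Sample 0 always
    opens a chunk, and a chunk's reception timestamp is the raw timestamp of
    its first sample. A backwards jump in the raw clock (recorder clock reset)
    also opens a chunk.
    """
    params = params or ChunkDejitterParams()
    raw = stream.raw_timestamps
    n = raw.shape[0]
    if n < 2:
        raise ValueError("stream too short: need at least 2 samples")
    if not stream.nominal_rate > 0:
        raise ValueError("invalid rate")

    threshold = params.boundary_factor / stream.nominal_rate
    diffs = np.diff(raw)
    starts = np.flatnonzero((diffs > threshold) | (diffs < 0)) + 1
    starts = np.concatenate(([0], starts))
    ends = np.concatenate((starts[1:] - 1, [n - 1]))

    chunks = [
        Chunk(start=int(s), end=int(e), reception_timestamp=float(raw[s]))
        for s, e in zip(starts, ends)
    ]
    _flag_short(chunks)
    cm = ChunkMap(chunks)
    cm.check_partition(n)
    return cm


def _flag_short(chunks: list[Chunk]) -> None:
    """Mark chunks well below the typical transfer size as short."""
    if len(chunks) < 2:
        return
    sizes = np.array([c.n_samples for c in chunks])
    typical = float(np.median(sizes))
    for c in chunks:
        c.short = c.n_samples < 0.75 * typical


def _segment_bounds(raw: np.ndarray, gap_threshold: float) -> list[tuple[int, int]]:
    diffs = np.diff(raw)
    starts = np.flatnonzero((diffs > gap_threshold) | (diffs < 0)) + 1
    starts = np.concatenate(([0], starts))
    ends = np.concatenate((starts[1:], [raw.shape[0]]))
    return [(int(s), int(e)) for s, e in zip(starts, ends)]


def regular_dejitter(
    stream: SampledStream, gap_threshold: float = 1.0
) -> SampledStream:
    """Linear per-segment dejittering (the conventional XDF-importer method).

    The recording is split into segments at raw inter-sample gaps larger than
    ``gap_threshold`` seconds (or at clock resets); within each segment the
    corrected timestamps are the fitted values of an OLS line of raw timestamp
    on sample index. Single-sample segments pass their timestamp through
    unchanged. Sample values are never modified.
    """
    raw = stream.raw_timestamps
    if raw.shape[0] < 2:
        raise ValueError("stream too short: need at least 2 samples")
    corrected = np.empty_like(raw)
    for s, e in _segment_bounds(raw, gap_threshold):
        seg = raw[s:e]
        if seg.shape[0] == 1:
            corrected[s:e] = seg
            continue
        idx = np.arange(seg.shape[0], dtype=np.float64)
        design = np.column_stack((idx, np.ones_like(idx)))
        coef, *_ = np.linalg.lstsq(design, seg, rcond=None)
        corrected[s:e] = design @ coef
    return stream.with_corrected(corrected)


def chunk_dejitter(
    stream: SampledStream, params: ChunkDejitterParams | None = None
) -> tuple[SampledStream, ChunkMap]:
    """Chunk-wise timestamp extrapolation with short-chunk shifting.

    1. Chunks are detected from the large inter-chunk gaps in the raw
       timestamps (:func:`detect_chunks`).
    2. Within each chunk, timestamps are extrapolated from the chunk's
       reception timestamp at the nominal rate:
       ``corrected[s + k] = T_c + k / rate``.
    3. In temporal order, any chunk whose extrapolated first timestamp does
       not exceed the previous chunk's corrected last timestamp (plus the
       overlap tolerance) is shifted right so it starts exactly one nominal
       interval after that chunk, and flagged ``shifted``. Shifts are applied
       sequentially so consecutive short chunks cascade.

    Returns the corrected stream and the chunk map annotated with flags and
    per-chunk shifts for audit.
    """
    params = params or ChunkDejitterParams()
    if not stream.nominal_rate > 0:
        raise ValueError("invalid rate")
    cm = detect_chunks(stream, params)
    dt = 1.0 / stream.nominal_rate

    corrected = np.empty_like(stream.raw_timestamps)
    # Exact ties (a chunk starting precisely at the previous corrected end)
    # must count as overlapping; guard the comparison against rounding noise
    # far below any physical timing scale.
    tie_eps = 1e-9
    prev_last: float | None = None
    for c in cm:
        k = np.arange(c.n_samples, dtype=np.float64)
        ts = c.reception_timestamp + k * dt
        if prev_last is not None and ts[0] <= prev_last + params.overlap_tolerance + tie_eps:
            delta = (prev_last + dt) - ts[0]
            ts = ts + delta
            c.shifted = True
            c.shift_s = float(delta)
        corrected[c.start : c.end + 1] = ts
        prev_last = float(ts[-1])

    return stream.with_corrected(corrected), cm
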