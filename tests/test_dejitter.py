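import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from eegtiming import (
    ChunkDejitterParams,
    SampledStream,
    SimConfig,
    chunk_dejitter,
    detect_chunks,
    regular_dejitter,
    simulate_recording,
)


def stream_from(ts, rate):
    ts = np.asarray(ts, float)
    return SampledStream(raw_timestamps=ts, data=np.zeros_like(ts), nominal_rate=rate)


def closed_form_ols(y):
    """Independent OLS oracle: fitted values of y on 0..n-1 via the textbook
    covariance/variance formulas (no linear-algebra solver)."""
    x = np.arange(len(y), dtype=float)
    xbar, ybar = x.mean(), y.mean()
    slope = np.sum((x - xbar) * (y - ybar)) / np.sum((x - xbar) ** 2)
    return ybar + slope * (x - xbar)


class TestDetectChunks:
    def test_gap_splits_into_two_chunks(self):
        ts = [0.0000, 0.0002, 0.0004, 0.4800, 0.4802, 0.4804]
        cm = detect_chunks(stream_from(ts, 125.0), ChunkDejitterParams(2.0))
        assert [(c.start, c.end) for c in cm] == [(0, 2), (3, 5)]
        assert [c.reception_timestamp for c in cm] == [0.0, 0.48]

    def test_regular_grid_is_one_chunk(self):
        cm = detect_chunks(stream_from(np.arange(10) / 125.0, 125.0))
        assert cm.n_chunks == 1 and cm[0].n_samples == 10

    def test_too_short_stream(self):
        with pytest.raises(ValueError, match="too short"):
            detect_chunks(stream_from([0.0], 125.0))

    @pytest.mark.parametrize("rate", [125.0, 250.0])
    def test_recovers_simulator_emission_log(self, rate):
        stream, _, truth = simulate_recording(
            SimConfig(rate=rate, duration=20.0, seed=1)
        )
        cm = detect_chunks(stream)
        assert list(cm.sizes) == truth.emitted_chunk_sizes

    def test_clock_reset_opens_chunk(self):
        ts = np.concatenate((np.arange(5) / 125.0, np.arange(5) / 125.0))
        cm = detect_chunks(stream_from(ts, 125.0))
        assert cm.n_chunks == 2 and cm[1].start == 5


class TestRegularDejitter:
    def test_exact_line_reproduced(self):
        ts = np.arange(100) / 250.0
        out = regular_dejitter(stream_from(ts, 250.0))
        np.testing.assert_allclose(out.corrected_timestamps, ts, atol=1e-9)

    def test_matches_closed_form_ols(self):
        rng = np.random.default_rng(42)
        ts = np.arange(200) / 250.0 + rng.normal(0, 5e-4, 200)
        ts.sort()
        out = regular_dejitter(stream_from(ts, 250.0))
        np.testing.assert_allclose(out.corrected_timestamps, closed_form_ols(ts), atol=1e-9)

    def test_segments_fitted_independently(self):
        seg1 = np.arange(50) / 250.0
        seg2 = 10.0 + np.arange(50) / 250.0
        ts = np.concatenate((seg1, seg2))
        out = regular_dejitter(stream_from(ts, 250.0), gap_threshold=1.0)
        np.testing.assert_allclose(out.corrected_timestamps, ts, atol=1e-9)

    def test_single_sample_segment_passthrough(self):
        ts = np.array([0.0, 0.004, 0.008, 7.0])
        out = regular_dejitter(stream_from(ts, 250.0), gap_threshold=1.0)
        assert out.corrected_timestamps[-1] == 7.0

    def test_values_untouched(self):
        ts = np.arange(20) / 250.0
        s = SampledStream(ts, np.arange(20.0), 250.0)
        out = regular_dejitter(s)
        np.testing.assert_array_equal(out.data, s.data)


class TestChunkDejitter:
    def test_single_chunk_extrapolation(self):
        ts = np.array([10.0, 10.0002, 10.0004])
        out, cm = chunk_dejitter(stream_from(ts, 125.0))
        np.testing.assert_allclose(out.corrected_timestamps, [10.0, 10.008, 10.016])
        assert cm.n_chunks == 1 and not cm[0].shifted

    def test_short_chunk_shifted_right(self):
        # 60-sample chunk received at 0.0 extrapolates to last = 0.472; a
        # 10-sample chunk received at 0.300 overlaps it and must be moved to
        # start one interval later, at 0.480, ending at 0.552.
        raw = np.concatenate(
            (0.0 + np.arange(60) * 2e-4, 0.300 + np.arange(10) * 2e-4)
        )
        out, cm = chunk_dejitter(stream_from(raw, 125.0))
        ct = out.corrected_timestamps
        assert cm.n_chunks == 2
        assert cm[1].shifted and cm[1].shift_s == pytest.approx(0.180)
        assert ct[59] == pytest.approx(0.472)
        assert ct[60] == pytest.approx(0.480)
        assert ct[-1] == pytest.approx(0.552)

    def test_constant_transport_gives_constant_offset(self):
        cfg = SimConfig(
            rate=125.0,
            duration=20.0,
            chunk_size_choices=[60],
            short_chunk_prob=0.0,
            seed=5,
        )
        stream, _, truth = simulate_recording(cfg)
        out, _ = chunk_dejitter(stream)
        offsets = out.corrected_timestamps - truth.true_sample_times
        # delivery lag = transport delay + (chunk size - 1) sample intervals
        expected = cfg.transport_delay + 59 / 125.0
        np.testing.assert_allclose(offsets, expected, atol=1e-9)

    def test_invalid_rate(self):
        s = stream_from([0.0, 1.0], 125.0)
        s.nominal_rate = 0.0
        with pytest.raises(ValueError, match="rate"):
            chunk_dejitter(s)

    def test_exact_grid_identity_for_both_methods(self):
        ts = np.arange(50) / 125.0
        s = stream_from(ts, 125.0)
        np.testing.assert_allclose(
            regular_dejitter(s).corrected_timestamps, ts, atol=1e-9
        )
        # one 50-sample "chunk" extrapolated from ts[0] is the grid itself
        np.testing.assert_allclose(
            chunk_dejitter(s)[0].corrected_timestamps, ts, atol=1e-9
        )


@settings(max_examples=40, deadline=None, derandomize=True)
@given(seed=st.integers(0, 10_000), short_prob=st.floats(0.0, 0.4))
def test_chunk_dejitter_invariants(seed, short_prob):
    """Whatever the chunk realization, corrected time must be strictly
    increasing, exactly grid-spaced inside chunks, and count-preserving."""
    cfg = SimConfig(
        rate=125.0, duration=8.0, short_chunk_prob=short_prob, seed=seed
    )
    stream, _, _ = simulate_recording(cfg)
    out, cm = chunk_dejitter(stream)
    ct = out.corrected_timestamps
    assert ct.shape == stream.raw_timestamps.shape
    assert np.all(np.diff(ct) > 0)
    dt = 1.0 / cfg.rate
    for c in cm:
        inner = np.diff(ct[c.start : c.end + 1])
        if inner.size:
            # grid-exact up to double-precision ULPs
            assert np.max(np.abs(inner - dt)) <= 1e-12


@settings(max_examples=30, deadline=None, derandomize=True)
@given(seed=st.integers(0, 10_000), n=st.integers(10, 80))
def test_regular_dejitter_matches_oracle_on_random_instances(seed, n):
    rng = np.random.default_rng(seed)
    ts = np.sort(np.arange(n) / 250.0 + rng.normal(0, 3e-4, n))
    out = regular_dejitter(stream_from(ts, 250.0))
    np.testing.assert_allclose(out.corrected_timestamps, closed_form_ols(ts), atol=1e-9)
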