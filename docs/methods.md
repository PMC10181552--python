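# Methods

## The measurement model

The timing benchmark emulated and analyzed here treats an EEG acquisition
chain as three stages between the stimulus software and the stored file:

1. **Stimulus path.** The stimulus software emits a marker at each intended
   playback time and plays a 5 ms square pulse at 10 Hz into one recorded
   channel. Between marker and physical pulse sits a constant hardware/audio
   delay (`hardware_lag`, default 25 ms) plus optional per-trial Gaussian
   onset jitter (`onset_jitter_sd`, default 0; draws are clipped so a pulse
   never precedes its marker).
2. **Sampling.** The amplifier samples on an exact `k/f` grid. Each sample
   value is the mean of the continuous signal over the preceding sample
   period (a one-sample boxcar). This stands in for the amplifier's
   anti-alias front-end; without it a 5 ms pulse could fall entirely between
   8 ms samples at 125 Hz and vanish, which physical amplifiers do not show.
   White Gaussian noise of `noise_sd` (default 1 µV) is added. The default
   pulse amplitude is 1 mV: the benchmark channel records a cable-fed
   line-level signal, so its noise floor is the amplifier's input-referred
   noise, not scalp-EEG background.
3. **Transport.** Either per-sample delivery with zero-mean stamping noise
   (`simulate_clean_recording`, `stamp_noise_sd` default 0.5 ms), or chunked
   delivery (`simulate_recording`): chunk sizes are drawn uniformly from
   {59, 60, 61} at 125 Hz and {119, 120, 121} at 250 Hz (~0.48 s of
   buffering); with probability `short_chunk_prob` (default 0.02) a chunk is
   truncated to `short_chunk_fraction` (default 0.25) of its size. A chunk
   is delivered at the generation time of its **last** sample plus a
   constant `transport_delay` (default 20 ms), and the raw timestamps of its
   samples are the delivery time plus a 0.2 ms per-sample stamping spacing —
   reproducing the observed pattern of near-identical timestamps within a
   chunk and large gaps between chunks. Samples still sitting in the
   transport buffer when the recording stops never reach the file, so the
   unfilled final buffer is dropped; the recording carries a 1.5 s
   post-stimulus tail so the last trial's window stays covered regardless.

Two deliberate non-degeneracies: the stimulus clock carries a constant
0.3 ms offset from the sample grid (`marker_lead` = 15.0003 s), because
real stimulus and amplifier clocks are never commensurate and exact
coincidence of markers with sample instants creates knife-edge boundary
decisions no real recording exhibits; and the stimulus block starts 15 s
into the recording — an ordinary operator lead-in, sized so that the
chunked time base has reached its steady state before trials begin (the
corrected timeline settles once the first maximum-size chunk arrives; with
uniform size draws the chance of that not happening among ~30 lead-in
chunks is below 1e-5).

## Dejittering

**Regular (per-segment OLS).** The stream is split at raw inter-sample gaps
above `gap_threshold` (default 1 s) or at backwards clock jumps; within each
segment the corrected timestamps are the fitted values of an ordinary
least-squares line of raw timestamp on sample index. Single-sample segments
pass through unchanged. Plain OLS is used; no trimming or re-weighting
scheme is applied, since for per-sample links the stamping noise is
zero-mean and a robustified fit changes nothing material.

**Chunk dejitter.** A chunk boundary is declared wherever the raw
inter-sample gap exceeds `boundary_factor / f` (default factor 2): within
chunks the stamping spacing is orders of magnitude below one sample
interval while inter-chunk gaps are tens of intervals, so any factor in
roughly (1.5, 50) detects identically and 2 leaves the widest margin. Each
chunk is extrapolated from its reception timestamp at the nominal rate
(the rate is taken from stream metadata and never re-estimated). Then, in
temporal order, any chunk whose extrapolated start does not exceed the
previous chunk's corrected end by more than `overlap_tolerance` (default 0)
is shifted right so that it starts exactly one sample interval after the
previous chunk, and flagged. Shifting to abut the *previous* chunk (rather
than closing the gap to the *next*) trusts earlier reception timestamps
over later ones; the applied shift is recorded per chunk so the alternative
can be audited. Shifts are applied sequentially so consecutive short chunks
cascade.

A useful consequence of the shift rule: with a constant transport delay,
once the first maximum-size chunk has arrived, every subsequent sample's
corrected timestamp equals its true generation time plus the same constant
(delay + chunk duration). This is exactly why the chunk method eliminates
run-to-run lag variance, and why the residual early-recording transient
(before the first maximum-size chunk) is excluded from the trial window by
the 15 s stimulus lead-in in the simulator's default geometry.

**Numerical ties.** Three comparisons sit on exact boundaries when the
simulator's arithmetic is exact: a chunk one sample smaller than its
predecessor lands exactly on the previous corrected end; and a marker
commensurate with the sample grid lands exactly on the epoch window edge.
Both comparisons carry a 1 ns guard so the outcome does not depend on
floating-point summation order. 1 ns is ~5 orders of magnitude below any
physical timing scale involved.

## Timing metrics

Epochs are the `round(1.0 s × f)` consecutive samples starting at the first
sample at or after `t0 − 200 ms`, aligned on a shared relative-time grid
over the half-open window `[−200, +800) ms`; a trial is dropped (and
counted) if its first sample lies more than one interval after the window
start or the recording ends inside the window. Each trial is
baseline-corrected by its pre-stimulus mean (`[−200, 0) ms`). The detection
threshold is half the post-stimulus maximum of the trial-averaged waveform;
a trial's latency is the relative time of its first post-stimulus sample
exceeding the threshold — at sample resolution, with no sub-sample
interpolation, so the quantization floor of a single latency is one sample
interval (8 ms at 125 Hz, 4 ms at 250 Hz, 2 ms at 500 Hz) and its SD
contribution is `(1/f)/√12`. Trials that never cross are excluded from the
summaries and reported. Lag is the mean and jitter the sample SD (n−1) of
the non-missing latencies; across-run summaries are unweighted means and
SDs over runs (SD reported as 0 for a single run).

**Aliasing caveat.** With markers every 100 ms, any total lag above 100 ms
is measured modulo the stimulus period: the first post-marker crossing
belongs to an earlier trial's pulse. Under chunked transport
(~0.52 s total delay) the reported lag is therefore the true lag mod
100 ms, and the first ⌈lag/100 ms⌉ trials of a run — whose epochs contain
no earlier pulse — report the unaliased latency instead. Those few
structural outliers inflate the run's jitter figure (the median/IQR columns
of the report show the actual spread); they affect every run identically,
so lag-variance comparisons are untouched. De-aliasing would require
non-periodic stimuli, which the benchmark's fixed 10 Hz train does not
provide.

## What the simulator does and does not show

The generator reproduces the features the correction algorithms act on:
chunk-size variation, short-chunk truncation, timestamp clustering,
constant transport delay, constant hardware lag, Gaussian onset jitter and
sampling quantization. It does **not** model clock drift between amplifier
and stimulus PC, load-dependent (time-varying) transport delay, sample
loss, amplifier analog characteristics, or real EEG background activity.
Passing tests therefore demonstrate algorithmic correctness and the
variance structure of the metrics under these idealized conditions, not
performance bounds on any particular hardware. In particular, run-to-run
lag SD being *exactly* zero under chunk dejittering is a property of
strictly constant delays; real links show sub-millisecond residuals.

## Test and benchmark problem sizes

Simulated benchmark runs use the study geometry: 40 s stimulus blocks of
400 trials at 10 Hz, 8 runs per configuration for across-run statistics,
20 repetitions per condition for the jitter-recovery Monte Carlo (each
repetition drawing its own stimulus-clock phase, as repeated physical runs
do — sampling that nuisance is what makes `√(σ² + q²)` the exact
expectation for the measured jitter, with `q = (1/f)/√12`). The OLS
cross-check compares the segment fit against the closed-form
covariance/variance formulas on 100 random instances at 1 ns tolerance.

## Known limitations

* The epoch rows are fixed-length and anchored at the window start, so a
  recording gap inside an epoch shifts later samples of that trial rather
  than inserting missing values.
* Latencies are sample-resolution by design; sub-sample interpolation would
  lower the quantization floor but change the metric's meaning.
* The XDF layer implements the subset of the format this package writes
  (double64/float32/string channels, explicit per-sample timestamps,
  no clock-offset resynchronization); clock alignment across streams is
  assumed to be handled by the acquisition layer.
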