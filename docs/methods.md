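# Methods

## The scheduling model

pulsestream models a real-time analysis pipeline as an ordered list of
plug-ins connected by named frame streams. Its behavioural contract has
four clauses:

1. **Unconditional forwarding.** Every frame entering the pipeline is
   forwarded past every downstream plug-in exactly once, whether or not that
   plug-in accepts it. Acceptance (the frame's stream matches the plug-in's
   subscription) only decides whether the frame is also queued for the
   plug-in's own worker. Forwarding is never blocked by any worker.
2. **One worker per plug-in.** At most one task is in flight per plug-in; a
   failing task drops its frame, is logged, and never stalls siblings.
3. **Latest-frame ticks.** Each plug-in's timer fires at fixed multiples of
   its tick period p = 1/f, anchored at activation. Between ticks, a newly
   accepted frame *replaces* the pending one (counted as a drop), so a tick
   that finds the worker idle always dispatches the most recent frame. This
   bounds the age of any dispatched frame by T + p (no temporal drift) at
   the price of throughput.
4. **Optional process-all mode.** Per plug-in, dropping can be disabled; the
   pending slot becomes an unbounded FIFO (with a high-water warning at
   1000 queued frames) for consumers that need every frame, e.g. writers.

### The ceiling law

For a task of constant duration T the dispatch pattern is periodic: a frame
dispatched at a tick occupies the worker through the next ⌊T/p⌋ tick
events, and the first tick strictly after completion dispatches again.
Hence the steady-state effective rate is

    f_eff = f / (⌊T/p⌋ + 1),

equal to f/⌈T/p⌉ whenever T is not an exact multiple of p. The boundary
convention (a completion landing exactly on a tick does not re-dispatch at
that tick) is deliberate: it is the limit of a real worker with any nonzero
scheduling overhead, and it is what live measurements show — a 100 ms wait
ticked at 20 Hz yields 6.67 Hz, not 10. Two caps apply on top of the law:
no plug-in can process faster than frames arrive (the source rate, 30 Hz in
the canonical benchmark), and in sequential wiring a stage's rate equals
min(its own law, the upstream emission rate) — a chain converges to its
slowest stage.

`predicted_effective_rate` adds a relative guard of 1e-9 to T/p before
flooring, so floating-point noise in an exact multiple cannot flip the
period count.

## The two engines

**Simulated engine.** A single-threaded discrete-event scheduler over a
clock that advances only through events. Event times are quantized to a
1 µs grid so times composed differently (k·p versus dispatch + T) compare
equal when they should. At equal timestamps the order is: source emissions,
then ticks, then worker completions. Emissions before ticks means a frame
arriving on the tick instant is dispatchable at that tick; ticks before
completions realizes the boundary convention above. Under this engine
scheduling outcomes are bit-exact across runs and measured rates match the
ceiling law to < 1e-6 relative (the residual is the µs grid), while a
15-minute session runs in about a second.

**Wall engine.** One thread per plug-in (plus one per source) implementing
the same contract on the monotonic clock; the artificial wait occupies the
worker via a stop-aware sleep. Two timing details matter. A late tick
(timer oversleep) fires immediately rather than skipping to the next
period — only periods genuinely consumed by a running task are skipped —
otherwise millisecond oversleeps systematically lose ticks. And each
plug-in's tick anchor is staggered by a deterministic quarter-period
(index mod 4)·p/4, so upstream emissions land mid-interval downstream
instead of racing the tick boundary; with aligned anchors, millisecond
jitter flips the arrival/tick order back and forth and spuriously drops or
double-buckets frames. With both in place, 15–20 s wall runs agree with the
law within ~1 % on an otherwise idle machine; tests allow 10 %.

## Telemetry

One record per completed task: plug-in stream, source frame id, source
acquisition time, dispatch time, completion time. Derived measures:

- *Execution time*: completion − dispatch (mean ± sd; under the simulated
  clock this is exactly the artificial wait).
- *Effective rate*: computed over a steady-state window (first 2 s of
  warm-up excluded) as (n−1)/(last − first completion), the reciprocal mean
  inter-completion interval. For constant-duration tasks this equals the
  ceiling law exactly; a count-per-window estimator would carry O(1/window)
  edge quantization. When intervals are genuinely non-uniform (tick grid
  beating against the arrival grid, e.g. 40 Hz ticks on a 30 Hz stream) the
  estimator is exact only per beat cycle, and tests allow 1 %.
- *Delay to input*: completion − the source frame's acquisition timestamp,
  matched by frame id (frames keep their source id and timestamp through
  every stage, which the shared-layer design makes free). For a single
  stage with constant T the delay lies in [T, T + p]; in a chain each stage
  adds up to one tick period, so the median delay falls as the requested
  rate rises, up to the arrival-rate cap.

The benchmark harness (`pulsestream bench`, `telemetry.run_benchmark`)
sweeps waits {0, 50, 100, 150, 200} ms against requested rates
{10, 20, 30, 40} Hz in parallel wiring (all plug-ins on 'Input') and
sequential wiring (each on its predecessor's stream, last layer), and
tabulates the three measures.

## The synthetic source

The frame generator stands in for a hardware framegrabber: 8-bit grayscale
frames of a configurable size (default 128×128 px) at a configurable rate
(default 30 Hz), containing a few Gaussian blobs drifting on seeded
sinusoidal paths under multiplicative Rayleigh speckle — enough ultrasound-
like structure to exercise blur, threshold and the classifier's histogram
features. Frames are random-access deterministic: frame k is generated from
a generator keyed on (seed, k), so a sequence is bit-identical across runs
and independent of how it is consumed. It does **not** emulate real probe
physics (depth-dependent attenuation, scan-line geometry, motion of
anatomy), so passing tests say nothing about model accuracy on real
streams — only about scheduling, routing and data-flow correctness, which
are content-independent.

## The mock classifier

The plane classifier computes eight histogram-moment features (mean, sd,
skewness, normalized entropy, quartiles, bright fraction), maps them
through a fixed linear layer to softmax scores over 14 labels (Background
plus 13 fetal standard views), and averages the last `taverage` score
vectors (default 1; the window is resized live and resets on stream
change). The coefficients are constants derived from a fixed internal seed,
so outputs are deterministic; the label it assigns to a frame is arbitrary
but stable. It exists to exercise the interface — metadata-writing, score
averaging, overlay layers, real-time reconfiguration — and any object with
`labels` and `scores(layer) -> (K,)` can be dropped in its place.

## Numerical and design choices

- **Blur**: Gaussian, σ = 5 px default, half-sample-symmetric ('reflect')
  boundary — the symmetric kernel then preserves the image mean to machine
  precision. **Threshold**: strictly-greater comparison; default level is
  half the dtype range (127.5 for uint8, 0.5 for floats in [0,1]).
- **Frame emission re-tagging**: a plug-in's output frame is re-labelled
  onto its own stream via a shallow view — new layer *list*, same pixel
  buffers — so sibling streams never see each other's appended layers while
  pixel data is still never copied.
- **Metadata**: scalars and strings only (JSON-serializable); plug-in
  written keys are namespaced `<stream>:<key>`. Reserved keys: stream,
  frame_id, acq_time, fps, label.
- **Stream naming collisions** between two non-input plug-ins of the same
  type get deterministic `-2`, `-3`, ... suffixes; source streams use the
  'Input', 'Input1', ... ordinal rule.
- **Sessions**: activation configures downstream before any frame flows
  (processing threads start before source threads); shutdown drains workers
  within the longest task time plus one second; exit codes 0/2/3 for
  clean/CLI error/activation error.
- **Problem sizes.** Tests and the acceptance script run the simulated
  engine for 10–120 simulated seconds per configuration (the law is reached
  within one dispatch cycle, so longer runs only shrink the window term),
  and the wall engine for 8–20 s spot checks at three grid points with a
  10 % tolerance. Synthetic frames are 16–128 px across; scheduling
  outcomes are independent of frame content and size.

## Known limitations

- The wall engine is subject to the host's timer resolution and load;
  its guarantees are statistical, not hard real-time.
- Video-container input depends on the imageio backends available at run
  time; image folders and the synthetic source are the tested paths.
- One producer per stream name; no many-to-one merging.
- Frames are single-channel 2D (colour optionally as three layers); 3D/4D
  volumes are out of scope.
- A plug-in re-emitting a frame merges its namespaced metadata; it does not
  reprocess frames already in flight when re-subscribed at run time.
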