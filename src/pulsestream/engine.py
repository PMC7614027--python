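"""The pipeline engine: concurrent plug-in execution with latest-frame ticks.

Two interchangeable execution back-ends implement one contract:

* each plug-in owns one worker; at most one task is in flight per plug-in;
* frame forwarding down the pipeline is never blocked by any worker;
* a plug-in's timer fires at fixed multiples of its tick period, anchored at
  activation; a tick dispatches the latest accepted pending frame iff the
  worker is idle; stale frames are dropped on arrival (unless process-all
  mode queues them);
* a failing worker drops its frame and logs, never stalling siblings.

:class:`SimulatedEngine` is a single-threaded discrete-event simulator whose
clock advances only through events, making scheduling outcomes bit-exact and
letting a 15-minute session run in well under a second.  Event times live on
a 1 µs grid; at equal timestamps, source emissions are handled before ticks
and ticks before worker completions — so a task whose duration is an exact
multiple of the tick period occupies one further period, which is the
behaviour of a real worker with any nonzero overhead.

:class:`WallEngine` runs the same contract on threads and the wall clock for
live sessions.

Use :func:`build_pipeline` to wire plug-ins and pick a back-end.
"""

from __future__ import annotations

import heapq
import itertools
import logging
import math
import threading
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .frames import StreamFrame, make_frame
from .scheduling import Clock, ScheduleState, SimulatedClock, WallClock
from .streams import StreamRegistry, assign_stream_names
from .telemetry import TelemetryLog, TelemetryRecord
from .plugins.base import Plugin, SourcePlugin

log = logging.getLogger("pulsestream")

_PRIO_EMIT, _PRIO_TICK, _PRIO_COMPLETE = 0, 1, 2
_US = 1_000_000  # event-time grid, ticks per second


def _q(t: float) -> float:
    """Quantize a simulated event time to the 1 µs grid."""
    return round(t * _US) / _US


@dataclass
class _Runtime:
    """Engine-side state for one pipeline position."""
    plugin: Plugin
    index: int
    stream: str
    state: ScheduleState = field(default_factory=ScheduleState)
    lock: threading.Lock = field(default_factory=threading.Lock)
    # sources
    emit_index: int = 0
    finished: bool = False
    # in-flight task (simulated mode)
    inflight: Optional[StreamFrame] = None
    dispatch_time: float = 0.0

    @property
    def is_source(self) -> bool:
        return isinstance(self.plugin, SourcePlugin)


class _EngineBase:
    """Wiring, delivery and telemetry shared by both back-ends."""

    def __init__(self, plugins: Sequence[Plugin],
                 registry: Optional[StreamRegistry] = None,
                 telemetry: Optional[TelemetryLog] = None):
        if not plugins:
            raise ValueError("a pipeline needs at least one plug-in")
        self.registry = registry if registry is not None else assign_stream_names(plugins)
        self.telemetry = telemetry if telemetry is not None else TelemetryLog()
        self.runtimes: list[_Runtime] = []
        for i, plugin in enumerate(plugins):
            stream = self.registry.stream_of(plugin)
            plugin.stream_name = stream
            rt = _Runtime(plugin=plugin, index=i, stream=stream)
            rt.state.tick_period = 1.0 / plugin.framerate
            rt.state.drop_disabled = bool(plugin.params.get("processall"))
            self.runtimes.append(rt)
        if not any(rt.is_source for rt in self.runtimes):
            raise ValueError("pipeline has no source of frames")
        # apply CLI-style stream/layer params as initial subscriptions
        for rt in self.runtimes:
            if rt.is_source:
                continue
            p = rt.plugin.params
            self.registry.resubscribe(rt.plugin, stream=p.get("stream") or None,
                                      layer=p.get("layer"))

    # -- wiring introspection --------------------------------------------

    def runtime_for(self, plugin: Plugin) -> _Runtime:
        for rt in self.runtimes:
            if rt.plugin is plugin:
                return rt
        raise KeyError("plugin not in this pipeline")

    def connection_lines(self) -> list[str]:
        names = [rt.plugin.display_name for rt in self.runtimes]
        return [f"{a} -> {b}" for a, b in zip(names, names[1:])]

    # -- delivery ---------------------------------------------------------

    def _deliver(self, frame: StreamFrame, from_index: int) -> None:
        """Forward ``frame`` to every plug-in downstream of ``from_index``.

        Forwarding is unconditional; acceptance only queues the frame for the
        receiving plug-in's own worker.
        """
        for rt in self.runtimes[from_index + 1:]:
            try:
                rt.plugin.on_forward(frame)
            except Exception:  # pragma: no cover - observer must not stall flow
                log.exception("on_forward failed in %s", rt.plugin.display_name)
            if rt.is_source:
                continue
            with rt.lock:
                sub = self.registry.subscription_of(rt.plugin)
                accepted = frame.stream_name == sub.stream
                rt.state.on_frame_received(frame, accepted)

    def _end_of_stream(self, rt: _Runtime) -> None:
        rt.finished = True
        for downstream in self.runtimes[rt.index + 1:]:
            try:
                downstream.plugin.on_end_of_stream(rt.stream)
            except Exception:  # pragma: no cover
                log.exception("on_end_of_stream failed in %s",
                              downstream.plugin.display_name)

    def _read_source_frame(self, rt: _Runtime, t: float) -> Optional[StreamFrame]:
        """Pull the next frame of a source, honouring loop mode; None at the end."""
        src: SourcePlugin = rt.plugin  # type: ignore[assignment]
        n = src.frame_count()
        idx = rt.emit_index
        wrap = 0
        if n is not None and idx >= n:
            if not src.params.get("loop"):
                return None
            wrap, idx = divmod(rt.emit_index, n)
        pixels = src.read_pixels(idx)
        if pixels is None:
            return None
        rt.emit_index += 1
        pixels = np.asarray(pixels)
        if pixels.ndim == 3:  # rgb-preserving source: one layer per channel
            frame = make_frame(pixels[..., 0], rt.stream, idx, t, src.emission_fps)
            for ch in range(1, pixels.shape[-1]):
                frame.add_layer(pixels[..., ch])
        else:
            frame = make_frame(pixels, rt.stream, idx, t, src.emission_fps)
        if wrap:
            frame.set_meta("wrap", wrap)
        self.telemetry.add_emission(rt.stream, idx, t)
        return frame

    def _execute(self, rt: _Runtime, frame: StreamFrame,
                 dispatch_time: float, completion_time_hint: Optional[float],
                 clock: Clock) -> None:
        """Run one worker task to completion and emit the result.

        ``completion_time_hint`` is the simulated completion instant (None
        under the wall clock, where time is measured).
        """
        sub = self.registry.subscription_of(rt.plugin)
        out: Optional[StreamFrame] = None
        ok = True
        try:
            out = rt.plugin.process(frame, sub.layer)
        except Exception:
            ok = False
            log.exception("worker of %s failed; frame %d dropped",
                          rt.plugin.display_name, frame.frame_id)
        completion = completion_time_hint if completion_time_hint is not None \
            else clock.now()
        with rt.lock:
            rt.state.on_complete(ok)
        if ok:
            self.telemetry.add(TelemetryRecord(
                plugin=rt.stream, frame_id=frame.frame_id,
                input_time=frame.acq_time, dispatch_time=dispatch_time,
                completion_time=completion))
            if rt.plugin.params.get("verbose"):
                log.info("%s processed frame %d at t=%.3f",
                         rt.plugin.display_name, frame.frame_id, completion)
            if out is not None:
                emitted = out.retag(rt.stream)
                self._deliver(emitted, rt.index)

    # -- run-time control -------------------------------------------------

    def set_param(self, plugin: Plugin, name: str, value) -> None:
        """Run-time reconfiguration; stream/layer changes re-subscribe atomically."""
        rt = self.runtime_for(plugin)
        if name == "stream":
            self.registry.resubscribe(plugin, stream=str(value))
        elif name == "layer":
            self.registry.resubscribe(plugin, layer=int(value))
        else:
            plugin.set_param(name, value)
            if name == "framerate":
                with rt.lock:
                    rt.state.tick_period = 1.0 / plugin.framerate

    def stats(self) -> dict[str, dict]:
        out = {}
        for rt in self.runtimes:
            s = rt.state
            out[rt.plugin.display_name] = {
                "stream": rt.stream,
                "received": s.frames_received if not rt.is_source else rt.emit_index,
                "processed": s.frames_processed,
                "dropped": s.frames_dropped,
                "pending": s.n_pending,
            }
        return out


# ---------------------------------------------------------------------------
# simulated (discrete-event) back-end
# ---------------------------------------------------------------------------

class SimulatedEngine(_EngineBase):
    """Deterministic single-threaded scheduler over a simulated clock."""

    def __init__(self, plugins: Sequence[Plugin], registry=None, telemetry=None):
        super().__init__(plugins, registry, telemetry)
        self.clock = SimulatedClock()
        self._heap: list = []
        self._seq = itertools.count()

    def _push(self, t: float, prio: int, fn, *args) -> None:
        heapq.heappush(self._heap, (round(t * _US), prio, next(self._seq), fn, args))

    def run(self, duration: float) -> TelemetryLog:
        """Activate everything and run ``duration`` simulated seconds."""
        t0 = self.clock.now()
        self.telemetry.t_start = t0
        for rt in self.runtimes:
            rt.plugin.activate()
            rt.state.activated = True
        # ticks first tick one period after activation; sources emit from t0
        for rt in self.runtimes:
            if rt.is_source:
                self._push(t0, _PRIO_EMIT, self._emit_event, rt, 0)
            else:
                self._push(_q(t0 + rt.state.tick_period), _PRIO_TICK,
                           self._tick_event, rt, 1)
        horizon = round((t0 + duration) * _US)
        while self._heap and self._heap[0][0] <= horizon:
            t_us, _prio, _seq, fn, args = heapq.heappop(self._heap)
            self.clock.advance_to(t_us / _US)
            fn(*args)
        self.clock.advance_to(t0 + duration)
        self.telemetry.t_end = self.clock.now()
        for rt in self.runtimes:
            rt.plugin.deactivate()
        return self.telemetry

    # -- event handlers ---------------------------------------------------

    def _emit_event(self, rt: _Runtime, k: int) -> None:
        t = self.clock.now()
        frame = self._read_source_frame(rt, t)
        if frame is None:
            self._end_of_stream(rt)
            return
        self._deliver(frame, rt.index)
        src: SourcePlugin = rt.plugin  # type: ignore[assignment]
        self._push(_q(self.telemetry.t_start + (k + 1) / src.emission_fps),
                   _PRIO_EMIT, self._emit_event, rt, k + 1)

    def _tick_event(self, rt: _Runtime, k: int) -> None:
        t = self.clock.now()
        with rt.lock:
            frame = rt.state.take_for_dispatch()
            period = rt.state.tick_period
        if frame is not None:
            rt.inflight = frame
            rt.dispatch_time = t
            self._push(_q(t + rt.plugin.task_duration()), _PRIO_COMPLETE,
                       self._complete_event, rt)
        self._push(_q(self.telemetry.t_start + (k + 1) * period), _PRIO_TICK,
                   self._tick_event, rt, k + 1)

    def _complete_event(self, rt: _Runtime) -> None:
        frame, rt.inflight = rt.inflight, None
        self._execute(rt, frame, rt.dispatch_time, self.clock.now(), self.clock)


# ---------------------------------------------------------------------------
# wall-clock (threaded) back-end
# ---------------------------------------------------------------------------

class WallEngine(_EngineBase):
    """One thread per plug-in; the same tick/drop contract on real time."""

    def __init__(self, plugins: Sequence[Plugin], registry=None, telemetry=None):
        super().__init__(plugins, registry, telemetry)
        self.clock = WallClock()
        self._stop = threading.Event()
        self._threads: list[threading.Thread] = []

    def start(self) -> None:
        self.telemetry.t_start = self.clock.now()
        for rt in self.runtimes:
            rt.plugin.activate()
            rt.state.activated = True
        # processing threads first so configuration precedes any frame flow
        for rt in self.runtimes:
            if not rt.is_source:
                th = threading.Thread(target=self._tick_loop, args=(rt,),
                                      name=f"tick-{rt.stream}", daemon=True)
                self._threads.append(th)
                th.start()
        for rt in self.runtimes:
            if rt.is_source:
                th = threading.Thread(target=self._source_loop, args=(rt,),
                                      name=f"source-{rt.stream}", daemon=True)
                self._threads.append(th)
                th.start()

    def stop(self, timeout: Optional[float] = None) -> TelemetryLog:
        """Signal shutdown and drain workers; completes within roughly the
        longest task time plus one second."""
        if timeout is None:
            timeout = 1.0 + max((rt.plugin.task_duration()
                                 for rt in self.runtimes if not rt.is_source),
                                default=0.0)
        self._stop.set()
        for th in self._threads:
            th.join(timeout)
        self.telemetry.t_end = self.clock.now()
        for rt in self.runtimes:
            rt.plugin.deactivate()
        return self.telemetry

    def run(self, duration: float) -> TelemetryLog:
        """Convenience: start, run for ``duration`` wall seconds, stop."""
        self.start()
        self._stop.wait(duration)
        return self.stop()

    def sources_finished(self) -> bool:
        return all(rt.finished for rt in self.runtimes if rt.is_source)

    # -- loops ------------------------------------------------------------

    def _source_loop(self, rt: _Runtime) -> None:
        src: SourcePlugin = rt.plugin  # type: ignore[assignment]
        t0 = self.clock.now()
        k = 0
        while not self._stop.is_set():
            target = t0 + k / src.emission_fps
            delta = target - self.clock.now()
            if delta > 0 and self._stop.wait(delta):
                break
            frame = self._read_source_frame(rt, self.clock.now())
            if frame is None:
                self._end_of_stream(rt)
                return
            self._deliver(frame, rt.index)
            k += 1  # a late emission still plays every frame, in order

    def _tick_loop(self, rt: _Runtime) -> None:
        # stagger each plug-in's tick anchor by a quarter-period so upstream
        # emissions land mid-interval downstream instead of racing the tick
        # boundary (timer jitter would otherwise drop or double-count frames)
        with rt.lock:
            period = rt.state.tick_period
        t0 = self.clock.now() + (rt.index % 4) * period / 4.0
        k = 1
        while not self._stop.is_set():
            with rt.lock:
                period = rt.state.tick_period
            target = t0 + k * period
            delta = target - self.clock.now()
            if delta > 0 and self._stop.wait(delta):
                break
            # the tick fires now, late or on time
            with rt.lock:
                frame = rt.state.take_for_dispatch()
            if frame is not None:
                dispatch = self.clock.now()
                wait = rt.plugin.task_duration()
                if wait > 0:
                    self._stop.wait(wait)  # artificial occupation of the worker
                self._execute(rt, frame, dispatch, None, self.clock)
            # next anchored tick strictly after now: periods consumed by the
            # task are skipped (they were busy no-ops), but mere oversleep of
            # an idle tick never loses a period
            k = max(k + 1,
                    math.floor((self.clock.now() - t0) / period) + 1)


def build_pipeline(plugins: Sequence[Plugin], clock: str = "simulated",
                   registry: Optional[StreamRegistry] = None,
                   telemetry: Optional[TelemetryLog] = None) -> _EngineBase:
    """Wire ``plugins`` (in pipeline order) into an engine.

    ``clock`` selects the back-end: ``"simulated"`` for exactly reproducible
    discrete-event runs, ``"wall"`` for live threaded execution.
    """
    if clock == "simulated":
        return SimulatedEngine(plugins, registry, telemetry)
    if clock == "wall":
        return WallEngine(plugins, registry, telemetry)
    raise ValueError(f"unknown clock mode {clock!r} (simulated|wall)")
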