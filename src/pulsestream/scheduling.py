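"""The real-time scheduling contract: ticks, latest-frame semantics, dropping.

Each processing plug-in owns one worker and a periodic *tick* at a
user-requested frame rate f (tick period p = 1/f, 20 Hz by default).  Frames
accepted between ticks land in a one-slot pending buffer: a newer frame
replaces — *drops* — the older one, so the worker, when a tick finds it idle,
always starts on the most recent frame and the pipeline never accumulates
temporal drift.  Dropping can be disabled per plug-in, in which case frames
queue in an unbounded FIFO and all of them are processed.

For a task of constant duration T, the steady-state processed rate follows a
ceiling law: the worker occupies ``floor(T/p) + 1`` tick periods per frame
(the tick coinciding exactly with a completion does not re-dispatch), hence

    effective rate = f / (floor(T/p) + 1)

which equals ``f / ceil(T/p)`` whenever T is not an exact multiple of p.
:func:`predicted_effective_rate` is the analytic oracle used by the telemetry
tests; the discrete-event engine reproduces it exactly under the simulated
clock.
"""

from __future__ import annotations

import math
import time
import warnings
from collections import deque
from dataclasses import dataclass, field
from typing import Optional

from .frames import StreamFrame

DEFAULT_FRAMERATE_HZ = 20.0

#: queued-frame count at which process-all mode emits a high-water warning
QUEUE_HIGH_WATER = 1000


# ---------------------------------------------------------------------------
# clocks
# ---------------------------------------------------------------------------

class Clock:
    """Monotone time source; wall for live use, simulated for reproducibility."""

    mode = "abstract"

    def now(self) -> float:
        raise NotImplementedError


class WallClock(Clock):
    mode = "wall"

    def __init__(self):
        self._t0 = time.monotonic()

    def now(self) -> float:
        return time.monotonic() - self._t0

    def sleep(self, seconds: float) -> None:
        if seconds > 0:
            time.sleep(seconds)


class SimulatedClock(Clock):
    """Time advances only via discrete events; scheduling is exactly repeatable."""

    mode = "simulated"

    def __init__(self):
        self._now = 0.0

    def now(self) -> float:
        return self._now

    def advance_to(self, t: float) -> None:
        if t < self._now:
            raise ValueError(f"simulated time cannot go backwards ({t} < {self._now})")
        self._now = t


# ---------------------------------------------------------------------------
# per-plugin runtime state
# ---------------------------------------------------------------------------

@dataclass
class ScheduleState:
    """Runtime state of one plug-in's timer/worker pair.

    Invariants: at most one pending frame when dropping is enabled; ``busy``
    is true exactly while a task is in flight; at quiescent points (no task in
    flight) ``frames_received == frames_processed + frames_dropped + pending``.
    """

    tick_period: float = 1.0 / DEFAULT_FRAMERATE_HZ
    pending: Optional[StreamFrame] = None
    queue: deque = field(default_factory=deque)
    busy: bool = False
    drop_disabled: bool = False
    frames_received: int = 0
    frames_processed: int = 0
    frames_dropped: int = 0
    activated: bool = False
    _warned_high_water: bool = field(default=False, repr=False)

    def on_frame_received(self, frame: StreamFrame, accepted: bool) -> None:
        """Register an arriving frame.  Forwarding happens in the engine,
        unconditionally; here only accepted frames enter the pending slot."""
        if not self.activated:
            warnings.warn("frame received before activation; discarded",
                          RuntimeWarning, stacklevel=2)
            return
        if not accepted:
            return
        self.frames_received += 1
        if self.drop_disabled:
            self.queue.append(frame)
            if len(self.queue) >= QUEUE_HIGH_WATER and not self._warned_high_water:
                self._warned_high_water = True
                warnings.warn(
                    f"process-all queue reached {len(self.queue)} frames",
                    RuntimeWarning, stacklevel=2)
        else:
            if self.pending is not None:
                self.frames_dropped += 1
            self.pending = frame

    def take_for_dispatch(self) -> Optional[StreamFrame]:
        """Called at a tick: if the worker is idle and a frame waits, claim it.

        Returns the frame to dispatch (marking the worker busy) or None.
        """
        if self.busy:
            return None
        frame: Optional[StreamFrame] = None
        if self.drop_disabled:
            if self.queue:
                frame = self.queue.popleft()
        else:
            frame, self.pending = self.pending, None
        if frame is not None:
            self.busy = True
        return frame

    def on_complete(self, ok: bool) -> None:
        """Worker finished (or raised): clear busy, count the outcome."""
        if not self.busy:
            raise RuntimeError("worker completion without a task in flight")
        self.busy = False
        if ok:
            self.frames_processed += 1
        else:
            self.frames_dropped += 1

    @property
    def n_pending(self) -> int:
        if self.drop_disabled:
            return len(self.queue)
        return 0 if self.pending is None else 1

    def conservation_holds(self) -> bool:
        return (self.frames_received
                == self.frames_processed + self.frames_dropped + self.n_pending
                + (1 if self.busy else 0))


# ---------------------------------------------------------------------------
# the analytic rate law
# ---------------------------------------------------------------------------

def predicted_effective_rate(f: float, T: float) -> float:
    """Steady-state processed-frames-per-second for constant task time ``T``.

    ``f`` is the requested tick rate in Hz (p = 1/f); ticks are anchored at
    activation and a completion landing exactly on a tick does not re-dispatch
    at that tick, so each frame occupies ``floor(T/p) + 1`` periods:

    >>> predicted_effective_rate(20.0, 0.1)   # 100 ms task at 20 Hz
    6.666666666666667
    >>> predicted_effective_rate(20.0, 0.01)  # sub-period task: full rate
    20.0

    A relative guard of 1e-9 absorbs floating-point noise in T/p when T is an
    exact multiple of p.
    """
    if f <= 0:
        raise ValueError("requested rate must be positive")
    if T < 0:
        raise ValueError("task time cannot be negative")
    periods = math.floor(T * f + 1e-9) + 1
    return f / periods
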