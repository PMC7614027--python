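"""Telemetry: per-task timing records and the derived performance measures.

The engine appends one :class:`TelemetryRecord` per completed worker task.
From these the harness computes the three quantities of interest for a
real-time pipeline:

* **execution time** — completion minus dispatch, per task;
* **effective frame rate** — frames a plug-in actually processes per second,
  bounded above by its requested tick rate and reduced by frame dropping;
* **delay to input** — completion timestamp minus the acquisition timestamp
  of the *source* frame the result derives from, tracked by frame id.

Rates and delays are reported over a steady-state window: the first
``warmup`` seconds (2 s by default) are excluded.  The effective rate is the
reciprocal mean inter-completion interval over the window — for a
constant-duration task under the simulated clock this equals the analytic
ceiling law exactly, with no edge quantization from counting in a window.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

DEFAULT_WARMUP_S = 2.0


@dataclass(frozen=True)
class TelemetryRecord:
    """One completed worker task."""
    plugin: str            # the plug-in's output stream name
    frame_id: int          # source frame the processed frame derives from
    input_time: float      # acquisition timestamp of that source frame (s)
    dispatch_time: float   # when the tick handed the frame to the worker (s)
    completion_time: float # when the worker finished (s)

    @property
    def execution_time(self) -> float:
        return self.completion_time - self.dispatch_time

    @property
    def delay(self) -> float:
        return self.completion_time - self.input_time


@dataclass
class TelemetryLog:
    """Append-only run log: task records plus source-emission bookkeeping."""
    records: list[TelemetryRecord] = field(default_factory=list)
    emissions: list[tuple[str, int, float]] = field(default_factory=list)
    t_start: float = 0.0
    t_end: float = 0.0

    def add(self, record: TelemetryRecord) -> None:
        self.records.append(record)

    def add_emission(self, stream: str, frame_id: int, t: float) -> None:
        self.emissions.append((stream, frame_id, t))

    def for_plugin(self, plugin: str) -> list[TelemetryRecord]:
        return [r for r in self.records if r.plugin == plugin]

    def plugins(self) -> list[str]:
        seen: dict[str, None] = {}
        for r in self.records:
            seen.setdefault(r.plugin, None)
        return list(seen)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [(r.plugin, r.frame_id, r.input_time, r.dispatch_time,
              r.completion_time, r.execution_time, r.delay) for r in self.records],
            columns=["plugin", "frame_id", "input_time", "dispatch_time",
                     "completion_time", "execution_time", "delay"])


class EmptyTelemetryError(ValueError):
    """Raised when a summary is requested for a plug-in with no records."""


def _steady_records(log: TelemetryLog, plugin: str, warmup: float,
                    window: Optional[float]) -> list[TelemetryRecord]:
    start = log.t_start + warmup
    end = log.t_end if window is None else start + window
    if window is not None and end > log.t_end + 1e-9:
        raise ValueError(
            f"window of {window} s exceeds the run "
            f"({log.t_end - start:.3f} s available after warm-up)")
    return [r for r in log.for_plugin(plugin)
            if start <= r.completion_time <= end]


def execution_time_summary(log: TelemetryLog, plugin: str) -> tuple[float, float]:
    """Sample mean and standard deviation (ddof=1) of execution times, seconds."""
    times = [r.execution_time for r in log.for_plugin(plugin)]
    if len(times) < 2:
        raise EmptyTelemetryError(
            f"need at least 2 records for {plugin!r}, have {len(times)}")
    arr = np.asarray(times)
    return float(arr.mean()), float(arr.std(ddof=1))


def effective_rate(log: TelemetryLog, plugin: str,
                   window: Optional[float] = None,
                   warmup: float = DEFAULT_WARMUP_S) -> float:
    """Steady-state processed frames per second for one plug-in.

    Computed as (n-1) / (last - first completion) over the window, i.e. the
    reciprocal mean inter-completion interval.
    """
    recs = _steady_records(log, plugin, warmup, window)
    if len(recs) < 2:
        raise EmptyTelemetryError(
            f"need at least 2 steady-state completions for {plugin!r}, "
            f"have {len(recs)}")
    span = recs[-1].completion_time - recs[0].completion_time
    if span <= 0:
        raise EmptyTelemetryError(f"degenerate completion span for {plugin!r}")
    return (len(recs) - 1) / span


def delay_to_input(log: TelemetryLog, plugin: str,
                   warmup: float = DEFAULT_WARMUP_S) -> np.ndarray:
    """Per-frame delays (seconds) between a plug-in's output and the source.

    Each completed task carries the source frame's acquisition timestamp, so
    the delay is ``completion - input_time``.  Records whose frame id never
    appeared in the source emission log are skipped (counted, not raised).
    """
    recs = _steady_records(log, plugin, warmup, None)
    known_ids = {fid for _, fid, _ in log.emissions} if log.emissions else None
    delays = []
    skipped = 0
    for r in recs:
        if known_ids is not None and r.frame_id not in known_ids:
            skipped += 1
            continue
        delays.append(r.delay)
    arr = np.asarray(delays, dtype=float)
    if skipped:
        import warnings
        warnings.warn(f"{skipped} record(s) with unmatched frame id skipped",
                      RuntimeWarning, stacklevel=2)
    return arr


# ---------------------------------------------------------------------------
# report tables
# ---------------------------------------------------------------------------

def report(log: TelemetryLog, layout: str, *,
           warmup: float = DEFAULT_WARMUP_S) -> pd.DataFrame:
    """One tidy table per layout.

    ``"table2"``  plugin x (mean, sd) execution time in ms.
    ``"table3"``  plugin x (mean rate Hz) with inter-completion sd.
    ``"fig3"``    plugin x delay distribution summary (median/p10/p90, ms).
    """
    rows = []
    if layout == "table2":
        for plugin in log.plugins():
            mean, sd = execution_time_summary(log, plugin)
            rows.append((plugin, mean * 1e3, sd * 1e3))
        return pd.DataFrame(rows, columns=["plugin", "exec_mean_ms", "exec_sd_ms"])
    if layout == "table3":
        for plugin in log.plugins():
            recs = _steady_records(log, plugin, warmup, None)
            if len(recs) < 2:
                continue
            times = np.asarray([r.completion_time for r in recs])
            ivals = np.diff(times)
            rate = (len(recs) - 1) / (times[-1] - times[0])
            sd = float(np.std(1.0 / ivals[ivals > 0], ddof=1)) if len(ivals) > 1 else 0.0
            rows.append((plugin, rate, sd))
        return pd.DataFrame(rows, columns=["plugin", "rate_hz", "rate_sd_hz"])
    if layout == "fig3":
        for plugin in log.plugins():
            d = delay_to_input(log, plugin, warmup=warmup)
            if d.size == 0:
                continue
            rows.append((plugin, float(np.median(d)) * 1e3,
                         float(np.percentile(d, 10)) * 1e3,
                         float(np.percentile(d, 90)) * 1e3))
        return pd.DataFrame(rows, columns=["plugin", "delay_median_ms",
                                           "delay_p10_ms", "delay_p90_ms"])
    raise ValueError(f"unknown layout {layout!r} (table2|table3|fig3)")


# ---------------------------------------------------------------------------
# the benchmark harness (wait x rate grid, parallel and sequential wiring)
# ---------------------------------------------------------------------------

def run_benchmark(waits_ms: Sequence[float] = (0, 50, 100, 150, 200),
                  rates_hz: Sequence[float] = (10, 20, 30, 40),
                  duration: float = 60.0,
                  clock: str = "simulated",
                  source_fps: float = 30.0,
                  parallel_rate_hz: float = 20.0,
                  seed: int = 0,
                  warmup: float = DEFAULT_WARMUP_S) -> dict[str, pd.DataFrame]:
    """Run the wait x rate experiment grid and tabulate the results.

    Configuration 1 wires the three processing plug-ins in parallel (all on
    'Input' at ``parallel_rate_hz``); the remaining configurations wire them in
    sequence at each rate in ``rates_hz``.  The artificial wait is applied to
    the first processing plug-in (the blur stage).  Returns tables shaped like
    the execution-time table ("table2"), the effective-rate table ("table3")
    and the delay curves ("fig3").
    """
    from .experiments import run_pipeline_experiment  # local import: cycle

    exec_rows, rate_rows, delay_rows = [], [], []
    configs: list[tuple[str, float]] = [("parallel", parallel_rate_hz)]
    configs += [("sequential", r) for r in rates_hz]
    for wiring, rate in configs:
        for wait_ms in waits_ms:
            log, names = run_pipeline_experiment(
                wiring=wiring, rate_hz=rate, wait_s=wait_ms / 1e3,
                duration=duration, clock=clock, source_fps=source_fps,
                seed=seed)
            for plugin in names:
                try:
                    mean, sd = execution_time_summary(log, plugin)
                    exec_rows.append((wiring, rate, wait_ms, plugin,
                                      mean * 1e3, sd * 1e3))
                except EmptyTelemetryError:
                    pass
                try:
                    r_eff = effective_rate(log, plugin, warmup=warmup)
                    rate_rows.append((wiring, rate, wait_ms, plugin, r_eff))
                except EmptyTelemetryError:
                    pass
                d = delay_to_input(log, plugin, warmup=warmup)
                if d.size:
                    delay_rows.append((wiring, rate, wait_ms, plugin,
                                       float(np.median(d)) * 1e3))
    return {
        "table2": pd.DataFrame(exec_rows, columns=[
            "wiring", "rate_hz", "wait_ms", "plugin", "exec_mean_ms", "exec_sd_ms"]),
        "table3": pd.DataFrame(rate_rows, columns=[
            "wiring", "rate_hz", "wait_ms", "plugin", "rate_hz_measured"]),
        "fig3": pd.DataFrame(delay_rows, columns=[
            "wiring", "rate_hz", "wait_ms", "plugin", "delay_median_ms"]),
    }
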