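"""Canonical pipeline experiments for the telemetry harness.

One pipeline, two wirings.  The pipeline is synthetic source -> blur (with an
artificial worker wait) -> threshold -> plane classifier.  In *parallel*
wiring all three processing plug-ins subscribe to the 'Input' stream, so each
runs independently at its own tick rate.  In *sequential* wiring each
subscribes to the previous plug-in's stream (last layer), so throughput is
limited by the slowest upstream stage.  These two wirings, swept over waits
and requested rates, produce the effective-frame-rate and delay behaviour
the engine is designed around.
"""

from __future__ import annotations

from typing import Sequence

from .engine import build_pipeline
from .plugins import (CppAlgorithm, FrameSource, Gui, PythonAlgorithm,
                      StandardPlaneDetection)
from .telemetry import TelemetryLog

PROCESSING_STREAMS = ("pythonalgorithm", "cppalgorithm", "standardplanedetection")


def make_experiment_plugins(wiring: str, rate_hz: float, wait_s: float,
                            source_fps: float = 30.0, seed: int = 0,
                            frame_size: int = 128,
                            with_sink: bool = True) -> list:
    """The source>blur>threshold>classifier pipeline, wired as requested.

    ``wait_s`` is the artificial wait applied to the blur plug-in's worker.
    All three processing plug-ins tick at ``rate_hz``.  The source is
    unbounded so any duration can be run against it.
    """
    if wiring not in ("parallel", "sequential"):
        raise ValueError(f"wiring must be 'parallel' or 'sequential', got {wiring!r}")
    source = FrameSource(fps=source_fps, duration=0, seed=seed,
                         width=frame_size, height=frame_size)
    blur = PythonAlgorithm(framerate=rate_hz, delay=wait_s)
    threshold = CppAlgorithm(framerate=rate_hz)
    classifier = StandardPlaneDetection(framerate=rate_hz)
    if wiring == "sequential":
        threshold.set_param("stream", "pythonalgorithm")
        threshold.set_param("layer", -1)
        classifier.set_param("stream", "cppalgorithm")
        classifier.set_param("layer", -1)
    plugins = [source, blur, threshold, classifier]
    if with_sink:
        plugins.append(Gui(framerate=rate_hz))
    return plugins


def run_pipeline_experiment(wiring: str, rate_hz: float, wait_s: float,
                            duration: float, clock: str = "simulated",
                            source_fps: float = 30.0, seed: int = 0,
                            frame_size: int = 128,
                            ) -> tuple[TelemetryLog, Sequence[str]]:
    """Run one grid point and return its telemetry log plus the three
    processing stream names (blur, threshold, classifier, in pipeline order)."""
    plugins = make_experiment_plugins(wiring, rate_hz, wait_s,
                                      source_fps=source_fps, seed=seed,
                                      frame_size=frame_size)
    engine = build_pipeline(plugins, clock=clock)
    log = engine.run(duration)
    return log, PROCESSING_STREAMS
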