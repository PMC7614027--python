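"""Plug-in author API.

A plug-in is a unit of work with a display name, a parameter table, and a
``process`` method that takes a frame and returns a frame (usually the same
frame with a result layer appended) or ``None`` (sinks).  Source plug-ins
(``is_input = True``) instead implement ``read_pixels``/``frame_count`` and
are driven by the engine at their emission rate.

Every plug-in automatically carries the universal parameters ``stream``,
``layer``, ``framerate``, ``time`` and ``verbose``, settable from the command
line as ``--<pluginname>_<param> <value>`` and re-settable at run time.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any, ClassVar, Optional

import numpy as np

from ..frames import StreamFrame
from ..scheduling import DEFAULT_FRAMERATE_HZ
from ..streams import normalize_plugin_name


@dataclass(frozen=True)
class ParamSpec:
    """One configurable parameter: python type, default, one-line help."""
    type: type
    default: Any
    help: str = ""


UNIVERSAL_PARAMS: dict[str, ParamSpec] = {
    "stream": ParamSpec(str, None, "input stream to accept (default 'Input')"),
    "layer": ParamSpec(int, -1, "layer of the accepted stream to process (-1 = last)"),
    "framerate": ParamSpec(float, DEFAULT_FRAMERATE_HZ,
                           "requested tick rate in Hz"),
    "time": ParamSpec(int, 0, "1 to record worker execution times"),
    "verbose": ParamSpec(int, 0, "1 for per-frame log lines"),
    "processall": ParamSpec(int, 0,
                            "1 to disable frame dropping and queue every frame"),
}


@dataclass(frozen=True)
class PluginDescriptor:
    """A discovered plug-in, as listed at startup and used for CLI routing."""
    display_name: str
    stream_name: str
    is_input: bool
    params: dict[str, ParamSpec] = field(default_factory=dict)
    requested_framerate: float = DEFAULT_FRAMERATE_HZ


class Plugin:
    display_name: ClassVar[str] = "Plugin"
    is_input: ClassVar[bool] = False
    #: plug-in specific parameters; universal ones are merged in automatically
    PARAMS: ClassVar[dict[str, ParamSpec]] = {}

    def __init__(self, **params: Any):
        self.params: dict[str, Any] = {
            name: spec.default for name, spec in self.param_specs().items()}
        for name, value in params.items():
            self.set_param(name, value)
        #: set by the engine at wiring time; used to namespace metadata keys
        self.stream_name: str = normalize_plugin_name(self.display_name)

    # -- parameters -------------------------------------------------------

    @classmethod
    def param_specs(cls) -> dict[str, ParamSpec]:
        merged = dict(UNIVERSAL_PARAMS)
        merged.update(cls.PARAMS)
        return merged

    @classmethod
    def normalized_name(cls) -> str:
        return normalize_plugin_name(cls.display_name)

    @classmethod
    def describe(cls) -> PluginDescriptor:
        return PluginDescriptor(
            display_name=cls.display_name,
            stream_name="Input" if cls.is_input else cls.normalized_name(),
            is_input=cls.is_input,
            params=cls.param_specs(),
            requested_framerate=UNIVERSAL_PARAMS["framerate"].default,
        )

    def set_param(self, name: str, value: Any) -> None:
        """Set one parameter, coercing to the declared type; raises on unknowns
        and on values that do not coerce."""
        specs = self.param_specs()
        if name not in specs:
            raise KeyError(
                f"{self.display_name}: unknown parameter {name!r} "
                f"(known: {', '.join(sorted(specs))})")
        spec = specs[name]
        if value is not None and spec.type is not type(None):
            try:
                value = spec.type(value)
            except (TypeError, ValueError) as exc:
                raise ValueError(
                    f"{self.display_name}: parameter {name!r} expects "
                    f"{spec.type.__name__}, got {value!r}") from exc
        self.params[name] = value

    @property
    def framerate(self) -> float:
        return float(self.params["framerate"])

    # -- lifecycle hooks --------------------------------------------------

    def activate(self) -> None:
        """Called once before any frame flows; override for resource setup."""

    def deactivate(self) -> None:
        """Called at shutdown; override to flush resources."""

    def on_forward(self, frame: StreamFrame) -> None:
        """Called for *every* frame passing this pipeline position, accepted
        or not.  Sinks use it for per-stream accounting.  Must be fast and
        must never raise into the pipeline."""

    def on_end_of_stream(self, stream_name: str) -> None:
        """A source upstream finished; sinks flush here."""

    # -- the task ---------------------------------------------------------

    def task_duration(self) -> float:
        """Seconds the worker occupies beyond the computation itself (the
        artificial wait).  Under the simulated clock this *is* the task's
        duration; under the wall clock the engine sleeps it before computing."""
        return float(self.params.get("delay", 0.0) or 0.0)

    def process(self, frame: StreamFrame, layer_index: int) -> Optional[StreamFrame]:
        """Do the work on ``frame.get_layer(layer_index)`` and return the frame
        to emit (typically ``frame`` with a layer appended), or None to emit
        nothing."""
        raise NotImplementedError


class SourcePlugin(Plugin):
    """A producer of frames ('input plug-in'): emits on 'Input' at its own rate."""

    is_input: ClassVar[bool] = True
    PARAMS: ClassVar[dict[str, ParamSpec]] = {
        "loop": ParamSpec(int, 0, "1 to restart from the first frame at the end"),
    }

    @property
    def emission_fps(self) -> float:
        """Nominal frames per second this source emits at."""
        raise NotImplementedError

    def frame_count(self) -> Optional[int]:
        """Total frames available, or None for an unbounded source."""
        raise NotImplementedError

    def read_pixels(self, index: int) -> np.ndarray:
        """Pixels of frame ``index`` (0-based), as a 2D array."""
        raise NotImplementedError

    def process(self, frame: StreamFrame, layer_index: int) -> Optional[StreamFrame]:
        raise RuntimeError("source plug-ins do not process frames")
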