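"""Layered image frames travelling through a real-time pipeline.

A :class:`StreamFrame` is the single data record that every plug-in consumes
and produces: an ordered stack of 2D pixel *layers* sharing one spatial grid,
plus a string-keyed metadata map.  Plug-ins append their result as a new layer
on the *same* frame rather than emitting a copy, so pixel buffers are shared
by reference all the way down the pipeline and a result can always be traced
back to the exact source frame that produced it, even when different stages
run at different rates.

Reserved metadata keys (always present after a source emits a frame):

``stream``      name of the stream the frame travels on
``frame_id``    monotonically increasing integer per source
``acq_time``    acquisition timestamp in seconds (engine clock)
``fps``         the source's nominal frame rate in Hz
``label``       free-text annotation used by the file-writer sink

Plug-in written keys are namespaced as ``"<streamname>:<key>"`` to avoid
collisions between stages.
"""

from __future__ import annotations

from typing import Any, Iterator, Mapping

import numpy as np

RESERVED_KEYS = ("stream", "frame_id", "acq_time", "fps", "label")

Scalar = int | float | bool | str


class StreamFrame:
    """One timestamped, multi-layer image record.

    Parameters
    ----------
    layers
        Non-empty list of 2D arrays, all with identical height x width.
    metadata
        String-keyed map of scalars/strings.
    stream_name
        Name of the stream this frame travels on ('Input', 'pythonalgorithm', ...).
    frame_id
        Source-assigned integer, strictly increasing within one source.
    acq_time
        Acquisition time in seconds on the engine clock.
    source_fps
        Nominal emission rate of the originating source, in Hz.
    """

    __slots__ = ("_layers", "metadata", "stream_name", "frame_id",
                 "acq_time", "source_fps")

    def __init__(self, layers, metadata, stream_name, frame_id, acq_time,
                 source_fps):
        layers = list(layers)
        if not layers:
            raise ValueError("a frame needs at least one layer")
        shape0 = _check_2d(layers[0])
        for lay in layers[1:]:
            if _check_2d(lay) != shape0:
                raise ValueError(
                    f"layer shape {lay.shape} does not match frame shape {shape0}")
        self._layers: list[np.ndarray] = layers
        self.metadata: dict[str, Scalar] = dict(metadata)
        self.stream_name = str(stream_name)
        self.frame_id = int(frame_id)
        self.acq_time = float(acq_time)
        self.source_fps = float(source_fps)

    # -- layer access -----------------------------------------------------

    @property
    def n_layers(self) -> int:
        return len(self._layers)

    @property
    def shape(self) -> tuple[int, int]:
        return self._layers[0].shape  # type: ignore[return-value]

    @property
    def layers(self) -> tuple[np.ndarray, ...]:
        """The layer buffers, in append order (no copies)."""
        return tuple(self._layers)

    def add_layer(self, result: np.ndarray) -> "StreamFrame":
        """Append ``result`` as a new layer and return the same frame.

        The pre-existing layer buffers are untouched and not copied; the
        appended array is stored by reference.
        """
        shape = _check_2d(result)
        if shape != self.shape:
            raise ValueError(
                f"cannot add layer of shape {shape} to frame of shape {self.shape}")
        self._layers.append(result)
        return self

    def get_layer(self, index: int) -> np.ndarray:
        """Return layer ``index`` without copying; negative indices wrap (-1 = last)."""
        n = len(self._layers)
        if not -n <= index < n:
            raise IndexError(
                f"layer index {index} out of range for {n} layer(s) "
                f"(valid: {-n}..{n - 1})")
        return self._layers[index]

    def __iter__(self) -> Iterator[np.ndarray]:
        return iter(self._layers)

    # -- derivation -------------------------------------------------------

    def retag(self, stream_name: str,
              extra_metadata: Mapping[str, Scalar] | None = None) -> "StreamFrame":
        """A shallow re-labelled view of this frame for emission on another stream.

        Layer buffers are shared by reference (the no-copy contract); only the
        layer *list* and the metadata dict are new, so downstream appends do
        not mutate sibling streams' view of the stack.  ``frame_id`` and
        ``acq_time`` are preserved so results remain traceable to the source
        frame.
        """
        meta = dict(self.metadata)
        if extra_metadata:
            meta.update(extra_metadata)
        meta["stream"] = stream_name
        out = StreamFrame.__new__(StreamFrame)
        out._layers = list(self._layers)
        out.metadata = meta
        out.stream_name = stream_name
        out.frame_id = self.frame_id
        out.acq_time = self.acq_time
        out.source_fps = self.source_fps
        return out

    def set_meta(self, key: str, value: Scalar, namespace: str | None = None) -> None:
        """Write a metadata value, optionally namespaced as ``"<ns>:<key>"``."""
        if namespace is not None:
            key = f"{namespace}:{key}"
        self.metadata[key] = value

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        h, w = self.shape
        return (f"StreamFrame(stream={self.stream_name!r}, id={self.frame_id}, "
                f"{self.n_layers} layer(s) {h}x{w}, t={self.acq_time:.3f}s)")


def _check_2d(arr: Any) -> tuple[int, int]:
    arr = np.asarray(arr)
    if arr.ndim != 2 or arr.size == 0:
        raise ValueError(f"expected a non-empty 2D pixel array, got shape {arr.shape}")
    return arr.shape  # type: ignore[return-value]


def make_frame(pixels: np.ndarray, stream_name: str, frame_id: int,
               acq_time: float, fps: float,
               extra_metadata: Mapping[str, Scalar] | None = None) -> StreamFrame:
    """Build a one-layer frame with the reserved metadata keys populated."""
    _check_2d(pixels)
    metadata: dict[str, Scalar] = {
        "stream": stream_name,
        "frame_id": int(frame_id),
        "acq_time": float(acq_time),
        "fps": float(fps),
        "label": "",
    }
    if extra_metadata:
        metadata.update(extra_metadata)
    return StreamFrame([np.asarray(pixels)], metadata, stream_name, frame_id,
                       acq_time, fps)


def add_layer(frame: StreamFrame, result: np.ndarray) -> StreamFrame:
    """Functional alias for :meth:`StreamFrame.add_layer`."""
    return frame.add_layer(result)


def get_layer(frame: StreamFrame, index: int) -> np.ndarray:
    """Functional alias for :meth:`StreamFrame.get_layer`."""
    return frame.get_layer(index)
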