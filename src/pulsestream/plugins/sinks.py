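"""Sink plug-ins: the image file writer and a headless display.

Sinks consume frames without emitting a stream.  The writer turns a session
into a data-collection run: one PNG per layer plus a JSON metadata sidecar
per frame, filed under a label that can be switched live (``set
imagefilewriter_label <name>``) to annotate frame sequences by class during
an exam.  The display sink is headless: it keeps per-stream counters and the
latest classification summary, retrievable through the interactive ``stats``
command; no windowing system is required.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path
from typing import ClassVar, Optional

import numpy as np

from ..frames import StreamFrame
from .base import ParamSpec, Plugin

log = logging.getLogger("pulsestream")


def _layer_to_u8(layer: np.ndarray) -> np.ndarray:
    """Save-time conversion: soft float layers become 8-bit."""
    arr = np.asarray(layer)
    if arr.dtype == np.uint8:
        return arr
    arr = arr.astype(float)
    if arr.size and arr.max() <= 1.0 and arr.min() >= 0.0:
        arr = arr * 255.0
    return np.clip(np.round(arr), 0, 255).astype(np.uint8)


class ImageFileWriter(Plugin):
    """Writes each processed frame to disk: PNG per layer + JSON sidecar."""

    display_name: ClassVar[str] = "Image file writer"
    PARAMS: ClassVar[dict[str, ParamSpec]] = {
        "folder": ParamSpec(str, None, "output directory"),
        "label": ParamSpec(str, "default", "subfolder to file frames under"),
        "layers": ParamSpec(str, "all", "'all' or a single layer index to save"),
    }

    def __init__(self, **params):
        super().__init__(**params)
        self.frames_written = 0

    def activate(self) -> None:
        folder = self.params.get("folder")
        if not folder:
            raise FileNotFoundError("Image file writer: no folder configured")
        root = Path(folder).expanduser()
        root.mkdir(parents=True, exist_ok=True)
        probe = root / ".pulsestream-write-probe"
        try:
            probe.touch()
            probe.unlink()
        except OSError as exc:
            raise PermissionError(f"Image file writer: {root} not writable") from exc

    def process(self, frame: StreamFrame, layer_index: int) -> None:
        import imageio.v2 as iio
        # label read per frame, so a live 'set' switches folders losslessly
        label = str(self.params["label"])
        out = Path(self.params["folder"]).expanduser() / label
        stem = (f"{frame.stream_name}_{frame.frame_id:06d}_"
                f"{int(round(frame.acq_time * 1e6)):012d}")
        sel = self.params["layers"]
        indices = range(frame.n_layers) if sel == "all" else [int(sel)]
        try:
            out.mkdir(parents=True, exist_ok=True)
            for i in indices:
                iio.imwrite(out / f"{stem}_l{i}.png",
                            _layer_to_u8(frame.get_layer(i)))
            sidecar = dict(frame.metadata)
            sidecar.update(stream=frame.stream_name, frame_id=frame.frame_id,
                           acq_time=frame.acq_time, fps=frame.source_fps,
                           label=label, n_layers=frame.n_layers)
            (out / f"{stem}.json").write_text(json.dumps(sidecar, indent=1))
            self.frames_written += 1
        except OSError:
            log.exception("Image file writer: write failed; frame %d skipped",
                          frame.frame_id)
        return None


def read_frame_back(png_stem: Path) -> tuple[list[np.ndarray], dict]:
    """Reload the layers and sidecar written for one frame (round-trip check).

    ``png_stem`` is the path prefix shared by the frame's files, e.g.
    ``out/classA/Input_000003_000000100000``.
    """
    import imageio.v2 as iio
    meta = json.loads((png_stem.parent / (png_stem.name + ".json")).read_text())
    layers = [np.asarray(iio.imread(png_stem.parent / f"{png_stem.name}_l{i}.png"))
              for i in range(meta["n_layers"])]
    return layers, meta


class Gui(Plugin):
    """Headless display sink: per-stream accounting and last-frame summaries."""

    display_name: ClassVar[str] = "GUI"

    def __init__(self, **params):
        super().__init__(**params)
        self.stream_counts: dict[str, int] = {}
        self.stream_first_t: dict[str, float] = {}
        self.stream_last_t: dict[str, float] = {}
        self.last_label: str = ""
        self.last_scores: dict[str, float] = {}
        self.last_frame: Optional[StreamFrame] = None

    def on_forward(self, frame: StreamFrame) -> None:
        name = frame.stream_name
        self.stream_counts[name] = self.stream_counts.get(name, 0) + 1
        self.stream_first_t.setdefault(name, frame.acq_time)
        self.stream_last_t[name] = frame.acq_time

    def process(self, frame: StreamFrame, layer_index: int) -> None:
        try:
            self.last_frame = frame
            label = frame.metadata.get("label", "")
            if label:
                self.last_label = str(label)
            self.last_scores = {
                k.split("score_", 1)[1]: float(v)
                for k, v in frame.metadata.items() if "score_" in k}
        except Exception:  # a display must never stall the pipeline
            log.exception("GUI summary update failed")
        return None

    def stats(self) -> dict:
        """Per-stream received counts and arrival rates, plus the live label."""
        rates = {}
        for name, count in self.stream_counts.items():
            span = self.stream_last_t[name] - self.stream_first_t[name]
            rates[name] = (count - 1) / span if span > 0 and count > 1 else 0.0
        return {"received": dict(self.stream_counts),
                "arrival_rate_hz": rates,
                "label": self.last_label,
                "scores": dict(self.last_scores)}

    def render(self) -> Optional[np.ndarray]:
        """Last layer of the last displayed frame (what a window would show);
        None when nothing has arrived — headless operation never fails."""
        if self.last_frame is None:
            return None
        return self.last_frame.get_layer(-1)
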