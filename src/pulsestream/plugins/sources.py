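"""Source plug-ins: video file playback, image-folder playback, and a
synthetic frame generator standing in for a hardware framegrabber.

All sources emit 8-bit grayscale frames on the 'Input' stream at their
nominal frame rate; colour inputs are reduced by luminance average unless
``rgb 1`` is set, in which case the three channels are emitted as three
layers.  Pre-recorded material played back at acquisition rate makes a live
session reproducible in the lab.
"""

from __future__ import annotations

import math
from pathlib import Path
from typing import ClassVar, Optional

import numpy as np

from .base import ParamSpec, Plugin, SourcePlugin

_IMAGE_SUFFIXES = (".png", ".jpg", ".jpeg", ".bmp", ".tif", ".tiff")


def _to_gray_u8(arr: np.ndarray) -> np.ndarray:
    """Collapse an image array to 2D uint8 by luminance average."""
    arr = np.asarray(arr)
    if arr.ndim == 3:
        arr = arr[..., :3].mean(axis=-1)
    if arr.dtype != np.uint8:
        arr = np.clip(arr, 0, 255).astype(np.uint8)
    return arr


class VideoManager(SourcePlugin):
    """Reads and transmits frames from a video file at its native rate."""

    display_name: ClassVar[str] = "Video manager"
    PARAMS: ClassVar[dict[str, ParamSpec]] = {
        **SourcePlugin.PARAMS,
        "input": ParamSpec(str, None, "path to a video file"),
        "fps": ParamSpec(float, 0.0, "override the file's native frame rate (0 = native)"),
        "rgb": ParamSpec(int, 0, "1 to keep colour as three layers instead of luminance"),
    }

    def __init__(self, **params):
        super().__init__(**params)
        self._reader = None
        self._native_fps = 30.0
        self._n_frames: Optional[int] = None

    def activate(self) -> None:
        path = self.params.get("input")
        if not path:
            raise FileNotFoundError("Video manager: no --videomanager_input given")
        path = Path(path).expanduser()
        if not path.exists():
            raise FileNotFoundError(f"Video manager: {path} does not exist")
        if path.is_dir():
            # a directory of still images goes through the same frame loop
            self._frames = _list_images(path)
            if not self._frames:
                raise FileNotFoundError(f"Video manager: no images in {path}")
            self._n_frames = len(self._frames)
            self._native_fps = 30.0
            return
        import imageio.v2 as iio
        self._reader = iio.get_reader(str(path))
        meta = self._reader.get_meta_data()
        self._native_fps = float(meta.get("fps", 30.0) or 30.0)
        try:
            n = self._reader.count_frames()
            self._n_frames = None if math.isinf(n) else int(n)
        except Exception:
            self._n_frames = None

    def deactivate(self) -> None:
        if self._reader is not None:
            self._reader.close()
            self._reader = None

    @property
    def emission_fps(self) -> float:
        override = float(self.params.get("fps") or 0.0)
        return override if override > 0 else self._native_fps

    def frame_count(self) -> Optional[int]:
        return self._n_frames

    def read_pixels(self, index: int) -> Optional[np.ndarray]:
        if self._reader is not None:
            try:
                raw = self._reader.get_data(index)
            except IndexError:
                return None
        else:
            import imageio.v2 as iio
            raw = iio.imread(self._frames[index])
        if self.params.get("rgb") and np.asarray(raw).ndim == 3:
            return np.asarray(raw)[..., :3]
        return _to_gray_u8(raw)


class FileManager(SourcePlugin):
    """Plays back a folder of 2D image files at a given frame rate."""

    display_name: ClassVar[str] = "File manager"
    PARAMS: ClassVar[dict[str, ParamSpec]] = {
        **SourcePlugin.PARAMS,
        "input": ParamSpec(str, None, "folder of image files"),
    }

    def __init__(self, **params):
        super().__init__(**params)
        if float(self.params["framerate"]) <= 0:
            raise ValueError("File manager: framerate must be positive")
        self._files: list[Path] = []

    def activate(self) -> None:
        folder = self.params.get("input")
        if not folder:
            raise FileNotFoundError("File manager: no --filemanager_input given")
        folder = Path(folder).expanduser()
        if not folder.is_dir():
            raise FileNotFoundError(f"File manager: {folder} is not a folder")
        self._files = _list_images(folder)
        if not self._files:
            raise FileNotFoundError(f"File manager: no images in {folder}")

    @property
    def emission_fps(self) -> float:
        # the playback rate of a still-image folder *is* its framerate param
        return float(self.params["framerate"])

    def frame_count(self) -> Optional[int]:
        return len(self._files)

    def read_pixels(self, index: int) -> np.ndarray:
        return _read_image(self._files[index])


class FrameSource(SourcePlugin):
    """Synthetic frame generator: drifting Gaussian blobs under speckle noise.

    Stands in for a hardware framegrabber: with a fixed ``seed`` the emitted
    sequence is bit-identical across runs, and under the simulated clock it
    emits faster than real time.  The texture — a handful of bright blobs
    drifting over multiplicative speckle — exercises blur, threshold and the
    classifier the way ultrasound-like frames would.
    """

    display_name: ClassVar[str] = "Frame source"
    PARAMS: ClassVar[dict[str, ParamSpec]] = {
        **SourcePlugin.PARAMS,
        "fps": ParamSpec(float, 30.0, "emission rate in Hz"),
        "duration": ParamSpec(float, 10.0, "stream length in seconds (0 = unbounded)"),
        "width": ParamSpec(int, 128, "frame width in pixels"),
        "height": ParamSpec(int, 128, "frame height in pixels"),
        "seed": ParamSpec(int, 0, "seed of the frame generator"),
        "nblobs": ParamSpec(int, 3, "number of drifting blobs"),
    }

    def __init__(self, **params):
        super().__init__(**params)
        if float(self.params["fps"]) <= 0:
            raise ValueError("Frame source: fps must be positive")
        self._paths = None
        self._grid = None

    def _blob_paths(self) -> np.ndarray:
        """Per-blob drift parameters, fixed by the seed (shape nblobs x 6)."""
        if self._paths is None:
            rng = np.random.default_rng(int(self.params["seed"]))
            n = int(self.params["nblobs"])
            # centre_y, centre_x (fractions), radius_frac, drift phase/speed, sigma
            self._paths = np.column_stack([
                rng.uniform(0.25, 0.75, n), rng.uniform(0.25, 0.75, n),
                rng.uniform(0.1, 0.2, n), rng.uniform(0, 2 * np.pi, n),
                rng.uniform(0.2, 0.6, n), rng.uniform(0.05, 0.12, n)])
        return self._paths

    @property
    def emission_fps(self) -> float:
        return float(self.params["fps"])

    def frame_count(self) -> Optional[int]:
        duration = float(self.params["duration"])
        if duration <= 0:
            return None
        return int(round(duration * self.emission_fps))

    def read_pixels(self, index: int) -> np.ndarray:
        h, w = int(self.params["height"]), int(self.params["width"])
        t = index / self.emission_fps
        if self._grid is None or self._grid[0].shape != (h, w):
            self._grid = np.mgrid[0:h, 0:w]
        yy, xx = self._grid
        img = np.zeros((h, w))
        for cy, cx, r, phase, speed, sigma in self._blob_paths():
            y = (cy + r * np.sin(2 * np.pi * speed * t + phase)) * h
            x = (cx + r * np.cos(2 * np.pi * speed * t + phase)) * w
            s2 = (sigma * min(h, w)) ** 2
            img += np.exp(-((yy - y) ** 2 + (xx - x) ** 2) / (2 * s2))
        img = img / max(1, int(self.params["nblobs"]))
        # per-frame speckle, random-access deterministic in (seed, index)
        rng = np.random.default_rng([int(self.params["seed"]), 1 + index])
        speckle = rng.rayleigh(scale=0.35, size=(h, w))
        img = np.clip(img * (0.4 + speckle) * 255 + 20 * speckle, 0, 255)
        return img.astype(np.uint8)


def _list_images(folder: Path) -> list[Path]:
    return sorted(p for p in folder.iterdir()
                  if p.suffix.lower() in _IMAGE_SUFFIXES)


def _read_image(path: Path) -> np.ndarray:
    import imageio.v2 as iio
    return _to_gray_u8(iio.imread(path))
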