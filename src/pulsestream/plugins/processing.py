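"""Processing plug-ins: blur, binary threshold, and a mock standard-plane
classifier with temporal score averaging.

Each appends its result as a new layer on the shared input frame, so the
original pixels and every intermediate result coexist on one frame and any
output can be traced to the exact source frame it came from.  The blur and
threshold stages double as the template plug-ins for authors; each also takes
a ``delay`` parameter — an artificial wait occupying its worker — used by the
telemetry harness to probe the frame-dropping behaviour.
"""

from __future__ import annotations

from collections import deque
from dataclasses import dataclass
from typing import ClassVar, Optional

import numpy as np
from scipy import ndimage

from ..frames import StreamFrame
from .base import ParamSpec, Plugin

_DELAY_PARAM = ParamSpec(float, 0.0, "artificial wait occupying the worker, seconds")


class PythonAlgorithm(Plugin):
    """Gaussian blur of the selected layer (the 'python template' plug-in)."""

    display_name: ClassVar[str] = "Python Algorithm"
    PARAMS: ClassVar[dict[str, ParamSpec]] = {
        "sigma": ParamSpec(float, 5.0, "Gaussian standard deviation in pixels"),
        "delay": _DELAY_PARAM,
    }

    def process(self, frame: StreamFrame, layer_index: int) -> StreamFrame:
        sigma = float(self.params["sigma"])
        if sigma <= 0:
            raise ValueError("sigma must be positive")
        layer = frame.get_layer(layer_index).astype(float)
        # 'reflect' (half-sample symmetric) keeps the mean under the
        # normalized symmetric kernel
        blurred = ndimage.gaussian_filter(layer, sigma=sigma, mode="reflect")
        return frame.add_layer(blurred)


class CppAlgorithm(Plugin):
    """Binary threshold of the selected layer (the 'c++ template' plug-in)."""

    display_name: ClassVar[str] = "Cpp Algorithm"
    PARAMS: ClassVar[dict[str, ParamSpec]] = {
        "level": ParamSpec(float, float("nan"),
                           "threshold intensity (default: half the dtype range)"),
        "delay": _DELAY_PARAM,
    }

    @staticmethod
    def default_level(layer: np.ndarray) -> float:
        if np.issubdtype(layer.dtype, np.integer):
            info = np.iinfo(layer.dtype)
            return (float(info.max) + float(info.min)) / 2.0
        return 0.5

    def process(self, frame: StreamFrame, layer_index: int) -> StreamFrame:
        layer = frame.get_layer(layer_index)
        level = float(self.params["level"])
        if np.isnan(level):
            level = self.default_level(layer)
        mask = (np.asarray(layer) > level).astype(np.uint8)
        return frame.add_layer(mask)


# ---------------------------------------------------------------------------
# mock standard-plane classifier
# ---------------------------------------------------------------------------

#: Background plus the 13 fetal standard views of the 20-week screening exam
#: (the label space of the SonoNet plane detector).
PLANE_LABELS = (
    "Background", "Abdominal", "Brain (Cb.)", "Brain (Tv.)", "Femur",
    "Kidneys", "Lips", "LVOT", "Profile", "RVOT",
    "Spine (cor.)", "Spine (sag.)", "3VV", "4CH",
)


@dataclass(frozen=True)
class ClassifierScore:
    """Per-frame classifier output: raw softmax scores and their sliding mean."""
    class_labels: tuple[str, ...]
    raw_scores: np.ndarray
    averaged_scores: np.ndarray
    window: int

    @property
    def label(self) -> str:
        return self.class_labels[int(np.argmax(self.averaged_scores))]

    @property
    def confidence(self) -> float:
        return float(np.max(self.averaged_scores))


class MockPlaneModel:
    """Deterministic stand-in scorer behind the classifier interface.

    Synthetic: maps histogram-moment features of a frame through a fixed
    linear layer and a softmax over :data:`PLANE_LABELS`.  The coefficients
    are constants derived from a fixed internal seed (offset by the user
    ``seed``), so a given frame always yields the same score vector.  A
    trained network exposing the same ``scores(layer) -> (K,)`` surface can be
    dropped in its place.
    """

    _BASE_SEED = 20211209

    def __init__(self, seed: int = 0, labels: tuple[str, ...] = PLANE_LABELS):
        self.labels = labels
        rng = np.random.default_rng(self._BASE_SEED + int(seed))
        self._weights = rng.normal(scale=2.0, size=(len(labels), 8))
        self._bias = rng.normal(scale=0.5, size=len(labels))

    @staticmethod
    def features(layer: np.ndarray) -> np.ndarray:
        x = np.asarray(layer, dtype=float).ravel() / 255.0
        hist, _ = np.histogram(x, bins=16, range=(0, 1), density=False)
        p = hist / max(1, x.size)
        nz = p[p > 0]
        entropy = float(-(nz * np.log(nz)).sum())
        q25, q50, q75 = np.percentile(x, [25, 50, 75])
        std = float(x.std())
        skew = float(((x - x.mean()) ** 3).mean() / (std ** 3 + 1e-12))
        return np.array([x.mean(), std, skew, entropy / np.log(16),
                         q25, q50, q75, float((x > 0.5).mean())])

    def scores(self, layer: np.ndarray) -> np.ndarray:
        z = self._weights @ self.features(layer) + self._bias
        z = z - z.max()
        e = np.exp(z)
        return e / e.sum()


class StandardPlaneDetection(Plugin):
    """Plane classification with a sliding temporal average of the scores.

    The per-frame score vector is averaged over the last ``taverage`` frames
    to stabilize the predicted plane at high acquisition rates; the window
    length can be changed at run time.  The argmax label and its confidence
    are written to frame metadata, and a small score-bar overlay layer is
    appended for display sinks.
    """

    display_name: ClassVar[str] = "Standard plane detection"
    PARAMS: ClassVar[dict[str, ParamSpec]] = {
        "taverage": ParamSpec(int, 1, "number of frames in the temporal average"),
        "seed": ParamSpec(int, 0, "seed offsetting the mock model's coefficients"),
        "delay": _DELAY_PARAM,
    }

    def __init__(self, model=None, **params):
        super().__init__(**params)
        if int(self.params["taverage"]) < 1:
            raise ValueError("taverage must be >= 1")
        self.model = model if model is not None else \
            MockPlaneModel(seed=int(self.params["seed"]))
        self._window: deque[np.ndarray] = deque()
        self._window_stream: Optional[str] = None
        self.last_score: Optional[ClassifierScore] = None

    def score_frame(self, layer: np.ndarray, stream: str) -> ClassifierScore:
        """Score one layer and fold it into the temporal window."""
        n = int(self.params["taverage"])
        if n < 1:
            raise ValueError("taverage must be >= 1")
        if stream != self._window_stream:  # window resets on stream change
            self._window.clear()
            self._window_stream = stream
        raw = np.asarray(self.model.scores(layer), dtype=float)
        self._window.append(raw)
        while len(self._window) > n:
            self._window.popleft()
        averaged = np.mean(np.stack(self._window), axis=0)
        score = ClassifierScore(tuple(self.model.labels), raw, averaged, n)
        self.last_score = score
        return score

    def process(self, frame: StreamFrame, layer_index: int) -> StreamFrame:
        layer = frame.get_layer(layer_index)
        score = self.score_frame(np.asarray(layer), frame.stream_name)
        frame.metadata["label"] = score.label
        frame.set_meta("confidence", score.confidence, namespace=self.stream_name)
        for lab, s in zip(score.class_labels, score.averaged_scores):
            frame.set_meta(f"score_{lab}", float(s), namespace=self.stream_name)
        return frame.add_layer(self._overlay(score, frame.shape))

    @staticmethod
    def _overlay(score: ClassifierScore, shape: tuple[int, int]) -> np.ndarray:
        """Score bars, one row band per class, bar length = averaged score."""
        h, w = shape
        overlay = np.zeros(shape, dtype=np.uint8)
        k = len(score.class_labels)
        band = max(1, h // (2 * k))
        for c, s in enumerate(score.averaged_scores):
            r0 = c * band
            overlay[r0:r0 + band, :max(1, int(round(s * w)))] = 255
        return overlay
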