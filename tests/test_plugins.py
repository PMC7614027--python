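"""Built-in plug-ins: blur, threshold, classifier window, sources, writer."""

import json

import numpy as np
import pytest

from pulsestream import make_frame
from pulsestream.plugins import (CppAlgorithm, FileManager, FrameSource, Gui,
                                 ImageFileWriter, MockPlaneModel, PLANE_LABELS,
                                 PythonAlgorithm, StandardPlaneDetection,
                                 read_frame_back)


def _frame(pixels, stream="Input", i=0, t=0.0):
    return make_frame(np.asarray(pixels), stream, i, t, 30.0)


def _gaussian_kernel_2d(sigma, radius):
    """Independent closed-form oracle for the blur: sampled, normalized."""
    x = np.arange(-radius, radius + 1)
    k1 = np.exp(-x ** 2 / (2 * sigma ** 2))
    k1 /= k1.sum()
    return np.outer(k1, k1)


class TestBlur:
    def test_constant_image_is_fixed_point(self):
        f = _frame(np.full((16, 16), 37, dtype=np.uint8))
        PythonAlgorithm(sigma=3).process(f, 0)
        assert np.allclose(f.get_layer(1), 37.0)

    def test_centered_impulse_equals_sampled_kernel(self):
        sigma, radius = 2.0, 8  # truncation radius at 4 sigma
        img = np.zeros((33, 33))
        img[16, 16] = 1.0
        f = _frame(img)
        PythonAlgorithm(sigma=sigma).process(f, 0)
        expected = np.zeros((33, 33))
        expected[16 - radius:16 + radius + 1,
                 16 - radius:16 + radius + 1] = _gaussian_kernel_2d(sigma, radius)
        np.testing.assert_allclose(f.get_layer(1), expected, atol=1e-12)

    def test_linearity_and_mean_preservation(self):
        rng = np.random.default_rng(7)
        x = rng.uniform(0, 255, (32, 32))
        fa, fb = _frame(x), _frame(3.0 * x)
        plugin = PythonAlgorithm(sigma=4)
        plugin.process(fa, 0)
        plugin.process(fb, 0)
        np.testing.assert_allclose(fb.get_layer(1), 3.0 * fa.get_layer(1),
                                   rtol=1e-10)
        assert abs(fa.get_layer(1).mean() - x.mean()) < 1e-6

    def test_input_layer_untouched(self):
        x = np.arange(64, dtype=np.uint8).reshape(8, 8)
        f = _frame(x)
        before = f.get_layer(0).copy()
        PythonAlgorithm(sigma=2).process(f, 0)
        np.testing.assert_array_equal(f.get_layer(0), before)

    def test_invalid_sigma_rejected(self):
        with pytest.raises(ValueError, match="sigma"):
            PythonAlgorithm(sigma=0).process(_frame(np.zeros((4, 4))), 0)


class TestThreshold:
    @pytest.mark.parametrize("value,level,expected", [
        (100, 127, 0), (200, 127, 1)])
    def test_constant_images(self, value, level, expected):
        f = _frame(np.full((8, 8), value, dtype=np.uint8))
        CppAlgorithm(level=level).process(f, 0)
        assert np.all(f.get_layer(1) == expected)

    def test_half_half_foreground_fraction(self):
        img = np.zeros((10, 10), dtype=np.uint8)
        img[:, 5:] = 255
        f = _frame(img)
        CppAlgorithm(level=127).process(f, 0)
        assert f.get_layer(1).mean() == pytest.approx(0.5)

    def test_default_level_is_half_dtype_range(self):
        f = _frame(np.full((4, 4), 128, dtype=np.uint8))
        CppAlgorithm().process(f, 0)  # uint8 default level 127.5
        assert np.all(f.get_layer(1) == 1)

    def test_mask_idempotent_at_half_level(self):
        rng = np.random.default_rng(1)
        mask = (rng.uniform(size=(16, 16)) > 0.5).astype(np.uint8)
        f = _frame(mask)
        CppAlgorithm(level=0.5).process(f, 0)
        np.testing.assert_array_equal(f.get_layer(1), mask)

    def test_selects_requested_layer(self):
        f = _frame(np.zeros((8, 8), dtype=np.uint8))
        f.add_layer(np.full((8, 8), 200.0))
        CppAlgorithm(level=127).process(f, -1)
        assert np.all(f.get_layer(-1) == 1)


class _ScriptedModel:
    """Stub scorer replaying a fixed raw-score sequence."""
    labels = ("A", "B")

    def __init__(self, sequence):
        self._seq = list(sequence)
        self._i = 0

    def scores(self, layer):
        out = self._seq[self._i % len(self._seq)]
        self._i += 1
        return np.asarray(out, dtype=float)


class TestClassifier:
    def test_window_of_one_returns_raw(self):
        clf = StandardPlaneDetection(taverage=1)
        rng = np.random.default_rng(2)
        for i in range(5):
            s = clf.score_frame(rng.integers(0, 255, (32, 32)), "Input")
            np.testing.assert_allclose(s.averaged_scores, s.raw_scores)

    def test_constant_input_averaged_equals_raw(self):
        clf = StandardPlaneDetection(taverage=4)
        img = np.full((32, 32), 90, dtype=np.uint8)
        for _ in range(6):
            s = clf.score_frame(img, "Input")
        np.testing.assert_allclose(s.averaged_scores, s.raw_scores, atol=1e-12)

    def test_alternating_scores_average_to_half(self):
        clf = StandardPlaneDetection(
            model=_ScriptedModel([[0.9, 0.1], [0.1, 0.9]]), taverage=2)
        clf.score_frame(np.zeros((4, 4)), "Input")
        for _ in range(4):
            s = clf.score_frame(np.zeros((4, 4)), "Input")
            np.testing.assert_allclose(s.averaged_scores, [0.5, 0.5])

    def test_window_equals_brute_force_mean(self):
        clf = StandardPlaneDetection(taverage=5)
        rng = np.random.default_rng(3)
        raws = []
        for i in range(12):
            img = rng.integers(0, 255, (24, 24)).astype(np.uint8)
            raws.append(MockPlaneModel().scores(img))
            s = clf.score_frame(img, "Input")
            expected = np.mean(raws[max(0, i - 4):i + 1], axis=0)
            np.testing.assert_allclose(s.averaged_scores, expected, atol=1e-12)

    def test_scores_normalized_and_deterministic(self):
        img = np.random.default_rng(4).integers(0, 255, (32, 32))
        a = MockPlaneModel().scores(img)
        b = MockPlaneModel().scores(img)
        np.testing.assert_array_equal(a, b)
        assert a.sum() == pytest.approx(1.0, abs=1e-9)
        assert len(a) == len(PLANE_LABELS) == 14
        assert "Background" in PLANE_LABELS

    def test_window_resets_on_stream_change(self):
        clf = StandardPlaneDetection(
            model=_ScriptedModel([[0.9, 0.1], [0.1, 0.9]]), taverage=2)
        clf.score_frame(np.zeros((4, 4)), "Input")
        s = clf.score_frame(np.zeros((4, 4)), "other")  # raw [0.1, 0.9]
        np.testing.assert_allclose(s.averaged_scores, [0.1, 0.9])

    def test_invalid_window_rejected(self):
        with pytest.raises(ValueError, match="taverage"):
            StandardPlaneDetection(taverage=0)

    def test_process_writes_label_and_overlay(self):
        f = _frame(np.random.default_rng(5).integers(0, 255, (28, 28)
                                                     ).astype(np.uint8))
        clf = StandardPlaneDetection(taverage=1)
        clf.process(f, 0)
        assert f.metadata["label"] in PLANE_LABELS
        assert f.n_layers == 2
        assert f.metadata[f"{clf.stream_name}:confidence"] > 0


class TestSources:
    def test_synthetic_sequence_bit_identical_across_runs(self):
        a = FrameSource(seed=11, width=32, height=32)
        b = FrameSource(seed=11, width=32, height=32)
        for i in (0, 5, 17):
            np.testing.assert_array_equal(a.read_pixels(i), b.read_pixels(i))
        assert not np.array_equal(
            a.read_pixels(0), FrameSource(seed=12, width=32, height=32).read_pixels(0))

    def test_frame_count_is_duration_times_fps(self):
        assert FrameSource(fps=30, duration=1).frame_count() == 30
        assert FrameSource(fps=30, duration=900).frame_count() == 27000
        assert FrameSource(fps=30, duration=0).frame_count() is None

    def test_invalid_fps_rejected(self):
        with pytest.raises(ValueError, match="fps"):
            FrameSource(fps=0)

    def test_folder_source_plays_files_in_order(self, tmp_path):
        import imageio.v2 as iio
        for i in range(7):
            iio.imwrite(tmp_path / f"img{i}.png",
                        np.full((8, 8), 10 * i, dtype=np.uint8))
        src = FileManager(input=str(tmp_path), framerate=10)
        src.activate()
        assert src.frame_count() == 7
        assert src.emission_fps == 10.0
        assert src.read_pixels(3)[0, 0] == 30

    def test_missing_folder_is_activation_error(self):
        with pytest.raises(FileNotFoundError):
            FileManager(input="/nonexistent/folder").activate()


class TestWriter:
    def _run_writer(self, tmp_path, frames, label_switch_at=None):
        writer = ImageFileWriter(folder=str(tmp_path), label="classA")
        writer.activate()
        for i, f in enumerate(frames):
            if label_switch_at is not None and i == label_switch_at:
                writer.set_param("label", "classB")
            writer.process(f, -1)
        return writer

    def test_png_and_sidecar_per_frame(self, tmp_path):
        frames = [_frame(np.full((8, 8), i, dtype=np.uint8), i=i, t=i / 30)
                  for i in range(10)]
        self._run_writer(tmp_path, frames)
        out = tmp_path / "classA"
        assert len(list(out.glob("*.png"))) == 10
        assert len(list(out.glob("*.json"))) == 10

    def test_label_switch_splits_output(self, tmp_path):
        frames = [_frame(np.zeros((8, 8), dtype=np.uint8), i=i, t=i / 30)
                  for i in range(10)]
        self._run_writer(tmp_path, frames, label_switch_at=5)
        assert len(list((tmp_path / "classA").glob("*.json"))) == 5
        assert len(list((tmp_path / "classB").glob("*.json"))) == 5

    def test_round_trip_reconstructs_layers_and_metadata(self, tmp_path):
        rng = np.random.default_rng(6)
        f = _frame(rng.integers(0, 255, (16, 16)).astype(np.uint8), i=3, t=0.1)
        f.add_layer((rng.uniform(size=(16, 16)) > 0.5).astype(np.uint8))
        f.set_meta("confidence", 0.75, namespace="clf")
        self._run_writer(tmp_path, [f])
        stem = next((tmp_path / "classA").glob("*.json")).with_suffix("")
        layers, meta = read_frame_back(stem)
        assert len(layers) == 2
        np.testing.assert_array_equal(layers[0], f.get_layer(0))
        np.testing.assert_array_equal(layers[1], f.get_layer(1))
        assert meta["frame_id"] == 3
        assert meta["clf:confidence"] == 0.75

    def test_sidecar_records_stream_provenance(self, tmp_path):
        f = _frame(np.zeros((4, 4), dtype=np.uint8), stream="Input1")
        self._run_writer(tmp_path, [f])
        sidecar = json.loads(next((tmp_path / "classA").glob("*.json")).read_text())
        assert sidecar["stream"] == "Input1"

    def test_unusable_folder_is_activation_error(self, tmp_path):
        blocker = tmp_path / "occupied"
        blocker.write_text("not a directory")
        with pytest.raises(OSError):
            ImageFileWriter(folder=str(blocker)).activate()
        with pytest.raises(FileNotFoundError, match="no folder"):
            ImageFileWriter().activate()


class TestGuiSink:
    def test_counts_streams_and_reports_label(self):
        gui = Gui()
        for i in range(5):
            gui.on_forward(_frame(np.zeros((4, 4)), i=i, t=i / 30))
        f = _frame(np.zeros((4, 4)))
        f.metadata["label"] = "Head"
        gui.process(f, -1)
        stats = gui.stats()
        assert stats["received"]["Input"] == 5
        assert stats["label"] == "Head"
        assert stats["arrival_rate_hz"]["Input"] == pytest.approx(30.0)

    def test_render_headless_before_any_frame(self):
        assert Gui().render() is None
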