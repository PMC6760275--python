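"""Kymograph extraction, chamber lines, extent traces and beat detection."""

import numpy as np
import pytest

from cardioscreen.formats import VideoStack
from cardioscreen.kymo import (
    ChamberTrace,
    GeometryError,
    LineSelection,
    chamber_extent_trace,
    detect_beats,
    extract_kymograph,
    place_chamber_lines,
)


def _stack(frames):
    return VideoStack(np.asarray(frames, dtype=float), fps=75.9,
                      pixel_size_um=1.23)


class TestExtractKymograph:
    def test_constant_video_gives_constant_kymograph(self):
        stack = _stack(np.full((4, 20, 20), 7.0))
        kymo = extract_kymograph(
            stack, LineSelection((2, 10), (17, 10))
        )
        assert np.allclose(kymo.matrix, 7.0)
        assert kymo.n_frames == 4

    def test_vertical_bar_appears_at_its_position(self):
        frames = np.zeros((3, 20, 20))
        frames[:, :, 12] = 100.0
        kymo = extract_kymograph(
            _stack(frames), LineSelection((0, 10), (19, 10))
        )
        assert np.argmax(kymo.matrix[0]) == 12
        assert kymo.matrix[0, 5] == 0.0

    def test_out_of_bounds_line_rejected(self):
        stack = _stack(np.zeros((2, 10, 10)))
        with pytest.raises(GeometryError):
            extract_kymograph(stack, LineSelection((0, 5), (30, 5)))

    def test_degenerate_line_rejected(self):
        with pytest.raises(GeometryError):
            LineSelection((0, 0), (2, 0))


class TestSaveKymograph:
    def test_png_and_tiff_written(self, tmp_path):
        from cardioscreen.kymo import Kymograph, save_kymograph
        kymo = Kymograph(np.random.default_rng(0).random((20, 30)),
                         fps=75.9, pixel_size_um=1.23)
        for name in ("k.png", "k.tif"):
            save_kymograph(kymo, tmp_path / name)
            assert (tmp_path / name).stat().st_size > 0


class TestPlaceChamberLines:
    def test_midpoints_at_fractions(self):
        axis = LineSelection((0, 0), (0, 100))
        v, a = place_chamber_lines(axis, (0.25, 0.75))
        assert np.allclose((np.array(v.start) + np.array(v.end)) / 2, (0, 25))
        assert np.allclose((np.array(a.start) + np.array(a.end)) / 2, (0, 75))

    def test_perpendicularity(self):
        axis = LineSelection((3, 4), (40, 60))
        v, a = place_chamber_lines(axis)
        assert abs(np.dot(axis.direction, v.direction)) < 1e-9
        assert abs(np.dot(axis.direction, a.direction)) < 1e-9

    def test_rotation_equivariance(self):
        theta = np.deg2rad(37)
        rot = np.array([[np.cos(theta), -np.sin(theta)],
                        [np.sin(theta), np.cos(theta)]])
        axis = LineSelection((10, 5), (10, 105))
        p0, p1 = np.array(axis.start), np.array(axis.end)
        axis_rot = LineSelection(tuple(rot @ p0), tuple(rot @ p1))
        v, _ = place_chamber_lines(axis)
        v_rot, _ = place_chamber_lines(axis_rot)
        assert np.allclose(rot @ np.array(v.start), v_rot.start, atol=1e-9)
        assert np.allclose(rot @ np.array(v.end), v_rot.end, atol=1e-9)

    def test_fraction_bounds(self):
        axis = LineSelection((0, 0), (0, 100))
        with pytest.raises(GeometryError):
            place_chamber_lines(axis, (0.0, 0.75))


class TestChamberExtent:
    def test_bright_run_length_times_pixel_size(self):
        from cardioscreen.kymo import Kymograph
        m = np.zeros((3, 100))
        m[:, 30:70] = 255.0  # 40 px bright run
        kymo = Kymograph(m, fps=75.9, pixel_size_um=1.23)
        trace = chamber_extent_trace(kymo, threshold=100.0)
        assert np.allclose(trace.extent_um, 40 * 1.23)  # 49.2 um

    def test_empty_rows_masked(self):
        from cardioscreen.kymo import Kymograph
        m = np.zeros((4, 50))
        m[0, 10:20] = 200.0
        kymo = Kymograph(m, fps=75.9, pixel_size_um=1.0)
        trace = chamber_extent_trace(kymo, threshold=100.0)
        assert trace.extent_um[1] == 0.0
        assert trace.contraction.mask[1]
        assert not trace.contraction.mask[0]

    def test_extent_invariant_under_line_reversal(self, small_heart):
        from cardioscreen.pipeline import default_heart_axis
        stack, truth = small_heart
        v, _ = place_chamber_lines(default_heart_axis(stack, truth))
        v_rev = LineSelection(v.end, v.start, v.sampling_width_px, v.label)
        t1 = chamber_extent_trace(extract_kymograph(stack, v))
        t2 = chamber_extent_trace(extract_kymograph(stack, v_rev))
        assert np.allclose(t1.extent_um, t2.extent_um, atol=1.3)


class TestDetectBeats:
    def _sin_trace(self, freq_hz, duration=40.0, fps=75.9):
        t = np.arange(int(duration * fps)) / fps
        contraction = 2.0 + np.sin(2 * np.pi * freq_hz * t)
        return ChamberTrace(1.0 / contraction, fps=fps, pixel_size_um=1.23)

    def test_sinusoid_peak_count_matches_maxima_oracle(self):
        # 200 beats/min = 3.333 Hz; closed form: maxima at t = (k + 1/4)/f.
        # A maximum closer than half a smoothing window to the recording
        # edge cannot survive any centred smoother, so the oracle counts
        # maxima up to that margin: 133 for the 200 bpm case.
        fps = 75.9
        trace = self._sin_trace(200 / 60.0, fps=fps)
        beats = detect_beats(trace)
        f = 200 / 60.0
        t_last = (len(trace.extent_um) - 1) / fps - 0.5 * 5 / fps
        expected = int(np.floor((t_last - 0.25 / f) * f)) + 1
        assert beats.n_beats == expected == 133

    def test_simulated_200bpm_gives_133_beats(self):
        from cardioscreen.pipeline import default_heart_axis
        from cardioscreen.sim import HeartSimParams, simulate_heart_video
        stack, truth = simulate_heart_video(
            HeartSimParams(ventricular_bpm=200, seed=99)
        )
        v, _ = place_chamber_lines(default_heart_axis(stack, truth))
        beats = detect_beats(chamber_extent_trace(extract_kymograph(stack, v)))
        assert beats.n_beats == len(truth["ventricular_beat_times"]) == 133

    def test_flat_curve_has_no_beats(self):
        trace = ChamberTrace(np.full(400, 100.0), fps=75.9, pixel_size_um=1.23)
        beats = detect_beats(trace)
        assert beats.n_beats == 0

    def test_no_beats_inside_simulated_arrest_window(self):
        from cardioscreen.pipeline import default_heart_axis
        from cardioscreen.sim import HeartSimParams, simulate_heart_video
        stack, truth = simulate_heart_video(HeartSimParams(
            ventricular_bpm=150, duration=20.0, arrest_windows=((8.0, 2.0),),
            seed=5,
        ))
        v, _ = place_chamber_lines(default_heart_axis(stack, truth))
        beats = detect_beats(chamber_extent_trace(extract_kymograph(stack, v)))
        inside = (beats.beat_times > 8.1) & (beats.beat_times < 9.9)
        assert not inside.any()

    def test_beat_count_invariant_under_affine_intensity_rescale(self, small_heart):
        from cardioscreen.pipeline import default_heart_axis
        stack, truth = small_heart
        v, _ = place_chamber_lines(default_heart_axis(stack, truth))
        n0 = detect_beats(chamber_extent_trace(extract_kymograph(stack, v))).n_beats
        rescaled = VideoStack(stack.frames.astype(float) * 3.7 + 11.0,
                              fps=stack.fps, pixel_size_um=stack.pixel_size_um)
        n1 = detect_beats(chamber_extent_trace(extract_kymograph(rescaled, v))).n_beats
        assert n0 == n1 > 0

    def test_requires_two_seconds_of_signal(self):
        trace = ChamberTrace(np.ones(30), fps=75.9, pixel_size_um=1.23)
        with pytest.raises(ValueError):
            detect_beats(trace)
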