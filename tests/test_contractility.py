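"""Similarity traces, beat detection, and physiology metrics."""

import json

import numpy as np
import pytest

import cardiotrace as ct
from cardiotrace import DegenerateDataError, InvalidArgumentError
from cardiotrace.contractility import events_to_json, pearson_similarity


class TestPearson:
    @pytest.mark.parametrize(
        "a, b, expected",
        [
            ([1, 2, 3], [1, 2, 3], 1.0),
            ([1, 2, 3], [3, 2, 1], -1.0),
            ([1, 2, 3], [1, 2, 4], 9.0 / np.sqrt(84.0)),  # ~0.98198
        ],
    )
    def test_values(self, a, b, expected):
        assert pearson_similarity(a, b) == pytest.approx(expected, abs=1e-6)

    def test_zero_variance(self):
        with pytest.raises(DegenerateDataError):
            pearson_similarity([1, 1, 1], [1, 2, 3])

    def test_too_few_samples(self):
        with pytest.raises(InvalidArgumentError):
            pearson_similarity([1, 2], [1, 2])


class TestSpectralSimilarity:
    def test_self_similarity_is_one(self, rng):
        spec = ct.polar_fft(rng.standard_normal((8, 8)))
        assert ct.spectral_similarity(spec, spec) == 1.0

    def test_grid_mismatch(self, rng):
        a = ct.polar_fft(rng.standard_normal((8, 8)))
        b = ct.polar_fft(rng.standard_normal((16, 16)))
        with pytest.raises(InvalidArgumentError):
            ct.spectral_similarity(a, b)


class TestComputeTrace:
    def test_identical_frames_give_unit_similarity(self, rng):
        frame = rng.random((16, 16))
        stack = ct.FrameStack(frames=np.repeat(frame[None], 4, axis=0))
        mask = ct.Mask(raster=np.ones((16, 16)))
        trace = ct.compute_trace(stack, mask)
        assert np.allclose(trace.similarity, 1.0)
        assert np.allclose(trace.contraction, 0.0)

    def test_single_frame_stack(self, rng):
        stack = ct.FrameStack(frames=rng.random((1, 16, 16)))
        trace = ct.compute_trace(stack, ct.Mask(raster=np.ones((16, 16))))
        assert len(trace) == 1 and trace.similarity[0] == 1.0

    def test_bounds_and_reference(self, short_trace):
        assert np.all(short_trace.similarity >= -1.0)
        assert np.all(short_trace.similarity <= 1.0)
        assert short_trace.similarity[short_trace.reference_index] == 1.0

    def test_mask_shape_mismatch(self, rng):
        stack = ct.FrameStack(frames=rng.random((2, 16, 16)))
        with pytest.raises(InvalidArgumentError):
            ct.compute_trace(stack, ct.Mask(raster=np.ones((8, 8))))

    def test_gain_invariance(self, short_recording, short_trace):
        _, stack, mask, _ = short_recording
        scaled = ct.FrameStack(frames=stack.frames * 3.7, fps=stack.fps)
        tr = ct.compute_trace(scaled, mask)
        assert np.allclose(tr.similarity, short_trace.similarity, atol=1e-9)

    def test_offset_inside_mask_near_invariance(self, short_recording, short_trace):
        # the mask indicator leaks a little energy into nonzero frequencies,
        # so offset invariance is approximate rather than exact
        _, stack, mask, _ = short_recording
        shifted = ct.FrameStack(frames=stack.frames + 0.3 * mask.raster, fps=stack.fps)
        tr = ct.compute_trace(shifted, mask)
        assert np.abs(tr.similarity - short_trace.similarity).max() < 5e-3

    def test_rest_reference_picks_quiet_frame(self, short_recording):
        spec, stack, mask, truth = short_recording
        tr = ct.compute_trace(stack, mask, ct.TraceConfig(reference="rest"))
        # the most at-rest frame should not sit in the contracted plateau
        peak_frame = int(round(truth.peak_s.iloc[0] * spec.fps))
        assert abs(tr.reference_index - peak_frame) > 3
        assert tr.similarity[tr.reference_index] == 1.0

    def test_rotation_leaves_trace_unchanged(self, short_recording, short_trace):
        _, stack, mask, _ = short_recording
        rot = ct.FrameStack(frames=np.rot90(stack.frames, axes=(1, 2)).copy(), fps=stack.fps)
        rmask = ct.Mask(raster=np.rot90(mask.raster).copy())
        tr = ct.compute_trace(rot, rmask)
        assert np.abs(tr.similarity - short_trace.similarity).max() < 1e-6


def synthetic_pulse_trace(spec, amp=0.05, fps=30.0, duration=3.0):
    """Trace built directly from the generator's activation waveform."""
    t = np.arange(int(duration * fps)) / fps
    contraction = amp * spec.pulse(t - 0.5)
    return ct.ContractionTrace(similarity=1.0 - contraction, fps=fps)


class TestDetectEvents:
    def test_constant_trace(self):
        trace = ct.ContractionTrace(similarity=np.ones(100), fps=30.0)
        assert ct.detect_events(trace) == []

    def test_too_short(self):
        trace = ct.ContractionTrace(similarity=np.ones(2), fps=30.0)
        with pytest.raises(InvalidArgumentError):
            ct.detect_events(trace)

    def test_triangular_pulse(self):
        c = np.zeros(120)
        apex = 60
        c[45:76] = 1.0 - np.abs(np.arange(45, 76) - apex) / 15.0
        trace = ct.ContractionTrace(similarity=1.0 - c, fps=30.0)
        events = ct.detect_events(trace)
        assert len(events) == 1
        ev = events[0]
        assert ev.peak_frame == apex
        assert ev.onset_frame <= ev.peak_frame <= ev.end_frame
        assert ev.amplitude == pytest.approx(1.0, abs=0.05)

    def test_pulse_shape_events_and_metrics(self):
        spec = ct.SyntheticRecordingSpec()
        trace = synthetic_pulse_trace(spec)
        events = ct.detect_events(trace)
        assert len(events) == 1
        metrics = ct.summarize(trace, events)
        frame = 1.0 / trace.fps
        # activation peaks at the plateau center; recovery is closed-form
        peak_t = 0.5 + spec.rise_time_s + spec.plateau_s / 2.0
        assert events[0].peak_frame * frame == pytest.approx(peak_t, abs=1.5 * frame)
        expected_r50 = spec.plateau_s / 2.0 + spec.decay_tau_s * np.log(2.0)
        assert metrics.relaxation_time_50 == pytest.approx(expected_r50, abs=1.5 * frame)
        assert metrics.n_events == 1


class TestSummarize:
    def test_empty_events(self):
        trace = ct.ContractionTrace(similarity=np.ones(90), fps=30.0)
        m = ct.summarize(trace, [])
        assert m.n_events == 0 and m.beat_rate == 0.0
        assert m.time_to_peak is None and m.mean_amplitude is None

    def test_beat_rate_nine_events_thirty_seconds(self):
        """Nine detected beats over a 30 s trace recover the 0.3 Hz pacing."""
        fps, T = 30.0, 900
        c = np.zeros(T)
        for k in range(9):
            apex = int(k * 100 + 20)
            c[apex - 6 : apex + 7] = 1.0 - np.abs(np.arange(-6, 7)) / 6.0
        trace = ct.ContractionTrace(similarity=1.0 - c, fps=fps)
        events = ct.detect_events(trace, ct.DetectionConfig(stim_freq_hz=0.3))
        m = ct.summarize(trace, events)
        assert m.n_events == 9
        assert m.beat_rate == pytest.approx(0.3)

    def test_symmetric_triangle_time_to_peak(self):
        c = np.zeros(90)
        c[0:31] = 1.0 - np.abs(np.arange(0, 31) - 15) / 15.0
        trace = ct.ContractionTrace(similarity=1.0 - c, fps=30.0)
        events = ct.detect_events(trace)
        m = ct.summarize(trace, events)
        assert m.time_to_peak == pytest.approx(0.5, abs=1.0 / 30.0)


class TestSerialization:
    def test_trace_csv_roundtrip(self, tmp_path, short_trace):
        path = tmp_path / "trace.csv"
        short_trace.to_csv(path)
        back = ct.ContractionTrace.from_csv(path)
        assert back.fps == pytest.approx(short_trace.fps)
        assert np.allclose(back.similarity, short_trace.similarity, atol=1e-8)
        assert back.reference_index == short_trace.reference_index

    def test_events_json_schema(self, tmp_path):
        c = np.zeros(120)
        c[45:76] = 1.0 - np.abs(np.arange(45, 76) - 60) / 15.0
        trace = ct.ContractionTrace(similarity=1.0 - c, fps=30.0)
        events = ct.detect_events(trace)
        metrics = ct.summarize(trace, events)
        path = tmp_path / "events.json"
        events_to_json(events, metrics, path, fps=trace.fps)
        data = json.loads(path.read_text())
        assert data["schema_version"]
        assert len(data["events"]) == 1
        assert data["metrics"]["n_events"] == 1
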