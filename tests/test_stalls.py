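"""Stall detection: projection, vesselness, segmentation, event calling."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from stallflow import (
    AngiogramSpec,
    AngiogramStack,
    SegmentMap,
    SegmentTraces,
    detect_stalls,
    detect_stalls_in_stack,
    enhance_vessels,
    extract_traces,
    flatten_mip,
    generate_angiogram,
    segment_capillaries,
    stall_metrics,
)


class TestFlattenMip:
    def test_single_slice_is_identity(self, rng):
        vol = rng.random((4, 1, 8, 8))
        out = flatten_mip(vol)
        assert np.array_equal(out.frames, vol[:, 0])

    def test_takes_maximum_over_z(self):
        vol = np.zeros((1, 3, 2, 2))
        vol[0, :, 1, 1] = [1, 5, 3]
        assert flatten_mip(vol).frames[0, 1, 1] == 5

    def test_all_zero_volume_stays_zero(self):
        assert not flatten_mip(np.zeros((2, 3, 4, 4))).frames.any()

    def test_rejects_non_4d(self):
        with pytest.raises(ValueError, match="4-D"):
            flatten_mip(np.zeros((3, 4, 4)))


class TestEnhanceVessels:
    def test_constant_image_gives_zero_response(self):
        assert not enhance_vessels(np.full((32, 32), 3.7)).any()

    def test_bright_line_response_peaks_on_centerline(self):
        img = np.zeros((40, 40))
        img[19:22, 5:35] = 1.0  # width-3 horizontal line
        resp = enhance_vessels(img)
        on_line = resp[20, 10:30].mean()
        off_line = resp[5:15, 10:30].mean()
        assert on_line > 10 * off_line

    def test_response_in_unit_interval(self, rng):
        resp = enhance_vessels(rng.random((48, 48)))
        assert resp.min() >= 0.0 and resp.max() <= 1.0


def _tube_image(shape=(64, 64)):
    img = np.zeros(shape)
    img[30:33, 8:56] = 1.0
    return img


class TestSegmentCapillaries:
    def test_single_tube_is_one_segment(self):
        seg = segment_capillaries(_tube_image(), threshold=0.5)
        assert seg.n_segments == 1

    def test_crossing_tubes_cut_into_four_segments(self):
        # a "+" of two crossing tubes: the skeleton has one central branch
        # point; cutting there leaves the four arms
        img = np.zeros((64, 64))
        img[31:34, 6:58] = 1.0
        img[6:58, 31:34] = 1.0
        seg = segment_capillaries(img, threshold=0.5)
        assert seg.n_segments == 4

    def test_empty_mask_raises(self):
        with pytest.raises(ValueError, match="no capillaries"):
            segment_capillaries(np.zeros((32, 32)), threshold=0.5)

    def test_detected_count_in_expected_band_for_default_generator(self):
        stack, _, _ = generate_angiogram(AngiogramSpec(n_frames=10, stall_fraction=0.0, seed=0))
        seg, _, _ = detect_stalls_in_stack(stack)
        assert 200 <= seg.n_segments <= 300


class TestExtractTraces:
    def test_constant_stack_gives_constant_traces(self):
        stack = AngiogramStack(np.full((4, 16, 16), 7.0), frame_interval_s=1.0)
        labels = np.zeros((16, 16), dtype=int)
        labels[2:5, 2:10] = 1
        traces = extract_traces(stack, SegmentMap(labels))
        assert np.allclose(traces.values, 7.0)

    def test_zeroed_frame_dips_only_there(self):
        frames = np.ones((8, 16, 16))
        labels = np.zeros((16, 16), dtype=int)
        labels[3, 2:12] = 1
        frames[5][labels == 1] = 0.0
        traces = extract_traces(AngiogramStack(frames, 1.0), SegmentMap(labels))
        assert traces.values[0, 5] == 0.0
        assert np.allclose(np.delete(traces.values[0], 5), 1.0)

    def test_shape_is_segments_by_frames(self):
        labels = np.zeros((16, 16), dtype=int)
        labels[1, 1:6] = 1
        labels[10, 1:6] = 2
        traces = extract_traces(AngiogramStack(np.ones((5, 16, 16)), 1.0), SegmentMap(labels))
        assert traces.values.shape == (2, 5)


def _trace_matrix(rows):
    return SegmentTraces(np.asarray(rows, dtype=float), frame_interval_s=9.0)


class TestDetectStalls:
    def test_run_length_event(self):
        traces = _trace_matrix([[10, 10, 1, 1, 1, 1, 10, 10, 10, 10]])
        rec = detect_stalls(traces, alpha=0.5)
        assert [(e.start_frame, e.duration_frames) for e in rec.events] == [(2, 4)]

    def test_short_dip_below_minimum_duration_discarded(self):
        traces = _trace_matrix([[10, 10, 1, 1, 10, 10, 10, 10]])
        assert detect_stalls(traces, alpha=0.5, min_duration=3).events == []

    def test_constant_trace_has_no_events(self):
        assert detect_stalls(_trace_matrix([[5.0] * 12])).events == []

    @pytest.mark.parametrize("alpha", [0.0, 1.0, 1.5, -0.2])
    def test_alpha_out_of_range_rejected(self, alpha):
        with pytest.raises(ValueError, match="alpha"):
            detect_stalls(_trace_matrix([[1.0] * 6]), alpha=alpha)

    def test_lowering_alpha_never_adds_events(self, rng):
        """Monotone robustness: a stricter (lower) threshold can only remove
        flagged frames, hence never increases the event count."""
        values = rng.gamma(2.0, 1.0, size=(30, 60))
        traces = SegmentTraces(values, frame_interval_s=9.0)
        counts = [
            len(detect_stalls(traces, alpha=a).events) for a in (0.9, 0.7, 0.5, 0.3, 0.1)
        ]
        assert all(a >= b for a, b in zip(counts, counts[1:]))

    def test_frame_duplication_doubles_durations(self, rng):
        """Duplicating every frame and doubling min_duration yields the same
        events with doubled start/duration."""
        values = np.where(rng.random((20, 40)) < 0.08, 0.01, 1.0)
        traces = SegmentTraces(values, frame_interval_s=9.0)
        doubled = SegmentTraces(np.repeat(values, 2, axis=1), frame_interval_s=4.5)
        rec1 = detect_stalls(traces, alpha=0.5, min_duration=3)
        rec2 = detect_stalls(doubled, alpha=0.5, min_duration=6)
        ev1 = sorted((e.segment_id, 2 * e.start_frame, 2 * e.duration_frames) for e in rec1.events)
        ev2 = sorted((e.segment_id, e.start_frame, e.duration_frames) for e in rec2.events)
        assert ev1 == ev2

    def test_no_false_positives_on_noiseless_constant_stack(self):
        stack = AngiogramStack(np.ones((20, 16, 16)), 9.0)
        labels = np.zeros((16, 16), dtype=int)
        labels[4:7, 2:12] = 1
        traces = extract_traces(stack, SegmentMap(labels))
        assert detect_stalls(traces).events == []


@given(
    st.lists(st.sampled_from([0.2, 10.0]), min_size=3, max_size=50),
    st.integers(min_value=1, max_value=5),
)
@settings(deadline=None, max_examples=200, derandomize=True)
def test_event_calling_matches_brute_force_scan(values, min_duration):
    """Oracle: a plain python scan over the trace enumerates the same events
    as the vectorized run-length detector."""
    min_duration = min(min_duration, len(values))  # precondition: T >= min_duration
    trace = _trace_matrix([values])
    thr = 0.5 * np.median(values)
    expected, run = [], 0
    for i, v in enumerate(values + [np.inf]):
        if v < thr:
            run += 1
        else:
            if run >= min_duration:
                expected.append((i - run, run))
            run = 0
    rec = detect_stalls(trace, alpha=0.5, min_duration=min_duration)
    got = [(e.start_frame, e.duration_frames) for e in rec.events]
    assert got == expected


class TestStallMetrics:
    def test_proportion_counts_stalled_segments(self):
        traces = _trace_matrix(
            [[10, 10, 1, 1, 1, 10, 10, 10, 10, 10]] * 2 + [[10.0] * 10] * 8
        )
        rec = detect_stalls(traces, alpha=0.5)
        m = stall_metrics(rec, frame_interval_s=9.0)
        assert m.proportion_stalled == pytest.approx(0.2)

    def test_three_frames_at_nine_seconds_is_27s(self):
        traces = _trace_matrix([[10, 1, 1, 1, 10, 10, 10, 10, 10, 10]])
        m = stall_metrics(detect_stalls(traces, alpha=0.5), frame_interval_s=9.0)
        assert m.mean_duration_frames == 3
        assert m.mean_duration_s == pytest.approx(27.0)

    def test_no_events_gives_zero_proportion_empty_durations(self):
        m = stall_metrics(detect_stalls(_trace_matrix([[1.0] * 10])), frame_interval_s=9.0)
        assert m.proportion_stalled == 0.0
        assert m.durations_frames == []

    def test_event_rate_pools_multiple_events_per_segment(self):
        traces = _trace_matrix(
            [[10, 10, 10, 10, 1, 1, 1, 10, 10, 10, 10, 1, 1, 1, 10, 10]] + [[10.0] * 16]
        )
        rec = detect_stalls(traces, alpha=0.5)
        m = stall_metrics(rec)
        assert m.proportion_stalled == pytest.approx(0.5)
        assert m.event_rate == pytest.approx(1.0)
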