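"""Saccade/blink labeling and fixation segmentation."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from femdrift.errors import InsufficientDataError, TooShortError
from femdrift.events import (
    BLINK,
    DISCARDED,
    FIXATION,
    SACCADE,
    EventLabels,
    FixationSegment,
    detect_blinks,
    detect_saccades,
    label_events,
    restrict_to_middle,
    run_lengths,
    segment_fixations,
    summarize_fixations,
)
from femdrift.recording import EyeData, GazeRecording


def _recording_from_positions(pos, pupil=None):
    pos = np.asarray(pos, dtype=float)
    n = len(pos)
    pupil = np.full(n, 900.0) if pupil is None else np.asarray(pupil, float)
    eye = EyeData(x=pos[:, 0], y=pos[:, 1], pupil=pupil)
    return GazeRecording(t=np.arange(n) * 2.0, left=eye)


BURST_STEPS_DEG = (0.1, 0.2, 0.3, 0.2, 0.1)  # ramping: peak 125 deg/s, acc > 1e4 deg/s^2


def _burst_trace(starts, n=200):
    """Stationary trace with accelerating high-velocity bursts at ``starts``."""
    steps = np.zeros(n)
    for start in starts:
        steps[start : start + len(BURST_STEPS_DEG)] = BURST_STEPS_DEG
    x = np.cumsum(steps) * 35.0  # deg -> px
    return np.column_stack([x, np.zeros(n)]), list(starts)


class TestSaccadeDetection:
    def test_static_trace_is_one_fixation(self):
        rec = _recording_from_positions(np.tile([350.0, 280.0], (100, 1)))
        labels = detect_saccades(rec)
        assert labels.events() == [("fixation", 0, 100)]

    def test_single_burst_detected_with_onset_accuracy(self):
        pos, onsets = _burst_trace([80])
        rec = _recording_from_positions(pos)
        labels = detect_saccades(rec)
        saccades = labels.events_of("saccade")
        assert len(saccades) == 1
        assert abs(saccades[0][0] - onsets[0]) <= 1

    def test_crossings_within_continuation_window_merge(self):
        # two bursts separated by 5 samples (10 ms < 20 ms window)
        pos, _ = _burst_trace([80, 90])
        rec = _recording_from_positions(pos)
        assert len(detect_saccades(rec).events_of("saccade")) == 1

    def test_crossings_beyond_window_stay_separate(self):
        # separated by 15 samples (30 ms > 20 ms window)
        pos, _ = _burst_trace([80, 100], n=250)
        rec = _recording_from_positions(pos)
        assert len(detect_saccades(rec).events_of("saccade")) == 2

    def test_subthreshold_velocity_not_a_saccade(self):
        # 10 deg/s drift: below the 30 deg/s criterion
        pos = np.column_stack([np.arange(100) * 0.02 * 35.0 / 10, np.zeros(100)])
        rec = _recording_from_positions(pos)
        assert detect_saccades(rec).events_of("saccade") == []

    def test_too_short_recording_raises(self):
        rec = _recording_from_positions([[0.0, 0.0], [0.0, 0.0]])
        with pytest.raises(TooShortError):
            detect_saccades(rec)


class TestBlinkDetection:
    def _blinky_recording(self, loss_runs, n=300):
        pupil = np.full(n, 900.0)
        for s, e in loss_runs:
            pupil[s:e] = 0.0
        return _recording_from_positions(np.tile([350.0, 280.0], (n, 1)), pupil)

    def test_no_pupil_loss_no_blinks(self):
        rec = self._blinky_recording([])
        labels = detect_blinks(rec, labels=detect_saccades(rec))
        assert labels.events_of("blink") == []

    def test_nearby_losses_merge_into_one_blink(self):
        # two losses separated by 40 samples = 80 ms < 100 ms
        rec = self._blinky_recording([(50, 60), (100, 110)])
        labels = detect_blinks(rec, labels=detect_saccades(rec))
        blinks = labels.events_of("blink")
        assert len(blinks) == 1
        assert blinks[0] == (50, 110)

    def test_distant_losses_stay_separate(self):
        # separated by 120 samples = 240 ms
        rec = self._blinky_recording([(30, 40), (160, 170)])
        labels = detect_blinks(rec, labels=detect_saccades(rec))
        assert len(labels.events_of("blink")) == 2

    def test_post_blink_window_discarded(self):
        rec = self._blinky_recording([(50, 60)])
        labels = detect_blinks(rec, labels=detect_saccades(rec))
        # 50 ms = 25 samples after the blink end
        assert (labels.labels[60:85] == DISCARDED).all()
        assert (labels.labels[85:] == FIXATION).all()

    def test_flanking_saccade_absorbed_into_blink(self):
        lab = np.full(100, FIXATION, np.int8)
        lab[40:45] = SACCADE
        pupil = np.full(100, 900.0)
        pupil[45:55] = 0.0
        rec = _recording_from_positions(np.tile([0.0, 0.0], (100, 1)), pupil)
        labels = detect_blinks(rec, labels=EventLabels(lab))
        assert (labels.labels[40:55] == BLINK).all()


class TestSegmentation:
    def _labels(self, spans):
        n = max(e for _, e in spans.values()) if spans else 0
        lab = np.full(n, FIXATION, np.int8)
        return lab

    def test_trim_removes_exactly_10ms(self):
        lab = np.full(50, FIXATION, np.int8)  # 100 ms run
        segs = segment_fixations(EventLabels(lab), min_duration_ms=50.0)
        assert len(segs) == 1
        assert segs[0].duration_ms == 90.0
        assert segs[0].start == 3 and segs[0].end == 48

    def test_run_shorter_than_trim_total_dropped(self):
        lab = np.full(4, FIXATION, np.int8)  # 8 ms run < 10 ms trim
        assert segment_fixations(EventLabels(lab), min_duration_ms=0.0) == []

    def test_alternating_runs_counted_by_run_length_encoding(self):
        k = 5
        pieces = []
        for _ in range(k):
            pieces += [np.full(40, FIXATION, np.int8), np.full(6, SACCADE, np.int8)]
        pieces.append(np.full(40, FIXATION, np.int8))
        lab = np.concatenate(pieces)
        fix_runs = [r for r in run_lengths(lab) if r[0] == FIXATION]
        assert len(fix_runs) == k + 1
        segs = segment_fixations(EventLabels(lab), min_duration_ms=50.0)
        assert len(segs) == k + 1

    def test_min_duration_filter_is_monotone(self):
        rng = np.random.default_rng(0)
        lab = np.concatenate(
            [np.full(int(n), v, np.int8)
             for n, v in zip(rng.integers(5, 80, 40), [FIXATION, SACCADE] * 20)]
        )
        counts = [
            len(segment_fixations(EventLabels(lab), min_duration_ms=d))
            for d in (0.0, 30.0, 60.0, 100.0)
        ]
        assert counts == sorted(counts, reverse=True)

    def test_middle_window_restriction(self):
        seg = FixationSegment(start=100, end=145)  # 90 ms
        mid = restrict_to_middle(seg, window_ms=50.0)
        assert (mid.start, mid.end) == (110, 135)
        exact = FixationSegment(start=0, end=25)  # 50 ms
        assert restrict_to_middle(exact) == exact
        short = FixationSegment(start=0, end=20)  # 40 ms
        assert restrict_to_middle(short) is None


class TestSummaries:
    def test_mean_and_median_of_known_durations(self):
        segs = [FixationSegment(start=0, end=50),
                FixationSegment(start=60, end=160),
                FixationSegment(start=170, end=320)]
        s = summarize_fixations(segs)  # durations 100, 200, 300 ms
        assert s.mean_duration_ms == 200.0
        assert s.median_duration_ms == 200.0
        assert s.count == 3

    def test_single_segment(self):
        s = summarize_fixations([FixationSegment(start=0, end=70)])
        assert s.mean_duration_ms == s.median_duration_ms == 140.0

    def test_empty_input_raises(self):
        with pytest.raises(InsufficientDataError):
            summarize_fixations([])


@settings(max_examples=50, deadline=None, derandomize=True)
@given(st.lists(st.integers(min_value=0, max_value=3), min_size=1, max_size=200))
def test_event_list_reconstructs_labels_exactly(codes):
    """Events partition all samples: run-length encoding is a bijection."""
    lab = np.array(codes, dtype=np.int8)
    rebuilt = np.empty_like(lab)
    events = EventLabels(lab).events()
    total = 0
    name_to_code = {"fixation": 0, "saccade": 1, "blink": 2, "discarded": 3}
    for kind, s, e in events:
        assert e > s
        rebuilt[s:e] = name_to_code[kind]
        total += e - s
    assert total == len(lab)
    assert (rebuilt == lab).all()


class TestParserOnSyntheticTruth:
    def test_saccade_recall_and_onset_error(self, clean_parsed):
        rec, truth, labels, _ = clean_parsed
        detected = labels.events_of("saccade")
        hits = sum(
            any(abs(ds - s) <= 2 for ds, _ in detected)
            for s, _ in truth.saccade_events()
        )
        assert hits / len(truth.saccade_events()) >= 0.95

    def test_fixation_count_matches_script(self, clean_parsed):
        rec, truth, _, segments = clean_parsed
        assert abs(len(segments) - len(truth.fixation_events())) <= 1

    def test_recovered_durations_match_schedule(self, clean_parsed):
        """Each parsed segment is its scripted fixation minus the 10 ms trim."""
        rec, truth, _, segments = clean_parsed
        true_durs = sorted((e - s) * 2.0 for s, e in truth.fixation_events())
        got_durs = sorted(seg.duration_ms + 10.0 for seg in segments)
        assert np.allclose(true_durs, got_durs, atol=8.0)

    def test_blink_handling_preserves_fixation_count(self, blinky_recording):
        rec, truth = blinky_recording
        labels = label_events(rec)
        segs = segment_fixations(labels, dt_ms=rec.dt_ms)
        assert abs(len(segs) - len(truth.fixation_events())) <= 1
        assert len(labels.events_of("blink")) == sum(
            1 for k, _, _ in truth.events if k == "blink"
        )
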