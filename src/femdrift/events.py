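"""Event labeling: saccades, blinks, and trimmed fixation segments.

Saccades are detected by joint velocity/acceleration thresholding
(default 30 deg/s and 8000 deg/s^2): a saccade starts when both criteria
hold for more than two sampling periods (>= 3 consecutive samples) and
continues as long as the criteria recur within a 20 ms window. Blinks
are runs of pupil loss; spurious saccades flanking a blink are absorbed
into it, the 50 ms after each blink is discarded, and blinks closer than
100 ms are merged. Fixations are the remaining runs, trimmed by 6 ms at
the start (saccade overshoot) and 4 ms at the end (saccade onset).
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .errors import InsufficientDataError, TooShortError
from .recording import GazeRecording

FIXATION, SACCADE, BLINK, DISCARDED = 0, 1, 2, 3
LABEL_NAMES = {FIXATION: "fixation", SACCADE: "saccade", BLINK: "blink", DISCARDED: "discarded"}


def run_lengths(values: np.ndarray) -> list[tuple[int, int, int]]:
    """Run-length encode an integer array as (value, start, end) half-open."""
    values = np.asarray(values)
    if values.size == 0:
        return []
    change = np.nonzero(np.diff(values))[0] + 1
    starts = np.concatenate([[0], change])
    ends = np.concatenate([change, [values.size]])
    return [(int(values[s]), int(s), int(e)) for s, e in zip(starts, ends)]


@dataclass
class EventLabels:
    """Per-sample labels plus the derived non-overlapping event list."""

    labels: np.ndarray  # int codes, one per sample

    def events(self) -> list[tuple[str, int, int]]:
        """Sorted, non-overlapping (kind, start, end) events covering all samples."""
        return [(LABEL_NAMES[v], s, e) for v, s, e in run_lengths(self.labels)]

    def events_of(self, kind: str) -> list[tuple[int, int]]:
        return [(s, e) for k, s, e in self.events() if k == kind]

    def copy(self) -> "EventLabels":
        return EventLabels(self.labels.copy())

    def __len__(self) -> int:
        return len(self.labels)


@dataclass(frozen=True)
class FixationSegment:
    """A trimmed drift trajectory: sample range [start, end) of one eye."""

    start: int
    end: int
    eye: str = "left"
    trimmed: bool = True
    dt_ms: float = 2.0

    def __post_init__(self):
        if self.end <= self.start:
            raise TooShortError("fixation segment must contain samples")

    @property
    def n_samples(self) -> int:
        return self.end - self.start

    @property
    def duration_ms(self) -> float:
        return self.n_samples * self.dt_ms

    def positions(self, rec: GazeRecording) -> np.ndarray:
        return rec.eye(self.eye).positions[self.start : self.end]


def velocity_deg(rec: GazeRecording, eye: str = "left") -> np.ndarray:
    """Gaze speed in deg/s from two-point central differences (one-sided at ends)."""
    pos = rec.geometry.px_to_degrees(rec.eye(eye).positions)
    v = np.gradient(pos, rec.dt_ms / 1000.0, axis=0)
    return np.hypot(v[:, 0], v[:, 1])


def acceleration_deg(rec: GazeRecording, eye: str = "left") -> np.ndarray:
    """Gaze acceleration magnitude in deg/s^2 (central difference of velocity)."""
    pos = rec.geometry.px_to_degrees(rec.eye(eye).positions)
    dt = rec.dt_ms / 1000.0
    v = np.gradient(pos, dt, axis=0)
    a = np.gradient(v, dt, axis=0)
    return np.hypot(a[:, 0], a[:, 1])


def detect_saccades(
    rec: GazeRecording,
    eye: str = "left",
    vel_thresh: float = 30.0,
    acc_thresh: float = 8000.0,
    min_consecutive: int = 2,
    continuation_window_ms: float = 20.0,
) -> EventLabels:
    """Label saccades by joint velocity/acceleration thresholding.

    A saccade starts when both thresholds are exceeded for strictly more
    than ``min_consecutive`` sampling periods and extends whenever the
    criteria recur within ``continuation_window_ms``. All other valid
    samples are labeled fixation; invalid samples are labeled discarded
    (blink handling refines them later).
    """
    n = rec.n_samples
    if n < 3:
        raise TooShortError("need at least 3 samples to estimate velocity")
    speed = velocity_deg(rec, eye)
    acc = acceleration_deg(rec, eye)
    crit = (speed > vel_thresh) & (acc > acc_thresh) & rec.eye(eye).valid

    labels = np.full(n, FIXATION, dtype=np.int8)
    labels[~rec.eye(eye).valid] = DISCARDED

    gap_samples = int(round(continuation_window_ms / rec.dt_ms))
    runs = [(s, e) for v, s, e in run_lengths(crit.astype(np.int8)) if v == 1]
    i = 0
    while i < len(runs):
        s, e = runs[i]
        if e - s < min_consecutive + 1:
            i += 1
            continue
        # extend through any criterion recurrence within the window
        j = i + 1
        while j < len(runs) and runs[j][0] - e <= gap_samples:
            e = runs[j][1]
            j += 1
        labels[s:e] = SACCADE
        i = j
    return EventLabels(labels)


def detect_blinks(
    rec: GazeRecording,
    eye: str = "left",
    labels: EventLabels | None = None,
    post_blink_discard_ms: float = 50.0,
    merge_gap_ms: float = 100.0,
) -> EventLabels:
    """Label blinks from pupil loss, refining existing saccade labels.

    Pupil-invalid runs become blinks; blinks separated by less than
    ``merge_gap_ms`` are merged (intervening samples folded into the one
    blink event); saccade labels touching a blink are absorbed into it;
    and ``post_blink_discard_ms`` after each blink is discarded.
    """
    n = rec.n_samples
    out = labels.copy() if labels is not None else EventLabels(np.full(n, FIXATION, np.int8))
    lab = out.labels
    eyedata = rec.eye(eye)
    invalid = ~eyedata.valid

    blink_runs = [(s, e) for v, s, e in run_lengths(invalid.astype(np.int8)) if v == 1]
    if not blink_runs:
        return out

    gap_samples = int(round(merge_gap_ms / rec.dt_ms))
    merged = [list(blink_runs[0])]
    for s, e in blink_runs[1:]:
        if s - merged[-1][1] < gap_samples:
            merged[-1][1] = e
        else:
            merged.append([s, e])

    for s, e in merged:
        lab[s:e] = BLINK

    # absorb spurious saccades immediately flanking each blink
    for s, e in merged:
        i = s
        while i > 0 and lab[i - 1] == SACCADE:
            i -= 1
        lab[i:s] = BLINK
        j = e
        while j < n and lab[j] == SACCADE:
            j += 1
        lab[e:j] = BLINK

    # discard the window after each (possibly extended) blink
    discard = int(round(post_blink_discard_ms / rec.dt_ms))
    for v, s, e in run_lengths(lab):
        if v == BLINK:
            stop = min(n, e + discard)
            sub = lab[e:stop]
            sub[sub != BLINK] = DISCARDED
    return out


def label_events(rec: GazeRecording, eye: str = "left", **kwargs) -> EventLabels:
    """Full event labeling: saccade detection followed by blink handling."""
    sacc_keys = {"vel_thresh", "acc_thresh", "min_consecutive", "continuation_window_ms"}
    blink_keys = {"post_blink_discard_ms", "merge_gap_ms"}
    unknown = set(kwargs) - sacc_keys - blink_keys
    if unknown:
        raise TypeError(f"unknown parameters: {sorted(unknown)}")
    labels = detect_saccades(rec, eye, **{k: v for k, v in kwargs.items() if k in sacc_keys})
    return detect_blinks(rec, eye, labels, **{k: v for k, v in kwargs.items() if k in blink_keys})


def segment_fixations(
    labels: EventLabels,
    trim_start_ms: float = 6.0,
    trim_end_ms: float = 4.0,
    min_duration_ms: float = 50.0,
    dt_ms: float = 2.0,
    eye: str = "left",
) -> list[FixationSegment]:
    """Trim fixation runs and drop those too short after trimming.

    The default ``min_duration_ms`` of 50 ms keeps every surviving
    segment long enough to contribute displacement pairs up to 20 ms
    lags (the model-fitting range).
    """
    trim_start = int(round(trim_start_ms / dt_ms))
    trim_end = int(round(trim_end_ms / dt_ms))
    min_samples = int(np.ceil(min_duration_ms / dt_ms))
    out = []
    for v, s, e in run_lengths(labels.labels):
        if v != FIXATION:
            continue
        s2, e2 = s + trim_start, e - trim_end
        if e2 - s2 >= min_samples and e2 > s2:
            out.append(FixationSegment(start=s2, end=e2, eye=eye, trimmed=True, dt_ms=dt_ms))
    return out


@dataclass(frozen=True)
class FixationSummary:
    count: int
    rate_per_s: float
    mean_duration_ms: float
    median_duration_ms: float


def summarize_fixations(
    segments: list[FixationSegment], total_time_s: float | None = None
) -> FixationSummary:
    """Count and duration summaries over fixation segments."""
    if not segments:
        raise InsufficientDataError("no fixation segments to summarize")
    durations = np.array([s.duration_ms for s in segments])
    if total_time_s is None:
        total_time_s = durations.sum() / 1000.0
    return FixationSummary(
        count=len(segments),
        rate_per_s=len(segments) / total_time_s if total_time_s > 0 else float("nan"),
        mean_duration_ms=float(durations.mean()),
        median_duration_ms=float(np.median(durations)),
    )


def restrict_to_middle(fix: FixationSegment, window_ms: float = 50.0) -> FixationSegment | None:
    """Centered sub-segment of exactly ``window_ms``; None if too short.

    Used to test that drift scaling is not an artifact of residual
    muscle tension near the flanking saccades.
    """
    win = int(round(window_ms / fix.dt_ms))
    n = fix.n_samples
    if n < win:
        return None
    if n == win:
        return fix
    cut = (n - win) // 2
    return replace(fix, start=fix.start + cut, end=fix.start + cut + win)
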