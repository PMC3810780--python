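"""Fixation-level descriptive statistics: drift directions and pupil CV."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import ParameterError
from .events import EventLabels, FixationSegment
from .recording import GazeRecording


def wrap_angle(theta):
    """Wrap angles to (-pi, pi]."""
    out = np.mod(np.asarray(theta, dtype=float) + np.pi, 2 * np.pi) - np.pi
    out = np.where(out == -np.pi, np.pi, out)
    return out


@dataclass
class DriftDirectionStats:
    """Per-fixation drift angles and offsets to neighboring saccades."""

    table: pd.DataFrame       # theta, dtheta_prev, dtheta_next per fixation
    n_zero_excluded: int      # fixations with zero net displacement

    def histogram(self, column: str, bins: int = 36) -> tuple[np.ndarray, np.ndarray]:
        vals = self.table[column].dropna().to_numpy()
        return np.histogram(vals, bins=bins, range=(-np.pi, np.pi))


def _saccade_direction(rec: GazeRecording, eye: str, start: int, end: int) -> float:
    pos = rec.eye(eye).positions
    d = pos[end - 1] - pos[start]
    if np.hypot(*d) == 0:
        return np.nan
    return float(np.arctan2(d[1], d[0]))


def drift_direction_stats(
    segments: list[FixationSegment],
    rec: GazeRecording,
    labels: EventLabels,
    eye: str = "left",
) -> DriftDirectionStats:
    """Absolute drift angles and differences to neighboring saccade angles.

    The drift angle of a fixation is the direction of the vector joining
    its first and last points, in the screen frame (theta = 0, +-pi
    horizontal; +-pi/2 vertical). dtheta_prev / dtheta_next are the
    wrapped differences to the direction of the previous / next saccade.
    Fixations with zero net displacement have no angle and are excluded
    (their count is reported).
    """
    saccades = labels.events_of("saccade")
    sacc_dirs = [_saccade_direction(rec, eye, s, e) for s, e in saccades]
    sacc_starts = np.array([s for s, _ in saccades], dtype=int)

    rows = []
    n_zero = 0
    pos = rec.eye(eye).positions
    for seg in segments:
        d = pos[seg.end - 1] - pos[seg.start]
        if np.hypot(*d) == 0:
            n_zero += 1
            continue
        theta = float(np.arctan2(d[1], d[0]))
        prev_dir = next_dir = np.nan
        if sacc_starts.size:
            before = np.nonzero(sacc_starts < seg.start)[0]
            after = np.nonzero(sacc_starts >= seg.end)[0]
            if before.size:
                prev_dir = sacc_dirs[before[-1]]
            if after.size:
                next_dir = sacc_dirs[after[0]]
        rows.append(
            {
                "theta": theta,
                "dtheta_prev": float(wrap_angle(theta - prev_dir)) if np.isfinite(prev_dir) else np.nan,
                "dtheta_next": float(wrap_angle(theta - next_dir)) if np.isfinite(next_dir) else np.nan,
            }
        )
    table = pd.DataFrame(rows, columns=["theta", "dtheta_prev", "dtheta_next"])
    return DriftDirectionStats(table=table, n_zero_excluded=n_zero)


def pupil_cv(fix: FixationSegment, rec: GazeRecording, eye: str = "left") -> float:
    """Coefficient of variation (sample SD / mean) of pupil area in a fixation."""
    p = rec.eye(eye).pupil[fix.start : fix.end]
    mean = float(np.mean(p))
    if mean <= 0:
        raise ParameterError("pupil CV undefined: nonpositive mean pupil area")
    if len(p) < 2:
        return 0.0
    return float(np.std(p, ddof=1) / mean)
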