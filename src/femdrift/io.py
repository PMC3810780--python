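"""Reading and writing the canonical delimited-text gaze dialect.

The canonical dialect is a comma-separated table with a mandatory header
row. Columns ``time_ms, x_left_px, y_left_px, pupil_left`` are required;
``x_right_px, y_right_px, pupil_right`` are optional (their absence marks
a monocular recording). Floats are written in shortest round-tripping
form, so ``write_gaze_table(read_gaze_table(f))`` reproduces a canonical
file bit-for-bit.

An adapter for EyeLink-ASC-style sample lines (``time x y pupil``,
whitespace separated, no header) is provided via ``format_spec="asc"``.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import FormatError
from .recording import EyeData, GazeRecording, ScreenGeometry

MANDATORY_COLUMNS = ["time_ms", "x_left_px", "y_left_px", "pupil_left"]
RIGHT_COLUMNS = ["x_right_px", "y_right_px", "pupil_right"]


def _infer_rate(t: np.ndarray) -> float:
    dt = float(np.median(np.diff(t)))
    if dt <= 0:
        raise FormatError("timestamps are not increasing")
    return 1000.0 / dt


def read_gaze_table(
    path,
    format_spec: str = "canonical",
    sampling_rate: float | None = None,
    geometry: ScreenGeometry | None = None,
) -> GazeRecording:
    """Read a delimited-text gaze table into a :class:`GazeRecording`.

    Parameters
    ----------
    format_spec
        ``"canonical"`` (CSV with header), ``"tsv"`` (tab separated,
        same columns), or ``"asc"`` (EyeLink-ASC-style monocular sample
        lines ``time x y pupil``).
    sampling_rate
        Declared sampling rate in Hz; inferred from the median timestamp
        spacing when omitted. Non-uniform timestamps raise
        :class:`~femdrift.errors.SamplingError` naming the first bad index.
    """
    path = Path(path)
    if format_spec == "asc":
        df = pd.read_csv(
            path, sep=r"\s+", header=None,
            names=["time_ms", "x_left_px", "y_left_px", "pupil_left"],
        )
    elif format_spec in ("canonical", "csv", "tsv"):
        sep = "\t" if format_spec == "tsv" else ","
        df = pd.read_csv(path, sep=sep)
    else:
        raise FormatError(f"unknown format_spec {format_spec!r}")

    missing = [c for c in MANDATORY_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"missing mandatory column(s): {', '.join(missing)}")

    t = df["time_ms"].to_numpy(dtype=float)
    rate = sampling_rate if sampling_rate is not None else _infer_rate(t)
    left = EyeData(
        x=df["x_left_px"].to_numpy(dtype=float),
        y=df["y_left_px"].to_numpy(dtype=float),
        pupil=df["pupil_left"].to_numpy(dtype=float),
    )
    right = None
    if all(c in df.columns for c in RIGHT_COLUMNS):
        right = EyeData(
            x=df["x_right_px"].to_numpy(dtype=float),
            y=df["y_right_px"].to_numpy(dtype=float),
            pupil=df["pupil_right"].to_numpy(dtype=float),
        )
    return GazeRecording(
        t=t, left=left, right=right, sampling_rate=rate,
        geometry=geometry or ScreenGeometry(),
    )


def write_gaze_table(rec: GazeRecording, path, format_spec: str = "canonical") -> None:
    """Write a recording in the canonical dialect (lossless round trip)."""
    data = {
        "time_ms": rec.t,
        "x_left_px": rec.left.x,
        "y_left_px": rec.left.y,
        "pupil_left": rec.left.pupil,
    }
    if rec.right is not None:
        data["x_right_px"] = rec.right.x
        data["y_right_px"] = rec.right.y
        data["pupil_right"] = rec.right.pupil
    sep = "\t" if format_spec == "tsv" else ","
    pd.DataFrame(data).to_csv(path, sep=sep, index=False, lineterminator="\n")


def write_events_csv(labels, rec: GazeRecording, path) -> None:
    """Write labeled events as CSV (kind, start_ms, end_ms)."""
    rows = [
        {"kind": kind, "start_ms": rec.t[s], "end_ms": rec.t[e - 1] + rec.dt_ms}
        for kind, s, e in labels.events()
    ]
    pd.DataFrame(rows, columns=["kind", "start_ms", "end_ms"]).to_csv(
        path, index=False, lineterminator="\n"
    )


def write_segments_csv(segments, rec: GazeRecording, path) -> None:
    """Write fixation segments as CSV."""
    rows = [
        {
            "eye": seg.eye,
            "start_index": seg.start,
            "end_index": seg.end,
            "start_ms": rec.t[seg.start],
            "duration_ms": seg.duration_ms,
            "trimmed": seg.trimmed,
        }
        for seg in segments
    ]
    pd.DataFrame(
        rows,
        columns=["eye", "start_index", "end_index", "start_ms", "duration_ms", "trimmed"],
    ).to_csv(path, index=False, lineterminator="\n")


def write_curve_csv(curve, path, subject: str = "") -> None:
    """Write a displacement or scaling curve as tidy CSV."""
    df = curve.to_frame()
    if subject:
        df.insert(0, "subject", subject)
    df.to_csv(path, index=False, lineterminator="\n")


def write_json(obj, path) -> None:
    Path(path).write_text(json.dumps(obj, indent=2, sort_keys=True) + "\n")


def read_json(path):
    return json.loads(Path(path).read_text())
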