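"""Core containers for binocular gaze recordings.

A recording is a uniformly sampled time series of gaze position (screen
pixels, origin top-left, y increasing downward) and pupil area for one or
two eyes, together with the screen geometry needed to convert pixels to
degrees of visual angle. Sample indices are 0-based and ranges half-open.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import ParameterError, SamplingError


@dataclass(frozen=True)
class ScreenGeometry:
    """Screen geometry of the recording setup.

    Parameters
    ----------
    px_per_degree
        Conversion factor between screen pixels and degrees of visual
        angle (px/deg). Must be positive.
    video_extent_deg
        (horizontal, vertical) extent of the stimulus in degrees.
    """

    px_per_degree: float = 35.0
    video_extent_deg: tuple[float, float] = (20.0, 16.0)

    def __post_init__(self):
        if not self.px_per_degree > 0:
            raise ParameterError("px_per_degree must be positive")

    def px_to_degrees(self, v):
        """Convert pixels to degrees of visual angle."""
        return np.asarray(v, dtype=float) / self.px_per_degree

    def degrees_to_px(self, v):
        """Convert degrees of visual angle to pixels."""
        return np.asarray(v, dtype=float) * self.px_per_degree

    @property
    def video_extent_px(self) -> tuple[float, float]:
        w, h = self.video_extent_deg
        return (w * self.px_per_degree, h * self.px_per_degree)


def px_to_degrees(v, geometry: ScreenGeometry):
    """Convert pixels to degrees for the given geometry."""
    return geometry.px_to_degrees(v)


def degrees_to_px(v, geometry: ScreenGeometry):
    """Convert degrees to pixels for the given geometry."""
    return geometry.degrees_to_px(v)


@dataclass
class EyeData:
    """Per-eye channels: gaze position (px), pupil area, validity flags."""

    x: np.ndarray
    y: np.ndarray
    pupil: np.ndarray
    valid: np.ndarray = None

    def __post_init__(self):
        self.x = np.asarray(self.x, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        self.pupil = np.asarray(self.pupil, dtype=float)
        n = len(self.x)
        if not (len(self.y) == len(self.pupil) == n):
            raise ParameterError("per-eye channels must have equal length")
        if self.valid is None:
            self.valid = (
                np.isfinite(self.x) & np.isfinite(self.y) & (self.pupil > 0)
            )
        else:
            self.valid = np.asarray(self.valid, dtype=bool)
            if len(self.valid) != n:
                raise ParameterError("valid mask length mismatch")

    def __len__(self) -> int:
        return len(self.x)

    @property
    def positions(self) -> np.ndarray:
        """(n, 2) array of gaze positions in px."""
        return np.column_stack([self.x, self.y])


@dataclass
class GazeRecording:
    """A uniformly sampled gaze/pupil recording for one or two eyes.

    ``t`` is in milliseconds and must be strictly increasing with spacing
    ``1000 / sampling_rate`` (2 ms at the 500 Hz default).
    """

    t: np.ndarray
    left: EyeData
    right: EyeData | None = None
    sampling_rate: float = 500.0
    geometry: ScreenGeometry = field(default_factory=ScreenGeometry)
    timestamp_tol_ms: float = 0.01

    def __post_init__(self):
        self.t = np.asarray(self.t, dtype=float)
        n = len(self.t)
        if len(self.left) != n:
            raise ParameterError("left-eye channels must match timestamps")
        if self.right is not None and len(self.right) != n:
            raise ParameterError("right-eye channels must match timestamps")
        dt = 1000.0 / self.sampling_rate
        diffs = np.diff(self.t)
        bad = np.nonzero(np.abs(diffs - dt) > self.timestamp_tol_ms)[0]
        if bad.size:
            i = int(bad[0]) + 1
            raise SamplingError(
                f"non-uniform timestamp at index {i}: spacing "
                f"{diffs[bad[0]]:g} ms, expected {dt:g} ms",
                index=i,
            )

    @property
    def n_samples(self) -> int:
        return len(self.t)

    @property
    def dt_ms(self) -> float:
        return 1000.0 / self.sampling_rate

    @property
    def binocular(self) -> bool:
        return self.right is not None

    @property
    def monocular(self) -> bool:
        return self.right is None

    def eye(self, which: str = "left") -> EyeData:
        if which == "left":
            return self.left
        if which == "right":
            if self.right is None:
                raise ParameterError("recording has no right-eye data")
            return self.right
        raise ParameterError(f"unknown eye {which!r}")

    @property
    def duration_ms(self) -> float:
        return self.n_samples * self.dt_ms
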