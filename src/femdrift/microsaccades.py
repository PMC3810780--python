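"""Binocular microsaccade detection with surrogate-corrected excess rate.

Detection follows the velocity-threshold method of Engbert and
colleagues: per eye and per fixation, velocities are estimated with a
5-sample moving-window difference, a median-based SD estimate sets an
elliptic threshold (multiplier ``lam``), and candidate events must
exceed it for a minimum duration. Only binocular events (temporal
overlap in both eyes) are kept, and events within a 30 ms interval
centered on normal saccades are discarded as overshoots.

Because threshold detectors fire on noise, the detected rate is
corrected by the rate measured on amplitude-adjusted Fourier-transform
surrogates of the per-fixation velocity components, which preserve the
velocity distributions but destroy the temporal phase structure that
real microsaccades require. The excess of the data rate over the mean
surrogate rate estimates the true rate.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import ParameterError, TooShortError
from .events import EventLabels, FIXATION
from .events import run_lengths
from .recording import EyeData, GazeRecording
from .surrogates import aaft_surrogate


@dataclass(frozen=True)
class MicrosaccadeEvent:
    """A binocular microsaccade: [start, end) sample indices."""

    start: int
    end: int
    peak_velocity_dps: float
    amplitude_deg: float
    eyes: str = "both"

    def __post_init__(self):
        if self.end <= self.start:
            raise ParameterError("event must span at least one sample")


def moving_window_velocity(pos: np.ndarray, dt_s: float) -> np.ndarray:
    """5-sample moving-window velocity estimate, per component.

    v_i = (x_{i+2} + x_{i+1} - x_{i-1} - x_{i-2}) / (6 dt); the two
    samples at each end are set to zero (undefined by the stencil).
    """
    n = len(pos)
    v = np.zeros_like(pos, dtype=float)
    if n >= 5:
        v[2:-2] = (pos[4:] + pos[3:-1] - pos[1:-3] - pos[:-4]) / (6.0 * dt_s)
    return v


def _median_sd(v: np.ndarray) -> float:
    med = np.median(v)
    sd2 = np.median(v**2) - med**2
    return float(np.sqrt(max(sd2, 1e-12)))


def _detect_monocular(
    v: np.ndarray, lam: float, min_samples: int, sx: float, sy: float
) -> list[tuple[int, int, float]]:
    """Candidate events in one eye's (n, 2) velocity series (deg/s)."""
    test = (v[:, 0] / (lam * sx)) ** 2 + (v[:, 1] / (lam * sy)) ** 2 > 1.0
    out = []
    for val, s, e in run_lengths(test.astype(np.int8)):
        if val == 1 and e - s >= min_samples:
            peak = float(np.max(np.hypot(v[s:e, 0], v[s:e, 1])))
            out.append((s, e, peak))
    return out


def detect_microsaccades(
    rec: GazeRecording,
    labels: EventLabels,
    lam: float = 5.0,
    min_duration_ms: float = 6.0,
    saccade_exclusion_ms: float = 30.0,
    min_fixation_samples: int = 12,
) -> list[MicrosaccadeEvent]:
    """Binocular microsaccades within the fixation-labeled spans.

    Raises if the recording is monocular: monocular excursions cannot be
    distinguished from tracker noise by this method.
    """
    if rec.monocular:
        raise ParameterError("microsaccade detection requires a binocular recording")
    dt_s = rec.dt_ms / 1000.0
    min_samples = max(1, int(round(min_duration_ms / rec.dt_ms)))
    half_excl = int(round(saccade_exclusion_ms / 2.0 / rec.dt_ms))
    saccades = labels.events_of("saccade")
    spans = [
        (s, e)
        for val, s, e in run_lengths(labels.labels)
        if val == FIXATION and e - s >= min_fixation_samples
    ]

    # per-eye velocities per span; threshold SDs pooled over the whole
    # recording's fixation samples (robust to single near-straight drifts)
    velocities: dict[str, dict[tuple[int, int], np.ndarray]] = {}
    thresholds: dict[str, tuple[float, float]] = {}
    for eye in ("left", "right"):
        velocities[eye] = {}
        interior = []
        for s, e in spans:
            pos = rec.geometry.px_to_degrees(rec.eye(eye).positions[s:e])
            v = moving_window_velocity(pos, dt_s)
            velocities[eye][(s, e)] = v
            if e - s > 4:
                interior.append(v[2:-2])
        pooled = np.vstack(interior) if interior else np.zeros((1, 2))
        thresholds[eye] = (_median_sd(pooled[:, 0]), _median_sd(pooled[:, 1]))

    events: list[MicrosaccadeEvent] = []
    for s, e in spans:
        per_eye = []
        for eye in ("left", "right"):
            sx, sy = thresholds[eye]
            per_eye.append(
                _detect_monocular(velocities[eye][(s, e)], lam, min_samples, sx, sy)
            )
        # binocular: left/right candidates overlapping in time
        for ls, le, lpeak in per_eye[0]:
            for rs, re, rpeak in per_eye[1]:
                lo, hi = max(ls, rs), min(le, re)
                if hi <= lo:
                    continue
                gs, ge = s + lo, s + hi
                if any(gs < se + half_excl and ge > ss - half_excl for ss, se in saccades):
                    break
                disp = (
                    rec.eye("left").positions[ge - 1]
                    - rec.eye("left").positions[gs]
                )
                amp = float(np.hypot(*rec.geometry.px_to_degrees(disp)))
                events.append(
                    MicrosaccadeEvent(
                        start=gs, end=ge,
                        peak_velocity_dps=max(lpeak, rpeak),
                        amplitude_deg=amp,
                    )
                )
                break
    return events


def _fixation_spans(labels: EventLabels, min_samples: int) -> list[tuple[int, int]]:
    return [
        (s, e)
        for val, s, e in run_lengths(labels.labels)
        if val == FIXATION and e - s >= min_samples
    ]


def _aaft_recording(rec: GazeRecording, labels: EventLabels, rng, min_samples: int) -> GazeRecording:
    """Copy of ``rec`` with per-fixation, per-eye, per-component AAFT steps.

    Each fixation's step (velocity) series is AAFT-surrogated per
    component and reintegrated from the fixation's first sample, so the
    within-fixation velocity distributions are preserved exactly.
    """
    eyes = {}
    for name in ("left", "right"):
        src = rec.eye(name)
        x, y = src.x.copy(), src.y.copy()
        for s, e in _fixation_spans(labels, min_samples):
            for arr in (x, y):
                steps = np.diff(arr[s:e])
                if len(steps) < 8:
                    continue
                arr[s + 1 : e] = arr[s] + np.cumsum(aaft_surrogate(steps, rng))
        eyes[name] = EyeData(x=x, y=y, pupil=src.pupil.copy(), valid=src.valid.copy())
    return GazeRecording(
        t=rec.t, left=eyes["left"], right=eyes["right"],
        sampling_rate=rec.sampling_rate, geometry=rec.geometry,
    )


@dataclass
class ExcessRateResult:
    data_rate: float            # detected events per second of fixation
    surrogate_mean: float
    surrogate_sd: float
    surrogate_rates: list[float]

    @property
    def excess(self) -> float:
        return self.data_rate - self.surrogate_mean

    def to_dict(self) -> dict:
        return {
            "data_rate_per_s": self.data_rate,
            "surrogate_mean_per_s": self.surrogate_mean,
            "surrogate_sd_per_s": self.surrogate_sd,
            "excess_rate_per_s": self.excess,
            "n_surrogates": len(self.surrogate_rates),
        }


def excess_rate(
    rec: GazeRecording,
    labels: EventLabels,
    n_surrogates: int = 10,
    seed=0,
    surrogate_method: str = "aaft",
    **detect_kwargs,
) -> ExcessRateResult:
    """Surrogate-corrected microsaccade rate (events / s of fixation).

    ``surrogate_method="identity"`` uses the data as its own surrogate
    (excess is then exactly zero; a consistency control).
    """
    if surrogate_method not in ("aaft", "identity"):
        raise ParameterError(f"unknown surrogate_method {surrogate_method!r}")
    min_fix = detect_kwargs.get("min_fixation_samples", 12)
    spans = _fixation_spans(labels, min_fix)
    total_s = sum(e - s for s, e in spans) * rec.dt_ms / 1000.0
    if total_s <= 0:
        raise TooShortError("no fixation time to analyze")
    data_rate = len(detect_microsaccades(rec, labels, **detect_kwargs)) / total_s
    ss = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    rates = []
    for child in ss.spawn(n_surrogates):
        rng = np.random.default_rng(child)
        surr = rec if surrogate_method == "identity" else _aaft_recording(rec, labels, rng, min_fix)
        rates.append(len(detect_microsaccades(surr, labels, **detect_kwargs)) / total_s)
    mean = float(np.mean(rates)) if rates else 0.0
    sd = float(np.std(rates, ddof=1)) if len(rates) > 1 else 0.0
    return ExcessRateResult(
        data_rate=float(data_rate), surrogate_mean=mean, surrogate_sd=sd,
        surrogate_rates=[float(r) for r in rates],
    )
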