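"""Synthetic eye-tracker recordings with full ground truth.

Emulates the acquisition conditions of a head-mounted video tracker:
500 Hz sampling, ~35 px/degree screen geometry, gaze coordinates
quantized to 0.1 px, fixations of roughly 100-1000 ms (lognormal with
mean ~424 ms and median ~290 ms) separated by saccades that exceed the
30 deg/s and 8000 deg/s^2 parser thresholds, blinks with pupil loss and
spurious flanking velocity artifacts, and optional conjugate
microsaccade injections. Drift within fixations is generated by the
memory-walk model at known (tau, sigma, alpha), scaled to a physical
step size, so every downstream estimate can be checked against the
generating truth.

Saccades use a minimum-jerk position profile x(s) = A (10 s^3 - 15 s^4
+ 6 s^5): peak velocity 1.875 A/T and peak acceleration ~5.77 A/T^2,
with zero velocity at both endpoints.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .errors import GeneratorError, ParameterError, TooShortError
from .io import write_gaze_table
from .model import ModelParams, simulate_walk
from .recording import EyeData, GazeRecording, ScreenGeometry

DT_MS = 2.0
FS = 500.0

# lognormal fixation durations solved from target mean 424 ms / median 290 ms:
# median = e^mu, mean = e^{mu + s^2/2}
FIX_MU = float(np.log(290.0))
FIX_S = float(np.sqrt(2.0 * np.log(424.0 / 290.0)))

MINJERK_PEAK_VEL = 1.875          # x A / T
MINJERK_PEAK_ACC = 5.7735         # x A / T^2  (= 10/sqrt(3))


@dataclass(frozen=True)
class MicrosaccadeInjection:
    onset_ms: float               # offset from fixation start
    amplitude_deg: float = 0.2
    duration_ms: float = 16.0
    direction: float = 0.0        # radians, screen frame


@dataclass(frozen=True)
class FixationPlan:
    duration_ms: float
    drift: ModelParams = field(default_factory=lambda: ModelParams(tau=10))
    step_scale_px: float = 0.1
    microsaccades: tuple = ()

    def __post_init__(self):
        if self.duration_ms < 4.0:
            raise ParameterError("fixation must last at least 4 ms")


@dataclass(frozen=True)
class SaccadePlan:
    amplitude_deg: float
    direction: float              # radians, screen frame
    duration_ms: float

    def __post_init__(self):
        if self.duration_ms < 6.0:
            raise ParameterError("saccade must last at least 6 ms")


@dataclass(frozen=True)
class BlinkPlan:
    duration_ms: float = 120.0


@dataclass
class SceneScript:
    """Ordered, non-overlapping event plan with its own seed."""

    events: list
    seed: int = 0
    geometry: ScreenGeometry = field(default_factory=ScreenGeometry)
    start_px: tuple[float, float] = (350.0, 280.0)
    vergence_offset_px: tuple[float, float] = (2.5, 0.0)
    tracker_noise_px: float = 0.02
    pupil_base: float = 900.0
    pupil_mod_frac: float = 0.004   # slow sinusoidal modulation: CV << 1%
    pupil_period_ms: float = 2000.0
    quantum_px: float = 0.1

    @property
    def n_fixations(self) -> int:
        return sum(isinstance(e, FixationPlan) for e in self.events)

    @property
    def n_saccades(self) -> int:
        return sum(isinstance(e, SaccadePlan) for e in self.events)


def minimum_jerk(amplitude: float, n_samples: int) -> np.ndarray:
    """Minimum-jerk displacement profile over n_samples (excludes start)."""
    s = np.arange(1, n_samples + 1) / n_samples
    return amplitude * (10 * s**3 - 15 * s**4 + 6 * s**5)


def generate_saccade(
    start_px: np.ndarray,
    end_px: np.ndarray,
    duration_ms: float,
    geometry: ScreenGeometry | None = None,
    vel_thresh: float = 30.0,
    acc_thresh: float = 8000.0,
) -> np.ndarray:
    """Minimum-jerk saccade samples from start (exclusive) to end (inclusive).

    Raises :class:`GeneratorError` if the implied peak velocity or
    acceleration does not exceed the parser thresholds — such a saccade
    would be undetectable by design.
    """
    geometry = geometry or ScreenGeometry()
    start_px = np.asarray(start_px, dtype=float)
    end_px = np.asarray(end_px, dtype=float)
    n = int(round(duration_ms / DT_MS))
    if n < 3:
        raise GeneratorError("saccade duration below 6 ms")
    amp_deg = float(np.hypot(*geometry.px_to_degrees(end_px - start_px)))
    t_s = duration_ms / 1000.0
    peak_vel = MINJERK_PEAK_VEL * amp_deg / t_s
    peak_acc = MINJERK_PEAK_ACC * amp_deg / t_s**2
    if peak_vel <= vel_thresh or peak_acc <= acc_thresh:
        raise GeneratorError(
            f"saccade of {amp_deg:.2f} deg in {duration_ms:.0f} ms peaks at "
            f"{peak_vel:.1f} deg/s, {peak_acc:.0f} deg/s^2: below thresholds"
        )
    frac = minimum_jerk(1.0, n)
    return start_px[None, :] + frac[:, None] * (end_px - start_px)[None, :]


def generate_fixation_drift(
    params: ModelParams,
    duration_ms: float,
    step_scale_px: float = 0.1,
    seed=0,
    start_px=(0.0, 0.0),
    grid_size: int = 512,
) -> np.ndarray:
    """Memory-walk drift at 500 Hz: duration/2 samples, steps scaled to px.

    The model's abstract unit step maps to ``step_scale_px`` per 2 ms
    sample (default 0.1 px, i.e. drift speeds far below the saccade
    thresholds).
    """
    if duration_ms < 4.0:
        raise TooShortError("drift must span at least 2 samples")
    n = int(round(duration_ms / DT_MS))
    walk = simulate_walk(params, n - 1, seed=seed, grid_size=grid_size)
    return np.asarray(start_px, dtype=float) + step_scale_px * walk


@dataclass
class SyntheticGroundTruth:
    """Per-sample truth behind a rendered recording."""

    labels: np.ndarray            # 'fixation' | 'saccade' | 'blink' codes as str
    events: list                  # (kind, start_index, end_index)
    drift_params: list            # ModelParams per fixation, in order
    microsaccade_events: list     # (start_index, end_index)
    prequant_left: np.ndarray     # (n, 2) positions before quantization
    script: SceneScript

    def saccade_events(self) -> list[tuple[int, int]]:
        return [(s, e) for k, s, e in self.events if k == "saccade"]

    def fixation_events(self) -> list[tuple[int, int]]:
        return [(s, e) for k, s, e in self.events if k == "fixation"]

    def to_json_dict(self) -> dict:
        return {
            "events": [[k, int(s), int(e)] for k, s, e in self.events],
            "drift_params": [p.to_dict() for p in self.drift_params],
            "microsaccade_events": [[int(s), int(e)] for s, e in self.microsaccade_events],
            "n_samples": int(len(self.labels)),
            "max_quantization_error_px": float(
                np.max(np.abs(self.prequant_left - np.round(self.prequant_left * 10) / 10))
            ) if len(self.prequant_left) else 0.0,
        }


def _quantize(x: np.ndarray, quantum: float) -> np.ndarray:
    return np.round(x / quantum) * quantum


def render_recording(script: SceneScript) -> tuple[GazeRecording, SyntheticGroundTruth]:
    """Render a script into a binocular recording plus its ground truth.

    Blinks hold gaze, zero the pupil, and add brief high-velocity
    artifacts immediately before and after the pupil loss (the spurious
    saccades a video tracker reports around blinks).
    """
    rng = np.random.default_rng(np.random.SeedSequence(script.seed))
    pos_chunks: list[np.ndarray] = []
    label_chunks: list[np.ndarray] = []
    events = []
    drift_params = []
    micro_events = []
    pupil_valid_chunks: list[np.ndarray] = []
    current = np.asarray(script.start_px, dtype=float)
    cursor = 0

    def emit(chunk: np.ndarray, label: str, pupil_ok):
        nonlocal cursor
        n = len(chunk)
        pos_chunks.append(chunk)
        label_chunks.append(np.full(n, label, dtype=object))
        if np.isscalar(pupil_ok):
            pupil_ok = np.full(n, pupil_ok, dtype=bool)
        pupil_valid_chunks.append(np.asarray(pupil_ok, dtype=bool))
        events.append((label, cursor, cursor + n))
        cursor += n

    for ev in script.events:
        if isinstance(ev, FixationPlan):
            n = int(round(ev.duration_ms / DT_MS))
            drift = generate_fixation_drift(
                ev.drift, ev.duration_ms, ev.step_scale_px,
                seed=rng.integers(2**31), start_px=current,
            )[:n]
            for ms in ev.microsaccades:
                i0 = int(round(ms.onset_ms / DT_MS))
                nn = int(round(ms.duration_ms / DT_MS))
                if i0 + nn > n:
                    raise ParameterError("microsaccade injection exceeds fixation")
                amp_px = script.geometry.degrees_to_px(ms.amplitude_deg)
                disp = minimum_jerk(float(amp_px), nn)
                vec = np.array([np.cos(ms.direction), np.sin(ms.direction)])
                drift[i0 : i0 + nn] += disp[:, None] * vec[None, :]
                drift[i0 + nn :] += disp[-1] * vec[None, :]
                micro_events.append((cursor + i0, cursor + i0 + nn))
            emit(drift, "fixation", True)
            drift_params.append(ev.drift)
            current = drift[-1].copy()
        elif isinstance(ev, SaccadePlan):
            amp_px = script.geometry.degrees_to_px(ev.amplitude_deg)
            target = current + amp_px * np.array(
                [np.cos(ev.direction), np.sin(ev.direction)]
            )
            chunk = generate_saccade(current, target, ev.duration_ms, script.geometry)
            emit(chunk, "saccade", True)
            current = target.astype(float)
        elif isinstance(ev, BlinkPlan):
            n = int(round(ev.duration_ms / DT_MS))
            if n < 6:
                raise ParameterError("blink must span at least 12 ms")
            art = 2  # pupil-valid spurious high-velocity samples on each side
            glitch = float(script.geometry.degrees_to_px(2.0))
            pre = current + np.outer([0.5, 1.0], [0.0, glitch])
            post = current + np.outer([1.0, 0.5], [0.0, glitch])
            hold = np.tile(current + [0.0, glitch], (n - 2 * art, 1))
            chunk = np.vstack([pre, hold, post])
            ok = np.r_[np.ones(art, bool), np.zeros(n - 2 * art, bool), np.ones(art, bool)]
            emit(chunk, "blink", ok)
        else:
            raise ParameterError(f"unknown scene event {ev!r}")

    pos = np.vstack(pos_chunks)
    labels = np.concatenate(label_chunks)
    pupil_ok = np.concatenate(pupil_valid_chunks)
    n = len(pos)
    t = np.arange(n) * DT_MS

    def render_eye(offset: np.ndarray) -> tuple[EyeData, np.ndarray]:
        noisy = pos + offset + rng.normal(0.0, script.tracker_noise_px, size=pos.shape)
        q = _quantize(noisy, script.quantum_px)
        pupil = script.pupil_base * (
            1.0 + script.pupil_mod_frac * np.sin(2 * np.pi * t / script.pupil_period_ms)
        ) + rng.normal(0.0, 0.3, size=n)
        pupil = np.where(pupil_ok, pupil, 0.0)
        return EyeData(x=q[:, 0], y=q[:, 1], pupil=pupil), noisy

    left, left_prequant = render_eye(np.zeros(2))
    right, _ = render_eye(np.asarray(script.vergence_offset_px, dtype=float))
    rec = GazeRecording(t=t, left=left, right=right, sampling_rate=FS,
                        geometry=script.geometry)
    truth = SyntheticGroundTruth(
        labels=labels, events=events, drift_params=drift_params,
        microsaccade_events=micro_events, prequant_left=left_prequant, script=script,
    )
    return rec, truth


def saccade_duration_ms(amplitude_deg: float) -> float:
    """Main-sequence-like duration, rounded to the sample grid."""
    dur = min(16.0 + 1.5 * amplitude_deg, 32.0)
    return round(dur / DT_MS) * DT_MS


def make_scene_script(
    n_fixations: int = 20,
    seed: int = 0,
    drift: ModelParams | None = None,
    step_scale_px: float = 0.1,
    blink_every: int = 0,
    microsaccade_rate_per_s: float = 0.0,
    duration_range_ms: tuple[float, float] = (100.0, 1000.0),
    saccade_amplitude_range_deg: tuple[float, float] = (2.0, 6.0),
    geometry: ScreenGeometry | None = None,
) -> SceneScript:
    """Random plan: n fixations separated by saccades, optional blinks.

    Fixation durations are lognormal (median ~290 ms, mean ~424 ms)
    clipped to ``duration_range_ms``; saccade directions alternate
    around the screen center to keep gaze on screen.
    """
    rng = np.random.default_rng(np.random.SeedSequence(entropy=seed, spawn_key=(1,)))
    geometry = geometry or ScreenGeometry()
    drift = drift or ModelParams(tau=10)
    events: list = []
    pos = np.asarray([350.0, 280.0])
    center = np.asarray(geometry.video_extent_px) / 2.0
    blink_pending = False
    for i in range(n_fixations):
        dur = float(np.clip(rng.lognormal(FIX_MU, FIX_S), *duration_range_ms))
        if blink_pending:
            # the 50 ms discarded after a blink must leave a usable fixation
            dur = max(dur, 300.0)
        dur = round(dur / DT_MS) * DT_MS
        micro = ()
        if microsaccade_rate_per_s > 0:
            k = rng.poisson(microsaccade_rate_per_s * dur / 1000.0)
            onsets = np.sort(rng.uniform(30.0, max(31.0, dur - 50.0), size=k))
            # enforce separation so injections never overlap
            kept, last = [], -1e9
            for o in onsets:
                if o - last >= 40.0:
                    kept.append(o)
                    last = o
            micro = tuple(
                MicrosaccadeInjection(
                    onset_ms=float(o), direction=float(rng.uniform(0, 2 * np.pi))
                )
                for o in kept
            )
        events.append(
            FixationPlan(duration_ms=dur, drift=drift,
                         step_scale_px=step_scale_px, microsaccades=micro)
        )
        blink_pending = False
        if blink_every and (i + 1) % blink_every == 0 and i < n_fixations - 1:
            # blink between two fixations, with no saccade at this junction
            # (a saccade adjacent to a blink is folded into the blink by the
            # parser's absorption rule and would be unrecoverable by design)
            events.append(BlinkPlan(duration_ms=float(rng.uniform(120.0, 200.0))))
            blink_pending = True
        elif i < n_fixations - 1:
            amp = float(rng.uniform(*saccade_amplitude_range_deg))
            to_center = np.arctan2(center[1] - pos[1], center[0] - pos[0])
            direction = float(to_center + rng.uniform(-np.pi / 2, np.pi / 2))
            events.append(SaccadePlan(amplitude_deg=amp, direction=direction,
                                      duration_ms=saccade_duration_ms(amp)))
            pos = pos + geometry.degrees_to_px(amp) * np.array(
                [np.cos(direction), np.sin(direction)]
            )
    return SceneScript(events=events, seed=seed, geometry=geometry)


FIXTURE_NAMES = ("clean", "blinky", "microsaccade_rich", "ballistic_drift", "diffusive_drift")


def fixture_script(name: str, seed: int = 0) -> SceneScript:
    """Deterministic small scripts exercising different pipeline aspects.

    The two drift-regime fixtures use a larger drift step (0.3 px per
    sample) so the 0.1 px coordinate quantization stays subdominant in
    short-lag displacements.
    """
    base = dict(n_fixations=12, seed=seed)
    if name == "clean":
        return make_scene_script(**base)
    if name == "blinky":
        return make_scene_script(**base, blink_every=3)
    if name == "microsaccade_rich":
        return make_scene_script(
            n_fixations=16, seed=seed, microsaccade_rate_per_s=1.5,
            duration_range_ms=(300.0, 1000.0),
        )
    if name == "ballistic_drift":
        return make_scene_script(
            **base, drift=ModelParams(tau=10, sigma=1.0, alpha=100.0),
            step_scale_px=0.3,
        )
    if name == "diffusive_drift":
        return make_scene_script(
            **base, drift=ModelParams(tau=0), step_scale_px=0.3,
        )
    raise ParameterError(f"unknown fixture {name!r}; choose from {FIXTURE_NAMES}")


def make_fixture_suite(out_dir, seed: int = 0, names=FIXTURE_NAMES) -> dict:
    """Write the deterministic fixture recordings + ground-truth sidecars."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = {"seed": int(seed), "fixtures": {}}
    for name in names:
        rec, truth = render_recording(fixture_script(name, seed=seed))
        write_gaze_table(rec, out / f"{name}.csv")
        sidecar = truth.to_json_dict()
        (out / f"{name}.truth.json").write_text(json.dumps(sidecar, indent=2) + "\n")
        manifest["fixtures"][name] = {
            "recording": f"{name}.csv",
            "truth": f"{name}.truth.json",
            "n_samples": sidecar["n_samples"],
        }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    return manifest
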