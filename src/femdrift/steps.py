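"""Step decomposition of drift trajectories and pooled step distributions.

Each drift trajectory is treated as a random walk whose steps join
consecutive gaze samples. A step is described by its length (px,
proportional to instantaneous velocity at the fixed 2 ms sampling
interval) and its turn angle relative to the previous step, signed
counterclockwise in (-pi, pi] with exact reversals mapped to +pi.

Because the tracker quantizes coordinates to 0.1 px, raw turn-angle
histograms are sharply discretized; distributions are therefore built
from positions jittered by i.i.d. uniform(-0.05, 0.05) px noise per
coordinate before recomputing the steps.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import InsufficientDataError, TooShortError
from .events import FixationSegment
from .recording import GazeRecording


def turn_angles_from_steps(steps: np.ndarray) -> np.ndarray:
    """Signed turn angle from step j-1 to step j, in (-pi, pi].

    Counterclockwise positive; a perfect reversal maps to +pi (the
    deterministic tie-break for the half-open range).
    """
    a, b = steps[:-1], steps[1:]
    cross = a[:, 0] * b[:, 1] - a[:, 1] * b[:, 0]
    dot = a[:, 0] * b[:, 0] + a[:, 1] * b[:, 1]
    theta = np.arctan2(cross, dot)
    theta[theta == -np.pi] = np.pi
    return theta


@dataclass
class StepSeries:
    """Step vectors, lengths, and turn angles of one drift trajectory."""

    steps: np.ndarray        # (n_steps, 2) px
    start: np.ndarray        # (2,) first gaze point, px

    @classmethod
    def from_positions(cls, positions: np.ndarray) -> "StepSeries":
        positions = np.asarray(positions, dtype=float)
        if len(positions) < 3:
            raise TooShortError("need >= 3 samples to decompose steps and turns")
        return cls(steps=np.diff(positions, axis=0), start=positions[0].copy())

    @property
    def n_steps(self) -> int:
        return len(self.steps)

    @property
    def lengths(self) -> np.ndarray:
        return np.hypot(self.steps[:, 0], self.steps[:, 1])

    @property
    def turn_angles(self) -> np.ndarray:
        return turn_angles_from_steps(self.steps)

    @property
    def positions(self) -> np.ndarray:
        return self.start + np.vstack([[0.0, 0.0], np.cumsum(self.steps, axis=0)])


def decompose_steps(fix: FixationSegment, rec: GazeRecording) -> StepSeries:
    """Step decomposition of one fixation's drift trajectory."""
    return StepSeries.from_positions(fix.positions(rec))


@dataclass
class JointStepDistribution:
    """2-D histogram of (turn angle, step length) pooled over fixations."""

    counts: np.ndarray       # (n_theta_bins, n_length_bins)
    theta_edges: np.ndarray  # radians, spanning (-pi, pi]
    length_edges: np.ndarray  # px
    jitter_px: float

    @property
    def total(self) -> float:
        return float(self.counts.sum())

    def marginal_theta(self) -> np.ndarray:
        return self.counts.sum(axis=1)

    def marginal_length(self) -> np.ndarray:
        return self.counts.sum(axis=0)

    def conditional_length_given_theta(self) -> np.ndarray:
        """Rows: P(L bin | theta bin); zero rows left as zeros."""
        m = self.marginal_theta()
        with np.errstate(invalid="ignore", divide="ignore"):
            cond = self.counts / m[:, None]
        cond[m == 0] = 0.0
        return cond


def jittered_distributions(
    trajectories: list[np.ndarray],
    jitter_px: float = 0.05,
    seed=None,
    n_theta_bins: int = 36,
    n_length_bins: int = 40,
    length_max: float | None = None,
) -> JointStepDistribution:
    """Pooled joint (theta, L) histogram from jittered gaze trajectories.

    Positions are perturbed by i.i.d. uniform(-jitter, +jitter) px per
    coordinate before step computation, smearing the 0.1 px coordinate
    quantization. Histogram mass equals the pooled turn count; step
    lengths enter jointly with the turn angle of the same step.
    """
    if not trajectories:
        raise InsufficientDataError("no trajectories given")
    rng = np.random.default_rng(seed)
    thetas, lengths = [], []
    for pos in trajectories:
        pos = np.asarray(pos, dtype=float)
        if len(pos) < 3:
            continue
        jit = pos + rng.uniform(-jitter_px, jitter_px, size=pos.shape)
        steps = np.diff(jit, axis=0)
        thetas.append(turn_angles_from_steps(steps))
        lengths.append(np.hypot(steps[1:, 0], steps[1:, 1]))
    if not thetas:
        raise InsufficientDataError("no trajectory long enough for steps")
    theta = np.concatenate(thetas)
    length = np.concatenate(lengths)
    if length_max is None:
        length_max = float(length.max()) * (1 + 1e-9) + 1e-12
    theta_edges = np.linspace(-np.pi, np.pi, n_theta_bins + 1)
    length_edges = np.linspace(0.0, length_max, n_length_bins + 1)
    counts, _, _ = np.histogram2d(theta, length, bins=[theta_edges, length_edges])
    return JointStepDistribution(
        counts=counts, theta_edges=theta_edges, length_edges=length_edges,
        jitter_px=jitter_px,
    )
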