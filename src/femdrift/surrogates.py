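"""Surrogate walks and series that destroy targeted structure.

Three constructions, each removing one ingredient while preserving
another:

* ``empirical_walk`` — i.i.d. (turn angle, step length) draws from the
  pooled empirical joint distribution: preserves step anisotropy,
  destroys serial dependence between steps.
* ``shuffle_walk`` — permutes a trajectory's step vectors: preserves
  the step multiset (and hence the endpoint) exactly, destroys order.
* ``aaft_surrogate`` — amplitude-adjusted Fourier-transform surrogate
  of a 1-D series: preserves the value distribution exactly and the
  linear autocorrelation approximately, randomizes temporal phase.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import InsufficientDataError, TooShortError
from .steps import JointStepDistribution, StepSeries


@dataclass
class SurrogateWalk:
    positions: np.ndarray
    provenance: str   # empirical_iid | step_shuffle | aaft
    seed: object = None
    source: str = ""


def isotropic_walk(n_steps: int, seed, step_length: float = 1.0) -> np.ndarray:
    """Uncorrelated 2-D walk: uniform headings, fixed step length."""
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    theta = rng.uniform(0.0, 2 * np.pi, n_steps)
    steps = step_length * np.column_stack([np.cos(theta), np.sin(theta)])
    return np.vstack([[0.0, 0.0], np.cumsum(steps, axis=0)])


def empirical_walk(
    dist: JointStepDistribution, n_steps: int, seed, start=(0.0, 0.0)
) -> SurrogateWalk:
    """Walk with i.i.d. (theta, L) drawn from the empirical joint histogram.

    Draws are uniform within the selected 2-D bin; headings accumulate
    (theta is a turn relative to the previous heading), so anisotropy in
    the turn-angle marginal is preserved while serial dependence between
    steps is destroyed. The initial heading is uniform.
    """
    if dist.total <= 0:
        raise InsufficientDataError("empty step distribution")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    probs = (dist.counts / dist.total).ravel()
    idx = rng.choice(len(probs), size=n_steps, p=probs)
    it, il = np.unravel_index(idx, dist.counts.shape)
    te, le = dist.theta_edges, dist.length_edges
    theta = te[it] + rng.random(n_steps) * (te[it + 1] - te[it])
    length = le[il] + rng.random(n_steps) * (le[il + 1] - le[il])
    headings = rng.uniform(0, 2 * np.pi) + np.cumsum(theta)
    steps = length[:, None] * np.column_stack([np.cos(headings), np.sin(headings)])
    positions = np.asarray(start, dtype=float) + np.vstack(
        [[0.0, 0.0], np.cumsum(steps, axis=0)]
    )
    return SurrogateWalk(positions=positions, provenance="empirical_iid", seed=seed)


def shuffle_walk(series: StepSeries, seed) -> SurrogateWalk:
    """Reconstitute the walk from a random permutation of its step vectors.

    The step multiset — and therefore the endpoint and the full-lag
    displacement — are preserved by construction.
    """
    if series.n_steps < 2:
        raise TooShortError("need >= 2 steps to shuffle")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    perm = rng.permutation(series.n_steps)
    steps = series.steps[perm]
    positions = series.start + np.vstack([[0.0, 0.0], np.cumsum(steps, axis=0)])
    return SurrogateWalk(positions=positions, provenance="step_shuffle", seed=seed)


def phase_randomize(x: np.ndarray, seed) -> np.ndarray:
    """Linear Fourier surrogate: randomize phases, keep amplitudes.

    DC and (for even length) Nyquist components are left untouched, so
    the mean and the periodogram are preserved exactly.
    """
    x = np.asarray(x, dtype=float)
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    n = len(x)
    spec = np.fft.rfft(x)
    k = len(spec)
    nyquist = 1 if n % 2 == 0 else 0
    n_free = k - 1 - nyquist
    phases = rng.uniform(0, 2 * np.pi, n_free)
    spec[1 : 1 + n_free] = np.abs(spec[1 : 1 + n_free]) * np.exp(1j * phases)
    return np.fft.irfft(spec, n=n)


def aaft_surrogate(x: np.ndarray, seed) -> np.ndarray:
    """Amplitude-adjusted Fourier-transform surrogate of a 1-D series.

    Rank-remap the data onto a Gaussian, phase-randomize, and remap the
    original sorted values onto the ranks of the result. The sorted
    values of the output equal the sorted values of the input exactly.
    """
    x = np.asarray(x, dtype=float)
    if len(x) < 8:
        raise TooShortError("AAFT needs at least 8 samples")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    n = len(x)
    ranks_x = np.argsort(np.argsort(x, kind="stable"), kind="stable")
    gauss = np.sort(rng.standard_normal(n))
    y = gauss[ranks_x]                    # Gaussianized series with x's rank order
    yp = phase_randomize(y, rng)
    ranks_yp = np.argsort(np.argsort(yp, kind="stable"), kind="stable")
    return np.sort(x)[ranks_yp]
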