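"""Approximately self-avoiding random walk with an imprecise finite memory.

The walker remembers its last tau positions, each blurred into an
isotropic 2-D Gaussian of width sigma (px), modeling the finite spatial
precision of the oculomotor history representation:

    n(x) = sum_{m=1}^{tau} (1 / 2 pi sigma^2) exp(-|x - x_m|^2 / 2 sigma^2),

so that the history integrates to tau. Converting to polar coordinates
about the current position and integrating over radius gives the
angular density of remembered points per radian,

    n(theta) = (1/2pi) sum_m e^{-r_m^2/2sigma^2}
               [1 + sqrt(pi) R_m e^{R_m^2} erfc(-R_m)],
    R_m(theta) = r_m cos(theta - theta_m) / (sigma sqrt(2)).

(The decaying prefactor e^{-r_m^2/2sigma^2} is required for this to be
the radial integral of the Gaussian mixture; this is verified against
adaptive quadrature in the test suite.) The next step direction is
drawn from the penalized distribution

    p(theta) = exp(-alpha n(theta)) / integral exp(-alpha n(theta)) dtheta,

so well-visited directions are avoided, the more strongly the larger
the penalty strength alpha. Steps have unit length by default and one
step corresponds to one 2 ms sample. Angles are absolute directions in
the fixed frame; "turn angles" relative to the previous step emerge
from the geometry, since the previous position always lies in the
memory at distance one step.

Limits: tau = 0 or alpha = 0 give an isotropic uncorrelated walk
(normal diffusion, H ~ 1); large alpha forbids backtracking and gives
near-ballistic short-time behavior (H ~ 2); very large sigma blurs the
history over all directions and restores H ~ 1.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import special

from ._kernels import HAVE_NUMBA, simulate_walk_kernel
from .errors import ParameterError
from .scaling import DisplacementCurve, ScalingCurve, msd_curve, scaling_curve

DEFAULT_GRID_SIZE = 1024


@dataclass(frozen=True)
class ModelParams:
    """Memory-walk parameters.

    tau : memory length in time points (x 2 ms for physical units)
    sigma : blur width of remembered points, px
    alpha : penalty strength (dimensionless)
    """

    tau: int
    sigma: float = 1.0
    alpha: float = 1.0

    def __post_init__(self):
        if not (isinstance(self.tau, (int, np.integer)) and self.tau >= 0):
            raise ParameterError(f"tau must be a non-negative integer, got {self.tau!r}")
        if not self.sigma > 0:
            raise ParameterError(f"sigma must be positive, got {self.sigma!r}")
        if not self.alpha >= 0:
            raise ParameterError(f"alpha must be non-negative, got {self.alpha!r}")

    def to_dict(self) -> dict:
        return {"tau": int(self.tau), "sigma": float(self.sigma), "alpha": float(self.alpha)}


@dataclass
class WalkState:
    """Current position, history buffer (most recent first), step index."""

    position: np.ndarray
    history: np.ndarray   # (n_hist, 2), n_hist = min(j, tau)
    step_index: int = 0


@dataclass
class AngularDensity:
    """History density n(theta) and turn distribution p(theta) on a grid.

    ``angles`` are the centers of G uniform bins covering [0, 2pi).
    """

    angles: np.ndarray
    n: np.ndarray
    p: np.ndarray | None = None
    r_m: np.ndarray = field(default_factory=lambda: np.empty(0))
    theta_m: np.ndarray = field(default_factory=lambda: np.empty(0))

    @property
    def grid_size(self) -> int:
        return len(self.angles)

    @property
    def bin_width(self) -> float:
        return 2 * np.pi / self.grid_size


def grid_angles(grid_size: int = DEFAULT_GRID_SIZE) -> np.ndarray:
    """Bin-center angle grid on [0, 2pi)."""
    return (np.arange(grid_size) + 0.5) * (2 * np.pi / grid_size)


def history_density_at(x, history, sigma: float) -> float:
    """Planar history density n(x): sum of unit-mass 2-D Gaussians."""
    if sigma <= 0:
        raise ParameterError("sigma must be positive")
    history = np.atleast_2d(np.asarray(history, dtype=float))
    if history.size == 0:
        return 0.0
    d2 = np.sum((history - np.asarray(x, dtype=float)) ** 2, axis=1)
    return float(np.sum(np.exp(-d2 / (2 * sigma**2))) / (2 * np.pi * sigma**2))


def angular_density_closed(r_m, theta_m, sigma: float, angles) -> np.ndarray:
    """Closed-form n(theta) for history points at polar (r_m, theta_m).

    Numerically stable for r/sigma >> 1: the product
    e^{-c} e^{R^2} erfc(-R) is evaluated as e^{-c sin^2(dtheta)} erfc(-R)
    whose factors are all bounded (c = r^2/2sigma^2, R^2 - c =
    -c sin^2(dtheta)).
    """
    r_m = np.atleast_1d(np.asarray(r_m, dtype=float))
    theta_m = np.atleast_1d(np.asarray(theta_m, dtype=float))
    angles = np.asarray(angles, dtype=float)
    c = (r_m**2) / (2 * sigma**2)              # (M,)
    dth = angles[None, :] - theta_m[:, None]   # (M, G)
    R = (r_m / (sigma * np.sqrt(2)))[:, None] * np.cos(dth)
    tail = np.sqrt(np.pi) * R * np.exp(-c[:, None] * np.sin(dth) ** 2) * special.erfc(-R)
    per_point = np.exp(-c)[:, None] + tail
    return per_point.sum(axis=0) / (2 * np.pi)


def angular_density(
    state: WalkState, sigma: float, grid_size: int = DEFAULT_GRID_SIZE
) -> AngularDensity:
    """History angular density seen from the current position."""
    if sigma <= 0:
        raise ParameterError("sigma must be positive")
    hist = np.atleast_2d(np.asarray(state.history, dtype=float))
    if hist.size == 0:
        raise ParameterError("history buffer is empty")
    rel = hist - np.asarray(state.position, dtype=float)
    r_m = np.hypot(rel[:, 0], rel[:, 1])
    theta_m = np.arctan2(rel[:, 1], rel[:, 0])
    angles = grid_angles(grid_size)
    n = angular_density_closed(r_m, theta_m, sigma, angles)
    return AngularDensity(angles=angles, n=n, r_m=r_m, theta_m=theta_m)


def turn_probability(density: AngularDensity, alpha: float) -> AngularDensity:
    """Fill p(theta) proportional to exp(-alpha n(theta)), normalized on the grid."""
    if alpha < 0:
        raise ParameterError("alpha must be non-negative")
    w = np.exp(-alpha * (density.n - density.n.min()))
    total = w.sum() * density.bin_width
    if not total > 0:
        raise ParameterError("turn distribution normalizer vanished")
    density.p = w / total
    return density


def _sample_from_grid(p: np.ndarray, bin_width: float, u: float) -> float:
    """Inverse-CDF draw from a piecewise-constant density on the angle grid."""
    w = p * bin_width
    cum = np.cumsum(w)
    target = u * cum[-1]
    k = int(np.searchsorted(cum, target))
    k = min(k, len(w) - 1)
    prev = cum[k - 1] if k > 0 else 0.0
    frac = (target - prev) / w[k] if w[k] > 0 else 0.5
    return (k + frac) * bin_width


def step(
    state: WalkState,
    params: ModelParams,
    rng: np.random.Generator,
    step_length: float = 1.0,
    grid_size: int = DEFAULT_GRID_SIZE,
) -> WalkState:
    """Advance the walk by one step, updating the history buffer."""
    u = float(rng.random())
    if params.tau == 0 or len(state.history) == 0 or params.alpha == 0:
        theta = 2 * np.pi * u
    else:
        dens = turn_probability(angular_density(state, params.sigma, grid_size), params.alpha)
        theta = _sample_from_grid(dens.p, dens.bin_width, u)
    new_pos = state.position + step_length * np.array([np.cos(theta), np.sin(theta)])
    history = np.vstack([state.position[None, :], state.history])[: params.tau]
    return WalkState(position=new_pos, history=history, step_index=state.step_index + 1)


def _simulate_walk_python(n_steps, tau, sigma, alpha, step_length, u, grid_size):
    """Vectorized pure-python walk iteration (same algorithm as the kernel)."""
    pos = np.zeros((n_steps + 1, 2))
    angles = grid_angles(grid_size)
    bw = 2 * np.pi / grid_size
    for j in range(n_steps):
        nh = min(j, tau)
        if nh == 0 or alpha == 0.0:
            theta = 2 * np.pi * u[j]
        else:
            rel = pos[j - nh : j] - pos[j]
            r_m = np.hypot(rel[:, 0], rel[:, 1])
            theta_m = np.arctan2(rel[:, 1], rel[:, 0])
            n = angular_density_closed(r_m, theta_m, sigma, angles)
            w = np.exp(-alpha * (n - n.min()))
            cum = np.cumsum(w)
            target = u[j] * cum[-1]
            k = min(int(np.searchsorted(cum, target)), grid_size - 1)
            prev = cum[k - 1] if k > 0 else 0.0
            frac = (target - prev) / w[k] if w[k] > 0 else 0.5
            theta = (k + frac) * bw
        pos[j + 1] = pos[j] + step_length * np.array([np.cos(theta), np.sin(theta)])
    return pos


def simulate_walk(
    params: ModelParams,
    n_steps: int,
    seed,
    step_length: float = 1.0,
    grid_size: int = DEFAULT_GRID_SIZE,
) -> np.ndarray:
    """Simulate one memory walk; returns (n_steps + 1, 2) positions.

    The first direction is uniform (empty history); the buffer grows
    from the start point until it holds tau positions. ``seed`` may be
    an int, a SeedSequence, or a Generator; one uniform variate drives
    each step, so runs are reproducible bit-for-bit given the seed.
    """
    if n_steps < 1:
        raise ParameterError("n_steps must be >= 1")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    u = rng.random(n_steps)
    if HAVE_NUMBA:
        return simulate_walk_kernel(
            n_steps, int(params.tau), float(params.sigma), float(params.alpha),
            float(step_length), u, int(grid_size),
        )
    return _simulate_walk_python(
        n_steps, int(params.tau), float(params.sigma), float(params.alpha),
        float(step_length), u, int(grid_size),
    )


def simulate_ensemble(
    params: ModelParams,
    n_walks: int,
    n_steps: int,
    seed,
    step_length: float = 1.0,
    grid_size: int = DEFAULT_GRID_SIZE,
) -> list[np.ndarray]:
    """Simulate ``n_walks`` independent walks with per-walk child streams."""
    ss = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    return [
        simulate_walk(params, n_steps, np.random.default_rng(child),
                      step_length=step_length, grid_size=grid_size)
        for child in ss.spawn(n_walks)
    ]


def model_msd_curve(
    params: ModelParams,
    n_walks: int = 100,
    n_steps: int = 500,
    seed=0,
    m_max: int = 100,
    grid_size: int = DEFAULT_GRID_SIZE,
    dt_ms: float = 2.0,
) -> DisplacementCurve:
    """Pair-weighted pooled D^2 over an ensemble of model walks."""
    walks = simulate_ensemble(params, n_walks, n_steps, seed, grid_size=grid_size)
    return msd_curve(walks, m_max=m_max, dt_ms=dt_ms)


def model_H_curve(
    params: ModelParams,
    n_walks: int = 100,
    n_steps: int = 500,
    seed=0,
    m_max: int = 100,
    grid_size: int = DEFAULT_GRID_SIZE,
    dt_ms: float = 2.0,
) -> ScalingCurve:
    """Ensemble scaling-exponent curve H(dt) for one parameter set."""
    return scaling_curve(
        model_msd_curve(params, n_walks, n_steps, seed, m_max, grid_size, dt_ms)
    )
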