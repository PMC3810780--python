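"""Mean squared displacement and scaling-exponent curves.

The displacement estimator for a trajectory x_1..x_N at lag m samples is

    D^2(m) = 1/(N-m) * sum_{i=1}^{N-m} ||x_{i+m} - x_i||^2 ,

with physical lag dt = m / f_s. Curves from many trajectories are pooled
pair-weighted: squared-displacement sums and pair counts are aggregated
across trajectories before dividing, which is unbiased when trajectory
lengths vary (an unweighted mean of per-trajectory curves is available
as an option). The scaling exponent H(dt) is the log-log slope of D^2
vs dt, computed by centered differences at interior lags and one-sided
differences at the ends; H = 1 is normal diffusion, H > 1 persistence
(superdiffusion), H < 1 antipersistence (subdiffusion).

Summaries: H_1 is the slope between dt = 2 ms and 4 ms; H_peak is the
maximum of H over dt <= 30 ms (the superdiffusive regime) and dt_peak
its lag.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import InsufficientDataError, ParameterError


@dataclass
class DisplacementCurve:
    """Pooled D^2(m) on the lag grid m = 1..m_max (dt = m / f_s)."""

    m: np.ndarray            # integer lags, samples
    d2: np.ndarray           # px^2
    pair_count: np.ndarray   # pooled (i, i+m) pairs per lag
    dt_ms: float = 2.0       # physical duration of one lag unit

    @property
    def dt(self) -> np.ndarray:
        """Physical lags in ms."""
        return self.m * self.dt_ms

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"dt_ms": self.dt, "d2_px2": self.d2, "pair_count": self.pair_count}
        )


def msd_curve(
    trajectories: list[np.ndarray],
    m_max: int | None = None,
    dt_ms: float = 2.0,
    pooling: str = "pairs",
) -> DisplacementCurve:
    """Pooled mean squared displacement over trajectories.

    Parameters
    ----------
    trajectories
        Sequence of (N_k, 2) position arrays; each contributes lags
        m <= N_k - 1.
    m_max
        Largest lag; defaults to max_k(N_k) - 1.
    pooling
        ``"pairs"`` (default) aggregates sums and pair counts before
        dividing; ``"mean"`` averages per-trajectory D^2 curves with
        equal weight per trajectory.
    """
    trajectories = [np.asarray(p, dtype=float) for p in trajectories if len(p) >= 2]
    if not trajectories:
        raise InsufficientDataError("no trajectory long enough for any lag")
    if m_max is None:
        m_max = max(len(p) for p in trajectories) - 1
    m = np.arange(1, m_max + 1)
    sums = np.zeros(m_max)
    pairs = np.zeros(m_max, dtype=np.int64)
    per_traj = np.zeros(m_max) if pooling == "mean" else None
    contrib = np.zeros(m_max, dtype=np.int64)
    for pos in trajectories:
        n = len(pos)
        top = min(m_max, n - 1)
        for k in range(1, top + 1):
            d = pos[k:] - pos[:-k]
            s = float(np.einsum("ij,ij->", d, d))
            sums[k - 1] += s
            pairs[k - 1] += n - k
            contrib[k - 1] += 1
            if per_traj is not None:
                per_traj[k - 1] += s / (n - k)
    if pooling == "pairs":
        valid = pairs > 0
        if not valid.any():
            raise InsufficientDataError("no displacement pairs at any lag")
        d2 = np.full(m_max, np.nan)
        d2[valid] = sums[valid] / pairs[valid]
    elif pooling == "mean":
        valid = contrib > 0
        d2 = np.full(m_max, np.nan)
        d2[valid] = per_traj[valid] / contrib[valid]
    else:
        raise ParameterError(f"unknown pooling {pooling!r}")
    keep = pairs > 0
    return DisplacementCurve(m=m[keep], d2=d2[keep], pair_count=pairs[keep], dt_ms=dt_ms)


@dataclass
class ScalingCurve:
    """H(dt) with the short-time summaries H_1, H_peak, dt_peak."""

    dt: np.ndarray           # ms
    h: np.ndarray            # dimensionless
    h1: float = field(default=np.nan)
    h_peak: float = field(default=np.nan)
    dt_peak: float = field(default=np.nan)

    def h_at(self, dt_ms: float) -> float:
        i = np.nonzero(np.isclose(self.dt, dt_ms))[0]
        if i.size == 0:
            raise KeyError(f"lag {dt_ms} ms not on the grid")
        return float(self.h[i[0]])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"dt_ms": self.dt, "h": self.h})


def scaling_curve(
    curve: DisplacementCurve,
    peak_window_ms: float = 30.0,
    smooth: int = 0,
) -> ScalingCurve:
    """Log-log slope of D^2 vs dt with centered differences.

    One-sided differences are used at the first and last lags. ``smooth``
    applies an optional centered moving average of that half-width to
    D^2 in log space before differentiation (off by default).
    """
    d2 = np.asarray(curve.d2, dtype=float)
    if np.any(~np.isfinite(d2)) or np.any(d2 <= 0):
        bad = int(curve.m[np.nonzero(~(d2 > 0))[0][0]])
        raise ParameterError(f"nonpositive D^2 at lag m={bad}: log-log slope undefined")
    logt = np.log(curve.dt)
    logd = np.log(d2)
    if smooth > 0:
        kernel = np.ones(2 * smooth + 1) / (2 * smooth + 1)
        pad = np.pad(logd, smooth, mode="edge")
        logd = np.convolve(pad, kernel, mode="valid")
    h = np.gradient(logd, logt)
    dt = curve.dt
    h1 = np.nan
    i2 = np.nonzero(np.isclose(dt, 2.0))[0]
    i4 = np.nonzero(np.isclose(dt, 4.0))[0]
    if i2.size and i4.size:
        h1 = float((logd[i4[0]] - logd[i2[0]]) / (logt[i4[0]] - logt[i2[0]]))
    win = dt <= peak_window_ms
    h_peak = dt_peak = np.nan
    if win.any():
        k = int(np.argmax(h[win]))
        h_peak = float(h[win][k])
        dt_peak = float(dt[win][k])
    return ScalingCurve(dt=dt, h=h, h1=h1, h_peak=h_peak, dt_peak=dt_peak)


def fit_loglog_slope(curve: DisplacementCurve) -> float:
    """Single power-law exponent: least-squares slope of log D^2 vs log dt."""
    d2 = np.asarray(curve.d2, dtype=float)
    if np.any(d2 <= 0):
        raise ParameterError("nonpositive D^2: log-log fit undefined")
    slope, _ = np.polyfit(np.log(curve.dt), np.log(d2), 1)
    return float(slope)
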