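"""Lookup-table inversion: fit memory-walk parameters to H curves.

A lookup table holds ensemble H curves precomputed on a grid of
(tau, sigma, alpha): a list of integer tau slices, each sampled on a
logarithmically spaced (sigma, alpha) grid. Fitting is an exhaustive
sum-of-squared-errors scan of the data curve against every table curve
over short lags (default dt <= 20 ms, where the model captures the
data); ties break toward the smallest tau, then alpha, then sigma
(parsimony of memory). Per-grid-point seeds are fixed by the root seed,
so a table — and therefore any fit against it — is deterministic.

The full published-scale grid (51 x 51 over sigma in [1e-2, 10^0.4] px
and alpha in [1e-2, 1e2], tau = 1..20, 100 walks x 500 steps per point)
is a long-running build; a coarse preset (9 x 9, tau in {2, 5, 10, 15,
20}, 30 walks x 300 steps) supports desk-scale parameter recovery.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import IncompleteTableError, ParameterError
from .model import ModelParams, model_msd_curve
from .scaling import ScalingCurve, scaling_curve


@dataclass(frozen=True)
class GridSpec:
    """Parameter grid: tau slices x log-spaced (sigma, alpha)."""

    taus: tuple = tuple(range(1, 21))
    sigma_min: float = 1e-2
    sigma_max: float = 10**0.4
    n_sigma: int = 51
    alpha_min: float = 1e-2
    alpha_max: float = 1e2
    n_alpha: int = 51

    @property
    def sigmas(self) -> np.ndarray:
        return np.logspace(np.log10(self.sigma_min), np.log10(self.sigma_max), self.n_sigma)

    @property
    def alphas(self) -> np.ndarray:
        return np.logspace(np.log10(self.alpha_min), np.log10(self.alpha_max), self.n_alpha)

    def to_dict(self) -> dict:
        return {
            "taus": list(self.taus),
            "sigma_min": self.sigma_min, "sigma_max": self.sigma_max,
            "n_sigma": self.n_sigma,
            "alpha_min": self.alpha_min, "alpha_max": self.alpha_max,
            "n_alpha": self.n_alpha,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "GridSpec":
        d = dict(d)
        d["taus"] = tuple(d["taus"])
        return cls(**d)


def coarse_grid() -> GridSpec:
    """Desk-scale grid: 9 x 9 (sigma, alpha), tau in {2, 5, 10, 15, 20}."""
    return GridSpec(taus=(2, 5, 10, 15, 20), n_sigma=9, n_alpha=9)


@dataclass(frozen=True)
class SimSettings:
    n_walks: int = 100
    n_steps: int = 500
    m_max: int = 25
    grid_size: int = 512
    dt_ms: float = 2.0

    def to_dict(self) -> dict:
        return {
            "n_walks": self.n_walks, "n_steps": self.n_steps,
            "m_max": self.m_max, "grid_size": self.grid_size, "dt_ms": self.dt_ms,
        }


COARSE_SETTINGS = SimSettings(n_walks=30, n_steps=300)


_LOG_KEY_SCALE = 1_000_000
_LOG_KEY_OFFSET = 100_000_000


def point_seed(root_seed: int, tau: int, sigma: float, alpha: float) -> np.random.SeedSequence:
    """Deterministic per-point seed stream, keyed by the parameter values.

    Keying by (tau, log10 sigma, log10 alpha) in micro-decade units —
    not by grid indices — means the same parameter point receives the
    same stream in any grid, so coarse and fine tables agree exactly at
    shared points.
    """
    key = (
        int(tau),
        _LOG_KEY_OFFSET + int(round(np.log10(sigma) * _LOG_KEY_SCALE)),
        _LOG_KEY_OFFSET + int(round(np.log10(alpha) * _LOG_KEY_SCALE)),
    )
    return np.random.SeedSequence(entropy=int(root_seed), spawn_key=key)


@dataclass
class LookupTable:
    grid: GridSpec
    settings: SimSettings
    root_seed: int
    dt: np.ndarray                               # shared lag grid, ms
    curves: np.ndarray                           # (n_tau, n_sigma, n_alpha, n_lags) H
    built: np.ndarray = field(default=None)      # bool per tau slice

    def __post_init__(self):
        if self.built is None:
            self.built = np.ones(len(self.grid.taus), dtype=bool)

    @property
    def complete(self) -> bool:
        return bool(self.built.all())

    def missing(self) -> list[int]:
        return [t for t, b in zip(self.grid.taus, self.built) if not b]

    def curve_at(self, i_tau: int, i_sigma: int, i_alpha: int) -> ScalingCurve:
        return ScalingCurve(dt=self.dt.copy(), h=self.curves[i_tau, i_sigma, i_alpha].copy())

    def params_at(self, i_tau: int, i_sigma: int, i_alpha: int) -> ModelParams:
        return ModelParams(
            tau=int(self.grid.taus[i_tau]),
            sigma=float(self.grid.sigmas[i_sigma]),
            alpha=float(self.grid.alphas[i_alpha]),
        )

    # --- persistence: directory of per-tau CSV slices + JSON manifest ---

    def save(self, out_dir) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        for i, tau in enumerate(self.grid.taus):
            if not self.built[i]:
                continue
            self._save_slice(out, i)
        self._write_manifest(out)

    def _save_slice(self, out: Path, i_tau: int) -> None:
        tau = self.grid.taus[i_tau]
        ns, na, nl = self.curves.shape[1:]
        isig, ial, il = np.meshgrid(range(ns), range(na), range(nl), indexing="ij")
        df = pd.DataFrame(
            {
                "i_sigma": isig.ravel(), "i_alpha": ial.ravel(),
                "sigma": self.grid.sigmas[isig.ravel()],
                "alpha": self.grid.alphas[ial.ravel()],
                "dt_ms": self.dt[il.ravel()],
                "h": self.curves[i_tau].reshape(-1),
            }
        )
        df.to_csv(out / f"tau_{tau:02d}.csv", index=False, lineterminator="\n")

    def _write_manifest(self, out: Path) -> None:
        manifest = {
            "grid": self.grid.to_dict(),
            "settings": self.settings.to_dict(),
            "root_seed": self.root_seed,
            "dt_ms_grid": [float(x) for x in self.dt],
            "built_taus": [int(t) for t, b in zip(self.grid.taus, self.built) if b],
            "complete": self.complete,
        }
        (out / "manifest.json").write_text(json.dumps(manifest, indent=2) + "\n")

    @classmethod
    def load(cls, in_dir) -> "LookupTable":
        src = Path(in_dir)
        manifest = json.loads((src / "manifest.json").read_text())
        grid = GridSpec.from_dict(manifest["grid"])
        settings = SimSettings(**manifest["settings"])
        dt = np.asarray(manifest["dt_ms_grid"], dtype=float)
        curves = np.full(
            (len(grid.taus), grid.n_sigma, grid.n_alpha, len(dt)), np.nan
        )
        built = np.zeros(len(grid.taus), dtype=bool)
        for i, tau in enumerate(grid.taus):
            f = src / f"tau_{tau:02d}.csv"
            if not f.exists():
                continue
            df = pd.read_csv(f)
            curves[i, df["i_sigma"], df["i_alpha"],
                   np.searchsorted(dt, df["dt_ms"])] = df["h"]
            built[i] = True
        return cls(grid=grid, settings=settings, root_seed=manifest["root_seed"],
                   dt=dt, curves=curves, built=built)


def build_lookup(
    grid: GridSpec | None = None,
    settings: SimSettings | None = None,
    seed: int = 0,
    out_dir=None,
    resume: bool = True,
    progress=None,
) -> LookupTable:
    """Build (or resume) the table of ensemble H curves over the grid.

    When ``out_dir`` is given, each completed tau slice is persisted
    immediately and the manifest marks the table incomplete until every
    slice exists, so an interrupted build resumes where it stopped.
    """
    grid = grid or GridSpec()
    settings = settings or SimSettings()
    dt = np.arange(1, settings.m_max + 1) * settings.dt_ms
    n_tau = len(grid.taus)
    curves = np.full((n_tau, grid.n_sigma, grid.n_alpha, settings.m_max), np.nan)
    built = np.zeros(n_tau, dtype=bool)
    table = LookupTable(grid=grid, settings=settings, root_seed=int(seed),
                        dt=dt, curves=curves, built=built)

    out = Path(out_dir) if out_dir is not None else None
    if out is not None and resume and (out / "manifest.json").exists():
        prev = LookupTable.load(out)
        if (prev.grid == grid and prev.settings == settings
                and prev.root_seed == int(seed)):
            table.curves[prev.built] = prev.curves[prev.built]
            table.built[:] = prev.built
    if out is not None:
        out.mkdir(parents=True, exist_ok=True)
        table._write_manifest(out)

    sigmas, alphas = grid.sigmas, grid.alphas
    for i_tau, tau in enumerate(grid.taus):
        if table.built[i_tau]:
            continue
        for i_sigma, sigma in enumerate(sigmas):
            for i_alpha, alpha in enumerate(alphas):
                params = ModelParams(tau=int(tau), sigma=float(sigma), alpha=float(alpha))
                dc = model_msd_curve(
                    params,
                    n_walks=settings.n_walks, n_steps=settings.n_steps,
                    seed=point_seed(seed, int(tau), float(sigma), float(alpha)),
                    m_max=settings.m_max, grid_size=settings.grid_size,
                    dt_ms=settings.dt_ms,
                )
                table.curves[i_tau, i_sigma, i_alpha] = scaling_curve(dc).h
            if progress is not None:
                progress(tau, i_sigma)
        table.built[i_tau] = True
        if out is not None:
            table._save_slice(out, i_tau)
            table._write_manifest(out)
    return table


@dataclass
class FitResult:
    params: ModelParams
    indices: tuple[int, int, int]
    sse: float
    dt: np.ndarray                 # lags used in the fit, ms
    residuals: np.ndarray          # |H_model - H_data| / H_data per lag
    runners_up: list[dict]

    def to_dict(self) -> dict:
        return {
            "tau": self.params.tau,
            "sigma_px": self.params.sigma,
            "alpha": self.params.alpha,
            "indices": list(self.indices),
            "sse": self.sse,
            "dt_ms": [float(x) for x in self.dt],
            "relative_residuals": [float(x) for x in self.residuals],
            "runners_up": self.runners_up,
        }


def fit_H_curve(
    data: ScalingCurve,
    table: LookupTable,
    dt_max_ms: float = 20.0,
    n_runners_up: int = 5,
) -> FitResult:
    """Exhaustive minimum-SSE scan of the data H curve against the table.

    SSE is computed on H (not D^2) with uniform weight per lag over
    dt <= ``dt_max_ms``; ties break toward smaller tau, then alpha,
    then sigma.
    """
    if not table.complete:
        raise IncompleteTableError(
            f"lookup table is missing tau slices {table.missing()}",
            missing=table.missing(),
        )
    mask = table.dt <= dt_max_ms
    if not mask.any():
        raise ParameterError("no table lags within the fit range")
    lags = table.dt[mask]
    try:
        data_h = np.array([data.h_at(dt) for dt in lags])
    except KeyError as exc:
        raise ParameterError(f"data curve does not cover the fit range: {exc}") from exc

    diffs = table.curves[..., mask] - data_h            # (nt, ns, na, L)
    sse = np.einsum("...l,...l->...", diffs, diffs)
    best = None
    entries = []
    # iteration order implements the tie-break: tau, then alpha, then sigma
    for i_tau in range(sse.shape[0]):
        for i_alpha in range(sse.shape[2]):
            for i_sigma in range(sse.shape[1]):
                v = float(sse[i_tau, i_sigma, i_alpha])
                entries.append((v, i_tau, i_sigma, i_alpha))
                if best is None or v < best[0]:
                    best = (v, i_tau, i_sigma, i_alpha)
    v, i_tau, i_sigma, i_alpha = best
    params = table.params_at(i_tau, i_sigma, i_alpha)
    model_h = table.curves[i_tau, i_sigma, i_alpha, mask]
    residuals = np.abs(model_h - data_h) / np.abs(data_h)
    entries.sort(key=lambda t: t[0])
    runners = [
        {"tau": int(table.grid.taus[it]), "sigma_px": float(table.grid.sigmas[isg]),
         "alpha": float(table.grid.alphas[ia]), "sse": float(sv)}
        for sv, it, isg, ia in entries[1 : 1 + n_runners_up]
    ]
    return FitResult(params=params, indices=(i_tau, i_sigma, i_alpha), sse=v,
                     dt=lags, residuals=residuals, runners_up=runners)


def fit_report(fit: FitResult, data: ScalingCurve, table: LookupTable,
               threshold: float = 0.05) -> dict:
    """Residual diagnostics: within-range flag and beyond-range comparison."""
    within = bool(np.all(fit.residuals < threshold))
    beyond = []
    i_tau, i_sigma, i_alpha = fit.indices
    for k, dt in enumerate(table.dt):
        if dt <= fit.dt[-1]:
            continue
        try:
            dh = data.h_at(dt)
        except KeyError:
            continue
        mh = float(table.curves[i_tau, i_sigma, i_alpha, k])
        beyond.append({"dt_ms": float(dt), "h_data": dh, "h_model": mh,
                       "relative_residual": abs(mh - dh) / abs(dh)})
    report = fit.to_dict()
    report["residuals_below_threshold"] = within
    report["residual_threshold"] = threshold
    report["beyond_fit_range"] = beyond
    return report
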