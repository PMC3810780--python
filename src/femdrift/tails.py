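"""Maximum-likelihood fits to the tail of the step-length distribution.

Four candidate families are fitted to observations above a fixed lower
cutoff x_min (default 0.1 px, one coordinate-quantization unit):
lognormal, Weibull, power law with exponential cutoff, and exponential.
All likelihoods are truncated at x_min (density renormalized on
(x_min, inf)) so log-likelihoods are directly comparable across
families, in the spirit of Clauset-style tail fitting with x_min held
fixed. Step lengths are unimodal and heavy-tailed in practice; a
distinct second mode at high velocity would instead indicate
microsaccade contamination.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import integrate, optimize, stats

from .errors import InsufficientDataError, ParameterError

FAMILIES = ("lognormal", "weibull", "powerlaw_cutoff", "exponential")


@dataclass
class TailFitResult:
    family: str
    params: dict
    xmin: float
    loglik: float
    n_tail: int

    def to_dict(self) -> dict:
        return {
            "family": self.family,
            "params": self.params,
            "xmin": self.xmin,
            "loglik": self.loglik,
            "n_tail": self.n_tail,
        }

    def upper_cumulative(self, x: np.ndarray) -> np.ndarray:
        """P(X > x | X > xmin) for the fitted family (for plotting/export)."""
        x = np.asarray(x, dtype=float)
        if self.family == "exponential":
            return np.exp(-self.params["rate"] * (x - self.xmin))
        if self.family == "lognormal":
            d = stats.lognorm(self.params["s"], scale=np.exp(self.params["mu"]))
        elif self.family == "weibull":
            d = stats.weibull_min(self.params["shape"], scale=self.params["scale"])
        elif self.family == "powerlaw_cutoff":
            a, lam = self.params["exponent"], self.params["rate"]
            z = _plc_norm(a, lam, self.xmin)
            out = np.array(
                [integrate.quad(lambda u: u ** (-a) * np.exp(-lam * u), xi, np.inf)[0] / z
                 for xi in x]
            )
            return out
        else:  # pragma: no cover
            raise ParameterError(f"unknown family {self.family}")
        return d.sf(x) / d.sf(self.xmin)


def _plc_norm(a: float, lam: float, xmin: float) -> float:
    """Normalization integral of x^-a exp(-lam x) on (xmin, inf)."""
    val, _ = integrate.quad(lambda x: x ** (-a) * np.exp(-lam * x), xmin, np.inf)
    return val


def _fit_exponential(x: np.ndarray, xmin: float) -> tuple[dict, float]:
    rate = 1.0 / (float(np.mean(x)) - xmin)
    ll = len(x) * np.log(rate) - rate * float(np.sum(x - xmin))
    return {"rate": rate}, ll


def _truncated_ll(logpdf, logsf_xmin, x):
    with np.errstate(all="ignore"):
        ll = float(np.sum(logpdf(x)) - len(x) * logsf_xmin)
    return ll if np.isfinite(ll) else -np.inf


def _fit_lognormal(x: np.ndarray, xmin: float) -> tuple[dict, float]:
    logx = np.log(x)
    x0 = np.array([float(np.mean(logx)), np.log(max(float(np.std(logx)), 1e-3))])

    def neg(p):
        with np.errstate(all="ignore"):
            mu, s = p[0], np.exp(p[1])
            d = stats.lognorm(s, scale=np.exp(mu))
            return -_truncated_ll(d.logpdf, d.logsf(xmin), x)

    res = optimize.minimize(neg, x0, method="Nelder-Mead",
                            options={"xatol": 1e-8, "fatol": 1e-10, "maxiter": 2000})
    mu, s = float(res.x[0]), float(np.exp(res.x[1]))
    return {"mu": mu, "s": s}, -float(res.fun)


def _fit_weibull(x: np.ndarray, xmin: float) -> tuple[dict, float]:
    x0 = np.array([0.0, np.log(float(np.mean(x)))])

    def neg(p):
        with np.errstate(all="ignore"):
            k, c = np.exp(p[0]), np.exp(p[1])
            d = stats.weibull_min(k, scale=c)
            return -_truncated_ll(d.logpdf, d.logsf(xmin), x)

    res = optimize.minimize(neg, x0, method="Nelder-Mead",
                            options={"xatol": 1e-8, "fatol": 1e-10, "maxiter": 2000})
    k, c = float(np.exp(res.x[0])), float(np.exp(res.x[1]))
    return {"shape": k, "scale": c}, -float(res.fun)


def _fit_powerlaw_cutoff(x: np.ndarray, xmin: float) -> tuple[dict, float]:
    slogx, sx, n = float(np.sum(np.log(x))), float(np.sum(x)), len(x)
    x0 = np.array([1.0, np.log(1.0 / float(np.mean(x)))])

    def neg(p):
        a, lam = p[0], np.exp(p[1])
        if not (-10 < a < 20):
            return np.inf
        try:
            z = _plc_norm(a, lam, xmin)
        except Exception:
            return np.inf
        if not np.isfinite(z) or z <= 0:
            return np.inf
        return -(-n * np.log(z) - a * slogx - lam * sx)

    res = optimize.minimize(neg, x0, method="Nelder-Mead",
                            options={"xatol": 1e-8, "fatol": 1e-10, "maxiter": 2000})
    a, lam = float(res.x[0]), float(np.exp(res.x[1]))
    return {"exponent": a, "rate": lam}, -float(res.fun)


_FITTERS = {
    "exponential": _fit_exponential,
    "lognormal": _fit_lognormal,
    "weibull": _fit_weibull,
    "powerlaw_cutoff": _fit_powerlaw_cutoff,
}


def fit_step_tail(
    lengths: np.ndarray,
    family: str,
    xmin: float = 0.1,
    min_tail: int = 50,
) -> TailFitResult:
    """MLE of one family on the tail of step lengths above ``xmin``.

    The cutoff is held fixed; the likelihood is renormalized on
    (xmin, inf) so that log-likelihoods can be compared across families.
    """
    if family not in _FITTERS:
        raise ParameterError(f"unknown family {family!r}; choose from {FAMILIES}")
    x = np.asarray(lengths, dtype=float)
    x = x[x > xmin]
    if len(x) < min_tail:
        raise InsufficientDataError(
            f"only {len(x)} observations above xmin={xmin}; need >= {min_tail}"
        )
    params, ll = _FITTERS[family](x, xmin)
    if not np.isfinite(ll):
        raise ParameterError(f"{family} tail fit did not converge (loglik={ll})")
    return TailFitResult(family=family, params=params, xmin=xmin, loglik=ll, n_tail=len(x))


def compare_tail_families(lengths: np.ndarray, xmin: float = 0.1) -> dict[str, TailFitResult]:
    """Fit all four families; keys ordered by decreasing log-likelihood."""
    fits = {fam: fit_step_tail(lengths, fam, xmin=xmin) for fam in FAMILIES}
    return dict(sorted(fits.items(), key=lambda kv: -kv[1].loglik))
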