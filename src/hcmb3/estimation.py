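"""Frequentist estimation of hcMB-III parameters from an angle sample.

Eight methods are implemented, all as optimisation problems over the positive
shape triple (alpha, beta, gamma), parameterised internally as log-shapes so
every iterate stays in the positive orthant:

=======  ==============================================================
tag      objective
=======  ==============================================================
MLE      maximise the log-likelihood l(alpha, beta, gamma)
LSE      minimise sum_i (G(theta_(i)) - p_i)^2,   p_i = i/(n+1)
WLSE     minimise sum_i (G(theta_(i)) - p_i)^2 / V_i,
         V_i = i(n-i+1) / ((n+2)(n+1)^2)
PCE      minimise sum_i (t_(i) - Q_lin(p_i))^2 on the projected line
         t = tan(theta/2)  (an angle-scale variant is available)
MPSE     maximise (1/(n+1)) sum log[G(theta_(i)) - G(theta_(i-1))],
         with G(theta_(0)) = 0 and G(theta_(n+1)) = 1
CVME     minimise 1/(12n) + sum_i (G(theta_(i)) - (2i-1)/(2n))^2
ADE      minimise -n - (1/n) sum (2i-1)[log G_(i) + log(1-G_(n+1-i))]
RTADE    minimise n/2 - 2 sum G_(i) - (1/n) sum (2i-1) log(1-G_(n+1-i))
=======  ==============================================================

Optimisation is a derivative-free simplex (Nelder-Mead) search from eight
spread starting points (one of them a quartile-matching heuristic with
gamma = 1); the MLE is additionally polished by L-BFGS-B with the analytic
score.  MLE standard errors come from the inverse observed information
(the negative Hessian of l at the optimum, finite-differenced from the
analytic score), and asymptotic confidence intervals are
psi_hat +/- z_{lambda/2} * sqrt(diag J^-1).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy import optimize, special
from sklearn.base import BaseEstimator

from .distribution import HcParams, logpdf, pdf, validate_params

__all__ = [
    "FitResult",
    "METHODS",
    "log_likelihood",
    "score",
    "fit",
    "fit_mle",
    "fit_least_squares",
    "fit_percentile",
    "fit_mps",
    "fit_min_distance",
    "evaluate_objective",
    "HalfCircularMB3Estimator",
]

METHODS = ("MLE", "LSE", "WLSE", "PCE", "MPSE", "CVME", "ADE", "RTADE")

_CDF_FLOOR = 1e-300
_CDF_CEIL = 1.0 - 1e-16
# methods whose printed objective is maximised; internally all are minimised
_MAXIMIZED = {"MLE", "MPSE"}


@dataclass(frozen=True)
class FitResult:
    """Outcome of one estimation run."""

    method_tag: str
    params_hat: HcParams
    objective_value: float
    converged: bool
    n_obs: int
    n_starts_used: int
    se: Optional[tuple[float, float, float]] = None
    aci: Optional[tuple[tuple[float, float], ...]] = None
    message: str = ""


# ---------------------------------------------------------------------------
# sample cache: everything the objectives need, computed once per sample
# ---------------------------------------------------------------------------

class _Sample:
    __slots__ = ("theta", "theta_sorted", "t", "log_t", "n", "p_i", "v_i",
                 "sum_log_sec", "idx_2i1")

    def __init__(self, sample, min_n: int = 4):
        th = np.asarray(sample, dtype=float).ravel()
        if th.size < min_n:
            raise ValueError(f"need at least {min_n} observations, got {th.size}")
        if np.any(th <= 0) or np.any(th >= np.pi) or not np.all(np.isfinite(th)):
            raise ValueError("all angles must lie strictly inside (0, pi)")
        self.theta = th
        self.theta_sorted = np.sort(th)
        self.t = np.tan(self.theta_sorted / 2.0)
        self.log_t = np.log(self.t)
        self.n = th.size
        i = np.arange(1, self.n + 1, dtype=float)
        self.p_i = i / (self.n + 1)
        self.v_i = i * (self.n - i + 1) / ((self.n + 2) * (self.n + 1) ** 2)
        self.sum_log_sec = -np.sum(np.log(np.cos(th / 2.0)))
        self.idx_2i1 = 2.0 * i - 1.0

    def log_z(self, b, g):
        """log(1 + g * t^-b) at the sorted points, overflow-safe."""
        return np.logaddexp(0.0, np.log(g) - b * self.log_t)

    def cdf_sorted(self, a, b, g):
        return np.exp(-(a / g) * self.log_z(b, g))


# ---------------------------------------------------------------------------
# log-likelihood and analytic score
# ---------------------------------------------------------------------------

def _loglik(cache: _Sample, a, b, g) -> float:
    n = cache.n
    lz = cache.log_z(b, g)
    return (
        n * np.log(a) + n * np.log(b) - n * np.log(2.0)
        + 2.0 * cache.sum_log_sec
        - (b + 1.0) * np.sum(cache.log_t)
        - (a / g + 1.0) * np.sum(lz)
    )


def _score(cache: _Sample, a, b, g) -> np.ndarray:
    lz = cache.log_z(b, g)
    # t^-beta / (1 + g t^-beta) = 1 / (t^beta + g), computed overflow-safe
    with np.errstate(over="ignore"):
        w = 1.0 / (np.exp(b * cache.log_t) + g)
    s_lz = np.sum(lz)
    da = cache.n / a - s_lz / g
    db = cache.n / b - np.sum(cache.log_t) + (a + g) * np.sum(cache.log_t * w)
    dg = (a / g**2) * s_lz - (a / g + 1.0) * np.sum(w)
    return np.array([da, db, dg])


def log_likelihood(sample, params) -> float:
    """Log-likelihood l(alpha, beta, gamma) of an angle sample.

    Identical to ``sum(logpdf(theta_i))``; observations at the boundary
    contribute -inf.
    """
    p = validate_params(params)
    th = np.asarray(sample, dtype=float).ravel()
    if np.any(th <= 0):
        return -np.inf
    return float(_loglik(_Sample(th, min_n=1), *p))


def score(sample, params) -> np.ndarray:
    """Analytic gradient (dl/dalpha, dl/dbeta, dl/dgamma) of the log-likelihood."""
    p = validate_params(params)
    return _score(_Sample(sample, min_n=1), *p)


# ---------------------------------------------------------------------------
# objectives (all minimised internally)
# ---------------------------------------------------------------------------

def _log_expm1(x):
    x = np.asarray(x, dtype=float)
    with np.errstate(over="ignore"):
        out = np.where(x > 33.0, x, np.log(np.expm1(np.minimum(x, 33.0))))
    return out


def _obj_mle(cache, a, b, g):
    return -_loglik(cache, a, b, g)


def _obj_ls(cache, a, b, g, weighted: bool):
    r = cache.cdf_sorted(a, b, g) - cache.p_i
    return float(np.sum(r * r / cache.v_i)) if weighted else float(np.sum(r * r))


def _obj_pce(cache, a, b, g, scale: str):
    # linear MB-III quantile at p_i:  Q(p) = g^(1/b) * (p^(-g/a) - 1)^(-1/b)
    log_q = (np.log(g) - _log_expm1(-(g / a) * np.log(cache.p_i))) / b
    with np.errstate(over="ignore"):
        q = np.exp(log_q)
    if scale == "linear":
        r = cache.t - q
    elif scale == "angle":
        r = cache.theta_sorted - 2.0 * np.arctan(q)
    else:  # pragma: no cover - guarded upstream
        raise ValueError(f"unknown PCE scale {scale!r}")
    return float(np.sum(r * r))


def _obj_mps(cache, a, b, g):
    u = cache.cdf_sorted(a, b, g)
    d = np.diff(np.concatenate(([0.0], u, [1.0])))
    if np.any(d <= 0):
        # standard spacing repair: a tied (zero) spacing is replaced by the
        # density at the tied point
        bad = np.nonzero(d <= 0)[0]
        dens = pdf(cache.theta_sorted, (a, b, g))
        d = d.copy()
        for j in bad:
            d[j] = max(dens[min(j, cache.n - 1)], _CDF_FLOOR)
    return -float(np.mean(np.log(np.maximum(d, _CDF_FLOOR))))


def _obj_cvm(cache, a, b, g):
    n = cache.n
    r = cache.cdf_sorted(a, b, g) - cache.idx_2i1 / (2.0 * n)
    return 1.0 / (12.0 * n) + float(np.sum(r * r))


def _obj_ad(cache, a, b, g):
    n = cache.n
    u = np.clip(cache.cdf_sorted(a, b, g), _CDF_FLOOR, _CDF_CEIL)
    return -n - float(
        np.sum(cache.idx_2i1 * (np.log(u) + np.log1p(-u[::-1]))) / n
    )


def _obj_rtad(cache, a, b, g):
    n = cache.n
    u = np.clip(cache.cdf_sorted(a, b, g), _CDF_FLOOR, _CDF_CEIL)
    return (
        n / 2.0
        - 2.0 * float(np.sum(u))
        - float(np.sum(cache.idx_2i1 * np.log1p(-u[::-1]))) / n
    )


def _objective(cache, method: str, pce_scale: str):
    method = method.upper()
    if method == "MLE":
        return lambda a, b, g: _obj_mle(cache, a, b, g)
    if method == "LSE":
        return lambda a, b, g: _obj_ls(cache, a, b, g, False)
    if method == "WLSE":
        return lambda a, b, g: _obj_ls(cache, a, b, g, True)
    if method == "PCE":
        return lambda a, b, g: _obj_pce(cache, a, b, g, pce_scale)
    if method == "MPSE":
        return lambda a, b, g: _obj_mps(cache, a, b, g)
    if method == "CVME":
        return lambda a, b, g: _obj_cvm(cache, a, b, g)
    if method == "ADE":
        return lambda a, b, g: _obj_ad(cache, a, b, g)
    if method == "RTADE":
        return lambda a, b, g: _obj_rtad(cache, a, b, g)
    raise ValueError(f"unknown method {method!r}; known: {METHODS}")


# ---------------------------------------------------------------------------
# multistart optimiser
# ---------------------------------------------------------------------------

_FIXED_STARTS = (
    (1.0, 1.0, 1.0),
    (0.5, 2.0, 1.0),
    (2.0, 0.5, 2.0),
    (1.0, 4.0, 0.5),
    (4.0, 1.0, 4.0),
    (0.5, 0.5, 2.0),
    (3.0, 3.0, 3.0),
)


def _heuristic_start(cache: _Sample) -> tuple[float, float, float]:
    """Quartile-matching start: gamma = 1 and a log-logistic-style (alpha, beta)."""
    q1, q2, q3 = np.quantile(cache.t, [0.25, 0.5, 0.75])
    if q3 > q1 > 0:
        b0 = float(np.clip(2.0 * np.log(3.0) / np.log(q3 / q1), 0.2, 50.0))
    else:
        b0 = 1.0
    with np.errstate(over="ignore"):
        denom = np.log1p(q2 ** (-b0)) if q2 > 0 else np.inf
    a0 = float(np.clip(np.log(2.0) / denom, 0.05, 50.0)) if np.isfinite(denom) and denom > 0 else 1.0
    return (a0, b0, 1.0)


def _starts(cache: _Sample, n_starts: int) -> list[tuple[float, float, float]]:
    pool = [_heuristic_start(cache), *_FIXED_STARTS]
    if n_starts > len(pool):
        n_starts = len(pool)
    return pool[:n_starts]


def _minimize_multistart(cache, fun, n_starts, maxiter=2000):
    def in_z(z):
        with np.errstate(all="ignore"):
            v = fun(*np.exp(z))
        return v if np.isfinite(v) else 1e30

    best = None
    any_converged = False
    for s in _starts(cache, n_starts):
        res = optimize.minimize(
            in_z, np.log(s), method="Nelder-Mead",
            options=dict(maxiter=maxiter, xatol=1e-7, fatol=1e-9),
        )
        any_converged = any_converged or bool(res.success)
        if best is None or res.fun < best.fun:
            best = res
    return best, any_converged


def _observed_information(cache: _Sample, psi: np.ndarray) -> np.ndarray:
    """J = -Hessian of the log-likelihood at psi, by central differences of the score."""
    h = 1e-5 * np.maximum(np.abs(psi), 1.0)
    J = np.zeros((3, 3))
    for j in range(3):
        up, dn = psi.copy(), psi.copy()
        up[j] += h[j]
        dn[j] -= h[j]
        J[:, j] = -(_score(cache, *up) - _score(cache, *dn)) / (2.0 * h[j])
    return 0.5 * (J + J.T)


def fit(
    sample,
    method: str = "MLE",
    n_starts: int = 8,
    pce_scale: str = "linear",
    alpha_level: float = 0.05,
    compute_se: bool = True,
) -> FitResult:
    """Fit hcMB-III to an angle sample with one of the eight methods.

    Parameters
    ----------
    sample : array-like of angles in (0, pi), radians
    method : one of ``METHODS`` (case-insensitive)
    n_starts : number of simplex starting points (max 8)
    pce_scale : "linear" (tan(theta/2) residuals, the default) or "angle"
    alpha_level : 1 - confidence level of the MLE asymptotic intervals
    compute_se : attach observed-information SEs and ACIs to MLE fits
    """
    method = method.upper()
    if pce_scale not in ("linear", "angle"):
        raise ValueError(f"pce_scale must be 'linear' or 'angle', got {pce_scale!r}")
    cache = _Sample(sample)
    if method == "MPSE" and np.any(np.diff(cache.theta_sorted) == 0):
        warnings.warn(
            "tied observations: zero spacings are replaced by the density at "
            "the tied point in the MPS objective",
            stacklevel=2,
        )
    fun = _objective(cache, method, pce_scale)
    best, converged = _minimize_multistart(cache, fun, int(n_starts))

    if method == "MLE":
        # gradient polish in log-parameter space with the analytic score
        def nll_and_grad(z):
            psi = np.exp(z)
            with np.errstate(all="ignore"):
                val = -_loglik(cache, *psi)
                grad = -_score(cache, *psi) * psi
            if not np.isfinite(val):
                return 1e30, np.zeros(3)
            return val, grad

        pol = optimize.minimize(nll_and_grad, best.x, jac=True, method="L-BFGS-B")
        if np.isfinite(pol.fun) and pol.fun <= best.fun:
            best = pol
            converged = converged or bool(pol.success)

    psi = np.exp(best.x)
    # a fit that escapes along the alpha-gamma likelihood ridge (parameters
    # running away to the edge of the positive orthant) is not a convergence
    if np.any(psi > 1e5) or np.any(psi < 1e-5):
        converged = False
    params_hat = HcParams(*psi)
    obj = fun(*psi)
    if method in _MAXIMIZED:
        obj = -obj

    se = aci = None
    if method == "MLE" and compute_se:
        try:
            J = _observed_information(cache, psi)
            cov = np.linalg.inv(J)
            var = np.diag(cov)
            if np.all(var > 0):
                se = tuple(float(np.sqrt(v)) for v in var)
                zq = special.ndtri(1.0 - alpha_level / 2.0)
                aci = tuple(
                    (float(p - zq * s), float(p + zq * s)) for p, s in zip(psi, se)
                )
        except np.linalg.LinAlgError:  # singular information: report no SEs
            pass

    return FitResult(
        method_tag=method,
        params_hat=params_hat,
        objective_value=float(obj),
        converged=bool(converged),
        n_obs=cache.n,
        n_starts_used=min(int(n_starts), 1 + len(_FIXED_STARTS)),
        se=se,
        aci=aci,
    )


def evaluate_objective(sample, method: str, params, pce_scale: str = "linear") -> float:
    """Re-evaluate a method's objective (on its reported scale) at given parameters."""
    method = method.upper()
    cache = _Sample(sample)
    val = _objective(cache, method, pce_scale)(*validate_params(params))
    return float(-val) if method in _MAXIMIZED else float(val)


def fit_mle(sample, **kw) -> FitResult:
    """Maximum-likelihood fit with SEs and asymptotic confidence intervals."""
    return fit(sample, "MLE", **kw)


def fit_least_squares(sample, weighted: bool = False, **kw) -> FitResult:
    """Ordinary (LSE) or variance-weighted (WLSE) least-squares cdf fit."""
    return fit(sample, "WLSE" if weighted else "LSE", **kw)


def fit_percentile(sample, **kw) -> FitResult:
    """Percentile fit: match projected order statistics to model quantiles."""
    return fit(sample, "PCE", **kw)


def fit_mps(sample, **kw) -> FitResult:
    """Maximum-product-of-spacings fit."""
    return fit(sample, "MPSE", **kw)


def fit_min_distance(sample, which: str = "CVME", **kw) -> FitResult:
    """Minimum-distance fit: which in {"CVME", "ADE", "RTADE"}."""
    which = which.upper()
    if which not in ("CVME", "ADE", "RTADE"):
        raise ValueError(f"which must be CVME, ADE or RTADE, got {which!r}")
    return fit(sample, which, **kw)


class HalfCircularMB3Estimator(BaseEstimator):
    """scikit-learn style estimator for the hcMB-III shape parameters.

    Parameters
    ----------
    method : str, default "MLE"
        One of MLE, LSE, WLSE, PCE, MPSE, CVME, ADE, RTADE.
    n_starts : int, default 8
        Simplex starting points for the multistart search.
    pce_scale : {"linear", "angle"}, default "linear"
        Residual scale of the percentile objective.
    alpha_level : float, default 0.05
        1 - confidence level of the MLE asymptotic intervals.

    Attributes
    ----------
    alpha_, beta_, gamma_ : float
        Fitted shape parameters.
    params_ : HcParams
    result_ : FitResult
        Full fit diagnostics (objective, convergence, SEs/ACIs for MLE).

    Examples
    --------
    >>> from hcmb3 import HalfCircularMB3, HalfCircularMB3Estimator
    >>> theta = HalfCircularMB3(2, 3, 4).rvs(500, seed=0)
    >>> est = HalfCircularMB3Estimator(method="MPSE").fit(theta)
    >>> est.params_  # doctest: +SKIP
    HcParams(alpha=..., beta=..., gamma=...)
    """

    def __init__(self, method: str = "MLE", n_starts: int = 8,
                 pce_scale: str = "linear", alpha_level: float = 0.05):
        self.method = method
        self.n_starts = n_starts
        self.pce_scale = pce_scale
        self.alpha_level = alpha_level

    @staticmethod
    def _as_angles(X) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        if X.ndim == 2 and X.shape[1] == 1:
            X = X[:, 0]
        if X.ndim != 1:
            raise ValueError("expected a 1-d array of angles or an (n, 1) column")
        return X

    def fit(self, X, y=None):
        theta = self._as_angles(X)
        self.result_ = fit(
            theta, method=self.method, n_starts=self.n_starts,
            pce_scale=self.pce_scale, alpha_level=self.alpha_level,
        )
        self.params_ = self.result_.params_hat
        self.alpha_, self.beta_, self.gamma_ = self.params_
        self.n_features_in_ = 1
        return self

    def score_samples(self, X) -> np.ndarray:
        """Log-density of the fitted distribution at the given angles."""
        self._check_fitted()
        return np.atleast_1d(logpdf(self._as_angles(X), self.params_))

    def score(self, X, y=None) -> float:
        """Mean log-likelihood per observation under the fitted distribution."""
        return float(np.mean(self.score_samples(X)))

    def sample(self, n_samples: int = 1, random_state=None) -> np.ndarray:
        from .distribution import rng as _rng
        self._check_fitted()
        return _rng(n_samples, self.params_, np.random.default_rng(random_state))

    def _check_fitted(self):
        if not hasattr(self, "params_"):
            raise AttributeError("estimator is not fitted; call fit() first")
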