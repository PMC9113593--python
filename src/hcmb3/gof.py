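"""Model selection and distribution-adequacy statistics for fitted families.

Information criteria from a maximised likelihood (k parameters, n points):

    AIC  = -2l + 2k
    CAIC = AIC + 2k(k+1)/(n-k-1)      (the finite-sample corrected AIC)
    BIC  = -2l + k log n

Adequacy statistics from the fitted probability integral transforms
u_i = F_hat(theta_(i)):

    W^2 = sum_i (u_i - (2i-1)/(2n))^2 + 1/(12n)
    A^2 = -n - (1/n) sum_i (2i-1) [log u_i + log(1 - u_{n+1-i})]

with the usual small-sample modifications W* = W^2 (1 + 0.5/n) and
A* = A^2 (1 + 0.75/n + 2.25/n^2) applied by default.  The Kolmogorov-Smirnov
statistic uses the asymptotic Kolmogorov distribution for its p-value.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Callable, Optional, Sequence

import numpy as np
from scipy import optimize, special

from .families import FAMILIES, ProjectedFamily, family_cdf, family_logpdf

__all__ = [
    "GofReport",
    "information_criteria",
    "gof_statistics",
    "ks_test",
    "ttt_transform",
    "fit_family_mle",
    "compare_models",
    "write_report",
]


@dataclass(frozen=True)
class GofReport:
    model: str
    minus2loglik: float
    aic: float
    caic: float
    bic: float
    a_star: float
    w_star: float
    ks_stat: float
    ks_pvalue: float
    k_params: int
    n_obs: int
    params: tuple = ()
    fit_ok: bool = True


def information_criteria(minus2loglik: float, k: int, n: int):
    """(AIC, CAIC, BIC) from -2 log-likelihood with k parameters and n observations."""
    k, n = int(k), int(n)
    aic = minus2loglik + 2.0 * k
    if n <= k + 1:
        raise ValueError(f"CAIC undefined for n={n} <= k+1={k + 1}")
    caic = aic + 2.0 * k * (k + 1) / (n - k - 1)
    bic = minus2loglik + k * np.log(n)
    return float(aic), float(caic), float(bic)


def _pit(sample, fitted_cdf) -> np.ndarray:
    th = np.sort(np.asarray(sample, dtype=float).ravel())
    u = np.asarray(fitted_cdf(th), dtype=float)
    if np.any(u <= 0.0) or np.any(u >= 1.0):
        warnings.warn("fitted cdf values at {0,1} clamped for log-based statistics",
                      stacklevel=3)
        u = np.clip(u, 1e-300, 1.0 - 1e-16)
    return u


def gof_statistics(sample, fitted_cdf, modified: bool = True):
    """(A*, W*): Anderson-Darling and Cramer-von Mises adequacy statistics.

    ``modified=False`` returns the raw A^2, W^2 without the small-sample
    correction factors.
    """
    u = _pit(sample, fitted_cdf)
    n = u.size
    if n < 2:
        raise ValueError("need at least two observations")
    i = np.arange(1, n + 1)
    w2 = float(np.sum((u - (2 * i - 1) / (2 * n)) ** 2) + 1.0 / (12 * n))
    a2 = float(-n - np.sum((2 * i - 1) * (np.log(u) + np.log1p(-u[::-1]))) / n)
    if modified:
        return a2 * (1.0 + 0.75 / n + 2.25 / n**2), w2 * (1.0 + 0.5 / n)
    return a2, w2


def ks_test(sample, fitted_cdf):
    """One-sample Kolmogorov-Smirnov statistic and asymptotic p-value."""
    th = np.sort(np.asarray(sample, dtype=float).ravel())
    n = th.size
    if n < 1:
        raise ValueError("empty sample")
    u = np.asarray(fitted_cdf(th), dtype=float)
    i = np.arange(1, n + 1)
    d = float(np.max(np.maximum(i / n - u, u - (i - 1) / n)))
    pvalue = float(special.kolmogorov(np.sqrt(n) * d))
    return d, pvalue


def ttt_transform(sample):
    """Scaled total-time-on-test curve of a positive sample.

    Returns ``(u, g, increasing_hazard)`` where u_r = r/n, g_r =
    [sum_{i<=r} x_(i) + (n-r) x_(r)] / sum x_(i) for r = 0..n, and
    ``increasing_hazard`` flags a concave curve (curve above the diagonal on
    average).
    """
    x = np.sort(np.asarray(sample, dtype=float).ravel())
    n = x.size
    if n < 2:
        raise ValueError("need at least two observations")
    total = x.sum()
    if total <= 0:
        raise ValueError("TTT transform needs positive values")
    cums = np.concatenate(([0.0], np.cumsum(x)))
    r = np.arange(0, n + 1)
    g = (cums + (n - r) * np.concatenate(([0.0], x))) / total
    g[-1] = 1.0  # pin the normalisation against cumsum round-off
    u = r / n
    increasing = bool(np.mean(g[1:-1] - u[1:-1]) > 0)
    return u, g, increasing


# ---------------------------------------------------------------------------
# per-family maximum likelihood and the model-comparison table
# ---------------------------------------------------------------------------

_FAMILY_STARTS_2 = ((1.0, 1.0), (0.5, 2.0), (2.0, 0.5), (4.0, 1.0), (1.0, 4.0), (3.0, 3.0))
_FAMILY_STARTS_3 = (
    (1.0, 1.0, 1.0), (0.5, 2.0, 1.0), (2.0, 0.5, 2.0), (1.0, 4.0, 0.5),
    (4.0, 1.0, 4.0), (0.5, 0.5, 2.0), (3.0, 3.0, 3.0), (2.0, 3.0, 4.0),
)


def fit_family_mle(sample, family_tag: str, n_starts: int = 8):
    """Maximum-likelihood fit of any registered projected family.

    Returns ``(ProjectedFamily, loglik, converged)``.
    """
    th = np.asarray(sample, dtype=float).ravel()
    spec = FAMILIES[family_tag]  # KeyError on unknown tag is informative enough

    if family_tag == "hcmb3":
        from .estimation import fit as _fit_mb3

        res = _fit_mb3(th, "MLE", n_starts=n_starts, compute_se=False)
        fam = ProjectedFamily("hcmb3", tuple(res.params_hat))
        return fam, res.objective_value, res.converged

    def nll(z):
        with np.errstate(all="ignore"):
            lp = family_logpdf(th, ProjectedFamily(family_tag, tuple(np.exp(z))))
            v = -np.sum(lp)
        return v if np.isfinite(v) else 1e30

    starts = _FAMILY_STARTS_3 if spec.n_params == 3 else _FAMILY_STARTS_2
    best, converged = None, False
    for s in starts[:n_starts]:
        res = optimize.minimize(nll, np.log(s), method="Nelder-Mead",
                                options=dict(maxiter=2000, xatol=1e-7, fatol=1e-9))
        converged = converged or bool(res.success)
        if best is None or res.fun < best.fun:
            best = res
    fam = ProjectedFamily(family_tag, tuple(np.exp(best.x)))
    return fam, -float(best.fun), converged


def compare_models(sample, families: Sequence[str], n_starts: int = 8) -> list[GofReport]:
    """Fit each family by MLE and rank the GoF reports by AIC (ties by BIC).

    Per-family fit failures produce a row with ``fit_ok=False`` and NaN
    statistics instead of aborting the comparison.
    """
    th = np.asarray(sample, dtype=float).ravel()
    n = th.size
    if len(families) < 1:
        raise ValueError("need at least one family")
    reports = []
    for tag in families:
        try:
            fam, loglik, _ = fit_family_mle(th, tag, n_starts=n_starts)
            m2l = -2.0 * loglik
            k = FAMILIES[tag].n_params
            aic, caic, bic = information_criteria(m2l, k, n)
            cdf = lambda x, fam=fam: family_cdf(x, fam)
            a_star, w_star = gof_statistics(th, cdf)
            d, p = ks_test(th, cdf)
            reports.append(GofReport(tag, m2l, aic, caic, bic, a_star, w_star,
                                     d, p, k, n, fam.params, True))
        except Exception as exc:  # noqa: BLE001 - per-row failure is reported, not fatal
            warnings.warn(f"fit of family {tag!r} failed: {exc}", stacklevel=2)
            nan = float("nan")
            reports.append(GofReport(tag, nan, nan, nan, nan, nan, nan, nan, nan,
                                     FAMILIES.get(tag, None).n_params if tag in FAMILIES else 0,
                                     n, (), False))
    reports.sort(key=lambda r: (not r.fit_ok, r.aic if np.isfinite(r.aic) else np.inf,
                                r.bic if np.isfinite(r.bic) else np.inf))
    return reports


def write_report(reports: Sequence[GofReport], path, sep: str = "\t") -> None:
    """Write the model-comparison table as delimited text, one model per row."""
    cols = ("model", "minus2loglik", "aic", "caic", "bic", "a_star", "w_star",
            "ks_stat", "ks_pvalue")
    with open(path, "w") as fh:
        fh.write(sep.join(cols) + "\n")
        for r in reports:
            fh.write(sep.join([r.model] + [f"{getattr(r, c):.10g}" for c in cols[1:]]) + "\n")
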