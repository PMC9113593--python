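"""Projected half-circular families related to hcMB-III.

Each family is a linear law on (0, inf) pushed onto [0, pi) through the
inverse stereographic projection x = tan(theta/2):

    G(theta) = F_linear(tan(theta/2)),
    g(theta) = (1/2) * sec^2(theta/2) * f_linear(tan(theta/2)).

Registry tags:

========  ==========================================  ==========
tag       linear cdf at x = tan(theta/2)              parameters
========  ==========================================  ==========
hcmb3     [1 + g*x^-b]^(-a/g)                         (a, b, g)
hcburr3   [1 + x^-b]^(-a)                             (a, b)
hcgiw     exp(-g * (a/x)^b)                           (a, b, g)
hcll      1 / (1 + a^b * x^-b)                        (a, b)
hcgamma   gamma(shape=a, rate=b)                      (a, b)
hcburr12  1 - (1 + x^c)^(-k)                          (c, k)
========  ==========================================  ==========

The two-parameter hcgamma/hcburr12 projections use the textbook linear cdfs
(scipy.stats gamma and burr12); scipy.stats.burr is the Burr III law and
scipy.stats.fisk the log-logistic, so those stand behind hcburr3/hcll.
"""

from __future__ import annotations

from typing import Callable, NamedTuple

import numpy as np
from scipy import stats

from .distribution import linear_cdf as _mb3_linear_cdf, validate_params

__all__ = ["FAMILIES", "ProjectedFamily", "family_cdf", "family_pdf", "family_logpdf"]


class _FamilySpec(NamedTuple):
    n_params: int
    param_names: tuple[str, ...]
    linear_cdf: Callable[[np.ndarray, tuple], np.ndarray]
    linear_logpdf: Callable[[np.ndarray, tuple], np.ndarray]


def _mb3_linear_logpdf(x, p):
    a, b, g = p
    lx = np.log(x)
    return (
        np.log(a) + np.log(b) - (b + 1.0) * lx
        + (-a / g - 1.0) * np.logaddexp(0.0, np.log(g) - b * lx)
    )


def _giw_linear_cdf(x, p):
    a, b, g = p
    return np.exp(-g * (a / np.asarray(x, dtype=float)) ** b)


def _giw_linear_logpdf(x, p):
    a, b, g = p
    x = np.asarray(x, dtype=float)
    return np.log(g) + np.log(b) + b * np.log(a) - (b + 1.0) * np.log(x) - g * (a / x) ** b


FAMILIES: dict[str, _FamilySpec] = {
    "hcmb3": _FamilySpec(
        3, ("alpha", "beta", "gamma"),
        lambda x, p: _mb3_linear_cdf(x, p),
        _mb3_linear_logpdf,
    ),
    "hcburr3": _FamilySpec(
        2, ("alpha", "beta"),
        lambda x, p: stats.burr.cdf(x, c=p[1], d=p[0]),
        lambda x, p: stats.burr.logpdf(x, c=p[1], d=p[0]),
    ),
    "hcgiw": _FamilySpec(
        3, ("alpha", "beta", "gamma"),
        _giw_linear_cdf,
        _giw_linear_logpdf,
    ),
    "hcll": _FamilySpec(
        2, ("alpha", "beta"),
        lambda x, p: stats.fisk.cdf(x, c=p[1], scale=p[0]),
        lambda x, p: stats.fisk.logpdf(x, c=p[1], scale=p[0]),
    ),
    "hcgamma": _FamilySpec(
        2, ("alpha", "beta"),
        lambda x, p: stats.gamma.cdf(x, a=p[0], scale=1.0 / p[1]),
        lambda x, p: stats.gamma.logpdf(x, a=p[0], scale=1.0 / p[1]),
    ),
    "hcburr12": _FamilySpec(
        2, ("c", "k"),
        lambda x, p: stats.burr12.cdf(x, c=p[0], d=p[1]),
        lambda x, p: stats.burr12.logpdf(x, c=p[0], d=p[1]),
    ),
}


class ProjectedFamily(NamedTuple):
    """A tagged member of the projected-family registry with its parameters."""

    family_tag: str
    params: tuple

    def validate(self) -> "ProjectedFamily":
        if self.family_tag not in FAMILIES:
            raise KeyError(
                f"unknown family {self.family_tag!r}; known: {sorted(FAMILIES)}"
            )
        spec = FAMILIES[self.family_tag]
        p = tuple(float(v) for v in self.params)
        if len(p) != spec.n_params:
            raise ValueError(
                f"{self.family_tag} takes {spec.n_params} parameters, got {len(p)}"
            )
        if any((not np.isfinite(v)) or v <= 0 for v in p):
            raise ValueError(f"{self.family_tag} parameters must be positive, got {p}")
        if self.family_tag == "hcmb3":
            validate_params(p)
        return ProjectedFamily(self.family_tag, p)


def _tan_half(theta):
    th = np.asarray(theta, dtype=float)
    if np.any(th < 0) or np.any(th >= np.pi) or not np.all(np.isfinite(th)):
        raise ValueError("angles must lie in [0, pi)")
    return np.tan(th / 2.0)


def family_cdf(theta, family: ProjectedFamily):
    """Projected cdf F_linear(tan(theta/2)) of a registered family."""
    fam = family.validate()
    t = _tan_half(theta)
    out = np.where(t > 0, FAMILIES[fam.family_tag].linear_cdf(np.maximum(t, 1e-300), fam.params), 0.0)
    return float(out) if np.ndim(theta) == 0 else out


def family_logpdf(theta, family: ProjectedFamily):
    """Projected log-density: log f_linear(tan(theta/2)) + 2 log sec(theta/2) - log 2."""
    fam = family.validate()
    th = np.asarray(theta, dtype=float)
    t = _tan_half(th)
    jac = -np.log(2.0) - 2.0 * np.log(np.cos(th / 2.0))
    with np.errstate(divide="ignore", invalid="ignore"):
        lp = FAMILIES[fam.family_tag].linear_logpdf(np.maximum(t, 1e-300), fam.params)
    out = np.where(t > 0, lp + jac, -np.inf)
    return float(out) if np.ndim(theta) == 0 else out


def family_pdf(theta, family: ProjectedFamily):
    return np.exp(family_logpdf(theta, family))
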