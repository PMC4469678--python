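"""Closed-form two-pass performance and consistency predictions.

For the observers defined in :mod:`ppmatch.observer_models` this module
evaluates, as a function of the decision-variable signal-to-noise ratio
``d'_D`` and the internal-to-external noise ratio ``rho = sigma_I/sigma_E``:

* ``p_C``   — proportion correct on a single pass;
* ``p_CC``  — probability of two correct responses on a repeated pair;
* ``p_II``  — probability of two incorrect responses;
* ``p_A = p_CC + p_II`` — probability of agreeing responses.

For the probability-matching (VPPM) observer, working in units of the total
decision-variable SD, the posterior of the correct response on a signal-A
trial is the logistic ``f(u) = expit(-d'(u - d'/2))`` and

    p_C  = E[f(U)],                         U ~ N(0, 1)
    p_CC = E_u[ m(u)^2 ],   m(u) = E_v[f(u + v)]
    p_II = E_u[ (1 - m(u))^2 ]

where u is the (scaled) shared external part, with SD ``1/sqrt(1+rho^2)``,
and v the internal part, with SD ``1/sqrt(1+rho^-2)``.  These are the
standard double-integral forms; they are evaluated by nested adaptive
quadrature, with a tensor Gauss-Hermite grid available as a cross-check.

For the unbiased MAP observer ``p_C = Phi(d'/2)``, and the pair of passes
is a bivariate normal with correlation ``c = 1/(1+rho^2)``, so

    p_CC = Phi2(d'/2, d'/2; c),   p_II = Phi2(-d'/2, -d'/2; c)

which this module evaluates exactly through Owen's T function; the
equivalent single-integral quadrature forms are kept as ``method="quad"``.

``rho`` may be 0 or ``inf``; values below 1e-6 / above 1e6 are routed to
the analytic limits to avoid overflow in the ``(1 + rho^-2)`` terms.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import NamedTuple, Sequence

import numpy as np
from scipy import integrate
from scipy.special import expit, ndtr, owens_t

__all__ = [
    "TheoryPoint",
    "TwoPassProbs",
    "vppm_pc",
    "vppm_pa",
    "map_pc",
    "map_pa",
    "model_curves",
    "iso_rho_contour",
    "agreement_floor",
    "DEFAULT_D_GRID",
    "DEFAULT_RHOS",
]

# rho outside these bounds is treated as the analytic 0 / infinity limit
RHO_LO = 1e-6
RHO_HI = 1e6
# infinite integrals truncated at this many effective SDs of the Gaussian weight
TRUNC_SD = 10.0
_EPSABS = 1e-10

# the (d', rho) grids used for the model two-pass curves
DEFAULT_D_GRID = tuple(np.linspace(0.0, 2.6, 8))
DEFAULT_RHOS = (0.0, 1.0, 2.0)


class TwoPassProbs(NamedTuple):
    p_CC: float
    p_II: float
    p_A: float


@dataclass(frozen=True)
class TheoryPoint:
    """One (d'_D, rho) point of a model two-pass curve."""

    rule: str
    d_prime_D: float
    rho: float
    p_C: float
    p_CC: float
    p_II: float
    p_A: float


def _check_dprime(d_prime_D: float) -> float:
    d = float(d_prime_D)
    if not math.isfinite(d) or d < 0:
        raise ValueError(f"d_prime_D must be finite and >= 0, got {d_prime_D}")
    return d


def _check_rho(rho: float) -> float:
    r = float(rho)
    if math.isnan(r) or r < 0:
        raise ValueError(f"rho must be >= 0 (or inf), got {rho}")
    return r


def _phi(x):
    return np.exp(-0.5 * x * x) / math.sqrt(2.0 * math.pi)


def _f_correct(u, d):
    # posterior probability of the correct response on a signal-A trial,
    # expressed as a logistic: phi(u) / (phi(u) + phi(u - d'))
    return expit(-d * (u - d / 2.0))


def agreement_floor(p_C: float) -> float:
    """Agreement of two independent passes: p_C^2 + (1-p_C)^2 (rho->inf)."""
    return p_C * p_C + (1.0 - p_C) * (1.0 - p_C)


# --------------------------------------------------------------------------
# VPPM observer
# --------------------------------------------------------------------------

def vppm_pc(d_prime_D: float) -> float:
    """Proportion correct of the probability-matching observer.

    Evaluates the single integral E[f(U)] with U ~ N(0,1) by adaptive
    quadrature.  Depends on d'_D only (the internal/external split does not
    affect single-pass performance).  Lies in [0.5, 1).
    """
    d = _check_dprime(d_prime_D)
    if d == 0.0:
        return 0.5
    lo, hi = -TRUNC_SD, TRUNC_SD + d
    val, _ = integrate.quad(lambda u: _phi(u) * _f_correct(u, d), lo, hi,
                            epsabs=_EPSABS, limit=200)
    return float(val)


def _vppm_pa_quad(d: float, rho: float, trunc: float, epsabs: float) -> TwoPassProbs:
    s_u = 1.0 / math.sqrt(1.0 + rho * rho)        # SD of shared external part
    s_v = 1.0 / math.sqrt(1.0 + rho ** -2)        # SD of internal part

    def m(u):
        val, _ = integrate.quad(
            lambda v: _f_correct(u + v, d) * _phi(v / s_v) / s_v,
            -trunc * s_v, trunc * s_v, epsabs=epsabs, limit=200)
        return val

    def outer(sq_of):
        val, _ = integrate.quad(
            lambda u: sq_of(m(u)) ** 2 * _phi(u / s_u) / s_u,
            -trunc * s_u, trunc * s_u, epsabs=epsabs, limit=200)
        return val

    p_cc = outer(lambda x: x)
    p_ii = outer(lambda x: 1.0 - x)
    return TwoPassProbs(float(p_cc), float(p_ii), float(p_cc + p_ii))


def _vppm_pa_tensor(d: float, rho: float, n_nodes: int = 201) -> TwoPassProbs:
    # tensor Gauss-Hermite fallback on the same nested-expectation form
    x, w = np.polynomial.hermite_e.hermegauss(n_nodes)
    w = w / math.sqrt(2.0 * math.pi)
    s_u = 1.0 / math.sqrt(1.0 + rho * rho)
    s_v = 1.0 / math.sqrt(1.0 + rho ** -2)
    u = s_u * x[:, None]
    v = s_v * x[None, :]
    m = _f_correct(u + v, d) @ w
    p_cc = float(np.dot(w, m * m))
    p_ii = float(np.dot(w, (1.0 - m) ** 2))
    return TwoPassProbs(p_cc, p_ii, p_cc + p_ii)


def _vppm_pa_rho0(d: float, trunc: float, epsabs: float) -> TwoPassProbs:
    # degenerate inner integral: m(u) = f(u), u ~ N(0,1)
    lo, hi = -trunc, trunc + d
    p_cc, _ = integrate.quad(lambda u: _phi(u) * _f_correct(u, d) ** 2,
                             lo, hi, epsabs=epsabs, limit=200)
    p_ii, _ = integrate.quad(lambda u: _phi(u) * (1 - _f_correct(u, d)) ** 2,
                             lo, hi, epsabs=epsabs, limit=200)
    return TwoPassProbs(float(p_cc), float(p_ii), float(p_cc + p_ii))


def vppm_pa(d_prime_D: float, rho: float, method: str = "quad",
            trunc: float = TRUNC_SD, epsabs: float = _EPSABS) -> TwoPassProbs:
    """(p_CC, p_II, p_A) for the probability-matching observer.

    ``rho`` may be 0 (degenerate inner integral) or ``inf`` (independent
    passes, ``p_A = p_C^2 + (1-p_C)^2``).  ``method`` is ``"quad"`` (nested
    adaptive quadrature, default) or ``"tensor"`` (Gauss-Hermite grid).
    """
    d = _check_dprime(d_prime_D)
    r = _check_rho(rho)
    if d == 0.0:
        return TwoPassProbs(0.25, 0.25, 0.5)
    if r > RHO_HI or math.isinf(r):
        p_c = vppm_pc(d)
        return TwoPassProbs(p_c * p_c, (1 - p_c) ** 2, agreement_floor(p_c))
    if r < RHO_LO:
        return _vppm_pa_rho0(d, trunc, epsabs)
    if method == "quad":
        return _vppm_pa_quad(d, r, trunc, epsabs)
    if method == "tensor":
        return _vppm_pa_tensor(d, r)
    raise ValueError(f"unknown method {method!r}")


# --------------------------------------------------------------------------
# MAP observer
# --------------------------------------------------------------------------

def map_pc(d_prime_D: float) -> float:
    """Proportion correct of the unbiased MAP observer: Phi(d'_D / 2)."""
    d = _check_dprime(d_prime_D)
    return float(ndtr(d / 2.0))


def _phi2_hh(h, c):
    """P(X <= h, Y <= h) for standard bivariate normal with correlation c."""
    h = np.asarray(h, dtype=float)
    c = np.asarray(c, dtype=float)
    c = np.clip(c, 0.0, 1.0)
    k = np.sqrt((1.0 - c) / (1.0 + c))
    return ndtr(h) - 2.0 * owens_t(h, k)


def _map_pa_bvn(d: float, rho: float) -> TwoPassProbs:
    h = d / 2.0
    c = 1.0 / (1.0 + rho * rho)
    p_cc = float(_phi2_hh(h, c))
    p_ii = float(_phi2_hh(-h, c))
    return TwoPassProbs(p_cc, p_ii, p_cc + p_ii)


def _map_pa_quad(d: float, rho: float, trunc: float, epsabs: float) -> TwoPassProbs:
    # single-integral forms: p_CC = rho * Int Phi(a - u)^2 phi(rho u) du,
    # a = d'/2 * sqrt(1 + rho^-2); after t = rho*u the weight is standard
    # normal and the sigmoid-squared step sits at t ~ d'/2 * sqrt(1+rho^2)
    a = d / 2.0 * math.sqrt(1.0 + rho ** -2)
    t0 = min(max(d / 2.0 * math.sqrt(1.0 + rho * rho), -trunc), trunc)

    def one(sign):
        val, _ = integrate.quad(
            lambda t: ndtr(sign * (a - t / rho)) ** 2 * _phi(t),
            -trunc, trunc, points=[t0], epsabs=epsabs, limit=400)
        return val

    p_cc = one(+1.0)
    p_ii = one(-1.0)
    return TwoPassProbs(float(p_cc), float(p_ii), float(p_cc + p_ii))


def map_pa(d_prime_D: float, rho: float, method: str = "bvn",
           trunc: float = TRUNC_SD, epsabs: float = _EPSABS) -> TwoPassProbs:
    """(p_CC, p_II, p_A) for the unbiased MAP observer.

    ``method="bvn"`` (default) evaluates the exact bivariate-normal
    orthant form through Owen's T; ``method="quad"`` evaluates the
    single-integral quadrature forms.  ``rho=0`` gives p_A = 1 (both
    passes identical); ``rho=inf`` gives independent passes.
    """
    d = _check_dprime(d_prime_D)
    r = _check_rho(rho)
    p_c = map_pc(d)
    if r < RHO_LO:
        return TwoPassProbs(p_c, 1.0 - p_c, 1.0)
    if r > RHO_HI or math.isinf(r):
        return TwoPassProbs(p_c * p_c, (1 - p_c) ** 2, agreement_floor(p_c))
    if method == "bvn":
        return _map_pa_bvn(d, r)
    if method == "quad":
        return _map_pa_quad(d, r, trunc, epsabs)
    raise ValueError(f"unknown method {method!r}")


def map_pa_vec(d_prime_D, rho):
    """Vectorized p_A for the MAP observer (closed form; arrays broadcast)."""
    d = np.asarray(d_prime_D, dtype=float)
    r = np.asarray(rho, dtype=float)
    h = d / 2.0
    with np.errstate(divide="ignore"):
        c = 1.0 / (1.0 + r * r)
    return _phi2_hh(h, c) + _phi2_hh(-h, c)


# --------------------------------------------------------------------------
# Curves and contours
# --------------------------------------------------------------------------

def model_curves(rule: str, rho: float,
                 d_grid: Sequence[float] = DEFAULT_D_GRID) -> list[TheoryPoint]:
    """(p_C, p_A) points along a d'_D grid at fixed rho for one rule."""
    d_grid = list(d_grid)
    if not d_grid:
        raise ValueError("d_grid must be nonempty")
    pts = []
    for d in d_grid:
        if rule == "vppm":
            p_c = vppm_pc(d)
            probs = vppm_pa(d, rho)
        elif rule == "map":
            p_c = map_pc(d)
            probs = map_pa(d, rho)
        else:
            raise ValueError(f"unknown rule {rule!r}")
        pts.append(TheoryPoint(rule=rule, d_prime_D=float(d), rho=float(rho),
                               p_C=p_c, p_CC=probs.p_CC, p_II=probs.p_II,
                               p_A=probs.p_A))
    return pts


def iso_rho_contour(rho: float,
                    d_grid: Sequence[float] = DEFAULT_D_GRID) -> list[tuple[float, float]]:
    """MAP (p_A, p_C) locus at fixed rho over a d' grid.

    The rho=inf contour is the parabola p_A = p_C^2 + (1-p_C)^2 through
    (0.5, 0.5); rho=0 gives p_A = 1 everywhere.
    """
    out = []
    for d in d_grid:
        p_c = map_pc(d)
        p_a = map_pa(d, rho).p_A
        out.append((float(p_a), float(p_c)))
    return out
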