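"""Apparent internal-to-external noise estimation (Burgess-Colborne inversion).

Given observed two-pass proportions (p_C_hat, p_A_hat), find the sensitivity
d'_D and internal-to-external noise ratio rho of the additive-Gaussian MAP
observer that reproduces them, by numerically minimizing

    (p_C_hat - p_C(d', rho))^2 + (p_A_hat - p_A(d', rho))^2

against the MAP closed forms.  On the feasible interior this is a
two-equation / two-unknown system and the residual is ~0.  The estimate is
called the *apparent* ratio, written rho_tilde: applied to a MAP observer
it recovers the true sigma_I/sigma_E, while applied to a probability
matcher it attributes extra apparent noise to the matching rule.

Feasibility: two independent passes at proportion correct p agree with
probability p^2 + (1-p)^2, so observed points below that parabola cannot be
reached at any finite rho; they are reported as rho_tilde = +inf with
``feasible=False``.  Points exactly on the parabola (e.g. chance
performance with chance agreement, (0.5, 0.5)) are feasible with
rho_tilde = +inf.

The bootstrap follows the binomial-resampling scheme with 10,000 replicates
by default; correct and consistent counts are resampled independently.
Estimates whose upper 95% bound exceeds twice the point estimate are
flagged as discarded.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, replace

import numpy as np
from scipy import optimize
from scipy.special import ndtr, ndtri

from .observer_models import TwoPassSummary
from .two_pass_theory import agreement_floor, map_pa, map_pa_vec, map_pc, vppm_pa, vppm_pc

__all__ = [
    "TwoPassSummary",
    "NoiseEstimate",
    "estimate_apparent_noise",
    "vppm_apparent_rho_curve",
    "bootstrap_ci",
    "apply_discard_rule",
]

_BOUNDARY_TOL = 1e-12
# coarse search grids: d' in [0, 6]; rho 0 plus log-spaced in [0.05, 20]
_D_GRID = np.linspace(0.0, 6.0, 61)
_RHO_GRID = np.concatenate([[0.0], np.geomspace(0.05, 20.0, 60)])
_GRID_CACHE: dict[str, np.ndarray] = {}


@dataclass(frozen=True)
class NoiseEstimate:
    """Output of the apparent-noise inversion for one condition."""

    d_prime_hat: float
    rho_tilde: float          # may be +inf
    objective: float          # residual sum of squares at the optimum
    feasible: bool            # False iff input lies below the rho=inf parabola
    p_C_hat: float
    p_A_hat: float
    ci_low: float = math.nan  # bootstrap 95% bounds on rho_tilde
    ci_high: float = math.nan
    discarded: bool = False


def _grids():
    if "pa" not in _GRID_CACHE:
        _GRID_CACHE["pc"] = np.array([map_pc(d) for d in _D_GRID])
        _GRID_CACHE["pa"] = map_pa_vec(_D_GRID[:, None], _RHO_GRID[None, :])
    return _GRID_CACHE["pc"], _GRID_CACHE["pa"]


def _as_proportions(summary):
    if isinstance(summary, TwoPassSummary):
        return summary.p_C_hat, summary.p_A_hat
    p_c, p_a = summary
    return float(p_c), float(p_a)


def _reflect(p_c: float) -> float:
    if p_c < 0.5:
        warnings.warn(
            f"p_C_hat={p_c:.4f} < 0.5; reflecting to {1 - p_c:.4f} "
            "(unbiased-observer assumption)", stacklevel=3)
        return 1.0 - p_c
    return p_c


def _boundary_objective(p_c: float, p_a: float) -> float:
    # best fit restricted to the rho=inf contour p_A = p_C^2 + (1-p_C)^2
    def g(d):
        pc = map_pc(d)
        return (p_c - pc) ** 2 + (p_a - agreement_floor(pc)) ** 2

    res = optimize.minimize_scalar(g, bounds=(0.0, 10.0), method="bounded")
    return float(res.fun)


def estimate_apparent_noise(summary) -> NoiseEstimate:
    """Invert observed (p_C_hat, p_A_hat) to apparent (d'_hat, rho_tilde).

    ``summary`` is a :class:`TwoPassSummary` or a ``(p_C_hat, p_A_hat)``
    pair.  Minimization: the sum-of-squares objective is evaluated on a
    cached coarse grid (d' in [0, 6]; rho = 0 plus log-spaced values up to
    20, ties broken toward the smallest rho), then refined with bounded
    Nelder-Mead.  Inputs on or below the independence parabola return
    rho_tilde = +inf.
    """
    p_c, p_a = _as_proportions(summary)
    if not (0.0 <= p_c <= 1.0 and 0.0 <= p_a <= 1.0):
        raise ValueError(f"proportions outside [0, 1]: ({p_c}, {p_a})")
    p_c = _reflect(p_c)
    d_hat0 = 2.0 * float(ndtri(p_c)) if p_c < 1.0 else math.inf
    floor = agreement_floor(p_c)
    if p_a <= floor + _BOUNDARY_TOL:
        feasible = p_a >= floor - _BOUNDARY_TOL
        obj = 0.0 if feasible else _boundary_objective(p_c, p_a)
        return NoiseEstimate(d_prime_hat=d_hat0, rho_tilde=math.inf,
                             objective=obj, feasible=feasible,
                             p_C_hat=p_c, p_A_hat=p_a)

    def objective(x):
        d, r = x
        if d < 0 or r < 0:
            return 1e6
        probs = map_pa(d, r)
        return (p_c - map_pc(d)) ** 2 + (p_a - probs.p_A) ** 2

    pc_grid, pa_grid = _grids()
    obj_grid = (p_c - pc_grid[:, None]) ** 2 + (p_a - pa_grid) ** 2
    best = float(np.min(obj_grid))
    cand = np.argwhere(obj_grid <= best + 1e-15)   # tie-break to smallest rho
    jj = int(cand[:, 1].min())
    ii = int(cand[cand[:, 1] == jj][0, 0])
    x0 = np.array([_D_GRID[ii], _RHO_GRID[jj]])
    res = optimize.minimize(
        objective, x0, method="Nelder-Mead",
        bounds=[(0.0, 10.0), (0.0, 50.0)],
        options={"xatol": 1e-9, "fatol": 1e-18, "maxiter": 4000, "maxfev": 4000})
    d_hat, rho_tilde = float(res.x[0]), float(res.x[1])
    return NoiseEstimate(d_prime_hat=d_hat, rho_tilde=rho_tilde,
                         objective=float(res.fun), feasible=True,
                         p_C_hat=p_c, p_A_hat=p_a)


def _invert_rho_vec(p_c: np.ndarray, p_a: np.ndarray, n_bisect: int = 80) -> np.ndarray:
    """Vectorized profile inversion used by the bootstrap.

    d' is pinned by p_C (d' = 2 Phi^-1(p_C)); p_A is monotone decreasing in
    rho, equivalently increasing in the pass correlation c = 1/(1+rho^2),
    so rho is found by bisection on c in [0, 1].
    """
    p_c = np.clip(np.where(p_c < 0.5, 1.0 - p_c, p_c), 0.5, 1.0 - 1e-12)
    d = 2.0 * ndtri(p_c)
    h = d / 2.0
    floor = p_c ** 2 + (1.0 - p_c) ** 2

    from .two_pass_theory import _phi2_hh  # local import to keep API surface small

    def pa_of_c(c):
        return _phi2_hh(h, c) + _phi2_hh(-h, c)

    rho = np.full(p_c.shape, np.nan)
    infeasible = p_a <= floor + _BOUNDARY_TOL
    saturated = p_a >= 1.0 - 1e-15
    todo = ~(infeasible | saturated)
    lo = np.zeros(p_c.shape)
    hi = np.ones(p_c.shape)
    for _ in range(n_bisect):
        mid = 0.5 * (lo + hi)
        too_high = pa_of_c(mid) > p_a     # agreement too high -> need lower c
        hi = np.where(too_high, mid, hi)
        lo = np.where(too_high, lo, mid)
    c = 0.5 * (lo + hi)
    with np.errstate(divide="ignore"):
        rho_todo = np.sqrt(np.clip(1.0 / c - 1.0, 0.0, np.inf))
    rho[todo] = rho_todo[todo]
    rho[infeasible] = np.inf
    rho[saturated] = 0.0
    return rho


def bootstrap_ci(summary: TwoPassSummary, n_boot: int = 10_000,
                 rng: np.random.Generator | None = None) -> tuple[float, float]:
    """Percentile 95% bootstrap CI on rho_tilde.

    Resamples n_correct ~ Binomial(n_trials, p_C_hat) and
    n_consistent ~ Binomial(n_pairs, p_A_hat) independently, re-estimates
    rho_tilde for each replicate, and returns the 2.5% / 97.5% percentiles.
    Infinite replicate estimates sort to the upper end.
    """
    if n_boot < 2:
        raise ValueError(f"n_boot must be >= 2, got {n_boot}")
    if rng is None:
        rng = np.random.default_rng()
    p_c, p_a = summary.p_C_hat, summary.p_A_hat
    pc_b = rng.binomial(summary.n_trials, p_c, size=n_boot) / summary.n_trials
    pa_b = rng.binomial(summary.n_pairs, p_a, size=n_boot) / summary.n_pairs
    rho_b = _invert_rho_vec(pc_b, pa_b)
    # order-statistic quantiles: no interpolation, so infinite replicates
    # (which sort to the top) cannot produce inf - inf artifacts
    lo, hi = np.quantile(rho_b, [0.025, 0.975], method="nearest")
    return float(lo), float(hi)


def apply_discard_rule(estimate: NoiseEstimate) -> NoiseEstimate:
    """Flag unreliable estimates: CI upper bound > 2x the point estimate.

    Infinite rho_tilde is always discarded.
    """
    if math.isinf(estimate.rho_tilde):
        return replace(estimate, discarded=True)
    discarded = bool(estimate.ci_high > 2.0 * estimate.rho_tilde)
    return replace(estimate, discarded=discarded)


def vppm_apparent_rho_curve(rho_true: float, pc_grid) -> list[tuple[float, float]]:
    """Apparent noise ratio attributed to a VPPM observer, vs. p_C.

    For each target proportion correct: solve the VPPM performance integral
    for d', compute the VPPM agreement at ``rho_true``, and invert through
    the MAP model.  Targets at or below chance map to +inf.  For the
    noiseless matcher the curve rises steeply toward +inf as p_C -> 0.5.
    """
    out = []
    for p_c in pc_grid:
        p_c = float(p_c)
        if p_c <= 0.5:
            out.append((p_c, math.inf))
            continue
        if p_c >= 1.0:
            raise ValueError(f"target p_C must be < 1, got {p_c}")
        d = optimize.brentq(lambda x: vppm_pc(x) - p_c, 1e-9, 14.0, xtol=1e-12)
        p_a = vppm_pa(d, rho_true).p_A
        est = estimate_apparent_noise((p_c, p_a))
        out.append((p_c, est.rho_tilde))
    return out
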