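"""Efficiency of the probability-matching observer relative to the ideal.

Efficiency is the squared ratio of an observer's sensitivity to the ideal
observer's: eta = (d'/d'_ideal)^2.  The best case for the probability
matcher is analyzed: no internal noise and a decision variable that carries
all task-relevant information, so the ideal's sensitivity is the
decision-variable signal-to-noise ratio d'_D itself, while the matcher's
apparent sensitivity is read off its proportion correct as
d' = 2 Phi^-1(p_C).  Matching is strictly suboptimal, so eta < 1 for every
d'_D > 0.  Efficiency is carried as a fraction; percentage formatting is
left to the presentation layer.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import optimize
from scipy.special import ndtri

from .two_pass_theory import vppm_pc

__all__ = [
    "EfficiencyPoint",
    "apparent_dprime",
    "vppm_efficiency",
    "vppm_efficiency_at_pc",
    "DEFAULT_EFFICIENCY_D_GRID",
]

# evaluation grid for the efficiency-vs-performance curve
DEFAULT_EFFICIENCY_D_GRID = tuple(np.linspace(0.3, 4.7, 12))
_BRACKET = (1e-4, 12.0)


@dataclass(frozen=True)
class EfficiencyPoint:
    d_prime_D: float          # ideal sensitivity
    p_C: float                # matcher's proportion correct at that d'_D
    d_prime_apparent: float   # 2 Phi^-1(p_C)
    eta: float                # (d_prime_apparent / d_prime_D)^2, in (0, 1]


def apparent_dprime(p_C: float) -> float:
    """Sensitivity an unbiased 2AFC observer appears to have: 2 Phi^-1(p_C)."""
    if not (0.5 <= p_C < 1.0):
        raise ValueError(f"p_C must be in [0.5, 1), got {p_C}")
    return 2.0 * float(ndtri(p_C))


def vppm_efficiency(d_prime_D: float) -> EfficiencyPoint:
    """Best-case efficiency of the noiseless probability matcher at d'_D."""
    if not (d_prime_D > 0):
        raise ValueError(f"d_prime_D must be > 0, got {d_prime_D}")
    p_c = vppm_pc(d_prime_D)
    d_app = apparent_dprime(p_c)
    return EfficiencyPoint(d_prime_D=float(d_prime_D), p_C=p_c,
                           d_prime_apparent=d_app,
                           eta=(d_app / d_prime_D) ** 2)


def vppm_efficiency_at_pc(p_C_target: float) -> EfficiencyPoint:
    """Efficiency at a target performance level.

    Root-solves the matcher's performance integral for d'_D (monotone, so
    the root in the bracket (1e-4, 12) is unique) and evaluates eta there.
    """
    if not (0.5 < p_C_target < 1.0):
        raise ValueError(f"p_C_target must be in (0.5, 1), got {p_C_target}")
    lo, hi = _BRACKET
    if vppm_pc(hi) < p_C_target:
        raise ValueError(f"p_C_target={p_C_target} not attainable below d'={hi}")
    d = optimize.brentq(lambda x: vppm_pc(x) - p_C_target, lo, hi, xtol=1e-10)
    if abs(vppm_pc(d) - p_C_target) > 1e-6:
        raise RuntimeError("root solve failed to reach target performance")
    return vppm_efficiency(d)


def efficiency_curve(d_grid=DEFAULT_EFFICIENCY_D_GRID) -> list[EfficiencyPoint]:
    """Efficiency along a d'_D grid (default: evenly spaced on [0.3, 4.7])."""
    return [vppm_efficiency(d) for d in d_grid]
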