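"""Decision-variable observer models for two-alternative tasks.

An observer in a 2AFC (or two-alternative identification) task is modelled
at the level of a scalar decision variable ``D = E + I``.  ``E`` is the
stimulus-driven ("external") component: normal with mean 0 on signal-A
trials, mean ``mu_E`` on signal-B trials, and standard deviation ``sigma_E``
on both.  ``I`` is additive internal noise: zero-mean normal with standard
deviation ``sigma_I``, independent of ``E`` and redrawn on every
presentation.  The two signals are equally likely a priori.

Two decision rules are implemented:

* the *veridical posterior probability matching* (VPPM) rule, which responds
  A with probability equal to the true posterior ``P(A | d)``;
* the *maximum a posteriori* (MAP) rule, which deterministically picks the
  response with the larger posterior — equivalent to comparing ``d`` with
  the unbiased criterion ``mu_E / 2``.

Response coding: throughout this package response/signal ``"A"`` is encoded
as 0 and ``"B"`` as 1 wherever an integer coding is needed.

In a *two-pass* trial pair the external sample ``e`` is shared between the
two passes while the internal sample is drawn fresh, which is what makes
response consistency informative about the internal/external noise split.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.special import expit

__all__ = [
    "DecisionModel",
    "TwoPassTrialPair",
    "TwoPassSummary",
    "posterior_A",
    "vppm_respond",
    "map_respond",
    "simulate_two_pass",
]

SIGNALS = ("A", "B")


@dataclass(frozen=True)
class DecisionModel:
    """Gaussian decision-variable observer.

    Parameters
    ----------
    mu_E:
        Mean of the external component on signal-B trials (decision-variable
        units).  Signal-A trials have mean zero.
    sigma_E:
        Standard deviation of the external component; must be positive.
    sigma_I:
        Standard deviation of the additive internal noise; non-negative.
    """

    mu_E: float
    sigma_E: float = 1.0
    sigma_I: float = 0.0

    def __post_init__(self) -> None:
        if not (self.sigma_E > 0):
            raise ValueError(f"sigma_E must be > 0, got {self.sigma_E}")
        if self.sigma_I < 0:
            raise ValueError(f"sigma_I must be >= 0, got {self.sigma_I}")
        if not all(map(math.isfinite, (self.mu_E, self.sigma_E, self.sigma_I))):
            raise ValueError("model parameters must be finite")

    @property
    def sigma_D(self) -> float:
        """Total SD of the decision variable, sqrt(sigma_E^2 + sigma_I^2)."""
        return math.hypot(self.sigma_E, self.sigma_I)

    @property
    def d_prime_D(self) -> float:
        """Signal-to-noise ratio of the decision variable, mu_E / sigma_D."""
        return self.mu_E / self.sigma_D

    @property
    def rho(self) -> float:
        """Internal-to-external noise ratio sigma_I / sigma_E."""
        return self.sigma_I / self.sigma_E

    @classmethod
    def from_dprime_rho(cls, d_prime_D: float, rho: float,
                        sigma_E: float = 1.0) -> "DecisionModel":
        """Build a model with the given d'_D and rho (sigma_E fixed)."""
        if rho < 0:
            raise ValueError(f"rho must be >= 0, got {rho}")
        sigma_I = rho * sigma_E
        mu_E = d_prime_D * math.hypot(sigma_E, sigma_I)
        return cls(mu_E=mu_E, sigma_E=sigma_E, sigma_I=sigma_I)


@dataclass(frozen=True)
class TwoPassTrialPair:
    """One repeated trial: shared external sample, fresh internal samples."""

    pair_id: int
    signal: str              # "A" or "B"
    e: float                 # shared external sample (includes signal mean)
    i1: float                # internal sample, first pass
    i2: float                # internal sample, second pass
    r1: str                  # response, first pass
    r2: str                  # response, second pass


@dataclass(frozen=True)
class TwoPassSummary:
    """Counts from a two-pass run: correctness over trials, agreement over pairs.

    ``n_trials`` is the number of trials entering the proportion-correct
    denominator (2 * n_pairs for pure two-pass data, possibly more when
    unrepeated trials at the same signal level are pooled in).
    """

    n_pairs: int
    n_trials: int
    n_correct: int
    n_consistent: int

    def __post_init__(self) -> None:
        if self.n_pairs < 0 or self.n_trials < 0:
            raise ValueError("counts must be non-negative")
        if not (0 <= self.n_consistent <= self.n_pairs):
            raise ValueError(
                f"n_consistent={self.n_consistent} outside [0, {self.n_pairs}]")
        if not (0 <= self.n_correct <= self.n_trials):
            raise ValueError(
                f"n_correct={self.n_correct} outside [0, {self.n_trials}]")

    @property
    def p_C_hat(self) -> float:
        return self.n_correct / self.n_trials

    @property
    def p_A_hat(self) -> float:
        return self.n_consistent / self.n_pairs


def posterior_A(d, model: DecisionModel):
    """Posterior probability that the signal was A, given decision variable d.

    With equal priors, Bayes' theorem on the two Gaussian likelihoods reduces
    to a logistic in d:

        P(A|d) = phi(d; 0, s) / (phi(d; 0, s) + phi(d; mu_E, s))
               = expit(-mu_E (d - mu_E/2) / s^2),   s = sigma_D.

    Accepts scalars or arrays; rejects non-finite d.
    """
    d = np.asarray(d, dtype=float)
    if not np.all(np.isfinite(d)):
        raise ValueError("decision-variable sample d must be finite")
    s2 = model.sigma_D ** 2
    out = expit(-model.mu_E * (d - model.mu_E / 2.0) / s2)
    return float(out) if out.ndim == 0 else out


def vppm_respond(d, model: DecisionModel, rng: np.random.Generator):
    """Probability-matching response: A with probability P(A|d).

    Scalar d gives a scalar response ("A"/"B"); arrays vectorize.
    """
    p_a = posterior_A(d, model)
    draw = rng.random(np.shape(p_a))
    resp = np.where(draw < p_a, "A", "B")
    return str(resp) if resp.ndim == 0 else resp


def map_respond(d, model: DecisionModel):
    """MAP response: the alternative with the larger posterior.

    Implemented as the equivalent comparison of d with the midpoint
    criterion mu_E/2 (d below the criterion favours A), which also covers
    the mu_E = 0 case where the posterior is flat at 0.5.  The measure-zero
    tie at d == mu_E/2 is resolved in favour of A.
    """
    d = np.asarray(d, dtype=float)
    if not np.all(np.isfinite(d)):
        raise ValueError("decision-variable sample d must be finite")
    resp = np.where(d <= model.mu_E / 2.0, "A", "B")
    return str(resp) if resp.ndim == 0 else resp


def _responses(d, signal_is_b, model, rule, rng):
    if rule == "vppm":
        return vppm_respond(d, model, rng)
    if rule == "map":
        return map_respond(d, model)
    raise ValueError(f"unknown rule {rule!r}; expected 'vppm' or 'map'")


def simulate_two_pass(model: DecisionModel, n_pairs: int, rule: str,
                      rng: np.random.Generator, keep_records: bool = True):
    """Simulate a two-pass experiment of ``n_pairs`` repeated trials.

    Each pair draws a signal (fair Bernoulli), a shared external sample e,
    and two independent internal samples; responses follow ``rule``
    ("vppm" or "map").

    Returns ``(pairs, summary)`` where pairs is a list of
    :class:`TwoPassTrialPair` (or ``None`` when ``keep_records=False``,
    useful for large Monte-Carlo runs) and summary a :class:`TwoPassSummary`.
    """
    if n_pairs < 1:
        raise ValueError(f"n_pairs must be >= 1, got {n_pairs}")
    sig_b = rng.random(n_pairs) < 0.5           # fair draw per pair
    e = model.mu_E * sig_b + model.sigma_E * rng.standard_normal(n_pairs)
    i1 = model.sigma_I * rng.standard_normal(n_pairs)
    i2 = model.sigma_I * rng.standard_normal(n_pairs)
    r1 = _responses(e + i1, sig_b, model, rule, rng)
    r2 = _responses(e + i2, sig_b, model, rule, rng)
    signal = np.where(sig_b, "B", "A")
    n_correct = int(np.sum(r1 == signal) + np.sum(r2 == signal))
    n_consistent = int(np.sum(r1 == r2))
    summary = TwoPassSummary(n_pairs=n_pairs, n_trials=2 * n_pairs,
                             n_correct=n_correct, n_consistent=n_consistent)
    pairs = None
    if keep_records:
        pairs = [
            TwoPassTrialPair(pair_id=k, signal=str(signal[k]), e=float(e[k]),
                             i1=float(i1[k]), i2=float(i2[k]),
                             r1=str(r1[k]), r2=str(r2[k]))
            for k in range(n_pairs)
        ]
    return pairs, summary
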