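"""Synthetic two-pass 2AFC experiments at the decision-variable level.

Emulates the two experimental designs analysed by this package:

* **exp1** — long-run design: 33 blocks of 300 trials.  Signal magnitude
  ("contrast") follows a 1-up 2-down staircase (converging near 70.7%
  correct).  Within every block, trials 101-150 are replayed verbatim as
  trials 151-200: same signal, same contrast, same external-noise sample,
  fresh internal noise, staircase suspended.  Pooled over blocks this
  yields >= 100 repeated pairs at each of several contrast levels.
* **exp2** — short design: 500 trials per observer.  Trials 1-100 run the
  staircase; a Weibull psychometric function is then fit by maximum
  likelihood to those trials and inverted for the contrasts giving 65% and
  80% correct.  Trials 101-500 use those two contrasts in random order,
  organised as four 100-trial two-pass blocks (second 50 trials replay the
  first 50).

The bridge from contrast to the decision variable is linear transduction,
d'_D(c) = k * c with sigma_E fixed at 1, the minimal mapping consistent
with modelling observers at the decision-variable level.  The observer rule
("map" or "vppm") and its internal-to-external noise ratio are pluggable.

The staircase's step size, start value, and step law are not part of the
emulated protocol's contract (only its convergence target is); they default
to multiplicative 2 dB steps (factor 10**0.1) from a start contrast at
d' = 2 and are config-exposed; with 2 dB steps the pooled long-design
blocks concentrate at least 100 repeated pairs on 4-6 contrast levels, the
structure the protocol reports.

Trial indices are 1-based so that "trials 101-150" reads the same here as
in the protocol description.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import optimize

from .observer_models import DecisionModel, map_respond, vppm_respond

__all__ = [
    "ProtocolConfig",
    "TrialRecord",
    "WeibullFit",
    "WeibullFitError",
    "StaircaseState",
    "staircase_1up2down",
    "run_exp1",
    "run_exp2",
    "run_experiment",
    "fit_weibull",
]


@dataclass(frozen=True)
class ProtocolConfig:
    """Configuration of a synthetic experiment run.

    ``repeat_span`` maps a 1-based inclusive source span to its replay span
    within each block; the two spans must have equal length and must not
    overlap.
    """

    design: str                          # "exp1" or "exp2"
    n_blocks: int
    block_length: int
    repeat_span: tuple[tuple[int, int], tuple[int, int]]
    rule: str = "map"                    # observer decision rule
    rho: float = 0.0                     # sigma_I / sigma_E of the observer
    gain: float = 1.0                    # k in d'_D(c) = k * c
    start_contrast: float = 2.0          # staircase start (d' ~ 2 at k = 1)
    step_factor: float = 10.0 ** 0.1     # multiplicative staircase step (2 dB)
    n_staircase_trials: int = 100        # exp2: leading staircase segment
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.design not in ("exp1", "exp2"):
            raise ValueError(f"design must be 'exp1' or 'exp2', got {self.design!r}")
        (a0, a1), (b0, b1) = self.repeat_span
        if (a1 - a0) != (b1 - b0):
            raise ValueError("replay span must equal source span in length")
        if not (a1 < b0 or b1 < a0):
            raise ValueError("source and replay spans must not overlap")
        if self.start_contrast <= 0 or self.gain <= 0:
            raise ValueError("contrasts and gain must be positive")
        if self.step_factor <= 1.0:
            raise ValueError("step_factor must be > 1")

    @classmethod
    def exp1(cls, **kw) -> "ProtocolConfig":
        kw.setdefault("n_blocks", 33)
        kw.setdefault("block_length", 300)
        kw.setdefault("repeat_span", ((101, 150), (151, 200)))
        return cls(design="exp1", **kw)

    @classmethod
    def exp2(cls, **kw) -> "ProtocolConfig":
        # four two-pass blocks of 100 trials after the 100-trial staircase
        kw.setdefault("n_blocks", 4)
        kw.setdefault("block_length", 100)
        kw.setdefault("repeat_span", ((1, 50), (51, 100)))
        return cls(design="exp2", **kw)


@dataclass(frozen=True)
class TrialRecord:
    """One 2AFC trial.  ``pair_id`` links the two passes of a repeated pair
    (None for unrepeated trials).  ``e``/``i`` are the latent external and
    internal samples, kept for replay-integrity checks and debug output."""

    block: int
    trial_index: int          # 1-based, running within the whole session
    pair_id: int | None
    signal: str               # "A" or "B"
    contrast: float
    response: str
    correct: bool
    e: float = math.nan
    i: float = math.nan


class WeibullFitError(RuntimeError):
    """Raised when the psychometric-function fit fails or is non-identifiable."""


@dataclass(frozen=True)
class WeibullFit:
    """Weibull psychometric function p(c) = 0.5 + 0.5 (1 - exp(-(c/alpha)^beta)).

    Guess rate fixed at 0.5 (2AFC), no lapse; p(0) = 0.5 and p is monotone
    increasing with threshold parameter alpha > 0 and slope beta > 0.
    """

    alpha: float
    beta: float
    log_likelihood: float = math.nan

    def predict(self, c):
        c = np.asarray(c, dtype=float)
        p = 0.5 + 0.5 * (1.0 - np.exp(-((c / self.alpha) ** self.beta)))
        return float(p) if p.ndim == 0 else p

    def inverse(self, p: float) -> float:
        """Contrast at which the fitted function reaches proportion correct p."""
        if not (0.5 < p < 1.0):
            raise ValueError(f"p must be in (0.5, 1), got {p}")
        return self.alpha * (-math.log(2.0 * (1.0 - p))) ** (1.0 / self.beta)


# --------------------------------------------------------------------------
# Staircase
# --------------------------------------------------------------------------

@dataclass
class StaircaseState:
    """Contrast is tracked as an integer step index on a multiplicative
    ladder, so that every visit to the same level yields a bit-identical
    contrast value (required for exact per-level pooling downstream)."""

    base_contrast: float
    step_factor: float = 10.0 ** 0.1
    step_index: int = 0
    correct_streak: int = 0

    def __post_init__(self) -> None:
        if self.base_contrast <= 0:
            raise ValueError("contrast must be positive")

    @property
    def contrast(self) -> float:
        return self.base_contrast * self.step_factor ** self.step_index


def staircase_1up2down(state: StaircaseState, last_correct: bool) -> float:
    """Advance a 1-up 2-down staircase by one trial outcome; returns the
    contrast for the next trial.

    Each incorrect response raises contrast by one multiplicative step; two
    consecutive correct responses lower it by one step.  The asymptotic
    fixed point is the contrast where p(correct) = 1/sqrt(2) ~ 0.707.
    """
    if last_correct:
        state.correct_streak += 1
        if state.correct_streak == 2:
            state.step_index -= 1
            state.correct_streak = 0
    else:
        state.step_index += 1
        state.correct_streak = 0
    return state.contrast


# --------------------------------------------------------------------------
# Trial generation
# --------------------------------------------------------------------------

def _model_at(config: ProtocolConfig, contrast: float) -> DecisionModel:
    return DecisionModel(mu_E=config.gain * contrast, sigma_E=1.0,
                         sigma_I=config.rho)


def _play_trial(config, contrast, signal, e, i, rng):
    model = _model_at(config, contrast)
    d = e + i
    if config.rule == "vppm":
        resp = vppm_respond(d, model, rng)
    elif config.rule == "map":
        resp = map_respond(d, model)
    else:
        raise ValueError(f"unknown rule {config.rule!r}")
    return resp, resp == signal


def _fresh_trial(config, contrast, rng):
    signal = "B" if rng.random() < 0.5 else "A"
    model = _model_at(config, contrast)
    e = (model.mu_E if signal == "B" else 0.0) + rng.standard_normal()
    i = config.rho * rng.standard_normal()
    resp, correct = _play_trial(config, contrast, signal, e, i, rng)
    return signal, e, i, resp, correct


def run_exp1(config: ProtocolConfig, rng: np.random.Generator) -> list[TrialRecord]:
    """Run the long two-pass design; returns one TrialRecord per trial.

    Per block: trials up to the source span end are staircased; the replay
    span repeats the source span verbatim (signal, contrast, external
    sample) with fresh internal noise and the staircase frozen; remaining
    trials resume the staircase.  The staircase state carries across blocks.
    """
    if config.design != "exp1":
        raise ValueError(f"config.design must be 'exp1', got {config.design!r}")
    (src0, src1), (rep0, rep1) = config.repeat_span
    stair = StaircaseState(base_contrast=config.start_contrast,
                           step_factor=config.step_factor)
    records: list[TrialRecord] = []
    pair_counter = 0
    trial_counter = 0
    for block in range(1, config.n_blocks + 1):
        source: list[TrialRecord] = []
        for t in range(1, config.block_length + 1):
            trial_counter += 1
            if rep0 <= t <= rep1:
                # verbatim replay of the source span, staircase suspended
                src = source[t - rep0]
                i = config.rho * rng.standard_normal()
                resp, correct = _play_trial(config, src.contrast, src.signal,
                                            src.e, i, rng)
                records.append(TrialRecord(
                    block=block, trial_index=trial_counter,
                    pair_id=src.pair_id, signal=src.signal,
                    contrast=src.contrast, response=resp, correct=correct,
                    e=src.e, i=i))
                continue
            contrast = stair.contrast
            signal, e, i, resp, correct = _fresh_trial(config, contrast, rng)
            pair_id = None
            if src0 <= t <= src1:
                pair_counter += 1
                pair_id = pair_counter
            rec = TrialRecord(block=block, trial_index=trial_counter,
                              pair_id=pair_id, signal=signal, contrast=contrast,
                              response=resp, correct=correct, e=e, i=i)
            records.append(rec)
            if pair_id is not None:
                source.append(rec)
            staircase_1up2down(stair, correct)
    return records


def run_exp2(config: ProtocolConfig, rng: np.random.Generator) -> list[TrialRecord]:
    """Run the short design: staircase, Weibull threshold selection, then
    two-pass blocks at the fitted 65%- and 80%-correct contrasts."""
    if config.design != "exp2":
        raise ValueError(f"config.design must be 'exp2', got {config.design!r}")
    stair = StaircaseState(base_contrast=config.start_contrast,
                           step_factor=config.step_factor)
    records: list[TrialRecord] = []
    trial_counter = 0
    for _ in range(config.n_staircase_trials):
        trial_counter += 1
        contrast = stair.contrast
        signal, e, i, resp, correct = _fresh_trial(config, contrast, rng)
        records.append(TrialRecord(block=0, trial_index=trial_counter,
                                   pair_id=None, signal=signal,
                                   contrast=contrast, response=resp,
                                   correct=correct, e=e, i=i))
        staircase_1up2down(stair, correct)

    fit = fit_weibull(records)
    c_low, c_high = fit.inverse(0.65), fit.inverse(0.80)

    (src0, src1), (rep0, rep1) = config.repeat_span
    pair_counter = 0
    for block in range(1, config.n_blocks + 1):
        source: list[TrialRecord] = []
        for t in range(1, config.block_length + 1):
            trial_counter += 1
            if rep0 <= t <= rep1:
                src = source[t - rep0]
                i = config.rho * rng.standard_normal()
                resp, correct = _play_trial(config, src.contrast, src.signal,
                                            src.e, i, rng)
                records.append(TrialRecord(
                    block=block, trial_index=trial_counter,
                    pair_id=src.pair_id, signal=src.signal,
                    contrast=src.contrast, response=resp, correct=correct,
                    e=src.e, i=i))
                continue
            contrast = c_low if rng.random() < 0.5 else c_high
            signal, e, i, resp, correct = _fresh_trial(config, contrast, rng)
            pair_counter += 1
            rec = TrialRecord(block=block, trial_index=trial_counter,
                              pair_id=pair_counter, signal=signal,
                              contrast=contrast, response=resp,
                              correct=correct, e=e, i=i)
            records.append(rec)
            source.append(rec)
    return records


def run_experiment(config: ProtocolConfig,
                   rng: np.random.Generator | None = None) -> list[TrialRecord]:
    """Dispatch on config.design; seeds a generator from config.seed if needed."""
    if rng is None:
        rng = np.random.default_rng(config.seed)
    return run_exp1(config, rng) if config.design == "exp1" else run_exp2(config, rng)


# --------------------------------------------------------------------------
# Psychometric function fitting
# --------------------------------------------------------------------------

def fit_weibull(trials) -> WeibullFit:
    """Maximum-likelihood Weibull fit to per-trial (contrast, correct) data.

    ``trials`` is a list of TrialRecords or a ``(contrasts, correct)`` pair
    of arrays.  The Bernoulli log-likelihood is maximized over
    log-parameterized (alpha, beta).  Requires at least two distinct
    contrast levels and both outcomes present.
    """
    if isinstance(trials, tuple):
        c, y = np.asarray(trials[0], float), np.asarray(trials[1], bool)
    else:
        c = np.array([t.contrast for t in trials], dtype=float)
        y = np.array([t.correct for t in trials], dtype=bool)
    if len(np.unique(c)) < 2:
        raise WeibullFitError("need >= 2 distinct contrast levels")
    if y.all() or (~y).all():
        raise WeibullFitError("need both correct and incorrect outcomes")

    def nll(theta):
        alpha, beta = np.exp(theta)
        p = 0.5 + 0.5 * (1.0 - np.exp(-((c / alpha) ** beta)))
        p = np.clip(p, 1e-9, 1.0 - 1e-9)
        return -float(np.sum(np.where(y, np.log(p), np.log1p(-p))))

    # staircase data cluster near threshold, which leaves the slope weakly
    # constrained and lets the unbounded ML fit run off to beta -> 0 with a
    # huge alpha; bound the parameters to a broad plausible region instead
    bounds = [(math.log(c.min()) - 2.0, math.log(c.max()) + 2.0),
              (math.log(0.2), math.log(32.0))]
    x0 = np.log([np.median(c), 2.0])
    res = optimize.minimize(nll, x0, method="Nelder-Mead", bounds=bounds,
                            options={"xatol": 1e-8, "fatol": 1e-10,
                                     "maxiter": 2000})
    if not res.success and res.fun > nll(x0):
        raise WeibullFitError(f"Weibull fit did not converge: {res.message}")
    alpha, beta = np.exp(res.x)
    if not (np.isfinite(alpha) and np.isfinite(beta)):
        raise WeibullFitError("Weibull fit returned non-finite parameters")
    return WeibullFit(alpha=float(alpha), beta=float(beta),
                      log_likelihood=-float(res.fun))
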