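"""Statistical analyses over per-observer apparent-noise estimates.

Covers the pipeline from trial-level records to the summary statistics used
to test probability-matching predictions:

* pooling two-pass trials into per-contrast :class:`TwoPassSummary` counts;
* per-condition apparent-noise estimation with bootstrap CIs and the
  CI-based discard rule;
* least-squares regression of rho_tilde on proportion correct with
  bootstrapped slope CIs (long-design analysis);
* the low/high-performance ratio analysis rho_low/rho_high against a
  probability-matching prediction curve, with exact binomial sign tests
  (short-design analysis);
* trial/results CSV plumbing (infinities serialized as the literal "inf").

Presentation clipping (ratios shown at a maximum of 4.0) is applied only to
exported plot tables, never to the statistics themselves.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy import stats

from .noise_estimation import (NoiseEstimate, TwoPassSummary, apply_discard_rule,
                               bootstrap_ci, estimate_apparent_noise,
                               _invert_rho_vec, vppm_apparent_rho_curve)
from .synthetic_experiment import TrialRecord

__all__ = [
    "ObserverResult",
    "RatioResult",
    "TRIAL_COLUMNS",
    "trials_to_dataframe",
    "read_trial_csv",
    "write_trial_csv",
    "summarize_two_pass",
    "estimate_observer",
    "regression_slope",
    "ratio_analysis",
    "sign_test",
    "clip_for_plot",
    "write_estimates_csv",
    "write_ratios_csv",
]

TRIAL_COLUMNS = ["block", "trial_index", "pair_id", "signal", "contrast",
                 "response", "correct"]
LATENT_COLUMNS = ["e", "i"]
PLOT_CLIP = 4.0


@dataclass(frozen=True)
class ObserverResult:
    """Per-observer estimates, one :class:`NoiseEstimate` per condition,
    ordered by increasing p_C_hat."""

    observer_id: str
    design: str                       # "exp1" or "exp2"
    estimates: tuple[NoiseEstimate, ...]

    @property
    def retained(self) -> tuple[NoiseEstimate, ...]:
        return tuple(e for e in self.estimates if not e.discarded)


@dataclass(frozen=True)
class RatioResult:
    """Observed vs. predicted rho_low/rho_high for one short-design observer."""

    observer_id: str
    rho_low: float
    rho_high: float
    ratio_observed: float
    ratio_predicted: float
    below_diagonal: bool


# --------------------------------------------------------------------------
# Trial CSV plumbing
# --------------------------------------------------------------------------

def trials_to_dataframe(trials: list[TrialRecord], debug: bool = False) -> pd.DataFrame:
    """TrialRecords to a DataFrame; ``debug=True`` keeps latent e/i columns."""
    cols = TRIAL_COLUMNS + (LATENT_COLUMNS if debug else [])
    df = pd.DataFrame([{c: getattr(t, c) for c in cols} for t in trials])
    df["pair_id"] = df["pair_id"].astype("Int64")
    return df


def _validate_trials(df: pd.DataFrame, path: str = "<memory>") -> None:
    missing = [c for c in TRIAL_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required columns {missing}")
    paired = df.dropna(subset=["pair_id"])
    counts = paired.groupby("pair_id").size()
    bad = counts[counts != 2]
    if len(bad):
        raise ValueError(
            f"{path}: pair_id {int(bad.index[0])} appears {int(bad.iloc[0])} "
            "time(s); every pair must have exactly two passes")
    for col in ("signal", "contrast"):
        nun = paired.groupby("pair_id")[col].nunique()
        bad = nun[nun != 1]
        if len(bad):
            raise ValueError(
                f"{path}: pair_id {int(bad.index[0])} has mismatched "
                f"{col!r} across passes")


def write_trial_csv(trials_or_df, path, debug: bool = False) -> None:
    df = trials_or_df if isinstance(trials_or_df, pd.DataFrame) \
        else trials_to_dataframe(trials_or_df, debug=debug)
    df.to_csv(path, index=False)


def read_trial_csv(path) -> pd.DataFrame:
    """Read and validate a trial CSV (unknown columns are preserved)."""
    df = pd.read_csv(path)
    if "pair_id" in df.columns:
        df["pair_id"] = df["pair_id"].astype("Int64")
    _validate_trials(df, path=str(path))
    return df


# --------------------------------------------------------------------------
# Pooling and estimation
# --------------------------------------------------------------------------

def summarize_two_pass(df: pd.DataFrame, min_pairs: int = 1,
                       include_unrepeated: bool = False) -> dict[float, TwoPassSummary]:
    """Pool trials into per-contrast two-pass counts.

    Agreement is counted over repeated pairs; correctness is counted over
    the two-pass trials at each contrast, or over all trials at that
    contrast when ``include_unrepeated=True``.  Levels with fewer than
    ``min_pairs`` pairs are dropped.
    """
    if isinstance(df, list):
        df = trials_to_dataframe(df)
    _validate_trials(df)
    out: dict[float, TwoPassSummary] = {}
    paired = df.dropna(subset=["pair_id"])
    for contrast, grp in paired.groupby("contrast"):
        piv = grp.sort_values("trial_index").groupby("pair_id")["response"]
        n_pairs = piv.ngroups
        if n_pairs < min_pairs:
            continue
        n_consistent = int((piv.nunique() == 1).sum())
        pool = df[df["contrast"] == contrast] if include_unrepeated else grp
        out[float(contrast)] = TwoPassSummary(
            n_pairs=n_pairs, n_trials=len(pool),
            n_correct=int(pool["correct"].sum()),
            n_consistent=n_consistent)
    return out


def estimate_observer(df, observer_id: str, design: str,
                      rng: np.random.Generator, min_pairs: int = 100,
                      n_boot: int = 10_000,
                      include_unrepeated: bool = False) -> ObserverResult:
    """Full per-observer pipeline: pool, invert, bootstrap, discard-flag."""
    summaries = summarize_two_pass(df, min_pairs=min_pairs,
                                   include_unrepeated=include_unrepeated)
    ests = []
    for contrast in sorted(summaries):
        s = summaries[contrast]
        est = estimate_apparent_noise(s)
        lo, hi = bootstrap_ci(s, n_boot=n_boot, rng=rng)
        est = replace(est, ci_low=lo, ci_high=hi)
        ests.append(apply_discard_rule(est))
    ests.sort(key=lambda e: e.p_C_hat)
    return ObserverResult(observer_id=observer_id, design=design,
                          estimates=tuple(ests))


# --------------------------------------------------------------------------
# Long-design analysis: rho_tilde vs p_C regression
# --------------------------------------------------------------------------

def _ols_slope(x: np.ndarray, y: np.ndarray) -> float:
    return float(np.polyfit(x, y, 1)[0])


def regression_slope(result: ObserverResult, n_boot: int = 10_000,
                     rng: np.random.Generator | None = None,
                     method: str = "binomial",
                     summaries: dict[float, TwoPassSummary] | None = None
                     ) -> tuple[float, float, float]:
    """OLS slope of rho_tilde on p_C_hat across retained conditions, with a
    bootstrapped 95% CI.

    ``method="binomial"`` (default) resamples the per-condition correct and
    consistent counts parametrically and re-estimates each replicate;
    ``method="pairs"`` resamples the (p_C, rho) points with replacement.
    The binomial method needs the per-condition counts: they are taken from
    ``summaries`` when given, else reconstructed from the estimates' stored
    proportions with the retained conditions' pair counts unavailable —
    pass ``summaries`` for trial-level data.
    """
    if rng is None:
        rng = np.random.default_rng()
    pts = [e for e in result.retained if math.isfinite(e.rho_tilde)]
    if len(pts) < 2:
        raise ValueError("need >= 2 retained conditions for a regression")
    x = np.array([e.p_C_hat for e in pts])
    y = np.array([e.rho_tilde for e in pts])
    slope = _ols_slope(x, y)

    slopes = np.empty(n_boot)
    if method == "pairs":
        for b in range(n_boot):
            idx = rng.integers(0, len(pts), size=len(pts))
            while len(np.unique(x[idx])) < 2:
                idx = rng.integers(0, len(pts), size=len(pts))
            slopes[b] = _ols_slope(x[idx], y[idx])
    elif method == "binomial":
        if summaries is None:
            raise ValueError("binomial bootstrap needs per-condition summaries")
        conds = [summaries[c] for c in sorted(summaries)]
        conds = [s for s in conds
                 if any(abs(s.p_C_hat - e.p_C_hat) < 1e-12 for e in pts)]
        pc_b = np.stack([rng.binomial(s.n_trials, s.p_C_hat, n_boot) / s.n_trials
                         for s in conds])
        pa_b = np.stack([rng.binomial(s.n_pairs, s.p_A_hat, n_boot) / s.n_pairs
                         for s in conds])
        rho_b = _invert_rho_vec(pc_b.ravel(), pa_b.ravel()).reshape(pc_b.shape)
        for b in range(n_boot):
            ok = np.isfinite(rho_b[:, b])
            if ok.sum() >= 2 and len(np.unique(pc_b[ok, b])) >= 2:
                slopes[b] = _ols_slope(pc_b[ok, b], rho_b[ok, b])
            else:
                slopes[b] = np.nan
    else:
        raise ValueError(f"unknown bootstrap method {method!r}")
    lo, hi = np.nanquantile(slopes, [0.025, 0.975], method="nearest")
    return slope, float(lo), float(hi)


# --------------------------------------------------------------------------
# Short-design analysis: ratio of apparent noise at low vs high performance
# --------------------------------------------------------------------------

def ratio_analysis(result: ObserverResult, rho_model: float = 0.0) -> RatioResult | None:
    """Observed vs. predicted rho_low/rho_high for a two-condition observer.

    The prediction looks up the probability-matching apparent-noise curve
    (at internal-to-external ratio ``rho_model``, 0 for the noiseless
    model) at the observer's own two proportions correct.  Observers with
    an infinite rho_tilde in either condition are excluded (returns None).
    """
    if len(result.estimates) != 2:
        raise ValueError(
            f"ratio analysis needs exactly 2 conditions, got {len(result.estimates)}")
    low, high = sorted(result.estimates, key=lambda e: e.p_C_hat)
    if not (math.isfinite(low.rho_tilde) and math.isfinite(high.rho_tilde)):
        return None
    curve = vppm_apparent_rho_curve(rho_model, [low.p_C_hat, high.p_C_hat])
    pred_low, pred_high = curve[0][1], curve[1][1]
    if not (math.isfinite(pred_low) and math.isfinite(pred_high)) or pred_high == 0:
        return None
    ratio_obs = low.rho_tilde / high.rho_tilde
    ratio_pred = pred_low / pred_high
    return RatioResult(observer_id=result.observer_id,
                       rho_low=low.rho_tilde, rho_high=high.rho_tilde,
                       ratio_observed=ratio_obs, ratio_predicted=ratio_pred,
                       below_diagonal=bool(ratio_obs < ratio_pred))


def sign_test(flags, alternative: str = "greater") -> tuple[int, int, float]:
    """Exact binomial sign test on a list of booleans.

    Returns (k, n, p) for k successes in n at null probability 0.5.  The
    default one-sided alternative tests whether successes (e.g. "observed
    ratio below the predicted diagonal") are more frequent than chance.
    """
    flags = list(flags)
    n = len(flags)
    if n < 1:
        raise ValueError("need at least one observation")
    k = int(sum(bool(f) for f in flags))
    p = stats.binomtest(k, n, 0.5, alternative=alternative).pvalue
    return k, n, float(p)


# --------------------------------------------------------------------------
# Results export
# --------------------------------------------------------------------------

def clip_for_plot(values, clip: float = PLOT_CLIP):
    """Presentation-only clipping of ratios/estimates at ``clip`` (4.0)."""
    return np.minimum(np.asarray(values, dtype=float), clip)


def _fmt_inf(x: float) -> str:
    if math.isinf(x):
        return "inf"
    return repr(float(x))


def write_estimates_csv(results: list[ObserverResult], path) -> None:
    rows = []
    for r in results:
        for e in r.estimates:
            rows.append({
                "observer_id": r.observer_id, "design": r.design,
                "p_C_hat": e.p_C_hat, "p_A_hat": e.p_A_hat,
                "d_prime_hat": e.d_prime_hat,
                "rho_tilde": _fmt_inf(e.rho_tilde),
                "ci_low": _fmt_inf(e.ci_low), "ci_high": _fmt_inf(e.ci_high),
                "feasible": e.feasible, "discarded": e.discarded,
            })
    pd.DataFrame(rows).to_csv(path, index=False)


def write_ratios_csv(ratios: list[RatioResult], path, clipped: bool = True) -> None:
    """Export the ratio table for plotting; clipping (default on) affects
    only these exported values, never upstream statistics."""
    rows = []
    for r in ratios:
        obs, pred = r.ratio_observed, r.ratio_predicted
        if clipped:
            obs, pred = float(clip_for_plot(obs)), float(clip_for_plot(pred))
        rows.append({"observer_id": r.observer_id,
                     "ratio_observed": obs, "ratio_predicted": pred,
                     "below_diagonal": r.below_diagonal})
    pd.DataFrame(rows).to_csv(path, index=False)
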