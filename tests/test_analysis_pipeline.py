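"""Tests of the statistical pipeline over per-observer noise estimates."""

import math
from dataclasses import replace

import numpy as np
import pandas as pd
import pytest

from ppmatch import (NoiseEstimate, estimate_apparent_noise, read_trial_csv,
                     regression_slope, sign_test, summarize_two_pass,
                     trials_to_dataframe, vppm_apparent_rho_curve,
                     write_trial_csv)
from ppmatch.analysis_pipeline import (ObserverResult, PLOT_CLIP, RatioResult,
                                       clip_for_plot, estimate_observer,
                                       ratio_analysis, write_ratios_csv)


def _estimate(p_c, rho, ci=(0.5, 1.5), discarded=False):
    return NoiseEstimate(d_prime_hat=1.0, rho_tilde=rho, objective=0.0,
                         feasible=True, p_C_hat=p_c, p_A_hat=0.7,
                         ci_low=ci[0], ci_high=ci[1], discarded=discarded)


# --------------------------------------------------------------------------
# CSV plumbing
# --------------------------------------------------------------------------

def test_trial_csv_round_trip(tmp_path, exp1_map_run):
    _, records = exp1_map_run
    df = trials_to_dataframe(records[:600])
    path = tmp_path / "trials.csv"
    write_trial_csv(df, path)
    back = read_trial_csv(path)
    pd.testing.assert_frame_equal(back, df, check_dtype=False)


def test_orphan_pair_is_rejected(tmp_path, exp1_map_run):
    _, records = exp1_map_run
    df = trials_to_dataframe(records[:300])
    orphan = df[df["pair_id"].notna()]["pair_id"].iloc[0]
    broken = df.drop(df[df["pair_id"] == orphan].index[:1])
    path = tmp_path / "broken.csv"
    broken.to_csv(path, index=False)
    with pytest.raises(ValueError, match=str(int(orphan))):
        read_trial_csv(path)


def test_missing_columns_are_named(tmp_path):
    path = tmp_path / "bad.csv"
    pd.DataFrame({"block": [1], "trial_index": [1]}).to_csv(path, index=False)
    with pytest.raises(ValueError, match="missing required columns"):
        read_trial_csv(path)


def test_summaries_match_direct_tally(exp1_map_df):
    """Grouped per-contrast counts equal an independent in-memory tally."""
    summ = summarize_two_pass(exp1_map_df, min_pairs=100)
    paired = exp1_map_df.dropna(subset=["pair_id"])
    for contrast, s in summ.items():
        grp = paired[paired["contrast"] == contrast]
        assert s.n_trials == len(grp)
        assert s.n_correct == int(grp["correct"].sum())
        n_agree = 0
        for _, pair in grp.groupby("pair_id"):
            assert len(pair) == 2
            n_agree += int(pair["response"].iloc[0] == pair["response"].iloc[1])
        assert s.n_consistent == n_agree
        assert s.n_pairs == grp["pair_id"].nunique() >= 100


def test_statistics_invariant_to_row_order(exp1_map_df):
    shuffled = exp1_map_df.sample(frac=1.0, random_state=0)
    a = summarize_two_pass(exp1_map_df, min_pairs=100)
    b = summarize_two_pass(shuffled, min_pairs=100)
    assert a == b


def test_pooling_unrepeated_trials_is_optional(exp1_map_df):
    only_pairs = summarize_two_pass(exp1_map_df, min_pairs=100)
    pooled = summarize_two_pass(exp1_map_df, min_pairs=100,
                                include_unrepeated=True)
    assert set(pooled) == set(only_pairs)
    assert all(pooled[c].n_trials >= only_pairs[c].n_trials for c in pooled)
    assert all(pooled[c].n_pairs == only_pairs[c].n_pairs for c in pooled)


# --------------------------------------------------------------------------
# Regression analysis
# --------------------------------------------------------------------------

def test_constant_rho_gives_zero_slope():
    res = ObserverResult("o", "exp1", tuple(
        _estimate(p, 1.2) for p in (0.6, 0.65, 0.7, 0.75)))
    slope, lo, hi = regression_slope(res, n_boot=50,
                                     rng=np.random.default_rng(0),
                                     method="pairs")
    assert slope == pytest.approx(0.0, abs=1e-12)


def test_regression_needs_two_points():
    res = ObserverResult("o", "exp1", (_estimate(0.6, 1.0),))
    with pytest.raises(ValueError):
        regression_slope(res, n_boot=10, rng=np.random.default_rng(0),
                         method="pairs")


def test_noiseless_matcher_theoretical_slope():
    """The apparent-noise curve of the noiseless matcher between 58% and
    75% correct falls with slope ~ -5.6."""
    curve = vppm_apparent_rho_curve(0.0, [0.58, 0.75])
    (x0, y0), (x1, y1) = curve
    slope = (y1 - y0) / (x1 - x0)
    assert slope == pytest.approx(-5.6, abs=0.1)


def test_map_observer_regression_ci_covers_zero(exp1_map_df):
    """A constant-rho MAP observer shows no performance trend: the
    bootstrapped slope CI should cover zero."""
    rng = np.random.default_rng(21)
    summaries = summarize_two_pass(exp1_map_df, min_pairs=100)
    result = estimate_observer(exp1_map_df, "map_obs", "exp1", rng=rng,
                               min_pairs=100, n_boot=500)
    slope, lo, hi = regression_slope(result, n_boot=1000, rng=rng,
                                     summaries=summaries)
    assert lo < 0.0 < hi


# --------------------------------------------------------------------------
# Ratio analysis and sign tests
# --------------------------------------------------------------------------

def test_ratio_analysis_boundary_and_exclusions():
    low, high = _estimate(0.65, 1.4), _estimate(0.80, 0.8)
    res = ObserverResult("o", "exp2", (low, high))
    r = ratio_analysis(res, rho_model=0.0)
    assert r.rho_low == 1.4 and r.rho_high == 0.8
    assert r.ratio_observed == pytest.approx(1.75)
    assert r.ratio_predicted > 1.0
    # identical observed and predicted ratio -> not below the diagonal
    forced = RatioResult("o", 1.0, 1.0, r.ratio_predicted, r.ratio_predicted,
                         r.ratio_predicted < r.ratio_predicted)
    assert not forced.below_diagonal
    # infinite estimate in either condition excludes the observer
    res_inf = ObserverResult("o", "exp2",
                             (replace(low, rho_tilde=math.inf), high))
    assert ratio_analysis(res_inf, rho_model=0.0) is None
    with pytest.raises(ValueError):
        ratio_analysis(ObserverResult("o", "exp2", (low,)), rho_model=0.0)


def test_sign_test_exact_values():
    k, n, p = sign_test([True] * 5)
    assert (k, n) == (5, 5) and p == pytest.approx(0.5 ** 5)
    flags = [True] * 17 + [False] * 4
    k, n, p = sign_test(flags)
    # exact one-sided binomial sum: sum_{j=17}^{21} C(21,j) / 2^21
    expected = sum(math.comb(21, j) for j in range(17, 22)) / 2 ** 21
    assert (k, n) == (17, 21) and p == pytest.approx(expected, abs=1e-12)
    assert p == pytest.approx(0.0036, abs=2e-4)
    # 10 of 21 in the predicted direction: nowhere near significance
    _, _, p10 = sign_test([True] * 10 + [False] * 11)
    assert p10 > 0.4
    with pytest.raises(ValueError):
        sign_test([])


def test_clipping_only_affects_exported_tables(tmp_path):
    ratios = [RatioResult("a", 9.0, 1.0, 9.0, 2.0, False),
              RatioResult("b", 1.0, 1.0, 1.0, 6.0, True)]
    path = tmp_path / "ratios.csv"
    write_ratios_csv(ratios, path, clipped=True)
    out = pd.read_csv(path)
    assert out["ratio_observed"].max() <= PLOT_CLIP
    assert out["ratio_predicted"].max() <= PLOT_CLIP
    # the RatioResult objects used for statistics keep the raw values
    assert ratios[0].ratio_observed == 9.0
    assert list(clip_for_plot([0.5, 5.0])) == [0.5, PLOT_CLIP]
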