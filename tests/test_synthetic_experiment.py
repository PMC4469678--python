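"""Tests of the synthetic staircased two-pass experiment generator."""

import math

import numpy as np
import pytest

from ppmatch import estimate_apparent_noise, fit_weibull, run_exp2
from ppmatch.analysis_pipeline import summarize_two_pass
from ppmatch.synthetic_experiment import (ProtocolConfig, StaircaseState,
                                          WeibullFit, WeibullFitError,
                                          _fresh_trial, staircase_1up2down)


def test_config_validation():
    with pytest.raises(ValueError):
        ProtocolConfig.exp1(repeat_span=((101, 150), (151, 210)))  # unequal
    with pytest.raises(ValueError):
        ProtocolConfig.exp1(repeat_span=((101, 160), (151, 210)))  # overlap
    with pytest.raises(ValueError):
        ProtocolConfig.exp1(start_contrast=-1.0)
    cfg = ProtocolConfig.exp2()
    assert cfg.n_blocks == 4 and cfg.block_length == 100


def test_staircase_rule_definition():
    st = StaircaseState(base_contrast=1.0, step_factor=2.0)
    staircase_1up2down(st, True)
    assert st.contrast == 1.0            # one correct: no change yet
    staircase_1up2down(st, True)
    assert st.contrast == 0.5            # two in a row: one step down
    staircase_1up2down(st, False)
    assert st.contrast == 1.0            # an error: one step up
    staircase_1up2down(st, True)
    staircase_1up2down(st, False)
    assert st.contrast == 2.0            # streak resets after an error


def test_staircase_levels_are_bit_identical():
    st = StaircaseState(base_contrast=2.0)
    c0 = st.contrast
    staircase_1up2down(st, False)
    staircase_1up2down(st, True)
    staircase_1up2down(st, True)
    assert st.contrast == c0             # exact revisit of the same level


def test_staircase_converges_near_707():
    """Long-run 1-up 2-down tracking of a MAP observer settles near the
    70.7%-correct fixed point."""
    cfg = ProtocolConfig.exp1(rule="map", rho=1.0)
    rng = np.random.default_rng(9)
    st = StaircaseState(base_contrast=cfg.start_contrast,
                        step_factor=cfg.step_factor)
    correct = []
    for t in range(11_000):
        *_, c = _fresh_trial(cfg, st.contrast, rng)
        if t >= 1000:
            correct.append(c)
        staircase_1up2down(st, c)
    assert abs(np.mean(correct) - 0.707) < 0.01


def test_small_steps_converge_to_the_sqrt_half_contrast():
    """With step factor -> 1 the staircase tracks the contrast where the
    psychometric function passes 1/sqrt(2)."""
    from scipy.stats import norm
    cfg = ProtocolConfig.exp1(rule="map", rho=0.0, step_factor=10 ** 0.01)
    rng = np.random.default_rng(10)
    st = StaircaseState(base_contrast=cfg.start_contrast,
                        step_factor=cfg.step_factor)
    levels = []
    for t in range(20_000):
        *_, c = _fresh_trial(cfg, st.contrast, rng)
        if t >= 4000:
            levels.append(st.contrast)
        staircase_1up2down(st, c)
    # noiseless MAP: p(c) = Phi(k c / 2); fixed point at p = 1/sqrt(2)
    c_star = 2 * norm.ppf(1 / math.sqrt(2)) / cfg.gain
    assert np.median(levels) == pytest.approx(c_star, rel=0.05)


def test_exp1_structure_and_replay_integrity(exp1_map_run):
    cfg, records = exp1_map_run
    assert len(records) == 33 * 300
    paired = [r for r in records if r.pair_id is not None]
    assert len(paired) == 2 * 33 * 50
    by_pair = {}
    for r in paired:
        by_pair.setdefault(r.pair_id, []).append(r)
    assert len(by_pair) == 33 * 50
    for pid, (first, second) in by_pair.items():
        assert first.signal == second.signal
        assert first.contrast == second.contrast    # bit-identical
        assert first.e == second.e                  # shared external sample
        assert first.i != second.i                  # fresh internal noise
    # the staircase is frozen during replay: trials 151-200 in each block
    # carry the contrasts of trials 101-150 in order
    for b in range(1, 4):
        block = [r for r in records if r.block == b]
        src = [r.contrast for r in block[100:150]]
        rep = [r.contrast for r in block[150:200]]
        assert src == rep


def test_exp1_yields_protocol_scale_pair_counts(exp1_map_run):
    _, records = exp1_map_run
    from ppmatch import trials_to_dataframe
    summ = summarize_two_pass(trials_to_dataframe(records), min_pairs=100)
    assert len(summ) >= 4            # several analyzable contrast levels
    assert all(s.n_pairs >= 100 for s in summ.values())


def test_exp1_recovers_the_generating_noise_ratio(exp1_map_df):
    """Per-contrast estimates from a MAP observer with rho = 1 cover the
    generating ratio: the bootstrap 95% CI contains 1 at (nearly) every
    analyzable level, and the point estimates scatter around 1."""
    from ppmatch import bootstrap_ci
    summ = summarize_two_pass(exp1_map_df, min_pairs=100)
    assert len(summ) >= 4
    rng = np.random.default_rng(42)
    covered, rhos = [], []
    for s in summ.values():
        rhos.append(estimate_apparent_noise(s).rho_tilde)
        lo, hi = bootstrap_ci(s, n_boot=1000, rng=rng)
        covered.append(lo <= 1.0 <= hi)
    assert sum(covered) >= math.ceil(2 * len(covered) / 3)
    finite = [r for r in rhos if math.isfinite(r)]
    assert 0.5 < float(np.median(finite)) < 1.5


def test_exp2_structure():
    cfg = ProtocolConfig.exp2(rule="map", rho=1.0)
    records = run_exp2(cfg, np.random.default_rng(11))
    assert len(records) == 500
    paired = [r for r in records if r.pair_id is not None]
    assert len(paired) == 400                      # four two-pass blocks
    assert len({r.pair_id for r in paired}) == 200
    contrasts = sorted({r.contrast for r in paired})
    assert len(contrasts) == 2                     # the 65% and 80% levels
    assert contrasts[0] < contrasts[1]
    # staircase segment is unpaired and precedes the fixed-contrast blocks
    assert all(r.pair_id is None for r in records[:100])
    # replay integrity within each two-pass block
    by_pair = {}
    for r in paired:
        by_pair.setdefault(r.pair_id, []).append(r)
    for first, second in by_pair.values():
        assert (first.signal, first.contrast, first.e) == \
               (second.signal, second.contrast, second.e)


def test_exp2_design_mismatch_raises():
    with pytest.raises(ValueError):
        run_exp2(ProtocolConfig.exp1(), np.random.default_rng(0))


def test_weibull_fit_recovery():
    """ML refit of data generated from a known psychometric function
    recovers the threshold parameter within 15%."""
    rng = np.random.default_rng(12)
    true = WeibullFit(alpha=1.4, beta=2.5)
    c = rng.uniform(0.3, 3.5, size=2000)
    y = rng.random(2000) < true.predict(c)
    fit = fit_weibull((c, y))
    assert fit.alpha == pytest.approx(true.alpha, rel=0.15)
    # p(c) = 0.75 exactly at c = alpha * (ln 2)^(1/beta)
    c75 = fit.alpha * math.log(2.0) ** (1.0 / fit.beta)
    assert fit.predict(c75) == pytest.approx(0.75, abs=1e-12)
    assert fit.inverse(0.75) == pytest.approx(c75, abs=1e-12)


def test_weibull_fit_identifiability_errors():
    with pytest.raises(WeibullFitError):
        fit_weibull(([1.0, 1.0, 1.0], [True, False, True]))
    with pytest.raises(WeibullFitError):
        fit_weibull(([0.5, 1.0, 2.0], [True, True, True]))


def test_exp2_thresholds_bracket_the_staircase_level():
    """The fitted 65% and 80% contrasts straddle the ~71%-correct level the
    staircase converged on."""
    cfg = ProtocolConfig.exp2(rule="map", rho=1.0)
    rng = np.random.default_rng(13)
    records = run_exp2(cfg, rng)
    stair_trials = records[:100]
    fit = fit_weibull(stair_trials)
    c65, c80 = fit.inverse(0.65), fit.inverse(0.80)
    c71 = fit.inverse(1 / math.sqrt(2))
    assert c65 < c71 < c80
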