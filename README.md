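# ppmatch

Tools for testing **posterior probability matching** accounts of perceptual
decision making against classic **signal detection** accounts, using two-pass
response consistency and ideal-observer efficiency analysis.

## The problem

In a 2AFC task an observer's decisions are partly random: identical stimuli
can elicit different responses. Signal detection theory attributes this
randomness to additive internal noise on a decision variable *D* = *E* + *I*
(external component *E* ~ N(0 or μ_E, σ_E), internal component
*I* ~ N(0, σ_I)), followed by a deterministic maximum-a-posteriori (MAP)
choice. Posterior probability matching instead holds that the observer
computes the true posterior *P*(A|*d*) and responds A *with that
probability* — an intrinsically stochastic rule (here called VPPM,
veridical posterior probability matching).

The two accounts are separable with a **two-pass experiment**: present every
trial twice (same signal, same external noise, fresh internal noise) and
measure the proportion correct *P*<sub>C</sub> and the proportion of
repeated trials answered the same way twice, *P*<sub>A</sub>. From
(*P̂*<sub>C</sub>, *P̂*<sub>A</sub>) one can infer the **apparent
internal-to-external noise ratio** ρ̃ — the σ_I/σ_E an additive-noise MAP
observer would need to produce those proportions. Applied to a true MAP
observer the inversion recovers its actual ratio; applied to a probability
matcher it attributes extra apparent noise to the matching rule, and the
attributed ρ̃ rises steeply as performance falls toward chance (at
*P*<sub>C</sub> = *P*<sub>A</sub> = 0.5, ρ̃ = ∞). Matching is also
strikingly inefficient: its best-case efficiency
η = (2Φ⁻¹(*P*<sub>C</sub>)/*d′*<sub>D</sub>)² is far below the ideal
observer's at low-to-moderate performance.

The package provides:

- `observer_models` — the Gaussian decision-variable observer and the
  trial-level VPPM and MAP rules, plus a vectorized two-pass simulator;
- `two_pass_theory` — closed-form *P*<sub>C</sub>, *P*<sub>CC</sub>,
  *P*<sub>II</sub>, *P*<sub>A</sub> for both rules (quadrature for the
  matching observer, exact bivariate-normal forms for MAP);
- `noise_estimation` — the sum-of-squares inversion of
  (*P̂*<sub>C</sub>, *P̂*<sub>A</sub>) to (d̂′, ρ̃), binomial bootstrap CIs,
  and the CI-based discard rule;
- `efficiency` — matching efficiency versus performance;
- `synthetic_experiment` — staircased two-pass sessions (a long 33-block
  design and a short 500-trial design with Weibull threshold selection) with
  a pluggable observer rule;
- `analysis_pipeline` — per-observer estimation, ρ̃-vs-*P*<sub>C</sub>
  regression with bootstrap slope CIs, low/high-performance ratio analysis
  with exact sign tests, and CSV plumbing.

## Worked example

```python
>>> import ppmatch as pm
>>> # apparent noise ratio attributed to a noiseless probability matcher
>>> pm.vppm_apparent_rho_curve(0.0, [0.58, 0.75])
[(0.58, 1.8978965641926795), (0.75, 0.9336190830945759)]
>>> # its best-case efficiency at 69% correct
>>> pt = pm.vppm_efficiency_at_pc(0.69)
>>> round(pt.d_prime_D, 3), round(100 * pt.eta, 1)
(1.498, 43.8)
```

At 58% correct a *noiseless* probability matcher looks, through the
consistency analysis, like a MAP observer with almost twice as much internal
as external noise (ρ̃ ≈ 1.90), falling to ρ̃ ≈ 0.93 by 75% correct — a
steep performance dependence (slope ≈ −5.6) that constant-noise MAP
observers do not show. And at 69% correct the matcher can achieve at most
≈ 44% efficiency, below efficiencies that practised human observers have
reached in comparable discrimination tasks.

A synthetic short-design cohort, end to end:

```python
>>> import numpy as np
>>> from ppmatch import ProtocolConfig, run_exp2, trials_to_dataframe
>>> from ppmatch.analysis_pipeline import estimate_observer, ratio_analysis
>>> recs = run_exp2(ProtocolConfig.exp2(rule="vppm", rho=0.0),
...                 np.random.default_rng(5))
>>> df = trials_to_dataframe(recs)
>>> res = estimate_observer(df, "obs1", "exp2",
...                         np.random.default_rng(0), min_pairs=1, n_boot=2000)
>>> [round(e.rho_tilde, 2) for e in res.estimates]  # low vs high performance
[1.81, 0.82]
```

The same five stages are exposed as a CLI (`ppmatch theory | efficiency |
estimate | simulate | analyze`); see `ppmatch --help`.

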