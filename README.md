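# diffgillespie

Differentiable Gillespie simulation for stochastic gene expression:
simulate chemical reaction networks exactly, simulate them *smoothly* so
that trajectory statistics become differentiable in the kinetic
parameters, and use those gradients to fit rate constants to data and to
design promoter circuits with prescribed dose-response curves.

Intended users: quantitative/systems biologists and biophysicists working
with stochastic models of transcription (telegraph-type promoter models,
nonequilibrium promoter cycles) who want gradient-based parameter
estimation or circuit design instead of likelihood-free grid searches.

## The idea

The direct-method Gillespie algorithm draws a waiting time
τ = −ln(u)/R (R = Σᵢ rᵢ the total propensity) and picks the next reaction
as the smallest i′ with Σ_{i≤i′} rᵢ/R > u′.  Both the selection and the
update x ← x + S_{i′} are step functions of the rate constants, so
trajectories cannot be differentiated.  The smoothed variant replaces the
selection staircase with logistic sigmoids of steepness 1/a on the
cumulative propensity fractions,

    i′ = 1 + Σ_{i<N} σ((u′ − qᵢ)/a),      qᵢ = Σ_{j≤i} rⱼ/R,

and the one-hot update with a Gaussian surrogate of the Kronecker delta,

    x ← x + Σᵢ exp(−(i′−i)²/b) · Sᵢ.

With the uniform draws held fixed, every simulation output is then a
smooth function of the parameters (defaults 1/a = 200, 1/b = 20), and
pathwise gradients flow through the waiting times, the selection, and the
updates — here via a small forward-mode dual-number core (`_ad`), well
matched to the ≤ 7 parameters of the models shipped.

On top of the two simulators the package provides:

* **Accuracy metrics** — integer-binned empirical PMFs, moments, entropy,
  KL and Jensen–Shannon divergences, and the divergence/entropy ratio used
  to quantify smoothed-vs-exact agreement.
* **Inference** — moment-matching losses for single- and multi-condition
  data, ADAM in log-parameter space with winsorized pathwise gradients,
  curvature-based confidence intervals, loss-landscape scans, and a
  synthetic-data benchmark generator (targets always from the exact
  simulator).
* **Promoter models** — the two-state telegraph model with closed-form
  mean/Fano and a truncated master-equation solver, and a four-state
  activator-driven promoter whose cycle can break detailed balance, with
  exact stationary solves (null space + differentiable tree formula) and
  thermodynamic observables (drive Δμ, cycle flux J, power Φ = JΔμ).
* **Design** — fit the four-state promoter's seven switching parameters so
  its dose-response matches a target curve; report sharpness and energy
  dissipation.

See `docs/methods.md` for the model conventions, numerical choices, and
the gradient contract (what pathwise gradients do and do not estimate).

## Worked example

Two-state telegraph promoter at the benchmark point
(kon = 0.5, koff = 1, r = 10, γ = 1; time in units of 1/koff):

```python
import numpy as np
from diffgillespie import (TwoStateParams, build_two_state, two_state_mean_fano,
                           ensemble_final_states, simulate_dga, DGAConfig,
                           empirical_pdf, jsd_over_entropy)
from diffgillespie.promoters import TWO_STATE_X0

p = TwoStateParams(kon_r=0.5, koff_r=1.0, r=10.0, gamma=1.0)
net = build_two_state()
print(two_state_mean_fano(p))
# (6.666666666666667, 2.333333333333333)   <- closed-form mean mRNA and Fano

exact = ensemble_final_states(net, TWO_STATE_X0, p.as_dict(),
                              T=1e4, n_traj=2000, seed=101)
batch = simulate_dga(net, TWO_STATE_X0, p.as_dict(), T=1e4,
                     config=DGAConfig(n_traj=2000), seed=202)
m_exact = exact[:, 2].astype(float)
m_smooth = batch.final_states[:, 2]
print(round(m_exact.mean(), 3), round(m_smooth.mean(), 3))
# 6.524 7.056    <- exact vs smoothed stationary mean (the smoothed
#                   simulator overestimates slightly)
print(round(jsd_over_entropy(empirical_pdf(m_smooth), empirical_pdf(m_exact)), 4))
# 0.0026         <- Jensen-Shannon divergence between the two stationary
#                   mRNA laws, normalized by the exact law's entropy:
#                   a ~0.3% discrepancy relative to the total uncertainty
```

Fitting rates to moment data (γ known) and designing a sharp dose-response:

```python
from diffgillespie.inference import MomentTargets, SimSettings, fit_two_state
from diffgillespie.design import make_reference_target, design_fit

tg = MomentTargets.from_mean_fano(mean=6.667, fano=2.333)
fit = fit_two_state(tg, free=["kon_r", "r"], fixed={"gamma": 1.0},
                    settings=SimSettings(), n_iter=300, seed=0)
print(fit.theta_hat)   # recovered rates; fit.ci holds per-parameter intervals

res = design_fit(make_reference_target("sharp"), seed=0)
print(round(res.sharpness, 3), round(res.drive, 2), round(res.power, 4))
# 0.341 2.75 0.0046   <- sharper targets need a dissipative promoter cycle
```

A `diffgillespie` command-line tool wraps the same workflows
(`simulate-exact`, `simulate-dga`, `benchmark-accuracy`, `fit-two-state`,
`design-four-state`, `landscape`, `sweep-smoothing`, `make-synthetic`);
every run writes its artifacts plus a reproducibility manifest to a run
directory.  `diffgillespie --help` lists options.

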