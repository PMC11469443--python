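# Methods

## The simulation model

A reaction network is a continuous-time Markov jump process: species counts
`x`, stoichiometric matrix `S` (one row per reaction), and propensities
`r_i(x)`.  The exact direct method draws the waiting time to the next event
from an exponential with total rate `R = Σ_i r_i`,

    t ← t − ln(u)/R,          u ~ U(0,1],

selects the reaction as the smallest `i'` whose cumulative probability
`q_{i'} = Σ_{i≤i'} r_i/R` exceeds a second uniform draw `u'`, and applies
`x ← x + S_{i'}`.  `exact_ssa` implements this literally and is the oracle
for everything else.

Rate laws are restricted to `k`, `k·x_j`, and `k·c[·x_j]` with `c` an
external scalar (an activator concentration).  These cover every model in
the package and keep all propensities smooth in state and parameters, which
the differentiable path requires.  Promoter conformations are encoded as
one indicator species per state rather than an enum, because the smoothed
dynamics need promoter state to live in the (real-valued) species vector.

## The smoothed (differentiable) stepper

Reaction selection and the state update are the two non-differentiable
operations.  They are replaced by

* sigmoid selection: `i' = 1 + Σ_{i<N} σ((u' − q_i)/a)`, `σ` the logistic
  function.  The cumulative fractions `q_i` are used — the selection rule is
  only equivalent to the direct method in the `a → 0` limit when the
  staircase is built on partial sums;
* a Gaussian surrogate for the Kronecker delta:
  `x ← x + Σ_i exp(−(i'−i)²/b)·S_i`.

Defaults `1/a = 200`, `1/b = 20` — small enough that single steps match the
exact method to ~1e-4 in the index for draws away from selection
boundaries, large enough that gradients remain finite in double precision.
A sweep utility (`sweep-smoothing`) reports the divergence ratio on a
`1/a ∈ {50,100,200,400} × 1/b ∈ {5,10,20,40}` grid for recalibration on
other models.

Numerical guards, all configurable in `DGAConfig`:

* `rate_floor = 1e-10` added to `R` before divisions;
* a softplus-style smooth clamp (sharpness `1e3`) keeps species nonnegative
  while letting gradients pass through transient undershoots;
* **indicator renormalization** (on by default): when `u'` lands within
  ~`a` of a cumulative fraction the index is genuinely fractional and the
  update is partial.  Combined with the clamp, partial promoter flips leak
  indicator mass (the positive half of the update lands while the negative
  half is clamped away); the leak compounds into an unbounded drift of the
  total gene copy number on long horizons.  Renormalizing the indicator
  block to unit sum after each step removes the drift entirely and is what
  makes the long-horizon (`T = 1e4`) steady-state benchmark meaningful.
  Both behaviors are available (`renormalize_indicators`).

Trajectories run to a fixed horizon `T`, not a fixed step count; the final
step is applied and overshoots, so elapsed times are ≥ `T` and the final
state includes one event past the horizon (the exact ensemble, by
contrast, holds the pre-overshoot state — a one-event difference that
matters only for observables with O(1/T·R) resolution).  Finished
trajectories are retired out of the vectorized batch; uniforms come from
one counter-based Philox stream consumed full-width per lockstep
iteration, so a run is bit-reproducible given `(seed, n_traj)`.

Soft occupancy: each waiting interval contributes its duration times the
pre-step promoter-indicator fractions; row sums are 1 by construction.

### What the gradient is — and what it is not

With the uniform draws held fixed, every batch output is a smooth function
of the kinetic parameters, differentiated here by forward-mode dual numbers
(`_ad`; parameter counts are ≤ 7, where forward mode is cheaper and simpler
than reverse mode).  Three facts shape how the gradients must be used:

1. **The pathwise gradient is exact for the fixed-noise map.**  Central
   finite differences with matched seeds reproduce it to <1e-4 — but only
   when the per-trajectory event counts are also frozen (`frozen_steps`)
   and the step is tiny (~1e-8 relative).  Under a fixed horizon the event
   count is itself a function of the parameters, and it flips at parameter
   perturbations of order 1e-6; an FD probe across such a flip measures the
   jump, not the derivative.  Event counts are part of the frozen
   randomness under common random numbers.
2. **The fixed-noise loss is violently wiggly below the smoothing scale.**
   Sigmoid selection boundaries have local gain O(1/a); trajectories that
   cross one during a batch contribute tangents orders of magnitude above
   typical.  The raw gradient estimator is therefore extremely
   heavy-tailed: unbiased for the smoothed expected loss, but with variance
   dominated by rare huge entries.
3. **Optimization therefore uses winsorized gradients.**  Per-trajectory
   moment tangents are clipped at ±20 (mRNA counts per unit log-parameter)
   before averaging — a standard bias/variance trade that reduces the
   estimator's standard deviation by ~2 orders of magnitude and makes ADAM
   converge; the unclipped estimator remains the one checked against finite
   differences.

## Parameter inference

Loss for one condition: `L = (⟨m̂⟩−⟨m⟩)² + (σ̂−σ)²` with `⟨m̂⟩, σ̂` from one
smoothed batch (defaults: `T = 10`, 2000 trajectories).  Multi-condition
data (per-condition mean and Fano factor) share `(r, γ)` with one `kon_r`
per condition and σ-targets `sqrt(f·⟨m⟩)`; all conditions share one noise
base per iteration, which also makes the loss exactly permutation-
symmetric in the conditions.  Time is measured in units of the repressor
unbinding rate (`koff_r = 1`).

ADAM runs in log-parameter space (rates are positive, spanning
`[0.1, 10]`): defaults learning rate 0.05, 300 iterations, mild 1/(1+0.015·t)
decay, fresh noise each iteration, matched noise within a gradient
evaluation.  Because the per-iteration loss is stochastic, the reported
optimum is the average of the last 30% of iterates in log space (Polyak
tail averaging).  When no starting point is supplied, a coarse 5-points-
per-axis log-grid scan of the simulated loss picks the starting basin —
the grid scan uses the same simulator as the fit, not closed forms.

Confidence intervals follow the curvature prescription exactly as adopted:
`δ_i = (∂²L/∂θ_i²)⁻¹` from a symmetric quadratic fit over ±5% perturbations
with matched seeds, and the asymmetric interval
`[θ_i − δ_i, θ_i + 1.96·δ_i]`.  Two quirks are preserved deliberately:
`δ` is an inverse curvature (units of θ², not θ), and the left endpoint is
not scaled by 1.96 — so the interval is not a conventional Wald interval.
A side condition relating the endpoints cannot hold for a symmetric
quadratic; the discrepancy is documented, not resolved.
`standard_halfwidth` provides the conventional `1.96·sqrt(2/curvature)`
alternative.  These intervals ignore parameter correlations; 2-D landscape
scans (`landscape`) are the intended diagnostic for the flat valleys that
moment-matching losses have (with all three of `kon_r, r, γ` free the
optimum is a degenerate ridge — fits reach the loss floor while parameters
wander along it).

## Synthetic benchmark data

The generator draws `kon_r, r, γ` uniformly in `[0.1, 10]` (`koff_r = 1`),
20 sets by default, and computes each set's stationary mean and standard
deviation from an exact-simulation ensemble (2000 trajectories, horizon
`max(50, 30/γ)` — ≥30 mRNA lifetimes, flushing the deterministic initial
condition).  Targets are *never* produced by the smoothed simulator.
Target-side Monte-Carlo standard errors (delta method for the sd) are
attached so that recovery checks can compare prediction and target with
both uncertainties included.  What passing recovery tests show is that the
full loop — smoothed simulation, pathwise gradients, ADAM — recovers the
data-generating moments; they do not show robustness to measurement noise,
cell-to-cell heterogeneity, or model misspecification, none of which the
generator emulates.

## Two-state oracles

Stationary mean `⟨m⟩ = (r/γ)·koff/(kon+koff)` and Fano factor
`f = 1 + r·kon/((kon+koff)(kon+koff+γ))` are verified against a brute-force
truncated master-equation solve (joint promoter×mRNA chain, truncation at
mean + 12 sd + 25) before use as oracles anywhere else.

## Four-state promoter and circuit design

States: 0 = OFF/unbound, 1 = OFF/bound, 2 = ON/bound, 3 = ON/unbound.
Activator binding `c·kb` (0→1) and `c·η_ba·kb` (3→2); unbinding `ku` (1→0)
and `η_ua·ku` (2→3); activation `ka` (0→3) and `η_ab·ka` (1→2);
inactivation `ki` (3→0) and `η_ib·ki` (2→1).  The base switching rates
`ka, ki` are free parameters alongside `ku` and the four η multipliers;
`kb = 0.02` and the transcription rate `r` are fixed (time and output
units).  Transcription occurs at the same rate `r` in both ON states, so
the mean production rate is `⟨r̄⟩ = r·(π₂+π₃)` and only promoter occupancy
needs simulating — mRNA is not a species in this model.

The stationary law is computed two ways: a null-space solve of the 4×4
generator (oracle), and a Markov-chain-tree-theorem closed form (the four
spanning trees of the 0-1-2-3 cycle), which is a polynomial in the rates
and hence differentiable with the same dual numbers as the simulator.
Thermodynamics: drive `Δμ = ln(η_ab·η_ua/(η_ib·η_ba))` (zero iff detailed
balance), cycle flux `J = π₀·kb·c − π₁·ku` (equal on every cycle edge at
stationarity), dissipated power `Φ = J·Δμ ≥ 0`.

Design: a target dose-response (mean production rate on 10 log-spaced
concentrations in `[1e-2, 1e2]`, modeled as a 6th-degree polynomial in
log10 c) is matched by ADAM on the seven free parameters in log space.  The
inner response evaluation defaults to the exact tree-formula solve — it is
equally differentiable and Monte-Carlo-free; the smoothed-simulation
occupancy route (`inner="dga"`, n = 600 simulations per concentration) is
provided and validated against the exact one.  Because many circuits
realize the same curve at different dissipation, a second optimization
phase adds a small `1e-4·Δμ²` tie-break so the reported design is the
minimum-dissipation circuit compatible with the target; reported power
then measures the dissipation the target's sharpness *requires*.  The two
reference targets are logistic curves in log-concentration: the shallow
one at the maximal slope a single-site promoter reaches in detailed
balance (Hill ≈ 1), the sharp one steeper than any equilibrium solution.
Sharpness is `max_c c·∂⟨r̄⟩/∂c`, evaluated by centered differences in
`ln c` on a 50-point dense grid (the 10-point design grid is too coarse
for a stable maximum).

## Known limitations

* The smoothed simulator misestimates distribution tails and promoter
  occupancies by a few percent at the default smoothing (it overestimates
  the active-state occupancy of the telegraph model by ~0.1 at the
  benchmark point); moments carry a systematic upward bias of order 5–10%.
* Raw pathwise gradients are heavy-tailed (above); any use outside the
  provided winsorized path should expect extreme variance.
* Only steady-state observables are targeted; dynamical (time-resolved)
  inference, rare-event statistics, and time-varying rate laws are out of
  scope.
* Mass-action combinatorics for multi-copy reactants are not implemented;
  rate laws are at most linear in a single species.
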