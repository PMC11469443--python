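"""Differentiable Gillespie stepping.

The exact direct method is non-differentiable in the kinetic parameters at
two points: the reaction choice (a staircase of Heaviside steps in the second
uniform draw) and the state update (a Kronecker delta on the chosen index).
The smoothed stepper replaces

* the Heaviside selection with logistic sigmoids of steepness ``1/a``
  applied to the *cumulative* propensity fractions ``q_i = sum_{j<=i} r_j/R``,
  giving a real-valued index ``i' = 1 + sum_{i<N} sigma((u' - q_i)/a)``;
* the Kronecker delta with a squared-index Gaussian of width ``b``,
  ``w_i = exp(-(i' - i)^2 / b)``, so the state update becomes
  ``x <- x + sum_i w_i S_i``.

In the limit a, b -> 0 both reduce to the exact algorithm whenever the draw
does not sit exactly on a selection boundary.  With the uniform draws held
fixed, every output is a smooth function of the kinetic parameters, so
pathwise (common-random-numbers) gradients can be propagated with the
dual-number machinery in :mod:`._ad`.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np

from . import _ad
from .exact_ssa import _LockstepUniforms
from .network import ReactionNetwork, propensities, propensities_batch_dual, total_rate

logger = logging.getLogger(__name__)

__all__ = [
    "SmoothingParams",
    "DGAConfig",
    "TrajectoryBatch",
    "waiting_time",
    "soft_index",
    "soft_stoich_weights",
    "dga_step",
    "simulate_dga",
    "gradient_of",
    "NumericalInstabilityError",
]


class NumericalInstabilityError(RuntimeError):
    pass


@dataclass(frozen=True)
class SmoothingParams:
    """Smoothing hyperparameters: sigmoid steepness scale ``a`` and Gaussian
    index width ``b``.  Defaults 1/a = 200, 1/b = 20 — small enough to track
    the exact algorithm closely while keeping gradients numerically stable."""

    a: float = 1.0 / 200.0
    b: float = 1.0 / 20.0

    def __post_init__(self):
        if self.a <= 0 or self.b <= 0:
            raise ValueError("smoothing parameters a, b must be positive")

    @classmethod
    def from_inverse(cls, one_over_a: float = 200.0, one_over_b: float = 20.0):
        return cls(a=1.0 / one_over_a, b=1.0 / one_over_b)


@dataclass(frozen=True)
class DGAConfig:
    """Run-control knobs for batched smoothed simulation."""

    n_traj: int = 2000
    max_steps: int = 1_000_000
    rate_floor: float = 1e-10
    clamp_nonnegative: bool = True
    clamp_sharpness: float = 1e3
    # Renormalize promoter-indicator species to unit sum after each soft
    # update.  Fractional index selections combined with the nonnegativity
    # clamp otherwise leak indicator mass (the positive half of a partial
    # update lands while the negative half is clamped away), which compounds
    # into an unbounded drift of the total gene copy number on long horizons.
    renormalize_indicators: bool = True

    def __post_init__(self):
        if self.max_steps < 1 or self.rate_floor < 0 or self.n_traj < 1:
            raise ValueError("invalid DGAConfig")


@dataclass
class TrajectoryBatch:
    """Ensemble outputs of one batched smoothed simulation.

    For a fixed ``seed`` (hence fixed noise draws) every field is a smooth
    function of the kinetic parameters; fields are duals when the simulation
    was run with dual parameters.
    """

    final_states: object  # (n_traj, n_species) array or Dual
    elapsed_times: object  # (n_traj,)
    occupancy: object | None  # (n_traj, n_indicator) soft time-in-state fractions
    seed: object
    n_overrun: int = 0
    noise_record: np.ndarray | None = None  # (n_steps, n_traj, 2) if recorded
    step_counts: np.ndarray = field(default_factory=lambda: np.zeros(0, dtype=int))


def waiting_time(R, u):
    """Exponential waiting time tau = -ln(u)/R; differentiable in R."""
    if np.any(np.asarray(_ad.value(u)) <= 0.0):
        raise ValueError("waiting-time draw u must lie in (0, 1]")
    return -_ad.log(u) / R


def soft_index(r, u_prime, a: float):
    """Smoothed reaction index from cumulative propensity fractions.

    ``r``: (..., N) propensities; returns a real index in (1, N) that
    approaches the exact (1-based) direct-method index as a -> 0.
    """
    R = total_rate(r)
    q = _ad.cumsum(r, axis=-1)[..., :-1]  # last fraction is identically 1
    frac = q / _ad.unsqueeze(R, -1)
    z = _ad.unsqueeze(u_prime, -1) - frac
    return 1.0 + _ad.asum(_ad.sigmoid(z * (1.0 / a)), axis=-1)


def soft_stoich_weights(i_prime, N: int, b: float):
    """Gaussian surrogate of the Kronecker delta on the reaction index.

    Returns (..., N) weights ``exp(-(i' - i)^2 / b)`` for i = 1..N.
    """
    idx = np.arange(1, N + 1, dtype=float)
    if isinstance(i_prime, _ad.Dual):
        diff = _ad.stack([i_prime - i for i in idx], axis=-1)
    else:
        diff = np.asarray(i_prime)[..., None] - idx
    return _ad.exp(-(diff**2) * (1.0 / b))


def dga_step(
    network: ReactionNetwork,
    state,
    t,
    params: dict,
    smoothing: SmoothingParams,
    u,
    u_prime,
    externals: dict | None = None,
    config: DGAConfig = DGAConfig(),
):
    """One smoothed step: returns ``(state', t', i', tau)``.

    All four outputs are differentiable in the parameters for fixed draws.
    """
    r = propensities(network, state, params, externals)
    R = total_rate(r) + config.rate_floor
    tau = waiting_time(R, u)
    i_prime = soft_index(r, u_prime, smoothing.a)
    w = soft_stoich_weights(i_prime, network.n_reactions, smoothing.b)
    new_state = state + _ad.dot_const(w, network.stoichiometry.astype(float))
    if config.clamp_nonnegative:
        new_state = _ad.smooth_clamp(new_state, config.clamp_sharpness)
    return new_state, t + tau, i_prime, tau


def _renormalize_indicators(state, indicator_cols):
    """Rescale the promoter-indicator columns of a batch state to unit sum."""
    cols = (slice(None), list(indicator_cols))
    ind = state[cols]
    norm = _ad.asum(ind, axis=-1) + 1e-12
    scaled = ind / _ad.unsqueeze(norm, -1)
    if isinstance(state, _ad.Dual):
        val = state.val.copy()
        tan = state.tan.copy()
        val[:, list(indicator_cols)] = scaled.val
        tan[:, list(indicator_cols), :] = scaled.tan
        return _ad.Dual(val, tan)
    out = state.copy()
    out[:, list(indicator_cols)] = scaled
    return out


def simulate_dga(
    network: ReactionNetwork,
    x0,
    params: dict,
    T: float,
    smoothing: SmoothingParams = SmoothingParams(),
    config: DGAConfig = DGAConfig(),
    seed=0,
    externals: dict | None = None,
    record_noise: bool = False,
    frozen_steps: np.ndarray | None = None,
) -> TrajectoryBatch:
    """Batched smoothed simulation of ``config.n_traj`` trajectories to ``T``.

    Each trajectory advances until its clock *exceeds* ``T`` (the final step
    is applied and overshoots, so ``elapsed_times >= T``) or ``max_steps`` is
    hit.  Soft state-occupancy fractions are accumulated from the (clamped,
    renormalized) promoter-indicator species weighted by step duration.
    Uniform draws are consumed full-width from one counter-based stream per
    run; rerunning with the same seed and batch size is bit-identical.

    ``frozen_steps`` (per-trajectory event counts) overrides the horizon
    stopping rule: each trajectory takes exactly that many steps.  Under
    common random numbers the event count is itself part of the frozen
    randomness; finite-difference gradient checks freeze the counts of a
    base run so that the perturbed losses sample the same smooth branch of
    the loss that the pathwise derivative differentiates.
    """
    if T <= 0:
        raise ValueError("horizon T must be positive")
    n = config.n_traj
    S_names = network.indicator_species
    dual = any(isinstance(v, _ad.Dual) for v in params.values())
    P = next((v.n_params for v in params.values() if isinstance(v, _ad.Dual)), 0)

    def _zeros(shape):
        z = np.zeros(shape)
        return _ad.Dual(z, np.zeros(shape + (P,))) if dual else z

    state = np.tile(np.asarray(x0, dtype=float), (n, 1))
    if dual:
        state = _ad.Dual(state, np.zeros(state.shape + (P,)))
    t = _zeros((n,))
    n_ind = len(S_names)
    occ = _zeros((n, n_ind)) if S_names else None

    # full-width output buffers; finished rows are retired into them so the
    # working arrays can be compacted to the still-running subset
    out_state = _zeros((n, network.n_species))
    out_t = _zeros((n,))
    out_occ = _zeros((n, n_ind)) if S_names else None
    out_steps = np.zeros(n, dtype=int)

    live = np.arange(n)  # global trajectory ids of the working rows
    active = np.ones(n, dtype=bool)
    steps_taken = np.zeros(n, dtype=int)
    fro = None if frozen_steps is None else np.asarray(frozen_steps, dtype=int)
    draws = _LockstepUniforms(seed, n)
    noise: list[np.ndarray] | None = [] if record_noise else None
    Sf = network.stoichiometry.astype(float)

    def _retire(rows_mask):
        """Move finished working rows into the output buffers."""
        nonlocal state, t, occ, live, active, steps_taken
        done = np.flatnonzero(rows_mask)
        keep = np.flatnonzero(~rows_mask)
        gids = live[done]
        if dual:
            out_state.val[gids] = state.val[done]
            out_state.tan[gids] = state.tan[done]
            out_t.val[gids] = t.val[done]
            out_t.tan[gids] = t.tan[done]
            if occ is not None:
                out_occ.val[gids] = occ.val[done]
                out_occ.tan[gids] = occ.tan[done]
        else:
            out_state[gids] = state[done]
            out_t[gids] = t[done]
            if occ is not None:
                out_occ[gids] = occ[done]
        out_steps[gids] = steps_taken[done]
        state = state[keep]
        t = t[keep]
        if occ is not None:
            occ = occ[keep]
        live = live[keep]
        active = active[keep]
        steps_taken = steps_taken[keep]

    for _ in range(config.max_steps):
        if live.size == 0:
            break
        u01_full, up_full = draws.next_pair()
        if noise is not None:
            noise.append(np.stack([1.0 - u01_full, up_full], axis=-1))
        u = 1.0 - u01_full[live]  # (0, 1] for the log
        up = up_full[live]
        r = propensities_batch_dual(network, state, params, externals)
        R = total_rate(r) + config.rate_floor
        dead = _ad.value(R) <= 2.0 * config.rate_floor
        tau = waiting_time(R, u)
        if frozen_steps is not None:
            active = steps_taken < fro[live]
        fire = active & ~dead
        all_fire = bool(fire.all())
        mask = fire.astype(float)
        tau_m = tau if all_fire else tau * mask
        if occ is not None:
            # the pre-step state holds for the waiting interval tau
            cols = (slice(None), list(S_names))
            ind = state[cols]
            if not (S_names and config.renormalize_indicators):
                # without per-step renormalization indicators can stray; keep
                # them nonnegative before normalizing the occupancy weights
                ind = _ad.smooth_clamp(ind, config.clamp_sharpness)
            norm = _ad.asum(ind, axis=-1)
            frac = ind / _ad.unsqueeze(norm, -1)
            occ = occ + frac * _ad.unsqueeze(tau_m, -1)
        i_prime = soft_index(r, up, smoothing.a)
        w = soft_stoich_weights(i_prime, network.n_reactions, smoothing.b)
        new_state = state + _ad.dot_const(w, Sf)
        if config.clamp_nonnegative:
            new_state = _ad.smooth_clamp(new_state, config.clamp_sharpness)
        if S_names and config.renormalize_indicators:
            new_state = _renormalize_indicators(new_state, S_names)
        state = new_state if all_fire else _ad.where(fire[:, None], new_state, state)
        t = t + tau_m
        steps_taken += fire
        if frozen_steps is None:
            finished = _ad.value(t) > T
            active &= ~(finished | dead)
        else:
            active = (steps_taken < fro[live]) & ~dead
        inactive = ~active
        if inactive.all() or inactive.mean() > 0.4:
            _retire(inactive)

    n_overrun = int(active.sum())
    if live.size:
        _retire(np.ones(live.size, dtype=bool))
    if n_overrun > 0.01 * n:
        warnings.warn(
            f"{n_overrun}/{n} trajectories hit max_steps={config.max_steps} "
            f"before reaching T={T}",
            RuntimeWarning,
            stacklevel=2,
        )
    occ_out = None
    if out_occ is not None:
        tv = _ad.value(out_t)
        denom = _ad.where(tv > 0, out_t, np.ones_like(tv))
        occ_out = out_occ / _ad.unsqueeze(denom, -1)
    return TrajectoryBatch(
        final_states=out_state,
        elapsed_times=out_t,
        occupancy=occ_out,
        seed=seed,
        n_overrun=n_overrun,
        noise_record=np.array(noise) if noise else None,
        step_counts=out_steps,
    )


def gradient_of(
    summary_fn,
    network: ReactionNetwork,
    x0,
    params: dict,
    free: list[str],
    T: float,
    smoothing: SmoothingParams = SmoothingParams(),
    config: DGAConfig = DGAConfig(),
    seed=0,
    externals: dict | None = None,
    log_space: bool = False,
):
    """Pathwise gradient of a scalar batch summary w.r.t. named parameters.

    ``summary_fn`` maps a :class:`TrajectoryBatch` to a scalar (dual-aware,
    built from the :mod:`._ad` free functions).  The same noise draws are used
    for the value and the gradient (common random numbers).  Returns
    ``(value, grad)`` with ``grad`` a dict over ``free``.
    """
    dual_params = _ad.seed_duals(params, free, log_space=log_space)
    batch = simulate_dga(
        network, x0, dual_params, T, smoothing, config, seed, externals
    )
    out = summary_fn(batch)
    if not isinstance(out, _ad.Dual):
        # summary does not touch any tracked parameter
        return float(_ad.value(out)), {name: 0.0 for name in free}
    val = float(np.asarray(out.val))
    g = np.asarray(out.tan, dtype=float).reshape(-1)
    if not np.all(np.isfinite(g)) or not np.isfinite(val):
        bad = [free[i] for i in range(len(free)) if not np.isfinite(g[i])]
        raise NumericalInstabilityError(
            f"non-finite gradient entries for parameters {bad or free}; "
            "consider larger smoothing parameters a or b"
        )
    return val, dict(zip(free, g))
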