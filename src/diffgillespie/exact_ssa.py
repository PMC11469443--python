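"""Exact Gillespie direct-method simulation.

This module is the ground-truth oracle against which the smoothed simulator
is benchmarked.  The direct method draws an exponential waiting time
tau = -ln(u)/R from the total rate R = sum_i r_i, picks the reaction index as
the smallest i' whose cumulative probability sum_{i<=i'} r_i/R exceeds a
second uniform draw, and applies the corresponding stoichiometry row.

Two execution paths are provided:

* :func:`simulate_exact` — a single trajectory with its full event list.
* :func:`ensemble_final_states` — many trajectories advanced in vectorized
  lockstep, consuming full-width draws from one counter-based Philox stream
  per run, so results are bit-reproducible for a given ``(seed, n_traj)``
  and trajectories are statistically independent.

Reaction indices are reported 1-based, matching the usual statement of the
direct method.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .network import ReactionNetwork, propensities

__all__ = [
    "AbsorbingState",
    "Trajectory",
    "step_exact",
    "simulate_exact",
    "ensemble_final_states",
    "trajectory_to_frame",
    "ensemble_to_frame",
]


class AbsorbingState(Exception):
    """Raised when the total rate is zero: no further reaction can fire."""


def step_exact(network, state, t, params, u, u_prime, externals=None):
    """One direct-method step.  Returns ``(state', t', i')`` with i' 1-based.

    ``u`` must lie in (0, 1] (waiting time), ``u_prime`` in (0, 1)
    (reaction choice).  Raises :class:`AbsorbingState` when R == 0.
    """
    state = np.asarray(state)
    r = np.asarray(propensities(network, state, params, externals), dtype=float)
    R = r.sum()
    if R <= 0.0:
        raise AbsorbingState(f"total rate {R} at state {state}")
    tau = -np.log(u) / R
    cum = np.cumsum(r)
    i0 = int(np.searchsorted(cum, u_prime * R, side="right"))
    i0 = min(i0, network.n_reactions - 1)  # guard u' == 1 edge
    new_state = state + network.stoichiometry[i0]
    return new_state, t + tau, i0 + 1


@dataclass
class Trajectory:
    """Piecewise-constant sample path of one exact simulation.

    ``states[k]`` holds from ``times[k]`` to ``times[k+1]``; the trajectory is
    defined up to the horizon ``T`` with the final state held from the last
    event (or from t=0 if absorbing immediately).
    """

    times: np.ndarray  # (n_events + 1,), times[0] == 0
    states: np.ndarray  # (n_events + 1, n_species) int
    reaction_indices: np.ndarray  # (n_events,) 1-based
    horizon: float
    absorbed: bool = False

    @property
    def final_state(self) -> np.ndarray:
        return self.states[-1]

    def time_average(self) -> np.ndarray:
        """Time-averaged state over [0, horizon]."""
        durations = np.diff(np.append(self.times, self.horizon))
        return (durations[:, None] * self.states).sum(axis=0) / self.horizon


def simulate_exact(network, x0, params, T, seed, externals=None) -> Trajectory:
    """Simulate one trajectory to horizon ``T``; bit-reproducible per seed."""
    if T <= 0:
        raise ValueError("horizon T must be positive")
    seq = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    rng = np.random.Generator(np.random.Philox(seq))
    state = np.asarray(x0, dtype=int)
    t = 0.0
    times = [0.0]
    states = [state.copy()]
    idxs: list[int] = []
    absorbed = False
    while True:
        u, up = rng.random(2)
        try:
            new_state, t_new, i = step_exact(
                network, state, t, params, 1.0 - u, up, externals
            )
        except AbsorbingState:
            absorbed = True
            break
        if t_new > T:
            break
        state, t = new_state, t_new
        times.append(t)
        states.append(state.copy())
        idxs.append(i)
    return Trajectory(
        times=np.array(times),
        states=np.array(states, dtype=int),
        reaction_indices=np.array(idxs, dtype=int),
        horizon=float(T),
        absorbed=absorbed,
    )


class _LockstepUniforms:
    """Uniform draws for a lockstep trajectory ensemble.

    One counter-based Philox stream per run, consumed full-width: every
    lockstep iteration draws one ``(u, u')`` pair for *every* trajectory
    (finished rows discard theirs), so the sequence seen by trajectory ``i``
    is a fixed function of ``(seed, n, i)`` alone — rerunning with the same
    seed and batch size is bit-identical, and rows are independent.
    """

    def __init__(self, seed, n):
        seq = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
        self._gen = np.random.Generator(np.random.Philox(seq))
        self._n = n

    def next_pair(self):
        u = self._gen.random((self._n, 2))
        return u[:, 0], u[:, 1]


def ensemble_final_states(
    network: ReactionNetwork,
    x0,
    params: dict,
    T: float,
    n_traj: int,
    seed,
    externals: dict | None = None,
    max_steps: int = 100_000_000,
):
    """Final states at time ``T`` of ``n_traj`` independent exact trajectories.

    Trajectories are advanced in lockstep with masked updates; a trajectory
    whose next waiting time would overshoot ``T`` keeps its current state
    (piecewise-constant semantics), and an absorbing state (R == 0) holds to
    the horizon.  Returns an ``(n_traj, n_species)`` integer matrix.
    """
    if n_traj < 1:
        raise ValueError("n_traj must be >= 1")
    S = network.stoichiometry
    state = np.tile(np.asarray(x0, dtype=np.int64), (n_traj, 1))
    t = np.zeros(n_traj)
    active = np.ones(n_traj, dtype=bool)
    draws = _LockstepUniforms(seed, n_traj)
    for _ in range(max_steps):
        if not active.any():
            break
        u, up = draws.next_pair()
        r = np.asarray(propensities(network, state, params, externals), dtype=float)
        R = r.sum(axis=1)
        dead = R <= 0.0
        safe_R = np.where(dead, 1.0, R)
        tau = -np.log1p(-u) / safe_R  # -log(1-u): u in [0,1) -> (0,1] draw
        t_new = t + tau
        overshoot = t_new > T
        fire = active & ~dead & ~overshoot
        if fire.any():
            cum = np.cumsum(r, axis=1)
            target = up * R
            idx = (cum <= target[:, None]).sum(axis=1)
            idx = np.minimum(idx, network.n_reactions - 1)
            state[fire] += S[idx[fire]]
            t[fire] = t_new[fire]
        active &= ~(dead | overshoot)
    else:
        raise RuntimeError("ensemble_final_states exceeded max_steps")
    return state


def trajectory_to_frame(traj: Trajectory, network, trajectory_id: int = 0) -> pd.DataFrame:
    """Event list as a tidy frame (trajectory_id, time, species..., reaction_index)."""
    n = len(traj.times)
    data = {"trajectory_id": np.full(n, trajectory_id), "time": traj.times}
    for j, name in enumerate(network.species_names):
        data[name] = traj.states[:, j]
    data["reaction_index"] = np.concatenate([[0], traj.reaction_indices])
    return pd.DataFrame(data)


def ensemble_to_frame(final_states, network) -> pd.DataFrame:
    df = pd.DataFrame(final_states, columns=list(network.species_names))
    df.insert(0, "trajectory_id", np.arange(len(df)))
    return df
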