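"""Built-in promoter models and their analytic / semi-analytic oracles.

Two models are shipped:

* the two-state (telegraph) promoter: a gene toggling between a
  transcriptionally active state (repressor-free, transcription at rate r)
  and a repressed state (repressor bound), with repressor binding/unbinding
  rates kon_r/koff_r and first-order mRNA degradation at rate gamma.  Time is
  conventionally measured in units of the repressor unbinding rate
  (koff_r = 1).  Mean mRNA and Fano factor have closed forms, and the full
  stationary mRNA law is available from a truncated chemical-master-equation
  solve, so this model anchors every accuracy benchmark.

* a four-state promoter driven by an activator at concentration c: the locus
  is OFF (s=0 unbound, s=1 bound) or ON (s=2 bound, s=3 unbound), with
  transcription at rate r from either ON state.  The eta multipliers let the
  cycle break detailed balance; the nonequilibrium drive is
  ln(eta_ab*eta_ua/(eta_ib*eta_ba)).  mRNA is not simulated for this model —
  the mean production rate r*(pi_2 + pi_3) only needs the promoter-state
  occupancies.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import scipy.linalg

from . import _ad
from .network import RateLaw, ReactionNetwork

__all__ = [
    "TwoStateParams",
    "FourStateParams",
    "build_two_state",
    "TWO_STATE_X0",
    "FOUR_STATE_X0",
    "four_state_sim_params",
    "two_state_mean_fano",
    "two_state_master_equation_pdf",
    "build_four_state",
    "four_state_rate_matrix",
    "four_state_steady_state",
    "four_state_steady_state_smooth",
    "mean_production_rate",
]


@dataclass(frozen=True)
class TwoStateParams:
    """Telegraph-model rates, all in units of 1/time with koff_r = 1."""

    kon_r: float = 0.5
    koff_r: float = 1.0
    r: float = 10.0
    gamma: float = 1.0

    def __post_init__(self):
        for name in ("kon_r", "koff_r", "r", "gamma"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")

    def as_dict(self) -> dict:
        return {"kon_r": self.kon_r, "koff_r": self.koff_r, "r": self.r, "gamma": self.gamma}


def build_two_state(params: TwoStateParams | None = None) -> ReactionNetwork:
    """Reaction network for the telegraph promoter.

    Species: (g_free, g_bound, m); reactions bind / unbind / transcribe /
    degrade.  Parameter values are supplied at simulation time, so the same
    network object serves any parameter point.
    """
    return ReactionNetwork(
        species_names=("g_free", "g_bound", "m"),
        stoichiometry=np.array(
            [
                [-1, +1, 0],  # repressor binds: active -> repressed
                [+1, -1, 0],  # repressor unbinds
                [0, 0, +1],  # transcription (active state only)
                [0, 0, -1],  # mRNA degradation
            ]
        ),
        rate_laws=(
            RateLaw("linear", "kon_r", species=0),
            RateLaw("linear", "koff_r", species=1),
            RateLaw("linear", "r", species=0),
            RateLaw("linear", "gamma", species=2),
        ),
        reaction_names=("bind", "unbind", "transcribe", "degrade"),
        indicator_species=(0, 1),
    )


TWO_STATE_X0 = np.array([1, 0, 0])  # start active with no mRNA


def two_state_mean_fano(params: TwoStateParams) -> tuple[float, float]:
    """Closed-form stationary mean mRNA and Fano factor of the telegraph model.

    mean = (r/gamma) * koff/(kon+koff);
    fano = 1 + r*kon / ((kon+koff) * (kon+koff+gamma)).
    Cross-checked against the truncated master-equation solve in the tests.
    """
    kon, koff, r, g = params.kon_r, params.koff_r, params.r, params.gamma
    mean = (r / g) * koff / (kon + koff)
    fano = 1.0 + r * kon / ((kon + koff) * (kon + koff + g))
    return mean, fano


def two_state_master_equation_pdf(
    params: TwoStateParams, m_max: int | None = None
) -> np.ndarray:
    """Stationary mRNA distribution from a truncated master-equation solve.

    The joint chain over (promoter state, mRNA count 0..m_max) is solved for
    its null vector; the returned array is the marginal P(m), length
    ``m_max + 1``.  Truncation defaults to mean + 12*sd + 25, far beyond any
    appreciable mass.
    """
    mean, fano = two_state_mean_fano(params)
    if m_max is None:
        m_max = int(mean + 12.0 * np.sqrt(fano * mean) + 25)
    n = m_max + 1
    kon, koff, r, g = params.kon_r, params.koff_r, params.r, params.gamma
    # index: s * n + m, s=0 active (free), s=1 repressed (bound)
    Q = np.zeros((2 * n, 2 * n))

    def idx(s, m):
        return s * n + m

    for m in range(n):
        Q[idx(0, m), idx(1, m)] += kon  # binding: active -> repressed
        Q[idx(1, m), idx(0, m)] += koff
        if m + 1 < n:
            Q[idx(0, m), idx(0, m + 1)] += r  # transcription in active state
        if m > 0:
            for s in (0, 1):
                Q[idx(s, m), idx(s, m - 1)] += g * m
    np.fill_diagonal(Q, Q.diagonal() - Q.sum(axis=1))
    ns = scipy.linalg.null_space(Q.T)
    if ns.shape[1] != 1:
        ns = ns[:, [0]]
    pi = np.abs(ns[:, 0])
    pi /= pi.sum()
    return pi[:n] + pi[n:]


@dataclass(frozen=True)
class FourStateParams:
    """Rates of the four-state activator-driven promoter.

    ``kb`` is the activator binding rate constant (per concentration per
    time; conventionally fixed at 0.02, i.e. time in units of 1/kb up to the
    grid scale), ``ku`` the unbinding rate in the OFF state, ``ka``/``ki``
    the base OFF->ON / ON->OFF switching rates with the activator unbound,
    and the four eta factors multiply those rates when the activator is bound
    (eta_ab, eta_ib) or when the promoter is ON (eta_ba, eta_ua).  ``r`` is
    the transcription rate in the ON states.  Detailed balance holds iff
    eta_ab*eta_ua == eta_ib*eta_ba.
    """

    ku: float
    ka: float
    ki: float
    eta_ab: float = 1.0
    eta_ib: float = 1.0
    eta_ba: float = 1.0
    eta_ua: float = 1.0
    kb: float = 0.02
    r: float = 1.0

    def __post_init__(self):
        for name in ("ku", "ka", "ki", "eta_ab", "eta_ib", "eta_ba", "eta_ua", "kb", "r"):
            if _ad.value(getattr(self, name)) <= 0:
                raise ValueError(f"{name} must be positive")

    FREE_NAMES = ("ku", "ka", "ki", "eta_ab", "eta_ib", "eta_ba", "eta_ua")

    def as_dict(self) -> dict:
        return {
            n: getattr(self, n)
            for n in ("ku", "ka", "ki", "eta_ab", "eta_ib", "eta_ba", "eta_ua", "kb", "r")
        }

    def with_values(self, **kw) -> "FourStateParams":
        return replace(self, **kw)


# directed transitions (from_state, to_state, rate expression)
# states: 0 = OFF/unbound, 1 = OFF/bound, 2 = ON/bound, 3 = ON/unbound
def _four_state_edges(p: dict, c):
    return [
        (0, 1, p["kb"] * c),
        (1, 0, p["ku"]),
        (3, 2, p["eta_ba"] * p["kb"] * c),
        (2, 3, p["eta_ua"] * p["ku"]),
        (0, 3, p["ka"]),
        (3, 0, p["ki"]),
        (1, 2, p["eta_ab"] * p["ka"]),
        (2, 1, p["eta_ib"] * p["ki"]),
    ]


def build_four_state(params: FourStateParams) -> ReactionNetwork:
    """Network over four promoter-indicator species; activator concentration
    enters as the external scalar ``c``.  mRNA is not a species here."""
    edges = [
        (0, 1, RateLaw("external", "kb", species=0, scalar="c")),
        (1, 0, RateLaw("linear", "ku", species=1)),
        (3, 2, RateLaw("external", "eta_ba_kb", species=3, scalar="c")),
        (2, 3, RateLaw("linear", "eta_ua_ku", species=2)),
        (0, 3, RateLaw("linear", "ka", species=0)),
        (3, 0, RateLaw("linear", "ki", species=3)),
        (1, 2, RateLaw("linear", "eta_ab_ka", species=1)),
        (2, 1, RateLaw("linear", "eta_ib_ki", species=2)),
    ]
    S = np.zeros((8, 4), dtype=int)
    names = []
    for i, (a, b, _) in enumerate(edges):
        S[i, a] = -1
        S[i, b] = +1
        names.append(f"s{a}->s{b}")
    return ReactionNetwork(
        species_names=("s0_off_unbound", "s1_off_bound", "s2_on_bound", "s3_on_unbound"),
        stoichiometry=S,
        rate_laws=tuple(law for _, _, law in edges),
        reaction_names=tuple(names),
        indicator_species=(0, 1, 2, 3),
    )


def four_state_sim_params(params: FourStateParams) -> dict:
    """Composite rate constants used by :func:`build_four_state`'s rate laws."""
    return {
        "kb": params.kb,
        "ku": params.ku,
        "ka": params.ka,
        "ki": params.ki,
        "eta_ba_kb": params.eta_ba * params.kb,
        "eta_ua_ku": params.eta_ua * params.ku,
        "eta_ab_ka": params.eta_ab * params.ka,
        "eta_ib_ki": params.eta_ib * params.ki,
    }


FOUR_STATE_X0 = np.array([1, 0, 0, 0])


def four_state_rate_matrix(params: FourStateParams, c: float) -> np.ndarray:
    """Generator matrix Q with Q[i, j] the i->j rate, rows summing to zero."""
    Q = np.zeros((4, 4))
    for a, b, rate in _four_state_edges(params.as_dict(), c):
        Q[a, b] += rate
    np.fill_diagonal(Q, -Q.sum(axis=1))
    return Q


def four_state_steady_state(params: FourStateParams, c: float) -> np.ndarray:
    """Stationary distribution pi with Q^T pi = 0, by an explicit null-space
    solve (the oracle route; positive rates make the chain irreducible)."""
    Q = four_state_rate_matrix(params, c)
    ns = scipy.linalg.null_space(Q.T)
    if ns.shape[1] != 1:
        raise np.linalg.LinAlgError("degenerate stationary solve")
    pi = np.abs(ns[:, 0])
    return pi / pi.sum()


def four_state_steady_state_smooth(param_map: dict, c):
    """Stationary distribution via the Markov-chain tree theorem.

    pi_s is proportional to the sum over spanning trees rooted at s of the
    product of edge rates directed toward s.  The state graph is the 4-cycle
    0-1-2-3, whose spanning trees are the four 3-edge paths; the resulting
    polynomial in the rates is smooth, so this route is differentiable
    (accepts dual-number rates) and is used inside design optimization.
    ``param_map`` uses the FourStateParams field names; ``c`` may be an array.
    """
    rate = {}
    for a, b, v in _four_state_edges(
        {
            "kb": param_map["kb"],
            "ku": param_map["ku"],
            "ka": param_map["ka"],
            "ki": param_map["ki"],
            "eta_ba": param_map["eta_ba"],
            "eta_ua": param_map["eta_ua"],
            "eta_ab": param_map["eta_ab"],
            "eta_ib": param_map["eta_ib"],
        },
        c,
    ):
        rate[(a, b)] = v * np.ones(np.shape(_ad.value(c)))
    cycle = [0, 1, 2, 3]
    weights = []
    for s in range(4):
        # sum over the 4 spanning trees (cycle minus one edge), edges directed to s
        total = 0.0
        for drop in range(4):
            edges = [
                (cycle[k], cycle[(k + 1) % 4]) for k in range(4) if k != drop
            ]
            prod = 1.0
            for (a, b) in edges:
                # orient each tree edge toward the root s along the path
                prod = prod * _tree_edge_rate(rate, a, b, s, edges)
            total = total + prod
        weights.append(total)
    Z = weights[0] + weights[1] + weights[2] + weights[3]
    return [w / Z for w in weights]


def _tree_edge_rate(rate, a, b, root, edges):
    """Rate of the undirected tree edge {a, b} directed toward ``root``.

    In a tree, the correct orientation of {a,b} points along the unique path
    to the root: the endpoint farther from the root transitions toward the
    nearer one.
    """
    # breadth-first distances to root within the tree
    adj = {}
    for (x, y) in edges:
        adj.setdefault(x, []).append(y)
        adj.setdefault(y, []).append(x)
    dist = {root: 0}
    frontier = [root]
    while frontier:
        nxt = []
        for u in frontier:
            for v in adj.get(u, []):
                if v not in dist:
                    dist[v] = dist[u] + 1
                    nxt.append(v)
        frontier = nxt
    if dist[a] > dist[b]:
        return rate[(a, b)]
    return rate[(b, a)]


def mean_production_rate(pi, r):
    """Average mRNA production rate r * (pi_2 + pi_3) (the ON states)."""
    total = _ad.value(pi[0] + pi[1] + pi[2] + pi[3]) if isinstance(pi, list) else np.sum(
        _ad.value(pi), axis=0
    )
    if np.any(np.abs(np.asarray(total) - 1.0) > 1e-6):
        raise ValueError("pi is not normalized")
    return (pi[2] + pi[3]) * r
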