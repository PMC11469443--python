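"""Reaction-network definitions: species, stoichiometry, and rate laws.

A :class:`ReactionNetwork` couples an integer stoichiometric matrix ``S``
(one row per reaction, one column per species) with a parameterized rate law
per reaction.  Rate laws are deliberately restricted to products of a rate
constant, an optional single species abundance, and an optional external
scalar (e.g. an activator concentration): this covers every promoter model
shipped here while keeping propensities smooth functions of state and
parameters, which the differentiable simulator requires.

Promoter conformations are encoded as one indicator species per state
(exactly one indicator equals 1 in exact simulation); ``indicator_species``
records which columns are indicators so occupancy statistics can be computed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import yaml

from . import _ad


class ConfigurationError(ValueError):
    """A rate law references a parameter or scalar that was not supplied."""


class ShapeError(ValueError):
    """Dimension mismatch between state, stoichiometry, or rate laws."""


_FORMS = ("constant", "linear", "external")


@dataclass(frozen=True)
class RateLaw:
    """Propensity of one reaction: ``param * [species abundance] * [scalar]``.

    form="constant"  -> k
    form="linear"    -> k * x[species]
    form="external"  -> k * scalar  (optionally gated by a species indicator)
    """

    form: str
    param: str
    species: int | None = None
    scalar: str | None = None

    def __post_init__(self):
        if self.form not in _FORMS:
            raise ConfigurationError(f"unknown rate-law form {self.form!r}")
        if self.form == "linear" and self.species is None:
            raise ConfigurationError("linear rate law needs a species index")
        if self.form == "external" and self.scalar is None:
            raise ConfigurationError("external rate law needs a scalar name")


@dataclass
class ReactionNetwork:
    """Species, stoichiometry, and rate laws of a chemical reaction network."""

    species_names: tuple[str, ...]
    stoichiometry: np.ndarray  # (n_reactions, n_species) int
    rate_laws: tuple[RateLaw, ...]
    reaction_names: tuple[str, ...] = ()
    indicator_species: tuple[int, ...] = ()

    def __post_init__(self):
        self.species_names = tuple(self.species_names)
        self.stoichiometry = np.asarray(self.stoichiometry, dtype=int)
        self.rate_laws = tuple(self.rate_laws)
        if self.stoichiometry.ndim != 2:
            raise ShapeError("stoichiometry must be 2-D (reactions x species)")
        if self.stoichiometry.shape[1] != len(self.species_names):
            raise ShapeError(
                f"stoichiometry has {self.stoichiometry.shape[1]} species columns, "
                f"but {len(self.species_names)} species are named"
            )
        if len(self.rate_laws) != self.stoichiometry.shape[0]:
            raise ShapeError(
                f"{len(self.rate_laws)} rate laws for "
                f"{self.stoichiometry.shape[0]} stoichiometry rows"
            )
        if not self.reaction_names:
            self.reaction_names = tuple(f"R{i+1}" for i in range(self.n_reactions))
        self.reaction_names = tuple(self.reaction_names)
        self.indicator_species = tuple(self.indicator_species)

    @property
    def n_species(self) -> int:
        return len(self.species_names)

    @property
    def n_reactions(self) -> int:
        return self.stoichiometry.shape[0]

    @property
    def parameter_names(self) -> tuple[str, ...]:
        seen: list[str] = []
        for law in self.rate_laws:
            if law.param not in seen:
                seen.append(law.param)
        return tuple(seen)

    # -- serialization -------------------------------------------------
    def to_dict(self) -> dict:
        return {
            "species": list(self.species_names),
            "indicator_species": list(self.indicator_species),
            "reactions": [
                {
                    "name": name,
                    "stoichiometry": row.tolist(),
                    "form": law.form,
                    "param": law.param,
                    **({"species": law.species} if law.species is not None else {}),
                    **({"scalar": law.scalar} if law.scalar is not None else {}),
                }
                for name, row, law in zip(
                    self.reaction_names, self.stoichiometry, self.rate_laws
                )
            ],
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ReactionNetwork":
        reactions = d["reactions"]
        return cls(
            species_names=tuple(d["species"]),
            stoichiometry=np.array([r["stoichiometry"] for r in reactions], dtype=int),
            rate_laws=tuple(
                RateLaw(
                    form=r["form"],
                    param=r["param"],
                    species=r.get("species"),
                    scalar=r.get("scalar"),
                )
                for r in reactions
            ),
            reaction_names=tuple(r["name"] for r in reactions),
            indicator_species=tuple(d.get("indicator_species", ())),
        )

    def save(self, path) -> None:
        path = str(path)
        with open(path, "w") as fh:
            if path.endswith(".json"):
                json.dump(self.to_dict(), fh, indent=2)
            else:
                yaml.safe_dump(self.to_dict(), fh, sort_keys=False)

    @classmethod
    def load(cls, path) -> "ReactionNetwork":
        path = str(path)
        with open(path) as fh:
            d = json.load(fh) if path.endswith(".json") else yaml.safe_load(fh)
        return cls.from_dict(d)


def propensities(network: ReactionNetwork, state, params: dict, externals: dict | None = None):
    """Evaluate the propensity vector r(x) for one state or a batch of states.

    ``state`` has shape (n_species,) or (batch, n_species); plain arrays or
    duals are accepted for both state and parameter values, and the result is
    a dual whenever either input is.  Returns shape (..., n_reactions).
    """
    externals = externals or {}
    sv = _ad.value(state)
    if np.shape(sv)[-1] != network.n_species:
        raise ShapeError(
            f"state has {np.shape(sv)[-1]} species, network has {network.n_species}"
        )
    rs = []
    for law in network.rate_laws:
        try:
            k = params[law.param]
        except KeyError:
            raise ConfigurationError(f"missing parameter {law.param!r}") from None
        r = k
        if law.scalar is not None:
            try:
                r = r * externals[law.scalar]
            except KeyError:
                raise ConfigurationError(f"missing external scalar {law.scalar!r}") from None
        if law.species is not None:
            r = state[..., law.species] * r
        else:
            r = r * np.ones(np.shape(sv)[:-1])
        rs.append(r)
    return _ad.stack(rs, axis=-1)


def propensities_batch_dual(
    network: ReactionNetwork, state, params: dict, externals: dict | None = None
):
    """Batch propensity evaluation with preallocated dual buffers.

    Semantics identical to :func:`propensities` for a (batch, n_species)
    state; avoids per-law stacking overhead on the hot simulation path.
    """
    externals = externals or {}
    from . import _ad as ad

    dual = isinstance(state, ad.Dual) or any(
        isinstance(v, ad.Dual) for v in params.values()
    )
    if not dual:
        return propensities(network, state, params, externals)
    P = (
        state.n_params
        if isinstance(state, ad.Dual)
        else next(v.n_params for v in params.values() if isinstance(v, ad.Dual))
    )
    sv = state.val if isinstance(state, ad.Dual) else np.asarray(state, dtype=float)
    st = state.tan if isinstance(state, ad.Dual) else None
    k = sv.shape[0]
    N = network.n_reactions
    rv = np.empty((k, N))
    rt = np.zeros((k, N, P))
    for i, law in enumerate(network.rate_laws):
        try:
            p = params[law.param]
        except KeyError:
            raise ConfigurationError(f"missing parameter {law.param!r}") from None
        pv, pt = ad.value(p), (p.tan if isinstance(p, ad.Dual) else None)
        if law.scalar is not None:
            try:
                c = externals[law.scalar]
            except KeyError:
                raise ConfigurationError(
                    f"missing external scalar {law.scalar!r}"
                ) from None
            pv = pv * c
            if pt is not None:
                pt = pt * c
        if law.species is None:
            rv[:, i] = pv
            if pt is not None:
                rt[:, i, :] = pt
        else:
            j = law.species
            rv[:, i] = pv * sv[:, j]
            if st is not None:
                rt[:, i, :] = pv * st[:, j, :]
            if pt is not None:
                rt[:, i, :] += sv[:, j, None] * pt
    return ad.Dual(rv, rt)


def total_rate(r):
    """Total exit rate R = sum_i r_i (last axis)."""
    if np.shape(_ad.value(r))[-1] == 0:
        raise ShapeError("empty propensity vector")
    return _ad.asum(r, axis=-1)


@dataclass
class ValidationIssue:
    severity: str  # "error" | "warning"
    message: str


@dataclass
class ValidationReport:
    issues: list[ValidationIssue] = field(default_factory=list)

    @property
    def ok(self) -> bool:
        return not any(i.severity == "error" for i in self.issues)

    def messages(self) -> list[str]:
        return [f"{i.severity}: {i.message}" for i in self.issues]


def validate_network(network: ReactionNetwork | dict) -> ValidationReport:
    """Static diagnostics: shape mismatches and reactions that can drive a
    species negative (a consuming reaction whose rate is not gated by a
    species it consumes can fire from a zero-abundance state).

    Accepts either a constructed network or a raw specification dict; for a
    dict, structural problems that the constructor would reject are reported
    as issues instead of raised.
    """
    report = ValidationReport()
    if isinstance(network, dict):
        try:
            network = ReactionNetwork.from_dict(network)
        except (ValueError, KeyError) as err:
            report.issues.append(ValidationIssue("error", str(err)))
            return report
    for i, (law, row) in enumerate(zip(network.rate_laws, network.stoichiometry)):
        consumed = set(np.flatnonzero(row < 0))
        if consumed and (law.species is None or law.species not in consumed):
            report.issues.append(
                ValidationIssue(
                    "warning",
                    f"reaction {network.reaction_names[i]!r} consumes species "
                    f"{[network.species_names[j] for j in sorted(consumed)]} but its rate "
                    "law is not proportional to a consumed species: abundances can go "
                    "negative",
                )
            )
        if law.species is not None and not (0 <= law.species < network.n_species):
            report.issues.append(
                ValidationIssue("error", f"rate law {i} references species index {law.species}")
            )
    for j in network.indicator_species:
        if not (0 <= j < network.n_species):
            report.issues.append(
                ValidationIssue("error", f"indicator species index {j} out of range")
            )
    return report
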