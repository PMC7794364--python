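"""Core stoichiometric-model data structures and structural edits.

A :class:`MetabolicModel` is the in-memory representation of a
constraints-based metabolic network: a set of metabolites, a set of
reactions (each a sparse stoichiometry column with flux bounds and an
optional gene-protein-reaction rule), and a linear objective.  The model
implies a stoichiometric matrix ``S`` of shape
``(n_metabolites, n_reactions)``; the steady-state flux polytope is
``{v : S v = 0, lb <= v <= ub}``.

Sign convention (used everywhere in this package): for exchange
reactions, negative flux = uptake from the environment, positive flux =
secretion.  Flux units are mmol/gDW/h throughout.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from enum import Enum
from typing import Iterable, Mapping

import numpy as np

__all__ = [
    "Metabolite",
    "Reaction",
    "MetabolicModel",
    "FluxVector",
    "SolveStatus",
    "ValidationError",
    "validate_model",
    "find_exchanges",
    "add_reaction",
    "MASS_BALANCE_TOL",
]

#: Default numerical tolerance for the steady-state residual max|S.v|.
MASS_BALANCE_TOL = 1e-6


class ValidationError(ValueError):
    """Raised when a model or reaction violates a structural invariant."""


@dataclass(frozen=True)
class Metabolite:
    """A chemical species in a compartment.

    Compartment codes follow the usual convention: ``c`` cytosol,
    ``m`` mitochondrion, ``e`` extracellular.
    """

    id: str
    name: str = ""
    compartment: str = "c"

    def __post_init__(self) -> None:
        if not self.id:
            raise ValidationError("metabolite id must be non-empty")
        if not self.compartment:
            raise ValidationError(f"metabolite {self.id!r}: compartment must be non-empty")


@dataclass(frozen=True)
class Reaction:
    """A stoichiometry column with flux bounds and an optional GPR rule.

    ``stoichiometry`` maps metabolite id to coefficient; negative
    coefficients are consumed, positive produced.  ``gpr`` is an infix
    boolean expression over gene symbols with ``and`` / ``or`` and
    parentheses (empty string = no gene association).
    """

    id: str
    stoichiometry: Mapping[str, float]
    lower_bound: float = -1000.0
    upper_bound: float = 1000.0
    gpr: str = ""
    name: str = ""

    def __post_init__(self) -> None:
        if not self.id:
            raise ValidationError("reaction id must be non-empty")
        object.__setattr__(self, "stoichiometry", dict(self.stoichiometry))

    @property
    def is_exchange(self) -> bool:
        """True iff the reaction touches exactly one metabolite."""
        return len(self.stoichiometry) == 1

    @property
    def is_reversible(self) -> bool:
        return self.lower_bound < 0 < self.upper_bound

    def with_bounds(self, lower: float, upper: float) -> "Reaction":
        return replace(self, lower_bound=lower, upper_bound=upper)


class SolveStatus(str, Enum):
    OPTIMAL = "optimal"
    INFEASIBLE = "infeasible"
    UNBOUNDED = "unbounded"


@dataclass
class FluxVector:
    """One flux distribution: per-reaction values, objective value, status."""

    values: dict[str, float]
    objective_value: float
    status: SolveStatus

    def __getitem__(self, reaction_id: str) -> float:
        return self.values[reaction_id]


@dataclass
class MetabolicModel:
    """A stoichiometric model: metabolites, reactions, linear objective.

    The ``objective`` maps reaction ids to weights (the vector ``c`` of
    the FBA problem ``max c.v``); most models carry a single biomass
    entry with weight 1.
    """

    metabolites: list[Metabolite] = field(default_factory=list)
    reactions: list[Reaction] = field(default_factory=list)
    objective: dict[str, float] = field(default_factory=dict)
    name: str = ""

    # ---- lookups -------------------------------------------------------

    @property
    def metabolite_ids(self) -> list[str]:
        return [m.id for m in self.metabolites]

    @property
    def reaction_ids(self) -> list[str]:
        return [r.id for r in self.reactions]

    def get_reaction(self, reaction_id: str) -> Reaction:
        for r in self.reactions:
            if r.id == reaction_id:
                return r
        raise KeyError(f"reaction {reaction_id!r} not in model {self.name!r}")

    def get_metabolite(self, metabolite_id: str) -> Metabolite:
        for m in self.metabolites:
            if m.id == metabolite_id:
                return m
        raise KeyError(f"metabolite {metabolite_id!r} not in model {self.name!r}")

    def has_reaction(self, reaction_id: str) -> bool:
        return any(r.id == reaction_id for r in self.reactions)

    def has_metabolite(self, metabolite_id: str) -> bool:
        return any(m.id == metabolite_id for m in self.metabolites)

    # ---- matrix view ---------------------------------------------------

    def stoichiometric_matrix(self) -> np.ndarray:
        """Dense S of shape (n_metabolites, n_reactions), row/column order
        following ``self.metabolites`` / ``self.reactions``."""
        met_index = {m.id: i for i, m in enumerate(self.metabolites)}
        S = np.zeros((len(self.metabolites), len(self.reactions)))
        for j, rxn in enumerate(self.reactions):
            for met_id, coeff in rxn.stoichiometry.items():
                S[met_index[met_id], j] = coeff
        return S

    def bounds_arrays(self) -> tuple[np.ndarray, np.ndarray]:
        lb = np.array([r.lower_bound for r in self.reactions], dtype=float)
        ub = np.array([r.upper_bound for r in self.reactions], dtype=float)
        return lb, ub

    def objective_array(self) -> np.ndarray:
        c = np.zeros(len(self.reactions))
        for j, r in enumerate(self.reactions):
            if r.id in self.objective:
                c[j] = self.objective[r.id]
        return c

    # ---- edits (copy-on-write) ----------------------------------------

    def copy(self) -> "MetabolicModel":
        return MetabolicModel(
            metabolites=list(self.metabolites),
            reactions=list(self.reactions),
            objective=dict(self.objective),
            name=self.name,
        )

    def with_reaction_bounds(self, reaction_id: str, lower: float, upper: float) -> "MetabolicModel":
        """Return a copy with one reaction's bounds replaced."""
        if lower > upper:
            raise ValidationError(
                f"reaction {reaction_id!r}: lower bound {lower} > upper bound {upper}"
            )
        new = self.copy()
        new.reactions = [
            r.with_bounds(lower, upper) if r.id == reaction_id else r for r in new.reactions
        ]
        if not self.has_reaction(reaction_id):
            raise KeyError(f"reaction {reaction_id!r} not in model")
        return new

    def with_objective(self, objective: Mapping[str, float]) -> "MetabolicModel":
        for rid in objective:
            if not self.has_reaction(rid):
                raise KeyError(f"objective reaction {rid!r} not in model")
        new = self.copy()
        new.objective = dict(objective)
        return new


# ---------------------------------------------------------------------------
# Structural operations
# ---------------------------------------------------------------------------

def validate_model(model: MetabolicModel) -> list[str]:
    """Check all structural invariants; return human-readable violations.

    Violations are data, not exceptions: an empty list means the model is
    well formed.  The check never mutates the model.
    """
    violations: list[str] = []
    met_ids = model.metabolite_ids
    seen_mets: set[str] = set()
    for mid in met_ids:
        if mid in seen_mets:
            violations.append(f"metabolite {mid!r}: duplicate id")
        seen_mets.add(mid)

    seen_rxns: set[str] = set()
    for rxn in model.reactions:
        if rxn.id in seen_rxns:
            violations.append(f"reaction {rxn.id!r}: duplicate id")
        seen_rxns.add(rxn.id)
        if rxn.lower_bound > rxn.upper_bound:
            violations.append(
                f"reaction {rxn.id!r}: lower bound {rxn.lower_bound} exceeds "
                f"upper bound {rxn.upper_bound}"
            )
        if not rxn.stoichiometry:
            violations.append(f"reaction {rxn.id!r}: empty stoichiometry")
        dangling = sorted(set(rxn.stoichiometry) - seen_mets_all(model))
        if dangling:
            violations.append(
                f"reaction {rxn.id!r}: references unknown metabolites {dangling}"
            )
    for rid in model.objective:
        if rid not in seen_rxns:
            violations.append(f"objective: references unknown reaction {rid!r}")
    return violations


def seen_mets_all(model: MetabolicModel) -> set[str]:
    return set(model.metabolite_ids)


def find_exchanges(model: MetabolicModel) -> list[str]:
    """Ids of exchange reactions (single-metabolite columns), sorted."""
    return sorted(r.id for r in model.reactions if r.is_exchange)


def add_reaction(
    model: MetabolicModel,
    reaction: Reaction,
    new_metabolites: Iterable[Metabolite] = (),
) -> MetabolicModel:
    """Return a copy of ``model`` with one reaction (and any new
    metabolites it needs) appended.

    The original model is never modified; all pre-existing columns are
    carried over unchanged.  A duplicate reaction id is a conflict.
    """
    if model.has_reaction(reaction.id):
        raise ValidationError(f"reaction id {reaction.id!r} already present in model")
    new = model.copy()
    for met in new_metabolites:
        if not new.has_metabolite(met.id):
            new.metabolites.append(met)
    missing = sorted(set(reaction.stoichiometry) - set(new.metabolite_ids))
    if missing:
        raise ValidationError(
            f"reaction {reaction.id!r}: references unknown metabolites {missing}"
        )
    new.reactions.append(reaction)
    return new
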