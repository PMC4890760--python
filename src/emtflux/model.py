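"""Stoichiometric containers for irreversible signalling/metabolic networks.

A :class:`StoichiometricModel` holds *m* species and *r* reactions and
exposes the m-by-r stoichiometric matrix ``S`` (reactants negative,
products positive).  Steady state means ``S v = 0`` for the flux vector
``v``, with elementwise bounds ``l <= v <= u``.  All reactions are
irreversible, so ``l >= 0`` except where an explicit relaxation opens a
secretion direction.

Flux in a signalling network is the rate of a phosphorylation, binding or
dimerisation event, in arbitrary units (AU).
"""

from __future__ import annotations

import copy
import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np

from .gpr import GPRRule, format_gpr, gpr_genes, parse_gpr

__all__ = [
    "Species",
    "Reaction",
    "StoichiometricModel",
    "RegulatoryAnnotation",
    "ModelValidationError",
    "classify_reactions",
    "DEFAULT_UPPER_BOUND",
]

#: Default flux ceiling for internal reactions (AU); effectively unbounded.
DEFAULT_UPPER_BOUND = 1000.0

SPECIES_ROLES = ("signaling-component", "modifier-product", "boundary")


class ModelValidationError(ValueError):
    """A model or one of its parts violates a structural invariant."""


@dataclass
class Species:
    """A network component: protein, complex or metabolite."""

    id: str
    name: str = ""
    role: str = "signaling-component"

    def __post_init__(self) -> None:
        if not self.id:
            raise ModelValidationError("species id must be non-empty")
        if self.role not in SPECIES_ROLES:
            raise ModelValidationError(
                f"species {self.id!r}: unknown role {self.role!r}; expected one of {SPECIES_ROLES}"
            )


@dataclass
class Reaction:
    """An irreversible reaction with signed stoichiometry and flux bounds.

    ``kind`` is ``"exchange"`` iff the reaction touches exactly one species
    (a boundary uptake or secretion), ``"internal"`` otherwise.
    """

    id: str
    stoichiometry: dict[str, float]
    lower_bound: float = 0.0
    upper_bound: float = DEFAULT_UPPER_BOUND
    gpr: GPRRule | None = None
    name: str = ""

    def __post_init__(self) -> None:
        if not self.id:
            raise ModelValidationError("reaction id must be non-empty")
        if isinstance(self.gpr, str):
            self.gpr = parse_gpr(self.gpr)
        self.stoichiometry = {s: float(c) for s, c in self.stoichiometry.items()}
        for sid, coef in self.stoichiometry.items():
            if coef == 0 or not math.isfinite(coef):
                raise ModelValidationError(
                    f"reaction {self.id!r}: coefficient for {sid!r} is {coef}; "
                    "must be nonzero and finite"
                )
        if self.lower_bound > self.upper_bound:
            raise ModelValidationError(
                f"reaction {self.id!r}: lower bound {self.lower_bound} exceeds "
                f"upper bound {self.upper_bound}"
            )

    @property
    def kind(self) -> str:
        return "exchange" if len(self.stoichiometry) == 1 else "internal"

    @property
    def reactants(self) -> dict[str, float]:
        return {s: -c for s, c in self.stoichiometry.items() if c < 0}

    @property
    def products(self) -> dict[str, float]:
        return {s: c for s, c in self.stoichiometry.items() if c > 0}

    @property
    def gpr_string(self) -> str:
        return "" if self.gpr is None else format_gpr(self.gpr)

    def genes(self) -> set[str]:
        return gpr_genes(self.gpr)

    def formula(self) -> str:
        """Human-readable ``A + 2 B -> C`` form (exchanges: ``-> A`` / ``A ->``)."""

        def side(terms: dict[str, float]) -> str:
            parts = []
            for sid in sorted(terms):
                coef = terms[sid]
                coef_s = "" if coef == 1 else (f"{coef:g} ")
                parts.append(f"{coef_s}{sid}")
            return " + ".join(parts)

        return f"{side(self.reactants)} -> {side(self.products)}".strip()


class StoichiometricModel:
    """An ordered collection of species and reactions with an S matrix."""

    def __init__(
        self,
        species: Iterable[Species] = (),
        reactions: Iterable[Reaction] = (),
        metadata: Mapping[str, str] | None = None,
    ) -> None:
        self.species: list[Species] = list(species)
        self.reactions: list[Reaction] = list(reactions)
        self.metadata: dict[str, str] = dict(metadata or {})
        self._check_unique_ids()

    # -- basic queries ------------------------------------------------------

    @property
    def species_ids(self) -> list[str]:
        return [s.id for s in self.species]

    @property
    def reaction_ids(self) -> list[str]:
        return [r.id for r in self.reactions]

    @property
    def m(self) -> int:
        return len(self.species)

    @property
    def r(self) -> int:
        return len(self.reactions)

    def get_species(self, sid: str) -> Species:
        try:
            return self._species_index_map()[sid]
        except KeyError:
            raise KeyError(f"no species {sid!r} in model") from None

    def get_reaction(self, rid: str) -> Reaction:
        for rxn in self.reactions:
            if rxn.id == rid:
                return rxn
        raise KeyError(f"no reaction {rid!r} in model")

    def _species_index_map(self) -> dict[str, Species]:
        return {s.id: s for s in self.species}

    def genes(self) -> set[str]:
        out: set[str] = set()
        for rxn in self.reactions:
            out |= rxn.genes()
        return out

    # -- matrix view --------------------------------------------------------

    @property
    def S(self) -> np.ndarray:
        """The m-by-r stoichiometric matrix (dense; these networks are small)."""
        idx = {sid: i for i, sid in enumerate(self.species_ids)}
        S = np.zeros((self.m, self.r))
        for j, rxn in enumerate(self.reactions):
            for sid, coef in rxn.stoichiometry.items():
                S[idx[sid], j] = coef
        return S

    @property
    def lower_bounds(self) -> np.ndarray:
        return np.array([r.lower_bound for r in self.reactions])

    @property
    def upper_bounds(self) -> np.ndarray:
        return np.array([r.upper_bound for r in self.reactions])

    # -- editing ------------------------------------------------------------

    def add_species(self, species: Species) -> None:
        if species.id in set(self.species_ids):
            raise ModelValidationError(f"duplicate species id {species.id!r}")
        self.species.append(species)

    def add_reaction(self, reaction: Reaction) -> None:
        if reaction.id in set(self.reaction_ids):
            raise ModelValidationError(f"duplicate reaction id {reaction.id!r}")
        known = set(self.species_ids)
        missing = set(reaction.stoichiometry) - known
        if missing:
            raise ModelValidationError(
                f"reaction {reaction.id!r} references unknown species {sorted(missing)}"
            )
        self.reactions.append(reaction)

    def remove_reactions(self, rids: Iterable[str]) -> None:
        drop = set(rids)
        unknown = drop - set(self.reaction_ids)
        if unknown:
            raise KeyError(f"cannot remove unknown reactions {sorted(unknown)}")
        self.reactions = [r for r in self.reactions if r.id not in drop]

    def copy(self) -> "StoichiometricModel":
        return copy.deepcopy(self)

    # -- validation ---------------------------------------------------------

    def _check_unique_ids(self) -> None:
        for label, ids in (("species", self.species_ids), ("reaction", self.reaction_ids)):
            seen: set[str] = set()
            for i in ids:
                if i in seen:
                    raise ModelValidationError(f"duplicate {label} id {i!r}")
                seen.add(i)

    def validate(self) -> None:
        """Assert every structural invariant; raise on the first violation."""
        self._check_unique_ids()
        known = set(self.species_ids)
        used: set[str] = set()
        for rxn in self.reactions:
            missing = set(rxn.stoichiometry) - known
            if missing:
                raise ModelValidationError(
                    f"reaction {rxn.id!r} references unknown species {sorted(missing)}"
                )
            if rxn.lower_bound < 0 and rxn.kind == "internal":
                raise ModelValidationError(
                    f"internal reaction {rxn.id!r} has negative lower bound "
                    f"{rxn.lower_bound}; all internal reactions are irreversible"
                )
            if rxn.kind == "internal" and (not rxn.reactants or not rxn.products):
                raise ModelValidationError(
                    f"internal reaction {rxn.id!r} must have at least one reactant "
                    "and one product"
                )
            used |= set(rxn.stoichiometry)
        orphan = known - used
        if orphan:
            raise ModelValidationError(
                f"species not used by any reaction: {sorted(orphan)}"
            )

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, StoichiometricModel):
            return NotImplemented
        return (
            [(s.id, s.name, s.role) for s in self.species]
            == [(s.id, s.name, s.role) for s in other.species]
            and [
                (r.id, r.name, r.stoichiometry, r.lower_bound, r.upper_bound, r.gpr_string)
                for r in self.reactions
            ]
            == [
                (r.id, r.name, r.stoichiometry, r.lower_bound, r.upper_bound, r.gpr_string)
                for r in other.reactions
            ]
        )

    def __repr__(self) -> str:
        return (
            f"<StoichiometricModel {self.metadata.get('id', '')} "
            f"m={self.m} r={self.r}>"
        )


@dataclass
class RegulatoryAnnotation:
    """Per-reaction regulator lists plus the protein→gene map.

    ``modifiers`` are phosphorylated protein entities that catalyse their
    target reaction; ``activators`` and ``inhibitors`` regulate it
    positively/negatively.  ``protein_genes`` maps each protein id to its
    encoding genes; ``protein_relation`` says how a multi-gene protein
    combines: a ``"complex"`` needs all genes (AND), an ``"isoform"`` set
    needs any one (OR).
    """

    modifiers: dict[str, list[str]] = field(default_factory=dict)
    activators: dict[str, list[str]] = field(default_factory=dict)
    inhibitors: dict[str, list[str]] = field(default_factory=dict)
    protein_genes: dict[str, list[str]] = field(default_factory=dict)
    protein_relation: dict[str, str] = field(default_factory=dict)

    def proteins(self) -> set[str]:
        out: set[str] = set()
        for table in (self.modifiers, self.activators, self.inhibitors):
            for plist in table.values():
                out |= set(plist)
        return out

    def validate(self, model: StoichiometricModel) -> None:
        rids = set(model.reaction_ids)
        for label, table in (
            ("modifier", self.modifiers),
            ("activator", self.activators),
            ("inhibitor", self.inhibitors),
        ):
            for rid in table:
                if rid not in rids:
                    raise ModelValidationError(
                        f"{label} annotation references unknown reaction {rid!r}"
                    )
        for protein, genes in self.protein_genes.items():
            if not genes:
                raise ModelValidationError(f"protein {protein!r} maps to no genes")


def classify_reactions(model: StoichiometricModel) -> dict[str, list[str]]:
    """Partition reaction ids into internal and exchange sets.

    A reaction is an exchange iff its stoichiometry touches exactly one
    species; the partition is exhaustive and disjoint by construction.
    """
    out: dict[str, list[str]] = {"internal": [], "exchange": []}
    for rxn in model.reactions:
        out[rxn.kind].append(rxn.id)
    return out
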