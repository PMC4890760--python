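"""Synthetic pathways, expression tables and sign tables with ground truth.

Every stage of the pipeline is testable without downloads: the generator
emits small mass-balanced irreversible networks (acyclic in their
internal reactions, so dead ends are guaranteed before boundary closure),
regulatory annotations with planted modifiers and inhibitors, expression
tables with known up/down calls, and sign tables with analytically known
predicted directions.

Ground truth for the minimal-exchange stage is computed at generation
time by exhaustive enumeration: subsets of candidate boundary reactions
in order of increasing size, with an LP feasibility check per subset.
The enumeration runs over the dead-end species, each of which provably
needs its own boundary reaction in an irreversible network (a species
whose S-row has a single sign can only be balanced by its own exchange),
so the first feasible subset size is the global minimum.

The generator is deterministic: the same spec yields byte-identical
outputs.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import linprog

from .model import (
    DEFAULT_UPPER_BOUND,
    Reaction,
    RegulatoryAnnotation,
    Species,
    StoichiometricModel,
)
from .reconstruction import find_dead_ends

__all__ = [
    "SyntheticSpec",
    "make_network",
    "make_expression",
    "make_sign_table",
    "minimal_exchange_oracle",
]

TOPOLOGIES = ("chain", "branch", "diamond", "random-dag")
_ORACLE_SPECIES_CAP = 20
_ORACLE_CANDIDATE_CAP = 14


@dataclass
class SyntheticSpec:
    """Declarative description of one synthetic study condition."""

    n_species: int = 8
    n_internal_reactions: int | None = None
    topology: str = "random-dag"
    n_modifiers: int = 2
    n_inhibitors: int = 1
    n_activators: int = 0
    planted_up_E: list[str] | None = None
    planted_up_M: list[str] | None = None
    effect: float = 3.0
    cutoff: float = 2.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.topology not in TOPOLOGIES:
            raise ValueError(f"unknown topology {self.topology!r}; choose from {TOPOLOGIES}")
        if self.n_species < 2:
            raise ValueError("need at least 2 species")
        if self.topology == "diamond" and self.n_species < 4:
            raise ValueError("diamond topology needs at least 4 species")
        if self.effect < self.cutoff:
            raise ValueError(
                f"planted effect size {self.effect} is below the call cutoff "
                f"{self.cutoff}; planted genes would be unrecoverable"
            )


def _edges_for(spec: SyntheticSpec, rng: np.random.Generator) -> list[tuple[int, int]]:
    n = spec.n_species
    if spec.topology == "chain":
        return [(i, i + 1) for i in range(n - 1)]
    if spec.topology == "branch":
        # a short stem, then one branch per remaining species off the hub
        edges = [(0, 1)]
        edges += [(1, k) for k in range(2, n)]
        return edges
    if spec.topology == "diamond":
        # source -> middle layer -> sink
        middle = list(range(1, n - 1))
        edges = [(0, k) for k in middle] + [(k, n - 1) for k in middle]
        return edges
    # random DAG: every species (but the first) has one parent earlier in
    # the topological order; optional extra forward edges up to the target
    edges = [(int(rng.integers(0, i)), i) for i in range(1, n)]
    target = spec.n_internal_reactions or (n - 1 + n // 3)
    seen = set(edges)
    attempts = 0
    while len(edges) < target and attempts < 50 * target:
        attempts += 1
        i, j = sorted(rng.choice(n, size=2, replace=False))
        if (int(i), int(j)) not in seen:
            edges.append((int(i), int(j)))
            seen.add((int(i), int(j)))
    return edges


def make_network(
    spec: SyntheticSpec,
) -> tuple[StoichiometricModel, RegulatoryAnnotation, dict]:
    """Generate a pathway, its regulatory annotation and ground truth.

    Returns ``(model, annotation, truth)`` where ``truth`` holds the dead
    end set, the brute-force minimal exchange cardinality/sets and the
    planted regulator layout.
    """
    if spec.n_species > _ORACLE_SPECIES_CAP:
        raise ValueError(
            f"n_species={spec.n_species} exceeds the ground-truth oracle cap "
            f"({_ORACLE_SPECIES_CAP}); generate without ground truth instead"
        )
    rng = np.random.default_rng(spec.seed)
    edges = _edges_for(spec, rng)

    species = [Species(f"S{i}", name=f"component {i}") for i in range(spec.n_species)]
    reactions = [
        Reaction(f"R{k + 1}", {f"S{i}": -1.0, f"S{j}": 1.0}, 0.0, DEFAULT_UPPER_BOUND)
        for k, (i, j) in enumerate(edges)
    ]
    model = StoichiometricModel(
        species, reactions, {"id": f"synthetic-{spec.topology}-{spec.seed}"}
    )
    model.validate()

    ann = RegulatoryAnnotation()
    rids = [r.id for r in reactions]
    n_regulated = spec.n_modifiers + spec.n_inhibitors + spec.n_activators
    if n_regulated > len(rids):
        raise ValueError(
            f"{n_regulated} regulated reactions requested but only {len(rids)} reactions"
        )
    chosen = list(rng.choice(rids, size=n_regulated, replace=False))
    mod_rids = chosen[: spec.n_modifiers]
    inh_rids = chosen[spec.n_modifiers: spec.n_modifiers + spec.n_inhibitors]
    act_rids = chosen[spec.n_modifiers + spec.n_inhibitors:]

    def add_protein(prefix: str, idx: int, table: dict, rid: str, relation: str) -> str:
        pid = f"{prefix}{idx}"
        n_genes = int(rng.integers(1, 3))
        ann.protein_genes[pid] = [f"g{pid}_{k}" for k in range(1, n_genes + 1)]
        ann.protein_relation[pid] = relation
        table.setdefault(rid, []).append(pid)
        return pid

    for k, rid in enumerate(mod_rids, start=1):
        add_protein("MOD", k, ann.modifiers, rid, "complex")
    for k, rid in enumerate(inh_rids, start=1):
        add_protein("INH", k, ann.inhibitors, rid, "isoform")
    for k, rid in enumerate(act_rids, start=1):
        add_protein("ACT", k, ann.activators, rid, "complex")

    dead = find_dead_ends(model)
    cardinality, minimal_sets = minimal_exchange_oracle(model)
    truth = {
        "dead_ends": sorted(dead),
        "min_exchange_cardinality": cardinality,
        "minimal_exchange_sets": minimal_sets,
        "modifier_reactions": mod_rids,
        "inhibitor_reactions": inh_rids,
        "activator_reactions": act_rids,
        "edges": edges,
    }
    return model, ann, truth


def minimal_exchange_oracle(
    model: StoichiometricModel,
    forced_lower: float = 1.0,
    bound: float = DEFAULT_UPPER_BOUND,
) -> tuple[int, list[list[str]]]:
    """Brute-force minimum number of boundary reactions closing all dead ends.

    Candidates are two-sided exchanges on the dead-end species (one per
    species; a dead-end species can only be balanced by its own exchange,
    so restricting the enumeration to them preserves global optimality).
    Subsets are enumerated in order of increasing size and checked by LP:
    internal reactions forced to [forced_lower, bound], chosen exchanges
    free in [-bound, bound].  Returns the minimum cardinality and every
    minimal subset (as sorted species-id lists).
    """
    dead = sorted(find_dead_ends(model))
    if len(dead) > _ORACLE_CANDIDATE_CAP:
        raise ValueError(
            f"{len(dead)} dead ends exceed the enumeration cap ({_ORACLE_CANDIDATE_CAP})"
        )
    S_full = model.S
    sidx = {sid: i for i, sid in enumerate(model.species_ids)}
    m, r = S_full.shape
    internal = [j for j, rxn in enumerate(model.reactions) if rxn.kind == "internal"]
    lb = model.lower_bounds.astype(float)
    ub = model.upper_bounds.astype(float)
    for j in internal:
        lb[j] = forced_lower
        ub[j] = max(ub[j], forced_lower)

    def feasible(subset: tuple[str, ...]) -> bool:
        cols = [np.eye(m)[:, [sidx[sid]]] for sid in subset]
        S = np.hstack([S_full] + cols) if cols else S_full
        bounds = list(zip(lb, ub)) + [(-bound, bound)] * len(subset)
        res = linprog(
            c=np.zeros(S.shape[1]),
            A_eq=S,
            b_eq=np.zeros(m),
            bounds=bounds,
            method="highs",
        )
        return res.status == 0

    for k in range(len(dead) + 1):
        winners = [
            sorted(subset)
            for subset in itertools.combinations(dead, k)
            if feasible(subset)
        ]
        if winners:
            return k, winners
    raise RuntimeError("no exchange subset over the dead-end species is feasible")


def make_expression(
    spec: SyntheticSpec, model: StoichiometricModel
) -> tuple[pd.DataFrame, dict[str, str]]:
    """Expression table with planted up-E/up-M genes and the truth map.

    Planted up-E genes get fold <= -effect at p <= 0.01 (up-M symmetric);
    background genes stay below the cutoff in |fold| with uniform
    p-values, so the classifier recovers exactly the planted calls.
    """
    genes = sorted(model.genes())
    if not genes:
        raise ValueError("model has no GPR genes; build GPRs before planting expression")
    rng = np.random.default_rng(spec.seed + 1)

    if spec.planted_up_E is None and spec.planted_up_M is None:
        shuffled = list(genes)
        rng.shuffle(shuffled)
        k = max(1, len(genes) // 4)
        up_E = shuffled[:k]
        up_M = shuffled[k: 2 * k]
    else:
        up_E = list(spec.planted_up_E or [])
        up_M = list(spec.planted_up_M or [])
    unknown = (set(up_E) | set(up_M)) - set(genes)
    if unknown:
        raise ValueError(f"planted genes not in the model: {sorted(unknown)}")
    if set(up_E) & set(up_M):
        raise ValueError("a gene cannot be planted in both directions")

    rows = []
    truth: dict[str, str] = {}
    for gene in genes:
        if gene in up_E:
            fold = -(spec.effect + abs(rng.normal(0, 0.2 * spec.effect)))
            p = rng.uniform(0.0005, 0.01)
            truth[gene] = "up_E"
        elif gene in up_M:
            fold = spec.effect + abs(rng.normal(0, 0.2 * spec.effect))
            p = rng.uniform(0.0005, 0.01)
            truth[gene] = "up_M"
        else:
            fold = rng.uniform(-0.8, 0.8) * spec.cutoff
            if fold == 0:
                fold = 0.1 * spec.cutoff
            p = rng.uniform(0.0, 1.0)
            truth[gene] = "unchanged"
        rows.append({"gene_id": gene, "fold_change": fold, "p_value": p})
    return pd.DataFrame(rows), truth


def make_sign_table(
    genes: list[str], seed: int = 0, declared_fold: float = 0.5, pathway: str = "AKT"
) -> tuple[pd.DataFrame, dict[str, str]]:
    """Random ±1 sign table plus the analytically true directions.

    Under the declared pathway fold (mesenchymal/epithelial), a +1 gene
    is down in whichever context has the lower pathway flux; -1 inverts.
    """
    if not genes:
        raise ValueError("need a non-empty gene list")
    if not declared_fold > 0:
        raise ValueError("declared_fold must be positive")
    rng = np.random.default_rng(seed)
    signs = rng.choice([1, -1], size=len(genes))
    table = pd.DataFrame(
        {
            "gene_id": genes,
            "pathway": pathway,
            "sign": signs,
            "reference": "synthetic",
        }
    )
    truth: dict[str, str] = {}
    if declared_fold != 1:
        higher_in_E = declared_fold < 1
        for gene, sign in zip(genes, signs):
            if (sign == +1) == higher_in_E:
                truth[gene] = "down_in_M"
            else:
                truth[gene] = "down_in_E"
    return table, truth
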