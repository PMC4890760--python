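"""From raw pathway to feasible constraint-based signalling model.

The pipeline stages implemented here follow the reconstruction recipe for
signalling networks:

1. :func:`convert_pathway` — default bounds [0, 1000] AU on every internal
   reaction (all reactions irreversible, so lower bounds are zero).
2. :func:`insert_modifiers` — a modifier (a phosphorylated protein that
   catalyses a downstream transition) is written into its target reaction
   as a co-substrate producing a spent form: ``A + mod -> B + mod_p``,
   with boundary reactions ``-> mod`` (production) and ``mod_p ->``
   (consumption).  This keeps stoichiometry unambiguous while connecting
   the modifier to its targets.
3. :func:`build_gprs` — Boolean gene rules: complexes joined by AND,
   isoform sets by OR, inhibitors wrapped in NOT; a reaction with both a
   modifier and an inhibitor gets ``modifier AND NOT inhibitor``.
4. :func:`add_minimal_exchanges` — dead-end species (only produced or only
   consumed) block steady-state flux.  A candidate exchange is opened for
   every species, all internal reactions are forced to carry flux >= 1,
   and a mixed-integer program (:func:`relax_rxns`) picks the minimum
   number of exchanges whose bounds must be relaxed.  Only those survive
   into the final model.

The relaxation MILP minimises the number of relaxed reactions ``sum(y_j)``
subject to ``S v = 0``, ``l_j - n_j <= v_j <= u_j + p_j`` for candidates,
ordinary bounds elsewhere, and big-M coupling ``p_j, n_j <= M y_j`` with
binary ``y_j``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp
from scipy.optimize import Bounds, LinearConstraint, linprog, milp

from .gpr import And, GPRRule, Not, Or, Gene, format_gpr
from .model import (
    DEFAULT_UPPER_BOUND,
    ModelValidationError,
    Reaction,
    RegulatoryAnnotation,
    Species,
    StoichiometricModel,
)

__all__ = [
    "RelaxationProblem",
    "RelaxationResult",
    "RelaxationInfeasibleError",
    "convert_pathway",
    "insert_modifiers",
    "build_gprs",
    "find_dead_ends",
    "relax_rxns",
    "add_minimal_exchanges",
]

logger = logging.getLogger(__name__)

#: Big-M constant coupling relaxation amounts to their binary indicators.
DEFAULT_BIG_M = 1000.0
#: Flux floor forced onto internal reactions while closing dead ends (AU).
DEFAULT_FORCED_LOWER = 1.0

_MILP_OPTIONS = {"mip_rel_gap": 0.0, "presolve": True}
_INTEGRALITY_TOL = 1e-6
_AMOUNT_TOL = 1e-6


class RelaxationInfeasibleError(RuntimeError):
    """The MILP is infeasible even with every candidate reaction relaxed."""

    def __init__(self, message: str, species: list[str] | None = None):
        super().__init__(message)
        self.species = species or []


@dataclass
class RelaxationProblem:
    """Inputs of the minimal-relaxation MILP.

    ``candidates`` (R_r) are the reactions whose bounds may be relaxed;
    every other reaction (R_n) keeps its stated bounds.
    """

    model: StoichiometricModel
    candidates: list[str]
    big_M: float = DEFAULT_BIG_M

    def __post_init__(self) -> None:
        rids = set(self.model.reaction_ids)
        unknown = set(self.candidates) - rids
        if unknown:
            raise ModelValidationError(f"unknown candidate reactions {sorted(unknown)}")
        if self.big_M <= 0:
            raise ModelValidationError("big_M must be positive")


@dataclass
class RelaxationResult:
    """Output of :func:`relax_rxns`.

    ``relaxed`` holds the reaction ids with ``y_j = 1``; ``p``/``n`` the
    upper/lower bound relaxation amounts; ``v`` the witness flux vector.
    """

    relaxed: list[str]
    p: dict[str, float]
    n: dict[str, float]
    v: dict[str, float]
    objective: float
    alpha: float | None = None
    extras: dict = field(default_factory=dict)

    @property
    def cardinality(self) -> int:
        return len(self.relaxed)


def convert_pathway(
    pathway: StoichiometricModel,
    annotation: RegulatoryAnnotation | None = None,
    default_ub: float = DEFAULT_UPPER_BOUND,
) -> tuple[StoichiometricModel, RegulatoryAnnotation]:
    """Apply default irreversibility bounds to a raw pathway.

    Every internal reaction gets bounds [0, ``default_ub``] AU.  The
    pathway must not contain exchange reactions yet — the system boundary
    is introduced later by :func:`add_minimal_exchanges`.
    """
    if not pathway.reactions:
        raise ModelValidationError("pathway has no reactions")
    model = pathway.copy()
    for rxn in model.reactions:
        if not rxn.stoichiometry:
            raise ModelValidationError(f"reaction {rxn.id!r} has empty stoichiometry")
        rxn.lower_bound = 0.0
        rxn.upper_bound = default_ub
    model.metadata.setdefault("default_ub", str(default_ub))
    ann = annotation if annotation is not None else RegulatoryAnnotation()
    ann.validate(model)
    return model, ann


def insert_modifiers(
    model: StoichiometricModel,
    annotation: RegulatoryAnnotation,
    default_ub: float = DEFAULT_UPPER_BOUND,
) -> StoichiometricModel:
    """Rewrite modifier catalysis into explicit stoichiometry.

    For each reaction with modifiers, each modifier ``mod`` becomes a
    co-substrate and its spent form ``mod_p`` a co-product; boundary
    reactions ``-> mod`` and ``mod_p ->`` are added once per modifier.
    Mass is conserved: the rewritten column consumes one ``mod`` and
    produces one ``mod_p``.
    """
    out = model.copy()
    known = set(out.species_ids)
    spent_name: dict[str, str] = {}

    def spent_for(mod: str) -> str:
        if mod not in spent_name:
            candidate = f"{mod}_p"
            while candidate in known:
                candidate += "_p"
            spent_name[mod] = candidate
        return spent_name[mod]

    exchanges_to_add: list[Reaction] = []
    seen_exchange: set[str] = set()
    for rid, mods in annotation.modifiers.items():
        rxn = out.get_reaction(rid)
        for mod in mods:
            if mod in rxn.reactants:
                raise ModelValidationError(
                    f"modifier {mod!r} is already a reactant of {rid!r}; "
                    "stoichiometry would be ambiguous"
                )
            if mod not in known:
                out.add_species(Species(mod, role="signaling-component"))
                known.add(mod)
            mod_p = spent_for(mod)
            if mod_p not in known:
                out.add_species(Species(mod_p, role="modifier-product"))
                known.add(mod_p)
            rxn.stoichiometry[mod] = rxn.stoichiometry.get(mod, 0.0) - 1.0
            rxn.stoichiometry[mod_p] = rxn.stoichiometry.get(mod_p, 0.0) + 1.0
            if mod not in seen_exchange:
                exchanges_to_add.append(
                    Reaction(f"EX_{mod}_in", {mod: 1.0}, 0.0, default_ub,
                             name=f"production of {mod}")
                )
                exchanges_to_add.append(
                    Reaction(f"EX_{mod_p}_out", {mod_p: -1.0}, 0.0, default_ub,
                             name=f"consumption of {mod_p}")
                )
                seen_exchange.add(mod)
    for rxn in exchanges_to_add:
        out.add_reaction(rxn)
    out.metadata["modifier_exchanges"] = str(len(exchanges_to_add))
    return out


def _protein_expr(protein: str, annotation: RegulatoryAnnotation) -> GPRRule | None:
    genes = annotation.protein_genes.get(protein)
    if not genes:
        logger.warning("protein %r has no gene mapping; skipped in GPR", protein)
        return None
    if len(genes) == 1:
        return Gene(genes[0])
    relation = annotation.protein_relation.get(protein, "complex")
    node = And if relation == "complex" else Or
    return node(tuple(Gene(g) for g in genes))


def build_gprs(
    model: StoichiometricModel, annotation: RegulatoryAnnotation
) -> StoichiometricModel:
    """Attach Boolean gene rules derived from the regulatory annotation.

    Positive regulators (modifiers, activators) are joined by AND — all are
    required; inhibitor proteins are joined by OR (any inhibitor suffices)
    and wrapped in a single NOT.  Boundary reactions created for a modifier
    inherit that modifier's rule.  Unannotated reactions carry no rule.
    """
    out = model.copy()
    by_id = {r.id: r for r in out.reactions}
    modifier_expr: dict[str, GPRRule] = {}

    for rid in by_id:
        positives: list[GPRRule] = []
        for table in (annotation.modifiers, annotation.activators):
            for protein in table.get(rid, []):
                expr = _protein_expr(protein, annotation)
                if expr is not None:
                    positives.append(expr)
                    if table is annotation.modifiers:
                        modifier_expr[protein] = expr
        negatives: list[GPRRule] = []
        for protein in annotation.inhibitors.get(rid, []):
            expr = _protein_expr(protein, annotation)
            if expr is not None:
                negatives.append(expr)
        rule: GPRRule | None = None
        if positives:
            rule = positives[0] if len(positives) == 1 else And(tuple(positives))
        if negatives:
            neg = negatives[0] if len(negatives) == 1 else Or(tuple(negatives))
            neg = Not(neg)
            rule = neg if rule is None else And((rule, neg))
        if rule is not None:
            by_id[rid].gpr = rule

    # boundary reactions of a modifier carry the modifier's own gene rule
    for protein, expr in modifier_expr.items():
        for rid in (f"EX_{protein}_in", f"EX_{protein}_p_out"):
            if rid in by_id and by_id[rid].gpr is None:
                by_id[rid].gpr = expr
    return out


def find_dead_ends(model: StoichiometricModel) -> set[str]:
    """Species that are only produced or only consumed.

    A species is a dead end iff every nonzero entry of its S-matrix row has
    the same sign, so no steady-state flux can pass through it.
    """
    produced: set[str] = set()
    consumed: set[str] = set()
    for rxn in model.reactions:
        for sid, coef in rxn.stoichiometry.items():
            (produced if coef > 0 else consumed).add(sid)
    return {s.id for s in model.species} - (produced & consumed)


def relax_rxns(problem: RelaxationProblem) -> RelaxationResult:
    """Minimum-cardinality bound relaxation (mixed-integer program).

    Solved in two stages for determinism: first minimise the number of
    relaxed reactions, then — with that cardinality fixed — minimise the
    total relaxation amount ``sum(p_j + n_j)``, with a vanishing
    lexicographic preference for earlier reaction ids to break residual
    ties.
    """
    model = problem.model
    S = sp.csc_matrix(model.S)
    m, r = S.shape
    lb, ub = model.lower_bounds, model.upper_bounds
    rid_index = {rid: j for j, rid in enumerate(model.reaction_ids)}
    cand = [rid_index[rid] for rid in problem.candidates]
    nc = len(cand)
    M = problem.big_M

    # variable layout: [v (r), p (nc), n (nc), y (nc)]
    nvar = r + 3 * nc
    v_lo, v_hi = lb.copy(), ub.copy()
    for k, j in enumerate(cand):
        v_lo[j] = lb[j] - M
        v_hi[j] = ub[j] + M
    lower = np.concatenate([v_lo, np.zeros(nc), np.zeros(nc), np.zeros(nc)])
    upper = np.concatenate([v_hi, np.full(nc, M), np.full(nc, M), np.ones(nc)])
    integrality = np.concatenate([np.zeros(r + 2 * nc), np.ones(nc)])

    rows: list[sp.spmatrix] = []
    los: list[np.ndarray] = []
    his: list[np.ndarray] = []

    # steady state S v = 0
    rows.append(sp.hstack([S, sp.csc_matrix((m, 3 * nc))]))
    los.append(np.zeros(m))
    his.append(np.zeros(m))

    if nc:
        sel = sp.csc_matrix(
            (np.ones(nc), (np.arange(nc), cand)), shape=(nc, r)
        )
        eye = sp.identity(nc, format="csc")
        zero = sp.csc_matrix((nc, nc))
        # v_j + n_j >= l_j
        rows.append(sp.hstack([sel, zero, eye, zero]))
        los.append(lb[cand])
        his.append(np.full(nc, np.inf))
        # v_j - p_j <= u_j
        rows.append(sp.hstack([sel, -eye, zero, zero]))
        los.append(np.full(nc, -np.inf))
        his.append(ub[cand])
        # p_j - M y_j <= 0 ; n_j - M y_j <= 0
        rows.append(sp.hstack([sp.csc_matrix((nc, r)), eye, zero, -M * eye]))
        los.append(np.full(nc, -np.inf))
        his.append(np.zeros(nc))
        rows.append(sp.hstack([sp.csc_matrix((nc, r)), zero, eye, -M * eye]))
        los.append(np.full(nc, -np.inf))
        his.append(np.zeros(nc))

    A = sp.vstack(rows, format="csc")
    constraints = [LinearConstraint(A, np.concatenate(los), np.concatenate(his))]

    def solve(c: np.ndarray, extra: LinearConstraint | None = None):
        cons = constraints + ([extra] if extra is not None else [])
        res = milp(
            c=c,
            constraints=cons,
            bounds=Bounds(lower, upper),
            integrality=integrality,
            options=_MILP_OPTIONS,
        )
        return res

    # stage 1: minimise cardinality
    c1 = np.zeros(nvar)
    c1[r + 2 * nc:] = 1.0
    res1 = solve(c1)
    if not res1.success:
        dead = sorted(find_dead_ends(model))
        raise RelaxationInfeasibleError(
            "relaxation MILP infeasible even with all candidates relaxed; "
            f"unsatisfiable species: {dead}",
            species=dead,
        )
    k_star = int(round(res1.x[r + 2 * nc:].sum()))

    # stage 2: fix cardinality, minimise total relaxation amount with a
    # tiny id-ordered preference so ties resolve deterministically
    c2 = np.zeros(nvar)
    c2[r: r + 2 * nc] = 1.0
    order = np.argsort(np.argsort(problem.candidates))
    c2[r + 2 * nc:] = 1e-6 * (1.0 + order / max(nc, 1))
    card_row = np.zeros(nvar)
    card_row[r + 2 * nc:] = 1.0
    res2 = solve(c2, LinearConstraint(card_row[None, :], -np.inf, k_star))
    res = res2 if res2.success else res1

    x = res.x
    v = x[:r]
    p = x[r: r + nc]
    n = x[r + nc: r + 2 * nc]
    y = x[r + 2 * nc:]
    relaxed, p_map, n_map = [], {}, {}
    for k, rid in enumerate(problem.candidates):
        if y[k] > 1 - _INTEGRALITY_TOL:
            p_k = p[k] if p[k] > _AMOUNT_TOL else 0.0
            n_k = n[k] if n[k] > _AMOUNT_TOL else 0.0
            if p_k or n_k:
                relaxed.append(rid)
                p_map[rid] = p_k
                n_map[rid] = n_k
    # re-check: indicators without any actual relaxation do not count
    return RelaxationResult(
        relaxed=relaxed,
        p=p_map,
        n=n_map,
        v=dict(zip(model.reaction_ids, v)),
        objective=float(len(relaxed)),
        extras={"milp_cardinality": k_star},
    )


def add_minimal_exchanges(
    model: StoichiometricModel,
    forced_lower: float = DEFAULT_FORCED_LOWER,
    big_M: float = DEFAULT_BIG_M,
    default_ub: float = DEFAULT_UPPER_BOUND,
) -> tuple[StoichiometricModel, RelaxationResult]:
    """Close all dead ends with a minimal set of boundary reactions.

    A zero-bounded candidate exchange is opened for every species, internal
    lower bounds are forced to ``forced_lower`` so every reaction must
    carry flux, and :func:`relax_rxns` selects the minimum number of
    candidates to relax.  Each selected candidate becomes a directed
    boundary reaction in the final model — ``-> X`` (production/uptake)
    when its upper bound was relaxed, ``X ->`` (secretion) when its lower
    bound was; the remaining candidates are dropped and internal lower
    bounds restored to zero.
    """
    work = model.copy()
    existing_exchanges = {r.id for r in work.reactions if r.kind == "exchange"}
    internal_ids = [r.id for r in work.reactions if r.kind == "internal"]
    for rid in internal_ids:
        rxn = work.get_reaction(rid)
        rxn.lower_bound = forced_lower
        rxn.upper_bound = max(rxn.upper_bound, forced_lower)

    candidates = []
    for sid in work.species_ids:
        cid = f"_CAND_EX_{sid}"
        work.add_reaction(Reaction(cid, {sid: 1.0}, 0.0, 0.0, name=f"candidate exchange {sid}"))
        candidates.append(cid)

    result = relax_rxns(RelaxationProblem(work, candidates, big_M=big_M))

    final = model.copy()
    added = []
    for cid in result.relaxed:
        sid = cid[len("_CAND_EX_"):]
        if result.p.get(cid, 0.0) > 0:  # upper bound relaxed: production into system
            rid = f"EX_{sid}_in"
            if rid not in existing_exchanges:
                final.add_reaction(
                    Reaction(rid, {sid: 1.0}, 0.0, default_ub, name=f"production of {sid}")
                )
                added.append(rid)
        if result.n.get(cid, 0.0) > 0:  # lower bound relaxed: secretion out of system
            rid = f"EX_{sid}_out"
            if rid not in existing_exchanges:
                final.add_reaction(
                    Reaction(rid, {sid: -1.0}, 0.0, default_ub, name=f"secretion of {sid}")
                )
                added.append(rid)
    final.metadata["minimal_exchange_count"] = str(len(result.relaxed))
    final.metadata["added_exchange_reactions"] = str(len(added))
    result.extras["added_exchange_reactions"] = added
    return final, result


def check_all_internal_can_carry_flux(
    model: StoichiometricModel, forced_lower: float = DEFAULT_FORCED_LOWER
) -> bool:
    """LP check: can every internal reaction carry flux >= ``forced_lower``
    simultaneously under the model's stated bounds?"""
    S = model.S
    lb, ub = model.lower_bounds, model.upper_bounds
    for j, rxn in enumerate(model.reactions):
        if rxn.kind == "internal":
            lb[j] = max(lb[j], forced_lower)
    res = linprog(
        c=np.zeros(model.r),
        A_eq=S,
        b_eq=np.zeros(model.m),
        bounds=list(zip(lb, ub)),
        method="highs",
    )
    return bool(res.status == 0)
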