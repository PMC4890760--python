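"""Predicting phenotype reversal as a minimal bound-relaxation problem.

Given the mesenchymal context model and the epithelial mean flux vector
``v_E`` (from random sampling), we search for the smallest set of
mesenchymal reactions whose bounds must be relaxed for a steady-state
flux distribution to approach ``v_E`` — a MOMA-style objective::

    minimise  alpha * ||v - v_E||  +  (1 - alpha) * sum_j y_j

subject to ``S v = 0``, mesenchymal bounds relaxable by big-M amounts on
the selected reactions (``l_j - n_j <= v_j <= u_j + p_j``, ``p_j, n_j <=
M y_j``, binary ``y_j``).  ``||.||`` is the Euclidean norm; ``alpha``
trades flux proximity against the number of interventions.

The mixed-integer quadratic program is solved exactly by enumerating
candidate subsets in order of increasing cardinality, with a convex
least-distance projection per subset (for a fixed subset the problem is
the Euclidean projection of ``v_E`` onto the widened polytope) and
pruning once the cardinality term alone exceeds the incumbent.  For
candidate sets too large to enumerate, a greedy forward selection over
the same projections is used instead and flagged in the result.

The relaxed reactions map to genes through their GPRs; genes under a NOT
(inhibitors) are flagged separately since the intervention they suggest
has the opposite sign.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
from scipy.linalg import null_space
from scipy.optimize import Bounds, LinearConstraint, minimize

from .gpr import gpr_genes, inhibitor_genes
from .model import StoichiometricModel
from .reconstruction import DEFAULT_BIG_M
from .sampling import InfeasibleModelError, _check_feasible

__all__ = ["ReversalTarget", "minimize_distance", "genes_for_reactions"]

_EXACT_LIMIT = 12
_AMOUNT_TOL = 1e-5
_DIST_TOL = 1e-7


@dataclass
class ReversalTarget:
    """Result of the distance-minimising relaxation."""

    relaxed: list[str]
    p: dict[str, float]
    n: dict[str, float]
    v: dict[str, float]
    distance: float
    objective: float
    alpha: float
    genes: set[str] = field(default_factory=set)
    inhibitor_flagged: set[str] = field(default_factory=set)
    extras: dict = field(default_factory=dict)

    @property
    def cardinality(self) -> int:
        return len(self.relaxed)


class _Projector:
    """Euclidean projection of a target vector onto {Sv=0, box bounds}."""

    def __init__(self, S: np.ndarray, target: np.ndarray):
        self.S = S
        self.target = target
        self.N = null_space(S)
        # feasible seeds are projected into null(S) coordinates
        self.z_target = self.N.T @ target if self.N.size else None

    def project(self, lb: np.ndarray, ub: np.ndarray) -> tuple[np.ndarray, float]:
        if self.N.size == 0:
            v = np.zeros(self.S.shape[1])
            return v, float(np.linalg.norm(v - self.target))
        N, t = self.N, self.target

        def fun(z):
            resid = N @ z - t
            return 0.5 * resid @ resid

        def jac(z):
            return N.T @ (N @ z - t)

        v0 = _check_feasible(self.S, lb, ub)
        z0 = N.T @ v0
        res = minimize(
            fun,
            z0,
            jac=jac,
            hess=lambda z: np.eye(N.shape[1]),
            method="trust-constr",
            constraints=[LinearConstraint(N, lb, ub)],
            options={"gtol": 1e-10, "xtol": 1e-12, "maxiter": 500, "verbose": 0},
        )
        v = N @ res.x
        v = np.clip(v, lb, ub)
        return v, float(np.linalg.norm(v - t))


def minimize_distance(
    model_M: StoichiometricModel,
    v_E: np.ndarray | dict[str, float],
    alpha: float = 0.5,
    candidates: list[str] | None = None,
    big_M: float = DEFAULT_BIG_M,
    method: str = "auto",
    normalize: bool = False,
) -> ReversalTarget:
    """Find the bound relaxations bringing the mesenchymal flux closest to
    the epithelial mean flux.

    Parameters
    ----------
    model_M:
        The mesenchymal context model; its bounds are the reference.
    v_E:
        Target mean flux vector, indexed like ``model_M.reactions`` (an
        array in reaction order or a dict keyed by reaction id; missing
        entries default to 0).
    alpha:
        Weight in [0, 1] on the flux-distance term; ``alpha = 0`` is the
        pure cardinality objective (no relaxation needed if the model is
        feasible), ``alpha = 1`` ignores the number of relaxed reactions.
    candidates:
        Reactions whose bounds may be relaxed (default: all reactions).
    method:
        ``"exact"`` (subset enumeration; exponential in the candidate
        count), ``"greedy"`` (forward selection) or ``"auto"`` (exact for
        up to 12 candidates, greedy beyond).
    normalize:
        If set, the distance term is divided by ``||v_E||`` to put the
        two objective terms on comparable scales.
    """
    if not 0 <= alpha <= 1:
        raise ValueError(f"alpha must be in [0, 1], got {alpha}")
    rids = model_M.reaction_ids
    if isinstance(v_E, dict):
        target = np.array([float(v_E.get(rid, 0.0)) for rid in rids])
    else:
        target = np.asarray(v_E, dtype=float)
        if target.shape != (len(rids),):
            raise ValueError(
                f"v_E has shape {target.shape}; expected ({len(rids)},) "
                "matching the model's reactions"
            )
    cand = list(candidates) if candidates is not None else list(rids)
    unknown = set(cand) - set(rids)
    if unknown:
        raise KeyError(f"unknown candidate reactions {sorted(unknown)}")
    if method == "auto":
        method = "exact" if len(cand) <= _EXACT_LIMIT else "greedy"
    if method not in ("exact", "greedy"):
        raise ValueError(f"unknown method {method!r}")

    S = model_M.S
    lb0 = model_M.lower_bounds.astype(float)
    ub0 = model_M.upper_bounds.astype(float)
    try:
        _check_feasible(S, lb0, ub0)
    except InfeasibleModelError:
        raise InfeasibleModelError(
            "mesenchymal model is infeasible before any relaxation"
        ) from None
    proj = _Projector(S, target)
    idx = {rid: j for j, rid in enumerate(rids)}
    scale = float(np.linalg.norm(target)) if normalize else 1.0
    if scale == 0:
        scale = 1.0

    def dist_for(subset: tuple[str, ...]) -> tuple[np.ndarray, float]:
        lb, ub = lb0.copy(), ub0.copy()
        for rid in subset:
            j = idx[rid]
            lb[j] = lb0[j] - big_M
            ub[j] = ub0[j] + big_M
        return proj.project(lb, ub)

    def total(d: float, k: int) -> float:
        return alpha * (d / scale) + (1 - alpha) * k

    best_subset: tuple[str, ...] = ()
    best_v, best_d = dist_for(())
    best_total = total(best_d, 0)
    d_empty = best_d

    if alpha == 0:
        pass  # the model is feasible, so the empty relaxation is optimal
    elif method == "exact" and alpha == 1:
        # cardinality is free: relax everything, keep the violated subset
        v_all, d_all = dist_for(tuple(cand))
        best_subset = tuple(
            rid
            for rid in cand
            if v_all[idx[rid]] > ub0[idx[rid]] + _AMOUNT_TOL
            or v_all[idx[rid]] < lb0[idx[rid]] - _AMOUNT_TOL
        )
        best_v, best_d, best_total = v_all, d_all, total(d_all, len(best_subset))
    elif method == "exact":
        done = False
        for k in range(1, len(cand) + 1):
            if (1 - alpha) * k >= best_total - _DIST_TOL or done:
                break
            for subset in itertools.combinations(sorted(cand), k):
                v, d = dist_for(subset)
                t = total(d, k)
                if t < best_total - _DIST_TOL:
                    best_subset, best_v, best_d, best_total = subset, v, d, t
                    if d < _DIST_TOL:  # perfect match; larger sets cannot win
                        done = True
                        break
    else:
        # violation-guided search: project the target onto the polytope
        # with every candidate relaxed; the reactions whose original
        # bounds the projection violates, ranked by violation size, give
        # the natural relaxation order.  Evaluate prefixes of that order,
        # then try pruning each member of the best prefix.
        v_all, _ = dist_for(tuple(cand))
        violation = {
            rid: max(0.0, v_all[idx[rid]] - ub0[idx[rid]], lb0[idx[rid]] - v_all[idx[rid]])
            for rid in cand
        }
        ranked = [rid for rid in sorted(cand, key=lambda r: -violation[r]) if violation[rid] > _AMOUNT_TOL]
        for k in range(1, len(ranked) + 1):
            if (1 - alpha) * k >= best_total - _DIST_TOL:
                break
            subset = tuple(sorted(ranked[:k]))
            v, d = dist_for(subset)
            t = total(d, k)
            if t < best_total - _DIST_TOL:
                best_subset, best_v, best_d, best_total = subset, v, d, t
        # pruning pass: drop members that do not pay for themselves
        improved = True
        while improved and best_subset:
            improved = False
            for rid in best_subset:
                subset = tuple(s for s in best_subset if s != rid)
                v, d = dist_for(subset)
                t = total(d, len(subset))
                if t < best_total - _DIST_TOL:
                    best_subset, best_v, best_d, best_total = subset, v, d, t
                    improved = True
                    break

    p_map, n_map = {}, {}
    relaxed = []
    for rid in best_subset:
        j = idx[rid]
        p_amt = max(0.0, best_v[j] - ub0[j])
        n_amt = max(0.0, lb0[j] - best_v[j])
        if p_amt > _AMOUNT_TOL or n_amt > _AMOUNT_TOL:
            relaxed.append(rid)
            p_map[rid] = p_amt if p_amt > _AMOUNT_TOL else 0.0
            n_map[rid] = n_amt if n_amt > _AMOUNT_TOL else 0.0

    genes, inhibitors = genes_for_reactions(model_M, relaxed)
    return ReversalTarget(
        relaxed=relaxed,
        p=p_map,
        n=n_map,
        v=dict(zip(rids, best_v)),
        distance=best_d,
        objective=best_total,
        alpha=alpha,
        genes=genes,
        inhibitor_flagged=inhibitors,
        extras={
            "method": method,
            "distance_term": alpha * (best_d / scale),
            "cardinality_term": (1 - alpha) * len(relaxed),
            "normalized": normalize,
            "distance_no_relaxation": d_empty,
        },
    )


def genes_for_reactions(
    model: StoichiometricModel, reaction_ids: list[str]
) -> tuple[set[str], set[str]]:
    """Union of GPR genes over the given reactions.

    Returns ``(genes, inhibitor_genes)``; the second set holds genes that
    appear under a NOT in at least one of the rules (their intervention
    direction is inverted).
    """
    genes: set[str] = set()
    inhibitors: set[str] = set()
    for rid in reaction_ids:
        rxn = model.get_reaction(rid)
        genes |= gpr_genes(rxn.gpr)
        inhibitors |= inhibitor_genes(rxn.gpr)
    return genes, inhibitors
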