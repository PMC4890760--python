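"""Shared fixtures: toy networks and independent oracle helpers."""

from __future__ import annotations

import itertools

import numpy as np
import pytest
from hypothesis import settings
from scipy.optimize import linprog

# property tests must be reproducible run-to-run
settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")

from emtflux.model import Reaction, Species, StoichiometricModel


def toy(species: str | list[str], reactions: list[tuple[str, dict, float, float]]):
    """Build a model from compact (id, stoichiometry, lb, ub) tuples."""
    sp = [Species(s) for s in species]
    rx = [Reaction(rid, stoich, lb, ub) for rid, stoich, lb, ub in reactions]
    return StoichiometricModel(sp, rx)


@pytest.fixture
def chain_model():
    """A -> B -> C with no boundary reactions (A and C are dead ends)."""
    return toy("ABC", [
        ("R1", {"A": -1, "B": 1}, 0, 1000),
        ("R2", {"B": -1, "C": 1}, 0, 1000),
    ])


@pytest.fixture
def branch_model():
    """A -> B; B -> C; B -> D (dead ends A, C, D)."""
    return toy("ABCD", [
        ("R1", {"A": -1, "B": 1}, 0, 1000),
        ("R2", {"B": -1, "C": 1}, 0, 1000),
        ("R3", {"B": -1, "D": 1}, 0, 1000),
    ])


@pytest.fixture
def closed_chain():
    """-> A -> B -> C -> : a feasible linear pipe with bounds [0, 10]."""
    return toy("ABC", [
        ("EX_A_in", {"A": 1}, 0, 10),
        ("R1", {"A": -1, "B": 1}, 0, 10),
        ("R2", {"B": -1, "C": 1}, 0, 10),
        ("EX_C_out", {"C": -1}, 0, 10),
    ])


@pytest.fixture
def diamond_model():
    """-> A; A -> B; A -> C; B -> D; C -> D; D -> (two parallel paths)."""
    return toy("ABCD", [
        ("EX_A_in", {"A": 1}, 0, 10),
        ("R_AB", {"A": -1, "B": 1}, 0, 10),
        ("R_AC", {"A": -1, "C": 1}, 0, 10),
        ("R_BD", {"B": -1, "D": 1}, 0, 10),
        ("R_CD", {"C": -1, "D": 1}, 0, 10),
        ("EX_D_out", {"D": -1}, 0, 10),
    ])


# ---------------------------------------------------------------------------
# independent oracles


def lp_feasible(S, lb, ub) -> bool:
    res = linprog(
        c=np.zeros(S.shape[1]),
        A_eq=S,
        b_eq=np.zeros(S.shape[0]),
        bounds=list(zip(lb, ub)),
        method="highs",
    )
    return res.status == 0


def brute_force_min_relaxation(model, candidates, big_M=1000.0):
    """Minimum relaxed-subset cardinality by exhaustive enumeration.

    For each candidate subset (in order of increasing size), widen the
    subset's bounds by big_M on both sides and check LP feasibility.
    Returns (cardinality, list of minimal subsets as sorted tuples).
    """
    S = model.S
    lb0 = model.lower_bounds.astype(float)
    ub0 = model.upper_bounds.astype(float)
    idx = {rid: j for j, rid in enumerate(model.reaction_ids)}
    for k in range(len(candidates) + 1):
        winners = []
        for subset in itertools.combinations(sorted(candidates), k):
            lb, ub = lb0.copy(), ub0.copy()
            for rid in subset:
                lb[idx[rid]] -= big_M
                ub[idx[rid]] += big_M
            if lp_feasible(S, lb, ub):
                winners.append(subset)
        if winners:
            return k, winners
    return None, []


def ternary_truth_table(expr_fn, genes):
    """Evaluate expr_fn over every ternary assignment of the given genes."""
    table = {}
    for states in itertools.product((-1, 0, 1), repeat=len(genes)):
        table[states] = expr_fn(dict(zip(genes, states)))
    return table
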