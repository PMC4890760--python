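"""Context-specific model pairs from differential gene expression.

A differential-expression table between a paired epithelial/mesenchymal
cell line carries one row per gene: a signed relative fold change
(negative = higher in the epithelial line, positive = higher in the
mesenchymal line) and a p-value.  Genes passing the fold cutoff at
p <= 0.05 are called up-in-E or up-in-M; calls propagate through GPRs to
reactions, and each called reaction is tightened in the *opposite* model:
since upper bounds are effectively infinite, up-regulation in one context
is simulated by shrinking the reaction's bounds to one-hundredth in the
counterpart.  Inhibition (a NOT rule) down-regulates the reaction in the
same model, which the ternary GPR semantics produce automatically.

Cutoffs are dataset-specific; the presets used for the breast epithelial
EMT lines are exposed in :data:`CUTOFF_PRESETS`.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .gpr import evaluate_gpr
from .model import StoichiometricModel

__all__ = [
    "RegulationCall",
    "ContextPair",
    "CUTOFF_PRESETS",
    "DEFAULT_TIGHTEN_FACTOR",
    "read_expression",
    "classify_regulation",
    "propagate_to_reactions",
    "build_context_pair",
]

logger = logging.getLogger(__name__)

#: Fold-change cutoffs used per cell line (on the table's own signed
#: relative scale, not log2), chosen relative to housekeeping-gene spread.
CUTOFF_PRESETS = {"D492": 2.0, "MCF7": 0.5, "MCF10A": 0.5, "HMLE": 0.3}

DEFAULT_TIGHTEN_FACTOR = 0.01
DEFAULT_ALPHA_P = 0.05

UP_E, UP_M, UNCHANGED = "up_E", "up_M", "unchanged"
_STATE_TO_TERNARY = {UP_E: +1, UP_M: -1, UNCHANGED: 0}
_TERNARY_TO_STATE = {+1: UP_E, -1: UP_M, 0: UNCHANGED}


@dataclass
class RegulationCall:
    """Ternary up-in-E / up-in-M / unchanged call for a gene or reaction."""

    subject: str
    state: str
    evidence: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.state not in _STATE_TO_TERNARY:
            raise ValueError(f"unknown regulation state {self.state!r}")

    @property
    def ternary(self) -> int:
        return _STATE_TO_TERNARY[self.state]


@dataclass
class ContextPair:
    """Paired context models sharing topology, differing only in bounds."""

    model_E: StoichiometricModel
    model_M: StoichiometricModel
    tighten_factor: float = DEFAULT_TIGHTEN_FACTOR
    provenance: dict = field(default_factory=dict)

    def differing_reactions(self) -> list[str]:
        out = []
        for re_, rm in zip(self.model_E.reactions, self.model_M.reactions):
            if (re_.lower_bound, re_.upper_bound) != (rm.lower_bound, rm.upper_bound):
                out.append(re_.id)
        return out


def read_expression(path, mapping: pd.DataFrame | None = None) -> pd.DataFrame:
    """Load an expression TSV (columns gene_id, fold_change, p_value).

    ``mapping`` is an optional probe→gene two-column frame (probe_id,
    gene_id) joined before classification, replacing any platform-specific
    identifiers.
    """
    table = pd.read_csv(path, sep="\t")
    required = {"gene_id", "fold_change", "p_value"}
    missing = required - set(table.columns)
    if missing:
        raise ValueError(f"expression table missing columns {sorted(missing)}")
    if mapping is not None:
        table = (
            table.rename(columns={"gene_id": "probe_id"})
            .merge(mapping, on="probe_id", how="inner")
            .drop(columns=["probe_id"])
        )
    return table


def classify_regulation(
    table: pd.DataFrame,
    cutoff: float,
    alpha_p: float = DEFAULT_ALPHA_P,
) -> dict[str, RegulationCall]:
    """Call each gene up-in-E, up-in-M or unchanged.

    A gene is called iff |fold_change| >= ``cutoff`` and p <= ``alpha_p``;
    the sign convention is negative = higher expression in the epithelial
    line.  Missing p-values are treated as not significant (with a logged
    warning), missing/zero folds as unchanged.
    """
    if cutoff <= 0:
        raise ValueError(f"cutoff must be positive, got {cutoff}")
    calls: dict[str, RegulationCall] = {}
    n_missing_p = 0
    for row in table.itertuples(index=False):
        gene = str(row.gene_id)
        fold = row.fold_change
        p = row.p_value
        state = UNCHANGED
        if p is None or (isinstance(p, float) and np.isnan(p)):
            n_missing_p += 1
        elif fold is not None and np.isfinite(fold) and fold != 0:
            if abs(fold) >= cutoff and p <= alpha_p:
                state = UP_E if fold < 0 else UP_M
        calls[gene] = RegulationCall(gene, state, {"fold_change": fold, "p_value": p})
    if n_missing_p:
        logger.warning(
            "%d genes had missing p-values and were treated as unchanged", n_missing_p
        )
    return calls


def propagate_to_reactions(
    model: StoichiometricModel,
    gene_calls: dict[str, RegulationCall],
) -> dict[str, RegulationCall]:
    """Propagate gene calls onto reactions through their GPRs.

    Gene states are mapped up-E → +1, up-M → -1, unchanged → 0 and each
    reaction's GPR is evaluated under the ternary AND=min / OR=max /
    NOT=negate semantics; genes without data default to unchanged.  A NOT
    rule implements the inhibitor convention: an inhibitor high in one
    context suppresses the reaction in that same context.
    """
    states = {g: c.ternary for g, c in gene_calls.items()}
    out: dict[str, RegulationCall] = {}
    for rxn in model.reactions:
        if rxn.gpr is None:
            out[rxn.id] = RegulationCall(rxn.id, UNCHANGED, {"gpr": ""})
            continue
        value = evaluate_gpr(rxn.gpr, states)
        out[rxn.id] = RegulationCall(
            rxn.id, _TERNARY_TO_STATE[value], {"gpr": rxn.gpr_string}
        )
    return out


def _apply_calls(
    model: StoichiometricModel,
    reaction_calls: dict[str, RegulationCall],
    tighten_state: str,
    tighten_factor: float,
    label: str,
) -> StoichiometricModel:
    """Tighten (both bounds x factor) every reaction called ``tighten_state``.

    The applied calls are recorded in the model metadata, making the edit
    idempotent: a reaction already tightened for the same state is left
    untouched on re-application.
    """
    out = model.copy()
    applied_key = "context_tightened"
    already = set((out.metadata.get(applied_key) or "").split(",")) - {""}
    for rxn in out.reactions:
        call = reaction_calls.get(rxn.id)
        if call is None or call.state != tighten_state or rxn.id in already:
            continue
        rxn.lower_bound *= tighten_factor
        rxn.upper_bound *= tighten_factor
        already.add(rxn.id)
    out.metadata[applied_key] = ",".join(sorted(already))
    out.metadata["context_label"] = label
    return out


def build_context_pair(
    model: StoichiometricModel,
    reaction_calls: dict[str, RegulationCall],
    tighten_factor: float = DEFAULT_TIGHTEN_FACTOR,
    provenance: dict | None = None,
) -> ContextPair:
    """Derive the epithelial/mesenchymal model pair from reaction calls.

    A reaction up-regulated in E keeps its bounds in the E model and has
    them multiplied by ``tighten_factor`` in the M model (1000 → 10 at the
    default one-hundredth factor), and symmetrically for up-M; unchanged
    reactions keep identical bounds in both.
    """
    if not 0 < tighten_factor < 1:
        raise ValueError(f"tighten_factor must be in (0, 1), got {tighten_factor}")
    model_E = _apply_calls(model, reaction_calls, UP_M, tighten_factor, "E")
    model_M = _apply_calls(model, reaction_calls, UP_E, tighten_factor, "M")
    return ContextPair(
        model_E=model_E,
        model_M=model_M,
        tighten_factor=tighten_factor,
        provenance=dict(provenance or {}),
    )
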