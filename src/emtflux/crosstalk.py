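"""Signalling→metabolism crosstalk: predictions, scoring and Met models.

AKT signalling regulates a set of metabolic genes (glycolysis, fatty-acid
and purine/pyrimidine metabolism positively; gluconeogenesis negatively).
Given the fold change of aggregate AKT-pathway flux between the
mesenchymal and epithelial context models and a literature sign table
(+1 = AKT induces the gene, -1 = AKT suppresses it), the expected
direction of each metabolic gene follows by sign arithmetic: with AKT
flux higher in the epithelial context (fold < 1), a +1 gene is predicted
lower in the mesenchymal cells (``down_in_M``) and a -1 gene lower in
the epithelial cells (``down_in_E``).

Predictions are scored against observed microarray directions by exact
matching; genes without detectable expression (``NA``) are excluded from
the denominator.  Percentages are reported truncated to one decimal,
matching the convention of the curated comparison table shipped with the
package (13/15 → 86.6).

The same gene directions can constrain a GPR-bearing metabolic model
into an epithelial/mesenchymal pair (Met_E / Met_M) with the identical
one-hundredth tightening mechanics used for the signalling models; pairs
are then compared by the per-reaction flux-span ratio ``s_M / s_E``.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd

from .context import (
    DEFAULT_TIGHTEN_FACTOR,
    UP_E,
    UP_M,
    ContextPair,
    RegulationCall,
    build_context_pair,
    propagate_to_reactions,
)
from .model import StoichiometricModel
from .sampling import FluxSampleSet

__all__ = [
    "DOWN_IN_M",
    "DOWN_IN_E",
    "NA",
    "PredictionReport",
    "read_sign_table",
    "load_packaged_sign_table",
    "load_packaged_table1",
    "predict_metabolic_expression",
    "score_agreement",
    "constrain_metabolic_model",
    "compare_flux_span",
    "truncate_percent",
]

logger = logging.getLogger(__name__)

DOWN_IN_M = "down_in_M"
DOWN_IN_E = "down_in_E"
NA = "NA"

_DIRECTIONS = (DOWN_IN_M, DOWN_IN_E)


def truncate_percent(fraction: float, decimals: int = 1) -> float:
    """Percentage truncated toward zero at ``decimals`` places (13/15 → 86.6)."""
    scale = 10 ** decimals
    return math.trunc(fraction * 100 * scale) / scale


def read_sign_table(path: str | Path) -> pd.DataFrame:
    """Load a regulation sign table (gene_id, pathway, sign, reference)."""
    table = pd.read_csv(path, sep="\t", dtype={"gene_id": str, "pathway": str})
    missing = {"gene_id", "pathway", "sign"} - set(table.columns)
    if missing:
        raise ValueError(f"sign table missing columns {sorted(missing)}")
    table["sign"] = table["sign"].astype(int)
    bad = table.loc[~table["sign"].isin([1, -1])]
    if not bad.empty:
        raise ValueError(f"signs must be +1 or -1; offending genes {list(bad.gene_id)}")
    if table.duplicated(["gene_id", "pathway"]).any():
        raise ValueError("sign table has duplicate (gene, pathway) rows")
    return table


def _packaged(name: str) -> Path:
    return resources.files("emtflux").joinpath("data", name)


def load_packaged_sign_table() -> pd.DataFrame:
    """The curated AKT→metabolic-gene sign table shipped with the package."""
    with resources.as_file(_packaged("akt_metabolic_signs.tsv")) as p:
        return read_sign_table(p)


def load_packaged_table1() -> pd.DataFrame:
    """The curated predicted-vs-observed comparison for AKT-regulated
    metabolic genes in the D492/D492M pair (20 genes, 5 without detectable
    expression)."""
    with resources.as_file(_packaged("akt_table1.tsv")) as p:
        # keep the literal "NA" marker (no detectable expression), do not
        # let pandas coerce it to NaN
        return pd.read_csv(p, sep="\t", keep_default_na=False)


def predict_metabolic_expression(
    pathway_fold: float,
    sign_table: pd.DataFrame,
    pathway: str = "AKT",
) -> dict[str, str]:
    """Predict per-gene expression direction from the pathway flux fold.

    ``pathway_fold`` is the aggregate mesenchymal/epithelial flux ratio of
    the regulating pathway.  fold < 1 with sign +1 → ``down_in_M``; sign
    -1 → ``down_in_E``; symmetric for fold > 1; fold == 1 → no call.
    """
    if not (pathway_fold > 0):
        raise ValueError(f"pathway fold must be positive, got {pathway_fold}")
    rows = sign_table.loc[sign_table["pathway"] == pathway]
    if rows.empty:
        raise KeyError(f"no sign-table rows for pathway {pathway!r}")
    predictions: dict[str, str] = {}
    for row in rows.itertuples(index=False):
        if pathway_fold == 1:
            continue  # flux identical in both contexts: no direction
        higher_in_E = pathway_fold < 1
        if (row.sign == +1) == higher_in_E:
            predictions[row.gene_id] = DOWN_IN_M
        else:
            predictions[row.gene_id] = DOWN_IN_E
    return predictions


@dataclass
class PredictionReport:
    """Scored agreement between predicted and observed gene directions."""

    rows: pd.DataFrame
    n_evaluable: int
    n_agree: int
    percent_agree: float
    percent_disagree: float
    disagreeing: list[str] = field(default_factory=list)

    @property
    def fraction_agree(self) -> float:
        return self.n_agree / self.n_evaluable if self.n_evaluable else float("nan")


def score_agreement(
    predicted: dict[str, str], observed: dict[str, str]
) -> PredictionReport:
    """Exact-match scoring of predictions against observed directions.

    Genes observed as ``NA`` (no detectable expression) are excluded from
    the denominator; the report lists the disagreeing genes.
    """
    records = []
    for gene in predicted:
        pred = predicted[gene]
        obs = observed.get(gene, NA)
        if pred not in _DIRECTIONS:
            raise ValueError(f"bad predicted direction {pred!r} for gene {gene}")
        if obs not in _DIRECTIONS + (NA,):
            raise ValueError(f"bad observed direction {obs!r} for gene {gene}")
        evaluable = obs != NA
        records.append(
            {
                "gene_id": gene,
                "predicted": pred,
                "observed": obs,
                "evaluable": evaluable,
                "agree": evaluable and pred == obs,
            }
        )
    rows = pd.DataFrame(records)
    n_eval = int(rows["evaluable"].sum()) if not rows.empty else 0
    n_agree = int(rows["agree"].sum()) if not rows.empty else 0
    disagreeing = (
        sorted(rows.loc[rows["evaluable"] & ~rows["agree"], "gene_id"]) if not rows.empty else []
    )
    frac = n_agree / n_eval if n_eval else float("nan")
    return PredictionReport(
        rows=rows,
        n_evaluable=n_eval,
        n_agree=n_agree,
        percent_agree=truncate_percent(frac) if n_eval else float("nan"),
        percent_disagree=truncate_percent(1 - frac) if n_eval else float("nan"),
        disagreeing=disagreeing,
    )


def constrain_metabolic_model(
    met_model: StoichiometricModel,
    gene_directions: dict[str, str],
    tighten_factor: float = DEFAULT_TIGHTEN_FACTOR,
) -> ContextPair:
    """Constrain a GPR-bearing metabolic model into a Met_E / Met_M pair.

    A gene predicted ``down_in_M`` is up-regulated in the epithelial
    context, so its reactions are tightened in Met_M (and symmetrically
    for ``down_in_E``) — the same mechanics as the signalling context
    pair.  Genes not present in any GPR are logged and skipped.
    """
    model_genes = met_model.genes()
    gene_calls: dict[str, RegulationCall] = {}
    skipped = []
    for gene, direction in gene_directions.items():
        if gene not in model_genes:
            skipped.append(gene)
            continue
        if direction == DOWN_IN_M:
            state = UP_E
        elif direction == DOWN_IN_E:
            state = UP_M
        else:
            raise ValueError(f"bad direction {direction!r} for gene {gene}")
        gene_calls[gene] = RegulationCall(gene, state, {"source": "crosstalk"})
    if skipped:
        logger.warning(
            "%d directed genes not found in any GPR of the metabolic model: %s",
            len(skipped),
            ", ".join(sorted(skipped)),
        )
    reaction_calls = propagate_to_reactions(met_model, gene_calls)
    return build_context_pair(
        met_model,
        reaction_calls,
        tighten_factor=tighten_factor,
        provenance={"source": "crosstalk", "skipped_genes": ",".join(sorted(skipped))},
    )


def compare_flux_span(
    set_E: FluxSampleSet,
    set_M: FluxSampleSet,
    span: str = "mean",
    epsilon: float = 1e-9,
    tolerance: float = 0.05,
) -> pd.DataFrame:
    """Per-reaction span ratio ``s_M / s_E`` between two sample sets.

    ``span`` selects the statistic (``"mean"`` = average flux, the default
    convention; ``"width"`` = max - min).  Zero spans in the denominator
    are epsilon-guarded and flagged.  Reactions are partitioned into
    ``higher_in_E`` (ratio < 1 - tolerance), ``higher_in_M`` (ratio >
    1 + tolerance) or ``similar``.
    """
    if set_E.reaction_ids != set_M.reaction_ids:
        raise ValueError("sample sets cover different reaction sets")
    s_E = set_E.span(span).to_numpy()
    s_M = set_M.span(span).to_numpy()
    guarded = s_E <= epsilon
    ratio = (s_M + epsilon) / (s_E + epsilon)
    partition = np.where(
        ratio < 1 - tolerance, "higher_in_E", np.where(ratio > 1 + tolerance, "higher_in_M", "similar")
    )
    return pd.DataFrame(
        {
            "span_E": s_E,
            "span_M": s_M,
            "span_ratio": ratio,
            "partition": partition,
            "denominator_guarded": guarded,
        },
        index=set_E.reaction_ids,
    )
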