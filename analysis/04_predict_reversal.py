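"""Predict reversal targets: which mesenchymal bounds must be relaxed.

Takes the sampled epithelial mean flux (step 03) as the target vector
and searches for the smallest relaxation of mesenchymal bounds whose
steady-state flux approaches it (alpha = 0.5 between flux distance and
intervention count).  Maps the relaxed reactions to genes through their
GPRs and flags inhibitor genes, whose intervention direction inverts.

Writes results/reversal/targets.tsv and summary.json.
"""

import json
import sys
from pathlib import Path

import pandas as pd

from emtflux.io import read_model
from emtflux.model import classify_reactions
from emtflux.reversal import minimize_distance

CTX = Path(__file__).resolve().parent.parent / "results" / "context"
SMP = Path(__file__).resolve().parent.parent / "results" / "sampling"
OUT = Path(__file__).resolve().parent.parent / "results" / "reversal"

ALPHA = 0.5


def main(seed: int = 42) -> dict:
    if not (SMP / "samples_E.tsv").exists():
        import importlib.util

        spec = importlib.util.spec_from_file_location(
            "sample_and_compare", Path(__file__).resolve().parent / "03_sample_and_compare.py"
        )
        mod = importlib.util.module_from_spec(spec)
        spec.loader.exec_module(mod)
        mod.main(seed)
    model_M, _ = read_model(CTX / "model_M.json")
    samples_E = pd.read_csv(SMP / "samples_E.tsv", sep="\t")
    v_E = samples_E[model_M.reaction_ids].mean().to_numpy()

    target = minimize_distance(model_M, v_E, alpha=ALPHA, method="greedy")
    parts = classify_reactions(model_M)
    internal = [r for r in target.relaxed if r in set(parts["internal"])]
    exchange = [r for r in target.relaxed if r in set(parts["exchange"])]

    OUT.mkdir(parents=True, exist_ok=True)
    rows = [
        {
            "reaction_id": rid,
            "kind": "internal" if rid in internal else "exchange",
            "upper_relaxation": target.p.get(rid, 0.0),
            "lower_relaxation": target.n.get(rid, 0.0),
            "genes": ";".join(sorted(model_M.get_reaction(rid).genes())),
        }
        for rid in target.relaxed
    ]
    pd.DataFrame(rows).to_csv(OUT / "targets.tsv", sep="\t", index=False)

    summary = {
        "alpha": ALPHA,
        "relaxed_reactions": target.cardinality,
        "internal": len(internal),
        "exchange": len(exchange),
        "genes": sorted(target.genes),
        "inhibitor_genes": sorted(target.inhibitor_flagged),
        "distance_before": target.extras["distance_no_relaxation"],
        "distance_after": target.distance,
    }
    (OUT / "summary.json").write_text(json.dumps(summary, indent=1))
    print(
        f"reversal: relax {target.cardinality} reactions "
        f"({len(internal)} internal + {len(exchange)} exchange); "
        f"flux distance {summary['distance_before']:.2f} -> {target.distance:.2f}"
    )
    print(f"associated genes ({len(target.genes)}): {', '.join(sorted(target.genes)) or 'none'}")
    if target.inhibitor_flagged:
        print(f"inhibitors (suppress, do not overexpress): {', '.join(sorted(target.inhibitor_flagged))}")
    return summary


if __name__ == "__main__":
    main(int(sys.argv[1]) if len(sys.argv) > 1 else 42)
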