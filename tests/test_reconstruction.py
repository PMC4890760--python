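"""Pathway conversion, modifier rewriting, GPR construction and the
minimal-exchange relaxation MILP."""

import numpy as np
import pytest

from emtflux.model import (
    ModelValidationError,
    Reaction,
    RegulatoryAnnotation,
    Species,
    StoichiometricModel,
    classify_reactions,
)
from emtflux.reconstruction import (
    RelaxationInfeasibleError,
    RelaxationProblem,
    add_minimal_exchanges,
    build_gprs,
    check_all_internal_can_carry_flux,
    convert_pathway,
    find_dead_ends,
    insert_modifiers,
    relax_rxns,
)
from emtflux.synthetic import SyntheticSpec, make_network

from conftest import brute_force_min_relaxation, toy


class TestConvertPathway:
    def test_default_bounds_applied(self, chain_model):
        model, ann = convert_pathway(chain_model)
        for rxn in model.reactions:
            assert (rxn.lower_bound, rxn.upper_bound) == (0.0, 1000.0)

    def test_annotation_passes_through(self, chain_model):
        ann_in = RegulatoryAnnotation(
            modifiers={"R2": ["MOD1"]}, protein_genes={"MOD1": ["g1"]}
        )
        _, ann = convert_pathway(chain_model, ann_in)
        assert ann.modifiers == {"R2": ["MOD1"]}

    def test_empty_pathway_rejected(self):
        with pytest.raises(ModelValidationError, match="no reactions"):
            convert_pathway(StoichiometricModel([Species("A")], []))


class TestInsertModifiers:
    def test_three_line_scheme(self, chain_model):
        ann = RegulatoryAnnotation(modifiers={"R1": ["mod1"]})
        out = insert_modifiers(chain_model, ann)
        r1 = out.get_reaction("R1")
        assert r1.stoichiometry == {"A": -1.0, "B": 1.0, "mod1": -1.0, "mod1_p": 1.0}
        assert out.get_species("mod1_p").role == "modifier-product"
        assert out.get_reaction("EX_mod1_in").stoichiometry == {"mod1": 1.0}
        assert out.get_reaction("EX_mod1_p_out").stoichiometry == {"mod1_p": -1.0}

    def test_no_modifier_no_change(self, chain_model):
        out = insert_modifiers(chain_model, RegulatoryAnnotation())
        assert out == chain_model

    def test_shared_modifier_reuses_species_and_exchanges(self, chain_model):
        ann = RegulatoryAnnotation(modifiers={"R1": ["m"], "R2": ["m"]})
        out = insert_modifiers(chain_model, ann)
        # r grew by exactly the two boundary reactions, not four
        assert out.r == chain_model.r + 2
        assert out.species_ids.count("m_p") == 1

    def test_mass_conservation_of_rewrite(self, chain_model):
        ann = RegulatoryAnnotation(modifiers={"R1": ["m"]})
        out = insert_modifiers(chain_model, ann)
        col = out.get_reaction("R1").stoichiometry
        assert col["m"] == -1.0 and col["m_p"] == 1.0

    def test_modifier_equal_to_reactant_rejected(self, chain_model):
        ann = RegulatoryAnnotation(modifiers={"R1": ["A"]})
        with pytest.raises(ModelValidationError, match="ambiguous"):
            insert_modifiers(chain_model, ann)


class TestBuildGprs:
    def test_complex_modifier_joined_by_and(self, chain_model):
        ann = RegulatoryAnnotation(
            modifiers={"R1": ["P1"]},
            protein_genes={"P1": ["gene1", "gene2"]},
            protein_relation={"P1": "complex"},
        )
        out = build_gprs(chain_model, ann)
        assert out.get_reaction("R1").gpr_string == "gene1 AND gene2"

    def test_isoform_inhibitor_wrapped_in_not(self, chain_model):
        ann = RegulatoryAnnotation(
            inhibitors={"R2": ["P2"]},
            protein_genes={"P2": ["gene3", "gene4"]},
            protein_relation={"P2": "isoform"},
        )
        out = build_gprs(chain_model, ann)
        assert out.get_reaction("R2").gpr_string == "NOT (gene3 OR gene4)"

    def test_modifier_and_inhibitor_combined(self, chain_model):
        ann = RegulatoryAnnotation(
            modifiers={"R1": ["P1"]},
            inhibitors={"R1": ["P2"]},
            protein_genes={"P1": ["g1"], "P2": ["g2"]},
            protein_relation={"P1": "complex", "P2": "isoform"},
        )
        out = build_gprs(chain_model, ann)
        assert out.get_reaction("R1").gpr_string == "g1 AND NOT g2"

    def test_unannotated_reaction_has_no_rule(self, chain_model):
        out = build_gprs(chain_model, RegulatoryAnnotation())
        assert all(r.gpr is None for r in out.reactions)

    def test_modifier_boundary_reactions_inherit_rule(self, chain_model):
        ann = RegulatoryAnnotation(
            modifiers={"R1": ["mod1"]},
            protein_genes={"mod1": ["g1"]},
            protein_relation={"mod1": "complex"},
        )
        model = insert_modifiers(chain_model, ann)
        out = build_gprs(model, ann)
        assert out.get_reaction("EX_mod1_in").gpr_string == "g1"
        assert out.get_reaction("EX_mod1_p_out").gpr_string == "g1"

    def test_unmapped_protein_skipped_with_warning(self, chain_model, caplog):
        ann = RegulatoryAnnotation(modifiers={"R1": ["orphan"]})
        with caplog.at_level("WARNING"):
            out = build_gprs(chain_model, ann)
        assert out.get_reaction("R1").gpr is None
        assert "orphan" in caplog.text


class TestFindDeadEnds:
    def test_chain_ends(self, chain_model):
        assert find_dead_ends(chain_model) == {"A", "C"}

    def test_closed_chain_has_none(self, closed_chain):
        assert find_dead_ends(closed_chain) == set()

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_row_sign_oracle_on_random_networks(self, seed):
        spec = SyntheticSpec(
            n_species=5 + seed, topology="random-dag", n_modifiers=0, n_inhibitors=0, seed=seed
        )
        model, _, _ = make_network(spec)
        S = model.S
        # independent oracle: scan each S row's signs directly
        expected = {
            sid
            for i, sid in enumerate(model.species_ids)
            if not ((S[i] > 0).any() and (S[i] < 0).any())
        }
        assert find_dead_ends(model) == expected


def _prepare_relaxation(model, candidates, forced_lower=1.0):
    """Zero candidate bounds and force internal lower bounds, as the
    orchestration does before calling the MILP."""
    work = model.copy()
    for rxn in work.reactions:
        if rxn.id in candidates:
            rxn.lower_bound = rxn.upper_bound = 0.0
        elif rxn.kind == "internal":
            rxn.lower_bound = forced_lower
    return work


class TestRelaxRxns:
    def test_chain_needs_both_end_exchanges(self, chain_model):
        model = chain_model.copy()
        for sid in "ABC":
            model.add_reaction(Reaction(f"EX_{sid}", {sid: 1.0}, 0, 0))
        work = _prepare_relaxation(model, {"EX_A", "EX_B", "EX_C"})
        result = relax_rxns(RelaxationProblem(work, ["EX_A", "EX_B", "EX_C"]))
        assert sorted(result.relaxed) == ["EX_A", "EX_C"]
        assert result.objective == 2

    def test_feasible_network_needs_nothing(self, closed_chain):
        result = relax_rxns(RelaxationProblem(closed_chain, list(closed_chain.reaction_ids)))
        assert result.relaxed == [] and result.objective == 0

    def test_branch_needs_three(self, branch_model):
        model = branch_model.copy()
        for sid in "ABCD":
            model.add_reaction(Reaction(f"EX_{sid}", {sid: 1.0}, 0, 0))
        cands = [f"EX_{s}" for s in "ABCD"]
        work = _prepare_relaxation(model, set(cands))
        result = relax_rxns(RelaxationProblem(work, cands))
        assert sorted(result.relaxed) == ["EX_A", "EX_C", "EX_D"]

    def test_infeasible_reports_species(self, chain_model):
        # no candidates at all: the forced lower bounds cannot be met
        work = _prepare_relaxation(chain_model, set())
        with pytest.raises(RelaxationInfeasibleError) as err:
            relax_rxns(RelaxationProblem(work, []))
        assert set(err.value.species) == {"A", "C"}

    @pytest.mark.parametrize("seed", range(8))
    def test_objective_matches_subset_enumeration(self, seed):
        """MILP cardinality equals the brute-force minimum over candidate
        subsets (LP feasibility per subset) on random DAG networks."""
        spec = SyntheticSpec(
            n_species=5 + seed % 4,
            topology="random-dag",
            n_modifiers=0,
            n_inhibitors=0,
            seed=100 + seed,
        )
        raw, _, _ = make_network(spec)
        model = raw.copy()
        cands = []
        for sid in model.species_ids:
            cid = f"EX_{sid}"
            model.add_reaction(Reaction(cid, {sid: 1.0}, 0, 0))
            cands.append(cid)
        work = _prepare_relaxation(model, set(cands))
        result = relax_rxns(RelaxationProblem(work, cands))
        k, minimal_sets = brute_force_min_relaxation(work, cands)
        assert result.cardinality == k
        assert tuple(sorted(result.relaxed)) in {tuple(s) for s in minimal_sets}


class TestAddMinimalExchanges:
    def test_chain_gets_two_exchanges(self, chain_model):
        final, result = add_minimal_exchanges(chain_model)
        assert result.cardinality == 2
        assert sorted(classify_reactions(final)["exchange"]) == ["EX_A_in", "EX_C_out"]

    def test_dead_end_free_model_untouched(self, closed_chain):
        final, result = add_minimal_exchanges(closed_chain)
        assert result.cardinality == 0
        assert final == closed_chain

    def test_closure_removes_all_dead_ends(self, branch_model):
        final, _ = add_minimal_exchanges(branch_model)
        assert find_dead_ends(final) == set()

    def test_all_internal_reactions_can_carry_flux(self, branch_model):
        final, _ = add_minimal_exchanges(branch_model)
        assert check_all_internal_can_carry_flux(final)

    def test_idempotent(self, branch_model):
        once, _ = add_minimal_exchanges(branch_model)
        twice, second = add_minimal_exchanges(once)
        assert second.cardinality == 0
        assert twice == once

    @pytest.mark.parametrize("seed", range(6))
    def test_cardinality_matches_generator_ground_truth(self, seed):
        spec = SyntheticSpec(
            n_species=6 + seed, topology="random-dag", n_modifiers=0, n_inhibitors=0, seed=seed
        )
        model, _, truth = make_network(spec)
        final, result = add_minimal_exchanges(model)
        assert result.cardinality == truth["min_exchange_cardinality"]
        assert find_dead_ends(final) == set()
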