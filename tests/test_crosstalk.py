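"""Signalling→metabolism predictions, agreement scoring and Met pairs."""

import numpy as np
import pandas as pd
import pytest

from emtflux.crosstalk import (
    DOWN_IN_E,
    DOWN_IN_M,
    NA,
    compare_flux_span,
    constrain_metabolic_model,
    load_packaged_sign_table,
    load_packaged_table1,
    predict_metabolic_expression,
    read_sign_table,
    score_agreement,
    truncate_percent,
)
from emtflux.sampling import FluxSampleSet, sample_fluxes
from emtflux.synthetic import make_sign_table

from conftest import toy


def signs(rows):
    return pd.DataFrame(rows, columns=["gene_id", "pathway", "sign", "reference"])


class TestPredict:
    def test_positive_gene_with_pathway_higher_in_E(self):
        table = signs([("GAPDH", "AKT", +1, "x")])
        assert predict_metabolic_expression(0.5, table) == {"GAPDH": DOWN_IN_M}

    def test_negative_gene_flips_direction(self):
        table = signs([("G6PC", "AKT", -1, "x")])
        assert predict_metabolic_expression(0.5, table) == {"G6PC": DOWN_IN_E}

    def test_fold_above_one_mirrors(self):
        table = signs([("GAPDH", "AKT", +1, "x"), ("G6PC", "AKT", -1, "x")])
        assert predict_metabolic_expression(2.0, table) == {
            "GAPDH": DOWN_IN_E,
            "G6PC": DOWN_IN_M,
        }

    def test_unit_fold_makes_no_call(self):
        table = signs([("GAPDH", "AKT", +1, "x")])
        assert predict_metabolic_expression(1.0, table) == {}

    def test_nonpositive_fold_rejected(self):
        with pytest.raises(ValueError):
            predict_metabolic_expression(0.0, signs([("g", "AKT", 1, "x")]))

    def test_direction_flips_when_fold_crosses_one(self):
        table = signs([("g", "AKT", +1, "x")])
        below = predict_metabolic_expression(0.9, table)["g"]
        above = predict_metabolic_expression(1.1, table)["g"]
        assert {below, above} == {DOWN_IN_M, DOWN_IN_E}

    def test_synthetic_sign_table_truth_reproduced(self):
        genes = [f"m{i}" for i in range(10)]
        table, truth = make_sign_table(genes, seed=4, declared_fold=0.5)
        assert predict_metabolic_expression(0.5, table) == truth


class TestScoring:
    def test_curated_comparison_table(self):
        t1 = load_packaged_table1()
        report = score_agreement(
            dict(zip(t1.gene_id, t1.proposed)), dict(zip(t1.gene_id, t1.observed))
        )
        assert (report.n_agree, report.n_evaluable) == (13, 15)
        assert report.percent_agree == 86.6
        assert report.percent_disagree == 13.3
        assert report.disagreeing == ["GLUT1", "SREBF1"]

    def test_all_agree_toy(self):
        pred = {f"g{i}": DOWN_IN_M for i in range(4)}
        report = score_agreement(pred, pred)
        assert report.percent_agree == 100.0 and report.disagreeing == []

    def test_na_genes_excluded_from_denominator(self):
        report = score_agreement(
            {"a": DOWN_IN_M, "b": DOWN_IN_M}, {"a": DOWN_IN_M, "b": NA}
        )
        assert report.n_evaluable == 1 and report.n_agree == 1

    @pytest.mark.parametrize("seed", range(5))
    def test_random_pairs_match_counting_oracle(self, seed):
        rng = np.random.default_rng(seed)
        genes = [f"g{i}" for i in range(30)]
        pred = {g: rng.choice([DOWN_IN_M, DOWN_IN_E]) for g in genes}
        obs = {g: rng.choice([DOWN_IN_M, DOWN_IN_E, NA]) for g in genes}
        report = score_agreement(pred, obs)
        n_eval = sum(1 for g in genes if obs[g] != NA)
        n_agree = sum(1 for g in genes if obs[g] != NA and obs[g] == pred[g])
        assert (report.n_evaluable, report.n_agree) == (n_eval, n_agree)

    def test_percent_truncation_convention(self):
        assert truncate_percent(13 / 15) == 86.6
        assert truncate_percent(2 / 15) == 13.3

    def test_packaged_sign_table_reproduces_curated_predictions(self):
        """The sign table composed with an AKT-higher-in-E fold must yield
        exactly the curated proposed directions."""
        t1 = load_packaged_table1()
        pred = predict_metabolic_expression(0.7, load_packaged_sign_table())
        assert pred == dict(zip(t1.gene_id, t1.proposed))


def metabolic_toy():
    m = toy(
        ["Glc", "G6P", "Out"],
        [
            ("EX_Glc_in", {"Glc": 1}, 0, 1000),
            ("HEX", {"Glc": -1, "G6P": 1}, 0, 1000),
            ("REST", {"G6P": -1, "Out": 1}, 0, 1000),
            ("EX_Out_out", {"Out": -1}, 0, 1000),
        ],
    )
    m.get_reaction("HEX").gpr = "HK1 OR HK2"
    m.get_reaction("HEX").__post_init__()
    return m


class TestMetPair:
    def test_gene_down_in_M_tightens_mesenchymal_reaction(self):
        met = metabolic_toy()
        pair = constrain_metabolic_model(met, {"HK1": DOWN_IN_M, "HK2": DOWN_IN_M})
        assert pair.model_M.get_reaction("HEX").upper_bound == pytest.approx(10.0)
        assert pair.model_E.get_reaction("HEX").upper_bound == 1000

    def test_empty_directions_give_identical_pair(self):
        met = metabolic_toy()
        pair = constrain_metabolic_model(met, {})
        assert pair.model_E == pair.model_M

    def test_only_gpr_hit_reactions_differ(self):
        met = metabolic_toy()
        pair = constrain_metabolic_model(met, {"HK1": DOWN_IN_M, "HK2": DOWN_IN_M})
        assert pair.differing_reactions() == ["HEX"]

    def test_unknown_gene_logged_and_skipped(self, caplog):
        met = metabolic_toy()
        with caplog.at_level("WARNING"):
            pair = constrain_metabolic_model(met, {"NOTAGENE": DOWN_IN_M})
        assert pair.model_E == pair.model_M
        assert "NOTAGENE" in caplog.text


class TestFluxSpan:
    def test_identical_sets_have_unit_ratio(self):
        fs = FluxSampleSet(np.random.default_rng(0).uniform(size=(50, 3)), ["a", "b", "c"])
        out = compare_flux_span(fs, fs)
        assert np.allclose(out["span_ratio"], 1.0)
        assert (out["partition"] == "similar").all()

    def test_hand_computed_two_reaction_case(self):
        E = FluxSampleSet(np.array([[2.0, 4.0], [4.0, 4.0]]), ["r1", "r2"])
        M = FluxSampleSet(np.array([[1.0, 8.0], [2.0, 8.0]]), ["r1", "r2"])
        out = compare_flux_span(E, M, span="mean")
        assert out.loc["r1", "span_ratio"] == pytest.approx(1.5 / 3.0, rel=1e-6)
        assert out.loc["r2", "span_ratio"] == pytest.approx(2.0, rel=1e-6)
        assert out.loc["r1", "partition"] == "higher_in_E"
        assert out.loc["r2", "partition"] == "higher_in_M"

    def test_zero_span_guarded_and_flagged(self):
        E = FluxSampleSet(np.zeros((10, 1)), ["r"])
        M = FluxSampleSet(np.ones((10, 1)), ["r"])
        out = compare_flux_span(E, M)
        assert bool(out.loc["r", "denominator_guarded"]) is True
        assert np.isfinite(out.loc["r", "span_ratio"])

    def test_planted_tightening_recovered(self):
        met = metabolic_toy()
        pair = constrain_metabolic_model(met, {"HK1": DOWN_IN_M, "HK2": DOWN_IN_M})
        fs_E = sample_fluxes(pair.model_E, n_samples=1500, seed=1, thinning=10)
        fs_M = sample_fluxes(pair.model_M, n_samples=1500, seed=2, thinning=10)
        out = compare_flux_span(fs_E, fs_M)
        assert out.loc["HEX", "span_ratio"] < 1.0
        assert out.loc["HEX", "partition"] == "higher_in_E"

    def test_width_definition_available(self):
        E = FluxSampleSet(np.array([[0.0], [4.0]]), ["r"])
        M = FluxSampleSet(np.array([[1.0], [2.0]]), ["r"])
        out = compare_flux_span(E, M, span="width")
        assert out.loc["r", "span_ratio"] == pytest.approx(0.25, rel=1e-6)


class TestSignTableIO:
    def test_bad_sign_rejected(self, tmp_path):
        p = tmp_path / "signs.tsv"
        p.write_text("gene_id\tpathway\tsign\treference\ng1\tAKT\t2\tx\n")
        with pytest.raises(ValueError, match="sign"):
            read_sign_table(p)

    def test_duplicate_rows_rejected(self, tmp_path):
        p = tmp_path / "signs.tsv"
        p.write_text(
            "gene_id\tpathway\tsign\treference\ng1\tAKT\t1\tx\ng1\tAKT\t-1\ty\n"
        )
        with pytest.raises(ValueError, match="duplicate"):
            read_sign_table(p)
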