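"""Flux-space sampling and the comparison statistics built on it."""

import numpy as np
import pandas as pd
import pytest

from emtflux.context import UP_E, RegulationCall, build_context_pair
from emtflux.sampling import (
    FluxSampleSet,
    InfeasibleModelError,
    compare,
    density_estimate,
    flux_variability,
    mean_flux,
    pathway_report,
    sample_fluxes,
)

from conftest import toy


def assert_valid_samples(model, samples: FluxSampleSet):
    S = model.S
    assert np.abs(S @ samples.samples.T).max() <= 1e-6
    assert (samples.samples >= model.lower_bounds - 1e-9).all()
    assert (samples.samples <= model.upper_bounds + 1e-9).all()


class TestSampler:
    def test_linear_pipe_forces_equal_fluxes(self, closed_chain):
        fs = sample_fluxes(closed_chain, n_samples=100, seed=0, thinning=5)
        assert_valid_samples(closed_chain, fs)
        for j in range(1, 4):
            assert np.allclose(fs.samples[:, 0], fs.samples[:, j], atol=1e-8)

    def test_deterministic_given_seed(self, diamond_model):
        a = sample_fluxes(diamond_model, n_samples=50, seed=7, thinning=5)
        b = sample_fluxes(diamond_model, n_samples=50, seed=7, thinning=5)
        assert np.array_equal(a.samples, b.samples)

    def test_diamond_mean_matches_rejection_sampling_oracle(self, diamond_model):
        """The polytope is 2-D (total flux t in [0,10], split s in [0,t]);
        uniform rejection sampling over that triangle is the oracle."""
        fs = sample_fluxes(diamond_model, n_samples=4000, seed=1, thinning=20)
        assert_valid_samples(diamond_model, fs)
        rng = np.random.default_rng(99)
        pts = rng.uniform(0, 10, size=(200_000, 2))  # (total, split)
        keep = pts[pts[:, 1] <= pts[:, 0]]
        oracle_total = keep[:, 0].mean()         # E[t] over the triangle
        oracle_branch = keep[:, 1].mean()        # E[s]: one branch's flux
        se = 3 * keep[:, 0].std() / np.sqrt(len(fs.samples))
        got = fs.mean()
        assert abs(got["EX_A_in"] - oracle_total) < max(3 * se, 0.25)
        assert abs(got["R_AB"] - oracle_branch) < max(3 * se, 0.25)

    def test_infeasible_model_raises_before_sampling(self):
        model = toy("AB", [
            ("R1", {"A": -1, "B": 1}, 5, 10),  # forced flux with no boundary
        ])
        with pytest.raises(InfeasibleModelError):
            sample_fluxes(model, n_samples=10, seed=0)

    def test_point_polytope_returns_fixed_flux(self):
        model = toy("AB", [
            ("EX_A_in", {"A": 1}, 2, 2),
            ("R1", {"A": -1, "B": 1}, 0, 10),
            ("EX_B_out", {"B": -1}, 0, 10),
        ])
        fs = sample_fluxes(model, n_samples=20, seed=0, thinning=2)
        assert np.allclose(fs.samples, 2.0, atol=1e-7)

    def test_shrinking_a_bound_never_raises_its_mean(self, diamond_model):
        wide = sample_fluxes(diamond_model, n_samples=2000, seed=3, thinning=10)
        tight_model = diamond_model.copy()
        tight_model.get_reaction("R_AB").upper_bound /= 100
        tight = sample_fluxes(tight_model, n_samples=2000, seed=3, thinning=10)
        assert tight.mean()["R_AB"] < wide.mean()["R_AB"]


class TestStatistics:
    def test_mean_flux_of_constant_and_mixed_columns(self):
        arr = np.array([[5.0, 0.0], [5.0, 10.0]])
        assert mean_flux(arr).tolist() == [5.0, 5.0]

    def test_mean_flux_matches_summation_oracle(self):
        rng = np.random.default_rng(0)
        arr = rng.uniform(size=(40, 7))
        manual = [sum(arr[i, j] for i in range(40)) / 40 for j in range(7)]
        assert np.allclose(mean_flux(arr), manual)

    def _sets(self, means_E, means_M, n=100):
        rids = [f"R{j}" for j in range(len(means_E))]
        E = FluxSampleSet(np.tile(means_E, (n, 1)).astype(float), rids)
        M = FluxSampleSet(np.tile(means_M, (n, 1)).astype(float), rids)
        return E, M

    def test_fold_and_log2(self):
        E, M = self._sets([2.0], [4.0])
        row = compare(E, M).iloc[0]
        assert row["fold"] == pytest.approx(2.0, rel=1e-4)
        assert row["log2_fold"] == pytest.approx(1.0, abs=1e-3)

    def test_identical_sets_have_unit_folds(self, diamond_model):
        fs = sample_fluxes(diamond_model, n_samples=200, seed=5, thinning=5)
        out = compare(fs, fs)
        assert np.allclose(out["fold"], 1.0)
        assert np.allclose(out["log2_fold"], 0.0)

    def test_same_model_different_seeds_within_noise(self, diamond_model):
        a = sample_fluxes(diamond_model, n_samples=3000, seed=1, thinning=10)
        b = sample_fluxes(diamond_model, n_samples=3000, seed=2, thinning=10)
        out = compare(a, b)
        # bootstrap the log2 fold under resampling of each chain
        rng = np.random.default_rng(0)
        for rid in ("EX_A_in", "R_AB"):
            j = a.reaction_ids.index(rid)
            boots = []
            for _ in range(200):
                ia = rng.integers(0, a.n_samples, a.n_samples)
                ib = rng.integers(0, b.n_samples, b.n_samples)
                boots.append(
                    np.log2(b.samples[ib, j].mean() / a.samples[ia, j].mean())
                )
            lo, hi = np.quantile(boots, [0.005, 0.995])
            width = max(hi - lo, 0.05)
            assert abs(out.loc[rid, "log2_fold"]) < 3 * width

    def test_mismatched_reaction_sets_rejected(self):
        E, _ = self._sets([1.0], [1.0])
        M = FluxSampleSet(np.ones((10, 1)), ["other"])
        with pytest.raises(ValueError):
            compare(E, M)


class TestDensity:
    def test_constant_column_is_degenerate_spike(self):
        fs = FluxSampleSet(np.full((100, 1), 3.25), ["R"])
        curve = density_estimate(fs, "R")
        assert curve.degenerate and curve.mode == 3.25

    def test_normal_column_mode_near_zero(self):
        rng = np.random.default_rng(11)
        fs = FluxSampleSet(rng.normal(0, 1, size=(5000, 1)), ["R"])
        curve = density_estimate(fs, "R")
        assert abs(curve.mode) < 0.2
        assert np.trapezoid(curve.density, curve.grid) == pytest.approx(1.0, abs=1e-3)

    def test_uniform_column_density_level(self):
        rng = np.random.default_rng(12)
        fs = FluxSampleSet(rng.uniform(0, 10, size=(5000, 1)), ["R"])
        curve = density_estimate(fs, "R")
        central = (curve.grid > 1.0) & (curve.grid < 9.0)
        assert np.all(np.abs(curve.density[central] - 0.1) < 0.02)

    def test_too_few_samples_rejected(self):
        fs = FluxSampleSet(np.zeros((10, 1)), ["R"])
        with pytest.raises(ValueError):
            density_estimate(fs, "R")


class TestPathwayReport:
    def _comparison(self, folds):
        idx = [f"R{j}" for j in range(len(folds))]
        return pd.DataFrame(
            {"fold": folds, "log2_fold": np.log2(folds)}, index=idx
        )

    def test_single_reaction_aggregate(self):
        summary, _ = pathway_report(self._comparison([2.0]), {"P": ["R0"]})
        assert summary.loc["P", "aggregate_fold"] == pytest.approx(2.0)

    def test_geometric_mean_cancels_reciprocal_folds(self):
        summary, _ = pathway_report(self._comparison([2.0, 0.5]), {"P": ["R0", "R1"]})
        assert summary.loc["P", "aggregate_fold"] == pytest.approx(1.0)

    def test_empty_pathway_rejected(self):
        with pytest.raises(ValueError):
            pathway_report(self._comparison([1.0]), {"P": []})

    def test_exchange_exclusion(self):
        comparison = self._comparison([2.0, 8.0])
        summary, heat = pathway_report(
            comparison, {"P": ["R0", "R1"]}, exclude_exchange_ids={"R1"}
        )
        assert summary.loc["P", "aggregate_fold"] == pytest.approx(2.0)
        assert list(heat.index) == ["R0"]

    def test_planted_tightening_shows_reduced_fold(self, diamond_model):
        calls = {"R_AB": RegulationCall("R_AB", UP_E), "R_BD": RegulationCall("R_BD", UP_E)}
        pair = build_context_pair(diamond_model, calls)
        fs_E = sample_fluxes(pair.model_E, n_samples=2000, seed=1, thinning=10)
        fs_M = sample_fluxes(pair.model_M, n_samples=2000, seed=2, thinning=10)
        summary, _ = pathway_report(compare(fs_E, fs_M), {"planted": ["R_AB", "R_BD"]})
        assert summary.loc["planted", "aggregate_fold"] < 1.0


class TestFVA:
    def test_matches_cobra_oracle(self, diamond_model):
        """Independent cross-check of the flux ranges against cobrapy."""
        cobra = pytest.importorskip("cobra")
        ours = flux_variability(diamond_model)

        cm = cobra.Model("diamond")
        metabolites = {
            sid: cobra.Metabolite(sid) for sid in diamond_model.species_ids
        }
        for rxn in diamond_model.reactions:
            cr = cobra.Reaction(rxn.id)
            cr.lower_bound, cr.upper_bound = rxn.lower_bound, rxn.upper_bound
            cm.add_reactions([cr])
            cr.add_metabolites({metabolites[s]: c for s, c in rxn.stoichiometry.items()})
        from cobra.flux_analysis import flux_variability_analysis

        theirs = flux_variability_analysis(cm, fraction_of_optimum=0.0)
        for rid in diamond_model.reaction_ids:
            assert ours.loc[rid, "minimum"] == pytest.approx(theirs.loc[rid, "minimum"], abs=1e-6)
            assert ours.loc[rid, "maximum"] == pytest.approx(theirs.loc[rid, "maximum"], abs=1e-6)
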