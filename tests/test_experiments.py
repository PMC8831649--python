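import copy
import math

import numpy as np
import pandas as pd
import pytest

import pcmodel as pm
from pcmodel.experiments import (residual_substrate, saturation_proxy,
                                 fit_vsyn_max, pathway_fractions,
                                 proteome_efficiency, up_slack,
                                 ETHANOL_FLUX_TOL)
from pcmodel.model_schema import (Metabolite, ReactionSpec, ProteinSpec,
                                  Compartment, RibosomeParams, BiomassSpec,
                                  CatalysisRule, Conditions, ModelSpec)


class TestResidualSubstrate:
    def test_half_saturation_identity(self):
        assert residual_substrate(0.5, 1.0) == pytest.approx(1.0)

    def test_zero_saturation(self):
        assert residual_substrate(0.0) == 0.0

    @pytest.mark.parametrize("s", [0.01, 0.3, 0.5, 0.9, 0.999])
    def test_forward_monod_inverts(self, s):
        c = residual_substrate(s, Km=1.3)
        assert c / (1.3 + c) == pytest.approx(s, rel=1e-12)

    def test_saturation_ceiling_rejected(self):
        with pytest.raises(ValueError):
            residual_substrate(1.0)


class TestSaturationSweep:
    def test_growth_monotone_in_saturation(self, fine_sweep):
        mu = fine_sweep.table.mu_max.to_numpy()
        assert np.all(np.diff(mu) > -1e-9)

    def test_low_saturation_transporter_only_pool_full(self, fine_sweep):
        row = fine_sweep.table.iloc[0]
        assert row.occ_plasma_membrane >= 0.999
        assert row.occ_mito_inner_membrane < 0.999

    def test_regime_boundaries_reported(self, fine_sweep):
        assert {"ethanol_onset_mu", "cytosol_full_mu"} <= \
            set(fine_sweep.boundaries)
        assert fine_sweep.boundaries["ethanol_onset_mu"] < \
            fine_sweep.boundaries["cytosol_full_mu"]

    def test_active_set_progression(self, fine_sweep):
        """Active pools progress transporter-only, then + mito membrane,
        then cytosol-involved as saturation rises."""
        seq = [frozenset(a.split(",")) if a else frozenset()
               for a in fine_sweep.table.active_constraints]
        stages = []
        for s in seq:
            if not stages or stages[-1] != s:
                stages.append(s)
        assert stages[0] == {"plasma_membrane"}
        assert {"mito_inner_membrane", "plasma_membrane"} in stages
        assert any("cytosol" in s for s in stages)
        # mito-membrane stage comes before the cytosol-involved stage
        i_mito = stages.index({"mito_inner_membrane", "plasma_membrane"})
        i_cyt = next(i for i, s in enumerate(stages) if "cytosol" in s)
        assert i_mito < i_cyt

    def test_carbon_balance_closes_along_sweep(self, toy_model, fine_sweep):
        for sol in fine_sweep.solutions:
            if sol is None:
                continue
            cb = pm.carbon_balance(sol, toy_model)
            assert abs(cb["residual"]) <= 1e-6 * max(cb["in"], 1e-12)

    def test_unsorted_grid_rejected(self, toy_pc):
        with pytest.raises(ValueError):
            pm.saturation_sweep(toy_pc, [0.5, 0.2])

    def test_infeasible_row_flagged_and_sweep_continues(self, toy_pc):
        import dataclasses
        cal = dataclasses.replace(pm.Calibration(), ngam=6.0)
        pc = pm.build_pc_model(pm.make_toy_yeast(cal))
        sw = pm.saturation_sweep(pc, [0.001, 0.5])
        assert list(sw.table.status) == ["infeasible", "optimal"]


@pytest.fixture(scope="module")
def curve(toy_pc):
    return pm.gratuitous_curve(
        toy_pc, [0.0, 0.03, 0.06, 0.09, 0.12, 0.15, 0.18, 0.21])


class TestGratuitousExpression:
    def test_unperturbed_fitness_is_one(self, curve):
        assert curve.table.relative_fitness.iloc[0] == pytest.approx(1.0)

    def test_growth_strictly_decreasing(self, curve):
        ok = curve.table[curve.table.status == "optimal"]
        assert np.all(np.diff(ok.mu_max.to_numpy()) < 0)

    def test_decline_concave_toward_feasibility_edge(self, curve):
        ok = curve.table[curve.table.status == "optimal"]
        d2 = np.diff(ok.mu_max.to_numpy(), n=2)
        assert np.all(d2 < 1e-9)

    def test_excess_fraction_flagged_infeasible(self, toy_pc):
        sw = pm.gratuitous_curve(toy_pc, [0.0, 0.5])
        assert list(sw.table.status) == ["optimal", "infeasible"]


class TestTranslationInhibition:
    def test_zero_inhibition_is_baseline(self, toy_pc, batch_solution):
        sw = pm.translation_inhibition(toy_pc, [0.0])
        assert sw.table.mu_max.iloc[0] == pytest.approx(batch_solution.mu,
                                                        abs=1e-9)

    def test_ribosome_fraction_rises_under_inhibition_at_fixed_mu(self, toy_model):
        """Paired solves at the same growth rate: the inhibited cell must
        dedicate a larger proteome fraction to ribosomes."""
        mu_probe = 0.25

        def rib_fraction(model):
            sol = pm.solve_at_mu(pm.build_pc_model(model), mu_probe)
            total = sum(p.mass * sol.enzyme_levels[p.id]
                        for p in model.proteins)
            return toy_model.protein("RIB").mass * sol.enzyme_levels["RIB"] / total

        inhibited = copy.deepcopy(toy_model)
        inhibited.ribosome.k_el *= 0.6
        assert rib_fraction(inhibited) > rib_fraction(toy_model) * 1.05


class TestConditionRuns:
    def test_galactose_ethanol_positive(self, galactose_run):
        sol, rec = galactose_run
        assert rec["ethanol"] > ETHANOL_FLUX_TOL
        assert 0.1 < sol.mu < 0.25

    def test_maltose_intermediate(self, toy_pc, galactose_run, batch_solution):
        sol_m, _ = pm.condition_run(toy_pc, pm.OVERLAYS["maltose"])
        assert galactose_run[0].mu < sol_m.mu < batch_solution.mu

    def test_glucose_overlay_matches_unmodified(self, toy_pc, batch_solution):
        sol, _ = pm.condition_run(toy_pc, pm.OVERLAYS["glucose"])
        assert sol.mu == pytest.approx(batch_solution.mu, abs=1e-9)


class TestPathwayFractions:
    def test_fractions_sum_to_one(self, batch_solution):
        df = pathway_fractions(batch_solution, pm.TOY_PATHWAYS)
        assert df.predicted_fraction.sum() == pytest.approx(1.0, abs=1e-9)

    def test_single_label_partition(self, toy_model, batch_solution):
        ann = {p.id: "all" for p in toy_model.proteins
               if not p.is_unspecified}
        df = pathway_fractions(batch_solution, ann)
        up = float(df.loc[df.pathway == "UP", "predicted_fraction"].iloc[0])
        all_frac = float(df.loc[df.pathway == "all",
                                "predicted_fraction"].iloc[0])
        assert all_frac == pytest.approx(1.0 - up, abs=1e-9)

    def test_unannotated_protein_warned_and_bucketed(self, batch_solution):
        ann = {k: v for k, v in pm.TOY_PATHWAYS.items() if k != "GLY"}
        with pytest.warns(UserWarning, match="GLY"):
            df = pathway_fractions(batch_solution, ann)
        assert "other" in set(df.pathway)


class TestSaturationProxy:
    def test_equal_levels_give_one(self):
        assert float(saturation_proxy(0.1, 0.1)) == 1.0

    def test_half_saturated(self):
        assert float(saturation_proxy(0.05, 0.10)) == pytest.approx(0.5)

    def test_exceeding_one_flagged(self):
        p = saturation_proxy(0.2, 0.1)
        assert p.exceeds_one

    def test_zero_measurement_undefined(self):
        with pytest.warns(UserWarning):
            p = saturation_proxy(0.1, 0.0)
        assert math.isnan(p) and p.undefined


class TestVsynMaxFit:
    def test_noiseless_recovery(self):
        mu = np.array([0.28, 0.30, 0.34, 0.38])
        series = pd.DataFrame({"mu": mu, "mito_fraction": 0.1 / mu})
        v, resid = fit_vsyn_max(series)
        assert v == pytest.approx(0.1, rel=1e-12)
        assert np.allclose(resid, 0.0)

    def test_single_point_arithmetic(self):
        v, _ = fit_vsyn_max(pd.DataFrame({"mu": [0.3],
                                          "mito_fraction": [0.2]}))
        assert v == pytest.approx(0.06)

    def test_fixed_degradation_shifts_estimate(self):
        series = pd.DataFrame({"mu": [0.3], "mito_fraction": [0.2]})
        v, _ = fit_vsyn_max(series, k_deg=0.1)
        assert v == pytest.approx(0.2 * 0.4)

    def test_all_zero_mu_rejected(self):
        with pytest.raises(ValueError):
            fit_vsyn_max(pd.DataFrame({"mu": [0.0], "mito_fraction": [0.2]}))


class TestProteomeEfficiency:
    def test_doubling_fermentative_kcats_doubles_atp_per_protein(self):
        import dataclasses
        # no turnover, so protein demand is exactly linear in 1/kcat
        cal = dataclasses.replace(pm.Calibration(), k_deg_enzyme=0.0)
        slow = pm.make_toy_yeast(cal)
        base = proteome_efficiency(pm.build_pc_model(slow))
        fast = copy.deepcopy(slow)
        for rule in fast.catalysis:
            if rule.reaction in ("t_glc", "glycolysis", "fermentation"):
                rule.kcat *= 2
        doubled = proteome_efficiency(pm.build_pc_model(fast))

        def get(df, strat):
            return float(df.set_index("strategy").loc[strat, "atp_per_protein"])

        assert get(doubled, "fermentation") == pytest.approx(
            2 * get(base, "fermentation"), rel=1e-9)

    def test_two_reaction_chain_closed_form(self):
        """Minimal chain: substrate uptake then ATP generation.  At zero
        growth with no turnover, minimal protein is exactly sum(v_i *
        MW_i / kcat_i) for a unit ATP flux."""
        k_up, k_atp, atp_per_rxn = 1e4, 2e4, 4.0
        model = ModelSpec(
            name="chain",
            metabolites=[Metabolite("s_ext", boundary=True),
                         Metabolite("s"),
                         Metabolite("aa", role="amino_acid"),
                         Metabolite("aa_ext", boundary=True),
                         Metabolite("atp", role="energy")],
            reactions=[ReactionSpec("t_s", {"s_ext": -1, "s": 1},
                                    tags={"uptake"}),
                       ReactionSpec("gen", {"s": -1, "atp": atp_per_rxn}),
                       ReactionSpec("t_aa", {"aa_ext": -1, "aa": 1})],
            proteins=[ProteinSpec("T", 500, "cytosol", k_deg=0.0),
                      ProteinSpec("G", 1000, "cytosol", k_deg=0.0),
                      ProteinSpec("R", 10000, "cytosol", is_ribosome=True),
                      ProteinSpec("UP", 100, "cytosol", is_unspecified=True)],
            compartments=[Compartment("cytosol", "volumetric", 10.0,
                                      fill_rule="equality")],
            catalysis=[CatalysisRule("t_s", "T", k_up),
                       CatalysisRule("gen", "G", k_atp)],
            ribosome=RibosomeParams(k_el=36000.0),
            biomass=BiomassSpec(ngam=0.0),
            conditions=Conditions(min_up_fraction=0.0),
        )
        pc = pm.build_pc_model(model)
        df = proteome_efficiency(pc, strategies={"chain": ["gen"]},
                                 atp_flux=1.0)
        v_gen = 1.0 / atp_per_rxn
        expected_mass = (v_gen * model.protein("G").mass / k_atp
                         + v_gen * model.protein("T").mass / k_up)
        got = float(df.set_index("strategy").loc["chain", "atp_per_protein"])
        assert got == pytest.approx(1.0 / expected_mass, rel=1e-9)

    def test_toy_strategy_ordering(self, toy_pc):
        df = proteome_efficiency(toy_pc).set_index("strategy")
        assert df.loc["fermentation", "atp_per_protein"] > \
            df.loc["respiration", "atp_per_protein"]
        assert df.loc["respiration", "atp_per_substrate"] > \
            df.loc["fermentation", "atp_per_substrate"]
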