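import copy
import dataclasses

import pytest

import pcmodel as pm
from pcmodel.model_schema import (Metabolite, ReactionSpec, ProteinSpec,
                                  Compartment, RibosomeParams, BiomassSpec,
                                  Conditions, ModelSpec)
from pcmodel.pc_builder import (make_synthesis, make_degradation,
                                synthesis_energy, build_pc_model,
                                ATP_PER_PEPTIDE_BOND, C_INIT, C_SCAN_PER_NT)


def _protein(length, utr=0, **kw):
    return ProteinSpec("X", length, "cytosol", utr_length=utr, **kw)


RIB = RibosomeParams(k_el=36000.0)


class TestSynthesis:
    def test_single_residue_costs_initiation_only(self):
        rxn = make_synthesis(_protein(1), RIB)
        assert rxn.stoichiometry["atp"] == -C_INIT
        assert rxn.stoichiometry["aa"] == -1.0
        assert rxn.stoichiometry["X"] == 1.0

    def test_elongation_energy_two_per_bond(self):
        rxn = make_synthesis(_protein(301), RIB)
        assert rxn.stoichiometry["atp"] == -(300 * ATP_PER_PEPTIDE_BOND + C_INIT)

    @pytest.mark.parametrize("utr0,utr1", [(0, 100), (40, 80), (10, 1000)])
    def test_utr_extension_costs_scan_energy_exactly(self, utr0, utr1):
        e0 = synthesis_energy(_protein(500, utr=utr0))
        e1 = synthesis_energy(_protein(500, utr=utr1))
        assert e1 - e0 == pytest.approx(C_SCAN_PER_NT * (utr1 - utr0))

    def test_zero_length_rejected(self):
        with pytest.raises(ValueError):
            make_synthesis(_protein(0), RIB)


class TestDegradation:
    def test_residues_conserved_through_lifecycle(self):
        p = _protein(700)
        syn = make_synthesis(p, RIB)
        deg = make_degradation(p)
        assert deg.stoichiometry["aa"] == -syn.stoichiometry["aa"]

    def test_steady_state_balance_by_hand(self):
        """At mu = 0.2/h with k_deg = 0.05/h and e pinned at 1 mmol/gDW the
        lifecycle balance forces v_syn = (mu + k_deg) * e = 0.25 and
        v_deg = 0.05, solved by hand from v_syn = (mu + k_deg) * e."""
        model = ModelSpec(
            name="mini",
            metabolites=[Metabolite("aa_ext", boundary=True),
                         Metabolite("atp_ext", boundary=True),
                         Metabolite("aa", role="amino_acid"),
                         Metabolite("atp", role="energy")],
            reactions=[ReactionSpec("t_aa", {"aa_ext": -1, "aa": 1}),
                       ReactionSpec("t_atp", {"atp_ext": -1, "atp": 1})],
            proteins=[ProteinSpec("X", 500, "cytosol", k_deg=0.05,
                                  fixed_level=1.0),
                      ProteinSpec("R", 10000, "cytosol", is_ribosome=True),
                      ProteinSpec("UP", 100, "cytosol", is_unspecified=True)],
            compartments=[Compartment("cytosol", "volumetric", 400.0,
                                      fill_rule="equality")],
            catalysis=[],
            ribosome=RibosomeParams(k_el=36000.0),
            biomass=BiomassSpec(),
            conditions=Conditions(min_up_fraction=0.0),
        )
        sol = pm.solve_at_mu(build_pc_model(model), 0.2)
        assert sol.optimal
        assert sol.fluxes["syn__X"] == pytest.approx(0.25, abs=1e-9)
        assert sol.fluxes["deg__X"] == pytest.approx(0.05, abs=1e-9)

    def test_zero_kdeg_carries_zero_flux(self, toy_pc, batch_solution):
        # the ribosome does not turn over in the reduced model
        assert batch_solution.fluxes["deg__RIB"] == pytest.approx(0.0, abs=1e-12)


class TestBuildStructure:
    def test_toy_has_one_density_and_three_pool_rows(self, toy_pc):
        density = [r for r in toy_pc.rows if r.category == "density"]
        pools = [r for r in toy_pc.rows if r.category == "pool"]
        assert len(density) == 1 and density[0].kind == "eq"
        assert len(pools) == 3
        assert all(r.kind == "ub" for r in pools)

    def test_every_protein_has_full_lifecycle(self, toy_model, toy_pc):
        for p in toy_model.proteins:
            assert f"syn__{p.id}" in toy_pc.var_index
            assert f"deg__{p.id}" in toy_pc.var_index
            assert f"enz__{p.id}" in toy_pc.var_index
            assert any(r.name == f"life__{p.id}" for r in toy_pc.rows)

    def test_each_catalysed_reaction_in_one_coupling_row(self, toy_model, toy_pc):
        coupled = [r.name for r in toy_pc.rows if r.category == "coupling"]
        assert sorted(coupled) == sorted(
            "cap__" + c.reaction for c in toy_model.catalysis)

    def test_build_is_deterministic(self, toy_model):
        a = build_pc_model(toy_model).to_debug_json()
        b = build_pc_model(toy_model).to_debug_json()
        assert a == b

    def test_unknown_compartment_rejected(self, toy_model):
        m = copy.deepcopy(toy_model)
        m.proteins[0].compartment = "vacuole"
        with pytest.raises(pm.ValidationError):
            build_pc_model(m)

    def test_relaxing_density_and_up_raises_growth(self, toy_model, batch_solution):
        relaxed = build_pc_model(toy_model, density_as_equality=False,
                                 enforce_min_up=False)
        mu_relaxed = pm.maximize_growth(relaxed).mu
        assert mu_relaxed > batch_solution.mu + 1e-3


class TestImportCapacity:
    def test_no_mito_proteins_no_import_row(self):
        m = pm.make_self_replicator(36000, 36000)
        pc = build_pc_model(m)
        assert not any(r.category == "import" for r in pc.rows)

    def test_toy_has_import_row(self, toy_pc):
        assert sum(r.category == "import" for r in toy_pc.rows) == 1

    def test_missing_importer_rejected(self, toy_model):
        m = copy.deepcopy(toy_model)
        m.import_params = None
        with pytest.raises(pm.ValidationError, match="importer"):
            build_pc_model(m)

    def test_raising_k_import_never_lowers_growth(self):
        mus = []
        for k_imp in [50.0, 200.0, 3600.0]:
            cal = dataclasses.replace(pm.Calibration(), k_import=k_imp)
            pc = build_pc_model(pm.make_toy_yeast(cal))
            mus.append(pm.maximize_growth(pc).mu)
        assert mus == sorted(mus)
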