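import copy
import dataclasses
import json

import pytest

import pcmodel as pm
from pcmodel.model_schema import (SchemaError, load_model, save_model,
                                  model_to_dict, load_overlay, save_overlay,
                                  import_sbml, read_annotations_tsv)


class TestLoadSave:
    def test_packaged_fixture_has_four_pools(self, tmp_path, toy_model):
        p = tmp_path / "m.json"
        save_model(toy_model, p)
        m = load_model(p)
        assert {c.id for c in m.compartments} == {
            "cytosol", "plasma_membrane", "mito_matrix",
            "mito_inner_membrane"}

    def test_round_trip_is_identity(self, tmp_path, toy_model):
        p1, p2 = tmp_path / "a.json", tmp_path / "b.json"
        save_model(toy_model, p1)
        m = load_model(p1)
        save_model(m, p2)
        assert model_to_dict(load_model(p2)) == model_to_dict(toy_model)
        assert p1.read_bytes() == p2.read_bytes()

    def test_empty_file_is_schema_error(self, tmp_path):
        p = tmp_path / "empty.json"
        p.write_text("")
        with pytest.raises(SchemaError):
            load_model(p)

    def test_missing_field_names_offender(self, tmp_path, toy_model):
        d = model_to_dict(toy_model)
        del d["ribosome"]
        p = tmp_path / "m.json"
        p.write_text(json.dumps(d))
        with pytest.raises(SchemaError, match="ribosome"):
            load_model(p)

    def test_dangling_reference_listed(self, tmp_path, toy_model):
        d = model_to_dict(toy_model)
        d["proteins"][0]["compartment"] = "nucleus"
        p = tmp_path / "m.json"
        p.write_text(json.dumps(d))
        with pytest.raises(pm.ValidationError, match="nucleus"):
            load_model(p)


class TestPackagedData:
    def test_packaged_fixture_matches_generator(self):
        from importlib import resources
        ref = resources.files("pcmodel").joinpath("data/toy_yeast.json")
        with resources.as_file(ref) as p:
            packaged = load_model(p)
        assert model_to_dict(packaged) == model_to_dict(pm.make_toy_yeast())

    def test_packaged_overlays_match(self):
        from importlib import resources
        for name, overlay in pm.OVERLAYS.items():
            ref = resources.files("pcmodel").joinpath(f"data/{name}.yaml")
            with resources.as_file(ref) as p:
                assert load_overlay(p) == overlay


class TestValidate:
    def test_toy_model_is_clean(self, toy_model):
        assert pm.validate(toy_model) == []

    def test_two_unspecified_proteins_flagged(self, toy_model):
        m = copy.deepcopy(toy_model)
        m.proteins[0].is_unspecified = True  # HXT, in addition to UP
        report = pm.validate(m)
        rules = [v.rule for v in report]
        assert any("is_unspecified" in r for r in rules)

    def test_zero_kcat_flagged(self, toy_model):
        m = copy.deepcopy(toy_model)
        m.catalysis[0].kcat = 0.0
        report = pm.validate(m)
        assert len(report) == 1
        assert report[0].rule == "kcat > 0"

    def test_negative_capacity_flagged(self, toy_model):
        m = copy.deepcopy(toy_model)
        m.compartments[0].capacity = -1.0
        assert any(v.rule == "capacity > 0" for v in pm.validate(m))


class TestOverlays:
    def test_galactose_overlay_values(self, toy_model):
        out = pm.apply_overlay(toy_model, pm.OVERLAYS["galactose"])
        assert out.transporter_pool().capacity == 3.0
        assert out.conditions.carbon_ngam == 3.0
        assert out.conditions.min_up_fraction == 0.49
        # original untouched
        assert toy_model.transporter_pool().capacity == 7.5

    def test_maltose_overlay_values(self, toy_model):
        out = pm.apply_overlay(toy_model, pm.OVERLAYS["maltose"])
        assert (out.transporter_pool().capacity,
                out.conditions.carbon_ngam,
                out.conditions.min_up_fraction) == (3.5, 0.0, 0.34)

    def test_identity_overlay_is_noop(self, toy_model):
        out = pm.apply_overlay(toy_model, pm.OVERLAYS["glucose"])
        assert model_to_dict(out) == model_to_dict(toy_model)

    def test_overlay_idempotent(self, toy_model):
        once = pm.apply_overlay(toy_model, pm.OVERLAYS["galactose"])
        twice = pm.apply_overlay(once, pm.OVERLAYS["galactose"])
        assert model_to_dict(once) == model_to_dict(twice)

    def test_overlay_without_transporter_errors(self):
        m = pm.make_self_replicator(36000, 36000)
        with pytest.raises(pm.ValidationError):
            pm.apply_overlay(m, pm.OVERLAYS["galactose"])

    def test_overlay_yaml_round_trip(self, tmp_path):
        p = tmp_path / "gal.yaml"
        save_overlay(pm.OVERLAYS["galactose"], p)
        ov = load_overlay(p)
        assert ov == pm.OVERLAYS["galactose"]

    def test_overlay_nonfinite_rejected(self, toy_model):
        bad = dataclasses.replace(pm.OVERLAYS["glucose"],
                                  carbon_ngam=float("nan"))
        with pytest.raises(ValueError):
            pm.apply_overlay(toy_model, bad)


class TestExternalFormats:
    def test_sbml_import_metabolites_and_reactions(self, tmp_path):
        cobra = pytest.importorskip("cobra")
        cb = cobra.Model("mini")
        a = cobra.Metabolite("a_c", formula="C6H12O6", compartment="c")
        b = cobra.Metabolite("b_c", formula="C3H4O3", compartment="c")
        r = cobra.Reaction("split")
        r.add_metabolites({a: -1, b: 2})
        cb.add_reactions([r])
        p = tmp_path / "mini.xml"
        cobra.io.write_sbml_model(cb, str(p))
        mets, rxns = import_sbml(p)
        assert {m.id: m.carbon for m in mets} == {"a_c": 6, "b_c": 3}
        assert rxns[0].stoichiometry == {"a_c": -1.0, "b_c": 2.0}

    def test_annotation_tsv_reader(self, tmp_path):
        p = tmp_path / "ann.tsv"
        p.write_text("protein_id\tlength\tcompartment\tw\tk_deg\tutr_length\n"
                     "P1\t300\tcytosol\t\t0.02\t40\n"
                     "P2\t550\tplasma_membrane\t7.26e15\t0\t0\n")
        prots = read_annotations_tsv(p)
        assert prots[0].length == 300 and prots[0].w is None
        assert prots[1].w == pytest.approx(7.26e15)
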