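"""Data model, biomass assembly and model I/O round trips."""

import numpy as np
import pytest

import netgs
from netgs.errors import FormatError, ValidationError
from netgs.model import UMOL_PER_MMOL


def write_chain_files(tmp_path):
    (tmp_path / "reactions.tsv").write_text(
        "id\tequation\tlb\tub\ttag\n"
        "UPTAKE\t-> A\t0\t10\t\n"
        "CONV\tA -> B\t0\t1000\t\n"
        "BIOMASS\tB ->\t0\t1000\tbiomass\n"
    )
    (tmp_path / "metabolites.tsv").write_text("id\nA\nB\n")
    return tmp_path


class TestReadModel:
    def test_chain_file_dimensions(self, tmp_path):
        model = netgs.read_model(write_chain_files(tmp_path), dialect="tsv")
        assert model.S.shape == (2, 3)
        assert model.reaction_ids == ["UPTAKE", "CONV", "BIOMASS"]  # file order kept
        assert model.biomass_id == "BIOMASS"
        assert model.exchange_ids == ["UPTAKE", "BIOMASS"]

    @pytest.mark.parametrize("dialect", ["tsv", "json", "sbml"])
    def test_write_read_round_trip(self, minimal, tmp_path, dialect):
        model, _ = minimal
        target = tmp_path / ("m" if dialect == "tsv" else f"m.{dialect}")
        netgs.write_model(model, target, dialect=dialect)
        back = netgs.read_model(target, dialect=dialect)
        assert back.reaction_ids == model.reaction_ids
        assert back.metabolite_ids == model.metabolite_ids
        np.testing.assert_array_equal(back.S, model.S)
        np.testing.assert_array_equal(back.lb, model.lb)
        np.testing.assert_array_equal(back.ub, model.ub)
        assert back.biomass_index == model.biomass_index
        assert back.tags == model.tags

    def test_sbml_and_tsv_agree(self, minimal, tmp_path):
        model, _ = minimal
        netgs.write_model(model, tmp_path / "m", dialect="tsv")
        netgs.write_model(model, tmp_path / "m.xml", dialect="sbml")
        a = netgs.read_model(tmp_path / "m", dialect="tsv")
        b = netgs.read_model(tmp_path / "m.xml", dialect="sbml")
        np.testing.assert_array_equal(a.S, b.S)
        np.testing.assert_array_equal(a.lb, b.lb)
        np.testing.assert_array_equal(a.ub, b.ub)

    def test_missing_biomass_is_validation_error(self, tmp_path):
        write_chain_files(tmp_path)
        text = (tmp_path / "reactions.tsv").read_text().replace("biomass", "")
        (tmp_path / "reactions.tsv").write_text(text)
        with pytest.raises(ValidationError, match="biomass"):
            netgs.read_model(tmp_path, dialect="tsv")

    def test_duplicate_reaction_id_rejected(self, tmp_path):
        write_chain_files(tmp_path)
        extra = "CONV\tA -> B\t0\t1000\t\n"
        (tmp_path / "reactions.tsv").write_text(
            (tmp_path / "reactions.tsv").read_text() + extra
        )
        with pytest.raises(ValidationError, match="duplicate"):
            netgs.read_model(tmp_path, dialect="tsv")

    def test_unknown_file_is_format_error(self, tmp_path):
        with pytest.raises(FormatError):
            netgs.read_model(tmp_path / "nope.json", dialect="json")

    def test_bad_json_names_line(self, tmp_path):
        p = tmp_path / "m.json"
        p.write_text("{\n  broken\n}")
        with pytest.raises(FormatError, match="line"):
            netgs.read_model(p, dialect="json")


class TestSetBiomass:
    def test_identity_composition(self, minimal):
        model, _ = minimal
        comp = netgs.BiomassComposition.from_model(model)
        out = netgs.set_biomass(model, comp)
        np.testing.assert_array_equal(out.S, model.S)

    def test_doubling_scales_column(self, minimal):
        model, _ = minimal
        comp = netgs.BiomassComposition.from_model(model)
        out = netgs.set_biomass(model, comp.scaled(2.0))
        np.testing.assert_allclose(
            out.S[:, out.biomass_index], 2.0 * model.S[:, model.biomass_index]
        )
        other = np.delete(np.arange(model.n_reactions), model.biomass_index)
        np.testing.assert_array_equal(out.S[:, other], model.S[:, other])

    def test_input_model_not_modified(self, minimal):
        model, _ = minimal
        before = model.S.copy()
        comp = netgs.BiomassComposition.from_model(model).scaled(3.0)
        netgs.set_biomass(model, comp)
        np.testing.assert_array_equal(model.S, before)

    def test_unknown_metabolite_named_in_error(self, minimal):
        model, _ = minimal
        comp = netgs.BiomassComposition({"X99": -10.0})
        with pytest.raises(ValidationError, match="X99"):
            netgs.set_biomass(model, comp)

    def test_idempotent(self, minimal):
        model, comps = minimal
        once = netgs.set_biomass(model, comps["E2"])
        twice = netgs.set_biomass(once, comps["E2"])
        np.testing.assert_array_equal(once.S, twice.S)


class TestAssembleBiomass:
    MASSES = {"glucose": 180.0, "glycine": 75.07, "alanine": 89.09}

    def test_unit_conversion(self):
        comp = netgs.assemble_biomass(
            {"glucose": 18.0}, 0.0, {}, None, molar_masses=self.MASSES
        )
        assert comp.coefficients["glucose"] == pytest.approx(-100.0)  # umol/gDW, consumed

    def test_zero_protein_gives_zero_amino_acids(self):
        comp = netgs.assemble_biomass(
            {"glucose": 18.0}, 0.0, {"glycine": 0.4, "alanine": 0.6}, None,
            molar_masses=self.MASSES,
        )
        assert comp.coefficients["glycine"] == 0.0
        assert comp.coefficients["alanine"] == 0.0

    def test_order_invariance_and_determinism(self):
        kw = dict(protein_total=5.0, aa_fractions={"glycine": 0.5, "alanine": 0.5},
                  fixed_components=None, molar_masses=self.MASSES)
        a = netgs.assemble_biomass({"glucose": 18.0, "glycine": 1.0}, **kw)
        b = netgs.assemble_biomass({"glycine": 1.0, "glucose": 18.0}, **kw)
        assert a.coefficients == b.coefficients

    def test_missing_molar_mass_fails_loudly(self):
        with pytest.raises(ValidationError, match="molar mass"):
            netgs.assemble_biomass({"mystery": 1.0}, 0.0, {}, None, molar_masses=self.MASSES)

    def test_negative_amount_rejected(self):
        with pytest.raises(ValidationError, match="negative"):
            netgs.assemble_biomass({"glucose": -1.0}, 0.0, {}, None, molar_masses=self.MASSES)

    def test_fractions_must_sum_to_one(self):
        with pytest.raises(ValidationError, match="sum"):
            netgs.assemble_biomass({}, 1.0, {"glycine": 0.7}, None, molar_masses=self.MASSES)

    def test_fixed_components_added(self):
        fixed = netgs.BiomassComposition({"cellwall": -300.0})
        comp = netgs.assemble_biomass(
            {"glucose": 18.0}, 0.0, {}, fixed, molar_masses=self.MASSES
        )
        assert comp.coefficients["cellwall"] == -300.0


class TestInvariants:
    def test_ratio_constraint_validation(self):
        with pytest.raises(ValidationError):
            netgs.RatioConstraints(carb_oxy=-1.0)
        with pytest.raises(ValidationError):
            netgs.RatioConstraints.interval(carb_oxy=(3.0, 1.0))
        assert netgs.RatioConstraints.fixed().is_fixed
        assert not netgs.RatioConstraints.interval().is_fixed

    def test_composition_from_model_round_trips_units(self, minimal):
        model, _ = minimal
        comp = netgs.BiomassComposition.from_model(model)
        col = model.biomass_column()
        for mid, c in comp.coefficients.items():
            assert c == pytest.approx(col[model.metabolite_index(mid)] * UMOL_PER_MMOL)

    def test_lb_above_ub_rejected(self, chain):
        chain.lb[0] = 20.0
        with pytest.raises(ValidationError, match="lb > ub"):
            chain.validate()

    def test_molar_mass_table_ships_with_package(self):
        masses = netgs.load_molar_masses()
        assert masses["sucrose"] == pytest.approx(342.30)
        assert all(m > 0 for m in masses.values())
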