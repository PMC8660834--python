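"""Biomass objective builder: coefficients, mass closure, GAM handling,
elemental summaries."""

import numpy as np
import pytest

from bifidoflux import (build_bof, elemental_summary, set_gam, solve_fba,
                        apply_medium)
from bifidoflux.biomass import (BiomassComposition, load_composition,
                                save_composition)
from bifidoflux.model import Metabolite, formula_weight, parse_formula
from bifidoflux.synthetic import make_strain_model, cdm_medium
from bifidoflux.synthetic.compositions import strain_composition


def glucose_catalogue():
    return {
        "glc__D_c": Metabolite(id="glc__D_c",
                               formula=parse_formula("C6H12O6")),
        "biomass_c": Metabolite(id="biomass_c"),
        "atp_c": Metabolite(id="atp_c",
                            formula=parse_formula("C10H12N5O13P3"),
                            charge=-4),
        "adp_c": Metabolite(id="adp_c",
                            formula=parse_formula("C10H12N5O10P2"),
                            charge=-3),
        "pi_c": Metabolite(id="pi_c", formula=parse_formula("HO4P"),
                           charge=-2),
        "h2o_c": Metabolite(id="h2o_c", formula=parse_formula("H2O")),
        "h_c": Metabolite(id="h_c", formula=parse_formula("H"), charge=1),
    }


def glucose_only_composition(gam=0.0):
    glc_mass = formula_weight(parse_formula("C6H12O6"))
    return BiomassComposition(
        fractions={"carbohydrate": 1.0},
        monomer_tables={"carbohydrate": {"glc__D_c": 1.0}},
        monomer_masses={"glc__D_c": glc_mass},
        gam=gam, name="glucose only")


class TestBuildBOF:
    def test_single_component_coefficient(self):
        """100% glucose biomass drains 1000/180.16 = 5.551 mmol per gram."""
        bof = build_bof(glucose_only_composition(), glucose_catalogue())
        assert bof.stoichiometry["glc__D_c"] == pytest.approx(-5.5506,
                                                              abs=1e-3)
        assert bof.stoichiometry["biomass_c"] == 1.0

    def test_fractions_must_sum_to_one(self):
        comp = glucose_only_composition()
        comp.fractions["carbohydrate"] = 0.9
        with pytest.raises(ValueError, match="sum"):
            build_bof(comp, glucose_catalogue())

    def test_unknown_monomer_named_in_error(self):
        comp = glucose_only_composition()
        comp.monomer_tables["carbohydrate"] = {"mystery_c": 1.0}
        comp.monomer_masses["mystery_c"] = 100.0
        with pytest.raises(KeyError, match="mystery_c"):
            build_bof(comp, glucose_catalogue())

    def test_mass_closure_one_gram_per_unit_flux(self, bb12, bb46):
        """The compiled strain BOFs consume 1.000 g of monomer mass per
        unit flux (checked by build_bof; re-verified here from scratch)."""
        for model in (bb12, bb46):
            bof = model.reaction("BIOMASS")
            consumed = -sum(
                coef * formula_weight(model.metabolite(met).formula)
                for met, coef in bof.stoichiometry.items()
                if met != "biomass_c") / 1000.0
            assert consumed == pytest.approx(1.0, abs=1e-4)

    def test_spreadsheet_oracle_for_protein_drain(self, bb12):
        """Amino-acid coefficients equal the hand-spreadsheet values
        1000 * fraction * molefrac / weighted residue mass."""
        comp = strain_composition("BB-12")
        table = comp.monomer_tables["protein"]
        residue = sum(f * comp.monomer_masses[m] for m, f in table.items())
        bof = bb12.reaction("BIOMASS")
        for met, frac in table.items():
            expected = 1000.0 * comp.fractions["protein"] * frac / residue
            # glutamate and glycine also appear in the soluble pool
            soluble = comp.monomer_tables["soluble_pool"].get(met, 0.0)
            residue_sol = sum(
                f * comp.monomer_masses[m]
                for m, f in comp.monomer_tables["soluble_pool"].items())
            expected += (1000.0 * comp.fractions["soluble_pool"] * soluble
                         / residue_sol)
            assert -bof.stoichiometry[met] == pytest.approx(expected,
                                                            rel=1e-9)

    def test_coefficients_scale_linearly_with_fraction(self):
        cat = glucose_catalogue()
        cat["gly_c"] = Metabolite(id="gly_c",
                                  formula=parse_formula("C2H5NO2"))
        def comp(frac):
            return BiomassComposition(
                fractions={"carbohydrate": frac, "protein": 1 - frac},
                monomer_tables={"carbohydrate": {"glc__D_c": 1.0},
                                "protein": {"gly_c": 1.0}},
                monomer_masses={"glc__D_c": 180.16, "gly_c": 75.07},
                name="two-part")
        c1 = build_bof(comp(0.2), cat).stoichiometry["glc__D_c"]
        c2 = build_bof(comp(0.4), cat).stoichiometry["glc__D_c"]
        assert c2 == pytest.approx(2 * c1, rel=1e-12)

    def test_polyamine_free_biomass_grows_without_polyamines(self):
        """With putrescine/spermidine dropped from the soluble pool, growth
        no longer depends on their supply; with them restored it does."""
        curated = make_strain_model("BB-12")
        legacy = make_strain_model("BB-12", include_polyamines=True)
        medium = cdm_medium("sucrose")  # contains no polyamines
        grown, _ = apply_medium(curated, medium)
        assert solve_fba(grown, "BIOMASS").objective_value > 1e-3
        starved, _ = apply_medium(legacy, medium)
        assert solve_fba(starved, "BIOMASS").objective_value <= 1e-9


class TestSetGAM:
    def test_gam_zero_removes_atp_term(self, core_model):
        model = make_strain_model("BB-12")
        stripped = set_gam(model, 0.0)
        bof = stripped.reaction("BIOMASS")
        # RNA still drains some nucleotide species, but no hydrolysis pair
        assert bof.stoichiometry.get("adp_c", 0.0) == 0.0

    def test_atp_coefficient_scales_between_settings(self):
        model = make_strain_model("BB-12", gam=39.31)
        m20 = set_gam(model, 20.0)
        adp_39 = model.reaction("BIOMASS").stoichiometry["adp_c"]
        adp_20 = m20.reaction("BIOMASS").stoichiometry["adp_c"]
        assert adp_39 == pytest.approx(39.31)
        assert adp_20 == pytest.approx(20.0)
        assert adp_20 / adp_39 == pytest.approx(20.0 / 39.31)

    def test_idempotence(self):
        model = make_strain_model("BB-46")
        once = set_gam(model, 17.5)
        twice = set_gam(once, 17.5)
        assert once.reaction("BIOMASS").stoichiometry == \
            twice.reaction("BIOMASS").stoichiometry

    def test_negative_gam_rejected(self, bb12):
        with pytest.raises(ValueError):
            set_gam(bb12, -1.0)

    def test_non_gam_coefficients_untouched(self):
        model = make_strain_model("BB-12")
        before = model.reaction("BIOMASS").stoichiometry
        after = set_gam(model, 11.0).reaction("BIOMASS").stoichiometry
        skip = {"atp_c", "adp_c", "pi_c", "h2o_c", "h_c"}
        for met, coef in before.items():
            if met not in skip:
                assert after[met] == coef


class TestElementalSummary:
    def test_glucose_only_biomass_is_ch2o(self):
        bof = build_bof(glucose_only_composition(), glucose_catalogue())
        summary = elemental_summary(bof, glucose_catalogue())
        assert summary.formula["C"] == 1.0
        assert summary.formula["H"] == pytest.approx(2.0)
        assert summary.formula["O"] == pytest.approx(1.0)
        assert summary.molecular_weight == pytest.approx(180.16 / 6,
                                                         abs=0.01)

    def test_summary_invariant_to_gam(self):
        cat = glucose_catalogue()
        with_gam = build_bof(glucose_only_composition(gam=30.0), cat)
        without = build_bof(glucose_only_composition(gam=0.0), cat)
        a = elemental_summary(with_gam, cat)
        b = elemental_summary(without, cat)
        assert a.molecular_weight == pytest.approx(b.molecular_weight,
                                                   rel=1e-9)
        for el, n in b.formula.items():
            assert a.formula[el] == pytest.approx(n, rel=1e-9)

    def test_two_route_weight_equality(self, bb12, bb46):
        """Weight from the per-C-mol formula equals total consumed mass
        divided by carbon flow — two independent accounting routes."""
        for model in (bb12, bb46):
            bof = model.reaction("BIOMASS")
            summary = elemental_summary(bof, model.metabolites)
            carbon = -sum(
                coef * model.metabolite(met).formula.get("C", 0.0)
                for met, coef in bof.stoichiometry.items()
                if met != "biomass_c")
            mass = -sum(
                coef * formula_weight(model.metabolite(met).formula)
                for met, coef in bof.stoichiometry.items()
                if met != "biomass_c")
            assert summary.molecular_weight == pytest.approx(mass / carbon,
                                                             rel=1e-9)

    def test_strain_biomass_close_to_printed_composition(self, bb12):
        """The reconstructed biomass lands near the reported cell formula
        CH1.57 N0.23 O0.43 P0.01 (within the tolerance expected of the
        reconstructed cell-wall/ion remainder)."""
        summary = elemental_summary(bb12.reaction("BIOMASS"),
                                    bb12.metabolites)
        assert summary.formula["H"] == pytest.approx(1.57, abs=0.1)
        assert summary.formula["N"] == pytest.approx(0.23, abs=0.05)
        assert summary.formula["O"] == pytest.approx(0.43, abs=0.05)
        assert summary.formula["P"] == pytest.approx(0.01, abs=0.02)

    def test_missing_formula_is_an_error(self):
        cat = glucose_catalogue()
        bof = build_bof(glucose_only_composition(), cat)
        cat["glc__D_c"].formula = {}
        with pytest.raises(ValueError, match="formula"):
            elemental_summary(bof, cat)


def test_composition_yaml_round_trip(tmp_path):
    comp = strain_composition("BB-46", gam=20.0,
                              pseudo_masses={"glycogen_c": 162.14,
                                             "peptidoglycan_c": 980.0,
                                             "cps_c": 162.14,
                                             "lta_c": 170.0,
                                             "lipid_c": 640.0})
    path = tmp_path / "comp.yaml"
    save_composition(comp, path)
    back = load_composition(path)
    assert back.fractions == comp.fractions
    assert back.gam == comp.gam
    assert back.monomer_tables == comp.monomer_tables
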