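"""Contrast chemistry, volume mixing, and mixture attenuation."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from ugidose import xsdata
from ugidose.materials import (ContrastAgent, ElementalComposition,
                               EZ_PAQUE, MixtureSpec, OMNIPAQUE_140,
                               REFERENCE_MATERIALS, agent_composition,
                               compound_to_elements, load_material_library,
                               mass_attenuation, mix_by_volume,
                               molecular_weight, parse_molecular_formula,
                               save_material_library, solution_mass_fractions)


@pytest.mark.parametrize("formula,expected", [
    ("BaSO4", {"Ba": 1, "S": 1, "O": 4}),
    ("H2O", {"H": 2, "O": 1}),
    ("C19H26I3N3O9", {"C": 19, "H": 26, "I": 3, "N": 3, "O": 9}),
    ("C10H12CaN2Na2O8", {"C": 10, "H": 12, "Ca": 1, "N": 2, "Na": 2, "O": 8}),
])
def test_formula_parsing(formula, expected):
    assert parse_molecular_formula(formula) == expected


@pytest.mark.parametrize("bad", ["", "X2O", "h2o", "C19H26Zz3", "C-4", "2HO"])
def test_formula_parse_errors_name_position(bad):
    with pytest.raises(ValueError, match="position"):
        parse_molecular_formula(bad)


@pytest.mark.parametrize("formula,printed", [
    ("BaSO4", 233.3880),
    ("H2O", 18.0146),
    ("C19H26I3N3O9", 821.1238),
    ("C10H12CaN2Na2O8", 374.2676),
    ("C4H11NO3", 121.1338),
])
def test_molecular_weights_match_printed_values(formula, printed):
    mw = molecular_weight(parse_molecular_formula(formula))
    assert abs(mw - printed) / printed < 5e-4  # table-vintage tolerance


def test_single_atom_weight_is_atomic_weight():
    from ugidose.atomic import atomic_weight
    assert molecular_weight({"Ba": 1}) == atomic_weight("Ba")


class TestSolutionChemistry:
    def test_barium_sulfate_suspension_fraction(self):
        fr = solution_mass_fractions(EZ_PAQUE)
        assert fr["BaSO4"] == pytest.approx(0.4098, abs=1e-4)
        assert sum(fr.values()) == pytest.approx(1.0, abs=1e-12)

    def test_iohexol_solution_fractions(self):
        fr = solution_mass_fractions(OMNIPAQUE_140)
        assert fr["C19H26I3N3O9"] == pytest.approx(0.2595, abs=1e-4)
        assert fr["C10H12CaN2Na2O8"] == pytest.approx(0.0001)
        assert fr["C4H11NO3"] == pytest.approx(0.0010)
        assert fr["H2O"] == pytest.approx(0.7394, abs=1e-4)

    def test_zero_concentration_is_pure_water(self):
        agent = ContrastAgent("blank", (("H2O", 18.0146, 1.0),),
                              density=1.0, concentration=0.0)
        fr = solution_mass_fractions(agent)
        assert fr["H2O"] == pytest.approx(1.0)

    def test_impossible_solution_rejected(self):
        agent = ContrastAgent("bad", (("BaSO4", 233.388, 1.0),),
                              density=1.0, concentration=2.0)
        with pytest.raises(ValueError, match="exceeds"):
            solution_mass_fractions(agent)


class TestElementExpansion:
    def test_water_elements(self):
        comp = compound_to_elements({"H2O": 1.0})
        assert comp.fractions["H"] == pytest.approx(0.1119, abs=1e-3)
        assert comp.fractions["O"] == pytest.approx(0.8881, abs=1e-3)

    def test_barium_fraction_of_suspension(self):
        comp = agent_composition(EZ_PAQUE)
        # 0.4098 x 137.327/233.388
        assert comp.fractions["Ba"] == pytest.approx(0.2411, abs=3e-4)

    def test_single_element_compound(self):
        comp = compound_to_elements({"Al": 1.0})
        assert comp.fractions == {"Al": 1.0}


class TestVolumeMixing:
    def test_single_part_identity(self):
        lib = REFERENCE_MATERIALS
        out = mix_by_volume(MixtureSpec((("tongue", 1.0),)), lib)
        assert out.density == pytest.approx(lib["tongue"].density)
        for sym, w in lib["tongue"].fractions.items():
            assert out.fractions[sym] == pytest.approx(w, abs=1e-12)

    def test_equal_density_mean(self):
        a = ElementalComposition("a", 1.0, {"H": 1.0})
        b = ElementalComposition("b", 1.0, {"O": 1.0})
        out = mix_by_volume(MixtureSpec((("a", 0.5), ("b", 0.5))),
                            {"a": a, "b": b})
        assert out.fractions["H"] == pytest.approx(0.5)
        assert out.fractions["O"] == pytest.approx(0.5)

    def test_barium_mixture_hand_calculation(self):
        lib = REFERENCE_MATERIALS
        out = mix_by_volume(MixtureSpec((("ez_paque", 0.3), ("tongue", 0.7))),
                            lib)
        assert out.density == pytest.approx(0.3 * 1.4641 + 0.7 * 1.05,
                                            abs=1e-4)
        assert out.fractions["Ba"] == pytest.approx(0.0902, abs=5e-4)

    def test_mixing_is_associative(self):
        lib = dict(REFERENCE_MATERIALS)
        three_way = mix_by_volume(MixtureSpec(
            (("water", 0.2), ("tongue", 0.3), ("ez_paque", 0.5))), lib)
        lib["bc"] = mix_by_volume(MixtureSpec(
            (("tongue", 0.375), ("ez_paque", 0.625))), lib)
        nested = mix_by_volume(MixtureSpec(
            (("water", 0.2), ("bc", 0.8))), lib)
        assert nested.density == pytest.approx(three_way.density, abs=1e-9)
        for sym in three_way.fractions:
            assert nested.fractions[sym] == pytest.approx(
                three_way.fractions[sym], abs=1e-9)

    def test_bad_volume_fractions_rejected(self):
        with pytest.raises(ValueError, match="sum"):
            MixtureSpec((("a", 0.5), ("b", 0.4)))


@settings(derandomize=True, max_examples=25, deadline=None)
@given(vf=st.floats(0.05, 0.95),
       ids=st.sampled_from([("water", "ez_paque"), ("tongue", "omnipaque_140"),
                            ("gi_contents", "ez_paque")]))
def test_mixture_fractions_always_normalised(vf, ids):
    a, b = ids
    out = mix_by_volume(MixtureSpec(((a, vf), (b, round(1.0 - vf, 12)))),
                        REFERENCE_MATERIALS)
    assert sum(out.fractions.values()) == pytest.approx(1.0, abs=1e-9)
    assert out.density > 0


class TestMassAttenuation:
    def test_single_element_exact_at_grid_energy(self):
        al = REFERENCE_MATERIALS["aluminium"]
        mu, _ = mass_attenuation(al, 60.0)
        assert mu == pytest.approx(xsdata.mu_rho_element("Al", 60.0), rel=1e-12)

    def test_water_against_reference_table(self):
        water = REFERENCE_MATERIALS["water"]
        for i, e in enumerate(xsdata.REFERENCE_GRID):
            mu, mu_en = mass_attenuation(water, float(e))
            assert mu == pytest.approx(xsdata.WATER_REFERENCE["mu"][i],
                                       rel=0.04)
            assert mu_en == pytest.approx(xsdata.WATER_REFERENCE["mu_en"][i],
                                          rel=1e-6)

    def test_water_mu_strictly_decreasing_20_150(self):
        water = REFERENCE_MATERIALS["water"]
        e = np.arange(20.0, 151.0, 5.0)
        mu = np.array([mass_attenuation(water, x)[0] for x in e])
        assert np.all(np.diff(mu) < 0)

    def test_mixture_bounded_by_constituents(self):
        mix = mix_by_volume(MixtureSpec((("ez_paque", 0.3), ("tongue", 0.7))),
                            REFERENCE_MATERIALS)
        for e in (20.0, 40.0, 60.0, 100.0):
            mu, _ = mass_attenuation(mix, e)
            elems = [xsdata.mu_rho_element(s, e) for s in mix.fractions]
            assert min(elems) <= mu <= max(elems)

    @pytest.mark.parametrize("agent,organ", [
        ("ez_paque", "gi_contents"), ("omnipaque_140", "gi_contents"),
    ])
    def test_contrast_raises_attenuation_40_80(self, agent, organ):
        mix = mix_by_volume(
            MixtureSpec(((agent, 0.3), (organ, 0.7))), REFERENCE_MATERIALS)
        for e in np.arange(40.0, 81.0, 5.0):
            assert mass_attenuation(mix, e)[0] > \
                mass_attenuation(REFERENCE_MATERIALS[organ], e)[0]

    def test_out_of_range_energy_rejected(self):
        with pytest.raises(ValueError, match="range"):
            mass_attenuation(REFERENCE_MATERIALS["water"], 200.0)


def test_material_library_round_trip(tmp_path):
    lib = {k: REFERENCE_MATERIALS[k] for k in ("water", "ez_paque", "skeleton")}
    path = tmp_path / "materials.json"
    save_material_library(lib, path)
    back = load_material_library(path)
    for mid, mat in lib.items():
        assert back[mid].density == pytest.approx(mat.density, rel=1e-9)
        for sym, w in mat.fractions.items():
            assert back[mid].fractions[sym] == pytest.approx(w, rel=1e-8)
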