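"""Synthetic phantom morphometry, region structure, and contrast application."""

import numpy as np
import pytest

from ugidose.materials import MixtureSpec
from ugidose.phantom import (ContrastDistribution, REGION_MATERIALS,
                             VoxelPhantom, apply_contrast, build_phantom)
from ugidose.protocols import load_protocol

EXPECTED_REGIONS = {
    "tongue", "oesophagus", "stomach_wall", "stomach_contents", "si_wall",
    "si_contents", "colon", "spleen", "kidneys", "lungs", "heart_wall",
    "thymus", "thyroid", "skeleton", "breast", "ovaries", "bladder",
    "liver", "brain", "skin", "residual", "air",
}


class TestMorphometry:
    @pytest.mark.parametrize("fixture,height,mass", [
        ("newborn", 51.0, 3.5), ("one_year", 76.0, 10.0)])
    def test_reference_height_and_mass(self, fixture, height, mass, request):
        p = request.getfixturevalue(fixture)
        assert abs(p.height_cm - height) / height < 0.05
        assert abs(p.body_mass_kg() - mass) / mass < 0.10

    def test_all_expected_regions_present(self, newborn):
        masses = newborn.region_masses()
        for region in EXPECTED_REGIONS:
            assert region in masses
            if region != "air":
                assert masses[region] > 0

    def test_no_arm_region(self, newborn):
        assert not any("arm" in name.lower()
                       for name, _ in newborn.regions.values())

    @pytest.mark.parametrize("region,target_g", [
        ("brain", 380.0), ("liver", 130.0), ("lungs", 60.0),
        ("kidneys", 25.0), ("thymus", 13.0), ("spleen", 9.5),
    ])
    def test_major_newborn_organ_masses(self, newborn, region, target_g):
        m = newborn.region_masses()[region]
        assert abs(m - target_g) / target_g < 0.15

    def test_craniocaudal_ordering(self, newborn):
        order = ["bladder", "si_wall", "stomach_wall", "heart_wall",
                 "thyroid", "tongue", "brain"]
        z = [newborn.region_centroid_cm(r)[2] for r in order]
        assert z == sorted(z)

    def test_stomach_contents_strictly_enclosed(self, newborn):
        lab = newborn.labels
        wall = newborn.label_of("stomach_wall")
        contents = newborn.label_of("stomach_contents")
        mask = lab == contents
        for ax, shift in [(0, 1), (0, -1), (1, 1), (1, -1), (2, 1), (2, -1)]:
            nb = np.roll(lab, shift, axis=ax)[mask]
            assert np.all(np.isin(nb, [wall, contents]))

    def test_deterministic_construction(self):
        a = build_phantom("newborn", 4.0)
        b = build_phantom("newborn", 4.0)
        np.testing.assert_array_equal(a.labels, b.labels)

    def test_voxel_size_range_enforced(self):
        with pytest.raises(ValueError):
            build_phantom("newborn", 0.5)
        with pytest.raises(ValueError):
            build_phantom("newborn", 8.0)

    def test_unknown_age_rejected(self):
        with pytest.raises(ValueError):
            build_phantom("five_year", 2.0)


@pytest.fixture(scope="module")
def dist():
    return load_protocol("newborn", "normal").contrast_distribution()


class TestContrast:
    def test_non_contrast_field_unchanged(self, newborn_coarse, dist):
        out = apply_contrast(newborn_coarse, dist, "1N")
        assert out is newborn_coarse

    def test_field_6_recipes(self, newborn_coarse, dist):
        out = apply_contrast(newborn_coarse, dist, "6N")
        stomach = out.material_of_region("stomach_contents")
        assert stomach.density == pytest.approx(1.4641, abs=1e-3)
        assert stomach.fractions["Ba"] == pytest.approx(0.2411, abs=1e-3)
        si = out.material_of_region("si_contents")
        # 10% suspension / 90% contents by volume
        expected_rho = 0.1 * 1.4641 + 0.9 * 1.03
        assert si.density == pytest.approx(expected_rho, abs=1e-3)

    def test_abnormal_field_3_uses_iodine(self, newborn_coarse):
        dist = load_protocol("newborn", "abnormal").contrast_distribution()
        out = apply_contrast(newborn_coarse, dist, "3A")
        stomach = out.material_of_region("stomach_contents")
        assert "I" in stomach.fractions
        assert stomach.density == pytest.approx(1.1638, abs=1e-3)

    def test_labels_never_change(self, newborn_coarse, dist):
        out = apply_contrast(newborn_coarse, dist, "6N")
        assert out.labels is newborn_coarse.labels or \
            np.array_equal(out.labels, newborn_coarse.labels)

    def test_only_listed_regions_modified(self, newborn_coarse, dist):
        out = apply_contrast(newborn_coarse, dist, "6N")
        changed = {name for lab, (name, mid) in out.regions.items()
                   if mid != newborn_coarse.regions[lab][1]}
        assert changed == {"stomach_contents", "si_contents"}

    def test_mass_changes_only_through_density(self, newborn_coarse, dist):
        out = apply_contrast(newborn_coarse, dist, "6N")
        m0 = newborn_coarse.region_masses()
        m1 = out.region_masses()
        rho_ratio = 1.4641 / 1.03
        assert m1["stomach_contents"] / m0["stomach_contents"] == \
            pytest.approx(rho_ratio, rel=1e-9)
        assert m1["stomach_wall"] == pytest.approx(m0["stomach_wall"])

    def test_unknown_field_rejected(self, newborn_coarse, dist):
        with pytest.raises(KeyError):
            apply_contrast(newborn_coarse, dist, "42X")

    def test_disallowed_region_rejected(self):
        with pytest.raises(ValueError, match="may not receive"):
            ContrastDistribution(
                {"1N": {"liver": MixtureSpec((("ez_paque", 1.0),))}})


def test_export_round_trip(tmp_path, newborn_coarse):
    stem = tmp_path / "phantom"
    newborn_coarse.save(stem)
    back = VoxelPhantom.load(stem)
    np.testing.assert_array_equal(back.labels, newborn_coarse.labels)
    assert back.voxel_cm == newborn_coarse.voxel_cm
    assert back.regions == newborn_coarse.regions
    assert back.body_mass_kg() == pytest.approx(
        newborn_coarse.body_mass_kg(), rel=1e-9)


def test_region_material_map_is_complete():
    for name, mat in REGION_MATERIALS.items():
        assert isinstance(mat, str)
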