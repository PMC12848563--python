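"""Monte Carlo transport: free paths, kerma estimators, kernel agreement."""

import numpy as np
import pytest

from ugidose import xsdata
from ugidose.beam import BeamField
from ugidose.materials import REFERENCE_MATERIALS
from ugidose.phantom import VoxelPhantom
from ugidose.transport import (KEV_TO_J, TransportConfig,
                               air_kerma_per_history, kap_per_history,
                               material_mu_arrays, primary_transmission,
                               run_transport)


def pencil(window=0.05):
    return BeamField("PA", (window, window), np.zeros(3))


def water_mu(energy):
    e, mu_pe, mu_in, _ = material_mu_arrays([REFERENCE_MATERIALS["water"]])
    i = np.argmin(np.abs(e - energy))
    return mu_pe[0, i] + mu_in[0, i]


def air_mu(energy):
    e, mu_pe, mu_in, _ = material_mu_arrays([REFERENCE_MATERIALS["air"]])
    i = np.argmin(np.abs(e - energy))
    return mu_pe[0, i] + mu_in[0, i]


class TestWoodcockFreePaths:
    def test_slab_transmission_matches_beer_lambert(self, water_slab, mono60):
        cfg = TransportConfig(histories=100_000, batches=20, seed=7)
        t, se = primary_transmission(water_slab, pencil(), mono60, cfg)
        expected = np.exp(-water_mu(60.0) * 10.0 - air_mu(60.0) * 5.0)
        assert abs(t - expected) < 3.0 * se

    def test_determinism(self, water_slab, mono60):
        cfg = TransportConfig(histories=10_000, batches=4, seed=3)
        beam = BeamField("PA", (2.0, 2.0), np.zeros(3))
        a = run_transport(water_slab, beam, mono60, cfg)
        b = run_transport(water_slab, beam, mono60, cfg)
        np.testing.assert_array_equal(a.batch_doses, b.batch_doses)

    def test_doses_nonnegative_and_bounded(self, water_slab, mono60):
        cfg = TransportConfig(histories=20_000, batches=10, seed=5)
        beam = BeamField("PA", (2.0, 2.0), np.zeros(3))
        r = run_transport(water_slab, beam, mono60, cfg)
        assert all(d >= 0 for d in r.dose.values())
        # total deposited energy cannot exceed emitted energy
        masses = {"water": 20 * 10 * 20 * 1.0, "air": np.nan}
        edep_kev = r.dose["water"] * masses["water"] * 1e-3 / KEV_TO_J
        assert edep_kev <= 60.5


class TestAirKerma:
    def test_monoenergetic_closed_form(self, mono60):
        cfg = TransportConfig(histories=100_000, batches=20, seed=3)
        beam = pencil()
        k, se = air_kerma_per_history(beam, mono60, cfg)
        es = np.linspace(59.5, 60.5, 2001)
        mu_en = sum(w * xsdata.mu_rho_element(s, es, "mu_en")
                    for s, w in xsdata.AIR_COMPOSITION.items())
        expected = np.trapezoid(es * mu_en, es) * KEV_TO_J * 1e3 \
            / beam.field_area_at(20.0)
        assert abs(k - expected) < 3.0 * se + 1e-4 * expected

    def test_inverse_square_between_20_and_40(self, mono60):
        beam = pencil(1.0)
        cfg = TransportConfig(histories=50_000, batches=20, seed=9)
        k20, s20 = air_kerma_per_history(beam, mono60, cfg, 20.0)
        k40, s40 = air_kerma_per_history(beam, mono60, cfg, 40.0)
        assert abs(k20 / k40 - 4.0) < 3.0 * 4.0 * np.hypot(s20 / k20,
                                                           s40 / k40)

    def test_kap_distance_invariance(self, mono60):
        beam = pencil(2.0)
        cfg = TransportConfig(histories=50_000, batches=20, seed=11)
        kap20, s20 = kap_per_history(beam, mono60, cfg, 20.0)
        kap40, s40 = kap_per_history(beam, mono60, cfg, 40.0)
        assert abs(kap20 - kap40) < 3.0 * np.hypot(s20, s40) + 1e-6 * kap20

    def test_kap_doubles_with_window_area(self, mono60):
        cfg = TransportConfig(histories=50_000, batches=20, seed=13)
        k1, _ = kap_per_history(pencil(1.0), mono60, cfg)
        k2, s2 = kap_per_history(
            BeamField("PA", (2.0, 1.0), np.zeros(3)), mono60, cfg)
        assert k2 == pytest.approx(2.0 * k1, rel=1e-3)


class TestKernelAgreement:
    def test_woodcock_vs_raymarch_32cube(self, mono60):
        labels = np.zeros((32, 32, 32), dtype=np.uint16)
        labels[:, :, :] = 1
        ph = VoxelPhantom(
            labels=labels, voxel_cm=(0.5, 0.5, 0.5),
            origin_cm=(-8.0, -8.0, -8.0),
            regions={0: ("air", "air"), 1: ("body", "water")},
            materials={"air": REFERENCE_MATERIALS["air"],
                       "water": REFERENCE_MATERIALS["water"]},
            age_class="cube", height_cm=16.0)
        beam = BeamField("PA", (1.5, 1.5), np.zeros(3))
        r_w = run_transport(ph, beam, mono60,
                            TransportConfig(histories=150_000, batches=20,
                                            seed=101), "woodcock")
        r_r = run_transport(ph, beam, mono60,
                            TransportConfig(histories=150_000, batches=20,
                                            seed=50101), "raymarch")
        dw, ew = r_w.dose["body"], r_w.relative_error["body"]
        dr, er = r_r.dose["body"], r_r.relative_error["body"]
        z = (dw - dr) / np.hypot(dw * ew, dr * er)
        assert abs(z) < 3.0

    def test_unknown_kernel_rejected(self, water_slab, mono60):
        with pytest.raises(ValueError):
            run_transport(water_slab, pencil(), mono60,
                          TransportConfig(histories=100, batches=2, seed=1),
                          "diffusion")


def test_relative_error_shrinks_with_histories(water_slab, mono60):
    beam = BeamField("PA", (2.0, 2.0), np.zeros(3))
    res = []
    for n in (10_000, 40_000, 160_000):
        r = run_transport(water_slab, beam, mono60,
                          TransportConfig(histories=n, batches=20, seed=21))
        res.append(r.relative_error["water"])
    # expect roughly 1/sqrt(n): each 4x step should at least halve-ish
    assert res[0] > res[1] > res[2]
    assert res[0] / res[2] > 2.0


def test_config_validation():
    with pytest.raises(ValueError):
        TransportConfig(histories=10, batches=20)
    with pytest.raises(ValueError):
        TransportConfig(cutoff_kev=0.5)
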