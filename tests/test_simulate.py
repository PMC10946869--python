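"""Phantom construction, spectral rendering, PTCR/HCD populations,
line-scan acquisition."""

import numpy as np
import pytest

from tptcr import simulate as sim
from tptcr.ioncalc import Species, mz_from_mass
from tptcr.targeting import predict_ptcr_products

from conftest import assert_population_close


class TestPhantom:
    def test_control_has_no_complex_anywhere(self):
        ph = sim.make_phantom(scenario=sim.ScenarioConfig("control", seed=3))
        assert (ph.abundance_maps["FABP1+bezafibrate"] == 0).all()

    def test_dosed_time_points_differ_by_constant_factor(self):
        ph2 = sim.make_phantom(scenario=sim.ScenarioConfig("dosed_2h", seed=3))
        ph6 = sim.make_phantom(scenario=sim.ScenarioConfig("dosed_6h", seed=3))
        a2 = ph2.abundance_maps["FABP1+bezafibrate"]
        a6 = ph6.abundance_maps["FABP1+bezafibrate"]
        nz = a6 > 0
        assert nz.any()
        ratios = a2[nz] / a6[nz]
        assert np.allclose(ratios, ratios[0])
        assert ratios[0] > 1

    def test_vessel_pixels_have_globin_not_complex(self):
        ph = sim.make_phantom(scenario=sim.ScenarioConfig("dosed_2h", seed=3))
        ves = ph.region_mask == sim.REGION_VESSEL
        assert ves.any()
        assert (ph.abundance_maps["heme-alpha-globin"][ves] > 0).all()
        assert (ph.abundance_maps["FABP1+bezafibrate"][ves] == 0).all()
        bulk = ph.region_mask == sim.REGION_BULK
        assert (ph.abundance_maps["heme-alpha-globin"][bulk] == 0).all()

    def test_empty_panel_rejected(self):
        with pytest.raises(ValueError):
            sim.make_phantom(species_panel=[])

    def test_oversized_vessel_rejected(self):
        with pytest.raises(ValueError):
            sim.make_phantom(8, 8, vessel_geometry={
                "shape": "disk", "center": (4, 4), "radius": 10})

    def test_scenario_ordering_enforced(self):
        with pytest.raises(ValueError):
            sim.ScenarioConfig("dosed_2h", {"control": 0.0, "dosed_2h": 0.2,
                                            "dosed_6h": 0.5})


class TestRenderSpectrum:
    def test_zero_abundance_gives_no_centroids(self, model):
        spec = sim.render_spectrum({}, model, (1500, 2000), mode="centroid",
                                   seed=4)
        assert len(spec.mz) == 0

    def test_single_species_single_charge_gives_one_cluster(self, quiet_model):
        sp = Species("X", 14675.4, role="complex")
        m = sim.SpectralModel(
            noise_floor=1e-12, shot_noise_scale=0.0,
            charge_envelopes={"X": {8: 1.0}},
        )
        spec = sim.render_spectrum({sp: 100.0}, m, (1500, 2500),
                                   mode="centroid", seed=0)
        assert len(spec.mz) == 1
        assert spec.mz[0] == pytest.approx(mz_from_mass(14675.4, 8), abs=0.05)

    def test_sim_mode_detects_sub_threshold_species(self, model, quiet_model):
        """Accumulation rescues a species too weak for full-scan detection."""
        sp = Species("X", 14675.4, role="complex")
        mz0 = mz_from_mass(14675.4, 8)
        # below threshold: noise-free full-scan apex under the centroid cut
        clean = sim.render_spectrum({sp: 4.0}, quiet_model, (1500, 3000),
                                    mode="profile", seed=0)
        assert clean.intensity.max() < (model.centroid_snr_threshold
                                        * model.noise_floor)
        simmed = sim.render_spectrum({sp: 4.0}, model, (1800, 1870),
                                     mode="SIM", accumulation=100, seed=2)
        cen = sim._centroid(simmed.mz, simmed.intensity, model, {})
        assert any(abs(m - mz0) <= 0.5 for m in cen.mz)

    def test_invalid_range_and_accumulation(self, model):
        with pytest.raises(ValueError):
            sim.render_spectrum({}, model, (2000, 1500))
        with pytest.raises(ValueError):
            sim.render_spectrum({}, model, (1500, 2000), accumulation=0)


class TestApplyPtcr:
    def test_zero_extent_is_identity(self):
        pop = {(1835.43, 8): 10.0}
        assert sim.apply_ptcr(pop, 0.0, 2) == pop

    def test_geometric_weights(self):
        pop = sim.apply_ptcr({(1835.43, 8): 7.0}, 0.5, 2)
        by_charge = {z: ab for (_, z), ab in pop.items()}
        assert by_charge[8] == pytest.approx(4.0)
        assert by_charge[7] == pytest.approx(2.0)
        assert by_charge[6] == pytest.approx(1.0)

    def test_product_mz_follows_mass_conserving_ladder(self):
        pop = sim.apply_ptcr({(1835.43, 8): 1.0}, 0.3, 2)
        expected = {p.charge: p.mz
                    for p in predict_ptcr_products(1835.43, 8, [7, 6])}
        for (mz, z), _ in pop.items():
            if z < 8:
                assert mz == pytest.approx(expected[z], abs=1e-9)

    def test_population_conserved(self):
        rng = np.random.default_rng(0)
        pop = {(float(rng.uniform(1000, 2000)), int(z)): float(rng.uniform(1, 50))
               for z in (8, 7, 6, 5)}
        out = sim.apply_ptcr(pop, 0.7, 3)
        assert sum(out.values()) == pytest.approx(sum(pop.values()), abs=1e-9)

    def test_charge_floor_at_one(self):
        out = sim.apply_ptcr({(500.0, 1): 1.0}, 0.9, 3)
        assert list(out) == [(500.0, 1)]


class TestApplyHcd:
    def test_full_dissociation(self):
        pre = mz_from_mass(14675.4, 8)
        out = sim.apply_hcd({(pre, 8): 5.0}, 1.0)
        assert len(out) == 1
        ((mz, z), ab), = out.items()
        assert z == 8 and ab == pytest.approx(5.0)
        assert mz == pytest.approx(pre - 361.10809 / 8, abs=1e-4)

    def test_zero_efficiency_is_identity(self):
        pop = {(1835.43, 8): 5.0}
        assert sim.apply_hcd(pop, 0.0) == pop

    def test_partial_dissociation_splits_at_same_charge(self):
        pre = mz_from_mass(14675.4, 8)
        out = sim.apply_hcd({(pre, 8): 10.0}, 0.5)
        assert len(out) == 2
        mzs = sorted(mz for (mz, _z) in out)
        assert pre - mzs[0] == pytest.approx(361.10809 / 8, abs=1e-5)
        assert_population_close(
            {k: 5.0 for k in out}, out
        )

    def test_population_conserved(self):
        out = sim.apply_hcd({(1835.43, 8): 3.0, (1977.51, 8): 2.0}, 0.4)
        assert sum(out.values()) == pytest.approx(5.0, abs=1e-9)


class TestAcquisition:
    def test_raster_coordinates_row_major(self, model, target_table):
        ph = sim.make_phantom(10, 10,
                              scenario=sim.ScenarioConfig("dosed_2h", seed=5))
        ds = sim.acquire_line_scans(ph, model, target_table=target_table, seed=5)
        assert len(ds.spectra) == 100
        assert ds.coordinates[0] == (0, 0)
        assert ds.coordinates[9] == (9, 0)
        assert ds.coordinates[10] == (0, 1)

    def test_determinism_bit_identical(self, model, target_table):
        ph = sim.make_phantom(6, 6, scenario=sim.ScenarioConfig("dosed_2h", seed=9))
        ds1 = sim.acquire_line_scans(ph, model, target_table=target_table, seed=9)
        ds2 = sim.acquire_line_scans(ph, model, target_table=target_table, seed=9)
        for a, b in zip(ds1.spectra, ds2.spectra):
            assert np.array_equal(a.intensity, b.intensity)
            assert np.array_equal(a.mz, b.mz)

    def test_tptcr_pixels_carry_expected_products(self, dosed_dataset,
                                                  complex_entry, globin_entry,
                                                  quiet_model, target_table):
        phantom, _ = dosed_dataset
        # noise-free re-acquisition for unambiguous presence checks
        ds = sim.acquire_line_scans(phantom, quiet_model,
                                    target_table=target_table, seed=0)
        bulk_yx = tuple(np.argwhere(phantom.region_mask == sim.REGION_BULK)[0])
        ves_yx = tuple(np.argwhere(phantom.region_mask == sim.REGION_VESSEL)[0])

        def signal_at(spec, mz0):
            return spec.intensity[np.abs(spec.mz - mz0) <= 0.5].sum()

        bulk_spec = ds.spectrum_at(bulk_yx[1], bulk_yx[0])
        ves_spec = ds.spectrum_at(ves_yx[1], ves_yx[0])
        cplx7 = complex_entry.product_ions()[0].mz
        glob7 = globin_entry.product_ions()[0].mz
        assert signal_at(bulk_spec, cplx7) > 1.0
        assert signal_at(bulk_spec, glob7) < 1e-6
        assert signal_at(ves_spec, glob7) > 1.0
        assert signal_at(ves_spec, cplx7) < 1e-6

    def test_control_has_no_complex_products_anywhere(self, quiet_model,
                                                      target_table,
                                                      complex_entry):
        ph = sim.make_phantom(8, 8, scenario=sim.ScenarioConfig("control", seed=2))
        ds = sim.acquire_line_scans(ph, quiet_model, target_table=target_table,
                                    seed=2)
        cplx7 = complex_entry.product_ions()[0].mz
        for spec in ds.spectra:
            assert spec.intensity[np.abs(spec.mz - cplx7) <= 0.5].sum() < 1e-6


def test_snr_grows_as_sqrt_of_accumulation(model):
    sp = Species("X", 14675.4, role="complex")
    mz0 = mz_from_mass(14675.4, 8)

    def reps(acc, seed0):
        return [sim.render_spectrum({sp: 100.0}, model, (mz0 - 10, mz0 + 10),
                                    mode="SIM", accumulation=acc, seed=seed0 + r)
                for r in range(50)]

    ratio = (sim.estimate_snr(reps(100, 5010), mz0)
             / sim.estimate_snr(reps(1, 10), mz0))
    assert ratio == pytest.approx(10.0, rel=0.25)
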