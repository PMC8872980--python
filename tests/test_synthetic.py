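"""Generator ground truth, forward-model consistency and determinism."""

import numpy as np
import pytest

import kpuumap as km
from kpuumap.errors import ConfigurationError, DataValidationError
from kpuumap.synthetic import PARENCHYMA


class TestDefaultProfiles:
    def test_whole_section_kpuu_matches_published_values(self, profiles,
                                                         atlas, tissue):
        targets = {"risperidone": 0.10, "clozapine": 0.31,
                   "olanzapine": 0.82}
        for drug, target in targets.items():
            got = profiles[drug].whole_section_kpuu(atlas, tissue)
            assert got == pytest.approx(target, rel=1e-9)

    def test_risperidone_cortical_subregion_truths(self, risperidone):
        assert risperidone.kpuu_roi["MCx"] == pytest.approx(0.08)
        assert risperidone.kpuu_roi["Pir"] == pytest.approx(0.12)

    @pytest.mark.parametrize("drug,fold", [
        ("risperidone", 1.3), ("clozapine", 1.2), ("olanzapine", 1.5)])
    def test_insular_cortex_concentration_excess(self, profiles, atlas,
                                                 tissue, drug, fold):
        p = profiles[drug]
        whole = p.whole_section_concentration(atlas, tissue, "in_vivo")
        assert p.true_concentration("InCx", "in_vivo") / whole == \
            pytest.approx(fold, rel=1e-9)

    def test_white_matter_lower_in_both_conditions(self, profiles, atlas,
                                                   tissue):
        for p in profiles.values():
            for cond in ("in_vivo", "brain_slice"):
                whole = p.whole_section_concentration(atlas, tissue, cond)
                for wm in ("cc", "ec", "aca"):
                    assert p.true_concentration(wm, cond) < whole
                # corpus callosum carries the lowest exposure
                assert p.true_concentration("cc", cond) == min(
                    p.true_concentration(r, cond) for r in p.regions())

    def test_all_v_u_positive_finite(self, profiles):
        for p in profiles.values():
            for v in p.v_u_roi.values():
                assert np.isfinite(v) and v > 0

    def test_f_u_plasma_bounds_enforced(self, risperidone):
        with pytest.raises(DataValidationError):
            km.DrugProfile(name="x", c_u_plasma_ss=1.0, c_u_buffer_ss=1.0,
                           f_u_plasma=1.5)


class TestGenerateSection:
    def test_noiseless_forward_model_inversion(self, risperidone, atlas,
                                               zero_noise):
        ds = km.generate_section(risperidone, "in_vivo", atlas, zero_noise,
                                 seed=3)
        mass = ds.grid.pixel_tissue_mass()
        analyte = ds.channel("risperidone").intensities
        for region in ("MCx", "cc", "InCx"):
            mean_i = analyte[atlas[region]].mean()
            conc = mean_i / (risperidone.response_factor * mass)
            assert conc == pytest.approx(
                risperidone.true_concentration(region, "in_vivo"), rel=1e-12)

    def test_same_seed_bit_identical(self, risperidone, atlas):
        noise = km.NoiseModel()
        a = km.generate_section(risperidone, "in_vivo", atlas, noise, seed=11)
        b = km.generate_section(risperidone, "in_vivo", atlas, noise, seed=11)
        for ca, cb in zip(a.channels, b.channels):
            assert np.array_equal(ca.intensities, cb.intensities)
        c = km.generate_section(risperidone, "in_vivo", atlas, noise, seed=12)
        assert not np.array_equal(a.channels[0].intensities,
                                  c.channels[0].intensities)

    def test_invivo_over_slice_equals_kpuu_when_buffer_equals_plasma(
            self, risperidone, atlas):
        # V_u cancels algebraically in the paired forward model
        assert risperidone.c_u_buffer_ss == risperidone.c_u_plasma_ss
        for region in atlas.labels + [PARENCHYMA]:
            ratio = (risperidone.true_concentration(region, "in_vivo")
                     / risperidone.true_concentration(region, "brain_slice"))
            assert ratio == pytest.approx(risperidone.kpuu_roi[region],
                                          rel=1e-12)

    def test_control_sections_carry_only_background(self, risperidone,
                                                    atlas):
        noise = km.NoiseModel(pixel_cv=0.0, gain_amplitude=0.0,
                              is_spray_cv=0.0, background=5.0)
        ds = km.generate_section(risperidone, "control", atlas, noise,
                                 seed=1)
        analyte = ds.channel("risperidone").intensities
        assert np.allclose(analyte[ds.tissue_mask], 5.0)
        assert np.all(analyte[~ds.tissue_mask] == 0)

    def test_unknown_region_is_configuration_error(self, risperidone,
                                                   zero_noise, grid):
        profile = km.DrugProfile(
            name="risperidone", c_u_plasma_ss=1.0, c_u_buffer_ss=1.0,
            f_u_plasma=0.5, kpuu_roi={"MCx": 0.1}, v_u_roi={"MCx": 10.0})
        atlas = km.default_atlas(grid)  # contains regions beyond MCx
        with pytest.raises(ConfigurationError):
            km.generate_section(profile, "in_vivo", atlas, zero_noise,
                                seed=0)


class TestGenerateCalibration:
    def test_zero_noise_curve_recovers_response_model(self, risperidone,
                                                      atlas, zero_noise):
        control = km.generate_section(risperidone, "control", atlas,
                                      zero_noise, seed=5)
        layout = km.default_layout("risperidone")
        spotted = km.generate_calibration(control, risperidone, layout,
                                          zero_noise, seed=5, atlas=atlas)
        curve = km.calibration_from_section(spotted, layout, "risperidone")
        # slope = R × pixel_mass / (R_IS × m_IS), intercept 0
        expected = (risperidone.response_factor
                    * control.grid.pixel_tissue_mass()
                    / (risperidone.is_response_factor
                       * risperidone.is_amount_per_pixel))
        assert curve.slope == pytest.approx(expected, rel=1e-9)
        assert curve.intercept == pytest.approx(0.0, abs=1e-9)
        assert curve.r_squared == pytest.approx(1.0, abs=1e-9)

    def test_six_spots_detectable_above_background(self, risperidone,
                                                   atlas):
        noise = km.NoiseModel(pixel_cv=0.05, gain_amplitude=0.1,
                              is_spray_cv=0.02, background=2.0)
        control = km.generate_section(risperidone, "control", atlas, noise,
                                      seed=6)
        layout = km.default_layout("risperidone")
        assert len(layout.spots) == 6
        spotted = km.generate_calibration(control, risperidone, layout,
                                          noise, seed=6, atlas=atlas)
        analyte = spotted.channel("risperidone").intensities
        off_spot = spotted.tissue_mask & ~layout.combined_mask(spotted.grid)
        bg = analyte[off_spot].mean()
        for spot in layout.spots:
            assert analyte[spot.mask(spotted.grid)].mean() > 3 * bg

    def test_doubling_volume_doubles_spot_intensity(self, risperidone,
                                                    atlas, zero_noise):
        control = km.generate_section(risperidone, "control", atlas,
                                      zero_noise, seed=7)

        def spot_mean(volume):
            layout = km.CalibrationLayout(spots=[km.CalibrationSpot(
                center=(62, 44), standard_concentration=100.0,
                spotted_volume=volume)])
            s = km.generate_calibration(control, risperidone, layout,
                                        zero_noise, seed=7)
            return s.channel("risperidone").intensities[
                layout.spots[0].mask(control.grid)].mean()

        assert spot_mean(80.0) == pytest.approx(2 * spot_mean(40.0),
                                                rel=1e-12)

    def test_off_tissue_spot_rejected(self, risperidone, atlas, zero_noise):
        control = km.generate_section(risperidone, "control", atlas,
                                      zero_noise, seed=8)
        layout = km.CalibrationLayout(spots=[km.CalibrationSpot(
            center=(0, 0), standard_concentration=25.0)])
        with pytest.raises(DataValidationError):
            km.generate_calibration(control, risperidone, layout,
                                    zero_noise, seed=8)

    def test_spot_on_atlas_region_rejected(self, risperidone, atlas,
                                           zero_noise):
        control = km.generate_section(risperidone, "control", atlas,
                                      zero_noise, seed=9)
        layout = km.CalibrationLayout(spots=[km.CalibrationSpot(
            center=(34, 30), standard_concentration=25.0)])  # inside CPu
        with pytest.raises(ConfigurationError):
            km.generate_calibration(control, risperidone, layout,
                                    zero_noise, seed=9, atlas=atlas)


class TestGenerateBulk:
    def test_zero_cv_replicates_equal_truth(self, risperidone):
        for matrix, truth in (
                ("plasma_total", risperidone.c_tot_plasma_ss),
                ("buffer_unbound", risperidone.c_u_buffer_ss)):
            samples = km.generate_bulk(risperidone, matrix, 4, 0.0, seed=1)
            assert [s.value for s in samples] == pytest.approx([truth] * 4)

    def test_fu_one_means_total_equals_unbound(self):
        p = km.DrugProfile(name="x", c_u_plasma_ss=50.0, c_u_buffer_ss=50.0,
                           f_u_plasma=1.0)
        assert p.c_tot_plasma_ss == pytest.approx(p.c_u_plasma_ss)

    def test_sample_mean_within_monte_carlo_band(self, risperidone):
        n, cv = 6, 0.1
        samples = km.generate_bulk(risperidone, "buffer_unbound", n, cv,
                                   seed=42)
        truth = risperidone.c_u_buffer_ss
        mean = np.mean([s.value for s in samples])
        assert abs(mean - truth) / truth < 3 * cv / np.sqrt(n)


class TestNoiseModel:
    def test_gain_amplitude_bound(self):
        with pytest.raises(DataValidationError):
            km.NoiseModel(gain_amplitude=1.0)

    def test_negative_cv_rejected(self):
        with pytest.raises(DataValidationError):
            km.NoiseModel(pixel_cv=-0.1)
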