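"""IS normalization, tissue-equivalent conversion, calibration fitting and
region quantitation."""

import numpy as np
import pytest

import kpuumap as km
from kpuumap.errors import (
    ConfigurationError,
    DataValidationError,
    DegenerateInputError,
    InsufficientDataError,
)


class TestNormalizeToIs:
    def test_uniform_is_divides_analyte(self, small_section):
        norm = km.normalize_to_is(small_section, "drugX")
        tissue = small_section.tissue_mask
        expected = small_section.channel("drugX").intensities[tissue] / 50.0
        assert np.allclose(norm.values[tissue], expected)

    def test_shared_gain_cancels_exactly(self, small_section):
        gain = 1.0 + 0.4 * np.random.default_rng(0).random(
            small_section.grid.shape)
        scaled = km.SectionDataset(
            grid=small_section.grid,
            channels=[km.ChannelImage(c.analyte_id, c.role,
                                      c.intensities * gain, group=c.group)
                      for c in small_section.channels],
            tissue_mask=small_section.tissue_mask,
            condition=small_section.condition)
        a = km.normalize_to_is(small_section, "drugX")
        b = km.normalize_to_is(scaled, "drugX")
        assert np.allclose(a.values[a.valid], b.values[b.valid], rtol=1e-12)

    def test_generator_gain_cancellation(self, risperidone, atlas):
        """Normalized region means with gain amplitude 0.3 equal the
        zero-gain case (the property IS normalization exists for)."""
        flat = km.NoiseModel.zero()
        wavy = km.NoiseModel(pixel_cv=0.0, gain_amplitude=0.3,
                             is_spray_cv=0.0, background=0.0)
        a = km.generate_section(risperidone, "in_vivo", atlas, flat, seed=2)
        b = km.generate_section(risperidone, "in_vivo", atlas, wavy, seed=2)
        na = km.normalize_to_is(a, "risperidone")
        nb = km.normalize_to_is(b, "risperidone")
        for region in atlas.labels:
            ma, _ = na.mean_over(atlas[region])
            mb, _ = nb.mean_over(atlas[region])
            assert mb == pytest.approx(ma, abs=1e-12 * max(1.0, abs(ma)))

    def test_low_is_pixels_flagged_invalid(self, small_section):
        is_ch = small_section.internal_standard_for("drugX")
        is_ch.intensities[3, 3] = 1e-6  # far below 1% of median
        norm = km.normalize_to_is(small_section, "drugX")
        assert not norm.valid[3, 3]
        assert norm.values[3, 3] == 0.0

    def test_missing_is_channel(self, small_grid):
        ds = km.SectionDataset(
            grid=small_grid,
            channels=[km.ChannelImage("a", "analyte",
                                      np.ones(small_grid.shape))],
            tissue_mask=np.ones(small_grid.shape, bool),
            condition="control")
        with pytest.raises(ConfigurationError):
            km.normalize_to_is(ds, "a")


class TestSpotTissueEquivalent:
    def test_reproduces_lloq_worked_example(self, grid):
        # 25 ng/mL × 40 nL on a 1.0-mm (0.785 mm²) spot, 12 µm, 1.027 g/cm³
        got = km.spot_tissue_equivalent(25.0, 40.0, 0.785, grid)
        assert got == pytest.approx(103.0, rel=0.01)

    def test_linear_in_volume_and_concentration(self, grid):
        base = km.spot_tissue_equivalent(25.0, 40.0, 0.785, grid)
        assert km.spot_tissue_equivalent(25.0, 80.0, 0.785, grid) == \
            pytest.approx(2 * base, rel=1e-12)
        assert km.spot_tissue_equivalent(100.0, 40.0, 0.785, grid) == \
            pytest.approx(4 * base, rel=1e-12)

    def test_zero_area_rejected(self, grid):
        with pytest.raises(DataValidationError):
            km.spot_tissue_equivalent(25.0, 40.0, 0.0, grid)


def _wls_oracle(x, y, w):
    """Closed-form weighted normal equations for [intercept, slope] plus
    the intercept standard error."""
    X = np.column_stack([np.ones_like(x), x])
    W = np.diag(w)
    xtwx = X.T @ W @ X
    beta = np.linalg.solve(xtwx, X.T @ W @ y)
    resid = y - X @ beta
    dof = len(x) - 2
    s2 = float(resid @ W @ resid) / dof
    cov = s2 * np.linalg.inv(xtwx)
    return beta, float(np.sqrt(cov[0, 0]))


class TestFitCalibration:
    exact = [(25, 0.5), (50, 1.0), (100, 2.0), (250, 5.0), (500, 10.0),
             (1000, 20.0)]

    def test_exact_linear_data(self):
        curve = km.fit_calibration(self.exact)
        assert curve.slope == pytest.approx(0.02, rel=1e-9)
        assert curve.intercept == pytest.approx(0.0, abs=1e-9)
        assert curve.r_squared == pytest.approx(1.0, abs=1e-12)
        assert curve.accepted
        assert curve.lod == pytest.approx(0.0, abs=1e-6)
        assert curve.lloq == pytest.approx(25.0)

    @pytest.mark.parametrize("weighting", ["none", "inverse_x2"])
    def test_matches_normal_equations_oracle(self, weighting):
        rng = np.random.default_rng(5)
        x = np.array([25.0, 50.0, 100.0, 250.0, 500.0, 1000.0])
        y = 0.02 * x + 0.3 + rng.normal(0, 0.2, x.size)
        curve = km.fit_calibration(list(zip(x, y)), weighting=weighting)
        w = 1.0 / x**2 if weighting == "inverse_x2" else np.ones_like(x)
        (b0, b1), sigma = _wls_oracle(x, y, w)
        assert curve.intercept == pytest.approx(b0, rel=1e-10)
        assert curve.slope == pytest.approx(b1, rel=1e-10)
        assert curve.sigma_intercept == pytest.approx(sigma, rel=1e-10)
        assert curve.lod == pytest.approx(3.3 * sigma / b1, rel=1e-10)

    def test_too_few_points(self):
        with pytest.raises(InsufficientDataError):
            km.fit_calibration([(25, 0.5), (50, 1.0)])

    def test_negative_slope_rejected(self):
        curve = km.fit_calibration([(25, 5.0), (50, 4.0), (100, 3.0),
                                    (250, 2.0)])
        assert not curve.accepted
        assert "slope" in curve.rejection_reason

    def test_flat_noise_fails_f_test(self):
        rng = np.random.default_rng(0)
        pts = [(x, 1.0 + 1e-6 * rng.random()) for x in
               (25, 50, 100, 250, 500, 1000)]
        curve = km.fit_calibration(pts)
        assert not curve.accepted

    def test_weighted_mode_requires_r2(self):
        rng = np.random.default_rng(2)
        x = np.array([25.0, 50.0, 100.0, 250.0, 500.0, 1000.0])
        y = 0.02 * x + rng.normal(0, 2.0, x.size)  # heavy noise
        curve = km.fit_calibration(list(zip(x, y)), weighting="inverse_x2")
        if curve.r_squared < 0.99:
            assert not curve.accepted


class TestQuantifyRegion:
    def test_linear_readout(self):
        from kpuumap.quantitation import NormalizedImage
        curve = km.CalibrationCurve(slope=0.02, intercept=0.0,
                                    sigma_intercept=0.0, r_squared=1.0,
                                    f_test_p=0.0, lod=0.0, lloq=25.0)
        norm = NormalizedImage(values=np.full((4, 4), 2.0),
                               valid=np.ones((4, 4), bool))
        res = km.quantify_region(norm, np.ones((4, 4), bool), curve,
                                 region_label="MCx")
        assert res.concentration == pytest.approx(100.0)
        assert res.n_pixels == 16
        assert not res.below_lloq

    def test_intensity_below_intercept_clipped_and_flagged(self):
        from kpuumap.quantitation import NormalizedImage
        curve = km.CalibrationCurve(slope=0.02, intercept=1.0,
                                    sigma_intercept=0.0, r_squared=1.0,
                                    f_test_p=0.0, lod=0.0, lloq=25.0)
        norm = NormalizedImage(values=np.full((3, 3), 0.5),
                               valid=np.ones((3, 3), bool))
        res = km.quantify_region(norm, np.ones((3, 3), bool), curve)
        assert res.concentration == 0.0
        assert res.clipped and res.below_lloq

    def test_empty_mask_degenerate(self):
        from kpuumap.quantitation import NormalizedImage
        curve = km.CalibrationCurve(slope=1.0, intercept=0.0,
                                    sigma_intercept=0.0, r_squared=1.0,
                                    f_test_p=0.0, lod=0.0, lloq=1.0)
        norm = NormalizedImage(values=np.ones((3, 3)),
                               valid=np.ones((3, 3), bool))
        with pytest.raises(DegenerateInputError):
            km.quantify_region(norm, np.zeros((3, 3), bool), curve)

    def test_rejected_curve_refused(self):
        from kpuumap.quantitation import NormalizedImage
        curve = km.CalibrationCurve(slope=-1.0, intercept=0.0,
                                    sigma_intercept=0.0, r_squared=0.0,
                                    f_test_p=1.0, lod=np.inf, lloq=1.0,
                                    accepted=False,
                                    rejection_reason="non-positive slope")
        norm = NormalizedImage(values=np.ones((3, 3)),
                               valid=np.ones((3, 3), bool))
        with pytest.raises(ConfigurationError):
            km.quantify_region(norm, np.ones((3, 3), bool), curve)

    def test_monotone_in_intensity(self):
        from kpuumap.quantitation import NormalizedImage
        curve = km.fit_calibration(TestFitCalibration.exact)
        concs = []
        for level in (0.5, 1.0, 2.0, 5.0):
            norm = NormalizedImage(values=np.full((2, 2), level),
                                   valid=np.ones((2, 2), bool))
            concs.append(km.quantify_region(
                norm, np.ones((2, 2), bool), curve).concentration)
        assert all(a < b for a, b in zip(concs, concs[1:]))


class TestEndToEndIdentity:
    def test_zero_noise_quantitation_inverts_generator(self, risperidone,
                                                       atlas, zero_noise):
        """Full chain at zero noise recovers the generator's regional
        concentrations to ≤ 1e-6 relative, in every condition."""
        study = km.run_study(risperidone, noise=zero_noise, seed=4,
                             n_invivo=2, n_slice=2, bulk_cv=0.0)
        for table, cond in ((study.invivo_tables[0], "in_vivo"),
                            (study.slice_tables[0], "brain_slice")):
            for region in atlas.labels:
                truth = risperidone.true_concentration(region, cond)
                got = table[region].concentration
                assert got == pytest.approx(truth, rel=1e-6)

    def test_whole_section_is_pixel_weighted_mean_of_parts(
            self, risperidone, atlas, zero_noise):
        """Conservation: whole-section concentration equals the
        pixel-count-weighted mean over regions + unannotated tissue."""
        ds = km.generate_section(risperidone, "in_vivo", atlas, zero_noise,
                                 seed=13)
        curve = km.fit_calibration(TestFitCalibration.exact)
        norm = km.normalize_to_is(ds, "risperidone")
        whole = km.quantify_region(norm, ds.tissue_mask, curve)
        parts, weights = [], []
        for mask in list(atlas.regions.values()) + [
                ds.tissue_mask & ~atlas.union()]:
            r = km.quantify_region(norm, mask, curve)
            parts.append(r.concentration)
            weights.append(r.n_pixels)
        weighted = np.average(parts, weights=weights)
        assert whole.concentration == pytest.approx(weighted, rel=1e-9)


class TestQcEvaluate:
    def test_perfect_replicates_pass(self):
        qc = km.qc_evaluate([100.0, 100.0, 100.0], 100.0)
        assert qc.bias_percent == 0.0
        assert qc.rsd_percent == 0.0
        assert qc.passed

    def test_systematic_bias_fails_accuracy(self):
        qc = km.qc_evaluate([80.0, 80.0, 80.0], 100.0)
        assert qc.bias_percent == pytest.approx(-20.0)
        assert not qc.accuracy_pass
        assert not qc.passed

    def test_rsd_arithmetic(self):
        qc = km.qc_evaluate([90.0, 100.0, 110.0], 100.0)
        assert qc.rsd_percent == pytest.approx(10.0)

    def test_nominal_must_be_positive(self):
        with pytest.raises(DataValidationError):
            km.qc_evaluate([1.0, 2.0], 0.0)

    def test_needs_two_replicates(self):
        with pytest.raises(InsufficientDataError):
            km.qc_evaluate([100.0], 100.0)
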