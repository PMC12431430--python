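"""White-standard referencing, normalization, peak alignment, CSV dialect."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from leafphong.phong_core import DomainError, PhongParameters, URIDFCurve, eval_bridf
from leafphong.preprocess import (
    AlignmentError,
    GonioMeasurement,
    NormalizationError,
    RadianceRecord,
    align_peak,
    design_grid,
    normalize_uridf,
    peak_location,
    read_measurement_csv,
    reference_to_white_standard,
    write_measurement_csv,
)
from leafphong.synthetic_data import default_cucumber_like_profile, generate_measurement


class TestWhiteStandardReferencing:
    def test_perfect_standard_at_normal(self):
        rec = RadianceRecord(1.0, 1.0, 0.0, 0.0, 550.0)
        assert reference_to_white_standard(rec) == pytest.approx(1 / np.pi, rel=1e-12)

    def test_oblique_incidence(self):
        rec = RadianceRecord(1.0, 1.0, 40.0, 0.0, 550.0)
        expected = 1.0 / (np.pi * np.cos(np.radians(40.0)))
        assert reference_to_white_standard(rec) == pytest.approx(expected, rel=1e-12)
        assert reference_to_white_standard(rec) == pytest.approx(0.4156, abs=1e-4)

    def test_dark_sample(self):
        assert reference_to_white_standard(RadianceRecord(0.0, 1.0, 40.0, 20.0, 550.0)) == 0.0

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(lp=st.floats(0.0, 10.0), scale=st.floats(0.1, 5.0))
    def test_linear_in_probe_radiance(self, lp, scale):
        base = reference_to_white_standard(RadianceRecord(lp, 2.0, 40.0, 30.0, 550.0))
        scaled = reference_to_white_standard(
            RadianceRecord(lp * scale, 2.0, 40.0, 30.0, 550.0)
        )
        assert scaled == pytest.approx(base * scale, rel=1e-9, abs=1e-15)

    def test_rejects_nonpositive_standard(self):
        with pytest.raises(DomainError):
            RadianceRecord(1.0, 0.0, 40.0, 0.0, 550.0)

    def test_rejects_grazing_incidence(self):
        with pytest.raises(DomainError):
            reference_to_white_standard(RadianceRecord(1.0, 1.0, 90.0, 0.0, 550.0))


class TestDesignGrid:
    def test_main_grid_excludes_near_normal_band(self):
        grid = design_grid(40.0)
        assert grid[0] == -75.0 and grid[-1] == 75.0
        assert 0.0 in grid
        assert not np.any((np.abs(grid) < 13.0) & (grid != 0.0))
        assert np.all(np.diff(grid[grid >= 15.0]) == 5.0)

    def test_validation_grid_is_coarser(self):
        grid = design_grid(60.0)
        assert grid[0] == -70.0 and grid[-1] == 70.0
        assert np.all(np.diff(grid[grid >= 20.0]) == 10.0)

    def test_measurement_rejects_points_in_excluded_band(self):
        meas = GonioMeasurement()
        bad = URIDFCurve(40.0, np.array([-10.0, 0.0, 10.0]), np.ones(3), 630.0)
        with pytest.raises(ValueError):
            meas.add(bad)


class TestNormalization:
    def test_constant_curve_density(self):
        grid = np.linspace(-75.0, 75.0, 31)
        curve = URIDFCurve(40.0, grid, np.full(31, 5.0), 630.0)
        out = normalize_uridf(curve)
        expected = 1.0 / np.radians(150.0)
        np.testing.assert_allclose(out.values, expected, rtol=1e-12)
        assert out.values[0] == pytest.approx(0.3820, abs=1e-4)

    def test_idempotent_and_scale_invariant(self, curve_factory):
        curve = curve_factory(PhongParameters(0.1, 0.05, 0.6), 40.0)
        once = normalize_uridf(curve)
        integral = np.trapezoid(once.values, np.radians(once.theta_r))
        assert integral == pytest.approx(1.0, abs=1e-9)
        twice = normalize_uridf(once)
        np.testing.assert_allclose(twice.values, once.values, rtol=1e-12)
        scaled = curve.copy()
        scaled.values = curve.values * 7.0
        np.testing.assert_allclose(
            normalize_uridf(scaled).values, once.values, rtol=1e-12
        )

    def test_all_zero_curve_rejected(self):
        curve = URIDFCurve(40.0, np.array([-20.0, 0.0, 20.0]), np.zeros(3), 630.0)
        with pytest.raises(NormalizationError):
            normalize_uridf(curve)


class TestPeakAlignment:
    def test_aligned_dataset_passes_through(self):
        profile = default_cucumber_like_profile()
        profile.noise_cv = 0.0
        profile.hemi_noise_cv = 0.0
        meas, _, truth = generate_measurement(profile, (40.0,))
        dense = np.linspace(-75.0, 75.0, 601)
        reference = eval_bridf(truth.at(630.0), 40.0, dense)
        aligned, offset = align_peak(meas, reference)
        assert offset == pytest.approx(0.0, abs=0.3)
        before = meas.curve(550.0, 40.0)
        after = aligned.curve(550.0, 40.0)
        common = np.intersect1d(before.theta_r, after.theta_r)
        b = before.values[np.isin(before.theta_r, common)]
        a = after.values[np.isin(after.theta_r, common)]
        np.testing.assert_allclose(a, b, rtol=0.05)

    @pytest.mark.parametrize("injected", [2.0, 4.0])
    def test_recovers_injected_misalignment(self, injected):
        """An angular tilt of the sample is recovered within half a degree."""
        profile = default_cucumber_like_profile()
        profile.noise_cv = 0.0
        profile.hemi_noise_cv = 0.0
        profile.misalignment = injected
        meas, _, truth = generate_measurement(profile, (40.0,))
        dense = np.linspace(-75.0, 75.0, 601)
        reference = eval_bridf(truth.at(630.0), 40.0, dense)
        _, offset = align_peak(meas, reference)
        assert offset == pytest.approx(injected, abs=0.5)

    def test_double_alignment_is_stable(self):
        profile = default_cucumber_like_profile()
        profile.noise_cv = 0.0
        profile.hemi_noise_cv = 0.0
        profile.misalignment = 3.0
        meas, _, truth = generate_measurement(profile, (40.0,))
        dense = np.linspace(-75.0, 75.0, 601)
        reference = eval_bridf(truth.at(630.0), 40.0, dense)
        aligned, _ = align_peak(meas, reference)
        _, second = align_peak(aligned, reference)
        assert second == pytest.approx(0.0, abs=0.5)

    def test_boundary_peak_rejected(self):
        grid = np.array([-70.0, -30.0, 0.0, 30.0, 70.0])
        rising = URIDFCurve(40.0, grid, np.array([0.1, 0.2, 0.3, 0.4, 0.5]), 630.0)
        with pytest.raises(AlignmentError):
            peak_location(rising)

    def test_missing_reference_wavelength(self):
        meas = GonioMeasurement()
        grid = np.array([-30.0, 0.0, 30.0])
        meas.add(URIDFCurve(40.0, grid, np.array([0.1, 0.3, 0.2]), 550.0))
        reference = URIDFCurve(40.0, grid, np.array([0.1, 0.3, 0.2]), 630.0)
        with pytest.raises(AlignmentError):
            align_peak(meas, reference)


class TestCsvRoundTrip:
    def test_round_trip_preserves_curves(self, tmp_path):
        profile = default_cucumber_like_profile()
        meas, _, _ = generate_measurement(profile, (30.0, 40.0))
        path = tmp_path / "meas.csv"
        write_measurement_csv(meas, path)
        back = read_measurement_csv(path)
        assert set(back.curves) == set(meas.curves)
        for key in meas.curves:
            np.testing.assert_allclose(
                back.curves[key].values, meas.curves[key].values, rtol=1e-9
            )

    def test_missing_columns_rejected(self, tmp_path):
        path = tmp_path / "bad.csv"
        path.write_text("a,b\n1,2\n")
        with pytest.raises(ValueError):
            read_measurement_csv(path)
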