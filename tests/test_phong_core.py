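"""Analytic reflectance model: closed forms, peak geometry, energy."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from leafphong.phong_core import (
    DomainError,
    PhongParameters,
    SpectralPhongSet,
    URIDFCurve,
    analytic_hemispherical_reflectance,
    eval_bridf,
    shininess_to_exponent,
    specular_proportion,
)


class TestParameterValidation:
    def test_rejects_energy_gain(self):
        with pytest.raises(DomainError):
            PhongParameters(0.6, 0.3, 0.5, 0.2)

    @pytest.mark.parametrize("bad", [dict(d=-0.1, s=0.1, g=0.5),
                                     dict(d=0.1, s=-0.1, g=0.5),
                                     dict(d=0.1, s=0.1, g=1.5),
                                     dict(d=0.1, s=0.1, g=0.5, t=-0.2)])
    def test_rejects_invalid_fields(self, bad):
        with pytest.raises(DomainError):
            PhongParameters(**bad)

    def test_spectral_set_requires_matching_lengths(self):
        p = PhongParameters(0.1, 0.1, 0.5)
        with pytest.raises(ValueError):
            SpectralPhongSet(np.array([440.0, 450.0]), [p])

    def test_curve_rejects_decreasing_grid(self):
        with pytest.raises(ValueError):
            URIDFCurve(40.0, [10.0, 5.0], [1.0, 1.0], 630.0)


class TestShininessMap:
    @pytest.mark.parametrize("g,n", [(0.0, 1.0), (0.5, 10.0), (0.6, 10.0**1.2)])
    def test_map_values(self, g, n):
        assert shininess_to_exponent(g) == pytest.approx(n, rel=1e-12)

    def test_strictly_increasing(self):
        gs = np.linspace(0.0, 0.94, 20)
        ns = [shininess_to_exponent(g) for g in gs]
        assert np.all(np.diff(ns) > 0)

    @pytest.mark.parametrize("g", [-0.1, 1.0, 1.2])
    def test_domain(self, g):
        with pytest.raises(DomainError):
            shininess_to_exponent(g)


class TestBridf:
    def test_lambertian_closed_form(self):
        """With s=0 the URIDF is exactly (d/pi)*cos(theta_r) everywhere."""
        grid = np.linspace(-85.0, 85.0, 101)
        curve = eval_bridf(PhongParameters(0.2, 0.0, 0.3), 40.0, grid)
        assert curve.values == pytest.approx(
            0.2 / np.pi * np.cos(np.radians(grid)), rel=1e-12
        )
        assert curve.values[np.argmin(np.abs(grid))] == pytest.approx(0.06366, abs=1e-5)

    def test_angle_domain(self):
        with pytest.raises(DomainError):
            eval_bridf(PhongParameters(0.2, 0.0, 0.3), 90.0, [0.0])
        with pytest.raises(DomainError):
            eval_bridf(PhongParameters(0.2, 0.0, 0.3), 40.0, [91.0])

    def test_specular_peak_displaced_toward_normal(self):
        """At 40 degrees incidence the cosine weighting shifts the peak ~-3."""
        grid = np.linspace(-85.0, 85.0, 6801)
        curve = eval_bridf(PhongParameters(0.0, 0.1, 0.6), 40.0, grid)
        peak = grid[np.argmax(curve.values)]
        assert peak == pytest.approx(37.0, abs=0.5)

    def test_peak_satisfies_stationary_point_equation(self):
        """In-plane argmax obeys tan(theta_r - theta_i) = -tan(theta_r)/n."""
        grid = np.linspace(-89.0, 89.0, 35601)
        for theta_i in (20.0, 40.0, 60.0):
            curve = eval_bridf(PhongParameters(0.0, 0.1, 0.6), theta_i, grid)
            peak = np.radians(grid[np.argmax(curve.values)])
            n = shininess_to_exponent(0.6)
            lhs = np.tan(peak - np.radians(theta_i))
            rhs = -np.tan(peak) / n
            assert lhs == pytest.approx(rhs, abs=2e-3)

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(
        d=st.floats(0.01, 0.4), s=st.floats(0.01, 0.3), g=st.floats(0.0, 0.9),
        scale=st.floats(0.1, 2.0),
    )
    def test_linear_in_d_and_s(self, d, s, g, scale):
        grid = np.linspace(-75.0, 75.0, 31)
        base_d = eval_bridf(PhongParameters(d, 0.0, g), 40.0, grid).values
        base_s = eval_bridf(PhongParameters(0.0, s, g), 40.0, grid).values
        combo = eval_bridf(PhongParameters(d, s, g), 40.0, grid).values
        np.testing.assert_allclose(combo, base_d + base_s, rtol=1e-10)
        if d * scale + s * scale <= 1.0:
            scaled = eval_bridf(
                PhongParameters(d * scale, s * scale, g), 40.0, grid
            ).values
            np.testing.assert_allclose(scaled, combo * scale, rtol=1e-10)


class TestHemisphericalReflectance:
    def test_lambertian_conserves_energy(self):
        for ti in (0.0, 30.0, 60.0, 85.0):
            assert analytic_hemispherical_reflectance(
                PhongParameters(0.2, 0.0, 0.5), ti
            ) == pytest.approx(0.2, abs=1e-12)

    def test_full_lobe_at_normal_incidence(self):
        r = analytic_hemispherical_reflectance(PhongParameters(0.0, 0.1, 0.6), 0.0)
        assert r == pytest.approx(0.1, abs=1e-4)

    def test_grazing_truncation_loses_energy(self):
        r = analytic_hemispherical_reflectance(PhongParameters(0.0, 0.1, 0.6), 85.0)
        assert r < 0.1

    def test_non_increasing_in_incidence(self):
        p = PhongParameters(0.1, 0.1, 0.7)
        rs = [analytic_hemispherical_reflectance(p, ti) for ti in range(0, 89, 5)]
        assert np.all(np.diff(rs) <= 1e-12)
        assert rs[0] == pytest.approx(0.2, abs=1e-4)

    def test_bounded_by_total_weight(self):
        p = PhongParameters(0.1, 0.15, 0.4)
        for ti in (10.0, 50.0, 80.0):
            assert 0.0 <= analytic_hemispherical_reflectance(p, ti) <= 0.25 + 1e-12

    def test_consistent_with_hemispherical_integral_of_bridf(self):
        """2-D quadrature of the full off-plane URIDF reproduces d + s*P."""
        from leafphong.phong_core import (
            lobe_fraction_above_horizon,
            shininess_to_exponent,
            weighted_lobe_normalizer,
        )
        d, s, g, ti = 0.1, 0.08, 0.6, 40.0
        n = shininess_to_exponent(g)
        p_above = lobe_fraction_above_horizon(ti, n)
        z = weighted_lobe_normalizer(ti, n)
        # integrate diffuse + specular intensity over the upper hemisphere
        theta = np.linspace(0.0, np.pi / 2, 400)
        phi = np.linspace(0.0, 2 * np.pi, 800)
        tt, pp = np.meshgrid(theta, phi, indexing="ij")
        axis = np.array([np.sin(np.radians(ti)), 0.0, np.cos(np.radians(ti))])
        dirs = np.stack(
            [np.sin(tt) * np.cos(pp), np.sin(tt) * np.sin(pp), np.cos(tt)], -1
        )
        cos_alpha = np.clip(dirs @ axis, 0.0, None)
        intensity = d / np.pi * np.cos(tt) + s * p_above / z * cos_alpha**n * np.cos(tt)
        integral = np.trapezoid(
            np.trapezoid(intensity * np.sin(tt), phi, axis=1), theta
        )
        expected = analytic_hemispherical_reflectance(PhongParameters(d, s, g), ti)
        assert integral == pytest.approx(expected, rel=1e-3)


class TestSpecularProportion:
    def test_benchmark_component_pair(self):
        assert specular_proportion(PhongParameters(0.14, 0.06, 0.6)) == pytest.approx(
            0.3, abs=1e-12
        )

    def test_limits(self):
        assert specular_proportion(PhongParameters(0.2, 0.0, 0.5)) == 0.0
        assert specular_proportion(PhongParameters(0.2, 0.2, 0.5)) == 0.5

    def test_undefined_for_black_surface(self):
        with pytest.raises(DomainError):
            specular_proportion(PhongParameters(0.0, 0.0, 0.5))
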