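"""Synthetic gonioreflectometer datasets with known ground truth.

Emulates the goniometric measurement campaign on a cucumber-like leaf so
every pipeline stage can be exercised without instrument data: per-
wavelength Phong parameters with chlorophyll-type spectral structure
(diffuse minima near the 450 and 670 nm absorption bands, maxima in the
green and far-red), curves sampled on the instrument's angular design grids
(±75° in 5° steps at the 40° fit angle, ±70° in 10° steps at the 30°/60°
validation angles, the band (−13°, 13°) unmeasured except 0°), positive
multiplicative measurement noise, a small optional angular misalignment of
the sample, and integrating-sphere spectra with their own noise level.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from . import phong_core
from .fit_pipeline import HemisphericalOptics
from .phong_core import PhongParameters, SpectralPhongSet
from .preprocess import GonioMeasurement, design_grid

__all__ = [
    "SyntheticLeafProfile",
    "default_cucumber_like_profile",
    "generate_measurement",
    "replicate_profiles",
]


@dataclass
class SyntheticLeafProfile:
    """Ground-truth spectral surface description of a synthetic leaf."""

    wavelengths: np.ndarray
    d_profile: np.ndarray
    s_profile: np.ndarray
    g: float = 0.6
    tau_profile: np.ndarray = field(default_factory=lambda: np.array([]))
    noise_cv: float = 0.01  # multiplicative noise on URIDF values
    hemi_noise_cv: float = 0.005  # noise on integrating-sphere spectra
    misalignment: float = 0.0  # degrees, sample tilt
    seed: int = 0

    def __post_init__(self) -> None:
        self.wavelengths = np.asarray(self.wavelengths, dtype=float)
        self.d_profile = np.asarray(self.d_profile, dtype=float)
        self.s_profile = np.asarray(self.s_profile, dtype=float)
        self.tau_profile = np.asarray(self.tau_profile, dtype=float)
        if self.tau_profile.size == 0:
            self.tau_profile = np.zeros_like(self.d_profile)
        if not (
            self.wavelengths.size
            == self.d_profile.size
            == self.s_profile.size
            == self.tau_profile.size
        ):
            raise ValueError("spectral profiles must share the wavelength grid")
        if self.noise_cv < 0 or self.hemi_noise_cv < 0:
            raise ValueError("noise coefficients must be non-negative")
        total = self.d_profile + self.s_profile + self.tau_profile
        if np.any(total > 1.0 + 1e-9):
            raise ValueError("infeasible profile: d + s + t exceeds 1")

    def truth(self, surface_label: str = "synthetic") -> SpectralPhongSet:
        params = [
            PhongParameters(d, s, self.g, t)
            for d, s, t in zip(self.d_profile, self.s_profile, self.tau_profile)
        ]
        return SpectralPhongSet(self.wavelengths, params, surface_label)


def _gauss(x: np.ndarray, center: float, width: float) -> np.ndarray:
    return np.exp(-(((x - center) / width) ** 2))


def _sigmoid(x: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-x))


def default_cucumber_like_profile(
    step: float = 10.0, seed: int = 0
) -> SyntheticLeafProfile:
    """Profile emulating an abaxial cucumber leaf surface.

    The diffuse spectrum has chlorophyll absorption minima near 450 and
    670 nm, a green maximum near 550 nm and a strong far-red rise beyond
    700 nm.  The specular proportion s/(d+s) is anti-correlated with the
    diffuse spectrum: 0.2–0.4 in the blue and red bands, 0.1–0.2 in the
    green, modest again in the far-red.
    """
    wl = np.arange(440.0, 740.0 + 1e-9, step)
    d = 0.05 + 0.07 * _gauss(wl, 550.0, 45.0) + 0.25 * _sigmoid((wl - 705.0) / 8.0)
    ps = (
        0.30
        - 0.15 * _gauss(wl, 550.0, 50.0)
        - 0.10 * _sigmoid((wl - 705.0) / 8.0)
    )
    s = d * ps / (1.0 - ps)
    tau = 1.2 * d
    return SyntheticLeafProfile(wl, d, s, g=0.6, tau_profile=tau, seed=seed)


def generate_measurement(
    profile: SyntheticLeafProfile,
    theta_i_set: tuple[float, ...] = (30.0, 40.0, 60.0),
) -> tuple[GonioMeasurement, HemisphericalOptics, SpectralPhongSet]:
    """Generate a goniometric dataset, integrating-sphere spectra and truth.

    Curves are the analytic model evaluated on the design grid for each
    incidence angle, shifted by the profile's misalignment and multiplied by
    lognormal noise of the stated coefficient of variation (mean one).
    Hemispherical values come from the analytic reflectance oracle at the
    40° fit angle.  Everything is reproducible from ``profile.seed``.
    """
    rng = np.random.default_rng(profile.seed)
    truth = profile.truth()
    meas = GonioMeasurement({}, surface="synthetic")

    def noisy(values: np.ndarray, cv: float) -> np.ndarray:
        if cv <= 0:
            return values
        sigma = np.sqrt(np.log1p(cv**2))
        return values * rng.lognormal(-0.5 * sigma**2, sigma, size=values.shape)

    for j, wl in enumerate(profile.wavelengths):
        params = truth.params[j]
        for ti in theta_i_set:
            grid = design_grid(ti)
            ideal = phong_core.eval_bridf(
                params, ti, grid - profile.misalignment, wavelength=wl
            )
            values = noisy(ideal.values, profile.noise_cv)
            curve = phong_core.URIDFCurve(ti, grid, values, wl, role="measured")
            meas.add(curve)

    rho = np.array(
        [
            phong_core.analytic_hemispherical_reflectance(p, 40.0)
            for p in truth.params
        ]
    )
    tau = profile.tau_profile.copy()
    rho = noisy(rho, profile.hemi_noise_cv)
    tau = noisy(tau, profile.hemi_noise_cv)
    hemi = HemisphericalOptics(profile.wavelengths, rho, tau)
    return meas, hemi, truth


def replicate_profiles(
    profile: SyntheticLeafProfile, n_leaves: int = 5, seed: int = 0
) -> list[SyntheticLeafProfile]:
    """Perturbed copies of a profile emulating five leaves (one per order).

    Diffuse and specular spectra are scaled by independent lognormal factors
    (5 % and 8 % CV) and the shininess is jittered slightly; each replicate
    carries its own data seed.
    """
    rng = np.random.default_rng(seed)
    out = []
    for k in range(n_leaves):
        d_scale = rng.lognormal(0.0, 0.05)
        s_scale = rng.lognormal(0.0, 0.08)
        g_jitter = rng.uniform(-0.02, 0.02)
        d = profile.d_profile * d_scale
        s = profile.s_profile * s_scale
        # keep the perturbed profile inside the energy simplex
        total = d + s + profile.tau_profile
        over = total.max()
        if over > 1.0:
            d, s = d / over, s / over
        out.append(
            replace(
                profile,
                d_profile=d,
                s_profile=s,
                g=float(np.clip(profile.g + g_jitter, 0.0, 0.95)),
                seed=int(rng.integers(0, 2**31 - 1)),
            )
        )
    return out
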