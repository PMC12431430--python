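"""Analytic Phong/Blinn reflectance model for leaf surfaces.

The surface is described by four per-wavelength weights: a diffuse
(Lambertian) reflectance ``d``, a specular reflectance ``s`` concentrated in
a lobe about the mirror direction, a shininess ``g`` in ``[0, 1]`` that
controls the lobe sharpness, and a diffuse transparency ``t``.  ``g`` is a
normalized stand-in for the classical Phong exponent ``n``; the default map
is ``n = 10**(2 g)`` so that ``g = 0.6`` gives ``n ≈ 16`` — a lobe whose
cosine-weighted peak is displaced from the mirror direction by roughly
−1.3°, −3° and −6° at incidence angles of 20°, 40° and 60°, the magnitudes
observed with goniometric leaf measurements.

Curves are expressed as the URIDF — the reflected-intensity distribution
over the reflection angle θr at fixed incidence θi, i.e. the BRDF multiplied
by cos θr.  Signed in-plane angles are used throughout: negative θr lies on
the same side of the normal as the light source, so the specular peak sits
near ``θr ≈ +θi``.  All public interfaces take degrees.

Energy model
------------
The specular lobe is a probability lobe: a fraction ``s`` of the incident
flux scatters into directions distributed about the mirror axis, and the
part of the lobe that would pass below the surface horizon is lost
(truncated, not renormalized).  The directional-hemispherical reflectance is
therefore ``d + s · P(θi, n)`` with ``P`` the above-horizon fraction of the
lobe — close to ``d + s`` at all but grazing incidence, which is the
angle-invariance a scene renderer realizes when it treats ``s`` as a
scattering probability.  The angular *intensity* of the surviving lobe
carries the cos θr weighting of the URIDF definition, which displaces the
peak away from the mirror direction.  Both quantities come from the same
quadratures so the analytic curves are the exact expectation of the
Monte-Carlo gonioreflectometer in :mod:`leafphong.gonio_sim`.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Literal, Sequence

import numpy as np

__all__ = [
    "PhongParameters",
    "SpectralPhongSet",
    "URIDFCurve",
    "shininess_to_exponent",
    "eval_bridf",
    "analytic_hemispherical_reflectance",
    "specular_proportion",
    "lobe_fraction_above_horizon",
    "weighted_lobe_normalizer",
]


class DomainError(ValueError):
    """An angle or parameter is outside the model's domain."""


@dataclass(frozen=True)
class PhongParameters:
    """Per-wavelength Phong surface description.

    Parameters
    ----------
    d : float
        Diffuse reflectance weight (dimensionless, >= 0).
    s : float
        Specular reflectance weight (dimensionless, >= 0).
    g : float
        Shininess in [0, 1]; mapped to the lobe exponent by
        :func:`shininess_to_exponent`.
    t : float
        Diffuse transparency (transmittance) weight, >= 0.
    """

    d: float
    s: float
    g: float
    t: float = 0.0

    def __post_init__(self) -> None:
        if self.d < 0 or self.s < 0 or self.t < 0:
            raise DomainError("d, s and t must be non-negative")
        if not 0.0 <= self.g <= 1.0:
            raise DomainError("g must lie in [0, 1]")
        if self.d + self.s + self.t > 1.0 + 1e-12:
            raise DomainError(
                f"d + s + t = {self.d + self.s + self.t:.6f} exceeds 1 (energy gain)"
            )

    @property
    def exponent(self) -> float:
        return shininess_to_exponent(self.g)

    def with_scale(self, factor: float) -> "PhongParameters":
        """Rescale d and s by a common factor, keeping their ratio."""
        return replace(self, d=self.d * factor, s=self.s * factor)


@dataclass
class URIDFCurve:
    """Reflected-intensity distribution over θr at fixed θi and wavelength."""

    theta_i: float
    theta_r: np.ndarray
    values: np.ndarray
    wavelength: float
    role: Literal["measured", "phong", "diffuse-baseline"] = "measured"

    def __post_init__(self) -> None:
        self.theta_r = np.asarray(self.theta_r, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.theta_r.shape != self.values.shape:
            raise ValueError("theta_r and values must have identical shapes")
        if np.any(np.diff(self.theta_r) <= 0):
            raise ValueError("theta_r must be strictly increasing")
        if np.any(np.abs(self.theta_r) >= 90.0):
            raise DomainError("all |theta_r| must be < 90 degrees")
        if np.any(self.values < -1e-12):
            raise ValueError("URIDF values must be non-negative")

    def copy(self) -> "URIDFCurve":
        return URIDFCurve(
            self.theta_i,
            self.theta_r.copy(),
            self.values.copy(),
            self.wavelength,
            self.role,
        )


@dataclass
class SpectralPhongSet:
    """One :class:`PhongParameters` record per wavelength."""

    wavelengths: np.ndarray
    params: Sequence[PhongParameters]
    surface_label: str = "synthetic"

    def __post_init__(self) -> None:
        self.wavelengths = np.asarray(self.wavelengths, dtype=float)
        if np.any(np.diff(self.wavelengths) <= 0):
            raise ValueError("wavelengths must be strictly increasing")
        if len(self.params) != self.wavelengths.size:
            raise ValueError("one parameter record per wavelength required")

    def __len__(self) -> int:
        return self.wavelengths.size

    def at(self, wavelength: float) -> PhongParameters:
        idx = int(np.argmin(np.abs(self.wavelengths - wavelength)))
        if abs(self.wavelengths[idx] - wavelength) > 1e-6:
            raise KeyError(f"wavelength {wavelength} nm not in set")
        return self.params[idx]


def shininess_to_exponent(g: float) -> float:
    """Map normalized shininess g in [0, 1) to a Phong lobe exponent n.

    Uses ``n = 10**(2 g)``, a strictly increasing map with ``n(0) = 1``;
    ``g = 1`` (an infinitely sharp lobe) is rejected.
    """
    if not 0.0 <= g < 1.0:
        raise DomainError(f"shininess g={g} outside [0, 1)")
    return float(10.0 ** (2.0 * g))


def _phi_integrals(alpha: np.ndarray, theta_m: float) -> tuple[np.ndarray, np.ndarray]:
    """Azimuthal integrals of the above-horizon condition about the lobe axis.

    For a lobe axis at zenith angle ``theta_m`` and a direction at angle
    ``alpha`` from the axis with azimuth phi, the direction's zenith cosine is
    ``cos θ = cos α cos θm + sin α sin θm cos φ``.  Returns, for each alpha,
    the phi-measure of the above-horizon region and the integral of cos θ
    over it (closed forms).
    """
    alpha = np.asarray(alpha, dtype=float)
    a = np.cos(alpha) * np.cos(theta_m)
    b = np.sin(alpha) * np.sin(theta_m)
    length = np.empty_like(a)
    cosint = np.empty_like(a)

    tiny = b < 1e-14
    length[tiny] = np.where(a[tiny] > 0, 2.0 * np.pi, 0.0)
    cosint[tiny] = np.where(a[tiny] > 0, 2.0 * np.pi * a[tiny], 0.0)

    nb = ~tiny
    r = np.empty_like(a)
    r[nb] = -a[nb] / b[nb]
    full = nb & (r <= -1.0)
    none = nb & (r >= 1.0)
    part = nb & ~full & ~none
    length[full] = 2.0 * np.pi
    cosint[full] = 2.0 * np.pi * a[full]
    length[none] = 0.0
    cosint[none] = 0.0
    phi0 = np.arccos(np.clip(r[part], -1.0, 1.0))
    length[part] = 2.0 * phi0
    cosint[part] = 2.0 * (a[part] * phi0 + b[part] * np.sin(phi0))
    return length, cosint


# Gauss-Legendre nodes on [0, 1]; the substitution u = cos^(n+1) alpha below
# removes the cos^n peak of the lobe so a fixed rule is accurate for any n.
_GL_NODES, _GL_WEIGHTS = np.polynomial.legendre.leggauss(128)
_GL_U = 0.5 * (_GL_NODES + 1.0)
_GL_W = 0.5 * _GL_WEIGHTS


def _lobe_integrals(theta_i: float, n: float) -> tuple[float, float]:
    """Above-horizon lobe fraction P and weighted normalizer Z by quadrature.

    With ``u = cos^(n+1) α`` the unweighted-lobe measure becomes ``du``, so
    both integrals are smooth in u and a fixed 128-node Gauss-Legendre rule
    resolves them to ~1e-12 for exponents up to a few hundred.
    """
    theta_m = np.radians(abs(theta_i))
    if theta_m >= np.pi / 2:
        raise DomainError("|theta_i| must be < 90 degrees")
    if theta_m == 0.0:
        return 1.0, float(2.0 * np.pi / (n + 2.0))
    # the phi-integrals have a kink where the lobe circle first dips below
    # the horizon (alpha = pi/2 - theta_m); integrate each panel separately
    u_kink = float(np.cos(np.pi / 2 - theta_m) ** (n + 1.0))
    p = 0.0
    z = 0.0
    for lo, hi in ((0.0, u_kink), (u_kink, 1.0)):
        if hi <= lo:
            continue
        u = lo + (hi - lo) * _GL_U
        w = (hi - lo) * _GL_W
        cos_a = u ** (1.0 / (n + 1.0))
        alpha = np.arccos(np.clip(cos_a, 0.0, 1.0))
        length, cosint = _phi_integrals(alpha, theta_m)
        p += float(np.sum(w * length) / (2.0 * np.pi))
        z += float(np.sum(w * cosint) / (n + 1.0))
    return min(p, 1.0), z


def lobe_fraction_above_horizon(theta_i: float, n: float) -> float:
    """Fraction of the normalized cos^n lobe lying above the surface horizon.

    The lobe axis is the mirror direction (zenith angle |θi|).  The lobe is
    the probability density ``(n+1)/(2π) cos^n α`` over the hemisphere about
    its axis; the below-horizon part is lost by truncation.
    """
    return _lobe_integrals(theta_i, n)[0]


def weighted_lobe_normalizer(theta_i: float, n: float) -> float:
    """Normalizer Z(θi, n) = ∫_above cos^n α · cos θ dω of the weighted lobe.

    ``cos α`` is measured from the mirror axis and ``cos θ`` from the surface
    normal; the integral runs over the above-horizon part of the lobe
    hemisphere.  At θi = 0 this is exactly ``2π/(n+2)``.
    """
    return _lobe_integrals(theta_i, n)[1]


def eval_bridf(
    params: PhongParameters,
    theta_i: float,
    theta_r_grid: np.ndarray | Sequence[float],
    wavelength: float = float("nan"),
) -> URIDFCurve:
    """Evaluate the analytic in-plane URIDF on a grid of reflection angles.

    The diffuse term is ``(d/π)·cos θr`` (it integrates to ``d`` over the
    hemisphere).  The specular term is the cos θr-weighted truncated lobe
    ``s · P(θi,n) · cos^n α · cos θr / Z(θi,n)`` with ``α = θr − θi`` in
    plane, ``P`` the above-horizon lobe fraction and ``Z`` the weighted-lobe
    normalizer, so that its hemispherical integral equals ``s·P(θi,n)`` and
    its peak sits slightly normal-ward of the mirror direction.
    """
    theta_r_grid = np.asarray(theta_r_grid, dtype=float)
    if abs(theta_i) >= 90.0:
        raise DomainError("|theta_i| must be < 90 degrees")
    if np.any(np.abs(theta_r_grid) >= 90.0):
        raise DomainError("all |theta_r| must be < 90 degrees")

    tr = np.radians(theta_r_grid)
    values = params.d / np.pi * np.cos(tr)
    if params.s > 0.0:
        n = params.exponent
        cos_alpha = np.clip(np.cos(np.radians(theta_r_grid - theta_i)), 0.0, None)
        p_above = lobe_fraction_above_horizon(theta_i, n)
        z = weighted_lobe_normalizer(theta_i, n)
        values = values + params.s * p_above / z * cos_alpha**n * np.cos(tr)
    return URIDFCurve(theta_i, theta_r_grid, values, wavelength, role="phong")


def analytic_hemispherical_reflectance(params: PhongParameters, theta_i: float) -> float:
    """Directional-hemispherical reflectance ``d + s·P(θi, n)``.

    ``P`` is the fraction of the normalized specular lobe above the surface
    horizon (numerical quadrature); below-horizon lobe energy is truncated.
    The value lies in ``[0, d+s]``, equals ``d+s`` at normal incidence and is
    non-increasing in θi.
    """
    if abs(theta_i) >= 90.0:
        raise DomainError("|theta_i| must be < 90 degrees")
    if params.s == 0.0:
        return params.d
    n = params.exponent
    return params.d + params.s * lobe_fraction_above_horizon(theta_i, n)


def specular_proportion(params: PhongParameters) -> float:
    """Specular proportion p_s = s / (d + s)."""
    total = params.d + params.s
    if total <= 0.0:
        raise DomainError("specular proportion undefined for d + s = 0")
    return params.s / total
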