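"""Monte-Carlo virtual gonioreflectometer (vGRM).

Mimics a goniophotometric bench: a collimated-but-finite light source (full
cone angle 14.25° by default) illuminates a flat sample, and a semicircular
arc of non-overlapping sensor discs in the plane of incidence (distance to
sensor diameter 1:30, one sensor every 2°) tallies the reflected rays.  Each
incident ray is terminated exactly once — reflected, transmitted or
absorbed — so the energy bookkeeping is exact by counts.

Scattering follows :mod:`leafphong.phong_core`'s model by roulette:

* with probability ``d`` the ray reflects diffusely (cosine-sampled),
* with probability ``s`` it enters the specular branch: a direction is drawn
  from the unweighted lobe ``(n+1)/(2π) cos^n α`` about the per-ray mirror
  axis and the ray is *absorbed* if that draw lies below the surface horizon
  (truncated lobe energy); a surviving ray's final direction is then drawn
  from the cos θr-weighted lobe density by rejection, so the sensor tallies
  converge to :func:`leafphong.phong_core.eval_bridf`,
* with probability ``t`` it transmits diffusely (cosine-sampled downward),
* otherwise it is absorbed.

Per-tally standard errors come from binomial counting statistics.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal

import numpy as np

from .phong_core import DomainError, PhongParameters, URIDFCurve

__all__ = [
    "SimulationConfig",
    "SimulationResult",
    "simulate_uridf",
    "simulate_hemispherical",
    "simulate_diffuse_reflectance",
    "source_count",
    "hemisphere_sources",
]


class ConfigError(ValueError):
    """Simulation configuration violates a geometric or sanity invariant."""


@dataclass
class SimulationConfig:
    """Geometry and sampling settings of the virtual gonioreflectometer."""

    n_rays: int = 10_000_000
    source_aperture: float = 14.25  # full cone angle, degrees
    sensor_ratio: float = 30.0  # distance-to-sensor-diameter ratio
    sensor_spacing: float = 2.0  # degrees between sensor centers
    sensor_range: float = 75.0  # sensors span [-range, range]
    seed: int = 0
    mode: Literal["directional", "diffuse-hemisphere"] = "directional"

    def __post_init__(self) -> None:
        if self.n_rays < 10_000:
            raise ConfigError("n_rays must be at least 10^4")
        if self.source_aperture <= 0:
            raise ConfigError("source_aperture must be positive")
        if self.sensor_subtended_angle > self.sensor_spacing:
            raise ConfigError(
                f"sensors overlap: subtended angle "
                f"{self.sensor_subtended_angle:.3f}° exceeds spacing "
                f"{self.sensor_spacing}°"
            )

    @property
    def sensor_subtended_angle(self) -> float:
        """Full angle (degrees) a sensor disc subtends at the sample."""
        return float(2.0 * np.degrees(np.arctan(0.5 / self.sensor_ratio)))

    @property
    def sensor_thetas(self) -> np.ndarray:
        n_half = int(round(self.sensor_range / self.sensor_spacing))
        return np.arange(-n_half, n_half + 1) * self.sensor_spacing


@dataclass
class SimulationResult:
    """Tallies of one virtual-gonioreflectometer run."""

    rho_sim: float
    tau_sim: float
    rho_std_error: float
    tau_std_error: float
    rays_reflected: int
    rays_transmitted: int
    rays_absorbed: int
    n_rays: int
    uridf: URIDFCurve | None = None
    uridf_std_error: np.ndarray | None = None


def _orthonormal_frames(axes: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Per-row orthonormal vectors completing each unit axis to a frame."""
    helper = np.zeros_like(axes)
    near_z = np.abs(axes[:, 2]) > 0.9
    helper[near_z, 0] = 1.0
    helper[~near_z, 2] = 1.0
    e1 = np.cross(axes, helper)
    e1 /= np.linalg.norm(e1, axis=1, keepdims=True)
    e2 = np.cross(axes, e1)
    return e1, e2


def _directions_about(
    axes: np.ndarray, cos_alpha: np.ndarray, phi: np.ndarray
) -> np.ndarray:
    e1, e2 = _orthonormal_frames(axes)
    sin_alpha = np.sqrt(np.clip(1.0 - cos_alpha**2, 0.0, None))
    return (
        axes * cos_alpha[:, None]
        + e1 * (sin_alpha * np.cos(phi))[:, None]
        + e2 * (sin_alpha * np.sin(phi))[:, None]
    )


def _sample_cone(nominal: np.ndarray, half_angle_rad: float, n: int, rng) -> np.ndarray:
    """Directions uniform per solid angle within a cone about ``nominal``."""
    cos_min = np.cos(half_angle_rad)
    cos_a = rng.uniform(cos_min, 1.0, size=n)
    phi = rng.uniform(0.0, 2.0 * np.pi, size=n)
    axes = np.broadcast_to(nominal, (n, 3)).copy()
    return _directions_about(axes, cos_a, phi)


def _cosine_hemisphere(n: int, rng, downward: bool = False) -> np.ndarray:
    u = rng.random(n)
    phi = rng.uniform(0.0, 2.0 * np.pi, size=n)
    r = np.sqrt(u)
    z = np.sqrt(1.0 - u)
    dirs = np.column_stack([r * np.cos(phi), r * np.sin(phi), z])
    if downward:
        dirs[:, 2] *= -1.0
    return dirs


def _sample_weighted_lobe(axes: np.ndarray, n_exp: float, rng) -> np.ndarray:
    """Draw from the density ∝ cos^n α · cos θ over the above-horizon lobe.

    Rejection from the unweighted lobe with acceptance probability cos θ;
    draws below the horizon are rejected and redrawn (the energy loss of the
    truncated lobe is accounted for separately by the caller).
    """
    n = axes.shape[0]
    out = np.empty((n, 3))
    pending = np.arange(n)
    for _ in range(100_000):
        if pending.size == 0:
            break
        m = pending.size
        cos_a = rng.random(m) ** (1.0 / (n_exp + 1.0))
        phi = rng.uniform(0.0, 2.0 * np.pi, size=m)
        cand = _directions_about(axes[pending], cos_a, phi)
        accept = (cand[:, 2] > 0.0) & (rng.random(m) < cand[:, 2])
        out[pending[accept]] = cand[accept]
        pending = pending[~accept]
    if pending.size:  # pragma: no cover - astronomically unlikely
        out[pending] = axes[pending]
    return out


def _trace(
    params: PhongParameters,
    incident: np.ndarray,
    rng,
    want_directions: bool,
) -> tuple[np.ndarray | None, int, int, int]:
    """Scatter incident rays once; return reflected directions and counts."""
    n = incident.shape[0]
    u = rng.random(n)
    d, s, t = params.d, params.s, params.t
    diffuse = u < d
    specular = (u >= d) & (u < d + s)
    transmit = (u >= d + s) & (u < d + s + t)

    n_trans = int(np.count_nonzero(transmit))
    reflected_dirs = []

    n_diff = int(np.count_nonzero(diffuse))
    if n_diff:
        dirs = _cosine_hemisphere(n_diff, rng)
        if want_directions:
            reflected_dirs.append(dirs)

    n_spec_refl = 0
    n_spec = int(np.count_nonzero(specular))
    if n_spec:
        n_exp = params.exponent
        mirror = incident[specular].copy()
        mirror[:, 2] *= -1.0  # reflect about the surface normal
        # survival draw from the unweighted lobe: below-horizon => absorbed
        cos_a = rng.random(n_spec) ** (1.0 / (n_exp + 1.0))
        phi = rng.uniform(0.0, 2.0 * np.pi, size=n_spec)
        trial = _directions_about(mirror, cos_a, phi)
        alive = trial[:, 2] > 0.0
        n_spec_refl = int(np.count_nonzero(alive))
        if n_spec_refl and want_directions:
            dirs = _sample_weighted_lobe(mirror[alive], n_exp, rng)
            reflected_dirs.append(dirs)

    n_refl = n_diff + n_spec_refl
    out = np.concatenate(reflected_dirs, axis=0) if reflected_dirs else None
    return out, n_refl, n_trans, n - n_refl - n_trans


def _binomial_se(k: int, n: int) -> float:
    p = k / n
    return float(np.sqrt(max(p * (1.0 - p), 0.0) / n))


def simulate_uridf(
    params: PhongParameters,
    theta_i: float,
    config: SimulationConfig,
    wavelength: float = float("nan"),
) -> SimulationResult:
    """Simulate the URIDF and hemispherical tallies for a directional source.

    Reproducible for a fixed ``config.seed``; the URIDF estimator converges
    to :func:`leafphong.phong_core.eval_bridf` as the ray count grows, up to
    the angular blurring of the finite source aperture.
    """
    if abs(theta_i) >= 90.0:
        raise DomainError("|theta_i| must be < 90 degrees")
    if config.mode != "directional":
        raise ConfigError("simulate_uridf requires directional mode")
    rng = np.random.default_rng(config.seed)
    ti = np.radians(theta_i)
    # source on the negative-theta_r side: incoming rays travel toward +x
    nominal = np.array([np.sin(ti), 0.0, -np.cos(ti)])
    incident = _sample_cone(
        nominal, np.radians(config.source_aperture / 2.0), config.n_rays, rng
    )
    dirs, n_refl, n_trans, n_abs = _trace(params, incident, rng, want_directions=True)

    sensors = config.sensor_thetas
    delta = np.arctan(0.5 / config.sensor_ratio)  # sensor cap half-angle
    omega = 2.0 * np.pi * (1.0 - np.cos(delta))  # cap solid angle
    counts = np.zeros(sensors.size, dtype=np.int64)
    if dirs is not None and dirs.size:
        psi = np.degrees(np.arctan2(dirs[:, 0], dirs[:, 2]))
        idx = np.rint((psi - sensors[0]) / config.sensor_spacing).astype(int)
        ok = (idx >= 0) & (idx < sensors.size)
        if np.any(ok):
            sen = np.radians(sensors[idx[ok]])
            dots = dirs[ok, 0] * np.sin(sen) + dirs[ok, 2] * np.cos(sen)
            hit = dots >= np.cos(delta)
            counts = np.bincount(idx[ok][hit], minlength=sensors.size)

    n = config.n_rays
    uridf_vals = counts / (n * omega)
    uridf_se = np.array([_binomial_se(int(k), n) for k in counts]) / omega
    curve = URIDFCurve(theta_i, sensors, uridf_vals, wavelength, role="phong")
    return SimulationResult(
        rho_sim=n_refl / n,
        tau_sim=n_trans / n,
        rho_std_error=_binomial_se(n_refl, n),
        tau_std_error=_binomial_se(n_trans, n),
        rays_reflected=n_refl,
        rays_transmitted=n_trans,
        rays_absorbed=n_abs,
        n_rays=n,
        uridf=curve,
        uridf_std_error=uridf_se,
    )


def simulate_hemispherical(
    params: PhongParameters, theta_i: float, config: SimulationConfig
) -> SimulationResult:
    """Hemispherical reflectance/transmittance only (no sensor arc)."""
    if abs(theta_i) >= 90.0:
        raise DomainError("|theta_i| must be < 90 degrees")
    rng = np.random.default_rng(config.seed)
    ti = np.radians(theta_i)
    nominal = np.array([np.sin(ti), 0.0, -np.cos(ti)])
    incident = _sample_cone(
        nominal, np.radians(config.source_aperture / 2.0), config.n_rays, rng
    )
    _, n_refl, n_trans, n_abs = _trace(params, incident, rng, want_directions=False)
    n = config.n_rays
    return SimulationResult(
        rho_sim=n_refl / n,
        tau_sim=n_trans / n,
        rho_std_error=_binomial_se(n_refl, n),
        tau_std_error=_binomial_se(n_trans, n),
        rays_reflected=n_refl,
        rays_transmitted=n_trans,
        rays_absorbed=n_abs,
        n_rays=n,
    )


def source_count(zenith_segments: int, azimuth_segments: int) -> int:
    """Number of directional sources discretizing the illumination hemisphere."""
    if zenith_segments < 1 or azimuth_segments < 1:
        raise ConfigError("segment counts must be >= 1")
    return zenith_segments * azimuth_segments


def hemisphere_sources(
    zenith_segments: int = 9, azimuth_segments: int = 12
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Source zeniths, azimuths and irradiance weights of the diffuse sky.

    Defaults enumerate zenith 10°…90° in 10° steps and azimuth 0°…330° in
    30° steps (108 sources).  Weights are the cosine-projected irradiance of
    a uniform sky per source ring, ``w ∝ cos θ · sin θ``, shared equally
    among the azimuth positions.
    """
    count = source_count(zenith_segments, azimuth_segments)
    zen = np.arange(1, zenith_segments + 1) * (90.0 / zenith_segments)
    azi = np.arange(azimuth_segments) * (360.0 / azimuth_segments)
    zz, aa = np.meshgrid(zen, azi, indexing="ij")
    zz, aa = zz.ravel(), aa.ravel()
    assert zz.size == count
    w = np.cos(np.radians(zz)) * np.sin(np.radians(zz))
    w = np.clip(w, 0.0, None)
    w[w < 1e-12] = 0.0  # the 90-degree ring carries no projected irradiance
    return zz, aa, w / w.sum()


def simulate_diffuse_reflectance(
    params: PhongParameters,
    config: SimulationConfig,
    zenith_segments: int = 9,
    azimuth_segments: int = 12,
) -> SimulationResult:
    """Total reflected fraction under discretized diffuse illumination.

    Averages the directional hemispherical reflectance over the source grid
    with cosine-projected-irradiance weighting; the total ray budget is
    allocated to sources in proportion to their weight.
    """
    if config.mode != "diffuse-hemisphere":
        raise ConfigError("simulate_diffuse_reflectance requires diffuse-hemisphere mode")
    zen, azi, w = hemisphere_sources(zenith_segments, azimuth_segments)
    rng = np.random.default_rng(config.seed)
    n_per = np.maximum(np.rint(w * config.n_rays).astype(int), 0)

    rho = 0.0
    tau = 0.0
    var_rho = 0.0
    var_tau = 0.0
    tot_refl = tot_trans = tot_abs = tot_rays = 0
    for zk, ak, wk, nk in zip(zen, azi, w, n_per):
        if nk == 0 or wk == 0.0:
            continue
        ti = np.radians(zk)
        phi = np.radians(ak)
        nominal = np.array(
            [np.sin(ti) * np.cos(phi), np.sin(ti) * np.sin(phi), -np.cos(ti)]
        )
        incident = _sample_cone(
            nominal, np.radians(config.source_aperture / 2.0), nk, rng
        )
        _, n_refl, n_trans, n_abs = _trace(params, incident, rng, want_directions=False)
        pr, pt = n_refl / nk, n_trans / nk
        rho += wk * pr
        tau += wk * pt
        var_rho += wk**2 * pr * (1.0 - pr) / nk
        var_tau += wk**2 * pt * (1.0 - pt) / nk
        tot_refl += n_refl
        tot_trans += n_trans
        tot_abs += n_abs
        tot_rays += nk
    return SimulationResult(
        rho_sim=rho,
        tau_sim=tau,
        rho_std_error=float(np.sqrt(var_rho)),
        tau_std_error=float(np.sqrt(var_tau)),
        rays_reflected=tot_refl,
        rays_transmitted=tot_trans,
        rays_absorbed=tot_abs,
        n_rays=tot_rays,
    )
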