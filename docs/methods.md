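# Methods

This note documents the reflectance model, the numerical choices behind the
fitting pipeline and the simulator, what the synthetic data generator does
and does not emulate, and the known limitations.

## Reflectance model

A leaf surface is described per wavelength by four non-negative weights
with d + s + t ≤ 1:

| parameter | meaning | typical leaf value |
|---|---|---|
| d | diffuse (Lambertian) reflectance | 0.05–0.3 |
| s | specular lobe reflectance | 0.01–0.1 |
| g | shininess in [0, 1); lobe exponent n = 10^(2g) | ≈ 0.6 |
| t | diffuse transparency (transmittance) | 0.05–0.4 |

The shininess map n = 10^(2g) is a package choice: renderers that expose a
normalized shininess do not publish their internal map, and any strictly
increasing map is admissible for fitting. This one puts g = 0.6 at n ≈ 16,
which reproduces the few-degree normal-ward displacement of the measured
specular peak (about −1.3°, −2.8° and −5.2° at θi = 20°, 40°, 60°; the
in-plane stationary point satisfies tan(θr − θi) = −tan(θr)/n). The map is
centralized in `shininess_to_exponent` and can be swapped without touching
the rest of the code.

### Energy versus intensity of the specular lobe

Two requirements pull the classical energy-normalized Phong lobe in
opposite directions. The measured URIDF carries the cos θr intensity
weighting, which shifts the peak off the mirror direction; but goniometric
data and path-traced renderers both show total reflectance nearly
independent of the incidence angle, whereas a fixed-normalization lobe
s·(n+2)/(2π)·cos^n α has hemispherical reflectance ≈ s·cos θi (a 4 %
deviation between 0° and 60° for s/d = 0.2 — an order of magnitude larger
than observed). The package therefore treats s as a *scattering
probability*: on specular reflection the outgoing direction is distributed
about the mirror axis, the part of the lobe below the surface horizon is
lost (truncated, never renormalized), and the surviving intensity carries
the cos θr weighting. Concretely,

* hemispherical reflectance R(θi) = d + s·P(θi, n), with P the
  above-horizon fraction of the probability lobe (n+1)/(2π)·cos^n α —
  equal to 1 at normal incidence, ≈ 0.9995 at 40° for n = 16, and falling
  only near grazing incidence (truncation is the single loss mechanism, so
  R declines at grazing angles);
* angular intensity (URIDF) = s·P(θi,n)·cos^n α·cos θr / Z(θi,n), where
  Z(θi,n) = ∫_above cos^n α·cos θ dω normalizes the weighted lobe; at
  θi = 0 this reduces exactly to the classical s·(n+2)/(2π)·cos^n α·cos θr.

Both P and Z come from the same quadrature, so the analytic curve is the
exact expectation of the Monte-Carlo sampler and either can serve as the
oracle for the other.

### Quadrature

P and Z are one-dimensional integrals over the lobe polar angle α after the
azimuthal part is done in closed form. The substitution u = cos^(n+1) α
turns the lobe measure into du, removing the sharp cos^n peak; the
integrand's only remaining structure is a kink where the lobe circle first
dips below the horizon (α = 90° − θi), so the integral is split there and
each panel evaluated with a 128-node Gauss–Legendre rule. Agreement with
adaptive quadrature is ~1e-6 absolute in P over n ∈ [1, 200] and θi up to
89°, at ~0.2 ms per evaluation — fast enough to sit inside the optimizer's
objective.

## Virtual gonioreflectometer

The simulator mirrors the physical bench: a source cone of full angle
14.25° (uniform per solid angle — the emission profile across the
collimation aperture is not otherwise constrained), a flat sample, and
sensor discs in the plane of incidence every 2° from −75° to 75° with a
1:30 distance-to-diameter ratio (subtended angle 1.91°, so discs never
overlap). Each ray is terminated exactly once by roulette — diffuse
reflection with probability d (cosine-sampled), specular with probability
s, transmission with probability t (cosine-sampled downward), absorption
otherwise — so reflected + transmitted + absorbed counts equal the ray
budget exactly and every tally has binomial counting statistics.

In the specular branch, survival is decided by a draw from the unweighted
lobe (cos α = u^(1/(n+1)), azimuth uniform): a draw below the horizon is
absorbed, which realizes the truncation loss 1 − P(θi,n). A surviving
ray's direction is then drawn from the cos θ-weighted lobe density by
rejection, so the sensor tallies converge to the analytic URIDF. URIDF
estimates are bin counts divided by rays and by the sensor cap solid angle;
a Lambertian surface then reproduces (d/π)·cos θr without further
calibration.

Diffuse-sky illumination is discretized into 9 zenith × 12 azimuth = 108
directional sources (zenith 10°…90°, azimuth 0°…330°); each source is
weighted by the cosine-projected irradiance of a uniform sky, w ∝
cos θ·sin θ (the 90° ring carries zero weight), and the ray budget is
allocated proportionally.

The finite source aperture blurs the specular peak by design, as in the
physical device. Oracle-equivalence tests therefore run the simulator with
a near-collimated source (0.02°), because the analytic expectation assumes
a collimated beam; all default simulations keep 14.25°.

## Fitting pipeline

* **Alignment.** The dataset is shifted by one shared angular offset
  estimated from the 630 nm peak (3-point parabolic sub-grid
  interpolation; the 5° measurement grid cannot resolve a ~3° shift
  otherwise). Because the predicted peak position depends on the unknown
  shininess, alignment is two-pass: align against the curve at the initial
  parameters, fit the 630 nm curve, rebuild the reference from that fit and
  realign from the original data. Curves whose maximum sits on the grid
  boundary are rejected.
* **Normalization.** Unit trapezoidal integral over θr in radians. The
  unmeasured (−13°, 13°) band is simply absent from integrals and
  residuals — no imputation; measurement and model are normalized on the
  same grid, so the common gap cancels in the fit.
* **Pattern fit.** `lmfit` Levenberg–Marquardt over (d, s, g) with bounds
  d, s ∈ [0, 1], g ∈ [0, 0.95], initial values d = s = 0.5, g = 0.7,
  optimizer defaults otherwise, 200 function evaluations cap. The model
  curve is re-normalized each iteration, making the objective invariant to
  the overall (d, s) scale; the deliberately flat direction is handled by
  the LM damping, and only the ratio and g are interpreted.
* **Scaling.** First-order scale ρm/(d+s), then at most 10 multiplicative
  corrections ρm/ρ_sim until the relative deviation is ≤ 0.8 % (the loop
  tolerance of the measurement workflow this mirrors). With the default
  analytic engine the loop typically terminates at the first check with
  deviations ~0.003 %, because the only gap the correction has to close is
  the tiny above-horizon lobe deficit. Targets requiring d + s + t > 1
  raise an infeasibility error. Residuals are unweighted.
* **Engines.** The analytic model is the default objective (smooth, fast);
  the Monte-Carlo engine re-uses a fixed seed per evaluation
  (common random numbers) so the optimizer sees a deterministic objective.

## Synthetic data generator

The generator's defaults are the study conditions used throughout the
tests: 31 wavelengths (440–740 nm, 10 nm step), incidence angles
{30°, 40°, 60°} on the instrument design grids with the (−13°, 13°)
exclusion, 1 % multiplicative lognormal noise on curve values (radiance
ratios are positive, so noise is multiplicative; mean is kept at one),
0.5 % noise on the integrating-sphere spectra, and optional angular
misalignment. The diffuse spectrum is built from a green Gaussian plus a
far-red sigmoid over a flat base; the specular proportion is
anti-correlated with it (≈ 0.30 in blue/red, 0.15 in green, ≈ 0.2 far-red),
matching the qualitative spectral structure reported for cucumber leaves.
Transmittance is 1.2× the diffuse spectrum. Five-leaf replicate sets for
the paired t-test surface perturb d and s by lognormal factors (5 %/8 % CV)
and jitter g by ±0.02.

What the generator does *not* emulate: spatial heterogeneity within a leaf
(veins, curvature beyond a rigid tilt), wavelength-correlated noise,
Fresnel brightening of the specular lobe at grazing incidence, and any
radiative-transfer realism of the leaf interior. Passing recovery tests
therefore demonstrate that the pipeline inverts its own forward model under
realistic noise and sampling — not that the Phong model is an adequate
description of any particular species.

## Problem sizes

Test and reproduction runs use 10⁶ rays per Monte-Carlo evaluation (σ on a
reflectance of 0.24 ≈ 4×10⁻⁴) and the 31-wavelength spectral grid; the
simulator default of 10⁷ rays is available for higher-fidelity runs.

## Known limitations

* The shininess map is a convention; fitted g values are comparable only
  under the same map (the exponent n is the transferable quantity).
* The model is in-plane and azimuthally isotropic; out-of-plane BRDF
  anisotropy, Fresnel effects, microfacet masking/shadowing and
  polarization are out of scope, so the fit underestimates grazing-angle
  specular amplitudes on real leaves.
* Transmission is purely diffuse with total t; no transmitted lobe is
  modeled.
* The statistical tests are unadjusted across wavelengths (per-wavelength
  paired t-tests); treat contiguous significant bands, not single
  wavelengths, as meaningful.
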