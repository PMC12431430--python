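"""Convert raw goniometric radiance ratios into fit-ready URIDF curves.

The measurement chain records the spectral radiance reflected by the sample
and references it to a calibrated white standard measured at normal
incidence and observation.  For a near-Lambertian standard the irradiance
follows ``E = L·π``, so the BRDF is the radiance ratio divided by
``π·cos θi``, and the URIDF adds the ``cos θr`` intensity weighting:

    URIDF = L_probe · cos θr / (L_wst · π · cos θi)

Before fitting, each curve is normalized to unit integral over θr (trapezoid
rule, θr in radians) and the whole dataset is angularly shifted by a single
offset estimated from the 630 nm peak, which compensates both the systematic
cosine-weighting peak displacement and any tilt of the leaf in the holder.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .phong_core import DomainError, URIDFCurve

__all__ = [
    "RadianceRecord",
    "GonioMeasurement",
    "reference_to_white_standard",
    "normalize_uridf",
    "align_peak",
    "peak_location",
    "design_grid",
    "read_measurement_csv",
    "write_measurement_csv",
    "AlignmentError",
    "NormalizationError",
]

#: angular band around θr = 0 that the instrument cannot reach (source
#: occlusion), except for θr = 0 itself
EXCLUDED_BAND: tuple[float, float] = (-13.0, 13.0)


class AlignmentError(ValueError):
    """Peak alignment failed (e.g. maximum on the grid boundary)."""


class NormalizationError(ValueError):
    """A curve cannot be normalized (all values zero)."""


@dataclass(frozen=True)
class RadianceRecord:
    """One raw goniometric sample: probe and white-standard radiances."""

    L_probe: float
    L_wst: float
    theta_i: float
    theta_r: float
    wavelength: float

    def __post_init__(self) -> None:
        if self.L_wst <= 0:
            raise DomainError("white-standard radiance must be positive")
        if self.L_probe < 0:
            raise DomainError("probe radiance must be non-negative")


def reference_to_white_standard(rec: RadianceRecord) -> float:
    """URIDF value from a radiance ratio (white-standard referencing)."""
    if abs(rec.theta_i) >= 90.0 or abs(rec.theta_r) >= 90.0:
        raise DomainError("angles must satisfy |theta| < 90 degrees")
    cos_i = np.cos(np.radians(rec.theta_i))
    if cos_i <= 0:
        raise DomainError("cos(theta_i) must be positive")
    return float(
        rec.L_probe * np.cos(np.radians(rec.theta_r)) / (rec.L_wst * np.pi * cos_i)
    )


def design_grid(theta_i: float, excluded: tuple[float, float] = EXCLUDED_BAND) -> np.ndarray:
    """Reflection-angle grid of the measurement design for one θi.

    The main dataset (θi = 40°) spans −75°…75° in 5° steps; the validation
    datasets (30°, 60° — and any other angle) span −70°…70° in 10° steps.
    Angles strictly inside the excluded band are dropped, except θr = 0.
    """
    if abs(theta_i - 40.0) < 1e-9:
        grid = np.arange(-75.0, 75.0 + 1e-9, 5.0)
    else:
        grid = np.arange(-70.0, 70.0 + 1e-9, 10.0)
    lo, hi = excluded
    keep = ~((grid > lo) & (grid < hi)) | (grid == 0.0)
    return grid[keep]


@dataclass
class GonioMeasurement:
    """A full goniometric dataset: URIDF curves keyed by (wavelength, θi)."""

    curves: dict[tuple[float, float], URIDFCurve] = field(default_factory=dict)
    surface: str = "synthetic"
    leaf_order: int | None = None
    excluded_band: tuple[float, float] = EXCLUDED_BAND

    def add(self, curve: URIDFCurve) -> None:
        lo, hi = self.excluded_band
        inside = (curve.theta_r > lo) & (curve.theta_r < hi) & (curve.theta_r != 0.0)
        if np.any(inside):
            raise ValueError("curve has points inside the excluded band")
        self.curves[(curve.wavelength, curve.theta_i)] = curve

    @property
    def wavelengths(self) -> np.ndarray:
        return np.unique([wl for wl, _ in self.curves])

    @property
    def theta_i_set(self) -> np.ndarray:
        return np.unique([ti for _, ti in self.curves])

    def curve(self, wavelength: float, theta_i: float) -> URIDFCurve:
        return self.curves[(wavelength, theta_i)]

    def copy(self) -> "GonioMeasurement":
        return GonioMeasurement(
            {k: c.copy() for k, c in self.curves.items()},
            self.surface,
            self.leaf_order,
            self.excluded_band,
        )


def normalize_uridf(curve: URIDFCurve) -> URIDFCurve:
    """Scale a curve so its trapezoidal integral over θr (radians) equals 1."""
    if curve.theta_r.size < 2:
        raise NormalizationError("need at least two grid points")
    integral = np.trapezoid(curve.values, np.radians(curve.theta_r))
    if integral <= 0:
        raise NormalizationError("cannot normalize an all-zero curve")
    out = curve.copy()
    out.values = curve.values / integral
    return out


def peak_location(curve: URIDFCurve) -> float:
    """Sub-grid peak position (degrees) via 3-point parabolic interpolation.

    The measurement grids are too coarse (5–10°) to resolve the few-degree
    cosine-weighting displacement directly, so a parabola is fitted through
    the discrete maximum and its two neighbours.
    """
    i = int(np.argmax(curve.values))
    if i == 0 or i == curve.values.size - 1:
        raise AlignmentError("curve maximum lies on the grid boundary")
    x = curve.theta_r[i - 1 : i + 2]
    y = curve.values[i - 1 : i + 2]
    a, b, _ = np.polyfit(x, y, 2)
    if a >= 0:
        raise AlignmentError("no interior parabolic maximum")
    return float(-b / (2.0 * a))


def _shift_curve(curve: URIDFCurve, offset: float) -> URIDFCurve:
    """Resample a curve shifted by ``-offset`` onto its original grid.

    The shifted curve is ``values(θr + offset)`` (linear interpolation);
    grid points falling outside the measured range are dropped.
    """
    src = curve.theta_r + offset
    inside = (src >= curve.theta_r[0] - 1e-9) & (src <= curve.theta_r[-1] + 1e-9)
    new_theta = curve.theta_r[inside]
    new_vals = np.interp(src[inside], curve.theta_r, curve.values)
    return URIDFCurve(curve.theta_i, new_theta, new_vals, curve.wavelength, curve.role)


def align_peak(
    meas: GonioMeasurement,
    sim_reference: URIDFCurve,
    reference_wavelength: float = 630.0,
) -> tuple[GonioMeasurement, float]:
    """Angularly align a dataset using its 630 nm specular peak.

    The offset is the measured 630 nm peak position minus the simulated
    reference peak position (both sub-grid, parabolic); every curve of the
    measurement is then shifted by ``-offset`` and resampled onto its own
    grid.  One shared offset per dataset, per incidence angle of the
    reference curve.
    """
    key = (reference_wavelength, sim_reference.theta_i)
    if key not in meas.curves:
        raise AlignmentError(
            f"reference wavelength {reference_wavelength} nm at "
            f"theta_i={sim_reference.theta_i}° not present in measurement"
        )
    offset = peak_location(meas.curves[key]) - peak_location(sim_reference)
    aligned = GonioMeasurement(
        {}, meas.surface, meas.leaf_order, meas.excluded_band
    )
    for key_, curve in meas.curves.items():
        aligned.curves[key_] = _shift_curve(curve, offset)
    return aligned, float(offset)


# ---------------------------------------------------------------------------
# long-format CSV dialect
# ---------------------------------------------------------------------------

_COLUMNS = ["wavelength_nm", "theta_i_deg", "theta_r_deg", "value"]


def write_measurement_csv(meas: GonioMeasurement, path: str | Path) -> None:
    rows = []
    for (wl, ti), curve in sorted(meas.curves.items()):
        for tr, v in zip(curve.theta_r, curve.values):
            rows.append(
                {
                    "wavelength_nm": wl,
                    "theta_i_deg": ti,
                    "theta_r_deg": tr,
                    "value": v,
                    "surface": meas.surface,
                    "leaf_order": "" if meas.leaf_order is None else meas.leaf_order,
                }
            )
    pd.DataFrame(rows).to_csv(path, index=False, float_format="%.10g")


def read_measurement_csv(path: str | Path) -> GonioMeasurement:
    df = pd.read_csv(path)
    missing = [c for c in _COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"measurement CSV missing columns: {missing}")
    surface = str(df["surface"].iloc[0]) if "surface" in df.columns else "synthetic"
    leaf_order = None
    if "leaf_order" in df.columns and not df["leaf_order"].isna().all():
        try:
            leaf_order = int(df["leaf_order"].iloc[0])
        except (TypeError, ValueError):
            leaf_order = None
    meas = GonioMeasurement({}, surface, leaf_order)
    for (wl, ti), grp in df.groupby(["wavelength_nm", "theta_i_deg"]):
        grp = grp.sort_values("theta_r_deg")
        curve = URIDFCurve(
            float(ti),
            grp["theta_r_deg"].to_numpy(float),
            grp["value"].to_numpy(float),
            float(wl),
        )
        meas.curves[(float(wl), float(ti))] = curve
    return meas
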