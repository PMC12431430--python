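"""Validation statistics for fitted reflectance models.

Four complementary checks quantify how well a fitted Phong parameter set
reproduces goniometric measurements, and how much it improves on the
purely diffuse (Lambertian) assumption common in canopy light models:

* ``nrmse`` — RMSE between simulated and measured URIDF, normalized to the
  mean of the measured curve (pattern deviation at the fit angle);
* ``nrmse_peak_normalized`` — both curves first divided by their own maxima
  (scale-free transfer check at validation incidence angles);
* ``nrmse_diffuse_baseline`` — the same peak-normalized statistic against a
  Lambertian curve scaled to the measured peak (the cost of ignoring
  angular anisotropy);
* ``amplitude_ratio`` — ratio of un-normalized curve maxima between
  incidence angles (is the reflectance magnitude trend captured?);
* ``delta_nrmse_test`` — paired per-leaf difference diffuse − Phong with a
  two-sided paired t-test (positive means the Phong model is better);
* ``delta_rho`` — percent deviation of total reflectance from the 40°
  reference (angle-invariance of reflected energy).

p-values are reported unadjusted across wavelengths.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .phong_core import URIDFCurve

__all__ = [
    "nrmse",
    "nrmse_peak_normalized",
    "nrmse_diffuse_baseline",
    "amplitude_ratio",
    "delta_nrmse_test",
    "delta_rho",
    "PairedDifferenceResult",
    "UndefinedStatisticError",
]


class UndefinedStatisticError(ValueError):
    """The statistic's normalizer or variance is zero."""


def _check_grids(sim: URIDFCurve, meas: URIDFCurve) -> None:
    if sim.theta_r.shape != meas.theta_r.shape or not np.allclose(
        sim.theta_r, meas.theta_r
    ):
        raise ValueError("curves must share an identical theta_r grid")


def nrmse(sim: URIDFCurve, meas: URIDFCurve) -> float:
    """RMSE normalized to the mean of the measured curve."""
    _check_grids(sim, meas)
    mean_meas = float(np.mean(meas.values))
    if mean_meas == 0.0:
        raise UndefinedStatisticError("measured curve has zero mean")
    return float(np.sqrt(np.mean((sim.values - meas.values) ** 2)) / mean_meas)


def nrmse_peak_normalized(sim: URIDFCurve, meas: URIDFCurve) -> float:
    """NRMSE after dividing each curve by its own maximum."""
    _check_grids(sim, meas)
    max_sim = float(np.max(sim.values))
    max_meas = float(np.max(meas.values))
    if max_sim <= 0.0 or max_meas <= 0.0:
        raise UndefinedStatisticError("curve maximum must be positive")
    sim_n = sim.values / max_sim
    meas_n = meas.values / max_meas
    denom = float(np.mean(meas_n))
    if denom == 0.0:
        raise UndefinedStatisticError("normalized measured curve has zero mean")
    return float(np.sqrt(np.mean((sim_n - meas_n) ** 2)) / denom)


def nrmse_diffuse_baseline(meas: URIDFCurve) -> float:
    """Peak-normalized NRMSE of a Lambertian curve scaled to the measured peak.

    The diffuse baseline is ``URIDF_d ∝ cos θr``; after peak normalization
    the statistic quantifies the pattern error a purely diffuse model makes
    on this measurement.
    """
    if float(np.max(meas.values)) <= 0.0:
        raise UndefinedStatisticError("measured curve maximum must be positive")
    baseline = URIDFCurve(
        meas.theta_i,
        meas.theta_r,
        np.cos(np.radians(meas.theta_r)) * float(np.max(meas.values)),
        meas.wavelength,
        role="diffuse-baseline",
    )
    return nrmse_peak_normalized(baseline, meas)


def amplitude_ratio(meas_test: URIDFCurve, meas_main: URIDFCurve) -> float:
    """Ratio of un-normalized curve maxima (test over main dataset)."""
    max_main = float(np.max(meas_main.values))
    if max_main <= 0.0:
        raise UndefinedStatisticError("main-dataset maximum must be positive")
    return float(np.max(meas_test.values)) / max_main


@dataclass
class PairedDifferenceResult:
    """Mean paired NRMSE difference (diffuse − Phong) and its t-test."""

    delta_nrmse: float
    p_value: float
    t_statistic: float
    n: int
    degenerate: bool

    def __iter__(self):
        yield self.delta_nrmse
        yield self.p_value


def delta_nrmse_test(
    nrmse_diffuse: np.ndarray, nrmse_phong: np.ndarray
) -> PairedDifferenceResult:
    """Paired difference diffuse − Phong with a two-sided paired t-test.

    A positive mean difference indicates the Phong model is better.  Zero
    variance of the paired differences makes the t-statistic undefined; the
    result is flagged ``degenerate`` with a NaN p-value.
    """
    diffuse = np.asarray(nrmse_diffuse, dtype=float)
    phong = np.asarray(nrmse_phong, dtype=float)
    if diffuse.shape != phong.shape or diffuse.ndim != 1:
        raise ValueError("paired samples must be 1-D arrays of equal length")
    if diffuse.size < 2:
        raise ValueError("need at least two pairs")
    diff = diffuse - phong
    mean = float(np.mean(diff))
    sd = float(np.std(diff, ddof=1))
    # numerically constant differences (incl. float cancellation noise)
    scale = max(float(np.max(np.abs(diff))), np.finfo(float).tiny)
    if sd <= 1e-12 * scale:
        return PairedDifferenceResult(mean, float("nan"), float("nan"), diff.size, True)
    t_stat, p = stats.ttest_rel(diffuse, phong)
    return PairedDifferenceResult(mean, float(p), float(t_stat), diff.size, False)


def delta_rho(rho_at_theta: float, rho_at_40: float) -> float:
    """Percent deviation of total reflectance from the 40° reference."""
    if rho_at_40 <= 0.0:
        raise UndefinedStatisticError("reference reflectance must be positive")
    return (rho_at_theta - rho_at_40) / rho_at_40 * 100.0
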