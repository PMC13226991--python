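"""Measurement-uncertainty propagation for transferred quantifications.

Three relative standard-uncertainty components enter each reported
concentration: the regression uncertainty of the mean calibration model
(u_cal), the repeatability of the sample's peak areas (u_rep), and the
uncertainty of the single-point scaling factor (u_factor, conservatively
set to the intra-day precision RSD at the reference level, 3.77%, unless
configured otherwise).  They combine by root sum of squares and are
expanded with a coverage factor k (default 2, ≈95% under the GUM
convention).  An expanded relative uncertainty of at most 10% is treated as
fit for purpose for routine botanical quality control.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .calibration import PolynomialCurve
from .errors import NumericalError, RangeError
from .fixtures import U_FACTOR_REL_PCT

__all__ = [
    "UncertaintyBudget",
    "combine_rss",
    "budget_for_sample",
    "calibration_uncertainty",
]

FIT_FOR_PURPOSE_LIMIT_PCT = 10.0


@dataclass(frozen=True)
class UncertaintyBudget:
    """Relative uncertainty budget of one reported concentration (all %)."""

    u_cal_rel: float
    u_rep_rel: float
    u_factor_rel: float
    combined_rel: float
    coverage_k: float
    expanded_rel: float
    fit_for_purpose: bool


def combine_rss(components) -> float:
    """Root-sum-square combination of relative uncertainties (%)."""
    c = np.atleast_1d(np.asarray(components, dtype=float))
    if np.any(c < 0):
        raise NumericalError("uncertainty components must be >= 0")
    return float(np.sqrt(np.sum(c**2)))


def budget_for_sample(
    u_cal: float,
    u_rep: float,
    u_factor: float = U_FACTOR_REL_PCT,
    k: float = 2.0,
) -> UncertaintyBudget:
    """Assemble the full budget for one sample."""
    if k <= 0:
        raise NumericalError(f"coverage factor must be > 0, got {k}")
    combined = combine_rss([u_cal, u_rep, u_factor])
    expanded = k * combined
    return UncertaintyBudget(
        u_cal_rel=float(u_cal), u_rep_rel=float(u_rep),
        u_factor_rel=float(u_factor), combined_rel=combined,
        coverage_k=float(k), expanded_rel=float(expanded),
        fit_for_purpose=bool(expanded <= FIT_FOR_PURPOSE_LIMIT_PCT),
    )


def calibration_uncertainty(curve: PolynomialCurve, conc: float) -> float:
    """Relative regression uncertainty (%) of an inverse prediction.

    Linearised propagation: the standard error of the fitted mean response
    at ``conc`` (from the curve's retained coefficient covariance) is
    divided by the local slope to convert it to the concentration axis,
    then expressed relative to ``conc``.  Zero-residual fits give 0%; the
    uncertainty grows toward the range edges with the design leverage.
    """
    lo, hi = curve.conc_range
    if not (lo <= conc <= hi):
        raise RangeError(f"conc {conc} outside calibrated range [{lo}, {hi}]")
    if curve.coef_cov is None:
        raise NumericalError(
            "curve carries no fit covariance; refit with fit_second_order "
            "or build via mean_curve"
        )
    xvec = np.array([1.0, conc, conc * conc])
    var_area = float(xvec @ curve.coef_cov @ xvec)
    if var_area <= 0:
        return 0.0
    slope = curve.derivative(conc)
    if slope == 0:
        raise NumericalError("flat calibration at this concentration")
    u_conc = np.sqrt(var_area) / abs(slope)
    return float(100.0 * u_conc / conc)
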