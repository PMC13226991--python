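"""Single-point calibration transfer: the iterative factor.

A plate's response scale is corrected against the study's mean calibration
curve through one reference standard (250 µg/mL by default):

    factor = (mean-curve predicted area at the reference level)
             / (observed area at that level on the plate)

Quantification then inverts the mean curve and multiplies the concentration
by the factor (concentration-domain correction, the published order of
operations), or — as a documented alternative — scales the observed area by
the factor before inversion (response-domain).  For a strictly linear
response the two coincide and remove a multiplicative plate effect exactly;
for a quadratic they differ by a curvature term.

Despite its name the published procedure is a single-pass ratio; a
fixed-point refinement mode is provided for completeness and converges to
the same value after one update.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .calibration import PolynomialCurve, fit_second_order, invert_curve, predict_area
from .data import PlateTable
from .errors import NumericalError, SchemaError

__all__ = [
    "IterativeFactorResult",
    "SensitivityTable",
    "compute_factor",
    "quantify_iterative",
    "percent_difference",
    "sensitivity_analysis",
    "sensitivity_from_matrix",
]


@dataclass(frozen=True)
class IterativeFactorResult:
    """A per-plate scaling factor derived from one reference level."""

    reference_conc: float  # µg/mL
    predicted_ref_area: float  # AU, from the mean curve
    observed_ref_area: float  # AU, from the plate
    factor: float  # dimensionless, predicted / observed


def compute_factor(
    mean_curve: PolynomialCurve,
    observed_ref_area: float,
    reference_conc: float,
    fixed_point: bool = False,
    tol: float = 1e-6,
    max_iter: int = 50,
) -> IterativeFactorResult:
    """Derive the plate's scaling factor from the reference standard.

    Parameters
    ----------
    mean_curve : PolynomialCurve
        The cross-plate mean calibration.
    observed_ref_area : float
        Peak area of the reference standard measured on this plate (> 0).
    reference_conc : float
        Reference level in µg/mL; must lie in the mean curve's range.
    fixed_point : bool
        Refine by re-deriving the factor from the corrected reference area
        until the change is below ``tol``.  The update is idempotent, so
        this converges to the single-pass ratio after one iteration; the
        flag exists to make that explicit.
    """
    if observed_ref_area <= 0:
        raise NumericalError(
            "reference band not detected (observed area must be > 0)"
        )
    predicted = predict_area(mean_curve, reference_conc)
    factor = predicted / observed_ref_area
    if fixed_point:
        for _ in range(max_iter):
            corrected = observed_ref_area * factor
            new = factor * (predicted / corrected)
            if abs(new - factor) <= tol * abs(factor):
                factor = new
                break
            factor = new
    if factor <= 0:
        raise NumericalError(f"non-positive factor {factor:g}")
    return IterativeFactorResult(
        reference_conc=reference_conc,
        predicted_ref_area=predicted,
        observed_ref_area=observed_ref_area,
        factor=factor,
    )


def quantify_iterative(
    mean_curve: PolynomialCurve,
    factor: float | IterativeFactorResult,
    sample_area: float,
    mode: str = "concentration",
) -> float:
    """Quantify one observed area via the mean curve and the plate factor.

    ``mode="concentration"`` (default): invert the mean curve, then multiply
    the concentration by the factor.  ``mode="response"``: multiply the area
    by the factor, then invert.
    """
    f = factor.factor if isinstance(factor, IterativeFactorResult) else factor
    if f <= 0:
        raise NumericalError(f"factor must be positive, got {f}")
    if mode == "concentration":
        return invert_curve(mean_curve, sample_area) * f
    if mode == "response":
        return invert_curve(mean_curve, sample_area * f)
    raise ValueError(f"unknown correction mode {mode!r}")


def percent_difference(c_iterative: float, c_plate_specific: float) -> float:
    """Signed % difference of the transferred vs plate-specific value."""
    if c_plate_specific == 0:
        raise NumericalError("plate-specific concentration is zero")
    return 100.0 * (c_iterative - c_plate_specific) / c_plate_specific


@dataclass
class SensitivityTable:
    """Reference-level sensitivity analysis (plates × candidate levels).

    ``per_plate_pct_diff[i][j]`` is the signed % difference between the
    factor-corrected mean-curve quantification and the plate-specific one
    for plate i under candidate level j (``nan`` where the level was
    missing on a plate).  ``column_means`` are signed arithmetic means over
    plates; ``selected_level`` minimises |column mean|, ties resolved
    toward the level closest to the geometric mid-range.
    """

    candidate_levels: list[float]  # µg/mL
    plate_ids: list[str]
    per_plate_pct_diff: np.ndarray  # (n_plates, n_levels)
    column_means: list[float]
    selected_level: float

    def to_frame(self):
        import pandas as pd

        df = pd.DataFrame(
            self.per_plate_pct_diff, index=self.plate_ids,
            columns=[f"{lvl:g}" for lvl in self.candidate_levels],
        )
        df.loc["Average"] = self.column_means
        return df


def _select_level(levels: list[float], column_means: list[float]) -> float:
    best = min(abs(m) for m in column_means if np.isfinite(m))
    candidates = [
        lvl for lvl, m in zip(levels, column_means)
        if np.isfinite(m) and np.isclose(abs(m), best)
    ]
    if len(candidates) == 1:
        return candidates[0]
    # tie: prefer the level closest to the geometric mid-range
    mid = float(np.sqrt(min(levels) * max(levels)))
    return min(candidates, key=lambda lvl: abs(np.log(lvl / mid)))


def sensitivity_from_matrix(
    matrix: dict[str, dict[float, float]], level_unit_to_ug: float = 1000.0
) -> SensitivityTable:
    """Build a sensitivity table from an already-computed % difference matrix
    (e.g. the published one, keyed plate → level in mg/mL)."""
    plate_ids = list(matrix)
    levels = sorted({lvl for row in matrix.values() for lvl in row})
    arr = np.array(
        [[matrix[p].get(lvl, np.nan) for lvl in levels] for p in plate_ids]
    )
    col_means = [float(np.nanmean(arr[:, j])) for j in range(arr.shape[1])]
    levels_ug = [lvl * level_unit_to_ug for lvl in levels]
    return SensitivityTable(
        candidate_levels=levels_ug,
        plate_ids=plate_ids,
        per_plate_pct_diff=arr,
        column_means=col_means,
        selected_level=_select_level(levels_ug, col_means),
    )


def sensitivity_analysis(
    plates: list[PlateTable],
    mean_calibration: PolynomialCurve,
    candidate_levels: list[float],
) -> SensitivityTable:
    """Evaluate candidate reference levels across plates.

    For each plate and each candidate level, the factor is derived from the
    plate's observed standard track at that level; every sample track on
    the plate is then quantified both ways (factor-corrected mean curve vs
    the plate's own calibration) and the cell holds the mean signed %
    difference over the plate's tracks.  A level missing on a plate flags
    that cell ``nan`` and excludes it from the column mean.
    """
    plate_ids = [p.plate_id for p in plates]
    arr = np.full((len(plates), len(candidate_levels)), np.nan)
    for i, plate in enumerate(plates):
        plate_curve = fit_second_order(plate.standards)
        if not plate.samples:
            raise NumericalError(
                f"plate {plate.plate_id!r} has no sample tracks to check "
                "the calibration transfer on"
            )
        for j, level in enumerate(candidate_levels):
            try:
                observed = plate.standard_area(level)
                fac = compute_factor(mean_calibration, observed, level)
                diffs = []
                for track in plate.samples:
                    c_iter = quantify_iterative(
                        mean_calibration, fac, track.peak_area
                    )
                    c_plate = invert_curve(plate_curve, track.peak_area)
                    diffs.append(percent_difference(c_iter, c_plate))
                arr[i, j] = float(np.mean(diffs))
            except (SchemaError, NumericalError):
                continue  # level absent/out of range on this plate -> flagged

    col_means = [
        float(np.nanmean(arr[:, j])) if np.isfinite(arr[:, j]).any() else np.nan
        for j in range(arr.shape[1])
    ]
    return SensitivityTable(
        candidate_levels=list(candidate_levels),
        plate_ids=plate_ids,
        per_plate_pct_diff=arr,
        column_means=col_means,
        selected_level=_select_level(list(candidate_levels), col_means),
    )
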