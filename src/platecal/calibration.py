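"""Second-order densitometric calibration.

Peak area y responds to concentration x (µg/mL) through a quadratic
y = a2·x² + a1·x + a0 fitted per plate by ordinary least squares; plate
curves are summarised across a study by coefficient-wise averaging into a
mean calibration curve.  Inverse prediction solves the quadratic for the
unique in-range root — monotonicity over the working range is checked at
fit time so the admissible root is unambiguous.

LOD/LOQ follow the 3.3·SE/S and 10·SE/S convention, with SE taken as the
residual standard error of a straight-line fit over the low (linear)
subrange and S its slope.  The choice of SE is isolated in
:func:`low_level_se_slope` so alternatives can be swapped in.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .data import StandardPoint
from .errors import DegenerateDataError, NumericalError, RangeError

__all__ = [
    "PolynomialCurve",
    "LodLoq",
    "fit_second_order",
    "predict_area",
    "invert_curve",
    "low_level_se_slope",
    "lod_loq",
    "plate_lod_loq",
    "mean_curve",
    "mean_lod_loq",
]


@dataclass(frozen=True)
class PolynomialCurve:
    """A concentration→response calibration y = a2·x² + a1·x + a0.

    ``conc_range`` is the calibrated span in µg/mL; predictions outside it
    are refused unless an extrapolation tolerance is given.  ``monotone``
    records whether the fitted response increases strictly over the range
    (it must, for inversion to have a unique root).  ``coef_cov`` is the
    3×3 covariance of (a0, a1, a2) retained from fitting, used for
    regression-uncertainty propagation; ``residual_se`` the response-scale
    residual standard error.
    """

    a2: float
    a1: float
    a0: float
    r_squared: float
    conc_range: tuple[float, float]
    n_points: int = 0
    monotone: bool = True
    residual_se: float = 0.0
    coef_cov: np.ndarray | None = field(default=None, repr=False, compare=False)

    def __post_init__(self) -> None:
        lo, hi = self.conc_range
        if not (lo < hi):
            raise NumericalError(
                f"conc_range must satisfy min < max, got {self.conc_range}"
            )

    @property
    def coefficients(self) -> tuple[float, float, float]:
        """(a2, a1, a0), descending powers."""
        return (self.a2, self.a1, self.a0)

    def derivative(self, conc: float) -> float:
        """Local slope dy/dx at ``conc`` (AU per µg/mL)."""
        return 2.0 * self.a2 * conc + self.a1

    def predict(self, conc, extrapolation_tol: float = 0.0):
        return predict_area(self, conc, extrapolation_tol)

    def invert(self, area: float) -> float:
        return invert_curve(self, area)

    def to_dict(self) -> dict:
        """Small JSON-serialisable record for reuse across runs."""
        return {
            "a2": float(self.a2), "a1": float(self.a1), "a0": float(self.a0),
            "r_squared": float(self.r_squared),
            "conc_range": [float(v) for v in self.conc_range],
            "n_points": int(self.n_points), "monotone": bool(self.monotone),
            "residual_se": float(self.residual_se),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "PolynomialCurve":
        d = dict(d)
        d["conc_range"] = tuple(d["conc_range"])
        return cls(**d)


@dataclass(frozen=True)
class LodLoq:
    """Limits of detection/quantification from SE and slope.

    lod = 3.3·SE/S and loq = 10·SE/S, so loq/lod = 10/3.3 by construction.
    """

    se_low: float
    slope: float
    lod: float
    loq: float


def _is_monotone(a2: float, a1: float, lo: float, hi: float) -> bool:
    # strictly increasing over [lo, hi]: derivative positive at both ends
    return (2 * a2 * lo + a1) > 0 and (2 * a2 * hi + a1) > 0


def fit_second_order(
    standards: list[StandardPoint], weighting: str | None = None
) -> PolynomialCurve:
    """Fit the quadratic calibration by least squares.

    Parameters
    ----------
    standards : list of StandardPoint
        At least three distinct concentrations.
    weighting : {None, "1/x2"}
        Optional 1/x² weighting for the acknowledged heteroscedasticity of
        densitometric responses; plain OLS by default.

    Returns
    -------
    PolynomialCurve
        With ``r_squared`` against the fitted values, ``conc_range`` the
        span of the standards, fit covariance retained, and ``monotone``
        flagged False (warning, not error) if the fitted response is not
        strictly increasing over the range.
    """
    x = np.array([s.concentration for s in standards], dtype=float)
    y = np.array([s.peak_area for s in standards], dtype=float)
    if np.unique(x).size < 3:
        raise DegenerateDataError(
            f"quadratic fit needs >= 3 distinct concentrations, "
            f"got {np.unique(x).size}"
        )
    if weighting is None:
        w = np.ones_like(x)
    elif weighting == "1/x2":
        w = 1.0 / x**2
    else:
        raise ValueError(f"unknown weighting {weighting!r}")

    X = np.column_stack([np.ones_like(x), x, x**2])  # ascending powers
    sw = np.sqrt(w)
    coef, *_ = np.linalg.lstsq(X * sw[:, None], y * sw, rcond=None)
    a0, a1, a2 = (float(c) for c in coef)

    yhat = X @ coef
    resid = y - yhat
    ss_res = float(np.sum(w * resid**2))
    ybar = float(np.average(y, weights=w))
    ss_tot = float(np.sum(w * (y - ybar) ** 2))
    r2 = 1.0 if ss_tot == 0 else 1.0 - ss_res / ss_tot

    dof = x.size - 3
    s2 = ss_res / dof if dof > 0 else 0.0
    XtWX = (X * w[:, None]).T @ X
    try:
        cov = s2 * np.linalg.inv(XtWX)
    except np.linalg.LinAlgError as exc:
        raise DegenerateDataError("rank-deficient calibration design") from exc

    lo, hi = float(x.min()), float(x.max())
    return PolynomialCurve(
        a2=a2, a1=a1, a0=a0, r_squared=float(r2), conc_range=(lo, hi),
        n_points=int(x.size), monotone=_is_monotone(a2, a1, lo, hi),
        residual_se=float(np.sqrt(s2)), coef_cov=cov,
    )


def predict_area(curve: PolynomialCurve, conc, extrapolation_tol: float = 0.0):
    """Evaluate the calibration at ``conc`` (µg/mL; scalar or array).

    ``extrapolation_tol`` widens the admissible range by that fraction of
    the span on each side (default 0: strict).
    """
    c = np.asarray(conc, dtype=float)
    lo, hi = curve.conc_range
    pad = extrapolation_tol * (hi - lo)
    if np.any(c < lo - pad) or np.any(c > hi + pad):
        raise RangeError(
            f"concentration outside calibrated range [{lo}, {hi}] ug/mL"
        )
    out = curve.a2 * c**2 + curve.a1 * c + curve.a0
    return float(out) if np.isscalar(conc) else out


def invert_curve(curve: PolynomialCurve, area: float) -> float:
    """Inverse prediction: the concentration whose predicted area is ``area``.

    Solves a2·c² + a1·c + (a0 − area) = 0 and returns the unique root inside
    ``conc_range``; falls back to the linear solution when |a2| is below a
    machine-scaled threshold.  Refuses non-monotone curves with two in-range
    roots rather than choosing silently.
    """
    lo, hi = curve.conc_range
    y_lo, y_hi = predict_area(curve, lo), predict_area(curve, hi)
    y_min, y_max = min(y_lo, y_hi), max(y_lo, y_hi)
    tol = 1e-9 * max(abs(y_min), abs(y_max), 1e-300)
    if area < y_min - tol or area > y_max + tol:
        raise RangeError(
            f"area {area:g} outside invertible range [{y_min:g}, {y_max:g}]"
        )
    a2, a1, c0 = curve.a2, curve.a1, curve.a0 - area
    # scale-aware degeneracy test: quadratic term negligible across the range
    if abs(a2) * max(abs(lo), abs(hi)) ** 2 < 1e-12 * max(abs(a1) * hi, 1e-300):
        if a1 == 0:
            raise NumericalError("degenerate flat curve cannot be inverted")
        root = -c0 / a1
        return float(np.clip(root, lo, hi))
    disc = a1 * a1 - 4.0 * a2 * c0
    if disc < 0:
        raise NumericalError(f"no real root for area {area:g}")
    sq = np.sqrt(disc)
    roots = sorted(((-a1 - sq) / (2 * a2), (-a1 + sq) / (2 * a2)))
    span = hi - lo
    inside = [r for r in roots if lo - 1e-9 * span <= r <= hi + 1e-9 * span]
    if len(inside) == 0:
        raise RangeError(f"no root inside [{lo}, {hi}] for area {area:g}")
    if len(inside) > 1 and not np.isclose(inside[0], inside[1]):
        raise NumericalError(
            "two in-range roots (non-monotone curve); refusing to choose"
        )
    return float(np.clip(inside[0], lo, hi))


def low_level_se_slope(
    standards: list[StandardPoint], n_low: int = 3
) -> tuple[float, float]:
    """SE and slope inputs of the LOD/LOQ formula from a plate's standards.

    A straight line is fitted over the ``n_low`` lowest concentration levels
    (the linear subrange); SE is its residual standard error in response
    units, S its slope.
    """
    pts = sorted(standards, key=lambda s: s.concentration)[:n_low]
    if len(pts) < 3:
        raise DegenerateDataError("need >= 3 low-range standards for SE")
    x = np.array([p.concentration for p in pts])
    y = np.array([p.peak_area for p in pts])
    slope, intercept = np.polyfit(x, y, 1)
    resid = y - (slope * x + intercept)
    se = float(np.sqrt(np.sum(resid**2) / (x.size - 2)))
    return se, float(slope)


def lod_loq(se_low: float, slope: float) -> LodLoq:
    """Limits of detection and quantification: 3.3·SE/S and 10·SE/S."""
    if slope <= 0:
        raise NumericalError(f"slope must be positive, got {slope}")
    if se_low < 0:
        raise NumericalError(f"SE must be >= 0, got {se_low}")
    ratio = se_low / slope
    return LodLoq(se_low=se_low, slope=slope, lod=3.3 * ratio, loq=10.0 * ratio)


def plate_lod_loq(standards: list[StandardPoint], n_low: int = 3) -> LodLoq:
    """LOD/LOQ of one plate, via :func:`low_level_se_slope`."""
    return lod_loq(*low_level_se_slope(standards, n_low))


def mean_curve(curves: list[PolynomialCurve]) -> PolynomialCurve:
    """Cross-plate mean calibration: coefficient-wise arithmetic mean.

    ``conc_range`` is the intersection of the input ranges; ``r_squared``
    the mean of the inputs (a diagnostic, not a goodness-of-fit of the mean
    curve itself).  The coefficient covariance is the empirical covariance
    of the per-plate coefficient vectors divided by the number of plates —
    the sampling covariance of the mean, which carries the plate-to-plate
    scatter into downstream uncertainty propagation.
    """
    if not curves:
        raise DegenerateDataError("mean_curve of an empty list")
    lo = max(c.conc_range[0] for c in curves)
    hi = min(c.conc_range[1] for c in curves)
    if not lo < hi:
        raise NumericalError("curves have disjoint concentration ranges")
    coefs = np.array([[c.a0, c.a1, c.a2] for c in curves])
    a0, a1, a2 = coefs.mean(axis=0)
    k = len(curves)
    if k > 1:
        cov = np.cov(coefs, rowvar=False, ddof=1) / k
    else:
        cov = curves[0].coef_cov
    res_se = float(np.mean([c.residual_se for c in curves]))
    return PolynomialCurve(
        a2=float(a2), a1=float(a1), a0=float(a0),
        r_squared=float(np.mean([c.r_squared for c in curves])),
        conc_range=(lo, hi), n_points=int(np.sum([c.n_points for c in curves])),
        monotone=_is_monotone(a2, a1, lo, hi), residual_se=res_se,
        coef_cov=cov,
    )


def mean_lod_loq(per_plate: list[LodLoq]) -> tuple[float, float]:
    """Study-level LOD/LOQ: arithmetic means of the per-plate values."""
    if not per_plate:
        raise DegenerateDataError("mean_lod_loq of an empty list")
    return (
        float(np.mean([p.lod for p in per_plate])),
        float(np.mean([p.loq for p in per_plate])),
    )


def rescale_curve(curve: PolynomialCurve, k: float) -> PolynomialCurve:
    """Curve with all responses multiplied by ``k`` (testing/simulation aid)."""
    cov = None if curve.coef_cov is None else curve.coef_cov * k * k
    return replace(
        curve, a2=curve.a2 * k, a1=curve.a1 * k, a0=curve.a0 * k,
        residual_se=curve.residual_se * abs(k), coef_cov=cov,
    )
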