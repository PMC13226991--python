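"""Method-comparison statistics: transferred vs plate-specific quantification.

Three complementary views establish whether quantifying against a factor-
corrected mean calibration is analytically equivalent to refitting a curve
on every plate: a paired t-test with Pearson correlation and the dispersion
of signed percentage differences; a Bland–Altman analysis with an a-priori
equivalence margin (±5% relative, with an absolute floor near the lower
bound of quantification); and a ratio-plot diagnostic that decomposes the
inter-plate error structure into multiplicative and additive components.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .errors import DegenerateDataError, NumericalError

__all__ = [
    "PairedTestResult",
    "BlandAltmanResult",
    "RatioDiagnostic",
    "paired_t_test",
    "bland_altman",
    "ratio_diagnostic",
]

LOA_MULTIPLIER = 1.96  # normal 95%, no small-sample t correction


@dataclass(frozen=True)
class PairedTestResult:
    """Two-sided paired t-test plus association and dispersion measures.

    ``pct_diff_variance`` is the sample variance of the signed percentage
    differences 100·(x−y)/y (%²) — the dispersion statistic whose published
    acceptance threshold is < 2%.
    """

    t_value: float
    p_value: float
    df: int
    correlation: float
    pct_diff_variance: float


def paired_t_test(x, y) -> PairedTestResult:
    """Compare two paired quantification series (e.g. transferred vs
    plate-specific concentrations of the same tracks)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise DegenerateDataError("paired series must be 1-D of equal length")
    n = x.size
    if n < 3:
        raise DegenerateDataError(f"paired t-test needs n >= 3, got {n}")
    d = x - y
    if np.std(d, ddof=1) == 0:
        raise DegenerateDataError(
            "differences have zero variance; the paired t statistic is "
            "undefined (identical offsets)"
        )
    t_res = stats.ttest_rel(x, y)
    r = float(stats.pearsonr(x, y).statistic)
    if np.any(y == 0):
        raise NumericalError("zero reference value in percentage differences")
    pct = 100.0 * d / y
    return PairedTestResult(
        t_value=float(t_res.statistic),
        p_value=float(t_res.pvalue),
        df=n - 1,
        correlation=r,
        pct_diff_variance=float(np.var(pct, ddof=1)),
    )


@dataclass(frozen=True)
class BlandAltmanResult:
    """95% limits of agreement with an a-priori equivalence margin.

    ``equivalent`` is True when both limits lie inside ±margin, where
    margin = max(margin_abs, margin_rel% of the grand mean of the paired
    measurements).
    """

    mean_diff: float
    sd_diff: float
    loa_low: float
    loa_high: float
    margin_rel: float  # %
    margin_abs: float  # same unit as the measurements
    margin: float
    equivalent: bool
    n: int


def bland_altman(x, y, margin_rel: float = 5.0,
                 margin_abs: float = 0.15) -> BlandAltmanResult:
    """Bland–Altman agreement of two methods measuring the same items."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise DegenerateDataError("paired series must be 1-D of equal length")
    if x.size < 3:
        raise DegenerateDataError(f"Bland–Altman needs n >= 3, got {x.size}")
    d = x - y
    mean_diff = float(d.mean())
    sd_diff = float(d.std(ddof=1))
    loa_low = mean_diff - LOA_MULTIPLIER * sd_diff
    loa_high = mean_diff + LOA_MULTIPLIER * sd_diff
    grand_mean = float(((x + y) / 2).mean())
    margin = max(margin_abs, margin_rel / 100.0 * abs(grand_mean))
    return BlandAltmanResult(
        mean_diff=mean_diff, sd_diff=sd_diff,
        loa_low=float(loa_low), loa_high=float(loa_high),
        margin_rel=margin_rel, margin_abs=margin_abs, margin=float(margin),
        equivalent=bool(-margin <= loa_low and loa_high <= margin),
        n=int(x.size),
    )


@dataclass(frozen=True)
class RatioDiagnostic:
    """Error-structure decomposition from observed/mean response ratios.

    A purely multiplicative plate effect gives a flat ratio across the
    calibration range; additive baseline error makes the ratio
    concentration-dependent, inflating dispersion and slopes at the low
    end.  ``verdict`` is ``"multiplicative-dominant"`` when the per-plate
    ratio-vs-log10(c) slopes over the upper half of the range are
    negligible: the median absolute slope must stay below
    ``slope_threshold``, an effective threshold of
    max(absolute floor, 3 × the median slope standard error implied by the
    plates' own fit residuals) — so random track noise never triggers a
    "mixed" verdict, only a systematic high-range trend does.  The
    low-to-high dispersion ratio is reported separately as the
    additive-noise signature.
    """

    levels: np.ndarray  # µg/mL
    ratios: np.ndarray  # (n_plates, n_levels)
    per_level_dispersion: np.ndarray  # sd of ratios per level
    per_plate_slope: np.ndarray  # d ratio / d log10(conc), full range
    high_range_slopes: np.ndarray  # same, upper half of the levels
    low_high_dispersion_ratio: float
    slope_threshold: float
    verdict: str

    @property
    def additive_at_low_end(self) -> bool:
        """True when low-level ratio dispersion clearly exceeds high-level."""
        return self.low_high_dispersion_ratio > 1.5


def ratio_diagnostic(levels, responses, mean_response=None,
                     slope_threshold: float = 0.02) -> RatioDiagnostic:
    """Ratio plot of observed plate responses against the mean response.

    Parameters
    ----------
    levels : array (n_levels,)
        Shared concentration grid, µg/mL.
    responses : array (n_plates, n_levels)
        Observed standard responses per plate.
    mean_response : array (n_levels,), optional
        Reference responses; cross-plate mean of ``responses`` by default.
    slope_threshold : float
        Absolute floor of the verdict cut-off for |d ratio / d log10(c)|
        over the upper range; the effective cut-off additionally scales
        with the slope noise implied by the fit residuals.
    """
    levels = np.asarray(levels, dtype=float)
    responses = np.atleast_2d(np.asarray(responses, dtype=float))
    if responses.shape[0] < 2 and mean_response is None:
        raise DegenerateDataError("ratio diagnostic needs >= 2 plates")
    if responses.shape[1] != levels.size:
        raise DegenerateDataError("responses and level grid differ in length")
    if mean_response is None:
        mean_response = responses.mean(axis=0)
    mean_response = np.asarray(mean_response, dtype=float)
    if np.any(mean_response == 0):
        raise NumericalError("zero mean response at some level")
    ratios = responses / mean_response
    disp = ratios.std(axis=0, ddof=1) if responses.shape[0] > 1 else np.zeros(
        levels.size
    )
    logc = np.log10(levels)
    slopes = np.array([np.polyfit(logc, r, 1)[0] for r in ratios])
    half = levels.size // 2
    hi_idx = slice(half, None)
    x_hi = logc[hi_idx]
    slope_ses = []
    if levels.size - half >= 2:
        hi_slopes = []
        sxx = float(np.sum((x_hi - x_hi.mean()) ** 2))
        for r in ratios:
            coef, res, *_ = np.polyfit(x_hi, r[hi_idx], 1, full=True)
            hi_slopes.append(coef[0])
            dof = x_hi.size - 2
            if dof > 0 and res.size:
                slope_ses.append(np.sqrt(float(res[0]) / dof / sxx))
        hi_slopes = np.array(hi_slopes)
    else:
        hi_slopes = slopes
    lo_disp = float(disp[:half].mean()) if half else float(disp.mean())
    hi_disp = float(disp[hi_idx].mean())
    ratio_lh = lo_disp / hi_disp if hi_disp > 0 else np.inf
    # random track noise inflates both the slopes and their standard errors
    # in step; only a systematic high-range trend exceeds 3x the noise scale
    noise_scale = 3.0 * float(np.median(slope_ses)) if slope_ses else 0.0
    effective = max(slope_threshold, noise_scale)
    verdict = (
        "multiplicative-dominant"
        if float(np.median(np.abs(hi_slopes))) < effective
        else "mixed"
    )
    return RatioDiagnostic(
        levels=levels, ratios=ratios, per_level_dispersion=disp,
        per_plate_slope=slopes, high_range_slopes=hi_slopes,
        low_high_dispersion_ratio=float(ratio_lh),
        slope_threshold=effective, verdict=verdict,
    )
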