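"""ICH-style method-validation statistics.

Covers what the underlying assay validation computes: relative standard
deviations for precision/reproducibility, Rf robustness under varied
development conditions (acceptance: Rf spread < 0.05), spike-recovery
accuracy, and spectral specificity by Pearson correlation of in-situ UV
spectra (pass when r > 0.99).

All standard deviations use the sample (n−1) convention.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .data import Spectrum
from .errors import DegenerateDataError, NumericalError

__all__ = [
    "PrecisionReport",
    "RecoveryResult",
    "rsd",
    "precision_report",
    "robustness_table",
    "recovery",
    "spectral_correlation",
]

RF_SPREAD_LIMIT = 0.05
SPECIFICITY_THRESHOLD = 0.99


def rsd(values) -> float:
    """Relative standard deviation, % — 100 · sample sd / mean."""
    x = np.asarray(values, dtype=float)
    if x.size < 2:
        raise DegenerateDataError(f"RSD needs n >= 2, got n={x.size}")
    m = x.mean()
    if m == 0:
        raise DegenerateDataError("RSD undefined for zero mean")
    return float(100.0 * x.std(ddof=1) / m)


@dataclass(frozen=True)
class PrecisionReport:
    """Per-level RSDs for an intra-day or inter-day design.

    The intra-day design applies each calibration level once per plate on
    several plates the same day (single replicate per plate); the RSD is
    computed across plates per level.  Inter-day repeats across days.
    """

    design: str  # "intra_day" | "inter_day"
    per_level: list[tuple[float, float]]  # (concentration µg/mL, RSD %)


def precision_report(areas_by_level: dict[float, list[float]],
                     design: str = "intra_day") -> PrecisionReport:
    """RSD of repeated peak areas per concentration level."""
    if design not in ("intra_day", "inter_day"):
        raise ValueError(f"unknown design {design!r}")
    per_level = [(float(c), rsd(v)) for c, v in sorted(areas_by_level.items())]
    return PrecisionReport(design=design, per_level=per_level)


def robustness_table(rf_by_condition: dict[str, dict[str, float]]) -> pd.DataFrame:
    """Summarise Rf stability across development conditions.

    Parameters
    ----------
    rf_by_condition : mapping condition → {track → Rf}
        At least two conditions; every condition must report the same tracks.

    Returns
    -------
    DataFrame indexed by track with ``mean``, ``rsd``, ``spread`` and a
    ``pass`` flag (max − min Rf < 0.05).  Note a printed RSD can look small
    while the spread still breaches the 0.05 acceptance window; both are
    reported so the discrepancy is visible.
    """
    conditions = list(rf_by_condition)
    if len(conditions) < 2:
        raise DegenerateDataError("robustness needs >= 2 conditions")
    track_sets = [set(rf_by_condition[c]) for c in conditions]
    if any(s != track_sets[0] for s in track_sets[1:]):
        raise NumericalError("inconsistent track sets across conditions")
    rows = {}
    for track in rf_by_condition[conditions[0]]:
        vals = np.array([rf_by_condition[c][track] for c in conditions])
        spread = float(vals.max() - vals.min())
        rows[track] = {
            "mean": float(vals.mean()),
            "rsd": rsd(vals),
            "spread": spread,
            "pass": spread < RF_SPREAD_LIMIT,
        }
    return pd.DataFrame.from_dict(rows, orient="index")


@dataclass(frozen=True)
class RecoveryResult:
    """One spike-recovery experiment, recovery = 100·detected/(original+added)."""

    original: float  # µg/mL
    added: float  # µg/mL
    detected: float  # µg/mL
    recovery_percent: float
    rsd_percent: float | None = None


def recovery(original: float, added: float, detected: float,
             rsd_percent: float | None = None) -> RecoveryResult:
    """Spike-recovery accuracy of a quantification."""
    if added <= 0:
        raise NumericalError("added amount must be > 0")
    if original < 0 or detected < 0:
        raise NumericalError("original and detected must be >= 0")
    pct = 100.0 * detected / (original + added)
    return RecoveryResult(original, added, detected, float(pct), rsd_percent)


def spectral_correlation(a: Spectrum, b: Spectrum) -> float:
    """Pearson correlation of two UV spectra (specificity check, pass > 0.99).

    Spectra on different wavelength grids are brought onto the overlap of
    the two grids by linear interpolation.
    """
    if np.array_equal(a.wavelengths, b.wavelengths):
        ya, yb = a.absorbances, b.absorbances
    else:
        lo = max(a.wavelengths[0], b.wavelengths[0])
        hi = min(a.wavelengths[-1], b.wavelengths[-1])
        if not lo < hi:
            raise NumericalError("spectra have disjoint wavelength ranges")
        grid = np.linspace(lo, hi, 201)
        ya = np.interp(grid, a.wavelengths, a.absorbances)
        yb = np.interp(grid, b.wavelengths, b.absorbances)
    if np.std(ya) == 0 or np.std(yb) == 0:
        raise DegenerateDataError("zero-variance spectrum has no correlation")
    return float(stats.pearsonr(ya, yb).statistic)
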