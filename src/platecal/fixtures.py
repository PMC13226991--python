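"""Published reference data for the koumine HPTLC study, embedded verbatim.

These are the printed tables of the source study on *Gelsemium elegans*:
per-plate calibration equations, validation statistics, the reference-level
sensitivity matrix, per-sample koumine contents, and the editorial
part/province sample groupings.  They serve as golden data for tests and as
inputs to the aggregation and sensitivity computations; the package never
derives them.

``"--"`` cells of the content table (detection below the LOQ) are encoded as
censored records, not as zeros and not as missing values; zero imputation
happens only inside aggregation.
"""

from __future__ import annotations

from dataclasses import dataclass

__all__ = [
    "Table6Row",
    "RecoveryRow",
    "StudyFixtures",
    "load_study_fixtures",
]

# Per-plate calibration equations (peak area vs µg/mL), printed precision,
# as (a2, a1, a0, r_squared), plates 1..28.
TABLE2_CURVES: dict[int, tuple[float, float, float, float]] = {
    1: (-3e-09, 2e-05, 0.0005, 0.9999),
    2: (-3e-09, 2e-05, 0.0003, 0.9999),
    3: (-3e-09, 2e-05, 0.0002, 1.0),
    4: (-3e-09, 2e-05, 8e-05, 0.9999),
    5: (-3e-09, 2e-05, 0.0002, 0.9999),
    6: (-3e-09, 2e-05, 0.0002, 1.0),
    7: (-3e-09, 2e-05, 3e-05, 1.0),
    8: (-3e-09, 2e-05, -0.0004, 0.9999),
    9: (-3e-09, 2e-05, 0.0004, 0.9999),
    10: (-4e-09, 2e-05, 0.0004, 1.0),
    11: (-4e-09, 2e-05, 0.0004, 0.9999),
    12: (-4e-09, 2e-05, 0.0002, 0.9998),
    13: (-3e-09, 2e-05, -2e-05, 0.9995),
    14: (-3e-09, 2e-05, 8e-05, 0.9996),
    15: (-3e-09, 2e-05, -0.0008, 0.9996),
    16: (-3e-09, 2e-05, 0.0004, 0.9998),
    17: (-3e-09, 2e-05, 0.0002, 0.9997),
    18: (-3e-09, 2e-05, 0.0015, 0.9998),
    19: (-2e-09, 1e-05, 0.0013, 0.9997),
    20: (-3e-09, 2e-05, 0.0009, 0.9998),
    21: (-3e-09, 2e-05, 0.0003, 0.9998),
    22: (-3e-09, 2e-05, -0.001, 0.9997),
    23: (-4e-09, 2e-05, 0.0004, 0.9997),
    24: (-4e-09, 2e-05, 0.0007, 0.9999),
    25: (-2e-09, 2e-05, -0.0004, 0.9999),
    26: (-3e-09, 2e-05, 0.0003, 0.9998),
    27: (-4e-09, 2e-05, -0.0003, 0.9996),
    28: (-4e-09, 2e-05, 0.0009, 1.0),
}

# Intra-day precision / inter-day reproducibility RSD% per level (µg/mL).
TABLE1_PRECISION: dict[float, tuple[float, float]] = {
    125.0: (3.6082, 3.8781),
    250.0: (3.7736, 2.7730),
    500.0: (2.9773, 2.5772),
    1000.0: (1.7697, 1.5906),
    2000.0: (1.2907, 1.9726),
}

# Robustness Rf tables: row -> (rf_triple, printed_mean, printed_rsd).
TABLE3_SOLVENT_VOLUME = {
    "Koumine": ((0.570, 0.580, 0.590), 0.580, 1.7241),
    "Stem": ((0.570, 0.580, 0.580), 0.577, 1.0006),
    "Leaf": ((0.580, 0.590, 0.590), 0.587, 0.9836),
}
TABLE4_EQUILIBRATION = {
    "Koumine": ((0.550, 0.580, 0.590), 0.573, 3.6308),
    "Stem": ((0.550, 0.580, 0.600), 0.577, 4.3641),
    "Leaf": ((0.560, 0.580, 0.600), 0.580, 3.4483),
    "Root": ((0.550, 0.580, 0.610), 0.580, 5.1724),
}
TABLE5_DOSAGE_SPEED = {
    "Koumine": ((0.58, 0.58, 0.57), 0.577, 1.0012),
    "Stem": ((0.59, 0.58, 0.58), 0.583, 0.9897),
    "Leaf": ((0.59, 0.58, 0.57), 0.580, 1.7241),
    "Root": ((0.59, 0.57, 0.57), 0.577, 2.0024),
}


@dataclass(frozen=True)
class Table6Row:
    """One sample of the published content table.

    ``mean`` is µg koumine per mg dry material; ``pm`` the printed "±" value
    (stored verbatim — the study does not say whether it is an sd or an SEM,
    though RSD = 100·pm/mean holds row-wise); ``correlation`` the spectral
    specificity coefficient against pure koumine.  Censored rows (below the
    LOQ) carry ``None`` in every numeric field.
    """

    sample_id: str
    mean: float | None
    pm: float | None
    rsd: float | None
    correlation: float | None

    @property
    def censored(self) -> bool:
        return self.mean is None


_T6 = [
    ("GW001-S", 2.473, 0.097, 3.92, 0.9968),
    ("GW002-S", 1.273, 0.071, 5.58, 0.9972),
    ("GW003-S", 1.308, 0.068, 5.20, 0.996),
    ("GW004-S", 1.155, 0.046, 3.98, 0.9902),
    ("GW005-S", None, None, None, None),
    ("GW006-S", 4.220, 0.216, 5.12, 0.9981),
    ("GW007-S", 4.399, 0.179, 4.07, 0.9995),
    ("GW008-S", 2.843, 0.122, 4.29, 0.999),
    ("GW009-S", None, None, None, None),
    ("GW010-S", 5.629, 0.218, 3.87, 0.9975),
    ("GW011-S", 2.708, 0.106, 3.91, 0.9973),
    ("GW012-S", 7.454, 0.218, 3.77, 0.9979),
    ("GW013-S", 3.031, 0.118, 3.89, 0.9964),
    ("GW014-S", 1.500, 0.057, 3.80, 0.9941),
    ("GW015-S", 2.583, 0.099, 3.83, 0.9975),
    ("GW016-S", 1.223, 0.063, 5.15, None),
    ("GW017-S", 4.000, 0.194, 4.85, 0.997),
    ("GW018-S", 4.533, 0.191, 4.21, 0.997),
    ("GW019-S", 4.376, 0.165, 3.77, 0.9982),
    ("GW020-S", 4.920, 0.196, 3.98, 0.9973),
    ("GW021-S", 4.234, 0.164, 3.87, 0.9966),
    ("GW022-S", None, None, None, None),
    ("GW023-S", 3.299, 0.172, 5.21, 0.9977),
    ("GW024-S", 1.147, 0.044, 3.84, None),
    ("GW025-S", 1.637, 0.071, 4.34, 0.9947),
    ("GW026-S", 2.349, 0.098, 4.17, 0.9913),
    ("GW027-S", 1.466, 0.095, 6.48, 0.9985),
    ("GW028-S", None, None, None, None),
    ("GW029-S", None, None, None, None),
    ("GW030-S", 1.645, 0.070, 4.26, 0.9916),
    ("GW031-S", 1.130, 0.046, 4.07, 0.9976),
    ("GW032-S", 1.518, 0.059, 3.82, 0.9903),
    ("GW033-S", 1.879, 0.088, 4.58, 0.998),
    ("GW034-S", 1.539, 0.066, 4.29, 0.9992),
    ("GW035-S", 1.211, 0.079, 6.61, None),
    ("GW036-S", 2.008, 0.088, 4.33, 0.9989),
    ("GW037-S", None, None, None, None),
    ("GW038-S", 1.686, 0.116, 6.88, 0.9961),
    ("GW039-R", 7.000, 0.370, 5.29, 0.9907),
    ("GW040-R", 5.159, 0.212, 4.11, 0.993),
    ("GW041-R", 9.000, 0.352, 3.80, 0.9989),
    ("GW042-R", 3.717, 0.217, 5.87, 0.9972),
    ("GW043-R", 6.067, 0.234, 3.79, 0.9965),
    ("GW044-R", 1.322, 0.052, 3.86, 0.9982),
    ("GW045-R", 6.356, 0.261, 4.06, 0.9977),
    ("GW046-R", 7.561, 0.329, 4.32, 0.9957),
    ("GW047-R", 3.294, 0.124, 3.76, 0.9972),
    ("GW048-R", 7.418, 0.281, 3.77, 0.9977),
    ("GW049-R", None, None, None, None),
    ("GW050-R", 4.489, 0.174, 3.79, 0.9936),
    ("GW051-R", 5.696, 0.222, 3.79, 0.9911),
    ("GW052-L", None, None, None, None),
    ("GW053-L", 3.036, 0.118, 3.79, 0.9905),
    ("GW054-L", None, None, None, None),
    ("GW055-L", None, None, None, None),
    ("GW056-L", 1.945, 0.128, 6.58, None),
    ("GW057-L", None, None, None, None),
    ("GW058-L", None, None, None, None),
    ("GW059-L", 4.281, 0.181, 4.04, 0.9927),
    ("GW060-L", 1.609, 0.074, 4.60, 0.9902),
    ("GW061-L", None, None, None, None),
    ("GW062-L", 1.032, 0.047, 4.55, None),
    ("GW063-L", 2.255, 0.108, 4.74, 0.9921),
    ("GW064-L", None, None, None, None),
    ("GW065-L", 1.578, 0.072, 4.56, 0.9907),
    ("GW066-L", 3.044, 0.154, 5.03, 0.9903),
    ("GW067-L", 1.592, 0.086, 5.34, 0.9918),
]

TABLE6_CONTENTS: dict[str, Table6Row] = {
    sid: Table6Row(sid, *rest) for sid, *rest in _T6
}


@dataclass(frozen=True)
class RecoveryRow:
    """One spiking experiment of the published recovery table.

    ``printed_recovery`` is reproduced verbatim; the Stem row's printed
    109.49% does not follow from detected/(original+added) (which gives
    100.68%) under any standard recovery formula and is flagged as a
    suspected erratum (``erratum=True``), excluded from golden checks.
    """

    part: str
    original: float  # µg/mL
    added: float  # µg/mL
    detected: float  # µg/mL
    detected_pm: float
    printed_recovery: float  # %
    rsd: float  # %
    erratum: bool = False


TABLE7_RECOVERY: dict[str, RecoveryRow] = {
    "Stem": RecoveryRow("Stem", 247.30, 250.00, 500.68, 19.46, 109.49, 3.89,
                        erratum=True),
    "Leaf": RecoveryRow("Leaf", 228.10, 250.00, 456.49, 18.31, 95.48, 4.01),
    "Root": RecoveryRow("Root", 498.80, 500.00, 987.40, 37.29, 98.86, 3.78),
}

# Reference-level sensitivity matrix: signed % difference between the
# factor-corrected mean-curve quantification and the plate-specific one,
# for ten plates and five candidate reference levels (keyed in mg/mL).
TABLE8_SENSITIVITY: dict[str, dict[float, float]] = {
    "Plate 1": {0.0625: -31.75, 0.125: 9.42, 0.25: -3.74, 0.5: 1.52, 1.0: 2.41},
    "Plate 10": {0.0625: -28.83, 0.125: 7.39, 0.25: -0.21, 0.5: 2.95, 1.0: 14.46},
    "Plate 11": {0.0625: -39.84, 0.125: 3.41, 0.25: -3.69, 0.5: 2.43, 1.0: 13.07},
    "Plate 12": {0.0625: 75.34, 0.125: 4.80, 0.25: -0.09, 0.5: 17.54, 1.0: 5.72},
    "Plate 21": {0.0625: 42.06, 0.125: 14.68, 0.25: 1.36, 0.5: -1.54, 1.0: 9.94},
    "Plate 23": {0.0625: -20.93, 0.125: 2.39, 0.25: 5.78, 0.5: 4.64, 1.0: 5.29},
    "Plate 25": {0.0625: 11.72, 0.125: 5.36, 0.25: 4.60, 0.5: 6.74, 1.0: 27.66},
    "Plate 26": {0.0625: -25.30, 0.125: -8.76, 0.25: -0.07, 0.5: -0.91, 1.0: 6.69},
    "Plate 27": {0.0625: -14.85, 0.125: -13.19, 0.25: 1.00, 0.5: -1.04, 1.0: 4.51},
    "Plate 28": {0.0625: 0.08, 0.125: -10.69, 0.25: 1.87, 0.5: -0.51, 1.0: 5.39},
}

# Editorial part/province subgroups (11 matched stem/root/leaf triples,
# 7 locations in Fujian and 4 in Guangxi).
SUBGROUPS: dict[str, dict[str, list[str]]] = {
    "Fujian": {
        "stem": ["GW037-S", "GW035-S", "GW023-S", "GW012-S", "GW033-S",
                 "GW034-S", "GW027-S"],
        "root": ["GW051-R", "GW050-R", "GW046-R", "GW041-R", "GW045-R",
                 "GW043-R", "GW048-R"],
        "leaf": ["GW052-L", "GW058-L", "GW059-L", "GW056-L", "GW066-L",
                 "GW067-L", "GW061-L"],
    },
    "Guangxi": {
        "stem": ["GW032-S", "GW022-S", "GW029-S", "GW024-S"],
        "root": ["GW049-R", "GW044-R", "GW042-R", "GW040-R"],
        "leaf": ["GW062-L", "GW063-L", "GW053-L", "GW054-L"],
    },
}

# Study-level constants.
MEAN_LOD_UG_ML = 30.6595
MEAN_LOQ_UG_ML = 92.9075
REFERENCE_LEVEL_UG_ML = 250.0
U_FACTOR_REL_PCT = 3.77  # = Table 1 intra-day RSD at the 250 µg/mL reference
PCT_DIFF_VARIANCE = 1.69  # %², published dispersion of method differences
PAIRED_TEST = {"p": 0.506, "t": 0.668, "correlation": 0.987}
LOA_CONTENT = (-0.07, 0.06)  # µg/mg, published 95% limits of agreement
EQUIVALENCE_MARGIN_REL_PCT = 5.0
EQUIVALENCE_MARGIN_ABS_UG_MG = 0.15
EXPANDED_UNCERTAINTY_BAND_PCT = (4.5, 8.8)

# The published cross-plate mean calibration equation, stored verbatim.
# Its coefficients are numerically incompatible with the per-plate
# equations above under any single unit choice for x, so it is never used
# for computation — a documented inconsistency of the source tables.
PRINTED_MEAN_CURVE = {"a2": 8.08e-04, "a1": 0.0406, "a0": -0.0188,
                      "r_squared": 0.998}


@dataclass(frozen=True)
class StudyFixtures:
    """Bundle of the embedded study tables (dict-style access supported)."""

    table1: dict
    table2: dict
    table3: dict
    table4: dict
    table5: dict
    table6: dict[str, Table6Row]
    table7: dict[str, RecoveryRow]
    table8: dict[str, dict[float, float]]
    subgroups: dict[str, dict[str, list[str]]]
    constants: dict

    def __getitem__(self, key: str):
        return getattr(self, key)


def load_study_fixtures() -> StudyFixtures:
    """Return the embedded study tables.

    Examples
    --------
    >>> fx = load_study_fixtures()
    >>> fx["table6"]["GW001-S"].mean
    2.473
    >>> fx["table8"]["Plate 12"][0.25]
    -0.09
    """
    return StudyFixtures(
        table1=TABLE1_PRECISION,
        table2=TABLE2_CURVES,
        table3=TABLE3_SOLVENT_VOLUME,
        table4=TABLE4_EQUILIBRATION,
        table5=TABLE5_DOSAGE_SPEED,
        table6=TABLE6_CONTENTS,
        table7=TABLE7_RECOVERY,
        table8=TABLE8_SENSITIVITY,
        subgroups=SUBGROUPS,
        constants={
            "mean_lod": MEAN_LOD_UG_ML,
            "mean_loq": MEAN_LOQ_UG_ML,
            "reference_level": REFERENCE_LEVEL_UG_ML,
            "u_factor_rel": U_FACTOR_REL_PCT,
            "pct_diff_variance": PCT_DIFF_VARIANCE,
            "paired_test": PAIRED_TEST,
            "loa_content": LOA_CONTENT,
            "margin_rel": EQUIVALENCE_MARGIN_REL_PCT,
            "margin_abs": EQUIVALENCE_MARGIN_ABS_UG_MG,
            "expanded_band": EXPANDED_UNCERTAINTY_BAND_PCT,
            "printed_mean_curve": PRINTED_MEAN_CURVE,
        },
    )
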