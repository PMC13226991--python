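"""Domain types and plate-table I/O.

The densitometric unit of work is one HPTLC plate: a set of standard tracks
(known concentration, measured peak area) and a set of sample tracks
(unknown concentration, measured peak area at the analyte's Rf).  All
concentrations are held internally in µg/mL; mg/mL inputs are converted at
the I/O boundary.

CSV schema (long format, one row per track)::

    plate_id, kind, level_or_sample_id, concentration, unit, peak_area, rf

``kind`` is ``standard`` or ``sample``; ``concentration``/``unit`` apply to
standards, ``rf`` to samples.  ``unit`` may be ``ug/mL`` (default) or
``mg/mL`` (values multiplied by 1000 on read).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import SchemaError

__all__ = [
    "StandardPoint",
    "SampleTrack",
    "PlateTable",
    "SampleMetadata",
    "Spectrum",
    "read_plate_table",
    "read_plate_tables",
    "write_plate_table",
    "read_metadata",
    "write_metadata",
    "read_spectrum",
    "write_spectrum",
]

#: multiplicative conversion into the canonical µg/mL
_UNIT_FACTORS = {"ug/ml": 1.0, "µg/ml": 1.0, "mg/ml": 1000.0}

PLATE_COLUMNS = [
    "plate_id",
    "kind",
    "level_or_sample_id",
    "concentration",
    "unit",
    "peak_area",
    "rf",
]


@dataclass(frozen=True)
class StandardPoint:
    """One calibration track: a known concentration and its peak area.

    Parameters
    ----------
    level_id : str
        Label of the calibration level (e.g. ``"250"``).
    concentration : float
        Analyte concentration in µg/mL; must be positive.
    peak_area : float
        Densitometric peak area (AU); must be finite.
    """

    level_id: str
    concentration: float
    peak_area: float

    def __post_init__(self) -> None:
        if not (self.concentration > 0):
            raise SchemaError(
                f"standard {self.level_id!r}: concentration must be > 0, "
                f"got {self.concentration!r}"
            )
        if not math.isfinite(self.peak_area):
            raise SchemaError(
                f"standard {self.level_id!r}: peak_area must be finite"
            )


@dataclass(frozen=True)
class SampleTrack:
    """One sample track: measured peak area at the analyte's Rf."""

    sample_id: str
    peak_area: float
    rf: float = 0.58
    replicate_index: int = 0

    def __post_init__(self) -> None:
        if not (0.0 <= self.rf <= 1.0):
            raise SchemaError(
                f"sample {self.sample_id!r}: rf must lie in [0, 1], got {self.rf!r}"
            )
        if not (self.peak_area >= 0):
            raise SchemaError(
                f"sample {self.sample_id!r}: peak_area must be >= 0"
            )


@dataclass
class PlateTable:
    """One plate's standards and sample tracks — the unit of calibration."""

    plate_id: str
    standards: list[StandardPoint] = field(default_factory=list)
    samples: list[SampleTrack] = field(default_factory=list)

    def __post_init__(self) -> None:
        n_levels = len({s.concentration for s in self.standards})
        if n_levels < 3:
            raise SchemaError(
                f"plate {self.plate_id!r}: insufficient calibration levels "
                f"({n_levels} distinct concentrations; a quadratic fit needs >= 3)"
            )

    @property
    def levels(self) -> list[float]:
        """Sorted distinct standard concentrations (µg/mL)."""
        return sorted({s.concentration for s in self.standards})

    def standard_area(self, concentration: float, rtol: float = 1e-9) -> float:
        """Mean observed peak area of the standard track(s) at ``concentration``.

        Raises
        ------
        SchemaError
            If no standard at that level is present on the plate.
        """
        areas = [
            s.peak_area
            for s in self.standards
            if math.isclose(s.concentration, concentration, rel_tol=rtol)
        ]
        if not areas:
            raise SchemaError(
                f"plate {self.plate_id!r}: no standard at {concentration} ug/mL"
            )
        return float(np.mean(areas))


@dataclass(frozen=True)
class SampleMetadata:
    """Per-sample study metadata: plant part, province, extraction factors.

    ``part`` is one of ``stem``/``root``/``leaf``; ids follow the -S/-R/-L
    suffix convention and the two must agree.  ``mass_mg`` and ``volume_mL``
    turn a solution concentration into dry-weight content.
    """

    sample_id: str
    part: str
    province: str = ""
    plate_id: str = ""
    mass_mg: float = 100.0
    volume_mL: float = 1.0

    _SUFFIX = {"S": "stem", "R": "root", "L": "leaf"}

    def __post_init__(self) -> None:
        if self.part not in ("stem", "root", "leaf"):
            raise SchemaError(
                f"{self.sample_id!r}: part must be stem/root/leaf, got {self.part!r}"
            )
        if not (self.mass_mg > 0 and self.volume_mL > 0):
            raise SchemaError(f"{self.sample_id!r}: mass and volume must be > 0")
        suffix = self.sample_id.rsplit("-", 1)[-1] if "-" in self.sample_id else ""
        if suffix in self._SUFFIX and self._SUFFIX[suffix] != self.part:
            raise SchemaError(
                f"{self.sample_id!r}: id suffix -{suffix} conflicts with part "
                f"{self.part!r}"
            )


@dataclass(frozen=True)
class Spectrum:
    """An in-situ UV absorbance spectrum on the 200–400 nm scanning grid."""

    wavelengths: np.ndarray
    absorbances: np.ndarray

    def __post_init__(self) -> None:
        wl = np.asarray(self.wavelengths, dtype=float)
        ab = np.asarray(self.absorbances, dtype=float)
        object.__setattr__(self, "wavelengths", wl)
        object.__setattr__(self, "absorbances", ab)
        if wl.shape != ab.shape or wl.ndim != 1:
            raise SchemaError("spectrum: wavelength and absorbance lengths differ")
        if wl.size >= 2 and not np.all(np.diff(wl) > 0):
            raise SchemaError("spectrum: wavelengths must be strictly increasing")


# ---------------------------------------------------------------------------
# CSV I/O


def _unit_factor(unit: str, row: int) -> float:
    key = str(unit).strip().lower().replace("μ", "µ").replace("µ", "u")
    key = key.replace("u", "u")  # normalised
    for name, factor in _UNIT_FACTORS.items():
        if key == name.replace("µ", "u"):
            return factor
    raise SchemaError(f"row {row}: unknown concentration unit {unit!r}")


def _plates_from_frame(df: pd.DataFrame) -> list[PlateTable]:
    missing = [c for c in PLATE_COLUMNS[:6] if c not in df.columns]
    if missing:
        raise SchemaError(f"plate table: missing columns {missing}")
    plates: list[PlateTable] = []
    for plate_id, sub in df.groupby("plate_id", sort=False):
        standards: list[StandardPoint] = []
        samples: list[SampleTrack] = []
        replicate_counter: dict[str, int] = {}
        for idx, row in sub.iterrows():
            kind = str(row["kind"]).strip().lower()
            try:
                area = float(row["peak_area"])
            except (TypeError, ValueError):
                raise SchemaError(
                    f"row {idx}: non-numeric peak_area {row['peak_area']!r}"
                ) from None
            label = str(row["level_or_sample_id"])
            if kind == "standard":
                try:
                    conc = float(row["concentration"])
                except (TypeError, ValueError):
                    raise SchemaError(
                        f"row {idx}: non-numeric concentration "
                        f"{row['concentration']!r}"
                    ) from None
                unit = row.get("unit", "ug/mL")
                if pd.isna(unit) or str(unit).strip() == "":
                    unit = "ug/mL"
                conc *= _unit_factor(unit, idx)
                standards.append(StandardPoint(label, conc, area))
            elif kind == "sample":
                rf = row.get("rf", np.nan)
                rf = 0.58 if pd.isna(rf) else float(rf)
                if "replicate_index" in sub.columns and not pd.isna(
                    row.get("replicate_index")
                ):
                    rep = int(row["replicate_index"])
                else:
                    rep = replicate_counter.get(label, 0)
                    replicate_counter[label] = rep + 1
                samples.append(SampleTrack(label, area, rf, rep))
            else:
                raise SchemaError(
                    f"row {idx}: kind must be 'standard' or 'sample', got {kind!r}"
                )
        plates.append(PlateTable(str(plate_id), standards, samples))
    return plates


def read_plate_tables(path) -> list[PlateTable]:
    """Read a long-format CSV holding one or more plates."""
    df = pd.read_csv(path)
    plates = _plates_from_frame(df)
    if not plates:
        raise SchemaError(f"{path}: no plate rows found")
    return plates


def read_plate_table(path) -> PlateTable:
    """Read a long-format CSV holding exactly one plate."""
    plates = read_plate_tables(path)
    if len(plates) != 1:
        raise SchemaError(
            f"{path}: expected a single plate, found {len(plates)} "
            f"({[p.plate_id for p in plates]})"
        )
    return plates[0]


def plates_to_frame(plates: list[PlateTable] | PlateTable) -> pd.DataFrame:
    """Serialise plates to the documented long-format table (µg/mL)."""
    if isinstance(plates, PlateTable):
        plates = [plates]
    rows = []
    for plate in plates:
        for s in plate.standards:
            rows.append(
                (plate.plate_id, "standard", s.level_id, s.concentration,
                 "ug/mL", s.peak_area, "", "")
            )
        for t in plate.samples:
            rows.append(
                (plate.plate_id, "sample", t.sample_id, "", "", t.peak_area,
                 t.rf, t.replicate_index)
            )
    return pd.DataFrame(rows, columns=PLATE_COLUMNS + ["replicate_index"])


def write_plate_table(plates, path) -> None:
    """Write one plate or a list of plates to CSV."""
    plates_to_frame(plates).to_csv(path, index=False)


def read_metadata(path) -> dict[str, SampleMetadata]:
    """Read the sample metadata CSV into a mapping keyed by sample id."""
    df = pd.read_csv(path)
    required = {"sample_id", "part"}
    missing = required - set(df.columns)
    if missing:
        raise SchemaError(f"metadata: missing columns {sorted(missing)}")
    out: dict[str, SampleMetadata] = {}
    for _, row in df.iterrows():
        md = SampleMetadata(
            sample_id=str(row["sample_id"]),
            part=str(row["part"]),
            province=str(row.get("province", "") or ""),
            plate_id=str(row.get("plate_id", "") or ""),
            mass_mg=float(row.get("mass_mg", 100.0)),
            volume_mL=float(row.get("volume_mL", 1.0)),
        )
        out[md.sample_id] = md
    return out


def write_metadata(metadata: dict[str, SampleMetadata], path) -> None:
    pd.DataFrame([vars(m) for m in metadata.values()]).to_csv(path, index=False)


def read_spectrum(path) -> Spectrum:
    """Read a two-column (wavelength_nm, absorbance) CSV."""
    df = pd.read_csv(path)
    if df.shape[1] < 2:
        raise SchemaError(f"{path}: spectrum CSV needs two columns")
    return Spectrum(df.iloc[:, 0].to_numpy(float), df.iloc[:, 1].to_numpy(float))


def write_spectrum(spectrum: Spectrum, path) -> None:
    pd.DataFrame(
        {"wavelength_nm": spectrum.wavelengths, "absorbance": spectrum.absorbances}
    ).to_csv(path, index=False)
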