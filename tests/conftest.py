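"""Shared fixtures: reference-scale curves and hand-built study objects."""

import pytest

from platecal import (
    PlateTable,
    SampleMetadata,
    SampleQuantResult,
    SampleTrack,
    StandardPoint,
    load_study_fixtures,
)

# the five validated working-range levels, µg/mL
WORKING_LEVELS = (125.0, 250.0, 500.0, 1000.0, 2000.0)
# the five calibration-transfer levels, µg/mL
TRANSFER_LEVELS = (62.5, 125.0, 250.0, 500.0, 1000.0)


def quadratic(a2, a1, a0):
    return lambda c: a2 * c * c + a1 * c + a0


@pytest.fixture(scope="session")
def fixtures():
    return load_study_fixtures()


@pytest.fixture
def plate1_curve_fn():
    """Plate 1's published calibration as a callable."""
    return quadratic(-3e-09, 2e-05, 0.0005)


def make_standards(fn, levels=WORKING_LEVELS, scale=1.0):
    return [StandardPoint(f"{c:g}", c, scale * fn(c)) for c in levels]


def make_plate(plate_id, fn, levels=TRANSFER_LEVELS, scale=1.0,
               sample_concs=(), replicates=1):
    standards = make_standards(fn, levels, scale)
    samples = []
    for i, c in enumerate(sample_concs):
        for rep in range(replicates):
            samples.append(
                SampleTrack(f"{plate_id}-S{i + 1}", scale * fn(c), 0.58, rep)
            )
    return PlateTable(plate_id, standards, samples)


@pytest.fixture
def linear_fn():
    return quadratic(0.0, 2e-05, 0.0)


def table6_quant_results(fixtures):
    """Table-6 pass-through: published contents as quantification results."""
    out = []
    for sid, row in fixtures.table6.items():
        out.append(
            SampleQuantResult(
                sample_id=sid,
                conc_solution=(row.mean or 0.0) * 100.0,  # 100 mg / 1 mL
                content=row.mean or 0.0,
                censored=row.censored,
                rsd_percent=row.rsd,
            )
        )
    return out


def subgroup_metadata(fixtures):
    """Province/part metadata for the 33 editorially matched samples."""
    md = {}
    part_of = {"stem": "stem", "root": "root", "leaf": "leaf"}
    for province, parts in fixtures.subgroups.items():
        for part, ids in parts.items():
            for sid in ids:
                md[sid] = SampleMetadata(
                    sample_id=sid, part=part_of[part], province=province
                )
    return md
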