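"""Model/Results interface over the calibration-transfer pipeline.

:class:`CalibrationStudy` is built from plate tables (optionally with
sample metadata and a :class:`~platecal.quantify.RunConfig`); ``fit()``
fits all per-plate curves, the mean calibration, LOD/LOQ, per-plate
factors and the per-sample quantification, returning a
:class:`CalibrationStudyResults` that carries the estimates, their
uncertainty budgets, diagnostics and a ``summary()`` table.  Equivalence
statistics, the reference-level sensitivity analysis and the ratio-plot
diagnostic hang off the results object.

>>> from platecal import CalibrationStudy, SimConfig
>>> res = CalibrationStudy.from_simulation(SimConfig(seed=7)).fit()
>>> print(res.summary())            # doctest: +SKIP
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .data import PlateTable, SampleMetadata, read_metadata, read_plate_tables
from .equivalence import (
    BlandAltmanResult,
    PairedTestResult,
    RatioDiagnostic,
    bland_altman,
    paired_t_test,
    ratio_diagnostic,
)
from .errors import NumericalError
from .factor import SensitivityTable, sensitivity_analysis
from .quantify import RunConfig, StudyReport, run_study
from .simulate import SimConfig, _invert_tolerant, simulate_study

__all__ = ["CalibrationStudy", "CalibrationStudyResults"]


class CalibrationStudy:
    """A multi-plate HPTLC quantification study, ready to fit.

    Parameters
    ----------
    plates : list of PlateTable
        The study's plates (standards + sample tracks).
    metadata : mapping sample id → SampleMetadata, optional
        Plant part / province / extraction factors per sample.
    config : RunConfig, optional
        Pipeline settings (reference level, correction mode, margins, ...).
    """

    def __init__(self, plates: list[PlateTable],
                 metadata: dict[str, SampleMetadata] | None = None,
                 config: RunConfig | None = None):
        if not plates:
            raise NumericalError("a study needs at least one plate")
        self.plates = list(plates)
        self.metadata = metadata
        self.config = config or RunConfig()
        self.truth = None  # filled by from_simulation

    @classmethod
    def from_csv(cls, plates_path, metadata_path=None,
                 config: RunConfig | None = None) -> "CalibrationStudy":
        plates = read_plate_tables(plates_path)
        metadata = read_metadata(metadata_path) if metadata_path else None
        return cls(plates, metadata, config)

    @classmethod
    def from_simulation(cls, sim_config: SimConfig,
                        config: RunConfig | None = None) -> "CalibrationStudy":
        study = simulate_study(sim_config)
        obj = cls(study.plates, None, config)
        obj.truth = study.truth
        return obj

    def fit(self) -> "CalibrationStudyResults":
        """Fit curves, factor and quantification; return the results."""
        report = run_study(self.plates, self.metadata, self.config)
        return CalibrationStudyResults(self, report)


class CalibrationStudyResults:
    """Fitted study: curves, factors, quantification, diagnostics."""

    def __init__(self, model: CalibrationStudy, report: StudyReport):
        self.model = model
        self.report = report

    # -- direct access -----------------------------------------------------
    @property
    def plate_curves(self):
        return self.report.plate_curves

    @property
    def mean_calibration(self):
        return self.report.mean_calibration

    @property
    def factors(self):
        return self.report.factors

    @property
    def lod(self):
        return self.report.lod

    @property
    def loq(self):
        return self.report.loq

    @property
    def results(self):
        return self.report.results

    @property
    def aggregates(self):
        return self.report.aggregates

    def per_sample(self) -> pd.DataFrame:
        return self.report.per_sample_frame()

    # -- diagnostics -------------------------------------------------------
    def paired_concentrations(self) -> pd.DataFrame:
        """Transferred vs plate-specific concentration for every sample.

        Both methods quantify the same replicate-mean areas; this is the
        paired series behind the equivalence statistics.
        """
        rows = []
        for plate in self.model.plates:
            pc = self.report.plate_curves[plate.plate_id]
            fac = self.report.factors.get(plate.plate_id)
            if fac is None:
                continue
            by_sample: dict[str, list[float]] = {}
            for t in plate.samples:
                by_sample.setdefault(t.sample_id, []).append(t.peak_area)
            for sid, areas in by_sample.items():
                area = float(np.mean(areas))
                try:
                    c_plate = _invert_tolerant(pc, area)
                    match = [r for r in self.report.results
                             if r.sample_id == sid]
                    if not match:
                        continue
                    rows.append((sid, plate.plate_id, match[0].conc_solution,
                                 c_plate))
                except NumericalError:
                    continue
        return pd.DataFrame(
            rows, columns=["sample_id", "plate_id", "c_iterative", "c_plate"]
        )

    def equivalence(self, margin_rel: float | None = None,
                    margin_abs: float | None = None
                    ) -> tuple[PairedTestResult, BlandAltmanResult]:
        """Paired t-test and Bland–Altman of transferred vs plate-specific."""
        cfg = self.report.config
        pairs = self.paired_concentrations()
        t = paired_t_test(pairs.c_iterative, pairs.c_plate)
        ba = bland_altman(
            pairs.c_iterative.to_numpy(), pairs.c_plate.to_numpy(),
            margin_rel if margin_rel is not None else cfg.margin_rel,
            margin_abs if margin_abs is not None else cfg.margin_abs,
        )
        return t, ba

    def sensitivity(self, candidate_levels=None) -> SensitivityTable:
        """Reference-level sensitivity analysis on this study's plates."""
        levels = (candidate_levels if candidate_levels is not None
                  else self.report.config.candidate_levels)
        return sensitivity_analysis(
            self.model.plates, self.report.mean_calibration, list(levels)
        )

    def ratio_plot(self, **kwargs) -> RatioDiagnostic:
        """Observed/mean response ratios across the standard levels."""
        levels = sorted(
            set.intersection(*(set(p.levels) for p in self.model.plates))
        )
        if len(levels) < 2:
            raise NumericalError("no shared level grid across plates")
        responses = np.array(
            [[p.standard_area(lvl) for lvl in levels] for p in self.model.plates]
        )
        return ratio_diagnostic(levels, responses, **kwargs)

    # -- presentation ------------------------------------------------------
    def summary(self) -> str:
        """Plain-text study summary (curves, limits, factors, contents)."""
        rep = self.report
        mc = rep.mean_calibration
        lines = [
            "Calibration-transfer study summary",
            "=" * 50,
            f"plates: {len(self.model.plates)}   samples quantified: "
            f"{len(rep.results)}   censored (< LOQ): "
            f"{sum(r.censored for r in rep.results)}",
            f"mean calibration: y = {mc.a2:.3e}x^2 + {mc.a1:.3e}x + "
            f"{mc.a0:.3e}  (mean R^2 = {mc.r_squared:.4f})",
            f"working range: {mc.conc_range[0]:g}-{mc.conc_range[1]:g} ug/mL",
            f"mean LOD = {rep.lod:.4f} ug/mL   mean LOQ = {rep.loq:.4f} ug/mL",
            f"reference level: {rep.config.reference_level:g} ug/mL "
            f"({rep.config.correction_mode}-domain correction)",
        ]
        if rep.factors:
            f_vals = [f.factor for f in rep.factors.values()]
            lines.append(
                f"iterative factors: median {np.median(f_vals):.4f} "
                f"(range {min(f_vals):.4f}-{max(f_vals):.4f})"
            )
        if rep.results:
            exp = [r.budget.expanded_rel for r in rep.results if r.budget]
            lines.append(
                f"expanded uncertainty (k={rep.config.coverage_k:g}): "
                f"mean {np.mean(exp):.2f}%  range {min(exp):.2f}-"
                f"{max(exp):.2f}%"
            )
        if rep.aggregates:
            lines.append("-" * 50)
            lines.append("group aggregates (zero-imputed means, ug/mg):")
            for a in rep.aggregates:
                rng = ("" if a.min_detected is None else
                       f"  ({a.min_detected:.3f}-{a.max_detected:.3f})")
                lines.append(
                    f"  {a.group[0]:>6s}/{a.group[1]:<8s} n={a.n_total:<3d} "
                    f"censored={a.n_censored:<3d} mean={a.mean_content:.3f}"
                    f"{rng}"
                )
        if rep.errors:
            lines.append(f"stage errors: {len(rep.errors)} (see .report.errors)")
        return "\n".join(lines)

    def __repr__(self) -> str:  # pragma: no cover
        return (f"<CalibrationStudyResults: {len(self.model.plates)} plates, "
                f"{len(self.report.results)} samples>")
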