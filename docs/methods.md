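# Methods

This note records the statistical model behind `platecal`, the conventions
and defaults it commits to, what the synthetic-data generator does and does
not emulate, and the numerical choices a maintainer should know about.

## Calibration model

Densitometric peak area responds to concentration through a second-order
polynomial y = a₂x² + a₁x + a₀ (y in AU, x in µg/mL), fitted per plate by
ordinary least squares. The quadratic term captures the saturation of
optical response at high band loads; over the default working levels
(62.5–1000 µg/mL at the reference scale, areas ≈ 0.002–0.02 AU) the
curvature is mild and the fitted response is strictly increasing. All
concentrations are carried internally in µg/mL; mg/mL inputs convert at
the I/O boundary, which removes the 1000× ambiguity that arises when both
unit systems appear in one workflow.

Fits retain their residual standard error and coefficient covariance
s²(XᵀX)⁻¹ so that regression uncertainty can be propagated later.
An optional 1/x² weighting is exposed for the acknowledged
heteroscedasticity of densitometric responses but is off by default: the
plain polynomial calibration is the convention this workflow follows, and
the validation statistics are defined against it.

**Monotonicity and inversion.** Inverse prediction solves
a₂c² + a₁c + (a₀ − A) = 0 in closed form and returns the unique root in
the calibrated range. Monotonicity over the range (vertex −a₁/2a₂ outside
it) is checked at fit time and flagged, so the admissible root is
unambiguous; a curve with two in-range roots raises instead of choosing
silently. When |a₂| is negligible at the scale of the range the linear
solution is used. Areas outside [y(min), y(max)] raise a range error;
pipeline code that quantifies noisy tracks widens the admissible range by
25% of the span so measurement noise at the range edges does not abort a
study.

**Mean calibration curve.** The study-level curve is the coefficient-wise
arithmetic mean of the per-plate fits — not a refit on pooled points —
with range equal to the intersection of the per-plate ranges. Its
coefficient covariance is the empirical covariance of the per-plate
coefficient vectors divided by the number of plates (the sampling
covariance of the mean), which carries plate-to-plate scatter into the
uncertainty budget. Its recorded R² is the mean of the inputs' values and
is a diagnostic only.

**LOD/LOQ.** LOD = 3.3·SE/S and LOQ = 10·SE/S, so LOQ/LOD = 10/3.3 by
construction. SE is operationalised as the residual standard error of a
straight-line fit over the three lowest levels (the approximately linear
subrange), in response units, and S as that line's slope. This choice is
isolated in one function (`low_level_se_slope`) so alternatives (e.g. the
intercept's standard error) can be swapped in. Study-level limits are the
arithmetic means of the per-plate values.

## The iterative factor

The per-plate scaling factor is the ratio of the mean curve's predicted
area at one reference level to the plate's observed area there. Despite
the name, the procedure is a single-pass ratio: an optional fixed-point
mode that re-derives the factor from corrected areas converges to the same
value after one update and exists only to make that explicit.

Two conventions are deliberate:

- **Correction domain.** The default multiplies the *concentration* by the
  factor after inverting the mean curve; the documented alternative scales
  the *response* before inversion. For a linear response the two coincide
  and cancel a multiplicative plate effect exactly (an analytic property
  the tests assert); for the quadratic they differ by a curvature term of
  roughly 0.15·|g−1| in relative concentration at mid-range (g the plate
  effect), i.e. below 1% for plate effects within ±6%. The concentration-
  domain default matches the order of operations this workflow defines.
- **Reference-area source.** In the full pipeline the plate's observed
  reference area defaults to the plate's *fitted* calibration evaluated at
  the reference level, which smooths single-track noise through all of the
  plate's standards; `ref_area_source="observed"` uses the raw reference
  track instead, which is the right choice when a plate carries only the
  single reference standard. The sensitivity analysis always uses the raw
  observed track at each candidate level, since its purpose is to compare
  the levels as they were measured.

**Reference-level sensitivity.** For each plate and each candidate level
the factor is derived from that level and every sample track is quantified
both ways (factor-corrected mean curve vs the plate's own curve); the cell
is the mean signed percentage difference. Column means are signed
arithmetic means over plates; the selected level minimises the absolute
column mean, with exact ties resolved toward the level nearest the
geometric mid-range (mid-range levels have the best signal-to-noise
trade-off: above the additive baseline floor, below the saturating top).
A level missing on a plate flags that cell and drops it from the mean
rather than failing the analysis.

## Validation conventions

- RSD = 100 · sample standard deviation (n−1) / mean, everywhere. The
  embedded robustness tables reproduce to four decimals under this
  convention — with one caveat: two rows of the solvent-volume table were
  evidently printed with the standard deviation divided by the mean
  *rounded to three decimals* rather than the exact mean (1.0006 vs the
  exact 1.0012, and 0.9836 vs 0.9841). The golden sweep therefore accepts
  a printed RSD that matches either computation at 4 d.p.; `rsd()` itself
  always uses the exact mean.
- Robustness passes when the Rf spread (max − min across conditions) is
  below 0.05. A row can reproduce its printed RSD and still breach the
  window (the equilibration-time root row spans 0.06); both numbers are
  reported so the discrepancy is visible rather than hidden.
- Recovery = 100·detected/(original + added). The embedded stem recovery
  row is flagged as a suspected erratum: its printed 109.49% does not
  follow from its own inputs under any standard recovery formula (the
  computed value is 100.68%); it is excluded from golden checks.
- Spectral specificity is the Pearson correlation of two absorbance
  vectors on the 200–400 nm grid (linear interpolation onto the overlap
  when grids differ), passing above 0.99.

## Equivalence analysis

The paired series compares transferred vs plate-specific quantification of
the *same* replicate-mean areas. Three views:

- **Paired t-test** (two-sided) with the Pearson correlation of the pair
  and the sample variance of signed percentage differences. The variance
  of percentage differences is the dispersion statistic with a < 2%
  acceptance reading; it is reported as an interpretation (the underlying
  definition is the sample variance of 100·(x−y)/y) with the threshold
  configurable. Note the built-in circularity: the reference standard that
  drives the factor also participates in the plate-specific fit, which
  deflates the differences; deriving the factor from the raw observed
  track (`ref_area_source="observed"`) while fitting the plate curve on
  all standards is the closest available held-out variant, and spike
  recovery provides the external check.
- **Bland–Altman** with limits of agreement at mean ± 1.96·sd (normal
  95%, no small-sample t correction, standard practice for this analysis)
  and an a-priori equivalence margin max(0.15 µg/mg, 5% of the grand
  mean); equivalence requires both limits inside ±margin.
- **Ratio diagnostic.** Ratios of observed to mean response per level,
  with per-level dispersion and per-plate slopes of ratio vs log₁₀(c).
  The verdict is "multiplicative-dominant" when the median absolute
  high-range slope is below an effective threshold of
  max(0.02, 3 × the median slope standard error implied by the plates'
  own fit residuals). The threshold is noise-scaled on purpose: random
  track noise inflates the slopes and their standard errors in step, so
  only a *systematic* high-range trend (e.g. a common additive offset,
  which makes the ratio g + ε/(b·c), strictly decreasing) triggers
  "mixed". The low-to-high dispersion ratio is reported separately as the
  additive-noise signature at the bottom of the range.

## Uncertainty budgets

Relative standard uncertainties combine by root sum of squares:

u² = u_cal² + u_rep² + u_factor²,  U = k·u.

- **u_cal** — regression uncertainty of the mean calibration at the
  sample's concentration: the standard error of the fitted mean response
  (from the retained coefficient covariance) divided by the local slope,
  relative to the concentration. Linearised propagation; a parametric
  bootstrap cross-checks it in the tests within 10%.
- **u_rep** — repeatability of the sample's replicate tracks, as the RSD
  of the replicate areas divided by √n. The reported content is the
  replicate mean, so its standard uncertainty is the standard error of
  that mean.
- **u_factor** — the single-point factor's relative uncertainty, default
  3.77% (the intra-day precision RSD at the 250 µg/mL reference level),
  supplied as configuration rather than hard-coded.
- **k** — coverage factor, default 2 (≈95% under the usual convention),
  configurable.

An expanded uncertainty of at most 10% is flagged fit-for-purpose —
appropriate for routine botanical quality control rather than regulatory
release testing. Under the default simulated study the mean expanded
uncertainty comes out near 9%, inside that band.

## Censoring and aggregation

A solution concentration strictly below the study LOQ is censored. Two
behaviours apply at different stages, both deliberate: per sample the
content is reported as undetected (masked in the per-sample table); inside
group aggregates censored samples are imputed as zero, so a group mean is
(sum of detected contents)/n_total, while the reported min–max range spans
detected samples only. Raising the LOQ can only censor more samples, never
fewer (monotonicity, property-tested). No maximum-likelihood treatment of
left-censoring (Tobit, Kaplan–Meier) is attempted — zero imputation is the
aggregation rule this workflow defines. Dry-weight content is
conc × volume/mass (µg/mg), with the standard extraction of 100 mg dried
powder in 1 mL as the metadata default.

The part/province subgroups used for geographic comparison are an
editorial selection (matched stem/root/leaf triples from shared
locations); they ship as a named fixture list rather than being inferred
from metadata.

## The synthetic-data generator

Each track's area is g·f(c)·(1 + ε_prop) + ε_add with

| parameter | default | meaning |
| --- | --- | --- |
| f | −3·10⁻⁹x² + 2·10⁻⁵x + 5·10⁻⁴ | true response at the reference study's area scale |
| levels | 62.5–1000 µg/mL (5 levels) | standards per plate |
| n_plates | 28 | plates per study |
| plate_effect_sd | 0.05 | sd of log g, g log-normal with median 1 |
| proportional_sd | 0.02 | relative track noise |
| additive_sd | 2·10⁻⁴ AU | baseline noise (≈10% of the lowest standard's area, ≈1% of the highest) |
| samples_per_plate | 3 | distinct samples, each applied in `replicates` = 3 tracks (9 sample tracks + 5 standards ≈ one 15-track plate) |
| sample_conc_range | 100–900 µg/mL | uniform true concentrations (contents ≈ 1–9 µg/mg at the default extraction) |

The 5% plate effect makes inter-plate variability the dominant error
component in the working range — the regime in which a single-point
multiplicative correction is the right tool and which the ratio diagnostic
confirms as multiplicative-dominant; the additive term reproduces the
widened ratio dispersion at the bottom of the range. A single seed
deterministically spawns per-plate substreams, so extending a study with
more plates never reshuffles the earlier ones.

What the generator does *not* emulate: densitogram/band-shape effects
(responses are drawn directly at peak-area level), Rf drift and band
misassignment, matrix interference, drift *within* a plate, correlated
day effects across plates, and real between-sample content distributions
(truth is uniform). Passing tests therefore demonstrate the statistical
machinery under a known mixed-error model, not the chromatographic
fidelity of any particular assay.

Monte-Carlo problem sizes used by the tests and the acceptance script —
100 seeded studies for the RMSE comparison of quantification strategies,
200 replicates for the limits-of-agreement coverage (under the
two-component 2%/2% error model), three studies for the uncertainty band —
were chosen so the checks are stable at the percentage resolution being
asserted.

## Known limitations

- Coefficient-wise curve averaging assumes all plates share one response
  shape up to scale; a plate with a genuinely different curvature biases
  the mean curve rather than being detected.
- The single-point factor corrects only multiplicative offsets; additive
  baseline shifts leak into low-concentration results, which is why the
  reference level sits mid-range and why the ratio diagnostic reports the
  low-end dispersion separately.
- The equivalence statistics are partially circular when the factor and
  the plate-specific curve share the reference standard (see above);
  treat the paired-test p-value as an internal consistency check, not an
  external validation.
- One embedded cross-plate mean-curve equation is stored verbatim for
  reference but never used in computation: its printed coefficients are
  dimensionally incompatible with the per-plate equations under any single
  unit choice for x. The package always derives the mean curve from the
  per-plate fits instead.
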