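# Methods

This note documents the statistical models behind each stage of
`urimet`, the defaults and why they were chosen, the behaviour of the
synthetic-data generator, and the numerical decisions that matter when
reproducing results.

## Specific-gravity calibration and conversion

Urinary specific gravity (SG, dimensionless, ≥ 1.000) is proportional in
its excess over water (x = SG − 1) to the total solute concentration, and
a differential refractive-index detector responds linearly in x.  The
calibration is therefore the straight line

    area = slope · x + intercept

fitted by weighted least squares with weights 1/x^w (default w = 2).  The
1/x² weighting gives each calibration standard equal *relative* influence,
which matters because urine SG values cluster in the low end of the
calibrated span (typically 1.002–1.057 for an NaCl series).  The fit is
delegated to `statsmodels` WLS; the test suite checks it against the
closed-form weighted normal equations.

The intercept is estimated rather than constrained to zero: blank water
defines the zero differential by construction, so the estimate should be
near zero, but leaving it free absorbs small flow/temperature offsets and
costs one degree of freedom out of ten.

**Accuracy and precision are computed on SG − 1, not SG.**  With values
like 1.003, a 17% error in solute content changes SG by only 0.0005;
statistics on the raw SG scale would be dominated by the constant unit
offset and understate relative error by three orders of magnitude.
Acceptance bands default to 100 ± 15% accuracy and ≤ 15% CV per level.

Converted values are rounded *half away from zero* at the instrument's
displayed digit count (3 digits for UG-D-style refractometers, 4 for
UG-α-style), using the decimal semantics of the shortest float repr so
that e.g. 1.0015 reads 1.002 exactly as on a display.  The unrounded
value is retained for dilution planning.  Conversions outside
(1.000, 1.100] are flagged out-of-range, and conversions beyond the
fitted calibration span are flagged extrapolated; neither raises, because
concentrated urines legitimately exceed the NaCl span and should be
reviewable rather than dropped.

Method agreement uses Bland–Altman statistics on paired differences
d = y − x: bias = mean(d), limits of agreement = bias ± 1.96·SD(d) with
the n−1 denominator.  The multiplier is fixed at the normal 95% value;
no small-sample t-correction is applied.

## Dilution planning

Under the linear solute model the SG after diluting V_urine into a total
V_total of water is 1 + (SG_sample − 1)·V_urine/V_total, so the volume
that lands on a target SG is the Levine–Fahys rule

    V_urine = V_total · (SG_target − 1) / (SG_sample − 1).

Defaults: target SG 1.002 (the lowest normal physiological value, chosen
so essentially all samples are diluted, never concentrated), total volume
340 µL, pipetting grid 0.1 µL.  Samples at or below the target are used
undiluted and flagged `undiluted_below_target`; ok-rows whose urine
volume falls below the 1 µL pipetting floor are flagged
`volume_below_min` rather than rejected.  Water volume is computed as
total minus the *rounded* urine volume, so the dispensed total is exact
on the grid — liquid handlers dispense two components to a fixed final
volume.

## Batch design

An analytical batch is one 96-well plate: 70 study samples, 20 pooled
study QC (SQC) wells, 2 laboratory reference QC (RQC) wells, 4 blanks.
The injection sequence opens with a blank pair and five SQC conditioning
injections (configurable), runs samples in blocks of at most five each
followed by an SQC, places the RQCs mid-sequence, and closes with the
remaining SQCs and a blank pair.  Every assigned well is injected exactly
once, and no achievable layout produces more than five consecutive sample
injections.  Exact QC well positions on the plate (corner blanks, centre
RQCs, evenly spread SQCs) are a convention, configurable rather than
asserted; only the counts and the interspacing rule are contractual.

## Signal-drift correction

LC–MS intensities drift with injection order.  The pooled SQC is
chemically identical in every injection, so per feature and per batch the
SQC trend is a direct estimate of the technical drift.  The model is
multiplicative — drift scales signals — so fitting is done on log
intensities and the correction divides the fitted factor out:

    corrected = raw · c / f(order)

1. **Fit.**  A natural cubic smoothing spline (Reinsch form; hat matrix
   A(λ) = (I + λK)⁻¹ on injection order rescaled to [0, 1]) is fitted to
   log SQC intensity.  λ is chosen from a geometric grid of 25 values
   spanning 1e−8…1e2 by leave-one-out cross-validation, computed exactly
   through the linear-smoother identity (LOO residual = residual/(1−Aᵢᵢ));
   the brute-force refit oracle in the test suite confirms the identity.
   The grid floor of 1e−8 lets a noiseless smooth trend be reproduced to
   ~1e−8 at the QC points.  Because the hat matrices depend only on the
   QC positions, they are shared across all features with the same
   usable-QC pattern, which keeps a 200-feature, 3-plate run under a
   second.
2. **Fallbacks.**  QC points with missing or non-positive intensity are
   dropped (log of zero is undefined, and the dropped points remain
   auditable).  With fewer than 5 usable QCs the fit is a straight line in
   log space; below `min_qc` (default 4) the feature/batch pair is skipped
   and passed through unchanged — never an exception.
3. **Extrapolation.**  Outside the first/last QC order the fitted factor
   is held constant: splines diverge when extrapolated, and a constant is
   the conservative choice for the few leading/trailing injections.
4. **Anchoring.**  The scale c pins the corrected SQC median of each
   batch exactly to a reference level: the whole-run raw SQC median when
   `align_batches=True` (default; this aligns plate-level offsets so
   whole-cohort statistics are meaningful), or the batch's own raw SQC
   median when `False` (which preserves each batch median bit-for-bit).
   Batches never share a fit.

Fitting on the log scale guarantees a strictly positive fitted curve; the
non-positive-curve skip path remains as a guard against numerical
pathology.  The correction is the identity on drift-free noiseless data
and is scale-equivariant (multiplying a feature by c multiplies its
corrected values by c).

## Feature quality metrics and filtering

All statistics are computed on raw intensities (not log), per feature:

* CV% = 100·SD/mean with the n−1 denominator, over SQC injections
  (`cv_qc`) and study samples (`cv_sample`);
* D-ratio = 100·SD_SQC/SD_sample — the share of technical in total
  variation; standard deviations, not MAD;
* missingness = percentage of sample injections below 5× the blank
  reference, where the reference is the mean blank intensity of the
  injection's own batch (whole-run mean blank when a batch has no usable
  blank), and a missing value counts as below;
* IQR with linear-interpolation quantiles; skewness is the adjusted
  Fisher–Pearson estimator (`scipy.stats.skew(..., bias=False)`);
* a dynamic-range flag: mean SQC intensity within [1.5·10³, 3.5·10⁶]
  (inclusive), the quantitative range of the instrument these defaults
  describe.

Statistics whose denominator vanishes (zero mean, zero sample SD) are
reported as NaN with an `undefined` flag and **fail** the corresponding
filter — silently passing an uncomputable feature would not be auditable.
Filter comparisons are strict exactly as printed in the criteria:
CV_QC < 35, missingness < 90, D-ratio < 55, IQR > 80; a CV of exactly
35.0 fails.  Two IQR presets are shipped because the stated criteria use
both forms: `strict` (IQR > 80) and `nonzero-iqr` (IQR > 0, dropping
only no-variability features); neither is asserted as canonical.

Technical internal standards (tIS) are exogenous compounds spiked at a
constant level into every sample; their CVs measure pure technical
precision.  Run acceptance requires CV_QC < 10% and CV_sample < 20%
(strict), evaluated per batch and for the whole run.  The five-compound
panels used by the positive- and negative-ionization methods (pyrantel,
CHES, fluorocytosine, PIPES, HEPES; and fluorocinnamic acid,
tricarballylic acid, CHES, PIPES, HEPES) ship as named defaults.

## Spectral matching and curation

The similarity score is the unweighted dot product on the 0–1000 scale:

    score = 1000 · (Σ_pairs Iq·Ir)² / (Σ Iq² · Σ Ir²)

over a one-to-one pairing of query and reference peaks within an m/z
tolerance (default 0.01 Da, a typical Q-TOF MS2 value).  "Unweighted"
means raw intensities: no m/z weighting and no square-root transform; a
weighted variant exists but is off by default.  Pairing is an optimal
assignment (scipy `linear_sum_assignment`) maximizing the matched
intensity-product sum, with a vanishing per-pair bonus so that among
equal-sum pairings the one with more matches wins; the test suite proves
equality with exhaustive enumeration on all ≤ 6-peak suites.  A greedy
nearest-m/z rule was deliberately not used: in crowded m/z regions it can
pair a close low-intensity peak and miss the score-optimal assignment.

Curation accepts an annotation when (per confidence level) mass shift
< 10 mDa; additionally RT shift < 0.5 min for AMRT and AMRT-MS/MS; and
additionally score > 700 with ≥ 3 matched peaks for AMRT-MS/MS — the
matched-peak floor guards against spuriously high scores from sparse
spectra.  All thresholds are strict: a score of exactly 700 or 2 matched
peaks is rejected.  A manual override path records `accept_with_comment`
and requires a non-empty explanatory comment.

## Synthetic-data generator

The generator emulates the statistical structure the workflow assumes:
full 96-well batches injected in the QC-interspaced sequence; feature
base intensities log-normal (log10 mean 4.6, SD 0.8, spanning the
instrument's dynamic range so the range filter is exercised); SQCs
sharing one latent pool level per feature; study samples multiplying a
biological log-normal factor (log10 SD 0.25, ≈ 60% CV — a plausible
between-subject spread for urinary metabolites and comfortably above the
technical floor, so D-ratios are informative); blanks at 0.5% of the
feature mean; injection noise multiplicative log-normal scaled so its CV
equals the requested fraction exactly (default 3%, the precision the
platform achieves per batch).

**Drift amplitude is defined as the RMS fractional deviation of the
drift factor over a batch**, so an amplitude of 0.20 contributes ~20
percentage points to the raw pooled-QC CV — the regime a drifting
multi-week acquisition shows before correction.  A sinusoid therefore
uses peak deviation amplitude·√2 with a random phase per feature and
batch; linear drift uses slope amplitude·√12 with random sign; the
random smooth curve is a three-mode Fourier sum rescaled to the target
RMS.  The tIS panel is simulated drift-affected by default (so the
correction has something to remove) next to an always-drift-free control
panel (ids suffixed `_nodrift`).

Everything derives from a single integer seed and identical specs give
bit-identical tables; ground truth (latent levels, per-injection drift
factors, noise CV) is returned for recovery tests.

What the generator does **not** emulate: retention-time drift and peak
shape, correlated noise between co-eluting features, ion suppression and
other analyte-specific matrix effects, heteroscedastic count noise at low
intensity, and batch-to-batch level shifts beyond what random drift
phases induce.  Passing the simulated recovery suite therefore shows the
estimator removes smooth multiplicative injection-order drift at
realistic noise; it does not certify performance against matrix effects
or RT instability on real data.

The SG cohort generator draws SG − 1 log-normal (median 0.012, log-SD
0.7, clipped to (1.000, 1.060]), spanning well over the 15-fold solute
range seen across hydration states.

## Problem sizes in the tests and the acceptance script

The simulated-cohort recovery runs 200 features over three full plates
(70 samples + 20 SQCs + 2 RQCs + 4 blanks each, 288 injections) with 20%
RMS sinusoidal drift and 3% injection noise — large enough for stable
medians, small enough to run in seconds.  The calibration and metric
oracles use 100 random 10-point curves and 50-feature tables; the
spectral oracle suite uses 40 random pairs of ≤ 6-peak spectra including
deliberately crowded 0.05 Da windows; Bland–Altman recovery uses 842
synthetic pairs with bias −0.0001 SG and SD 0.0006 (the magnitude of
refractometer-vs-RID differences).  All are seeded.

## Known limitations

* The drift estimator assumes the pooled QC is representative of every
  feature's matrix; analyte-specific suppression is not modelled.
* Smoothing-parameter selection by LOO-CV can choose near-interpolation
  when QC replicates are few and quiet; the grid floor bounds how wiggly
  the curve can get, and the linear fallback covers sparse-QC batches.
* The natural-spline boundary condition (zero curvature at the first and
  last QC) costs up to ~1e−4 relative accuracy between knots near the
  batch edges on strongly trending data; at QC points the fit is exact to
  the smoothing bias.
* Missingness treats any missing sample intensity as below the blank
  threshold; exporters that encode true zeros as blanks will inflate it.
* No imputation, no RT alignment, no multivariate (PCA-style) QC
  outlier detection, and no post-acquisition intensity normalization
  beyond drift correction.
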