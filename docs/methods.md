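# Methods

## Scope and data model

The package chains three analysis stages — DNA-ploidy typing, imaging
mass-spectrometry (IMS) biomarker discovery, and tissue-microarray (TMA)
survival statistics — around five core containers: `DNAHistogram`
(per-nucleus DNA content in c-units), `IMSDataset` (one profile spectrum per
grid pixel on a shared m/z axis), `PeakMatrix` (integrated peak areas per
pixel per window, optionally class-labeled), `TrainedModel` (feature set,
weights, classifier parameters, confidence threshold), and `CohortRecord`
(one TMA patient).  The 28-record TMA cohort, the protein-mass lookup rows,
and the published peak/weight lists ship as plain-text fixtures; the raw
imaging data behind the discovery stage were never deposited, so that stage
runs on synthetic slides with known ground truth.

## Auer DNA-histogram typing

DNA values are standardized as `c = 2 * IOD / mean(control IOD)`, anchoring
the lymphocyte control at 2c.  The typing rules use the closed diploid
region [1.5, 2.5]c and tetraploid region [3.5, 4.5]c, with "exceeding"
always strict (> 2.5c, > 4.5c):

* **IV** (aneuploid): fraction of nuclei > 4.5c exceeds 5%.  An optional,
  off-by-default scatter rule (≥ 20 nuclei above 5c with coefficient of
  variation > 0.25) stands in for the subjective "distinctly scattered"
  criterion; it is configurable because no quantitative definition exists.
* **II**: a stem line in the tetraploid region and diploid + tetraploid
  fractions jointly > 90%.
* **I**: a single diploid-region stem line with < 10% of nuclei above 2.5c.
* **III**: fallback for euploid populations failing I/II — proliferating
  near-diploid histograms with mass between the regions.

The verbal rules overlap, so they are applied in the fixed precedence
IV → II → I → III; this makes every nonempty histogram classifiable exactly
once and keeps the side-conditions consistent.  Stem lines are modes of a
0.2c-binned histogram holding ≥ 5% of nuclei (plateaus merged), reported as
the mean c-value of the mode's bin neighborhood to 2 decimals.  Fewer than
500 nuclei sets a quality flag rather than failing: the 500-nuclei rule is
an acquisition guideline, not a mathematical precondition.  Both the count
above 4.5c and above 5c are reported, since published "5c-exceeding" columns
do not state which bound they use.

## Spectral preprocessing

The chain is fixed and logged: mass-range restriction (default
2,000–25,000 Da) → recalibration → TIC normalization → convex-hull baseline
correction → class averaging → peak picking → end-point integration.
Normalization precedes baseline correction deliberately, following the
processing order the original workflow describes; the order is configurable.

* **Recalibration** fits one multiplicative m/z factor per spectrum: the
  top-10 local maxima are matched to the reference's maxima within a
  5,000 ppm search window and the factor is the median matched ratio.
  Spectra with |shift| > 1,000 ppm are excluded ("shift over limit"), as are
  spectra with no matchable peaks.  A single global factor is the simplest
  model consistent with a ppm-expressed cap.
* **Null spectra** (TIC below 1e-6 × the slide's median TIC) are excluded
  with a machine-readable reason; retained + excluded always equals the
  input pixel count.
* **Baseline** is the lower convex hull of the (m/z, intensity) points
  (monotone-chain construction, linear interpolation between hull vertices),
  clamped pointwise to the signal so the corrected intensity is non-negative
  everywhere.  The "flatness" knob (default 0.8) maps to an optional median
  pre-filter of window (1 − flatness) × n applied before hull construction —
  the parameter mirrors an undocumented vendor setting, so the hull
  subtraction is kept as the defined core and the filter as an exposed
  pre-smoothing.  Pure hull correction (flatness 1.0) is exactly idempotent;
  with the default filter idempotence holds on smooth spectra and degrades
  only to the noise scale on noisy ones.
* **Peak picking** runs on a baseline-corrected class-average spectrum.
  Noise is estimated as 1.4826 × the median absolute deviation of the
  corrected intensities.  A local maximum becomes a window when its apex
  clears the median intensity by `snr × noise` (default snr = 3) *and* its
  prominence clears the same bar; the prominence requirement exists because
  on spectra with ~10^4 samples an apex-only threshold admits hundreds of
  pure-noise maxima.  Window bounds are the flanking prominence bases
  tightened to the 95%-height crossing and truncated at midpoints between
  adjacent accepted peaks, so windows never overlap.  The vendor software's
  exact picking criterion is unpublished; this SNR definition is a declared
  stand-in.
* **End-point integration**: the trapezoidal integral over the window minus
  the integral of the chord joining the endpoint intensities, clamped at 0.
  Window endpoints are linearly interpolated so narrow windows remain
  well-defined on recalibrated axes.  Chord subtraction makes the area
  invariant to any affine-in-m/z offset across the window.

## Discovery and classification

Regions of interest (disjoint, in-grid) label the rows of the peak matrix.
Per-peak ROC AUC — (concordant pairs + 0.5 × ties) / (n1 × n0), positive
class defaulting to the higher-mean class and never flipped to
max(AUC, 1 − AUC) — filters peaks at a strict AUC > 0.75.  Two classifier
kinds are trained on standardized peak areas:

* **snn**: a single-hidden-layer feed-forward network (hidden size
  2 × n_peaks, logistic activations, full-batch L-BFGS to tolerance 1e-6,
  seeded initialization).  The proprietary network the original workflow
  used is undescribed; this is the smallest architecture honoring
  "neural network" with reproducible training.  Reported per-peak weights
  are the normalized mean absolute first-layer weights.
* **quick**: weighted nearest-centroid, per-peak weights proportional to the
  between-/within-class variance ratio and normalized to sum 1, with a
  softmax over negative weighted squared distances as the posterior.

Model selection maximizes cross-validated **recognition capability**
(stratified k-fold, per-class percent correct, overall = unweighted class
mean); exact ties prefer the snn.  Whole-slide classification assigns each
retained pixel its argmax class when the top posterior reaches the
confidence threshold (default 0.5 — the rejection option is implied by
published unclassified regions, but no threshold was stated) and
UNCLASSIFIED otherwise; pixels excluded upstream are UNCLASSIFIED with
confidence 0.  Posteriors are clipped below 1 by 1e-9 so a threshold of 1.0
rejects every pixel even when a float posterior saturates.  Peak annotation
returns all proteins within ± 1 Da of a query mass, sorted by |Δm|.  No
multiple-testing correction is applied in peak selection (the workflow
filters by AUC only); a Benjamini–Hochberg option exists but is off by
default.

## Clinical statistics

* **Medians** are computed in decimal arithmetic (even groups: mean of the
  two central order statistics) and rounded half-up to 4 decimals, matching
  the printed precision.
* **Mann–Whitney U** uses exact enumeration for tie-free combined samples of
  ≤ 12, otherwise the normal approximation with tie and continuity
  correction.
* **Optimal cutoff**: candidates are midpoints of adjacent distinct values
  (decimal midpoints, so 0.4448/0.4529 regenerate exactly 0.4489) plus the
  all-negative boundary at the maximum, so a non-discriminating marker
  scores Youden 0 rather than a negative value.  The Youden-maximal cutoff
  wins; ties break toward higher specificity, then the lower cutoff.  A case
  is positive iff value > cutoff, with equality assigned negative — the
  published scoring rule uses two strict inequalities and never assigns
  equality.  Sensitivity/specificity are additionally reported as half-up
  integer percents (regenerating 44% = 4/9 and 89% = 8/9).
* **Cox**: Newton–Raphson maximization of the univariate partial likelihood,
  convergence tolerance 1e-10, observed-information standard error, Breslow
  tie handling by default with Efron available (both are standard; Breslow
  reproduces the published hazard ratio exactly and matches the defaults of
  the clinical software of the study's era).  The 95% Wald interval uses the
  exact normal quantile z = 1.959964; with 1.96 the upper bound differs in
  the third decimal from the published interval.  Coefficients diverging
  past |beta| = 50 (monotone likelihood) are flagged non-convergent.
* **Kaplan–Meier / log-rank** delegate to lifelines; the in-package Cox fit
  is cross-checked against lifelines' Efron implementation and an
  independent scalar maximization of the partial likelihood in the tests.
* **Binary regression** of marker on ploidy: logistic Wald p via
  statsmodels, Fisher's exact p alongside; a zero cell triggers the
  Haldane–Anscombe 0.5 correction, flagged.

## Synthetic data

`synthgen` draws all randomness from one seeded `numpy.random.Generator`
per call; identical spec + seed is bit-reproducible.

* **Slides**: Gaussian peaks (linear-TOF peaks are broad and smooth) with
  FWHM = m/z / 600 (constant resolving power), planted at the published
  marker masses 2,395; 3,376; 4,761; 4,977; 6,663; 8,581 Da; in the default
  two-class layout the discriminating markers 2,395 and 4,977 carry a 2-fold
  mean contrast with 20% relative intensity noise.  The baseline is a
  decaying exponential plus a slow positive sinusoid — smooth, positive, and
  concave enough to give the hull corrector nontrivial work.  Per-pixel
  multiplicative calibration jitter is drawn on the ppm scale; additive
  Gaussian noise is clamped at 0; a configurable fraction of pixels is
  emitted with ~zero intensity to exercise the null-spectrum exclusion.
  Grid default 20 × 10 at 90 µm pitch, m/z axis step 2 Da — sizes chosen as
  a desk-scale analogue of a whole-slide acquisition.
* **Histograms**: stem-line normal mixture plus a uniform (4.6, 8.0)c
  scattered component; residual weight spreads uniformly between the diploid
  and tetraploid regions, emulating S-phase nuclei.  The implied Auer type
  is returned for recovery testing.
* **Cohorts**: per-group immunopositivity as clipped normals on [0, 1]
  (normal mucosa 0.05 ± 0.05, diploid 0.30 ± 0.15, aneuploid 0.40 ± 0.20 —
  chosen to resemble the fixture's group spreads), exponential survival
  (baseline hazard 0.005/month) with the planted hazard ratio applied to
  marker-positive patients, administrative censoring at 174 months (the
  follow-up span of the study cohort).

What the generator does **not** emulate: isotope envelopes, adducts,
detector saturation, matrix cluster ions, spatially correlated tissue
texture, staining artifacts, or non-proportional hazards.  Passing tests
therefore demonstrate that the chain recovers planted structure under its
own model assumptions, not that it would reach the same rates on real
acquisitions.

## Known limitations

* The published IMS classification rates (90%/99% discovery; 92%/78% and
  92%/96% validation) cannot be reproduced — the raw imaging data were never
  deposited.  The synthetic-slide recovery results are a desk-scale
  substitute under planted effect sizes.
* The published normal-vs-carcinoma "sensitivity of 89% at 100% specificity"
  does not recompute from the printed duplicate-averaged IP values (which
  give 15/18 = 83% at 100% specificity); it was likely computed
  pre-averaging or on a larger carcinoma set.  It is documented here as a
  discrepancy and not asserted anywhere.
* One published aneuploid sample (stem line 2.03, 0.8% of nuclei above 5c)
  fails the quantitative > 5% rule and was presumably called via the
  subjective scatter clause; it is not used as a test case.
* The genetic-algorithm classifier mentioned alongside the two implemented
  kinds is out of scope: the final published models were network-based.
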