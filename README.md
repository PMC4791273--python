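# ploidyims

An open, tested re-implementation of an analysis chain that links three
stages of a colorectal-cancer biomarker study:

1. **DNA ploidy assessment** — per-nucleus DNA-content histograms from
   Feulgen image cytometry, standardized against a lymphocyte control
   (assigned 2c), are classified into Auer types I–IV; types I–III are
   euploid, type IV (more than 5% of nuclei beyond 4.5c, or distinctly
   scattered values) is aneuploid.
2. **MALDI imaging mass spectrometry discovery** — per-pixel linear-TOF
   profile spectra (m/z 2,000–25,000) are mass-range restricted, recalibrated
   by spectral alignment (1,000 ppm cap), TIC-normalized, baseline-corrected
   with a convex-hull algorithm, and reduced to peak areas by end-point
   integration over windows picked on class-average spectra.  Peaks are
   filtered by ROC AUC (> 0.75), classifiers (supervised neural network and a
   weighted nearest-centroid "quick" classifier) are trained on region-of-
   interest spectra and selected by cross-validated recognition capability,
   and whole slides are segmented pixel by pixel with an UNCLASSIFIED
   rejection state.
3. **Clinical validation** — on a 28-sample tissue microarray (10 normal
   mucosa, 9 diploid and 9 aneuploid carcinomas, shipped as a fixture),
   thymosin-beta-4 immunopositivity (IP) is compared across groups
   (Mann–Whitney U), dichotomized at the Youden-optimal cutoff
   (sensitivity + specificity maximal; positive iff IP > cutoff), and tested
   as a survival predictor by Kaplan–Meier curves, the log-rank test, and a
   univariate Cox proportional-hazards fit
   `h(t | x) = h0(t) * exp(beta * x)` with Breslow tie handling and
   HR = exp(beta_hat), 95% CI = exp(beta_hat ± z_0.975 * SE).

No raw imaging data are available for the spectral stages, so a first-class
synthetic-data generator (`ploidyims.synthgen`) produces slides, DNA
histograms and survival cohorts with known planted structure; every pipeline
stage is tested against that ground truth.

## Worked example

```python
from ploidyims import clinstats

records = clinstats.load_tma_cohort()          # 28 patients
tumors = clinstats.select(records, "tumor")    # 18 carcinomas

print(clinstats.group_median(records, "diploid"))    # 0.2673
print(clinstats.group_median(records, "aneuploid"))  # 0.3615

cut = clinstats.optimal_cutoff(
    [r.ip for r in tumors], [r.ploidy == "aneuploid" for r in tumors]
)
print(cut.cutoff, cut.sensitivity_pct, cut.specificity_pct)  # 0.4489 44 89

marker = clinstats.dichotomize(tumors, cut.cutoff)   # 5 positive, 13 negative
cox = clinstats.cox_univariate(
    [r.survival_months for r in tumors],
    [r.event for r in tumors],
    [1.0 if marker[r.id] else 0.0 for r in tumors],
)
print(round(cox.hr, 3), round(cox.ci_low, 3), round(cox.ci_high, 3))
# 12.959 2.352 71.399
```

The medians are the group-wise IP medians (even groups report the mean of
the two central order statistics, rounded half-up to 4 decimals).  The
cutoff 0.4489 is the midpoint of the adjacent observed IP values 0.4448 and
0.4529; at that cutoff 4 of 9 aneuploid carcinomas are marker-positive
(sensitivity 44%) and 8 of 9 diploid carcinomas marker-negative
(specificity 89%).  The Cox fit says marker-positive patients face a
roughly 13-fold death hazard, with a wide interval reflecting only 8 events.

The full demo pipeline (synthetic slide -> preprocessing -> discovery ->
segmentation -> clinical statistics) runs from the shell:

```sh
ploidyims run-all --seed 1 --out out/
ploidyims tma-stats
ploidyims annotate --mz 4977 --mz 5150
```

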