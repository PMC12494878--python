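# Methods

This note documents the models, conventions, and design choices behind
`aggloscan`, in the spirit of a statistical-software methods appendix. It
states no empirical result beyond what the test suite and
`scripts/acceptance.py` themselves compute.

## 1. The puncta operator

Within each segmented cell the operator (`image_quant.detect_puncta`):

1. computes the cell's median intensity (numpy linear-interpolation
   percentiles; even counts average the central pair);
2. marks candidate pixels with intensity ≥ `foci_fold_threshold` × median
   **and** ≥ background + `background_margin_AU` (defaults 2.5 and 100 AU).
   The fold condition is read multiplicatively and both conditions are
   conjunctive. Pixel candidacy uses ≥; the per-cell classifier below uses
   strict >. Both comparisons are configurable;
3. finds connected components of candidates inside the cell (8-connectivity
   by default, 4 available) and keeps only the **largest**, breaking ties
   deterministically by (min row, then min col);
4. annotates the call with circularity 4πA/P², using the Crofton
   (line-intercept) perimeter estimator with 4 directions. Discrete
   geometry can push circularity slightly above 1; regions of ≤ 2 pixels
   are assigned 1.0 by convention. The shape gate is circularity > 0.4:
   round puncta pass, high-aspect filaments fail.

"The background" is not defined in the assay's usual description; here it
defaults to the median of non-cell (label 0) pixels per field, with an
explicit override. The same operator and defaults apply to the red channel
unless overridden.

A cell is *foci-positive* (`classify_foci_cell`) when max/median intensity
strictly exceeds 2.5 — "above 2.5" read strictly, so exactly 2.5 is
negative. The decision depends only on the intensity ratio and is therefore
invariant under positive rescaling of the cell's pixels. A zero median
yields an infinite ratio: the cell classifies positive and is flagged.

**Segmentation.** Global threshold → hole filling → minimum-area filter
(30 px) → labeling. The default threshold is the *triangle* method rather
than Otsu: in sparse fields the background holds ~90% of pixels and Otsu's
two-class criterion places the cut inside the cell-brightness range,
dropping dim cells, while the triangle method keys on the dominant
background peak and stays robust. Otsu remains available
(`method="otsu"`), and an externally supplied label mask bypasses
segmentation entirely.

## 2. Dissolution assay

Cells are binned into `n_bins = 10` empirical quantiles of the red/green
median-intensity ratio, computed per construct (each dataset gets its own
bin edges). Per bin we report the foci-positive fraction with a 95% Wilson
score interval — chosen over the Wald interval for its behavior at
fractions near 0 and 1 (Wald available via `ci_method="normal"`). Ratios
use medians, consistent with the per-cell statistics' emphasis on medians.

The qualitative agglomerate/aggregate judgment is formalized as the
**dissolution index**: with pooled (cell-weighted) foci fractions over the
bottom and top thirds of the bins (⌊n_bins/3⌋ bins each),

    index = 1 − top_fraction / baseline_fraction, clipped to [−1, 1].

Defaults: agglomerate at index ≥ 0.8, aggregate at ≤ 0.2, intermediate
between; a zero baseline leaves the index undefined and the call is
intermediate with a flag. The cutoffs are exposed in configuration; they
were chosen so that the three synthetic regimes of the generator (§6) map
onto the three labels with a wide margin.

## 3. Co-localization

Per cell, each channel's ⌈0.10 × area⌉ brightest pixels inside the mask
form a set; the score is |A∩B| / |A∪B|. Ties at the intensity cutoff break
by row-major pixel order after a stable sort by intensity descending, so
scores are exactly reproducible. Because only ranks matter, the score is
invariant under any strictly monotone transform of either channel and
symmetric under channel swap. A channel constant inside the mask has no
usable ranking and reports "no signal". The conventional interpretation
thresholds (shared foci > 0.45, unrelated < 0.3) are reported annotations,
never filters.

Strain-level summaries average scores over foci-positive cells only;
fewer than 20 usable cells → `NA_too_few_cells`, no defined score →
`NA_no_signal`. The construct × marker matrix is clustered with average
linkage on pairwise-complete Euclidean distances (rescaled by shared-column
count; pairs with no shared non-NA entry get the maximal observed distance
plus ε so the linkage stays well-defined), with scipy's deterministic leaf
order.

## 4. Growth and competition fitness

**Doubling time.** All windows of ≥ `min_window = 5` points are slid over
log2(OD) vs time; among windows with R² ≥ 0.99 the steepest slope wins
(earliest window on exact ties). Doubling time is 1/slope (slope in
doublings/min); exact on noise-free exponentials, and on logistic curves
the R² gate excludes the plateau so the low-density rate is recovered.
Zero/negative OD points are excluded with a warning. AUC is the trapezoidal
integral of OD over time in hours, computed over the full curve.

**Serial dilution.** A 1:D dilution regrown to saturation costs log2(D)
generations; 1:1000 ≈ 9.97, reported as about 10 per daily cycle.

**Competition.** Frequencies f_t = count_x/(count_x+count_y) evolve under a
constant per-generation selection coefficient s as a logistic in the
log-odds, so ln(f/(1−f)) is regressed on cumulative generations
(cycle × generations-per-cycle) by unweighted least squares; s = e^slope − 1.
Checkpoints at f ∈ {0, 1} carry no log-odds information and are dropped
with a warning; a Haldane +0.5 count correction is available by flag.
Selective advantage S = (r_x − r_y)/r_ref with r_ref defaulting to the
wild-type competitor's rate (the usual normalization when one strain is
the reference); SE across replicates is sample SD/√n.

## 5. ΔCD

Both spectra are linearly interpolated onto the union of their wavelength
grids restricted to the overlapping range, and ΔCD is the trapezoidal
integral of |wt − mut| there. Integration bounds are returned alongside,
and an explicit range override lets users match a published window. Units
follow the inputs; no mean-residue-ellipticity conversion is applied.
ΔCD is non-negative, symmetric, and satisfies the triangle inequality on a
shared grid.

## 6. Synthetic data

Generators emulate the instruments, not their physics. What they capture —
and deliberately do not:

* **Fields.** Cells are non-overlapping ellipses (semi-axes 6–11 px,
  rejection-sampled placement with a bounded retry budget that errors with
  the attempted density). Base intensity is log-normal (median 500 AU,
  σ = 0.35) — an assumption, since the real intensity distribution of
  cells is not established; background is additive (default 200 AU) and
  noise is additive Gaussian. Foci are 2-D Gaussians (spots, σ = 2 px) or
  rotated anisotropic ridges (filaments, aspect ≥ 4 so sub-0.4 circularity
  is generable on demand), scaled so the peak ≈ `focus_peak_fold` × base.
  Not modeled: PSF/shot noise, cell-cycle morphology, budding geometry,
  touching cells — segmentation is intentionally never the bottleneck, so
  passing tests validate the downstream operators, not a segmenter's
  robustness on hard images.
* **Dissolution populations** are generated at the record level (ratio,
  focus flag, max/median ratio): in the *agglomerate* regime
  P(focus | ratio) is a decreasing logistic in log(red/green) with slope
  −`dissolution_steepness` (default 3) about the midpoint of the
  log-uniform ratio range (default 0.1–10); in the *aggregate* regime it is
  constant at 0.4; the *intermediate* regime compresses the logistic into
  [0.12, 0.40] and draws dimmer foci (max/median 2.7–3.6 vs 3.2–8.0).
  The exact P(focus | ratio) used is recorded per cell, and focus cells
  always exceed (non-focus cells never reach) the 2.5 classifier threshold,
  so estimators can be checked for exact truth recovery.
* **Growth** is logistic with multiplicative log-normal noise;
  **competition** treats growth as deterministic and puts binomial noise
  only at the imaging/counting step, matching image-based quantification.
* **Abundance** matrices are log-normal (log2 base ~ N(20, 2), within-group
  noise 0.25 log2 units, six samples per group as in a
  three-biological × two-technical design) with DE proteins shifted by
  log2(fold) in one group, missing-at-random dropout, a stated fraction of
  single-peptide proteins, and random category assignments. Real data's
  intensity-dependent missingness and correlated complexes are not modeled.
* **Spectra** are sums of Gaussians over wavelength; the true ΔCD is
  computed analytically on a 100×-refined quadrature grid.

Reproducibility: a single global seed fans out to fixed per-operation child
seeds (SeedSequence over (seed, crc32(op name))), so any stage rerun in
isolation reproduces its stream bit-identically.

## 7. Proteomics

Filters: ≥ 2 unique peptides and detection in ≥ 80% of samples, each
reported separately. Quantile normalization operates on detected values
(classic mean-of-k-th-smallest mapping at equal detected counts;
interpolated quantile mapping otherwise; missing entries stay missing).
Imputation is deliberately simple and labelled in the output metadata:
`half_min` (half the row minimum — censoring-at-detection-limit reading) or
`knn` (rows centered by their detected means, neighbors by correlation of
centered profiles, donors transfer deviations). These are documented
method-variants, not attempts to reproduce model-based imputation, and
downstream numbers should be read accordingly. Technical replicates can be
collapsed into biological replicates by log-scale averaging before testing
to avoid pseudo-replication.

Differential testing is a per-protein two-sided Welch t-test on log2
intensities (again a documented substitute for moderated-variance models),
BH-adjusted; hits require |fold| strictly > 1.68 in either direction and
adjusted P < 0.05; the exclusivity rule takes set differences of hits
across two contrasts on a shared universe.

Enrichment: for m iterations (default 10⁶) draw n = |hits| proteins from
the universe without replacement; every category is scored against the
same draw (joint resampling — the marginal null per category is exactly
hypergeometric, and joint draws preserve those marginals while reflecting
category overlap in the joint distribution). p = fraction of iterations
with overlap ≥ observed; zero exceedances report p = 1/m flagged as an
upper bound (finite-resolution honesty), and BH runs across the tested
(k ≥ 1) categories. Sampling is vectorized (argpartition of random keys)
and chunked to bound memory.

## 8. Problem sizes and numerical conventions

Defaults used by the test suite and acceptance script — chosen as realistic
desk-scale study conditions: dissolution populations of 5000 cells (10
bins of ~500), 100 seeded discrimination runs (50 per regime pair);
detector error rates on 500 cells across five fields at 4–8× peak fold and
4% intensity noise; competition recovery over 200 replicates at g = 10,
4 cycles, 1000 counted cells; enrichment checks at 10⁵ iterations on
≤ 25-protein universes against exact combinatorial tails. Coordinates are
0-based (row, col) throughout; images are float AU in memory and 16-bit
TIFF on disk (rounded, clipped); all CSV headers are those documented in
the functions that write them.

## 9. Known limitations

* The estimators are validated against the generators' idealizations;
  robustness to real microscopy artifacts (uneven illumination, debris,
  out-of-focus cells) is untested by construction.
* The dissolution index reduces a ten-bin profile to one number; profiles
  that dip non-monotonically can land in "intermediate" without being
  biologically intermediate.
* Welch + simple imputation will not reproduce moderated-model hit lists
  on real data at the margin; the hit rule's fold threshold dominates in
  clear-effect regimes.
* The log-odds competition estimator drops fixated checkpoints; under
  strong selection with few counted cells the Haldane flag should be used.
* Chemostat generation accounting is a unit conversion performed by the
  caller (elapsed time over the per-volume turnover); only serial-transfer
  competitions are simulated natively.
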