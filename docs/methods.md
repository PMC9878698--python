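# Methods

This note documents the models, estimators, parameter choices and known
limitations of `phenotray`. It is written for a user who wants to know
exactly what each number the package prints means and which design choices
were genuinely open.

## 1. Tray-image measurement workflow

The imaging model assumes a fixed overhead camera photographing one
half-tray of `rows × cols` wells (default 12 × 12), with four visually
separable surfaces: the well soil ("tray color"), the plastic ridges
between wells, the background around the tray, and the green rosettes.

The workflow (`imaging.process_tray`) runs six stages:

1. **Crop.** The tray is the largest connected region passing the
   tray-color filter, after a morphological closing (disk radius 3 px by
   default) that bridges the ridge lines separating the well faces. The
   bounding box is padded by 1 px so the outermost ridge lines survive the
   crop. If no region covers at least 20% of the frame the stage *fails
   explicitly* and the run either uses the configured manual-crop
   coordinates or stops — a mis-detected tray is never silently passed
   through.
2. **Color filters.** Filters are per-channel box bounds in RGB (0–255) or
   HSV (0–1, scikit-image convention). HSV is the recommended space for
   real photographs because hue isolates green rosettes robustly; the
   original system's thresholds are not published, so all bounds live in
   the run configuration. For synthetic imagery,
   `synthetic.reference_tray_filter` / `reference_plant_filter` derive
   bounds from the palette with thresholds at channel *midpoints* between
   competing colors, which makes the classification of interpolated
   boundary pixels unbiased (a pixel is counted as plant when it is more
   than half plant by blend fraction).
3. **Grid lines.** The Hough input is the complement of the tray and plant
   masks within the filled tray region, i.e. the ridge lines. The vote
   accumulator uses 1-px ρ resolution and 0.25° θ resolution; lines whose
   normal lies within ±20° of the x axis are classed vertical, within ±20°
   of the y axis horizontal. Exactly rows+1 / cols+1 peaks per class are
   taken after non-maximum suppression with a radius of half the expected
   line spacing; fewer is an error naming the axis and the count found.
   Each accepted line is then refined by a total-least-squares fit to mask
   pixels within 2 px, which removes the accumulator quantization error
   (sub-pixel line placement matters because the homography is anchored on
   the outer corners).
4. **Grid geometry.** Corner (i, j) is the intersection of the i-th
   horizontal and j-th vertical line. The corner mesh must be monotone in
   both indices; near-parallel same-class lines intersecting inside the
   image are a degenerate-grid error. The homography is a projective fit
   of the **four outer corners** onto an axis-aligned square grid of side
   `cell_px` per cell; interior corners are used only for residual
   diagnostics reported in the run log.
5. **Rectification.** The *original unfiltered* image is inverse-mapped
   with bilinear interpolation onto the `rows·cell_px × cols·cell_px`
   orthographic frame. Plant masks are recomputed after rectification.
6. **Measurement.** The plant mask of each cell sub-image is split into
   8-connected components; components below `min_blob_px` (default 10) are
   despeckled away and the remaining pixel counts are **summed** — a well
   may hold a group of seedlings, and the aggregate area is the phenotype.
   Despeckling by component size rather than morphological opening keeps
   areas integer-exact and testable. An optional calibration factor
   (mm²/px, user-supplied; the camera geometry is rig-specific) converts
   areas to mm².

Coordinates are 0-based pixels, x right, y down; grid indices 0-based
row-major.

**Accuracy.** For an unwarped, noiseless tray the pipeline is *exactly*
lossless: measured per-cell areas equal the generator's ground-truth pixel
counts as integers, and with margin 0 the cell areas partition the
whole-image plant-mask count. Under projective warps (corner displacements
up to ~5% of the frame) the double bilinear interpolation (render + 
rectify) limits accuracy at blob boundaries: areas agree with ground truth
to ≤ 2% relative error for rosettes above ~100 px, with an absolute floor
of about 2–3 px for the smallest blobs (high boundary curvature loses a
fraction of a pixel per boundary unit). The area–truth Pearson correlation
over a full 144-cell tray spanning 50–4000 px exceeds 0.999.

## 2. Growth and heritability statistics

- `growth_rate_percent(initial, final)` = (final − initial)·100/initial;
  negative for shrinking or dying plants.
- `ecotype_growth_rate(day0, day30)` = day30·100/day0, the cold-course
  growth measure computed per accession.
- `proportionate_tolerance(rates)` = rateᵢ·100/Σrates; sums to 100 by
  construction.
- `log_transform` uses the natural log (the base is a free choice; only
  monotone order and relative spacing matter for the rank-based and
  t-based tests downstream) with an optional offset for zero areas.
- `broad_sense_heritability` fits the one-way random-effects ANOVA
  y_ar = μ + g_a + e_ar. σ̂²e = MS_within; σ̂²g = (MS_between −
  MS_within)/n₀ clamped at 0, with n₀ = (N − Σnᵢ²/N)/(k−1) the standard
  unequal-replication coefficient (equal to the replicate count for
  balanced panels). H² = σ̂²g/(σ̂²g + σ̂²e), clamped to [0, 1]; it is
  invariant to shifting and scaling of the phenotype. Whether heritability
  should be computed on raw or log areas is not fixed by the workflow;
  the estimator takes whatever column it is given and the CLI exposes a
  `--log` switch (default raw).
- `compare_mutant` performs a two-sided two-sample t-test, Welch by
  default (the pooled Student variant is available via `equal_var=True`;
  Welch is the safer default when mutant and wild-type variances differ).
  Significance means p < α/m with m the number of mutant × treatment
  comparisons in the experiment (overridable). Two zero-variance samples
  with equal means give p = 1 by convention.

Simulated panels at σ²g = 21, σ²e = 4 with 417 accessions × 3 replicates
(the reference panel size) have true H² = 21/25 = 0.84; the ANOVA estimate
has a standard deviation of ≈ 0.011 at this size and its mean over 200
replicate panels is within ±0.01 of truth.

## 3. Association scans

Genotypes are biallelic dosages (0/1/2, NaN for missing). Missing calls
are mean-imputed per SNP before scanning (the conventional choice for
single-SNP scans; no haplotype imputation is attempted). MAF filtering is
strict (> threshold, default 0.05) and always drops monomorphic SNPs.

**LR scan.** Ordinary least squares of y on dosage plus intercept,
two-sided t test on the slope with n − 2 df. The implementation is
vectorized but algebraically identical to the closed-form simple
regression formulas (tested to 1e-10). SNPs with zero dosage variance
after imputation are flagged and reported with p = 1.

**Kinship.** K = ZZᵀ/m with Z the dosage matrix centered at 2p̂ and scaled
by √(2p̂(1−p̂)) per SNP (VanRaden standardization); symmetrized and checked
PSD to tolerance.

**EMMAX-style mixed model.** Variance components are estimated *once*
under the null (intercept-only) model: the intercept is projected out of
K, the phenotype is rotated by the eigenvectors of the projected kinship,
and the restricted likelihood is maximized over δ = σ²e/σ²g on
log₁₀ δ ∈ [−10, 10] (coarse 81-point grid to locate the basin, then
bounded Brent to 1e-8). Each SNP is then tested by GLS with covariance
σ²g(K + δI) fixed: the data are whitened by (K + δI)^(−1/2) from the
unprojected eigendecomposition and the same marginal regression machinery
is applied, df = n − 2. With K = I the model collapses exactly to the LR
scan (verified to 1e-4 in −log₁₀ p). The scan also reports the pseudo-
heritability 1/(1 + δ).

**Diagnostics.** λ_GC = median(χ²₁-quantiles of p)/median(χ²₁); QQ-plot
coordinates are expected vs observed −log₁₀ p. On null simulations the LR
scan is calibrated: the fraction of tests at −log₁₀ p ≥ 4.5 matches
10^−4.5 within binomial error over 10⁶ tests, and λ = 1.00 ± 0.02 on 10⁵
uniform p-values. In two-subpopulation simulations with a group phenotype
shift (Balding–Nichols allele frequencies, Fst 0.1–0.2), the LR scan
inflates severely while the mixed-model scan stays within λ ∈ [0.9, 1.1].

**Candidate calling.** A gene is a candidate iff some SNP with
−log₁₀ p ≥ 4.5 (the conventional arbitrary cutoff; configurable) lies in
its 1-based inclusive body [start, end] or in its strand-aware promoter
window — [start − 2000, start − 1] for + genes, [end + 1, end + 2000] for
− genes. Both boundaries are exact and tested at 1999/2001 bp and
4.49/4.50. Raising the threshold can only remove candidates. Bonferroni-
adjusted significance is additionally available as an optional column;
the primary rule is the fixed cutoff. BED input (0-based half-open) is
converted on read; GFF3 gene features are taken as-is.

## 4. Mutant validation and concordance

Validation outcomes from per-mutant significance calls: ≥ 2 significant
mutants → `validated`; exactly 1 significant among ≥ 2 tested →
`strong_candidate`; 0 among ≥ 2 → `rejected`; a single tested mutant is
`insufficient` evidence. The rule is invariant to mutant order.

Concordance compares the gene's cold/normal expression ratio with the
**mean** of its mutants' growth ratios versus wild type. The mean (rather
than requiring all mutants to agree) is deliberate: a single atypical
insertion — e.g. a promoter insertion that up-regulates rather than
knocks out the gene — should not flip a gene whose other mutants behave
consistently. Repressed gene (ratio < 1) with mean mutant growth > 1 →
negative regulator of chilling tolerance; induced gene with mean growth
< 1 → positive regulator; exact ties at 1 are `indeterminate`, never
silently concordant. In the packaged 16-gene table, significance is taken
as given by table membership; live runs derive it from `compare_mutant`.

On the packaged tables this yields 9 concordant-negative, 4 concordant-
positive, 3 discordant genes (13/16 concordant) and a 12.5% overlap with
previously reported genes (2 of 16).

## 5. Synthetic-data generator

The generator defines the study conditions under which the package is
validated; its defaults are fixed and not tuned per test.

- **Tray renderer.** Rosettes are unions of 3–9 overlapping disks (leaf
  lobes) confined strictly to their cell interior; the ground-truth
  manifest records the exact rasterized pixel count of each union in the
  unwarped frame, which by palette construction equals the plant-filter
  count. Warps are projective transforms given by four corner
  displacements of up to ~5–10% of the image size (convexity enforced);
  additive Gaussian pixel noise (sd 2 on 0–255 in the validation
  scenarios) is clipped to range. All randomness flows from a single
  passed-in seed; identical specs give bitwise-identical images and
  manifests.
- **Phenotype panels.** value(a, r) = μ + g_a + e_ar, g_a ~ N(0, σ²g),
  e_ar ~ N(0, σ²e). Reference conditions: 417 accessions × 3 replicates,
  σ²g = 21, σ²e = 4 (H² = 0.84).
- **Genotype panels.** SNPs at uniform allele frequencies in (0.05, 0.5];
  Hardy–Weinberg Binomial(2, p) dosages; optional subpopulations with
  Balding–Nichols per-group frequencies at a configurable Fst and a
  group-level phenotype shift; planted causal SNPs add effect × dosage.

What the generator does *not* emulate — and therefore what passing tests
do not demonstrate about real data: leaf overlap between adjacent wells,
shadows and illumination gradients, soil texture resembling plant color,
camera lens distortion (the warp family is purely projective), linkage
disequilibrium between SNPs, and multi-locus genetic architectures.
Real-image thresholds will need tuning per rig; the package's claim is
that the *algorithms* are correct when their assumptions hold.

## 6. Problem sizes and numerical choices

The validation suite uses desk-scale problem sizes chosen to make
Monte-Carlo error small relative to each tolerance: 144-cell trays at
40–84 px cells, 10⁶ null association tests (120 accessions × 5 × 200k
SNPs), 300 accessions × 3000 SNPs for structured-scan comparisons, and
417 × 3 phenotype panels. Homography estimation uses scikit-image's
normalized DLT; rectification clamps and rounds to uint8; p-values are
floored at the smallest positive double so −log₁₀ p stays finite; REML
tolerance is 1e-8 on log₁₀ δ; kinship symmetry tolerance 1e-10 and
eigenvalue floor −1e-8.

## 7. Known limitations

- The imaging workflow assumes exactly one tray per frame and a complete,
  roughly axis-aligned grid (rotations within ±20° of upright).
- EMMAX's single null-model variance estimate is an approximation; strong
  single-SNP effects slightly deflate their own test statistics compared
  with a per-SNP REML fit (the standard trade-off of the method).
- Per-SNP mean imputation is only sensible at the low missingness rates
  typical of resequencing panels.
- The fixed −log₁₀ p ≥ 4.5 calling threshold is a convention, not a
  family-wise error control; Bonferroni columns are provided for users
  who want one.
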