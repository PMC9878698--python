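# phenotray

Tray-image rosette phenotyping and chilling-tolerance association analysis
for *Arabidopsis thaliana* accession panels.

High-throughput chilling-tolerance studies grow hundreds of natural
accessions in plug trays (12 × 12 wells per camera frame), photograph them
on a fixed schedule, and use the projected 2-D rosette leaf area of each
well as the growth phenotype. `phenotray` implements the desk side of such
a study end to end, for researchers building or validating this kind of
phenomics → GWAS → mutant-validation workflow:

- **Tray imaging** — the six-step measurement workflow: tray cropping via a
  color filter, detection of the cell-boundary ridges as Hough-transform
  lines, recovery of the tray plane from the line intersections, projective
  rectification of the *original unfiltered* image to an orthographic view,
  per-cell segmentation, and rosette-area/color measurement by aggregating
  8-connected components that pass a plant color filter.
- **Phenotype statistics** — growth rate `(final − initial)·100/initial`,
  per-ecotype cold-course growth rate `day30·100/day0`, proportionate
  tolerance (each ecotype's rate as a share of the panel total),
  broad-sense heritability *H²* = σ²g/(σ²g + σ²e) from one-way
  random-effects ANOVA, and mutant-vs-Col-0 Welch *t*-tests under a
  Bonferroni-adjusted α.
- **Association scans** — minor-allele-frequency filtering (strictly
  MAF > 0.05 by default), a per-SNP linear-regression scan, and an
  EMMAX-style mixed-model scan: variance components of
  *y* = Xβ + u + ε, u ~ N(0, σ²g K), ε ~ N(0, σ²e I) estimated once under
  the null by REML on the eigendecomposition of the kinship matrix K, then
  per-SNP generalized least squares. Genomic-control λ and QQ coordinates
  diagnose residual structure; candidate genes are called where a SNP with
  −log₁₀ p ≥ 4.5 falls in a gene body or its strand-aware 2-kb upstream
  promoter window.
- **Candidate analysis** — validation outcomes from per-mutant significance
  (≥ 2 significant mutants → validated) and the expression–phenotype
  concordance classes relating a gene's cold-stress transcript change to
  its knockouts' growth; the study's curated 16-gene and 9-gene tables
  ship as TSV fixtures.
- **Synthetic data** — because raw tray photographs and resequencing data
  are not redistributable, a first-class generator renders tray images with
  an *exact* per-cell pixel-count manifest (rosettes as unions of disks),
  simulates accession panels with chosen variance components, and simulates
  genotype/phenotype pairs with planted causal SNPs and optional two-level
  population structure. Every downstream module is tested against these
  ground truths.

## Worked example

Measure a perspective-warped synthetic tray and compare against the
generator's exact manifest:

```python
import numpy as np
from scipy.stats import pearsonr
from phenotray import synthetic as syn
from phenotray.imaging import TrayPipelineConfig, process_tray

rng = np.random.default_rng(7)
base = syn.TraySpec(cell_px=84, margin_px=70, noise_sd=2.0, rng_seed=7)
spec = syn.TraySpec(cell_px=84, margin_px=70, noise_sd=2.0, rng_seed=7,
                    warp=syn.corner_warp(base, rng, max_frac=0.05))
rosettes = syn.random_rosettes(spec, rng, area_range=(50, 4000))
image, manifest = syn.render_tray(spec, rosettes)

config = TrayPipelineConfig(
    tray_filter=syn.reference_tray_filter(spec),
    plant_filter=syn.reference_plant_filter(spec),
    rows=12, cols=12, cell_px=84)
table, log = process_tray(image, config)
r, _ = pearsonr(table.sort_values(["row", "col"])["area_px"],
                manifest.sort_values(["row", "col"])["pixel_count"])
print(table.head(3))
print(f"r = {r:.4f}")
```

prints

```
image_id  row  col  area_px  area_mm2     mean_r      mean_g     mean_b  n_components
    tray    0    0     1321       NaN  49.827403  177.462528  59.608630             1
    tray    0    1     3553       NaN  49.898114  178.393189  59.729243             1
    tray    0    2       45       NaN  49.577778  166.644444  57.755556             1
r = 1.0000
```

Each row is one well: the measured rosette area in pixels, the mean RGB
color over retained plant pixels, and the number of retained blobs. The
correlation against the exact ground-truth manifest is 1.0000 to four
decimals despite the perspective warp; without a warp the areas are
integer-exact. Heritability of a simulated accession panel at the study's
variance components:

```python
from phenotray.stats import broad_sense_heritability
panel = syn.simulate_phenotype_panel(
    syn.PanelSimSpec(417, 3, var_genetic=21.0, var_residual=4.0,
                     mean=100.0, rng_seed=11))
est = broad_sense_heritability(panel)
print(f"h2 = {est.h2:.3f}")   # h2 = 0.820  (truth: 21/25 = 0.84)
```

The same operations are exposed on the command line
(`phenotray --help`): `simulate-tray`, `simulate-panel`, `simulate-gwas`,
`process-tray`, `growth`, `heritability`, `compare-mutants`, `gwas`,
`candidates classify|summarize`, and `run` (the full YAML-configured
pipeline). For instance:

```bash
$ phenotray candidates summarize
{
 "concordant_negative": 9,
 "concordant_positive": 4,
 "discordant": 3,
 ...
 "total_concordant": 13,
 "overlap_percent": 12.5
}
```

of the 16 validated genes, nine are cold-repressed with enhanced-growth
knockouts, four cold-induced with reduced-growth knockouts, and two
(12.5%) were already known from earlier genetic studies.

## Documentation

`docs/methods.md` describes the models, estimators, numerical choices and
the scope of the synthetic-data generator in detail.
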