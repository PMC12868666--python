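# Methods

## The analysis problem

An imaging spatial transcriptomics (IST) run yields, per tissue section:
segmented cell boundary polygons, a cells × genes raw count matrix over a
targeted panel, and cell coordinates in micrometres. Post-run
immunofluorescence (IF) on the *same* section stains phospho-synuclein
(pSyn) inclusions, imaged in its own pixel frame. The package joins the two
modalities and quantifies (i) which cell types are vulnerable to pathology,
(ii) which genes' expression tracks vulnerability across types, and (iii)
what distinguishes pathology-bearing from pathology-free cells of the same
type, after controlling for transgene dose.

## Coordinate conventions and registration

Images are `[row, col]` arrays with `x = col`, `y = row`, y increasing
downward; pixel `(0, 0)` has continuous coordinate `(0.0, 0.0)` at its
center. Spatial coordinates are micrometres, same orientation. The stored
affine is a homogeneous 3×3 matrix mapping image *pixel* coordinates to
spatial micrometres (the direction in which an extracted registration is
applied to the IF image); the inverse is computed on demand and
`A·A⁻¹ = I` holds to 1e-9. Registration itself (estimating the affine) is
out of scope: the affine is an input artifact, produced interactively in
real experiments and exactly known in simulation.

## Segmentation contract

Cell boundaries are derived from nuclei label masks by bounded nuclear
expansion: every pixel within `expand_um` (default 5 μm, the platform's
convention) of some nucleus takes the label of the nucleus whose *pixel
set* is nearest — measured from the nuclear boundary, not the centroid —
and nucleus pixels always keep their own label. Distance is Euclidean
between pixel centers; whether real platforms measure geodesically around
neighboring cells is not observable from their outputs, so straight-line
distance is adopted as a documented convention. Ties go to the smaller
label, which makes the result deterministic and independent of processing
order. Implementation: per-label exact Euclidean distance transforms in
padded bounding boxes; squared pixel distances are integers, so rounding
`d²` makes every threshold and tie comparison exact — the module agrees
pixel-for-pixel with a brute-force nearest-nucleus scan.

Boundary polygons are traced from each territory's outer contour at the
0.5 iso-level (sub-pixel, midway between foreground and background pixel
centers), holes ignored, collinear vertices collapsed. Polygon area matches
pixel count × pixel area to within ~2 pixel areas.

## Pathology overlay

Inclusions are 8-connected components of `image ≥ threshold`. The
threshold is a required parameter fixed once per experiment (applied
identically to every sample); it is not estimated from data. Components
smaller than `min_area_px` (default 4 px) are discarded as noise — a
convention, adopted because single-pixel speckle otherwise dominates at
realistic noise levels. An inclusion's centroid is the unweighted mean of
its pixel coordinates; centroids (not whole masks) are mapped to spatial
coordinates and tested against cell polygons. Containment is
boundary-inclusive (a centroid exactly on an edge counts as inside) —
deterministic and matching common geometry-library semantics. An inclusion
whose centroid lies in no polygon is an *orphan*: counted, logged, and
excluded from all statistics. A centroid inside several (overlapping)
polygons — which the segmentation contract precludes — is assigned to the
smallest and logged.

## Expression

Log-normalization is `v = ln(1 + c/ℓ · s)` with library size ℓ and scale
factor `s = 10⁴` (the single-cell default; reference-atlas profiles often
use 10⁶ — both are parameters). Cells with zero library size must be
filtered first and are reported by id. All linear-scale summaries use
`expm1(v)`; per-type means average `expm1` per cell then take the mean
(`expm1_mean`), with the alternative (mean of `v`) behind a flag, since
figure-legend formulas pin the unit but not the order of operations.

Cell types are annotated by Pearson correlation of each cell's marker-gene
vector against per-type reference profiles (scaled average expression,
per-gene mean 0/sd 1 across types), replacing upstream graph clustering;
externally computed labels can be supplied through the `cell_type`
metadata column instead. Zero-variance cells and exact ties are left
unassigned. Cross-platform comparison offers per-gene OLS of scaled
profiles (slope, r², p) and the full types × types Pearson matrix.

## Vulnerability statistics

Vulnerability is `100 · n_pos / n_cells` per (sample, cell type); samples
are the replicates (one dot per sample), and groups below `min_cells`
(default 10) are flagged. Types are compared by one-way ANOVA plus Tukey
HSD on the per-sample percentages; types present in fewer than two samples
are excluded. When every group has zero within-group variance the F
statistic and Tukey p-values are degenerate (0/0); the implementation
returns p = 0 for pairs with different means and p = 1 otherwise.

The gene screen regresses per-type mean %pSyn⁺ (averaged over transgenic
samples) on per-type mean expression, one OLS per gene, BH across the gene
set; points are cell types, not sample×type rows. Expression can come from
non-transgenic cells (pre-existing correlates) or transgenic cells
(transgene-dependent correlates) — both runs are supported, as is
restriction to excitatory-neuron subsets; subsets are recomputed from
scratch. The slope is reported in the %pSyn⁺-on-expression orientation;
for simple OLS, r² and p are identical in either orientation. Genes with
no expression variance across types get slope 0, r² 0, p 1 by convention.

**Compositional caveat.** Library-size normalization closes the
composition: types rich in highly expressed markers depress every other
gene's normalized share, so genes with constant transcriptional rates can
still correlate (negatively) with a marker-rich vulnerable class. This is
a property of the data transform, not an artifact of this implementation.
The default synthetic panel exhibits it (and the demo run shows filler
genes with negative slopes); the rate-balanced `mechanism_config`
removes it, making filler genes genuinely null — that configuration is the
benchmark for mechanism-recovery claims.

## Pseudo-bulk differential expression

Raw counts (never normalized values) are summed over cells sharing
(cell type, sample, pSyn status); groups under `min_cells` are dropped.
Size factors are DESeq-style median-of-ratios against a geometric-mean
reference over genes with all-nonzero counts, normalized to geometric mean
1, falling back to library sizes (logged) if no such gene exists. Each
gene is fit with an NB GLM (log link, size-factor offsets); dispersion α
(`Var = μ + αμ²`) is estimated per gene by profile maximum likelihood over
α ∈ [1e-8, 100] (bounded Brent on log α, inner Fisher scoring), and the
group coefficient is tested by Wald z. Two deliberate simplifications
relative to full DESeq2: no empirical-Bayes dispersion shrinkage toward a
mean-dispersion trend, and no independent filtering or outlier refitting —
targeted panels of tens to hundreds of genes, aggregated to pseudo-bulk
depth, neither need nor reliably support them, and the calibration and
power of the simpler estimator are verified directly by simulation
(`tests/test_acceptance.py`). BH runs within each cell type × comparison
family, restricted to the custom add-on panel.

The percentile stratification contrasts pSyn⁻ cells above the type's 75th
percentile of transgene expression with pSyn⁺ cells below its 25th
percentile (linear-interpolation quantiles over all transgenic cells of
the type); strata under 10 cells skip the type. The three-way design
splits cells into non-tg, pSyn⁺-tg, and pSyn⁻-tg and runs the three
pairwise contrasts per excitatory-neuron type (inhibitory and non-neuronal
types excluded by configuration: their pSyn⁺ counts are too low to form
replicated pseudo-bulks). The consensus rule keeps genes significant in
the same direction in ≥ 2 cell types.

The per-cell GLM regresses a gene's raw count on the cell's linear-scale
transgene expression (NB, log link, log-library-size offset), transgenic
cells of one type, pSyn status deliberately ignored; non-convergent fits
fall back to Poisson with robust (HC0) standard errors and are flagged.
Whether "expression" should be counts or log-normalized values is a
genuine ambiguity of such analyses; NB-on-counts is the default (matching
the count-based frameworks the field uses), with a Gaussian-on-lognorm
option behind the `family` flag.

## The synthetic tissue generator

The generator reproduces the study layout the statistics assume: 2
genotypes × 2 sexes × `n_per_group` samples. Defaults (one tissue =
600 × 450 μm, ~880 cells):

* **Geometry** — five excitatory subtypes in cortical-depth bands
  (L2/3 0–30%, L4/5 30–45%, two L5 types 45–65%, L6 65–100%), inhibitory
  neurons and glia scattered; Poisson counts per band with hard-core
  nucleus separation (sum of radii + 1 px) via rejection sampling; nuclei
  are circles (radius 2.5–3 μm) — sufficient to exercise the expansion
  algorithm, though real non-neuronal shapes are more diverse. Boundaries
  are produced by the package's own expansion contract at 0.5 μm/px.
* **Expression** — counts `NB(μ = ℓ_c · r[type, gene]/Σr, α_gene)` with
  Gamma-distributed library sizes (cv 0.25; neurons ≈ 250, glia ≈ 120
  total counts, matching targeted-panel depth); a 36-gene panel: marker
  genes per type, the transgene hSNCA (zero rate in non-tg; per-sex
  multiplier, default M ×1.25, with *no* planted link from that to
  pathology — the dissociation is left to the user), mouse mSnca, the
  kinase Plk2 with a planted gradient peaking in L5 ET and lowest in
  L5 IT, and 24 constant-rate filler genes. α defaults to 0.3 (α = 0
  gives the Poisson limit). Fold-change spike-ins multiply rates by
  2^log2FC for transgenic cells (`spike_genotype`) or pSyn⁺ cells
  (`spike_psyn`, resampled after pathology assignment since pathology
  depends on expression).
* **Pathology** — per-cell Bernoulli with
  `logit P = β₀ + β_SNCA x_SNCA + β_Plk2 x_Plk2 + β_type` on
  log-normalized covariates; defaults (β₀ = −7.6, β_SNCA = 0.3,
  β_Plk2 = 0.8; offsets −1.5/−2 for InN/glia) chosen once to yield the
  vulnerability pattern reported for this model class — ~50% in L5 ET,
  ~20–40% in other ExN subtypes, a few percent in InN and glia. Non-tg
  cells are always negative.
* **Imaging** — one disk inclusion (radius 1.5 μm, intensity 200 on
  background 20 ± Gaussian sd 5, uint16) at each pSyn⁺ cell's nucleus
  center, rendered in an image frame rotated (±5°) and translated
  (±30 μm) relative to the tissue at 1 μm/px; the true affine is stored
  with the bundle. Placing inclusions at nucleus centers keeps the planted
  centroid a deep-interior point, so boundary clipping cannot detach an
  inclusion from its owner; multi-inclusion or orphan scenarios are
  constructed directly in tests. No optics (PSF, tiling), no transcript
  spots, no 3D.

Determinism: one seed; every sample draws from its own
`SeedSequence` child stream, so bundles are byte-stable and independent of
generation order. The pipeline derives all stage streams from the single
run seed.

What passing tests do *not* show about real data: the generator has no
segmentation errors (polygons are exactly the truth the overlay is scored
against), no registration error beyond the planted affine, no spatial
autocorrelation of expression within a type, no doublets or ambient
counts, and pathology follows the planted logistic exactly. Recovery
results are therefore upper bounds on real-data performance; the package's
claims are about the correctness of the computations, not about biology.

## Problem sizes and tolerances

Test and acceptance runs use desk-scale sizes chosen to keep the full
battery around two minutes while leaving comfortable statistical margins:
320 × 240 μm sections (~250 cells) for end-to-end overlay checks; 4
samples × 200 cells/type for vulnerability recovery (binomial 4σ bands;
Tukey power over 100 replicates); 50 replicates for mechanism, DE
(200 genes, 4 vs 4 pseudo-samples, α = 0.1) and GLM (n = 2000 cells,
planted β = 0.5) recovery. Closed-form identities (expm1 inverse,
pseudo-bulk count conservation, label-swap antisymmetry, profile-
correlation diagonal) are asserted at 1e-12–1e-8.

## Known limitations

* Inclusions are assigned by centroid only; intensity-based per-cell
  quantification and nuclear vs neuritic pattern classification are out of
  scope.
* Dispersion estimation is gene-wise; with very few pseudo-samples the
  estimates are noisy, and the Wald test is anti-conservative at extreme
  dispersions (mitigated by the profile floor and verified calibration at
  the design sizes above).
* `anova_tukey` treats per-sample percentages as exchangeable replicates;
  cell-level mixed models are not implemented.
* Reference-based annotation assumes the reference covers all types
  present; novel types are silently assigned to the nearest profile.
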