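# spatipath

Pathology-aware analysis of imaging spatial transcriptomics (IST) data.

In synucleinopathy mouse models, phospho-synuclein (pSyn; α-synuclein
phosphorylated at Ser129) inclusions form in some neurons and not others.
Because IST platforms (e.g. Xenium) preserve tissue morphology, the same
section can be stained afterward for pSyn by immunofluorescence (IF),
letting every segmented, transcriptomically profiled cell be scored for
pathology. `spatipath` implements that join and the statistics built on it,
for anyone quantifying *selective vulnerability* — which cell types develop
pathology, and which genes track it:

1. **Segmentation contract** — nuclei label masks are expanded outward a
   fixed distance (default 5 μm), each pixel going to its nearest nucleus,
   truncated where territories collide (`segmentation`).
2. **Pathology overlay** — the IF image is thresholded into inclusion
   objects; inclusion centroids are mapped through the stored image→spatial
   affine; a cell is pSyn⁺ iff an inclusion centroid falls within its
   boundary polygon (`pathology_overlay`).
3. **Vulnerability** — per sample and cell type, the percent of cells
   pSyn⁺; one-way ANOVA with Tukey HSD across types, and per-gene OLS of
   %pSyn⁺ on mean expression (expm1 of log-normalized counts) with
   Benjamini–Hochberg correction (`vulnerability`).
4. **Pathology-stratified DE** — percentile stratification
   (pSyn⁻/transgene-high > 75th percentile vs pSyn⁺/transgene-low < 25th),
   pseudo-bulk aggregation over (cell type, sample, pSyn status),
   negative-binomial Wald tests with median-of-ratios size factors, a
   ≥2-cell-type same-direction DEG consensus rule, and per-cell NB GLMs of
   gene expression against transgene (hSNCA) expression (`diffexp`).
5. **Synthetic tissue** — a generator producing full Xenium-like sample
   bundles (polygons, counts, metadata, IF image, affine) with known ground
   truth: layered cortical cell types, NB counts over a targeted panel, and
   pathology planted by a logistic mechanism
   `logit P(pSyn⁺) = β₀ + β_SNCA·x_SNCA + β_Plk2·x_Plk2 + β_type`
   (`synthetic_data`). Every downstream stage is tested by recovering what
   the generator planted.

Statistical conventions: log-normalization is `v = ln(1 + c/ℓ·s)` with
scale factor `s = 10⁴`; linear-scale summaries use `expm1(v)`; the NB model
is mean/dispersion with `Var = μ + αμ²`, gene-wise dispersion by profile
maximum likelihood (floor 10⁻⁸, no shrinkage trend); BH-adjusted p < 0.05
throughout.

## Worked example

```bash
spatipath run --seed 1 --out demo/
spatipath report --run-dir demo/
```

simulates 4 non-tg + 4 α-syn-tg cortical sections (~880 cells each),
overlays the rendered pSyn IF images, annotates cell types against
reference profiles, and runs the full statistics. The report prints, among
other tables:

```
## Vulnerability (% pSyn+ per cell type, mean over samples)
              mean   std  count
L2/3 IT ExN  33.78  0.63      2
L4/5 IT ExN  27.44  0.38      2
L5 ET ExN    49.10  5.70      2
L5 IT ExN    30.03  2.63      2
L6 ExN       42.03  0.51      2
InN           0.96  1.36      2
Astro         1.33  0.60      2
Micro         0.00  0.00      2

## Top genes by vulnerability regression r2
    gene   slope     r2      p  p_adj
Filler10 -1.3319 0.9372 0.0001 0.0028
    Plk2  0.0603 0.9076 0.0003 0.0046
 Slc17a7  0.0214 0.8550 0.0010 0.0098
```

Reading this: excitatory neurons are far more vulnerable than inhibitory
neurons and glia, with a planted gradient peaking in L5 ET (~50%) — the
pattern the simulator's logistic mechanism encodes through Plk2 expression.
The regression recovers Plk2 (positive slope: more kinase, more pathology).
The filler genes appearing with *negative* slopes are a real property of
library-size-normalized data, not a bug: types rich in highly expressed
markers dilute every other gene's normalized share (compositional closure),
so constant-rate genes anti-correlate with the marker-rich vulnerable
types. The rate-balanced benchmark configuration
(`synthetic_data.mechanism_config`) removes this coupling and shows filler
genes are then null, as expected. The consensus DEG table likewise flags
Plk2 as upregulated in pSyn⁺ cells across multiple ExN subtypes — a
selection effect of the planted mechanism, recovered by the three-way
(non-tg / pSyn⁻-tg / pSyn⁺-tg) pseudo-bulk design.

Per-sample bundles can also be written to disk and processed step by step
(`spatipath simulate`, `segment`, `overlay`, `annotate`, `vulnerability`);
all artifacts are plain formats (GeoJSON, MatrixMarket, TSV, TIFF).

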