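# Methods

This note documents the models, algorithms and design choices behind the
package, stage by stage, and what the synthetic benchmarks do and do not
demonstrate about real data.

## 1. The phenotyping problem

Bulliform cells are enlarged adaxial epidermal cells of grass leaves,
arranged in columns parallel to the lateral veins; their patterning
(how many columns, how wide) varies across maize inbred lines and
relates to leaf rolling and drought response. The pipeline measures two
phenotypes per microscopy image of a leaf-epidermis glue impression —
**bulliform column number** and **average column width** — at panel
scale, then maps their genetic architecture.

## 2. Image preparation (`bulliform.imaging`)

Raw images are converted to grayscale (ITU-R 601 luminance weights),
resized to 968 x 1292 with anti-aliased bilinear interpolation, scaled
to [0, 1] floats, cropped to 960 x 960 and split into four 480 x 480
quadrant tiles. Two choices were genuinely open and are fixed as:

- **Crop anchor**: top-left of the standardized frame (deterministic and
  simplest; the offset is recorded in tile metadata).
- **Resize policy**: direct resize to the target shape (stretch), not
  aspect-preserving padding.

`crop_and_tile` and `reassemble` are exact inverses on the 960 x 960
domain; this is property-tested, so segmentation maps survive the tile
round trip bit-exactly.

## 3. Segmentation (`bulliform.nn`, `bulliform.unet`, `bulliform.segmentation`)

A classic U-net: a contracting phase of repeated [two 3 x 3
convolutions + 2 x 2 max-pool] units, an expanding phase of repeated
[2 x 2 up-convolution + concatenation with the matching encoder feature
map + two 3 x 3 convolutions] units, and a 1 x 1 sigmoid head. Channel
widths double per level from `base_channels`. The implementation is
pure numpy (im2col convolutions, manually derived backward passes,
Adam, binary cross-entropy on logits), single-threaded-deterministic:
identical seeds give bit-identical models on any platform. Gradient
correctness is verified against central differences in float64.

**Ensemble.** Five members are trained on the same tiles and differ
*only* by random seed (`seed, seed+1, ...`), the minimal reading of an
ensemble whose members are not otherwise distinguished. Per-pixel
sigmoid outputs are averaged arithmetically and thresholded at 0.5 to
produce the binary segmentation map. The aggregate probability is
always inside the min/max envelope of the members (tested).

**Hyperparameters.** Defaults: learning rate 5e-5 (selectable on a 10%
validation split by final-epoch validation cross-entropy, ties to the
smaller rate, divergent rates excluded), Adam, 50 epochs, batch 2,
threshold 0.5, no augmentation (a deliberate default: the synthetic
training signal is not inflated by invented transforms). All are
exposed in `UNetConfig`.

**Scaled-down benchmark.** Training a 480-px five-member ensemble is a
GPU-scale job, so correctness is demonstrated on a reduced problem
chosen once: 128 x 128 tiles, depth 2, 8 base channels, 96 training
tiles (10% held out for validation), 24 test images, learning rate
1e-3, 10 epochs, batch 4. Pass criteria: held-out pixel F1 >= 0.9 and
column-count accuracy >= 96%, mirroring the accuracy regime reported
for full-scale bulliform phenotyping (96.46% / 89.33%). The benchmark
shows the architecture, training loop and aggregation are correct and
that the ensemble learns texture-vs-column discrimination; it does not
show robustness to real-image nuisances (illumination gradients,
macrohairs, prickle hairs, focus variation), which the synthetic
generator deliberately omits.

**Accuracy metric.** The published accuracy formula is not fully
specified, so the package defines and documents its own stand-in:
per-trait accuracy = 100 x (1 - mean over images of
|predicted - manual| / manual), with zero/undefined manual values
excluded with a warning. "Manual" traits are computed from the manual
mask by the identical trait code.

## 4. Trait quantification (`bulliform.traits`)

The counting axis is not self-evident from a prose rule of "more than
three continuous pixels"; since bulliform columns are vertical
structures, the package counts on the **vertical occupancy profile**:
the fraction of bulliform pixels per image column, thresholded at 0.5
(configurable), with maximal runs of marked columns counted when
**strictly longer than 3 px** (i.e. >= 4). A per-scanline variant
(count runs per row, median across rows) ships behind `mode="scanline"`
for sensitivity analysis. The profile count is property-tested against
a brute-force run-length oracle on random layouts.

Width: the literal ratio (total bulliform pixels / column count) has
units of pixels^2 per column; dividing by the number of rows containing
any bulliform pixel and multiplying by the micrometer-per-pixel scale
gives a width in micrometers, equal to the mean per-column pixel width
for full-height columns. Both the raw ratio and the normalized width
are reported. The pixel scale of the original microscope setup is
unpublished, so `um_per_px` is a required configuration value with no
hidden default in I/O paths (library default 1.0 = pixel units).

Aggregation: image -> plot means (up to 15 images: five plants x three
shots), widths undefined on empty maps excluded from the width mean
only, contribution counts recorded.

## 5. Synthetic data (`bulliform.synth`)

- **Images**: bright vertical bands (intensity 0.75) with sinusoidal
  edge jitter and +-20% per-column width jitter on a darker (0.45)
  background textured by band-passed noise at an epidermal-cell scale,
  plus Gaussian pixel noise (SD 0.08). Truth traits are *recomputed
  from the emitted mask* by the trait module, so generator and
  quantifier can never disagree. Columns are laid out on an even grid
  with jitter; layouts that cannot fit raise instead of overlapping.
- **Field trial**: two environments, 26 incomplete blocks of 18
  experimental entries plus the two checks (N28HT, Mo17) at random
  positions — a 20-row x 26-column grid per environment, 468 lines,
  one replicate per environment. The incomplete block is the grid
  column; the crossed "column within environment" effect is carried by
  the 20-level row factor so both effects stay estimable. Plot values
  are sums of i.i.d. normal draws per term. Flowering time is simulated
  analogously with optional genetic correlation to the trait.
- **Genotypes**: lines are founder mosaics. Founder haplotypes are
  Bernoulli(p_j) with a Gaussian-copula AR(1) dependence (coefficient
  0.95 per adjacent SNP) along each LD block; each line copies one
  founder, switching with probability 0.02 per SNP and forcibly at
  block boundaries; 1% per-SNP mutation. This yields r^2 decaying
  smoothly with inter-SNP distance, `ld_block_len=1` degenerates to
  independent markers, and founder sharing creates the population
  structure the kinship must absorb. Inbred coding 0/2 with small het
  and missing rates; planted QTL are given mid-range (0.3-0.5) founder
  frequencies so they remain well polymorphic.
- **Annotation/DE**: non-overlapping gene intervals by slot
  partitioning; a configurable fraction of genes is up-/downregulated
  at FDR < 0.10.

## 6. Mixed models (`bulliform.quantgen`)

Model: y = X beta + sum_i Z_i u_i + e with fixed grand mean + check
effects and independent random environment, genotype, G x E,
block(env), column(env) terms. Genotype and G x E design columns carry
zero loadings on check plots (checks are fixed, BLUPs are for
experimental lines).

**REML.** Average-information updates with step-halving; whenever an AI
step fails to increase the restricted likelihood, an EM step (monotone
by construction) is taken instead, so the log-likelihood path is
non-decreasing (tested). Non-negativity by projection to a floor of
1e-10 x var(y); convergence when the log-likelihood changes by less
than 1e-6 (max 500 iterations, diagnostic error beyond). The component
covariance is the inverse average-information matrix at convergence.
Correctness anchors: exact agreement (1e-6) with MS-based ANOVA
estimators on balanced one-way designs, and agreement with lme4's REML
within 2% on a replicated two-environment design.

**Identifiability caveat.** With a single replicate per line and
environment — the actual layout of the emulated trial — sigma2_GxE and
sigma2_e are confounded for experimental plots (only their sum, and
what the replicated checks contribute, is identified); REML solutions
lie on a near-flat ridge and the individual estimates are arbitrary
along it. Line-mean heritability is invariant along that ridge (it
involves GxE/2 + e/2 under two environments and one replicate), which
is why it is the recovery target; component-wise recovery tests use a
replicated design instead.

**Outlier screening.** The model's fitted marginal covariance whitens
the data (Cholesky); Studentized deleted residuals of the whitened
fixed-effects regression are compared with the two-sided t critical
value at alpha = 0.05 and n - p - 1 df, single pass, unadjusted (a
Bonferroni option exists). On clean data this removes ~alpha of the
observations by construction.

**Model reduction.** Backward elimination: each removable random term
is tested by twice the REML log-likelihood difference against the
boundary-corrected null (equal mixture of chi-square 0 and chi-square
1); the least significant term above 0.05 is removed and the model
refitted. Genotype is never removed. The 2-level environment component
has essentially one degree of freedom and is rarely "significant";
tests treat its fate as unconstrained.

**Heritability.** Plot basis h2 = s2_G / (s2_G + s2_e); line-mean basis
h2 = s2_G / (s2_G + s2_GxE / nE + s2_e / (nE nr)) with harmonic-mean
numbers of environments and replicates computed from the realized data.
Standard errors by the first-order delta method using the REML
component covariance; validated against a parametric bootstrap.

## 7. GWAS (`bulliform.gwas`, `bulliform.candidates`)

- **SNP QC**: minor-allele count >= 40, call rate >= 60%,
  heterozygosity <= 10%, per-SNP inbreeding F = 1 - h_obs / 2p(1-p)
  >= 0.8; allele counts over non-missing calls (two per line);
  monomorphic SNPs dropped with a reason code.
- **LD**: r^2 is the squared Pearson correlation of dosages over shared
  non-missing lines (equivalent to haplotype r^2 for inbreds). Pruning
  is greedy PLINK-style (window 50 SNPs, step 5, threshold r^2 0.2; of
  an offending pair the lower-MAF member is removed).
- **Kinship**: VanRaden, K = W W' / (2 sum p_j (1-p_j)), W centered at
  2p_j, missing dosages mean-imputed (haplotype imputation is out of
  scope, and mean imputation is also used for PCA and testing).
- **Covariates**: BIC over {flowering-time BLUP in/out} x {0..10
  leading genotype PCs}, scored with the full-ML log-likelihood of the
  null kinship model (ML, not REML, because fixed effects differ across
  candidates); parameter count = fixed effects + 2 variance components.
- **P3D scan**: variance components of y = X beta + u + e,
  u ~ N(0, s2_g K), estimated once by REML via the spectral
  decomposition of K (profiled over the variance ratio, Brent search,
  boundary checked), then fixed; each mean-imputed SNP is tested by a
  GLS Wald t-test after whitening, df = n - p - 1. With K = I this
  reduces exactly to per-SNP OLS (tested to 1e-8). Benjamini-Hochberg
  step-up q-values; significance at q <= 0.05. No compression/
  clustering of K.
- **Candidate windows**: for the minimum-p SNP, r^2 against all
  same-chromosome SNPs; the window is the 1-based inclusive positional
  span of SNPs with r^2 > 0.5 (top SNP included; degenerate single-
  point window reported when no partner exceeds the threshold). Genes
  overlapping the window are flagged up/down/not-DE from the DE table
  at FDR < 0.10.

**Calibration measurement.** Type-I error is evaluated on the LD-pruned
(r^2 <= 0.2) subset of the null scan, pooled over three independent
structured null panels: within a panel, LD clusters false positives and
the binomial reference interval (which assumes independent tests) is
too narrow for the raw per-SNP rate; pruned tests are close to
independent and pooling removes the single-realization fragility.

## 8. Problem sizes

Chosen once as the package's desk-scale study conditions: segmentation
benchmark 96 + 24 images at 128 px with 5 members x 10 epochs;
heritability at the emulated panel scale (468 planted, 461 analysed
lines, 2 environments); GWAS nulls at 200 lines x 2000 SNPs (x3
panels), power at 400 lines x 1000 SNPs x 20 replicates with a QTL
explaining roughly 15% of phenotypic variance.

## 9. Known limitations

- The synthetic images contain no macrohairs, prickle hairs, lighting
  gradients or instance-level cell boundaries; benchmark accuracies do
  not transfer to real glue impressions.
- Genotypes come from a founder-mosaic model, not a coalescent; allele-
  frequency spectra and long-range LD are stylized.
- Mixed models assume independent homoscedastic random effects — no
  spatial (AR1 x AR1) field models, no multivariate/G x E GWAS.
- The single-replicate G x E/residual confounding above is a property
  of the emulated design itself, not an implementation artifact.
- With two environments the environment variance is essentially
  unidentified; it is kept in the model for structure, not inference.
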