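# Methods

`nichespace` implements a trait-based ("periodic table of niches") analysis
of woody plant communities: species are positioned in a continuous
two-dimensional niche space built from 11 functional traits, the space is
searched for taxonomic convergence, and niche positions are compared across
biomes. This note documents the model, the numerical conventions, the
synthetic data generator and the design choices that were genuinely open.

## Trait model

Eleven traits are grouped into three functional niche dimensions:

| dimension | traits | units |
|---|---|---|
| leaf economy | LA, LDMC, SLA, LNC | cm², g/g, cm²/g, g/kg |
| mechanical support | STD, MPH, MDBH | g/cm³, m, cm |
| reproductive phenology | FLT, FRT, FLD, FRD | Julian day, days |

Derivations: LDMC = leaf dry mass / fresh mass (validated to (0, 1]);
SLA = leaf area / dry mass; STD = branch-segment dry mass / fresh volume.
MPH and MDBH are the 95th percentile of height and DBH over at least 20
individuals per species; the quantile convention is linear interpolation
between order statistics (Hyndman–Fan type 7, numpy's default) — the
convention is not forced by anything else in the analysis, so it is fixed
here and used consistently.

Phenology uses a fixed non-leap 365-day calendar (forced by the worked
anchor August 1 = day 213). A flowering window of months *a..b* covers
Julian days first(*a*)..last(*b*); mean time is the midpoint rounded half
up (258.5 → 259 — half-up is the only rounding consistent with that printed
anchor) and duration is the day difference. Windows with last month before
first month are cross-year; they are refused by default and unrolled into
the following year only under an explicit `allow_wraparound` flag, because
no encoding for them is documented for the original data.

Species measured at two sites enter as two independent analysis rows keyed
by (species_id, biome). The field sampling rule — only species with
strictly more than 20 individuals — is `abundance_filter`.

## Nested ordination ("PCA of PCAs")

All traits are log10-transformed. Stage 1 runs one PCA per dimension on the
standardized (correlation-scale) trait block; stage 2 runs a PCA on the six
standardized PC1/PC2 species-score columns of the three stage-1 analyses.
The stage-2 PC1/PC2 plane is the niche space.

Numerical conventions:

* Both stages are ordinary PCA on the correlation matrix. Standardization
  at stage 1 is required because trait units are incommensurate; at stage 2
  it makes the eigenvalues sum to 6, so percent variance of component *k*
  is exactly eigenvalue_k/6 × 100 (asserted to 1e-8 in the tests).
* PCA is computed by SVD of the centered/scaled matrix with ddof = 1
  statistics; eigenvalues below 1e-10 are clamped to zero. Rank-deficient
  input (a six-species biome against six stage-2 columns) is allowed; the
  zero tail is reported and a small-n warning raised.
* Axis orientation is arbitrary in PCA; every axis is flipped so its
  largest-magnitude loading is positive (`fix_sign`, idempotent), making
  all reports deterministic. Published loading signs are therefore
  reproduced only up to per-axis orientation.
* Each axis is annotated with its dominant variable(s): the largest
  |loading|, with ties within 1e-6 joined (so near-collinear height and
  diameter read as one "plant size" annotation).
* Loadings are reported in two conventions: unit eigenvectors (primary)
  and eigenvectors scaled by √eigenvalue (secondary, vegan-style species
  scaling, which can exceed 1 in magnitude). No equivalence to any
  particular published scaling constant is asserted.

## Niche plots and convergence

The niche plane is partitioned into half-open 0.5 × 0.5 squares anchored at
the origin — the anchoring is not documented anywhere, and origin-anchored
half-open cells are the unique choice that makes assignment total,
deterministic and translation-consistent. The reported plots are the k = 8
cells containing at least two species whose centers lie nearest the origin
(ties broken by angle, then cell index); single-species cells carry no
convergence information. For each plot the convergence ratio is
|families| / |species| ∈ (0, 1]: 1 means every co-occurring species is from
a different family. A space with no multi-species central plot is flagged
"periodicity not assessable" — the expected outcome for a six-species
community.

As an optional extension (clearly labelled, off by default) a permutation
null is provided: family labels are shuffled across species and the mean
central-plot ratio recomputed, giving a reference distribution that the
observed ratio can be compared against. The original procedure interprets
the raw ratio without a null.

## Cross-biome comparison

Biome differences on each pooled axis are tested with the Kruskal–Wallis
rank test, implemented from the rank-sum formula with tie correction and a
chi-square approximation (group sizes here are ≥ 6); scipy's implementation
serves as an independent cross-check in the tests, not as the
implementation. The compact letter display is built from Dunn-type pairwise
rank comparisons (pooled-rank variance with tie correction) with Holm
adjustment at α = 0.05 — the exact post-hoc behind the published letters is
not documented, so the adjustment method is configurable. Letters are
assigned one per maximal clique of the non-significance graph, which
guarantees the display property: two biomes share a letter **iff** their
pairwise comparison is non-significant.

## Synthetic communities

The original field data are available only on request, so the pipeline is
exercised on a generator whose defaults state a fixed world:

* 215 species rows — 90 tropical (TF), 70 subtropical (SF), 49
  warm-temperate (WF), 6 cold-temperate (CF) — with 8 species shared
  between adjacent sites; 116 genera nested in 55 abstract families
  (F01..F55); abundances log-series-like with minimum 21 (the field rule
  samples only species with > 20 individuals).
* Traits follow a block latent factor model on the log10 scale:
  log10(trait) = μ_t + σ_t (w_t · z + noise_sd · ε), with two latent
  factors per dimension (economics + leaf size; stature + stem density;
  phenological duration + timing) and noise_sd = 0.3. Phenological timing
  traits carry a ×2.2 noise multiplier: they come from a flora database at
  month resolution and are genuinely noisier than measured traits, which
  also separates the duration and timing sub-blocks spectrally so stage-1
  PC1 is a duration axis and PC2 a timing axis, the published pattern.
* Within-biome latent correlations: economics vs stem density −0.75
  (acquisitive species have light stems) and leaf size vs plant size +0.6.
  These couplings are what make the pooled PC1 an economics/density axis
  and PC2 a size axis.
* Biome mean shifts follow two *distinct* monotone latitudinal profiles:
  economics (and stem density, inverted) change most sharply at the
  tropical end (TF +1.0 → CF −1.2 sd), while leaf size and stature fall off
  toward the temperate sites and collapse in the cold-temperate forest
  (+0.65 → −2.3 sd); phenological duration follows the economics profile at
  0.3×. A rank-one between-biome structure cannot place signal on both
  pooled axes (the second axis is the residual of the first), so the
  rank-two geometry is a structural requirement of the pattern the real
  communities show, not a tuning knob.
* Out-of-bounds draws (e.g. LDMC > 1 g/g, DBH < 1 cm) are rejected and
  redrawn — noise first, then the species' latent position — never clipped,
  so the factor model stays exact conditional on acceptance.
* Month windows are derived from the continuous FLT/FLD (FRT/FRD) values;
  the trait table keeps the continuous values, so windows agree with them
  only to month resolution, and fruiting windows are nudged to start no
  earlier than flowering.
* `plant_convergent_cluster` moves n species to a chosen latent-space
  point (± a uniform perturbation of given radius) with noise-free trait
  regeneration and reassigns their families across n distinct labels,
  planting a known convergent cluster for end-to-end verification.

What the generator does **not** emulate: real taxonomy (families are
abstract labels independent of niche position — which inflates convergence
ratios toward 1 relative to real phylogenetically structured data),
intraspecific variance, spatial structure within plots, environmental
covariates, and cross-year phenology. A green end-to-end test therefore
establishes that the *machinery* recovers a known world of the stated
shape, not that any particular field result is reproduced; the published
PCA tables derive from request-only raw data and their numeric values are
out of reach by design.

### Interpreting the end-to-end biome pattern

The qualitative reproduction check asserts: Kruskal–Wallis P < 0.001 on
both pooled axes, and biome centroids ordered tropical → subtropical →
warm-temperate → cold-temperate along the principal axis of the centroid
scatter in the niche plane. The path formulation is used because per-axis
centroid orderings are partly determined by how pooled PCA splits a shared
biome gradient between axes (the second axis receives a residualized,
generally non-monotone contrast), whereas the latitudinal progression of
centroids through the plane is the robust, interpretable signature of the
gradient.

## Known limitations

* Eigenvector sign and near-tied eigenvalues: with nearly equal stage-2
  eigenvalues the PC1/PC2 plane is stable but individual axes can rotate
  between similar datasets; reports are deterministic for fixed input.
* The compact letter display is clique-based; for pathological
  non-transitive decision matrices it can emit more letters than the
  classical insert-and-absorb display, but the sharing property always
  holds exactly.
* The 0.5-unit plot grid is resolution-sensitive near cell boundaries;
  species within numerical noise of a boundary are assigned by the
  half-open rule, not merged.
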