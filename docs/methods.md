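# Methods

This note documents the models, estimators and numerical choices behind
`toxqtl`, and what the synthetic-data generators do and do not emulate.

## Phenotype processing

The unit of measurement is one animal passing a large-particle flow
cytometer: TOF (length proxy), EXT (optical-density proxy) and three
fluorescence channels, keyed by plate/well/strain/condition/dose. Mapping
operates on per-well summaries:

- `n` and `norm.n = n / n_sorted` — brood size normalized by the number of
  animals sorted into the well (default 3);
- `mean.TOF`; `mean.norm.EXT` and `mean.norm.yellow` — means of the
  **per-animal** ratios EXT/TOF and yellow/TOF (not ratios of means; the
  per-animal form is the literal reading of "normalized by animal length");
- q10/q25/q50/q75/q90 per channel, with the type-7 linear-interpolation
  quantile rule. The rule is stated because upstream tools do not fix one;
  any order-statistics convention would serve, but results must be
  reproducible to the digit.

Assay regression replaces each trait by residuals of `trait ~ block`
(categorical), i.e. within-block centering; a single block is an identity
transform with a warning. Two outlier rules are provided because replicated
and unreplicated designs need different ones:

- `prune_outliers_sd` — per (trait, strain, condition), drop replicates more
  than k·SD (default k = 2, sample SD) from the strain mean; inert for
  groups with < 3 replicates or zero spread.
- `prune_outliers_fence` — per trait across strains, drop values outside
  [q25 − 2·IQR, q75 + 2·IQR]. **This fence rule is this package's own
  re-specification**: the pruning heuristic used by the upstream sorter
  -processing tooling is not published, so a conventional IQR fence stands
  in; treat pruned counts as implementation-defined.

Control regression fits one global line `toxin ~ control` over
strain-matched pairs (strain means on each side) and keeps residuals. A
per-strain fit is impossible with one replicate per strain, which is the
mapping design; the global fit removes the shared growth component while
preserving strain contrasts. Pairwise deltas (toxin − control) were the
alternative reading; residuals were chosen because they also absorb scale
differences between conditions.

## PCA composite traits

Traits are scaled to mean 0, SD 1 (n−1 denominator throughout). PCA is the
SVD of the centered scaled matrix, equivalent to eigendecomposition of the
trait correlation matrix. Retained components: the smallest k whose
cumulative variance fraction reaches 0.90. PCA signs are arbitrary, so each
loading column is flipped to make its largest-magnitude entry positive;
without this convention PC1 comparisons across runs are meaningless. When
several dose levels are analyzed together, scaling is done across all
concentrations pooled (within-concentration scaling would erase the dose
signal the composite trait is meant to carry).

## Heritability

Replicate-based broad-sense H² fits `y ~ 1 + (1|strain)` by REML
(statsmodels MixedLM) and reports σ²strain/(σ²strain+σ²resid). Perfect
within-strain repeatability short-circuits to H² = 1 (the mixed model is
degenerate there). The closed-form balanced one-way ANOVA estimator
(MSB − MSW)/(MSB + (r−1)MSW) agrees within 1e-4 on balanced designs and is
the test oracle.

Kinship-based variance components fit y = 1µ + u_A (+ u_AA) + e with
Var(u_A) = σ²A·A by REML. Kinship flavors:

- additive correlation — Pearson correlation of strain genotype vectors
  (undefined for a strain fixed genome-wide for one founder; an error names
  the strain);
- realized additive (VanRaden) — columns centered by 2(p−0.5) on the −1/+1
  scale, A = WWᵀ / (2Σp(1−p)); for fully inbred lines the mean diagonal is
  near 2 (= 1 + f with f = 1);
- epistatic — the Hadamard square A∘A of an additive kinship.

Numerics: single-kinship fits profile the REML likelihood over
δ = σ²A/σ²e in the kinship eigenbasis (ridge jitter 1e-6 on the diagonal),
scanning log δ on a 41-point grid over [−10, 10] then refining with bounded
scalar minimization; the lower grid edge is reported as δ = 0. Two-kinship
fits optimize both log-ratios by Nelder-Mead from three starts and compare
against the single-component and null boundary fits, so vanishing
components land exactly on the boundary. **Caveat:** A and A∘A are highly
correlated on structured panels, so the additive/epistatic *split* is weakly
identified at n ≈ 100–250; the total H² and the additive-only h² are the
stable quantities, and per-seed two-component splits should not be
over-read. No standard errors are attached to any variance component.

ANOVA effect sizes are one-way: partial
ω² = (SS_g − df_g·MS_e)/(SS_g + (N − df_g)·MS_e), reported as computed —
slightly negative values under the null are kept so the estimator stays
unbiased near zero (common implementations floor at 0). Cohen's
f = √(η²/(1−η²)) with η² = SS_g/SS_total; perfect separation reports +∞.
The "fraction of an effect recapitulated" helper is the plain ratio of two
Cohen's f values; no published formula pins this definition down, so ratios
above 1 are flagged but returned.

## Linkage mapping

LOD_m = −n·ln(1−r_m²)/(2 ln 10); monomorphic markers score 0 with a flag
rather than erroring mid-scan; missing genotypes drop strains pairwise with
n adjusted per marker. Permutation thresholds permute whole strain rows of
the multi-trait matrix jointly — the only scheme that preserves trait-trait
correlation — and take the per-trait empirical 95th percentile of
genome-wide maxima (1000 permutations by default; fewer than 20 is
rejected). The 1.5-LOD-drop interval walks contiguously out from the
chromosome peak to the outermost markers within 1.5 LOD. "Three iterations"
is implemented as forward-search residualization: each iteration scans the
residuals of the original trait on all previously detected peak-marker
genotypes, keeping at most one peak per chromosome (the first, strongest
detection); this is the standard reading of an iterated single-marker scan
and is documented as an interpretation. Variance explained is always the
squared correlation of the peak marker with the *original* trait.

## Association mapping

Filters: any missing call removes a marker; MAF strictly below 0.05 removes
a marker (exactly 0.05 survives). LD pruning slides a 50-marker window by
10; while any retained pair inside the window has r² ≥ 0.8, the lower-MAF
member of the worst pair is dropped (ties: later position). The removal
order inside PLINK-style pruning is not standardized, so only the
postcondition (no retained within-window pair at r² ≥ 0.8) is contractual.

The scan is exact per-marker REML ("P3D = false"): the kinship is
eigendecomposed once, each marker's design [1, g] is rotated, δ re-optimized,
and β tested by a two-sided Wald t with n − 2 df. With K = I this reduces
algebraically to the OLS F-test (an oracle test enforces 1e-8 agreement).
An approximate mode estimates δ once under the null and reuses it. Effect
sizes are on the −1/+1 genotype scale; p-values are invariant to that
choice. No genomic-control rescaling is applied — relatedness control is
the kinship term only.

M_eff sums marker-correlation eigenvalues capped at 1, computed via SVD of
the standardized strain×marker matrix so cost is bounded by the strain
count. Note the genome-wide spectrum of an n-strain panel has at most n−1
nonzero eigenvalues, so M_eff saturates near the strain count when markers
vastly outnumber strains; `per_chromosome=True` decomposes chromosomes
separately and sums, which relaxes that bound and matches how much larger
published M_eff values on strain-limited panels arise. Both the Bonferroni
threshold −log₁₀(0.05/M) and the eigenvalue threshold −log₁₀(0.05/M_eff)
are always reported; which one defines the mapped set is left to the caller.

Regions of interest extend each run of significant markers by ±100 SNV
positions (clamped at chromosome ends; overlapping extensions merge). Fine
mapping re-runs the same mixed model on all unpruned variants inside the
region and reports each variant's r² with the genome-scan peak, grouping
variants in complete LD with the top fine-map hit.

## Tajima's D

D = (π − θ_W)/√(e₁S + e₂S(S−1)) with the standard constants a₁…e₂; π is
computed from per-site allele counts (Σ 2k(n−k)/(n(n−1)), identical to the
mean pairwise difference count), θ_W = S/a₁ with S the segregating sites in
the window. S = 0 returns NaN (undefined, never 0); n < 4 is an error.
Windows are SNV-count-defined (500 SNVs, sliding 50 by default); an
incomplete trailing window is dropped. An "outgroup" parameter is accepted
for interface parity with upstream tooling and ignored — D uses folded
frequencies and needs no outgroup, and no outgroup-based site exclusion is
applied. Note that with integer allele counts π and θ_W (both rational)
never coincide exactly at small n, so D = 0 is a limit, not an attainable
value; the test suite checks the sign dichotomy and a dual-implementation
oracle instead.

## Synthetic data: what it emulates, and what it does not

RIAIL panels: a population of n F1 individuals is randomly intermated for
`generations − 1` rounds; crossovers per chromosome per meiosis are Poisson
with mean equal to the map length in Morgans, positions uniform on the
genetic map, no interference. Lines are then selfed (up to 25 rounds,
residual heterozygous runs resolved to one haplotype — expected residual
heterozygosity < 1e-7). This reproduces the map expansion of advanced
intercross panels (adjacent-marker LD falls with generations) and realistic
founder-mosaic genomes. Defaults are the mapping panel's dimensions: 252
strains, 1454 markers on six 50-cM chromosomes, 10 generations.

Wild panels: strains are mosaics of K founder haplotypes with geometric
block lengths (mean 30 markers), founder usage weighted by cluster-specific
Dirichlet draws (unequal relatedness); the derived allele at each site is
carried by k of the K founders with P(k) ∝ 1/k, the neutral-equilibrium
site-frequency shape, so diversity statistics sit near their neutral
expectations when founder usage is uniform and K ≈ n ("equilibrium-like"
setting: `n_founders = n_strains, n_clusters = 1`). Optional swept
intervals force founder-0 haplotypes with probability 0.95, suppressing
diversity. This is a founder-mosaic model, not a coalescent: it produces
LD, structure and an approximately neutral SFS, but no recombination-rate
heterogeneity, mutation model, or demographic history — passing tests show
the estimators behave on data with these features, not that they are robust
to everything real wild isolates contain.

Phenotypes: y is a weighted sum of standardized components. Planted QTL
genotypes, the block effect and the residual are sequentially
orthogonalized and scaled in-sample, so each QTL's realized variance
fraction is *exact* (a 35% QTL has sample r² = 0.350 at the causal marker).
The polygenic score is drawn from the genotype-correlation kinship
(Cholesky) and deliberately kept at population scale: forcing its realized
variance to a fixed value conditions the draw in a way that biases REML
variance-component estimates upward by ~0.07 on low-rank kinships.
Consequently realized polygenic fractions fluctuate seed to seed, and
recovery tests check means over ≥ 8 seeds.

Sorter plates: per-well brood counts are Poisson around a strain- and
dose-dependent mean following a unit-Hill dose response (mean halves at the
EC50, default 1000 µM for brood, 2000 µM for length); per-animal TOF is
lognormal (CV 0.25) with EXT and fluorescence scaling with TOF; one plate is
one assay block with an optional lognormal shift. Doses monotonically
depress brood and length. Not emulated: bubbles/contamination (inputs are
assumed clean records), well-position effects, or count saturation.

Determinism: every generator consumes a `SimulationConfig` whose seed fans
out into fixed per-purpose streams; identical configs give byte-identical
outputs. Planted truth (marker indices, variance fractions, block labels)
is returned alongside every simulated trait.

## Problem sizes in the standing checks

The acceptance script and test suite run at the study's panel dimensions
where that is cheap (252 × 1454 linkage panels, 86-strain association
panels, n = 200 variance-component fits) and scale the replication, not the
model: 500 null datasets (50 panels × 10 traits) with 200 permutations each
for threshold calibration, 50 panels for QTL recovery, 20 seeds for
heritability recovery, 1000 fuzz cases for each oracle-agreement check.
These sizes give Monte-Carlo standard errors comfortably inside the stated
tolerance bands (e.g. ±0.01 on a 0.05 false-positive rate estimated from
500 datasets).

## Known limitations

- Single-marker models only: no interval mapping with hidden genotype
  probabilities, composite interval mapping, epistasis scans, imputation,
  or multi-trait mixed models.
- Variance components carry no uncertainty estimates.
- The additive/epistatic decomposition is weakly identified on structured
  panels (see above).
- The IQR fence outlier rule is a stand-in for an unpublished heuristic.
- The wild-panel generator trades demographic realism for speed and
  dependency-lightness; absolute values of diversity statistics (as opposed
  to contrasts like swept vs neutral) should not be interpreted.
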