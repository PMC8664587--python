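# Methods

## The model

Two additive quantitative traits are carried by a diploid, randomly mating
population of N hermaphrodites with nonoverlapping generations. An
individual's phenotype vector **z** is the sum of the effects of its 2L
allele copies at the causal loci — there is no environmental deviation, so
phenotypic (co)variances equal genetic (co)variances and the G-matrix is
estimated directly from phenotypes.

Viability selection is Gaussian stabilizing + correlational:

    w(z) = exp(-1/2 (z - θ)ᵀ Ω⁻¹ (z - θ)),    Ω = ω² [[1, ρω], [ρω, 1]]

ω² (default 100, with 50 for "strong" selection) is the width of the
surface per trait — smaller means stronger stabilizing selection — and ρω
(grid 0, 0.06, 0.5, 0.85, 0.9) tilts the surface to favor matched
combinations of the two traits. Optima default to θ = (10, 10).

Two genetic architectures are contrasted. In the *pleiotropy* architecture
each causal locus affects both traits and a single mutation perturbs both:
effects are bivariate Gaussian N₂(0, α²I), with no mutational correlation.
In the *linkage* architecture causal loci come in pairs — one member per
trait — separated by a configurable map distance (0, 0.1, 1 cM), each
pair on its own chromosome (or all pairs clustered on one chromosome at a
configurable spacing). A mutation at a pair member moves one trait only;
both traits move in one generation only when both members mutate
(probability μ² per gamete), so the joint mutational distribution is a
cross along the trait axes rather than a bivariate Gaussian. Any
cross-trait covariance under the linkage architecture must therefore come
from linkage disequilibrium built by correlational selection, not from
mutational input.

Mutation follows the continuum-of-alleles model: each transmitted allele
copy mutates with haploid per-locus probability μ (grid 1e-3, 1e-4, 1e-5)
and the increment ~ N(0, α²) (grid α² = 0.001 small / 0.1 large) is added
to the current allelic value. μ ≫ α²/ω² is the Gaussian regime (many small
mutations; per-locus allelic distributions stay near-normal); μ ≪ α²/ω² is
the house-of-cards regime (rare large mutations; leptokurtic allelic
distributions). The classifier uses factor-of-10 margins around
μ = α²/ω² since only the orders of the inequalities are prescribed.

Recombination uses the Haldane map function r = (1 − e^(−2d/100))/2 per
adjacent-locus interval (no interference); chromosomes assort
independently. Neutral markers are reversible diallelic loci (μ = 1e-6)
used as GWAS markers; dense panels place 1000 (reduced: 100) equidistant
markers on a 0.1 cM chromosome around each causal unit, giving r ≈ 1e-6
between neighbors.

In *QTN mode* causal loci are biallelic: each locus gets a fixed effect
magnitude (default |N(0, α²)| per locus; equal magnitudes optional) and
mutation flips the allele's sign, so causal variants are scannable like
SNPs. Initial signs are random but shared population-wide (monomorphic
start); the residual θ − Σ effects is absorbed into a non-evolving basal
phenotype offset so generation 0 sits exactly on the optimum, as in
continuum mode where each allele copy at a trait-k locus starts at
θ_k/(2 n_k).

### Life cycle and regulation

Each generation, offspring are produced by drawing two parents uniformly
with replacement (selfing allowed, rate 1/N), each contributing one
recombined, mutated gamete; the juvenile survives with probability w(z);
reproduction repeats until exactly N survivors exist (soft selection to a
fixed carrying capacity — the regulation scheme itself is a design choice,
as only "survival probability" and constant N are prescribed). With
unidirectional migration at backward rate m, an offspring draws *both*
parents from the source deme with probability m; the source deme evolves
concurrently under its own selection regime and receives no migrants.
Crossovers are sampled sparsely (binomial counts per interval), which
keeps dense marker panels cheap.

Migration runs place the source optimum 10 units from the focal optimum
along the selection diagonal, θ_source = θ_focal + (10/√2)(1, 1); a
literal alternative optimum can be configured. Both demes burn in to
their own balance before migration starts. QTN mode is not combined with
migration (the basal offset is deme-specific).

## Theory

Closed forms in `pleiolink.theory`:

* Gaussian-regime equilibrium per-locus genetic covariance and variance,
  transcribed so that b/c = ρω/(1 + √(1 − ρω²)) — the equilibrium genetic
  correlation, independent of μ, α², ω² (0.627 at ρω = 0.9; 0.268 at 0.5).
  These are infinite-population results; drift pulls the realized
  correlation toward the (diagonal) mutation matrix, i.e. downward, and
  does so more strongly for the linkage architecture.
* The house-of-cards single-locus G-matrix for mutational direction θ,
  in both the matrix form 2μ·aaᵀ/(aᵀΩ⁻¹a) and the trigonometric closed
  form; they agree to machine precision and the on-axis directions
  (nonpleiotropic mutations) give exactly zero covariance. Totals over n
  independent loci scale linearly (linkage equilibrium between loci).

## Association mapping

A final-generation sample (default 1000 individuals; reduced scale 250 to
500) carries minor-allele dosages for all biallelic loci (neutral SNPs and
QTNs; ties at frequency 0.5 resolve toward the 1-labelled state),
phenotypes, and a truth table flagging which causal loci segregate in the
sample. Continuum QTL are not representable as SNPs; they stay in the
truth table and in haplotype-level arrays used for LD statistics.

* GRM: centered (not variance-standardized) relatedness
  K = (1/M) Σ (g − ḡ)(g − ḡ)ᵀ over markers with MAF ≥ 0.001.
* Univariate scans: per-marker simple linear regression per trait,
  two-sided t test, Benjamini-Hochberg at FDR α = 0.1. QTN scans adjust
  over the segregating QTNs only.
* Multivariate scan: bivariate linear mixed model with polygenic
  covariance K ⊗ Vg and residual I ⊗ Ve. Vg, Ve (2×2) are estimated once
  under the no-marker null by REML after an eigendecomposition of K
  (log-Cholesky parameterization, Nelder-Mead), then held fixed while
  each marker's fixed effects on both traits are tested by a 2-df
  generalized-least-squares likelihood ratio (χ²₂ p-values). This
  fixed-components scan keeps the whole scan O(M) after one
  eigendecomposition; per-marker REML refits are deliberately out of
  scope. Significance uses Storey q-values (π₀ from the cubic smoother on
  the λ = 0.05…0.95 grid, clamped to (0, 1]; π₀ = 1 reproduces BH
  exactly) at α = 0.1.
* Discovery metrics: a segregating causal locus is *discovered* when a
  significant SNP lies within 0.05 cM on the same chromosome; univariate
  "pleiotropy" requires discovery in both scans. For QTN scans, FPR =
  fraction of segregating nonpleiotropic QTNs whose own genotype is
  significant for both traits; FNR = fraction of segregating pleiotropic
  QTNs that are not. LD between significant SNPs and their nearest (in
  cM, configurable) segregating causal locus uses a multiallelic r² —
  Σ D²ij normalized by (1 − Σp²)(1 − Σq²) — which reduces to the squared
  Pearson correlation for diallelic loci; continuum alleles are
  identified by exact value (well-defined under additive mutation from a
  monomorphic start).

## What the generator emulates, and what it does not

The synthetic-data engine reproduces the study conditions: polygenic
architectures (120 loci per trait; 60 supported), the mutation grids
above, the selection surfaces, unidirectional island-mainland migration,
dense neutral marker panels, and QTN mode. It does not emulate sequence-
level genomes, variable recombination along a chromosome, environmental
trait variance, population-size change, or more than two demes/traits —
so passing tests demonstrate the comparative behavior of architectures
under the stated model, not robustness of GWAS conclusions to population
structure, covariates or ascertainment found in real data.

## Problem sizes used by the test suite and acceptance script

Full-scale runs (N = 5000, 50,000 generations, 10-50 replicates, up to
120,000 markers) are cluster-budget jobs exposed through
`run_experiment(..., scale="full")`. The package's own desk-scale choices,
fixed once from pilot calibration of equilibration times and replicate
noise, are:

* analytic/oracle checks: exact, seconds;
* neutral-drift checks: N = 100-200, 20-40 replicates;
* directional equilibrium contrasts: N = 300, 60 loci per trait, 2,500
  generations, 3 replicates, with Gcor time-averaged over the final half
  of the run to damp single-generation fluctuation. The
  pleiotropy-vs-linkage and between-pair-clustering contrasts use
  μ = 1e-4 (a grid value the classifier still places in the HoC regime at
  α² = 0.1, ω² = 100), because at μ = 1e-5 too few mutations arrive at
  desk-scale N·T for a stable contrast. The within-pair-distance
  contrast uses the small-effect cell (α² = 0.001, μ = 1e-3), where the
  distance effect is expressed; at α² = 0.1 with μ = 1e-3 the
  infinite-population equilibrium is distance-independent;
* the migration contrast: N = 300, 30 pleiotropic loci, μ = 1e-3,
  α² = 0.1, 1,000 generations of burn-in + 1,500 of migration. The high
  mutational input matters here: with negligible local standing variance
  a single rare migrant family (displaced along the selection diagonal)
  already saturates the focal-deme correlation at any m, and the
  migration-rate ordering is unresolvable at small N;
* the quantitative anchor (μ = 1e-3, α² = 0.1, ρω = 0.9): N = 1000,
  2,500 generations, 3 replicates per architecture;
* association-mapping end-to-end: N = 400, 20 chromosomes × 41-SNP
  panels, 4,000 generations, μ = 1e-5 (few large-effect alleles per
  locus — the condition under which a marker tags a pleiotropic allele
  set more easily than a linked pair's two sets), whole-population
  samples, 6 replicates, with the neutral-panel rate scaled to keep
  4Nμ at the full-scale 0.02 and discovery rates pooled over replicates
  (discovered / segregating) because per-replicate denominators are
  small.

At these sizes drift is stronger than at full scale: equilibrium genetic
correlations sit below the infinite-population expectation (e.g. ~0.45
instead of 0.63 for the Gaussian-regime linkage anchor at N = 1000), and
discovery rates are lower than the published full-scale values. The
directional contrasts — which architecture maintains more correlation,
how mutation rate, map distance and migration move it, and which scan
type calls more (spurious) pleiotropy — are the quantities these scales
are chosen to resolve.

## Numerical choices and edge cases

* Genetic correlation is defined as 0 (flagged) when either trait
  variance is 0; multiallelic r² is 0 when a locus is monomorphic.
* Allelic kurtosis uses population moments (no small-sample correction)
  and rejects degenerate distributions.
* Population regulation raises once mean fitness falls below 1e-12
  (regulation would not terminate).
* REML non-convergence is reported per scan; the kinship matrix must be
  PSD (eigenvalues clipped at 0 after a symmetric average).
* One seeded generator (numpy PCG64) per replicate drives every random
  choice; identical configs and seeds are bit-reproducible. Replicate
  seeds map injectively to (cell, seed) pairs in `run_experiment`.
* Locus ids are globally unique in genome order and define genotype
  column order everywhere; within a linked pair the trait-1 member comes
  first (symmetry makes the choice immaterial).
* Neutral-marker mutation flips are placed by uniform draws after a
  binomial count of flip events; at the panel rates used (≤1e-6 per
  allele) coincident draws are negligible.

## Known limitations

* The mixed-model scan tests markers with fixed null variance components
  (score-test flavor); p-values can be slightly conservative or liberal
  for markers with very large effects.
* The drift-aware Gaussian-regime equilibrium (mutation-selection-drift
  expectation) is not implemented in closed form; comparisons against it
  are qualitative only.
* Multiallelic r² treats every bit-distinct continuum value as a
  distinct allele, which is exact for the simulator's own output but not
  meaningful for externally rounded data.
* QTN mode assigns a pleiotropic QTN the same magnitude on both traits
  (sign-linked); per-trait magnitudes are not independent, which is one
  of several defensible readings of "same allelic effect sizes as the
  continuous case".
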