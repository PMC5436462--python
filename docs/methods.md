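# Methods

## Model and test

`funepi` tests whether two gene regions interact in shaping the
per-position read-count curve of a target gene.  All three objects —
response curve and the two genotype profiles — are treated as functions of
genomic position, remapped affinely onto [0, 1].

**Genotype functions.**  Each SNP is encoded by the frequency-centered map
MM → 2P_m, Mm → P_m − P_M, mm → −2P_M, where P_M and P_m are the major and
minor allele frequencies estimated from the analysis sample.  Under exact
Hardy–Weinberg proportions every encoded column has mean zero
(2P_M²P_m + 2P_MP_m(P_m − P_M) − 2P_MP_m² = 0), so the genotype function is
centered by construction.  A sample's encoded vector, indexed by the SNP
positions in [0, 1], is treated as a discrete function; no smoother is
applied to these step-like data.  Expansion coefficients are functional
principal component (FPCA) scores computed with trapezoid quadrature at the
(generally non-uniform) SNP positions.  A single-SNP gene degenerates to
the centered encoded column (quadrature weight 1).

**Response.**  Raw per-position counts are regridded onto a common uniform
grid of m sub-intervals by local polynomial regression (LOESS) after the
affine remap, then expanded by FPCA on the grid.  Optionally the curves are
divided by per-sample size factors first (`normalize_curves`, on by default
when factors are supplied).

**Regression and Wald test.**  With scores ξ (n×J), η (n×L), Y (n×K) and
optional covariates W (n×d), the design is A = [E W ξ η Γ] where row i of Γ
is ξ_iᵀ ⊗ η_iᵀ (column (j,l) at index j·L + l, 0-based).  Least squares
gives b̂ = (AᵀA)⁺AᵀY and residual covariance Σ̂ = RᵀR/(n − rank A).  Under
homoscedastic errors var(vec(b̂)) = Σ̂ ⊗ (AᵀA)⁺; with vec() stacking the
coefficient matrix column-wise (K-major), the covariance of the interaction
block is exactly Λ = Σ̂ ⊗ G with G the trailing JL×JL block of (AᵀA)⁺ — an
identity the test suite verifies by extracting the corresponding rows and
columns of the full Kronecker product.  The statistic
T_I = vec(γ̂)ᵀΛ⁺vec(γ̂) is referred to χ² with df = rank Λ (JLK in the
regular case).  Λ is inverted through a symmetric eigendecomposition with a
relative eigenvalue cutoff of 1e-10; rank-deficient designs use the
Moore–Penrose inverse throughout, with df reduced to the rank.

A note on the residual covariance: dividing RᵀR by (n−q)·K instead of
(n−q) shrinks Σ̂ K-fold and would inflate T_I by the same factor,
destroying the χ²_{JLK} null for K > 1.  The package uses the standard
multivariate-OLS denominator (n − q), which is what makes the statistic's
null distribution and the reported type-1 errors attainable.

## Tunable parameters

| parameter | default | meaning |
|---|---|---|
| `var_explained` | 0.8 | smallest J, L, K whose eigenvalues reach this cumulative variance fraction |
| `max_components` | none | hard cap per basis; J·L·K is additionally capped at n/2 |
| `grid_m` | 256 | sub-intervals of the common [0,1] grid (128 used in the simulation studies; 2456 — the median gene length of the motivating data — is available) |
| `loess_span`, `loess_degree` | 0.3, 2 | LOESS neighbourhood fraction and local polynomial degree (tricube weights) |
| `hwe_alpha` | 1e-9 | exact Hardy–Weinberg filter threshold in QC |
| `normalize_curves` | true | divide curves by per-sample size factors when supplied |

The 80% variance rule is applied uniformly to both genotype bases and the
response basis; keeping J·L·K below n/2 keeps the interaction block's
degrees of freedom well under the sample size, which is what the χ²
approximation needs.

## Quadrature and numerical choices

Integrals are trapezoid sums — exact for the piecewise-linear
representation of functions on a grid, and the natural companion of a
piecewise-linear FPCA discretization.  FPCA is computed as the
eigendecomposition of the quadrature-weighted sample covariance matrix
(W^{1/2} C W^{1/2}); eigenfunction signs are fixed by making the entry of
largest absolute value positive (first such entry on ties), so results are
deterministic.  Scores of the fitted FPCA satisfy var(score_j) =
eigenvalue_j exactly (ddof 1).  Grids with fewer than 4 sub-intervals are
refused; LOESS requires at least degree + 2 distinct positions.  Constant
curves are allowed everywhere (they produce a zero-variance FPCA and, for
the response, a single constant component, under which the functional test
reduces to the scalar-response test — a tested equivalence).

## Comparators

* **SFGM** — same genotype design, scalar response (by default the
  size-factor-normalized total count, rank-based inverse-normal transformed
  with the Blom offset 3/8); df = JL.
* **RNAmin** — the scalar test run at every grid position, minimum p
  reported raw (deliberately uncorrected, hence anticonservative — a
  documented property, not a calibrated test).
* **min-P pairwise** — the functional-response model per cross-gene SNP
  pair with the two encoded SNPs and their product as scalar predictors
  (df = K per pair); raw minimum over pairs.  Encoded (centered) genotypes
  are used for consistency with the main test.
* **PCA regression** — plain (unweighted) PCA of the sample × position
  matrix, components to 80% variance, same predictors and Wald test.

## Synthetic data

**Genotypes** are independent biallelic SNPs under HWE with minor-allele
frequencies drawn from a rare spectrum U(0.001, 0.05) or a mixed spectrum
(half the SNPs common, U(0.05, 0.5)); columns that QC would discard
(monomorphic, singleton) are redrawn.  Population frequencies, positions
and causal flags define a "population"; every simulation replicate samples
a fresh cohort of individuals from it.  Defaults: 10 SNPs per gene (20 in
power runs), causal fraction 10% (type-1) or 20% (power).  No linkage
disequilibrium is simulated; `max_r2` on independent genes is accordingly
tiny (~1e-3 at n = 10,000).

**Template curves** stand in for a library of real RNA-seq genes: each gene
has a smooth baseline of 2–4 Gaussian bumps over its own region (uneven
lengths and position counts, so the LOESS regrid is exercised) and two
smooth between-sample variation modes — an amplitude mode (sd 0.3 of the
baseline) and a localized shape mode.  They emulate smooth, low-rank,
positively-valued coverage with correlated cross-sample variation; they do
not emulate discreteness of counts, sequencing noise at single-base
resolution, or library-size artifacts, so passing tests speak to the
statistical machinery on smooth function-valued traits, not to robustness
against count noise.

**Null trait models.**  The mean function and error process are estimated
from the templates: regrid every gene to the common grid, average over
genes per sample, take the pointwise mean as μ(τ) (the average-FPC-score
construction collapses to exactly this under a centered FPCA), and run FPCA
on the centered pooled matrix to obtain error eigenfunctions φ_t and the
score covariance Σ̂.  Simulated errors are ε_i(τ) = Σ_t ε_it φ_t(τ) with
ε_i ~ N(0, Σ̂) — a correlated Gaussian process with the template's
second-order structure.  Model 1 adds nothing else; models 2 and 3 add
marginal terms Σ_j x_ij·r_j·α(τ) (and the analogue for the second gene)
over the causal SNPs, with per-SNP multipliers r_j, s_k ~ U(0.5, 1.5) and
effect functions proportional to the leading error eigenfunctions (scale:
one first-error-score standard deviation by default).

**Power generator.**  For every causal cross-gene SNP pair h, an individual
receives λ_h·g(τ), where λ_h is 0 or the risk parameter r according to a
two-locus penetrance pattern over minor-allele counts:

* Dominant-OR-Dominant — r iff ≥1 minor allele at either locus;
* Dominant-AND-Dominant — r iff ≥1 at both;
* Recessive-OR-Recessive — r iff 2 minor alleles at either locus;
* Threshold — r iff ≥3 minor alleles across the pair.

The tables are config-overridable.  The genotype coefficient function g(τ)
is the leading template eigenfunction with its positional mean removed
(unit L2 norm), scaled by twice the first error-score standard deviation:
demeaning makes the signal purely positional (the overall expression level
barely moves, which is why the scalar-response test stays at α), and the
scale was chosen once so that the risk sweep r ∈ [0, 1] spans the regime
from null to strong effect with monotone-rising power; much larger scales
push the generator into a regime where the unmodeled nonlinear part of the
penetrance signal inflates Σ̂ faster than the captured interaction grows,
and power saturates or dips.  μ(τ) is included so that r = 0 reduces
bit-exactly to the Model-1 null generator on the same random stream.
Power runs average over 5 independently drawn genotype populations, as the
type-1 tables average over 10 gene pairs.

## Problem sizes used in the shipped studies

Type-1 error: n = 1000, grid m = 128, 10 template genes, 10 gene pairs,
2000 replicates.  Null-distribution check: one fixed design, 2000 Gaussian
replicates.  Power: n = 2000, m = 128, 500 replicates per risk value over
r ∈ {0, 0.2, 0.5, 0.8}.  Coefficient-covariance convergence: n = 5000, 500
replicates.  These are desk-scale renditions of the motivating study's
n ∈ [1000, 5000] × 5000-replicate design; the method is unchanged, only
the Monte-Carlo sizes differ.

## Known limitations

* No linkage disequilibrium in simulated genotypes and no resampling of
  real haplotype panels; LD-structured simulation is future work.
* The error model is exactly Gaussian in score space; no heavy-tail option.
* The homoscedasticity assumption var(vec(ε)) = Σ ⊗ I_n is taken at face
  value; no sandwich/robust covariance variant is provided.
* Power under penetrance models is population-dependent: causal SNPs that
  load weakly on the retained genotype components (small quadrature weight,
  very low MAF) contribute little to the interaction design, and the
  unmodeled nonlinear remainder of their signal mildly inflates the
  residual covariance — visible as conservatism at intermediate effect
  sizes for recessive-type models.
* RNAmin's minimum is reported raw and is anticonservative by construction.
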