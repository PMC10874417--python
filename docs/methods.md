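# Methods

## Statistical model

The scan tests each unordered SNP pair {j, k} by comparing two nested
ordinary-least-squares models of a quantitative trait `Y`:

- reduced: `Y ~ 1 + C + S_j + S_k`
- full: `Y ~ 1 + C + S_j + S_k + S_j·S_k`

where `S ∈ {0, 1, 2}` are minor-allele counts and `C` holds age (years),
a 0/1 male indicator, and two diagnosis dummies (MCI, AD) against the NC
reference — four covariate columns, so the full model has
`1 + 4 + 3 = 8` parameters and the partial F statistic for the single
interaction term has `(1, n − 8)` degrees of freedom. The p-value is the
upper tail of that F distribution; under Gaussian errors it is exact, which
is why the null p-values are uniform without asymptotic correction (the
type-I calibration in the acceptance script checks this empirically).
`F = (β_int/se_int)²` holds identically, and the statistic is symmetric in
the pair, invariant to sample reordering and to SNP storage order.

Assumptions: a linear, homoscedastic Gaussian trait model; biallelic
autosomal SNPs coded additively; covariates measured without error; one
pair fitted at a time (when several true interactions exist, the others act
as independent extra noise in each single-pair fit, which costs power but
does not bias the tested term, since simulated genotypes are independent
across loci).

## Numerical scheme of the blocked scan

Covariates are residualised out of the trait and all clean genotype columns
once via a QR decomposition of `[1, C]`. For a tile of pairs the product
columns are formed explicitly, residualised against the same basis, and all
per-pair statistics are assembled from cross-products with a closed-form
2×2 projection (removing the two additive columns). This is an algebraic
re-arrangement, not an approximation: tests assert agreement with the naive
per-pair fit to better than 1e-8 relative (measured ~1e-11).

Delicate pairs are routed to the exact per-pair path for authoritative
classification: near-collinear additive columns (relative determinant
≤ 1e-8), a product column nearly in the span of the reduced design, or a
near-zero full-model RSS. Rank-deficient designs yield an `invalid` result
with NaN statistics — reported, never dropped, so pair accounting is exact.
A perfect fit (RSS_full ≤ 1e-12·TSS) is flagged `degenerate` with F = +inf,
p = 0. Zero trait variance on a fitted subset is detected with a relative
tolerance (TSS ≤ 1e-16·n·mean(y²)) because a constant vector's computed TSS
is rounding noise, not exactly zero.

Missing genotypes: `complete_case` (default) drops samples missing either
SNP of a pair; pairs touching a column with missingness go through the
exact path so the per-pair subset is honoured exactly, while fully observed
columns use the tile engine. `mean_impute` fills each column's mean over
phenotype/covariate-complete rows, after which every pair is tile-eligible.
The choice is surfaced because standard practice varies; complete-case is
the default as the assumption-free option.

## Variance partition

`variance_partition` performs one unpivoted QR of the block-ordered design
`[1, C, S_j, S_k, S_j·S_k]` and reads each block's explained sum of squares
from the squared projections of `Y` on the corresponding Q columns. This
makes the increments sums of squares rather than differences of fitted R²
values: they are non-negative by construction, sum to the full R² exactly,
and the F recomputed from the interaction increment,
`(dr2_int / (1 − r2_full)) · df₂`, reproduces the scan F to ~1e-12 relative
instead of the ~1e-8 a difference-of-R² evaluation achieves near F ≈ 0.
All three nested models share one listwise-complete subset; mixing subsets
can make increments negative, which would break the partition's semantics.
A whole-sample covariate R² is reported separately because cohort papers
conventionally quote that single number (~13% here) rather than per-pair
values.

## Quality control

Filters run in the protocol's listed order, each computed on the survivors
of the earlier steps: SNP call rate ≥ 0.95 → sample call rate ≥ 0.95 →
MAF ≥ 0.05 → sex check → listed exclusions → HWE p ≥ 1e-6 → autosomes only
→ non-missing phenotype. The composite is idempotent.

- HWE is the 1-df chi-square goodness-of-fit test against binomial genotype
  proportions; at MAF ≥ 0.05 and n ≈ 858 the exact mid-p variant would make
  no difference at a 1e-6 cutoff, so the simpler test is used. Monomorphic
  columns return (χ² = 0, p = 1) by convention. The filter skips
  non-autosomal SNPs: hemizygous X calls violate the diploid expectation by
  construction, and those SNPs leave at the autosome step regardless.
- The sex check computes an inbreeding-style
  `F = (O_hom − E_hom)/(L − E_hom)` from X-chromosome genotypes with
  per-locus expected heterozygosity `2p(1−p)` estimated from the cohort;
  F < 0.2 reads female, F > 0.8 male. Samples whose inference contradicts
  (or cannot confirm) a reported sex are removed.
- Relatedness and ancestry removals are not computed here — they depend on
  procedures outside this pipeline's scope — and enter as a user-supplied
  sample-ID exclusion list applied as its own reported step.

## Synthetic cohorts

The generator emulates the structure the analysis assumes, at the study's
scale: n = 858 samples; independent biallelic SNPs in Hardy–Weinberg
proportions with allele frequencies uniform on (0.05, 0.5); age ~ U(55, 91)
years, sex ~ Bernoulli(0.5), diagnosis ~ categorical(0.331, 0.534, 0.134)
for NC/MCI/AD; Gaussian noise with σ = 1 by default. Covariate effect
sizes are solved in closed form so the covariates explain 13.3% of the
covariate-plus-noise variance (split 50/10/40 across age/sex/diagnosis,
with the AD effect 2.75× the MCI effect, mirroring the cohort's trait
means); across seeds at n = 858 the realised whole-sample covariate R²
averages ~0.137 with sd ~0.02.

Planted epistasis uses the generative counterpart of the fitted model.
For independent HWE genotypes with mean `m = 2p` and variance
`v = 2p(1−p)`, the residual of the product `S_j·S_k` on `{1, S_j, S_k}`
has variance `v_j·v_k`, so the hierarchical interaction increment of a
planted pair is `β_int²·v_j·v_k / Var(Y)` exactly. Because every planted
coefficient scales with `√Var(Y)`, the total genetic variance share `g` is
a pure function of the targets and allele frequencies, giving the closed
form `Var(Y) = (cov_var + σ²)/(1 − g)` and per-pair coefficients that hit
their population ΔR² targets exactly (the registry records them, and a
100 000-sample simulation reproduces the 0.05 target within ±0.005).

A raw multiplicative term also induces an additive component
(`Cov(S_j S_k, S_j) = m_k v_j`), so a pair planted at interaction share *t*
carries an additive share ≈ `t(m_k²/v_k + m_j²/v_j)`. At high minor-allele
frequencies this makes five simultaneous 5% pairs infeasible (`g ≥ 1`);
planted loci therefore default to a fixed allele frequency of 0.25
(`SimSpec.planted_maf`), where the joint budget is comfortably feasible.
Explicit per-SNP main effects default to a 0.3% variance share each —
marginal by design, so detection must come from the interaction term.

What the generator does *not* emulate, and hence what passing tests do not
establish about real cohorts: linkage disequilibrium (an optional
haplotype-copy mechanism plants single LD pairs for testing the
independence report, but there is no genome-wide LD map), realistic
allele-frequency spectra, population structure or relatedness, genotyping
batch effects, and the strict positivity of a biomarker ratio (the trait is
generated on an unconstrained real scale; the fitted model is
Gaussian-linear, so positivity is cosmetic). Recovery rates measured here
are therefore best-case for the stated effect sizes.

## Problem sizes in tests and the acceptance script

The statistical checks run at the sizes the properties are defined at:
100 random instances (n = 200) for oracle agreement, 2000 independent null
pairs (n = 500) for type-I calibration, 200 replicates of n = 858 with
1000 SNPs and 5 planted pairs for recovery and effect estimation, and a
40-SNP full scan (780 pairs) for tiling invariance and decomposition
consistency. Recovery is measured by testing the planted pairs against the
Bonferroni threshold over C(1000, 2) — the threshold carries the full
multiplicity burden, and a planted pair's rejection does not depend on the
other 499 495 tests being executed. Measured values at seed 1: recovery
0.955, mean estimated ΔR²_int 0.0507, type-I rate 0.0585 (99% binomial band
[0.0374, 0.0633]), KS uniformity p 0.91.

## Design choices and limitations

- **Significance threshold.** No single "correct" pairwise threshold
  exists; the default is Bonferroni α = 0.05 over the tested pair count,
  always surfaced as a parameter (`--alpha` / `--p-threshold`).
- **LD metric.** Composite genotype r² (squared Pearson correlation of
  allele counts over complete cases) rather than EM haplotype r²: the
  pipeline carries no phase information, and at a 0.8 screening threshold
  the distinction is immaterial. D′ and haplotype-block structure are out
  of scope.
- **Gene mapping.** A SNP maps to *every* gene whose interval extended by
  the window (default 100 kb, boundary inclusive, GRCh37 coordinates
  expected) contains it — not nearest-gene-only — and intergenic SNPs stay
  unmapped; both behaviours are needed for faithful gene-pair accounting.
  Gene symbols are upper-cased before any matching.
- **PLINK codec.** The SNP-major 2-bit PLINK-1 format is implemented
  directly (decode LUT 00→2, 01→missing, 10→1, 11→0 of the counted A1
  allele); no frequency-based re-polarisation at read time, so write→read
  round trips are bit-exact. Individual-major files (mode 0x00), VCF/BGEN,
  dosages and phased data are unsupported.
- **Parallelism.** The engine is single-process; the tiling contract
  (results independent of block partitioning) is what a multi-worker
  partition of the pair space would rely on, and is property-tested.
- **Scale.** The blocked engine is written for desk-scale experiments
  (thousands of SNPs, millions of pairs). A genome-wide 563 980-SNP scan —
  1.6·10¹¹ pairs — needs cluster or GPU parallelism and is out of scope.
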