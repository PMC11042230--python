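# Methods

## Storage model

A `.sgen` fileset stores diploid biallelic genotypes in additive coding
(0/1/2 alternate-allele copies, 3 = missing) one variant at a time, in one
of two record encodings:

- **Sparse (difflist)**: ordered (sample index, value) pairs for every
  sample with a nonzero code — including missing, which is a deviation from
  the all-reference default and must never be conflated with 0. Each entry
  is 5 bytes: a 4-byte little-endian unsigned index (capping cohorts at
  2³² − 1 samples, ample for current biobanks) and a 1-byte code.
- **Dense**: 2 bits per sample, sample 0 in the low-order bit pair,
  ⌈n/4⌉ bytes.

The encoder picks sparse iff 5k < ⌈n/4⌉, so total body size never exceeds
the all-dense equivalent; ties go dense (equal size, cheaper decode). Each
variant adds exactly 4 directory bytes — a record-type byte plus a 3-byte
little-endian record length. The 3-byte length caps a record at 16 MiB,
which a dense record reaches only beyond 67M samples; record-type codes ≥ 2
are reserved for encodings this dialect does not implement (LD-compressed,
dosage, multiallelic/phased records). The global header is 2 magic bytes
plus n_variants and n_samples as 8-byte little-endian integers. Variant and
sample metadata live in sidecar text files (`.svar`/`.ssam`, BIM/FAM
dialects), mirroring the PLINK ecosystem's binary/text split.

The PLINK-1 BED importer translates that format's 2-bit code table (00 =
hom A1, 01 = missing, 10 = het, 11 = hom A2) into additive A1 counts; the
internal missing code is 3 in both encodings so downstream code handles one
convention.

## Regression engine

Per variant the model is y = Xβ + ε, X = [X_c x_g] with X_c = intercept +
covariates shared by all variants. Writing X′X = [[A, B], [B′, D]] with
A = X_c′X_c, B = X_c′x_g, D = x_g′x_g, the block-inverse identity

    (X'X)^-1 = [[A^-1 + A^-1 B F^-1 B' A^-1, -A^-1 B F^-1],
                [-F^-1 B' A^-1,              F^-1        ]],   F = D - B' A^-1 B

lets the engine precompute A, A⁻¹, X_c′y and y′y once and finish each
variant in O(p(k+p)) arithmetic: B and x_g′y touch only the k difflist
entries, D costs O(k), the block algebra O(p²). RSS = y′y − y′Xβ̂,
se(β̂_g) = √(RSS/(n−p) · F⁻¹), and the two-sided p-value comes from the
Student t distribution with n − p degrees of freedom. A class-level
entry-touch counter on the record type verifies, in tests, that the sparse
path reads exactly k genotype entries and never densifies.

Numerical choices:

- Singularity: F ≤ 10⁻¹² · max(D, 1) → status SINGULAR (monomorphic or
  collinear genotype). An empty difflist gives F = 0 and is SINGULAR.
- Exact fits (RSS = 0, e.g. a noise-free phenotype equal to the genotype)
  report the coefficient with se 0, |t| = ∞, p = 0 rather than hiding the
  estimate behind a singular status.
- The covariate design is validated once by pivoted QR; rank deficiency is
  reported with the offending column indices.
- Negative RSS from floating-point cancellation is clamped to 0.

Missing genotypes are not supported on the block-inverse path (they would
invalidate the cached A⁻¹); the scan router sends any variant whose record
carries a missing entry — and any dense-stored variant — to a per-variant
dense solve that drops the missing rows for that variant only. The
t-distribution degrees of freedom use the per-variant n_used − p; whether
the reference implementation adjusts df for per-variant missingness is
ambiguous, and this is the conservative reading.

Multi-phenotype scans group phenotype columns by missingness mask; columns
sharing a mask share one covariate cache and one pass over the variants,
with the variant-dependent quantities (B, D, F) computed once per variant
and applied to all columns. Results are identical to independent
single-phenotype scans, which the tests assert.

## Residualized fast modes

**qt-residualize.** One upfront fit gives r = y − X_c(X_c′X_c)⁻¹X_c′y; the
per-variant model is then r ~ intercept + genotype (p = 2). n, Σr and Σr²
are precomputed over all samples; each missing genotype subtracts its
sample's r and r² (compensated with `math.fsum`, since the subtractive
update can cancel catastrophically when k is large), and the genotype sums
accumulate over the listed nonzero entries, so a difflist costs O(k)
regardless of missingness. This equals a dense refit on the non-missing
subset exactly (property-tested), but is *approximate* relative to the full
model: the residuals spent p − 1 degrees of freedom that the p = 2 fit does
not know about, deflating t by roughly a factor √((n−p)/(n−2)) — about
0.2% at n = 2000 with 10 covariates, and vanishing at biobank n. The
residualized-vs-full −log₁₀ p agreement on a synthetic rare-variant cohort
(R² > 0.999 at n = 2000) quantifies this.

**cc-residualize.** The binary analogue is not uniquely determined by the
description it implements; this package's construction: fit the
covariate-only logistic model once, freeze η = X_c γ̂ as a per-sample
offset, and fit logit(μ) = η + b₀ + b_g·g per variant (the intercept is
re-estimated per variant; freezing it with the covariates is the noted
alternative). Rows with missing genotype are dropped. The same fallback
triggers as the full baseline (below) apply at p = 2, so quasi-separated
rare variants get Firth-penalized refits on both the fast and slow paths —
without this the two paths diverge badly exactly where rare-variant
logistic regression is hardest.

**firth-fallback.** The slow baseline: a full-covariate per-variant Newton
logistic fit, refitted with the Firth penalty l*(β) = l(β) + ½log|I(β)|
when the plain fit (a) fails to converge in 25 iterations, (b) produces
any |β_j| > 50, or (c) pins a fitted probability within 10⁻⁸ of 0 or 1.
The pin threshold matters: under quasi-separation the plain score can
vanish numerically at a large-but-finite β̂, so convergence alone does not
certify a usable fit.

Newton iterations converge on max |score| < 10⁻⁸ or max coefficient change
< 10⁻¹⁰, with up to 10 step-halvings whenever a step would decrease the
(penalized) log-likelihood, and an objective-plateau criterion (relative
improvement < 10⁻¹¹) because the penalized problem is solved with the
unpenalized information as Hessian and can stall with a tiny residual
score. Wald tests (standard normal reference) are used for all binary
traits; likelihood-ratio tests are not implemented, a known divergence risk
against implementations that switch tests per variant.

## SVD phenotype reduction

`pheno_svd` standardizes (center, unit variance, ddof = 1) the complete
rows of the n × k phenotype matrix — rows with any missing phenotype are
dropped, not imputed — and takes a thin SVD. It keeps the smallest d with
cumulative squared-singular-value fraction ≥ the requested threshold.
Standardizing first makes variance-explained scale-free; component signs
are fixed by making each component's largest-magnitude loading positive so
output is deterministic across LAPACK drivers. Scores (UΣ, restricted to d
columns) are scanned like ordinary phenotypes and the loadings are written
alongside for interpretation; covariate adjustment is applied to the
scores during the scan, i.e. the SVD sees raw standardized phenotypes (the
alternative ordering — residualize, then decompose — is equally defensible
and not implemented). Since per-variant p-values are invariant under
affine phenotype transforms, a rank-1 panel reduces to d = 1 with component
p-values equal to the underlying phenotype's scan, which is asserted in
tests.

## Synthetic cohorts

The generator emulates the regime that motivates the sparse machinery:
per-variant MAFs on [5 × 10⁻⁴, 0.05] drawn via a Beta(1, 3) skew on the
log scale — steeper than log-uniform, as sequencing site-frequency spectra
are, and enough to keep > 95% of variants on the sparse encoding (a
log-uniform spectrum would leave ~15% of variants above the sparse/dense
break-even near MAF 0.025) — plus a 2% common-variant admixture uniform on
[0.05, 0.5]. Genotypes are binomial(2, MAF) i.i.d. across samples
(Hardy-Weinberg, no linkage disequilibrium — LD is irrelevant to
per-variant regression correctness and omitting it keeps null tests
independent); missingness is MCAR at rate 0.01 by default. Quantitative
phenotypes are X_c γ + Σ g β + ε with standard-normal covariates, γ ~
N(0, 0.5²), ε ~ N(0, 1); binary phenotypes come from the logistic model
with intercept solved by bisection so the *expected* case fraction hits the
request. Phenotypes are generated from the pre-missingness genotypes.

What passing tests on these cohorts do **not** show: robustness to LD and
population structure, to informative (non-MCAR) missingness, to relatedness,
or to case-control imbalance beyond the configured fractions. They do show
algorithmic correctness (fast paths ≡ oracles to 10⁻⁸), null calibration,
and planted-effect recovery under the stated sampling model.

## Validation design and problem sizes

- Fast-path equivalence is property-tested over randomized n ∈ [50, 2000],
  p − 1 ∈ [0, 20], k ∈ [1, n/2] (> 1000 variants), against dense solves and
  statsmodels OLS; the Firth solver is checked against direct numerical
  maximization of the penalized likelihood.
- Residualization fidelity uses one cohort of n = 2000, 10 covariates,
  5000 rare variants with 50 planted effects; quantitative agreement is
  asserted at R² > 0.999 and the cc-residualize/firth-fallback comparison
  at R² > 0.85 with slope in (0.85, 1.05).
- Type-I error is pooled over independent null cohorts (≥ 10,000 tests per
  path) and must lie in the 99% binomial band around 0.05. Quantitative
  paths are calibrated on the default rare-skewed spectrum — the t test is
  exact under Gaussian noise at any carrier count. Binary Wald paths are
  calibrated on a common-variant spectrum (MAF uniform on [0.05, 0.5]):
  Wald p-values are genuinely miscalibrated at minor-allele counts of a few,
  a known limitation of every Wald-based rare-variant logistic analysis,
  and no calibration claim is made there.
- Effect recovery: 100 replicates of n = 5000 with β = 0.5 at MAF 0.02
  must cover the truth within ±3 se at least 99 times.

## Known limitations

- No dosages, multiallelic sites, phase, LD-compression, or BGEN/VCF
  readers; the binary format is this package's own dialect, not
  byte-compatible with other tools' formats.
- Wald-only inference for binary traits; no saddlepoint or genomic-control
  correction; no mixed models or relatedness adjustment.
- The qt-residualize df approximation above; exact only as n → ∞.
- SVD component effect sizes are not back-transformed to per-phenotype
  effects.
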