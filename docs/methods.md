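# Methods

## Model

All tests operate in the polygenic linear mixed model for a quantitative
trait measured on `n` possibly related individuals:

    Y = X α + (genetic term) + γ + ε,
    γ ~ N(0, σ²G Φ),   ε ~ N(0, σ²E I_n),

where `X` (n×p) holds the covariates (intercept, sex, age, smoking by
default), `Φ` is twice the pedigree kinship matrix (diagonal `1 + F_i`),
and (σ²G, σ²E) are the polygenic and residual variance components.  The
marginal covariance is Σ = σ²G Φ + σ²E I.

Two set-level tests are provided for a set of `q` rare-variant dosage
columns `G` with per-variant weights `w_j` (Wu weights, the Beta(1, 25)
density at the sample MAF, by default):

* **famBT** (weighted burden): the genetic term is `g β` with
  `g = Σ_j w_j G_j`; H₀: β = 0 against a two-sided alternative.  Collapsing
  to a single score makes the test powerful when effects share a direction
  and weak when they do not.
* **famSKAT** (kernel / variance-component): the genetic term is `G W β`
  with `β ~ N(0, τ I_q)`; H₀: τ = 0 against τ > 0.  The score statistic is

      Q = r' Σ̂⁻¹ G W W' G' Σ̂⁻¹ r,    r = Y − X α̂,

  whose null law is `Σ_k λ_k χ²₁` with `λ_k` the nonzero eigenvalues of
  `W' G' P G W`, `P = Σ̂⁻¹ − Σ̂⁻¹X(X'Σ̂⁻¹X)⁻¹X'Σ̂⁻¹`.  Random effect
  directions do not cancel, so the test keeps power under mixed-sign
  architectures.

Both tests are *score* tests under one shared covariates-only null fit per
trait.  Nothing set-specific is refitted, so a genome-wide scan costs one
n×n eigendecomposition plus O(n·q) work per set.  A per-set REML Wald
variant of the burden test exists behind `method="wald"` purely as a
cross-check; in well-behaved cases the two agree to about two significant
figures.

## Null model fitting

REML, not ML, to keep variance components unbiased with covariates in the
model.  After one eigendecomposition `Φ = U D U'`, the restricted
likelihood is profiled over the heritability ratio h² = σ²G/(σ²G+σ²E) on
[0, 1] (bounded scalar minimization, tolerance 1e−8 on h²; the two interval
edges are checked explicitly because the bounded search can stall short of
a boundary optimum).  Boundary estimates are accepted and flagged.  When Φ
carries no kinship contrast (Φ = cI), σ²G and σ²E are unidentifiable; the
fit then reports total variance with h² pinned to 0 and a `confounded`
flag.  Non-PSD Φ and rank-deficient X are hard errors.

## Quadratic-form p-values

Tail probabilities of `Σ λ_k χ²₁` use characteristic-function inversion
(Imhof's integral).  The integrand `sin θ(u) / (u ρ(u))` oscillates with
half-period 2π/Q under a monotone envelope, so the integral is computed as
a series of half-period segments — each by composite 16-point
Gauss–Legendre with sub-panels that keep the arctan part of the phase
resolved — summed with repeated averaging (Euler transformation) of the
partial sums.  The scheme is fully vectorized and was checked against
exact scaled-χ² cases, adaptive QUADPACK integration, and 10⁶-draw
Monte-Carlo samples: agreement is at machine/Monte-Carlo precision across
eigenvalue spreads of 10⁴ and p-values down to 10⁻¹².  A single eigenvalue
is special-cased to the exact χ²₁ tail.  When the inversion fails, returns
a value outside (0, 1], or sits below 10⁻¹³ (the practical floor of its
absolute accuracy), the Liu–Tang–Zhang moment-matched noncentral-χ²
approximation is used instead; the method actually applied is recorded in
the output (`pvalue_method`).  Reported p-values are floored at the
smallest positive double; exact zero is never emitted.

Kernel eigenvalues below 1e−10 × the largest are discarded as numerical
rank noise (duplicated or constant columns otherwise contribute spurious
near-zero terms).

## Variant classification and sets

Sample MAF is `min(p̄, 1−p̄)` with `p̄ = mean(dosage)/2`.  Variants with
MAF > 5% are common (tested single-marker), MAF in (0, 5%] rare (the 5%
boundary counts as rare), MAF = 0 monomorphic and excluded everywhere —
a 0-MAF variant carries no information and its Beta density weight would
be ill-posed.  Gene-based (GB) sets take rare nonsynonymous/splice-site
variants inside each gene span; sliding-window (SW) sets take all rare
variants in 4000-bp windows stepped by 2000 bp, anchored at coordinate 1
of the tiled extent (the anchor is configurable; a fixed phase keeps the
tiling deterministic and testable).  Coordinates are 1-based inclusive,
matching VCF POS.  Dosages are used as coded in the input — MAF folding
affects classification and weights only — with an optional flip-to-minor
switch (off by default) for files coded on the major allele.

## Phenotype preparation

Baseline = the first exam at which age, SBP, DBP, medication status and
smoking are all non-missing; individuals without such an exam are dropped,
and individuals medicated at baseline are excluded (no +10/+5 mmHg
medication adjustment — exclusion sidesteps the imputation entirely).  SBP
is rank-based inverse-normal transformed; DBP is analyzed raw.  The
transform uses Blom offsets, Φ⁻¹((r − 3/8)/(n + 1/4)), with average ranks
for ties; the offset constant is configurable since several conventions
(3/8, 1/3, 1/2) circulate and the choice is immaterial beyond the third
decimal of the scores.  Row order is preserved end to end: kinship and
dosage matrices are aligned to the analysis table by an explicit id
alignment step, and order divergence is an error, never a silent reorder.

## Synthetic data

The generator stands in for restricted family blood-pressure cohorts and
reproduces exactly the structure the methods rely on:

* **Pedigrees** — independent three-generation families from a template
  (default: two grandparents, one of their children, a married-in spouse,
  one grandchild; 150 families, n = 750).
* **Genotypes** — haplotype-level gene-dropping from founder haplotypes
  drawn Bernoulli(founder MAF); each offspring inherits one whole
  haplotype per parent (no recombination within the simulated region), so
  Mendelian consistency is exact and designated variant pairs that share a
  founder haplotype column are in perfect LD (r = 1).
* **Traits** — Y = Xα + Gβ + γ + ε per the model above, with independent
  polygenic/residual draws per trait.  Defaults: σ²G = 0.3, σ²E = 0.7
  (h² = 0.3) on the latent scale; age uniform on 16–92 years with effect
  0.01/year, female probability 0.57 with effect −0.3, smoking probability
  0.222 with effect 0 (smoking is carried as a covariate but unassociated
  with the traits).  Three traits per replicate: a pure-null polygenic
  trait (`q1`), a DBP-like trait (mmHg location/scale 70.5/11, analyzed
  raw) and an SBP-like trait (118.7/15, analyzed rank-normalized).

Two stock panels:

* **null panel** — 110 genes of 3 kb tiling a 440-kb region every 4 kb,
  six rare nonsynonymous variants per gene plus 110 intergenic rare
  variants, founder MAFs log-uniform on (0.005, 0.04); no trait effects.
  This feeds the type-I-error study: ~110 GB sets and ~219 SW windows per
  replicate.
* **MAP4-like panel** — one 120-kb gene with six rare coding variants
  (founder MAF 0.02–0.035, spaced so no 4-kb window holds two): five carry
  the same negative effect on both traits and the sixth is a zero-effect
  perfect-LD proxy of the first; plus three 4-variant regulatory clusters
  with balanced mixed-direction effects (±regulatory β at matched MAFs),
  so the expected weighted burden cancels within windows while the kernel
  variance signal remains.

The effect sizes of the MAP4-like scenario (coding β = −0.85, regulatory
β = ±1.4 on the unit-variance latent scale) are a *deliberate calibration,
not an empirical fact*: the generating effect sizes of the workshop data
this scenario emulates were never published, so the defaults were chosen
once such that gene-based power ≈ 1 at α = 2.5×10⁻⁶ at n ≈ 750 — the
regime the original analysis reports — and are not meant as estimates of
real blood-pressure architecture.  What the simulation *does* establish is
distribution-free: null calibration of both tests on related samples, and
the qualitative power ordering (burden ≥ kernel under same-direction
effects; kernel ≫ burden under mixed directions).

What the generator does **not** emulate: recombination and realistic LD
decay (whole-haplotype transmission makes within-region LD stronger than
real data), missing data and longitudinal exams (single complete baseline
exam, nobody medicated — the real-data exclusion path is tested on
handcrafted fixtures), medication use, genotyping/imputation error, and
population structure beyond the pedigree.  Passing tests therefore
demonstrate statistical correctness of the methods under their model
assumptions, not robustness to those real-data complications.

## Replicate studies

A study fixes one pedigree (so Φ and its eigendecomposition are computed
once) and re-drops genotypes and re-simulates traits each replicate; the
workshop design this emulates likewise fixed the sample across its 200
phenotype replicates (it also fixed genotypes; re-dropping them here makes
pooled null tests less dependent and exercises the transmission code).

* **Type-I error** — 200 replicates of the null panel; all set-level
  p-values of the null trait are pooled across sets and replicates
  (~22,000 GB and ~44,000 SW tests) and rejection proportions are reported
  at α = 0.05 and 0.001 with exact binomial CIs.  Pooling granularity is a
  documented choice; it maximizes precision at the cost of within-replicate
  dependence.
* **Power** — 100 replicates of the MAP4-like panel; per replicate the GB
  p-value is compared with 2.5×10⁻⁶ and the minimum SW p over the ~60
  windows overlapping the gene, multiplied by 60, with 3.3×10⁻⁸.  The ×60
  min-p adjustment is conservative (the windows are correlated) and is kept
  as the emulated study's own choice; the multiplier is a parameter.

Default problem sizes (n = 750, 200/100 replicates) run in a few minutes
on one CPU; the calibration test inside the test suite uses
n = 400 (80 families) with the same 200 replicates, which leaves the
pooled binomial 99% interval at ±0.004 around 0.05.

## Numerical choices and edge cases

* Constant burden scores and rank-0 kernels raise a typed
  `UndefinedTestError`; drivers skip such sets with the reason logged.
* Eigenvalues of Φ are clipped at 0 (they can be −1e−16 numerically); Φ
  with eigenvalues below −1e−6·max is rejected as non-PSD.
* Sampling γ uses per-family Cholesky factors of the Φ blocks with 1e−10
  jitter (pedigree blocks can be exactly singular).
* Duplicate (individual, exam) phenotype rows, duplicate gene names,
  half-specified parents and pedigree cycles are malformed-input errors;
  individuals referenced only as parents are materialized as founders with
  a warning.
* Wald vs score for the burden test, and the window-tiling anchor, are the
  two places the emulated analysis left genuinely open; both are exposed
  as options with the defaults documented above.

## Known limitations

No SKAT-O style ρ-combination of the two tests; no binary-trait kernels or
small-sample moment adjustments; no empirical (genotype-based) kinship —
the relationship matrix is pedigree-derived only; no X-chromosome kinship;
annotation flags are consumed, never predicted.
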