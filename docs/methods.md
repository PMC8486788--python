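# Methods

This note documents the models, parameter choices and numerical
conventions behind `locopgs`, and what the synthetic experiments do and
do not establish about real data.

## The two-stage model

Both scan stages fit, per variant *j*, the fixed-effects linear model

    y_i = α + Σ_k γ_k c_ik [+ δ PGS_c(i)] + β x_ij + ε_i,

where `x_ij` is the mean-imputed hard-call dosage (copies of the counted
allele a1) and the bracketed term appears only in stage 2, with `c` the
chromosome of variant *j*. The reported effect `BETA` is allelic (per
copy of a1), `SE` its standard error with residual degrees of freedom
`n − rank(design) − 1`, and `P` the two-sided t-tail probability. We use
the t reference rather than a normal approximation so the scan is exact
at the small n used in unit tests; how the score covariate's degree of
freedom is charged is an implementation decision, and we charge exactly
one (the score column enters the design like any other covariate).
Binary traits are fitted with the same linear model on the 0/1 labels —
adequate for rank/threshold decisions at the simulated prevalences, and
matching common practice for large-cohort linear association on
case-control labels; no logistic option is provided.

Computationally the trait and the dosage block are residualized once per
covariate design against an orthonormal basis built by sequential
Gram-Schmidt; per-variant statistics then follow from vectorized
cross-products. By the Frisch–Waugh–Lovell theorem this equals the joint
per-variant solve; the test suite checks agreement with a naive
`lstsq` full-design oracle to 1e-10 relative error. Covariate columns
whose residual variance after projection falls below 1e-12 are dropped
with a warning (the scan API) or raise naming the columns
(`residualize`). Categorical covariates are one-hot expanded. Variants
that are monomorphic after imputation yield NaN `BETA/SE/P` records and
are never silently dropped.

The model assumes unrelated samples: it is the fixed-effects reduction
of the sparse-mixed-model scans used at biobank scale, and no
genetic-relationship-matrix machinery is included. Relatedness handling
is a documented limitation, not a goal.

## LOCO polygenic scores

Weights come from greedy P-value clumping: candidates are the variants
with P ≤ `p_threshold` (default 5e-5, a deliberately conservative choice
— scores dominated by false positives destabilize the second-stage
false-positive rate, hence thresholds above 0.01 require an explicit
override); the smallest-P unclaimed candidate becomes an index and
claims all unclaimed same-chromosome candidates within
±`clump_window_bp` (default 250 kb, a standard P&T default; exposed in
config) whose genotype r² with it exceeds `clump_r2` (default 0.1). r²
is computed on mean-imputed dosages of the study genotypes themselves
(single-cohort setting; no external LD reference). Ties in P break by
(chromosome, position) ascending, making the procedure deterministic.

Scores are weighted allele-dosage sums with allele matching: a weight
whose effect allele equals the matrix's a2 contributes `2 − dosage`;
unmatched alleles are excluded with a logged count. The LOCO column for
chromosome c is, by default, `total − contribution_c` after one global
clump — identical to re-clumping with chromosome c excluded whenever LD
does not cross chromosomes (true of the simulator by construction) and
C times cheaper; a strict `per_exclusion` mode exists and the tests
verify the two agree on simulated data. Scores are not standardized
before use as covariates (the linear model is invariant to affine
rescaling of a covariate).

Why this is safe: the score for chromosome c contains no chromosome-c
variants, so its sample correlation with any tested genotype is O(1/√n);
the measured mean absolute correlation on simulated data is ≈0.02 at
n = 2,000, well below 3/√n. That near-orthogonality is what keeps β̂
unbiased and the type-I error nominal while the score soaks up
background genetic variance from the residual — the entire source of the
power gain.

Alternative weight procedures (shrinkage predictors, external
meta-analysis weights) plug in through `register_weight_method`; the
built-in `pt` method is the only one shipped.

## Genotype simulator

Haplotypes come from a latent Gaussian copula: within an LD block the
latent N(0,1) variables of adjacent variants follow an AR(1) process
with correlation `ld_rho` (independently on the two gametes, chains
broken at block and chromosome boundaries), each thresholded at the
allele-frequency quantile. This yields exact marginal frequencies, a
monotone and tunable genotype r², and LD strictly confined within
chromosomes. MAF is drawn uniform on [lo, hi] (default [0.05, 0.5]) or
Beta-shaped; `fst > 0` splits the cohort into two equal subpopulations
with Balding–Nichols Beta-distributed subpopulation frequencies.
Missing calls are injected completely at random at a configurable rate
(default 0); all downstream dosage arithmetic mean-imputes per variant.

Positions are placed every 10 kb from 1 on each chromosome, so bp
windows translate directly into variant counts (1 Mb = 100 variants)
and window semantics are testable without a genetic map. Coordinates
are 1-based; every window in the package is inclusive at both ends.
Each operation takes a single integer seed and draws from one generator,
making every fixture bit-reproducible.

QC defaults mirror standard pre-GWAS filtering: observed MAF ≥ 0.05%
(an unusually permissive cutoff; it is a parameter, and desk-scale
simulations typically use 0.01), missingness ≤ 2%, and a 1-df chi-square
Hardy–Weinberg test at α = 1e-4 (no exact test or mid-p — the
chi-square is closed-form testable and close to standard tool behaviour
at simulated sample sizes). PCA operates on LD-pruned (greedy sliding
window; variant-count windows by default, bp windows optional),
mean-imputed, standardized dosages via thin SVD, so score columns are
orthogonal by construction.

What the simulator does **not** emulate: realistic recombination maps
and LD decay, MAF-dependent effect coupling, genotyping batch
artifacts, relatedness, or cross-chromosome admixture LD. Passing tests
therefore demonstrate the method's internal correctness and its
behaviour under clean polygenic architectures, not performance on any
particular cohort.

## Phenotype simulator

Causal variants are drawn uniformly without replacement from variants
with MAF ≥ 0.01 (configurable; very rare causal variants make
single-variant power degenerate at desk-scale n), optionally restricted
to a chromosome mask. Effects are i.i.d. standard normal on the
standardized-genotype scale — each causal variant contributes h²/m_c of
the phenotypic variance in expectation — with an `allelic` switch for
frequency-independent allelic effects. Genetic values use standardized
dosages `(x − 2p)/√(2p(1−p))`; environmental noise is scaled against
the **realized** sample variance of g, `var(e) = var(g)(1−h²)/h²`, so
the realized heritability tracks the target tightly (within ±0.02 in
the acceptance check at n = 20,000). At h² = 0 the trait is pure N(0,1)
noise; at h² = 1 it equals g exactly.

Binary traits rank-threshold the same liability: the ⌈k·n⌉ largest
liabilities are cases, giving exact prevalence. Default covariates are
synthetic sex (Bernoulli 0.5) and age (uniform integer 40–70) with zero
true effect, so covariate adjustment is exercised without confounding;
nonzero covariate effects can be requested.

The even-chromosome null design restricts causal variants to even
chromosomes; because LD never crosses chromosomes, every odd-chromosome
variant is exactly null, giving a clean substrate for false-positive
calibration of the second stage.

## Evaluation metrics

* **Power** — fraction of causal variants whose own P passes the
  threshold (default 5e-8). This is the strictest reading of
  "causal variants recovered"; a window-based recovery mode (any
  significant variant within a distance counts) is available.
* **ROC/AUC** — positives are causal variants; negatives exclude
  non-causal variants within an exclusion radius of any causal variant
  on the same chromosome (default 1 Mb; same-chromosome only, since bp
  distances across chromosomes are not meaningful). Ties use the
  average-rank convention, so AUC equals the trapezoidal area of the
  tie-grouped curve. ROC points are reported on a specificity grid of
  width 1e-4. Desk-scale experiment drivers default the exclusion to
  100 kb because simulated chromosomes span only ~3 Mb.
* **MEDSE** — median over causal variants of the squared error of the
  standardized effect estimate (allelic β̂ rescaled by √(2p̂(1−p̂)),
  sign-aligned to the truth's effect allele). Computed on the
  standardized scale because the truth is generated there.
* **FPR** — fraction of a designated null variant set below α; reported
  at configurable α (defaults 5e-5 and 5e-8; the null-calibration
  experiments also use 0.05).
* **Independent loci** — strict clumping at P ≤ 5e-9, 5 Mb windows,
  r² = 0.01.
* Records with NaN statistics are excluded from ROC/FPR denominators
  with logged counts.

## Experiment design and problem sizes

Replicate experiments fix the genotype substrate and redraw phenotypes
only (seed_i = base_seed + i), mirroring how a fixed cohort is reused
across simulation replicates; paired per-replicate differences and a
paired t statistic summarize stage-2 vs stage-1 contrasts. The shipped
experiments use 4,000 samples × 3,000 variants (power, 25 replicates),
2,000 × 2,000 (calibration, 200 replicates) and 20,000 × 400
(heritability control) — sizes chosen so the full suite runs in minutes
on a single CPU while leaving the method's qualitative behaviour
(power gain present, growing with h², no null inflation, MEDSE
reduction) clearly resolved above Monte-Carlo noise.

## Known limitations

* Fixed-effects scan only: no relatedness correction, no
  variance-component estimation.
* Linear (not logistic) association for binary traits.
* Hard-call genotypes only; no imputed dosages, phased output, or
  X/Y/MT chromosomes; VCF is out of scope (PLINK 1 filesets are the
  interchange format).
* The P&T threshold is global; per-chromosome threshold optimization is
  deliberately not attempted.
* The copula LD model is stationary within blocks; it is a test
  substrate, not a population-genetic simulator.
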