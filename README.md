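# locopgs

Two-stage genome-wide association scans with **leave-one-chromosome-out
polygenic score (LOCO PGS) covariates**.

## The problem

In a GWAS of a polygenic trait, the variant being tested explains a tiny
slice of the phenotypic variance while thousands of causal variants
elsewhere in the genome contribute the rest. A plain fixed-effects scan
leaves that background genetic variance in the error term, inflating the
standard error of every per-variant effect estimate and costing power.
Mixed models absorb the background through a genetic relationship matrix,
but at substantial computational cost.

`locopgs` implements a simple, modular alternative:

1. **Stage 1** — an ordinary covariate-adjusted linear-model scan:
   `y = α + Σ γ_k c_k + β x_j + ε` per variant *j*.
2. **LOCO PGS** — from the stage-1 summary statistics, build one
   pruning-and-thresholding polygenic score per chromosome *c*, using
   only variants **not** on *c* (P ≤ 5×10⁻⁵ after LD clumping at
   r² = 0.1 in ±250 kb windows):
   `PGS_c(i) = Σ_{j: chr(j) ≠ c} β̂_j d_ij`.
3. **Stage 2** — rescan chromosome-wise with the matching score as an
   extra fixed effect: `y = α + Σ γ_k c_k + δ·PGS_c + β x_j + ε`.

Because the score is built from other chromosomes only, it is
approximately uncorrelated with the tested genotype (no proximal
contamination), so the scan stays calibrated while the residual variance
shrinks — which is exactly where the power gain comes from.

The package also provides everything needed to demonstrate this on
synthetic data: a genotype simulator (tunable MAF spectrum, block LD via
a latent Gaussian copula, optional two-population Balding–Nichols
structure), a phenotype simulator with controlled narrow-sense
heritability (quantitative and liability-threshold case-control traits),
PLINK 1 bed/bim/fam I/O, variant QC, PCA, and evaluation metrics (power,
ROC/AUC with causal-region exclusion, MEDSE of effect estimates,
false-positive rate, independent-locus counts).

Audience: statistical geneticists and methods developers who want a
transparent, fully scripted desk-scale testbed for background-genetic-
effect correction in GWAS.

## Worked example

```python
from locopgs import (GenotypeSimSpec, PhenoSimSpec, simulate_genotypes,
                     simulate_quantitative, run_two_stage)

G = simulate_genotypes(GenotypeSimSpec(
    n_samples=4000, variants_per_chromosome=300, n_chromosomes=10,
    ld_block_size=10, ld_rho=0.5, seed=1001))
pheno, truth = simulate_quantitative(G, PhenoSimSpec(n_causal=60, h2=0.5, seed=2001))
res = run_two_stage(G, pheno, truth=truth, exclusion_bp=100_000)
print(f"power   {res.metrics_stage1.power:.3f} -> {res.metrics_stage2.power:.3f}")
print(f"medse   {res.metrics_stage1.medse:.4f} -> {res.metrics_stage2.medse:.4f}")
print(f"auc     {res.metrics_stage1.auc:.3f} -> {res.metrics_stage2.auc:.3f}")
```

prints

```
power   0.350 -> 0.550
medse   0.0165 -> 0.0088
auc     0.863 -> 0.931
```

i.e. on this replicate the LOCO PGS covariate recovers 33 of the 60
causal variants at 5×10⁻⁸ instead of 21, roughly halves the median
squared error of the standardized effect estimates at the causal
variants, and improves the ranking of causal over null variants
(AUC 0.863 → 0.931). The same workflow is available from the shell via
the `locopgs` command (`simulate-genotypes`, `simulate-phenotype`,
`scan`, `loco-pgs`, `scan-loco`, `run`, `replicates`, `evaluate`,
`export-covariates`).

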