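"""Shared fixtures: small synthetic substrates reused across test modules."""

import numpy as np
import pandas as pd
import pytest

from locopgs import (
    GenotypeMatrix,
    GenotypeSimSpec,
    PhenoSimSpec,
    simulate_genotypes,
    simulate_quantitative,
)


def make_matrix(dosages, chrom=None, pos=None, ids=None, a1="A", a2="G"):
    """Build a GenotypeMatrix from a raw dosage array with default metadata."""
    dosages = np.asarray(dosages, dtype=np.int8)
    n, m = dosages.shape
    chrom = np.ones(m, dtype=int) if chrom is None else np.asarray(chrom)
    if pos is None:
        pos = np.empty(m, dtype=int)
        for c in np.unique(chrom):
            idx = np.flatnonzero(chrom == c)
            pos[idx] = 1 + np.arange(len(idx)) * 10_000
    ids = [f"v{j}" for j in range(m)] if ids is None else list(ids)
    variants = pd.DataFrame(
        {"id": ids, "chrom": chrom, "pos": pos, "a1": a1, "a2": a2}
    )
    return GenotypeMatrix(dosages=dosages, variants=variants)


@pytest.fixture(scope="session")
def geno_small():
    """500 samples x 4 chromosomes x 100 variants, block LD."""
    spec = GenotypeSimSpec(
        n_samples=500,
        variants_per_chromosome=100,
        n_chromosomes=4,
        ld_block_size=5,
        ld_rho=0.5,
        seed=11,
    )
    return simulate_genotypes(spec)


@pytest.fixture(scope="session")
def geno_medium():
    """2,000 samples x 10 chromosomes x 200 variants, block LD."""
    spec = GenotypeSimSpec(
        n_samples=2_000,
        variants_per_chromosome=200,
        n_chromosomes=10,
        ld_block_size=10,
        ld_rho=0.5,
        seed=7,
    )
    return simulate_genotypes(spec)


@pytest.fixture(scope="session")
def quantitative_trait(geno_medium):
    spec = PhenoSimSpec(n_causal=40, h2=0.5, seed=3)
    pheno, truth = simulate_quantitative(geno_medium, spec)
    return pheno, truth
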