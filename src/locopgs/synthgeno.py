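"""Synthetic genotype simulation, variant QC and principal components.

The simulator produces hard-call genotypes with a controllable minor-allele
frequency spectrum, block LD structure and optional two-population
Balding-Nichols divergence.  LD is generated through a latent Gaussian
copula: within an LD block the latent variables of adjacent variants follow
an AR(1) process with correlation ``ld_rho``, independently on each of the
two gametes, and each latent value is thresholded at the allele-frequency
quantile to yield a haplotype allele.  This gives exact marginal
frequencies together with a tunable genotype correlation, and LD never
crosses chromosome (or block) boundaries.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from scipy import stats

from .genotypes import MISSING, GenotypeMatrix

logger = logging.getLogger(__name__)

#: bp distance between adjacent simulated variants; positions start at 1,
#: so a 1 Mb window spans 100 variants and a 5 Mb window spans 500.
POSITION_STRIDE_BP = 10_000


@dataclass
class GenotypeSimSpec:
    """Parameters of the synthetic genotype generator.

    ``maf_distribution`` is either ``("uniform", lo, hi)`` — MAF drawn
    uniformly on [lo, hi] — or ``("beta", a, b)`` — a Beta(a, b) draw
    rescaled onto [0.01, 0.5] for a skewed, rare-variant-heavy spectrum.
    ``fst`` > 0 splits the cohort into two equal subpopulations whose
    variant frequencies are drawn from the Balding-Nichols
    Beta(p(1-F)/F, (1-p)(1-F)/F) distribution around the ancestral
    frequency p.
    """

    n_samples: int
    variants_per_chromosome: int
    n_chromosomes: int = 22
    maf_distribution: tuple = ("uniform", 0.05, 0.5)
    ld_block_size: int = 1
    ld_rho: float = 0.0
    fst: float = 0.0
    missing_rate: float = 0.0
    seed: int = 0

    def validate(self) -> None:
        if self.n_samples <= 0 or self.variants_per_chromosome <= 0:
            raise ValueError("n_samples and variants_per_chromosome must be positive")
        if self.n_chromosomes <= 0:
            raise ValueError("n_chromosomes must be positive")
        if not 0.0 <= self.ld_rho < 1.0:
            raise ValueError("ld_rho must lie in [0, 1)")
        if self.ld_block_size < 1:
            raise ValueError("ld_block_size must be >= 1")
        if self.fst < 0:
            raise ValueError("fst must be >= 0")
        if not 0.0 <= self.missing_rate < 1.0:
            raise ValueError("missing_rate must lie in [0, 1)")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "GenotypeSimSpec":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        if "maf_distribution" in raw:
            raw["maf_distribution"] = tuple(raw["maf_distribution"])
        return cls(**raw)

    def to_yaml(self, path: str | Path) -> None:
        data = asdict(self)
        data["maf_distribution"] = list(self.maf_distribution)
        with open(path, "w") as fh:
            yaml.safe_dump(data, fh, sort_keys=False)


def _draw_mafs(rng: np.random.Generator, dist: tuple, m: int) -> np.ndarray:
    kind = dist[0]
    if kind == "uniform":
        lo, hi = float(dist[1]), float(dist[2])
        if not 0.0 <= lo <= hi <= 0.5:
            raise ValueError("uniform MAF bounds must satisfy 0 <= lo <= hi <= 0.5")
        return rng.uniform(lo, hi, size=m)
    if kind == "beta":
        a, b = float(dist[1]), float(dist[2])
        return 0.01 + 0.49 * rng.beta(a, b, size=m)
    raise ValueError(f"unknown maf_distribution kind {kind!r}")


def _ar1_latent(
    rng: np.random.Generator, n: int, m: int, rho: float, block: int
) -> np.ndarray:
    """Latent N(0,1) field with AR(1) correlation rho inside each block."""
    z = rng.standard_normal((n, m))
    if rho > 0.0 and block > 1:
        c = np.sqrt(1.0 - rho * rho)
        for j in range(1, m):
            if j % block != 0:  # block boundaries break the chain
                z[:, j] = rho * z[:, j - 1] + c * z[:, j]
    return z


def simulate_genotypes(spec: GenotypeSimSpec) -> GenotypeMatrix:
    """Simulate a genotype matrix according to ``spec``.

    The dosage counts copies of allele ``a1``, whose population frequency
    is the drawn MAF (``a1`` is the minor allele by construction).  With
    ``fst`` > 0 the first ``n // 2`` samples form subpopulation 0 and the
    remainder subpopulation 1.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    n = spec.n_samples
    mpc = spec.variants_per_chromosome
    m = spec.n_chromosomes * mpc

    maf = _draw_mafs(rng, spec.maf_distribution, m)

    two_pops = spec.fst > 0
    if two_pops:
        pop = np.zeros(n, dtype=np.int8)
        pop[n // 2 :] = 1
        f = spec.fst
        a = maf * (1.0 - f) / f
        b = (1.0 - maf) * (1.0 - f) / f
        pop_freq = np.stack([rng.beta(a, b), rng.beta(a, b)])  # (2, m)
    else:
        pop = np.zeros(n, dtype=np.int8)
        pop_freq = np.stack([maf, maf])

    dosages = np.empty((n, m), dtype=np.int8)
    for c in range(spec.n_chromosomes):
        sl = slice(c * mpc, (c + 1) * mpc)
        thr = stats.norm.ppf(pop_freq[:, sl])  # (2, mpc)
        geno = np.zeros((n, mpc), dtype=np.int8)
        for _gamete in range(2):
            z = _ar1_latent(rng, n, mpc, spec.ld_rho, spec.ld_block_size)
            for k in (0, 1):
                rows = pop == k
                if rows.any():
                    geno[rows] += (z[rows] < thr[k][None, :]).astype(np.int8)
        dosages[:, sl] = geno

    if spec.missing_rate > 0:
        mask = rng.random((n, m)) < spec.missing_rate
        dosages[mask] = MISSING

    chrom = np.repeat(np.arange(1, spec.n_chromosomes + 1), mpc)
    offset = np.tile(np.arange(mpc), spec.n_chromosomes)
    pos = 1 + offset * POSITION_STRIDE_BP
    variants = pd.DataFrame(
        {
            "id": [f"snp{c}_{i + 1}" for c, i in zip(chrom, offset)],
            "chrom": chrom,
            "pos": pos,
            "a1": "A",
            "a2": "G",
        }
    )
    return GenotypeMatrix(dosages=dosages, variants=variants)


# ----------------------------------------------------------------------
# variant QC
# ----------------------------------------------------------------------
def hwe_test(n0: np.ndarray, n1: np.ndarray, n2: np.ndarray):
    """One-degree-of-freedom chi-square Hardy-Weinberg test.

    Parameters are per-variant counts of dosage-0, dosage-1 and dosage-2
    genotypes among non-missing calls.  Returns ``(statistic, p_value)``
    arrays; monomorphic variants get statistic 0 and P 1.
    """
    n0 = np.asarray(n0, dtype=float)
    n1 = np.asarray(n1, dtype=float)
    n2 = np.asarray(n2, dtype=float)
    ntot = n0 + n1 + n2
    with np.errstate(invalid="ignore", divide="ignore"):
        p = (2 * n2 + n1) / (2 * ntot)
        q = 1.0 - p
        exp = np.stack([ntot * q * q, 2 * ntot * p * q, ntot * p * p])
        obs = np.stack([n0, n1, n2])
        chi2 = np.where(exp > 0, (obs - exp) ** 2 / np.where(exp > 0, exp, 1.0), 0.0)
        stat = chi2.sum(axis=0)
    mono = (p <= 0) | (p >= 1) | (ntot == 0)
    stat = np.where(mono, 0.0, stat)
    pval = stats.chi2.sf(stat, df=1)
    pval = np.where(mono, 1.0, pval)
    return stat, pval


def qc_filter(
    G: GenotypeMatrix,
    maf_min: float = 0.0005,
    missingness_max: float = 0.02,
    hwe_alpha: float = 1e-4,
) -> GenotypeMatrix:
    """Apply the standard variant QC filters; the sample set is unchanged.

    A variant is retained iff its observed MAF >= ``maf_min``, its missing
    fraction <= ``missingness_max`` and its HWE chi-square P >= ``hwe_alpha``.
    An empty result is legal and logged, not an error.
    """
    for name, v in [
        ("maf_min", maf_min),
        ("missingness_max", missingness_max),
        ("hwe_alpha", hwe_alpha),
    ]:
        if not 0.0 <= v <= 1.0:
            raise ValueError(f"{name} must lie in [0, 1]")

    maf = G.minor_allele_frequencies()
    miss = G.missing_rates()
    counts = G.genotype_counts()
    _, hwe_p = hwe_test(counts[:, 0], counts[:, 1], counts[:, 2])

    keep = (
        (np.nan_to_num(maf, nan=0.0) >= maf_min)
        & (miss <= missingness_max)
        & (hwe_p >= hwe_alpha)
    )
    n_drop = int((~keep).sum())
    if n_drop:
        logger.info(
            "qc_filter removed %d / %d variants (MAF<%g, miss>%g or HWE P<%g)",
            n_drop, G.n_variants, maf_min, missingness_max, hwe_alpha,
        )
    if not keep.any():
        logger.warning("qc_filter removed every variant")
    return G.take_variants(keep)


# ----------------------------------------------------------------------
# LD pruning and principal components
# ----------------------------------------------------------------------
def ld_prune(
    G: GenotypeMatrix,
    prune_r2: float,
    window: int = 50,
    step: int = 20,
    unit: str = "variants",
) -> np.ndarray:
    """Greedy sliding-window LD pruning; returns kept variant indices.

    ``unit`` is ``"variants"`` (window/step counted in variants, the
    default) or ``"bp"``.  Within each window, for each pair with
    genotype r^2 > ``prune_r2`` the member with the lower MAF is dropped
    (ties drop the later variant).
    """
    if unit not in ("variants", "bp"):
        raise ValueError("unit must be 'variants' or 'bp'")
    keep = np.ones(G.n_variants, dtype=bool)
    maf = np.nan_to_num(G.minor_allele_frequencies(), nan=0.0)
    chrom = np.asarray(G.variants["chrom"])
    pos = np.asarray(G.variants["pos"])

    for c in np.unique(chrom):
        idx = np.flatnonzero(chrom == c)
        Z = G.standardized(idx)
        Z = Z - Z.mean(axis=0)
        norms = np.sqrt((Z**2).sum(axis=0))
        norms[norms == 0] = 1.0
        Z = Z / norms
        if unit == "variants":
            windows = [
                np.arange(s, min(s + window, len(idx)))
                for s in range(0, len(idx), step)
            ]
        else:
            p = pos[idx]
            windows = [
                np.flatnonzero((p >= lo) & (p <= lo + window))
                for lo in range(int(p.min()), int(p.max()) + 1, step)
            ]
        for members in windows:
            if len(members) < 2:
                continue
            R = Z[:, members].T @ Z[:, members]
            for a in range(len(members)):
                ia = idx[members[a]]
                if not keep[ia]:
                    continue
                for b in range(a + 1, len(members)):
                    ib = idx[members[b]]
                    if not keep[ib]:
                        continue
                    if R[a, b] ** 2 > prune_r2:
                        drop = ib if maf[ib] <= maf[ia] else ia
                        keep[drop] = False
                        if drop == ia:
                            break
    return np.flatnonzero(keep)


def principal_components(
    G: GenotypeMatrix, k: int, prune_r2: float = 0.1, window: int = 50, step: int = 20
) -> np.ndarray:
    """Top-k PC scores of the LD-pruned, standardized genotype matrix.

    Scores are U * S columns of the thin SVD of the column-centered
    standardized dosages, hence mutually orthogonal.
    """
    kept = ld_prune(G, prune_r2=prune_r2, window=window, step=step)
    Z = G.standardized(kept)
    Z = Z - Z.mean(axis=0)
    if k > min(Z.shape):
        raise ValueError(f"k={k} exceeds min(n, m)={min(Z.shape)}")
    U, S, _ = np.linalg.svd(Z, full_matrices=False)
    tol = max(Z.shape) * np.finfo(float).eps * (S[0] if S.size else 0.0)
    rank = int((S > tol).sum())
    if k > rank:
        raise ValueError(f"k={k} exceeds the rank {rank} of the pruned matrix")
    return U[:, :k] * S[:k]
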