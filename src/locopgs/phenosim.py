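"""Quantitative and case-control phenotype simulation.

Traits are additive: a set of causal variants is drawn uniformly from the
eligible variants, per-variant effects are i.i.d. standard normal on the
standardized-genotype scale (so each causal variant contributes on average
h2 / m_c of the phenotypic variance), and environmental noise is scaled
against the *realized* sample variance of the genetic values so that the
realized narrow-sense heritability tracks the target tightly.  Binary
traits are produced by rank-thresholding the same continuous liability at
the top ``prevalence`` fraction, which makes the case count exact.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .genotypes import GenotypeMatrix

TRAIT_QUANTITATIVE = "quantitative"
TRAIT_BINARY = "binary"


@dataclass
class PhenoSimSpec:
    """Parameters of the phenotype simulator.

    ``causal_chromosome_mask`` restricts causal variants to a set of
    chromosomes (e.g. even chromosomes for the null design).  Causal
    variants must have MAF >= ``min_causal_maf`` (default 0.01) to avoid
    degenerate single-variant power at moderate sample sizes.
    ``effect_scale`` chooses whether the i.i.d. normal effects apply on
    the standardized-genotype scale (default, equal expected variance per
    causal variant) or on the raw allelic scale.
    """

    n_causal: int
    h2: float
    trait_type: str = TRAIT_QUANTITATIVE
    prevalence: float | None = None
    causal_chromosome_mask: tuple | None = None
    min_causal_maf: float = 0.01
    effect_scale: str = "standardized"
    covariate_effects: dict | None = None
    seed: int = 0

    def validate(self) -> None:
        if not 0.0 <= self.h2 <= 1.0:
            raise ValueError("h2 must lie in [0, 1]")
        if self.n_causal < 0:
            raise ValueError("n_causal must be >= 0")
        if self.n_causal == 0 and self.h2 > 0:
            raise ValueError("h2 > 0 requires at least one causal variant")
        if self.trait_type not in (TRAIT_QUANTITATIVE, TRAIT_BINARY):
            raise ValueError(f"unknown trait_type {self.trait_type!r}")
        if self.trait_type == TRAIT_BINARY:
            if self.prevalence is None or not 0.0 < self.prevalence < 1.0:
                raise ValueError("binary traits need prevalence in (0, 1)")
        if self.effect_scale not in ("standardized", "allelic"):
            raise ValueError("effect_scale must be 'standardized' or 'allelic'")


@dataclass
class SimulationTruth:
    """Ground truth of one simulated phenotype replicate."""

    causal_ids: np.ndarray
    causal_index: np.ndarray  # column indices into the genotype matrix
    chrom: np.ndarray
    pos: np.ndarray
    effect_allele: np.ndarray  # allele whose count the effect applies to (a1)
    beta_std: np.ndarray  # effects on the standardized-genotype scale
    beta_allelic: np.ndarray  # beta_std / sqrt(2 p (1 - p))
    genetic_values: np.ndarray
    realized_h2: float

    @property
    def n_causal(self) -> int:
        return len(self.causal_ids)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "SNP": self.causal_ids,
                "CHR": self.chrom,
                "BP": self.pos,
                "A1": self.effect_allele,
                "BETA_STD": self.beta_std,
                "BETA_ALLELIC": self.beta_allelic,
            }
        )

    def to_tsv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)


@dataclass
class PhenotypeTable:
    """Per-sample trait values plus fixed-effect covariates."""

    sample_ids: np.ndarray
    trait: np.ndarray
    covariates: pd.DataFrame
    trait_type: str = TRAIT_QUANTITATIVE

    def __post_init__(self) -> None:
        self.sample_ids = np.asarray(self.sample_ids, dtype=object)
        self.trait = np.asarray(self.trait, dtype=float)
        if len(self.trait) != len(self.sample_ids):
            raise ValueError("trait and sample_ids lengths differ")
        if len(self.covariates) not in (0, len(self.sample_ids)):
            raise ValueError("covariates rows must match sample_ids")

    def aligned_to(self, sample_ids: np.ndarray) -> "PhenotypeTable":
        """Reorder rows to match ``sample_ids`` (error on missing samples)."""
        order = pd.Series(
            np.arange(len(self.sample_ids)), index=self.sample_ids
        ).reindex(np.asarray(sample_ids, dtype=object))
        if order.isna().any():
            missing = list(order.index[order.isna()][:5])
            raise KeyError(f"phenotype table is missing samples {missing}")
        idx = order.to_numpy(dtype=int)
        return PhenotypeTable(
            sample_ids=self.sample_ids[idx],
            trait=self.trait[idx],
            covariates=self.covariates.iloc[idx].reset_index(drop=True)
            if len(self.covariates)
            else self.covariates,
            trait_type=self.trait_type,
        )

    def to_tsv(self, path: str | Path, trait_name: str = "TRAIT") -> None:
        out = pd.DataFrame({"FID": self.sample_ids, "IID": self.sample_ids})
        out[trait_name] = self.trait
        for col in self.covariates.columns:
            out[col] = np.asarray(self.covariates[col])
        out.to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(
        cls, path: str | Path, trait_name: str = "TRAIT"
    ) -> "PhenotypeTable":
        df = pd.read_csv(path, sep="\t", dtype={"FID": str, "IID": str})
        covar_cols = [c for c in df.columns if c not in ("FID", "IID", trait_name)]
        trait = df[trait_name].to_numpy(dtype=float)
        trait_type = (
            TRAIT_BINARY
            if np.isin(trait, [0.0, 1.0]).all() and len(np.unique(trait)) <= 2
            else TRAIT_QUANTITATIVE
        )
        return cls(
            sample_ids=df["IID"].to_numpy(dtype=object),
            trait=trait,
            covariates=df[covar_cols].reset_index(drop=True),
            trait_type=trait_type,
        )


def _default_covariates(rng: np.random.Generator, n: int) -> pd.DataFrame:
    # synthetic nuisance covariates with zero true effect by default
    return pd.DataFrame(
        {
            "sex": rng.integers(0, 2, size=n).astype(float),
            "age": rng.integers(40, 71, size=n).astype(float),
        }
    )


def _eligible_indices(G: GenotypeMatrix, spec: PhenoSimSpec) -> np.ndarray:
    maf = np.nan_to_num(G.minor_allele_frequencies(), nan=0.0)
    ok = maf >= spec.min_causal_maf
    if spec.causal_chromosome_mask is not None:
        mask = set(spec.causal_chromosome_mask)
        ok &= np.isin(np.asarray(G.variants["chrom"]), list(mask))
    return np.flatnonzero(ok)


def _simulate_liability(G: GenotypeMatrix, spec: PhenoSimSpec):
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    n = G.n_samples

    eligible = _eligible_indices(G, spec)
    if spec.n_causal > len(eligible):
        raise ValueError(
            f"n_causal={spec.n_causal} exceeds the {len(eligible)} eligible variants"
        )
    causal = np.sort(rng.choice(eligible, size=spec.n_causal, replace=False))

    p = np.asarray(G.variants["freq_a1"], dtype=float)[causal]
    scale = np.sqrt(2.0 * p * (1.0 - p))
    if spec.effect_scale == "standardized":
        beta_std = rng.standard_normal(spec.n_causal)
    else:
        beta_allelic_draw = rng.standard_normal(spec.n_causal)
        beta_std = beta_allelic_draw * scale

    if spec.n_causal > 0:
        W = G.standardized(causal)
        g = W @ beta_std
    else:
        g = np.zeros(n)

    if spec.h2 == 0.0:
        # pure-noise phenotype: the drawn effects are not expressed
        y = rng.standard_normal(n)
        realized_h2 = 0.0
    elif spec.h2 == 1.0:
        y = g.copy()
        realized_h2 = 1.0
    else:
        var_g = g.var()
        e = rng.standard_normal(n) * math.sqrt(var_g * (1.0 - spec.h2) / spec.h2)
        y = g + e
        realized_h2 = float(var_g / y.var())

    covar = _default_covariates(rng, n)
    if spec.covariate_effects:
        for name, eff in spec.covariate_effects.items():
            y = y + eff * covar[name].to_numpy()

    truth = SimulationTruth(
        causal_ids=G.variant_ids[causal],
        causal_index=causal,
        chrom=np.asarray(G.variants["chrom"])[causal],
        pos=np.asarray(G.variants["pos"])[causal],
        effect_allele=np.asarray(G.variants["a1"], dtype=object)[causal],
        beta_std=beta_std,
        beta_allelic=np.where(scale > 0, beta_std / np.where(scale > 0, scale, 1), 0.0),
        genetic_values=g,
        realized_h2=realized_h2,
    )
    return y, covar, truth


def simulate_quantitative(G: GenotypeMatrix, spec: PhenoSimSpec):
    """Simulate a continuous trait; returns ``(PhenotypeTable, SimulationTruth)``."""
    if spec.trait_type != TRAIT_QUANTITATIVE:
        raise ValueError("spec.trait_type must be 'quantitative'")
    y, covar, truth = _simulate_liability(G, spec)
    pheno = PhenotypeTable(
        sample_ids=G.sample_ids, trait=y, covariates=covar,
        trait_type=TRAIT_QUANTITATIVE,
    )
    return pheno, truth


def simulate_binary(G: GenotypeMatrix, spec: PhenoSimSpec):
    """Simulate a case-control trait under the liability-threshold model.

    The ``ceil(prevalence * n)`` samples with the largest liability are
    cases; the returned truth carries the liability-scale effects.
    """
    if spec.trait_type != TRAIT_BINARY:
        raise ValueError("spec.trait_type must be 'binary'")
    liability, covar, truth = _simulate_liability(G, spec)
    n = G.n_samples
    n_cases = math.ceil(spec.prevalence * n)
    order = np.argsort(-liability, kind="stable")
    labels = np.zeros(n)
    labels[order[:n_cases]] = 1.0
    pheno = PhenotypeTable(
        sample_ids=G.sample_ids, trait=labels, covariates=covar,
        trait_type=TRAIT_BINARY,
    )
    return pheno, truth


def null_design(G: GenotypeMatrix, spec: PhenoSimSpec):
    """Even-chromosome causal design for false-positive-rate calibration.

    Causal variants are restricted to even chromosomes; every
    odd-chromosome variant is genuinely null.  Returns
    ``(PhenotypeTable, SimulationTruth, null_variant_ids)`` where the null
    ids are the odd-chromosome variant ids.
    """
    chroms = G.chromosomes
    even = tuple(int(c) for c in chroms if int(c) % 2 == 0)
    if not even:
        raise ValueError("genotype matrix has no even-numbered chromosomes")
    spec = replace(spec, causal_chromosome_mask=even)
    if spec.trait_type == TRAIT_BINARY:
        pheno, truth = simulate_binary(G, spec)
    else:
        pheno, truth = simulate_quantitative(G, spec)
    odd_mask = np.asarray(G.variants["chrom"]).astype(int) % 2 == 1
    null_ids = G.variant_ids[odd_mask]
    return pheno, truth, null_ids
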