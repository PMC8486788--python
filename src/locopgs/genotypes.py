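"""Core genotype container shared by every stage of the pipeline.

Genotypes are hard-call allele counts: each entry counts copies of the
variant's ``a1`` allele (0, 1 or 2), with :data:`MISSING` (-1) marking a
missing call.  Variant metadata travels alongside the dosage matrix in a
pandas DataFrame so that downstream steps (clumping windows, LOCO
partitioning, allele matching) never need a second lookup structure.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

#: Sentinel for a missing hard call in an int8 dosage matrix.
MISSING = np.int8(-1)

#: Required columns of the variant metadata frame.
VARIANT_COLUMNS = ("id", "chrom", "pos", "a1", "a2")

#: Tolerance for the stored-vs-recomputed allele-frequency invariant.
FREQ_TOL = 1e-12


def _as_int8(dosages: np.ndarray) -> np.ndarray:
    arr = np.asarray(dosages)
    if arr.dtype != np.int8:
        arr = arr.astype(np.int8)
    return arr


@dataclass
class GenotypeMatrix:
    """n samples x m variants hard-call dosage matrix plus metadata.

    Parameters
    ----------
    dosages
        ``(n, m)`` int8 array with entries in ``{0, 1, 2, MISSING}``;
        the value counts copies of the variant's ``a1`` allele.
    variants
        DataFrame with columns ``id, chrom, pos, a1, a2`` (one row per
        variant, aligned with the columns of ``dosages``).  A
        ``freq_a1`` column holding the observed a1 allele frequency is
        added on construction if absent.
    sample_ids
        Length-n sequence of unique sample identifiers.
    """

    dosages: np.ndarray
    variants: pd.DataFrame
    sample_ids: np.ndarray = field(default=None)

    def __post_init__(self) -> None:
        self.dosages = _as_int8(self.dosages)
        if self.dosages.ndim != 2:
            raise ValueError("dosages must be a 2-D (samples x variants) array")
        n, m = self.dosages.shape
        if self.sample_ids is None:
            self.sample_ids = np.array([f"S{i + 1:06d}" for i in range(n)])
        self.sample_ids = np.asarray(self.sample_ids, dtype=object)
        if len(self.sample_ids) != n:
            raise ValueError(
                f"sample_ids length {len(self.sample_ids)} != {n} dosage rows"
            )
        if not isinstance(self.variants, pd.DataFrame):
            self.variants = pd.DataFrame(self.variants)
        missing_cols = set(VARIANT_COLUMNS) - set(self.variants.columns)
        if missing_cols:
            raise ValueError(f"variants frame missing columns {sorted(missing_cols)}")
        if len(self.variants) != m:
            raise ValueError(
                f"variants frame has {len(self.variants)} rows for {m} dosage columns"
            )
        self.variants = self.variants.reset_index(drop=True)
        bad = ~np.isin(self.dosages, [0, 1, 2, MISSING])
        if bad.any():
            raise ValueError("dosages contain values outside {0, 1, 2, MISSING}")
        if (self.variants["a1"] == self.variants["a2"]).any():
            raise ValueError("a1 and a2 must differ for every variant")
        self._check_sorted_positions()
        if "freq_a1" not in self.variants.columns:
            self.variants["freq_a1"] = self.allele_frequencies()
        else:
            stored = np.asarray(self.variants["freq_a1"], dtype=float)
            observed = self.allele_frequencies()
            ok = np.isnan(stored) & np.isnan(observed)
            ok |= np.abs(stored - observed) <= FREQ_TOL
            if not ok.all():
                raise ValueError(
                    "stored freq_a1 disagrees with frequency recomputed from dosages"
                )

    def _check_sorted_positions(self) -> None:
        chrom = np.asarray(self.variants["chrom"])
        pos = np.asarray(self.variants["pos"])
        if (pos < 1).any():
            raise ValueError("positions must be >= 1 (1-based coordinates)")
        for c in np.unique(chrom):
            p = pos[chrom == c]
            if np.any(np.diff(p) <= 0):
                raise ValueError(
                    f"positions on chromosome {c} must be strictly increasing"
                )

    # ------------------------------------------------------------------
    # basic shape / metadata accessors
    # ------------------------------------------------------------------
    @property
    def n_samples(self) -> int:
        return self.dosages.shape[0]

    @property
    def n_variants(self) -> int:
        return self.dosages.shape[1]

    @property
    def chromosomes(self) -> np.ndarray:
        """Sorted unique chromosome labels present in the matrix."""
        return np.unique(np.asarray(self.variants["chrom"]))

    @property
    def variant_ids(self) -> np.ndarray:
        return np.asarray(self.variants["id"], dtype=object)

    # ------------------------------------------------------------------
    # per-variant summaries
    # ------------------------------------------------------------------
    def allele_frequencies(self) -> np.ndarray:
        """Observed a1 allele frequency per variant from non-missing calls.

        Variants with no non-missing calls get ``nan``.
        """
        d = self.dosages
        obs = d != MISSING
        n_obs = obs.sum(axis=0)
        counts = np.where(obs, d, 0).sum(axis=0, dtype=np.int64)
        with np.errstate(invalid="ignore", divide="ignore"):
            freq = counts / (2.0 * n_obs)
        return np.where(n_obs > 0, freq, np.nan)

    def minor_allele_frequencies(self) -> np.ndarray:
        p = self.allele_frequencies()
        return np.minimum(p, 1.0 - p)

    def missing_rates(self) -> np.ndarray:
        return (self.dosages == MISSING).mean(axis=0)

    def genotype_counts(self) -> np.ndarray:
        """``(m, 3)`` counts of dosage 0/1/2 among non-missing calls."""
        out = np.empty((self.n_variants, 3), dtype=np.int64)
        for g in (0, 1, 2):
            out[:, g] = (self.dosages == g).sum(axis=0)
        return out

    # ------------------------------------------------------------------
    # numeric views
    # ------------------------------------------------------------------
    def imputed(self, columns: np.ndarray | None = None) -> np.ndarray:
        """Float64 dosages with missing calls replaced by the variant mean."""
        cols = slice(None) if columns is None else np.asarray(columns)
        d = self.dosages[:, cols].astype(np.float64)
        miss = d == MISSING
        if miss.any():
            obs = ~miss
            with np.errstate(invalid="ignore"):
                mean = np.where(
                    obs.sum(axis=0) > 0,
                    np.where(obs, d, 0.0).sum(axis=0) / obs.sum(axis=0),
                    0.0,
                )
            d = np.where(miss, mean[None, :], d)
        return d

    def standardized(self, columns: np.ndarray | None = None) -> np.ndarray:
        """Mean-imputed dosages standardized to (x - 2p) / sqrt(2p(1-p)).

        Monomorphic variants (p in {0, 1}) become all-zero columns.
        """
        d = self.imputed(columns)
        cols = slice(None) if columns is None else np.asarray(columns)
        p = np.asarray(self.variants["freq_a1"], dtype=float)[cols]
        denom = np.sqrt(2.0 * p * (1.0 - p))
        safe = denom > 0
        z = np.zeros_like(d)
        z[:, safe] = (d[:, safe] - 2.0 * p[safe]) / denom[safe]
        return z

    # ------------------------------------------------------------------
    # subsetting
    # ------------------------------------------------------------------
    def take_variants(self, index: np.ndarray) -> "GenotypeMatrix":
        """Subset variants by boolean mask or integer index (order preserved)."""
        index = np.asarray(index)
        if index.dtype == bool:
            index = np.flatnonzero(index)
        return GenotypeMatrix(
            dosages=self.dosages[:, index],
            variants=self.variants.iloc[index].reset_index(drop=True),
            sample_ids=self.sample_ids,
        )

    def take_samples(self, index: np.ndarray) -> "GenotypeMatrix":
        index = np.asarray(index)
        if index.dtype == bool:
            index = np.flatnonzero(index)
        sub = self.variants.drop(columns=["freq_a1"], errors="ignore")
        return GenotypeMatrix(
            dosages=self.dosages[index, :],
            variants=sub,
            sample_ids=self.sample_ids[index],
        )

    def variant_indexer(self) -> pd.Series:
        """Map variant id -> column index."""
        return pd.Series(np.arange(self.n_variants), index=self.variants["id"])
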