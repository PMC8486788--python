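"""Polygenic-score construction by pruning & thresholding, and LOCO scores.

The pruning-and-thresholding (P&T) weight method keeps approximately
LD-independent index variants below a P-value threshold via plink-style
greedy clumping: repeatedly take the smallest-P unclaimed variant as an
index and claim every unclaimed variant on the same chromosome within a bp
window whose genotype r^2 with the index exceeds the clumping threshold.
Index variants keep their estimated allelic effect as the score weight.

Leave-one-chromosome-out (LOCO) scores — one per chromosome, built from
the other chromosomes' variants only — serve as fixed-effect covariates in
the second-stage scan.  By default clumping runs once on the genome-wide
statistics and the LOCO column for chromosome c is obtained by subtracting
chromosome c's contribution from the total score; this is exactly the
per-exclusion result whenever LD does not cross chromosomes, and a strict
per-exclusion mode is available for validation.

Alternative weight methods (e.g. shrinkage-based predictors) plug in via
:func:`register_weight_method`; the default threshold of 5e-5 is
deliberately conservative and thresholds above 0.01 require an explicit
override, since scores dominated by null variants can destabilize the
second-stage false-positive rate.
"""

from __future__ import annotations

import hashlib
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Callable

import numpy as np
import pandas as pd

from .genotypes import GenotypeMatrix

logger = logging.getLogger(__name__)

WEIGHT_COLUMNS = ["SNP", "CHR", "BP", "A1", "WEIGHT"]

#: P-value thresholds above this require allow_high_threshold=True
HIGH_THRESHOLD_GUARD = 0.01


@dataclass
class PGSConfig:
    """Configuration of P&T score construction.

    ``p_threshold`` (default 5e-5) gates variant inclusion;
    ``clump_r2``/``clump_window_bp`` control LD clumping (defaults 0.1 and
    250 kb); ``weight_method`` names a registered weight procedure
    (``"pt"`` built in); ``per_exclusion`` re-clumps from scratch for each
    excluded chromosome instead of deriving LOCO columns by subtraction.
    """

    p_threshold: float = 5e-5
    clump_r2: float = 0.1
    clump_window_bp: int = 250_000
    weight_method: str = "pt"
    per_exclusion: bool = False
    allow_high_threshold: bool = False

    def __post_init__(self) -> None:
        if not 0.0 < self.p_threshold <= 1.0:
            raise ValueError("p_threshold must lie in (0, 1]")
        if not 0.0 <= self.clump_r2 <= 1.0:
            raise ValueError("clump_r2 must lie in [0, 1]")
        if self.clump_window_bp <= 0:
            raise ValueError("clump_window_bp must be positive")
        if self.p_threshold > HIGH_THRESHOLD_GUARD and not self.allow_high_threshold:
            raise ValueError(
                f"p_threshold={self.p_threshold} exceeds {HIGH_THRESHOLD_GUARD}; "
                "high thresholds can inflate the downstream false-positive rate "
                "— set allow_high_threshold=True to override"
            )


@dataclass
class LocoScoreSet:
    """n samples x C chromosomes of leave-one-chromosome-out scores.

    Column c is the polygenic score built excluding chromosome c.
    """

    scores: np.ndarray
    chromosomes: np.ndarray
    sample_ids: np.ndarray
    config: PGSConfig | None = None
    weight_table: pd.DataFrame | None = None
    source_fingerprint: str | None = None

    def __post_init__(self) -> None:
        self.scores = np.asarray(self.scores, dtype=float)
        self.chromosomes = np.asarray(self.chromosomes)
        if self.scores.shape != (len(self.sample_ids), len(self.chromosomes)):
            raise ValueError("scores shape does not match samples x chromosomes")

    def column(self, chromosome) -> np.ndarray:
        hit = np.flatnonzero(self.chromosomes == chromosome)
        if len(hit) != 1:
            raise KeyError(f"no LOCO score column for chromosome {chromosome}")
        return self.scores[:, hit[0]]

    def to_tsv(self, path: str | Path) -> None:
        out = pd.DataFrame({"FID": self.sample_ids, "IID": self.sample_ids})
        for j, c in enumerate(self.chromosomes):
            out[f"PGS_LOCO_{c}"] = self.scores[:, j]
        out.to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path: str | Path) -> "LocoScoreSet":
        df = pd.read_csv(path, sep="\t", dtype={"FID": str, "IID": str})
        score_cols = [c for c in df.columns if c.startswith("PGS_LOCO_")]
        chroms = np.array([int(c.removeprefix("PGS_LOCO_")) for c in score_cols])
        return cls(
            scores=df[score_cols].to_numpy(dtype=float),
            chromosomes=chroms,
            sample_ids=df["IID"].to_numpy(dtype=object),
        )


def _empty_weight_table() -> pd.DataFrame:
    return pd.DataFrame(
        {
            "SNP": pd.Series(dtype=object),
            "CHR": pd.Series(dtype=int),
            "BP": pd.Series(dtype=int),
            "A1": pd.Series(dtype=object),
            "WEIGHT": pd.Series(dtype=float),
        }
    )


def clump(
    stats_df: pd.DataFrame,
    G_ref: GenotypeMatrix,
    p_threshold: float,
    clump_r2: float,
    clump_window_bp: int,
) -> pd.DataFrame:
    """Greedy LD clumping of a summary-statistic frame.

    Returns a weight table (``SNP CHR BP A1 WEIGHT``) whose rows are the
    index variants, weighted by their allelic effect estimates.  Ties in P
    break by (chromosome, position) ascending.  Variants absent from the
    reference panel are skipped with a logged count.
    """
    indexer = G_ref.variant_indexer()
    present = stats_df["SNP"].isin(indexer.index)
    n_absent = int((~present).sum())
    if n_absent:
        logger.warning("clump: %d variants absent from the reference panel", n_absent)
    cand = stats_df.loc[present & stats_df["P"].notna() & (stats_df["P"] <= p_threshold)]
    cand = cand.sort_values(["P", "CHR", "BP"], kind="mergesort").reset_index(drop=True)
    if cand.empty:
        return _empty_weight_table()

    gcols = indexer[cand["SNP"]].to_numpy()
    chrom = cand["CHR"].to_numpy()
    bp = cand["BP"].to_numpy()
    claimed = np.zeros(len(cand), dtype=bool)

    # standardized dosage columns of the candidates, for r^2 lookups
    Z = G_ref.standardized(gcols)
    Z = Z - Z.mean(axis=0)
    norms = np.linalg.norm(Z, axis=0)
    norms[norms == 0] = 1.0
    Z = Z / norms

    index_rows = []
    for i in range(len(cand)):
        if claimed[i]:
            continue
        claimed[i] = True
        index_rows.append(i)
        near = (
            ~claimed
            & (chrom == chrom[i])
            & (np.abs(bp - bp[i]) <= clump_window_bp)
        )
        if near.any():
            r = Z[:, near].T @ Z[:, i]
            hit = np.flatnonzero(near)[r**2 > clump_r2]
            claimed[hit] = True

    sel = cand.iloc[index_rows]
    table = pd.DataFrame(
        {
            "SNP": sel["SNP"].to_numpy(),
            "CHR": sel["CHR"].to_numpy(),
            "BP": sel["BP"].to_numpy(),
            "A1": sel["A1"].to_numpy(),
            "WEIGHT": sel["BETA"].to_numpy(dtype=float),
        }
    )
    return table.sort_values(["CHR", "BP"], kind="mergesort").reset_index(drop=True)


def score(G: GenotypeMatrix, weights: pd.DataFrame) -> np.ndarray:
    """Per-sample weighted allele-dosage sum for a weight table.

    The dosage entering the sum counts copies of the weight's effect
    allele: matrix variants whose ``a2`` is the effect allele contribute
    ``2 - dosage``.  Variants whose effect allele matches neither matrix
    allele are excluded with a logged count; missing dosages contribute
    the variant mean.  Raises on zero overlapping variants.
    """
    indexer = G.variant_indexer()
    present = weights["SNP"].isin(indexer.index)
    usable = weights.loc[present].copy()
    if usable.empty:
        raise ValueError("no overlap between the weight table and the genotypes")
    gcols = indexer[usable["SNP"]].to_numpy()
    a1 = np.asarray(G.variants["a1"], dtype=object)[gcols]
    a2 = np.asarray(G.variants["a2"], dtype=object)[gcols]
    eff = usable["A1"].to_numpy(dtype=object)
    direct = eff == a1
    flipped = eff == a2
    bad = ~(direct | flipped)
    n_skipped = int((~present).sum() + bad.sum())
    if n_skipped:
        logger.warning("score: excluded %d variants (absent or allele mismatch)",
                       n_skipped)
    keep = ~bad
    if not keep.any():
        raise ValueError("no overlap between the weight table and the genotypes")
    D = G.imputed(gcols[keep])
    D = np.where(flipped[keep][None, :], 2.0 - D, D)
    w = usable["WEIGHT"].to_numpy(dtype=float)[keep]
    return D @ w


def _chromosome_contributions(G: GenotypeMatrix, weights: pd.DataFrame, chroms):
    """Total score and per-chromosome contribution matrix ``(n, C)``."""
    n = G.n_samples
    contrib = np.zeros((n, len(chroms)))
    for j, c in enumerate(chroms):
        wc = weights.loc[weights["CHR"] == c]
        if len(wc):
            contrib[:, j] = score(G, wc)
    return contrib.sum(axis=1), contrib


# ----------------------------------------------------------------------
# weight-method registry
# ----------------------------------------------------------------------
WeightMethod = Callable[[pd.DataFrame, GenotypeMatrix, PGSConfig], pd.DataFrame]

_WEIGHT_METHODS: dict[str, WeightMethod] = {}


def register_weight_method(name: str, procedure: WeightMethod) -> None:
    """Register a procedure mapping (stats, reference panel, config) to a
    weight table, selectable through ``PGSConfig.weight_method``."""
    _WEIGHT_METHODS[name] = procedure


def get_weight_method(name: str) -> WeightMethod:
    try:
        return _WEIGHT_METHODS[name]
    except KeyError:
        raise KeyError(
            f"unknown weight method {name!r}; registered: {sorted(_WEIGHT_METHODS)}"
        ) from None


def _pt_weights(stats_df, G_ref, cfg: PGSConfig) -> pd.DataFrame:
    return clump(stats_df, G_ref, cfg.p_threshold, cfg.clump_r2, cfg.clump_window_bp)


register_weight_method("pt", _pt_weights)


def _fingerprint(stats_df: pd.DataFrame) -> str:
    h = hashlib.sha256()
    h.update(np.ascontiguousarray(stats_df["P"].to_numpy(dtype=float)).tobytes())
    h.update("".join(map(str, stats_df["SNP"].head(100))).encode())
    return h.hexdigest()[:16]


def loco_pgs(
    stats_df: pd.DataFrame, G: GenotypeMatrix, cfg: PGSConfig | None = None
) -> LocoScoreSet:
    """Build the leave-one-chromosome-out score set from summary statistics.

    Requires at least two chromosomes.  If no variant passes the P-value
    threshold the score set is all zeros (logged), which downstream scans
    treat as "no background correction".
    """
    cfg = cfg or PGSConfig()
    chroms = G.chromosomes
    if len(chroms) < 2:
        raise ValueError("LOCO scores need at least two chromosomes")
    method = get_weight_method(cfg.weight_method)

    n = G.n_samples
    if cfg.per_exclusion:
        chrom_arr = np.asarray(G.variants["chrom"])
        scores = np.zeros((n, len(chroms)))
        tables = []
        for j, c in enumerate(chroms):
            keep = chrom_arr != c
            G_excl = G.take_variants(keep)
            stats_excl = stats_df.loc[stats_df["CHR"] != c]
            table = method(stats_excl, G_excl, cfg)
            tables.append(table.assign(EXCLUDED_CHR=c))
            if len(table):
                scores[:, j] = score(G_excl, table)
        weight_table = (
            pd.concat(tables, ignore_index=True) if tables else _empty_weight_table()
        )
    else:
        weight_table = method(stats_df, G, cfg)
        if len(weight_table) == 0:
            logger.info("loco_pgs: empty weight table, all scores zero")
            scores = np.zeros((n, len(chroms)))
        else:
            total, contrib = _chromosome_contributions(G, weight_table, chroms)
            scores = total[:, None] - contrib

    return LocoScoreSet(
        scores=scores,
        chromosomes=chroms,
        sample_ids=G.sample_ids,
        config=cfg,
        weight_table=weight_table,
        source_fingerprint=_fingerprint(stats_df),
    )


def write_weight_table(weights: pd.DataFrame, path: str | Path) -> None:
    weights.to_csv(path, sep="\t", index=False)


def read_weight_table(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"SNP": str, "A1": str})
    missing = set(WEIGHT_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"weight table missing columns {sorted(missing)}")
    return df
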