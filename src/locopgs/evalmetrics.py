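"""Evaluation of scan output against simulation truth.

Covers the quantities used to compare the two scan stages: power
(proportion of causal variants recovered at a significance level), ROC and
AUC with a causal-region exclusion zone, median squared error (MEDSE) of
standardized effect estimates at the causal variants, false-positive rate
on a designated null variant set, and independent-locus counts via strict
clumping.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

from .genotypes import GenotypeMatrix
from .pgs import clump
from .phenosim import SimulationTruth

logger = logging.getLogger(__name__)

ALPHA_GENOME_WIDE = 5e-8

#: specificity grid resolution for reported ROC points
ROC_GRID_STEP = 1e-4


def _causal_pvalues(stats_df: pd.DataFrame, truth: SimulationTruth) -> pd.DataFrame:
    sub = stats_df.set_index("SNP")
    missing = [i for i in truth.causal_ids if i not in sub.index]
    if missing:
        raise KeyError(f"causal variants absent from the statistics: {missing[:10]}")
    return sub.loc[truth.causal_ids]


def power(
    stats_df: pd.DataFrame,
    truth: SimulationTruth,
    alpha_gw: float = ALPHA_GENOME_WIDE,
    window_bp: int | None = None,
) -> float:
    """Proportion of causal variants recovered at significance ``alpha_gw``.

    By default a causal variant counts as recovered only if its own P-value
    passes the threshold (the strict reading).  With ``window_bp`` set, it
    also counts if any variant within that distance on the same chromosome
    passes.
    """
    if truth.n_causal == 0:
        return 0.0
    rows = _causal_pvalues(stats_df, truth)
    hit = rows["P"].to_numpy() < alpha_gw
    if window_bp is not None:
        sig = stats_df.loc[stats_df["P"] < alpha_gw]
        for k, (c, b) in enumerate(zip(truth.chrom, truth.pos)):
            if hit[k]:
                continue
            near = (sig["CHR"].to_numpy() == c) & (
                np.abs(sig["BP"].to_numpy() - b) <= window_bp
            )
            hit[k] = bool(near.any())
    return float(np.mean(hit))


def _exclusion_mask(stats_df, truth, exclusion_bp):
    """True for non-causal variants within ``exclusion_bp`` of a causal one
    on the same chromosome (both ends inclusive)."""
    chrom = stats_df["CHR"].to_numpy()
    bp = stats_df["BP"].to_numpy()
    excluded = np.zeros(len(stats_df), dtype=bool)
    for c in np.unique(truth.chrom):
        cpos = np.sort(truth.pos[truth.chrom == c])
        rows = chrom == c
        if not rows.any():
            continue
        j = np.searchsorted(cpos, bp[rows])
        left = np.where(j > 0, np.abs(bp[rows] - cpos[np.maximum(j - 1, 0)]), np.inf)
        right = np.where(
            j < len(cpos), np.abs(cpos[np.minimum(j, len(cpos) - 1)] - bp[rows]), np.inf
        )
        excluded[rows] = np.minimum(left, right) <= exclusion_bp
    return excluded


def roc_auc(
    stats_df: pd.DataFrame,
    truth: SimulationTruth,
    exclusion_bp: int = 1_000_000,
    grid_step: float = ROC_GRID_STEP,
):
    """ROC points and AUC for ranking causal vs null variants by P-value.

    Positives are the causal variants; negatives are the non-causal
    variants farther than ``exclusion_bp`` from every causal variant on
    the same chromosome.  Ties in P use the average-rank convention, so
    the AUC equals the trapezoidal area of the tie-grouped ROC curve.
    Returns ``(roc_points, auc)`` with ``roc_points`` a DataFrame of
    (specificity, sensitivity) on a specificity grid of width
    ``grid_step``.
    """
    is_causal = stats_df["SNP"].isin(truth.causal_ids).to_numpy()
    drop = _exclusion_mask(stats_df, truth, exclusion_bp) & ~is_causal
    usable = stats_df["P"].notna().to_numpy()
    n_na = int((~usable).sum())
    if n_na:
        logger.info("roc_auc: excluding %d not-available records", n_na)
    keep = usable & ~drop
    p = stats_df["P"].to_numpy()[keep]
    y = is_causal[keep]
    n_pos, n_neg = int(y.sum()), int((~y).sum())
    if n_neg == 0:
        raise ValueError("no negative variants remain after causal-region exclusion")
    if n_pos == 0:
        raise ValueError("no causal variants present")

    # midrank Mann-Whitney AUC on the -P ranking
    ranks = sps.rankdata(-p)
    auc = (ranks[y].sum() - n_pos * (n_pos + 1) / 2) / (n_pos * n_neg)

    # stepwise ROC over increasing P cutoffs, ties grouped
    order = np.argsort(p, kind="mergesort")
    ys = y[order]
    ps = p[order]
    tp = np.cumsum(ys)
    fp = np.cumsum(~ys)
    last_of_tie = np.r_[ps[1:] != ps[:-1], True]
    tpr = tp[last_of_tie] / n_pos
    fpr = fp[last_of_tie] / n_neg

    spec_grid = np.arange(0.0, 1.0 + grid_step / 2, grid_step)
    fpr_grid = 1.0 - spec_grid
    # sensitivity at specificity s: largest tpr with fpr <= 1 - s
    idx = np.searchsorted(fpr, fpr_grid, side="right") - 1
    sens = np.where(idx >= 0, tpr[np.maximum(idx, 0)], 0.0)
    roc_points = pd.DataFrame({"specificity": spec_grid, "sensitivity": sens})
    return roc_points, float(auc)


def sensitivity_difference(
    stats_a: pd.DataFrame,
    stats_b: pd.DataFrame,
    truth: SimulationTruth,
    exclusion_bp: int = 1_000_000,
    grid_step: float = ROC_GRID_STEP,
) -> pd.DataFrame:
    """Sensitivity(a) - sensitivity(b) on the shared specificity grid."""
    pa, _ = roc_auc(stats_a, truth, exclusion_bp, grid_step)
    pb, _ = roc_auc(stats_b, truth, exclusion_bp, grid_step)
    return pd.DataFrame(
        {
            "specificity": pa["specificity"],
            "delta_sensitivity": pa["sensitivity"] - pb["sensitivity"],
        }
    )


def medse(stats_df: pd.DataFrame, truth: SimulationTruth) -> float:
    """Median squared error of standardized effect estimates at causal variants.

    Allelic estimates are rescaled by sqrt(2 p (1 - p)) using the reported
    frequency of the truth's effect allele, with the sign aligned when the
    statistics report the other allele as the effect allele.
    """
    rows = _causal_pvalues(stats_df, truth)
    beta = rows["BETA"].to_numpy(dtype=float)
    freq = rows["FREQ"].to_numpy(dtype=float)
    same = rows["A1"].to_numpy(dtype=object) == truth.effect_allele
    beta = np.where(same, beta, -beta)
    p_eff = np.where(same, freq, 1.0 - freq)
    if np.any((p_eff <= 0) | (p_eff >= 1)):
        raise ValueError("causal variant with allele frequency 0 or 1")
    beta_std_hat = beta * np.sqrt(2.0 * p_eff * (1.0 - p_eff))
    return float(np.median((beta_std_hat - truth.beta_std) ** 2))


def false_positive_rate(
    stats_df: pd.DataFrame, null_variant_ids, alpha: float
) -> float:
    """Fraction of the null variant set with P below ``alpha``."""
    null_ids = np.asarray(null_variant_ids, dtype=object)
    if len(null_ids) == 0:
        raise ValueError("empty null variant set")
    sub = stats_df.loc[stats_df["SNP"].isin(null_ids)]
    p = sub["P"].to_numpy(dtype=float)
    ok = np.isfinite(p)
    n_na = int((~ok).sum())
    if n_na:
        logger.info("false_positive_rate: excluding %d not-available records", n_na)
    if not ok.any():
        raise ValueError("null variant set has no usable records")
    return float(np.mean(p[ok] < alpha))


def independent_loci(
    stats_df: pd.DataFrame,
    G_ref: GenotypeMatrix,
    p_threshold: float = 5e-9,
    window_bp: int = 5_000_000,
    r2: float = 0.01,
) -> int:
    """Count of independent significant loci by strict clumping."""
    return len(clump(stats_df, G_ref, p_threshold, r2, window_bp))


@dataclass
class EvalReport:
    """Flat bundle of evaluation metrics for one statistics set."""

    power: float
    auc: float
    medse: float
    fpr: dict = field(default_factory=dict)  # alpha -> rate
    n_independent_loci: int | None = None
    roc_points: pd.DataFrame | None = None

    def to_row(self) -> pd.Series:
        row = {"power": self.power, "auc": self.auc, "medse": self.medse}
        for alpha, rate in self.fpr.items():
            row[f"fpr_{alpha:g}"] = rate
        if self.n_independent_loci is not None:
            row["n_independent_loci"] = self.n_independent_loci
        return pd.Series(row)


def evaluate(
    stats_df: pd.DataFrame,
    truth: SimulationTruth,
    null_variant_ids=None,
    alpha_gw: float = ALPHA_GENOME_WIDE,
    fpr_alphas: tuple = (5e-5, 5e-8),
    G_ref: GenotypeMatrix | None = None,
    exclusion_bp: int = 1_000_000,
) -> EvalReport:
    """Assemble the full evaluation report for one statistics set.

    ``null_variant_ids`` defaults to the non-causal variants outside the
    ROC exclusion zone; pass an explicit set (e.g. odd-chromosome ids from
    the null design) to reproduce the calibration analysis.
    """
    roc_points, auc = roc_auc(stats_df, truth, exclusion_bp)
    if null_variant_ids is None:
        is_causal = stats_df["SNP"].isin(truth.causal_ids).to_numpy()
        drop = _exclusion_mask(stats_df, truth, exclusion_bp)
        null_variant_ids = stats_df["SNP"].to_numpy()[~is_causal & ~drop]
    fpr = {a: false_positive_rate(stats_df, null_variant_ids, a) for a in fpr_alphas}
    n_loci = independent_loci(stats_df, G_ref) if G_ref is not None else None
    return EvalReport(
        power=power(stats_df, truth, alpha_gw),
        auc=auc,
        medse=medse(stats_df, truth),
        fpr=fpr,
        n_independent_loci=n_loci,
        roc_points=roc_points,
    )
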