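"""Covariate-adjusted single-variant association scans.

The scan is an ordinary fixed-effects linear model, fitted per variant:

    trait = intercept + covariates + beta * dosage + error

valid for the unrelated-sample setting the simulator produces.  Rather
than solving one least-squares problem per variant, the trait and the
dosage columns are residualized once against the covariate design (an
orthonormal basis obtained by sequential Gram-Schmidt) and the per-variant
coefficient, its standard error and a two-sided t-test P-value follow from
vectorized cross-products — the Frisch-Waugh-Lovell identity guarantees
this equals the full joint fit.  Binary traits are fitted with the same
linear model on the 0/1 labels.

The leave-one-chromosome-out variant of the scan appends the matching
per-chromosome polygenic score as one extra fixed-effect column and spends
one extra residual degree of freedom on it.
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .genotypes import GenotypeMatrix
from .phenosim import PhenotypeTable

logger = logging.getLogger(__name__)

#: residual-variance threshold below which a covariate column is collinear
COLLINEAR_TOL = 1e-12

SUMSTAT_COLUMNS = ["SNP", "CHR", "BP", "A1", "A2", "FREQ", "N", "BETA", "SE", "P"]

_SCAN_CHUNK = 2048  # variants residualized per block, bounds peak memory


def _orthonormal_basis(columns, names, n):
    """Sequential Gram-Schmidt; returns (Q, kept_names, dropped_names).

    A column whose residual variance after projection on the previously
    kept columns falls below :data:`COLLINEAR_TOL` is dropped.
    """
    kept, dropped, qs = [], [], []
    for vec, name in zip(columns, names):
        v = np.asarray(vec, dtype=float).copy()
        for q in qs:
            v -= (q @ v) * q
        if v @ v / n < COLLINEAR_TOL:
            dropped.append(name)
            continue
        qs.append(v / np.linalg.norm(v))
        kept.append(name)
    Q = np.column_stack(qs) if qs else np.empty((n, 0))
    return Q, kept, dropped


def design_basis(
    covariates: pd.DataFrame | None,
    n: int,
    extra: dict[str, np.ndarray] | None = None,
    on_collinear: str = "drop",
):
    """Orthonormal basis of the fixed-effect design (intercept always first).

    ``on_collinear`` is ``"drop"`` (log a warning and continue) or
    ``"raise"`` (error naming the collinear columns).
    """
    cols = [np.ones(n)]
    names = ["intercept"]
    if covariates is not None and len(covariates.columns):
        if len(covariates) != n:
            raise ValueError("covariate rows do not match the sample count")
        expanded = pd.get_dummies(covariates, dtype=float)  # one-hot categoricals
        for c in expanded.columns:
            cols.append(expanded[c].to_numpy(dtype=float))
            names.append(str(c))
    if extra:
        for name, vec in extra.items():
            vec = np.asarray(vec, dtype=float)
            if len(vec) != n:
                raise ValueError(f"extra covariate {name!r} has wrong length")
            cols.append(vec)
            names.append(name)
    Q, kept, dropped = _orthonormal_basis(cols, names, n)
    if dropped:
        if on_collinear == "raise":
            raise ValueError(f"collinear covariate columns: {dropped}")
        logger.warning("dropping collinear covariate columns: %s", dropped)
    return Q, kept, dropped


def residualize(M: np.ndarray, covariates: pd.DataFrame) -> np.ndarray:
    """Project the columns of ``M`` off the covariate space (with intercept).

    Returns ``M - C (C'C)^-1 C' M``; raises on a rank-deficient design,
    naming the collinear columns.
    """
    M = np.atleast_2d(np.asarray(M, dtype=float))
    if M.shape[0] == 1 and M.size > 1:
        M = M.T
    n = M.shape[0]
    Q, _, _ = design_basis(covariates, n, on_collinear="raise")
    return M - Q @ (Q.T @ M)


def _scan_block(Xr, yr, syy, df):
    """Per-variant slope, SE and P from residualized dosages ``Xr``."""
    sxx = np.einsum("ij,ij->j", Xr, Xr)
    sxy = Xr.T @ yr
    ok = sxx > 1e-10
    beta = np.full(sxx.shape, np.nan)
    se = np.full(sxx.shape, np.nan)
    pval = np.full(sxx.shape, np.nan)
    beta[ok] = sxy[ok] / sxx[ok]
    rss = np.maximum(syy - np.where(ok, sxy**2 / np.where(ok, sxx, 1.0), 0.0), 0.0)
    sigma2 = rss / df
    se[ok] = np.sqrt(sigma2[ok] / sxx[ok])
    with np.errstate(invalid="ignore", divide="ignore"):
        tstat = beta / se
    pval[ok] = 2.0 * stats.t.sf(np.abs(tstat[ok]), df)
    return beta, se, pval


def _scan_columns(G, cols, y, Q, rank):
    n = G.n_samples
    yr = y - Q @ (Q.T @ y)
    syy = yr @ yr
    df = n - rank - 1
    if df <= 0:
        raise ValueError(f"non-positive residual degrees of freedom ({df})")
    betas, ses, ps = [], [], []
    for start in range(0, len(cols), _SCAN_CHUNK):
        block = cols[start : start + _SCAN_CHUNK]
        X = G.imputed(block)
        Xr = X - Q @ (Q.T @ X)
        b, s, p = _scan_block(Xr, yr, syy, df)
        betas.append(b)
        ses.append(s)
        ps.append(p)
    return np.concatenate(betas), np.concatenate(ses), np.concatenate(ps)


def _records(G, cols, beta, se, pval):
    v = G.variants.iloc[cols]
    return pd.DataFrame(
        {
            "SNP": v["id"].to_numpy(),
            "CHR": v["chrom"].to_numpy(),
            "BP": v["pos"].to_numpy(),
            "A1": v["a1"].to_numpy(),
            "A2": v["a2"].to_numpy(),
            "FREQ": v["freq_a1"].to_numpy(dtype=float),
            "N": G.n_samples,
            "BETA": beta,
            "SE": se,
            "P": pval,
        }
    )


def _check_alignment(G: GenotypeMatrix, pheno: PhenotypeTable) -> PhenotypeTable:
    if np.array_equal(pheno.sample_ids, G.sample_ids):
        return pheno
    return pheno.aligned_to(G.sample_ids)


def gwas_scan(
    G: GenotypeMatrix,
    pheno: PhenotypeTable,
    covariates: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Stage-1 association scan over every variant of ``G``.

    ``covariates`` defaults to ``pheno.covariates``; pass an empty frame
    for an intercept-only model.  Monomorphic variants (zero dosage
    variance after imputation) yield NaN BETA/SE/P records rather than
    being dropped.  Returns a summary-statistic frame with columns
    ``SNP CHR BP A1 A2 FREQ N BETA SE P``.
    """
    pheno = _check_alignment(G, pheno)
    if covariates is None:
        covariates = pheno.covariates
    n = G.n_samples
    Q, kept, _ = design_basis(covariates, n)
    cols = np.arange(G.n_variants)
    beta, se, pval = _scan_columns(G, cols, pheno.trait, Q, len(kept))
    return _records(G, cols, beta, se, pval)


def gwas_scan_loco(
    G: GenotypeMatrix,
    pheno: PhenotypeTable,
    scores,
    covariates: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Stage-2 scan with the matching LOCO polygenic score as a covariate.

    For each chromosome c the column ``scores[:, c]`` is appended to the
    covariate design before fitting the chromosome-c variants, reducing
    the residual degrees of freedom by one (unless the column is constant,
    in which case it is dropped as collinear and the fit coincides with
    :func:`gwas_scan`).  ``scores`` is a :class:`~locopgs.pgs.LocoScoreSet`.
    """
    pheno = _check_alignment(G, pheno)
    if covariates is None:
        covariates = pheno.covariates
    n = G.n_samples
    chrom = np.asarray(G.variants["chrom"])
    frames = []
    for c in G.chromosomes:
        score_col = scores.column(c)  # raises on a missing chromosome
        Q, kept, _ = design_basis(
            covariates, n, extra={f"PGS_LOCO_{c}": score_col}
        )
        cols = np.flatnonzero(chrom == c)
        beta, se, pval = _scan_columns(G, cols, pheno.trait, Q, len(kept))
        frames.append(_records(G, cols, beta, se, pval))
    out = pd.concat(frames, ignore_index=True)
    # restore the input variant order
    order = pd.Series(np.arange(G.n_variants), index=G.variants["id"])
    return out.iloc[np.argsort(order[out["SNP"]].to_numpy())].reset_index(drop=True)


# ----------------------------------------------------------------------
# summary-statistic file dialect (SNP CHR BP A1 A2 FREQ N BETA SE P)
# ----------------------------------------------------------------------
def write_sumstats(stats_df: pd.DataFrame, path: str | Path) -> None:
    out = stats_df.copy()
    out["P"] = [f"{p:.6e}" if np.isfinite(p) else "NA" for p in out["P"]]
    out.to_csv(path, sep="\t", index=False, na_rep="NA")


def read_sumstats(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"SNP": str, "A1": str, "A2": str},
                     na_values=["NA"])
    missing = set(SUMSTAT_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"summary-statistic file missing columns {sorted(missing)}")
    return df
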