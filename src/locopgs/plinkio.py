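"""PLINK 1 binary fileset (bed/bim/fam) reader and writer.

The .bed file is written in SNP-major mode with the standard 3-byte magic
header (0x6c 0x1b 0x01).  Each variant occupies ceil(n/4) bytes; within a
byte the lowest-order two bits encode the first sample.  The 2-bit codes
follow the published encoding, interpreted against the .bim alleles:

====  =============================  ===================
code  genotype                       a1 dosage stored
====  =============================  ===================
0b00  homozygous A1                  2
0b01  missing                        MISSING
0b10  heterozygous                   1
0b11  homozygous A2                  0
====  =============================  ===================

Round trips through :func:`write_plink` / :func:`read_plink` are bit-exact
for dosages (including missing calls), variant metadata and sample IDs.
"""

from __future__ import annotations

import os
from pathlib import Path

import numpy as np
import pandas as pd

from .genotypes import MISSING, GenotypeMatrix

_MAGIC = bytes([0x6C, 0x1B, 0x01])

# dosage value (indexed as dosage + 1, i.e. [-1, 0, 1, 2]) -> 2-bit code
_DOSAGE_TO_CODE = np.array([0b01, 0b11, 0b10, 0b00], dtype=np.uint8)
# 2-bit code -> dosage value
_CODE_TO_DOSAGE = np.array([2, MISSING, 1, 0], dtype=np.int8)


def write_plink(G: GenotypeMatrix, prefix: str | os.PathLike) -> None:
    """Write ``prefix``.bed/.bim/.fam for a genotype matrix."""
    prefix = Path(prefix)
    prefix.parent.mkdir(parents=True, exist_ok=True)
    n, m = G.n_samples, G.n_variants

    codes = _DOSAGE_TO_CODE[G.dosages.T.astype(np.int16) + 1]  # (m, n)
    n_pad = -n % 4
    if n_pad:
        pad = np.zeros((m, n_pad), dtype=np.uint8)  # zero bits beyond n are ignored
        codes = np.concatenate([codes, pad], axis=1)
    codes = codes.reshape(m, -1, 4)
    weights = np.array([1, 4, 16, 64], dtype=np.uint8)
    payload = (codes * weights).sum(axis=2, dtype=np.uint16).astype(np.uint8)

    with open(prefix.with_suffix(".bed"), "wb") as fh:
        fh.write(_MAGIC)
        fh.write(payload.tobytes())

    v = G.variants
    bim = pd.DataFrame(
        {
            "chrom": v["chrom"],
            "id": v["id"],
            "cm": 0,
            "pos": v["pos"],
            "a1": v["a1"],
            "a2": v["a2"],
        }
    )
    bim.to_csv(prefix.with_suffix(".bim"), sep="\t", header=False, index=False)

    fam = pd.DataFrame(
        {
            "fid": G.sample_ids,
            "iid": G.sample_ids,
            "pid": 0,
            "mid": 0,
            "sex": 0,
            "pheno": -9,
        }
    )
    fam.to_csv(prefix.with_suffix(".fam"), sep="\t", header=False, index=False)


def read_plink(prefix: str | os.PathLike) -> GenotypeMatrix:
    """Read a ``prefix``.bed/.bim/.fam triple into a :class:`GenotypeMatrix`.

    Raises
    ------
    ValueError
        On a magic-number mismatch or when the bed payload size is
        inconsistent with the bim/fam dimensions.
    """
    prefix = Path(prefix)
    bim = pd.read_csv(
        prefix.with_suffix(".bim"),
        sep=r"\s+",
        header=None,
        names=["chrom", "id", "cm", "pos", "a1", "a2"],
        dtype={"id": str, "a1": str, "a2": str},
    )
    fam = pd.read_csv(
        prefix.with_suffix(".fam"),
        sep=r"\s+",
        header=None,
        names=["fid", "iid", "pid", "mid", "sex", "pheno"],
        dtype={"fid": str, "iid": str},
    )
    n, m = len(fam), len(bim)

    raw = np.fromfile(prefix.with_suffix(".bed"), dtype=np.uint8)
    if raw[:3].tobytes() != _MAGIC:
        raise ValueError(f"{prefix}.bed: bad magic number (not a PLINK 1 bed file)")
    bytes_per_variant = (n + 3) // 4
    payload = raw[3:]
    if payload.size != m * bytes_per_variant:
        raise ValueError(
            f"{prefix}.bed: payload of {payload.size} bytes inconsistent with "
            f"{m} variants x {n} samples ({m * bytes_per_variant} expected)"
        )

    payload = payload.reshape(m, bytes_per_variant)
    codes = np.empty((m, bytes_per_variant * 4), dtype=np.uint8)
    for k in range(4):
        codes[:, k::4] = (payload >> (2 * k)) & 0b11
    dosages = _CODE_TO_DOSAGE[codes[:, :n]].T  # (n, m)

    variants = bim[["id", "chrom", "pos", "a1", "a2"]].copy()
    return GenotypeMatrix(
        dosages=dosages,
        variants=variants,
        sample_ids=fam["iid"].to_numpy(dtype=object),
    )
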