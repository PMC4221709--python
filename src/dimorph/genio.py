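"""Genotype container and PLINK 1 binary (bed/bim/fam) input/output.

Dosages are stored as int8 counts of the A1 allele with ``MISSING`` (-1) as
the in-memory sentinel.  The on-disk format is the standard SNP-major bed
layout (magic 0x6c 0x1b 0x01, two bits per genotype, four samples per byte).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = ["GenotypeMatrix", "FormatError", "read_genotypes", "write_genotypes"]

_MAGIC = bytes([0x6C, 0x1B, 0x01])

# 2-bit bed codes -> dosage of A1: 00 hom A1 (2), 01 missing, 10 het, 11 hom A2
_CODE_TO_DOSAGE = np.array([2, -1, 1, 0], dtype=np.int8)
_DOSAGE_TO_CODE = {2: 0b00, -1: 0b01, 1: 0b10, 0: 0b11}


class FormatError(ValueError):
    """Malformed or mutually inconsistent genotype files."""


@dataclass
class GenotypeMatrix:
    """Individuals x SNPs dosage matrix with SNP map and sample metadata.

    Attributes
    ----------
    dosages : int8 array (n_samples, n_snps), entries in {0, 1, 2, MISSING}
    snps : DataFrame with columns chrom, snp, cm, bp, a1, a2
    samples : DataFrame with at least iid; optional sire, dam, sex, batch,
        generation
    """

    MISSING = np.int8(-1)

    dosages: np.ndarray
    snps: pd.DataFrame
    samples: pd.DataFrame

    def __post_init__(self) -> None:
        n, m = self.dosages.shape
        if len(self.samples) != n:
            raise FormatError(
                f"sample metadata has {len(self.samples)} rows, matrix has {n}"
            )
        if len(self.snps) != m:
            raise FormatError(f"SNP map has {len(self.snps)} rows, matrix has {m}")

    @property
    def n_samples(self) -> int:
        return self.dosages.shape[0]

    @property
    def n_snps(self) -> int:
        return self.dosages.shape[1]

    def is_missing(self) -> np.ndarray:
        return self.dosages == self.MISSING

    def call_rate_samples(self) -> np.ndarray:
        return 1.0 - self.is_missing().mean(axis=1)

    def call_rate_snps(self) -> np.ndarray:
        return 1.0 - self.is_missing().mean(axis=0)

    def autosomal_mask(self) -> np.ndarray:
        chrom = self.snps["chrom"].astype(str)
        return ~chrom.isin(["X", "Y", "XY", "MT"]).to_numpy()

    def subset(self, samples=None, snps=None) -> "GenotypeMatrix":
        """Row/column subset by boolean mask or integer index."""
        si = np.arange(self.n_samples) if samples is None else np.asarray(samples)
        vi = np.arange(self.n_snps) if snps is None else np.asarray(snps)
        if si.dtype == bool:
            si = np.flatnonzero(si)
        if vi.dtype == bool:
            vi = np.flatnonzero(vi)
        return GenotypeMatrix(
            dosages=self.dosages[np.ix_(si, vi)].copy(),
            snps=self.snps.iloc[vi].reset_index(drop=True),
            samples=self.samples.iloc[si].reset_index(drop=True),
        )

    def dosages_float(self) -> np.ndarray:
        """Dosages as float with NaN for missing."""
        d = self.dosages.astype(float)
        d[self.dosages == self.MISSING] = np.nan
        return d

    # -- PLINK binary ------------------------------------------------------

    def write_plink(self, prefix: str | Path) -> None:
        write_genotypes(self, prefix)

    @classmethod
    def read_plink(cls, prefix: str | Path) -> "GenotypeMatrix":
        return read_genotypes(prefix)


def _norm_chrom(c: str) -> str:
    c = str(c)
    return "X" if c in ("X", "23") else c


def write_genotypes(g: GenotypeMatrix, prefix: str | Path) -> None:
    """Write a bed/bim/fam triplet (variant-major bed v1.00)."""
    prefix = Path(prefix)
    n, m = g.dosages.shape

    samples = g.samples
    fam = pd.DataFrame(
        {
            "fid": samples.get("fid", pd.Series(["0"] * n)),
            "iid": samples["iid"],
            "sire": samples.get("sire", pd.Series([""] * n)).replace("", "0"),
            "dam": samples.get("dam", pd.Series([""] * n)).replace("", "0"),
            "sex": samples.get("sex", pd.Series(["0"] * n)).map(
                {"M": "1", "F": "2"}
            ).fillna("0"),
            "pheno": ["-9"] * n,
        }
    )
    fam.to_csv(prefix.with_suffix(".fam"), sep="\t", header=False, index=False)

    bim = pd.DataFrame(
        {
            "chrom": g.snps["chrom"].map(_norm_chrom),
            "snp": g.snps["snp"],
            "cm": g.snps["cm"],
            "bp": g.snps["bp"],
            "a1": g.snps["a1"],
            "a2": g.snps["a2"],
        }
    )
    bim.to_csv(prefix.with_suffix(".bim"), sep="\t", header=False, index=False)

    # pack 4 samples per byte, sample i in bits 2*(i mod 4)
    codes = np.empty((m, n), dtype=np.uint8)
    d = g.dosages.T  # SNP-major
    codes[d == 2] = 0b00
    codes[d == GenotypeMatrix.MISSING] = 0b01
    codes[d == 1] = 0b10
    codes[d == 0] = 0b11
    nbytes = (n + 3) // 4
    padded = np.zeros((m, nbytes * 4), dtype=np.uint8)
    padded[:, :n] = codes
    packed = (
        padded[:, 0::4]
        | (padded[:, 1::4] << 2)
        | (padded[:, 2::4] << 4)
        | (padded[:, 3::4] << 6)
    )
    with open(prefix.with_suffix(".bed"), "wb") as fh:
        fh.write(_MAGIC)
        fh.write(packed.tobytes())


def read_genotypes(prefix: str | Path) -> GenotypeMatrix:
    """Read a bed/bim/fam triplet; dosages are A1-allele counts.

    Raises FormatError naming the offending file for bad magic bytes,
    truncation, or bed/bim/fam dimension mismatch.
    """
    prefix = Path(prefix)
    bed, bim_p, fam_p = (prefix.with_suffix(s) for s in (".bed", ".bim", ".fam"))
    for p in (bed, bim_p, fam_p):
        if not p.exists():
            raise FormatError(f"{p}: file not found")

    fam = pd.read_csv(
        fam_p, sep=r"\s+", header=None,
        names=["fid", "iid", "sire", "dam", "sex", "pheno"], dtype=str,
    )
    bim = pd.read_csv(
        bim_p, sep=r"\s+", header=None,
        names=["chrom", "snp", "cm", "bp", "a1", "a2"],
        dtype={"chrom": str, "snp": str, "a1": str, "a2": str},
    )
    n, m = len(fam), len(bim)

    raw = bed.read_bytes()
    if raw[:3] != _MAGIC:
        raise FormatError(f"{bed}: bad magic bytes (not a SNP-major bed v1.00)")
    nbytes = (n + 3) // 4
    if len(raw) - 3 != m * nbytes:
        raise FormatError(
            f"{bed}: {len(raw) - 3} data bytes, expected {m * nbytes} "
            f"for {n} samples x {m} SNPs"
        )
    packed = np.frombuffer(raw, dtype=np.uint8, offset=3).reshape(m, nbytes)
    codes = np.empty((m, nbytes * 4), dtype=np.uint8)
    codes[:, 0::4] = packed & 0b11
    codes[:, 1::4] = (packed >> 2) & 0b11
    codes[:, 2::4] = (packed >> 4) & 0b11
    codes[:, 3::4] = (packed >> 6) & 0b11
    dosage = _CODE_TO_DOSAGE[codes[:, :n]].T.copy()

    samples = pd.DataFrame(
        {
            "fid": fam["fid"],
            "iid": fam["iid"],
            "sire": fam["sire"].replace("0", ""),
            "dam": fam["dam"].replace("0", ""),
            "sex": fam["sex"].map({"1": "M", "2": "F"}).fillna(""),
        }
    )
    snps = pd.DataFrame(
        {
            "chrom": bim["chrom"].map(_norm_chrom),
            "snp": bim["snp"],
            "cm": bim["cm"].astype(float),
            "bp": bim["bp"].astype(int),
            "a1": bim["a1"],
            "a2": bim["a2"],
        }
    )
    return GenotypeMatrix(dosages=dosage, snps=snps, samples=samples)
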