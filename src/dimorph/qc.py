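"""Sample- and SNP-level genotype quality control.

Filters follow the conventional pre-GWAS pipeline for chip data from an
experimental cross: per-sample call rate and Mendelian-inconsistency rate,
then per-SNP call rate, minor allele frequency, Hardy-Weinberg exact test
and Mendelian error rate.  All thresholds are strict inequalities (a value
equal to the threshold fails).  Samples are filtered first, SNPs second,
one pass each.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import gammaln

from .genio import GenotypeMatrix
from .simulate import Pedigree

__all__ = [
    "QCReport",
    "minor_allele_frequency",
    "hwe_exact_test",
    "mendel_error_rates",
    "sample_qc",
    "snp_qc",
]


class DegenerateOutputError(ValueError):
    """Nothing survives a filter — downstream analysis would be empty."""


class UndefinedInputError(ValueError):
    """Input carries no usable information (e.g. all genotypes missing)."""


@dataclass
class QCReport:
    """Thresholds used plus per-filter removal counts.

    ``n_snps_retained`` is the N_snp that parametrises the per-scan
    suggestive (1/N) and genome-wide (0.05/N) significance thresholds.
    """

    thresholds: dict = field(default_factory=dict)
    n_samples_in: int = 0
    n_samples_retained: int = 0
    n_snps_in: int = 0
    n_snps_retained: int = 0
    removed_samples: dict = field(default_factory=dict)
    removed_snps: dict = field(default_factory=dict)

    def to_frame(self) -> pd.DataFrame:
        rows = [("samples_in", self.n_samples_in),
                ("samples_retained", self.n_samples_retained)]
        rows += [(f"samples_removed[{k}]", v) for k, v in self.removed_samples.items()]
        rows += [("snps_in", self.n_snps_in),
                 ("snps_retained", self.n_snps_retained)]
        rows += [(f"snps_removed[{k}]", v) for k, v in self.removed_snps.items()]
        rows += [(f"threshold[{k}]", v) for k, v in self.thresholds.items()]
        return pd.DataFrame(rows, columns=["item", "value"])

    def write(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)


def minor_allele_frequency(dosages: np.ndarray) -> float:
    """MAF from a dosage column; missing entries (-1 or NaN) are ignored."""
    d = np.asarray(dosages, dtype=float)
    d = d[~np.isnan(d)]
    d = d[d >= 0]
    if d.size == 0:
        raise UndefinedInputError("all genotypes missing; MAF undefined")
    f = d.sum() / (2 * d.size)
    return float(min(f, 1.0 - f))


def _maf_per_snp(g: GenotypeMatrix) -> np.ndarray:
    d = g.dosages_float()
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        f = np.nanmean(d, axis=0) / 2.0
    return np.minimum(f, 1.0 - f)


def hwe_exact_test(n_AA: int, n_Aa: int, n_aa: int) -> float:
    """Exact conditional Hardy-Weinberg test (probability ordering).

    Conditions on the observed allele counts and sums the probabilities of
    all heterozygote counts (same parity) whose conditional probability does
    not exceed that of the observed count.  Returns a p-value in (0, 1].
    """
    if min(n_AA, n_Aa, n_aa) < 0:
        raise UndefinedInputError("negative genotype count")
    n = n_AA + n_Aa + n_aa
    if n == 0:
        raise UndefinedInputError("no genotyped individuals")
    n_rare = min(2 * n_AA + n_Aa, 2 * n_aa + n_Aa)
    hets = np.arange(n_rare % 2, n_rare + 1, 2)
    # P(h | allele counts) = n! 2^h / (n_r_hom! h! n_c_hom!) / C(2n, n_rare)
    rare_hom = (n_rare - hets) // 2
    common_hom = n - hets - rare_hom
    logp = (
        gammaln(n + 1)
        - gammaln(rare_hom + 1)
        - gammaln(hets + 1)
        - gammaln(common_hom + 1)
        + hets * np.log(2.0)
    )
    logp -= logp.max()
    prob = np.exp(logp)
    prob /= prob.sum()
    obs = prob[hets == n_Aa][0]
    p = prob[prob <= obs * (1.0 + 1e-12)].sum()
    return float(min(p, 1.0))


# allowed child dosage given (sire, dam) dosages under biallelic inheritance
_ALLOWED = np.zeros((3, 3, 3), dtype=bool)
for _s in range(3):
    for _d in range(3):
        for _gs in ({0} if _s == 0 else {1} if _s == 2 else {0, 1}):
            for _gd in ({0} if _d == 0 else {1} if _d == 2 else {0, 1}):
                _ALLOWED[_s, _d, _gs + _gd] = True


def mendel_error_rates(
    g: GenotypeMatrix, pedigree: Pedigree
) -> tuple[np.ndarray, np.ndarray]:
    """Per-SNP and per-sample Mendelian error rates over resolvable trios.

    An (offspring, SNP) call is an error iff the offspring dosage is
    impossible given both parents' non-missing dosages; rates divide errors
    by assessable calls (all three non-missing).  Individuals outside any
    trio contribute nothing and have rate 0.
    """
    ids = {iid: i for i, iid in enumerate(g.samples["iid"])}
    trios = []
    for _, row in pedigree.table.iterrows():
        if row["sire"] and row["dam"]:
            c, s, d = ids.get(row["id"]), ids.get(row["sire"]), ids.get(row["dam"])
            if c is not None and s is not None and d is not None:
                trios.append((c, s, d))
    n, m = g.dosages.shape
    snp_err = np.zeros(m)
    snp_tot = np.zeros(m)
    smp_err = np.zeros(n)
    smp_tot = np.zeros(n)
    if not trios:
        warnings.warn("no resolvable trios; Mendelian error rates are all 0")
        return snp_err, smp_err
    D = g.dosages
    for c, s, d in trios:
        ok = (D[c] >= 0) & (D[s] >= 0) & (D[d] >= 0)
        err = np.zeros(m, dtype=bool)
        err[ok] = ~_ALLOWED[D[s][ok], D[d][ok], D[c][ok]]
        snp_err += err
        snp_tot += ok
        smp_err[c] = err.sum()
        smp_tot[c] = ok.sum()
    with np.errstate(invalid="ignore", divide="ignore"):
        snp_rate = np.where(snp_tot > 0, snp_err / np.maximum(snp_tot, 1), 0.0)
        smp_rate = np.where(smp_tot > 0, smp_err / np.maximum(smp_tot, 1), 0.0)
    return snp_rate, smp_rate


def sample_qc(
    g: GenotypeMatrix,
    pedigree: Pedigree | None = None,
    call_rate_min: float = 0.10,
    mendel_rate_max: float = 0.05,
) -> tuple[GenotypeMatrix, QCReport]:
    """Drop samples with call rate <= call_rate_min or Mendelian
    inconsistency rate >= mendel_rate_max (keep is strict on both sides)."""
    _check_fraction(call_rate_min=call_rate_min, mendel_rate_max=mendel_rate_max)
    cr = g.call_rate_samples()
    keep = cr > call_rate_min
    removed = {"call_rate": int((~keep).sum())}
    if pedigree is not None:
        _, smp_rate = mendel_error_rates(g, pedigree)
        mkeep = smp_rate < mendel_rate_max
        removed["mendel_rate"] = int((keep & ~mkeep).sum())
        keep &= mkeep
    if not keep.any():
        raise DegenerateOutputError("sample QC removed every sample")
    out = g.subset(samples=keep)
    report = QCReport(
        thresholds={
            "sample_call_rate_min": call_rate_min,
            "sample_mendel_rate_max": mendel_rate_max,
        },
        n_samples_in=g.n_samples,
        n_samples_retained=out.n_samples,
        n_snps_in=g.n_snps,
        n_snps_retained=g.n_snps,
        removed_samples=removed,
    )
    return out, report


def snp_qc(
    g: GenotypeMatrix,
    pedigree: Pedigree | None = None,
    call_rate_min: float = 0.9,
    maf_min: float = 0.05,
    hwe_p_min: float = 1e-6,
    mendel_rate_max: float = 0.1,
) -> tuple[GenotypeMatrix, QCReport]:
    """Keep SNPs passing all four filters simultaneously.

    Filters (all strict): call rate > call_rate_min, MAF > maf_min, HWE
    exact p > hwe_p_min, Mendelian error rate < mendel_rate_max.  The HWE
    test uses F2 individuals when the pedigree identifies them (founder and
    F1 genotype frequencies are not expected to be in equilibrium),
    otherwise all samples.
    """
    _check_fraction(
        call_rate_min=call_rate_min, maf_min=maf_min,
        hwe_p_min=hwe_p_min, mendel_rate_max=mendel_rate_max,
    )
    cr = g.call_rate_snps()
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        maf = _maf_per_snp(g)
    maf = np.nan_to_num(maf, nan=0.0)

    if pedigree is not None and "generation" in g.samples.columns:
        hwe_rows = (g.samples["generation"] == "F2").to_numpy()
        if not hwe_rows.any():
            hwe_rows = np.ones(g.n_samples, dtype=bool)
    else:
        hwe_rows = np.ones(g.n_samples, dtype=bool)
    D = g.dosages[hwe_rows]
    n_aa = (D == 0).sum(axis=0)
    n_het = (D == 1).sum(axis=0)
    n_AA = (D == 2).sum(axis=0)
    hwe_p = np.ones(g.n_snps)
    for j in range(g.n_snps):
        tot = n_AA[j] + n_het[j] + n_aa[j]
        hwe_p[j] = hwe_exact_test(n_AA[j], n_het[j], n_aa[j]) if tot else 1.0

    if pedigree is not None:
        mendel_rate, _ = mendel_error_rates(g, pedigree)
    else:
        mendel_rate = np.zeros(g.n_snps)

    pass_cr = cr > call_rate_min
    pass_maf = maf > maf_min
    pass_hwe = hwe_p > hwe_p_min
    pass_mendel = mendel_rate < mendel_rate_max
    keep = pass_cr & pass_maf & pass_hwe & pass_mendel
    if not keep.any():
        raise DegenerateOutputError("SNP QC removed every SNP")
    out = g.subset(snps=keep)
    report = QCReport(
        thresholds={
            "snp_call_rate_min": call_rate_min,
            "maf_min": maf_min,
            "hwe_p_min": hwe_p_min,
            "snp_mendel_rate_max": mendel_rate_max,
        },
        n_samples_in=g.n_samples,
        n_samples_retained=g.n_samples,
        n_snps_in=g.n_snps,
        n_snps_retained=out.n_snps,
        removed_snps={
            "call_rate": int((~pass_cr).sum()),
            "maf": int((pass_cr & ~pass_maf).sum()),
            "hwe": int((pass_cr & pass_maf & ~pass_hwe).sum()),
            "mendel_rate": int((pass_cr & pass_maf & pass_hwe & ~pass_mendel).sum()),
        },
    )
    return out, report


def _check_fraction(**kwargs: float) -> None:
    for name, v in kwargs.items():
        if not 0.0 <= v <= 1.0:
            raise ValueError(f"{name}={v} outside [0,1]")
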