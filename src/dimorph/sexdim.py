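"""Sex-stratified scans and sexual-dimorphism statistics.

Given a genotyped cohort with trait, sex and batch information, this module
runs the combined and per-sex kinship-corrected scans, tests each SNP for a
sex-differential allelic effect with the two-stratum z-statistic

    Z = (beta_male - beta_female) / sqrt(se_male^2 + se_female^2),

tests per-trait heritability differences between the sexes with a
label-permutation test, and accounts for the overlap between stratified and
combined scan signals.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .genio import GenotypeMatrix
from .mixedmodel import (
    AssocResult,
    KinshipMatrix,
    PolygenicModel,
    PolygenicResults,
    reml_h2,
)

__all__ = [
    "significance_thresholds",
    "design_matrix",
    "stratified_scans",
    "StratifiedScans",
    "z_dimorphism",
    "SexDimResult",
    "heritability_permutation_test",
    "HeritabilityComparison",
    "compare_scans",
    "ScanComparison",
    "zdist_shift_test",
]

MIN_STRATUM_N = 30


def significance_thresholds(n_snp: int) -> tuple[float, float]:
    """Per-scan (suggestive, genome-wide) p-value thresholds: 1/N and 0.05/N.

    The suggestive level allows one false positive per genome scan; the
    genome-wide level is the Bonferroni 5% bound.
    """
    if n_snp < 1:
        raise ValueError("n_snp must be >= 1")
    return 1.0 / n_snp, 0.05 / n_snp


def design_matrix(
    batch=None, sex=None, intercept: bool = True
) -> np.ndarray:
    """Fixed-effect design: intercept, optional male indicator, batch
    indicators (first level as reference, levels taken from the data)."""
    cols = []
    n = None
    if sex is not None:
        sex = pd.Series(sex).astype(str).to_numpy()
        n = sex.size
    if batch is not None:
        batch = pd.Series(batch).to_numpy()
        n = batch.size
    if n is None:
        raise ValueError("need batch and/or sex")
    if intercept:
        cols.append(np.ones(n))
    if sex is not None:
        cols.append((sex == "M").astype(float))
    if batch is not None:
        levels = pd.unique(batch)
        for lev in levels[1:]:
            cols.append((batch == lev).astype(float))
    return np.column_stack(cols)


@dataclass
class StratifiedScans:
    male: AssocResult | None
    female: AssocResult | None
    combined: AssocResult | None
    fits: dict = field(default_factory=dict)  # stratum -> PolygenicResults
    skipped: dict = field(default_factory=dict)  # stratum -> reason


def _scan_one(g, y, X, K_sub, ids) -> tuple[PolygenicResults, AssocResult]:
    fit = PolygenicModel(y, X, K_sub, ids=ids).fit()
    return fit, fit.score_scan(g)


def stratified_scans(
    g: GenotypeMatrix,
    y,
    sex,
    batch,
    K: KinshipMatrix,
    min_n: int = MIN_STRATUM_N,
) -> StratifiedScans:
    """Male-only, female-only and combined kinship-corrected scans.

    Stratified scans fit batch as the fixed effect with the kinship matrix
    restricted to the stratum's rows and columns; the combined scan fits
    sex plus batch with the full matrix.  Rows with missing trait values
    are dropped scan-wise.  A stratum below ``min_n`` is skipped with a
    reason; the other scans are still produced.
    """
    y = np.asarray(y, dtype=float)
    sex = pd.Series(sex).astype(str).to_numpy()
    batch = pd.Series(batch).to_numpy()
    ids = np.asarray(g.samples["iid"])
    ok = ~np.isnan(y)

    out = StratifiedScans(None, None, None)
    for label, mask in (("male", ok & (sex == "M")), ("female", ok & (sex == "F"))):
        n = int(mask.sum())
        if n < min_n:
            out.skipped[label] = f"stratum n={n} < {min_n}"
            continue
        sub_ids = list(ids[mask])
        X = design_matrix(batch=batch[mask])
        fit, scan = _scan_one(
            g.subset(samples=mask), y[mask], X, K.submatrix(sub_ids), sub_ids
        )
        out.fits[label] = fit
        setattr(out, label, scan)

    n_all = int(ok.sum())
    if n_all < min_n:
        out.skipped["combined"] = f"combined n={n_all} < {min_n}"
    else:
        sub_ids = list(ids[ok])
        X = design_matrix(batch=batch[ok], sex=sex[ok])
        fit, scan = _scan_one(
            g.subset(samples=ok), y[ok], X, K.submatrix(sub_ids), sub_ids
        )
        out.fits["combined"] = fit
        out.combined = scan
    return out


@dataclass
class SexDimResult:
    """Per-SNP sex-dimorphism z-test table.

    Columns: chrom, snp, bp, beta_m, se_m, beta_f, se_f, maf_m, maf_f, z,
    p_z, tested, reason.  Z is male minus female over the pooled standard
    error; under equal allelic effects it is standard normal.
    """

    table: pd.DataFrame
    maf_min: float = 0.05
    one_sided: str | None = None

    def significant(self, threshold: float) -> pd.DataFrame:
        t = self.table
        return t[t["tested"] & (t["p_z"] < threshold)]

    def write(self, path) -> None:
        out = self.table.rename(
            columns={
                "chrom": "CHR", "snp": "SNP", "bp": "BP",
                "beta_m": "BETA_M", "se_m": "SE_M",
                "beta_f": "BETA_F", "se_f": "SE_F",
                "maf_m": "MAF_M", "maf_f": "MAF_F",
                "z": "Z", "p_z": "P_Z", "tested": "TESTED", "reason": "REASON",
            }
        )
        out.to_csv(path, sep="\t", index=False)


def z_dimorphism(
    male: AssocResult,
    female: AssocResult,
    maf_min: float = 0.05,
    one_sided: str | None = None,
) -> SexDimResult:
    """z-test for sex-differential SNP effects from the two stratified scans.

    Z = (beta_m - beta_f) / sqrt(se_m^2 + se_f^2); under the null of equal
    effects Z ~ N(0,1).  SNPs with MAF below ``maf_min`` in either sex, or
    untested in either stratum, are flagged untested (low-MAF strata give
    unstable effect estimates).  ``one_sided`` in {'male', 'female'} tests
    for a larger effect in that sex; default is two-sided.
    """
    if one_sided not in (None, "male", "female"):
        raise ValueError("one_sided must be None, 'male' or 'female'")
    m = male.table.set_index("snp")
    f = female.table.set_index("snp")
    common = m.index.intersection(f.index)
    if len(common) == 0:
        raise ValueError("no shared SNPs between the stratified scans")
    m, f = m.loc[common], f.loc[common]

    var = m["se"] ** 2 + f["se"] ** 2
    tested = (
        m["tested"].to_numpy()
        & f["tested"].to_numpy()
        & (m["maf"].to_numpy() >= maf_min)
        & (f["maf"].to_numpy() >= maf_min)
        & (var.to_numpy() > 0)
    )
    z = np.full(len(common), np.nan)
    z[tested] = ((m["beta"] - f["beta"]) / np.sqrt(var)).to_numpy()[tested]
    if one_sided is None:
        p = 2.0 * stats.norm.sf(np.abs(z))
    elif one_sided == "male":
        p = stats.norm.sf(z)
    else:
        p = stats.norm.cdf(z)

    reason = np.where(tested, "", "")
    reason = np.where(~m["tested"].to_numpy() | ~f["tested"].to_numpy(),
                      "untested_stratum", reason)
    low = ((m["maf"].to_numpy() < maf_min) | (f["maf"].to_numpy() < maf_min))
    reason = np.where(
        m["tested"].to_numpy() & f["tested"].to_numpy() & low, "low_maf", reason
    )

    table = pd.DataFrame(
        {
            "chrom": m["chrom"].to_numpy(),
            "snp": common.to_numpy(),
            "bp": m["bp"].to_numpy(),
            "beta_m": m["beta"].to_numpy(),
            "se_m": m["se"].to_numpy(),
            "beta_f": f["beta"].to_numpy(),
            "se_f": f["se"].to_numpy(),
            "maf_m": m["maf"].to_numpy(),
            "maf_f": f["maf"].to_numpy(),
            "z": z,
            "p_z": np.where(tested, p, np.nan),
            "tested": tested,
            "reason": reason,
        }
    )
    return SexDimResult(table, maf_min=maf_min, one_sided=one_sided)


@dataclass
class HeritabilityComparison:
    trait: str
    h2_male: float
    h2_female: float
    observed: float  # |h2_male - h2_female|
    B: int
    pvalue: float
    null_values: np.ndarray | None = None


def _stratum_h2_batch(Kv, X_full, Y, mask, n_grid) -> np.ndarray:
    """h2 for every trait column of Y within one stratum, sharing one
    eigendecomposition of the stratum kinship."""
    Ks = Kv[np.ix_(mask, mask)]
    s, U = np.linalg.eigh(Ks)
    s = np.maximum(s, 0.0)
    X = X_full[mask]
    # drop all-zero batch columns and re-check rank within the stratum
    keep = (np.abs(X).sum(axis=0) > 0)
    X = X[:, keep]
    Xt = U.T @ X
    Yt = U.T @ Y[mask]
    return np.array(
        [reml_h2(s, Xt, Yt[:, t], n_grid=n_grid) for t in range(Yt.shape[1])]
    )


def heritability_permutation_test(
    y,
    sex,
    batch,
    K: KinshipMatrix,
    B: int = 1000,
    seed: int = 0,
    n_grid: int = 30,
    keep_null: bool = False,
    trait_names: list[str] | None = None,
):
    """Permutation test for a sex difference in heritability.

    The observed statistic is |h2_male - h2_female| from per-stratum REML
    fits (batch as fixed effect, kinship restricted to the stratum).  Sex
    labels are shuffled ``B`` times (stratum sizes preserved) and the
    statistic recomputed each time; p = (1 + #{null >= observed}) / (1 + B).

    ``y`` may be a vector or an (n, traits) matrix / DataFrame: with a
    matrix, every trait shares the same permutation set and per-permutation
    eigendecompositions, the natural batching when testing a trait panel.
    Returns a single `HeritabilityComparison` for vector input, else a
    list.  Aborts if more than 5% of permutation fits fail.
    """
    single = False
    if isinstance(y, pd.DataFrame):
        if trait_names is None:
            trait_names = list(y.columns)
        Y = y.to_numpy(dtype=float)
    else:
        Y = np.asarray(y, dtype=float)
        if Y.ndim == 1:
            Y = Y[:, None]
            single = True
    n, T = Y.shape
    if trait_names is None:
        trait_names = [f"trait{t+1}" for t in range(T)]
    if np.isnan(Y).any():
        raise ValueError("trait matrix contains missing values; drop rows first")
    sex = pd.Series(sex).astype(str).to_numpy()
    male = sex == "M"
    if male.sum() < MIN_STRATUM_N or (~male).sum() < MIN_STRATUM_N:
        raise ValueError(f"each sex needs >= {MIN_STRATUM_N} individuals")
    X_full = design_matrix(batch=batch)
    Kv = K.values
    if Kv.shape[0] != n:
        raise ValueError("kinship not aligned with traits")

    h2_m = _stratum_h2_batch(Kv, X_full, Y, male, n_grid)
    h2_f = _stratum_h2_batch(Kv, X_full, Y, ~male, n_grid)
    observed = np.abs(h2_m - h2_f)

    rng = np.random.default_rng(seed)
    null = np.empty((B, T))
    failures = 0
    for b in range(B):
        perm = rng.permutation(male)
        try:
            pm = _stratum_h2_batch(Kv, X_full, Y, perm, n_grid)
            pf = _stratum_h2_batch(Kv, X_full, Y, ~perm, n_grid)
            null[b] = np.abs(pm - pf)
        except np.linalg.LinAlgError:
            null[b] = np.nan
            failures += 1
    if failures > 0.05 * B:
        raise RuntimeError(
            f"{failures}/{B} permutation fits failed; permutation "
            "distribution unreliable"
        )
    valid = ~np.isnan(null).any(axis=1)
    nB = int(valid.sum())
    pvals = (1.0 + (null[valid] >= observed[None, :]).sum(axis=0)) / (1.0 + nB)

    results = [
        HeritabilityComparison(
            trait=trait_names[t],
            h2_male=float(h2_m[t]),
            h2_female=float(h2_f[t]),
            observed=float(observed[t]),
            B=nB,
            pvalue=float(pvals[t]),
            null_values=null[valid, t].copy() if keep_null else None,
        )
        for t in range(T)
    ]
    return results[0] if single else results


@dataclass
class ScanComparison:
    """Overlap accounting between stratified and combined significant sets."""

    threshold: float
    n_combined: int
    n_stratified: int
    n_intersection: int
    n_stratified_only: int
    n_combined_only: int
    stratified_only_pct_of_combined: float
    shared_pct_of_union: float

    @property
    def n_union(self) -> int:
        return self.n_combined + self.n_stratified - self.n_intersection

    @classmethod
    def from_sets(cls, stratified: set, combined: set,
                  threshold: float = np.nan) -> "ScanComparison":
        inter = stratified & combined
        union = stratified | combined
        if len(union) == 0:
            shared_pct = 0.0
        else:
            shared_pct = 100.0 * len(inter) / len(union)
        strat_only = len(stratified - combined)
        pct_of_combined = (
            100.0 * strat_only / len(combined) if combined else np.nan
        )
        return cls(
            threshold=threshold,
            n_combined=len(combined),
            n_stratified=len(stratified),
            n_intersection=len(inter),
            n_stratified_only=strat_only,
            n_combined_only=len(combined - stratified),
            stratified_only_pct_of_combined=pct_of_combined,
            shared_pct_of_union=shared_pct,
        )

    def to_frame(self) -> pd.DataFrame:
        d = {
            "threshold": self.threshold,
            "combined": self.n_combined,
            "stratified": self.n_stratified,
            "intersection": self.n_intersection,
            "stratified_only": self.n_stratified_only,
            "combined_only": self.n_combined_only,
            "union": self.n_union,
            "stratified_only_pct_of_combined": self.stratified_only_pct_of_combined,
            "shared_pct_of_union": self.shared_pct_of_union,
        }
        return pd.DataFrame(list(d.items()), columns=["item", "value"])


def compare_scans(
    male: AssocResult | None,
    female: AssocResult | None,
    combined: AssocResult,
    threshold: float,
    key_prefix: str = "",
) -> ScanComparison:
    """Compare significant SNP sets: stratified (significant in either sex)
    versus combined, at one per-scan threshold.

    ``key_prefix`` lets multi-trait callers namespace SNP ids with the
    trait so the accounting is over trait-SNP pairs.
    """
    if combined is None or combined.table.empty:
        raise ValueError("combined scan is empty")

    def sig_set(res):
        if res is None:
            return set()
        return {key_prefix + s for s in res.significant(threshold)["snp"]}

    stratified = sig_set(male) | sig_set(female)
    return ScanComparison.from_sets(stratified, sig_set(combined), threshold)


def zdist_shift_test(z_all, z_subset) -> tuple[float, float]:
    """Welch t-test asking whether a SNP subset sits in the tail of the
    |Z| distribution relative to all tested SNPs.

    Returns (t, p) two-sided.  Degenerate (zero-variance or singleton)
    inputs return NaN statistics rather than raising.
    """
    a = np.abs(np.asarray(z_all, dtype=float))
    s = np.abs(np.asarray(z_subset, dtype=float))
    a, s = a[~np.isnan(a)], s[~np.isnan(s)]
    if a.size == 0 or s.size == 0:
        raise ValueError("empty z vector")
    if a.size < 2 or s.size < 2 or (np.ptp(a) == 0 and np.ptp(s) == 0):
        warnings.warn("degenerate z-distribution comparison")
        return np.nan, np.nan
    t, p = stats.ttest_ind(s, a, equal_var=False)
    return float(t), float(p)
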