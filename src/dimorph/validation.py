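"""Simulation studies validating the statistical machinery.

Each function runs a self-contained experiment on the synthetic F2
generator — calibration of the dimorphism z-test, recovery of simulated
heritabilities and sex-specific QTL effects, calibration and power of the
heritability permutation test, and exact-oracle comparisons for the score
test and the Hardy-Weinberg exact test.  They are used by the test suite
and by ``scripts/acceptance.py``; problem sizes are chosen to finish on a
single CPU in minutes (see docs/methods.md).
"""

from __future__ import annotations

import math

import numpy as np
import pandas as pd
from scipy import stats

from .genio import GenotypeMatrix
from .mixedmodel import KinshipMatrix, PolygenicModel, genomic_kinship
from .qc import hwe_exact_test, snp_qc, mendel_error_rates
from .sexdim import (
    design_matrix,
    heritability_permutation_test,
    significance_thresholds,
    stratified_scans,
    z_dimorphism,
)
from .simulate import (
    FounderDivergence,
    Pedigree,
    QTL,
    SimulationConfig,
    TraitArchitecture,
    build_pedigree,
    gene_drop,
    pedigree_kinship,
    simulate_founders,
    simulate_traits,
)

#: 18 chromosomes x 112 SNPs ~ 2016 markers, the scan size used throughout
_SCAN_SNPS = 112
_SCAN_CHROMS = 18


def _sub_seed(seed: int, k: int) -> int:
    return int((seed * 10_007 + k) % (2**31 - 1))


def _f2_cohort(cfg: SimulationConfig):
    """Simulate and return (F2 genotypes, trait table aligned to them,
    full pedigree, clean full-pedigree genotypes)."""
    panel = simulate_founders(cfg)
    ped = build_pedigree(cfg)
    g = gene_drop(ped, panel, cfg)
    tt = simulate_traits(g, ped, cfg)
    f2 = (g.samples["generation"] == "F2").to_numpy()
    gf = g.subset(samples=f2)
    tt = tt.set_index("id").loc[gf.samples["iid"]].reset_index()
    return gf, tt, ped, g


def _f2_pedigree_kinship(ped: Pedigree) -> KinshipMatrix:
    A, ids = pedigree_kinship(ped)
    f2 = (ped.table["generation"] == "F2").to_numpy()
    return KinshipMatrix(
        A[np.ix_(f2, f2)], [i for i, m in zip(ids, f2) if m]
    )


# ---------------------------------------------------------------------------
# z-test calibration (null: equal effects, per-sex polygenic backgrounds)
# ---------------------------------------------------------------------------

def ztest_calibration(seed: int = 1, n_seeds: int = 5) -> dict:
    """Null calibration of the dimorphism z-test.

    Cohorts of ~900 F2 (paper-design pedigree), 2016 SNPs, polygenic
    h2 = 0.4 in both sexes with sex-specific polygenic backgrounds and no
    QTL.  Pools the two-sided p_Z over ``n_seeds`` cohorts and reports the
    fraction below 0.05 with its 3-binomial-SD band and the KS uniformity
    p-value.
    """
    pvals = []
    for k in range(n_seeds):
        cfg = SimulationConfig(
            n_snps=_SCAN_SNPS, n_chromosomes=_SCAN_CHROMS,
            pedigree_counts=(2, 17, 9, 59, 900, 6),
            traits=(TraitArchitecture(
                name="t", h2_male=0.4, h2_female=0.4, cross_sex_rg=0.0
            ),),
            seed=_sub_seed(seed, k),
        )
        gf, tt, ped, _ = _f2_cohort(cfg)
        K = genomic_kinship(gf)
        scans = stratified_scans(
            gf, tt["t"].to_numpy(), tt["sex"], tt["batch"], K
        )
        dim = z_dimorphism(scans.male, scans.female)
        pvals.append(dim.table.loc[dim.table["tested"], "p_z"].to_numpy())
    p = np.concatenate(pvals)
    frac = float((p < 0.05).mean())
    band = 3.0 * math.sqrt(0.05 * 0.95 / p.size)
    ks_p = float(stats.kstest(p, "uniform").pvalue)
    return {"fraction_p05": frac, "band": band, "ks_p": ks_p, "n": int(p.size)}


# ---------------------------------------------------------------------------
# dimorphic-locus recovery
# ---------------------------------------------------------------------------

def _qtl_cohort(seed: int, effect_male: float, effect_female: float):
    """Cohort of 900 F2 with one QTL at realized MAF ~ 0.3."""
    cfg0 = SimulationConfig(
        n_snps=_SCAN_SNPS, n_chromosomes=_SCAN_CHROMS,
        pedigree_counts=(2, 17, 9, 59, 900, 6), seed=seed,
    )
    panel = simulate_founders(cfg0)
    ped = build_pedigree(cfg0)
    g = gene_drop(ped, panel, cfg0)
    f2 = (g.samples["generation"] == "F2").to_numpy()
    gf = g.subset(samples=f2)
    freq = gf.dosages.mean(axis=0) / 2.0
    maf = np.minimum(freq, 1 - freq)
    qtl_idx = int(np.argmin(np.abs(maf - 0.3)))
    cfg = SimulationConfig(
        n_snps=_SCAN_SNPS, n_chromosomes=_SCAN_CHROMS,
        pedigree_counts=(2, 17, 9, 59, 900, 6),
        traits=(TraitArchitecture(
            name="t",
            qtls=(QTL(qtl_idx, effect_male, effect_female),),
            h2_male=0.3, h2_female=0.3,
        ),),
        seed=seed,
    )
    tt = simulate_traits(g, ped, cfg)
    tt = tt.set_index("id").loc[gf.samples["iid"]].reset_index()
    return gf, tt, qtl_idx


def dimorphic_recovery(seed: int = 1, n_seeds: int = 10) -> dict:
    """Recovery of sexually dimorphic QTL across seeds.

    Scenario A: male-only QTL (beta_m = 0.6 SD, beta_f = 0, MAF ~ 0.3) —
    counts seeds where the z-test flags the QTL at the suggestive level
    (1/N_snp).  Scenario B: opposite-sign QTL (+0.5 / -0.5 SD) — counts
    seeds where the QTL is stratified-significant (suggestive level in at
    least one sex, the union accounting used for stratified discoveries)
    while the combined scan p-value is attenuated relative to both strata;
    also reports the stricter count requiring both strata significant.
    """
    male_hits = 0
    opp_hits = 0
    opp_hits_both = 0
    for k in range(n_seeds):
        s = _sub_seed(seed, 100 + k)
        # scenario A
        gf, tt, qtl = _qtl_cohort(s, 0.6, 0.0)
        suggestive, _ = significance_thresholds(gf.n_snps)
        K = genomic_kinship(gf)
        scans = stratified_scans(gf, tt["t"].to_numpy(), tt["sex"], tt["batch"], K)
        dim = z_dimorphism(scans.male, scans.female)
        snp_name = gf.snps["snp"].iloc[qtl]
        row = dim.table.set_index("snp").loc[snp_name]
        if bool(row["tested"]) and row["p_z"] < suggestive:
            male_hits += 1
        # scenario B
        gf, tt, qtl = _qtl_cohort(_sub_seed(seed, 200 + k), 0.5, -0.5)
        K = genomic_kinship(gf)
        scans = stratified_scans(gf, tt["t"].to_numpy(), tt["sex"], tt["batch"], K)
        snp_name = gf.snps["snp"].iloc[qtl]
        pm = scans.male.table.set_index("snp").loc[snp_name, "p"]
        pf = scans.female.table.set_index("snp").loc[snp_name, "p"]
        pc = scans.combined.table.set_index("snp").loc[snp_name, "p"]
        attenuated = pc > max(pm, pf)
        if min(pm, pf) < suggestive and attenuated:
            opp_hits += 1
        if pm < suggestive and pf < suggestive and attenuated:
            opp_hits_both += 1
    return {
        "male_only_hits": male_hits,
        "opposite_sign_hits": opp_hits,
        "opposite_sign_hits_both_strata": opp_hits_both,
        "n_seeds": n_seeds,
    }


# ---------------------------------------------------------------------------
# heritability recovery
# ---------------------------------------------------------------------------

def h2_recovery(
    seed: int = 1, h2_values=(0.2, 0.6), n_reps: int = 10, n_f2: int = 500
) -> dict:
    """REML recovery of simulated polygenic heritability.

    Traits are generated from the pedigree-expected kinship and re-fitted
    with that same kinship (the correctly specified covariance; see
    docs/methods.md on why a realized F2 GRM attenuates).  Reports the mean
    estimate and mean error per true value over ``n_reps`` replicates.
    """
    out = {}
    for h2 in h2_values:
        ests = []
        for k in range(n_reps):
            cfg = SimulationConfig(
                n_snps=5, n_chromosomes=2,
                pedigree_counts=(2, 17, 9, 59, n_f2, 6),
                traits=(TraitArchitecture(
                    name="t", h2_male=h2, h2_female=h2, batch_sd=0.3
                ),),
                seed=_sub_seed(seed, int(h2 * 1000) + k),
            )
            ped = build_pedigree(cfg)
            tt = simulate_traits(None, ped, cfg)
            K = _f2_pedigree_kinship(ped)
            tt = tt.set_index("id").loc[K.ids].reset_index()
            X = design_matrix(batch=tt["batch"])
            fit = PolygenicModel(tt["t"].to_numpy(), X, K, ids=K.ids).fit()
            ests.append(fit.h2)
        out[h2] = {
            "mean_estimate": float(np.mean(ests)),
            "mean_error": float(np.mean(ests) - h2),
            "n_reps": n_reps,
        }
    return out


# ---------------------------------------------------------------------------
# permutation test: calibration and power
# ---------------------------------------------------------------------------

def permutation_calibration(
    seed: int = 1, n_traits: int = 50, B: int = 200, n_f2: int = 600
) -> dict:
    """Type-I error of the heritability permutation test.

    One cohort, ``n_traits`` null traits (identical generative model in
    both sexes: h2 = 0.3, shared polygenic background), tested jointly so
    all traits share the permutation set.  Reports the rejection rate at
    alpha = 0.05 with its 3-binomial-SD band.
    """
    traits = tuple(
        TraitArchitecture(name=f"t{i}", h2_male=0.3, h2_female=0.3)
        for i in range(n_traits)
    )
    cfg = SimulationConfig(
        n_snps=5, n_chromosomes=2,
        pedigree_counts=(2, 17, 9, 59, n_f2, 6),
        traits=traits, seed=_sub_seed(seed, 31),
    )
    ped = build_pedigree(cfg)
    tt = simulate_traits(None, ped, cfg)
    K = _f2_pedigree_kinship(ped)
    tt = tt.set_index("id").loc[K.ids].reset_index()
    names = [t.name for t in traits]
    res = heritability_permutation_test(
        tt[names], tt["sex"], tt["batch"], K,
        B=B, seed=_sub_seed(seed, 32),
    )
    rate = float(np.mean([r.pvalue <= 0.05 for r in res]))
    band = 3.0 * math.sqrt(0.05 * 0.95 / n_traits)
    return {"rejection_rate": rate, "band": band, "n_traits": n_traits, "B": B}


def permutation_power(
    seed: int = 1, n_reps: int = 10, B: int = 200, n_per_sex: int = 300
) -> dict:
    """Power of the permutation test at h2_male = 0.7 vs h2_female = 0.1.

    ~``n_per_sex`` F2 individuals per sex; reports the fraction of
    replicates with p <= 0.05.
    """
    hits = 0
    for k in range(n_reps):
        cfg = SimulationConfig(
            n_snps=5, n_chromosomes=2,
            pedigree_counts=(2, 17, 9, 59, 2 * n_per_sex, 6),
            traits=(TraitArchitecture(name="t", h2_male=0.7, h2_female=0.1),),
            seed=_sub_seed(seed, 300 + k),
        )
        ped = build_pedigree(cfg)
        tt = simulate_traits(None, ped, cfg)
        K = _f2_pedigree_kinship(ped)
        tt = tt.set_index("id").loc[K.ids].reset_index()
        res = heritability_permutation_test(
            tt["t"].to_numpy(), tt["sex"], tt["batch"], K,
            B=B, seed=_sub_seed(seed, 400 + k),
        )
        if res.pvalue <= 0.05:
            hits += 1
    return {"power": hits / n_reps, "hits": hits, "n_reps": n_reps, "B": B}


# ---------------------------------------------------------------------------
# exact oracles
# ---------------------------------------------------------------------------

def gls_oracle_max_rel_diff(seed: int = 1, n: int = 50, m: int = 100) -> dict:
    """Score scan vs a joint generalized-least-squares fit.

    With a diagonal kinship and variance components fixed at their known
    values the score-test beta, se and p must equal the per-SNP joint GLS
    solution; returns the largest relative deviation over ``m`` SNPs.
    """
    rng = np.random.default_rng(seed)
    d = rng.uniform(0.5, 2.0, size=n)
    K = np.diag(d)
    h2, sigma2_p = 0.5, 2.0
    V = sigma2_p * (h2 * K + (1 - h2) * np.eye(n))
    X = np.column_stack([np.ones(n), rng.standard_normal(n)])
    y = X @ np.array([1.0, 0.5]) + np.linalg.cholesky(V) @ rng.standard_normal(n)
    G = rng.integers(0, 3, size=(n, m)).astype(np.int8)
    g = GenotypeMatrix(
        dosages=G,
        snps=pd.DataFrame({
            "chrom": ["1"] * m, "snp": [f"s{j}" for j in range(m)],
            "cm": np.arange(m, dtype=float), "bp": np.arange(1, m + 1),
            "a1": ["A"] * m, "a2": ["B"] * m,
        }),
        samples=pd.DataFrame({"iid": [f"i{i}" for i in range(n)]}),
    )
    fit = PolygenicModel(y, X, K).fit(h2=h2, total_variance=sigma2_p)
    scan = fit.score_scan(g)

    Vinv = np.linalg.inv(V)
    worst = 0.0
    for j in range(m):
        gj = G[:, j].astype(float)
        if np.ptp(gj) == 0:
            continue
        Xj = np.column_stack([X, gj])
        C = np.linalg.inv(Xj.T @ Vinv @ Xj)
        b = C @ (Xj.T @ (Vinv @ y))
        beta_o, se_o = b[-1], math.sqrt(C[-1, -1])
        p_o = float(stats.chi2.sf((beta_o / se_o) ** 2, df=1))
        row = scan.table.iloc[j]
        for mine, oracle in ((row["beta"], beta_o), (row["se"], se_o),
                             (row["p"], p_o)):
            rel = abs(mine - oracle) / max(abs(oracle), 1e-300)
            worst = max(worst, rel)
    return {"max_rel_diff": float(worst), "n": n, "m": m}


def _hwe_oracle(n_AA: int, n_Aa: int, n_aa: int) -> float:
    """Independent exact-integer enumeration of the conditional HWE test."""
    n = n_AA + n_Aa + n_aa
    n_rare = min(2 * n_AA + n_Aa, 2 * n_aa + n_Aa)
    weights = {}
    for h in range(n_rare % 2, n_rare + 1, 2):
        ra = (n_rare - h) // 2
        co = n - h - ra
        weights[h] = (
            math.factorial(n)
            // (math.factorial(ra) * math.factorial(h) * math.factorial(co))
            * 2**h
        )
    total = sum(weights.values())
    obs = weights[n_Aa]
    return sum(w for w in weights.values() if w <= obs) / total


def hwe_enumeration_check(n_max: int = 50) -> dict:
    """Exact test vs integer enumeration for every genotype table n <= n_max."""
    worst = 0.0
    count = 0
    for n in range(1, n_max + 1):
        for n_AA in range(n + 1):
            for n_Aa in range(n - n_AA + 1):
                n_aa = n - n_AA - n_Aa
                p = hwe_exact_test(n_AA, n_Aa, n_aa)
                q = _hwe_oracle(n_AA, n_Aa, n_aa)
                worst = max(worst, abs(p - q))
                count += 1
    return {"max_abs_diff": float(worst), "n_tables": count}


def qc_bruteforce_check(seed: int = 1) -> dict:
    """SNP QC vs a literal reapplication of the four filter rules.

    A 2016-SNP panel with injected missingness and genotyping errors is
    filtered by `snp_qc`; an independent per-SNP loop recomputes call rate,
    MAF, the HWE exact p on F2 samples and the trio Mendel error rate, and
    applies the strict thresholds.  Reports the number of disagreements.
    """
    cfg = SimulationConfig(
        n_snps=_SCAN_SNPS, n_chromosomes=_SCAN_CHROMS,
        pedigree_counts=(2, 17, 9, 59, 250, 6),
        missing_rate=0.05, geno_error_rate=0.01, seed=_sub_seed(seed, 77),
    )
    panel = simulate_founders(cfg)
    ped = build_pedigree(cfg)
    g0 = gene_drop(ped, panel, cfg)
    from .simulate import inject_artifacts

    g = inject_artifacts(g0, cfg)
    kept, report = snp_qc(g, ped)
    kept_set = set(kept.snps["snp"])

    snp_rate, _ = mendel_error_rates(g, ped)
    f2 = (g.samples["generation"] == "F2").to_numpy()
    mismatches = 0
    for j in range(g.n_snps):
        col = g.dosages[:, j]
        n_called = int((col >= 0).sum())
        call_rate = n_called / g.n_samples
        alleles = col[col >= 0]
        if alleles.size:
            f = alleles.sum() / (2 * alleles.size)
            maf = min(f, 1 - f)
        else:
            maf = 0.0
        f2col = g.dosages[f2, j]
        counts = [(f2col == 2).sum(), (f2col == 1).sum(), (f2col == 0).sum()]
        hwe_p = _hwe_oracle(*counts) if sum(counts) else 1.0
        keep = (
            call_rate > 0.9 and maf > 0.05 and hwe_p > 1e-6
            and snp_rate[j] < 0.1
        )
        if keep != (g.snps["snp"].iloc[j] in kept_set):
            mismatches += 1
    return {"mismatches": mismatches, "n_snps": g.n_snps,
            "n_retained": report.n_snps_retained}


# ---------------------------------------------------------------------------
# simulator fidelity
# ---------------------------------------------------------------------------

def simulator_fidelity(seed: int = 1) -> dict:
    """Mendelian fidelity of the gene-dropping generator.

    Founders fixed for alternative alleles: every F1 genotype must be
    heterozygous; F2 genotype counts must fit 1:2:1; the pre-injection
    matrix must contain zero Mendelian errors.
    """
    cfg = SimulationConfig(
        n_snps=40, n_chromosomes=5,
        pedigree_counts=(2, 17, 9, 59, 1000, 6),
        founder_divergence=FounderDivergence.fixed(1.0, 0.0),
        seed=_sub_seed(seed, 55),
    )
    panel = simulate_founders(cfg)
    ped = build_pedigree(cfg)
    g = gene_drop(ped, panel, cfg)
    f1 = (g.samples["generation"] == "F1").to_numpy()
    f2 = (g.samples["generation"] == "F2").to_numpy()
    f1_het = float((g.dosages[f1] == 1).mean())
    # one SNP per chromosome: linkage makes same-chromosome SNPs dependent,
    # but counts pooled across chromosomes and individuals are multinomial
    cols = np.arange(0, g.n_snps, cfg.n_snps)
    D = g.dosages[np.ix_(f2, cols)]
    counts = np.array([(D == 0).sum(), (D == 1).sum(), (D == 2).sum()])
    chi_p = float(stats.chisquare(
        counts, f_exp=counts.sum() * np.array([0.25, 0.5, 0.25])
    ).pvalue)
    snp_rate, smp_rate = mendel_error_rates(g, ped)
    return {
        "f1_het_fraction": f1_het,
        "f2_segregation_chisq_p": chi_p,
        "mendel_errors": float(snp_rate.sum() + smp_rate.sum()),
    }
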