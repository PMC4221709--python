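"""Synthetic F2-cross generator: founders, gene dropping, artifacts, traits.

Emulates a two-breed intercross of the kind used for livestock QTL mapping:
two divergent founder breeds are crossed to an F1 generation, and F1 x F1
matings produce a large F2 cohort in which breed differences segregate.
Genotypes are produced by gene dropping (Mendelian transmission of founder
haplotypes down the pedigree with Haldane recombination), and quantitative
traits by an additive model with sex-specific QTL effects, a sex mean
offset, batch effects, a pedigree-structured polygenic term with per-sex
heritability, and Gaussian residuals.

The default pedigree reproduces the classic White Duroc x Erhualian design:
2 F0 boars x 17 F0 sows -> F1; 9 F1 boars x 59 F1 sows -> 1912 F2 pigs in
6 batches.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .genio import GenotypeMatrix

__all__ = [
    "FounderDivergence",
    "QTL",
    "TraitArchitecture",
    "SimulationConfig",
    "FounderPanel",
    "Pedigree",
    "simulate_founders",
    "build_pedigree",
    "gene_drop",
    "inject_artifacts",
    "simulate_traits",
    "pedigree_kinship",
    "simulate_study",
]


class ConfigurationError(ValueError):
    """Raised when a simulation configuration is internally inconsistent."""


class PedigreeError(ValueError):
    """Raised for structural pedigree problems (cycles, missing parents)."""


@dataclass(frozen=True)
class FounderDivergence:
    """Allele-frequency model for the two founder breeds.

    Per-SNP frequencies are drawn from Beta distributions, one per breed;
    divergent means produce the high-MAF F2 segregation characteristic of a
    breed cross.  ``freq_a`` / ``freq_b`` pin the frequencies to constants
    instead (used for fixation tests and controlled QTL frequencies).
    """

    beta_a: tuple[float, float] = (8.0, 2.0)
    beta_b: tuple[float, float] = (2.0, 8.0)
    freq_a: float | None = None
    freq_b: float | None = None

    def validate(self) -> None:
        for ab in (self.beta_a, self.beta_b):
            if min(ab) <= 0:
                raise ConfigurationError(f"Beta parameters must be positive, got {ab}")
        for f in (self.freq_a, self.freq_b):
            if f is not None and not 0.0 <= f <= 1.0:
                raise ConfigurationError(f"fixed founder frequency {f} outside [0,1]")

    @classmethod
    def fixed(cls, freq_a: float, freq_b: float) -> "FounderDivergence":
        return cls(freq_a=freq_a, freq_b=freq_b)


@dataclass(frozen=True)
class QTL:
    """A single additive QTL with sex-specific effects in residual-SD units."""

    snp_index: int
    effect_male: float
    effect_female: float


@dataclass(frozen=True)
class TraitArchitecture:
    """Generative architecture for one quantitative trait.

    h2_male / h2_female are the polygenic heritabilities per sex, defined
    against the polygenic + residual variance (QTL and batch variance sit on
    top).  sex_offset is the male-minus-female mean difference in trait
    units; batch effects are iid N(0, batch_sd^2) per batch.
    """

    name: str
    qtls: tuple[QTL, ...] = ()
    h2_male: float = 0.3
    h2_female: float = 0.3
    sex_offset: float = 0.0
    batch_sd: float = 0.0
    residual_sd: float = 1.0
    cross_sex_rg: float = 1.0
    category: str = "simulated"

    def validate(self, n_snps_total: int) -> None:
        for h2 in (self.h2_male, self.h2_female):
            if not 0.0 <= h2 < 1.0:
                raise ConfigurationError(
                    f"trait {self.name!r}: heritability {h2} outside [0,1)"
                )
        if self.residual_sd <= 0:
            raise ConfigurationError(f"trait {self.name!r}: residual_sd must be > 0")
        if self.batch_sd < 0:
            raise ConfigurationError(f"trait {self.name!r}: batch_sd must be >= 0")
        if not 0.0 <= self.cross_sex_rg <= 1.0:
            raise ConfigurationError(
                f"trait {self.name!r}: cross_sex_rg outside [0,1]"
            )
        for q in self.qtls:
            if not 0 <= q.snp_index < n_snps_total:
                raise ConfigurationError(
                    f"trait {self.name!r}: QTL index {q.snp_index} outside "
                    f"[0, {n_snps_total})"
                )


#: (n_sires_F0, n_dams_F0, n_sires_F1, n_dams_F1, n_F2, n_batches)
DEFAULT_PEDIGREE_COUNTS = (2, 17, 9, 59, 1912, 6)


@dataclass(frozen=True)
class SimulationConfig:
    n_snps: int = 100  # per chromosome
    n_chromosomes: int = 18
    chrom_length_cM: float = 100.0
    founder_divergence: FounderDivergence = field(default_factory=FounderDivergence)
    pedigree_counts: tuple[int, int, int, int, int, int] = DEFAULT_PEDIGREE_COUNTS
    traits: tuple[TraitArchitecture, ...] = ()
    male_fraction: float = 0.5
    missing_rate: float = 0.0
    geno_error_rate: float = 0.0
    analyzed_fraction: float = 1.0
    include_x: bool = False  # appends one X-like chromosome (autosomal coding)
    seed: int = 0

    @property
    def n_snps_total(self) -> int:
        return self.n_snps * (self.n_chromosomes + int(self.include_x))

    def validate(self) -> None:
        if self.n_snps <= 0 or self.n_chromosomes <= 0:
            raise ConfigurationError("n_snps and n_chromosomes must be positive")
        if self.chrom_length_cM <= 0:
            raise ConfigurationError("chrom_length_cM must be positive")
        for name in ("missing_rate", "geno_error_rate", "male_fraction", "analyzed_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ConfigurationError(f"{name}={v} outside [0,1]")
        if len(self.pedigree_counts) != 6 or any(c <= 0 for c in self.pedigree_counts):
            raise ConfigurationError(
                f"pedigree_counts must be 6 positive counts, got {self.pedigree_counts}"
            )
        self.founder_divergence.validate()
        for t in self.traits:
            t.validate(self.n_snps_total)


@dataclass
class FounderPanel:
    """Per-breed allele frequencies and phased founder haplotypes.

    ``haplotypes`` is (2 * n_founders, n_snps) int8 of allele indicators
    (1 = breed-A-typical allele); founder k owns rows 2k and 2k+1.
    """

    freq_a: np.ndarray
    freq_b: np.ndarray
    haplotypes: np.ndarray
    founder_ids: list[str]


@dataclass
class Pedigree:
    """Three-generation pedigree as a DataFrame wrapper.

    Columns: id, sire, dam (empty string for founders), generation in
    {F0, F1, F2}, sex in {M, F}, batch (int, -1 outside F2).
    """

    table: pd.DataFrame

    def __post_init__(self) -> None:
        req = {"id", "sire", "dam", "generation", "sex", "batch"}
        missing = req - set(self.table.columns)
        if missing:
            raise PedigreeError(f"pedigree table missing columns {sorted(missing)}")
        ids = self.table["id"]
        if ids.duplicated().any():
            raise PedigreeError("duplicate individual ids in pedigree")
        known = set(ids)
        gen = dict(zip(self.table["id"], self.table["generation"]))
        for _, row in self.table.iterrows():
            for parent in (row["sire"], row["dam"]):
                if row["generation"] == "F0":
                    if parent != "":
                        raise PedigreeError(f"founder {row['id']} has a parent")
                else:
                    if parent == "" or parent not in known:
                        raise PedigreeError(
                            f"{row['id']}: parent {parent!r} absent from pedigree"
                        )
                    expected = "F0" if row["generation"] == "F1" else "F1"
                    if gen[parent] != expected:
                        raise PedigreeError(
                            f"{row['id']} ({row['generation']}) has {gen[parent]} parent"
                        )

    @property
    def ids(self) -> list[str]:
        return list(self.table["id"])

    def generation(self, which: str) -> pd.DataFrame:
        return self.table[self.table["generation"] == which]

    def write(self, path) -> None:
        self.table.to_csv(path, sep="\t", index=False)

    @classmethod
    def read(cls, path) -> "Pedigree":
        t = pd.read_csv(path, sep="\t", dtype={"id": str, "sire": str, "dam": str})
        t["sire"] = t["sire"].fillna("")
        t["dam"] = t["dam"].fillna("")
        return cls(t)


def _rng(seed: int, stream: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([int(seed), int(stream)]))


def simulate_founders(config: SimulationConfig) -> FounderPanel:
    """Draw per-breed allele frequencies and phased founder haplotypes.

    Breed A supplies the F0 sires, breed B the F0 dams.  Deterministic
    given ``config.seed``.
    """
    config.validate()
    rng = _rng(config.seed, 1)
    m = config.n_snps_total
    div = config.founder_divergence
    if div.freq_a is not None:
        fa = np.full(m, float(div.freq_a))
    else:
        fa = rng.beta(*div.beta_a, size=m)
    if div.freq_b is not None:
        fb = np.full(m, float(div.freq_b))
    else:
        fb = rng.beta(*div.beta_b, size=m)

    n_sires, n_dams = config.pedigree_counts[:2]
    sire_ids = [f"F0_S{i+1}" for i in range(n_sires)]
    dam_ids = [f"F0_D{i+1}" for i in range(n_dams)]
    hap_a = (rng.random((2 * n_sires, m)) < fa).astype(np.int8)
    hap_b = (rng.random((2 * n_dams, m)) < fb).astype(np.int8)
    return FounderPanel(
        freq_a=fa,
        freq_b=fb,
        haplotypes=np.vstack([hap_a, hap_b]),
        founder_ids=sire_ids + dam_ids,
    )


def build_pedigree(config: SimulationConfig) -> Pedigree:
    """Construct the mating design: F0 -> F1 -> F2.

    F0 dams are assigned to F0 sires round-robin; the selected F1 breeders
    (first the boars, then the sows) are allocated across F0 matings
    round-robin; each F1 sow is mated to one F1 boar round-robin and F2
    litter sizes are as equal as possible.  F2 sex is Bernoulli
    (male_fraction); batches are assigned round-robin.
    """
    config.validate()
    n_s0, n_d0, n_s1, n_d1, n_f2, n_batches = config.pedigree_counts
    rng = _rng(config.seed, 2)

    rows: list[tuple] = []
    sires0 = [f"F0_S{i+1}" for i in range(n_s0)]
    dams0 = [f"F0_D{i+1}" for i in range(n_d0)]
    for s in sires0:
        rows.append((s, "", "", "F0", "M", -1))
    for d in dams0:
        rows.append((d, "", "", "F0", "F", -1))

    # F0 matings: dam i with sire i % n_s0
    matings0 = [(sires0[i % n_s0], dams0[i]) for i in range(n_d0)]
    f1_boars = [f"F1_B{i+1}" for i in range(n_s1)]
    f1_sows = [f"F1_S{i+1}" for i in range(n_d1)]
    for j, iid in enumerate(f1_boars + f1_sows):
        sire, dam = matings0[j % n_d0]
        rows.append((iid, sire, dam, "F1", "M" if j < n_s1 else "F", -1))

    # F1 matings: sow i with boar i % n_s1; near-equal litter sizes
    base, extra = divmod(n_f2, n_d1)
    k = 0
    for i, sow in enumerate(f1_sows):
        boar = f1_boars[i % n_s1]
        litter = base + (1 if i < extra else 0)
        for _ in range(litter):
            sex = "M" if rng.random() < config.male_fraction else "F"
            rows.append((f"F2_{k+1:05d}", boar, sow, "F2", sex, k % n_batches))
            k += 1

    table = pd.DataFrame(
        rows, columns=["id", "sire", "dam", "generation", "sex", "batch"]
    )
    return Pedigree(table)


def _snp_map(config: SimulationConfig) -> pd.DataFrame:
    """Evenly spaced SNPs; bp = cM * 1e6.  Optional trailing X chromosome."""
    chroms = [str(c + 1) for c in range(config.n_chromosomes)]
    if config.include_x:
        chroms.append("X")
    recs = []
    cm = np.linspace(0.0, config.chrom_length_cM, config.n_snps, endpoint=False)
    cm = cm + cm[1] / 2 if config.n_snps > 1 else cm + config.chrom_length_cM / 2
    for chrom in chroms:
        for j in range(config.n_snps):
            recs.append(
                (chrom, f"snp{chrom}_{j+1}", float(cm[j]), int(cm[j] * 1e6) + 1, "A", "B")
            )
    return pd.DataFrame(recs, columns=["chrom", "snp", "cm", "bp", "a1", "a2"])


def _meiosis(hap_pair: np.ndarray, cm_pos: np.ndarray, chrom_starts: np.ndarray,
             chrom_len: float, rng: np.random.Generator) -> np.ndarray:
    """One recombinant gamete under Haldane's no-interference model.

    Crossover counts per chromosome are Poisson(length in Morgans) with
    uniform positions; the starting parental haplotype is random per
    chromosome.
    """
    gamete = np.empty(hap_pair.shape[1], dtype=np.int8)
    n_chrom = len(chrom_starts) - 1
    morgans = chrom_len / 100.0
    for c in range(n_chrom):
        lo, hi = chrom_starts[c], chrom_starts[c + 1]
        pos = cm_pos[lo:hi]
        n_xo = rng.poisson(morgans)
        start = rng.integers(2)
        if n_xo == 0:
            which = np.full(hi - lo, start)
        else:
            xo = np.sort(rng.uniform(0.0, chrom_len, size=n_xo))
            which = (start + np.searchsorted(xo, pos)) % 2
        gamete[lo:hi] = np.where(which == 0, hap_pair[0, lo:hi], hap_pair[1, lo:hi])
    return gamete


def gene_drop(
    pedigree: Pedigree, panel: FounderPanel, config: SimulationConfig
) -> GenotypeMatrix:
    """Transmit founder haplotypes down the pedigree with recombination.

    Returns genotypes (breed-A allele dosage, 0/1/2) for every pedigree
    member.  By construction the output contains zero Mendelian errors.
    """
    config.validate()
    rng = _rng(config.seed, 3)
    snps = _snp_map(config)
    m = len(snps)
    if panel.haplotypes.shape[1] != m:
        raise ConfigurationError(
            f"panel covers {panel.haplotypes.shape[1]} SNPs, config defines {m}"
        )
    cm_pos = snps["cm"].to_numpy()
    chrom_starts = np.arange(
        0, m + config.n_snps, config.n_snps
    )

    table = pedigree.table
    ids = list(table["id"])
    idx = {iid: i for i, iid in enumerate(ids)}
    haps = np.zeros((len(ids), 2, m), dtype=np.int8)

    founder_pos = {fid: k for k, fid in enumerate(panel.founder_ids)}
    for _, row in table.iterrows():
        i = idx[row["id"]]
        if row["generation"] == "F0":
            if row["id"] not in founder_pos:
                raise PedigreeError(f"founder {row['id']} absent from panel")
            k = founder_pos[row["id"]]
            haps[i] = panel.haplotypes[2 * k : 2 * k + 2]
        else:
            si, di = idx[row["sire"]], idx[row["dam"]]
            haps[i, 0] = _meiosis(haps[si], cm_pos, chrom_starts,
                                  config.chrom_length_cM, rng)
            haps[i, 1] = _meiosis(haps[di], cm_pos, chrom_starts,
                                  config.chrom_length_cM, rng)

    dosage = (haps[:, 0, :] + haps[:, 1, :]).astype(np.int8)
    samples = table.rename(columns={"id": "iid"})[
        ["iid", "sire", "dam", "generation", "sex", "batch"]
    ].copy()
    return GenotypeMatrix(dosages=dosage, snps=snps, samples=samples)


def inject_artifacts(
    genotypes: GenotypeMatrix, config: SimulationConfig
) -> GenotypeMatrix:
    """Overlay missingness and genotyping errors; the input is untouched.

    Errors replace a dosage with one of the two other dosages uniformly;
    missingness is applied after errors and wins where both hit.
    """
    config.validate()
    rng = _rng(config.seed, 4)
    d = genotypes.dosages.copy()
    if config.geno_error_rate > 0:
        err = rng.random(d.shape) < config.geno_error_rate
        shift = rng.integers(1, 3, size=d.shape, dtype=np.int8)
        d = np.where(err, (d + shift) % 3, d).astype(np.int8)
    if config.missing_rate > 0:
        miss = rng.random(d.shape) < config.missing_rate
        d[miss] = GenotypeMatrix.MISSING
    return GenotypeMatrix(
        dosages=d, snps=genotypes.snps.copy(), samples=genotypes.samples.copy()
    )


def pedigree_kinship(pedigree: Pedigree) -> tuple[np.ndarray, list[str]]:
    """Pedigree-expected additive relationship matrix (Wright's numerator
    relationship), founders unrelated and non-inbred.  Diagonal is
    1 + inbreeding coefficient; this is the expectation of a VanRaden-type
    genomic relationship matrix."""
    table = pedigree.table
    ids = list(table["id"])
    idx = {iid: i for i, iid in enumerate(ids)}
    n = len(ids)
    sire = [idx.get(s, -1) for s in table["sire"]]
    dam = [idx.get(d, -1) for d in table["dam"]]
    A = np.zeros((n, n))
    # ids are in generation order by construction of build_pedigree
    for i in range(n):
        s, d = sire[i], dam[i]
        if s == -1 and d == -1:
            A[i, i] = 1.0
        else:
            A[i, i] = 1.0 + 0.5 * A[s, d]
        for j in range(i):
            if s == -1 and d == -1:
                a = 0.0
            else:
                a = 0.5 * (A[j, s] + A[j, d])
            A[i, j] = A[j, i] = a
    return A, ids


def simulate_traits(
    genotypes: GenotypeMatrix | None, pedigree: Pedigree, config: SimulationConfig
) -> pd.DataFrame:
    """Simulate F2 trait values under the additive generative model.

    trait = sex_offset * 1[male] + batch effect + sum_q dosage_q * effect_{q,sex}
            * residual_sd + polygenic + residual

    The polygenic term has covariance rg^(i!=j sexes) sigma_g(sex_i)
    sigma_g(sex_j) A_ij with A the pedigree-expected relationship and
    sigma2_g(s) = h2_s/(1-h2_s) * residual_sd^2, so the configured h2 is
    recovered as sigma2_g/(sigma2_g + sigma2_e) within each sex.
    cross_sex_rg is the genetic correlation between the sexes: 1 shares one
    polygenic background, 0 gives each sex its own.  Returns a trait table
    (one row per analyzed F2 individual) with id, sex, batch and one column
    per trait.
    """
    config.validate()
    if genotypes is None and any(t.qtls for t in config.traits):
        raise ConfigurationError("QTL architecture requires genotypes")
    rng = _rng(config.seed, 5)
    A, ids = pedigree_kinship(pedigree)
    table = pedigree.table
    f2_mask = (table["generation"] == "F2").to_numpy()
    f2 = table[f2_mask].reset_index(drop=True)
    A_f2 = A[np.ix_(f2_mask, f2_mask)]
    # one Cholesky shared across traits; jitter guards numerical PSD loss
    L = np.linalg.cholesky(A_f2 + 1e-9 * np.eye(len(f2)))

    if genotypes is not None:
        gpos = {iid: i for i, iid in enumerate(genotypes.samples["iid"])}
        rows_g = np.array([gpos[i] for i in f2["id"]])
    male = (f2["sex"] == "M").to_numpy()
    batch = f2["batch"].to_numpy()

    out = f2[["id", "sex", "batch"]].copy()
    for trait in config.traits:
        sd = trait.residual_sd
        sig_g = np.where(
            male,
            np.sqrt(trait.h2_male / (1 - trait.h2_male)) * sd,
            np.sqrt(trait.h2_female / (1 - trait.h2_female)) * sd,
        )
        y = np.zeros(len(f2))
        y += np.where(male, trait.sex_offset, 0.0)
        if trait.batch_sd > 0:
            beffects = rng.normal(0.0, trait.batch_sd, size=int(batch.max()) + 1)
            y += beffects[batch]
        for q in trait.qtls:
            dos = genotypes.dosages[rows_g, q.snp_index].astype(float)
            dos[dos == GenotypeMatrix.MISSING] = np.nan
            dos = np.nan_to_num(dos, nan=float(np.nanmean(dos)))
            eff = np.where(male, q.effect_male, q.effect_female) * sd
            y += dos * eff
        rg = trait.cross_sex_rg
        u_shared = L @ rng.standard_normal(len(f2))
        u_m = L @ rng.standard_normal(len(f2))
        u_f = L @ rng.standard_normal(len(f2))
        u_own = np.where(male, u_m, u_f)
        y += sig_g * (np.sqrt(rg) * u_shared + np.sqrt(1.0 - rg) * u_own)
        y += rng.normal(0.0, sd, size=len(f2))
        out[trait.name] = y

    if config.analyzed_fraction < 1.0:
        keep = rng.random(len(out)) < config.analyzed_fraction
        out = out[keep].reset_index(drop=True)
    return out


def simulate_study(
    config: SimulationConfig,
) -> tuple[GenotypeMatrix, Pedigree, pd.DataFrame]:
    """Run the full generator: founders -> pedigree -> gene drop ->
    artifacts -> traits.  Traits are simulated from the clean genotypes;
    the returned matrix carries the injected artifacts."""
    panel = simulate_founders(config)
    ped = build_pedigree(config)
    clean = gene_drop(ped, panel, config)
    traits = simulate_traits(clean, ped, config)
    noisy = inject_artifacts(clean, config)
    return noisy, ped, traits
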