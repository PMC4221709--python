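"""End-to-end pipeline: configuration, orchestration, run manifest.

A run goes simulate (optional) -> genotype QC -> phenotype prep -> combined
and sex-stratified scans -> per-SNP dimorphism z-tests -> per-trait
heritability permutation tests -> stratified-vs-combined comparison, with
every stage writing tab-delimited tables under the output directory and a
JSON manifest recording seeds, checksums and timings.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from scipy import stats

from . import __version__
from .genio import GenotypeMatrix, read_genotypes
from .mixedmodel import genomic_kinship
from .pheno import sex_effect_table
from .qc import sample_qc, snp_qc
from .sexdim import (
    compare_scans,
    heritability_permutation_test,
    significance_thresholds,
    stratified_scans,
    z_dimorphism,
    zdist_shift_test,
    ScanComparison,
)
from .simulate import (
    FounderDivergence,
    Pedigree,
    QTL,
    SimulationConfig,
    TraitArchitecture,
    simulate_study,
)

log = logging.getLogger("dimorph")

__all__ = ["PipelineConfig", "RunManifest", "run_pipeline",
           "spearman_h2_correlation", "load_simulation_config"]


@dataclass
class QCConfig:
    sample_call_rate: float = 0.10
    sample_mendel: float = 0.05
    snp_call_rate: float = 0.9
    maf: float = 0.05
    hwe_p: float = 1e-6
    snp_mendel: float = 0.1


@dataclass
class PipelineConfig:
    outdir: str = "dimorph_run"
    seed: int = 0
    permutations: int = 1000
    simulate: dict | None = None
    bed_prefix: str | None = None
    phenotypes: str | None = None
    pedigree: str | None = None
    traits: list[str] | None = None
    qc: QCConfig = field(default_factory=QCConfig)
    maf_min_z: float = 0.05
    suggestive: float | None = None  # override; default 1/N_snp post-QC
    genomewide: float | None = None

    def validate(self) -> None:
        if self.simulate is None and (
            self.bed_prefix is None or self.phenotypes is None
        ):
            raise ValueError(
                "config needs either a 'simulate' block or input paths "
                "(bed_prefix + phenotypes)"
            )

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        qc = QCConfig(**raw.pop("qc", {}))
        cfg = cls(qc=qc, **raw)
        cfg.validate()
        return cfg

    def to_yaml(self, path) -> None:
        d = asdict(self)
        Path(path).write_text(yaml.safe_dump(d, sort_keys=False))


def load_simulation_config(block: dict, seed: int) -> SimulationConfig:
    """Build a SimulationConfig from a config-file dict."""
    block = dict(block)
    traits = []
    for t in block.pop("traits", []):
        t = dict(t)
        qtls = tuple(QTL(**q) for q in t.pop("qtls", []))
        traits.append(TraitArchitecture(qtls=qtls, **t))
    div = block.pop("founder_divergence", None)
    kwargs = dict(block)
    if div is not None:
        kwargs["founder_divergence"] = FounderDivergence(**div)
    if "pedigree_counts" in kwargs:
        kwargs["pedigree_counts"] = tuple(kwargs["pedigree_counts"])
    kwargs.setdefault("seed", seed)
    return SimulationConfig(traits=tuple(traits), **kwargs)


@dataclass
class RunManifest:
    version: str
    config_hash: str
    seeds: dict = field(default_factory=dict)
    outputs: dict = field(default_factory=dict)  # path -> sha256
    timings: dict = field(default_factory=dict)
    stages_run: list = field(default_factory=list)

    def write(self, path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=2, sort_keys=True))


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _stage_seeds(seed: int) -> dict:
    """Counter-based per-stage seeds derived from the global seed."""
    names = ["simulate", "qc", "prep", "scan", "dimorphism", "permute", "compare"]
    children = np.random.SeedSequence(seed).spawn(len(names))
    return {n: int(c.generate_state(1)[0] % (2**31)) for n, c in zip(names, children)}


def spearman_h2_correlation(h2_male, h2_female) -> tuple[float, float]:
    """Spearman rank correlation of per-trait heritabilities across sexes."""
    a = np.asarray(h2_male, dtype=float)
    b = np.asarray(h2_female, dtype=float)
    if a.size != b.size or a.size < 3:
        raise ValueError("need >= 3 paired heritabilities")
    if np.ptp(a) == 0 or np.ptp(b) == 0:
        import warnings

        warnings.warn("constant heritability vector; correlation undefined")
        return np.nan, np.nan
    rho, p = stats.spearmanr(a, b)
    return float(rho), float(p)


def run_pipeline(config: PipelineConfig, resume: bool = False) -> RunManifest:
    """Execute the full pipeline and return the run manifest.

    With ``resume=True`` a stage whose outputs already exist is skipped
    (its files are still checksummed into the manifest).
    """
    config.validate()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    seeds = _stage_seeds(config.seed)
    cfg_hash = hashlib.sha256(
        json.dumps(asdict(config), sort_keys=True, default=str).encode()
    ).hexdigest()
    manifest = RunManifest(version=__version__, config_hash=cfg_hash, seeds=seeds)

    def record(stage: str, t0: float, *paths: Path) -> None:
        manifest.stages_run.append(stage)
        manifest.timings[stage] = round(time.time() - t0, 3)
        for p in paths:
            manifest.outputs[str(p.relative_to(outdir))] = _sha256(p)

    # --- stage: simulate / load ------------------------------------------
    t0 = time.time()
    if config.simulate is not None:
        sim_cfg = load_simulation_config(config.simulate, seeds["simulate"])
        prefix = outdir / "simulated"
        ped_path = outdir / "pedigree.tsv"
        pheno_path = outdir / "phenotypes.tsv"
        have = all(
            p.exists()
            for p in (prefix.with_suffix(".bed"), ped_path, pheno_path)
        )
        if resume and have:
            g = GenotypeMatrix.read_plink(prefix)
            ped = Pedigree.read(ped_path)
            traits = pd.read_csv(pheno_path, sep="\t", dtype={"id": str})
            log.info("simulate: resumed from existing outputs")
        else:
            g, ped, traits = simulate_study(sim_cfg)
            g.write_plink(prefix)
            ped.write(ped_path)
            traits.to_csv(pheno_path, sep="\t", index=False)
        # genotype samples carry generation/sex/batch from the simulator
        record("simulate", t0, prefix.with_suffix(".bed"),
               prefix.with_suffix(".bim"), prefix.with_suffix(".fam"),
               ped_path, pheno_path)
    else:
        g = read_genotypes(config.bed_prefix)
        ped = Pedigree.read(config.pedigree) if config.pedigree else None
        traits = pd.read_csv(config.phenotypes, sep="\t", dtype={"id": str})
        record("load", t0)

    trait_cols = config.traits or [
        c for c in traits.columns if c not in ("id", "sex", "batch")
    ]

    # --- stage: qc --------------------------------------------------------
    t0 = time.time()
    qcc = config.qc
    g1, rep_s = sample_qc(
        g, ped, call_rate_min=qcc.sample_call_rate,
        mendel_rate_max=qcc.sample_mendel,
    )
    g2, rep_v = snp_qc(
        g1, ped, call_rate_min=qcc.snp_call_rate, maf_min=qcc.maf,
        hwe_p_min=qcc.hwe_p, mendel_rate_max=qcc.snp_mendel,
    )
    qc_path = outdir / "qc_report.tsv"
    pd.concat([rep_s.to_frame(), rep_v.to_frame()]).to_csv(
        qc_path, sep="\t", index=False
    )
    n_snp = rep_v.n_snps_retained
    suggestive, genomewide = significance_thresholds(n_snp)
    suggestive = config.suggestive or suggestive
    genomewide = config.genomewide or genomewide
    record("qc", t0, qc_path)
    log.info("qc: %d SNPs retained; suggestive=%.3g genome-wide=%.3g",
             n_snp, suggestive, genomewide)

    # restrict to analyzed F2 individuals with phenotype rows
    meta = g2.samples
    if "generation" in meta.columns:
        f2_mask = (meta["generation"] == "F2").to_numpy()
    else:
        f2_mask = ~(meta["sire"].astype(str) == "") if "sire" in meta else np.ones(
            len(meta), dtype=bool
        )
    id_col = "id" if "id" in traits.columns else "iid"
    traits = traits.set_index(id_col)
    keep = f2_mask & meta["iid"].isin(traits.index).to_numpy()
    g_f2 = g2.subset(samples=keep)
    tt = traits.loc[g_f2.samples["iid"]].reset_index()
    sex = tt["sex"].astype(str).to_numpy()
    batch = tt["batch"].to_numpy()

    # --- stage: prep ------------------------------------------------------
    t0 = time.time()
    sex_tab = sex_effect_table(tt, trait_cols)
    prep_path = outdir / "sex_effects.tsv"
    sex_tab.to_csv(prep_path, sep="\t", index=False)
    record("prep", t0, prep_path)

    # --- stage: scans + dimorphism ---------------------------------------
    t0 = time.time()
    K = genomic_kinship(g_f2, autosomes_only=True)
    scan_paths, dim_paths = [], []
    dim_tables = {}
    scans_by_trait = {}
    for name in trait_cols:
        y = tt[name].to_numpy(dtype=float)
        scans = stratified_scans(g_f2, y, sex, batch, K)
        scans_by_trait[name] = scans
        for label in ("male", "female", "combined"):
            res = getattr(scans, label)
            if res is not None:
                p = outdir / f"scan_{name}_{label}.tsv"
                res.write(p)
                scan_paths.append(p)
        if scans.male is not None and scans.female is not None:
            dim = z_dimorphism(scans.male, scans.female, maf_min=config.maf_min_z)
            dim_tables[name] = dim
            p = outdir / f"dimorphism_{name}.tsv"
            dim.write(p)
            dim_paths.append(p)
    record("scan", t0, *scan_paths)
    manifest.timings["dimorphism"] = 0.0
    for p in dim_paths:
        manifest.outputs[str(p.relative_to(outdir))] = _sha256(p)
    manifest.stages_run.append("dimorphism")

    # --- stage: heritability permutation ---------------------------------
    t0 = time.time()
    Y = tt[trait_cols].to_numpy(dtype=float)
    ok = ~np.isnan(Y).any(axis=1)
    comparisons = heritability_permutation_test(
        Y[ok], sex[ok], batch[ok], K.submatrix(list(g_f2.samples["iid"][ok])),
        B=config.permutations, seed=seeds["permute"], trait_names=trait_cols,
    )
    categories = {}
    if config.simulate is not None:
        for t in config.simulate.get("traits", []):
            categories[t.get("name")] = t.get("category", "simulated")
    h2_tab = pd.DataFrame(
        {
            "trait": [c.trait for c in comparisons],
            "h2_male": [c.h2_male for c in comparisons],
            "h2_female": [c.h2_female for c in comparisons],
            "abs_difference": [c.observed for c in comparisons],
            "perm_p": [c.pvalue for c in comparisons],
            "B": [c.B for c in comparisons],
            "category": [categories.get(c.trait, "unknown")
                         for c in comparisons],
        }
    )
    h2_path = outdir / "heritability_by_sex.tsv"
    h2_tab.to_csv(h2_path, sep="\t", index=False)
    extra = [h2_path]
    if len(comparisons) >= 3:
        rho, rho_p = spearman_h2_correlation(
            h2_tab["h2_male"], h2_tab["h2_female"]
        )
        sp_path = outdir / "h2_spearman.tsv"
        pd.DataFrame([("rho", rho), ("p", rho_p)],
                     columns=["item", "value"]).to_csv(
            sp_path, sep="\t", index=False
        )
        extra.append(sp_path)
    record("permute", t0, *extra)

    # --- stage: compare ---------------------------------------------------
    t0 = time.time()
    agg_strat, agg_comb = set(), set()
    z_all, z_new = [], []
    for name, scans in scans_by_trait.items():
        if scans.combined is None:
            continue
        cmp_ = compare_scans(
            scans.male, scans.female, scans.combined, suggestive,
            key_prefix=f"{name}:",
        )

        def sig(res):
            if res is None:
                return set()
            return {f"{name}:{s}" for s in res.significant(suggestive)["snp"]}

        strat = sig(scans.male) | sig(scans.female)
        comb = sig(scans.combined)
        agg_strat |= strat
        agg_comb |= comb
        if name in dim_tables:
            zt = dim_tables[name].table
            zs = zt.loc[zt["tested"], ["snp", "z"]]
            z_all.append(zs["z"].to_numpy())
            only = {s.split(":", 1)[1] for s in (strat - comb)}
            z_new.append(zs.loc[zs["snp"].isin(only), "z"].to_numpy())
    overall = ScanComparison.from_sets(agg_strat, agg_comb, suggestive)
    cmp_path = outdir / "scan_comparison.tsv"
    overall.to_frame().to_csv(cmp_path, sep="\t", index=False)
    if z_all and z_new and np.concatenate(z_new).size >= 2:
        t_stat, t_p = zdist_shift_test(
            np.concatenate(z_all), np.concatenate(z_new)
        )
        pd.DataFrame(
            [("t", t_stat), ("p", t_p)], columns=["item", "value"]
        ).to_csv(outdir / "zshift_test.tsv", sep="\t", index=False)
        manifest.outputs["zshift_test.tsv"] = _sha256(outdir / "zshift_test.tsv")
    record("compare", t0, cmp_path)

    manifest.write(outdir / "manifest.json")
    return manifest
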