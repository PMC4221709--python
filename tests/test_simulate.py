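"""Generator correctness: founders, pedigree, gene dropping, artifacts,
trait architecture."""

import numpy as np
import pytest
from scipy import stats

import dimorph as dm
from dimorph.simulate import ConfigurationError, PedigreeError, pedigree_kinship


def _cfg(**kw):
    base = dict(n_snps=40, n_chromosomes=3, pedigree_counts=(2, 6, 4, 10, 120, 3),
                seed=1)
    base.update(kw)
    return dm.SimulationConfig(**base)


class TestFounders:
    def test_fixed_divergence_fixes_haplotypes(self):
        cfg = _cfg(founder_divergence=dm.FounderDivergence.fixed(1.0, 0.0))
        panel = dm.simulate_founders(cfg)
        n_sires = cfg.pedigree_counts[0]
        assert (panel.haplotypes[: 2 * n_sires] == 1).all()
        assert (panel.haplotypes[2 * n_sires :] == 0).all()

    def test_same_seed_reproduces_panel(self):
        cfg = _cfg()
        a, b = dm.simulate_founders(cfg), dm.simulate_founders(cfg)
        assert np.array_equal(a.haplotypes, b.haplotypes)
        assert np.array_equal(a.freq_a, b.freq_a)

    def test_zero_divergence_pools_to_half(self):
        # both breeds fixed at 0.5: pooled founder allele frequency must sit
        # within 3 binomial SD of 0.5
        cfg = _cfg(n_snps=400,
                   founder_divergence=dm.FounderDivergence.fixed(0.5, 0.5))
        panel = dm.simulate_founders(cfg)
        freq = panel.haplotypes.mean()
        n_alleles = panel.haplotypes.size
        assert abs(freq - 0.5) < 3 * np.sqrt(0.25 / n_alleles)

    def test_invalid_divergence_rejected(self):
        with pytest.raises(ConfigurationError):
            dm.FounderDivergence(beta_a=(0.0, 2.0)).validate()
        with pytest.raises(ConfigurationError):
            dm.FounderDivergence(freq_a=1.5).validate()


class TestPedigree:
    def test_paper_design_counts_are_default(self):
        assert dm.SimulationConfig().pedigree_counts == (2, 17, 9, 59, 1912, 6)

    def test_structure(self):
        ped = dm.build_pedigree(_cfg())
        t = ped.table
        assert (t[t.generation == "F0"].sire == "").all()
        f1 = t[t.generation == "F1"]
        f0_ids = set(t[t.generation == "F0"].id)
        assert set(f1.sire) <= f0_ids and set(f1.dam) <= f0_ids
        f2 = t[t.generation == "F2"]
        f1_ids = set(f1.id)
        assert set(f2.sire) <= f1_ids and set(f2.dam) <= f1_ids
        assert (f2.batch >= 0).all() and (t[t.generation != "F2"].batch == -1).all()

    def test_inconsistent_pedigree_rejected(self):
        ped = dm.build_pedigree(_cfg())
        bad = ped.table.copy()
        bad.loc[bad.generation == "F2", "sire"] = "nobody"
        with pytest.raises(PedigreeError):
            dm.Pedigree(bad)

    def test_batches_round_robin(self):
        ped = dm.build_pedigree(_cfg())
        counts = ped.table.query("generation == 'F2'").batch.value_counts()
        assert counts.max() - counts.min() <= 1


class TestGeneDrop:
    def test_f1_forced_heterozygosity(self):
        cfg = _cfg(founder_divergence=dm.FounderDivergence.fixed(1.0, 0.0))
        g = dm.gene_drop(dm.build_pedigree(cfg), dm.simulate_founders(cfg), cfg)
        f1 = (g.samples["generation"] == "F1").to_numpy()
        assert (g.dosages[f1] == 1).all()

    def test_f2_segregation_1_2_1(self):
        cfg = _cfg(founder_divergence=dm.FounderDivergence.fixed(1.0, 0.0),
                   pedigree_counts=(2, 6, 4, 10, 600, 3))
        g = dm.gene_drop(dm.build_pedigree(cfg), dm.simulate_founders(cfg), cfg)
        f2 = (g.samples["generation"] == "F2").to_numpy()
        # one SNP per chromosome so pooled counts are truly multinomial
        cols = np.arange(0, g.n_snps, cfg.n_snps)
        D = g.dosages[np.ix_(f2, cols)]
        counts = [(D == k).sum() for k in (0, 1, 2)]
        p = stats.chisquare(counts, f_exp=np.sum(counts) * np.array(
            [0.25, 0.5, 0.25])).pvalue
        assert p > 0.01

    def test_no_mendel_errors_before_injection(self, small_study):
        g, ped, _ = small_study
        snp_rate, smp_rate = dm.mendel_error_rates(g, ped)
        assert snp_rate.sum() == 0 and smp_rate.sum() == 0

    def test_determinism(self, small_config):
        panel = dm.simulate_founders(small_config)
        ped = dm.build_pedigree(small_config)
        a = dm.gene_drop(ped, panel, small_config)
        b = dm.gene_drop(ped, panel, small_config)
        assert np.array_equal(a.dosages, b.dosages)

    def test_f2_frequency_matches_founder_mean(self, small_study, small_config):
        g, ped, _ = small_study
        panel = dm.simulate_founders(small_config)
        f2 = (g.samples["generation"] == "F2").to_numpy()
        freq = g.dosages[f2].mean(axis=0) / 2.0
        # realized founder-pool frequencies (breeds weighted equally);
        # drift through the handful of F0/F1 parents sets the tolerance
        n_sires = small_config.pedigree_counts[0]
        f_a = panel.haplotypes[: 2 * n_sires].mean(axis=0)
        f_b = panel.haplotypes[2 * n_sires :].mean(axis=0)
        expected = (f_a + f_b) / 2.0
        assert np.corrcoef(freq, expected)[0, 1] > 0.8
        assert np.abs(freq - expected).mean() < 0.1

    def test_sib_genotype_correlation_tracks_kinship(self, small_study):
        g, ped, _ = small_study
        f2 = (g.samples["generation"] == "F2").to_numpy()
        K = dm.genomic_kinship(g.subset(samples=f2)).values
        A, ids = pedigree_kinship(ped)
        A2 = A[np.ix_(f2, f2)]
        iu = np.triu_indices_from(K, 1)
        rho = stats.spearmanr(K[iu], A2[iu]).statistic
        assert rho > 0.5


class TestArtifacts:
    def test_zero_rates_identity(self, small_study, small_config):
        g, _, _ = small_study
        out = dm.inject_artifacts(g, small_config)
        assert np.array_equal(out.dosages, g.dosages)
        assert out.dosages is not g.dosages

    def test_full_missingness(self, small_study, small_config):
        from dataclasses import replace

        g, _, _ = small_study
        cfg = replace(small_config, missing_rate=1.0)
        out = dm.inject_artifacts(g, cfg)
        assert (out.dosages == dm.GenotypeMatrix.MISSING).all()
        assert (g.dosages != dm.GenotypeMatrix.MISSING).all()  # input intact

    def test_missing_rate_realized(self, small_study, small_config):
        from dataclasses import replace

        g, _, _ = small_study
        cfg = replace(small_config, missing_rate=0.1)
        out = dm.inject_artifacts(g, cfg)
        n = out.dosages.size
        realized = (out.dosages == dm.GenotypeMatrix.MISSING).mean()
        assert abs(realized - 0.1) < 3 * np.sqrt(0.1 * 0.9 / n)

    def test_error_rate_perturbs_to_other_dosage(self, small_study, small_config):
        from dataclasses import replace

        g, _, _ = small_study
        cfg = replace(small_config, geno_error_rate=0.05)
        out = dm.inject_artifacts(g, cfg)
        changed = out.dosages != g.dosages
        n = g.dosages.size
        assert abs(changed.mean() - 0.05) < 3 * np.sqrt(0.05 * 0.95 / n)
        assert set(np.unique(out.dosages)) <= {0, 1, 2}


class TestTraits:
    def test_noise_only_variance(self):
        cfg = _cfg(pedigree_counts=(2, 6, 4, 10, 500, 3),
                   traits=(dm.TraitArchitecture(
                       name="t", h2_male=0.0, h2_female=0.0, residual_sd=2.0),))
        ped = dm.build_pedigree(cfg)
        tt = dm.simulate_traits(None, ped, cfg)
        v = tt["t"].var()
        n = len(tt)
        lo = 4.0 * stats.chi2.ppf(0.005, n - 1) / (n - 1)
        hi = 4.0 * stats.chi2.ppf(0.995, n - 1) / (n - 1)
        assert lo < v < hi

    def test_sex_offset_recovered(self):
        # the abdominal-fat-like scenario: 72 g male-female offset with batch
        cfg = _cfg(pedigree_counts=(2, 6, 4, 10, 500, 3),
                   traits=(dm.TraitArchitecture(
                       name="fat", h2_male=0.2, h2_female=0.2,
                       sex_offset=72.0, batch_sd=10.0, residual_sd=30.0),))
        ped = dm.build_pedigree(cfg)
        tt = dm.simulate_traits(None, ped, cfg)
        res = dm.sex_effect_model(tt["fat"], tt["sex"], tt["batch"])
        assert abs(res.estimate - 72.0) < 1.96 * res.se * 1.5

    def test_sex_specific_qtl_slopes(self):
        # one QTL acting in males only: per-sex regression slopes recover
        # (0.5, 0) on average across replicates
        slopes_m, slopes_f = [], []
        for seed in range(20):
            cfg = _cfg(seed=seed, pedigree_counts=(2, 6, 4, 10, 300, 3),
                       founder_divergence=dm.FounderDivergence.fixed(0.9, 0.1),
                       traits=(dm.TraitArchitecture(
                           name="t", qtls=(dm.QTL(7, 0.5, 0.0),),
                           h2_male=0.0, h2_female=0.0),))
            panel = dm.simulate_founders(cfg)
            ped = dm.build_pedigree(cfg)
            g = dm.gene_drop(ped, panel, cfg)
            tt = dm.simulate_traits(g, ped, cfg)
            pos = {i: k for k, i in enumerate(g.samples["iid"])}
            dos = g.dosages[[pos[i] for i in tt["id"]], 7].astype(float)
            for sex, acc in (("M", slopes_m), ("F", slopes_f)):
                m = (tt["sex"] == sex).to_numpy()
                acc.append(np.polyfit(dos[m], tt["t"][m], 1)[0])
        se_m = np.std(slopes_m) / np.sqrt(20)
        se_f = np.std(slopes_f) / np.sqrt(20)
        assert abs(np.mean(slopes_m) - 0.5) < 3 * se_m
        assert abs(np.mean(slopes_f)) < 3 * se_f

    def test_infeasible_heritability_rejected(self):
        with pytest.raises(ConfigurationError):
            dm.TraitArchitecture(name="t", h2_male=1.0).validate(10)

    def test_qtl_outside_panel_rejected(self):
        with pytest.raises(ConfigurationError):
            _cfg(traits=(dm.TraitArchitecture(
                name="t", qtls=(dm.QTL(10**6, 0.5, 0.5),)),)).validate()

    def test_optional_x_chromosome(self):
        cfg = _cfg(include_x=True)
        panel = dm.simulate_founders(cfg)
        ped = dm.build_pedigree(cfg)
        g = dm.gene_drop(ped, panel, cfg)
        assert (g.snps["chrom"] == "X").sum() == cfg.n_snps
        K = dm.genomic_kinship(
            g.subset(samples=(g.samples["generation"] == "F2").to_numpy())
        )
        assert K.autosomal_only

    def test_traits_deterministic(self, small_config, small_study):
        g, ped, traits = small_study
        again = dm.simulate_traits(g, ped, small_config)
        assert np.array_equal(traits["bodyweight"], again["bodyweight"])
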