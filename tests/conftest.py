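import numpy as np
import pandas as pd
import pytest

import dimorph as dm


@pytest.fixture(scope="session")
def small_config():
    """Compact F2 study: 4 chromosomes x 50 SNPs, 240 F2, one polygenic
    trait with a sex offset and batch effects."""
    return dm.SimulationConfig(
        n_snps=50,
        n_chromosomes=4,
        pedigree_counts=(2, 6, 4, 12, 240, 4),
        traits=(
            dm.TraitArchitecture(
                name="bodyweight",
                h2_male=0.4,
                h2_female=0.4,
                sex_offset=1.0,
                batch_sd=0.3,
            ),
        ),
        seed=42,
    )


@pytest.fixture(scope="session")
def small_study(small_config):
    """(genotypes-with-artifacts-off, pedigree, traits) for the small config."""
    panel = dm.simulate_founders(small_config)
    ped = dm.build_pedigree(small_config)
    g = dm.gene_drop(ped, panel, small_config)
    traits = dm.simulate_traits(g, ped, small_config)
    return g, ped, traits


@pytest.fixture(scope="session")
def f2_cohort(small_study):
    """F2-only genotypes with the trait table aligned to them."""
    g, ped, traits = small_study
    f2 = (g.samples["generation"] == "F2").to_numpy()
    gf = g.subset(samples=f2)
    tt = traits.set_index("id").loc[gf.samples["iid"]].reset_index()
    return gf, tt


def toy_matrix(dosages, chrom=None):
    """GenotypeMatrix from a plain array, minimal metadata."""
    d = np.asarray(dosages, dtype=np.int8)
    n, m = d.shape
    snps = pd.DataFrame(
        {
            "chrom": chrom if chrom is not None else ["1"] * m,
            "snp": [f"s{j+1}" for j in range(m)],
            "cm": np.arange(m, dtype=float),
            "bp": np.arange(1, m + 1) * 1000,
            "a1": ["A"] * m,
            "a2": ["B"] * m,
        }
    )
    samples = pd.DataFrame({"iid": [f"i{i+1}" for i in range(n)]})
    return dm.GenotypeMatrix(dosages=d, snps=snps, samples=samples)
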