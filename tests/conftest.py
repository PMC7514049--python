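import numpy as np
import pandas as pd
import pytest

from priortho.synthetic_data import (GenotypeMatrix, SimConfig,
                                     simulate_gene_map, simulate_genotypes,
                                     simulate_gwas_summary, _snp_metadata)


@pytest.fixture(scope="session")
def small_config():
    return SimConfig(seed=42, n_chrom=1, chrom_len_bp=4_000_000,
                     n_genes=120, n_snps_per_chrom=800,
                     n_individuals_gwas=400, n_individuals_validation=300,
                     n_causal_snps=20)


@pytest.fixture(scope="session")
def small_study(small_config):
    """A complete small synthetic study shared across test modules."""
    genes_h, genes_c, orth = simulate_gene_map(small_config)
    geno = simulate_genotypes(small_config)
    cand = genes_c["gene_id"].iloc[:15].tolist()
    sim = simulate_gwas_summary(geno, genes_c, cand, small_config)
    return {"config": small_config, "genes_h": genes_h, "genes_c": genes_c,
            "orth": orth, "geno": geno, "cand": cand, "sim": sim}


def make_genotypes(dosages, positions=None, chrom="1"):
    """Hand-built GenotypeMatrix from an (n_individuals, n_snps) array."""
    dosages = np.asarray(dosages, dtype=np.float32)
    m = dosages.shape[1]
    if positions is None:
        positions = np.arange(1, m + 1) * 1000
    meta = _snp_metadata([chrom] * m, np.asarray(positions), dosages)
    ids = [f"I{i:03d}" for i in range(dosages.shape[0])]
    return GenotypeMatrix(ids, meta, dosages)


@pytest.fixture
def toy_genotypes():
    rng = np.random.default_rng(7)
    return make_genotypes(rng.integers(0, 3, size=(50, 20)))
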