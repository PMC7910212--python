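import numpy as np
import pandas as pd
import pytest

from endopls import GeneratorConfig, GenotypeMatrix, SummaryStats


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def make_geno(dosages, alleles=None, positions=None, chroms=None):
    """Small genotype matrix with simple metadata for unit tests."""
    dosages = np.asarray(dosages, dtype=float)
    n, m = dosages.shape
    alleles = alleles or [("A", "G")] * m
    snps = pd.DataFrame({
        "snp_id": [f"rs{j}" for j in range(m)],
        "chrom": chroms if chroms is not None else ["1"] * m,
        "pos": positions if positions is not None else [1000 * (j + 1) for j in range(m)],
        "counted_allele": [a for a, _ in alleles],
        "other_allele": [b for _, b in alleles],
    })
    subjects = np.array([f"S{i}" for i in range(n)])
    return GenotypeMatrix(subjects, snps, dosages)


def make_stats(betas, ps, alleles=None, snp_ids=None, positions=None, chroms=None):
    m = len(betas)
    alleles = alleles or [("A", "G")] * m
    return SummaryStats(pd.DataFrame({
        "snp_id": snp_ids or [f"rs{j}" for j in range(m)],
        "chrom": chroms if chroms is not None else ["1"] * m,
        "pos": positions if positions is not None else [1000 * (j + 1) for j in range(m)],
        "effect_allele": [a for a, _ in alleles],
        "other_allele": [b for _, b in alleles],
        "beta": betas,
        "se": [0.1] * m,
        "p": ps,
    }))


@pytest.fixture
def small_gen_cfg():
    """Desk-scale generator: fast enough for per-test cohorts."""
    return GeneratorConfig(n_subjects=300, n_snps=300, grid_shape=(8, 8, 8), cluster_radius=1.0,
                           n_causal_shared=20, n_causal_specific=20, seed=7)
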