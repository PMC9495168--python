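import numpy as np
import pytest

from gsfs.containers import GenotypeMatrix
from gsfs.simdata import SimConfig, simulate_population


@pytest.fixture(scope="session")
def small_pop():
    """A modest population with real signal, shared across tests."""
    cfg = SimConfig(
        n_individuals=400, n_chromosomes=3, snps_per_chromosome=200,
        n_qtl=20, h2=0.3, seed=1,
    )
    return cfg, *simulate_population(cfg)


@pytest.fixture(scope="session")
def unstructured_geno():
    """LD-free genotypes for GRM/GWAS property checks."""
    cfg = SimConfig(
        n_individuals=300, n_chromosomes=2, snps_per_chromosome=400,
        n_qtl=0, h2=0.3, ld_rho=0.0, seed=7,
    )
    from gsfs.simdata import simulate_genotypes

    return simulate_genotypes(cfg)


def toy_genotypes(codes, chrom=None, pos=None):
    """Wrap a raw code array in a GenotypeMatrix with trivial metadata."""
    codes = np.asarray(codes, dtype=float)
    n, m = codes.shape
    return GenotypeMatrix(
        codes=codes,
        ids=np.asarray([f"i{k}" for k in range(n)]),
        snp_ids=np.asarray([f"s{k}" for k in range(m)]),
        chrom=np.ones(m, dtype=int) if chrom is None else np.asarray(chrom),
        pos=np.arange(1, m + 1) if pos is None else np.asarray(pos),
    )
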