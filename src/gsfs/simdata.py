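"""Synthetic breeding-population generator.

Emulates the statistical structure genomic-selection studies on dairy
cattle assume: multi-chromosome genotypes with adjacent-marker linkage
disequilibrium, a sparse set of additive QTL producing a target
heritability h2, and de-regressed proofs (DRPs) whose per-individual
noise variance follows the reliability model
``var(DRP_j - TBV_j) = sigma2_a * (1 - r2_j) / r2_j``.

LD is generated by a first-order Gaussian Markov chain on each gamete:
adjacent markers share a latent correlation ``ld_rho``, so marker-level
LD decays geometrically with map distance.  The phenotypic variance is
normalized to 1, making ``sigma2_a = h2``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .containers import GenotypeMatrix, PhenotypeTable

__all__ = [
    "SimConfig",
    "TrueState",
    "simulate_genotypes",
    "simulate_true_effects",
    "simulate_drp",
    "simulate_population",
]


@dataclass(frozen=True)
class SimConfig:
    """Parameters of the synthetic population.

    Defaults describe a desk-scale Holstein-like population: 1500
    individuals, 5 chromosomes x 1000 SNPs, 100 additive QTL with
    h2 = 0.3, moderate adjacent-marker LD, DRP reliabilities straddling
    the 0.40 validation filter, and birth years around a 2013
    reference/validation cutoff.
    """

    n_individuals: int = 1500
    n_chromosomes: int = 5
    snps_per_chromosome: int = 1000
    n_qtl: int = 100
    h2: float = 0.3
    maf_range: tuple[float, float] = (0.05, 0.5)
    ld_rho: float = 0.6
    reliability_range: tuple[float, float] = (0.3, 0.95)
    birth_year_range: tuple[int, int] = (2008, 2015)
    missing_rate: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_individuals <= 0:
            raise ValueError("n_individuals must be positive")
        if self.n_chromosomes <= 0 or self.snps_per_chromosome <= 0:
            raise ValueError("need at least one chromosome and one SNP")
        if self.n_qtl < 0 or self.n_qtl > self.total_snps:
            raise ValueError("n_qtl must be in [0, total SNPs]")
        if not 0 < self.h2 < 1:
            raise ValueError("h2 must be in (0, 1)")
        lo, hi = self.maf_range
        if not (0 < lo <= hi <= 0.5):
            raise ValueError("maf_range must lie within (0, 0.5]")
        if not 0 <= self.ld_rho < 1:
            raise ValueError("ld_rho must be in [0, 1)")
        rlo, rhi = self.reliability_range
        if not (0 < rlo <= rhi <= 1):
            raise ValueError("reliability_range must lie within (0, 1]")
        if not 0 <= self.missing_rate < 1:
            raise ValueError("missing_rate must be in [0, 1)")

    @property
    def total_snps(self) -> int:
        return self.n_chromosomes * self.snps_per_chromosome


@dataclass
class TrueState:
    """Ground truth of the simulation: QTL positions/effects, true
    breeding values and the additive genetic variance they realize."""

    qtl_indices: np.ndarray
    qtl_effects: np.ndarray
    tbv: np.ndarray
    sigma2_a: float

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"qtl_index": self.qtl_indices, "effect": self.qtl_effects}
        )


def _simulate_gametes(
    rng: np.random.Generator, n: int, thresholds: np.ndarray, rho: float
) -> np.ndarray:
    """One chromosome's worth of gametes for n individuals.

    Latent AR(1) chain z_k = rho*z_{k-1} + sqrt(1-rho^2)*eps along the
    chromosome; allele = 1 where z < Phi^-1(p), so each marker carries
    its target allele frequency while adjacent markers stay correlated.
    Returns an (n, 2, m) array of 0/1 alleles.
    """
    m = thresholds.shape[0]
    z = np.empty((n, 2, m))
    z[:, :, 0] = rng.standard_normal((n, 2))
    if m > 1:
        innov = rng.standard_normal((n, 2, m - 1)) * np.sqrt(1.0 - rho**2)
        for k in range(1, m):
            z[:, :, k] = rho * z[:, :, k - 1] + innov[:, :, k - 1]
    return (z < thresholds).astype(float)


def simulate_genotypes(config: SimConfig) -> GenotypeMatrix:
    """Simulate additive-coded genotypes with per-chromosome LD chains."""
    rng = np.random.default_rng(config.seed)
    n, m_chr = config.n_individuals, config.snps_per_chromosome
    blocks, snp_ids, chrom, pos = [], [], [], []
    for c in range(1, config.n_chromosomes + 1):
        p = rng.uniform(*config.maf_range, size=m_chr)
        thresholds = stats.norm.ppf(p)
        gametes = _simulate_gametes(rng, n, thresholds, config.ld_rho)
        blocks.append(gametes.sum(axis=1))
        snp_ids.extend(f"chr{c}_snp{j + 1}" for j in range(m_chr))
        chrom.extend([c] * m_chr)
        pos.extend(1000 * (j + 1) for j in range(m_chr))
    codes = np.concatenate(blocks, axis=1)
    if config.missing_rate > 0:
        mask = rng.random(codes.shape) < config.missing_rate
        codes[mask] = np.nan
    return GenotypeMatrix(
        codes=codes,
        ids=np.asarray([f"ind{j + 1}" for j in range(n)]),
        snp_ids=np.asarray(snp_ids),
        chrom=np.asarray(chrom),
        pos=np.asarray(pos),
    )


def simulate_true_effects(geno: GenotypeMatrix, config: SimConfig) -> TrueState:
    """Draw QTL and additive effects; rescale so var(TBV) = h2.

    With phenotypic variance normalized to 1, the realized additive
    variance sigma2_a equals h2 exactly (empirically, over the simulated
    individuals).  TBV is computed from column-centered genotype codes,
    so it is invariant to which allele is counted.
    """
    if config.n_qtl > geno.n_snps:
        raise ValueError("n_qtl exceeds number of simulated SNPs")
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 1]))
    if config.n_qtl == 0:
        return TrueState(
            qtl_indices=np.empty(0, dtype=int),
            qtl_effects=np.empty(0),
            tbv=np.zeros(geno.n_individuals),
            sigma2_a=0.0,
        )
    qtl = np.sort(rng.choice(geno.n_snps, size=config.n_qtl, replace=False))
    beta = rng.standard_normal(config.n_qtl)
    X = np.nan_to_num(geno.codes[:, qtl], nan=0.0)
    Xc = X - X.mean(axis=0)
    raw = Xc @ beta
    v = raw.var()
    if v == 0:
        raise ValueError("QTL genotypes carry no variance; cannot scale to h2")
    scale = np.sqrt(config.h2 / v)
    return TrueState(
        qtl_indices=qtl,
        qtl_effects=beta * scale,
        tbv=raw * scale,
        sigma2_a=config.h2,
    )


def simulate_drp(
    state: TrueState,
    reliabilities: np.ndarray,
    seed: int,
    birth_year_range: tuple[int, int] = (2008, 2015),
    ids: np.ndarray | None = None,
) -> PhenotypeTable:
    """DRP_j = TBV_j + noise, var(noise_j) = sigma2_a*(1-r2_j)/r2_j.

    r2 = 1 gives a noiseless DRP equal to the true breeding value.
    Birth years are drawn uniformly over ``birth_year_range``.
    """
    r2 = np.asarray(reliabilities, dtype=float)
    if r2.shape[0] != state.tbv.shape[0]:
        raise ValueError("one reliability per individual required")
    if np.any(r2 <= 0) or np.any(r2 > 1):
        raise ValueError("reliabilities must lie in (0, 1]")
    rng = np.random.default_rng(np.random.SeedSequence([seed, 2]))
    noise_sd = np.sqrt(state.sigma2_a * (1.0 - r2) / r2)
    drp = state.tbv + noise_sd * rng.standard_normal(r2.shape[0])
    years = rng.integers(
        birth_year_range[0], birth_year_range[1] + 1, size=r2.shape[0]
    )
    if ids is None:
        ids = np.asarray([f"ind{j + 1}" for j in range(r2.shape[0])])
    return PhenotypeTable(
        pd.DataFrame(
            {"id": ids, "drp": drp, "reliability": r2, "birth_year": years}
        )
    )


def simulate_population(
    config: SimConfig,
) -> tuple[GenotypeMatrix, TrueState, PhenotypeTable]:
    """Full draw: genotypes, ground truth, and a DRP phenotype table
    with reliabilities uniform over ``config.reliability_range``."""
    geno = simulate_genotypes(config)
    truth = simulate_true_effects(geno, config)
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 3]))
    r2 = rng.uniform(*config.reliability_range, size=config.n_individuals)
    pheno = simulate_drp(
        truth, r2, seed=config.seed,
        birth_year_range=config.birth_year_range, ids=geno.ids,
    )
    return geno, truth, pheno
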