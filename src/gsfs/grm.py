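"""Genomic relationship matrices.

Two constructions are provided:

* ``vanraden1`` — VanRaden's first method, ``G = Z Z' / (2 Σ p(1-p))``
  with ``Z`` the column-centered allele counts.  Used for GBLUP.
* ``gcta_eq2`` — per-SNP standardized off-diagonals,
  ``G_jk = (1/N) Σ_i (x_ij - 2p_i)(x_ik - 2p_i) / (2p_i(1-p_i))``,
  with the distinct diagonal
  ``G_jj = 1 + (1/N) Σ_i (x_ij² - (1+2p_i)x_ij + 2p_i²) / (2p_i(1-p_i))``.
  Used as the polygenic covariance in the mixed-model GWAS.

Both are invariant to which allele is counted at each SNP (the centered
cross-products cancel the sign flip), so the ambiguity of minor- versus
major-allele coding conventions is immaterial here.  Missing calls are
mean-imputed as 2p before centering; monomorphic SNPs are excluded from
both numerator and scaling.  Leave-one-chromosome-out (LOCO) variants
rebuild the matrix from all SNPs off the target chromosome.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .containers import GenotypeMatrix

__all__ = [
    "GRM",
    "allele_frequencies",
    "imputed_codes",
    "grm_vanraden1",
    "grm_gcta_eq2",
    "grm_loco",
]


@dataclass
class GRM:
    """A symmetric relationship matrix and how it was built."""

    matrix: np.ndarray
    method: str  # "vanraden1" | "gcta_eq2"
    snp_subset: np.ndarray  # indices actually used (monomorphic excluded)
    scale_constant: float  # 2*sum p(1-p) for vanraden1; N for gcta_eq2

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        if self.matrix.ndim != 2 or self.matrix.shape[0] != self.matrix.shape[1]:
            raise ValueError("GRM must be square")
        if not np.all(np.isfinite(self.matrix)):
            raise ValueError("GRM contains non-finite entries")

    @property
    def n(self) -> int:
        return self.matrix.shape[0]

    def min_eigenvalue(self) -> float:
        return float(np.linalg.eigvalsh(self.matrix)[0])


def allele_frequencies(geno: GenotypeMatrix) -> np.ndarray:
    """Counted-allele frequency per SNP, ignoring missing calls.

    Raises if any SNP has no observed calls.
    """
    observed = ~np.isnan(geno.codes)
    n_obs = observed.sum(axis=0)
    if np.any(n_obs == 0):
        bad = geno.snp_ids[n_obs == 0]
        raise ValueError(f"SNPs with all calls missing: {bad[:5]}...")
    return np.nansum(geno.codes, axis=0) / (2.0 * n_obs)


def imputed_codes(
    geno: GenotypeMatrix, freqs: np.ndarray | None = None
) -> tuple[np.ndarray, np.ndarray]:
    """Genotype codes with missing entries replaced by 2p; returns (X, p)."""
    p = allele_frequencies(geno) if freqs is None else np.asarray(freqs)
    X = geno.codes.copy()
    miss = np.isnan(X)
    if miss.any():
        X[miss] = np.broadcast_to(2.0 * p, X.shape)[miss]
    return X, p


def _resolve_subset(
    geno: GenotypeMatrix, snp_subset: np.ndarray | None, p: np.ndarray
) -> np.ndarray:
    subset = (
        np.arange(geno.n_snps) if snp_subset is None else np.asarray(snp_subset)
    )
    if subset.size == 0:
        raise ValueError("empty SNP subset")
    poly = (p[subset] > 0) & (p[subset] < 1)
    dropped = subset.size - int(poly.sum())
    if dropped:
        warnings.warn(f"excluding {dropped} monomorphic SNPs from GRM")
    subset = subset[poly]
    if subset.size == 0:
        raise ValueError("all SNPs in subset are monomorphic")
    return subset


def grm_vanraden1(
    geno: GenotypeMatrix, snp_subset: np.ndarray | None = None
) -> GRM:
    """VanRaden method-1 GRM: Z Z' / (2 Σ p(1-p))."""
    X, p = imputed_codes(geno)
    subset = _resolve_subset(geno, snp_subset, p)
    ps = p[subset]
    Z = X[:, subset] - 2.0 * ps
    scale = 2.0 * float(np.sum(ps * (1.0 - ps)))
    G = (Z @ Z.T) / scale
    return GRM(matrix=(G + G.T) / 2.0, method="vanraden1",
               snp_subset=subset, scale_constant=scale)


def grm_gcta_eq2(
    geno: GenotypeMatrix, snp_subset: np.ndarray | None = None
) -> GRM:
    """Per-SNP standardized GRM with the distinct diagonal formula."""
    X, p = imputed_codes(geno)
    subset = _resolve_subset(geno, snp_subset, p)
    ps = p[subset]
    Xs = X[:, subset]
    denom = 2.0 * ps * (1.0 - ps)
    W = (Xs - 2.0 * ps) / np.sqrt(denom)
    N = subset.size
    G = (W @ W.T) / N
    diag = 1.0 + np.mean(
        (Xs**2 - (1.0 + 2.0 * ps) * Xs + 2.0 * ps**2) / denom, axis=1
    )
    np.fill_diagonal(G, diag)
    return GRM(matrix=(G + G.T) / 2.0, method="gcta_eq2",
               snp_subset=subset, scale_constant=float(N))


_BUILDERS = {"vanraden1": grm_vanraden1, "gcta_eq2": grm_gcta_eq2}


def grm_loco(
    geno: GenotypeMatrix, method: str, chromosome_to_exclude
) -> GRM:
    """GRM from all SNPs not on the excluded chromosome."""
    if method not in _BUILDERS:
        raise ValueError(f"unknown GRM method {method!r}")
    chroms = geno.chromosomes()
    if chroms.size < 2:
        raise ValueError("LOCO requires at least two chromosomes")
    off = np.flatnonzero(geno.chrom != chromosome_to_exclude)
    if off.size == geno.n_snps:
        warnings.warn(
            f"chromosome {chromosome_to_exclude!r} has no SNPs; "
            "LOCO GRM equals the full-genome GRM"
        )
    return _BUILDERS[method](geno, snp_subset=off)
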