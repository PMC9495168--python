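"""Marker and individual quality control.

Filters mirror standard SNP-array QC: individual call rate, SNP call
rate, minor allele frequency and an exact Hardy-Weinberg equilibrium
test, applied in that order in a single pass, with retention requiring
*strictly greater* than the threshold.  Non-autosomal SNPs are dropped
unconditionally.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import gammaln, logsumexp

from .containers import GenotypeMatrix

__all__ = ["QcThresholds", "QcReport", "hwe_exact_test", "hwe_exact_pvalues", "run_qc"]


@dataclass(frozen=True)
class QcThresholds:
    """Retention thresholds (retain iff metric > threshold, HWE p > hwe_p_min)."""

    ind_call_rate: float = 0.95
    snp_call_rate: float = 0.95
    maf_min: float = 0.01
    hwe_p_min: float = 1e-6
    hwe_method: str = "exact"  # or "chisq"

    def __post_init__(self) -> None:
        for name in ("ind_call_rate", "snp_call_rate", "maf_min", "hwe_p_min"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValueError(f"{name} must lie in [0, 1], got {v}")
        if self.hwe_method not in ("exact", "chisq"):
            raise ValueError("hwe_method must be 'exact' or 'chisq'")


@dataclass
class QcReport:
    """Per-item removal log: kind ('individual'|'snp'), id, reason."""

    removals: pd.DataFrame

    @property
    def n_removed(self) -> int:
        return len(self.removals)

    def counts_by_reason(self) -> pd.Series:
        return self.removals.groupby("reason").size()

    def to_tsv(self, path: str) -> None:
        self.removals.to_csv(path, sep="\t", index=False)


def _hwe_log_weights(n: int, n_minor: int) -> tuple[np.ndarray, np.ndarray]:
    """Log-probabilities of each attainable heterozygote count given
    n diploid individuals and n_minor copies of the rarer allele.

    Conditional on the allele counts, P(het = h) is proportional to
    n! / (n_hom_minor! h! n_hom_major!) * 2^h.
    """
    h = np.arange(n_minor % 2, min(n_minor, 2 * n - n_minor) + 1, 2)
    hom_minor = (n_minor - h) // 2
    hom_major = n - hom_minor - h
    logw = (
        h * np.log(2.0)
        - gammaln(hom_minor + 1)
        - gammaln(h + 1)
        - gammaln(hom_major + 1)
    )
    return h, logw - logsumexp(logw)


def hwe_exact_pvalues(n: int, n_minor: int) -> tuple[np.ndarray, np.ndarray]:
    """Two-sided exact HWE p-value for every attainable het count.

    Returns (het_counts, p_values).  The p-value at het count h sums
    the conditional probabilities of all het counts no more probable
    than h (ties counted, within a 1e-12 relative tolerance).
    """
    if n <= 0:
        raise ValueError("need at least one genotyped individual")
    if not 0 <= n_minor <= n:
        raise ValueError("minor-allele count must lie in [0, n]")
    h, logp = _hwe_log_weights(n, n_minor)
    p = np.exp(logp)
    # cumulative mass of states with probability <= each state's
    order = np.argsort(logp, kind="stable")
    csum = np.cumsum(p[order])
    pvals = np.empty_like(p)
    sorted_logp = logp[order]
    for rank, idx in enumerate(order):
        # include ties just above this rank
        j = rank
        while j + 1 < len(order) and sorted_logp[j + 1] <= logp[idx] + 1e-12:
            j += 1
        pvals[idx] = min(1.0, csum[j])
    return h, pvals


def hwe_exact_test(n_aa: int, n_ab: int, n_bb: int) -> float:
    """Two-sided conditional exact Hardy-Weinberg test.

    Parameters are genotype counts (one homozygote, heterozygote, other
    homozygote).  Monomorphic samples return p = 1 (the observed
    configuration is the only attainable one).
    """
    for c in (n_aa, n_ab, n_bb):
        if c < 0:
            raise ValueError("genotype counts must be non-negative")
    n = n_aa + n_ab + n_bb
    if n == 0:
        raise ValueError("all genotype counts are zero")
    n_a = 2 * n_aa + n_ab
    n_minor = min(n_a, 2 * n - n_a)
    h, pvals = hwe_exact_pvalues(n, n_minor)
    return float(pvals[np.searchsorted(h, n_ab)])


def _hwe_chisq(n_aa: int, n_ab: int, n_bb: int) -> float:
    """1-df chi-square HWE test (optional alternative to the exact test)."""
    from scipy.stats import chi2

    n = n_aa + n_ab + n_bb
    p = (2 * n_aa + n_ab) / (2 * n)
    exp = np.array([n * p**2, 2 * n * p * (1 - p), n * (1 - p) ** 2])
    obs = np.array([n_aa, n_ab, n_bb], dtype=float)
    nz = exp > 0
    stat = np.sum((obs[nz] - exp[nz]) ** 2 / exp[nz])
    return float(chi2.sf(stat, df=1))


def _is_autosomal(chrom: np.ndarray) -> np.ndarray:
    out = np.empty(chrom.shape[0], dtype=bool)
    for i, c in enumerate(chrom):
        try:
            int(c)
            out[i] = True
        except (TypeError, ValueError):
            out[i] = False
    return out


def run_qc(
    geno: GenotypeMatrix, thresholds: QcThresholds | None = None
) -> tuple[GenotypeMatrix, QcReport]:
    """Apply the QC filters; returns the filtered matrix and a report.

    Order: non-autosomal SNPs dropped; individuals by call rate; then
    SNPs by call rate, MAF (computed on retained individuals) and HWE,
    each SNP removed for the first criterion it fails.
    """
    if thresholds is None:
        thresholds = QcThresholds()
    if geno.n_individuals == 0 or geno.n_snps == 0:
        raise ValueError("empty genotype matrix")
    removals: list[tuple[str, str, str]] = []

    autosomal = _is_autosomal(geno.chrom)
    for sid in geno.snp_ids[~autosomal]:
        removals.append(("snp", sid, "non_autosomal"))
    keep_snps = np.flatnonzero(autosomal)
    codes = geno.codes[:, keep_snps]

    observed = ~np.isnan(codes)
    ind_cr = observed.mean(axis=1) if codes.shape[1] else np.ones(geno.n_individuals)
    keep_ind = ind_cr > thresholds.ind_call_rate
    for iid in geno.ids[~keep_ind]:
        removals.append(("individual", iid, "call_rate"))
    codes = codes[keep_ind]
    if codes.shape[0] == 0:
        raise ValueError("QC removed every individual")

    observed = ~np.isnan(codes)
    n_obs = observed.sum(axis=0)
    snp_cr = n_obs / codes.shape[0]
    alt = np.nansum(codes, axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        freq = alt / (2 * n_obs)
    maf = np.minimum(freq, 1 - freq)

    keep = np.ones(codes.shape[1], dtype=bool)
    reasons = np.empty(codes.shape[1], dtype=object)
    fail_cr = snp_cr <= thresholds.snp_call_rate
    reasons[fail_cr & keep] = "call_rate"
    keep &= ~fail_cr
    fail_maf = ~(maf > thresholds.maf_min)  # catches NaN (all-missing) too
    reasons[fail_maf & keep] = "maf"
    keep &= ~fail_maf
    for j in np.flatnonzero(keep):
        col = codes[:, j]
        col = col[~np.isnan(col)]
        n_bb = int(np.sum(col == 2))
        n_ab = int(np.sum(col == 1))
        n_aa = int(np.sum(col == 0))
        if thresholds.hwe_method == "exact":
            p = hwe_exact_test(n_aa, n_ab, n_bb)
        else:
            p = _hwe_chisq(n_aa, n_ab, n_bb)
        if not p > thresholds.hwe_p_min:
            keep[j] = False
            reasons[j] = "hwe"
    kept_ids = geno.snp_ids[keep_snps]
    for j in np.flatnonzero(~keep):
        removals.append(("snp", kept_ids[j], str(reasons[j])))
    if not keep.any():
        raise ValueError("QC removed every SNP")

    filtered = GenotypeMatrix(
        codes=codes[:, keep],
        ids=geno.ids[keep_ind],
        snp_ids=geno.snp_ids[keep_snps][keep],
        chrom=geno.chrom[keep_snps][keep],
        pos=geno.pos[keep_snps][keep],
    )
    report = QcReport(
        pd.DataFrame(removals, columns=["kind", "id", "reason"])
    )
    return filtered, report
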