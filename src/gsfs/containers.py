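"""Core in-memory containers shared across the pipeline.

Genotypes are held as an individuals x SNPs matrix of additive allele
counts (0/1/2) in float64 with ``NaN`` marking missing calls, together
with a SNP map (chromosome, position).  Phenotypes are a plain pandas
DataFrame wrapper with the columns the de-regressed-proof (DRP) workflow
needs: the DRP itself, its reliability r2 and the birth year used for
the reference/validation split.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["GenotypeMatrix", "PhenotypeTable"]


@dataclass
class GenotypeMatrix:
    """Additive-coded genotypes with a SNP map.

    Parameters
    ----------
    codes : ndarray, shape (n_individuals, n_snps)
        Allele counts in {0, 1, 2}; missing calls are NaN.
    ids : ndarray of str
        Individual identifiers (unique).
    snp_ids : ndarray of str
        SNP identifiers (unique).
    chrom : ndarray
        Chromosome label per SNP (int for autosomes; "X"/"Y"/"MT"
        style strings are treated as non-autosomal by QC).
    pos : ndarray of int
        Base-pair position per SNP.
    """

    codes: np.ndarray
    ids: np.ndarray
    snp_ids: np.ndarray
    chrom: np.ndarray
    pos: np.ndarray

    def __post_init__(self) -> None:
        self.codes = np.asarray(self.codes, dtype=float)
        self.ids = np.asarray(self.ids)
        self.snp_ids = np.asarray(self.snp_ids)
        self.chrom = np.asarray(self.chrom)
        self.pos = np.asarray(self.pos, dtype=int)
        n, m = self.codes.shape
        if len(self.ids) != n:
            raise ValueError(f"{len(self.ids)} ids for {n} genotype rows")
        if not (len(self.snp_ids) == len(self.chrom) == len(self.pos) == m):
            raise ValueError("SNP map length does not match genotype columns")

    @property
    def n_individuals(self) -> int:
        return self.codes.shape[0]

    @property
    def n_snps(self) -> int:
        return self.codes.shape[1]

    def chromosomes(self) -> np.ndarray:
        """Unique chromosome labels in map order."""
        _, idx = np.unique(self.chrom, return_index=True)
        return self.chrom[np.sort(idx)]

    def snp_indices_on(self, chromosome) -> np.ndarray:
        return np.flatnonzero(self.chrom == chromosome)

    def subset_individuals(self, row_idx: np.ndarray) -> "GenotypeMatrix":
        row_idx = np.asarray(row_idx)
        return GenotypeMatrix(
            codes=self.codes[row_idx],
            ids=self.ids[row_idx],
            snp_ids=self.snp_ids,
            chrom=self.chrom,
            pos=self.pos,
        )

    def subset_snps(self, col_idx: np.ndarray) -> "GenotypeMatrix":
        col_idx = np.asarray(col_idx)
        return GenotypeMatrix(
            codes=self.codes[:, col_idx],
            ids=self.ids,
            snp_ids=self.snp_ids[col_idx],
            chrom=self.chrom[col_idx],
            pos=self.pos[col_idx],
        )

    def snp_map(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"snp_id": self.snp_ids, "chrom": self.chrom, "pos": self.pos}
        )


@dataclass
class PhenotypeTable:
    """Per-individual DRP records.

    ``frame`` has columns: id, drp, reliability, birth_year.
    Reliability is the DRP reliability r2 in (0, 1].
    """

    frame: pd.DataFrame = field(repr=False)

    REQUIRED = ("id", "drp", "reliability", "birth_year")

    def __post_init__(self) -> None:
        missing = [c for c in self.REQUIRED if c not in self.frame.columns]
        if missing:
            raise ValueError(f"phenotype table missing columns: {missing}")
        if self.frame["id"].duplicated().any():
            raise ValueError("duplicate individual ids in phenotype table")
        r2 = self.frame["reliability"].to_numpy(dtype=float)
        if np.any(r2 <= 0) or np.any(r2 > 1):
            raise ValueError("reliability must lie in (0, 1]")

    @property
    def ids(self) -> np.ndarray:
        return self.frame["id"].to_numpy()

    @property
    def drp(self) -> np.ndarray:
        return self.frame["drp"].to_numpy(dtype=float)

    @property
    def reliability(self) -> np.ndarray:
        return self.frame["reliability"].to_numpy(dtype=float)

    @property
    def birth_year(self) -> np.ndarray:
        return self.frame["birth_year"].to_numpy(dtype=int)

    def __len__(self) -> int:
        return len(self.frame)

    def aligned_to(self, ids: np.ndarray) -> "PhenotypeTable":
        """Reorder rows to match an external id ordering."""
        indexed = self.frame.set_index("id")
        return PhenotypeTable(indexed.loc[np.asarray(ids)].reset_index())
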