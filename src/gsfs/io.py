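"""Readers and writers for the formats the pipeline exchanges.

Genotypes travel either as VCF (diploid GT fields; read back with
cyvcf2) or as a tab-delimited additive matrix plus a SNP map; phenotypes
and ground truth as TSV.  GRMs are written as labelled square TSV and,
for interchange with GCTA-family tools, in the GCTA binary dialect
(lower-triangle float32 ``.grm.bin`` with ``.grm.N.bin`` and ``.grm.id``).
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .containers import GenotypeMatrix, PhenotypeTable

__all__ = [
    "write_genotypes_tsv",
    "read_genotypes_tsv",
    "write_vcf",
    "read_vcf",
    "write_phenotypes_tsv",
    "read_phenotypes_tsv",
    "write_grm_tsv",
    "read_grm_tsv",
    "write_grm_gcta_bin",
    "read_grm_gcta_bin",
]


def write_genotypes_tsv(geno: GenotypeMatrix, prefix: str) -> None:
    """Write ``<prefix>.geno.tsv`` (individuals x SNPs) and ``<prefix>.map.tsv``."""
    frame = pd.DataFrame(geno.codes, index=geno.ids, columns=geno.snp_ids)
    frame.index.name = "id"
    frame.to_csv(prefix + ".geno.tsv", sep="\t", na_rep="NA")
    geno.snp_map().to_csv(prefix + ".map.tsv", sep="\t", index=False)


def read_genotypes_tsv(prefix: str) -> GenotypeMatrix:
    frame = pd.read_csv(prefix + ".geno.tsv", sep="\t", index_col="id")
    snp_map = pd.read_csv(prefix + ".map.tsv", sep="\t")
    return GenotypeMatrix(
        codes=frame.to_numpy(dtype=float),
        ids=frame.index.to_numpy(dtype=str),
        snp_ids=snp_map["snp_id"].to_numpy(dtype=str),
        chrom=snp_map["chrom"].to_numpy(),
        pos=snp_map["pos"].to_numpy(),
    )


def write_vcf(geno: GenotypeMatrix, path: str) -> None:
    """Write genotypes as a minimal diploid VCF 4.2.

    Additive code 0 -> 0/0, 1 -> 0/1, 2 -> 1/1, missing -> ./.; the
    counted (ALT) allele is arbitrarily A>G since the simulator carries
    no sequence context.
    """
    gt_map = {0.0: "0/0", 1.0: "0/1", 2.0: "1/1"}
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        for c in geno.chromosomes():
            fh.write(f"##contig=<ID={c}>\n")
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(map(str, geno.ids))
            + "\n"
        )
        for j in range(geno.n_snps):
            col = geno.codes[:, j]
            gts = "\t".join(
                "./." if np.isnan(v) else gt_map[float(v)] for v in col
            )
            fh.write(
                f"{geno.chrom[j]}\t{geno.pos[j]}\t{geno.snp_ids[j]}"
                f"\tA\tG\t.\t.\t.\tGT\t{gts}\n"
            )


def read_vcf(path: str) -> GenotypeMatrix:
    """Read a diploid VCF into additive coding via cyvcf2 (gts012)."""
    from cyvcf2 import VCF

    vcf = VCF(path, gts012=True)
    ids = np.asarray(vcf.samples)
    codes, snp_ids, chrom, pos = [], [], [], []
    for var in vcf:
        g = var.gt_types.astype(float)  # 0,1,2 dosage; 3 = missing
        g[g == 3] = np.nan
        codes.append(g)
        snp_ids.append(var.ID if var.ID else f"{var.CHROM}_{var.POS}")
        chrom.append(var.CHROM)
        pos.append(var.POS)
    vcf.close()
    if not codes:
        raise ValueError(f"no variants in {path}")
    chrom_arr = np.asarray(chrom)
    try:
        chrom_arr = chrom_arr.astype(int)
    except ValueError:
        pass
    return GenotypeMatrix(
        codes=np.column_stack(codes),
        ids=ids,
        snp_ids=np.asarray(snp_ids),
        chrom=chrom_arr,
        pos=np.asarray(pos, dtype=int),
    )


def write_phenotypes_tsv(pheno: PhenotypeTable, path: str) -> None:
    pheno.frame.to_csv(path, sep="\t", index=False)


def read_phenotypes_tsv(path: str) -> PhenotypeTable:
    return PhenotypeTable(pd.read_csv(path, sep="\t"))


def write_grm_tsv(matrix: np.ndarray, ids: np.ndarray, path: str) -> None:
    pd.DataFrame(matrix, index=ids, columns=ids).to_csv(path, sep="\t")


def read_grm_tsv(path: str) -> tuple[np.ndarray, np.ndarray]:
    frame = pd.read_csv(path, sep="\t", index_col=0)
    return frame.to_numpy(dtype=float), frame.index.to_numpy(dtype=str)


def write_grm_gcta_bin(
    matrix: np.ndarray, ids: np.ndarray, prefix: str, n_snps: int
) -> None:
    """GCTA binary GRM dialect: row-major lower triangle, float32."""
    n = matrix.shape[0]
    tri = matrix[np.tril_indices(n)].astype("<f4")
    tri.tofile(prefix + ".grm.bin")
    np.full(tri.shape, n_snps, dtype="<f4").tofile(prefix + ".grm.N.bin")
    with open(prefix + ".grm.id", "w") as fh:
        for i in ids:
            fh.write(f"{i}\t{i}\n")


def read_grm_gcta_bin(prefix: str) -> tuple[np.ndarray, np.ndarray]:
    ids = np.asarray(
        [line.split("\t")[1].strip() for line in open(prefix + ".grm.id")]
    )
    n = len(ids)
    tri = np.fromfile(prefix + ".grm.bin", dtype="<f4")
    if tri.size != n * (n + 1) // 2:
        raise ValueError(f"GRM size mismatch for {prefix}: {tri.size} values, n={n}")
    out = np.zeros((n, n))
    out[np.tril_indices(n)] = tri
    out = out + out.T - np.diag(np.diag(out))
    return out, ids
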