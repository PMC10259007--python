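"""Readers and writers for the pipeline's plain-text interchange formats.

Genotypes travel as VCF v4.2 (GT field only) with the SNP map recoverable
from the VCF columns; pedigrees, phenotypes, relationship matrices and
reports are TSV with headers.  Gene annotations are accepted as GFF3
(gene features) or 4-column BED.
"""

from __future__ import annotations

import re
from pathlib import Path

import numpy as np
import pandas as pd

from .containers import GenotypeMatrix, Pedigree, validate_snp_map

_GT_CODE = {2: "0/0", 1: "0/1", 0: "1/1", -1: "./."}


def write_vcf(genotypes: GenotypeMatrix, path: str | Path) -> None:
    """Write genotypes as VCF v4.2 with GT only.

    The dosage convention is the count of the REF allele, so code 2 maps
    to 0/0 and code 0 to 1/1.
    """
    path = Path(path)
    sm = genotypes.snp_map
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        for chrom in pd.unique(sm["chrom"]):
            fh.write(f"##contig=<ID={chrom}>\n")
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(genotypes.ids)
            + "\n"
        )
        codes = genotypes.codes
        for j, rec in enumerate(sm.itertuples(index=False)):
            gts = "\t".join(_GT_CODE[int(c)] for c in codes[:, j])
            fh.write(
                f"{rec.chrom}\t{rec.pos}\t{rec.snp_id}\t{rec.ref}\t{rec.alt}"
                f"\t.\t.\t.\tGT\t{gts}\n"
            )


def read_vcf(path: str | Path) -> GenotypeMatrix:
    """Read a VCF (plain or bgzipped) into a genotype matrix via cyvcf2."""
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    ids = list(vcf.samples)
    rows, recs = [], []
    for i, var in enumerate(vcf):
        # gt_types: 0=hom-ref, 1=het, 2=unknown, 3=hom-alt; dosage counts REF
        gt = var.gt_types
        code = np.where(gt == 0, 2, np.where(gt == 1, 1, np.where(gt == 3, 0, -1)))
        rows.append(code.astype(np.int8))
        recs.append(
            (
                var.ID or f"snp{i + 1}",
                var.CHROM,
                var.POS,
                var.REF,
                var.ALT[0] if var.ALT else "N",
            )
        )
    snp_map = pd.DataFrame(recs, columns=["snp_id", "chrom", "pos", "ref", "alt"])
    return GenotypeMatrix(ids=ids, snp_map=snp_map, codes=np.array(rows).T)


def write_pedigree(pedigree: Pedigree, path: str | Path) -> None:
    pedigree.df.to_csv(path, sep="\t", index=False)


def read_pedigree(path: str | Path) -> Pedigree:
    df = pd.read_csv(path, sep="\t", dtype={"id": str, "sire": str, "dam": str})
    return Pedigree(df)


def write_snp_map(snp_map: pd.DataFrame, path: str | Path) -> None:
    validate_snp_map(snp_map).to_csv(path, sep="\t", index=False)


def read_snp_map(path: str | Path) -> pd.DataFrame:
    return validate_snp_map(pd.read_csv(path, sep="\t", dtype={"snp_id": str, "chrom": str}))


def write_table(table: pd.DataFrame, path: str | Path) -> None:
    table.to_csv(path, sep="\t", index=False)


def read_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", dtype={"id": str, "dam": str, "sire": str})


def write_relationship_matrix(ids: list[str], values: np.ndarray, path: str | Path) -> None:
    pd.DataFrame(values, index=ids, columns=ids).to_csv(path, sep="\t")


def read_relationship_matrix(path: str | Path) -> tuple[list[str], np.ndarray]:
    df = pd.read_csv(path, sep="\t", index_col=0)
    return [str(c) for c in df.columns], df.to_numpy(dtype=np.float64)


_GFF_ATTR_PATTERNS = [
    re.compile(r"(?:^|;)\s*Name=([^;]+)"),
    re.compile(r"(?:^|;)\s*gene(?:_id)?=([^;]+)"),
    re.compile(r"(?:^|;)\s*ID=([^;]+)"),
]


def _gff_gene_name(attributes: str) -> str | None:
    for pattern in _GFF_ATTR_PATTERNS:
        m = pattern.search(attributes)
        if m:
            return m.group(1)
    return None


def read_annotation(path: str | Path) -> pd.DataFrame:
    """Gene intervals (chrom, start, end, gene; 1-based closed) from GFF3
    gene features or 4-column BED (half-open, converted)."""
    path = Path(path)
    if path.suffix.lower() == ".bed":
        bed = pd.read_csv(
            path, sep="\t", header=None, comment="#",
            names=["chrom", "start", "end", "gene"], usecols=range(4),
        )
        bed["start"] = bed["start"].astype(int) + 1  # BED is 0-based half-open
        bed["end"] = bed["end"].astype(int)
        return bed[["chrom", "start", "end", "gene"]]
    rows = []
    with open(path) as fh:
        for line in fh:
            if line.startswith("#") or not line.strip():
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 9 or parts[2] != "gene":
                continue
            name = _gff_gene_name(parts[8]) or f"{parts[0]}:{parts[3]}-{parts[4]}"
            rows.append((parts[0], int(parts[3]), int(parts[4]), name))
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "gene"])


def read_line_genotypes(path: str | Path) -> pd.DataFrame:
    """Isogenic line alleles: 2-column TSV (snp_id, allele)."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    if list(df.columns[:2]) != ["snp_id", "allele"]:
        df = df.iloc[:, :2]
        df.columns = ["snp_id", "allele"]
    return df
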