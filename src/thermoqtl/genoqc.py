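"""Genotype quality control: individual call rate, SNP call rate, minor
allele frequency and a Hardy-Weinberg chi-square test.

Thresholds follow common array-QC practice for aquaculture panels:
individuals genotyped for less than 90% of SNPs are removed first, then
SNPs are kept only if call rate > 0.97, MAF > 0.05 and the Hardy-Weinberg
p-value > 1e-5 (all strict inequalities in the stated direction).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .containers import GenotypeMatrix


@dataclass
class QcReport:
    """Per-rule removal counts plus per-SNP statistics.

    ``snp_stats`` columns: snp_id, call_rate, maf, hwe_chi2, hwe_p, removed,
    rule (first-triggering rule or empty).
    """

    n_input_individuals: int = 0
    n_input_snps: int = 0
    removed_individuals: pd.DataFrame = field(default_factory=pd.DataFrame)
    snp_stats: pd.DataFrame = field(default_factory=pd.DataFrame)

    @property
    def n_removed_individuals(self) -> int:
        return len(self.removed_individuals)

    @property
    def n_removed_snps(self) -> int:
        if self.snp_stats.empty:
            return 0
        return int(self.snp_stats["removed"].sum())

    def counts_by_rule(self) -> pd.Series:
        if self.snp_stats.empty:
            return pd.Series(dtype=int)
        removed = self.snp_stats[self.snp_stats["removed"]]
        return removed["rule"].value_counts()


def qc_individuals(
    genotypes: GenotypeMatrix, min_call: float = 0.90
) -> tuple[GenotypeMatrix, QcReport]:
    """Remove individuals genotyped for less than ``min_call`` of the SNPs.

    The rule is strictly "less than": a call rate exactly at the threshold
    is retained.
    """
    if genotypes.n_individuals == 0 or genotypes.n_snps == 0:
        raise ValueError("empty genotype matrix")
    call = genotypes.call_rate_individuals()
    keep = call >= min_call
    report = QcReport(
        n_input_individuals=genotypes.n_individuals,
        n_input_snps=genotypes.n_snps,
        removed_individuals=pd.DataFrame(
            {
                "id": [genotypes.ids[i] for i in np.flatnonzero(~keep)],
                "call_rate": call[~keep],
                "rule": "individual_call_rate",
            }
        ),
    )
    return genotypes.subset_individuals(keep), report


def hwe_test(n_aa: int, n_ab: int, n_bb: int) -> tuple[float, float]:
    """Pearson 1-df chi-square test against Hardy-Weinberg proportions.

    Expected counts are p^2, 2pq, q^2 times the total, with p the observed
    reference-allele frequency; no continuity correction.  Monomorphic
    counts return (nan, nan).
    """
    counts = np.array([n_aa, n_ab, n_bb], dtype=np.float64)
    if np.any(counts < 0):
        raise ValueError("genotype counts must be non-negative")
    n = counts.sum()
    if n < 1:
        raise ValueError("need at least one genotyped individual")
    p = (2 * counts[0] + counts[1]) / (2 * n)
    if p in (0.0, 1.0):
        return float("nan"), float("nan")
    q = 1.0 - p
    expected = n * np.array([p * p, 2 * p * q, q * q])
    chi2 = float(np.sum((counts - expected) ** 2 / expected))
    return chi2, float(stats.chi2.sf(chi2, df=1))


def _hwe_vectorised(codes: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Chi-square and p per SNP column; nan for monomorphic columns."""
    called = codes >= 0
    n_bb = ((codes == 0) & called).sum(axis=0).astype(np.float64)
    n_ab = (codes == 1).sum(axis=0).astype(np.float64)
    n_aa = (codes == 2).sum(axis=0).astype(np.float64)
    n = n_aa + n_ab + n_bb
    with np.errstate(divide="ignore", invalid="ignore"):
        p = (2 * n_aa + n_ab) / (2 * n)
        q = 1.0 - p
        e_aa, e_ab, e_bb = n * p * p, n * 2 * p * q, n * q * q
        chi2 = (
            (n_aa - e_aa) ** 2 / e_aa
            + (n_ab - e_ab) ** 2 / e_ab
            + (n_bb - e_bb) ** 2 / e_bb
        )
    mono = (p <= 0.0) | (p >= 1.0) | (n == 0)
    chi2 = np.where(mono, np.nan, chi2)
    pval = np.where(mono, np.nan, stats.chi2.sf(np.nan_to_num(chi2), df=1))
    return chi2, pval


def qc_snps(
    genotypes: GenotypeMatrix,
    min_call: float = 0.97,
    min_maf: float = 0.05,
    min_hwe_p: float = 1e-5,
) -> tuple[GenotypeMatrix, QcReport]:
    """Keep SNPs with call rate > ``min_call``, MAF > ``min_maf`` and
    Hardy-Weinberg p > ``min_hwe_p`` (strict inequalities).

    MAF is computed on non-missing calls only.  Apply individual QC first;
    statistics here are computed once on the retained individuals, so
    rerunning on the output removes nothing.
    """
    call = genotypes.call_rate_snps()
    maf = genotypes.maf()
    chi2, hwe_p = _hwe_vectorised(genotypes.codes)

    fail_call = ~(call > min_call)
    fail_maf = ~(maf > min_maf)
    fail_hwe = ~(np.nan_to_num(hwe_p, nan=1.0) > min_hwe_p)
    removed = fail_call | fail_maf | fail_hwe
    rule = np.full(genotypes.n_snps, "", dtype=object)
    rule[fail_hwe] = "hwe"
    rule[fail_maf] = "maf"
    rule[fail_call] = "snp_call_rate"  # first-triggering rule wins

    report = QcReport(
        n_input_individuals=genotypes.n_individuals,
        n_input_snps=genotypes.n_snps,
        snp_stats=pd.DataFrame(
            {
                "snp_id": genotypes.snp_map["snp_id"],
                "call_rate": call,
                "maf": maf,
                "hwe_chi2": chi2,
                "hwe_p": hwe_p,
                "removed": removed,
                "rule": rule,
            }
        ),
    )
    return genotypes.subset_snps(~removed), report
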