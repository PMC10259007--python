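"""Replicated simulation experiments at desk scale.

These functions regenerate the study design end to end (pedigree ->
genotypes -> challenge -> analysis) and measure how well the pipeline
recovers the generating parameters.  They are the backbone of the
recovery checks and of ``scripts/acceptance.py``; each takes one master
seed from which every per-replicate seed is derived.

Desk-scale defaults (n = 800-1,000 offspring, 2,000-3,000 SNPs) keep a
replicate in seconds while preserving the family structure -- 99 sires x
76 dams in 10 factorial blocks -- that identifies the dam and additive
components.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from . import gwas, peaks, pheno, qtlcall, relmat, syndata, varcomp
from .containers import GenotypeMatrix, Pedigree
from .syndata import QtlEffect, TruthRecord


def _rep_seed(master: int, rep: int) -> int:
    return int((master * 10_007 + rep * 101) % (2**31 - 1))


def simulate_study(
    seed: int,
    n_offspring: int = 800,
    n_snps: int = 3000,
    h2: float = 0.29,
    dam_ratio: float = 0.06,
    qtls: list[QtlEffect] | None = None,
    qtl_freqs: dict[str, float] | None = None,
    missing_rate: float = 0.0,
) -> tuple[Pedigree, GenotypeMatrix, TruthRecord, pd.DataFrame]:
    """One synthetic study: factorial matings, gene-dropped genotypes,
    challenge phenotypes standardized within group.

    ``qtl_freqs`` pins the founder allele frequency of selected QTL SNPs
    (e.g. to put a planted locus at a target MAF).
    """
    ped = syndata.make_pedigree(seed=seed, n_offspring=n_offspring)
    snp_map = syndata.default_snp_map(n_snps=n_snps, seed=seed)
    rng = np.random.default_rng(seed + 7)
    freqs = rng.uniform(0.1, 0.9, size=n_snps)
    if qtl_freqs:
        lookup = {s: i for i, s in enumerate(snp_map["snp_id"])}
        for snp_id, f in qtl_freqs.items():
            freqs[lookup[snp_id]] = f
    geno = syndata.gene_drop(ped, snp_map, freqs, missing_rate=missing_rate, seed=seed + 1)
    truth = syndata.challenge_truth(h2=h2, dam_ratio=dam_ratio, qtls=qtls or [])
    challenge = syndata.simulate_challenge(ped, geno, truth, seed=seed + 2)
    challenge = pheno.standardize_rtle(challenge)
    return ped, geno, truth, challenge


def h2_dam_recovery(
    n_reps: int = 20,
    seed: int = 1,
    n_offspring: int = 800,
    n_snps: int = 3000,
    h2: float = 0.29,
    dam_ratio: float = 0.06,
    blend_weight: float = 0.95,
) -> pd.DataFrame:
    """Genomic REML recovery of heritability and the dam variance share.

    Each replicate simulates a fresh study under the configured ratios,
    builds the blended VanRaden matrix over the phenotyped offspring
    (blend target: pedigree A) and fits the univariate day + dam + animal
    model.  Returns one row per replicate (h2, dam_ratio, converged).
    """
    rows = []
    for rep in range(n_reps):
        s = _rep_seed(seed, rep)
        ped, geno, truth, challenge = simulate_study(
            s, n_offspring=n_offspring, n_snps=n_snps, h2=h2, dam_ratio=dam_ratio
        )
        a = relmat.a_matrix(ped)
        off = geno.subset_individuals(challenge["id"].tolist())
        g = relmat.g_matrix(off, blend_weight=blend_weight, a=a)
        fit = varcomp.reml_fit(challenge, "tle", g, include_dam=True)
        rows.append(
            {"rep": rep, "h2": fit.h2, "dam_ratio": fit.dam_ratio,
             "converged": fit.converged}
        )
    return pd.DataFrame(rows)


def contrast_recovery(
    n_reps: int = 20,
    seed: int = 1,
    n_offspring: int = 1000,
    n_snps: int = 2000,
    hom_diff_sd: float = 0.69,
    qtl_maf: float = 0.42,
    h2: float = 0.29,
    dam_ratio: float = 0.06,
    blend_weight: float = 0.95,
) -> pd.DataFrame:
    """Recovery of the homozygote contrast at a planted additive QTL.

    The allele substitution effect is half the target homozygote
    difference (in phenotypic-SD units); the QTL founder frequency is
    pinned at the target MAF.  Each replicate fits the null animal model
    and contrasts the day/dam-adjusted phenotype at the planted SNP.
    Returns per-replicate difference in % of the phenotypic SD plus the
    dominance estimate and its p-value.
    """
    rows = []
    for rep in range(n_reps):
        s = _rep_seed(seed, rep)
        snp_map = syndata.default_snp_map(n_snps=n_snps, seed=s)
        qtl_snp = snp_map["snp_id"].iloc[n_snps // 2]
        qtl = QtlEffect(qtl_snp, add_effect=hom_diff_sd / 2.0)
        ped, geno, truth, challenge = simulate_study(
            s, n_offspring=n_offspring, n_snps=n_snps, h2=h2,
            dam_ratio=dam_ratio, qtls=[qtl], qtl_freqs={qtl_snp: qtl_maf},
        )
        a = relmat.a_matrix(ped)
        off = geno.subset_individuals(challenge["id"].tolist())
        g = relmat.g_matrix(off, blend_weight=blend_weight, a=a)
        fit = varcomp.reml_fit(challenge, "tle", g, include_dam=True)
        contrast = peaks.peak_contrast(challenge, fit, geno, qtl_snp)
        rows.append(
            {
                "rep": rep,
                "hom_diff_pct_sd": contrast.hom_difference_sd * 100.0,
                "dominance": contrast.dominance,
                "dominance_p": contrast.dominance_p,
                "maf": contrast.maf,
            }
        )
    return pd.DataFrame(rows)


def rg_recovery(
    n_reps: int = 12,
    seed: int = 1,
    n_offspring: int = 800,
    n_snps: int = 2000,
    rg: float = -0.49,
    blend_weight: float = 0.95,
) -> pd.DataFrame:
    """Bivariate REML recovery of the genetic correlation between the
    standardized resistance trait and juvenile body weight (both recorded
    on the same fish; dam effect on resistance only)."""
    rows = []
    for rep in range(n_reps):
        s = _rep_seed(seed, rep)
        ped, geno, truth, challenge = simulate_study(
            s, n_offspring=n_offspring, n_snps=n_snps
        )
        truth.bw1_gcor = rg  # generator default; explicit for clarity
        a = relmat.a_matrix(ped)
        off = geno.subset_individuals(challenge["id"].tolist())
        g = relmat.g_matrix(off, blend_weight=blend_weight, a=a)
        fit = varcomp.reml_fit_bivariate(
            challenge, "tle", challenge, "bw1", g,
            include_dam_x=True, include_dam_y=False,
            fix_residual_cov=True,  # generator residuals are independent
        )
        rows.append({"rep": rep, "r_g": fit.r_g, "converged": fit.converged})
    return pd.DataFrame(rows)


def null_gwas_calibration(
    n_reps: int = 5,
    seed: int = 1,
    n_offspring: int = 400,
    n_snps: int = 1000,
    n_cycles: int = 6000,
    burn_in: int = 600,
) -> pd.DataFrame:
    """Sampler calibration on phenotypes with no genetic effects.

    Returns per replicate the maximum logBF, the number of SNPs at
    logBF >= 6, the number of called QTL regions and the gap between the
    mean posterior inclusion probability and the posterior pi."""
    rows = []
    for rep in range(n_reps):
        s = _rep_seed(seed, rep)
        ped, geno, truth, challenge = simulate_study(
            s, n_offspring=n_offspring, n_snps=n_snps, h2=0.0, dam_ratio=0.0
        )
        config = gwas.GibbsConfig(n_cycles=n_cycles, burn_in=burn_in, thin=10, seed=s)
        result = gwas.bayescpi_fit(challenge, geno, config)
        regions = qtlcall.call_qtl(result)
        rows.append(
            {
                "rep": rep,
                "max_logbf": float(result.snp_table["logbf"].max()),
                "n_snps_logbf6": int((result.snp_table["logbf"] >= 6.0).sum()),
                "n_qtl": len(regions),
                "pip_pi_gap": float(
                    abs(result.snp_table["pip"].mean() - result.pi_mean)
                ),
            }
        )
    return pd.DataFrame(rows)


def planted_qtl_power(
    n_reps: int = 10,
    seed: int = 1,
    n_offspring: int = 1000,
    n_snps: int = 2000,
    qtl_var_share: float = 0.30,
    qtl_maf: float = 0.42,
    h2: float = 0.29,
    n_cycles: int = 8000,
    burn_in: int = 1000,
) -> pd.DataFrame:
    """Power to detect one planted QTL explaining a share of the genetic
    variance: a SNP within 1 Mb of the plant must reach logBF >= 6."""
    rows = []
    for rep in range(n_reps):
        s = _rep_seed(seed, rep)
        snp_map = syndata.default_snp_map(n_snps=n_snps, seed=s)
        qtl_snp = snp_map["snp_id"].iloc[n_snps // 2]
        a_eff = float(
            np.sqrt(qtl_var_share * h2 / (2.0 * qtl_maf * (1.0 - qtl_maf)))
        )
        ped, geno, truth, challenge = simulate_study(
            s, n_offspring=n_offspring, n_snps=n_snps, h2=h2,
            qtls=[QtlEffect(qtl_snp, a_eff)], qtl_freqs={qtl_snp: qtl_maf},
        )
        config = gwas.GibbsConfig(n_cycles=n_cycles, burn_in=burn_in, thin=10, seed=s)
        result = gwas.bayescpi_fit(challenge, geno, config)
        snp = result.snp_table
        qrow = snp[snp["snp_id"] == qtl_snp].iloc[0]
        near = snp[
            (snp["chrom"] == qrow["chrom"])
            & ((snp["pos"] - qrow["pos"]).abs() <= 1_000_000)
        ]
        rows.append(
            {
                "rep": rep,
                "hit": bool((near["logbf"] >= 6.0).any()),
                "qtl_logbf": float(qrow["logbf"]),
                "max_near_logbf": float(near["logbf"].max()),
            }
        )
    return pd.DataFrame(rows)


def dual_seed_gebv_correlation(
    seed: int = 1,
    n_offspring: int = 800,
    n_snps: int = 2000,
    n_cycles: int = 20_000,
    burn_in: int = 2000,
) -> float:
    """Convergence check: correlation of genomic values from two sampler
    runs on the same data that differ only in their seed."""
    s = _rep_seed(seed, 0)
    ped, geno, truth, challenge = simulate_study(
        s, n_offspring=n_offspring, n_snps=n_snps
    )
    base = dict(n_cycles=n_cycles, burn_in=burn_in, thin=10)
    run_a = gwas.bayescpi_fit(challenge, geno, gwas.GibbsConfig(seed=s + 11, **base))
    run_b = gwas.bayescpi_fit(challenge, geno, gwas.GibbsConfig(seed=s + 23, **base))
    _, r = gwas.convergence_check(run_a, run_b)
    return r
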