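"""Genotype contrasts at peak SNPs and isogenic-line concordance.

After a QTL peak is called, the phenotype corrected for the day and dam
effects of the null animal model is compared across the three genotype
classes at the peak SNP: the homozygote difference is expressed as a
percentage of the phenotypic SD (for the standardized resistance trait the
SD is 1, so the difference is read directly), significance comes from a
Tukey HSD across the classes, and the dominance deviation d = mean(het) -
(mean(hom0) + mean(hom2)) / 2 is tested with a one-sample t-test of the
heterozygotes' adjusted values against the observed homozygote midpoint.

The isogenic-line check asks whether, at every strongly associated SNP
where two fully inbred (or line-homozygous) genomes differ, the line known
to be more resistant carries the allele the GWAS estimated as favourable
(reference allele if the effect is positive, alternate otherwise).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .containers import GenotypeMatrix
from .gwas import GwasResult
from .varcomp import VarianceComponents


@dataclass
class PeakContrast:
    snp_id: str
    maf: float
    class_means: dict[int, float]  # genotype code -> adjusted-phenotype mean
    class_ns: dict[int, int]
    hom_difference_sd: float  # |mean(2) - mean(0)| as a fraction of phenotypic SD
    favourable_homozygote: int  # genotype code (0 or 2) with the higher mean
    tukey_p: float  # Tukey-adjusted p for the two homozygote classes
    dominance: float
    dominance_p: float
    complete: bool  # all three genotype classes observed


def adjusted_phenotype(
    table: pd.DataFrame,
    fitted_null_model: VarianceComponents,
    trait: str = "tle",
    day_col: str = "group",
    dam_col: str = "dam",
) -> pd.Series:
    """Phenotype minus the null-model day estimates and dam predictions.

    The null model is the animal model without the SNP; its fixed-effect
    estimates (intercept absorbed into the day solutions) and dam BLUPs are
    subtracted from the raw trait.
    """
    fe = fitted_null_model.fixed_effects
    adj = table[trait].to_numpy(dtype=np.float64).copy()
    adj -= fe["intercept"]
    for name, value in fe.items():
        if name.startswith(f"{day_col}["):
            level = name[len(day_col) + 1 : -1]
            adj -= np.where(table[day_col].astype(str) == level, value, 0.0)
    if fitted_null_model.dam_blup is not None:
        dam_pred = (
            table[dam_col].astype(str).map(fitted_null_model.dam_blup).fillna(0.0)
        )
        adj -= dam_pred.to_numpy(dtype=np.float64)
    return pd.Series(adj, index=table.index, name=f"{trait}_adj")


def peak_contrast(
    table: pd.DataFrame,
    fitted_null_model: VarianceComponents,
    genotypes: GenotypeMatrix,
    snp_id: str,
    trait: str = "tle",
    day_col: str = "group",
    dam_col: str = "dam",
    dominance_test: str = "t",
    n_boot: int = 500,
    boot_seed: int = 0,
) -> PeakContrast:
    """Contrast the day/dam-adjusted phenotype across genotype classes at
    one SNP.

    The homozygote difference is reported as a positive fraction of the
    phenotypic SD with the favourable homozygote named.  A missing
    genotype class flags the contrast incomplete (difference and tests NaN
    where undefined).

    ``dominance_test`` selects how d is tested: ``"t"`` is a one-sample
    t-test of the heterozygotes against the observed homozygote midpoint
    treated as a constant (anticonservative, since the midpoint's sampling
    error and the family correlation of sibs are ignored); ``"bootstrap"``
    resamples all three classes, which accounts for the midpoint error.
    """
    if dominance_test not in ("t", "bootstrap"):
        raise ValueError("dominance_test must be 't' or 'bootstrap'")
    geno = genotypes.subset_individuals(table["id"].tolist())
    codes = geno.codes[:, geno.snp_index(snp_id)]
    adj = adjusted_phenotype(table, fitted_null_model, trait, day_col, dam_col)
    called = codes >= 0
    x = adj.to_numpy()[called]
    g = codes[called]

    sd_p = float(np.std(table[trait].to_numpy(dtype=np.float64), ddof=1))
    p_ref = float(g.mean() / 2.0)
    maf = min(p_ref, 1.0 - p_ref)

    groups = {int(k): x[g == k] for k in (0, 1, 2)}
    class_means = {k: (float(v.mean()) if v.size else float("nan")) for k, v in groups.items()}
    class_ns = {k: int(v.size) for k, v in groups.items()}
    complete = all(class_ns[k] >= 1 for k in (0, 1, 2))

    if class_ns[0] >= 2 and class_ns[2] >= 2 and class_ns[1] >= 1:
        tukey = stats.tukey_hsd(groups[0], groups[1], groups[2])
        tukey_p = float(tukey.pvalue[0, 2])
    else:
        tukey_p = float("nan")

    if class_ns[0] and class_ns[2]:
        diff = class_means[2] - class_means[0]
        hom_difference_sd = abs(diff) / sd_p
        favourable = 2 if diff >= 0 else 0
    else:
        hom_difference_sd, favourable = float("nan"), -1

    if complete and class_ns[1] >= 2:
        midpoint = 0.5 * (class_means[0] + class_means[2])
        dominance = class_means[1] - midpoint
        if dominance_test == "bootstrap":
            rng = np.random.default_rng(boot_seed)
            d_star = np.empty(n_boot)
            for b in range(n_boot):
                d_star[b] = (
                    rng.choice(groups[1], class_ns[1]).mean()
                    - 0.5 * (rng.choice(groups[0], class_ns[0]).mean()
                             + rng.choice(groups[2], class_ns[2]).mean())
                )
            shifted = d_star - dominance  # null distribution centred at 0
            dominance_p = float(
                min(1.0, 2.0 * min((shifted >= dominance).mean(),
                                   (shifted <= dominance).mean()) + 1.0 / n_boot)
            )
        elif np.std(groups[1], ddof=1) > 0:
            dominance_p = float(stats.ttest_1samp(groups[1], midpoint).pvalue)
        else:
            dominance_p = float("nan")
    else:
        dominance, dominance_p = float("nan"), float("nan")

    return PeakContrast(
        snp_id=snp_id,
        maf=maf,
        class_means=class_means,
        class_ns=class_ns,
        hom_difference_sd=hom_difference_sd,
        favourable_homozygote=favourable,
        tukey_p=tukey_p,
        dominance=dominance,
        dominance_p=dominance_p,
        complete=complete,
    )


def contrasts_table(contrasts: list[PeakContrast]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "snp_id": [c.snp_id for c in contrasts],
            "maf": [round(c.maf, 2) for c in contrasts],
            "hom_difference_sd": [c.hom_difference_sd for c in contrasts],
            "favourable_homozygote": [c.favourable_homozygote for c in contrasts],
            "tukey_p": [c.tukey_p for c in contrasts],
            "dominance": [c.dominance for c in contrasts],
            "dominance_p": [c.dominance_p for c in contrasts],
            "complete": [c.complete for c in contrasts],
        }
    )


def isogenic_concordance(
    gwas_result: GwasResult,
    line_sensitive: pd.DataFrame,
    line_resistant: pd.DataFrame,
    logbf_threshold: float = 6.0,
) -> pd.DataFrame:
    """Check whether the resistant line carries the favourable allele at
    every strongly associated SNP where the two line genomes differ.

    Line genotypes are 2-column frames (snp_id, allele) giving the single
    allele each line is fixed for.  The favourable allele is the reference
    allele when the model-averaged effect is positive, the alternate
    otherwise.  Returns one row per differing supra-threshold SNP with a
    ``concordant`` flag.
    """
    for frame, nm in ((line_sensitive, "sensitive"), (line_resistant, "resistant")):
        if frame["snp_id"].duplicated().any():
            raise ValueError(f"duplicate SNP ids in the {nm} line genotypes")
    sens = line_sensitive.set_index("snp_id")["allele"]
    resi = line_resistant.set_index("snp_id")["allele"]
    snp = gwas_result.snp_table
    strong = snp[snp["logbf"] > logbf_threshold]

    rows = []
    for rec in strong.itertuples(index=False):
        if rec.snp_id not in sens.index or rec.snp_id not in resi.index:
            continue
        a_sens, a_resi = str(sens[rec.snp_id]), str(resi[rec.snp_id])
        if a_sens == a_resi:
            continue
        ref, alt = _ref_alt(gwas_result, rec.snp_id)
        favourable = ref if rec.effect > 0 else alt
        rows.append(
            {
                "snp_id": rec.snp_id,
                "chrom": rec.chrom,
                "pos": rec.pos,
                "allele_sensitive": a_sens,
                "allele_resistant": a_resi,
                "logbf": rec.logbf,
                "favourable_allele": favourable,
                "concordant": a_resi == favourable,
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "snp_id", "chrom", "pos", "allele_sensitive", "allele_resistant",
            "logbf", "favourable_allele", "concordant",
        ],
    )


def _ref_alt(gwas_result: GwasResult, snp_id: str) -> tuple[str, str]:
    snp = gwas_result.snp_table
    row = snp[snp["snp_id"] == snp_id]
    if "ref" in snp.columns and "alt" in snp.columns:
        return str(row["ref"].iloc[0]), str(row["alt"].iloc[0])
    raise KeyError(
        "GWAS result carries no ref/alt alleles; attach them to snp_table "
        "before the concordance check"
    )
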