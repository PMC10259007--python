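"""Synthetic study generator: matings, genotypes, challenge and harvest data.

The generator emulates the design of a commercial rainbow-trout study:
76 dams mated to 99 sires in 10 independent full-factorial blocks, offspring
genotyped on a SNP array and phenotyped either for acute-hyperthermia
resistance (time to loss of equilibrium under a piecewise heating curve) or
for harvest traits.  The latent resistance of a fish decomposes as

    latent = mu + day + dam + sum_q z_q * a_q + polygenic + residual

and is mapped onto the group's heating timeline through the inverse of the
curve's cumulative-heat function, so that raw times are a monotone function
of resistance with the configured group mean and spread.

Polygenic values are sums of many small marker effects (QTL SNPs excluded),
so REML/GBLUP and the Bayesian sampler see the same genome that generated
the data.  Every operation takes an explicit seed and is bit-reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .containers import (
    GenotypeMatrix,
    HeatingCurve,
    Pedigree,
    default_heating_curves,
)

# Per-group raw-time targets (minutes) mirroring the seven-group challenge:
# (mean, SD, relative size).  First group phenotyped after the shortest
# acclimation loses equilibrium earliest with the tightest spread; the last
# group latest with the widest spread.
DEFAULT_GROUP_TIME_TARGETS: dict[str, tuple[float, float]] = {
    "G1": (318.7, 14.1),
    "G2": (394.9, 23.2),
    "G3": (424.8, 24.4),
    "G4": (424.9, 34.2),
    "G5": (446.8, 34.0),
    "G6": (407.4, 30.3),
    "G7": (473.8, 61.6),
}
DEFAULT_GROUP_WEIGHTS: dict[str, int] = {
    "G1": 187, "G2": 196, "G3": 192, "G4": 195, "G5": 199, "G6": 196, "G7": 162,
}

HARVEST_BASIS_TRAITS = ["bw2", "fl", "fat_ant", "fat_post", "hgc_pct", "head_pct"]


@dataclass
class QtlEffect:
    """A planted biallelic QTL: additive effect ``a`` per reference-allele
    copy and dominance deviation ``d`` of the heterozygote."""

    snp_id: str
    add_effect: float
    dom_effect: float = 0.0


@dataclass
class TruthRecord:
    """Ground truth of one simulated study, for recovery tests.

    Variance components are on the latent-resistance scale (phenotypic
    variance ``var_additive + var_dam + var_residual``; planted QTL variance
    counts inside ``var_additive``).  ``bw1_*`` parametrise the correlated
    juvenile body-weight trait; ``genetic_cov`` is the genetic covariance of
    the harvest-trait basis (see :data:`HARVEST_BASIS_TRAITS`).
    """

    var_additive: float
    var_dam: float
    var_residual: float
    day_effects: dict[str, float] = field(default_factory=dict)
    qtls: list[QtlEffect] = field(default_factory=list)
    bw1_h2: float = 0.19
    bw1_gcor: float = -0.49
    bw1_mean: float = 87.4
    bw1_sd: float = 12.2
    genetic_cov: np.ndarray | None = None
    seed: int | None = None
    # filled by the simulators
    breeding_values: pd.Series | None = None
    breeding_values_bw1: pd.Series | None = None
    harvest_genetic_values: pd.DataFrame | None = None
    violation_ids: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        for name in ("var_additive", "var_dam", "var_residual"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.genetic_cov is not None:
            g = np.asarray(self.genetic_cov, dtype=np.float64)
            if not np.allclose(g, g.T):
                raise ValueError("genetic covariance matrix must be symmetric")
            self.genetic_cov = g

    @property
    def var_phenotypic(self) -> float:
        return self.var_additive + self.var_dam + self.var_residual


def challenge_truth(
    h2: float = 0.29,
    dam_ratio: float = 0.06,
    sigma_p2: float = 1.0,
    qtls: list[QtlEffect] | None = None,
    **kwargs,
) -> TruthRecord:
    """Truth record from variance *ratios*: h2 and the dam share of
    phenotypic variance (defaults are the genomic estimates the study
    design is calibrated to: h2 = 0.29, dam share 6%)."""
    if not (0.0 <= h2 <= 1.0 and 0.0 <= dam_ratio <= 1.0 and h2 + dam_ratio <= 1.0):
        raise ValueError("h2 and dam_ratio must be in [0,1] and sum to <= 1")
    return TruthRecord(
        var_additive=h2 * sigma_p2,
        var_dam=dam_ratio * sigma_p2,
        var_residual=(1.0 - h2 - dam_ratio) * sigma_p2,
        qtls=list(qtls or []),
        **kwargs,
    )


def _per_block(value, n_blocks: int, total_like: str) -> list[int]:
    if np.isscalar(value):
        counts = [int(value)] * n_blocks
    else:
        counts = [int(v) for v in value]
        if len(counts) != n_blocks:
            raise ValueError(f"need {n_blocks} per-block {total_like} counts")
    if any(c < 1 for c in counts):
        raise ValueError(f"{total_like} counts must be >= 1")
    return counts


def default_block_design() -> tuple[list[int], list[int]]:
    """10 blocks of 9-10 sires x 7-8 dams totalling 99 sires and 76 dams."""
    sires = [10] * 9 + [9]
    dams = [8] * 6 + [7] * 4
    return sires, dams


def make_pedigree(
    n_blocks: int = 10,
    sires_per_block=None,
    dams_per_block=None,
    offspring_per_pair: int = 1,
    seed: int = 0,
    n_offspring: int | None = None,
) -> Pedigree:
    """Full-factorial block matings: every sire x dam pair within a block.

    With ``n_offspring`` given, that many offspring are drawn uniformly over
    the mated pairs instead of a fixed ``offspring_per_pair`` per family
    (family sizes then vary as in a hatchery mix).  Deterministic for a
    fixed seed.
    """
    if n_blocks < 1:
        raise ValueError("n_blocks must be >= 1")
    if sires_per_block is None and dams_per_block is None and n_blocks == 10:
        sires_per_block, dams_per_block = default_block_design()
    sires_per_block = _per_block(sires_per_block if sires_per_block is not None else 10, n_blocks, "sire")
    dams_per_block = _per_block(dams_per_block if dams_per_block is not None else 8, n_blocks, "dam")
    if n_offspring is None and offspring_per_pair < 1:
        raise ValueError("offspring_per_pair must be >= 1")

    rng = np.random.default_rng(seed)
    rows: list[tuple[str, str, str, int]] = []
    pairs: list[tuple[str, str]] = []
    for b in range(n_blocks):
        sires = [f"B{b + 1}_S{i + 1}" for i in range(sires_per_block[b])]
        dams = [f"B{b + 1}_D{j + 1}" for j in range(dams_per_block[b])]
        rows.extend((s, "0", "0", 0) for s in sires)
        rows.extend((d, "0", "0", 0) for d in dams)
        pairs.extend((s, d) for s in sires for d in dams)

    if n_offspring is not None:
        if n_offspring < 1:
            raise ValueError("n_offspring must be >= 1")
        picks = rng.integers(0, len(pairs), size=n_offspring)
    else:
        picks = np.repeat(np.arange(len(pairs)), offspring_per_pair)
    for k, pair_idx in enumerate(picks):
        s, d = pairs[pair_idx]
        rows.append((f"F{k + 1:05d}", s, d, 1))
    return Pedigree(pd.DataFrame(rows, columns=["id", "sire", "dam", "generation"]))


def default_snp_map(
    n_snps: int = 3000,
    n_chrom: int = 15,
    chrom_length_bp: int = 50_000_000,
    seed: int = 0,
) -> pd.DataFrame:
    """SNP map with uniformly placed loci on equally sized chromosomes."""
    rng = np.random.default_rng(seed)
    per = np.full(n_chrom, n_snps // n_chrom)
    per[: n_snps % n_chrom] += 1
    recs = []
    bases = np.array(list("ACGT"))
    for c, m in enumerate(per, start=1):
        pos = np.sort(rng.choice(np.arange(1, chrom_length_bp + 1), size=m, replace=False))
        refs = rng.choice(bases, size=m)
        alts = np.array([rng.choice(bases[bases != r]) for r in refs])
        for i, (bp, ref, alt) in enumerate(zip(pos, refs, alts), start=1):
            recs.append((f"SNP_{c}_{i}", f"chr{c}", int(bp), ref, alt))
    return pd.DataFrame(recs, columns=["snp_id", "chrom", "pos", "ref", "alt"])


def gene_drop(
    pedigree: Pedigree,
    snp_map: pd.DataFrame,
    founder_allele_freqs: np.ndarray,
    missing_rate: float = 0.0,
    seed: int = 0,
) -> GenotypeMatrix:
    """Drop alleles down the pedigree: founders at Hardy-Weinberg
    proportions, offspring from independent Mendelian gametes per locus
    (no linkage)."""
    freqs = np.asarray(founder_allele_freqs, dtype=np.float64)
    if freqs.shape != (len(snp_map),):
        raise ValueError("one founder frequency per SNP required")
    if np.any((freqs < 0.0) | (freqs > 1.0)):
        raise ValueError("founder allele frequencies must lie in [0, 1]")
    if not (0.0 <= missing_rate < 1.0):
        raise ValueError("missing_rate must lie in [0, 1)")

    rng = np.random.default_rng(seed)
    n, p = pedigree.n, len(snp_map)
    parents = pedigree.parent_indices()
    codes = np.empty((n, p), dtype=np.int8)
    for i in range(n):
        si, di = parents[i]
        if si < 0 and di < 0:
            codes[i] = rng.binomial(2, freqs).astype(np.int8)
            continue
        if si < 0 or di < 0:
            raise ValueError(f"animal {pedigree.ids[i]} has exactly one known parent")
        gs, gd = codes[si], codes[di]
        gam_s = (gs == 2) | ((gs == 1) & (rng.random(p) < 0.5))
        gam_d = (gd == 2) | ((gd == 1) & (rng.random(p) < 0.5))
        codes[i] = gam_s.astype(np.int8) + gam_d.astype(np.int8)
    if missing_rate > 0.0:
        codes[rng.random(codes.shape) < missing_rate] = -1
    return GenotypeMatrix(ids=pedigree.ids, snp_map=snp_map, codes=codes)


def default_group_assignment(
    ids: list[str],
    groups: list[str] | None = None,
    weights: dict[str, int] | None = None,
    seed: int = 0,
) -> pd.Series:
    """Random assignment of fish to challenge groups, sizes proportional to
    the seven-group design by default."""
    if groups is None:
        groups = list(DEFAULT_GROUP_TIME_TARGETS)
    w = np.array([(weights or DEFAULT_GROUP_WEIGHTS).get(g, 1) for g in groups], float)
    w /= w.sum()
    rng = np.random.default_rng(seed)
    counts = rng.multinomial(len(ids), w)
    labels = np.repeat(groups, counts)
    rng.shuffle(labels)
    return pd.Series(labels, index=ids, name="group")


def _marker_effect_values(
    z_centered: np.ndarray, scale_sum: float, target_var: float, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """Polygenic values as a sum of many small marker effects."""
    p = z_centered.shape[1]
    if scale_sum <= 0:
        raise ValueError("no polymorphic background SNPs to carry polygenic variance")
    alpha = rng.normal(0.0, np.sqrt(target_var / scale_sum), size=p)
    return z_centered @ alpha, alpha


def simulate_challenge(
    pedigree: Pedigree,
    genotypes: GenotypeMatrix,
    truth: TruthRecord,
    heating_curves: dict[str, HeatingCurve] | None = None,
    group_assignment: pd.Series | None = None,
    seed: int = 0,
    group_time_targets: dict[str, tuple[float, float]] | None = None,
    time_map: str = "cumheat",
) -> pd.DataFrame:
    """Simulate the acute-hyperthermia challenge for the pedigree offspring.

    Returns a challenge table (columns ``id, group, rtle, bw1, dam, sire``)
    with raw times in minutes.  True breeding values for resistance and for
    juvenile body weight are stored on ``truth``.

    ``time_map`` picks how latent resistance becomes a raw time:
    ``"cumheat"`` (default) inverts the group's cumulative-heat curve, so
    the raw times carry the mild skew of a decelerating heat load;
    ``"linear"`` is a plain affine map to the group's target mean/SD.
    Both are monotone in latent resistance.
    """
    if time_map not in ("cumheat", "linear"):
        raise ValueError("time_map must be 'cumheat' or 'linear'")
    rng = np.random.default_rng(seed)
    curves = heating_curves if heating_curves is not None else default_heating_curves()
    targets = group_time_targets or DEFAULT_GROUP_TIME_TARGETS

    off_ids = pedigree.offspring()
    ped_df = pedigree.df.set_index("id")
    geno = genotypes.subset_individuals(off_ids)
    if group_assignment is None:
        group_assignment = default_group_assignment(
            off_ids, groups=list(curves), seed=int(rng.integers(2**31 - 1))
        )
    groups = group_assignment.reindex(off_ids)
    if groups.isna().any():
        raise ValueError("every fish needs a group assignment")
    for g in groups.unique():
        if g not in curves:
            raise KeyError(f"no heating curve for group {g!r}")
        if g not in targets:
            raise KeyError(f"no raw-time target for group {g!r}")

    n = len(off_ids)
    z = geno.mean_imputed()
    p_hat = z.mean(axis=0) / 2.0
    z_centered = z - 2.0 * p_hat

    qtl_idx = np.array([geno.snp_index(q.snp_id) for q in truth.qtls], dtype=np.int64)
    qtl_var = 0.0
    u_qtl = np.zeros(n)
    dom_dev = np.zeros(n)
    for q, j in zip(truth.qtls, qtl_idx):
        pj = p_hat[j]
        qtl_var += 2.0 * pj * (1.0 - pj) * q.add_effect**2
        u_qtl += q.add_effect * z_centered[:, j]
        if q.dom_effect != 0.0:
            het = (geno.codes[:, j] == 1).astype(np.float64)
            dom_dev += q.dom_effect * (het - het.mean())
    var_poly = truth.var_additive - qtl_var
    if var_poly < -1e-9:
        raise ValueError(
            f"planted QTL variance {qtl_var:.4f} exceeds the configured "
            f"additive variance {truth.var_additive:.4f}"
        )
    var_poly = max(var_poly, 0.0)

    bg = np.setdiff1d(np.arange(geno.n_snps), qtl_idx)
    scale_bg = float(np.sum(2.0 * p_hat[bg] * (1.0 - p_hat[bg])))
    if var_poly > 0.0:
        u_poly, alpha_bg = _marker_effect_values(z_centered[:, bg], scale_bg, var_poly, rng)
    else:
        u_poly, alpha_bg = np.zeros(n), np.zeros(len(bg))
    u_true = u_poly + u_qtl

    dams = ped_df.loc[off_ids, "dam"].to_numpy()
    dam_levels, dam_codes = np.unique(dams, return_inverse=True)
    dam_effects = rng.normal(0.0, np.sqrt(truth.var_dam), size=len(dam_levels))
    residual = rng.normal(0.0, np.sqrt(truth.var_residual), size=n)
    day = np.array([truth.day_effects.get(g, 0.0) for g in groups])
    latent = day + dam_effects[dam_codes] + u_true + dom_dev + residual

    # monotone map onto each group's heating timeline
    sigma_p = np.sqrt(truth.var_phenotypic)
    rtle = np.empty(n)
    for g in groups.unique():
        mask = (groups == g).to_numpy()
        curve = curves[g]
        mean_t, sd_t = targets[g]
        ctu_mean = curve.cumulative_heat(mean_t)
        slope = curve.temperature(mean_t) - curve.initial_temp
        zscore = (latent[mask] - truth.day_effects.get(g, 0.0)) / sigma_p if sigma_p > 0 else 0.0
        if time_map == "linear":
            rtle[mask] = mean_t + sd_t * zscore
        else:
            ctu = np.maximum(ctu_mean + sd_t * slope * zscore, 0.0)
            rtle[mask] = curve.inverse_cumulative_heat(ctu)

    # correlated juvenile body weight (all markers as its polygenic basis)
    alpha_t_full = np.zeros(geno.n_snps)
    alpha_t_full[bg] = alpha_bg
    for q, j in zip(truth.qtls, qtl_idx):
        alpha_t_full[j] = q.add_effect
    var_a_bw = truth.bw1_h2 * truth.bw1_sd**2
    scale_all = float(np.sum(2.0 * p_hat * (1.0 - p_hat)))
    r = truth.bw1_gcor
    if truth.var_additive > 0 and var_a_bw > 0:
        lam = r * np.sqrt(var_a_bw / truth.var_additive)
        alpha_bw = lam * alpha_t_full + rng.normal(
            0.0, np.sqrt(max(1.0 - r**2, 0.0) * var_a_bw / scale_all), size=geno.n_snps
        )
        u_bw = z_centered @ alpha_bw
    else:
        u_bw = np.zeros(n)
    bw1 = truth.bw1_mean + u_bw + rng.normal(
        0.0, np.sqrt(max(1.0 - truth.bw1_h2, 0.0)) * truth.bw1_sd, size=n
    )

    truth.breeding_values = pd.Series(u_true, index=off_ids, name="bv_tle")
    truth.breeding_values_bw1 = pd.Series(u_bw, index=off_ids, name="bv_bw1")
    if truth.seed is None:
        truth.seed = seed

    return pd.DataFrame(
        {
            "id": off_ids,
            "group": groups.to_numpy(),
            "rtle": rtle,
            "bw1": bw1,
            "dam": dams,
            "sire": ped_df.loc[off_ids, "sire"].to_numpy(),
        }
    )


def default_harvest_genetic_cov() -> np.ndarray:
    """Genetic covariance of the harvest basis (bw2, fl, fat_ant, fat_post,
    hgc_pct, head_pct) built from moderate heritabilities and a strong
    weight-length genetic correlation."""
    sd_p = np.array([106.2, 15.2, 1.2, 1.2, 1.0, 0.7])
    h2 = np.array([0.26, 0.31, 0.45, 0.45, 0.61, 0.30])
    corr = np.array(
        [
            [1.00, 0.75, -0.15, -0.15, 0.08, 0.05],
            [0.75, 1.00, -0.25, -0.25, 0.02, 0.05],
            [-0.15, -0.25, 1.00, 0.90, 0.28, 0.00],
            [-0.15, -0.25, 0.90, 1.00, 0.28, 0.00],
            [0.08, 0.02, 0.28, 0.28, 1.00, -0.30],
            [0.05, 0.05, 0.00, 0.00, -0.30, 1.00],
        ]
    )
    sd_g = sd_p * np.sqrt(h2)
    return corr * np.outer(sd_g, sd_g)


HARVEST_TRAIT_MEANS = {
    "bw2": 977.5, "fl": 446.5, "fat_ant": 4.9, "fat_post": 4.9,
    "hgc_pct": 78.7, "head_pct": 11.0,
}
HARVEST_PHEN_SD = {
    "bw2": 106.2, "fl": 15.2, "fat_ant": 1.2, "fat_post": 1.2,
    "hgc_pct": 1.0, "head_pct": 0.7,
}


def simulate_harvest(
    pedigree: Pedigree,
    genotypes: GenotypeMatrix,
    truth: TruthRecord,
    n_violations: int = 24,
    seed: int = 0,
) -> pd.DataFrame:
    """Simulate harvest phenotypes with a configured genetic covariance.

    The genetically governed basis is ``bw2, fl, fat_ant, fat_post,
    hgc_pct, head_pct``; component weights are derived from it (HGCW =
    HGC% x BW2, HeadW = Head% x BW2, ViscW closes the weight balance to
    within 10 g) and exactly ``n_violations`` records get a planted carcass
    weight inconsistency larger than 10 g.  Violating ids are stored on
    ``truth.violation_ids``.
    """
    rng = np.random.default_rng(seed)
    off_ids = pedigree.offspring()
    if n_violations > len(off_ids):
        raise ValueError("cannot plant more violations than fish")
    geno = genotypes.subset_individuals(off_ids)
    n = len(off_ids)

    gcov = truth.genetic_cov if truth.genetic_cov is not None else default_harvest_genetic_cov()
    k = len(HARVEST_BASIS_TRAITS)
    if gcov.shape != (k, k):
        raise ValueError(f"genetic covariance must be {k}x{k} for {HARVEST_BASIS_TRAITS}")
    eigmin = float(np.linalg.eigvalsh(gcov).min())
    if eigmin < -1e-8 * max(1.0, float(np.abs(gcov).max())):
        raise ValueError(
            f"genetic covariance is not positive semi-definite (min eigenvalue {eigmin:.3e})"
        )
    chol = np.linalg.cholesky(gcov + 1e-10 * np.eye(k) * max(1.0, np.trace(gcov)))

    z = geno.mean_imputed()
    p_hat = z.mean(axis=0) / 2.0
    z_centered = z - 2.0 * p_hat
    scale_all = float(np.sum(2.0 * p_hat * (1.0 - p_hat)))
    if scale_all <= 0:
        raise ValueError("no polymorphic SNPs to carry genetic (co)variance")
    alpha = rng.normal(0.0, np.sqrt(1.0 / scale_all), size=(geno.n_snps, k))
    u = z_centered @ alpha @ chol.T  # (n, k), cov ~ gcov

    means = np.array([HARVEST_TRAIT_MEANS[t] for t in HARVEST_BASIS_TRAITS])
    var_p = np.array([HARVEST_PHEN_SD[t] ** 2 for t in HARVEST_BASIS_TRAITS])
    var_e = var_p - np.diag(gcov)
    if np.any(var_e < 0):
        raise ValueError("genetic variances exceed the phenotypic variances")
    e = rng.normal(0.0, np.sqrt(var_e), size=(n, k))
    vals = means + u + e
    basis = pd.DataFrame(vals, columns=HARVEST_BASIS_TRAITS, index=off_ids)
    basis["bw2"] = basis["bw2"].clip(lower=300.0)
    basis["hgc_pct"] = basis["hgc_pct"].clip(60.0, 90.0)
    basis["head_pct"] = basis["head_pct"].clip(6.0, 16.0)

    hgcw = basis["hgc_pct"].to_numpy() / 100.0 * basis["bw2"].to_numpy()
    headw = basis["head_pct"].to_numpy() / 100.0 * basis["bw2"].to_numpy()
    loss = np.clip(rng.normal(3.0, 2.0, size=n), 0.0, 9.0)  # blood/fin losses < 10 g
    viscw = basis["bw2"].to_numpy() - hgcw - headw - loss

    violators = rng.choice(n, size=n_violations, replace=False)
    sign = rng.choice([-1.0, 1.0], size=n_violations)
    hgcw[violators] += loss[violators] + sign * (11.0 + rng.uniform(0.0, 20.0, size=n_violations))

    ped_df = pedigree.df.set_index("id")
    table = pd.DataFrame(
        {
            "id": off_ids,
            "slaughter_day": [f"D{1 + i % 3}" for i in range(n)],
            "bw2": basis["bw2"].to_numpy(),
            "fl": basis["fl"].to_numpy(),
            "fat_ant": basis["fat_ant"].to_numpy(),
            "fat_post": basis["fat_post"].to_numpy(),
            "headw": headw,
            "hgcw": hgcw,
            "viscw": viscw,
            "dam": ped_df.loc[off_ids, "dam"].to_numpy(),
            "sire": ped_df.loc[off_ids, "sire"].to_numpy(),
        }
    )
    truth.violation_ids = [off_ids[i] for i in sorted(violators)]
    truth.harvest_genetic_values = pd.DataFrame(
        u, columns=HARVEST_BASIS_TRAITS, index=off_ids
    )
    return table
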