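"""BayesC-pi Gibbs sampler for the standardized resistance phenotype.

The fitted model for fish k challenged on day i from dam j is

    TLE_ijk = mu + day_i + dam_j + sum_l delta_l z_kl a_l + e_ijk

where each SNP effect a_l is zero with probability 1 - pi and Gaussian
N(0, sigma_a^2) otherwise; pi itself is sampled from its Beta conditional
on the number of SNPs currently in the model.  Evidence per SNP is the
Bayes factor of posterior versus prior inclusion odds, reported as
logBF = 2 ln BF; a logBF of 6 or more at the locally strongest SNP is
treated as strong QTL evidence downstream.

The per-cycle sweep (fixed day effects, IID dam effects, all SNP
indicator/effect pairs, pi and the three variances) is compiled with numba;
two differently seeded runs on the same data are the standard convergence
check (genomic value correlation > 0.99).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from numba import njit

from .containers import GenotypeMatrix


@dataclass
class GibbsConfig:
    """MCMC settings.  Desk-scale defaults (20,000 cycles, 2,000 burn-in,
    thinning 10) keep a run in tens of seconds on a few thousand SNPs; the
    full-scale setting used for dense arrays (600,000 / 10,000 / 40) is a
    config choice, not a default.

    ``alpha``/``beta`` parametrise the Beta(alpha, beta - alpha) prior on
    pi: alpha is the expected number of SNPs with a non-zero effect among
    beta total SNPs (both default from the panel size at fit time).
    """

    n_cycles: int = 20_000
    burn_in: int = 2_000
    thin: int = 10
    alpha: float | None = None
    beta: float | None = None
    seed: int = 0
    prior_df: float = 4.0
    h2_prior: float = 0.5
    pi_fixed: float | None = None  # force pi (1.0 -> all SNPs in: GBLUP limit)
    bf_pi_mode: str = "posterior"  # 'posterior' or 'prior' pi in the BF odds

    def __post_init__(self) -> None:
        if not (0 < self.burn_in < self.n_cycles):
            raise ValueError("need 0 < burn_in < n_cycles")
        if self.thin < 1:
            raise ValueError("thinning interval must be >= 1")
        if self.alpha is not None and self.beta is not None and not self.alpha < self.beta:
            raise ValueError("alpha (expected non-zero SNPs) must be < beta (total)")


@dataclass
class GwasResult:
    """Posterior summaries of one sampler run."""

    snp_table: pd.DataFrame  # snp_id, chrom, pos, pip, effect, logbf
    gebv: pd.Series  # posterior-mean genomic value per animal
    pi_mean: float
    var_genetic: float  # posterior mean variance of the genomic values
    var_dam: float
    var_residual: float
    n_saved: int
    seed: int
    traces: pd.DataFrame = field(repr=False, default_factory=pd.DataFrame)
    config: GibbsConfig | None = None


@njit(cache=True)
def _gibbs_kernel(
    z, zz, y, day_codes, n_days, dam_codes, n_dams, include_dam,
    n_cycles, burn_in, thin, alpha_pi, beta_rest, pi_fixed,
    nu_a, scale_a0, nu_e, scale_e0, nu_c, scale_c0, snp_order, seed,
):
    np.random.seed(seed)
    p, n = z.shape
    day_eff = np.zeros(n_days)
    day_n = np.zeros(n_days)
    for i in range(n):
        day_n[day_codes[i]] += 1.0
    dam_eff = np.zeros(n_dams)
    dam_n = np.zeros(n_dams)
    for i in range(n):
        dam_n[dam_codes[i]] += 1.0

    a = np.zeros(p)
    delta = np.zeros(p, dtype=np.int8)
    e = y.copy()
    # initialise day effects at group means
    for i in range(n):
        day_eff[day_codes[i]] += y[i] / day_n[day_codes[i]]
    for i in range(n):
        e[i] -= day_eff[day_codes[i]]

    sig_e = scale_e0
    sig_a = scale_a0
    sig_c = scale_c0
    pi = pi_fixed if pi_fixed > 0.0 else alpha_pi / (alpha_pi + beta_rest)

    n_saved = 0
    pip_count = np.zeros(p)
    a_sum = np.zeros(p)
    gebv_sum = np.zeros(n)
    pi_sum = 0.0
    max_saved = (n_cycles - burn_in) // thin + 1
    traces = np.zeros((max_saved, 5))  # var_g, sig_c, sig_e, pi, m_in

    for cycle in range(n_cycles):
        # --- fixed day effects (flat prior Gaussian conditionals) ---
        sums = np.zeros(n_days)
        for i in range(n):
            e[i] += day_eff[day_codes[i]]
            sums[day_codes[i]] += e[i]
        for d_ in range(n_days):
            day_eff[d_] = sums[d_] / day_n[d_] + np.random.normal() * np.sqrt(
                sig_e / day_n[d_]
            )
        for i in range(n):
            e[i] -= day_eff[day_codes[i]]

        # --- IID dam effects ---
        if include_dam:
            sums_c = np.zeros(n_dams)
            for i in range(n):
                e[i] += dam_eff[dam_codes[i]]
                sums_c[dam_codes[i]] += e[i]
            ssc = 0.0
            for j in range(n_dams):
                denom = dam_n[j] + sig_e / sig_c
                dam_eff[j] = sums_c[j] / denom + np.random.normal() * np.sqrt(
                    sig_e / denom
                )
                ssc += dam_eff[j] * dam_eff[j]
            for i in range(n):
                e[i] -= dam_eff[dam_codes[i]]
            sig_c = (ssc + nu_c * scale_c0) / np.random.chisquare(n_dams + nu_c)

        # --- SNP indicator/effect pairs ---
        log_prior_odds = np.log(pi / (1.0 - pi)) if pi < 1.0 else 1e30
        m_in = 0
        ssa = 0.0
        for s_ in range(p):
            l = snp_order[s_]
            u = zz[l]
            if u <= 0.0:
                delta[l] = 0
                a[l] = 0.0
                continue
            rhs = 0.0
            for i in range(n):
                rhs += z[l, i] * e[i]
            if delta[l] == 1:
                rhs += u * a[l]
            c_ = u + sig_e / sig_a
            log_odds = (
                log_prior_odds
                + 0.5 * np.log(sig_e / (sig_a * c_))
                + 0.5 * rhs * rhs / (sig_e * c_)
            )
            if log_odds > 35.0:
                incl = True
            elif log_odds < -35.0:
                incl = False
            else:
                incl = np.random.random() < 1.0 / (1.0 + np.exp(-log_odds))
            old = a[l] if delta[l] == 1 else 0.0
            if incl:
                new = rhs / c_ + np.random.normal() * np.sqrt(sig_e / c_)
                a[l] = new
                delta[l] = 1
                m_in += 1
                ssa += new * new
            else:
                new = 0.0
                a[l] = 0.0
                delta[l] = 0
            diff = old - new
            if diff != 0.0:
                for i in range(n):
                    e[i] += z[l, i] * diff

        # --- pi, effect variance, residual variance ---
        if pi_fixed > 0.0:
            pi = pi_fixed
        else:
            pi = np.random.beta(alpha_pi + m_in, beta_rest + p - m_in)
            if pi < 1e-8:
                pi = 1e-8
            if pi > 1.0 - 1e-8:
                pi = 1.0 - 1e-8
        sig_a = (ssa + nu_a * scale_a0) / np.random.chisquare(m_in + nu_a)
        sse = 0.0
        for i in range(n):
            sse += e[i] * e[i]
        sig_e = (sse + nu_e * scale_e0) / np.random.chisquare(n + nu_e)

        # --- accumulate thinned post-burn-in samples ---
        if cycle >= burn_in and (cycle - burn_in) % thin == 0:
            gmean = 0.0
            g = np.empty(n)
            for i in range(n):
                g[i] = y[i] - e[i] - day_eff[day_codes[i]] - dam_eff[dam_codes[i]]
                gmean += g[i]
            gmean /= n
            vg = 0.0
            for i in range(n):
                vg += (g[i] - gmean) ** 2
                gebv_sum[i] += g[i]
            vg /= n - 1
            for l in range(p):
                if delta[l] == 1:
                    pip_count[l] += 1.0
                    a_sum[l] += a[l]
            pi_sum += pi
            traces[n_saved, 0] = vg
            traces[n_saved, 1] = sig_c
            traces[n_saved, 2] = sig_e
            traces[n_saved, 3] = pi
            traces[n_saved, 4] = m_in
            n_saved += 1

    return pip_count, a_sum, gebv_sum, pi_sum, traces[:n_saved], n_saved


def compute_logbf(
    p_i: np.ndarray | float, pi_hat: float, n_saved_samples: int
) -> np.ndarray | float:
    """logBF = 2 ln( [P_i/(1-P_i)] / [pi/(1-pi)] ).

    Inclusion probabilities are floored at 1/n_saved and capped at
    1 - 1/n_saved so SNPs included (or excluded) in every saved sample get
    a finite value.
    """
    if not (0.0 < pi_hat < 1.0):
        raise ValueError("pi_hat must lie strictly inside (0, 1)")
    if n_saved_samples < 2:
        raise ValueError("need at least two saved samples")
    eps = 1.0 / n_saved_samples
    p = np.clip(np.asarray(p_i, dtype=np.float64), eps, 1.0 - eps)
    bf = (p / (1.0 - p)) / (pi_hat / (1.0 - pi_hat))
    out = 2.0 * np.log(bf)
    return out if out.shape else float(out)


def bayescpi_fit(
    table: pd.DataFrame,
    genotypes: GenotypeMatrix,
    config: GibbsConfig | None = None,
    trait: str = "tle",
    day_col: str = "group",
    dam_col: str = "dam",
    include_dam: bool = True,
) -> GwasResult:
    """Run the sampler on a standardized phenotype table.

    Animals are matched to genotype rows by id; genotypes are mean-imputed
    and centred.  Returns per-SNP posterior inclusion probabilities,
    model-averaged reference-allele effects and logBF, per-animal genomic
    values, posterior variance partitions and the variance/pi traces.
    """
    config = config or GibbsConfig()
    tab = table.dropna(subset=[trait]).reset_index(drop=True)
    y = tab[trait].to_numpy(dtype=np.float64)
    vy = float(np.var(y, ddof=1))
    if vy <= 0.0:
        raise ValueError("zero phenotypic variance")

    geno = genotypes.subset_individuals(tab["id"].tolist())
    z = geno.mean_imputed()
    p_hat = z.mean(axis=0) / 2.0
    z = z - 2.0 * p_hat
    zz = np.einsum("ij,ij->j", z, z)
    n, p = z.shape

    day_levels, day_codes = np.unique(tab[day_col].astype(str), return_inverse=True)
    dam_levels, dam_codes = np.unique(tab[dam_col].astype(str), return_inverse=True)

    beta_total = float(config.beta if config.beta is not None else p)
    alpha_pi = float(
        config.alpha if config.alpha is not None else max(4.0, round(0.01 * beta_total))
    )
    if not alpha_pi < beta_total:
        raise ValueError("alpha must be smaller than beta")
    het_sum = float(np.mean(2.0 * p_hat * (1.0 - p_hat)))
    scale_a0 = vy * config.h2_prior / (alpha_pi * 2.0 * max(het_sum, 1e-12))
    rng_seed = int(np.uint32(config.seed)) or 1

    order = np.random.default_rng(config.seed).permutation(p).astype(np.int64)
    pip_count, a_sum, gebv_sum, pi_sum, traces, n_saved = _gibbs_kernel(
        np.ascontiguousarray(z.T),
        zz,
        y,
        day_codes.astype(np.int64),
        len(day_levels),
        dam_codes.astype(np.int64),
        len(dam_levels),
        include_dam,
        config.n_cycles,
        config.burn_in,
        config.thin,
        alpha_pi,
        beta_total - alpha_pi,
        -1.0 if config.pi_fixed is None else float(config.pi_fixed),
        config.prior_df,
        scale_a0,
        config.prior_df,
        0.5 * vy,
        config.prior_df,
        0.05 * vy,
        order,
        rng_seed,
    )

    pip = pip_count / n_saved
    effect = a_sum / n_saved
    pi_mean = pi_sum / n_saved
    pi_for_bf = pi_mean if config.bf_pi_mode == "posterior" else alpha_pi / beta_total
    pi_for_bf = float(np.clip(pi_for_bf, 1e-8, 1.0 - 1e-8))
    logbf = compute_logbf(pip, pi_for_bf, n_saved)

    snp_table = pd.DataFrame(
        {
            "snp_id": geno.snp_map["snp_id"],
            "chrom": geno.snp_map["chrom"],
            "pos": geno.snp_map["pos"],
            "ref": geno.snp_map["ref"],
            "alt": geno.snp_map["alt"],
            "pip": pip,
            "effect": effect,
            "logbf": logbf,
        }
    )
    trace_df = pd.DataFrame(
        traces, columns=["var_genetic", "var_dam", "var_residual", "pi", "n_included"]
    )
    return GwasResult(
        snp_table=snp_table,
        gebv=pd.Series(gebv_sum / n_saved, index=tab["id"], name="gebv"),
        pi_mean=float(pi_mean),
        var_genetic=float(trace_df["var_genetic"].mean()),
        var_dam=float(trace_df["var_dam"].mean()) if include_dam else 0.0,
        var_residual=float(trace_df["var_residual"].mean()),
        n_saved=int(n_saved),
        seed=config.seed,
        traces=trace_df,
        config=config,
    )


def convergence_check(
    result_a: GwasResult,
    result_b: GwasResult,
    threshold: float = 0.99,
    trace_dir: str | None = None,
) -> tuple[bool, float]:
    """Dual-seed convergence check: Pearson correlation of the genomic
    values from two runs on the same data; pass iff r > ``threshold``.

    With ``trace_dir`` set, the variance/pi traces of both runs are written
    as TSV for visual inspection of the posterior densities.
    """
    if list(result_a.gebv.index) != list(result_b.gebv.index):
        raise ValueError("runs cover different animal lists")
    r = float(np.corrcoef(result_a.gebv.to_numpy(), result_b.gebv.to_numpy())[0, 1])
    if trace_dir is not None:
        from pathlib import Path

        d = Path(trace_dir)
        d.mkdir(parents=True, exist_ok=True)
        result_a.traces.to_csv(d / f"trace_seed{result_a.seed}.tsv", sep="\t", index=False)
        result_b.traces.to_csv(d / f"trace_seed{result_b.seed}.tsv", sep="\t", index=False)
    return r > threshold, r
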