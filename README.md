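# thermoqtl

Quantitative genetics of acute hyperthermia resistance in farmed rainbow
trout, as a reusable, tested pipeline. When a heat-challenge tank is warmed
at a controlled rate (3.1 °C/h for 1.5 h, then 0.9 °C/h), each fish
eventually loses equilibrium; the time at which it does — standardized
within challenge groups as **TLE** — is a selectable resistance trait.
`thermoqtl` implements everything needed to dissect its genetic
architecture, for breeders and quantitative geneticists who want to assess
selection potential and marker-assisted selection for thermal robustness:

* **Phenotype construction** — within-group z-scores of raw time to loss of
  equilibrium, cumulative degree-minutes, harvest-trait derivation (carcass
  yield HGC% = HGCW/BW2, fat% as the mean of two fat-meter sites) with a
  10-g weight-sum consistency filter.
* **Genotype QC** — individual call rate < 0.90 removed; SNPs kept when
  call rate > 0.97, MAF > 0.05 and Hardy–Weinberg χ² p > 1e-5.
* **Relationship matrices** — pedigree **A** (tabular method) and VanRaden
  **G** (method 1, observed frequencies, blended 0.95 G + 0.05 A).
* **AI-REML variance components** — the animal model
  `y = μ + day + dam + u + e` (univariate and bivariate), heritability
  `h² = σ²_u/σ²_p`, dam (maternal common-environment) variance share,
  genetic correlations `r_g = cov(u_x,u_y)/√(σ²_ux σ²_uy)`, AIC model
  comparison for the dam term.
* **BayesCπ GWAS** — a numba-compiled Gibbs sampler in which each SNP
  effect is zero with probability 1−π and Gaussian otherwise, with π
  sampled from its Beta conditional; per-SNP evidence as
  `logBF = 2·ln[(P_l/(1−P_l))/(π/(1−π))]`; dual-seed GEBV-correlation
  convergence checks (r > 0.99).
* **QTL calling** — peaks at logBF ≥ 6, credibility intervals by chaining
  supporting SNPs (logBF ≥ 3) through 200-kb windows, single-SNP artifact
  exclusion, % genetic variance explained, gene-annotation overlap.
* **Peak contrasts & isogenic lines** — homozygote differences in
  day/dam-adjusted TLE (Tukey HSD), dominance deviations, and concordance
  of GWAS-favourable alleles with resistant/sensitive isogenic-line
  genomes.
* **Synthetic data** — a generator emulating the full study design (10
  factorial mating blocks, 99 sires × 76 dams, Mendelian gene dropping,
  seven heating-curve groups, planted QTL, harvest traits with configured
  genetic covariance) with a truth record for recovery testing.

See `docs/methods.md` for the models, priors, numerical conventions, and
what the generator does and does not emulate.

## Worked example

Simulate a study with one strong planted QTL and run the pipeline:

```python
import numpy as np
from thermoqtl import syndata, pheno, relmat, varcomp, gwas, peaks

# design: 99 sires x 76 dams in 10 blocks, 800 offspring, 2,000 SNPs
ped = syndata.make_pedigree(seed=7, n_offspring=800)
snp_map = syndata.default_snp_map(n_snps=2000, seed=7)
freqs = np.random.default_rng(8).uniform(0.1, 0.9, 2000)
freqs[1000] = 0.42                                # planted QTL at MAF 0.42
geno = syndata.gene_drop(ped, snp_map, freqs, seed=9)

qtl = syndata.QtlEffect(snp_map["snp_id"][1000], add_effect=0.345)
truth = syndata.challenge_truth(h2=0.29, dam_ratio=0.06, qtls=[qtl])
challenge = pheno.standardize_rtle(
    syndata.simulate_challenge(ped, geno, truth, seed=10))

g = relmat.g_matrix(geno.subset_individuals(challenge["id"].tolist()),
                    blend_weight=0.95, a=relmat.a_matrix(ped))
fit = varcomp.reml_fit(challenge, "tle", g, include_dam=True)
print(f"h2 = {fit.h2:.2f} +/- {fit.h2_se:.2f}, "
      f"dam share = {100 * fit.dam_ratio:.1f}%")

result = gwas.bayescpi_fit(challenge, geno, gwas.GibbsConfig(seed=11))
top = result.snp_table.nlargest(1, "logbf").iloc[0]
print(f"top SNP {top.snp_id}: logBF = {top.logbf:.1f}")

contrast = peaks.peak_contrast(challenge, fit, geno, top.snp_id)
print(f"homozygote difference = {100 * contrast.hom_difference_sd:.0f}% of SD "
      f"(Tukey p = {contrast.tukey_p:.1e})")
```

Output (seeds as above):

```
h2 = 0.25 +/- 0.07, dam share = 8.0%
top SNP SNP_8_65: logBF = 20.3
homozygote difference = 49% of SD (Tukey p = 1.3e-06)
```

`SNP_8_65` is exactly the planted QTL, found at logBF 20 against a
declaration threshold of 6. The single-replicate estimates scatter around
the generating values (h² 0.25 ± 0.07 vs 0.29; contrast 49% of SD vs the
planted 69%, within its ~9-point replicate SE); averaged over 20 replicate
studies they recover the truth — that averaging is what
`scripts/acceptance.py` does. A homozygote contrast of half a phenotypic
SD at a single SNP is what makes such a locus a candidate for
marker-assisted selection.

The same stages are scriptable from a shell:

```bash
thermoqtl run-all --seed 7 --n-offspring 800 --n-snps 2000 --out run/
thermoqtl simulate --seed 1 --out sim/      # or stage by stage
thermoqtl qc --vcf sim/genotypes.vcf --out qc/
```

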