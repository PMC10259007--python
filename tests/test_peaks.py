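import numpy as np
import pandas as pd
import pytest

from thermoqtl import experiments, peaks, relmat, syndata, varcomp
from thermoqtl.containers import GenotypeMatrix
from thermoqtl.gwas import GwasResult
from thermoqtl.syndata import QtlEffect


def _null_model(day_levels=("G1",), dam_blup=None):
    """A null-model stand-in with known (zero) day solutions."""
    fe = {"intercept": 0.0}
    for lev in day_levels[1:]:
        fe[f"group[{lev}]"] = 0.0
    return varcomp.VarianceComponents(
        components={"additive": 0.3, "dam": 0.05, "residual": 0.65},
        se={}, loglik=0.0, aic=0.0, converged=True, boundary=False,
        n_iter=1, n_obs=0, trait="tle",
        fixed_effects=pd.Series(fe),
        dam_blup=dam_blup,
    )


def _geno_single(codes, ref="A", alt="C"):
    sm = pd.DataFrame(
        {"snp_id": ["s0"], "chrom": ["chr1"], "pos": [100_000],
         "ref": [ref], "alt": [alt]}
    )
    return GenotypeMatrix(
        ids=[f"F{i}" for i in range(len(codes))], snp_map=sm,
        codes=np.asarray(codes, dtype=np.int8).reshape(-1, 1),
    )


def _table(values, geno):
    return pd.DataFrame(
        {"id": geno.ids, "group": "G1", "dam": "D0", "tle": values}
    )


class TestPeakContrast:
    def test_equal_class_means_give_null_contrast(self):
        codes = np.array([0] * 30 + [1] * 40 + [2] * 30)
        # values symmetric within each class: all class means exactly 0
        values = np.concatenate(
            [np.linspace(-1, 1, 30), np.linspace(-1, 1, 40), np.linspace(-1, 1, 30)]
        )
        geno = _geno_single(codes)
        c = peaks.peak_contrast(_table(values, geno), _null_model(), geno, "s0")
        assert c.hom_difference_sd == pytest.approx(0.0, abs=1e-12)
        assert c.tukey_p > 0.95
        assert c.dominance == pytest.approx(0.0, abs=1e-12)
        assert c.complete

    def test_additive_effect_detected_and_oriented(self):
        codes = np.array([0] * 30 + [1] * 40 + [2] * 30)
        values = codes * 0.5 + np.linspace(-0.01, 0.01, 100)
        geno = _geno_single(codes)
        c = peaks.peak_contrast(_table(values, geno), _null_model(), geno, "s0")
        sd = np.std(values, ddof=1)
        assert c.hom_difference_sd == pytest.approx(1.0 / sd, rel=0.05)
        assert c.favourable_homozygote == 2
        assert c.tukey_p < 1e-6
        assert c.dominance_p > 0.05  # purely additive

    def test_dominance_deviation_estimated(self):
        codes = np.array([0] * 30 + [1] * 40 + [2] * 30)
        rng = np.random.default_rng(1)
        values = codes * 0.2 + (codes == 1) * 0.3 + rng.standard_normal(100) * 0.05
        geno = _geno_single(codes)
        c = peaks.peak_contrast(_table(values, geno), _null_model(), geno, "s0")
        assert c.dominance == pytest.approx(0.3, abs=0.05)
        assert c.dominance_p < 0.01

    def test_missing_class_flagged_incomplete(self):
        codes = np.array([0] * 50 + [1] * 50)  # no hom-ref class
        geno = _geno_single(codes)
        c = peaks.peak_contrast(
            _table(np.random.default_rng(2).standard_normal(100), geno),
            _null_model(), geno, "s0",
        )
        assert not c.complete
        assert np.isnan(c.dominance)

    def test_day_and_dam_adjustment_subtracted(self):
        """A pure day shift and a known dam prediction vanish from the
        adjusted phenotype."""
        codes = np.array([0, 1, 2, 0, 1, 2])
        geno = _geno_single(codes)
        table = pd.DataFrame(
            {
                "id": geno.ids,
                "group": ["G1", "G1", "G1", "G2", "G2", "G2"],
                "dam": ["D1", "D1", "D1", "D2", "D2", "D2"],
                "tle": [0.0, 0.5, 1.0, 2.0, 2.5, 3.0],  # +2 day shift in G2
            }
        )
        model = _null_model(day_levels=("G1", "G2"))
        model.fixed_effects["group[G2]"] = 2.0
        adj = peaks.adjusted_phenotype(table, model)
        assert np.allclose(adj, [0.0, 0.5, 1.0, 0.0, 0.5, 1.0])
        model.dam_blup = pd.Series({"D1": 0.25, "D2": -0.25})
        adj2 = peaks.adjusted_phenotype(table, model)
        assert np.allclose(adj2, [-0.25, 0.25, 0.75, 0.25, 0.75, 1.25])

    def test_allele_relabelling_flips_consistently(self):
        """Swapping ref/alt (codes 2-g) mirrors the favourable homozygote
        but leaves the contrast magnitude unchanged."""
        rng = np.random.default_rng(3)
        codes = rng.integers(0, 3, 120)
        values = codes * 0.4 + rng.standard_normal(120) * 0.3
        g1 = _geno_single(codes)
        g2 = _geno_single(2 - codes, ref="C", alt="A")
        c1 = peaks.peak_contrast(_table(values, g1), _null_model(), g1, "s0")
        c2 = peaks.peak_contrast(_table(values, g2), _null_model(), g2, "s0")
        assert c1.hom_difference_sd == pytest.approx(c2.hom_difference_sd, rel=1e-9)
        assert c1.maf == pytest.approx(c2.maf)
        assert {c1.favourable_homozygote, c2.favourable_homozygote} == {0, 2}

    def test_dominance_test_size_under_additivity(self, small_study, small_grm):
        """Across purely additive SNPs, the constant-midpoint t-test is
        anticonservative (midpoint error and sib correlation ignored) but
        bounded; the bootstrap variant rejects less often."""
        fit = varcomp.reml_fit(small_study["challenge"], "tle", small_grm)
        geno = small_study["geno"]
        maf = geno.maf()
        testable = np.flatnonzero(maf > 0.25)[:60]
        reject_t = reject_boot = 0
        for j in testable:
            snp_id = geno.snp_map["snp_id"].iloc[j]
            c = peaks.peak_contrast(small_study["challenge"], fit, geno, snp_id)
            if c.complete and c.dominance_p < 0.05:
                reject_t += 1
            cb = peaks.peak_contrast(
                small_study["challenge"], fit, geno, snp_id,
                dominance_test="bootstrap", n_boot=300, boot_seed=j,
            )
            if cb.complete and cb.dominance_p < 0.05:
                reject_boot += 1
        assert reject_t <= 18            # inflated but bounded (< 30%)
        assert reject_boot <= reject_t   # midpoint-aware test is tighter
        assert reject_boot <= 9          # near-nominal: binom(60,.05)+3SE

    def test_planted_contrast_recovered_single_replicate(self):
        """One replicate of the homozygote-contrast design lands near the
        planted 0.69-SD difference."""
        df = experiments.contrast_recovery(n_reps=1, seed=4, n_offspring=800,
                                           n_snps=1000)
        assert df["hom_diff_pct_sd"].iloc[0] == pytest.approx(69.0, abs=25)


def _iso_result(effects, logbfs):
    n = len(effects)
    snp_table = pd.DataFrame(
        {
            "snp_id": [f"s{i}" for i in range(n)],
            "chrom": "chr13",
            "pos": np.arange(n) * 10_000 + 100_000,
            "ref": "A",
            "alt": "C",
            "pip": 0.5,
            "effect": effects,
            "logbf": logbfs,
        }
    )
    return GwasResult(
        snp_table=snp_table, gebv=pd.Series(dtype=float), pi_mean=0.01,
        var_genetic=1.0, var_dam=0.0, var_residual=1.0, n_saved=100, seed=0,
    )


def _line(alleles):
    return pd.DataFrame({"snp_id": [f"s{i}" for i in range(len(alleles))],
                         "allele": list(alleles)})


class TestIsogenicConcordance:
    def test_differing_snps_reported_with_favourable_allele(self):
        res = _iso_result([0.2, -0.3, 0.1, 0.4], [8.0, 7.0, 9.0, 2.0])
        report = peaks.isogenic_concordance(res, _line("CCAA"), _line("AAAC"))
        # s3 below threshold; s2 identical in both lines
        assert list(report["snp_id"]) == ["s0", "s1"]
        # s0: effect>0 -> favourable ref A; resistant carries A -> concordant
        assert report.loc[report["snp_id"] == "s0", "concordant"].item()
        # s1: effect<0 -> favourable alt C; resistant carries A -> discordant
        assert not report.loc[report["snp_id"] == "s1", "concordant"].item()

    def test_identical_lines_give_empty_report(self):
        res = _iso_result([0.2, -0.3], [8.0, 7.0])
        report = peaks.isogenic_concordance(res, _line("AC"), _line("AC"))
        assert report.empty

    def test_constructed_differences_counted_exactly(self):
        res = _iso_result([0.2, -0.3, 0.1, 0.4, -0.2], [8, 7, 9, 6.5, 2])
        report = peaks.isogenic_concordance(res, _line("CCCCC"), _line("AAACC"))
        assert len(report) == 3  # s0, s1, s2 differ above threshold; s3 same

    def test_duplicate_line_snp_ids_rejected(self):
        res = _iso_result([0.2], [8.0])
        dup = pd.DataFrame({"snp_id": ["s0", "s0"], "allele": ["A", "C"]})
        with pytest.raises(ValueError, match="duplicate"):
            peaks.isogenic_concordance(res, dup, _line("A"))

    def test_allele_relabelling_keeps_concordance(self):
        """Flipping ref/alt and the effect sign leaves the flag unchanged."""
        res = _iso_result([0.2], [8.0])
        rep = peaks.isogenic_concordance(res, _line("C"), _line("A"))
        flipped = _iso_result([-0.2], [8.0])
        flipped.snp_table.loc[0, ["ref", "alt"]] = ["C", "A"]
        rep2 = peaks.isogenic_concordance(flipped, _line("C"), _line("A"))
        assert rep["concordant"].item() == rep2["concordant"].item()
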