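import numpy as np
import pandas as pd
import pytest

from thermoqtl import syndata
from thermoqtl.containers import HeatingCurve, Pedigree, default_heating_curves
from thermoqtl.syndata import QtlEffect


class TestMakePedigree:
    def test_small_factorial_structure(self):
        ped = syndata.make_pedigree(
            n_blocks=2, sires_per_block=2, dams_per_block=2, offspring_per_pair=1, seed=0
        )
        offspring = ped.df[ped.df["generation"] == 1]
        assert len(offspring) == 8  # 2 blocks x 2 sires x 2 dams x 1
        for row in offspring.itertuples(index=False):
            assert row.sire.split("_")[0] == row.dam.split("_")[0]  # same block

    def test_default_design_matches_hatchery(self):
        ped = syndata.make_pedigree(seed=0, n_offspring=100)
        sires = {s for s in ped.df["sire"] if s != "0"} | {
            i for i in ped.founders() if "_S" in i
        }
        dams = {i for i in ped.founders() if "_D" in i}
        assert len(sires) == 99
        assert len(dams) == 76

    def test_mean_family_size_is_total_over_pairs(self):
        ped = syndata.make_pedigree(
            n_blocks=3, sires_per_block=3, dams_per_block=2, offspring_per_pair=4, seed=1
        )
        offspring = ped.df[ped.df["generation"] == 1]
        fam = offspring.groupby(["sire", "dam"]).size()
        assert fam.mean() == pytest.approx(len(offspring) / (3 * 3 * 2))
        assert (fam == 4).all()

    def test_rejects_nonpositive_counts(self):
        with pytest.raises(ValueError):
            syndata.make_pedigree(n_blocks=0)
        with pytest.raises(ValueError):
            syndata.make_pedigree(n_blocks=2, sires_per_block=0, dams_per_block=2)

    def test_deterministic_for_seed(self):
        a = syndata.make_pedigree(seed=5, n_offspring=50)
        b = syndata.make_pedigree(seed=5, n_offspring=50)
        pd.testing.assert_frame_equal(a.df, b.df)


class TestPedigreeInvariants:
    def test_parent_must_precede_offspring(self):
        with pytest.raises(ValueError, match="precede"):
            Pedigree(
                pd.DataFrame(
                    {
                        "id": ["K1", "S1"],
                        "sire": ["S1", "0"],
                        "dam": ["0", "0"],
                        "generation": [1, 0],
                    }
                )
            )

    def test_sire_dam_sets_disjoint(self):
        df = pd.DataFrame(
            {
                "id": ["X", "Y", "K1", "K2"],
                "sire": ["0", "0", "X", "Y"],
                "dam": ["0", "0", "Y", "X"],
                "generation": [0, 0, 1, 1],
            }
        )
        with pytest.raises(ValueError, match="both as sire and dam"):
            Pedigree(df)


class TestGeneDrop:
    def test_fixed_allele_gives_all_homozygotes(self, trio_pedigree):
        sm = syndata.default_snp_map(n_snps=5, n_chrom=1, seed=0)
        geno = syndata.gene_drop(trio_pedigree, sm, np.ones(5), seed=0)
        assert (geno.codes == 2).all()

    def test_mendelian_consistency_of_all_trios(self):
        ped = syndata.make_pedigree(seed=3, n_offspring=150)
        sm = syndata.default_snp_map(n_snps=60, n_chrom=3, seed=3)
        geno = syndata.gene_drop(ped, sm, np.random.default_rng(4).uniform(0.2, 0.8, 60), seed=5)
        pos = {a: i for i, a in enumerate(geno.ids)}
        for row in ped.df[ped.df["generation"] == 1].itertuples(index=False):
            child = geno.codes[pos[row.id]]
            sire = geno.codes[pos[row.sire]]
            dam = geno.codes[pos[row.dam]]
            # transmitted gamete from a hom parent is forced
            low = (sire == 2).astype(int) + (dam == 2).astype(int)
            high = 2 - ((sire == 0).astype(int) + (dam == 0).astype(int))
            assert (child >= low).all() and (child <= high).all()
        # opposite homozygote parents always give heterozygotes
        opp = np.flatnonzero((geno.codes[0] == 0) & (geno.codes[1] == 2))
        del opp  # founders are unrelated; trio rule already covered above

    def test_het_by_het_segregates_1_2_1(self):
        ped = syndata.make_pedigree(
            n_blocks=1, sires_per_block=1, dams_per_block=1, offspring_per_pair=6000, seed=7
        )
        sm = syndata.default_snp_map(n_snps=30, n_chrom=2, seed=7)
        geno = syndata.gene_drop(ped, sm, np.full(30, 0.5), seed=8)
        both_het = np.flatnonzero((geno.codes[0] == 1) & (geno.codes[1] == 1))
        assert both_het.size >= 3
        kids = geno.codes[2:, both_het]
        n = kids.shape[0]
        for frac, expected in ((kids == 0).mean(axis=0), 0.25), (
            (kids == 1).mean(axis=0),
            0.5,
        ), ((kids == 2).mean(axis=0), 0.25):
            se = np.sqrt(expected * (1 - expected) / n)
            assert (np.abs(frac - expected) < 3 * se + 1e-12).all()

    def test_allele_frequency_conserved_across_drops(self):
        ped = syndata.make_pedigree(seed=9, n_offspring=400)
        sm = syndata.default_snp_map(n_snps=40, n_chrom=2, seed=9)
        founder_freq = np.random.default_rng(10).uniform(0.2, 0.8, 40)
        diffs = []
        for rep in range(20):
            geno = syndata.gene_drop(ped, sm, founder_freq, seed=100 + rep)
            off = geno.subset_individuals(ped.offspring())
            diffs.append(off.ref_allele_freq() - founder_freq)
        mean_diff = np.mean(diffs, axis=0)
        # binomial SE of the mean offspring frequency over 20 drops
        se = np.sqrt(founder_freq * (1 - founder_freq) / (2 * 400 * 20)) * 2  # drift+sampling
        assert (np.abs(mean_diff) < 3 * se + 0.01).all()

    def test_rejects_bad_inputs(self, trio_pedigree):
        sm = syndata.default_snp_map(n_snps=3, n_chrom=1, seed=0)
        with pytest.raises(ValueError, match=r"\[0, 1\]"):
            syndata.gene_drop(trio_pedigree, sm, np.array([0.5, 1.2, 0.5]))
        with pytest.raises(ValueError, match="missing_rate"):
            syndata.gene_drop(trio_pedigree, sm, np.full(3, 0.5), missing_rate=1.0)

    def test_identical_seed_identical_output(self, trio_pedigree):
        sm = syndata.default_snp_map(n_snps=20, n_chrom=1, seed=0)
        f = np.full(20, 0.4)
        a = syndata.gene_drop(trio_pedigree, sm, f, missing_rate=0.1, seed=3)
        b = syndata.gene_drop(trio_pedigree, sm, f, missing_rate=0.1, seed=3)
        assert np.array_equal(a.codes, b.codes)


class TestHeatingCurve:
    def test_temperature_after_six_hours(self):
        curve = HeatingCurve(group="G", initial_temp=17.3)
        # 1.5 h at 3.1 degC/h then 4.5 h at 0.9 degC/h = +8.7 degC
        assert curve.temperature(360.0) == pytest.approx(17.3 + 8.7)

    def test_temperature_non_decreasing(self):
        curve = default_heating_curves()["G1"]
        t = np.linspace(0, 600, 1201)
        assert (np.diff(curve.temperature(t)) >= 0).all()

    def test_cumulative_heat_inverse_roundtrip(self):
        curve = HeatingCurve(group="G", initial_temp=17.0)
        times = np.array([30.0, 120.0, 400.0])
        back = curve.inverse_cumulative_heat(curve.cumulative_heat(times))
        assert np.allclose(back, times, atol=0.5)


class TestSimulateChallenge:
    def test_zero_variance_gives_identical_times(self):
        ped = syndata.make_pedigree(n_blocks=1, sires_per_block=2, dams_per_block=2,
                                    offspring_per_pair=10, seed=1)
        sm = syndata.default_snp_map(n_snps=50, n_chrom=1, seed=1)
        geno = syndata.gene_drop(ped, sm, np.full(50, 0.5), seed=2)
        truth = syndata.challenge_truth(h2=0.0, dam_ratio=0.0, sigma_p2=0.0)
        curves = {"G1": default_heating_curves()["G1"]}
        assign = pd.Series("G1", index=ped.offspring())
        table = syndata.simulate_challenge(
            ped, geno, truth, heating_curves=curves, group_assignment=assign, seed=3
        )
        assert table["rtle"].nunique() == 1

    def test_variance_decomposition_recovered(self):
        """Across replicate simulations, realized additive variance matches
        sigma_u2 and the phenotype decomposes as configured."""
        h2, dam_ratio, reps = 0.3, 0.06, 15
        var_u, r2 = [], []
        for rep in range(reps):
            ped = syndata.make_pedigree(seed=rep, n_offspring=500)
            sm = syndata.default_snp_map(n_snps=500, n_chrom=5, seed=rep)
            rng = np.random.default_rng(rep + 500)
            geno = syndata.gene_drop(ped, sm, rng.uniform(0.1, 0.9, 500), seed=rep + 1)
            truth = syndata.challenge_truth(h2=h2, dam_ratio=dam_ratio)
            table = syndata.simulate_challenge(ped, geno, truth, seed=rep + 2)
            from thermoqtl.pheno import standardize_rtle

            table = standardize_rtle(table)
            u = truth.breeding_values.loc[table["id"]].to_numpy()
            var_u.append(np.var(u, ddof=1))
            r2.append(np.corrcoef(table["tle"], u)[0, 1] ** 2)
        se_u = np.std(var_u, ddof=1) / np.sqrt(reps)
        assert abs(np.mean(var_u) - h2) < 2 * se_u + 0.01
        # squared correlation of TLE with the true breeding values ~ h2
        se_r = np.std(r2, ddof=1) / np.sqrt(reps)
        assert abs(np.mean(r2) - h2) < 2 * se_r + 0.02

    def test_planted_qtl_variance_adds_to_polygenic(self):
        ped = syndata.make_pedigree(seed=21, n_offspring=800)
        sm = syndata.default_snp_map(n_snps=400, n_chrom=4, seed=21)
        geno = syndata.gene_drop(ped, sm, np.full(400, 0.5), seed=22)
        qtl = QtlEffect(sm["snp_id"].iloc[200], add_effect=0.4)
        truth = syndata.challenge_truth(h2=0.3, dam_ratio=0.0, qtls=[qtl])
        syndata.simulate_challenge(ped, geno, truth, seed=23)
        u = truth.breeding_values.to_numpy()
        # total additive variance still matches sigma_u2 (QTL inside it)
        assert np.var(u, ddof=1) == pytest.approx(0.3, abs=0.06)

    def test_qtl_variance_exceeding_additive_rejected(self):
        ped = syndata.make_pedigree(seed=24, n_offspring=100)
        sm = syndata.default_snp_map(n_snps=50, n_chrom=1, seed=24)
        geno = syndata.gene_drop(ped, sm, np.full(50, 0.5), seed=25)
        qtl = QtlEffect(sm["snp_id"].iloc[0], add_effect=1.0)  # var 0.5 > 0.05
        truth = syndata.challenge_truth(h2=0.05, dam_ratio=0.0, qtls=[qtl])
        with pytest.raises(ValueError, match="exceeds"):
            syndata.simulate_challenge(ped, geno, truth, seed=26)

    def test_missing_heating_curve_reported(self):
        ped = syndata.make_pedigree(n_blocks=1, sires_per_block=2, dams_per_block=2,
                                    offspring_per_pair=3, seed=1)
        sm = syndata.default_snp_map(n_snps=10, n_chrom=1, seed=1)
        geno = syndata.gene_drop(ped, sm, np.full(10, 0.5), seed=2)
        truth = syndata.challenge_truth()
        assign = pd.Series("G99", index=ped.offspring())
        with pytest.raises(KeyError, match="G99"):
            syndata.simulate_challenge(ped, geno, truth, group_assignment=assign, seed=3)

    def test_identical_seed_bit_identical(self):
        ped = syndata.make_pedigree(seed=31, n_offspring=80)
        sm = syndata.default_snp_map(n_snps=60, n_chrom=2, seed=31)
        geno = syndata.gene_drop(ped, sm, np.full(60, 0.5), seed=32)
        t1 = syndata.challenge_truth()
        t2 = syndata.challenge_truth()
        a = syndata.simulate_challenge(ped, geno, t1, seed=33)
        b = syndata.simulate_challenge(ped, geno, t2, seed=33)
        pd.testing.assert_frame_equal(a, b)


@pytest.fixture(scope="module")
def harvest():
    ped = syndata.make_pedigree(seed=41, n_offspring=500)
    sm = syndata.default_snp_map(n_snps=400, n_chrom=4, seed=41)
    geno = syndata.gene_drop(
        ped, sm, np.random.default_rng(42).uniform(0.1, 0.9, 400), seed=43
    )
    truth = syndata.challenge_truth()
    table = syndata.simulate_harvest(ped, geno, truth, n_violations=24, seed=44)
    return table, truth


class TestSimulateHarvest:
    def test_planted_violations_and_only_them_exceed_threshold(self, harvest):
        table, truth = harvest
        disc = (table["bw2"] - (table["hgcw"] + table["headw"] + table["viscw"])).abs()
        flagged = set(table.loc[disc > 10.0, "id"])
        assert flagged == set(truth.violation_ids)
        assert len(flagged) == 24

    def test_downstream_filter_removes_exactly_planted(self, harvest):
        from thermoqtl.pheno import derive_and_filter_harvest

        table, truth = harvest
        kept, removed = derive_and_filter_harvest(table)
        assert sorted(removed["id"]) == sorted(truth.violation_ids)
        assert len(kept) + len(removed) == len(table)

    def test_identity_genetic_covariance_gives_uncorrelated_values(self):
        ped = syndata.make_pedigree(seed=45, n_offspring=500)
        sm = syndata.default_snp_map(n_snps=500, n_chrom=4, seed=45)
        geno = syndata.gene_drop(
            ped, sm, np.random.default_rng(46).uniform(0.1, 0.9, 500), seed=47
        )
        gcov = np.diag([2000.0, 70.0, 0.6, 0.6, 0.6, 0.15])
        corrs = []
        for rep in range(5):
            truth = syndata.challenge_truth()
            truth.genetic_cov = gcov
            syndata.simulate_harvest(ped, geno, truth, n_violations=0, seed=50 + rep)
            u = truth.harvest_genetic_values.to_numpy()
            c = np.corrcoef(u.T)
            corrs.append(c[np.triu_indices(6, k=1)])
        assert np.abs(np.mean(corrs, axis=0)).max() < 0.25

    def test_non_psd_covariance_rejected_with_diagnostic(self):
        ped = syndata.make_pedigree(seed=48, n_offspring=50)
        sm = syndata.default_snp_map(n_snps=50, n_chrom=1, seed=48)
        geno = syndata.gene_drop(ped, sm, np.full(50, 0.5), seed=49)
        truth = syndata.challenge_truth()
        bad = np.eye(6)
        bad[0, 1] = bad[1, 0] = 2.0  # correlation 2 -> indefinite
        truth.genetic_cov = bad
        with pytest.raises(ValueError, match="eigenvalue"):
            syndata.simulate_harvest(ped, geno, truth, seed=50)
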