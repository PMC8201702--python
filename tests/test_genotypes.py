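import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.special import gammaln

from divsel_gwas.genotypes import (
    AverageGenotypeMatrix,
    GenotypeError,
    GenotypeMatrix,
    allele_frequencies,
    certainty_summary,
    classical_mds,
    hwe_exact_pvalue,
    ibs_matrix,
    ibs_mds,
    predict_average_genotypes,
    qc_filter,
    read_dosage_tsv,
    read_plink,
    write_plink,
)
from conftest import toy_pedigree


def make_gm(values, chrom=None):
    values = np.asarray(values, dtype=float)
    m = values.shape[1]
    smap = pd.DataFrame(
        {
            "snp_id": [f"s{j}" for j in range(m)],
            "chrom": chrom if chrom is not None else ["1"] * m,
            "pos_bp": np.arange(1, m + 1) * 1000,
            "allele_counted": "A",
            "allele_other": "B",
        }
    )
    return GenotypeMatrix([f"i{k}" for k in range(values.shape[0])], smap, values)


def hwe_oracle(n_het, n_hom1, n_hom2):
    """Independent enumeration of the exact HWE distribution from the
    closed-form conditional probability (log-factorial form)."""
    n = n_het + n_hom1 + n_hom2
    n_a = 2 * n_hom1 + n_het

    def logp(h):
        homr = (n_a - h) // 2
        homc = n - h - homr
        if homr < 0 or homc < 0:
            return -np.inf
        return (
            gammaln(n + 1) - gammaln(homr + 1) - gammaln(homc + 1) - gammaln(h + 1)
            + h * np.log(2)
            + gammaln(n_a + 1) + gammaln(2 * n - n_a + 1) - gammaln(2 * n + 1)
        )
    hs = [h for h in range(n_a % 2, min(n_a, 2 * n - n_a) + 1, 2)]
    probs = np.exp([logp(h) for h in hs])
    probs /= probs.sum()
    obs = probs[hs.index(n_het)]
    return float(probs[probs <= obs * (1 + 1e-12)].sum())


class TestHweExact:
    @pytest.mark.parametrize(
        "counts",
        [(5, 3, 2), (57, 14, 50), (0, 10, 10), (20, 0, 0), (1, 0, 99), (100, 25, 25)],
    )
    def test_matches_independent_enumeration(self, counts):
        assert hwe_exact_pvalue(*counts) == pytest.approx(hwe_oracle(*counts), rel=1e-9)

    def test_all_heterozygous_is_extreme(self):
        assert hwe_exact_pvalue(1000, 0, 0) < 1e-10

    def test_equilibrium_counts_not_rejected(self):
        # 2pq:p^2:q^2 proportions at p=0.5
        assert hwe_exact_pvalue(50, 25, 25) > 0.5


class TestQcFilter:
    def test_clean_matrix_untouched_and_idempotent(self):
        rng = np.random.default_rng(1)
        p = 0.3
        vals = rng.binomial(2, p, size=(200, 20)).astype(float)
        gm = make_gm(vals)
        out, report = qc_filter(gm)
        assert report.removed_snps.empty and report.removed_individuals.empty
        out2, report2 = qc_filter(out)
        assert report2.removed_snps.empty and report2.removed_individuals.empty
        np.testing.assert_array_equal(out.values, out2.values)

    def test_hwe_filter_removes_all_het_snp(self):
        vals = np.ones((1000, 2))
        vals[:, 1] = np.tile([0, 1, 2, 1], 250)  # second SNP is HWE-consistent
        out, report = qc_filter(make_gm(vals))
        assert report.removed_snps.reason.tolist() == ["hwe"]
        assert out.snp_ids == ["s1"]

    def test_low_maf_snp_removed_with_reason_maf(self):
        rng = np.random.default_rng(2)
        vals = rng.binomial(2, 0.4, size=(1000, 2)).astype(float)
        # SNP 0: 4% missing (CF passes at 0.95) and MAF 0.5%
        vals[:, 0] = 0.0
        vals[rng.choice(1000, 10, replace=False), 0] = 1.0
        vals[rng.choice(1000, 40, replace=False), 0] = np.nan
        out, report = qc_filter(make_gm(vals))
        assert ("s0", "maf") in list(report.removed_snps.itertuples(index=False, name=None))

    def test_low_call_rate_individual_removed_first(self):
        rng = np.random.default_rng(3)
        vals = rng.binomial(2, 0.4, size=(50, 40)).astype(float)
        vals[0, :30] = np.nan  # individual i0 CR = 0.25
        out, report = qc_filter(make_gm(vals))
        assert list(report.removed_individuals["id"]) == ["i0"]
        # with i0 gone, no SNP should fail CF
        assert "call_frequency" not in set(report.removed_snps["reason"])

    def test_sex_chromosome_snps_removed(self):
        rng = np.random.default_rng(4)
        vals = rng.binomial(2, 0.4, size=(100, 3)).astype(float)
        gm = make_gm(vals, chrom=["1", "X", "1"])
        out, report = qc_filter(gm)
        assert ("s1", "unmapped_or_sex") in list(
            report.removed_snps.itertuples(index=False, name=None)
        )

    def test_all_snps_removed_raises(self):
        vals = np.ones((500, 1))  # all-het: HWE kills the only SNP
        with pytest.raises(GenotypeError, match="hwe"):
            qc_filter(make_gm(vals))

    def test_report_accounting_sums(self):
        rng = np.random.default_rng(5)
        vals = rng.binomial(2, 0.3, size=(300, 30)).astype(float)
        vals[:, 5] = 0.0  # monomorphic -> maf
        vals[: int(300 * 0.2), 10] = np.nan  # CF 0.8 -> call_frequency
        out, report = qc_filter(make_gm(vals))
        assert report.n_before[1] - report.n_after[1] == len(report.removed_snps)


class TestPredictAverageGenotypes:
    @pytest.fixture()
    def family(self):
        # two parents, genotypes chosen per test; two full sibs
        ped = toy_pedigree([("S", "0", "0"), ("D", "0", "0"),
                            ("K1", "S", "D"), ("K2", "S", "D")])
        ped.loc[ped.id.isin(["K1", "K2"]), "role"] = "response"
        return ped

    @pytest.mark.parametrize(
        "gs, gd, expected, cls",
        [
            (0, 0, 0.0, AverageGenotypeMatrix.CERTAIN),
            (2, 2, 2.0, AverageGenotypeMatrix.CERTAIN),
            (0, 2, 1.0, AverageGenotypeMatrix.CERTAIN),
            (1, 1, 1.0, AverageGenotypeMatrix.HALF_CERTAIN),
            (0, 1, 0.5, AverageGenotypeMatrix.UNCERTAIN),
            (1, 2, 1.5, AverageGenotypeMatrix.UNCERTAIN),
        ],
    )
    def test_parental_combinations(self, family, gs, gd, expected, cls):
        gm = make_gm([[gs], [gd]])
        gm.ids = ["S", "D"]
        avg = predict_average_genotypes(gm, family)
        assert avg.values[0, 0] == expected
        assert avg.certainty[0, 0] == cls

    def test_full_sibs_share_rows(self, small_sim, small_avg):
        ped = small_sim.pedigree.set_index("id")
        by_litter = {}
        for i in small_avg.ids:
            by_litter.setdefault((ped.loc[i, "sire"], ped.loc[i, "dam"]), []).append(i)
        checked = 0
        for sibs in by_litter.values():
            if len(sibs) > 1:
                rows = [small_avg.values[small_avg.ids.index(s)] for s in sibs]
                for r in rows[1:]:
                    np.testing.assert_array_equal(rows[0], r)
                checked += 1
        assert checked > 0

    def test_animals_with_ungenotyped_parent_excluded(self, family):
        gm = make_gm([[1]])
        gm.ids = ["S"]  # dam missing entirely
        avg = predict_average_genotypes(gm, family)
        assert avg.ids == []

    def test_per_snp_missing_parent_gives_missing_cell(self, family):
        gm = make_gm([[0, np.nan], [2, 1]])
        gm.ids = ["S", "D"]
        avg = predict_average_genotypes(gm, family)
        assert avg.values[0, 0] == 1.0
        assert np.isnan(avg.values[0, 1])
        assert avg.certainty[0, 1] == 0

    def test_linearity_of_cohort_frequency(self, small_sim, small_avg):
        """Predicted response frequency equals the mean of parental
        frequencies over the realized matings."""
        ped = small_sim.pedigree.set_index("id")
        bg = small_sim.breeder_genotypes
        bindex = {i: k for k, i in enumerate(bg.ids)}
        parent_rows = np.array(
            [[bindex[ped.loc[i, "sire"]], bindex[ped.loc[i, "dam"]]] for i in small_avg.ids]
        )
        expected = (bg.values[parent_rows[:, 0]] + bg.values[parent_rows[:, 1]]).mean(axis=0) / 4
        got = allele_frequencies(small_avg).to_numpy()
        np.testing.assert_allclose(got, expected, atol=1e-12)


class TestCertaintySummary:
    def test_hand_counted_mixture(self):
        ped = toy_pedigree(
            [("S1", "0", "0"), ("D1", "0", "0"), ("S2", "0", "0"), ("D2", "0", "0"),
             ("S3", "0", "0"), ("D3", "0", "0"), ("S4", "0", "0"), ("D4", "0", "0"),
             ("R1", "S1", "D1"), ("R2", "S2", "D2"), ("R3", "S3", "D3"), ("R4", "S4", "D4")]
        )
        ped.loc[ped.id.str.startswith("R"), "role"] = "response"
        # matings: two 0x0, one 0x1, one 1x1 -> (2 + 0.5) / 4 = 0.625
        gm = make_gm([[0], [0], [0], [0], [0], [1], [1], [1]])
        gm.ids = ["S1", "D1", "S2", "D2", "S3", "D3", "S4", "D4"]
        avg = predict_average_genotypes(gm, ped)
        per_snp, per_ind = certainty_summary(avg)
        assert per_snp["proportion_certain"].iloc[0] == pytest.approx(0.625)

    @pytest.mark.parametrize("g, expected", [(0, 1.0), (1, 0.5)])
    def test_uniform_matings(self, g, expected):
        ped = toy_pedigree([("S", "0", "0"), ("D", "0", "0"), ("R", "S", "D")])
        ped.loc[ped.id == "R", "role"] = "response"
        gm = make_gm([[g, g], [g, g]])
        gm.ids = ["S", "D"]
        _, per_ind = certainty_summary(predict_average_genotypes(gm, ped))
        assert per_ind["proportion_certain"].iloc[0] == pytest.approx(expected)


class TestAlleleFrequencies:
    def test_hand_sums(self):
        gm = make_gm(np.array([[2.0], [2.0]]))
        assert allele_frequencies(gm).iloc[0] == 1.0
        gm = make_gm(np.array([[0.0], [0.5], [1.0], [1.5], [2.0]]))
        assert allele_frequencies(gm).iloc[0] == pytest.approx(0.5)
        gm = make_gm(np.array([[1.5], [1.5], [0.5], [1.0]]))
        assert allele_frequencies(gm).iloc[0] == pytest.approx(0.5625)

    @settings(max_examples=25, deadline=None)
    @given(st.lists(st.sampled_from([0.0, 0.5, 1.0, 1.5, 2.0]), min_size=2, max_size=12),
           st.randoms(use_true_random=False))
    def test_invariant_to_order_and_duplication(self, dosages, rnd):
        gm = make_gm(np.array(dosages)[:, None])
        base = allele_frequencies(gm).iloc[0]
        shuffled = list(dosages)
        rnd.shuffle(shuffled)
        assert allele_frequencies(make_gm(np.array(shuffled)[:, None])).iloc[0] == pytest.approx(base)
        doubled = make_gm(np.array(dosages + dosages)[:, None])
        assert allele_frequencies(doubled).iloc[0] == pytest.approx(base)

    def test_empty_subset_rejected(self):
        with pytest.raises(GenotypeError):
            allele_frequencies(make_gm(np.ones((2, 1))), subset=[])


class TestIbsMds:
    def test_identical_individuals_collapse(self):
        vals = np.tile([0, 1, 2, 1, 0], (4, 1)).astype(float)
        vals = np.vstack([vals, np.array([[2, 1, 0, 1, 2.0]])])
        coords = ibs_mds(make_gm(vals), n_axes=1)
        first_four = coords.iloc[:4, 0].to_numpy()
        assert np.ptp(first_four) < 1e-9

    def test_toy_distance_reconstruction(self):
        d = np.array([[0.0, 0.3, 0.5], [0.3, 0.0, 0.4], [0.5, 0.4, 0.0]])
        coords, _ = classical_mds(d, n_axes=2)
        rec = np.sqrt(((coords[:, None, :] - coords[None, :, :]) ** 2).sum(-1))
        np.testing.assert_allclose(rec, d, atol=1e-9)

    def test_first_axis_separates_diverged_lines(self, small_sim):
        ped = small_sim.pedigree
        late = ped.query("role == 'breeder' and generation >= 6")
        gm = small_sim.breeder_genotypes.subset(ids=list(late["id"]))
        coords = ibs_mds(gm, n_axes=2)
        lines = late.set_index("id").loc[coords.index, "line"]
        a = coords.loc[(lines == "HRFI").to_numpy(), "axis1"]
        b = coords.loc[(lines == "LRFI").to_numpy(), "axis1"]
        # positive silhouette on axis 1: clusters are separated
        assert abs(a.mean() - b.mean()) > 2 * max(a.std(), b.std())

    def test_ibs_matrix_agrees_with_bruteforce(self):
        rng = np.random.default_rng(6)
        vals = rng.integers(0, 3, size=(6, 30)).astype(float)
        sim = ibs_matrix(make_gm(vals))
        for i in range(6):
            for j in range(6):
                expected = np.mean((2 - np.abs(vals[i] - vals[j])) / 2)
                assert sim[i, j] == pytest.approx(expected)

    def test_too_few_individuals_rejected(self):
        with pytest.raises(GenotypeError):
            ibs_mds(make_gm(np.ones((2, 5))))


class TestPlinkIO:
    def test_roundtrip(self, tmp_path, small_sim):
        gm = small_sim.breeder_genotypes.subset(ids=small_sim.breeder_genotypes.ids[:20])
        write_plink(gm, tmp_path / "g.ped", tmp_path / "g.map")
        back = read_plink(tmp_path / "g.ped", tmp_path / "g.map", orientation="major_zero")
        assert back.ids == gm.ids
        # counted allele may flip per SNP depending on observed frequency;
        # dosages must agree up to the documented orientation
        f_orig = gm.values.mean(axis=0) / 2
        for j in range(len(gm.snp_map)):
            col = back.values[:, j]
            if back.snp_map.allele_counted.iloc[j] == gm.snp_map.allele_counted.iloc[j]:
                np.testing.assert_array_equal(col, gm.values[:, j])
            else:
                np.testing.assert_array_equal(col, 2 - gm.values[:, j])
        assert (back.snp_map.pos_bp == gm.snp_map.pos_bp).all()

    def test_dosage_tsv_roundtrip(self, tmp_path, small_avg):
        small_avg.write_dosage_tsv(tmp_path / "avg.tsv")
        back = read_dosage_tsv(tmp_path / "avg.tsv")
        assert back.ids == small_avg.ids
        np.testing.assert_allclose(back.values, small_avg.values)
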