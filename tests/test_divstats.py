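import math
from fractions import Fraction

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import kaspop as kp
from kaspop.genotypes import HOM_REF, HET, HOM_ALT, MISSING
from conftest import make_matrix


def hwe_enumeration_oracle(n_aa: int, n_ab: int, n_bb: int):
    """Exact-rational enumeration of the conditional heterozygote-count
    distribution (independent of the implementation under test)."""
    n = n_aa + n_ab + n_bb
    na, nb = 2 * n_aa + n_ab, 2 * n_bb + n_ab
    if na == 0 or nb == 0:
        return Fraction(1)
    weights = {}
    for h in range(na % 2, min(na, nb) + 1, 2):
        aa, bb = (na - h) // 2, (nb - h) // 2
        weights[h] = Fraction(
            math.factorial(n) * 2**h,
            math.factorial(aa) * math.factorial(h) * math.factorial(bb),
        )
    total = sum(weights.values())
    obs = weights[n_ab]
    return sum(wt for wt in weights.values() if wt <= obs) / total


class TestPic:
    def test_maximum_at_half(self):
        assert kp.pic_biallelic(0.5) == pytest.approx(0.375, abs=1e-15)

    def test_fixed_allele_gives_zero(self):
        assert kp.pic_biallelic(1.0) == 0.0
        assert kp.pic_biallelic(0.0) == 0.0

    def test_closed_form_at_p01(self):
        assert kp.pic_biallelic(0.1) == pytest.approx(0.1638, abs=1e-12)

    @given(st.floats(0.0, 1.0))
    @settings(deadline=None, max_examples=200)
    def test_bounded_by_0375_and_below_he(self, p):
        pic = kp.pic_biallelic(p)
        he = 2 * p * (1 - p)
        assert pic <= 0.375 + 1e-12
        assert pic <= he + 1e-12
        # exact decomposition PIC = He - 2 p^2 q^2
        assert pic == pytest.approx(he - 2 * p**2 * (1 - p) ** 2, abs=1e-12)


class TestHweExact:
    @pytest.mark.parametrize(
        "counts",
        [(50, 0, 50), (25, 50, 25), (5, 3, 2), (12, 7, 0), (1, 1, 1), (0, 9, 0)],
    )
    def test_matches_rational_enumeration_oracle(self, counts):
        p, _ = kp.hwe_exact(*counts)
        oracle = float(hwe_enumeration_oracle(*counts))
        assert p == pytest.approx(oracle, rel=1e-9)

    def test_all_homozygote_split_is_extreme_deficit(self):
        p, direction = kp.hwe_exact(50, 0, 50)
        assert p < 1e-6
        assert direction == "deficit"

    def test_monomorphic_input(self):
        p, direction = kp.hwe_exact(20, 0, 0)
        assert p == 1.0
        assert direction == "none"

    def test_modal_configuration_not_significant(self):
        p, _ = kp.hwe_exact(25, 50, 25)
        assert p > 0.9

    def test_direction_tracks_conditional_expectation(self):
        # expectation = nA*nB/(2n-1); (4, 8, 0): nA=16, nB=8, n=12 -> 5.57
        _, direction = kp.hwe_exact(4, 8, 0)
        assert direction == "excess"
        _, direction = kp.hwe_exact(8, 0, 4)
        assert direction == "deficit"

    def test_invalid_counts_rejected(self):
        with pytest.raises(ValueError):
            kp.hwe_exact(0, 0, 0)

    def test_type_one_error_calibrated_under_panmixia(self):
        """At alpha = 0.05 the rejection rate over >= 1000 panmictic
        simulated loci stays within 3 binomial SEs of alpha (the exact
        test is conservative but must not over-reject)."""
        spec = kp.SimGenotypeSpec(1, 200, 1500, fst_target=0.0,
                                  fis_target=0.0, seed=42)
        m = kp.simulate_genotype_matrix(spec)
        rejections = 0
        for j in range(m.n_loci):
            col = m.calls[:, j]
            p, _ = kp.hwe_exact(
                int((col == HOM_REF).sum()),
                int((col == HET).sum()),
                int((col == HOM_ALT).sum()),
            )
            rejections += p <= 0.05
        rate = rejections / m.n_loci
        se = np.sqrt(0.05 * 0.95 / m.n_loci)
        assert abs(rate - 0.05) <= 3 * se


class TestScalarTransforms:
    @pytest.mark.parametrize(
        "h,expected", [(0.0, 0.0), (0.5, 1.5), (0.27, 0.4382623381)]
    )
    def test_theta_smm_closed_form(self, h, expected):
        assert kp.theta_smm(h) == pytest.approx(expected, abs=1e-9)

    def test_theta_smm_rejects_h_of_one(self):
        with pytest.raises(ValueError):
            kp.theta_smm(1.0)

    def test_theta_monotone_increasing(self):
        grid = np.linspace(0, 0.99, 50)
        vals = [kp.theta_smm(h) for h in grid]
        assert np.all(np.diff(vals) > 0)

    @pytest.mark.parametrize(
        "fst,expected", [(0.2, 1.0), (1.0, 0.0), (0.045, 5.3055555556)]
    )
    def test_gene_flow_closed_form(self, fst, expected):
        assert kp.gene_flow_nm(fst) == pytest.approx(expected, abs=1e-9)

    def test_gene_flow_undefined_below_zero(self):
        assert np.isnan(kp.gene_flow_nm(0.0))
        assert np.isnan(kp.gene_flow_nm(-0.1))

    def test_gene_flow_monotone_decreasing(self):
        grid = np.linspace(0.01, 1.0, 50)
        vals = [kp.gene_flow_nm(f) for f in grid]
        assert np.all(np.diff(vals) < 0)


class TestLocusDiversity:
    def test_closed_forms_at_p_half_n12(self):
        calls = np.array([[HOM_REF] * 3 + [HET] * 6 + [HOM_ALT] * 3]).T
        stats = kp.locus_diversity(make_matrix(calls))
        row = stats.iloc[0]
        assert row["He"] == pytest.approx(0.5)
        assert row["Ne"] == pytest.approx(2.0)
        assert row["I"] == pytest.approx(math.log(2), abs=1e-9)
        assert row["uHe"] == pytest.approx(24 / 23 * 0.5, abs=1e-9)

    def test_unbiased_factor_is_2n_over_2n_minus_1(self, small_matrix):
        stats = kp.locus_diversity(small_matrix)
        ok = stats["He"] > 0
        factor = stats.loc[ok, "uHe"] / stats.loc[ok, "He"]
        n = stats.loc[ok, "n_called"]
        assert np.allclose(factor, 2 * n / (2 * n - 1))

    def test_monomorphic_locus(self):
        stats = kp.locus_diversity(make_matrix([[HOM_ALT]] * 6))
        row = stats.iloc[0]
        assert row["Na"] == 1
        assert row["He"] == 0
        assert row["I"] == 0
        assert row["Ne"] == 1

    def test_uhe_with_he_027(self):
        # uHe = (24/23) * 0.27 at N = 12
        assert 24 / 23 * 0.27 == pytest.approx(0.2817, abs=5e-5)

    def test_pic_he_maf_inequality_chain(self, island_matrix):
        stats = kp.locus_diversity(island_matrix)
        ok = stats["defined"]
        assert (stats.loc[ok, "PIC"] <= stats.loc[ok, "He"] + 1e-12).all()
        assert (stats.loc[ok, "He"] <= 2 * stats.loc[ok, "MAF"] + 1e-12).all()
        assert (stats.loc[ok, "PIC"] <= 0.375 + 1e-12).all()

    def test_all_missing_locus_flagged(self):
        stats = kp.locus_diversity(make_matrix([[MISSING], [MISSING]]))
        assert not stats["defined"].iloc[0]


class TestAccessionSummary:
    def test_monomorphic_accession(self):
        m = make_matrix(np.full((6, 10), HOM_REF))
        summary = kp.accession_summary(m)
        row = summary.iloc[0]
        assert row["PPL"] == 0
        assert row["I"] == 0 and row["He"] == 0 and row["Ho"] == 0
        assert np.isnan(row["F"])

    def test_duplicate_accessions_identical_summaries(self, small_matrix):
        m = small_matrix
        doubled = kp.genotypes.GenotypeMatrix(
            sample_ids=m.sample_ids + [s + "_b" for s in m.sample_ids],
            accession_of_sample=m.accession_of_sample
            + [a + "B" for a in m.accession_of_sample],
            locus_ids=m.locus_ids,
            calls=np.vstack([m.calls, m.calls]),
            metadata=kp.simdata.default_accession_metadata(
                sorted(set(m.accession_of_sample) | {a + "B" for a in m.accession_of_sample})
            ),
        )
        summary = kp.accession_summary(doubled)
        for acc in m.accessions:
            a = summary.loc[acc].drop("n")
            b = summary.loc[acc + "B"].drop("n")
            assert np.allclose(a.to_numpy(dtype=float), b.to_numpy(dtype=float),
                               equal_nan=True)

    def test_inbreeding_recovered_from_generator_truth(self):
        vals = []
        for s in range(10):
            spec = kp.SimGenotypeSpec(1, 12, 200, fis_target=0.1, seed=900 + s)
            m = kp.simulate_genotype_matrix(spec)
            vals.append(kp.accession_summary(m)["F"].iloc[0])
        assert abs(np.mean(vals) - 0.1) < 0.05


class TestPrivateAlleles:
    def test_shared_allele_not_private(self):
        calls = np.array([[HET], [HET], [HET], [HET]])
        m = make_matrix(calls, accessions=["A1", "A1", "A2", "A2"])
        counts = kp.private_alleles(
            m, {"s0": "g1", "s1": "g1", "s2": "g2", "s3": "g2"}
        )
        assert counts.sum() == 0

    def test_single_hom_alt_individual_private(self):
        # alt allele observed only in g1's lone carrier; the reference
        # allele is shared (g1 also has a heterozygote)
        calls = np.array([[HOM_REF], [HOM_REF], [HOM_ALT], [HET]])
        m = make_matrix(calls)
        counts = kp.private_alleles(
            m, {"s0": "g2", "s1": "g2", "s2": "g1", "s3": "g1"}
        )
        assert counts["g1"] == 1
        assert counts["g2"] == 0

    def test_planted_counts_recovered(self):
        rng = np.random.default_rng(5)
        # 30 shared loci + planted exclusives: 4 in g1, 3 in g2, 1 in g3
        n_per = 8
        groups = ["g1"] * n_per + ["g2"] * n_per + ["g3"] * n_per
        cols = [rng.choice([HOM_REF, HET, HOM_ALT], size=3 * n_per) for _ in range(30)]
        planted = {"g1": 4, "g2": 3, "g3": 1}
        for gi, (g, k) in enumerate(planted.items()):
            for _ in range(k):
                col = np.full(3 * n_per, HOM_REF)
                col[gi * n_per] = HET  # alt allele only in this group
                cols.append(col)
        m = make_matrix(np.column_stack(cols),
                        accessions=["A1"] * n_per + ["A2"] * n_per + ["A3"] * n_per)
        counts = kp.private_alleles(m, dict(zip(m.sample_ids, groups)))
        for g, k in planted.items():
            assert counts[g] == k
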