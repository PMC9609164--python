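import numpy as np
import pandas as pd
import pytest
from scipy import stats

from perizygote import dnm_discovery as dd
from perizygote.records import GERMLINE, POST_ZYGOTIC

from conftest import make_trio_table


class TestExtractCandidates:
    def test_de_novo_retained_inherited_excluded(self):
        table = make_trio_table(
            [
                {"pos": 100},  # proband 0/1, parents 0/0 -> de novo
                {"pos": 200, "mother_gt": "0/1", "mother_ad": (15, 15)},
                {"pos": 300, "father_gt": "1/1", "father_ad": (0, 30)},
                {"pos": 400, "child_gt": "0/0", "child_ad": (30, 0)},
            ]
        )
        out = dd.extract_candidates(table)
        assert list(out["pos"]) == [100]

    @pytest.mark.parametrize("who", ["child_gq", "father_gq", "mother_gq"])
    def test_low_gq_excluded_in_any_member(self, who):
        table = make_trio_table([{"pos": 100}])
        table.loc[0, who] = 19
        assert len(dd.extract_candidates(table)) == 0
        table.loc[0, who] = 20
        assert len(dd.extract_candidates(table)) == 1

    def test_missing_column_is_schema_error(self):
        table = make_trio_table([{"pos": 100}]).drop(columns=["mother_gt"])
        with pytest.raises(KeyError, match="mother_gt"):
            dd.extract_candidates(table)


class TestApplyFilters:
    def test_low_alt_support_rejected(self):
        table = make_trio_table([{"pos": 100, "child_ad": (26, 4)}])
        kept, log = dd.apply_filters(table)
        assert len(kept) == 0
        assert list(log["reason"]) == ["alt_support"]

    def test_single_strand_rejected(self):
        table = make_trio_table(
            [{"pos": 100, "child_ad": (20, 10), "child_adf": 10, "child_adr": 0}]
        )
        kept, log = dd.apply_filters(table)
        assert len(kept) == 0
        assert list(log["reason"]) == ["strand"]

    @pytest.mark.parametrize(
        "flag,reason", [("near_indel", "near_indel"), ("repeat_masked", "repeat_mask")]
    )
    def test_annotation_flags_rejected(self, flag, reason):
        table = make_trio_table([{"pos": 100, flag: True}])
        kept, log = dd.apply_filters(table)
        assert len(kept) == 0
        assert list(log["reason"]) == [reason]

    def test_clustered_pair_both_removed(self):
        table = make_trio_table([{"pos": 100}, {"pos": 115}, {"pos": 400}])
        kept, log = dd.apply_filters(table)
        assert list(kept["pos"]) == [400]
        assert set(log["reason"]) == {"clustered"}

    def test_cluster_chain_grouping_transitive(self):
        # 100-118-136: each neighbour within 20 bp, ends 36 bp apart;
        # the whole chain goes
        table = make_trio_table([{"pos": 100}, {"pos": 118}, {"pos": 136}])
        kept, _ = dd.apply_filters(table)
        assert len(kept) == 0

    def test_cluster_rule_ignores_other_chromosome(self):
        table = make_trio_table(
            [{"chrom": "chr1", "pos": 100}, {"chrom": "chr2", "pos": 110}]
        )
        kept, _ = dd.apply_filters(table)
        assert len(kept) == 2

    def test_unsorted_input_rejected(self):
        table = make_trio_table([{"pos": 400}, {"pos": 100}])
        with pytest.raises(ValueError, match="sorted"):
            dd.apply_filters(table)

    def test_order_independence_after_sorting(self, rng):
        rows = [{"pos": int(p)} for p in rng.choice(100_000, 50, replace=False) * 3]
        table = make_trio_table(rows).sort_values(["chrom", "pos"], ignore_index=True)
        shuffled = (
            table.sample(frac=1, random_state=0)
            .sort_values(["chrom", "pos"], ignore_index=True)
        )
        kept_a, _ = dd.apply_filters(table)
        kept_b, _ = dd.apply_filters(shuffled)
        pd.testing.assert_frame_equal(kept_a, kept_b)


class TestClassifyZygosity:
    def test_low_vaf_clean_parents_is_postzygotic(self):
        assert dd.classify_zygosity(16, 4, 0, 0) == POST_ZYGOTIC

    def test_midpoint_vaf_is_germline(self):
        assert dd.classify_zygosity(10, 10, 0, 0) == GERMLINE

    def test_boundary_vaf_exactly_035_is_germline(self):
        assert dd.classify_zygosity(13, 7, 0, 0) == GERMLINE  # 7/20 = 0.35

    def test_high_vaf_clean_parents_is_postzygotic(self):
        assert dd.classify_zygosity(5, 15, 0, 0) == POST_ZYGOTIC  # 0.75

    def test_parental_read_blocks_postzygotic(self):
        assert dd.classify_zygosity(16, 4, 1, 0) == GERMLINE

    def test_zero_depth_is_error(self):
        with pytest.raises(ZeroDivisionError):
            dd.classify_zygosity(0, 0, 0, 0)

    def test_sensitivity_on_planted_mosaics(self, default_sim):
        """Planted post-zygotic variants are recalled from read evidence
        with high sensitivity at the default depth."""
        truth = default_sim.truth.dnms
        post = truth[truth["zygosity"] == POST_ZYGOTIC]
        merged = post.merge(default_sim.variants, on=["chrom", "pos"])
        labels = dd.classify_zygosity_table(merged)
        assert (labels == POST_ZYGOTIC).mean() >= 0.7  # small-n smoke check


class TestTiTv:
    def test_small_example(self):
        calls = [("A", "G"), ("C", "T"), ("G", "A"), ("A", "C")]
        assert dd.titv_ratio(calls) == 3.0

    def test_all_transversions(self):
        assert dd.titv_ratio([("A", "C"), ("C", "G")]) == 0.0

    def test_no_transversions_undefined(self):
        with pytest.raises(ZeroDivisionError):
            dd.titv_ratio([("A", "G")])

    def test_planted_two_to_one_spectrum(self, rng):
        # transitions drawn with probability 2/3 -> ratio ~2 at n=3000
        transitions = {"A": "G", "G": "A", "C": "T", "T": "C"}
        calls = []
        for _ in range(3000):
            ref = rng.choice(list("ACGT"))
            if rng.random() < 2 / 3:
                calls.append((ref, transitions[ref]))
            else:
                tv = [b for b in "ACGT" if b not in (ref, transitions[ref])]
                calls.append((ref, rng.choice(tv)))
        assert 1.8 <= dd.titv_ratio(calls) <= 2.2


class TestMutationCategories:
    def test_purine_strand_collapse_cpg(self):
        # G>A with reference 5'-C G A-3': pyrimidine strand reads T-C-G,
        # so this is a C>T at a CpG dinucleotide
        ref = {"chr1": "ACGA"}
        calls = pd.DataFrame(
            [{"chrom": "chr1", "pos": 3, "ref": "G", "alt": "A"}]
        )
        counts = dd.mutation_categories(calls, ref)
        assert counts["C>T at CpG"] == 1 and counts.sum() == 1

    def test_non_cpg_transition(self):
        ref = {"chr1": "AACAA"}
        calls = pd.DataFrame([{"chrom": "chr1", "pos": 3, "ref": "C", "alt": "T"}])
        counts = dd.mutation_categories(calls, ref)
        assert counts["C>T at non-CpG"] == 1

    def test_bins_sum_to_snv_count(self, default_sim):
        truth = default_sim.truth.dnms[["chrom", "pos", "ref", "alt"]]
        counts = dd.mutation_categories(truth, default_sim.reference)
        assert counts.sum() == len(truth)

    def test_contig_edge_is_error(self):
        # a C at the last base has no 3' context; a G at the first base
        # has no 5' context on the plus strand (3' on the pyrimidine one)
        calls = pd.DataFrame([{"chrom": "chr1", "pos": 2, "ref": "C", "alt": "T"}])
        with pytest.raises(IndexError):
            dd.mutation_categories(calls, {"chr1": "AC"})
        calls = pd.DataFrame([{"chrom": "chr1", "pos": 1, "ref": "G", "alt": "A"}])
        with pytest.raises(IndexError):
            dd.mutation_categories(calls, {"chr1": "GA"})


class TestProportionTest:
    def test_published_cohort_counts(self):
        _, p = dd.postzygotic_proportion_test(36, 470, 11, 361)
        assert round(p, 3) == 0.004

    def test_equal_proportions(self):
        z, p = dd.postzygotic_proportion_test(10, 100, 10, 100)
        assert z == 0.0 and p == 1.0

    @pytest.mark.parametrize(
        "k1,n1,k2,n2",
        [(36, 470, 11, 361), (30, 300, 15, 300), (60, 500, 40, 500)],
    )
    def test_against_fisher_exact_oracle(self, k1, n1, k2, n2):
        """At counts where the normal approximation is adequate the pooled
        z-test agrees with the exact conditional (Fisher) oracle."""
        _, p = dd.postzygotic_proportion_test(k1, n1, k2, n2)
        _, p_fisher = stats.fisher_exact([[k1, n1 - k1], [k2, n2 - k2]])
        assert abs(p - p_fisher) < 0.02

    def test_domain_errors(self):
        with pytest.raises(ValueError):
            dd.postzygotic_proportion_test(1, 0, 1, 10)
        with pytest.raises(ValueError):
            dd.postzygotic_proportion_test(11, 10, 1, 10)


class TestAgeRegression:
    def test_exact_line(self):
        ages = [20, 30, 40, 50]
        counts = [2 * a + 3 for a in ages]
        res = dd.germline_age_regression(ages, counts)
        assert res.slope == pytest.approx(2.0)
        assert res.intercept == pytest.approx(3.0)

    def test_constant_response(self):
        res = dd.germline_age_regression([20, 30, 40], [50, 50, 50])
        assert res.slope == pytest.approx(0.0)

    def test_constant_predictor_is_singular(self):
        with pytest.raises(np.linalg.LinAlgError):
            dd.germline_age_regression([30, 30, 30], [1, 2, 3])

    def test_needs_three_families(self):
        with pytest.raises(ValueError):
            dd.germline_age_regression([30, 40], [50, 60])


class TestRatesAndFrequencies:
    def test_unphased_rate(self):
        rates = dd.dnm_rate(91, 2.91e9)
        assert rates["unphased_per_bp"] == pytest.approx(91 / 5.82e9)

    def test_phased_extrapolation(self):
        rates = dd.dnm_rate(91, 2.91e9, phased_paternal=40, phased_maternal=10)
        assert rates["paternal_extrapolated_count"] == pytest.approx(72.8)

    def test_zero_dnms(self):
        assert dd.dnm_rate(0, 2.91e9)["unphased_per_bp"] == 0.0

    def test_invalid_size(self):
        with pytest.raises(ValueError):
            dd.dnm_rate(10, 0)

    def test_allele_frequency(self):
        assert round(dd.allele_frequency(2990, 21518), 3) == 0.139
        with pytest.raises(ValueError):
            dd.allele_frequency(5, 0)


class TestCohortIdentity:
    def test_total_is_germline_plus_postzygotic(self):
        from perizygote.fixtures import load_cohort_counts

        cohort = load_cohort_counts()
        assert (cohort["total"] == cohort["germline"] + cohort["post_zygotic"]).all()

    def test_mismatched_total_rejected(self):
        bad = pd.DataFrame({"germline": [10], "post_zygotic": [2], "total": [13]})
        with pytest.raises(ValueError):
            dd.cohort_summary(bad)
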