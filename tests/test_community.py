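"""Community-metric tests: diversity, group tests, aggregation, SCFA statistics."""

import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from gutwash.community import (
    FeatureTable,
    aggregate_by_rank,
    alpha_diversity_frame,
    alpha_group_test,
    faith_pd,
    fb_ratio,
    find_probiotic_asvs,
    pairwise_scfa_tests,
    parse_lineage,
    remove_probiotic_asvs,
    richness,
    scfa_taxon_correlation,
    shannon,
)


def _toy_table():
    counts = pd.DataFrame(
        {
            "S1": [100, 600, 300, 0, 5],
            "S2": [0, 300, 600, 50, 50],
        },
        index=["ASV_lgg", "ASV_f1", "ASV_b1", "ASV_p1", "ASV_f2"],
    )
    meta = pd.DataFrame(
        {"bioreplicate": ["BR1", "BR1"], "region": ["AC", "TC"],
         "period": ["pre", "pre"]},
        index=["S1", "S2"],
    )
    return FeatureTable(counts, meta)


TOY_TAXONOMY = {
    "ASV_lgg": "k__Bacteria; p__Firmicutes; c__Bacilli; o__Lactobacillales; "
               "f__Lactobacillaceae; g__Lacticaseibacillus; s__rhamnosus",
    "ASV_f1": "k__Bacteria; p__Firmicutes; c__; o__; f__; g__Blautia",
    "ASV_f2": "k__Bacteria; p__Firmicutes; c__; o__; f__; g__Roseburia",
    "ASV_b1": "k__Bacteria; p__Bacteroidetes; c__; o__; f__; g__Bacteroides",
    "ASV_p1": "k__Bacteria; p__Proteobacteria",
}


class TestLineageParsing:
    def test_full_lineage(self):
        ranks = parse_lineage(TOY_TAXONOMY["ASV_lgg"])
        assert ranks["phylum"] == "Firmicutes"
        assert ranks["genus"] == "Lacticaseibacillus"

    def test_empty_ranks_tolerated(self):
        ranks = parse_lineage("k__Bacteria; p__Firmicutes; g__")
        assert "genus" not in ranks

    def test_probiotic_detection_by_genus(self):
        assert find_probiotic_asvs(TOY_TAXONOMY) == {"ASV_lgg"}


class TestRemoveProbioticAsvs:
    def test_empty_target_identity(self):
        table = _toy_table()
        out = remove_probiotic_asvs(table, set())
        pd.testing.assert_frame_equal(out.counts, table.counts)

    def test_removal_bookkeeping(self):
        table = _toy_table()
        out = remove_probiotic_asvs(table, {"ASV_lgg"})
        assert "ASV_lgg" not in out.counts.index
        assert out.counts["S1"].sum() == table.counts["S1"].sum() - 100
        assert out.metadata.loc["S1", "removed_reads"] == 100

    def test_unknown_ids_warn(self):
        with pytest.warns(UserWarning, match="not in table"):
            remove_probiotic_asvs(_toy_table(), {"ASV_ghost"})

    def test_removing_everything_breaks_downstream_diversity(self):
        table = _toy_table()
        out = remove_probiotic_asvs(table, set(table.asv_ids))
        with pytest.raises(ValueError):
            shannon(out.counts["S1"].to_numpy())


class TestShannonRichness:
    def test_single_taxon_zero(self):
        assert shannon([42]) == 0.0

    def test_uniform_maximum(self):
        assert shannon([5, 5, 5, 5]) == pytest.approx(math.log(4), rel=1e-12)

    def test_three_one_split(self):
        assert shannon([3, 1]) == pytest.approx(0.5623, abs=1e-4)

    def test_log_base_switch(self):
        assert shannon([1, 1], base=2) == pytest.approx(1.0, rel=1e-12)

    def test_permutation_invariance_and_bounds(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            counts = rng.integers(0, 50, size=12)
            if counts.sum() == 0:
                continue
            h = shannon(counts)
            assert h == pytest.approx(shannon(rng.permutation(counts)), rel=1e-12)
            s = richness(counts)
            assert 0 <= h <= math.log(max(s, 1)) + 1e-12

    def test_all_zero_undefined(self):
        with pytest.raises(ValueError):
            shannon([0, 0, 0])

    def test_richness_examples(self):
        assert richness([0, 0, 0]) == 0
        assert richness([5, 0, 2, 1]) == 3

    def test_richness_drops_by_one_after_removal(self):
        table = _toy_table()
        out = remove_probiotic_asvs(table, {"ASV_lgg"})
        assert richness(out.counts["S1"]) == richness(table.counts["S1"]) - 1
        # absent in S2, so unchanged there
        assert richness(out.counts["S2"]) == richness(table.counts["S2"])


class TestFaithPD:
    def test_all_tips_total_length(self, worked_tree):
        assert faith_pd(worked_tree, {"A", "B", "C", "D"}) == pytest.approx(6.0)

    def test_single_tip_path_to_root(self, worked_tree):
        assert faith_pd(worked_tree, {"A"}) == pytest.approx(2.0)

    def test_cherry(self, worked_tree):
        assert faith_pd(worked_tree, {"A", "B"}) == pytest.approx(3.0)

    def test_monotone_under_tip_addition(self, worked_tree):
        pd_a = faith_pd(worked_tree, {"A"})
        pd_ac = faith_pd(worked_tree, {"A", "C"})
        pd_all = faith_pd(worked_tree, {"A", "B", "C", "D"})
        assert pd_a <= pd_ac <= pd_all

    def test_empty_set_warns_zero(self, worked_tree):
        with pytest.warns(UserWarning):
            assert faith_pd(worked_tree, set()) == 0.0

    def test_unknown_tip_error(self, worked_tree):
        with pytest.raises(ValueError, match="not in tree"):
            faith_pd(worked_tree, {"Z"})


class TestAlphaGroupTest:
    def test_hand_computed_f_statistic(self):
        # groups (1,2,3), (2,3,4), (3,4,5): SSB = 6, SSW = 6 -> F = 3 with df (2, 6)
        values = np.array([1, 2, 3, 2, 3, 4, 3, 4, 5], dtype=float)
        groups = np.array(["a"] * 3 + ["b"] * 3 + ["c"] * 3)
        res = alpha_group_test(values, groups)
        assert res.f_statistic == pytest.approx(3.0, rel=1e-12)
        assert (res.df_between, res.df_within) == (2, 6)
        assert len(res.pairwise) == 3
        assert set(res.pairwise.columns) == {"group1", "group2", "meandiff", "p_adj"}

    def test_identical_groups_no_signal(self):
        values = np.array([1.0, 2, 3, 1, 2, 3])
        groups = np.array(["a"] * 3 + ["b"] * 3)
        res = alpha_group_test(values, groups)
        assert res.f_statistic == pytest.approx(0.0, abs=1e-12)
        assert res.p_value == pytest.approx(1.0)

    def test_small_groups_excluded_with_warning(self):
        values = np.array([1.0, 2, 3, 2, 3, 4, 9])
        groups = np.array(["a"] * 3 + ["b"] * 3 + ["c"])
        with pytest.warns(UserWarning, match="excluded"):
            res = alpha_group_test(values, groups)
        assert res.excluded_groups == ["c"]
        assert res.df_between == 1

    def test_degenerate_zero_variance(self):
        with pytest.raises(ValueError, match="degenerate"):
            alpha_group_test(np.ones(6), np.array(["a"] * 3 + ["b"] * 3))

    def test_type_i_error_near_nominal(self):
        # exchangeable data with arbitrary labels: rejection rate ~ alpha
        rng = np.random.default_rng(123)
        groups = np.array(["a"] * 5 + ["b"] * 5 + ["c"] * 5)
        rejections = 0
        n_sim = 500
        for _ in range(n_sim):
            values = rng.normal(size=15)
            if alpha_group_test(values, groups).p_value < 0.05:
                rejections += 1
        assert abs(rejections / n_sim - 0.05) < 0.025


class TestAggregation:
    def test_single_phylum_collapses_to_one(self):
        counts = pd.DataFrame({"S1": [10, 20]}, index=["a", "b"])
        tax = {"a": "k__Bacteria; p__Firmicutes", "b": "k__Bacteria; p__Firmicutes"}
        out = aggregate_by_rank(FeatureTable(counts), tax, "phylum")
        assert out.shape == (1, 1)
        assert out.iloc[0, 0] == pytest.approx(1.0)

    def test_two_phyla_proportions(self):
        table = _toy_table()
        out = aggregate_by_rank(table, TOY_TAXONOMY, "phylum")
        assert out.loc["Firmicutes", "S1"] == pytest.approx(705 / 1005)
        assert out.loc["Bacteroidetes", "S1"] == pytest.approx(300 / 1005)

    def test_columns_normalised(self):
        rng = np.random.default_rng(9)
        counts = pd.DataFrame(
            rng.integers(1, 100, size=(8, 4)),
            index=[f"x{i}" for i in range(8)],
            columns=[f"S{i}" for i in range(4)],
        )
        tax = {f"x{i}": f"k__Bacteria; p__P{i % 3}" for i in range(8)}
        out = aggregate_by_rank(FeatureTable(counts), tax, "phylum")
        assert np.allclose(out.sum(axis=0), 1.0, atol=1e-12)

    def test_read_conservation_before_normalisation(self):
        table = _toy_table()
        labels = [
            parse_lineage(TOY_TAXONOMY[a]).get("phylum", "unclassified")
            for a in table.asv_ids
        ]
        summed = table.counts.groupby(pd.Index(labels)).sum()
        assert (summed.sum(axis=0) == table.counts.sum(axis=0)).all()

    def test_unassigned_pooled_as_unclassified(self):
        counts = pd.DataFrame({"S1": [10, 30]}, index=["a", "b"])
        out = aggregate_by_rank(
            FeatureTable(counts), {"a": "k__Bacteria"}, "phylum"
        )
        assert out.loc["unclassified", "S1"] == pytest.approx(1.0)

    def test_empty_sample_error(self):
        counts = pd.DataFrame({"S1": [0, 0]}, index=["a", "b"])
        with pytest.raises(ValueError, match="zero reads"):
            aggregate_by_rank(FeatureTable(counts), {}, "phylum")

    def test_bad_rank(self):
        with pytest.raises(ValueError):
            aggregate_by_rank(_toy_table(), TOY_TAXONOMY, "clade")


class TestFbRatio:
    def test_two_to_one(self):
        counts = pd.DataFrame({"S1": [600, 300]}, index=["f", "b"])
        tax = {"f": "k__Bacteria; p__Firmicutes", "b": "k__Bacteria; p__Bacteroidetes"}
        assert fb_ratio(FeatureTable(counts), tax)["S1"] == pytest.approx(2.0)

    def test_equal_abundance_unity(self):
        counts = pd.DataFrame({"S1": [300, 300]}, index=["f", "b"])
        tax = {"f": "k__Bacteria; p__Firmicutes", "b": "k__Bacteria; p__Bacteroidetes"}
        assert fb_ratio(FeatureTable(counts), tax)["S1"] == pytest.approx(1.0)

    def test_depth_invariance(self):
        tax = {"f": "k__Bacteria; p__Firmicutes", "b": "k__Bacteria; p__Bacteroidetes",
               "o": "k__Bacteria; p__Proteobacteria"}
        c1 = pd.DataFrame({"S1": [60, 30, 10]}, index=["f", "b", "o"])
        c2 = c1 * 10
        r1 = fb_ratio(FeatureTable(c1), tax)["S1"]
        r2 = fb_ratio(FeatureTable(c2), tax)["S1"]
        assert r1 == pytest.approx(r2, rel=1e-12)

    def test_zero_bacteroidetes_flagged_infinite(self):
        counts = pd.DataFrame({"S1": [600, 10]}, index=["f", "o"])
        tax = {"f": "k__Bacteria; p__Firmicutes", "o": "k__Bacteria; p__Proteobacteria"}
        assert np.isinf(fb_ratio(FeatureTable(counts), tax)["S1"])


def _brute_force_pearson(x, y):
    x, y = np.asarray(x, float), np.asarray(y, float)
    xm, ym = x - x.mean(), y - y.mean()
    return float((xm * ym).sum() / math.sqrt((xm ** 2).sum() * (ym ** 2).sum()))


class TestScfaCorrelation:
    def _frames(self, x, y):
        scfa = pd.DataFrame({"butanoic": x}, index=[f"S{i}" for i in range(len(x))])
        taxa = pd.DataFrame([y], index=["Bacteroides"],
                            columns=[f"S{i}" for i in range(len(y))])
        return scfa, taxa

    def test_perfect_positive(self):
        out = scfa_taxon_correlation(*self._frames([1, 2, 3], [2, 4, 6]))
        assert out["r"].iloc[0] == pytest.approx(1.0)

    def test_perfect_negative(self):
        out = scfa_taxon_correlation(*self._frames([1, 2, 3], [3, 2, 1]))
        assert out["r"].iloc[0] == pytest.approx(-1.0)

    def test_matches_product_moment_oracle(self):
        rng = np.random.default_rng(21)
        for _ in range(10):
            x = rng.normal(size=10)
            y = rng.normal(size=10)
            out = scfa_taxon_correlation(*self._frames(x, y))
            assert out["r"].iloc[0] == pytest.approx(
                _brute_force_pearson(x, y), rel=1e-12, abs=1e-12
            )

    def test_p_value_uses_t_distribution(self):
        rng = np.random.default_rng(4)
        x, y = rng.normal(size=12), rng.normal(size=12)
        out = scfa_taxon_correlation(*self._frames(x, y))
        r = out["r"].iloc[0]
        t = r * math.sqrt(10 / (1 - r * r))
        expected_p = 2 * stats.t.sf(abs(t), df=10)
        assert out["p"].iloc[0] == pytest.approx(expected_p, rel=1e-9)

    def test_zero_variance_reported_missing(self):
        out = scfa_taxon_correlation(*self._frames([1, 1, 1], [1, 2, 3]))
        assert np.isnan(out["r"].iloc[0]) and out["stars"].iloc[0] == ""

    def test_star_thresholds(self):
        # build exact p-values by construction via strong/weak correlations
        rng = np.random.default_rng(8)
        x = np.linspace(0, 1, 30)
        strong = x + rng.normal(0, 1e-3, 30)
        out = scfa_taxon_correlation(*self._frames(x, strong))
        assert out["stars"].iloc[0] == "***"


class TestPairwiseScfa:
    def _inputs(self, shift=0.0, n=4):
        rng = np.random.default_rng(17)
        samples, rows = {}, {}
        for period in ("pre", "late-post"):
            for i in range(n):
                sid = f"{period}_{i}"
                base = rng.normal(100, 5)
                samples[sid] = {"acetic": base + (shift if period == "late-post" else 0)}
                rows[sid] = {"bioreplicate": "BR1", "region": "AC", "period": period}
        return pd.DataFrame(samples).T, pd.DataFrame(rows).T

    def test_copied_groups_not_significant(self):
        scfa = pd.DataFrame(
            {"acetic": [10.0, 12.0, 14.0, 10.0, 12.0, 14.0]},
            index=["a1", "a2", "a3", "b1", "b2", "b3"],
        )
        meta = pd.DataFrame(
            {"bioreplicate": ["BR1"] * 6, "region": ["AC"] * 6,
             "period": ["pre"] * 3 + ["late-post"] * 3},
            index=scfa.index,
        )
        frame, n_sig = pairwise_scfa_tests(scfa, meta)
        assert n_sig == 0
        assert frame["t"].iloc[0] == pytest.approx(0.0, abs=1e-12)
        assert frame["p"].iloc[0] > 0.99

    def test_large_shift_detected(self):
        scfa, meta = self._inputs(shift=50.0, n=6)
        frame, n_sig = pairwise_scfa_tests(scfa, meta)
        assert n_sig == 1

    def test_understaffed_strata_skipped(self):
        scfa, meta = self._inputs(n=1)
        with pytest.warns(UserWarning, match="skipped"):
            frame, n_sig = pairwise_scfa_tests(scfa, meta)
        assert n_sig == 0
        assert frame["p"].isna().all()


class TestAlphaFrame:
    def test_frame_includes_metadata_and_depth(self, worked_tree):
        counts = pd.DataFrame(
            {"S1": [5, 5, 0, 0], "S2": [1, 1, 1, 1]}, index=["A", "B", "C", "D"]
        )
        meta = pd.DataFrame(
            {"bioreplicate": ["BR1", "BR1"], "region": ["AC", "TC"],
             "period": ["pre", "pre"]},
            index=["S1", "S2"],
        )
        frame = alpha_diversity_frame(FeatureTable(counts, meta), tree=worked_tree)
        assert frame.loc["S1", "richness"] == 2
        assert frame.loc["S1", "faith_pd"] == pytest.approx(3.0)
        assert frame.loc["S2", "faith_pd"] == pytest.approx(6.0)
        assert frame.loc["S2", "shannon"] == pytest.approx(math.log(4))
        assert frame.loc["S1", "depth"] == 10
        assert frame.loc["S1", "region"] == "AC"
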