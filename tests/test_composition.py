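"""Indicator values, set partitions, taxonomic targeting and HPI correlation."""

import numpy as np
import pandas as pd
import pytest

import epicarp as e
from epicarp import composition
from epicarp.errors import ParameterError


class TestIndval:
    def test_exclusive_ubiquitous_phylotype_scores_one(self):
        table = pd.DataFrame(
            {"a1": [5, 1], "a2": [3, 1], "b1": [0, 1], "b2": [0, 1]},
            index=["exclusive", "everywhere"],
        )
        res = composition.IndicatorAnalysis(table, ["a", "a", "b", "b"]).fit(
            permutations=99, seed=0
        )
        row = res.table.loc["exclusive"]
        assert row["group"] == "a"
        assert row["A"] == pytest.approx(1.0)
        assert row["B"] == pytest.approx(1.0)
        assert row["stat"] == pytest.approx(1.0)

    def test_uniform_phylotype_scores_sqrt_one_over_k(self):
        k = 3
        table = pd.DataFrame({f"s{i}": [2] for i in range(6)}, index=["flat"])
        groups = ["a", "a", "b", "b", "c", "c"]
        res = composition.IndicatorAnalysis(table, groups).fit(permutations=9, seed=0)
        row = res.table.loc["flat"]
        assert row["A"] == pytest.approx(1 / k)
        assert row["B"] == pytest.approx(1.0)
        assert row["stat"] == pytest.approx(np.sqrt(1 / k))

    def test_exact_p_matches_brute_force_enumeration(self):
        """n=8 samples in two groups of four: compare against a from-scratch
        oracle that loops over all 70 distinct label assignments."""
        from itertools import combinations

        rng = np.random.default_rng(1)
        table = pd.DataFrame(
            rng.integers(0, 12, size=(5, 8)),
            index=[f"t{i}" for i in range(5)],
            columns=[f"s{i}" for i in range(8)],
        )
        table.iloc[0, :4] += 10  # a real indicator for the first group
        groups = ["g1"] * 4 + ["g2"] * 4
        res = composition.IndicatorAnalysis(table, groups).fit(method="exact")

        def oracle_stat(x, labels):
            best = 0.0
            for g in set(labels):
                idx = [i for i, l in enumerate(labels) if l == g]
                other = [i for i in range(len(labels)) if i not in idx]
                mean_in = np.mean([x[i] for i in idx])
                mean_out = np.mean([x[i] for i in other])
                denom = mean_in + mean_out
                a = mean_in / denom if denom > 0 else 0.0
                b = np.mean([x[i] > 0 for i in idx])
                best = max(best, np.sqrt(a * b))
            return best

        x_all = table.to_numpy()
        for t, pid in enumerate(table.index):
            obs = oracle_stat(x_all[t], groups)
            count = 0
            total = 0
            for members in combinations(range(8), 4):
                labels = ["g2"] * 8
                for m in members:
                    labels[m] = "g1"
                total += 1
                count += oracle_stat(x_all[t], labels) >= obs - 1e-12
            assert res.table.loc[pid, "p"] == pytest.approx(count / total, abs=1e-12)

    def test_planted_indicators_are_recovered(self):
        """Fold-change-8 planted indicator taxa with 6 replicates per fruit are
        found at q < 0.05 and attributed to the right fruit."""
        params = e.SimulationParams(
            fruit_types=("cherry", "raspberry", "strawberry"),
            n_stages=2, n_replicates=3,  # 6 samples per fruit after pairing
            n_phylotypes=120, depth_mean=20_000,
            indicator_fold_change=8.0, n_indicator_taxa_per_fruit=6,
            background_spike_prevalence=0.0, seed=21,
        )
        ds = e.simulate_dataset(params)
        table = ds.table.drop(index=e.STANDARD_ID)
        groups = ds.metadata.loc[table.columns, "fruit_type"]
        res = composition.IndicatorAnalysis(table, groups).fit(permutations=299, seed=5)
        sig = res.significant(alpha=0.05)
        recovered = 0
        planted_total = 0
        for fruit, members in ds.truth.true_indicator_sets.items():
            for pid in members:
                planted_total += 1
                if pid in sig.index and sig.loc[pid, "group"] == fruit:
                    recovered += 1
        assert recovered / planted_total >= 0.9

    def test_empty_group_rejected(self, toy_table):
        with pytest.raises(ParameterError):
            composition.IndicatorAnalysis(toy_table, ["a", "a", "a", "a"])


class TestSetSummary:
    def test_venn_cells_partition_observed_phylotypes(self, small_dataset):
        table = small_dataset.table.drop(index=e.STANDARD_ID)
        groups = small_dataset.metadata.loc[table.columns, "fruit_type"]
        sets = composition.set_summary(table, groups)
        assert sum(sets.venn.values()) == sets.n_observed
        # core is inside every group's observed set
        for g in sets.groups:
            observed_in_g = set(table.index[sets.presence[g]])
            assert set(sets.core_ids) <= observed_in_g

    def test_membership_cases(self):
        table = pd.DataFrame(
            {"a1": [1, 1, 0], "b1": [1, 0, 1]},
            index=["shared", "only_a", "only_b"],
        )
        sets = composition.set_summary(table, ["a", "b"])
        assert sets.venn == {"a&b": 1, "a": 1, "b": 1}
        assert sets.unique_counts == {"a": 1, "b": 1}
        assert sets.core_ids == ["shared"]

    def test_invariant_to_abundance_scaling(self, small_dataset):
        table = small_dataset.table.drop(index=e.STANDARD_ID)
        groups = small_dataset.metadata.loc[table.columns, "fruit_type"]
        s1 = composition.set_summary(table, groups)
        s2 = composition.set_summary(table * 17, groups)
        assert s1.venn == s2.venn
        assert s1.core_ids == s2.core_ids

    def test_core_read_share_hand_example(self):
        table = pd.DataFrame(
            {"a1": [90, 10, 0], "b1": [90, 0, 10]},
            index=["core", "ua", "ub"],
        )
        sets = composition.set_summary(table, ["a", "b"])
        assert sets.core_read_share == pytest.approx(180 / 200)


class TestTaxonomyTargeting:
    def test_order_filter_selects_exactly_the_yeasts(self, small_dataset):
        tax = small_dataset.truth.taxonomy
        table = small_dataset.table
        subset = composition.filter_by_taxonomy(table, tax, "order", "Saccharomycetales")
        expected = set(tax.index[tax["order"] == "Saccharomycetales"]) & set(table.index)
        assert set(subset.index) == expected
        assert len(subset) > 0

    def test_genus_union_filter(self, small_dataset):
        tax = small_dataset.truth.taxonomy
        subset = composition.filter_by_taxonomy(
            small_dataset.table, tax, "genus", composition.ATTRACTIVE_GENERA
        )
        assert set(tax.loc[subset.index, "genus"]) <= set(composition.ATTRACTIVE_GENERA)
        assert len(subset) > 0

    def test_unknown_name_warns_and_returns_empty(self, small_dataset):
        with pytest.warns(UserWarning, match="no phylotypes match"):
            subset = composition.filter_by_taxonomy(
                small_dataset.table, small_dataset.truth.taxonomy, "order", "Nosuchales"
            )
        assert len(subset) == 0

    def test_unknown_rank_rejected(self, small_dataset):
        with pytest.raises(ParameterError, match="rank"):
            composition.filter_by_taxonomy(
                small_dataset.table, small_dataset.truth.taxonomy, "clade", "X"
            )


class TestAggregateReads:
    def test_single_row_subset_equals_that_row(self, toy_table):
        agg = composition.aggregate_reads(toy_table.iloc[[0]], ["a", "a", "b", "b"])
        pd.testing.assert_series_equal(
            agg.totals, toy_table.iloc[0].astype(float), check_names=False
        )

    def test_additivity_over_disjoint_subsets(self, toy_table):
        groups = ["a", "a", "b", "b"]
        t_a = composition.aggregate_reads(toy_table.iloc[[0]], groups).totals
        t_b = composition.aggregate_reads(toy_table.iloc[[1, 2]], groups).totals
        t_all = composition.aggregate_reads(toy_table, groups).totals
        pd.testing.assert_series_equal(t_all, t_a + t_b)

    def test_empty_subset_rejected(self, toy_table):
        with pytest.raises(ParameterError):
            composition.aggregate_reads(toy_table.iloc[[]], ["a", "a", "b", "b"])


class TestHpiCorrelation:
    def test_proportional_scores_correlate_perfectly(self):
        totals = pd.Series([1.0, 2.0, 3.0, 4.0], index=list("abcd"))
        hpi = pd.Series([10.0, 20.0, 30.0, 40.0], index=list("abcd"))
        r, p = composition.hpi_correlation(totals, hpi)
        assert r == pytest.approx(1.0)

    def test_antiproportional_scores_give_minus_one(self):
        totals = pd.Series([4.0, 3.0, 2.0, 1.0], index=list("abcd"))
        hpi = pd.Series([1.0, 2.0, 3.0, 4.0], index=list("abcd"))
        r, _ = composition.hpi_correlation(totals, hpi)
        assert r == pytest.approx(-1.0)

    def test_two_fruits_degenerate_with_p_withheld(self):
        totals = pd.Series([1.0, 2.0], index=["a", "b"])
        hpi = pd.Series([0.5, 1.5], index=["a", "b"])
        with pytest.warns(UserWarning, match="degenerate"):
            r, p = composition.hpi_correlation(totals, hpi)
        assert r == 1.0 and p is None

    def test_single_overlap_rejected(self):
        with pytest.raises(ParameterError):
            composition.hpi_correlation(
                pd.Series([1.0], index=["a"]), pd.Series([1.0], index=["a"])
            )
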