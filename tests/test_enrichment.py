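"""Percentage tables, rank-sum testing, FDR control, set intersections."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy.stats import rankdata

from bloomics import (
    bh_adjust,
    biogeo_screen,
    build_percent_table,
    filter_low_fus,
    pairwise_wilcoxon,
    run_enrichment,
    significant_set_intersections,
    taxon_fu_matrix,
    wilcoxon_rank_sum,
)
from bloomics.enrichment import significant_fus
from bloomics.types import Thresholds, ValidationError


def brute_force_ranksum_p(x, y):
    """Independent oracle: enumerate every label assignment and count rank
    sums at least as far from the null mean as the observed one."""
    pooled = np.concatenate([x, y])
    n, n1 = len(pooled), len(x)
    ranks = rankdata(pooled)
    w_obs = ranks[:n1].sum()
    mu = n1 * (n + 1) / 2.0
    dev = abs(w_obs - mu)
    hits = total = 0
    for combo in itertools.combinations(range(n), n1):
        total += 1
        if abs(ranks[list(combo)].sum() - mu) >= dev - 1e-9:
            hits += 1
    return hits / total


def _annotations(rows):
    return pd.DataFrame(
        rows,
        columns=[
            "gene_id",
            "genome_id",
            "cog_ids",
            "cog_categories",
            "ko_ids",
            "pfam_ids",
            "cazy_ids",
        ],
    )


def _genomes(gene_counts):
    return pd.DataFrame(
        {"genome_id": list(gene_counts), "gene_count": list(gene_counts.values())}
    )


class TestPercentTable:
    def test_normalisation_by_gene_count(self):
        rows = [
            (f"g{i}", "G1", ["COGX"], "", [], [], []) for i in range(8)
        ]
        table = build_percent_table(_annotations(rows), _genomes({"G1": 4000}), "COG")
        assert table.loc["G1", "COGX"] == pytest.approx(0.2)

    def test_multiletter_category_counts_both(self):
        rows = [("g1", "G1", [], "KT", [], [], [])]
        table = build_percent_table(
            _annotations(rows), _genomes({"G1": 100}), "COG_category"
        )
        assert table.loc["G1", "K"] == pytest.approx(1.0)
        assert table.loc["G1", "T"] == pytest.approx(1.0)

    def test_absent_fu_is_zero(self):
        rows = [("g1", "G1", ["COGX"], "", [], [], [])]
        table = build_percent_table(
            _annotations(rows), _genomes({"G1": 100, "G2": 100}), "COG"
        )
        assert table.loc["G2", "COGX"] == 0.0

    def test_gene_row_order_invariance(self):
        rows = [
            ("g1", "G1", ["A", "B"], "", [], [], []),
            ("g2", "G2", ["B"], "", [], [], []),
            ("g3", "G1", ["A"], "", [], [], []),
        ]
        g = _genomes({"G1": 50, "G2": 60})
        a = build_percent_table(_annotations(rows), g, "COG")
        b = build_percent_table(_annotations(rows[::-1]), g, "COG")
        pd.testing.assert_frame_equal(a, b)

    def test_annotation_without_metadata_rejected(self):
        rows = [("g1", "GX", ["A"], "", [], [], [])]
        with pytest.raises(ValidationError):
            build_percent_table(_annotations(rows), _genomes({"G1": 10}), "COG")

    def test_cazy_category_from_prefix(self):
        rows = [("g1", "G1", [], "", [], [], ["GH13", "GT2"])]
        table = build_percent_table(
            _annotations(rows), _genomes({"G1": 100}), "CAZY_category"
        )
        assert set(table.columns) == {"GH", "GT"}

    @pytest.mark.parametrize(
        "sums,kept",
        [([1.0, 2.0, 1.5], False), ([2.5, 2.5, 0.0], True), ([20, 20, 10], True)],
    )
    def test_low_sum_filter(self, sums, kept):
        table = pd.DataFrame({"FU1": sums}, index=["G1", "G2", "G3"])
        filtered = filter_low_fus(table)
        assert ("FU1" in filtered.columns) is kept


class TestWilcoxon:
    def test_complete_separation_with_tie(self):
        # enumeration over the C(6,3)=20 assignments gives one-sided 1/20
        assert wilcoxon_rank_sum([2, 3, 4], [0, 0, 1]) == pytest.approx(0.1)

    def test_symmetry(self):
        x, y = [1.0, 5.0, 2.0], [4.0, 4.0, 0.0]
        assert wilcoxon_rank_sum(x, y) == pytest.approx(wilcoxon_rank_sum(y, x))

    def test_identical_singletons(self):
        assert wilcoxon_rank_sum([5.0], [5.0]) == 1.0

    def test_empty_group_rejected(self):
        with pytest.raises(ValidationError):
            wilcoxon_rank_sum([], [1.0])

    @settings(max_examples=80, deadline=None)
    @given(
        x=st.lists(st.integers(0, 30), min_size=1, max_size=6),
        y=st.lists(st.integers(0, 30), min_size=1, max_size=6),
    )
    def test_matches_enumeration_oracle_with_ties(self, x, y):
        implementation = wilcoxon_rank_sum(x, y)
        if np.ptp(np.array(x + y)) == 0:
            assert implementation == 1.0
        else:
            assert implementation == pytest.approx(brute_force_ranksum_p(x, y))

    def test_large_sample_tie_corrected_normal(self):
        rng = np.random.default_rng(7)
        x = rng.integers(0, 5, 40).astype(float)
        y = rng.integers(1, 6, 40).astype(float)
        from scipy.stats import mannwhitneyu

        expected = mannwhitneyu(
            x, y, alternative="two-sided", method="asymptotic", use_continuity=True
        ).pvalue
        assert wilcoxon_rank_sum(x, y) == pytest.approx(float(expected))


class TestBH:
    def test_worked_example(self):
        assert bh_adjust([0.01, 0.02, 0.04]) == pytest.approx([0.03, 0.03, 0.04])

    def test_single_value_identity(self):
        assert bh_adjust([0.5]) == pytest.approx([0.5])

    def test_all_equal_stay_equal(self):
        out = bh_adjust([0.2, 0.2, 0.2, 0.2])
        assert np.allclose(out, 0.2)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValidationError):
            bh_adjust([0.5, 1.2])

    @settings(max_examples=60, deadline=None)
    @given(st.lists(st.floats(0, 1), min_size=1, max_size=30))
    def test_monotone_and_idempotent_compatible(self, p):
        adjusted = bh_adjust(p)
        order = np.argsort(p, kind="mergesort")
        assert np.all(np.diff(adjusted[order]) >= -1e-12)
        again = bh_adjust(adjusted)
        assert np.all(again >= adjusted - 1e-12)


class TestRunEnrichment:
    def _table(self, data, system="COG"):
        table = pd.DataFrame(data)
        table.attrs["system"] = system
        return table

    def test_identical_groups_no_signal(self):
        values = [1.0, 2.0, 3.0]
        table = self._table(
            {"FU1": values * 2, "FU2": values * 2},
        )
        table.index = [f"G{i}" for i in range(6)]
        groups = {f"G{i}": ("a" if i < 3 else "b") for i in range(6)}
        # a and b hold identical value multisets
        out = run_enrichment(table, groups, "a", "b")
        assert (out["p_raw"] == 1.0).all()
        assert significant_fus(out) == set()

    def test_small_group_skipped(self):
        table = self._table({"FU1": [1.0, 2.0, 3.0]})
        table.index = ["G0", "G1", "G2"]
        out = run_enrichment(table, {"G0": "a", "G1": "b", "G2": "b"}, "a", "b")
        assert out.empty

    def test_medium_growers_excluded(self):
        table = self._table({"FU1": [5.0, 6.0, 1.0, 2.0, 9.0, 9.5]})
        table.index = [f"G{i}" for i in range(6)]
        groups = {
            "G0": "fast",
            "G1": "fast",
            "G2": "slow",
            "G3": "slow",
            "G4": "medium",
            "G5": "medium",
        }
        out = run_enrichment(table, groups, "fast", "slow")
        assert out.loc[0, "mean_pct_g1"] == pytest.approx(5.5)
        assert out.loc[0, "mean_pct_g2"] == pytest.approx(1.5)

    def test_sort_stable_by_abs_delta(self):
        table = self._table(
            {"A": [1, 1, 5, 5], "B": [9, 9, 1, 1], "C": [2, 2, 2, 2]},
        )
        table.index = list("wxyz")
        groups = dict(zip("wxyz", ["g1", "g1", "g2", "g2"]))
        out = run_enrichment(table, groups, "g1", "g2")
        assert out["fu_id"].tolist() == ["B", "A", "C"]


class TestPairwise:
    def test_three_groups_three_pairs(self):
        rng = np.random.default_rng(0)
        table = pd.DataFrame({"FU1": rng.uniform(size=9)}, index=[f"G{i}" for i in range(9)])
        table.attrs["system"] = "COG"
        groups = {f"G{i}": ["fast", "medium", "slow"][i // 3] for i in range(9)}
        out = pairwise_wilcoxon(table, groups)
        assert sorted(out["comparison"]) == ["fast_vs_medium", "fast_vs_slow", "medium_vs_slow"]

    def test_small_group_pairs_skipped(self):
        table = pd.DataFrame({"FU1": range(5)}, index=[f"G{i}" for i in range(5)], dtype=float)
        table.attrs["system"] = "COG"
        groups = {"G0": "a", "G1": "a", "G2": "b", "G3": "b", "G4": "c"}
        out = pairwise_wilcoxon(table, groups)
        assert set(out["comparison"]) == {"a_vs_b"}


class TestIntersections:
    def test_exclusive_membership(self):
        kept, totals = significant_set_intersections(
            {"A": {"1", "2", "3", "4"}, "B": {"2", "3", "4", "5"}}
        )
        assert kept == {("A", "B"): {"2", "3", "4"}}
        assert totals == {"A": 4, "B": 4}

    def test_disjoint_sets_kept_separately(self):
        a = {str(i) for i in range(5)}
        b = {str(i) for i in range(10, 15)}
        kept, _ = significant_set_intersections({"A": a, "B": b})
        assert kept == {("A",): a, ("B",): b}

    def test_identical_sets_single_combination(self):
        s = {"x", "y", "z"}
        kept, _ = significant_set_intersections({"A": set(s), "B": set(s)})
        assert kept == {("A", "B"): s}

    def test_brute_force_over_membership_patterns(self):
        rng = np.random.default_rng(3)
        names = ["CL", "PL", "VL"]
        universe = [f"F{i}" for i in range(40)]
        sets = {
            name: {fu for fu in universe if rng.uniform() < 0.5} for name in names
        }
        kept, _ = significant_set_intersections(
            sets, Thresholds(intersection_min_size=1)
        )
        for fu in universe:
            pattern = tuple(sorted(n for n in names if fu in sets[n]))
            if pattern:
                assert fu in kept[pattern]


class TestBiogeoScreen:
    def _setup(self, rng):
        genomes = [f"G{i}" for i in range(18)]
        classes = pd.DataFrame(
            {
                "genome_id": genomes,
                "treatment": "VL",
                "growth_class": ["fast"] * 6 + ["medium"] * 6 + ["slow"] * 6,
            }
        )
        table = pd.DataFrame(index=genomes)
        table["K02040"] = np.where(
            np.arange(18) < 6, rng.uniform(2, 3, 18), rng.uniform(0, 0.2, 18)
        )
        table["K02274"] = rng.uniform(0.4, 0.6, 18)
        return table, classes

    def test_planted_fast_marker_labelled(self):
        table, classes = self._setup(np.random.default_rng(1))
        out = biogeo_screen(table, classes, {"pstS": ("K02040",), "coxA": ("K02274",)})
        row = out[(out["gene"] == "pstS") & (out["pair"] == "fast_vs_slow")]
        assert row["label"].iloc[0] == "fast_enriched"

    def test_flat_marker_neither(self):
        table, classes = self._setup(np.random.default_rng(1))
        out = biogeo_screen(table, classes, {"coxA": ("K02274",)})
        row = out[(out["gene"] == "coxA") & (out["pair"] == "fast_vs_slow")]
        assert row["label"].iloc[0] == "neither"

    def test_absent_marker_not_testable(self):
        table, classes = self._setup(np.random.default_rng(1))
        out = biogeo_screen(table, classes, {"pufM": ("K08929",)})
        assert out["label"].tolist() == ["not_testable"]


class TestTaxonFuMatrix:
    def test_identical_genomes_adjacent(self):
        rng = np.random.default_rng(0)
        table = pd.DataFrame(
            rng.uniform(size=(4, 3)), index=list("abcd"), columns=["F1", "F2", "F3"]
        )
        table.loc["d"] = table.loc["a"]
        _, row_order, _ = taxon_fu_matrix(table, ["F1", "F2", "F3"])
        ia, id_ = row_order.index("a"), row_order.index("d")
        assert abs(ia - id_) == 1

    def test_block_structure_separated(self):
        low = np.full((3, 4), 0.1)
        high = np.full((3, 4), 5.0)
        data = np.vstack([low, high])
        table = pd.DataFrame(
            data, index=[f"G{i}" for i in range(6)], columns=["A", "B", "C", "D"]
        )
        _, row_order, _ = taxon_fu_matrix(table, ["A", "B", "C", "D"])
        first_block = set(row_order[:3])
        assert first_block in ({"G0", "G1", "G2"}, {"G3", "G4", "G5"})

    def test_single_fu_ordered_by_value(self):
        table = pd.DataFrame({"A": [3.0, 1.0, 2.0]}, index=["x", "y", "z"])
        matrix, row_order, col_order = taxon_fu_matrix(table, ["A"])
        assert row_order == ["y", "z", "x"]
        assert col_order == ["A"]

    def test_unknown_fu_rejected(self):
        table = pd.DataFrame({"A": [1.0, 2.0]}, index=["x", "y"])
        with pytest.raises(ValidationError, match="NOPE"):
            taxon_fu_matrix(table, ["NOPE"])
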