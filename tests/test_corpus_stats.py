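"""Count tables and the pooled two-proportion Z statistic."""

import random

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import mirmotif as mm
from mirmotif.corpus_stats import preference_order, round_half_up, stars
from mirmotif.motif_core import BULGE3, BULGE5, INTERNAL
from mirmotif.reference import (
    INTERNAL_1X1_LABELS,
    internal_1x1_counts,
    reference_table,
)
from printed_tables import PRINTED_GROUPS_1X1, PRINTED_Z_1X1, Z_LABELS

counts_ns = st.tuples(
    st.integers(min_value=1, max_value=500),
    st.integers(min_value=1, max_value=500),
).map(lambda cn: (min(cn), max(cn)))


class TestZScore:
    def test_published_within_type_value(self):
        """G/G vs A/C among the 3860 internal loops prints as 1.26."""
        assert round_half_up(mm.zscore(325, 3860, 295, 3860).z) == 1.26

    def test_published_cross_type_value(self):
        """A bulges: 215 of 924 (3') vs 212 of 1089 (5') prints as 2.08."""
        r = mm.zscore(215, 924, 212, 1089)
        assert round_half_up(r.z) == 2.08
        assert r.significant

    def test_identical_proportions_give_zero(self):
        r = mm.zscore(37, 924, 37, 924)
        assert r.z == 0.0 and not r.significant

    def test_fields_consistent(self):
        r = mm.zscore(30, 100, 10, 50)
        assert r.p1 == 0.3 and r.p2 == 0.2
        assert r.phi == pytest.approx((30 + 10) / 150)
        assert np.sign(r.z) == np.sign(r.p1 - r.p2)

    def test_degenerate_pooled_proportions(self):
        for c1, c2 in ((0, 0), (10, 20)):
            r = mm.zscore(c1, 10, c2, 20)
            assert r.degenerate and r.z == 0.0 and not r.significant

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            mm.zscore(5, 0, 1, 10)
        with pytest.raises(ValueError):
            mm.zscore(11, 10, 1, 10)

    @settings(max_examples=100, deadline=None, derandomize=True)
    @given(counts_ns, counts_ns)
    def test_antisymmetry(self, a, b):
        (c1, n1), (c2, n2) = a, b
        z_ab = mm.zscore(c1, n1, c2, n2).z
        z_ba = mm.zscore(c2, n2, c1, n1).z
        assert z_ab == pytest.approx(-z_ba)


class TestZMatrix:
    def test_reproduces_printed_1x1_matrix(self):
        m = mm.zscore_matrix(list(Z_LABELS), internal_1x1_counts(), 3860)
        for row in Z_LABELS:
            for col_idx, col in enumerate(Z_LABELS):
                assert round_half_up(m.loc[row, col]) == PRINTED_Z_1X1[row][col_idx], (
                    row, col,
                )

    def test_all_equal_counts_give_zero_matrix(self):
        m = mm.zscore_matrix(["a", "b", "c"], [7, 7, 7], 100)
        assert (m.values == 0).all()

    def test_antisymmetric_with_zero_diagonal(self):
        rng = random.Random(3)
        counts = [rng.randint(0, 200) for _ in range(6)]
        m = mm.zscore_matrix([f"k{i}" for i in range(6)], counts, 500)
        assert np.allclose(m.values + m.values.T, 0.0)
        assert np.allclose(np.diag(m.values), 0.0)


class TestSignificanceGroups:
    def test_reproduces_published_1x1_groups(self):
        groups = mm.significance_groups(
            list(Z_LABELS), internal_1x1_counts(), 3860
        )
        assert groups == PRINTED_GROUPS_1X1

    def test_single_label(self):
        assert mm.significance_groups(["x"], [5], 100) == [["x"]]

    @pytest.mark.parametrize("n", [50, 500, 5000])
    def test_equal_counts_form_one_group(self, n):
        groups = mm.significance_groups(["a", "b", "c"], [9, 9, 9], n)
        assert groups == [["a", "b", "c"]]


class TestTables:
    def test_reference_fraction(self):
        tab = reference_table()
        assert tab.get(BULGE5, "U") / tab.total(BULGE5) == pytest.approx(
            257 / 1089
        )
        assert round(257 / 1089, 3) == 0.236

    def test_empty_records_make_empty_table(self):
        tab = mm.tabulate(mm.extract_corpus([]), "motif")
        assert tab.counts == {} and tab.type_totals == {}
        unique, fraction = mm.count_unique(tab)
        assert unique == 0 and np.isnan(fraction)

    def test_tabulate_orders_by_count_then_key(self, small_corpus):
        records = mm.extract_corpus(small_corpus.structures)
        tab = mm.tabulate(records, "motif")
        for mtype in tab.motif_types:
            items = tab.items_sorted(mtype)
            assert items == sorted(items, key=lambda kv: (-kv[1], kv[0]))
            assert sum(c for _, c in items) == tab.total(mtype)

    def test_tsv_roundtrip(self, tmp_path, small_corpus):
        tab = mm.tabulate(mm.extract_corpus(small_corpus.structures), "motif")
        path = tmp_path / "counts.tsv"
        tab.to_tsv(path)
        again = mm.MotifTable.from_tsv(path, "motif")
        assert again.counts == tab.counts

    def test_count_unique(self):
        tab = mm.MotifTable.from_counts(
            {(INTERNAL, "a"): 1, (INTERNAL, "b"): 2, (INTERNAL, "c"): 1}
        )
        assert mm.count_unique(tab) == (2, 0.5)
        all_single = mm.MotifTable.from_counts(
            {(INTERNAL, k): 1 for k in "abcd"}
        )
        assert mm.count_unique(all_single) == (4, 1.0)


class TestSizeSummary:
    def test_published_aggregate_shares(self):
        sizes = mm.summarize_by_size(reference_table())
        share = {
            (r.motif_type, r.size_class): r.fraction for r in sizes.itertuples()
        }
        assert round(100 * share[(BULGE5, "1")], 1) == 69.3
        assert round(100 * share[(BULGE3, "1")], 1) == 71.4
        assert round(100 * share[(INTERNAL, "1×1")], 1) == 55.4

    def test_mirror_pooling_and_others(self):
        tab = mm.MotifTable.from_counts(
            {
                (INTERNAL, "A/GG"): 3,
                (INTERNAL, "GG/A"): 2,
                (INTERNAL, "GUUG/AA"): 15,
                (BULGE5, "UCAACA"): 4,
            }
        )
        sizes = mm.summarize_by_size(tab)
        share = {
            (r.motif_type, r.size_class): r.count for r in sizes.itertuples()
        }
        assert share[(INTERNAL, "1×2/2×1")] == 5
        assert share[(INTERNAL, "others")] == 15
        assert share[(BULGE5, "others")] == 4

    def test_fractions_sum_to_one_per_type(self, small_corpus):
        records = mm.extract_corpus(small_corpus.structures)
        tab = mm.tabulate(records, "unpaired")
        sizes = mm.summarize_by_size(tab)
        for mtype, sub in sizes.groupby("motif_type"):
            assert sub["fraction"].sum() == pytest.approx(1.0)


class TestClosingPairPreferences:
    def test_single_motif_corpus(self):
        ss = mm.parse_dotbracket("x", "UCGAAAACAA", "(.(....).)")
        name = mm.name_motif(
            [e for e in mm.decompose(ss) if e.kind == INTERNAL][0], ss
        )
        assert name.motif_key == "(UA)C/A(GC)"
        records = mm.extract_corpus([ss] * 5)
        counts, orders = mm.closing_pair_preferences(records, ["C/A"])
        by = {
            (r.side, r.pair_class): r.count for r in counts.itertuples()
        }
        assert by[("5p", "AU")] == 5 and by[("3p", "GC")] == 5
        assert orders[("C/A", "5p")] == "AU"

    def test_pooling_orientation_invariance(self):
        # (UA)C/A(GC) and its relabelling (AU)C/A(CG) pool identically
        a = mm.parse_dotbracket("a", "UCGAAAACAA", "(.(....).)")
        b = mm.parse_dotbracket("b", "ACCAAAAGAU", "(.(....).)")
        names = []
        for ss in (a, b):
            (el,) = [e for e in mm.decompose(ss) if e.kind == INTERNAL]
            names.append(mm.name_motif(el, ss).motif_key)
        assert names == ["(UA)C/A(GC)", "(AU)C/A(CG)"]
        for ss in (a, b):
            counts, _ = mm.closing_pair_preferences(mm.extract_corpus([ss]))
            by = {(r.side, r.pair_class): r.count for r in counts.itertuples()}
            assert by == {("5p", "AU"): 1, ("3p", "GC"): 1}

    def test_empty_selection(self):
        counts, orders = mm.closing_pair_preferences(
            mm.extract_corpus([]), ["C/A"]
        )
        assert len(counts) == 0 and orders == {}

    def test_order_annotation_threshold(self):
        assert preference_order({"AU": 300, "GC": 100, "GU": 90}, 500) == (
            "AU>GC≈GU"
        )


class TestCompareCorpora:
    def test_identical_tables_no_stars(self, small_corpus):
        tab = mm.tabulate(mm.extract_corpus(small_corpus.structures), "unpaired")
        result = mm.compare_corpora(tab, tab)
        assert (result["z"] == 0).all()
        assert (result["stars"] == "").all()

    def test_large_difference_is_triple_starred(self):
        a = mm.MotifTable.from_counts(
            {(INTERNAL, "G/G"): 325}, type_totals={INTERNAL: 3860}
        )
        b = mm.MotifTable.from_counts(
            {(INTERNAL, "other"): 3860}, type_totals={INTERNAL: 3860}
        )
        row = mm.compare_corpora(a, b, [(INTERNAL, "G/G")]).iloc[0]
        assert abs(row.z) > 3.29 and row.stars == "***"

    def test_star_tiers_match_normal_quantiles(self):
        """Star boundaries sit at the two-sided normal quantiles
        1.95996 / 2.57583 / 3.29053."""
        from scipy.stats import norm

        for z, expected in [
            (1.9, ""), (1.95996, ""), (1.96, "*"),
            (2.5758, "*"), (2.576, "**"),
            (3.29, "**"), (3.2906, "***"), (5.0, "***"),
        ]:
            assert stars(2 * norm.sf(z)) == expected, z

    def test_absent_key_counts_zero(self):
        a = mm.MotifTable.from_counts(
            {(BULGE5, "U"): 10}, type_totals={BULGE5: 100}
        )
        b = mm.MotifTable.from_counts(
            {(BULGE5, "A"): 10}, type_totals={BULGE5: 100}
        )
        result = mm.compare_corpora(a, b)
        by_key = {r.key: r for r in result.itertuples()}
        assert by_key["U"].count_b == 0 and by_key["A"].count_a == 0
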