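"""Mature mapping, site context classification and enzyme attribution."""

import numpy as np
import pandas as pd
import pytest

import mirmotif as mm
from mirmotif.processing_sites import MappingError, assign_enzyme, call_arm


class TestMapMature:
    def test_substring_arithmetic(self):
        assert mm.map_mature("GGGAAAACCCUUU", "AAAACCC", min_length=5) == (4, 10)

    def test_span_length_matches_mature(self, small_corpus):
        for gt in small_corpus.ground_truths:
            ss = next(
                s for s in small_corpus.structures if s.id == gt.precursor_id
            )
            start, end = mm.map_mature(ss.sequence, gt.mature_seq)
            assert (start, end) == (gt.mature_start, gt.mature_end)
            assert end - start + 1 == len(gt.mature_seq)

    def test_absent_mature_is_an_error(self):
        with pytest.raises(MappingError):
            mm.map_mature("GGGAAAACCC", "AAAAAAAAAAAA")

    def test_too_short_mature_rejected(self):
        with pytest.raises(MappingError):
            mm.map_mature("GGGAAAACCC", "AAAAC")

    def test_multiple_occurrences_warn_and_take_first(self):
        prec = "AAGGGGGGGGGGUUAAGGGGGGGGGGUU"
        with pytest.warns(UserWarning, match="first occurrence"):
            assert mm.map_mature(prec, "GGGGGGGGGG") == (3, 12)

    def test_t_to_u_normalization(self):
        assert mm.map_mature("GGGAAAACCCUUU", "AAAACCCTT", min_length=5) == (4, 12)


class TestClassifySite:
    def test_bulged_nucleotide_gets_loop_motif(self):
        ss = mm.parse_dotbracket("f", "AUGAAAACU", "(.(....))")
        ctx = mm.classify_site(ss, 2)
        assert ctx.context == "bulge5"
        assert ctx.site_motif == "(AU)U/-(GC)"
        assert ctx.unpaired_key == "U"

    def test_paired_site_includes_neighbor_across_loop(self):
        ss = mm.parse_dotbracket("f", "AUGAAAACU", "(.(....))")
        ctx = mm.classify_site(ss, 1)
        assert ctx.context == "paired"
        # outer pair (1,9): no pair outward, inner neighbour across the
        # bulge is (3,8); the bulge it closes is annotated
        assert ctx.site_motif == "(AU)(GC)"
        assert ctx.loop_annotation == "(AU)U/-(GC)"

    def test_stacked_site_includes_both_neighbors(self):
        ss = mm.parse_dotbracket("p", "GGGAAAACCC", "(((....)))")
        ctx = mm.classify_site(ss, 2)
        assert ctx.context == "paired"
        assert ctx.site_motif == "(GC)(GC)(GC)"
        assert ctx.loop_annotation is None

    def test_terminal_and_hairpin_positions(self):
        ss = mm.parse_dotbracket("t", "AGGGAAAACCCA", ".(((....))).")
        assert mm.classify_site(ss, 1).context == "terminal"
        assert mm.classify_site(ss, 12).context == "terminal"
        assert mm.classify_site(ss, 6).context == "hairpin"

    def test_matches_per_position_oracle(self, random_structures):
        """Per-position contexts agree with a brute-force scan built on
        the decomposition oracle."""
        from conftest import oracle_elements

        for ss in random_structures[:80]:
            oracle = {}
            for kind, _pairs, positions in oracle_elements(ss):
                label = "terminal" if kind == "exterior" else kind
                for pos in positions:
                    oracle[pos] = label
            elements = mm.decompose(ss)
            for pos in range(1, ss.n + 1):
                expected = (
                    "paired" if ss.is_paired(pos) else oracle[pos]
                )
                assert mm.classify_site(ss, pos, elements).context == expected


class TestEnzymes:
    @pytest.mark.parametrize(
        "site, arm, enzyme",
        [
            ("start", "5p", "drosha"),
            ("end", "5p", "dicer"),
            ("start", "3p", "dicer"),
            ("end", "3p", "drosha"),
        ],
    )
    def test_attribution_rule(self, site, arm, enzyme):
        assert assign_enzyme(site, arm) == enzyme

    def test_ambiguous_arm_unassigned(self):
        assert assign_enzyme("start", "ambiguous") == "NA"

    def test_loop_spanning_mature_is_ambiguous(self):
        ss = mm.parse_dotbracket(
            "x", "GGGGGGGGAAAACCCCCCCC", "((((((((....))))))))"
        )
        assert call_arm(ss, 5, 16) == "ambiguous"
        assert call_arm(ss, 1, 8) == "5p"
        assert call_arm(ss, 13, 20) == "3p"

    def test_mirroring_swaps_arms_and_enzymes(self, small_corpus):
        """Reversing a precursor flips 5p<->3p, so start/end enzymes swap."""
        swapped = {"5p": "3p", "3p": "5p"}
        checked = 0
        for ss, gt in zip(
            small_corpus.structures, small_corpus.ground_truths
        ):
            if gt.arm not in swapped:
                continue
            n = ss.n
            rev_partner = tuple(
                (n + 1 - ss.partner[n - k]) if ss.partner[n - k] else 0
                for k in range(1, n + 1)
            )
            mirrored = mm.SecondaryStructure(
                ss.id, ss.sequence[::-1], rev_partner
            )
            m_start = n + 1 - gt.mature_end
            m_end = n + 1 - gt.mature_start
            assert call_arm(mirrored, m_start, m_end) == swapped[gt.arm]
            for site in ("start", "end"):
                opposite = "end" if site == "start" else "start"
                assert assign_enzyme(site, gt.arm) == assign_enzyme(
                    opposite, swapped[gt.arm]
                )
            checked += 1
        assert checked > 10


class TestSiteAnalysis:
    def test_contexts_match_planted_ground_truth(self, small_corpus):
        records = mm.analyze_sites(
            small_corpus.structures, small_corpus.mature_records()
        )
        truth = {}
        for gt in small_corpus.ground_truths:
            truth[(gt.precursor_id, "start")] = (gt.start_context, gt.arm)
            truth[(gt.precursor_id, "end")] = (gt.end_context, gt.arm)
        assert len(records) == 2 * len(small_corpus.ground_truths)
        for row in records.itertuples():
            ctx, arm = truth[(row.precursor_id, row.site)]
            assert row.context == ctx
            assert row.arm == arm
            assert row.enzyme == assign_enzyme(row.site, arm)

    def test_all_paired_sites_summary(self):
        ss = mm.parse_dotbracket(
            "p",
            "GGGGGGGGGGGGGGGAAAACCCCCCCCCCCCCCC",
            "(((((((((((((((....)))))))))))))))",
        )
        records = mm.analyze_sites([ss], [("m", "p", "G" * 12)])
        summary = mm.site_summary(records)
        assert summary["start_paired_fraction"] == 1.0
        assert summary["end_paired_fraction"] == 1.0
        assert summary["z"].z == 0.0

    def test_summary_recovers_planted_rates(self):
        """Paired fractions from synthetic Bernoulli site records land
        within 3 binomial standard errors of the planted 60 %/40 % rates,
        and the z sign follows p_start - p_end."""
        rng = np.random.default_rng(11)
        n = 2000
        rows = []
        for site, rate in (("start", 0.6), ("end", 0.4)):
            paired = rng.random(n) < rate
            rows += [
                {"site": site, "context": "paired" if p else "internal"}
                for p in paired
            ]
        summary = mm.site_summary(pd.DataFrame(rows))
        for site, rate in (("start", 0.6), ("end", 0.4)):
            se = np.sqrt(rate * (1 - rate) / n)
            assert abs(summary[f"{site}_paired_fraction"] - rate) < 3 * se
        assert summary["z"].z > 0

    def test_uniqueness_round_trip(self, small_corpus):
        records = mm.analyze_sites(
            small_corpus.structures, small_corpus.mature_records()
        )
        corpus_records = mm.extract_corpus(small_corpus.structures)
        table = mm.tabulate(corpus_records, "motif")
        summary, annotated = mm.site_uniqueness(records, table)
        # independent recount: a loop-context site is unique iff its motif
        # occurs once in the corpus
        expected = 0
        for row in records.itertuples():
            if row.context in ("paired", "terminal"):
                continue
            if table.get(row.context, row.site_motif) == 1:
                expected += 1
        assert summary["unique_sites"] == expected
        assert summary["unique_sites"] == int(annotated["is_unique"].sum())
        by_enzyme = summary["by_enzyme"]
        assert sum(by_enzyme.values()) <= summary["unique_sites"]

    def test_singleton_site_and_reference_overlap(self):
        records = pd.DataFrame(
            [
                {
                    "precursor_id": "p", "mature_id": "m", "site": "start",
                    "position": 2, "arm": "5p", "enzyme": "drosha",
                    "context": "bulge5", "site_motif": "(AU)U/-(GC)",
                    "unpaired_key": "U", "loop_annotation": "NA",
                },
                {
                    "precursor_id": "p", "mature_id": "m", "site": "end",
                    "position": 9, "arm": "5p", "enzyme": "dicer",
                    "context": "paired", "site_motif": "(AU)(GC)",
                    "unpaired_key": "NA", "loop_annotation": "NA",
                },
            ]
        )
        corpus = mm.MotifTable.from_counts(
            {("bulge5", "(AU)U/-(GC)"): 1, ("hairpin", "(GC)AAAA"): 2},
            key_level="motif",
        )
        reference = mm.MotifTable.from_counts(
            {("bulge5", "(AU)U/-(GC)"): 3}, key_level="motif"
        )
        summary, annotated = mm.site_uniqueness(records, corpus, reference)
        assert summary["unique_sites"] == 1
        assert summary["by_enzyme"] == {"dicer": 0, "drosha": 1}
        assert summary["reference_overlap"] == 1
        assert list(annotated["is_unique"]) == [True, False]
        # without a reference, overlap is omitted
        no_ref, _ = mm.site_uniqueness(records, corpus)
        assert "reference_overlap" not in no_ref
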