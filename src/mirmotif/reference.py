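"""Reference motif frequencies of the human miRNA hairpin precursor corpus.

These are the published counts of the twenty most frequent 5' bulges, 3'
bulges and internal loops (by unpaired key) from a survey of miRBase human
stem-loops folded by free-energy minimisation, together with the per-type
motif totals of that corpus.  They serve two roles in this package: as the
default frequency tables of the synthetic stem-loop generator, so that
generated corpora have realistic loop composition, and as fixture inputs
for the frequency statistics (the ten 1×1 internal-loop counts drive the
pairwise Z-score matrix).

The corpus totals are the Z-test denominators: 1089 5' bulges, 924 3'
bulges (a companion text figure says 922, but 924 is the total consistent
with the published fractions), 3860 internal loops, 1546 hairpin loops and
17 multibranch loops.
"""

from __future__ import annotations

from .corpus_stats import MotifTable
from .motif_core import BULGE3, BULGE5, HAIRPIN, INTERNAL, MULTIBRANCH

#: twenty most frequent 5' bulges (unpaired key, count)
BULGE5_COUNTS: tuple[tuple[str, int], ...] = (
    ("U", 257), ("A", 212), ("C", 163), ("G", 123),
    ("CU", 20), ("UU", 18), ("UC", 16), ("UA", 13), ("GU", 12),
    ("AA", 11), ("CA", 11), ("CC", 11), ("GA", 11), ("AU", 10),
    ("AC", 9), ("AG", 7), ("UG", 7), ("GG", 4), ("UCAACA", 4), ("ACC", 3),
)

#: twenty most frequent 3' bulges (unpaired key, count)
BULGE3_COUNTS: tuple[tuple[str, int], ...] = (
    ("A", 215), ("U", 195), ("C", 165), ("G", 85),
    ("GA", 15), ("UU", 12), ("AU", 11), ("UC", 9), ("AA", 8), ("CC", 8),
    ("CA", 7), ("GU", 7), ("UA", 7), ("CU", 6), ("AC", 5), ("GC", 5),
    ("GG", 5), ("UG", 5), ("AAA", 4), ("CUU", 4),
)

#: twenty most frequent internal loops (unpaired key, count)
INTERNAL_COUNTS: tuple[tuple[str, int], ...] = (
    ("G/G", 325), ("A/C", 295), ("C/A", 290), ("U/U", 288),
    ("U/C", 220), ("C/U", 199), ("A/A", 147), ("C/C", 130),
    ("G/A", 130), ("A/G", 113), ("UU/UU", 26), ("CA/CA", 21),
    ("GUUG/AA", 15), ("A/GG", 14), ("UU/U", 14), ("U/CU", 13),
    ("GA/A", 12), ("AG/G", 11), ("UU/CU", 11), ("A/GC", 10),
)

#: per-type motif totals of the reference corpus
TYPE_TOTALS: dict[str, int] = {
    BULGE5: 1089,
    BULGE3: 924,
    INTERNAL: 3860,
    HAIRPIN: 1546,
    MULTIBRANCH: 17,
}

#: the ten 1×1 internal loops in descending reference frequency
INTERNAL_1X1_LABELS: tuple[str, ...] = (
    "G/G", "A/C", "C/A", "U/U", "U/C", "C/U", "A/A", "C/C", "G/A", "A/G"
)


def internal_1x1_counts() -> list[int]:
    lookup = dict(INTERNAL_COUNTS)
    return [lookup[k] for k in INTERNAL_1X1_LABELS]


def reference_table() -> MotifTable:
    """The top-20 reference counts as an unpaired-level MotifTable.

    Type totals are the full corpus totals, not the top-20 sums, so
    fractions and Z denominators match the published corpus.
    """
    counts: dict[tuple[str, str], int] = {}
    for mtype, rows in (
        (BULGE5, BULGE5_COUNTS),
        (BULGE3, BULGE3_COUNTS),
        (INTERNAL, INTERNAL_COUNTS),
    ):
        for key, c in rows:
            counts[(mtype, key)] = c
    return MotifTable.from_counts(
        counts,
        key_level="unpaired",
        type_totals={k: TYPE_TOTALS[k] for k in (BULGE5, BULGE3, INTERNAL)},
    )


def default_motif_weights() -> dict[str, dict[str, float]]:
    """Generator default: loop keys weighted by the reference counts."""
    return {
        BULGE5: {k: float(c) for k, c in BULGE5_COUNTS},
        BULGE3: {k: float(c) for k, c in BULGE3_COUNTS},
        INTERNAL: {k: float(c) for k, c in INTERNAL_COUNTS},
    }


def default_type_weights() -> dict[str, float]:
    """Generator default: loop types weighted by the corpus totals."""
    return {
        BULGE5: float(TYPE_TOTALS[BULGE5]),
        BULGE3: float(TYPE_TOTALS[BULGE3]),
        INTERNAL: float(TYPE_TOTALS[INTERNAL]),
    }
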