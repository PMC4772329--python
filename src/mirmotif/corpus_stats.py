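"""Motif count tables and the pooled two-proportion Z statistic.

The statistic of the pipeline is the pooled-proportion Z-score: for a motif
observed ``count1`` times in ``n1`` trials versus ``count2`` in ``n2``,

    phi = (n1*p1 + n2*p2) / (n1 + n2)
    Z   = (p1 - p2) / sqrt(phi * (1 - phi) * (1/n1 + 1/n2))

with |Z| > 2 as the significance criterion for ordering motif frequencies
("A > U" vs "A ≈ U"), and conventional two-sided normal p-value tiers
(0.05 / 0.01 / 0.001) for star annotations in corpus-vs-corpus comparisons.
Within-corpus comparisons use the motif-type total as the sample size (all
internal loops for a 1×1 loop comparison, all 5' bulges for a 5'-bulge
comparison, and so on) unless the caller overrides it.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from decimal import Decimal, ROUND_HALF_UP
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import norm

from . import motif_core
from .motif_core import BULGE3, BULGE5, HAIRPIN, INTERNAL, MULTIBRANCH

#: key level -> motif-records column
KEY_COLUMNS = {
    "unpaired": "unpaired_key",
    "motif": "motif_key",
    "extended": "extended_key",
}

#: |Z| beyond which two occurrence frequencies are called different
Z_THRESHOLD = 2.0

#: two-sided p-value tiers for star annotations
STAR_TIERS = ((0.001, "***"), (0.01, "**"), (0.05, "*"))

#: pooling of closing base pairs: AU/UA, GC/CG, GU/UG are one class each
PAIR_CLASS = {
    "AU": "AU", "UA": "AU",
    "GC": "GC", "CG": "GC",
    "GU": "GU", "UG": "GU",
}


def round_half_up(x: float, ndigits: int = 2) -> float:
    """Round half away from zero, the convention used for presentation."""
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP))


def stars(p: float) -> str:
    for tier, mark in STAR_TIERS:
        if p < tier:
            return mark
    return ""


# -- Z statistic ---------------------------------------------------------


@dataclass(frozen=True)
class ZScoreResult:
    """Pooled two-proportion comparison of one motif between two samples."""

    count1: int
    n1: int
    count2: int
    n2: int
    p1: float
    p2: float
    phi: float
    z: float
    p_two_sided: float
    significant: bool
    degenerate: bool = False


def zscore(
    count1: int, n1: int, count2: int, n2: int, threshold: float = Z_THRESHOLD
) -> ZScoreResult:
    """Pooled two-proportion Z-score of count1/n1 versus count2/n2.

    Exact formula, no continuity correction; sign(z) = sign(p1 - p2).  When
    the pooled proportion is 0 or 1 the statistic is undefined and z is
    reported as 0 with ``degenerate=True``.
    """
    for c, n in ((count1, n1), (count2, n2)):
        if n < 1:
            raise ValueError("sample sizes must be >= 1")
        if not 0 <= c <= n:
            raise ValueError(f"count {c} outside [0, {n}]")
    p1 = count1 / n1
    p2 = count2 / n2
    phi = (n1 * p1 + n2 * p2) / (n1 + n2)
    if phi in (0.0, 1.0):
        return ZScoreResult(
            count1, n1, count2, n2, p1, p2, phi, 0.0, 1.0, False, True
        )
    z = (p1 - p2) / math.sqrt(phi * (1.0 - phi) * (1.0 / n1 + 1.0 / n2))
    p = 2.0 * norm.sf(abs(z))
    return ZScoreResult(
        count1, n1, count2, n2, p1, p2, phi, z, p, abs(z) > threshold
    )


def zscore_matrix(
    labels: Sequence[str],
    counts: Sequence[int],
    ns: int | Sequence[int],
) -> pd.DataFrame:
    """Antisymmetric matrix M[i, j] = zscore(counts[i], n_i, counts[j], n_j).z."""
    if len(labels) != len(counts):
        raise ValueError("labels and counts must have equal length")
    n_list = (
        [int(ns)] * len(labels)
        if np.isscalar(ns)
        else [int(v) for v in ns]
    )
    if len(n_list) != len(labels):
        raise ValueError("ns must be scalar or per-label")
    m = np.zeros((len(labels), len(labels)))
    for a in range(len(labels)):
        for b in range(len(labels)):
            if a == b:
                continue
            m[a, b] = zscore(counts[a], n_list[a], counts[b], n_list[b]).z
    return pd.DataFrame(m, index=list(labels), columns=list(labels))


def significance_groups(
    labels: Sequence[str],
    counts: Sequence[int],
    n: int | Sequence[int],
    threshold: float = Z_THRESHOLD,
) -> list[list[str]]:
    """Partition labels (sorted by descending count) into frequency groups.

    Greedy scan: the next label joins the current group iff its minimum
    |z| against the group's members is <= threshold, otherwise it starts a
    new group.  After grouping, every pair of labels across adjacent groups
    is verified to differ at |z| > threshold; violations are reported as
    warnings, not errors.
    """
    if len(labels) != len(counts):
        raise ValueError("labels and counts must have equal length")
    if not labels:
        return []
    n_list = (
        [int(n)] * len(labels) if np.isscalar(n) else [int(v) for v in n]
    )
    order = sorted(range(len(labels)), key=lambda k: -counts[k])
    groups: list[list[int]] = [[order[0]]]
    for idx in order[1:]:
        zmin = min(
            abs(zscore(counts[idx], n_list[idx], counts[m], n_list[m]).z)
            for m in groups[-1]
        )
        if zmin <= threshold:
            groups[-1].append(idx)
        else:
            groups.append([idx])
    for g1, g2 in zip(groups, groups[1:]):
        for a in g1:
            for b in g2:
                z = zscore(counts[a], n_list[a], counts[b], n_list[b]).z
                if abs(z) <= threshold:
                    warnings.warn(
                        f"adjacent groups not fully separated: "
                        f"|z({labels[a]}, {labels[b]})| = {abs(z):.2f}",
                        stacklevel=2,
                    )
    return [[labels[k] for k in g] for g in groups]


# -- count tables --------------------------------------------------------


@dataclass
class MotifTable:
    """Counts of motif keys at one key level over a corpus.

    ``counts`` maps (motif_type, key) to a non-negative count;
    ``type_totals`` holds the per-type sample sizes used as Z-test
    denominators.  Totals default to the per-type sum of counts but may be
    set explicitly (e.g. when the table holds only the most frequent keys
    of a larger corpus).
    """

    key_level: str
    counts: dict[tuple[str, str], int] = field(default_factory=dict)
    type_totals: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.key_level not in KEY_COLUMNS:
            raise ValueError(f"unknown key level {self.key_level!r}")
        if any(v < 0 for v in self.counts.values()):
            raise ValueError("negative motif count")
        sums: dict[str, int] = {}
        for (mtype, _key), c in self.counts.items():
            sums[mtype] = sums.get(mtype, 0) + c
        for mtype, s in sums.items():
            tot = self.type_totals.setdefault(mtype, s)
            if tot < s:
                raise ValueError(
                    f"type total {tot} for {mtype!r} below sum of counts {s}"
                )

    @classmethod
    def from_records(cls, records: pd.DataFrame, key_level: str) -> "MotifTable":
        col = KEY_COLUMNS[key_level]
        counts: dict[tuple[str, str], int] = {}
        if len(records):
            grouped = records.groupby(["motif_type", col]).size()
            counts = {
                (str(t), str(k)): int(v) for (t, k), v in grouped.items()
            }
        return cls(key_level, counts)

    @classmethod
    def from_counts(
        cls,
        counts: Mapping[tuple[str, str], int],
        key_level: str = "unpaired",
        type_totals: Mapping[str, int] | None = None,
    ) -> "MotifTable":
        return cls(key_level, dict(counts), dict(type_totals or {}))

    @property
    def motif_types(self) -> list[str]:
        return sorted(self.type_totals)

    def total(self, motif_type: str) -> int:
        return self.type_totals.get(motif_type, 0)

    def get(self, motif_type: str, key: str) -> int:
        return self.counts.get((motif_type, key), 0)

    def items_sorted(self, motif_type: str) -> list[tuple[str, int]]:
        """Keys of one type, descending count then lexicographic."""
        items = [
            (k, c) for (t, k), c in self.counts.items() if t == motif_type
        ]
        return sorted(items, key=lambda kv: (-kv[1], kv[0]))

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for mtype in self.motif_types:
            tot = self.total(mtype)
            for key, c in self.items_sorted(mtype):
                rows.append(
                    {
                        "motif_type": mtype,
                        "key": key,
                        "count": c,
                        "fraction": c / tot if tot else float("nan"),
                    }
                )
        return pd.DataFrame(
            rows, columns=["motif_type", "key", "count", "fraction"]
        )

    def to_tsv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path: str | Path, key_level: str = "unpaired") -> "MotifTable":
        df = pd.read_csv(path, sep="\t", keep_default_na=False, na_values=[])
        counts = {
            (str(r.motif_type), str(r.key)): int(r.count)
            for r in df.itertuples()
        }
        return cls(key_level, counts)


def tabulate(records: pd.DataFrame, key_level: str = "motif") -> MotifTable:
    """Aggregate motif records (exterior already excluded) into a table."""
    return MotifTable.from_records(records, key_level)


def count_unique(table: MotifTable) -> tuple[int, float]:
    """Number of keys occurring exactly once and their fraction of all motifs.

    The fraction is NaN for an empty table.
    """
    unique = sum(1 for c in table.counts.values() if c == 1)
    total = sum(table.counts.values())
    return unique, (unique / total if total else float("nan"))


# -- size-class summaries ------------------------------------------------


def _size_class_of_key(motif_type: str, key: str, key_level: str) -> str:
    """Derive the size class of a table key."""
    if key_level == "motif":
        m = motif_core.parse_motif(key)
        sides = m.sides
        motif_type = m.kind
    else:
        sides = tuple(key.split("/")) if motif_type == INTERNAL else (key,)
    if motif_type in (BULGE5, BULGE3):
        return str(len(sides[0]))
    if motif_type == INTERNAL:
        return f"{len(sides[0])}×{len(sides[1])}"
    if motif_type == HAIRPIN:
        return f"L-{len(sides[0])}"
    return "MB"


def _pool_size_class(
    motif_type: str,
    size: str,
    bulge_cutoff: int,
    internal_cutoff: int,
    hairpin_cutoff: int,
) -> str:
    if motif_type in (BULGE5, BULGE3):
        return size if int(size) <= bulge_cutoff else "others"
    if motif_type == INTERNAL:
        a, b = (int(v) for v in size.split("×"))
        if max(a, b) > internal_cutoff:
            return "others"
        lo, hi = sorted((a, b))
        return f"{lo}×{lo}" if lo == hi else f"{lo}×{hi}/{hi}×{lo}"
    if motif_type == HAIRPIN:
        return size if int(size.split("-")[1]) <= hairpin_cutoff else "others"
    return size


def summarize_by_size(
    table: MotifTable,
    *,
    bulge_cutoff: int = 4,
    internal_cutoff: int = 3,
    hairpin_cutoff: int = 9,
) -> pd.DataFrame:
    """Size-class distribution per motif type.

    Internal loops pool mirror classes (a×b with b×a); classes beyond the
    cutoffs (bulges > ``bulge_cutoff`` nt, internal loops with a side >
    ``internal_cutoff``, hairpins > ``hairpin_cutoff`` nt) pool into
    "others".  Fractions use the table's per-type totals as denominators.
    """
    acc: dict[tuple[str, str], int] = {}
    for (mtype, key), c in table.counts.items():
        size = _size_class_of_key(mtype, key, table.key_level)
        pooled = _pool_size_class(
            mtype, size, bulge_cutoff, internal_cutoff, hairpin_cutoff
        )
        acc[(mtype, pooled)] = acc.get((mtype, pooled), 0) + c
    rows = []
    for (mtype, size), c in sorted(acc.items(), key=lambda kv: (-kv[1], kv[0])):
        tot = table.total(mtype)
        rows.append(
            {
                "motif_type": mtype,
                "size_class": size,
                "count": c,
                "fraction": c / tot if tot else float("nan"),
            }
        )
    return pd.DataFrame(
        rows, columns=["motif_type", "size_class", "count", "fraction"]
    )


# -- closing-pair preferences --------------------------------------------


def preference_order(
    class_counts: Mapping[str, int], n: int, threshold: float = Z_THRESHOLD
) -> str:
    """Render an order string like "AU>GC≈GU" from pooled class counts."""
    items = sorted(class_counts.items(), key=lambda kv: (-kv[1], kv[0]))
    if not items:
        return ""
    out = [items[0][0]]
    for (la, ca), (lb, cb) in zip(items, items[1:]):
        z = zscore(ca, n, cb, n).z
        out.append(">" if abs(z) > threshold else "≈")
        out.append(lb)
    return "".join(out)


def closing_pair_preferences(
    records: pd.DataFrame,
    unpaired_keys: Sequence[str] | None = None,
    motif_type: str | None = INTERNAL,
    threshold: float = Z_THRESHOLD,
) -> tuple[pd.DataFrame, dict[tuple[str, str], str]]:
    """Pooled 5'/3' closing-pair class counts per selected unpaired key.

    AU/UA, GC/CG and GU/UG closing pairs are pooled into one class each.
    Returns (counts table, orders) where orders maps (unpaired_key, side)
    to an order string with ">" / "≈" annotations at the |z| threshold;
    the sample size for ordering is the selected loop's total occurrence
    count.  An empty selection returns empty results.
    """
    sel = records
    if motif_type is not None:
        sel = sel[sel["motif_type"] == motif_type]
    else:
        sel = sel[sel["motif_type"].isin(motif_core.TWO_SIDED)]
    if unpaired_keys is not None:
        sel = sel[sel["unpaired_key"].isin(list(unpaired_keys))]
    acc: dict[tuple[str, str, str], int] = {}
    totals: dict[str, int] = {}
    for row in sel.itertuples():
        m = motif_core.parse_motif(row.motif_key)
        cls5 = PAIR_CLASS[m.pairs[0]]
        cls3 = PAIR_CLASS[m.pairs[1]]
        key = str(row.unpaired_key)
        acc[(key, "5p", cls5)] = acc.get((key, "5p", cls5), 0) + 1
        acc[(key, "3p", cls3)] = acc.get((key, "3p", cls3), 0) + 1
        totals[key] = totals.get(key, 0) + 1
    rows = [
        {"unpaired_key": k, "side": side, "pair_class": cls, "count": c}
        for (k, side, cls), c in sorted(acc.items())
    ]
    frame = pd.DataFrame(
        rows, columns=["unpaired_key", "side", "pair_class", "count"]
    )
    orders: dict[tuple[str, str], str] = {}
    for key, n in totals.items():
        for side in ("5p", "3p"):
            cc = {
                cls: c for (k, s, cls), c in acc.items()
                if k == key and s == side
            }
            orders[(key, side)] = preference_order(cc, n, threshold)
    return frame, orders


# -- corpus-vs-corpus comparison -----------------------------------------


def compare_corpora(
    table_a: MotifTable,
    table_b: MotifTable,
    keys: Sequence[tuple[str, str]] | None = None,
) -> pd.DataFrame:
    """Per-key pooled Z comparison of two corpora at the same key level.

    A key absent from one table counts 0 against that table's type total.
    Stars follow two-sided normal p-value tiers (0.05 / 0.01 / 0.001).
    """
    if table_a.key_level != table_b.key_level:
        raise ValueError("tables must share a key level")
    if keys is None:
        keys = sorted(set(table_a.counts) | set(table_b.counts))
    rows = []
    for mtype, key in keys:
        na, nb = table_a.total(mtype), table_b.total(mtype)
        if na < 1 or nb < 1:
            continue
        r = zscore(table_a.get(mtype, key), na, table_b.get(mtype, key), nb)
        rows.append(
            {
                "motif_type": mtype,
                "key": key,
                "count_a": r.count1,
                "n_a": r.n1,
                "count_b": r.count2,
                "n_b": r.n2,
                "z": r.z,
                "p": r.p_two_sided,
                "stars": stars(r.p_two_sided),
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "motif_type", "key", "count_a", "n_a", "count_b", "n_b",
            "z", "p", "stars",
        ],
    )
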