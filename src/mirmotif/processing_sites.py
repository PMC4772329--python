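"""Mapping mature miRNAs and classifying processing-site contexts.

The first and last nucleotides of a mature miRNA define its start and end
processing sites on the hairpin precursor.  Each site falls in a structural
context: a paired (helical) position, a loop element (bulge, internal,
hairpin or multibranch loop), or the terminal/exterior region.  A site in a
loop is annotated with that loop's motif; a paired site is annotated with
its own base pair plus one stacked neighbour pair on each side (a
neighbouring loop's far closing pair counts as the neighbour across that
loop).

Enzyme attribution follows the biogenesis geometry: Drosha cuts at the
stem-distal end of the mature duplex and Dicer at the loop-proximal end, so
on the 5' arm the start site is the Drosha cut and the end site the Dicer
cut, and on the 3' arm the roles swap.  The arm is called by comparing the
mature span to the midpoint of the reference (5'-most) hairpin loop; a
mature spanning that midpoint gets an explicit "ambiguous" arm and no
enzyme.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import pandas as pd

from . import motif_core
from .corpus_stats import KEY_COLUMNS, MotifTable, ZScoreResult, zscore
from .motif_core import (
    EXTERIOR,
    HAIRPIN,
    LoopElement,
    MULTIBRANCH,
    NA,
    TWO_SIDED,
    decompose,
    name_motif,
)
from .structure_io import SecondaryStructure, _norm_seq

PAIRED = "paired"
TERMINAL = "terminal"
LOOP_CONTEXTS = frozenset(motif_core.MOTIF_KINDS)

ENZYME_BY_SITE_ARM = {
    ("start", "5p"): "drosha",
    ("end", "5p"): "dicer",
    ("start", "3p"): "dicer",
    ("end", "3p"): "drosha",
}

SITE_COLUMNS = [
    "precursor_id",
    "mature_id",
    "site",
    "position",
    "arm",
    "enzyme",
    "context",
    "site_motif",
    "unpaired_key",
    "loop_annotation",
]


class MappingError(ValueError):
    """Raised when a mature sequence has no exact match on its precursor."""


def map_mature(
    precursor_seq: str, mature_seq: str, min_length: int = 10
) -> tuple[int, int]:
    """1-based (start, end) of the first exact occurrence of the mature.

    Exact substring semantics after T→U normalisation; no fuzzy matching.
    Multiple occurrences take the first with a warning.
    """
    prec = _norm_seq(precursor_seq)
    mat = _norm_seq(mature_seq)
    if len(mat) < min_length:
        raise MappingError(
            f"mature sequence shorter than {min_length} nt: {mat!r}"
        )
    idx = prec.find(mat)
    if idx < 0:
        raise MappingError("mature sequence not found on precursor")
    if prec.find(mat, idx + 1) >= 0:
        warnings.warn(
            "mature sequence occurs more than once on precursor; "
            "using the first occurrence",
            stacklevel=2,
        )
    return idx + 1, idx + len(mat)


@dataclass(frozen=True)
class SiteContext:
    """Structural context of one processing-site nucleotide."""

    context: str
    site_motif: str
    unpaired_key: str | None = None
    loop_annotation: str | None = None


def _containing_element(
    elements: Sequence[LoopElement], position: int
) -> LoopElement | None:
    for el in elements:
        for s, e in el.unpaired_runs:
            if s <= position <= e:
                return el
    return None


def _outer_neighbor(ss, elements, i, j):
    """Next pair outward of (i, j): stacked, or across an adjacent loop."""
    st = motif_core._stacked_outer(ss, i, j)
    if st:
        return st
    for el in elements:
        if el.kind in TWO_SIDED and el.closing_pairs[1] == (i, j):
            return el.closing_pairs[0]
        if el.kind == MULTIBRANCH and (i, j) in el.closing_pairs[1:]:
            return el.closing_pairs[0]
    return None


def _inner_neighbor(ss, elements, i, j):
    """Next pair inward of (i, j): stacked, or across a two-sided loop.

    Inward of a hairpin there is nothing; inward of a multibranch there are
    several branches, so no single neighbour is reported.
    """
    st = motif_core._stacked_inner(ss, i, j)
    if st:
        return st
    for el in elements:
        if el.kind in TWO_SIDED and el.closing_pairs[0] == (i, j):
            return el.closing_pairs[1]
    return None


def classify_site(
    ss: SecondaryStructure,
    position: int,
    elements: Sequence[LoopElement] | None = None,
) -> SiteContext:
    """Context and site motif of one precursor position.

    Unpaired positions return their containing loop element's motif
    (``terminal`` in the exterior region); paired positions return context
    ``paired`` with the site's own pair flanked by its neighbour pairs,
    plus, when the pair closes a loop, that loop's motif as an annotation.
    """
    if not 1 <= position <= ss.n:
        raise ValueError(f"position {position} outside 1..{ss.n}")
    if elements is None:
        elements = decompose(ss)
    j = ss.partner_of(position)
    if j == 0:
        el = _containing_element(elements, position)
        if el is None or el.kind == EXTERIOR:
            return SiteContext(TERMINAL, NA)
        nm = name_motif(el, ss)
        return SiteContext(el.kind, nm.motif_key, nm.unpaired_key)
    i, jj = min(position, j), max(position, j)
    outer = _outer_neighbor(ss, elements, i, jj)
    inner = _inner_neighbor(ss, elements, i, jj)
    parts = []
    if outer:
        parts.append(motif_core._pt(ss, *outer))
    parts.append(motif_core._pt(ss, i, jj))
    if inner:
        parts.append(motif_core._pt(ss, *inner))
    annotations = [
        name_motif(el, ss).motif_key
        for el in elements
        if el.is_motif and (i, jj) in el.closing_pairs
    ]
    return SiteContext(
        PAIRED,
        "".join(parts),
        None,
        ";".join(annotations) if annotations else None,
    )


def reference_hairpin(
    ss: SecondaryStructure, elements: Sequence[LoopElement] | None = None
) -> LoopElement | None:
    """The 5'-most hairpin loop element, or None for a pair-free structure."""
    if elements is None:
        elements = decompose(ss)
    hairpins = [el for el in elements if el.kind == HAIRPIN]
    if not hairpins:
        return None
    return min(hairpins, key=lambda el: el.unpaired_runs[0][0])


def call_arm(
    ss: SecondaryStructure,
    start: int,
    end: int,
    elements: Sequence[LoopElement] | None = None,
) -> str:
    """"5p", "3p" or "ambiguous" for a mature span (start, end)."""
    hp = reference_hairpin(ss, elements)
    if hp is None:
        return "ambiguous"
    a, b = hp.unpaired_runs[0]
    mid = (a + b) / 2.0
    if end < mid:
        return "5p"
    if start > mid:
        return "3p"
    return "ambiguous"


def assign_enzyme(site: str, arm: str) -> str:
    """Drosha/Dicer attribution of a processing site given the arm."""
    if site not in ("start", "end"):
        raise ValueError(f"site must be 'start' or 'end', got {site!r}")
    if arm not in ("5p", "3p"):
        return NA
    return ENZYME_BY_SITE_ARM[(site, arm)]


def analyze_sites(
    structures: Mapping[str, SecondaryStructure] | Iterable[SecondaryStructure],
    matures: Iterable[tuple[str, str, str]],
) -> pd.DataFrame:
    """Two site records (start, end) per mature miRNA.

    ``matures`` yields (mature_id, precursor_id, mature_sequence) triples.
    """
    if not isinstance(structures, Mapping):
        structures = {ss.id: ss for ss in structures}
    rows = []
    for mature_id, precursor_id, seq in matures:
        ss = structures.get(precursor_id)
        if ss is None:
            raise MappingError(
                f"mature {mature_id!r}: unknown precursor {precursor_id!r}"
            )
        start, end = map_mature(ss.sequence, seq)
        elements = decompose(ss)
        arm = call_arm(ss, start, end, elements)
        if arm == "ambiguous":
            warnings.warn(
                f"mature {mature_id!r} spans the hairpin loop midpoint; "
                "arm ambiguous, enzymes unassigned",
                stacklevel=2,
            )
        for site, position in (("start", start), ("end", end)):
            ctx = classify_site(ss, position, elements)
            rows.append(
                {
                    "precursor_id": precursor_id,
                    "mature_id": mature_id,
                    "site": site,
                    "position": position,
                    "arm": arm,
                    "enzyme": assign_enzyme(site, arm),
                    "context": ctx.context,
                    "site_motif": ctx.site_motif,
                    "unpaired_key": ctx.unpaired_key or NA,
                    "loop_annotation": ctx.loop_annotation or NA,
                }
            )
    return pd.DataFrame(rows, columns=SITE_COLUMNS)


def site_summary(records: pd.DataFrame) -> dict:
    """Paired fractions of start and end sites, with their pooled Z.

    The Z sign convention is p_start - p_end.
    """
    out: dict = {}
    counts = {}
    for site in ("start", "end"):
        sub = records[records["site"] == site]
        n = len(sub)
        paired = int((sub["context"] == PAIRED).sum())
        counts[site] = (paired, n)
        out[f"{site}_paired_fraction"] = paired / n if n else float("nan")
        out[f"{site}_n"] = n
    (c1, n1), (c2, n2) = counts["start"], counts["end"]
    if n1 and n2:
        out["z"] = zscore(c1, n1, c2, n2)
    else:
        out["z"] = None
    return out


def site_uniqueness(
    records: pd.DataFrame,
    corpus_table: MotifTable,
    reference_table: MotifTable | None = None,
) -> tuple[dict, pd.DataFrame]:
    """Sites whose loop motif occurs exactly once in the corpus.

    A site record in a loop context carries that loop's key at the corpus
    table's key level; the site is unique iff the corpus count of
    (context, key) is exactly 1.  Overlap with a reference table is by
    exact (type, key) match and is omitted when no reference is given.
    Returns (summary, annotated records with is_unique / in_reference).
    """
    level = corpus_table.key_level
    if level not in ("unpaired", "motif"):
        raise ValueError("site uniqueness supports unpaired or motif keys")
    key_col = "unpaired_key" if level == "unpaired" else "site_motif"
    annotated = records.copy()
    is_unique = []
    in_reference = []
    for row in annotated.itertuples():
        if row.context in LOOP_CONTEXTS:
            key = str(getattr(row, key_col))
            uniq = corpus_table.get(row.context, key) == 1
            ref = (
                reference_table is not None
                and reference_table.get(row.context, key) > 0
            )
        else:
            uniq, ref = False, False
        is_unique.append(uniq)
        in_reference.append(ref)
    annotated["is_unique"] = is_unique
    annotated["in_reference"] = in_reference
    uniq_rows = annotated[annotated["is_unique"]]
    summary = {
        "unique_sites": int(len(uniq_rows)),
        "unique_keys": int(
            uniq_rows.groupby(["context", key_col]).ngroups
        ),
        "by_enzyme": {
            enz: int((uniq_rows["enzyme"] == enz).sum())
            for enz in ("dicer", "drosha")
        },
    }
    if reference_table is not None:
        summary["reference_overlap"] = int(
            uniq_rows[uniq_rows["in_reference"]]
            .groupby(["context", key_col])
            .ngroups
        )
    return summary, annotated
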