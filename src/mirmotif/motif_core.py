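"""Loop decomposition and the three-level motif nomenclature.

A nested secondary structure decomposes uniquely into loop elements —
hairpin loops, 5'/3' bulges, internal loops and multibranch loops — plus
helices and an exterior (dangling-end) region.  Each loop element is named
at three levels:

* ``unpaired_key`` — the loop nucleotides alone ("U", "A/C", "UUUAGU");
* ``motif_key`` — loop nucleotides plus closing base pair(s), e.g.
  "(AU)U/-(GC)" for a 5' bulge U closed by A·U outside and G·C inside;
* ``extended_key`` — the motif plus the first non-nearest-neighbour pair of
  each closing helix, "NA" where the helix has only one pair.

Both nucleotides of a closing pair are always written because of GU wobble
pairs, every pair is rendered ``(b[p]b[q])`` with p < q in precursor
coordinates (so the nucleotide 5' of the loop comes first), and the two
sides of a bulge or internal loop are separated by "/" with "-" for the
empty side.  A bulge is 5' or 3' according to whether its unpaired strand
lies 5' or 3' of the hairpin loop it leads to; because the structure is
nested this is simply which side of the two closing pairs carries the
unpaired run.  The same physical loop can therefore be written in two
orientations, related by the involution
``flip((XY) s1/s2 (WZ)) = (ZW) s2/s1 (YX)``.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

from .structure_io import SecondaryStructure

HAIRPIN = "hairpin"
BULGE5 = "bulge5"
BULGE3 = "bulge3"
INTERNAL = "internal"
MULTIBRANCH = "multibranch"
EXTERIOR = "exterior"

TWO_SIDED = frozenset({BULGE5, BULGE3, INTERNAL})
MOTIF_KINDS = (HAIRPIN, BULGE5, BULGE3, INTERNAL, MULTIBRANCH)

NA = "NA"

#: columns of the motif records table emitted by :func:`extract_motifs`
RECORD_COLUMNS = [
    "precursor_id",
    "motif_type",
    "size_class",
    "unpaired_key",
    "motif_key",
    "extended_key",
    "pos_outer_5p",
    "pos_outer_3p",
    "orientation",
]


class MotifParseError(ValueError):
    """Raised when a motif name string does not conform to the grammar."""


class UnsupportedKindError(ValueError):
    """Raised when an operation is applied to a loop kind it does not cover."""


@dataclass(frozen=True)
class LoopElement:
    """One decomposed loop, located on its precursor.

    ``closing_pairs`` are (i, j) with i < j; for two-sided loops the outer
    pair comes first, for multibranch loops the external pair comes first
    followed by the branch pairs in 5'→3' order.  ``unpaired_runs`` are
    inclusive 1-based ranges; a range with end < start is an empty side
    (bulges) or an empty gap between branches.
    """

    kind: str
    closing_pairs: tuple[tuple[int, int], ...]
    unpaired_runs: tuple[tuple[int, int], ...]
    precursor_id: str = ""

    @property
    def is_motif(self) -> bool:
        return self.kind != EXTERIOR

    @property
    def unpaired_positions(self) -> list[int]:
        out: list[int] = []
        for s, e in self.unpaired_runs:
            out.extend(range(s, e + 1))
        return out


@dataclass(frozen=True)
class MotifName:
    """The three key levels plus size class of one loop element."""

    unpaired_key: str
    motif_key: str
    extended_key: str
    size_class: str


def _run_len(run: tuple[int, int]) -> int:
    s, e = run
    return max(0, e - s + 1)


def _face(ss: SecondaryStructure, i: int, j: int):
    """Unpaired runs and child pairs of the face bounded by pair (i, j).

    With i=0, j=n+1 this scans the exterior face.  Returns
    (runs, children) where runs has len(children)+1 entries (empty ranges
    kept, so runs and children interleave in 5'→3' order).
    """
    runs: list[tuple[int, int]] = []
    children: list[tuple[int, int]] = []
    k = i + 1
    run_start = k
    while k < j:
        p = ss.partner_of(k)
        if p == 0:
            k += 1
        else:
            runs.append((run_start, k - 1))
            children.append((k, p))
            k = p + 1
            run_start = k
    runs.append((run_start, j - 1))
    return runs, children


def decompose(
    ss: SecondaryStructure, include_exterior: bool = True
) -> list[LoopElement]:
    """Decompose a structure into loop elements.

    Every position of the precursor belongs to exactly one of: a helix
    pair, one loop element's unpaired run, or the exterior region.  Stacked
    pair faces produce no element.  The exterior (dangling ends plus any
    linker between top-level helices) is returned as a final non-motif
    element when it is non-empty and ``include_exterior`` is true.
    """
    elements: list[LoopElement] = []
    if not ss.pairs:
        warnings.warn(
            f"{ss.id}: structure has no pairs; the whole molecule is exterior",
            stacklevel=2,
        )
    for i, j in ss.pairs:
        runs, children = _face(ss, i, j)
        if not children:
            elements.append(LoopElement(HAIRPIN, ((i, j),), tuple(runs), ss.id))
        elif len(children) == 1:
            side1, side2 = runs
            l1, l2 = _run_len(side1), _run_len(side2)
            if l1 == 0 and l2 == 0:
                continue  # stacked pairs
            if l1 > 0 and l2 > 0:
                kind = INTERNAL
            elif l1 > 0:
                kind = BULGE5
            else:
                kind = BULGE3
            elements.append(
                LoopElement(kind, ((i, j), children[0]), (side1, side2), ss.id)
            )
        else:
            elements.append(
                LoopElement(
                    MULTIBRANCH, ((i, j), *children), tuple(runs), ss.id
                )
            )
    if include_exterior:
        runs, _children = _face(ss, 0, ss.n + 1)
        runs = [r for r in runs if _run_len(r)]
        if runs:
            elements.append(LoopElement(EXTERIOR, (), tuple(runs), ss.id))
    return elements


def orient_bulge(element: LoopElement, ss: SecondaryStructure | None = None) -> str:
    """Return "bulge5" or "bulge3" for a bulge element.

    The unpaired run of a bulge sits on one strand of the helix leading
    down to its reference hairpin loop; in a nested structure the strand
    between the two closing pairs' 5' positions is always 5' of every
    position deeper in the stem, so orientation reduces to which side
    carries the run.
    """
    if element.kind not in (BULGE5, BULGE3):
        raise UnsupportedKindError(f"not a bulge: {element.kind}")
    side1, side2 = element.unpaired_runs
    return BULGE5 if _run_len(side1) else BULGE3


# -- naming --------------------------------------------------------------


def _pt(ss: SecondaryStructure, i: int, j: int) -> str:
    return f"({ss.base(i)}{ss.base(j)})"


def _run_seq(ss: SecondaryStructure, run: tuple[int, int]) -> str:
    s, e = run
    return ss.sequence[s - 1 : e] if e >= s else ""


def _stacked_outer(ss: SecondaryStructure, p: int, q: int):
    if p > 1 and q < ss.n and ss.partner_of(p - 1) == q + 1:
        return (p - 1, q + 1)
    return None


def _stacked_inner(ss: SecondaryStructure, p: int, q: int):
    if p + 1 < q - 1 and ss.partner_of(p + 1) == q - 1:
        return (p + 1, q - 1)
    return None


def _nn_token(ss: SecondaryStructure, pair) -> str:
    return _pt(ss, *pair) if pair else NA


def name_motif(element: LoopElement, ss: SecondaryStructure) -> MotifName:
    """Render all three key levels and the size class of a loop element."""
    kind = element.kind
    if kind == EXTERIOR:
        raise UnsupportedKindError("the exterior region is not a motif")
    if kind == HAIRPIN:
        (p, q), = element.closing_pairs
        loop = _run_seq(ss, element.unpaired_runs[0])
        motif = _pt(ss, p, q) + loop
        extended = _nn_token(ss, _stacked_outer(ss, p, q)) + motif
        return MotifName(loop, motif, extended, f"L-{len(loop)}")
    if kind in TWO_SIDED:
        (p1, q1), (p2, q2) = element.closing_pairs
        s1 = _run_seq(ss, element.unpaired_runs[0])
        s2 = _run_seq(ss, element.unpaired_runs[1])
        motif = (
            _pt(ss, p1, q1) + (s1 or "-") + "/" + (s2 or "-") + _pt(ss, p2, q2)
        )
        extended = (
            _nn_token(ss, _stacked_outer(ss, p1, q1))
            + motif
            + _nn_token(ss, _stacked_inner(ss, p2, q2))
        )
        if kind == INTERNAL:
            unpaired = f"{s1}/{s2}"
            size = f"{len(s1)}×{len(s2)}"
        else:
            unpaired = s1 or s2
            size = str(len(unpaired))
        return MotifName(unpaired, motif, extended, size)
    # multibranch: external pair, then runs and branch pairs interleaved,
    # terminated by the external pair in the opposite orientation
    (p, q), *branches = element.closing_pairs
    runs = element.unpaired_runs
    parts = [_pt(ss, p, q)]
    for run, br in zip(runs, branches):
        parts.append(_run_seq(ss, run))
        parts.append(_pt(ss, *br))
    parts.append(_run_seq(ss, runs[-1]))
    parts.append(f"({ss.base(q)}{ss.base(p)})")
    motif = "".join(parts)
    unpaired = "/".join(_run_seq(ss, r) or "-" for r in runs)
    extended = (
        _nn_token(ss, _stacked_outer(ss, p, q))
        + motif
        + "".join(_nn_token(ss, _stacked_inner(ss, *br)) for br in branches)
    )
    return MotifName(unpaired, motif, extended, "MB")


def extract_motifs(ss: SecondaryStructure) -> pd.DataFrame:
    """One motif-record row per non-exterior loop element of a structure."""
    rows = []
    for el in decompose(ss, include_exterior=False):
        nm = name_motif(el, ss)
        p1, q1 = el.closing_pairs[0]
        orientation = (
            "5p" if el.kind == BULGE5 else "3p" if el.kind == BULGE3 else NA
        )
        rows.append(
            {
                "precursor_id": ss.id,
                "motif_type": el.kind,
                "size_class": nm.size_class,
                "unpaired_key": nm.unpaired_key,
                "motif_key": nm.motif_key,
                "extended_key": nm.extended_key,
                "pos_outer_5p": p1,
                "pos_outer_3p": q1,
                "orientation": orientation,
            }
        )
    return pd.DataFrame(rows, columns=RECORD_COLUMNS)


def extract_corpus(structures: Iterable[SecondaryStructure]) -> pd.DataFrame:
    frames = [extract_motifs(ss) for ss in structures]
    if not frames:
        return pd.DataFrame(columns=RECORD_COLUMNS)
    return pd.concat(frames, ignore_index=True)


def write_motif_records(records: pd.DataFrame, path: str | Path) -> None:
    records.to_csv(path, sep="\t", index=False, na_rep=NA)


def read_motif_records(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(
        path, sep="\t", dtype={"size_class": str}, keep_default_na=False,
        na_values=[],
    )


# -- abstract motifs: parsing, formatting, flipping ----------------------


@dataclass(frozen=True)
class AbstractMotif:
    """A motif name detached from any precursor.

    ``pairs`` holds the closing pairs as two-letter strings in rendering
    order (outer then inner for two-sided loops; external then branches for
    multibranch loops — the terminal repeat of the external pair is
    implicit).  ``sides`` holds the unpaired strings, "" for an empty side.
    """

    kind: str
    pairs: tuple[str, ...]
    sides: tuple[str, ...]

    def format(self) -> str:
        if self.kind == HAIRPIN:
            return f"({self.pairs[0]}){self.sides[0]}"
        if self.kind in TWO_SIDED:
            return (
                f"({self.pairs[0]})"
                f"{self.sides[0] or '-'}/{self.sides[1] or '-'}"
                f"({self.pairs[1]})"
            )
        parts = [f"({self.pairs[0]})"]
        for side, pair in zip(self.sides, self.pairs[1:]):
            parts.append(side)
            parts.append(f"({pair})")
        parts.append(self.sides[-1])
        parts.append(f"({self.pairs[0][::-1]})")
        return "".join(parts)


_TOKEN_RE = re.compile(r"\(([ACGU]{2})\)|([ACGUN]+)|(/)|(-)")


def _tokenize(text: str):
    tokens = []
    pos = 0
    for m in _TOKEN_RE.finditer(text):
        if m.start() != pos:
            raise MotifParseError(
                f"unparseable motif text at offset {pos}: {text!r}"
            )
        if m.group(1):
            tokens.append(("pair", m.group(1)))
        elif m.group(2):
            tokens.append(("run", m.group(2)))
        elif m.group(3):
            tokens.append(("slash", "/"))
        else:
            tokens.append(("empty", ""))
        pos = m.end()
    if pos != len(text):
        raise MotifParseError(f"unparseable motif text at offset {pos}: {text!r}")
    return tokens


def parse_motif(text: str) -> AbstractMotif:
    """Parse a motif-key string back into an abstract motif.

    ``format(parse(s)) == s`` on canonical strings and
    ``parse(format(m)) == m`` always.
    """
    tokens = _tokenize(text)
    if not tokens or tokens[0][0] != "pair":
        raise MotifParseError(f"motif must start with a closing pair: {text!r}")
    kinds = [t[0] for t in tokens]
    if "slash" in kinds:
        # two-sided: pair side / side pair
        if (
            len(tokens) != 5
            or kinds[0] != "pair"
            or kinds[1] not in ("run", "empty")
            or kinds[2] != "slash"
            or kinds[3] not in ("run", "empty")
            or kinds[4] != "pair"
        ):
            raise MotifParseError(f"malformed two-sided motif: {text!r}")
        s1 = tokens[1][1]
        s2 = tokens[3][1]
        if not s1 and not s2:
            raise MotifParseError(f"two-sided motif with both sides empty: {text!r}")
        if s1 and s2:
            kind = INTERNAL
        elif s1:
            kind = BULGE5
        else:
            kind = BULGE3
        return AbstractMotif(kind, (tokens[0][1], tokens[4][1]), (s1, s2))
    n_pairs = kinds.count("pair")
    if n_pairs == 1:
        if len(tokens) != 2 or kinds[1] != "run":
            raise MotifParseError(f"malformed hairpin motif: {text!r}")
        loop = tokens[1][1]
        if len(loop) < 3:
            raise MotifParseError(f"hairpin loop shorter than 3: {text!r}")
        return AbstractMotif(HAIRPIN, (tokens[0][1],), (loop,))
    # multibranch: pair (run? pair)+ with the last pair the reversed external
    pairs: list[str] = [tokens[0][1]]
    sides: list[str] = []
    k = 1
    while k < len(tokens):
        if tokens[k][0] == "run":
            sides.append(tokens[k][1])
            k += 1
        else:
            sides.append("")
        if k >= len(tokens) or tokens[k][0] != "pair":
            raise MotifParseError(f"malformed multibranch motif: {text!r}")
        pairs.append(tokens[k][1])
        k += 1
    if len(pairs) < 3:
        raise MotifParseError(
            f"multibranch motif needs >= 2 branch pairs: {text!r}"
        )
    if pairs[-1] != pairs[0][::-1]:
        raise MotifParseError(
            f"multibranch motif must end with its external pair reversed: {text!r}"
        )
    return AbstractMotif(MULTIBRANCH, tuple(pairs[:-1]), tuple(sides))


def flip_motif(motif: AbstractMotif) -> AbstractMotif:
    """Map a two-sided motif onto its equal, oppositely oriented writing.

    ``flip((XY) s1/s2 (WZ)) = (ZW) s2/s1 (YX)``: the inner pair, reversed,
    becomes the outer pair, the sides swap, and bulge5 <-> bulge3.  flip is
    an involution and conserves the multiset of unpaired nucleotides.
    """
    if motif.kind not in TWO_SIDED:
        raise UnsupportedKindError(
            f"flip is defined for bulges and internal loops, not {motif.kind}"
        )
    if motif.kind == BULGE5:
        kind = BULGE3
    elif motif.kind == BULGE3:
        kind = BULGE5
    else:
        kind = INTERNAL
    return AbstractMotif(
        kind,
        (motif.pairs[1][::-1], motif.pairs[0][::-1]),
        (motif.sides[1], motif.sides[0]),
    )
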