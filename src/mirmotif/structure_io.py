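"""Reading, writing and validation of nested RNA secondary structures.

This module is the entry gate of the pipeline: every structure that reaches
motif extraction has passed the validator here.  A structure is a sequence
over {A, C, G, U, N} plus a 1-based pair table in which only canonical
Watson-Crick (AU/UA, GC/CG) and wobble (GU/UG) pairs count as paired,
pseudoknots are rejected, and every hairpin loop spans at least three
unpaired nucleotides.  These are the conventions of free-energy-minimisation
output (dot-bracket and CT files), which is what the pipeline consumes;
structure prediction itself happens upstream.

Coordinates are 1-based and inclusive throughout the package.
"""

from __future__ import annotations

import gzip
import warnings
from dataclasses import dataclass
from io import StringIO
from pathlib import Path
from typing import Iterable, Sequence

from Bio import SeqIO

RNA_ALPHABET = frozenset("ACGUN")
CANONICAL_PAIRS = frozenset(
    {("A", "U"), ("U", "A"), ("G", "C"), ("C", "G"), ("G", "U"), ("U", "G")}
)
#: minimum number of unpaired nucleotides in a hairpin loop
MIN_HAIRPIN_LOOP = 3


class StructureFormatError(ValueError):
    """Raised for malformed FASTA, dot-bracket or CT input."""


def _norm_seq(raw: str) -> str:
    """Uppercase and coerce DNA-style T to U."""
    return raw.strip().upper().replace("T", "U")


@dataclass(frozen=True)
class SecondaryStructure:
    """A pseudoknot-free secondary structure over one RNA sequence.

    ``partner[i-1]`` is the 1-based partner of position ``i``, or 0 when
    position ``i`` is unpaired.  All four type invariants (involution,
    nestedness, minimum hairpin span, canonical pairs only) are enforced at
    construction; instances are immutable, so a structure that exists is
    valid.
    """

    id: str
    sequence: str
    partner: tuple[int, ...]

    def __post_init__(self) -> None:
        seq = self.sequence
        n = len(seq)
        if n < 1:
            raise StructureFormatError(f"{self.id}: empty sequence")
        bad = set(seq) - RNA_ALPHABET
        if bad:
            raise StructureFormatError(
                f"{self.id}: illegal sequence characters {sorted(bad)}"
            )
        if len(self.partner) != n:
            raise StructureFormatError(
                f"{self.id}: partner table length {len(self.partner)} "
                f"!= sequence length {n}"
            )
        for i in range(1, n + 1):
            j = self.partner[i - 1]
            if j == 0:
                continue
            if not 1 <= j <= n or j == i:
                raise StructureFormatError(f"{self.id}: invalid partner {j} at {i}")
            if self.partner[j - 1] != i:
                raise StructureFormatError(
                    f"{self.id}: pair table not symmetric at ({i}, {j})"
                )
            if j > i:
                if j - i < MIN_HAIRPIN_LOOP + 1:
                    raise StructureFormatError(
                        f"{self.id}: pair ({i}, {j}) encloses a hairpin loop "
                        f"shorter than {MIN_HAIRPIN_LOOP}"
                    )
                duo = (seq[i - 1], seq[j - 1])
                if duo not in CANONICAL_PAIRS:
                    raise StructureFormatError(
                        f"{self.id}: non-canonical pair {duo[0]}-{duo[1]} "
                        f"at ({i}, {j})"
                    )
        # nestedness: closing positions must match the innermost open pair
        stack: list[int] = []
        for i in range(1, n + 1):
            j = self.partner[i - 1]
            if j > i:
                stack.append(j)
            elif 0 < j < i:
                if not stack or stack[-1] != i:
                    raise StructureFormatError(
                        f"{self.id}: pseudoknotted pair ({j}, {i})"
                    )
                stack.pop()

    # -- accessors -------------------------------------------------------

    @property
    def n(self) -> int:
        return len(self.sequence)

    @property
    def pairs(self) -> list[tuple[int, int]]:
        """All pairs (i, j) with i < j, sorted by i."""
        return [
            (i, self.partner[i - 1])
            for i in range(1, self.n + 1)
            if self.partner[i - 1] > i
        ]

    def partner_of(self, i: int) -> int:
        return self.partner[i - 1]

    def is_paired(self, i: int) -> bool:
        return self.partner[i - 1] != 0

    def base(self, i: int) -> str:
        return self.sequence[i - 1]

    @classmethod
    def from_pairs(
        cls, id: str, sequence: str, pairs: Iterable[tuple[int, int]]
    ) -> "SecondaryStructure":
        seq = _norm_seq(sequence)
        table = [0] * len(seq)
        for i, j in pairs:
            table[i - 1] = j
            table[j - 1] = i
        return cls(id, seq, tuple(table))


# -- FASTA ---------------------------------------------------------------


def parse_fasta(text: str) -> list[tuple[str, str]]:
    """Parse FASTA text into ordered (id, sequence) records.

    Sequences are uppercased and T is coerced to U.  Duplicate ids, empty
    records and characters outside the RNA alphabet raise
    :class:`StructureFormatError` naming the offending record.
    """
    if not text.strip():
        raise StructureFormatError("empty FASTA input")
    records: list[tuple[str, str]] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(StringIO(text), "fasta"):
        name = rec.id
        if not name:
            raise StructureFormatError("FASTA record with empty id")
        if name in seen:
            raise StructureFormatError(f"duplicate FASTA id {name!r}")
        seen.add(name)
        seq = _norm_seq(str(rec.seq))
        if not seq:
            raise StructureFormatError(f"FASTA record {name!r} has empty sequence")
        bad = set(seq) - RNA_ALPHABET
        if bad:
            raise StructureFormatError(
                f"FASTA record {name!r}: illegal characters {sorted(bad)}"
            )
        records.append((name, seq))
    if not records:
        raise StructureFormatError("no FASTA records found")
    return records


def write_fasta(records: Iterable[tuple[str, str]], width: int = 60) -> str:
    """Inverse of :func:`parse_fasta` on valid input."""
    out = []
    for name, seq in records:
        out.append(f">{name}")
        for k in range(0, len(seq), width):
            out.append(seq[k : k + width])
    return "\n".join(out) + "\n"


# -- dot-bracket ---------------------------------------------------------


def parse_dotbracket(
    id: str,
    sequence: str,
    structure_line: str,
    *,
    coerce_noncanonical: bool = False,
) -> SecondaryStructure:
    """Build a validated structure from a Vienna dot-bracket line.

    Only ``.()`` are accepted (nested structures need no extended bracket
    dialects).  Annotated non-canonical pairs — including any pair touching
    an N — are an error by default; with ``coerce_noncanonical=True`` they
    are demoted to unpaired, which matches their status in the
    minimum-free-energy sense.
    """
    seq = _norm_seq(sequence)
    struct = structure_line.strip()
    if len(struct) != len(seq):
        raise StructureFormatError(
            f"{id}: structure length {len(struct)} != sequence length {len(seq)}"
        )
    table = [0] * len(seq)
    stack: list[int] = []
    for col, ch in enumerate(struct, start=1):
        if ch == "(":
            stack.append(col)
        elif ch == ")":
            if not stack:
                raise StructureFormatError(f"{id}: unbalanced ')' at column {col}")
            i = stack.pop()
            table[i - 1] = col
            table[col - 1] = i
        elif ch != ".":
            raise StructureFormatError(f"{id}: illegal structure character {ch!r}")
    if stack:
        raise StructureFormatError(f"{id}: unbalanced '(' at column {stack[-1]}")
    for i in range(1, len(seq) + 1):
        j = table[i - 1]
        if j > i and (seq[i - 1], seq[j - 1]) not in CANONICAL_PAIRS:
            if coerce_noncanonical:
                table[i - 1] = 0
                table[j - 1] = 0
            else:
                raise StructureFormatError(
                    f"{id}: non-canonical pair {seq[i - 1]}-{seq[j - 1]} "
                    f"at ({i}, {j}); pass coerce_noncanonical=True to demote"
                )
    return SecondaryStructure(id, seq, tuple(table))


def write_dotbracket(structure: SecondaryStructure) -> str:
    """Render the dot-bracket line of a structure."""
    out = ["."] * structure.n
    for i, j in structure.pairs:
        out[i - 1] = "("
        out[j - 1] = ")"
    return "".join(out)


def parse_vienna(text: str, **kwargs) -> list[SecondaryStructure]:
    """Parse Vienna triplet records: ``>id``, sequence line, structure line."""
    lines = [ln.strip() for ln in text.splitlines() if ln.strip()]
    if not lines:
        raise StructureFormatError("empty dot-bracket input")
    structures = []
    k = 0
    while k < len(lines):
        if not lines[k].startswith(">"):
            raise StructureFormatError(
                f"expected '>' header, got {lines[k][:30]!r}"
            )
        if k + 2 >= len(lines):
            raise StructureFormatError(f"truncated record {lines[k][:30]!r}")
        name = lines[k][1:].split()[0]
        structures.append(parse_dotbracket(name, lines[k + 1], lines[k + 2], **kwargs))
        k += 3
    return structures


def write_vienna(structures: Iterable[SecondaryStructure]) -> str:
    out = []
    for ss in structures:
        out += [f">{ss.id}", ss.sequence, write_dotbracket(ss)]
    return "\n".join(out) + "\n"


# -- CT (connectivity table) ---------------------------------------------


def parse_ct(text: str, **kwargs) -> list[SecondaryStructure]:
    """Parse one or more concatenated CT records (RNAstructure dialect).

    Each record: a header line (length, then title) followed by one line per
    nucleotide with columns index, base, previous, next, partner (0 =
    unpaired), natural index.
    """
    lines = [ln for ln in text.splitlines() if ln.strip()]
    if not lines:
        raise StructureFormatError("empty CT input")
    structures = []
    k = 0
    count = 0
    while k < len(lines):
        head = lines[k].split()
        try:
            n = int(head[0])
        except (ValueError, IndexError):
            raise StructureFormatError(f"CT header not parseable: {lines[k][:40]!r}")
        title = head[1] if len(head) > 1 else f"ct_{count}"
        if len(lines) - (k + 1) < n:
            raise StructureFormatError(f"CT record {title!r} truncated")
        bases = []
        table = [0] * n
        for row in range(1, n + 1):
            cols = lines[k + row].split()
            if len(cols) < 6:
                raise StructureFormatError(
                    f"CT record {title!r}: line {row} has {len(cols)} columns"
                )
            idx = int(cols[0])
            if idx != row:
                raise StructureFormatError(
                    f"CT record {title!r}: index gap at line {row} (got {idx})"
                )
            bases.append(cols[1])
            table[row - 1] = int(cols[4])
        seq = _norm_seq("".join(bases))
        # explicit symmetry check for a clearer error than the validator's
        for i in range(1, n + 1):
            j = table[i - 1]
            if j and (not 1 <= j <= n or table[j - 1] != i):
                raise StructureFormatError(
                    f"CT record {title!r}: partner({i})={j} but "
                    f"partner({j})={table[j - 1] if 1 <= j <= n else '?'}"
                )
        coerce = kwargs.get("coerce_noncanonical", False)
        if coerce:
            for i in range(1, n + 1):
                j = table[i - 1]
                if j > i and (seq[i - 1], seq[j - 1]) not in CANONICAL_PAIRS:
                    table[i - 1] = 0
                    table[j - 1] = 0
        structures.append(SecondaryStructure(title, seq, tuple(table)))
        k += n + 1
        count += 1
    return structures


def write_ct(structures: Iterable[SecondaryStructure]) -> str:
    out = []
    for ss in structures:
        out.append(f"{ss.n}\t{ss.id}")
        for i in range(1, ss.n + 1):
            nxt = i + 1 if i < ss.n else 0
            out.append(
                f"{i}\t{ss.base(i)}\t{i - 1}\t{nxt}\t{ss.partner_of(i)}\t{i}"
            )
    return "\n".join(out) + "\n"


# -- file-level readers (plain or gzip) ----------------------------------


def _read_text(path: str | Path) -> str:
    p = Path(path)
    if p.suffix == ".gz":
        with gzip.open(p, "rt") as fh:
            return fh.read()
    return p.read_text()


def read_fasta(path: str | Path) -> list[tuple[str, str]]:
    return parse_fasta(_read_text(path))


def read_vienna(path: str | Path, **kwargs) -> list[SecondaryStructure]:
    return parse_vienna(_read_text(path), **kwargs)


def read_ct(path: str | Path, **kwargs) -> list[SecondaryStructure]:
    return parse_ct(_read_text(path), **kwargs)


def read_structures(
    path: str | Path, format: str = "dotbracket", **kwargs
) -> list[SecondaryStructure]:
    """Dispatch on ``format`` in {"dotbracket", "ct"}."""
    if format == "dotbracket":
        return read_vienna(path, **kwargs)
    if format == "ct":
        return read_ct(path, **kwargs)
    raise ValueError(f"unknown structure format {format!r}")
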