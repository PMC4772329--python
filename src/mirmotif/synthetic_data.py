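"""Seeded generation of miRBase-like stem-loops with known ground truth.

The generator builds each precursor outside-in as a single nested hairpin:
optional dangling ends, then alternating helix runs and two-sided loops
(5'/3' bulges and internal loops drawn from configurable frequency tables,
by default proportional to the reference corpus counts), terminated by a
hairpin loop, with a mature-miRNA span planted on one arm.  Because the
structure is assembled from explicit tokens, the full loop inventory, the
mature coordinates and the structural context of both processing sites are
known by construction — independently of the extraction code they are used
to test.

Everything is driven by one seeded NumPy generator (PCG64), so a fixed
spec yields byte-identical corpora.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from . import reference
from .corpus_stats import MotifTable
from .motif_core import (
    BULGE3,
    BULGE5,
    HAIRPIN,
    INTERNAL,
    MULTIBRANCH,
    parse_motif,
)
from .structure_io import SecondaryStructure, write_fasta, write_vienna

RNA_LETTERS = ("A", "C", "G", "U")

#: per-position structural state labels used in ground truth
ST_EXTERIOR = "terminal"
ST_PAIRED = "paired"


class GeneratorError(RuntimeError):
    pass


@dataclass
class GeneratorSpec:
    """Study conditions for a synthetic corpus.

    Defaults emulate the reference human pre-miRNA corpus: loop keys and
    loop types weighted by the published frequency tables, 2–6 interior
    loops per stem (the real corpus carries 1–14 motifs per precursor,
    about four on average), helix runs of 2–6 pairs, hairpin loops of 4–9
    nt, mature spans of 20–23 nt placed on either arm with equal
    probability, and helix pairs drawn GC:AU:GU = 2:2:1 so wobble closing
    pairs are exercised.
    """

    n_precursors: int = 100
    stem_pair_run: tuple[int, int] = (2, 6)
    loops_per_stem: tuple[int, int] = (2, 6)
    hairpin_loop_size: tuple[int, int] = (4, 9)
    mature_length: tuple[int, int] = (20, 23)
    arm_probability: float = 0.5
    dangling_end: tuple[int, int] = (1, 4)
    motif_weights: dict[str, dict[str, float]] = field(
        default_factory=reference.default_motif_weights
    )
    motif_type_weights: dict[str, float] = field(
        default_factory=reference.default_type_weights
    )
    helix_pair_weights: dict[str, float] = field(
        default_factory=lambda: {"GC": 2.0, "AU": 2.0, "GU": 1.0}
    )
    include_multibranch: bool = False
    id_prefix: str = "syn"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_precursors < 1:
            raise ValueError("n_precursors must be >= 1")
        for name in (
            "stem_pair_run",
            "loops_per_stem",
            "hairpin_loop_size",
            "mature_length",
            "dangling_end",
        ):
            lo, hi = getattr(self, name)
            if lo > hi or lo < 0:
                raise ValueError(f"empty or negative range for {name}: ({lo}, {hi})")
        if self.stem_pair_run[0] < 1:
            raise ValueError("stem_pair_run minimum must be >= 1")
        if self.hairpin_loop_size[0] < 3:
            raise ValueError("hairpin loops need >= 3 nucleotides")
        if self.mature_length[0] < 10:
            raise ValueError("mature length must be >= 10")
        if not 0.0 <= self.arm_probability <= 1.0:
            raise ValueError("arm_probability must be in [0, 1]")
        for mtype, table in self.motif_weights.items():
            if any(w < 0 for w in table.values()):
                raise ValueError(f"negative weight in motif_weights[{mtype!r}]")
        if any(w < 0 for w in self.motif_type_weights.values()):
            raise ValueError("negative motif type weight")
        if not self.helix_pair_weights or any(
            w < 0 for w in self.helix_pair_weights.values()
        ) or sum(self.helix_pair_weights.values()) == 0:
            raise ValueError("helix_pair_weights needs a positive weight")


@dataclass(frozen=True)
class PlantedElement:
    """One loop planted by the generator, with its expected names."""

    kind: str
    unpaired_key: str
    motif_key: str
    size_class: str
    pos_outer_5p: int
    pos_outer_3p: int


@dataclass(frozen=True)
class GroundTruth:
    """Everything the generator knows about one emitted precursor."""

    precursor_id: str
    elements: tuple[PlantedElement, ...]
    mature_id: str
    mature_seq: str
    mature_start: int
    mature_end: int
    arm: str
    start_context: str
    end_context: str


# -- sampling helpers ----------------------------------------------------


def _weighted_choice(rng: np.random.Generator, table: dict[str, float]) -> str:
    keys = list(table)
    weights = np.array([table[k] for k in keys], dtype=float)
    total = weights.sum()
    if total <= 0:
        raise GeneratorError("all weights zero")
    return keys[rng.choice(len(keys), p=weights / total)]


def _rand_int(rng: np.random.Generator, lohi: tuple[int, int]) -> int:
    return int(rng.integers(lohi[0], lohi[1] + 1))


def _rand_letters(rng: np.random.Generator, n: int) -> str:
    return "".join(RNA_LETTERS[k] for k in rng.integers(0, 4, size=n))


def _sample_pair(rng: np.random.Generator, spec: GeneratorSpec) -> tuple[str, str]:
    cls = _weighted_choice(rng, spec.helix_pair_weights)
    duo = cls if rng.random() < 0.5 else cls[::-1]
    return duo[0], duo[1]


@dataclass
class _Loop:
    kind: str
    s1: str
    s2: str
    forced_outer: str | None = None  # "XY": b5, b3 of the outer closing pair
    forced_inner: str | None = None


def _sample_loop(spec: GeneratorSpec, rng: np.random.Generator) -> _Loop:
    weights = {
        t: w for t, w in spec.motif_type_weights.items() if w > 0
    }
    mtype = _weighted_choice(rng, weights)
    key = _weighted_choice(rng, spec.motif_weights[mtype])
    if "(" in key:
        # motif-level key: sides and closing pairs both prescribed
        m = parse_motif(key)
        if m.kind not in (BULGE5, BULGE3, INTERNAL):
            raise GeneratorError(f"cannot plant motif key of kind {m.kind}")
        return _Loop(m.kind, m.sides[0], m.sides[1], m.pairs[0], m.pairs[1])
    if mtype == INTERNAL:
        s1, _, s2 = key.partition("/")
        if not s1 or not s2:
            raise GeneratorError(f"bad internal loop key {key!r}")
        return _Loop(INTERNAL, s1, s2)
    if mtype == BULGE5:
        return _Loop(BULGE5, key, "")
    if mtype == BULGE3:
        return _Loop(BULGE3, "", key)
    raise GeneratorError(f"cannot plant loops of type {mtype!r}")


def _loop_names(
    loop: _Loop, outer: tuple[str, str], inner: tuple[str, str]
) -> tuple[str, str, str]:
    """(unpaired_key, motif_key, size_class) from planted letters."""
    motif = (
        f"({outer[0]}{outer[1]})"
        f"{loop.s1 or '-'}/{loop.s2 or '-'}"
        f"({inner[0]}{inner[1]})"
    )
    if loop.kind == INTERNAL:
        return f"{loop.s1}/{loop.s2}", motif, f"{len(loop.s1)}×{len(loop.s2)}"
    bulged = loop.s1 or loop.s2
    return bulged, motif, str(len(bulged))


# -- single-hairpin assembly ---------------------------------------------


def _build_hairpin(
    spec: GeneratorSpec, rng: np.random.Generator, precursor_id: str
) -> tuple[SecondaryStructure, GroundTruth]:
    type_total = sum(max(w, 0.0) for w in spec.motif_type_weights.values())
    n_loops = _rand_int(rng, spec.loops_per_stem) if type_total > 0 else 0
    loops = [_sample_loop(spec, rng) for _ in range(n_loops)]
    n_helices = n_loops + 1
    helix_lens = [_rand_int(rng, spec.stem_pair_run) for _ in range(n_helices)]

    # a helix of one pair cannot carry two conflicting forced boundary pairs
    for i in range(1, n_helices):
        inner_force = loops[i - 1].forced_inner
        outer_force = loops[i].forced_outer if i < n_loops else None
        if (
            helix_lens[i] == 1
            and inner_force
            and outer_force
            and inner_force != outer_force
        ):
            helix_lens[i] = 2

    hp_len = _rand_int(rng, spec.hairpin_loop_size)
    hp_letters = _rand_letters(rng, hp_len)
    d5 = _rand_int(rng, spec.dangling_end)
    d3 = _rand_int(rng, spec.dangling_end)
    mature_len = _rand_int(rng, spec.mature_length)
    arm = "5p" if rng.random() < spec.arm_probability else "3p"

    sum_s1 = sum(len(lp.s1) for lp in loops)
    sum_s2 = sum(len(lp.s2) for lp in loops)
    if arm == "5p":
        region_len = d5 + sum(helix_lens) + sum_s1
    else:
        region_len = sum_s2 + sum(helix_lens) + d3
    if region_len < mature_len:
        helix_lens[0] += mature_len - region_len

    helix_pairs: list[list[tuple[str, str]]] = [
        [_sample_pair(rng, spec) for _ in range(h)] for h in helix_lens
    ]
    for i, lp in enumerate(loops):
        if lp.forced_outer:
            helix_pairs[i][-1] = (lp.forced_outer[0], lp.forced_outer[1])
        if lp.forced_inner:
            helix_pairs[i + 1][0] = (lp.forced_inner[0], lp.forced_inner[1])

    n_total = (
        d5
        + 2 * sum(helix_lens)
        + sum_s1
        + sum_s2
        + hp_len
        + d3
    )
    seq = [""] * (n_total + 1)  # 1-based
    partner = [0] * (n_total + 1)
    state = [ST_EXTERIOR] * (n_total + 1)  # index 0 unused

    for k, ch in enumerate(_rand_letters(rng, d5), start=1):
        seq[k] = ch
    for k, ch in enumerate(_rand_letters(rng, d3), start=n_total - d3 + 1):
        seq[k] = ch

    elements: list[PlantedElement] = []
    left = d5 + 1
    right = n_total - d3
    helix_left_start: list[int] = []
    for i in range(n_helices):
        helix_left_start.append(left)
        for t, (b5, b3) in enumerate(helix_pairs[i]):
            p, q = left + t, right - t
            seq[p], seq[q] = b5, b3
            partner[p], partner[q] = q, p
            state[p] = state[q] = ST_PAIRED
        left += helix_lens[i]
        right -= helix_lens[i]
        if i < n_loops:
            lp = loops[i]
            for t, ch in enumerate(lp.s1):
                seq[left + t] = ch
                state[left + t] = lp.kind
            for t, ch in enumerate(lp.s2):
                seq[right - len(lp.s2) + 1 + t] = ch
                state[right - len(lp.s2) + 1 + t] = lp.kind
            left += len(lp.s1)
            right -= len(lp.s2)
    if right - left + 1 != hp_len:
        raise GeneratorError("assembly arithmetic failed")  # pragma: no cover
    for t, ch in enumerate(hp_letters):
        seq[left + t] = ch
        state[left + t] = HAIRPIN
    hp_start, hp_end = left, right

    # planted loop elements with coordinates and expected names
    for i, lp in enumerate(loops):
        outer_p = helix_left_start[i] + helix_lens[i] - 1
        unp, motif, size = _loop_names(
            lp, helix_pairs[i][-1], helix_pairs[i + 1][0]
        )
        elements.append(
            PlantedElement(lp.kind, unp, motif, size, outer_p, partner[outer_p])
        )
    g_p = helix_left_start[-1] + helix_lens[-1] - 1
    g5, g3 = helix_pairs[-1][-1]
    elements.append(
        PlantedElement(
            HAIRPIN,
            hp_letters,
            f"({g5}{g3}){hp_letters}",
            f"L-{hp_len}",
            g_p,
            partner[g_p],
        )
    )

    # mature span entirely inside one arm
    if arm == "5p":
        lo, hi = 1, hp_start - 1
    else:
        lo, hi = hp_end + 1, n_total
    start = int(rng.integers(lo, hi - mature_len + 2))
    end = start + mature_len - 1
    sequence = "".join(seq[1:])
    mature_seq = sequence[start - 1 : end]
    if sequence.find(mature_seq) != start - 1:
        raise _Retry  # mature span is not the first occurrence; rebuild

    ctx = {pos: state[pos] for pos in (start, end)}
    structure = SecondaryStructure(precursor_id, sequence, tuple(partner[1:]))
    truth = GroundTruth(
        precursor_id,
        tuple(elements),
        f"{precursor_id}-mature",
        mature_seq,
        start,
        end,
        arm,
        ctx[start],
        ctx[end],
    )
    return structure, truth


class _Retry(Exception):
    pass


def _build_multibranch(
    spec: GeneratorSpec, rng: np.random.Generator, precursor_id: str
) -> tuple[SecondaryStructure, GroundTruth]:
    """A two-hairpin precursor exercising multibranch naming.

    Layout: dangle, external helix A, run r0, branch B (helix + hairpin),
    run r1, branch C (helix + hairpin), run r2, close of A, dangle.  The
    mature span sits in the 5' strand of helix A, so both its sites are
    paired and the arm is 5p.
    """
    mature_len = _rand_int(rng, spec.mature_length)
    d5 = _rand_int(rng, spec.dangling_end)
    d3 = _rand_int(rng, spec.dangling_end)
    hA = max(_rand_int(rng, spec.stem_pair_run), mature_len)
    hB = _rand_int(rng, spec.stem_pair_run)
    hC = _rand_int(rng, spec.stem_pair_run)
    lpB = _rand_int(rng, spec.hairpin_loop_size)
    lpC = _rand_int(rng, spec.hairpin_loop_size)
    runs = [
        _rand_letters(rng, _rand_int(rng, (1, 3))) for _ in range(3)
    ]
    pairsA = [_sample_pair(rng, spec) for _ in range(hA)]
    pairsB = [_sample_pair(rng, spec) for _ in range(hB)]
    pairsC = [_sample_pair(rng, spec) for _ in range(hC)]
    loopB = _rand_letters(rng, lpB)
    loopC = _rand_letters(rng, lpC)

    n_total = d5 + 2 * hA + sum(len(r) for r in runs) + 2 * hB + lpB + 2 * hC + lpC + d3
    seq = [""] * (n_total + 1)
    partner = [0] * (n_total + 1)
    state = [ST_EXTERIOR] * (n_total + 1)

    cur = 1
    for ch in _rand_letters(rng, d5):
        seq[cur] = ch
        cur += 1
    a_left = cur
    a_right_end = n_total - d3
    for t, (b5, b3) in enumerate(pairsA):
        p, q = a_left + t, a_right_end - t
        seq[p], seq[q] = b5, b3
        partner[p], partner[q] = q, p
        state[p] = state[q] = ST_PAIRED
    cur += hA

    def _mb_run(cur: int, letters: str) -> int:
        for ch in letters:
            seq[cur] = ch
            state[cur] = MULTIBRANCH
            cur += 1
        return cur

    def _branch(cur: int, pairs, loop_letters) -> tuple[int, int]:
        h = len(pairs)
        left = cur
        right = cur + 2 * h + len(loop_letters) - 1
        for t, (b5, b3) in enumerate(pairs):
            p, q = left + t, right - t
            seq[p], seq[q] = b5, b3
            partner[p], partner[q] = q, p
            state[p] = state[q] = ST_PAIRED
        for t, ch in enumerate(loop_letters):
            pos = left + h + t
            seq[pos] = ch
            state[pos] = HAIRPIN
        return right + 1, left

    cur = _mb_run(cur, runs[0])
    cur, b_left = _branch(cur, pairsB, loopB)
    cur = _mb_run(cur, runs[1])
    cur, c_left = _branch(cur, pairsC, loopC)
    cur = _mb_run(cur, runs[2])
    if cur != a_right_end - hA + 1:
        raise GeneratorError("multibranch assembly arithmetic failed")  # pragma: no cover
    for t, ch in enumerate(_rand_letters(rng, d3), start=n_total - d3 + 1):
        seq[t] = ch

    x5, x3 = pairsA[-1]
    bB5, bB3 = pairsB[0]
    bC5, bC3 = pairsC[0]
    ext_p = a_left + hA - 1
    mb_motif = (
        f"({x5}{x3}){runs[0]}({bB5}{bB3}){runs[1]}"
        f"({bC5}{bC3}){runs[2]}({x3}{x5})"
    )
    elements = [
        PlantedElement(
            MULTIBRANCH,
            "/".join(r or "-" for r in runs),
            mb_motif,
            "MB",
            ext_p,
            partner[ext_p],
        ),
        PlantedElement(
            HAIRPIN,
            loopB,
            f"({pairsB[-1][0]}{pairsB[-1][1]}){loopB}",
            f"L-{lpB}",
            b_left + hB - 1,
            partner[b_left + hB - 1],
        ),
        PlantedElement(
            HAIRPIN,
            loopC,
            f"({pairsC[-1][0]}{pairsC[-1][1]}){loopC}",
            f"L-{lpC}",
            c_left + hC - 1,
            partner[c_left + hC - 1],
        ),
    ]
    start = a_left
    end = start + mature_len - 1
    sequence = "".join(seq[1:])
    mature_seq = sequence[start - 1 : end]
    if sequence.find(mature_seq) != start - 1:
        raise _Retry
    structure = SecondaryStructure(precursor_id, sequence, tuple(partner[1:]))
    truth = GroundTruth(
        precursor_id,
        tuple(elements),
        f"{precursor_id}-mature",
        mature_seq,
        start,
        end,
        "5p",
        state[start],
        state[end],
    )
    return structure, truth


def generate_precursor(
    spec: GeneratorSpec,
    rng: np.random.Generator,
    index: int = 0,
    multibranch: bool = False,
) -> tuple[SecondaryStructure, GroundTruth]:
    """Generate one precursor with its ground truth.

    Resamples internally (fresh randomness from ``rng``) in the rare event
    that the planted mature span is not the first occurrence of its
    sequence on the precursor, so emitted records are never inconsistent.
    """
    precursor_id = f"{spec.id_prefix}-{index:04d}"
    builder = _build_multibranch if multibranch else _build_hairpin
    for _attempt in range(50):
        try:
            return builder(spec, rng, precursor_id)
        except _Retry:
            continue
    raise GeneratorError(
        f"could not plant a uniquely mapping mature span for {precursor_id}"
    )  # pragma: no cover


@dataclass
class SyntheticCorpus:
    """A generated corpus plus its complete planted ground truth."""

    spec: GeneratorSpec
    structures: list[SecondaryStructure]
    ground_truths: list[GroundTruth]

    def mature_records(self) -> list[tuple[str, str, str]]:
        """(mature_id, precursor_id, sequence) triples for site analysis."""
        return [
            (gt.mature_id, gt.precursor_id, gt.mature_seq)
            for gt in self.ground_truths
        ]

    def planted_records(self) -> pd.DataFrame:
        """Planted elements in motif-record layout (one row per loop)."""
        rows = [
            {
                "precursor_id": gt.precursor_id,
                "motif_type": el.kind,
                "size_class": el.size_class,
                "unpaired_key": el.unpaired_key,
                "motif_key": el.motif_key,
                "pos_outer_5p": el.pos_outer_5p,
                "pos_outer_3p": el.pos_outer_3p,
            }
            for gt in self.ground_truths
            for el in gt.elements
        ]
        return pd.DataFrame(rows)

    def planted_counts(self, key_level: str = "motif") -> MotifTable:
        col = "motif_key" if key_level == "motif" else "unpaired_key"
        counts: dict[tuple[str, str], int] = {}
        for gt in self.ground_truths:
            for el in gt.elements:
                key = (el.kind, getattr(el, col))
                counts[key] = counts.get(key, 0) + 1
        return MotifTable.from_counts(counts, key_level=key_level)

    def write(self, outdir: str | Path) -> dict[str, Path]:
        """Emit the corpus in the dialects the pipeline consumes."""
        out = Path(outdir)
        out.mkdir(parents=True, exist_ok=True)
        paths = {
            "precursors_fasta": out / "precursors.fasta",
            "structures": out / "structures.dbn",
            "matures_fasta": out / "matures.fasta",
            "ground_truth": out / "ground_truth.tsv",
            "mature_truth": out / "mature_truth.tsv",
            "planted_counts": out / "planted_counts.tsv",
            "metadata": out / "metadata.json",
        }
        paths["precursors_fasta"].write_text(
            write_fasta((ss.id, ss.sequence) for ss in self.structures)
        )
        paths["structures"].write_text(write_vienna(self.structures))
        paths["matures_fasta"].write_text(
            write_fasta(
                (gt.mature_id, gt.mature_seq) for gt in self.ground_truths
            )
        )
        self.planted_records().to_csv(paths["ground_truth"], sep="\t", index=False)
        pd.DataFrame(
            [
                {
                    "precursor_id": gt.precursor_id,
                    "mature_id": gt.mature_id,
                    "mature_seq": gt.mature_seq,
                    "start": gt.mature_start,
                    "end": gt.mature_end,
                    "arm": gt.arm,
                    "start_context": gt.start_context,
                    "end_context": gt.end_context,
                }
                for gt in self.ground_truths
            ]
        ).to_csv(paths["mature_truth"], sep="\t", index=False)
        self.planted_counts("motif").to_tsv(paths["planted_counts"])
        meta = dataclasses.asdict(self.spec)
        meta["rng"] = "numpy.random.Generator(PCG64)"
        paths["metadata"].write_text(json.dumps(meta, indent=2, default=str))
        return paths


def generate_corpus(spec: GeneratorSpec) -> SyntheticCorpus:
    """Generate ``spec.n_precursors`` precursors from ``spec.seed``."""
    rng = np.random.default_rng(spec.seed)
    structures = []
    truths = []
    for k in range(spec.n_precursors):
        mb = spec.include_multibranch and k == 0
        ss, gt = generate_precursor(spec, rng, index=k, multibranch=mb)
        structures.append(ss)
        truths.append(gt)
    return SyntheticCorpus(spec, structures, truths)
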