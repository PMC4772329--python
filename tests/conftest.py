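"""Shared fixtures: hand-built example structures, an independent random
nested-structure sampler, and small seeded synthetic corpora."""

from __future__ import annotations

import random

import pytest

import mirmotif as mm

CANONICAL = [("A", "U"), ("U", "A"), ("G", "C"), ("C", "G"), ("G", "U"), ("U", "G")]


def random_nested_structure(rng: random.Random, ident: str) -> mm.SecondaryStructure:
    """Sample a random pseudoknot-free structure, independently of the
    package's own generator (length-1 helices, 3-nt hairpin loops, stacked
    faces, multibranch loops and multiple top-level stems all occur)."""

    def letters(n: int) -> str:
        return "".join(rng.choice("ACGU") for _ in range(n))

    def stem(depth: int) -> tuple[str, str]:
        h = rng.randint(1, 4)
        roll = rng.random()
        if depth >= 3 or roll < 0.35:
            loop = letters(rng.randint(3, 8))
            core_seq, core_db = loop, "." * len(loop)
        elif roll < 0.85:
            l1, l2 = rng.randint(0, 3), rng.randint(0, 3)
            s, d = stem(depth + 1)
            core_seq = letters(l1) + s + letters(l2)
            core_db = "." * l1 + d + "." * l2
        else:
            seqs, dbs = [], []
            for k in range(rng.randint(2, 3)):
                run = letters(rng.randint(0, 2))
                s, d = stem(depth + 1)
                seqs += [run, s]
                dbs += ["." * len(run), d]
            tail = letters(rng.randint(0, 2))
            core_seq = "".join(seqs) + tail
            core_db = "".join(dbs) + "." * len(tail)
        pairs = [rng.choice(CANONICAL) for _ in range(h)]
        seq = (
            "".join(p[0] for p in pairs)
            + core_seq
            + "".join(p[1] for p in reversed(pairs))
        )
        db = "(" * h + core_db + ")" * h
        return seq, db

    d5, d3 = letters(rng.randint(0, 4)), letters(rng.randint(0, 3))
    seq, db = stem(0)
    if rng.random() < 0.2:  # a second top-level stem with an exterior linker
        mid = letters(rng.randint(1, 3))
        s2, d2 = stem(0)
        seq, db = seq + mid + s2, db + "." * len(mid) + d2
    return mm.parse_dotbracket(ident, d5 + seq + d3, "." * len(d5) + db + "." * len(d3))


@pytest.fixture(scope="session")
def random_structures() -> list[mm.SecondaryStructure]:
    rng = random.Random(20240117)
    return [random_nested_structure(rng, f"rand-{k:04d}") for k in range(400)]


@pytest.fixture(scope="session")
def small_corpus() -> mm.SyntheticCorpus:
    spec = mm.GeneratorSpec(n_precursors=60, seed=7, include_multibranch=True)
    return mm.generate_corpus(spec)


# -- brute-force decomposition oracle ------------------------------------


def oracle_elements(ss: mm.SecondaryStructure):
    """Quadratic face walker: for every pair (i, j), collect the positions
    of (i+1 .. j-1) not covered by any nested pair and the maximal nested
    pairs, then classify by branch count and side occupancy.  Returns a set
    of (kind, closing_pairs, unpaired_positions) triples, exterior included
    as ("exterior", (), positions)."""
    pairs = ss.pairs

    def face(i: int, j: int):
        inner = [(a, b) for (a, b) in pairs if i < a and b < j]
        children = sorted(
            (a, b)
            for (a, b) in inner
            if not any(c < a and b < d for (c, d) in inner)
        )
        acc = tuple(
            k
            for k in range(i + 1, j)
            if not ss.is_paired(k) and not any(a <= k <= b for (a, b) in inner)
        )
        return children, acc

    out = set()
    for i, j in pairs:
        children, acc = face(i, j)
        if not children:
            out.add(("hairpin", ((i, j),), acc))
        elif len(children) == 1:
            (a, b) = children[0]
            side1 = tuple(k for k in acc if k < a)
            side2 = tuple(k for k in acc if k > b)
            if not side1 and not side2:
                continue
            if side1 and side2:
                kind = "internal"
            elif side1:
                kind = "bulge5"
            else:
                kind = "bulge3"
            out.add((kind, ((i, j), (a, b)), acc))
        else:
            out.add(("multibranch", ((i, j), *children), acc))
    _children, acc = face(0, ss.n + 1)
    if acc:
        out.add(("exterior", (), acc))
    return out


def element_signature(el: mm.LoopElement):
    return (el.kind, el.closing_pairs, tuple(el.unpaired_positions))
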