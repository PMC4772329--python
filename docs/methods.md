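# Methods

## Scope and model

`mirmotif` analyses *given* secondary structures. A structure is a
pseudoknot-free pair table over {A, C, G, U, N}: only canonical
Watson–Crick (AU/UA, GC/CG) and wobble (GU/UG) pairs count as paired,
every pair (i, j) satisfies j − i ≥ 4 (hairpin loops of at least three
nucleotides), and N may appear in the sequence but never in a pair. These
are the conventions of minimum-free-energy folding output, the standard
source of pre-miRNA structures; prediction itself, suboptimal ensembles
and pseudoknots are out of scope. Pseudoknots are rejected rather than
broken — MFE output is nested by construction, so a crossing pair in the
input signals a malformed file, not a structure to repair. Annotated
non-canonical pairs are an error by default; an explicit
`coerce_noncanonical` option demotes them to unpaired, which is their
status in the MFE sense. Exactly one structure per precursor is accepted,
which sidesteps tie-breaking among equal-energy folds.

All coordinates are 1-based and inclusive on the precursor and are
inherited unchanged by every downstream table.

## Loop decomposition

For each closing pair the enclosed face is scanned once: unpaired runs
and maximal child pairs interleave in 5'→3' order. A face with no children
is a hairpin loop; with one child it is a stack (no element), a bulge
(one empty side) or an internal loop (both sides occupied); with two or
more children it is a multibranch loop. The exterior region (dangling
ends and any linker between top-level stems) is represented but flagged
non-motif and excluded from every count. Decomposition is a partition:
each position belongs to exactly one helix pair, one loop element's
unpaired run, or the exterior. The test suite checks equivalence against
an independent quadratic face-walking oracle on over a thousand random
nested structures, including shapes the generator never emits.

Bulge orientation (5' vs 3') is defined by the strand, relative to the
hairpin loop the stem leads to, that carries the unpaired run. In a nested
structure every position on the left strand between the two closing pairs
is 5' of everything deeper in the stem, so orientation reduces to which
side of the face is occupied — this also generalises deterministically to
multibranch-bearing structures (descending toward the 5'-most reachable
hairpin gives the same answer).

## Nomenclature

Every pair at positions (p, q), p < q, renders as `(b[p]b[q])` — both
letters, because GU wobble makes one letter ambiguous, and the 5'
nucleotide first. This single rendering rule is applied uniformly to
outer, inner and branch pairs; the only reversed rendering is the
terminal repeat of a multibranch loop's external pair. Two-sided loops
render outer pair, side 1, `/`, side 2, inner pair with `-` for an empty
side; hairpins render their single closing pair then the loop sequence.

Key levels:

* **unpaired** — loop nucleotides only. For bulges this is the bulged
  run alone (orientation is already carried by the motif type), for
  internal loops `s1/s2`, for multibranch loops the runs joined by `/`.
* **motif** — the full parenthesised form above. This level is a formal
  grammar; `parse_motif`/`format` are exact inverses, which the reference
  tables and site-uniqueness matching rely on.
* **extended** — the motif plus the first non-nearest-neighbour pair of
  each closing helix (the next stacked pair outward of the outer pair,
  inward of the inner pair), with a literal `NA` where the helix has only
  one pair or the neighbour is another loop. The published corpus never
  shows the missing-neighbour case, so the placeholder is this package's
  choice.

Size classes: bulges by length ("1", "2", …), internal loops "a×b" in
reading order (side 1 × side 2), hairpins "L-n", multibranch "MB".

The orientation flip `flip((XY)s1/s2(WZ)) = (ZW)s2/s1(YX)` is an
involution, maps bulge5 ↔ bulge3, and conserves the unpaired nucleotide
multiset; it is defined only for two-sided loops.

## Statistics

The pooled two-proportion Z-score (see README for the formula) is
computed in full precision with no continuity correction; rounding
half-away-from-zero to two decimals happens only at presentation. When
the pooled proportion is 0 or 1 the statistic is undefined and is
reported as z = 0 with a degenerate flag. |Z| > 2 is the significance
criterion for frequency orderings; star annotations in corpus
comparisons use the exact two-sided normal tiers 0.05/0.01/0.001 because
figures report p-value levels rather than the |Z| > 2 rule.

Within-corpus comparisons use the motif-type total as sample size for
both sides (3860 internal loops, 1089 5' bulges, 924 3' bulges in the
reference corpus); this is the convention under which the published
pairwise 1×1 matrix and the cross-category A-bulge Z of 2.08 are
reproduced exactly. The reference corpus's companion text total of 922
3' bulges is inconsistent with its own printed fractions and is not
used. Two cells of the published 1×1 matrix carry sign typos (they
contradict antisymmetry); the frozen test fixture corrects the signs and
keeps the printed magnitudes.

Frequency grouping is a greedy scan over labels in descending count: the
next label joins the current group iff its minimum |z| against the
group's members is ≤ 2, else it opens a new group; afterwards all
cross-adjacent-group pairs are verified at |z| > 2, with violations
reported as warnings. The published criterion states group membership but
not an algorithm; greedy-by-descending-count is the deterministic
procedure that reproduces the published three-group partition of the 1×1
loops.

Size summaries pool internal-loop mirror classes (a×b with b×a) — the
published tables pool 1×2 with 2×1; pooling all mirrors is the consistent
generalisation. Long tails pool into "others" above configurable cutoffs
(bulges > 4 nt, internal-loop side > 3, hairpins > 9 nt). Closing-pair
preference counts pool AU/UA, GC/CG and GU/UG into one class per side.
No multiple-testing correction is applied anywhere, deliberately matching
the analysis this package implements.

## Processing sites

Mature miRNAs are mapped by exact substring search (after T→U
normalisation, minimum 10 nt); miRBase matures are exact subsequences of
their hairpins, and fuzzy matching would silently shift sites. The first
and last mature nucleotides are the start and end processing sites. An
unpaired site inherits its loop element's motif; a paired site is
annotated with its own pair plus one stacked neighbour per side — the
minimal reading of "the neighbouring pairs are included" — where a
neighbour across an adjacent two-sided loop is that loop's far closing
pair. A site that *is* a loop's closing pair is classified paired but
carries the loop's motif as an annotation, so the unpaired-or-closing-pair
ambiguity of loop-adjacent sites stays representable.

The arm is called by midpoints: a mature whose span lies entirely 5' (3')
of the reference hairpin-loop midpoint is 5p (3p); a span covering the
midpoint is explicitly `ambiguous` and gets no enzyme. On the 5p arm the
start site is the Drosha cut and the end site the Dicer cut; on the 3p
arm the roles swap. Mirroring a precursor therefore swaps arms and the
start/end enzyme assignment, which is tested as a property.

Site uniqueness counts sites whose loop key (unpaired or motif level)
occurs exactly once in the corpus table, split by enzyme; overlap against
an optional reference table is by exact (type, key) match.

## Synthetic data

The generator emits single nested hairpins assembled outside-in:
dangling ends (1–4 nt), then alternating helix runs (2–6 pairs, GC:AU:GU
drawn 2:2:1 with random orientation) and two-sided loops, terminated by a
hairpin loop (4–9 nt), with a mature span (20–23 nt) planted wholly on
one arm with probability 0.5 per arm. Loops are drawn from frequency
tables defaulting to the reference corpus's top-20 counts, with loop
types weighted by the corpus totals; each stem carries 2–6 interior loops
(the real corpus has 1–14 motifs per precursor, about four on average —
the count field is this package's parametrisation, since the reference
analysis fixes only the totals). Keys may also be full motif-level names,
in which case the prescribed closing pairs are forced onto the adjacent
helix boundary pairs (a one-pair helix constrained differently from both
sides is lengthened to two). The outermost helix is extended when needed
so the chosen arm can hold the mature span. An option plants one
two-hairpin precursor so multibranch naming is exercised.

Because assembly is token-by-token, the complete loop inventory (kinds,
names, coordinates), the mature span and both site contexts are known by
construction, independently of the extraction code — the central
round-trip oracle demands *identical* inventories, not statistical
agreement. If a planted mature span is not the first occurrence of its
sequence on the precursor (rare), the precursor is rebuilt from fresh
randomness rather than emitted inconsistently. All randomness flows from
one seeded NumPy PCG64 generator, recorded in the corpus metadata; a
fixed spec yields byte-identical output.

What the generator does **not** emulate: real miRBase sequence
composition, dinucleotide bias, thermodynamic realism (structures are
asserted, not folded), G-quadruplexes or non-canonical annotations, and
loop co-occurrence correlations along a stem. Passing round-trip and
frequency-recovery tests therefore demonstrates correctness of the
extraction and statistics machinery on structurally realistic input, not
biological fidelity of any particular corpus.

## Numerical and interface choices

* Presentation rounding is half-away-from-zero at two decimals (matching
  the published tables); all internal computation is double precision.
* Count-table orderings are descending count, then lexicographic key —
  fully deterministic.
* Empty inputs are valid where a count of zero is meaningful (empty
  corpus → empty table; unique fraction of an empty table is NaN).
* Problem sizes in the test and acceptance runs — 400 random structures
  plus a 500-precursor corpus for the oracle-equivalence pool, 200–500
  precursors for round-trips and frequency recovery — were chosen as the
  smallest corpora at which the multinomial 3σ recovery checks are
  well-powered.
* FASTA parsing is built on Bio.SeqIO with a strict validation layer
  (duplicate ids, empty records, alphabet); errors name the offending
  record.

## Known limitations

* Absolute corpus-scale counts (total motif counts, unique-motif and
  unique-site tallies of the real human corpus) require the external
  miRBase corpus and its folding output; this package reproduces the
  published *statistics* from the published count tables and validates
  the machinery on synthetic corpora instead.
* The denominators behind the published paired-site percentages are not
  recoverable from the publication, so those percentages are not
  asserted; `site_summary` computes them for any given corpus.
* Multibranch extended keys report no inward neighbour for the external
  pair of a branch-facing helix side (several branches, no single
  neighbour).
* `map_mature` is exact-match only by design; matures edited relative to
  their precursor (or spanning splice boundaries) will not map.
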