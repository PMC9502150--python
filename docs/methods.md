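# Methods

This note records the model behind each stage of the aligner, the defaults
and why they were chosen, the rules that were genuinely open design choices,
and what the synthetic-data tests do and do not demonstrate.

## Index: colored compacted de Bruijn graph

Nodes of the de Bruijn graph are canonical k-mers (lexicographic minimum of
a k-mer and its reverse complement); *k* must be odd so no k-mer equals its
own reverse complement and the canonical form plus one orientation bit is
lossless.  Edges are the observed (k+1)-mers of the references (edge-centric
construction): junctions reflect what the references actually spell, not all
possible (k−1)-overlaps.

A unitig boundary is placed between consecutive k-mers c1 → c2 of a
reference walk unless all of the following hold:

1. c1 has exactly one outgoing extension base (strand-adjusted) and c2
   exactly one incoming;
2. the multiplicity of the c1→c2 edge equals the multiplicity of **both**
   k-mers — i.e. every occurrence of either k-mer takes this junction;
3. c1 ≠ c2 as canonical k-mers.

Condition 2 is the occurrence-uniform ("monochromatic") path restriction;
it is what guarantees that *every* occurrence of a unitig spells the full
unitig, so the occurrence table is exact and each reference is a tiling of
unitig occurrences with (k−1)-overlaps.  Condition 3 handles the centers of
reverse-complement palindromes (e.g. `AACCGGTT`) and homopolymer self-loops,
where an unbroken path would contain the same k-mer twice and k-mer-location
uniqueness would fail.  Construction walks each reference once, so linear
references always break would-be cycles (a cycle's entry k-mer fails the
multiplicity condition at the reference end).

Unitigs are stored in canonical orientation with uids assigned in sorted
sequence order, making construction and serialization independent of
reference input order.  The k-mer → (unitig, offset, orientation) lookup is
a plain exact map; the space-engineered encodings used by genome-scale
implementations (perfect hashing, bit-packed vectors, sparse sampling) are
out of scope here — the query contract, not the bit layout, is what the rest
of the pipeline depends on.  References are split at non-ACGT runs; k-mers
spanning an `N` are never created.  Default k = 31, the conventional
de Bruijn k for short-read indexing; CLI-overridable, 3 ≤ k ≤ 31 odd.

## Seeding: uni-MEMs and MEM compaction

The read is scanned once, left to right, in its given orientation; canonical
lookup tracks strand implicitly (a forward scan finds reverse-strand seeds
too, tagged by orientation).  On a k-mer hit at probe position *p* the match
is extended maximally in both directions within the unitig; extension stops
at a mismatch, the read boundary, or the unitig boundary.  The probe then
advances to `match_end − k + skip`.

Two rules here were open choices, fixed as follows:

* **Probe advance** `skip` defaults to 1.  With skip = 1 the next probe is
  exactly the first k-mer start not contained in the previous uni-MEM, and
  because a k-mer has a unique unitig location, every uni-MEM's first k-mer
  start is eventually probed: the collected set is provably complete (the
  test suite verifies equality with a quadratic maximal-exact-match oracle).
  Larger skips trade sensitivity for speed.
* **Left extension** is fully maximal (bounded only by unitig and read
  start).  With skip = 1 it is a no-op in practice — the probe always lands
  on a uni-MEM's first k-mer — but with skip > 1 it recovers match prefixes
  the probe jumped over.  Duplicate projections are removed during
  compaction, so maximal left extension cannot double-report seeds.

The repeat filter drops uni-MEMs whose unitig occurs more than `max_occs`
(default 1000) times; the comparison is strict (exactly 1000 is kept).  The
`allowHighMultiMappers` flag re-admits the dropped seeds only for a read end
whose seeds were *all* dropped — the mitigation is per read end, leaving
well-seeded ends untouched.

Compaction projects each uni-MEM onto every occurrence of its unitig and,
per (reference, orientation) and per diagonal, merges consecutive
projections that overlap by exactly k−1 on both read and reference — the
signature of a unitig junction.  Only exact (k−1)-overlap merges are
performed (plus dedup of identical/contained projections from small
branched unitigs); bridging larger gaps is chaining's job.

## Chaining

Anchors (MEMs) on one (reference, orientation) are sorted by reference end
position and chained by the recursion given in the README.  Decisions:

* The gap penalty depends only on the gap *difference* g = |d_r − d_t|:
  β(g) = 0.01·`avg_seed_len`·g + 0.5·log₂ g for g ≥ 1, 0 for g = 0, and ∞
  for g > C.  `avg_seed_len` is set to k.  Equal read/reference gaps
  (substitution stretches) are free, matching the coverage-score view of
  chain quality.  This closed form is this package's normative definition.
* C (maximum allowed gap difference) defaults to 100 bases — roughly the
  read length, i.e. no credible short-read indel is excluded — and is
  exposed as `maxAllowedGap`.
* Anchor transitions require strictly increasing read and reference starts
  and reference overlap at most k−1; read overlap is allowed but only newly
  covered read bases count (the `min(w, w+d_r, w+d_t)` gain term).
* Predecessor search uses the bounded-rounds heuristic: after the first
  extendable predecessor, at most `h` = 2 more candidates are examined.
  With h = ∞ the DP is exact (verified against exhaustive subset
  enumeration); at h = 2 the best score matches the exact value on ≥ 99% of
  random desk-scale instances (regression-tracked).
* Read ends are chained separately; a joint two-end DP with an end-switch
  state was considered and rejected in favor of per-end chaining plus an
  explicit pairing stage, which keeps orientation consistency trivial.
* Validity: chain score strictly greater than `consensusFraction` (0.65) ×
  read length.  Sub-optimality: per reference, keep chains scoring ≥ 0.90 ×
  that reference's best (boundary inclusive).  Ties everywhere break by
  (reference id, reference start, orientation), making output order
  deterministic.

## Between-MEM alignment

Anchors are exact matches and are never re-aligned; they enter the CIGAR as
M runs with the match bonus.  Read intervals between anchors are aligned
globally (end-to-end on both interval and the corresponding reference
interval) by an affine-gap Gotoh DP; a gap of length L costs
`gap_open + L·gap_extend`.  Read prefix/suffix outside the outermost
anchors are aligned in extension mode: the read tail is consumed end-to-end,
the reference end is free, and the window is the tail length plus a buffer

    buffer = floor((min_score_fraction · match · |tail| + |gap_open|) / |gap_extend|) + 1

— the longest indel that could still leave the tail's score acceptable.
Scoring defaults (match 2, mismatch −4, gap open −5, gap extend −3) follow
common short-read practice and are fully configurable; all tests pin
explicit values.  DP traceback ties break deterministically M > D > I, so
CIGARs are reproducible.  An alignment is accepted when its score is at
least `minScoreFraction` (0.65) of the perfect score `match · read_len`
(a zero fraction disables the filter).  By default reads align end-to-end
(no soft clipping); `--allow-soft-clip` lets extension alignments leave an
unalignable outer read end as an S run.

The DP cache is keyed by (mode, read substring, reference substring) — by
content, not coordinates — so identical inter-MEM gaps anywhere in a
redundant reference collection share one entry.  It is a bounded LRU
(default 10 000 entries); a cached result is identical to recomputation, and
the suite checks byte-identical output with the cache disabled.

The stitched score can never exceed the unconstrained full-read DP score
against the same window (anchoring only constrains), and for
substitution-only reads whose gaps are diagonal (d_r = d_t) it equals it;
both properties are tested.

## Pairing and orphan recovery

Concordant: same reference, opposite strands in FR order (forward mate not
downstream of the reverse mate), fragment length — rightmost end minus
leftmost start, the TLEN convention — at most `max_fragment_len` (default
1000, roughly 3× the simulated fragment mean).  RF and FF library layouts
are supported via `--orientation`.  Discordant pairs (same reference,
geometry violated) are reported only when no concordant pair exists
anywhere and `--allow-discordant` is set.  Pairs rank by summed score, then
reference id, then leftmost position; `-N` truncates, `--best-strata` keeps
only the top stratum.

Orphan recovery fires only when one end has zero accepted alignments
anywhere (the motivating case: its seeds all fell in a filtered repeat, or
clustered errors sank every chain).  For each alignment of the mapped end,
the mate is searched on the expected strand inside the fragment-length
window on the expected side by a fitting alignment (both reference ends
free); hits passing the normal acceptance threshold are paired as
orphan-recovered concordant pairs.  The window/acceptance mechanics are this
package's normative definition of the recovery step.

SAM output: primary = top-ranked record, others secondary (0x100); `NH` is
the number of reported alignments, `AS` the score; MAPQ is 60 for unique
primaries, 1 for multi-mapped primaries, 0 for secondaries (a coarse
convention, not a calibrated error probability).  All internal coordinates
are 0-based half-open; the single conversion to 1-based SAM POS happens in
the writer.

## Synthetic data

The generator emulates a uniform-coverage paired-end DNA-seq experiment:
i.i.d. uniform ACGT references (optionally a planted repeat at fixed period,
or diverged reference copies), clamped-normal fragment lengths in FR
orientation, per-base substitutions and 1–3 bp indels at given rates, flat
quality strings.  It does **not** model coverage or GC bias, quality-
correlated errors, platform error profiles, structural variation, or real
genome repeat structure; passing recovery rates therefore demonstrate
algorithmic correctness under the stated error model, not performance on
real libraries.  All randomness flows through one seeded generator; the
truth table (TSV) records source reference, position, strand and edit counts
per read end.

## Problem sizes and numerical choices

The test and acceptance workloads use: a 100 kb genome (k = 31) for index
spelling/lookup checks; twenty ≤ 50 kb genomes at k ∈ {9, 11, 15, 21} (some
with planted repeats) for compaction-oracle agreement — smaller k maximizes
real branching at these genome sizes; 500 × 200 bp reads against a 10 kb
repeat-bearing reference (k = 21) for seeding completeness; 1000 random
instances of ≤ 8 anchors for chaining enumeration; 1000 random string pairs
(≤ 50 bp) for the DP kernels; 10 000 2×100 bp pairs from a 1 Mb genome
(fragments 300 ± 30, substitutions 0.5%, indels 0.1%, plus an error-free
rerun) end-to-end; and a 500 bp repeat planted 1001 times (just above the
filter threshold) with 300 bp unique spacers for the repeat/orphan-recovery
scenario.  Chain scores are compared at 1e-9 absolute tolerance (pure float
arithmetic); alignment scores are integers and compared exactly.

## Known limitations

* The in-memory index is a hash map over Python strings: fine to a few Mb
  of reference, not engineered for genome-scale collections.
* Single-threaded by design; the per-read-pair independence contract is the
  stated parallelization seam.
* No spliced alignment, no local (both-ends-clipped) alignment mode, no
  fragment-length learning, no BAM/CRAM output.
* MAPQ is a convention, not a probability model.
* With `skip` > 1 seeding is no longer complete; the completeness guarantee
  (and its oracle test) holds for skip = 1 only.
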