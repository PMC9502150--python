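# puffalign

A desk-scale short-read aligner built on a **colored compacted de Bruijn
graph** (ccdBg) index.  It is aimed at people who want a transparent,
hackable reference implementation of graph-index alignment — the kind of
pipeline used to align DNA-seq reads against a transcriptome or a redundant
collection of genomes — with every stage (indexing, seeding, chaining,
stitching, pairing) exposed as an ordinary Python function and checked
against brute-force oracles.

## The method

**Index.** The de Bruijn graph over all reference k-mers (canonical k-mers,
odd *k*, default 31) is compacted into *unitigs*: maximal non-branching
paths whose every junction is traversed by *all* occurrences of its two
k-mers.  This occurrence-uniform ("monochromatic") restriction means each
reference is an exact tiling of unitig occurrences overlapping by *k*−1, and
every k-mer has a *unique* location ⟨unitig, offset, orientation⟩.  A
unitig-to-reference table maps each unitig to its ⟨reference, position,
orientation⟩ occurrences.  Lookup is an ordinary exact map with the same
query contract as the space-optimized structures used at genome scale.

**Seeding.** Reads are scanned left to right; each k-mer hit is extended in
both directions along read and unitig until a mismatch, read end, or unitig
end — a *uni-MEM*.  Because a k-mer inside a uni-MEM cannot occur in any
other unitig, greedy extension is safe.  Uni-MEMs whose unitig occurs more
than 1000 times are discarded (repeat filter; `--allowHighMultiMappers`
restores them for read ends that would otherwise lose every seed).  Each
surviving uni-MEM is projected to all reference occurrences of its unitig,
and projections overlapping by exactly *k*−1 on both read and reference —
the unitig-junction signature — are merged into full read-vs-reference MEMs.

**Chaining.** Per (reference, orientation, read end), MEMs are chained by
the minimap2-style dynamic program

```
f(i) = max( w_i ,  max_j  f(j) + min(w_i, w_i + d_r, w_i + d_t) - beta(|d_r - d_t|) )
```

where `w_i` is the MEM length and `d_r`, `d_t` are the read/reference gaps
to the predecessor, with β(g) = 0.01·k·g + 0.5·log₂g (0 at g = 0, ∞ for
g > *C*, the maximum
allowed gap, default 100).  Chains must score above `consensusFraction`
(0.65) of the read length, and per reference only chains within 10% of the
best are kept.

**Between-MEM alignment.** Chain anchors are kept as exact matches; only the
read intervals between anchors are aligned (global affine-gap DP), and the
read prefix/suffix outside the outermost anchors get reference-end-free
extension alignments.  Pieces are stitched into one CIGAR; DP results are
memoized in a content-keyed LRU cache so repeated reference regions are
aligned once.  Default scoring: match +2, mismatch −4, gap open −5, gap
extend −3; an alignment is accepted at ≥ 0.65 of the perfect score.

**Pairing.** Ends are joined into concordant pairs (same reference, FR
orientation, fragment ≤ 1000 bp); discordant pairs are reported only when no
concordant pair exists and `--allow-discordant` is set.  If one end has no
accepted alignment at all — typically seeds lost to the repeat filter — the
mate's position implies a window in which the missing end is recovered by a
fitting alignment (*orphan recovery*).

## Worked example

```bash
# simulate a 100 kb genome and 1000 paired-end reads with known truth
puffalign simulate --length 100000 --seed 5 --n-pairs 1000 -o sim

# build the ccdBg index and align
puffalign index -r sim.fa -o sim_idx -k 31
puffalign align -i sim_idx -1 sim_1.fq -2 sim_2.fq -o sim.sam
```

The align step prints (to stderr):

```
total=1000 aligned=997 concordant=997 orphan-recovered=52 unmapped=3
```

meaning 997 of 1000 pairs were reported as proper pairs — 52 of them via
orphan recovery, where one end's chain fell below the consensus score
threshold (clustered sequencing errors) and was instead recovered from its
mate's fragment window — and 3 pairs had too many errors on both ends to
place at all.  `sim.sam` is ordinary SAM v1: flags encode pairing and
strand, `AS` is the alignment score, `NH` the number of reported alignments
for the read.

The same pipeline is available as a library:

```python
from puffalign import build_index, read_fasta, AlignConfig, run_align
idx = build_index(read_fasta("sim.fa"), k=31)
with open("sim.sam", "w") as out:
    summary = run_align(idx, "sim_1.fq", "sim_2.fq", AlignConfig(), out)
```

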