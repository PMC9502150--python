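"""End-to-end read processing: seed, filter, compact, chain, align, pair, SAM.

Processing is per-read(-pair) independent and strictly in input order, with
deterministic tie-breaking at every stage, so identical invocations produce
byte-identical SAM output.
"""

from __future__ import annotations

import dataclasses
import logging
from typing import IO, List, Optional, Sequence, Union

from .alignment import (
    AlignmentCache,
    AlignmentResult,
    accept_alignment,
    align_from_chain,
)
from .chaining import chain_mems, select_valid_chains
from .config import AlignConfig
from .index import CcdbgIndex, load_index
from .io_formats import ReadRecord, read_fastq_pairs, write_sam
from .pairing import PairedAlignment, finalize_read, join_ends, recover_orphan
from .seeding import collect_unimems, compact_to_mems, filter_repetitive

logger = logging.getLogger("puffalign")

__all__ = ["AlignSummary", "align_read_end", "run_align"]


@dataclasses.dataclass
class AlignSummary:
    total: int = 0  # reads (single-end) or pairs (paired-end)
    aligned: int = 0
    concordant: int = 0
    orphan_recovered: int = 0
    unmapped: int = 0

    def as_dict(self) -> dict:
        return dataclasses.asdict(self)


def align_read_end(
    seq: str,
    index: CcdbgIndex,
    config: AlignConfig,
    cache: Optional[AlignmentCache] = None,
    read_end: Optional[int] = None,
) -> List[AlignmentResult]:
    """Full single-end pipeline for one read sequence: accepted alignments,
    deduplicated by locus, unranked."""
    if len(seq) < index.k:
        return []
    scoring = config.scoring()
    params = config.chaining_params(index.k)
    unimems = collect_unimems(seq, index, config.skip)
    unimems = filter_repetitive(unimems, config.max_occs, config.allow_high_multimappers)
    if not unimems:
        return []
    mems_map = compact_to_mems(unimems, index)
    chains = []
    for key in sorted(mems_map):
        chains.extend(chain_mems(mems_map[key], len(seq), params, k=index.k))
    selected = select_valid_chains(chains, len(seq), params)
    results: dict = {}
    for chain in selected:
        chain.read_end = read_end
        aln = align_from_chain(
            seq,
            chain,
            index,
            scoring,
            cache=cache,
            min_score_fraction=config.min_score_fraction,
            allow_soft_clip=config.allow_soft_clip,
        )
        if not accept_alignment(aln, len(seq), scoring, config.min_score_fraction):
            continue
        locus = (aln.ref_id, aln.ref_start, aln.fw)
        prev = results.get(locus)
        if prev is None or aln.score > prev.score:
            results[locus] = aln
    return [results[key] for key in sorted(results)]


def _orphan_pairs(
    mapped: Sequence[AlignmentResult],
    mate_seq: str,
    mapped_end: int,
    index: CcdbgIndex,
    config: AlignConfig,
) -> List[PairedAlignment]:
    scoring = config.scoring()
    params = config.pairing_params()
    pairs: List[PairedAlignment] = []
    seen = set()
    for aln in mapped:
        for rec in recover_orphan(
            aln, mate_seq, index, scoring, params, config.min_score_fraction
        ):
            key = (aln.ref_id, aln.ref_start, aln.fw, rec.ref_start, rec.fw)
            if key in seen:
                continue
            seen.add(key)
            rec = dataclasses.replace(rec, read_end=2 if mapped_end == 1 else 1)
            left, right = (aln, rec) if mapped_end == 1 else (rec, aln)
            pairs.append(
                PairedAlignment(
                    left=left,
                    right=right,
                    status="orphan-recovered",
                    pair_score=left.score + right.score,
                    fragment_len=max(left.ref_end, right.ref_end)
                    - min(left.ref_start, right.ref_start),
                )
            )
    pairs.sort(
        key=lambda p: (-p.pair_score, p.left.ref_id, min(p.left.ref_start, p.right.ref_start))
    )
    if params.best_strata and pairs:
        pairs = [p for p in pairs if p.pair_score == pairs[0].pair_score]
    return pairs[: params.max_alignments_per_read]


def run_align(
    index_or_dir: Union[CcdbgIndex, str],
    reads1,
    reads2,
    config: AlignConfig,
    out_sam: IO[str],
) -> AlignSummary:
    """Align a FASTQ file (or pair of files) against an index, writing SAM.

    ``reads1``/``reads2`` are FASTQ paths (``reads2`` None for single-end).
    Returns summary counts; also logs them at info level.
    """
    index = index_or_dir if isinstance(index_or_dir, CcdbgIndex) else load_index(index_or_dir)
    cache = AlignmentCache(config.cache_size)
    pparams = config.pairing_params()
    ref_names = index.ref_names
    summary = AlignSummary()

    records_out: List = []

    def process_pair(r1: ReadRecord, r2: Optional[ReadRecord]):
        summary.total += 1
        if r2 is None:
            singles = align_read_end(r1.seq, index, config, cache, read_end=1)
            if singles:
                summary.aligned += 1
            else:
                summary.unmapped += 1
            return finalize_read(r1, None, [], singles, pparams, ref_names)

        left = align_read_end(r1.seq, index, config, cache, read_end=1)
        right = align_read_end(r2.seq, index, config, cache, read_end=2)
        pairs: List[PairedAlignment] = []
        if left and right:
            pairs = join_ends(left, right, pparams)
        elif left and not right:
            pairs = _orphan_pairs(left, r2.seq, 1, index, config)
        elif right and not left:
            pairs = _orphan_pairs(right, r1.seq, 2, index, config)
        if pairs:
            summary.aligned += 1
            if pairs[0].status == "concordant":
                summary.concordant += 1
            elif pairs[0].status == "orphan-recovered":
                summary.orphan_recovered += 1
                summary.concordant += 1
        elif config.allow_discordant and (left or right):
            summary.aligned += 1
        else:
            summary.unmapped += 1
        return finalize_read(r1, r2, pairs, left or right, pparams, ref_names)

    for r1, r2 in read_fastq_pairs(reads1, reads2):
        records_out.extend(process_pair(r1, r2))

    write_sam([(r.name, len(r.seq)) for r in index.refs], records_out, out_sam)
    logger.info(
        "aligned %d/%d (%d concordant, %d orphan-recovered, %d unmapped); "
        "cache hits=%d misses=%d",
        summary.aligned, summary.total, summary.concordant,
        summary.orphan_recovered, summary.unmapped, cache.hits, cache.misses,
    )
    return summary
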