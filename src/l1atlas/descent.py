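"""Tracing L1 descent: 3' transductions and hot-L1 lineage assignment.

Transcriptional readthrough past the weak L1 poly(A) signal co-mobilizes
unique downstream genomic sequence ("3' transduction"), tagging daughter
copies with their progenitor's flank.  Soft-clipped 3'-ATLAS reads whose
primary segment maps at a progeny insertion and whose clipped tail maps
immediately downstream of a *different* full-length insertion reveal such
progeny -> progenitor links.  Separately, three well-characterized hot-L1
lineages (AC002980, RP, LRE3) carry distinctive transduced tag sequences
that can be searched directly in the reads.
"""

from __future__ import annotations

from collections import defaultdict
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

from .model import (
    DEFAULT_CONFIG,
    DEFAULT_LINEAGE_TAGS,
    GenomicInterval,
    InsertionCall,
    LineageTag,
    MappedRead,
    PipelineConfig,
    TransductionEvent,
)
from .preprocess import find_adapter


def _downstream_region(call: InsertionCall, window: int) -> GenomicInterval:
    """The window immediately downstream of a call's 3' junction, in the
    element's sense direction, on the strand its flank reads map to."""
    if call.orientation == "+":
        return GenomicInterval(call.chrom, call.insertion_point,
                               call.insertion_point + window, "-")
    return GenomicInterval(call.chrom, max(0, call.insertion_point - window),
                           max(1, call.insertion_point), "+")


def detect_transductions(
    split_reads: Iterable[MappedRead],
    calls: Sequence[InsertionCall],
    window: int = DEFAULT_CONFIG.transduction_window,
    config: PipelineConfig = DEFAULT_CONFIG,
) -> List[TransductionEvent]:
    """Link progeny insertions to their transduction progenitors.

    Both split segments must map unambiguously (MAPQ > mapq_min_split;
    the clipped tail is often low complexity, making this gate
    essential).  The primary segment must fall within ``window`` bp of
    some call's 3' cluster (the progeny); the clipped tail must map
    downstream-adjacent to a different full-length call, on the strand
    implied by that progenitor's orientation.  Events are aggregated per
    (progeny, progenitor) pair; any progeny compatible with more than one
    progenitor is discarded entirely.
    """
    full_length = [c for c in calls if c.full_length]
    support: Dict[Tuple[str, str], List[MappedRead]] = defaultdict(list)
    for read in split_reads:
        if read.clip is None:
            continue
        if read.mapq <= config.mapq_min_split or read.clip.clipped_mapq <= config.mapq_min_split:
            continue
        progeny = None
        for call in sorted(calls, key=lambda c: c.call_id):
            span = call.three_prime_cluster.span
            widened = GenomicInterval(
                span.chrom, max(0, span.start - window), span.end + window, span.strand
            )
            if widened.overlaps(read.locus):
                progeny = call
                break
        if progeny is None:
            continue
        clip_locus = read.clip.clipped_locus
        for prog in full_length:
            if prog.call_id == progeny.call_id:
                continue
            region = _downstream_region(prog, window)
            if region.overlaps(clip_locus) and region.strand == clip_locus.strand:
                support[(progeny.call_id, prog.call_id)].append(read)

    by_progeny: Dict[str, List[str]] = defaultdict(list)
    for (progeny_id, prog_id) in support:
        by_progeny[progeny_id].append(prog_id)

    events = []
    for (progeny_id, prog_id), reads in sorted(support.items()):
        if len(by_progeny[progeny_id]) > 1:
            continue  # ambiguous progeny eliminated wholesale
        loci = [r.clip.clipped_locus for r in reads]
        span = GenomicInterval(
            loci[0].chrom,
            min(l.start for l in loci),
            max(l.end for l in loci),
            loci[0].strand,
        )
        events.append(
            TransductionEvent(
                progeny_call_id=progeny_id,
                progenitor_call_id=prog_id,
                n_support_reads=len(reads),
                transduced_span=span,
            )
        )
    return events


def tag_in_read(
    seq: str,
    tag: LineageTag,
    error_rate: float = DEFAULT_CONFIG.lineage_error_rate,
    min_overlap: int = DEFAULT_CONFIG.lineage_min_overlap,
) -> bool:
    """Detection-only tag search: edit distance within
    floor(error_rate x aligned tag length), partial end matches allowed
    down to ``min_overlap`` nt."""
    return (
        find_adapter(seq, tag.sequence, error_rate, min_overlap, anchor="anywhere")
        is not None
    )


def assign_lineages(
    flank_reads: Sequence[Tuple[str, str, GenomicInterval, int, bool]],
    calls: Sequence[InsertionCall],
    tags: Sequence[LineageTag] = DEFAULT_LINEAGE_TAGS,
    old_subfamily_catalog: Sequence[GenomicInterval] = (),
    config: PipelineConfig = DEFAULT_CONFIG,
) -> Dict[str, Dict[str, int]]:
    """Attribute lineage-tagged reads to full-length insertion calls.

    ``flank_reads`` are (read_id, sequence, mapped locus, mapq,
    is_secondary) tuples for reads still containing poly(A)/L1/flank
    sequence (barcode and linker clipped).  Reads containing a tag
    (serial search, error rate 0.1, minimum overlap 16, no trimming) and
    mapping as unique primary alignments (MAPQ > mapq_min_split) are
    attributed to full-length calls whose 3' cluster they intersect;
    matches at reference insertions of older subfamilies are discarded.

    Returns per-call per-lineage supporting-read counts; calls gain a
    ``lineage`` annotation when exactly one lineage supports them (the
    best-supported when several do, both still reported in the counts).
    """
    full_length = [c for c in calls if c.full_length]
    counts: Dict[str, Dict[str, int]] = defaultdict(lambda: defaultdict(int))
    for read_id, seq, locus, mapq, is_secondary in flank_reads:
        if is_secondary or mapq <= config.mapq_min_split:
            continue
        matched_tag: Optional[LineageTag] = None
        for tag in tags:  # serial search: first matching tag wins
            if tag_in_read(seq, tag, config.lineage_error_rate, config.lineage_min_overlap):
                matched_tag = tag
                break
        if matched_tag is None:
            continue
        if any(
            iv.overlaps(locus) for iv in old_subfamily_catalog
        ):
            continue
        for call in full_length:
            span = call.three_prime_cluster.span
            region = GenomicInterval(
                span.chrom,
                max(0, span.start - config.known_insertion_window),
                span.end + config.known_insertion_window,
                span.strand,
            )
            if region.chrom == locus.chrom and region.start < locus.end and locus.start < region.end:
                counts[call.call_id][matched_tag.name] += 1

    for call in calls:
        per = counts.get(call.call_id)
        if per:
            call.lineage = max(per.items(), key=lambda kv: (kv[1], kv[0]))[0]
    return {cid: dict(per) for cid, per in counts.items()}
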