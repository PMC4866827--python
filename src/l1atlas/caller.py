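"""From mapped flank reads to insertion calls.

Stages: MAPQ/secondary filtering, linker-position PCR deduplication,
strand-aware interval clustering (bedtools-merge semantics: reads on the
same strand that overlap or are separated by <= 100 bp form one cluster),
insertion-point determination from the cluster hull, 5'/3' pairing into
full-length calls, catalog annotation, and RPM/TPM normalization.
"""

from __future__ import annotations

from collections import defaultdict
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

from .model import (
    DEFAULT_CONFIG,
    GenomicInterval,
    InsertionCall,
    MappedRead,
    PipelineConfig,
    ReadCluster,
)


def filter_alignments(alignments: Iterable[MappedRead], mapq_min: int = DEFAULT_CONFIG.mapq_min_call) -> List[MappedRead]:
    """Drop secondary alignments and ambiguous mappers (MAPQ <= mapq_min)."""
    return [a for a in alignments if not a.is_secondary and a.mapq > mapq_min]


def deduplicate(reads: Sequence[MappedRead]) -> Tuple[List[MappedRead], Dict[str, int]]:
    """Collapse PCR duplicates sharing a linker position.

    Reads are redundant if they start from the same fragmentation break
    (chrom, strand, linker position); each group keeps its longest member,
    ties broken by lexicographically smallest read id.  Returns the
    non-redundant reads plus a map read_id -> redundant group size, needed
    downstream for RPM normalization.
    """
    groups: Dict[Tuple[str, str, str, int], List[MappedRead]] = defaultdict(list)
    for r in reads:
        groups[(r.sample, r.locus.chrom, r.locus.strand, r.linker_pos)].append(r)
    keep: List[MappedRead] = []
    redundancy: Dict[str, int] = {}
    for members in groups.values():
        rep = min(members, key=lambda r: (-r.length, r.read_id))
        keep.append(rep)
        redundancy[rep.read_id] = len(members)
    keep.sort(key=lambda r: (r.locus.chrom, r.locus.start, r.locus.end, r.read_id))
    return keep, redundancy


def cluster_reads(
    nr_reads: Sequence[MappedRead],
    side: str,
    gap: int = DEFAULT_CONFIG.cluster_merge_gap,
    redundancy: Optional[Dict[str, int]] = None,
) -> List[ReadCluster]:
    """Merge same-strand reads that overlap or lie within ``gap`` bp.

    Input must be deduplicated and sorted by (chrom, start).  The cluster
    span is the union hull of its members; counts cover redundant reads
    (via the dedup bookkeeping), non-redundant members, and members whose
    trimming found a poly(A) tract or L1 sequence.
    """
    for a, b in zip(nr_reads, nr_reads[1:]):
        if (a.locus.chrom, a.locus.start) > (b.locus.chrom, b.locus.start):
            raise ValueError("cluster_reads requires input sorted by (chrom, start)")
    redundancy = redundancy or {}
    clusters: List[ReadCluster] = []
    by_strand: Dict[str, List[MappedRead]] = defaultdict(list)
    for r in nr_reads:
        by_strand[r.locus.strand].append(r)
    for strand in sorted(by_strand):
        current: List[MappedRead] = []
        cur_end = -1
        for r in by_strand[strand]:
            if current and (
                r.locus.chrom != current[0].locus.chrom
                or r.locus.start - cur_end > gap
            ):
                clusters.append(_make_cluster(current, side, redundancy))
                current = []
            cur_end = r.locus.end if not current else max(cur_end, r.locus.end)
            current.append(r)
        if current:
            clusters.append(_make_cluster(current, side, redundancy))
    clusters.sort(key=lambda c: (c.span.chrom, c.span.start, c.span.strand))
    return clusters


def _make_cluster(members: List[MappedRead], side: str, redundancy: Dict[str, int]) -> ReadCluster:
    chrom = members[0].locus.chrom
    start = min(m.locus.start for m in members)
    end = max(m.locus.end for m in members)
    strand = members[0].locus.strand
    return ReadCluster(
        span=GenomicInterval(chrom, start, end, strand),
        side=side,
        members=list(members),
        n_redundant=sum(redundancy.get(m.read_id, 1) for m in members),
        n_nonredundant=len(members),
        n_polyA_or_l1=sum(
            1 for m in members if m.features_found.polyA or m.features_found.l1_end
        ),
    )


def call_insertion_point(cluster: ReadCluster) -> Tuple[int, str]:
    """Derive the insertion coordinate and L1 orientation from a cluster.

    3'-ATLAS reads run from the downstream genomic break toward the L1, so
    a 3' cluster on the - strand marks a sense (+) element whose junction
    is the cluster's most upstream coordinate, while a 3' cluster on the +
    strand marks an antisense (-) element with the junction at the most
    downstream coordinate.  5' clusters mirror this.
    """
    s = cluster.span
    if cluster.side == "three_prime":
        if s.strand == "-":
            return s.start, "+"
        return s.end, "-"
    # five_prime
    if s.strand == "+":
        return s.end, "+"
    return s.start, "-"


def make_calls(
    three_p_clusters: Sequence[ReadCluster],
    sample: str = "unassigned",
    id_prefix: str = "L1",
) -> List[InsertionCall]:
    """Wrap each 3' cluster into a provisional insertion call."""
    calls = []
    ordered = sorted(three_p_clusters, key=lambda c: (c.span.chrom, c.span.start, c.span.strand))
    for i, cl in enumerate(ordered, 1):
        point, orientation = call_insertion_point(cl)
        calls.append(
            InsertionCall(
                call_id=f"{id_prefix}_{sample}_{i:04d}",
                chrom=cl.span.chrom,
                insertion_point=point,
                orientation=orientation,
                three_prime_cluster=cl,
                sample=sample,
            )
        )
    return calls


def pair_full_length(
    three_p: Sequence[InsertionCall],
    five_p: Sequence[ReadCluster],
    window: int = DEFAULT_CONFIG.fulllength_pair_window,
) -> List[InsertionCall]:
    """Match 5'-ATLAS clusters to 3' calls within the upstream window.

    A 3' call becomes full length when an orientation-compatible 5'
    cluster places the element's 5' end within ``window`` bp upstream (in
    L1 coordinates) of the 3' junction.  Each 5' cluster supports at most
    one 3' call (the nearest); the recorded pair distance is bimodal in
    practice — ~6 kb when the element body lies in the reference sequence
    and ~0 for non-reference insertions.
    """
    candidates = []  # (distance, call_idx, cluster_idx)
    for ci, call in enumerate(three_p):
        for ki, cl in enumerate(five_p):
            if cl.span.chrom != call.chrom:
                continue
            point5, orient5 = call_insertion_point(cl)
            if orient5 != call.orientation:
                continue
            if call.orientation == "+":
                dist = call.insertion_point - point5
            else:
                dist = point5 - call.insertion_point
            if 0 <= dist <= window:
                candidates.append((dist, ci, ki))
    candidates.sort(key=lambda t: (t[0], t[1], t[2]))
    used_calls: set = set()
    used_clusters: set = set()
    paired: Dict[int, Tuple[ReadCluster, int]] = {}
    for dist, ci, ki in candidates:
        if ci in used_calls or ki in used_clusters:
            continue
        used_calls.add(ci)
        used_clusters.add(ki)
        paired[ci] = (five_p[ki], dist)
    out = []
    for ci, call in enumerate(three_p):
        if ci in paired:
            cl, dist = paired[ci]
            call.five_prime_cluster = cl
            call.full_length = True
            call.pair_distance = dist
        out.append(call)
    return out


def _nearest_distance(point: int, chrom: str, catalog: Sequence[GenomicInterval]) -> Optional[int]:
    best = None
    for iv in catalog:
        d = iv.distance_to_point(chrom, point)
        if d is not None and (best is None or d < best):
            best = d
    return best


def annotate_calls(
    calls: Sequence[InsertionCall],
    catalogs: Dict[str, Sequence[GenomicInterval]],
    window: int = DEFAULT_CONFIG.known_insertion_window,
) -> List[InsertionCall]:
    """Annotate calls against reference/known catalogs, genes and CNVs.

    catalogs keys (each a list of intervals; missing keys treated empty):
    ``reference_l1``, ``fixed_l1``, ``known_polymorphic``, ``genes``
    (stranded), ``cnv`` (state carried in the interval's ``strand``-free
    companion list ``cnv_states`` parallel to ``cnv``; see io module).
    An insertion is "known" when it falls within ``window`` bp of a
    previously described insertion.
    """
    reference = list(catalogs.get("reference_l1", []))
    known_poly = list(catalogs.get("known_polymorphic", []))
    genes = list(catalogs.get("genes", []))
    cnv = list(catalogs.get("cnv", []))
    cnv_states = list(catalogs.get("cnv_states", ["unknown"] * len(cnv)))

    for call in calls:
        d_ref = _nearest_distance(call.insertion_point, call.chrom, reference)
        d_poly = _nearest_distance(call.insertion_point, call.chrom, known_poly)
        call.is_reference = d_ref is not None and d_ref <= window
        if call.is_reference:
            call.known_status = "reference"
        elif d_poly is not None and d_poly <= window:
            call.known_status = "known_polymorphic"
        else:
            call.known_status = "novel"

        senses = set()
        for g in genes:
            if g.chrom == call.chrom and g.start <= call.insertion_point < g.end:
                senses.add("sense" if g.strand == call.orientation else "antisense")
        if not senses:
            call.gene_context = "intergenic"
        elif senses == {"sense", "antisense"}:
            call.gene_context = "genic_both"
        else:
            call.gene_context = f"genic_{senses.pop()}"

        call.cnv_state = "unknown"
        for iv, state in zip(cnv, cnv_states):
            if iv.chrom == call.chrom and iv.start <= call.insertion_point < iv.end:
                call.cnv_state = state
                break
    return list(calls)


def normalize_counts(
    clusters: Sequence[ReadCluster],
    total_mapped_redundant: int,
    total_mapped_nonredundant: int,
) -> List[ReadCluster]:
    """Populate RPM (per million redundant mapped reads) and TPM (per
    million non-redundant mapped reads) for each cluster."""
    if total_mapped_redundant <= 0 or total_mapped_nonredundant <= 0:
        raise ValueError("mapped-read totals must be positive")
    for cl in clusters:
        cl.rpm = cl.n_redundant / total_mapped_redundant * 1e6
        cl.tpm = cl.n_nonredundant / total_mapped_nonredundant * 1e6
    return list(clusters)


def call_sample(
    alignments: Iterable[MappedRead],
    sample: str = "unassigned",
    config: PipelineConfig = DEFAULT_CONFIG,
) -> List[InsertionCall]:
    """Convenience chain: filter -> dedup -> cluster -> call -> pair.

    ``alignments`` mixes 3'- and 5'-side reads (side recorded per read).
    """
    filtered = filter_alignments(alignments, config.mapq_min_call)
    by_side: Dict[str, List[MappedRead]] = {"three_prime": [], "five_prime": []}
    for r in filtered:
        by_side[r.side].append(r)
    clusters_by_side = {}
    for side, reads in by_side.items():
        nr, redundancy = deduplicate(reads)
        clusters = cluster_reads(nr, side, config.cluster_merge_gap, redundancy)
        clusters_by_side[side] = clusters
    total_red = len(filtered)
    total_nr = sum(c.n_nonredundant for cs in clusters_by_side.values() for c in cs)
    for side in clusters_by_side:
        if total_red and total_nr:
            normalize_counts(clusters_by_side[side], total_red, total_nr)
    calls = make_calls(clusters_by_side["three_prime"], sample=sample)
    return pair_full_length(calls, clusters_by_side["five_prime"],
                            config.fulllength_pair_window)
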