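"""Locus-resolution and global L1 expression.

A locus's own transcription cannot be read from alignments inside the
highly identical L1 body; instead, sense readthrough transcripts in the
1 kb window immediately downstream of the element, and antisense-promoter
transcripts in the 1 kb window immediately upstream on the opposite
strand, serve as proxies.  Expression is quantified as FPKM — fragments
(stranded first mates, MAPQ >= 20, annotated exons masked) in the fixed
1 kb window per million mapped first mates — with 0.05 FPKM dividing
expressed from non-expressed copies.  Loci absent from a sample's genome
carry a distinguished NaN sentinel, never an FPKM of 0.

Global subfamily activity is read off alignments against the L1HS
consensus: the trinucleotide spelled at consensus positions 5927-5929
(1-based) distinguishes L1HS-Ta (ACA) from L1HS-PreTa (ACG) and the
older L1PA2+ (GAG).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform

from .model import (
    DEFAULT_CONFIG,
    GenomicInterval,
    InsertionCall,
    PipelineConfig,
)


@dataclass(frozen=True)
class RnaFragment:
    """A stranded paired-end fragment reduced to its first mate's 5' point."""

    chrom: str
    pos: int       # 0-based 5' position of mate 1
    strand: str    # strand of mate 1 == transcript strand (FR library)
    mapq: int
    sample: str = "sample"


@dataclass
class LocusExpressionMatrix:
    """Per-locus x per-sample sense/antisense FPKM with presence flags.

    ``sense_fpkm``/``antisense_fpkm`` hold NaN where the locus is absent
    from the sample's genome; ``presence`` is the authoritative mask.
    """

    sense_fpkm: pd.DataFrame
    antisense_fpkm: pd.DataFrame
    presence: pd.DataFrame
    expressed: Optional[pd.DataFrame] = None

    @property
    def loci(self) -> List[str]:
        return list(self.sense_fpkm.index)

    @property
    def samples(self) -> List[str]:
        return list(self.sense_fpkm.columns)


@dataclass
class SubfamilyCounts:
    """Diagnostic-trinucleotide read counts with per-million normalization."""

    counts: Dict[str, int]
    total_mapped_genome: int
    partial: int = 0

    @property
    def per_million(self) -> Dict[str, float]:
        return {
            k: v / self.total_mapped_genome * 1e6 for k, v in self.counts.items()
        }


@dataclass
class FlankProfile:
    """Mean signal in fixed bins across +-1 kb around insertion points."""

    group: str                      # expressed | non_expressed
    offsets: np.ndarray             # signed bin start offsets from the junction
    mean_signal: np.ndarray
    n_loci: int


def _windows_for_call(call: InsertionCall, flank: int) -> Tuple[GenomicInterval, GenomicInterval]:
    """(sense window, antisense window) for a call.

    Sense: 1 kb downstream of the 3' junction in the element's sense
    orientation, on the sense strand.  Antisense: 1 kb upstream of the
    element's 5' extremity (3' junction minus the pair distance, when
    known) on the opposite strand.
    """
    p3 = call.insertion_point
    p5 = p3 - (call.pair_distance or 0) if call.orientation == "+" else p3 + (call.pair_distance or 0)
    if call.orientation == "+":
        sense = GenomicInterval(call.chrom, p3, p3 + flank, "+")
        anti = GenomicInterval(call.chrom, max(0, p5 - flank), max(1, p5), "-")
    else:
        sense = GenomicInterval(call.chrom, max(0, p3 - flank), max(1, p3), "-")
        anti = GenomicInterval(call.chrom, p5, p5 + flank, "+")
    return sense, anti


def quantify_locus(
    rna_frags: Iterable[RnaFragment],
    call: InsertionCall,
    exons: Sequence[GenomicInterval],
    total_first_mates: int,
    config: PipelineConfig = DEFAULT_CONFIG,
) -> Tuple[float, float]:
    """Sense and antisense flanking-window FPKM for one locus.

    A fragment is "in the window" when its first mate's 5' position lies
    within it; fragments overlapping masked exons (same point rule) and
    mates below the RNA MAPQ gate are excluded.  FPKM = count /
    (total_first_mates / 1e6) / window_kb with the window fixed at 1 kb.
    """
    if total_first_mates <= 0:
        raise ValueError("total_first_mates must be positive")
    sense_w, anti_w = _windows_for_call(call, config.expression_flank)
    window_kb = config.expression_flank / 1000.0

    def masked(frag: RnaFragment) -> bool:
        return any(
            e.chrom == frag.chrom and e.start <= frag.pos < e.end for e in exons
        )

    n_sense = n_anti = 0
    for frag in rna_frags:
        if frag.mapq < config.mapq_min_rna:
            continue
        if masked(frag):
            continue
        if (
            frag.chrom == sense_w.chrom
            and sense_w.start <= frag.pos < sense_w.end
            and frag.strand == sense_w.strand
        ):
            n_sense += 1
        elif (
            frag.chrom == anti_w.chrom
            and anti_w.start <= frag.pos < anti_w.end
            and frag.strand == anti_w.strand
        ):
            n_anti += 1
    scale = total_first_mates / 1e6
    return n_sense / scale / window_kb, n_anti / scale / window_kb


def build_expression_matrix(
    frags_by_sample: Dict[str, Sequence[RnaFragment]],
    calls: Sequence[InsertionCall],
    presence: Dict[str, Dict[str, bool]],
    exons: Sequence[GenomicInterval] = (),
    totals: Optional[Dict[str, int]] = None,
    config: PipelineConfig = DEFAULT_CONFIG,
) -> LocusExpressionMatrix:
    """Quantify every (full-length) call in every sample.

    ``presence[sample][call_id]`` says whether the locus exists in that
    sample's genome; absent entries become NaN.  ``totals`` gives mapped
    first-mate library sizes (defaults to the per-sample fragment count).
    """
    samples = sorted(frags_by_sample)
    call_ids = [c.call_id for c in calls]
    sense = pd.DataFrame(np.nan, index=call_ids, columns=samples)
    anti = pd.DataFrame(np.nan, index=call_ids, columns=samples)
    pres = pd.DataFrame(False, index=call_ids, columns=samples)
    for sample in samples:
        frags = list(frags_by_sample[sample])
        total = (totals or {}).get(sample, len(frags))
        for call in calls:
            here = presence.get(sample, {}).get(call.call_id, True)
            pres.loc[call.call_id, sample] = here
            if not here:
                continue
            s, a = quantify_locus(frags, call, exons, total, config)
            sense.loc[call.call_id, sample] = s
            anti.loc[call.call_id, sample] = a
    return LocusExpressionMatrix(sense_fpkm=sense, antisense_fpkm=anti, presence=pres)


def classify_expressed(
    matrix: LocusExpressionMatrix,
    threshold: float = DEFAULT_CONFIG.expressed_fpkm_threshold,
) -> LocusExpressionMatrix:
    """Divide loci into expressed (> threshold) and non-expressed (<=).

    Absent loci stay absent — they belong to neither group.  The
    ``expressed`` frame uses pandas nullable booleans with pd.NA for
    absent entries.
    """
    expressed = (matrix.sense_fpkm > threshold) & matrix.presence
    expressed = expressed.astype("boolean").mask(~matrix.presence, pd.NA)
    matrix.expressed = expressed
    return matrix


@dataclass(frozen=True)
class ConsensusRead:
    """An end-to-end alignment against the L1HS consensus, stored in
    consensus orientation."""

    start: int  # 0-based on the consensus
    seq: str


def count_diagnostic_trinucleotides(
    consensus_alignments: Iterable[ConsensusRead],
    total_genome_mapped: int,
    positions: Sequence[int] = DEFAULT_CONFIG.diag_positions,
) -> SubfamilyCounts:
    """Count reads by the trinucleotide they spell at the diagnostic site.

    ``positions`` are 1-based consensus coordinates (converted here, at
    the boundary).  Reads must fully span the three positions; others are
    tallied as partial.  ACA marks L1HS-Ta, ACG L1HS-PreTa, GAG the older
    L1PA2+ subfamilies; everything else pools into "other".
    """
    lo = positions[0] - 1          # 0-based inclusive
    hi = positions[-1]             # 0-based exclusive
    counts = {"ACA": 0, "ACG": 0, "GAG": 0, "other": 0}
    partial = 0
    for read in consensus_alignments:
        end = read.start + len(read.seq)
        if read.start > lo or end < hi:
            if read.start < hi and end > lo:
                partial += 1
            continue
        tri = read.seq[lo - read.start:hi - read.start].upper()
        counts[tri if tri in counts else "other"] += 1
    return SubfamilyCounts(counts=counts, total_mapped_genome=total_genome_mapped,
                           partial=partial)


def half_total_contributors(fpkm_vector: Sequence[float]) -> int:
    """Smallest number of loci whose summed FPKM reaches half the total."""
    values = sorted((float(v) for v in fpkm_vector), reverse=True)
    if not values or any(v < 0 for v in values):
        raise ValueError("fpkm_vector must be non-empty and non-negative")
    total = sum(values)
    if total <= 0:
        raise ValueError("fpkm_vector must have positive sum")
    acc = 0.0
    for k, v in enumerate(values, 1):
        acc += v
        if acc >= total / 2:
            return k
    return len(values)  # unreachable with exact arithmetic


def flank_profile(
    signal: Dict[str, np.ndarray],
    calls: Sequence[InsertionCall],
    expressed_flags: Dict[str, bool],
    internal_mask: Sequence[GenomicInterval] = (),
    config: PipelineConfig = DEFAULT_CONFIG,
) -> Dict[str, FlankProfile]:
    """Mean per-bin signal across +-1 kb around insertion points, by group.

    ``signal`` maps chrom -> per-base coverage; ``expressed_flags`` maps
    call_id -> bool.  Positions inside masked internal L1 bodies are
    excluded from the aggregation, so bins over masked sequence average
    only the unmasked loci.
    """
    flank = config.expression_flank
    width = config.profile_bin
    n_bins = 2 * flank // width
    offsets = np.arange(-flank, flank, width)
    sums = {g: np.zeros(n_bins) for g in ("expressed", "non_expressed")}
    cnts = {g: np.zeros(n_bins) for g in ("expressed", "non_expressed")}
    for call in calls:
        if call.call_id not in expressed_flags:
            continue
        group = "expressed" if expressed_flags[call.call_id] else "non_expressed"
        track = signal.get(call.chrom)
        if track is None:
            continue
        center = call.insertion_point
        for b in range(n_bins):
            lo = center + int(offsets[b])
            hi = lo + width
            if lo < 0 or hi > len(track):
                continue
            positions = np.arange(lo, hi)
            keep = np.ones(width, dtype=bool)
            for iv in internal_mask:
                if iv.chrom == call.chrom:
                    keep &= ~((positions >= iv.start) & (positions < iv.end))
            if not keep.any():
                continue
            sums[group][b] += float(track[lo:hi][keep].mean())
            cnts[group][b] += 1
    out = {}
    for g in sums:
        with np.errstate(invalid="ignore"):
            mean = np.where(cnts[g] > 0, sums[g] / np.maximum(cnts[g], 1), np.nan)
        out[g] = FlankProfile(group=g, offsets=offsets, mean_signal=mean,
                              n_loci=int(cnts[g].max(initial=0)))
    return out


def cluster_samples(matrix: LocusExpressionMatrix) -> Tuple[np.ndarray, List[str]]:
    """Ward-linkage hierarchical clustering of samples.

    Distance: Euclidean between sample FPKM vectors, with loci absent
    from a sample's genome contributing 0 (a distance over a ragged
    matrix is otherwise undefined).  Returns (scipy linkage matrix,
    sample labels); deterministic given the matrix.
    """
    samples = matrix.samples
    if len(samples) < 2:
        raise ValueError("need at least two samples to cluster")
    X = matrix.sense_fpkm.fillna(0.0).T.to_numpy()
    Z = hierarchy.linkage(X, method="ward")
    return Z, samples


def cluster_loci(matrix: LocusExpressionMatrix) -> Tuple[np.ndarray, List[str]]:
    """Ward-linkage clustering of loci under the reciprocal-mean-product
    distance.

    d(i, j) = 1 / mean over shared-presence samples of (fpkm_i x fpkm_j).
    Loci with no detectable expression in any sample are excluded first;
    pairs with no common sample get a neutral distance equal to the mean
    of all computable pairwise distances; infinite distances (shared
    samples, all-zero products) are replaced by the maximum finite
    distance before linkage.
    """
    sense = matrix.sense_fpkm
    pres = matrix.presence
    keep = [
        lid for lid in matrix.loci
        if np.nansum(sense.loc[lid].to_numpy(dtype=float)) > 0
    ]
    if len(keep) < 2:
        raise ValueError("need at least two expressed loci to cluster")
    n = len(keep)
    D = np.full((n, n), np.nan)
    for i in range(n):
        D[i, i] = 0.0
        for j in range(i + 1, n):
            shared = pres.loc[keep[i]] & pres.loc[keep[j]]
            if not shared.any():
                continue  # neutral distance imputed below
            prod = (
                sense.loc[keep[i], shared[shared].index]
                * sense.loc[keep[j], shared[shared].index]
            ).to_numpy(dtype=float)
            mean_prod = float(np.mean(prod))
            D[i, j] = D[j, i] = math.inf if mean_prod == 0 else 1.0 / mean_prod
    off = D[np.triu_indices(n, k=1)]
    finite = off[np.isfinite(off)]
    if finite.size == 0:
        raise ValueError("no computable pairwise distances")
    neutral = float(finite.mean())
    D[np.isnan(D)] = neutral
    D[np.isinf(D)] = float(finite.max())
    np.fill_diagonal(D, 0.0)
    Z = hierarchy.linkage(squareform(D, checks=False), method="ward")
    return Z, keep


def linkage_to_newick(Z: np.ndarray, labels: Sequence[str]) -> str:
    """Render a scipy linkage matrix as a Newick string with branch lengths."""
    tree = hierarchy.to_tree(Z)

    def walk(node, parent_height: float) -> str:
        length = parent_height - (0.0 if node.is_leaf() else node.dist)
        if node.is_leaf():
            length = parent_height
            return f"{labels[node.id]}:{length:.6g}"
        left = walk(node.left, node.dist)
        right = walk(node.right, node.dist)
        return f"({left},{right}):{parent_height - node.dist:.6g}"

    return f"({walk(tree.left, tree.dist)},{walk(tree.right, tree.dist)});"
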