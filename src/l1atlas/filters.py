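"""The in-silico filtering tier.

Three independent boolean verdicts per putative insertion:

* read support — >=3 non-redundant 3' reads of which at least one ended
  in a poly(A) tract or L1 sequence, OR at least one 5' plus one 3'
  non-redundant read;
* spurious RB3PA1 priming — a partial primer match in the genome under
  the 3' cluster of a non-reference call whose supporting reads show
  flank immediately followed by primer, with no L1 or poly(A) in between;
* PreTa/older-subfamily contamination — the junction falls next to an
  annotated older-subfamily element (catalog-driven; the ~10x lower read
  support typical of such clusters is surfaced as a diagnostic ratio,
  not used as a hard rule).

Filters commute: each verdict depends only on the call and its static
context, never on another verdict.
"""

from __future__ import annotations

import statistics
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from .model import (
    DEFAULT_CONFIG,
    FilterVerdicts,
    GenomicInterval,
    InsertionCall,
    PipelineConfig,
    PrimerSiteMap,
    revcomp,
)


def apply_support_filter(call: InsertionCall, config: PipelineConfig = DEFAULT_CONFIG) -> bool:
    """True-positive support rule; returns the support_pass verdict."""
    c3 = call.three_prime_cluster
    branch1 = (
        c3.n_nonredundant >= config.support_min_3p_reads and c3.n_polyA_or_l1 >= 1
    )
    branch2 = (
        call.five_prime_cluster is not None
        and call.five_prime_cluster.n_nonredundant >= 1
        and c3.n_nonredundant >= 1
    )
    return branch1 or branch2


def build_primer_site_map(
    genome: Dict[str, str],
    primer: str,
    min_suffix: int = DEFAULT_CONFIG.primer_min_suffix,
    full_mismatches: int = DEFAULT_CONFIG.primer_full_mismatches,
) -> PrimerSiteMap:
    """Map every partial RB3PA1 priming site in the genome.

    Primer derivatives shortened one base at a time from the 5' end, down
    to ``min_suffix`` nt, are located as exact matches on both strands;
    the full primer is additionally located allowing up to
    ``full_mismatches`` substitutions.  Where several forms match one
    position (and strand), the longest is kept.

    ``genome`` maps chrom -> sequence (uppercase).
    """
    if len(primer) <= min_suffix:
        raise ValueError("primer must be longer than min_suffix")
    sites: Dict[Tuple[str, int, str], int] = {}

    def record(chrom: str, start: int, strand: str, length: int) -> None:
        key = (chrom, start, strand)
        if sites.get(key, 0) < length:
            sites[key] = length

    m = len(primer)
    for chrom, seq in genome.items():
        seq = seq.upper()
        rc = revcomp(seq)
        n = len(seq)
        # Exact suffix forms, longest first so shorter forms can never
        # overwrite a longer one at the same position.
        for L in range(m - 1, min_suffix - 1, -1):
            suffix = primer[m - L:]
            for hay, strand in ((seq, "+"), (rc, "-")):
                pos = hay.find(suffix)
                while pos >= 0:
                    start = pos if strand == "+" else n - pos - L
                    record(chrom, start, strand, L)
                    pos = hay.find(suffix, pos + 1)
        # Full primer with substitutions only (vectorized sliding compare).
        for hay, strand in ((seq, "+"), (rc, "-")):
            if n < m:
                continue
            arr = np.frombuffer(hay.encode("ascii"), dtype=np.uint8)
            mism = np.zeros(n - m + 1, dtype=np.int32)
            for k, ch in enumerate(primer):
                mism += arr[k:n - m + 1 + k] != ord(ch)
            for pos in np.nonzero(mism <= full_mismatches)[0]:
                start = int(pos) if strand == "+" else n - int(pos) - m
                record(chrom, start, strand, m)
    return PrimerSiteMap(primer=primer, sites=sites)


def apply_primer_artifact_filter(
    call: InsertionCall,
    site_map: PrimerSiteMap,
    window: int = DEFAULT_CONFIG.known_insertion_window,
) -> bool:
    """Spurious-priming verdict; True means the call is an artifact.

    All three criteria must combine: the call is not a reference
    insertion, a mapped primer site lies within (or within ``window`` bp
    of) its 3' cluster span — trimming removes the primer before mapping,
    so the priming site abuts rather than underlies the flank cluster —
    and at least one supporting read consists of genomic flank
    immediately followed by the primer with neither L1 nor poly(A)
    sequence.
    """
    if call.is_reference:
        return False
    span = call.three_prime_cluster.span
    widened = GenomicInterval(
        span.chrom, max(0, span.start - window), span.end + window, span.strand
    )
    if not site_map.overlapping(widened):
        return False
    for m in call.three_prime_cluster.members:
        f = m.features_found
        if f.primer and not f.l1_end and not f.polyA:
            return True
    return False


def apply_preta_filter(
    call: InsertionCall,
    old_subfamily_catalog: Sequence[GenomicInterval],
    window: int = DEFAULT_CONFIG.known_insertion_window,
    median_ta_support: Optional[float] = None,
) -> bool:
    """Older-subfamily verdict; True flags the call as PreTa/older.

    Catalog-driven: the junction must fall within ``window`` bp of an
    annotated older-element 3' end.  When the cohort's median Ta support
    is supplied, the call's support ratio against it is stored as a
    diagnostic (older-subfamily clusters typically show ~10x fewer reads).
    """
    hit = False
    for iv in old_subfamily_catalog:
        d = iv.distance_to_point(call.chrom, call.insertion_point)
        if d is not None and d <= window:
            hit = True
            break
    if hit and median_ta_support:
        call.preta_support_ratio = (
            call.three_prime_cluster.n_nonredundant / median_ta_support
        )
    return hit


def apply_filters(
    calls: Sequence[InsertionCall],
    site_map: Optional[PrimerSiteMap] = None,
    old_subfamily_catalog: Sequence[GenomicInterval] = (),
    config: PipelineConfig = DEFAULT_CONFIG,
) -> List[InsertionCall]:
    """Attach all three verdicts to every call (order-independent)."""
    supports = [c.three_prime_cluster.n_nonredundant for c in calls]
    median_support = statistics.median(supports) if supports else None
    for call in calls:
        call.filter_verdicts = FilterVerdicts(
            support_pass=apply_support_filter(call, config),
            primer_artifact=(
                apply_primer_artifact_filter(call, site_map, config.known_insertion_window)
                if site_map
                else False
            ),
            preta=apply_preta_filter(
                call, old_subfamily_catalog, config.known_insertion_window,
                median_support,
            ),
        )
    return list(calls)


def discovery_rate(
    calls: Sequence[InsertionCall],
    fixed_set: Sequence[GenomicInterval],
    window: int = DEFAULT_CONFIG.known_insertion_window,
    retained_only: bool = True,
) -> Tuple[float, List[GenomicInterval]]:
    """Fraction of a fixed reference set recovered by the call set.

    A fixed element counts as found when at least one (retained) call
    lies within ``window`` bp of it.  Returns (fraction, missed elements).
    """
    if not fixed_set:
        raise ValueError("fixed_set must be non-empty")
    usable = [c for c in calls if not retained_only or c.retained]
    missed = []
    found = 0
    for iv in fixed_set:
        hit = any(
            iv.distance_to_point(c.chrom, c.insertion_point) is not None
            and iv.distance_to_point(c.chrom, c.insertion_point) <= window
            for c in usable
        )
        if hit:
            found += 1
        else:
            missed.append(iv)
    return found / len(fixed_set), missed
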