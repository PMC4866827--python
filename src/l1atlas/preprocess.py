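"""ATLAS-seq read grammar: demultiplexing and error-tolerant trimming.

A 3'-ATLAS read has the anatomy::

    barcode + linker + genomic flank + polyA + L1 3' end + RB3PA1 primer

and a 5'-ATLAS read::

    RB5PA2 primer + L1 5' end + revcomp(genomic flank) + linker

Trimming reduces each read to its genomic flank, oriented flank -> L1,
recording which features were found.  Adapter search follows cutadapt
semantics: semi-global alignment, partial occurrences allowed at the
anchored read end, an error budget of floor(error_rate x aligned adapter
length) counting substitutions and indels alike.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Iterable, Iterator, List, Optional, Tuple, Union

from .model import (
    ConfigError,
    DEFAULT_CONFIG,
    FeatureFlags,
    PipelineConfig,
    RawRead,
    TrimmedRead,
    revcomp,
)


@dataclass(frozen=True)
class AdapterMatch:
    """Best occurrence of an adapter within a read.

    ``start``/``end`` delimit the matched region of the *read* (0-based,
    half-open); ``aligned_len`` is the number of adapter bases aligned.
    """

    start: int
    end: int
    n_errors: int
    adapter_name: str = ""
    aligned_len: int = 0


@dataclass(frozen=True)
class Rejection:
    """Why a read was dropped during trimming."""

    read_id: str
    reason: str  # no_linker | too_short | too_short_raw | missing_feature


def demultiplex(
    reads: Iterable[RawRead],
    barcodes: Dict[str, str],
    min_read_len: int = DEFAULT_CONFIG.min_read_len,
) -> Tuple[Dict[str, List[RawRead]], int]:
    """Assign reads to samples by exact 5' barcode match and strip the barcode.

    Only perfect barcode prefixes count; anything else is tallied as
    unassigned and dropped, as are reads shorter than ``min_read_len`` after
    barcode removal.  Returns (per-sample read lists, unassigned count).
    """
    seen: Dict[str, str] = {}
    for label, bc in barcodes.items():
        if bc in seen:
            raise ConfigError(f"duplicate barcode {bc!r} for samples {seen[bc]!r} and {label!r}")
        seen[bc] = label
    labels = list(barcodes)
    for i, a in enumerate(labels):
        for b in labels[i + 1:]:
            x, y = barcodes[a], barcodes[b]
            if x.startswith(y) or y.startswith(x):
                raise ConfigError(f"barcodes for {a!r} and {b!r} are prefixes of one another")

    out: Dict[str, List[RawRead]] = {label: [] for label in barcodes}
    unassigned = 0
    for read in reads:
        for label, bc in barcodes.items():
            if read.sequence.startswith(bc):
                if len(read.sequence) - len(bc) < min_read_len:
                    break
                out[label].append(
                    RawRead(
                        id=read.id,
                        sequence=read.sequence[len(bc):],
                        qualities=read.qualities[len(bc):],
                        sample=label,
                    )
                )
                break
        else:
            unassigned += 1
            continue
    return out, unassigned


def _semi_global_3p(
    seq: str, adapter: str, error_rate: float, min_overlap: int, allow_partial_end: bool
) -> Optional[Tuple[int, int, int, int]]:
    """Core DP: adapter matched inside ``seq`` with a free read prefix.

    Returns the best candidate as (n_errors, start, end, aligned_len) where
    the candidate set is every full occurrence of the adapter ending anywhere
    in the read plus, when ``allow_partial_end``, every adapter *prefix* of
    length >= min_overlap reaching the read's 3' end.  Best = fewest errors,
    then longest read span, then rightmost start (the most distal occurrence
    is trimmed, matching iterative 3'-end trimming).
    """
    n, m = len(seq), len(adapter)
    if m == 0:
        raise ValueError("adapter must be non-empty")
    INF = 10 ** 9
    # cost[j][i]: best edits aligning adapter[:i] to a suffix of seq[:j]
    # whose start is free; start[j][i]: read position where that alignment
    # begins (cell-level ties prefer the larger start = rightmost).
    cost_prev = [0] * (m + 1)
    for i in range(1, m + 1):
        cost_prev[i] = i
    start_prev = [0] * (m + 1)
    best: Optional[Tuple[int, int, int, int]] = None

    def consider(n_err: int, s: int, e: int, alen: int) -> None:
        nonlocal best
        if n_err > int(error_rate * alen):
            return
        cand = (n_err, -(e - s), -s)  # min errors, max span, max start
        if best is None or cand < (best[0], -(best[2] - best[1]), -best[1]):
            best = (n_err, s, e, alen)

    # j = 0 row: adapter aligned to empty suffix (pure deletions from read's
    # point of view) — full match only sensible for j > 0, skip.
    if allow_partial_end and n == 0:
        return None
    cost_cur = [0] * (m + 1)
    start_cur = [0] * (m + 1)
    for j in range(1, n + 1):
        cost_cur[0] = 0
        start_cur[0] = j  # alignment starting at j (empty adapter prefix)
        cj = seq[j - 1]
        for i in range(1, m + 1):
            sub = cost_prev[i - 1] + (0 if cj == adapter[i - 1] else 1)
            dele = cost_prev[i] + 1   # consume read base (gap in adapter)
            ins = cost_cur[i - 1] + 1  # consume adapter base (gap in read)
            c = min(sub, dele, ins)
            # tie preference: larger (rightmost) start
            s = -1
            if sub == c:
                s = start_prev[i - 1]
            if dele == c:
                s = max(s, start_prev[i])
            if ins == c:
                s = max(s, start_cur[i - 1])
            cost_cur[i] = c
            start_cur[i] = s
        # full adapter ending at read position j
        consider(cost_cur[m], start_cur[m], j, m)
        cost_prev, cost_cur = cost_cur, cost_prev
        start_prev, start_cur = start_cur, start_prev
    if allow_partial_end:
        # adapter prefixes reaching the read's 3' end (cost_prev now holds row n)
        for i in range(min_overlap, m):
            consider(cost_prev[i], start_prev[i], n, i)
    return best


def find_adapter(
    seq: str,
    adapter: str,
    error_rate: float = DEFAULT_CONFIG.adapter_error_rate,
    min_overlap: int = DEFAULT_CONFIG.min_adapter_overlap,
    anchor: str = "three_prime",
    adapter_name: str = "",
) -> Optional[AdapterMatch]:
    """Find the best error-tolerant occurrence of ``adapter`` in ``seq``.

    anchor:
      * ``three_prime`` — full occurrence anywhere, or a prefix of the
        adapter (>= min_overlap) running off the read's 3' end; ties favor
        the rightmost occurrence.
      * ``five_prime``  — mirror: full occurrence anywhere or an adapter
        suffix at the read's 5' end; ties favor the leftmost occurrence.
      * ``anywhere``    — full occurrence plus both partial end cases.

    Returns None when nothing matches within the error budget
    floor(error_rate x aligned adapter length).
    """
    if not adapter:
        raise ValueError("adapter must be non-empty")
    if anchor not in {"three_prime", "five_prime", "anywhere"}:
        raise ValueError(f"invalid anchor {anchor!r}")

    # Exact full occurrence short-circuits the DP: 0 errors with the maximal
    # aligned span is optimal under every tie-break rule.
    pos = seq.rfind(adapter) if anchor == "three_prime" else seq.find(adapter)
    if pos >= 0:
        return AdapterMatch(start=pos, end=pos + len(adapter), n_errors=0,
                            adapter_name=adapter_name, aligned_len=len(adapter))

    candidates: List[Tuple[int, int, int, int]] = []

    if anchor in {"three_prime", "anywhere"}:
        hit = _semi_global_3p(seq, adapter, error_rate, min_overlap,
                              allow_partial_end=True)
        if hit:
            candidates.append(hit)
    if anchor in {"five_prime", "anywhere"}:
        hit = _semi_global_3p(seq[::-1], adapter[::-1], error_rate, min_overlap,
                              allow_partial_end=True)
        if hit:
            n_err, s, e, alen = hit
            n = len(seq)
            candidates.append((n_err, n - e, n - s, alen))

    if not candidates:
        return None

    def key(c: Tuple[int, int, int, int]):
        n_err, s, e, _ = c
        if anchor == "three_prime":
            return (n_err, -(e - s), -s)   # rightmost
        return (n_err, -(e - s), s)        # leftmost

    n_err, s, e, alen = min(candidates, key=key)
    return AdapterMatch(start=s, end=e, n_errors=n_err,
                        adapter_name=adapter_name, aligned_len=alen)


def trim_quality_3p(read: RawRead, threshold: int = DEFAULT_CONFIG.quality_trim_threshold) -> RawRead:
    """Trim low-quality 3' bases with the standard running-sum rule.

    Cut at the position maximizing sum(threshold - q) over the removed
    suffix; nothing is removed when no suffix has a positive sum.
    """
    q = read.qualities
    best_sum = 0
    best_cut = len(q)
    running = 0
    for k in range(len(q) - 1, -1, -1):
        running += threshold - q[k]
        if running > best_sum:
            best_sum = running
            best_cut = k
    if best_cut == len(q):
        return read
    return RawRead(read.id, read.sequence[:best_cut], q[:best_cut], read.sample)


def _strip_trailing_polyA(seq: str, min_run: int = 3) -> Tuple[str, bool]:
    """Remove the most 3'-terminal poly(A) run if it spans >= min_run nt."""
    n = len(seq)
    k = n
    while k > 0 and seq[k - 1] == "A":
        k -= 1
    if n - k >= min_run:
        return seq[:k], True
    return seq, False


def trim_three_prime_read(
    read: RawRead,
    refs: Dict[str, str],
    config: PipelineConfig = DEFAULT_CONFIG,
) -> Union[TrimmedRead, Rejection]:
    """Reduce a demultiplexed 3'-ATLAS read to its genomic flank.

    The linker must be found (error-tolerantly) at the 5' end and is
    removed; after quality trimming, the RB3PA1 primer, the L1 3'-end
    sequence and a trailing poly(A) run are iteratively searched and
    removed from the 3' end, each recorded in the feature flags.  Reads
    with no detectable 3' feature are kept — they usually did not reach
    the L1 junction.  refs keys: ``linker``, ``primer``, ``l1_3p_end``.
    """
    linker = refs["linker"]
    m = find_adapter(read.sequence, linker, config.adapter_error_rate,
                     config.min_adapter_overlap, anchor="five_prime")
    if m is None:
        return Rejection(read.id, "no_linker")
    seq = read.sequence[m.end:]
    quals = read.qualities[m.end:]
    trimmed = trim_quality_3p(RawRead(read.id, seq, quals, read.sample),
                              config.quality_trim_threshold)
    seq = trimmed.sequence

    found_primer = found_l1 = found_polyA = False
    while True:
        progressed = False
        hit = find_adapter(seq, refs["primer"], config.adapter_error_rate,
                           config.min_adapter_overlap, anchor="three_prime")
        if hit is not None:
            seq = seq[:hit.start]
            found_primer = True
            progressed = True
        hit = find_adapter(seq, refs["l1_3p_end"], config.adapter_error_rate,
                           config.min_adapter_overlap, anchor="three_prime")
        if hit is not None:
            seq = seq[:hit.start]
            found_l1 = True
            progressed = True
        seq, stripped = _strip_trailing_polyA(seq)
        if stripped:
            found_polyA = True
            progressed = True
        if not progressed or not seq:
            break

    if len(seq) < config.min_read_len:
        return Rejection(read.id, "too_short")
    return TrimmedRead(
        id=read.id,
        flank_seq=seq,
        side="three_prime",
        features_found=FeatureFlags(linker=True, primer=found_primer,
                                    l1_end=found_l1, polyA=found_polyA),
        original_len=len(read.sequence),
        sample=read.sample,
    )


def trim_five_prime_read(
    read: RawRead,
    refs: Dict[str, str],
    config: PipelineConfig = DEFAULT_CONFIG,
) -> Union[TrimmedRead, Rejection]:
    """Reduce a demultiplexed 5'-ATLAS read to its genomic flank.

    Raw reads shorter than the size-selection threshold never reached the
    junction and are rejected; the RB5PA2 primer then the L1 5'-end
    sequence are trimmed from the 5' end, the linker from the 3' end, and
    any missing feature rejects the read.  The surviving flank is
    reverse-complemented so that it reads flank -> L1, like a 3' read.
    refs keys: ``linker``, ``primer``, ``l1_5p_end``.
    """
    if len(read.sequence) < config.min_5prime_read_len:
        return Rejection(read.id, "too_short_raw")

    seq = read.sequence
    hit = find_adapter(seq, refs["primer"], config.adapter_error_rate,
                       config.min_adapter_overlap, anchor="five_prime")
    if hit is None:
        return Rejection(read.id, "missing_feature")
    seq = seq[hit.end:]
    hit = find_adapter(seq, refs["l1_5p_end"], config.adapter_error_rate,
                       config.min_adapter_overlap, anchor="five_prime")
    if hit is None:
        return Rejection(read.id, "missing_feature")
    seq = seq[hit.end:]
    hit = find_adapter(seq, refs["linker"], config.adapter_error_rate,
                       config.min_adapter_overlap, anchor="three_prime")
    if hit is None:
        return Rejection(read.id, "missing_feature")
    seq = seq[:hit.start]

    if len(seq) < config.min_read_len:
        return Rejection(read.id, "too_short")
    return TrimmedRead(
        id=read.id,
        flank_seq=revcomp(seq),
        side="five_prime",
        features_found=FeatureFlags(linker=True, primer=True, l1_end=True,
                                    polyA=False),
        original_len=len(read.sequence),
        sample=read.sample,
    )


def trim_reads(
    reads: Iterable[RawRead],
    side: str,
    refs: Dict[str, str],
    config: PipelineConfig = DEFAULT_CONFIG,
) -> Iterator[Union[TrimmedRead, Rejection]]:
    """Apply the appropriate trimmer to a stream of demultiplexed reads."""
    trim = trim_three_prime_read if side == "three_prime" else trim_five_prime_read
    for read in reads:
        yield trim(read, refs, config)
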