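"""Synthetic-data generator with full ground truth.

Produces a toy genome with planted L1 insertions (reference and
non-reference, full-length and truncated, both orientations), ATLAS-seq
reads following the junction grammar (barcode + linker + flank + polyA +
L1 3' end + primer, and the 5' mirror), PCR duplicates sharing a linker
position, spurious primer-priming decoy loci, soft-clipped transduction
reads, lineage-tagged flanks, stranded RNA-seq fragments concentrated in
the 1 kb flanks of expressed loci, and consensus-mapped reads carrying
the subfamily-diagnostic trinucleotide.  Everything is deterministic
given the seed, and every read id resolves through the provenance map to
a planted feature or decoy class.

The adapter/primer/L1-end sequences used here are synthetic stand-ins
with realistic lengths, shared as module constants so that the trimming
grammar and the generator agree by construction.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Tuple

import numpy as np

from .expression import ConsensusRead, RnaFragment
from .model import (
    ClipSegment,
    DEFAULT_LINEAGE_TAGS,
    GenomicInterval,
    LineageTag,
    MappedRead,
    RawRead,
    revcomp,
)

# --- synthetic reference sequences (test stand-ins, not biological) -------
LINKER = "GTAATACGACTCACTATAGGGC"            # suppression-PCR linker, 22 nt
RB3PA1 = "ATACCTAATGCTAGATGACACA"            # 3' junction primer, 22 nt
RB5PA2 = "GGTTGATTAGCACCGCTTCTGA"            # 5' junction primer, 22 nt
L1_3P_END = "CCAAGATGGCCGAATAGGAACAGCTCCGGT"  # last 30 nt of the element
L1_5P_END = "AGGGGGAGGAGTCGCCAGTTAGCTCAACGT"  # first 30 nt of the element
BARCODES = ("CGTGAT", "ACATCG", "GCCTAA", "TGGTCA", "CACTGT", "ATTGGC")

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


def _random_seq(rng: np.random.Generator, n: int) -> str:
    return rng.choice(_BASES, size=n).tobytes().decode("ascii")


def _build_consensus() -> str:
    """Fixed synthetic L1HS consensus: 5' end motif, internal sequence,
    the ACA diagnostic trinucleotide at 1-based 5927-5929, the RB3PA1
    priming region and the 3' end motif."""
    rng = np.random.default_rng(7)  # fixed: the consensus is a constant
    length = 6019
    internal_len = length - len(L1_5P_END) - len(L1_3P_END)
    body = list(L1_5P_END + _random_seq(rng, internal_len) + L1_3P_END)
    body[5926:5929] = "ACA"                      # diagnostic site (0-based 5926)
    start = length - len(L1_3P_END) - len(RB3PA1) - 10
    body[start:start + len(RB3PA1)] = RB3PA1     # primer anneals in the 3' UTR
    return "".join(body)


L1HS_CONSENSUS = _build_consensus()
DIAG_0BASED = slice(5926, 5929)


@dataclass(frozen=True)
class SimulationParams:
    """Knobs of the generator; defaults mirror the in-silico
    discovery-rate experiment (123 fixed insertions, >=10 non-redundant
    3' reads each, 1% substitution errors, 30% PCR duplicates, 20
    spurious-priming decoy loci)."""

    n_insertions: int = 123
    fraction_full_length: float = 0.22
    fraction_reference: float = 1.0
    reads_per_insertion: int = 10      # non-redundant 3' reads
    reads_per_5p: int = 3              # non-redundant 5' reads (full-length)
    duplicate_rate: float = 0.3        # fraction of raw reads that are duplicates
    substitution_rate: float = 0.01
    n_primer_decoys: int = 20
    decoy_reads: int = 5
    n_transduction_pairs: int = 0
    transduction_reads: int = 3
    n_lineage_insertions: int = 0
    n_preta_elements: int = 0
    genome_len: Optional[int] = None   # derived from n_insertions when None
    flank_min: int = 40
    flank_max: int = 250
    polya_len: Tuple[int, int] = (10, 18)
    sample: str = "S1"
    # RNA-seq side
    rna_cell_lines: int = 3
    rna_replicates: int = 2
    rna_library_size: int = 200_000
    rna_background: int = 50   # genome-wide stray fragments; sparse so that
                               # silent 1-kb windows are usually empty
    frac_high_expressed: float = 0.05
    frac_low_expressed: float = 0.10
    frac_antisense: float = 0.05
    high_intensity: float = 60.0
    low_intensity: float = 12.0
    presence_rate: float = 0.8         # non-reference locus presence/cell line
    seed: int = 0

    def validate(self) -> "SimulationParams":
        for name in ("fraction_full_length", "fraction_reference",
                     "duplicate_rate", "presence_rate"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name} must lie in [0, 1], got {v}")
        if not (0.0 <= self.substitution_rate <= 1.0):
            raise ValueError("substitution_rate must lie in [0, 1]")
        for name in ("n_insertions", "reads_per_insertion", "n_primer_decoys",
                     "n_transduction_pairs", "n_lineage_insertions",
                     "n_preta_elements"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        return self


@dataclass
class PlantedInsertion:
    insertion_id: str
    chrom: str
    insertion_point: int         # 3' junction, 0-based
    orientation: str             # + / -
    full_length: bool
    truncation_len: int          # element length present (== consensus if full)
    in_reference: bool
    fixed: bool
    five_prime_point: Optional[int] = None   # set when the body spans sequence
    lineage: Optional[str] = None
    transduction_parent: Optional[str] = None
    subfamily: str = "Ta"        # Ta | PreTa
    expression_sense: float = 0.0
    expression_antisense: float = 0.0

    @property
    def element_span(self) -> GenomicInterval:
        """Reference-genome footprint (zero-width point for non-reference
        insertions is widened to 1 bp for interval arithmetic)."""
        if self.in_reference and self.five_prime_point is not None:
            lo = min(self.insertion_point, self.five_prime_point)
            hi = max(self.insertion_point, self.five_prime_point)
        else:
            lo, hi = self.insertion_point, self.insertion_point + 1
        return GenomicInterval(self.chrom, lo, max(hi, lo + 1), self.orientation)


@dataclass
class TruthSet:
    genome: Dict[str, str]
    insertions: List[PlantedInsertion]
    catalogs: Dict[str, list]
    decoy_sites: List[Tuple[str, int]]       # (chrom, site start)
    read_provenance: Dict[str, str] = field(default_factory=dict)
    params: Optional[SimulationParams] = None

    def insertion(self, insertion_id: str) -> PlantedInsertion:
        return next(i for i in self.insertions if i.insertion_id == insertion_id)


@dataclass
class AtlasReadSet:
    """Simulated ATLAS-seq libraries plus their true alignments."""

    reads_3p: List[RawRead]
    reads_5p: List[RawRead]
    alignments: Dict[str, MappedRead]        # read id -> truth alignment
    lineage_pool: List[Tuple[str, str, GenomicInterval, int, bool]]
    barcodes: Dict[str, str]


@dataclass
class RnaSeqSet:
    frags_by_sample: Dict[str, List[RnaFragment]]
    totals: Dict[str, int]
    presence: Dict[str, Dict[str, bool]]     # sample -> insertion_id -> bool
    consensus_reads: Dict[str, List[ConsensusRead]]
    total_genome_mapped: Dict[str, int]
    coverage: Dict[str, np.ndarray]
    cell_line_of: Dict[str, str]


CHROM = "chrT"


def make_genome_and_truth(params: SimulationParams) -> TruthSet:
    """Build the toy genome, plant insertions and derive all catalogs."""
    params.validate()
    rng = np.random.default_rng(params.seed)
    n = params.n_insertions + params.n_preta_elements
    slot = 9000
    margin = 20_000
    genome_len = params.genome_len or n * slot + params.n_primer_decoys * 1200 + 2 * margin
    needed = n * slot + 2 * margin
    if genome_len < needed:
        raise ValueError(
            f"genome_len={genome_len} too small for {n} insertions (need >= {needed})"
        )

    n_full = round(params.n_insertions * params.fraction_full_length)
    n_ref = round(params.n_insertions * params.fraction_reference)
    order = rng.permutation(params.n_insertions)
    full_ids = set(order[:n_full].tolist())
    ref_ids = set(rng.permutation(params.n_insertions)[:n_ref].tolist())
    # lineage-tagged insertions must be full length
    lineage_ids: Dict[int, LineageTag] = {}
    if params.n_lineage_insertions:
        if params.n_lineage_insertions > max(n_full, 1):
            full_ids.update(order[:params.n_lineage_insertions].tolist())
        pool = sorted(full_ids)[:params.n_lineage_insertions]
        for k, idx in enumerate(pool):
            lineage_ids[idx] = DEFAULT_LINEAGE_TAGS[k % len(DEFAULT_LINEAGE_TAGS)]

    pieces: List[str] = []
    cursor = 0          # final-genome coordinate
    insertions: List[PlantedInsertion] = []
    catalogs: Dict[str, list] = {
        "reference_l1": [], "fixed_l1": [], "known_polymorphic": [],
        "old_subfamily": [], "genes": [], "exons": [], "cnv": [], "cnv_states": [],
    }

    def emit(seq: str) -> None:
        nonlocal cursor
        pieces.append(seq)
        cursor += len(seq)

    emit(_random_seq(rng, margin))
    for i in range(n):
        is_preta = i >= params.n_insertions
        idx = i
        orientation = "+" if rng.random() < 0.5 else "-"
        if is_preta:
            full, in_ref, fixed = False, True, False
            trunc = int(rng.integers(500, 2000))
            iid = f"PRETA_{i - params.n_insertions:03d}"
            subfam = "PreTa"
        else:
            full = idx in full_ids
            in_ref = idx in ref_ids
            fixed = in_ref
            trunc = len(L1HS_CONSENSUS) if full else int(rng.integers(500, 5500))
            iid = f"INS_{idx:04d}"
            subfam = "Ta"
        body = L1HS_CONSENSUS[-trunc:] if subfam == "Ta" else _preta_body(trunc)
        emit(_random_seq(rng, int(rng.integers(1200, 1800))))
        if in_ref:
            if orientation == "+":
                p5 = cursor
                emit(body)
                p3 = cursor
            else:
                p3 = cursor
                emit(revcomp(body))
                p5 = cursor
            five_pt = p5 if full else None
        else:
            p3 = cursor
            five_pt = p3 if full else None
        rest = slot - (len(body) if in_ref else 0) - 1500
        emit(_random_seq(rng, max(rest, 600)))
        ins = PlantedInsertion(
            insertion_id=iid, chrom=CHROM, insertion_point=p3,
            orientation=orientation, full_length=full, truncation_len=trunc,
            in_reference=in_ref, fixed=fixed, five_prime_point=five_pt,
            lineage=lineage_ids[idx].name if (not is_preta and idx in lineage_ids) else None,
            subfamily=subfam,
        )
        insertions.append(ins)
        span = ins.element_span
        if is_preta:
            catalogs["old_subfamily"].append(span)
        else:
            if in_ref:
                catalogs["reference_l1"].append(span)
            else:
                catalogs["known_polymorphic"].append(span)
            if fixed:
                catalogs["fixed_l1"].append(span)

    decoy_sites: List[Tuple[str, int]] = []
    for d in range(params.n_primer_decoys):
        emit(_random_seq(rng, 500))
        # a spurious-priming site preceded by a poly(A)-like tract would be
        # indistinguishable from a genuine junction; plant the canonical case
        pieces[-1] = pieces[-1][:-1] + "C"
        site = cursor
        emit(RB3PA1)
        decoy_sites.append((CHROM, site))
        emit(_random_seq(rng, 500))
    emit(_random_seq(rng, margin))
    genome = {CHROM: "".join(pieces)}

    # transduction pairs: progenitor full length, progeny distinct
    ta = [x for x in insertions if x.subfamily == "Ta"]
    full_list = [x for x in ta if x.full_length]
    others = [x for x in ta if not x.full_length] or ta
    for t in range(params.n_transduction_pairs):
        if len(full_list) < 1 or len(ta) < 2:
            break
        prog = full_list[t % len(full_list)]
        progeny_pool = [x for x in ta if x.insertion_id != prog.insertion_id]
        progeny = progeny_pool[t % len(progeny_pool)]
        progeny.transduction_parent = prog.insertion_id

    # genes/exons: one gene over every third insertion point
    glen, elen = 4000, 300
    for k, ins in enumerate(insertions):
        if k % 3 == 0:
            gstart = max(0, ins.insertion_point - glen // 2)
            strand = "+" if k % 6 == 0 else "-"
            catalogs["genes"].append(
                GenomicInterval(CHROM, gstart, gstart + glen, strand)
            )
            catalogs["exons"].append(
                GenomicInterval(CHROM, gstart, gstart + elen, strand)
            )
    # CNV: five equal segments cycling through states
    states = ["normal", "amplified", "normal", "het_deletion", "uncovered"]
    seg = len(genome[CHROM]) // len(states)
    for s, state in enumerate(states):
        catalogs["cnv"].append(
            GenomicInterval(CHROM, s * seg, (s + 1) * seg if s < 4 else len(genome[CHROM]))
        )
        catalogs["cnv_states"].append(state)

    return TruthSet(genome=genome, insertions=insertions, catalogs=catalogs,
                    decoy_sites=decoy_sites, params=params)


def _preta_body(trunc: int) -> str:
    body = list(L1HS_CONSENSUS[-trunc:])
    off = trunc - (len(L1HS_CONSENSUS) - 5926)
    if 0 <= off <= trunc - 3:
        body[off:off + 3] = "ACG"   # PreTa diagnostic
    return "".join(body)


def _mutate(rng: np.random.Generator, seq: str, rate: float) -> str:
    if rate <= 0 or not seq:
        return seq
    arr = np.frombuffer(seq.encode("ascii"), dtype=np.uint8).copy()
    hits = np.nonzero(rng.random(len(arr)) < rate)[0]
    for h in hits:
        choices = _BASES[_BASES != arr[h]]
        arr[h] = rng.choice(choices)
    return arr.tobytes().decode("ascii")


def make_atlas_reads(truth: TruthSet, params: Optional[SimulationParams] = None) -> AtlasReadSet:
    """Generate 3'/5' ATLAS libraries and their true alignments."""
    params = params or truth.params or SimulationParams()
    rng = np.random.default_rng(params.seed + 1)
    genome = truth.genome[CHROM]
    barcode = BARCODES[0]
    reads_3p: List[RawRead] = []
    reads_5p: List[RawRead] = []
    alignments: Dict[str, MappedRead] = {}
    lineage_pool: List[Tuple[str, str, GenomicInterval, int, bool]] = []
    qual = lambda s: tuple([38] * len(s))
    counter = 0

    def polya() -> str:
        return "A" * int(rng.integers(params.polya_len[0], params.polya_len[1] + 1))

    def emit_3p(ins: PlantedInsertion, tag: Optional[LineageTag],
                clip_to: Optional[PlantedInsertion], d: int) -> None:
        nonlocal counter
        p = ins.insertion_point
        if ins.orientation == "+":
            flank = revcomp(genome[p:p + d])
            locus = GenomicInterval(CHROM, p, p + d, "-")
        else:
            flank = genome[p - d:p]
            locus = GenomicInterval(CHROM, p - d, p, "+")
        tag_seq = tag.sequence if tag else ""
        payload = flank + tag_seq + polya() + L1_3P_END + RB3PA1
        n_copies = 1
        while rng.random() < params.duplicate_rate:
            n_copies += 1
        for c in range(n_copies):
            counter += 1
            rid = f"r3_{counter:06d}"
            if c == 0:
                seq = barcode + LINKER + payload
                rl = locus
            else:
                t = int(rng.integers(1, 11))      # duplicates lose flank bases
                seq = barcode + LINKER + flank[: max(len(flank) - t, 1)]
                if locus.strand == "-":
                    rl = GenomicInterval(CHROM, min(locus.start + t, locus.end - 1),
                                         locus.end, "-")
                else:
                    rl = GenomicInterval(CHROM, locus.start,
                                         max(locus.end - t, locus.start + 1), "+")
            seq = _mutate(rng, seq, params.substitution_rate)
            clip = None
            if clip_to is not None and c == 0:
                clip = _clip_segment(rng, genome, clip_to)
            reads_3p.append(RawRead(rid, seq, qual(seq)))
            alignments[rid] = MappedRead(
                read_id=rid, locus=rl, mapq=60, side="three_prime",
                clip=clip, sample=params.sample,
            )
            truth.read_provenance[rid] = ins.insertion_id
            after_linker = seq[len(barcode) + len(LINKER):]
            lineage_pool.append((rid, after_linker, rl, 60, False))

    def emit_5p(ins: PlantedInsertion, d: int) -> None:
        nonlocal counter
        q = ins.five_prime_point
        assert q is not None
        if ins.orientation == "+":
            flank = genome[q - d:q]
            locus = GenomicInterval(CHROM, q - d, q, "+")
        else:
            flank = revcomp(genome[q:q + d])
            locus = GenomicInterval(CHROM, q, q + d, "-")
        counter += 1
        rid = f"r5_{counter:06d}"
        seq = RB5PA2 + L1_5P_END + revcomp(flank) + LINKER
        seq = _mutate(rng, seq, params.substitution_rate)
        reads_5p.append(RawRead(rid, barcode + seq, qual(barcode + seq)))
        alignments[rid] = MappedRead(
            read_id=rid, locus=locus, mapq=60, side="five_prime",
            sample=params.sample,
        )
        truth.read_provenance[rid] = ins.insertion_id

    for ins in truth.insertions:
        tag = None
        if ins.lineage:
            tag = next(t for t in DEFAULT_LINEAGE_TAGS if t.name == ins.lineage)
        n3 = params.reads_per_insertion
        if ins.subfamily == "PreTa":
            n3 = max(1, round(params.reads_per_insertion / 10))
        parent = (
            truth.insertion(ins.transduction_parent)
            if ins.transduction_parent else None
        )
        # distinct sonication breaks: planted non-redundant reads never
        # share a linker position
        d3 = rng.choice(
            np.arange(params.flank_min, params.flank_max + 1), size=n3,
            replace=False,
        )
        for k in range(n3):
            with_clip = parent if k < params.transduction_reads else None
            emit_3p(ins, tag, with_clip, int(d3[k]))
        if ins.full_length and ins.subfamily == "Ta":
            # 5' reads must clear the 133 nt raw size selection after the
            # primer (22) + L1 5' end (30) + linker (22) are accounted for
            d5 = rng.choice(
                np.arange(max(params.flank_min, 60), params.flank_max + 1),
                size=params.reads_per_5p, replace=False,
            )
            for k in range(params.reads_per_5p):
                emit_5p(ins, int(d5[k]))

    # spurious-priming decoys: flank + primer, no polyA/L1
    for dnum, (chrom, site) in enumerate(truth.decoy_sites):
        dd = rng.choice(
            np.arange(params.flank_min, params.flank_max + 1),
            size=params.decoy_reads, replace=False,
        )
        for k in range(params.decoy_reads):
            counter += 1
            rid = f"rd_{counter:06d}"
            d = int(dd[k])
            flank = genome[site - d:site]
            seq = barcode + LINKER + flank + RB3PA1
            seq = _mutate(rng, seq, params.substitution_rate)
            reads_3p.append(RawRead(rid, seq, qual(seq)))
            alignments[rid] = MappedRead(
                read_id=rid,
                locus=GenomicInterval(chrom, site - d, site, "+"),
                mapq=60, side="three_prime", sample=params.sample,
            )
            truth.read_provenance[rid] = f"decoy_{dnum:03d}"
            lineage_pool.append(
                (rid, seq[len(barcode) + len(LINKER):],
                 GenomicInterval(chrom, site - d, site, "+"), 60, False)
            )

    return AtlasReadSet(
        reads_3p=reads_3p, reads_5p=reads_5p, alignments=alignments,
        lineage_pool=lineage_pool, barcodes={params.sample: barcode},
    )


def _clip_segment(rng: np.random.Generator, genome: str, prog: PlantedInsertion) -> ClipSegment:
    """A soft-clipped tail mapping immediately downstream of the
    progenitor, on the strand its own flank reads use."""
    off = int(rng.integers(0, 200))
    length = int(rng.integers(60, 150))
    p = prog.insertion_point
    if prog.orientation == "+":
        locus = GenomicInterval(CHROM, p + off, p + off + length, "-")
        seq = revcomp(genome[p + off:p + off + length])
    else:
        locus = GenomicInterval(CHROM, max(0, p - off - length), p - off, "+")
        seq = genome[max(0, p - off - length):p - off]
    return ClipSegment(clipped_seq=seq, clipped_locus=locus, clipped_mapq=60)


def make_rnaseq_fragments(truth: TruthSet, params: Optional[SimulationParams] = None) -> RnaSeqSet:
    """Stranded RNA-seq fragments, consensus reads and a coverage track.

    Each cell line gets a fixed per-locus intensity vector (a few loci
    high, some low, most silent); replicates within a cell line share the
    vector and differ only by Poisson sampling.  Fragments are first-mate
    5' points on the transcript strand inside the 1 kb sense (downstream)
    or antisense (upstream) window.  Consensus reads carry ACA in
    proportion to the cell line's global Ta expression, next to fixed
    PreTa (ACG) and older-subfamily (GAG) pools.
    """
    params = params or truth.params or SimulationParams()
    rng = np.random.default_rng(params.seed + 2)
    genome_len = len(truth.genome[CHROM])
    loci = [i for i in truth.insertions if i.subfamily == "Ta" and i.full_length]

    frags: Dict[str, List[RnaFragment]] = {}
    totals: Dict[str, int] = {}
    presence: Dict[str, Dict[str, bool]] = {}
    consensus_reads: Dict[str, List[ConsensusRead]] = {}
    total_genome_mapped: Dict[str, int] = {}
    coverage = np.zeros(genome_len, dtype=np.float64)
    cell_line_of: Dict[str, str] = {}

    n_hi = max(1, round(len(loci) * params.frac_high_expressed)) if loci else 0
    n_lo = round(len(loci) * params.frac_low_expressed)

    for c in range(params.rna_cell_lines):
        cl = f"C{c + 1}"
        sense = {}
        anti = {}
        pres_cl = {}
        order = rng.permutation(len(loci))
        hi = set(order[:n_hi].tolist())
        lo = set(order[n_hi:n_hi + n_lo].tolist())
        for k, ins in enumerate(loci):
            present = ins.in_reference or rng.random() < params.presence_rate
            pres_cl[ins.insertion_id] = present
            sense[ins.insertion_id] = (
                params.high_intensity if k in hi
                else params.low_intensity if k in lo else 0.0
            ) if present else 0.0
            anti[ins.insertion_id] = (
                params.low_intensity
                if present and rng.random() < params.frac_antisense else 0.0
            )
        for r in range(params.rna_replicates):
            sample = f"{cl}_R{r + 1}"
            cell_line_of[sample] = cl
            presence[sample] = dict(pres_cl)
            out: List[RnaFragment] = []
            for ins in loci:
                lam_s, lam_a = sense[ins.insertion_id], anti[ins.insertion_id]
                p3 = ins.insertion_point
                p5 = ins.five_prime_point if ins.five_prime_point is not None else p3
                for _ in range(rng.poisson(lam_s)):
                    off = int(rng.integers(0, 1000))
                    if ins.orientation == "+":
                        pos, strand = p3 + off, "+"
                    else:
                        pos, strand = p3 - 1 - off, "-"
                    out.append(RnaFragment(CHROM, pos, strand, 60, sample))
                    coverage[max(0, pos):pos + 50] += 1.0
                for _ in range(rng.poisson(lam_a)):
                    off = int(rng.integers(0, 1000))
                    if ins.orientation == "+":
                        pos, strand = p5 - 1 - off, "-"
                    else:
                        pos, strand = p5 + off, "+"
                    out.append(RnaFragment(CHROM, max(0, pos), strand, 60, sample))
            for _ in range(params.rna_background):
                pos = int(rng.integers(0, genome_len))
                strand = "+" if rng.random() < 0.5 else "-"
                out.append(RnaFragment(CHROM, pos, strand, 60, sample))
            frags[sample] = out
            totals[sample] = params.rna_library_size

            # consensus diagnostic reads, scaled by global Ta expression
            global_ta = sum(sense.values())
            n_ta = rng.poisson(global_ta * 2)
            n_preta = rng.poisson(30)
            n_old = rng.poisson(100)
            reads = []
            for tri, count in (("ACA", n_ta), ("ACG", n_preta), ("GAG", n_old)):
                for _ in range(count):
                    start = int(rng.integers(DIAG_0BASED.stop - 75, DIAG_0BASED.start + 1))
                    seq = list(L1HS_CONSENSUS[start:start + 75])
                    seq[DIAG_0BASED.start - start:DIAG_0BASED.stop - start] = tri
                    reads.append(ConsensusRead(start=start, seq="".join(seq)))
            consensus_reads[sample] = reads
            total_genome_mapped[sample] = params.rna_library_size

    return RnaSeqSet(
        frags_by_sample=frags, totals=totals, presence=presence,
        consensus_reads=consensus_reads, total_genome_mapped=total_genome_mapped,
        coverage={CHROM: coverage}, cell_line_of=cell_line_of,
    )
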