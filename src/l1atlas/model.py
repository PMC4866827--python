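"""Shared domain types and the pipeline configuration.

All genomic coordinates are stored 0-based, half-open (BED convention).
Any 1-based surface — reports, the L1HS consensus positions of the
subfamily-diagnostic trinucleotide — is converted exactly once, at the
boundary where it enters or leaves the package.

Orientation convention (shared with the simulator and property-tested):
an L1 element on the + strand of the genome yields 3'-ATLAS flank reads
mapping on the - strand (the reads run from the downstream genomic break
back toward the element), and 5'-ATLAS reads — after the prescribed
reverse-complementation — mapping on the + strand.  The mirror holds for
elements on the - strand.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Tuple


class ConfigError(ValueError):
    """A pipeline configuration value violates its invariant."""


@dataclass(frozen=True)
class PipelineConfig:
    """Every tunable constant of the pipeline, with its working default.

    Defaults reflect the standard ATLAS-seq analysis settings: cutadapt-style
    trimming at 12% error rate with 8 nt minimum adapter overlap and a 25 nt
    minimum read length, Q12 quality trimming, MAPQ gates of >20 for insertion
    calling, >15 for split-read segments and >=20 for RNA fragments, 100 bp
    same-strand cluster merging, a 7 kb 5'/3' pairing window, 200 bp windows
    for matching known insertions, the RB3PA1 spurious-priming map built from
    exact suffixes down to 8 nt plus the full 22-mer at <=2 mismatches,
    >=3-read cluster support, 1 kb expression flanks at a 0.05 FPKM
    threshold, and the 5927-5929 (1-based) diagnostic trinucleotide of the
    L1HS consensus.
    """

    min_read_len: int = 25          # nt, post-trimming minimum flank length
    adapter_error_rate: float = 0.12
    min_adapter_overlap: int = 8    # nt, partial 3' adapter matches
    quality_trim_threshold: int = 12  # phred
    min_5prime_read_len: int = 133  # nt, raw 5'-ATLAS size selection
    mapq_min_call: int = 20         # exclusive: MAPQ <= 20 removed
    mapq_min_split: int = 15        # exclusive: both split segments need MAPQ > 15
    mapq_min_rna: int = 20          # inclusive: RNA fragments need MAPQ >= 20
    cluster_merge_gap: int = 100    # bp, reads separated by <= gap merge
    fulllength_pair_window: int = 7000  # bp upstream for 5' cluster pairing
    known_insertion_window: int = 200   # bp for catalog matching
    primer_min_suffix: int = 8      # nt, shortest exact primer suffix mapped
    primer_full_mismatches: int = 2  # substitutions allowed on the full primer
    support_min_3p_reads: int = 3   # non-redundant 3' reads for support
    expression_flank: int = 1000    # bp, FPKM quantification window
    expressed_fpkm_threshold: float = 0.05
    diag_positions: Tuple[int, int, int] = (5927, 5928, 5929)  # 1-based consensus
    lineage_error_rate: float = 0.1
    lineage_min_overlap: int = 16   # nt
    profile_bin: int = 50           # bp, flank metaprofile bin width
    preta_support_ratio: float = 10.0  # fold, diagnostic only
    transduction_window: int = 500  # bp, split-segment adjacency


_RATE_FIELDS = {"adapter_error_rate", "lineage_error_rate"}


def validate_config(config: PipelineConfig) -> PipelineConfig:
    """Return ``config`` unchanged if every invariant holds.

    Raises :class:`ConfigError` naming the offending field otherwise.
    """
    for f in dataclasses.fields(config):
        value = getattr(config, f.name)
        if f.name == "diag_positions":
            if len(value) != 3 or list(value) != [value[0], value[0] + 1, value[0] + 2]:
                raise ConfigError(
                    "diag_positions must be a contiguous 1-based length-3 window, "
                    f"got {value!r}"
                )
            if value[0] <= 0:
                raise ConfigError(f"diag_positions must be positive, got {value!r}")
            continue
        if not isinstance(value, (int, float)) or isinstance(value, bool):
            raise ConfigError(f"{f.name} must be numeric, got {value!r}")
        if value <= 0:
            raise ConfigError(f"{f.name} must be strictly positive, got {value!r}")
        if f.name in _RATE_FIELDS and not (0.0 < value < 1.0):
            raise ConfigError(f"{f.name} must lie in (0, 1), got {value!r}")
    return config


DEFAULT_CONFIG = validate_config(PipelineConfig())


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """0-based half-open interval, strand in {+, -, .}."""

    chrom: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self) -> None:
        if not self.chrom:
            raise ValueError("chrom must be non-empty")
        if not (0 <= self.start < self.end):
            raise ValueError(f"require 0 <= start < end, got [{self.start}, {self.end})")
        if self.strand not in {"+", "-", "."}:
            raise ValueError(f"invalid strand {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )

    def distance_to_point(self, chrom: str, point: int) -> Optional[int]:
        """Distance from ``point`` to this interval (0 if inside), or None if
        on another chromosome."""
        if chrom != self.chrom:
            return None
        if point < self.start:
            return self.start - point
        if point >= self.end:
            return point - self.end + 1
        return 0


@dataclass(frozen=True)
class RawRead:
    """A raw sequencing read; qualities are phred scores, same length."""

    id: str
    sequence: str
    qualities: Tuple[int, ...]
    sample: str = "unassigned"

    def __post_init__(self) -> None:
        if len(self.sequence) != len(self.qualities):
            raise ValueError(
                f"read {self.id}: sequence length {len(self.sequence)} != "
                f"qualities length {len(self.qualities)}"
            )


@dataclass(frozen=True)
class FeatureFlags:
    """Which grammar features were found (and removed) during trimming."""

    linker: bool = False
    primer: bool = False
    l1_end: bool = False
    polyA: bool = False


@dataclass(frozen=True)
class TrimmedRead:
    """An ATLAS read reduced to its genomic flank, oriented flank -> L1."""

    id: str
    flank_seq: str
    side: str  # three_prime | five_prime
    features_found: FeatureFlags
    original_len: int
    sample: str = "unassigned"

    def __post_init__(self) -> None:
        if self.side not in {"three_prime", "five_prime"}:
            raise ValueError(f"invalid side {self.side!r}")
        if not self.features_found.linker:
            raise ValueError("a TrimmedRead always carries its linker flag")


@dataclass(frozen=True)
class ClipSegment:
    """Mapping of the soft-clipped tail of a split read."""

    clipped_seq: str
    clipped_locus: GenomicInterval
    clipped_mapq: int


@dataclass(frozen=True)
class MappedRead:
    """A trimmed flank read with its genome alignment.

    ``linker_pos`` is the genomic coordinate of the fragmentation break
    (the flank-distal read end): ``locus.start`` for + strand alignments,
    ``locus.end`` for - strand alignments.
    """

    read_id: str
    locus: GenomicInterval
    mapq: int
    side: str = "three_prime"
    features_found: FeatureFlags = field(default_factory=FeatureFlags)
    is_secondary: bool = False
    clip: Optional[ClipSegment] = None
    sample: str = "unassigned"

    def __post_init__(self) -> None:
        if self.locus.strand not in {"+", "-"}:
            raise ValueError("a mapped read must carry a strand")

    @property
    def linker_pos(self) -> int:
        return self.locus.start if self.locus.strand == "+" else self.locus.end

    @property
    def length(self) -> int:
        return len(self.locus)


@dataclass
class ReadCluster:
    """A strand-aware merge of non-redundant flank reads."""

    span: GenomicInterval
    side: str
    members: List[MappedRead]
    n_redundant: int
    n_nonredundant: int
    n_polyA_or_l1: int
    rpm: Optional[float] = None
    tpm: Optional[float] = None

    def validate(self, gap: int) -> None:
        if self.n_nonredundant != len(self.members) or self.n_nonredundant < 1:
            raise ValueError("n_nonredundant must equal len(members) >= 1")
        if self.n_redundant < self.n_nonredundant:
            raise ValueError("n_redundant < n_nonredundant")
        if self.n_polyA_or_l1 > self.n_nonredundant:
            raise ValueError("n_polyA_or_l1 > n_nonredundant")
        strands = {m.locus.strand for m in self.members}
        sides = {m.side for m in self.members}
        if len(strands) != 1 or len(sides) != 1:
            raise ValueError("cluster members must share strand and side")
        loci = sorted(self.members, key=lambda m: m.locus.start)
        for a, b in zip(loci, loci[1:]):
            if b.locus.start - a.locus.end > gap:
                raise ValueError("cluster members separated by more than the merge gap")


@dataclass(frozen=True)
class FilterVerdicts:
    """Independent boolean verdicts of the three in-silico filters."""

    support_pass: bool = True
    primer_artifact: bool = False
    preta: bool = False

    @property
    def retained(self) -> bool:
        return self.support_pass and not self.primer_artifact and not self.preta


@dataclass
class InsertionCall:
    """One putative L1HS-Ta locus."""

    call_id: str
    chrom: str
    insertion_point: int          # 0-based coordinate of the 3' junction
    orientation: str              # strand of the L1 sense sequence: + or -
    three_prime_cluster: ReadCluster
    five_prime_cluster: Optional[ReadCluster] = None
    full_length: bool = False
    pair_distance: Optional[int] = None
    is_reference: bool = False
    known_status: str = "novel"   # reference | known_polymorphic | novel
    gene_context: str = "intergenic"  # genic_sense | genic_antisense | genic_both | intergenic
    cnv_state: str = "unknown"    # amplified | normal | het_deletion | uncovered | unknown
    filter_verdicts: FilterVerdicts = field(default_factory=FilterVerdicts)
    lineage: Optional[str] = None
    sample: str = "unassigned"
    preta_support_ratio: Optional[float] = None  # diagnostic, vs median Ta support

    def __post_init__(self) -> None:
        if self.orientation not in {"+", "-"}:
            raise ValueError(f"invalid orientation {self.orientation!r}")
        if self.full_length != (self.five_prime_cluster is not None):
            raise ValueError("full_length <=> five_prime_cluster present")
        if self.full_length != (self.pair_distance is not None):
            raise ValueError("pair_distance present <=> full_length")

    @property
    def retained(self) -> bool:
        return self.filter_verdicts.retained


@dataclass
class PrimerSiteMap:
    """Genome-wide map of partial primer matches.

    ``sites`` maps (chrom, start, strand) -> matched length in nt, keeping the
    longest matching form at each position.
    """

    primer: str
    sites: Dict[Tuple[str, int, str], int] = field(default_factory=dict)

    def overlapping(self, interval: GenomicInterval) -> List[Tuple[str, int, str, int]]:
        hits = []
        for (chrom, start, strand), length in self.sites.items():
            if chrom == interval.chrom and start < interval.end and start + length > interval.start:
                hits.append((chrom, start, strand, length))
        return hits


@dataclass(frozen=True)
class TransductionEvent:
    """A progeny insertion linked to its 3'-transduction progenitor."""

    progeny_call_id: str
    progenitor_call_id: str
    n_support_reads: int
    transduced_span: GenomicInterval

    def __post_init__(self) -> None:
        if self.progeny_call_id == self.progenitor_call_id:
            raise ValueError("progeny and progenitor must be distinct calls")
        if self.n_support_reads < 1:
            raise ValueError("n_support_reads must be >= 1")


@dataclass(frozen=True)
class LineageTag:
    name: str
    sequence: str


#: The three extensively characterized hot-L1 lineages with their
#: transduction-specific tag sequences.
DEFAULT_LINEAGE_TAGS: Tuple[LineageTag, ...] = (
    LineageTag("AC002980", "GCTTTATTGAGGTGTAACCAGCA"),
    LineageTag("RP", "TAAATTTAAAACTTTTTTTTTT"),
    LineageTag("LRE3", "CGGAATAGACATTTTGCTTTTCT"),
)


#: Distinguished sentinel for a locus absent from a sample's genome.  Never
#: conflated with an FPKM of 0 (an absent copy cannot be non-expressed).
ABSENT = float("nan")


_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]
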