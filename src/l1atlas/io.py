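"""Format readers/writers and the end-to-end pipeline driver.

SAM is read and written through pysam; flank-read metadata that SAM does
not model natively travels in private tags: ``ZS`` (ATLAS side, 3/5),
``ZB`` (sample), ``ZF`` (feature flags as four 0/1 characters:
linker, primer, l1_end, polyA), ``ZT`` (clipped tail sequence), plus the
standard ``SA`` tag for the clipped segment's locus and mapping quality.
Calls are serialized as BED6+ with documented extra columns and as
JSON-lines carrying the full record.
"""

from __future__ import annotations

import dataclasses
import json
import hashlib
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Optional, Sequence

import pysam
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from . import caller, filters, preprocess
from .model import (
    ClipSegment,
    DEFAULT_CONFIG,
    FeatureFlags,
    GenomicInterval,
    InsertionCall,
    MappedRead,
    PipelineConfig,
    PrimerSiteMap,
    RawRead,
)

__version__ = "0.1.0"


# --------------------------------------------------------------- FASTQ/FASTA

def read_fastq(path: str) -> List[RawRead]:
    reads = []
    for rec in SeqIO.parse(path, "fastq"):
        reads.append(
            RawRead(rec.id, str(rec.seq),
                    tuple(rec.letter_annotations["phred_quality"]))
        )
    return reads


def write_fastq(reads: Iterable[RawRead], path: str) -> None:
    records = []
    for r in reads:
        rec = SeqRecord(Seq(r.sequence), id=r.id, description="")
        rec.letter_annotations["phred_quality"] = list(r.qualities)
        records.append(rec)
    SeqIO.write(records, path, "fastq")


def read_fasta(path: str) -> Dict[str, str]:
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(path, "fasta")}


def write_fasta(seqs: Dict[str, str], path: str) -> None:
    SeqIO.write(
        [SeqRecord(Seq(s), id=name, description="") for name, s in seqs.items()],
        path, "fasta",
    )


# --------------------------------------------------------------------- SAM

def _flags_to_zf(f: FeatureFlags) -> str:
    return "".join("1" if x else "0" for x in (f.linker, f.primer, f.l1_end, f.polyA))


def _zf_to_flags(zf: str) -> FeatureFlags:
    return FeatureFlags(*(c == "1" for c in zf))


def write_sam(
    reads: Sequence[MappedRead],
    path: str,
    chrom_sizes: Dict[str, int],
) -> None:
    """Write mapped flank reads as coordinate-sorted SAM."""
    header = {
        "HD": {"VN": "1.6", "SO": "coordinate"},
        "SQ": [{"SN": c, "LN": n} for c, n in sorted(chrom_sizes.items())],
    }
    ordered = sorted(reads, key=lambda r: (r.locus.chrom, r.locus.start, r.read_id))
    with pysam.AlignmentFile(path, "w", header=header) as out:
        for r in ordered:
            a = pysam.AlignedSegment(out.header)
            a.query_name = r.read_id
            a.reference_name = r.locus.chrom
            a.reference_start = r.locus.start
            a.mapping_quality = r.mapq
            a.flag = (16 if r.locus.strand == "-" else 0) | (256 if r.is_secondary else 0)
            clip_len = len(r.clip.clipped_seq) if r.clip else 0
            if clip_len:
                a.cigarstring = f"{len(r.locus)}M{clip_len}S"
            else:
                a.cigarstring = f"{len(r.locus)}M"
            tags = [
                ("ZS", "3" if r.side == "three_prime" else "5"),
                ("ZB", r.sample),
                ("ZF", _flags_to_zf(r.features_found)),
            ]
            if r.clip:
                cl = r.clip.clipped_locus
                tags.append(
                    ("SA",
                     f"{cl.chrom},{cl.start + 1},{cl.strand},{len(cl)}M,"
                     f"{r.clip.clipped_mapq},0;")
                )
                tags.append(("ZT", r.clip.clipped_seq or "*"))
            a.set_tags(tags)
            out.write(a)


def read_alignments(path: str) -> List[MappedRead]:
    """Load SAM/BAM records into MappedRead objects.

    The clipped segment of a split read is recovered from the SA tag and
    the ZT sequence tag when present.  Malformed records raise with the
    read name.
    """
    reads = []
    with pysam.AlignmentFile(path, "r", check_sq=False) as fh:
        for a in fh:
            if a.is_unmapped:
                continue
            try:
                locus = GenomicInterval(
                    a.reference_name, a.reference_start,
                    a.reference_start + (a.reference_length or a.query_length),
                    "-" if a.is_reverse else "+",
                )
                clip = None
                if a.has_tag("SA"):
                    sa = a.get_tag("SA").rstrip(";").split(";")[0].split(",")
                    chrom, pos1, strand, cigar, mapq = sa[0], int(sa[1]), sa[2], sa[3], int(sa[4])
                    length = sum(
                        int(x) for x in _cigar_ref_lengths(cigar)
                    )
                    seq = a.get_tag("ZT") if a.has_tag("ZT") else ""
                    clip = ClipSegment(
                        clipped_seq="" if seq == "*" else seq,
                        clipped_locus=GenomicInterval(chrom, pos1 - 1, pos1 - 1 + length, strand),
                        clipped_mapq=mapq,
                    )
                reads.append(
                    MappedRead(
                        read_id=a.query_name,
                        locus=locus,
                        mapq=a.mapping_quality,
                        side=(
                            "five_prime"
                            if a.has_tag("ZS") and a.get_tag("ZS") == "5"
                            else "three_prime"
                        ),
                        features_found=(
                            _zf_to_flags(a.get_tag("ZF")) if a.has_tag("ZF")
                            else FeatureFlags()
                        ),
                        is_secondary=a.is_secondary,
                        clip=clip,
                        sample=a.get_tag("ZB") if a.has_tag("ZB") else "unassigned",
                    )
                )
            except (ValueError, IndexError) as exc:
                raise ValueError(f"malformed record {a.query_name!r}: {exc}") from exc
    return reads


def _cigar_ref_lengths(cigar: str) -> List[int]:
    out, num = [], ""
    for ch in cigar:
        if ch.isdigit():
            num += ch
        else:
            if ch in "MDN=X":
                out.append(int(num))
            num = ""
    return out


# --------------------------------------------------------------------- BED

def read_bed(path: str) -> List[GenomicInterval]:
    """Read a BED3/BED6 catalog; malformed lines raise with their number."""
    out = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            try:
                chrom, start, end = parts[0], int(parts[1]), int(parts[2])
                strand = parts[5] if len(parts) > 5 and parts[5] in "+-" else "."
                out.append(GenomicInterval(chrom, start, end, strand))
            except (ValueError, IndexError) as exc:
                raise ValueError(f"{path}:{lineno}: malformed BED record: {exc}") from exc
    return out


def write_bed(intervals: Iterable[GenomicInterval], path: str, names: Optional[Sequence[str]] = None) -> None:
    ivs = list(intervals)
    with open(path, "w") as fh:
        for i, iv in enumerate(ivs):
            name = names[i] if names else f"feature_{i + 1}"
            fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t{name}\t0\t{iv.strand}\n")


CALL_BED_COLUMNS = (
    "chrom", "start", "end", "call_id", "n_nonredundant", "strand",
    "side", "full_length", "pair_distance", "known_status",
    "support_pass", "primer_artifact", "preta", "lineage",
)


def write_calls(calls: Sequence[InsertionCall], path: str, fmt: str = "bed") -> None:
    """Serialize calls deterministically (chrom, coordinate, call_id).

    ``bed``: BED6+ with a header comment naming the extra columns.
    ``jsonl``: the full record, one JSON object per line.
    """
    ordered = sorted(calls, key=lambda c: (c.chrom, c.insertion_point, c.call_id))
    if fmt == "bed":
        with open(path, "w") as fh:
            fh.write("#" + "\t".join(CALL_BED_COLUMNS) + "\n")
            for c in ordered:
                v = c.filter_verdicts
                fh.write(
                    "\t".join(str(x) for x in (
                        c.chrom, c.insertion_point, c.insertion_point + 1,
                        c.call_id, c.three_prime_cluster.n_nonredundant,
                        c.orientation, c.three_prime_cluster.side,
                        int(c.full_length),
                        c.pair_distance if c.pair_distance is not None else ".",
                        c.known_status, int(v.support_pass),
                        int(v.primer_artifact), int(v.preta), c.lineage or ".",
                    )) + "\n"
                )
    elif fmt == "jsonl":
        with open(path, "w") as fh:
            for c in ordered:
                fh.write(json.dumps(call_to_record(c), sort_keys=True) + "\n")
    else:
        raise ValueError(f"unknown format {fmt!r}")


def call_to_record(c: InsertionCall) -> dict:
    def cluster(cl):
        if cl is None:
            return None
        return {
            "chrom": cl.span.chrom, "start": cl.span.start, "end": cl.span.end,
            "strand": cl.span.strand, "side": cl.side,
            "n_redundant": cl.n_redundant, "n_nonredundant": cl.n_nonredundant,
            "n_polyA_or_l1": cl.n_polyA_or_l1, "rpm": cl.rpm, "tpm": cl.tpm,
        }

    return {
        "call_id": c.call_id, "chrom": c.chrom,
        "insertion_point": c.insertion_point, "orientation": c.orientation,
        "full_length": c.full_length, "pair_distance": c.pair_distance,
        "is_reference": c.is_reference, "known_status": c.known_status,
        "gene_context": c.gene_context, "cnv_state": c.cnv_state,
        "sample": c.sample, "lineage": c.lineage,
        "filter_verdicts": dataclasses.asdict(c.filter_verdicts),
        "three_prime_cluster": cluster(c.three_prime_cluster),
        "five_prime_cluster": cluster(c.five_prime_cluster),
    }


def read_calls_bed(path: str) -> List[dict]:
    """Parse a calls BED back into plain records (round-trip surface)."""
    out = []
    with open(path) as fh:
        for line in fh:
            if line.startswith("#"):
                continue
            f = line.rstrip("\n").split("\t")
            out.append(dict(zip(CALL_BED_COLUMNS, f)))
    return out


# ------------------------------------------------------------------ config

def read_config_file(path: str) -> PipelineConfig:
    """Flat key=value text file mirroring PipelineConfig fields."""
    kwargs: Dict[str, object] = {}
    fields = {f.name: f for f in dataclasses.fields(PipelineConfig)}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.split("#")[0].strip()
            if not line:
                continue
            if "=" not in line:
                raise ValueError(f"{path}:{lineno}: expected key=value")
            key, _, raw = line.partition("=")
            key, raw = key.strip(), raw.strip()
            if key not in fields:
                raise ValueError(f"{path}:{lineno}: unknown config key {key!r}")
            if key == "diag_positions":
                kwargs[key] = tuple(int(x) for x in raw.split(","))
            elif "." in raw or "e" in raw.lower():
                kwargs[key] = float(raw)
            else:
                kwargs[key] = int(raw)
    from .model import validate_config
    return validate_config(PipelineConfig(**kwargs))


# ---------------------------------------------------------------- pipeline

@dataclass
class RunManifest:
    """Machine-readable record of a pipeline run."""

    version: str = __version__
    seed: Optional[int] = None
    config: Dict[str, object] = field(default_factory=dict)
    counts: Dict[str, int] = field(default_factory=dict)
    input_checksums: Dict[str, str] = field(default_factory=dict)

    def check_consistency(self) -> None:
        c = self.counts
        stages = [
            ("reads_3p_in", "reads_3p_trimmed"),
            ("alignments_in", "alignments_filtered"),
            ("calls_total", "calls_retained"),
        ]
        for a, b in stages:
            if a in c and b in c and c[b] > c[a]:
                raise ValueError(f"manifest inconsistency: {b} > {a}")

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self), sort_keys=True, indent=2)


def checksum_text(text: str) -> str:
    return hashlib.sha256(text.encode()).hexdigest()[:16]


@dataclass
class PipelineResult:
    calls: List[InsertionCall]
    site_map: Optional[PrimerSiteMap]
    manifest: RunManifest
    trimmed_3p: List
    trimmed_5p: List


def run_pipeline(
    reads_3p: Sequence[RawRead],
    reads_5p: Sequence[RawRead],
    alignments: Dict[str, MappedRead],
    refs: Dict[str, str],
    genome: Optional[Dict[str, str]] = None,
    catalogs: Optional[Dict[str, Sequence[GenomicInterval]]] = None,
    config: PipelineConfig = DEFAULT_CONFIG,
    sample: str = "S1",
    primer: Optional[str] = None,
    seed: Optional[int] = None,
    barcodes: Optional[Dict[str, str]] = None,
) -> PipelineResult:
    """The full in-memory chain: trim -> join alignments -> dedup ->
    cluster -> call -> pair -> annotate -> filter.

    ``refs`` carries the adapter reference sequences (``linker``,
    ``primer``, ``l1_3p_end``, ``l1_5p_end``).  ``alignments`` maps read
    id to its genome alignment (from any external aligner, or the
    simulator); reads rejected during trimming are excluded even when an
    alignment exists.  When ``genome`` and ``primer`` are given the
    spurious-priming site map is built and applied.
    """
    manifest = RunManifest(seed=seed, config=dataclasses.asdict(config))
    manifest.counts["reads_3p_in"] = len(reads_3p)
    manifest.counts["reads_5p_in"] = len(reads_5p)

    if barcodes:
        demux3, un3 = preprocess.demultiplex(reads_3p, barcodes, config.min_read_len)
        demux5, un5 = preprocess.demultiplex(reads_5p, barcodes, config.min_read_len)
        reads_3p = demux3.get(sample, [])
        reads_5p = demux5.get(sample, [])
        manifest.counts["reads_unassigned"] = un3 + un5

    trimmed_3p, trimmed_5p = [], []
    for read in reads_3p:
        res = preprocess.trim_three_prime_read(read, refs, config)
        if not isinstance(res, preprocess.Rejection):
            trimmed_3p.append(res)
    refs5 = dict(refs)
    if "l1_5p_end" in refs:
        refs5["l1_5p_end"] = refs["l1_5p_end"]
    if "primer_5p" in refs:
        refs5["primer"] = refs["primer_5p"]
    for read in reads_5p:
        res = preprocess.trim_five_prime_read(read, refs5, config)
        if not isinstance(res, preprocess.Rejection):
            trimmed_5p.append(res)
    manifest.counts["reads_3p_trimmed"] = len(trimmed_3p)
    manifest.counts["reads_5p_trimmed"] = len(trimmed_5p)

    joined: List[MappedRead] = []
    for tr in trimmed_3p + trimmed_5p:
        aln = alignments.get(tr.id)
        if aln is None:
            continue
        joined.append(
            dataclasses.replace(
                aln, features_found=tr.features_found,
                side=tr.side, sample=sample,
            )
        )
    manifest.counts["alignments_in"] = len(joined)
    filtered = caller.filter_alignments(joined, config.mapq_min_call)
    manifest.counts["alignments_filtered"] = len(filtered)

    calls = caller.call_sample(filtered, sample=sample, config=config)
    manifest.counts["clusters_3p"] = len(calls)
    manifest.counts["calls_total"] = len(calls)
    manifest.counts["calls_full_length"] = sum(c.full_length for c in calls)

    catalogs = catalogs or {}
    caller.annotate_calls(calls, catalogs, config.known_insertion_window)

    site_map = None
    if genome is not None and primer is not None:
        site_map = filters.build_primer_site_map(
            genome, primer, config.primer_min_suffix, config.primer_full_mismatches
        )
        manifest.counts["primer_sites"] = len(site_map.sites)
    filters.apply_filters(
        calls, site_map, catalogs.get("old_subfamily", ()), config
    )
    manifest.counts["calls_retained"] = sum(c.retained for c in calls)
    manifest.check_consistency()
    return PipelineResult(
        calls=calls, site_map=site_map, manifest=manifest,
        trimmed_3p=trimmed_3p, trimmed_5p=trimmed_5p,
    )
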