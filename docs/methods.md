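# Methods

This note documents the models and procedures implemented in `l1atlas`,
the parameters that matter, the design choices made where the design was
genuinely open, and what the synthetic-data generator does and does not
emulate.

## Coordinate and orientation conventions

All coordinates are 0-based, half-open (BED-compatible). Surfaces that are
conventionally 1-based — the consensus positions of the subfamily
diagnostic trinucleotide, BED-style reports — convert exactly once at the
boundary. An L1 element on the + genome strand produces 3'-side flank reads
mapping on the − strand (reads run from the downstream sonication break
back toward the element) and 5'-side reads, after reverse-complementation,
mapping on +; the mirror holds for − elements. The simulator and the caller
share this convention and it is property-tested end to end.

## Read grammar and trimming

A 3'-side junction read is `barcode + linker + genomic flank + polyA +
L1 3' end + primer`; a 5'-side read is `primer + L1 5' end +
revcomp(flank) + linker`. Demultiplexing requires a perfect barcode match.
Adapter search is a semi-global alignment with cutadapt semantics: partial
occurrences are allowed at the anchored read end with a minimum overlap of
8 nt, and the error budget is `floor(error_rate × aligned adapter length)`
(default rate 0.12), counting substitutions and indels alike. Ties are
broken toward fewest errors, then longest match, then the most distal
occurrence for 3'-anchored searches (leftmost otherwise). An exact
substring fast path short-circuits the dynamic program; a brute-force
enumeration oracle checks the DP in the test suite.

3' trimming: linker removed from the 5' end (reads without a linker are
dropped), running-sum quality trimming at Q12, then iterative removal at
the 3' end of primer, L1 3'-end sequence and the most terminal poly(A) run
(≥3 nt to set the flag — permissive, because the flag feeds the support
filter), repeated until a full pass removes nothing. Reads with no 3'
feature are kept: they usually did not reach the junction. Flanks shorter
than 25 nt are dropped. 5' trimming: raw reads under 133 nt are dropped
(they cannot span primer + L1 end + a useful flank + linker), then primer
and L1 5'-end are stripped from the 5' end and the linker from the 3' end;
a missing feature drops the read; the flank is reverse-complemented so
both libraries read flank→element.

A genomic adenine immediately abutting the poly(A) tail is inherently
indistinguishable from the tail, so the poly(A) strip may absorb trailing
flank A's. Junction coordinates are unaffected (they come from the
alignment), and the recovery tests account for this explicitly.

## Calling

Alignment gates: secondary alignments and MAPQ ≤ 20 removed (strict
inequality: 21 is kept). PCR duplicates share a fragmentation break, i.e.
the mapped coordinate of the flank-distal read end (leftmost base for +
reads, rightmost for −); each duplicate group keeps its longest read, ties
broken by smallest read id for determinism. Clustering merges same-strand
reads that overlap or lie within 100 bp (≤ 100, matching bedtools `-d`
semantics; the 100/101 boundary is covered by tests and cross-checked
against bedtools itself). The insertion point is the cluster hull's most
upstream coordinate for sense 3' clusters and most downstream for
antisense (mirrored for 5' clusters), which is exact on error-free data
because every 3' read ends at the junction.

Full-length pairing: each 3' call takes the nearest orientation-compatible
5' cluster whose 5' end lies within 7 kb upstream in element coordinates;
a 5' cluster pairs at most once (one-to-one; the possibility of a single
5' cluster serving two tandem 3' calls is deliberately excluded and such
conflicts simply remain unpaired). The recorded distance is bimodal by
construction: ~6 kb when the element body lies in the reference assembly,
~0 for non-reference insertions.

Annotation: an insertion is "known" when it falls within 200 bp of a
catalog record (reference elements first, then known polymorphic);
gene context is sense/antisense/both against overlapping stranded gene
records; CNV state is copied from the overlapping segment, with
"uncovered" excluded from downstream ploidy analyses. RPM/TPM normalize
redundant/non-redundant cluster counts per million mapped reads.

## Filters

Three independent, order-commuting verdicts:

* **support**: ≥3 non-redundant 3' reads with ≥1 ending in poly(A) or L1
  sequence, or ≥1 5' plus ≥1 3' non-redundant read.
* **spurious priming**: the genome-wide primer-site map records every exact
  3'-suffix of the primer down to 8 nt (both strands) plus the full 22-mer
  at ≤2 substitutions (substitutions only — suffix matching is exact by
  construction), keeping the longest form per position. A non-reference
  call is an artifact when a mapped site lies within, or within 200 bp of,
  its 3' cluster span *and* at least one supporting read is flank
  immediately followed by primer with neither L1 nor poly(A). The 200 bp
  tolerance exists because trimming removes the primer before mapping, so
  the flank cluster ends exactly where the priming site begins.
* **older subfamily**: catalog-driven — a junction within 200 bp of an
  annotated older-element 3' end is flagged. The observation that such
  clusters typically carry ~10× fewer reads than genuine young-subfamily
  clusters is surfaced as a diagnostic ratio against the cohort median,
  not used as a hard threshold (no principled cutoff exists).

The discovery rate is the fraction of a fixed reference set with at least
one retained call within 200 bp, with the missed elements returned for
inspection; it can be computed before or after filtering.

## Descent

Transductions: split reads must have both segments above MAPQ 15 (strict);
the primary segment identifies the progeny call (within 500 bp of a 3'
cluster), the clipped tail must map within 500 bp downstream of a
*different* full-length call, on the strand implied by that progenitor's
orientation (transduced sequence sits downstream of the progenitor in its
sense direction). Events aggregate supporting reads per pair; progenies
compatible with multiple progenitors are discarded wholesale. The 500 bp
adjacency window is a package choice (configurable) — the procedure itself
fixes no value.

Lineages: reads still carrying poly(A)/L1/flank sequence are searched
serially for the three tag sequences at error rate 0.1 and minimum overlap
16 (detection only, no trimming), then attributed through their mapped
flank position (primary, MAPQ > 15) to intersecting full-length calls;
matches at older-subfamily reference elements are discarded. Per-call
per-lineage read counts are always reported so that low-complexity
false-positive candidates (an issue for the RP tag, which is mostly A/T
homopolymer) can be reviewed rather than silently accepted.

## Expression

The sense window is the 1 kb immediately downstream of the 3' junction in
the element's sense orientation; the antisense window is the 1 kb upstream
of the element's 5' extremity (junction minus pair distance when the call
is full length) on the opposite strand. A fragment is "in the window" when
its first mate's 5' position falls inside it — a single-point rule that
cannot double count at boundaries. First mates need MAPQ ≥ 20; fragments
at masked exon positions are excluded, but the FPKM denominator keeps the
nominal 1 kb window (no effective-length rescaling; the window is a fixed
design constant). `expressed` means present in the sample's genome *and*
sense FPKM strictly above 0.05; absent copies are NaN throughout and
belong to neither group.

Diagnostic counting requires a read's consensus alignment to span all
three positions (5927–5929, 1-based); partial overlaps are tallied
separately. The half-of-total statistic is the smallest k such that the k
largest FPKM values sum to at least half the vector total (unique
regardless of ties); it is computed over full-length calls, matching the
set the expression matrix quantifies.

Flank metaprofiles average signal in 50 bp bins over ±1 kb around the
junction, per expressed/non-expressed group, with positions inside
annotated element bodies excluded so that reference-element interiors do
not dilute the flanking signal; bins with no unmasked contributor are NaN.

Sample clustering is Ward linkage on Euclidean distances between sample
FPKM vectors (absent loci contribute 0 — a ragged matrix has no defined
distance). scipy's Ward (the squared-distance update, Ward.D2) is used;
replicate-pairing behavior does not depend on the Ward variant. Locus
clustering uses the reciprocal mean product distance
`d(i,j) = 1 / mean over shared samples of (FPKM_i × FPKM_j)`; loci silent
everywhere are excluded first, pairs with no shared sample receive the
mean of all computable distances, and infinite distances (shared samples,
all-zero products) are replaced by the largest finite distance before
linkage.

## The simulator

The generator is the package's study-condition oracle, not a convenience
fixture. Its defaults are the discovery-rate experiment: 123 fixed
(reference) insertions, 22% full length, ≥10 non-redundant 3' reads per
insertion with distinct sonication breaks, 30% PCR duplicates (duplicates
share a linker position and lose 1–10 junction-proximal bases, so the
planted read is always the longest representative), 1% substitution
errors applied uniformly (including barcodes, which realistically loses
~6% of reads to the perfect-match demultiplexer), and 20 spurious-priming
decoy loci whose reads are flank+primer with no poly(A)/L1. Decoy sites
embed the full primer into the genome; the base immediately 5' of the
site is forced to be non-A, because a priming site behind a poly(A)-like
tract is genuinely indistinguishable from a real junction. A synthetic
6019 nt consensus (fixed, independent of the simulation seed) carries the
5'/3' end motifs, the diagnostic ACA and the primer's annealing region,
so reference element bodies create realistic primer-map hits near their
own junctions (exempted by the reference criterion, as in real data).
Truncated insertions keep a uniform 500–5500 nt 3' portion, so 5' pairing
fails for them by construction. Transduction pairs emit split reads whose
clipped tails map 0–200 bp downstream of the progenitor; lineage-tagged
insertions place the tag between flank and poly(A) in their reads, exactly
where a real transduced tag sits.

RNA-seq: each cell line draws a per-locus intensity vector (by default
~5% of full-length loci high, ~10% low, the rest silent; a small fraction
with antisense activity); replicates share the vector and differ only by
Poisson sampling. Fragments are first-mate 5' points on the transcript
strand inside the appropriate 1 kb window, plus a sparse genome-wide
background; library totals are fixed at 2×10^5 so FPKM values are
well-scaled but ~100× larger per fragment than in a deep real library —
the 0.05 threshold therefore separates "any signal" from "no signal" in
simulation, and threshold-boundary behavior is tested directly on
constructed matrices instead. Consensus reads carry ACA/ACG/GAG in
proportions tied to the planted global Ta expression.

What the simulator does not emulate: platform-specific homopolymer
errors, indel sequencing errors, mappability structure (every flank is
uniquely mappable by construction; MAPQ gates are exercised with
constructed records), fragment-length distributions, and genuine
multi-sample ATLAS demultiplexing (one barcode by default). Passing the
recovery tests therefore demonstrates the correctness of the pipeline's
logic under the stated noise model, not robustness to repeat-rich real
genomes.

## Determinism and problem sizes

Every stochastic component consumes a numpy `default_rng` stream derived
from the supplied seed; repeated runs are byte-identical, and pipeline
outputs are sorted deterministically (coordinate, then id; dedup ties by
read id). The bundled experiments run at desk scale — a ~1.3 Mb toy
genome, ~1,900 reads for the discovery experiment, ~60 insertions for the
lineage experiment — sizes chosen so the full test suite and the
reproduction script each complete in well under a minute of CPU while
every planted feature class is still represented many times over.
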