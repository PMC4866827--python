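"""Alignment filtering, deduplication, clustering, insertion-point calls,
5'/3' pairing, annotation and normalization."""

import random

import pytest
from hypothesis import given, settings, strategies as st

import l1atlas as la
from l1atlas.caller import (
    annotate_calls,
    call_insertion_point,
    cluster_reads,
    deduplicate,
    filter_alignments,
    make_calls,
    normalize_counts,
    pair_full_length,
)
from l1atlas.model import (
    FeatureFlags,
    GenomicInterval,
    MappedRead,
)


def mk(read_id, start, end, strand="-", mapq=60, secondary=False, chrom="chr1",
       side="three_prime", polyA=False):
    return MappedRead(
        read_id=read_id,
        locus=GenomicInterval(chrom, start, end, strand),
        mapq=mapq, side=side, is_secondary=secondary,
        features_found=FeatureFlags(linker=True, polyA=polyA),
    )


class TestFilterAlignments:
    def test_mapq_threshold_is_exclusive(self):
        reads = [mk("a", 0, 50, mapq=20), mk("b", 0, 50, mapq=21),
                 mk("c", 0, 50, mapq=60, secondary=True)]
        kept = filter_alignments(reads, 20)
        assert [r.read_id for r in kept] == ["b"]


class TestDeduplicate:
    def test_longest_read_represents_the_group(self):
        # same linker position (end, - strand), lengths 80 and 100
        a, b = mk("a", 120, 200), mk("b", 100, 200)
        kept, redundancy = deduplicate([a, b])
        assert [r.read_id for r in kept] == ["b"]
        assert redundancy["b"] == 2

    def test_distinct_linker_positions_both_kept(self):
        kept, _ = deduplicate([mk("a", 100, 200), mk("b", 100, 210)])
        assert len(kept) == 2

    def test_equal_length_tie_breaks_on_smallest_id(self):
        reads = [mk("rb", 110, 200), mk("ra", 110, 200), mk("rc", 130, 200)]
        kept, redundancy = deduplicate(reads)
        assert [r.read_id for r in kept] == ["ra"]
        assert redundancy["ra"] == 3

    def test_plus_strand_linker_is_start(self):
        # + strand reads share start (the linker side), differ at end
        kept, _ = deduplicate([mk("a", 100, 180, "+"), mk("b", 100, 200, "+")])
        assert [r.read_id for r in kept] == ["b"]


class TestClusterReads:
    def test_gap_within_100_merges(self):
        cl = cluster_reads([mk("a", 100, 200), mk("b", 250, 350)], "three_prime", 100)
        assert len(cl) == 1 and (cl[0].span.start, cl[0].span.end) == (100, 350)

    def test_gap_of_101_splits(self):
        cl = cluster_reads([mk("a", 100, 200), mk("b", 301, 400)], "three_prime", 100)
        assert len(cl) == 2

    def test_gap_of_exactly_100_merges(self):
        cl = cluster_reads([mk("a", 100, 200), mk("b", 300, 400)], "three_prime", 100)
        assert len(cl) == 1

    def test_opposite_strands_never_merge(self):
        cl = cluster_reads([mk("a", 100, 200, "+"), mk("b", 120, 220, "-")],
                           "three_prime", 100)
        assert len(cl) == 2

    def test_unsorted_input_rejected(self):
        with pytest.raises(ValueError):
            cluster_reads([mk("a", 500, 600), mk("b", 100, 200)], "three_prime")

    @settings(max_examples=60, deadline=None, derandomize=True)
    @given(st.lists(
        st.tuples(st.integers(0, 2000), st.integers(1, 120), st.sampled_from("+-")),
        min_size=1, max_size=60,
    ))
    def test_equivalent_to_transitive_closure(self, raw):
        reads = sorted(
            (mk(f"r{i}", s, s + l, strand) for i, (s, l, strand) in enumerate(raw)),
            key=lambda r: (r.locus.chrom, r.locus.start, r.locus.end, r.read_id),
        )
        got = cluster_reads(reads, "three_prime", 100)
        # O(n^2) transitive closure over the "within 100 bp, same strand" relation
        parent = list(range(len(reads)))

        def find(x):
            while parent[x] != x:
                parent[x] = parent[parent[x]]
                x = parent[x]
            return x

        for i in range(len(reads)):
            for j in range(i + 1, len(reads)):
                a, b = reads[i].locus, reads[j].locus
                if a.strand == b.strand and max(a.start, b.start) - min(a.end, b.end) <= 100:
                    parent[find(i)] = find(j)
        groups = {}
        for i, r in enumerate(reads):
            groups.setdefault(find(i), set()).add(r.read_id)
        expected = {frozenset(g) for g in groups.values()}
        observed = {frozenset(m.read_id for m in c.members) for c in got}
        assert observed == expected

    def test_matches_bedtools_merge(self, tmp_path):
        """Independent oracle: bedtools merge -s -d 100 on a random instance."""
        import shutil
        import subprocess

        if shutil.which("bedtools") is None:
            pytest.skip("bedtools unavailable")
        rng = random.Random(3)
        reads = sorted(
            (mk(f"r{i}", s, s + rng.randint(10, 80), rng.choice("+-"))
             for i, s in enumerate(rng.sample(range(5000), 80))),
            key=lambda r: r.locus.start,
        )
        bed = tmp_path / "reads.bed"
        bed.write_text("".join(
            f"chr1\t{r.locus.start}\t{r.locus.end}\t{r.read_id}\t0\t{r.locus.strand}\n"
            for r in sorted(reads, key=lambda r: (r.locus.start, r.locus.end))
        ))
        out = subprocess.run(
            ["bedtools", "merge", "-s", "-d", "100", "-c", "6", "-o", "distinct", "-i", str(bed)],
            capture_output=True, text=True, check=True,
        ).stdout.strip().splitlines()
        expected = {
            (int(f[1]), int(f[2]), f[3]) for f in (l.split("\t") for l in out)
        }
        got = {
            (c.span.start, c.span.end, c.span.strand)
            for c in cluster_reads(reads, "three_prime", 100)
        }
        assert got == expected


class TestInsertionPoint:
    def test_sense_three_prime_cluster(self):
        cl = cluster_reads([mk("a", 1000, 1200), mk("b", 1100, 1400)], "three_prime")[0]
        assert call_insertion_point(cl) == (1000, "+")

    def test_antisense_three_prime_cluster(self):
        cl = cluster_reads([mk("a", 1000, 1200, "+"), mk("b", 1100, 1400, "+")],
                           "three_prime")[0]
        assert call_insertion_point(cl) == (1400, "-")

    def test_five_prime_mirrors(self):
        plus = cluster_reads([mk("a", 1000, 1400, "+", side="five_prime")], "five_prime")[0]
        minus = cluster_reads([mk("a", 1000, 1400, "-", side="five_prime")], "five_prime")[0]
        assert call_insertion_point(plus) == (1400, "+")
        assert call_insertion_point(minus) == (1000, "-")

    def test_planted_coordinates_recovered_exactly(self, clean_sim):
        """Error-free simulation: every planted insertion is called at the
        exact coordinate and orientation (100% recall, 0 bp error)."""
        _, truth, _, result = clean_sim
        planted = {(i.insertion_point, i.orientation) for i in truth.insertions}
        called = {(c.insertion_point, c.orientation) for c in result.calls}
        assert planted <= called
        assert len(called) == len(planted)


class TestPairing:
    def _call(self, point, orientation, chrom="chr1"):
        strand = "-" if orientation == "+" else "+"
        lo = point if orientation == "+" else point - 150
        cl = cluster_reads([mk("a", lo, lo + 150, strand)], "three_prime")[0]
        return make_calls([cl], sample="s")[0]

    def _five(self, start, end, strand):
        return cluster_reads([mk("a", start, end, strand, side="five_prime")],
                             "five_prime")[0]

    def test_six_kb_upstream_pairs(self):
        call = self._call(10_000, "+")
        five = self._five(3_900, 4_000, "+")   # 5' end at 4000, 6000 bp upstream
        out = pair_full_length([call], [five], 7000)
        assert out[0].full_length and out[0].pair_distance == 6000

    def test_eight_kb_upstream_does_not_pair(self):
        call = self._call(10_000, "+")
        out = pair_full_length([call], [self._five(1_900, 2_000, "+")], 7000)
        assert not out[0].full_length and out[0].pair_distance is None

    def test_zero_distance_non_reference_pairs(self):
        call = self._call(10_000, "+")
        out = pair_full_length([call], [self._five(9_900, 10_000, "+")], 7000)
        assert out[0].full_length and out[0].pair_distance == 0

    def test_wrong_orientation_does_not_pair(self):
        call = self._call(10_000, "+")
        out = pair_full_length([call], [self._five(3_900, 4_000, "-")], 7000)
        assert not out[0].full_length

    def test_one_five_prime_cluster_pairs_at_most_once(self):
        calls = [self._call(10_000, "+"), self._call(10_300, "+")]
        five = self._five(9_900, 10_000, "+")
        out = pair_full_length(calls, [five], 7000)
        assert sum(c.full_length for c in out) == 1
        assert out[0].full_length  # the nearest call wins


class TestAnnotate:
    def _call(self, point):
        cl = cluster_reads([mk("a", point, point + 100)], "three_prime")[0]
        return make_calls([cl], sample="s")[0]

    def test_known_within_200bp(self):
        call = self._call(1000)
        annotate_calls([call], {
            "known_polymorphic": [GenomicInterval("chr1", 1150, 1160)],
        })
        assert call.known_status == "known_polymorphic"

    def test_novel_beyond_200bp(self):
        call = self._call(1000)
        annotate_calls([call], {
            "known_polymorphic": [GenomicInterval("chr1", 1300, 1310)],
            "reference_l1": [GenomicInterval("chr1", 5000, 5100)],
        })
        assert call.known_status == "novel" and not call.is_reference

    def test_gene_context_antisense(self):
        call = self._call(1000)   # orientation +
        annotate_calls([call], {"genes": [GenomicInterval("chr1", 500, 2000, "-")]})
        assert call.gene_context == "genic_antisense"

    def test_cnv_state_from_overlap(self):
        call = self._call(1000)
        annotate_calls([call], {
            "cnv": [GenomicInterval("chr1", 0, 5000)],
            "cnv_states": ["amplified"],
        })
        assert call.cnv_state == "amplified"


class TestNormalize:
    def test_rpm_tpm_arithmetic(self):
        cl = cluster_reads([mk(f"r{i}", 100 + i, 300 + i) for i in range(3)],
                           "three_prime")
        cl[0].n_redundant = 10
        out = normalize_counts(cl, 1_000_000, 2_000_000)
        assert out[0].rpm == pytest.approx(10.0)
        assert out[0].tpm == pytest.approx(1.5)

    def test_zero_totals_rejected(self):
        cl = cluster_reads([mk("a", 100, 200)], "three_prime")
        with pytest.raises(ValueError):
            normalize_counts(cl, 0, 10)


class TestOrderInvariance:
    def test_calling_is_invariant_to_read_order(self, clean_sim, refs):
        _, truth, reads, result = clean_sim
        joined = [a for a in reads.alignments.values()]
        rng = random.Random(5)
        shuffled = joined[:]
        rng.shuffle(shuffled)
        c1 = la.call_sample(joined, sample="S1")
        c2 = la.call_sample(shuffled, sample="S1")
        key = lambda cs: [(c.chrom, c.insertion_point, c.orientation,
                           c.three_prime_cluster.n_nonredundant) for c in cs]
        assert key(c1) == key(c2)
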