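"""Flanking-window FPKM, expressed classification, diagnostic trinucleotide
counting, half-of-total statistic, flank metaprofiles and the two
clusterings."""

import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist
from scipy.stats import spearmanr

import l1atlas as la
from l1atlas.caller import cluster_reads, make_calls
from l1atlas.expression import (
    ConsensusRead,
    LocusExpressionMatrix,
    RnaFragment,
    classify_expressed,
    cluster_loci,
    cluster_samples,
    count_diagnostic_trinucleotides,
    flank_profile,
    half_total_contributors,
    quantify_locus,
)
from l1atlas.model import FeatureFlags, GenomicInterval, MappedRead
from l1atlas.simulate import L1HS_CONSENSUS


def plus_call(point=10_000, chrom="chr1"):
    read = MappedRead("r", GenomicInterval(chrom, point, point + 100, "-"), 60,
                      features_found=FeatureFlags(linker=True, polyA=True))
    cl = cluster_reads([read], "three_prime")[0]
    return make_calls([cl], sample="s")[0]


class TestQuantifyLocus:
    def test_empty_window_is_zero(self):
        assert quantify_locus([], plus_call(), [], 1_000_000) == (0.0, 0.0)

    def test_fpkm_arithmetic(self):
        frags = [RnaFragment("chr1", 10_000 + 50 * i, "+", 60) for i in range(7)]
        s, a = quantify_locus(frags, plus_call(), [], 2_000_000)
        assert s == pytest.approx(3.5) and a == 0.0

    def test_mapq_19_not_counted(self):
        frags = [RnaFragment("chr1", 10_050, "+", 19)]
        assert quantify_locus(frags, plus_call(), [], 1_000_000)[0] == 0.0

    def test_exon_masking_drops_fragments(self):
        frags = [RnaFragment("chr1", 10_050, "+", 60),
                 RnaFragment("chr1", 10_500, "+", 60)]
        exons = [GenomicInterval("chr1", 10_000, 10_100)]
        s, _ = quantify_locus(frags, plus_call(), exons, 1_000_000)
        assert s == pytest.approx(1.0)

    def test_antisense_window_is_upstream_opposite_strand(self):
        frags = [RnaFragment("chr1", 9_500, "-", 60)]
        s, a = quantify_locus(frags, plus_call(), [], 1_000_000)
        assert s == 0.0 and a == pytest.approx(1.0)

    def test_scale_equivariance(self):
        """Doubling every count and the library total leaves FPKM fixed."""
        frags = [RnaFragment("chr1", 10_000 + 11 * i, "+", 60) for i in range(9)]
        s1, _ = quantify_locus(frags, plus_call(), [], 500_000)
        s2, _ = quantify_locus(frags * 2, plus_call(), [], 1_000_000)
        assert s1 == pytest.approx(s2)

    def test_strand_flip_moves_signal(self, clean_sim, rna_sim):
        """Planted sense fragments of a locus appear as that locus's sense
        FPKM; the mirrored antisense call sees none of them."""
        import dataclasses

        frags = [RnaFragment("chr1", 10_000 + 13 * i, "+", 60) for i in range(8)]
        call = plus_call()
        s_plus, a_plus = quantify_locus(frags, call, [], 1_000_000)
        flipped = plus_call()
        flipped.orientation = "-"
        s_minus, a_minus = quantify_locus(frags, flipped, [], 1_000_000)
        assert s_plus > 0 and s_minus == 0.0
        # the same fragments land in the flipped call's antisense window
        # only after mirroring the strand as well
        mirrored = [dataclasses.replace(f, strand="+") for f in frags]
        assert quantify_locus(mirrored, flipped, [], 1_000_000)[1] == pytest.approx(s_plus)

    def test_planted_levels_rank_correlate(self, rna_sim):
        truth, rna, fl_calls, matrix = rna_sim
        # compare recovered sense FPKM to planted fragment counts per locus
        sample = matrix.samples[0]
        col = matrix.sense_fpkm[sample].dropna()
        planted_rank = []
        got = []
        pt = {c.call_id: c.insertion_point for c in fl_calls}
        frags = rna.frags_by_sample[sample]
        for cid, fpkm in col.items():
            point = pt[cid]
            near = sum(1 for f in frags if abs(f.pos - point) <= 1000)
            planted_rank.append(near)
            got.append(fpkm)
        rho = spearmanr(planted_rank, got).statistic
        assert rho > 0.9


class TestClassifyExpressed:
    def _matrix(self, values, presence):
        idx = [f"L{i}" for i in range(len(values))]
        sense = pd.DataFrame({"s": values}, index=idx)
        pres = pd.DataFrame({"s": presence}, index=idx)
        return LocusExpressionMatrix(sense, sense.copy(), pres)

    def test_threshold_is_strict(self):
        m = classify_expressed(self._matrix([0.05, 0.051, 0.0], [True] * 3))
        assert list(m.expressed["s"]) == [False, True, False]

    def test_absent_locus_in_neither_group(self):
        m = classify_expressed(self._matrix([np.nan, 1.0], [False, True]))
        assert m.expressed["s"].isna().tolist() == [True, False]
        # absent is a sentinel, not zero
        assert np.isnan(m.sense_fpkm.loc["L0", "s"])


class TestDiagnosticTrinucleotides:
    def test_spelled_trinucleotides_counted(self):
        reads = [
            ConsensusRead(5900, L1HS_CONSENSUS[5900:5975]),                      # ACA
            ConsensusRead(5900, L1HS_CONSENSUS[5900:5926] + "ACG" + L1HS_CONSENSUS[5929:5975]),
            ConsensusRead(5900, L1HS_CONSENSUS[5900:5926] + "GAG" + L1HS_CONSENSUS[5929:5975]),
            ConsensusRead(5900, L1HS_CONSENSUS[5900:5926] + "TTT" + L1HS_CONSENSUS[5929:5975]),
        ]
        out = count_diagnostic_trinucleotides(reads, 10_000_000)
        assert out.counts == {"ACA": 1, "ACG": 1, "GAG": 1, "other": 1}

    def test_incomplete_span_ignored(self):
        reads = [ConsensusRead(5850, L1HS_CONSENSUS[5850:5928])]  # ends at 5928
        out = count_diagnostic_trinucleotides(reads, 1000)
        assert sum(out.counts.values()) == 0 and out.partial == 1

    def test_per_million_normalization(self):
        reads = [ConsensusRead(5900, L1HS_CONSENSUS[5900:5975])] * 50
        out = count_diagnostic_trinucleotides(reads, 10_000_000)
        assert out.per_million["ACA"] == pytest.approx(5.0)

    def test_planted_proportions_recovered(self, rna_sim):
        truth, rna, _, _ = rna_sim
        sample = sorted(rna.consensus_reads)[0]
        out = count_diagnostic_trinucleotides(
            rna.consensus_reads[sample], rna.total_genome_mapped[sample]
        )
        assert out.counts["ACA"] > 0 and out.counts["GAG"] > 0
        assert out.counts["other"] == 0


class TestHalfTotalContributors:
    @pytest.mark.parametrize(
        "vec, expected",
        [([4, 3, 2, 1], 2), ([1.0] * 10, 5), ([7.5], 1), ([1, 0, 0], 1)],
    )
    def test_examples(self, vec, expected):
        assert half_total_contributors(vec) == expected

    def test_all_zero_rejected(self):
        with pytest.raises(ValueError):
            half_total_contributors([0.0, 0.0])

    @settings(max_examples=200, deadline=None, derandomize=True)
    @given(st.lists(st.integers(0, 40), min_size=1, max_size=12).filter(lambda v: sum(v) > 0))
    def test_matches_exhaustive_minimum_subset(self, vec):
        k = half_total_contributors(vec)
        total = sum(vec)
        best = next(
            size
            for size in range(1, len(vec) + 1)
            for combo in itertools.combinations(vec, size)
            if sum(combo) * 2 >= total
        )
        assert k == best


class TestFlankProfile:
    def _calls(self):
        return [plus_call(10_000), plus_call(50_000)]

    def test_constant_signal_gives_flat_profile(self):
        signal = {"chr1": np.ones(100_000)}
        calls = self._calls()
        flags = {calls[0].call_id: True}
        calls[1].call_id = "other"
        flags["other"] = False
        out = flank_profile(signal, calls, flags)
        assert np.allclose(out["expressed"].mean_signal, 1.0)
        assert np.allclose(out["non_expressed"].mean_signal, 1.0)

    def test_planted_upstream_signal_recovered(self):
        signal = {"chr1": np.zeros(100_000)}
        signal["chr1"][9_000:10_000] = 2.0      # upstream of the expressed call
        calls = self._calls()
        calls[1].call_id = "other"
        flags = {calls[0].call_id: True, "other": False}
        out = flank_profile(signal, calls, flags)
        up = out["expressed"].offsets < 0
        assert np.all(out["expressed"].mean_signal[up] == 2.0)
        assert np.all(out["non_expressed"].mean_signal == 0.0)

    def test_masked_internal_region_excluded(self):
        signal = {"chr1": np.ones(100_000)}
        signal["chr1"][9_950:10_000] = 100.0    # inside the mask
        calls = [plus_call(10_000)]
        flags = {calls[0].call_id: True}
        mask = [GenomicInterval("chr1", 9_950, 10_000)]
        out = flank_profile(signal, calls, flags, internal_mask=mask)
        bin_idx = np.where(out["expressed"].offsets == -50)[0][0]
        assert np.isnan(out["expressed"].mean_signal[bin_idx])

    def test_bin_geometry(self):
        out = flank_profile({"chr1": np.ones(100_000)}, [plus_call(10_000)],
                            {plus_call(10_000).call_id: True})
        prof = out["expressed"]
        assert len(prof.offsets) == 40 and prof.offsets[0] == -1000


class TestClusterSamples:
    def test_identical_samples_merge_first(self):
        idx = ["L0", "L1", "L2"]
        sense = pd.DataFrame(
            {"a": [5.0, 0.0, 1.0], "b": [5.0, 0.0, 1.0], "c": [0.0, 9.0, 0.0]},
            index=idx,
        )
        pres = pd.DataFrame(True, index=idx, columns=["a", "b", "c"])
        m = LocusExpressionMatrix(sense, sense.copy(), pres)
        Z, labels = cluster_samples(m)
        first = sorted([labels[int(Z[0, 0])], labels[int(Z[0, 1])]])
        assert first == ["a", "b"] and Z[0, 2] == 0.0

    def test_replicates_are_mutual_nearest_neighbors(self, rna_sim):
        truth, rna, _, matrix = rna_sim
        Z, labels = cluster_samples(matrix)
        # each first-joining pair should be two replicates of one cell line
        n = len(labels)
        merged_pairs = []
        for row in Z:
            i, j = int(row[0]), int(row[1])
            if i < n and j < n:
                merged_pairs.append({labels[i].split("_")[0], labels[j].split("_")[0]})
        assert merged_pairs and all(len(p) == 1 for p in merged_pairs)

    def test_distances_match_direct_euclidean(self, rna_sim):
        _, _, _, matrix = rna_sim
        X = matrix.sense_fpkm.fillna(0.0).T.to_numpy()
        Z, _ = cluster_samples(matrix)
        Z2 = hierarchy.linkage(pdist(X), method="ward")
        assert np.allclose(Z[:, 2], Z2[:, 2])


class TestClusterLoci:
    def _matrix(self):
        idx = ["L0", "L1", "L2", "L3"]
        cols = ["A", "B", "C"]
        sense = pd.DataFrame(
            [[2.0, 4.0, np.nan], [3.0, 1.0, np.nan], [np.nan, np.nan, 5.0],
             [0.0, 0.0, 0.0]],
            index=idx, columns=cols,
        )
        pres = pd.DataFrame(
            [[True, True, False], [True, True, False], [False, False, True],
             [True, True, True]],
            index=idx, columns=cols,
        )
        return LocusExpressionMatrix(sense, sense.copy(), pres)

    def test_reciprocal_mean_product_distance(self):
        m = self._matrix()
        Z, labels = cluster_loci(m)
        # d(L0, L1) over shared samples {A, B}: 1/mean(2*3, 4*1) = 0.2
        assert "L3" not in labels          # silent everywhere -> excluded
        i, j = labels.index("L0"), labels.index("L1")
        # reconstruct the distance from the linkage: the first merge joins
        # the closest pair at its distance
        assert Z[0, 2] == pytest.approx(0.2)
        assert {int(Z[0, 0]), int(Z[0, 1])} == {i, j}

    def test_non_cooccurring_pair_gets_neutral_distance(self):
        m = self._matrix()
        Z, labels = cluster_loci(m)
        # only one computable distance (0.2), so the neutral distance is 0.2
        # and L2 joins at that height
        assert Z[1, 2] == pytest.approx(np.sqrt(np.mean([0.2 ** 2, 0.2 ** 2])), rel=0.5)
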