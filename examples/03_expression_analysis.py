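"""Locus-resolution L1 expression from simulated stranded RNA-seq.

Each full-length copy's own transcription is read from the 1 kb window
immediately downstream of it (sense strand), since alignments inside the
near-identical L1 bodies are uninformative; the upstream window on the
opposite strand reports antisense-promoter activity.  Expression is
FPKM over the fixed window, with >0.05 dividing expressed from
non-expressed copies, and absent polymorphic copies kept distinct from
silent ones.  Global subfamily activity comes from the trinucleotide at
consensus positions 5927-5929 (ACA = the young Ta subfamily).
"""

import l1atlas as la
from l1atlas import simulate as sim

params = la.SimulationParams(
    n_insertions=40, fraction_full_length=0.5, fraction_reference=0.5,
    substitution_rate=0.0, duplicate_rate=0.0, n_primer_decoys=0, seed=9,
)
truth = la.make_genome_and_truth(params)
reads = la.make_atlas_reads(truth, params)
refs = {
    "linker": sim.LINKER, "primer": sim.RB3PA1, "primer_5p": sim.RB5PA2,
    "l1_3p_end": sim.L1_3P_END, "l1_5p_end": sim.L1_5P_END,
}
result = la.run_pipeline(reads.reads_3p, reads.reads_5p, reads.alignments, refs,
                         catalogs=truth.catalogs, barcodes=reads.barcodes)
full_length = [c for c in result.calls if c.full_length]

rna = la.make_rnaseq_fragments(truth, params)
point_to_id = {i.insertion_point: i.insertion_id for i in truth.insertions}
presence = {
    s: {c.call_id: pres.get(point_to_id.get(c.insertion_point, ""), True)
        for c in full_length}
    for s, pres in rna.presence.items()
}
matrix = la.build_expression_matrix(rna.frags_by_sample, full_length, presence,
                                    totals=rna.totals)
matrix = la.classify_expressed(matrix)

print(f"full-length loci quantified: {len(matrix.loci)}")
print("expressed loci per sample:", matrix.expressed.sum().to_dict())

for sample in matrix.samples[:1]:
    v = matrix.sense_fpkm[sample].dropna()
    v = v[v > 0]
    k = la.half_total_contributors(v.to_list())
    print(f"{sample}: {k} locus/loci produce half of the total L1 FPKM "
          f"({len(v)} loci with signal)")

sc = la.count_diagnostic_trinucleotides(
    rna.consensus_reads["C1_R1"], rna.total_genome_mapped["C1_R1"]
)
print("diagnostic trinucleotide counts:", sc.counts)
print(f"Ta reads per million genome-mapped: {sc.per_million['ACA']:.1f}")

Z, labels = la.cluster_samples(matrix)
print("sample dendrogram (replicates pair):")
print(" ", la.linkage_to_newick(Z, labels))
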