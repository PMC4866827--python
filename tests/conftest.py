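"""Shared fixtures: small simulated datasets reused across test modules."""

import pytest

import l1atlas as la
from l1atlas import simulate as sim

REFS = {
    "linker": sim.LINKER,
    "primer": sim.RB3PA1,
    "primer_5p": sim.RB5PA2,
    "l1_3p_end": sim.L1_3P_END,
    "l1_5p_end": sim.L1_5P_END,
}


@pytest.fixture(scope="session")
def refs():
    return dict(REFS)


@pytest.fixture(scope="session")
def clean_sim():
    """Error-free, duplicate-free simulation: 30 insertions, transductions,
    no decoys.  The substrate for exactness properties."""
    params = la.SimulationParams(
        n_insertions=30, fraction_full_length=0.4, fraction_reference=0.5,
        n_transduction_pairs=3, substitution_rate=0.0, duplicate_rate=0.0,
        n_primer_decoys=0, seed=11,
    )
    truth = la.make_genome_and_truth(params)
    reads = la.make_atlas_reads(truth, params)
    result = la.run_pipeline(
        reads.reads_3p, reads.reads_5p, reads.alignments, dict(REFS),
        catalogs=truth.catalogs, barcodes=reads.barcodes,
    )
    return params, truth, reads, result


@pytest.fixture(scope="session")
def noisy_sim():
    """Default study conditions: 123 fixed insertions, 1% substitutions,
    30% duplicates, 20 spurious-priming decoys."""
    params = la.SimulationParams(seed=1)
    truth = la.make_genome_and_truth(params)
    reads = la.make_atlas_reads(truth, params)
    result = la.run_pipeline(
        reads.reads_3p, reads.reads_5p, reads.alignments, dict(REFS),
        genome=truth.genome, catalogs=truth.catalogs,
        primer=sim.RB3PA1, barcodes=reads.barcodes, seed=1,
    )
    return params, truth, reads, result


@pytest.fixture(scope="session")
def rna_sim(clean_sim):
    params, truth, reads, result = clean_sim
    rna = la.make_rnaseq_fragments(truth, params)
    fl_calls = [c for c in result.calls if c.full_length]
    pt2iid = {i.insertion_point: i.insertion_id for i in truth.insertions}
    presence = {
        s: {
            c.call_id: pres.get(pt2iid.get(c.insertion_point, ""), True)
            for c in fl_calls
        }
        for s, pres in rna.presence.items()
    }
    matrix = la.build_expression_matrix(
        rna.frags_by_sample, fl_calls, presence, totals=rna.totals
    )
    return truth, rna, fl_calls, la.classify_expressed(matrix)
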