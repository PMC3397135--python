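import numpy as np
import pytest

from haplopop import simulate


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture
def single_amplicon_config():
    """One 350 bp contig covered by a single amplicon: phase within the
    amplicon is fully determined by read support, so haplotype recovery
    has no unknowable junctions."""
    contig = simulate.ContigSpec("g1", 350, (("a1", 0, 350),))
    def make(**overrides):
        params = dict(n_individuals=30, contigs=(contig,), seed=5)
        params.update(overrides)
        return simulate.SimConfig(**params)
    return make


def call_one_contig(truth, config):
    """Run reads -> demux -> pileup -> variants -> haplotypes for every
    individual on the first contig; returns the list of HaplotypePairs."""
    from haplopop import haplotyper

    contig = config.contigs[0]
    tags = simulate.make_tags(config.n_individuals, config.rng("tags"))
    rng = config.rng("reads")
    reads = []
    for i in range(config.n_individuals):
        reads.extend(simulate.simulate_reads(
            truth.haplotypes[contig.id][i], contig, config, tags[i], rng,
            individual=f"ind{i:03d}"))
    assigned, _ = haplotyper.demultiplex(reads, tags, max_mismatch=1)
    design = haplotyper.AmpliconDesign(contig.id, contig.amplicons)
    ref = truth.references[contig.id]
    pairs = []
    for i in range(config.n_individuals):
        my_reads = assigned[tags[i]]
        if not my_reads:
            pairs.append(haplotyper.HaplotypePair(
                individual=f"ind{i:03d}", contig_id=contig.id,
                haplotype_1=None, haplotype_2=None, coverage_flag="missing"))
            continue
        columns, read_calls = haplotyper.align_and_pileup(my_reads, ref,
                                                          design)
        table = haplotyper.call_variants(columns, ref, contig.id)
        pairs.append(haplotyper.resolve_haplotypes(
            read_calls, table, design, columns, individual=f"ind{i:03d}"))
    return pairs
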