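"""Unit tests for demultiplexing, variant calling, and haplotype resolution."""

from collections import Counter

import numpy as np
import pytest

from haplopop import haplotyper, simulate
from haplopop.haplotyper import (AmpliconDesign, HaplotypePair, PileupColumn,
                                 VariantTable, build_tag, call_variants,
                                 demultiplex, resolve_haplotypes,
                                 genotype_matrix, align_and_pileup)
from haplopop.simulate import SimConfig, ContigSpec, TaggedRead

from conftest import call_one_contig


class TestBuildTag:
    @pytest.mark.parametrize("tag,adapter", [
        ("AAAAAAAA", "AAAAAAAAGCCCGGGCTTTTTTTT"),
        ("ACGTACGT", "ACGTACGTGCCCGGGCACGTACGT"),  # its own revcomp
    ])
    def test_adapter_structure(self, tag, adapter):
        assert build_tag(tag).full_adapter == adapter

    @pytest.mark.parametrize("bad", ["ACGTACG", "ACGTACGTA", "ACGTACGN"])
    def test_invalid_tags(self, bad):
        with pytest.raises(ValueError):
            build_tag(bad)


class TestDemultiplex:
    def test_exact_assignment_and_trim(self):
        tags = ["AAAACCCC", "GGGGTTTT"]
        adapter = build_tag("AAAACCCC").full_adapter
        read = TaggedRead(id="r1", seq=adapter + "ACGTACGT")
        assigned, unassigned = demultiplex([read], tags, max_mismatch=0)
        assert [r.seq for r in assigned["AAAACCCC"]] == ["ACGTACGT"]
        assert not unassigned

    def test_tie_goes_unassigned(self):
        # leading 8-mer one mismatch away from both tags
        tags = ["AAAAAAAA", "AAAAAAAC"]
        read = TaggedRead(id="r1", seq="AAAAAAAG" + "T" * 30)
        assigned, unassigned = demultiplex([read], tags, max_mismatch=1)
        assert not assigned["AAAAAAAA"] and not assigned["AAAAAAAC"]
        assert len(unassigned) == 1

    def test_duplicate_tags_rejected(self):
        with pytest.raises(ValueError):
            demultiplex([], ["AAAACCCC", "AAAACCCC"])

    def test_noise_free_library_fully_assigned(self, single_amplicon_config):
        cfg = single_amplicon_config(n_individuals=6, sub_error_rate=0.0,
                                     homopolymer_indel_rate=0.0,
                                     chimera_rate=0.0)
        truth = simulate.simulate_truth(cfg)
        tags = simulate.make_tags(6, cfg.rng("tags"))
        rng = cfg.rng("reads")
        reads, owner = [], {}
        for i in range(6):
            rs = simulate.simulate_reads(truth.haplotypes["g1"][i],
                                         cfg.contigs[0], cfg, tags[i], rng,
                                         individual=f"ind{i}")
            reads.extend(rs)
            owner.update({r.id: tags[i] for r in rs})
        assigned, unassigned = demultiplex(reads, tags, max_mismatch=0)
        assert not unassigned
        for tag, rs in assigned.items():
            assert all(owner[r.id] == tag for r in rs)


def _columns(counts_by_pos):
    cols = {}
    for pos, counts in counts_by_pos.items():
        cols[pos] = PileupColumn(position=pos, counts=Counter(counts))
    return cols


class TestCallVariants:
    def test_low_frequency_allele_eliminated(self):
        # 4% minor allele is below the 5% floor: monomorphic, no variant
        cols = _columns({0: {"A": 96, "G": 4}})
        table = call_variants(cols, "A", "c")
        assert table.variants == []
        assert table.consensus == "A"

    def test_retained_het_gets_iupac_code(self):
        cols = _columns({0: {"A": 90, "G": 10}})
        table = call_variants(cols, "A", "c")
        assert len(table.variants) == 1
        v = table.variants[0]
        assert v.alts == ("G",) and abs(v.maf - 0.10) < 1e-12
        assert table.consensus == "R"

    def test_zero_depth_column_is_N(self):
        cols = _columns({0: {"A": 50}})
        table = call_variants(cols, "AT", "c")
        assert table.consensus == "AN"

    def test_homozygous_nonreference_is_variant(self):
        cols = _columns({0: {"G": 100}})
        table = call_variants(cols, "A", "c")
        assert len(table.variants) == 1
        assert table.variants[0].alts == ("G",)
        assert table.consensus == "G"

    def test_empty_pileup_rejected(self):
        with pytest.raises(ValueError):
            call_variants({}, "A", "c")


class TestAlignAndPileup:
    design = AmpliconDesign("c", (("a", 0, 40),))
    ref = "ACGTACGTACGTAAAAACGTACGTACGTACGTACGTACGT"

    def test_error_free_read_counts(self):
        read = TaggedRead(id="r", seq=self.ref, amplicon_id="a", offset=0)
        cols, calls = align_and_pileup([read], self.ref, self.design)
        assert all(cols[i].counts[self.ref[i]] == 1 for i in range(40))
        assert calls["r"][1][5] == self.ref[5]

    def test_homopolymer_deletion_registers(self):
        # one base deleted inside the AAAAA run at positions 12-16
        seq = self.ref[:12] + "AAAA" + self.ref[17:]
        read = TaggedRead(id="r", seq=seq, amplicon_id="a", offset=0)
        cols, _ = align_and_pileup([read], self.ref, self.design)
        del_cols = [p for p, c in cols.items() if c.counts["-"] > 0]
        assert len(del_cols) == 1 and 12 <= del_cols[0] <= 16

    def test_read_without_anchor_is_seeded(self):
        read = TaggedRead(id="r", seq=self.ref[8:36])
        cols, calls = align_and_pileup([read], self.ref, self.design)
        assert calls["r"][1][8] == self.ref[8]
        assert min(calls["r"][1]) == 8 and max(calls["r"][1]) == 35

    def test_junk_read_discarded(self):
        read = TaggedRead(id="r", seq="T" * 40, amplicon_id="a", offset=0)
        cols, calls = align_and_pileup([read], self.ref, self.design)
        assert "r" not in calls

    def test_het_site_counts_near_binomial(self, single_amplicon_config):
        cfg = single_amplicon_config(n_individuals=2, sub_error_rate=0.0,
                                     homopolymer_indel_rate=0.0,
                                     chimera_rate=0.0, coverage_mean=100,
                                     seed=9)
        truth = simulate.simulate_truth(cfg)
        h1, h2 = truth.haplotypes["g1"][0]
        het = [i for i, (a, b) in enumerate(zip(h1, h2)) if a != b]
        if not het:
            pytest.skip("no heterozygous site drawn for this seed")
        reads = simulate.simulate_reads((h1, h2), cfg.contigs[0], cfg,
                                        "AAAACCCC", cfg.rng("r"))
        reads = [haplotyper._copy_read(r, r.seq[24:]) for r in reads]
        design = AmpliconDesign("g1", cfg.contigs[0].amplicons)
        cols, _ = align_and_pileup(reads, truth.references["g1"], design)
        pos = het[0]
        n = cols[pos].depth
        k = cols[pos].counts[h1[pos]]
        # 4-sigma binomial band around 50/50
        assert abs(k - n / 2) < 4 * np.sqrt(n * 0.25)


def _toy_table_and_design():
    ref = "A" * 10
    design = AmpliconDesign("c", (("a", 0, 10),))
    variants = [
        haplotyper.Variant(position=2, ref="A", alts=("G",),
                           frequencies={"A": 0.5, "G": 0.5}, kind="snp"),
        haplotyper.Variant(position=5, ref="A", alts=("C",),
                           frequencies={"A": 0.5, "C": 0.5}, kind="snp"),
        haplotyper.Variant(position=8, ref="A", alts=("T", "G"),
                           frequencies={"T": 0.5, "G": 0.5}, kind="snp"),
    ]
    table = VariantTable(contig_id="c", variants=variants,
                         consensus="AARAAMAADA")
    cols = _columns({i: {"A": 100} for i in range(10)})
    return table, design, cols


class TestResolveHaplotypes:
    def test_top_two_vectors_beat_chimeras(self):
        table, design, cols = _toy_table_and_design()
        read_calls = {}
        counts = {("A", "C", "T"): 40, ("G", "A", "G"): 38,
                  ("A", "C", "G"): 5, ("G", "A", "T"): 3}
        i = 0
        for vec, n in counts.items():
            for _ in range(n):
                read_calls[f"r{i}"] = ("a", {2: vec[0], 5: vec[1], 8: vec[2]})
                i += 1
        pair = resolve_haplotypes(read_calls, table, design, cols,
                                  min_coverage=1)
        got = {(pair.haplotype_1[2], pair.haplotype_1[5], pair.haplotype_1[8]),
               (pair.haplotype_2[2], pair.haplotype_2[5], pair.haplotype_2[8])}
        assert got == {("A", "C", "T"), ("G", "A", "G")}
        assert (pair.support_1, pair.support_2) == (40, 38)

    def test_homozygous_individual(self):
        design = AmpliconDesign("c", (("a", 0, 10),))
        table = VariantTable(contig_id="c", variants=[], consensus="A" * 10)
        cols = _columns({i: {"A": 50} for i in range(10)})
        read_calls = {f"r{i}": ("a", {j: "A" for j in range(10)})
                      for i in range(50)}
        pair = resolve_haplotypes(read_calls, table, design, cols)
        assert pair.haplotype_1 == pair.haplotype_2 == "A" * 10

    def test_low_coverage_flag_still_emits(self):
        table, design, cols = _toy_table_and_design()
        shallow = _columns({i: {"A": 20} for i in range(10)})
        read_calls = {f"r{i}": ("a", {2: "A", 5: "C", 8: "T"})
                      for i in range(20)}
        pair = resolve_haplotypes(read_calls, table, design, shallow,
                                  min_coverage=35)
        assert pair.coverage_flag == "low_coverage"
        assert pair.haplotype_1 is not None

    def test_no_reads_means_missing(self):
        table, design, cols = _toy_table_and_design()
        pair = resolve_haplotypes({}, table, design, cols)
        assert pair.coverage_flag == "missing"
        assert pair.haplotype_1 is None

    def test_support_never_exceeds_depth_and_is_ordered(
            self, single_amplicon_config):
        cfg = single_amplicon_config(n_individuals=10, chimera_rate=0.3,
                                     seed=13)
        truth = simulate.simulate_truth(cfg)
        pairs = call_one_contig(truth, cfg)
        for p in pairs:
            assert p.support_1 >= p.support_2
            assert p.support_1 <= 2500  # far below any amplicon depth bound

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_top_two_matches_enumeration_oracle(self, seed):
        # random instances with <=6 het sites, including forced ties
        rng = np.random.default_rng(seed)
        n_sites = int(rng.integers(1, 7))
        alleles = [("A", "G")] * n_sites
        vectors = [tuple(rng.choice(a) for a in alleles) for _ in range(30)]
        counter = Counter(vectors)
        # oracle: full enumeration of vector frequencies, same tie rule
        ranked = sorted(counter.items(), key=lambda kv: (-kv[1], kv[0]))
        expect_first = ranked[0]
        expect_second = ranked[1] if len(ranked) > 1 else None
        first, second = haplotyper._top_two(counter)
        assert first == expect_first and second == expect_second


class TestGenotypeMatrix:
    @staticmethod
    def _pair(ind, h1, h2):
        return HaplotypePair(individual=ind, contig_id="c", haplotype_1=h1,
                             haplotype_2=h2)

    def test_het_retained_at_threshold(self):
        pairs = [self._pair("i1", "AA", "AA"), self._pair("i2", "AA", "AT")]
        geno, mafs = genotype_matrix(pairs, "AA")
        assert list(geno.columns) == [2]
        assert geno[2].tolist() == [0.0, 1.0]
        assert mafs[2] == 0.25

    def test_monomorphic_dropped(self):
        pairs = [self._pair("i1", "AA", "AA"), self._pair("i2", "AA", "AA")]
        geno, _ = genotype_matrix(pairs, "AA")
        assert geno.shape[1] == 0

    def test_missing_individual_is_nan(self):
        pairs = [self._pair("i1", "AT", "AT"), self._pair("i2", "AA", "AT"),
                 HaplotypePair(individual="i3", contig_id="c",
                               haplotype_1=None, haplotype_2=None,
                               coverage_flag="missing")]
        geno, _ = genotype_matrix(pairs, "AA")
        assert np.isnan(geno.loc["i3", 2])


class TestChimeraRobustness:
    def test_recovery_non_increasing_in_chimera_rate(
            self, single_amplicon_config):
        rates = [0.0, 0.5, 0.9]
        recov = []
        for rate in rates:
            cfg = single_amplicon_config(n_individuals=25, chimera_rate=rate,
                                         sub_error_rate=0.0,
                                         homopolymer_indel_rate=0.0, seed=21)
            truth = simulate.simulate_truth(cfg)
            pairs = call_one_contig(truth, cfg)
            ok = sum({p.haplotype_1, p.haplotype_2} == {t1, t2}
                     for p, (t1, t2) in zip(pairs, truth.haplotypes["g1"]))
            recov.append(ok / 25)
        assert recov[0] == 1.0
        assert recov[0] >= recov[1] >= recov[2] or \
            (recov[0] >= recov[2] and max(recov) - min(recov) < 0.1)
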