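"""Chimera-aware diploid haplotype calling from tagged amplicon reads.

The procedure mirrors an amplicon-resequencing workflow for candidate
genes in a diploid outcrosser: reads carry an 8-base hairpin tag per
individual; after demultiplexing they are anchored and aligned to a
reference contig; per-column allele frequencies below 5% are discarded as
sequencing noise (homopolymer artifacts in particular); remaining
polymorphic columns become SNP/indel calls with IUPAC ambiguity codes in
the consensus; and the two haplotypes of each diploid are recovered per
amplicon by taking the two most read-supported allele combinations over
the heterozygous sites — minority combinations are presumed PCR chimeras
— then chained across amplicon overlaps via shared heterozygous sites.
"""

from __future__ import annotations

import logging
from collections import Counter, defaultdict
from dataclasses import dataclass, field

import numpy as np
from Bio.Align import PairwiseAligner
from Bio.Seq import reverse_complement

log = logging.getLogger(__name__)

SRFI_SITE = "GCCCGGGC"

IUPAC = {
    frozenset("A"): "A", frozenset("C"): "C", frozenset("G"): "G",
    frozenset("T"): "T",
    frozenset("AG"): "R", frozenset("CT"): "Y", frozenset("GC"): "S",
    frozenset("AT"): "W", frozenset("GT"): "K", frozenset("AC"): "M",
    frozenset("CGT"): "B", frozenset("AGT"): "D", frozenset("ACT"): "H",
    frozenset("ACG"): "V", frozenset("ACGT"): "N",
}

__all__ = [
    "TagSpec", "AmpliconDesign", "PileupColumn", "Variant", "VariantTable",
    "HaplotypePair", "build_tag", "demultiplex", "align_and_pileup",
    "call_variants", "resolve_haplotypes", "genotype_matrix",
]


@dataclass(frozen=True)
class TagSpec:
    """An individual's library tag: 8 unique bases, an SrfI site, and the
    reverse complement of the tag forming a self-annealing hairpin."""

    tag: str
    full_adapter: str


@dataclass(frozen=True)
class AmpliconDesign:
    """Tiling of overlapping amplicons over one contig (0-based half-open)."""

    contig_id: str
    amplicons: tuple  # of (amplicon_id, start, end), sorted by start

    def __post_init__(self):
        amps = list(self.amplicons)
        if amps != sorted(amps, key=lambda a: a[1]):
            raise ValueError("amplicons must be sorted by start")
        for (_, _, e0), (_, s1, _) in zip(amps, amps[1:]):
            if e0 <= s1:
                raise ValueError("consecutive amplicons must overlap")

    def amplicon(self, amp_id):
        for a in self.amplicons:
            if a[0] == amp_id:
                return a
        raise KeyError(amp_id)


@dataclass
class PileupColumn:
    position: int
    counts: Counter = field(default_factory=Counter)  # A/C/G/T/'-'
    insertions: Counter = field(default_factory=Counter)

    @property
    def depth(self):
        return sum(self.counts.values())


@dataclass(frozen=True)
class Variant:
    position: int            # 0-based contig coordinate
    ref: str
    alts: tuple              # retained non-reference alleles ('-' = deletion)
    frequencies: dict        # allele -> read frequency at the column
    kind: str                # 'snp' | 'indel'

    @property
    def position_1based(self):
        return self.position + 1

    @property
    def maf(self):
        return min(self.frequencies.values())


@dataclass
class VariantTable:
    contig_id: str
    variants: list           # of Variant, sorted by position
    consensus: str           # contig-length string, IUPAC at het SNPs

    def het_positions(self):
        """Positions with >=2 retained non-insertion alleles (SNP or del)."""
        return [v.position for v in self.variants
                if len(v.frequencies) >= 2 and not any(
                    len(a) > 1 for a in v.alts)]


@dataclass
class HaplotypePair:
    individual: str
    contig_id: str
    haplotype_1: str | None
    haplotype_2: str | None
    support_1: int = 0
    support_2: int = 0
    coverage_flag: str = "ok"          # ok | low_coverage | missing
    phase_confidence: dict = field(default_factory=dict)  # junction -> flag


def build_tag(tag: str) -> TagSpec:
    """Build the 24-base hairpin adapter: tag + SrfI site + revcomp(tag)."""
    if len(tag) != 8 or any(b not in "ACGT" for b in tag):
        raise ValueError("tag must be 8 bases over A/C/G/T")
    return TagSpec(tag=tag, full_adapter=tag + SRFI_SITE + reverse_complement(tag))


def demultiplex(reads, tags, max_mismatch=0):
    """Sort reads to individuals by their leading 8-mer.

    A read is assigned to the unique tag within ``max_mismatch`` of its
    first 8 bases; ties between two tags, or no tag in range, send the
    read to the unassigned bin. The 24-base adapter is trimmed from
    assigned reads.

    Returns ``(assigned, unassigned)`` with assigned a dict tag -> list.
    """
    tags = list(tags)
    if len(set(tags)) != len(tags):
        raise ValueError("duplicate tags in library")
    if max_mismatch < 0:
        raise ValueError("max_mismatch must be >= 0")
    specs = [build_tag(t) for t in tags]
    assigned = {t: [] for t in tags}
    unassigned = []
    adapter_len = len(specs[0].full_adapter)
    for read in reads:
        lead = read.seq[:8]
        hits = [t for t in tags
                if sum(a != b for a, b in zip(lead, t)) <= max_mismatch]
        if len(hits) == 1:
            trimmed = _copy_read(read, read.seq[adapter_len:])
            assigned[hits[0]].append(trimmed)
        else:
            unassigned.append(read)
    return assigned, unassigned


def _copy_read(read, new_seq):
    from .simulate import TaggedRead
    return TaggedRead(id=read.id, seq=new_seq, individual=read.individual,
                      amplicon_id=read.amplicon_id, offset=read.offset)


def _make_aligner():
    a = PairwiseAligner()
    a.mode = "global"
    a.match_score = 1
    a.mismatch_score = -1
    a.open_gap_score = -3
    a.extend_gap_score = -1
    # reads are sub-fragments of the amplicon: query end gaps are free
    try:
        a.open_end_deletion_score = 0
        a.extend_end_deletion_score = 0
    except AttributeError:  # older Biopython naming
        a.query_end_open_gap_score = 0
        a.query_end_extend_gap_score = 0
    return a


def _seed_offset(read_seq, ref, start, end):
    """Best ungapped anchor for the read inside [start, end) by seed scan."""
    seed = read_seq[:min(30, len(read_seq))]
    best, best_off = -1, start
    for off in range(start, max(start + 1, end - len(seed) + 1)):
        m = sum(a == b for a, b in zip(seed, ref[off:off + len(seed)]))
        if m > best:
            best, best_off = m, off
    return best_off


def align_and_pileup(reads, reference, design: AmpliconDesign,
                     min_identity=0.7):
    """Align reads to their amplicon interval and accumulate a pileup.

    Each read is anchored to one amplicon (simulator metadata when
    present, else a seed scan over every amplicon). An ungapped placement
    at the anchor offset is accepted when identity >= 0.9; otherwise the
    read is globally aligned to the amplicon interval with scores
    match +1 / mismatch -1 / gap open -3 / gap extend -1. Reads below
    ``min_identity`` are discarded with a warning.

    Returns ``(columns, read_calls)`` where columns maps position ->
    :class:`PileupColumn` and read_calls maps read id ->
    (amplicon_id, {position: base or '-'}).
    """
    aligner = _make_aligner()
    columns = {}
    read_calls = {}

    def col(pos):
        if pos not in columns:
            columns[pos] = PileupColumn(position=pos)
        return columns[pos]

    for read in reads:
        seq = read.seq
        if not seq:
            continue
        if read.amplicon_id is not None:
            amp_id, start, end = design.amplicon(read.amplicon_id)
            offset = read.offset
            if offset is None:
                offset = _seed_offset(seq, reference, start, end)
        else:
            best = None
            for a in design.amplicons:
                off = _seed_offset(seq, reference, a[1], a[2])
                m = sum(x == y for x, y in
                        zip(seq[:30], reference[off:off + 30]))
                if best is None or m > best[0]:
                    best = (m, a, off)
            _, (amp_id, start, end), offset = best

        # fast path: ungapped placement. An indel shifts every base after
        # it, so beyond a high overall identity the read's tail must also
        # match; otherwise fall through to the gapped aligner.
        ref_slice = reference[offset:offset + len(seq)]
        matches = sum(a == b for a, b in zip(seq, ref_slice))
        tail = min(15, len(seq))
        tail_matches = sum(a == b for a, b in
                           zip(seq[-tail:], ref_slice[-tail:]))
        if (len(ref_slice) == len(seq) and matches / len(seq) >= 0.95
                and tail_matches >= tail - 2):
            calls = {}
            for i, base in enumerate(seq):
                pos = offset + i
                col(pos).counts[base] += 1
                calls[pos] = base
            read_calls[read.id] = (amp_id, calls)
            continue

        target = reference[start:end]
        aln = aligner.align(target, seq)[0]
        t_aln, q_aln = str(aln[0]), str(aln[1])
        non_gap = [i for i, q in enumerate(q_aln) if q != "-"]
        q_first, q_last = non_gap[0], non_gap[-1]
        t_pos = start
        matches = 0
        calls = {}
        pending_ins = ""
        for ci, (tb, qb) in enumerate(zip(t_aln, q_aln)):
            if tb == "-":           # insertion relative to reference
                pending_ins += qb
                continue
            if pending_ins and t_pos > start:
                col(t_pos - 1).insertions[pending_ins] += 1
            pending_ins = ""
            if qb == "-":
                # gaps before the read starts / after it ends are absence
                if q_first < ci < q_last:
                    col(t_pos).counts["-"] += 1
                    calls[t_pos] = "-"
            else:
                col(t_pos).counts[qb] += 1
                calls[t_pos] = qb
                if qb == tb:
                    matches += 1
            t_pos += 1
        if matches / max(1, len(seq)) < min_identity:
            for pos, base in calls.items():
                columns[pos].counts[base] -= 1
            log.warning("read %s discarded: identity below %.2f",
                        read.id, min_identity)
            continue
        read_calls[read.id] = (amp_id, calls)
    return columns, read_calls


def call_variants(columns, reference, contig_id="contig",
                  maf_threshold=0.05) -> VariantTable:
    """Frequency-filtered SNP/indel calls and IUPAC consensus.

    At each covered column allele frequencies are read counts over depth;
    non-reference alleles below ``maf_threshold`` are eliminated as likely
    sequencing error. Columns retaining two or more alleles become
    variants and their consensus base is the IUPAC code of the retained
    bases; zero-depth columns yield 'N'. Insertion alleles passing the
    same filter are reported as indel variants (consensus keeps reference
    coordinates).
    """
    if not columns:
        raise ValueError("empty pileup")
    variants = []
    consensus = list(reference)
    for pos in range(len(reference)):
        colm = columns.get(pos)
        if colm is None or colm.depth == 0:
            consensus[pos] = "N"
            continue
        depth = colm.depth
        freqs = {a: c / depth for a, c in colm.counts.items() if c > 0}
        ref_base = reference[pos]
        # the low-frequency filter applies to every allele, reference
        # included: the reference is an anchoring aid, not evidence
        retained = {a: f for a, f in freqs.items() if f >= maf_threshold}
        if not retained:  # everything filtered (low-depth ties): majority
            top = max(freqs, key=freqs.get)
            retained = {top: freqs[top]}
        bases = frozenset(a for a in retained if a != "-")
        if len(retained) >= 2:
            alts = tuple(sorted(a for a in retained if a != ref_base))
            kind = "indel" if "-" in retained else "snp"
            variants.append(Variant(position=pos, ref=ref_base, alts=alts,
                                    frequencies=retained, kind=kind))
            consensus[pos] = IUPAC.get(bases, "N") if bases else "-"
        else:
            only = next(iter(retained))
            consensus[pos] = only if only != "-" else "-"
            if only not in (ref_base, "-"):
                # homozygous difference from the reference is still a variant
                variants.append(Variant(position=pos, ref=ref_base,
                                        alts=(only,), frequencies=retained,
                                        kind="snp"))
        for ins, c in colm.insertions.items():
            if c / depth >= maf_threshold:
                variants.append(Variant(
                    position=pos, ref=ref_base, alts=(ref_base + ins,),
                    frequencies={ref_base + ins: c / depth}, kind="indel"))
    return VariantTable(contig_id=contig_id, variants=variants,
                        consensus="".join(consensus))


def _top_two(counter):
    """Two most frequent allele vectors; ties broken lexicographically."""
    items = sorted(counter.items(), key=lambda kv: (-kv[1], kv[0]))
    if not items:
        return None, None
    first = items[0]
    second = items[1] if len(items) > 1 else None
    return first, second


def resolve_haplotypes(read_calls, table: VariantTable,
                       design: AmpliconDesign, columns,
                       individual="ind", min_coverage=35) -> HaplotypePair:
    """Reconstruct the two haplotypes of a diploid from read support.

    Per amplicon, reads covering every heterozygous site of that amplicon
    are grouped by their allele vector; the two most frequent vectors are
    taken as the true haplotypes (minority vectors are presumed PCR
    chimeras; a single vector means the individual is homozygous there).
    Amplicon-level pairs are chained across overlaps using heterozygous
    sites shared by both amplicons; junctions with no shared heterozygous
    site are flagged ``ambiguous`` and joined by support rank. Chosen
    alleles replace the IUPAC codes in the consensus. Support is the
    weakest per-amplicon read count along each chained haplotype, so it
    can never exceed any amplicon's depth.

    Contigs whose mean depth is below ``min_coverage`` keep their
    haplotypes but are flagged ``low_coverage``; contigs with no reads
    return ``missing`` with no haplotypes.
    """
    if not read_calls:
        return HaplotypePair(individual=individual, contig_id=table.contig_id,
                             haplotype_1=None, haplotype_2=None,
                             coverage_flag="missing")
    het = [p for p in table.het_positions()]
    amp_het = {a[0]: [p for p in het if a[1] <= p < a[2]]
               for a in design.amplicons}
    retained_alleles = {
        v.position: set(v.frequencies) for v in table.variants
        if len(v.frequencies) >= 2}

    # group reads per amplicon by allele vector over that amplicon's het sites
    amp_pairs = {}   # amp_id -> ((vec1, n1), (vec2, n2) or None)
    for amp_id, _, _ in design.amplicons:
        sites = amp_het[amp_id]
        if not sites:
            amp_pairs[amp_id] = None
            continue
        counts = Counter()
        for rid, (a_id, calls) in read_calls.items():
            if a_id != amp_id:
                continue
            if all(s in calls for s in sites):
                vec = tuple(calls[s] for s in sites)
                if all(b in retained_alleles[s] for s, b in zip(sites, vec)):
                    counts[vec] += 1
        if not counts:
            # no read spans all het sites: fall back to per-site top alleles
            vecs = []
            for rank in range(2):
                vec = []
                for s in sites:
                    alleles = sorted(retained_alleles[s],
                                     key=lambda a: (-columns[s].counts[a], a))
                    vec.append(alleles[min(rank, len(alleles) - 1)])
                vecs.append(tuple(vec))
            amp_pairs[amp_id] = ((vecs[0], 0), (vecs[1], 0))
            continue
        first, second = _top_two(counts)
        amp_pairs[amp_id] = (first, second)

    # chain amplicon pairs across overlaps
    hap_a, hap_b = {}, {}          # position -> allele
    support_a, support_b = [], []
    phase_conf = {}
    prev_amp = None
    for amp_id, start, end in design.amplicons:
        pair = amp_pairs[amp_id]
        if pair is None:
            prev_amp = (amp_id, start, end)
            continue
        (v1, n1), second = pair
        v2, n2 = second if second is not None else (v1, n1)
        sites = amp_het[amp_id]
        orient = (v1, n1, v2, n2)
        if prev_amp is not None:
            junction = f"{prev_amp[0]}|{amp_id}"
            shared = [s for s in sites if s in hap_a]
            if shared:
                agree = sum(hap_a[s] == v1[sites.index(s)] and
                            hap_b[s] == v2[sites.index(s)] for s in shared)
                agree_sw = sum(hap_a[s] == v2[sites.index(s)] and
                               hap_b[s] == v1[sites.index(s)] for s in shared)
                if agree_sw > agree:
                    orient = (v2, n2, v1, n1)
                phase_conf[junction] = "joined"
            else:
                phase_conf[junction] = "ambiguous"  # join by support rank
        w1, c1, w2, c2 = orient
        for s, (a, b) in zip(sites, zip(w1, w2)):
            hap_a.setdefault(s, a)
            hap_b.setdefault(s, b)
        support_a.append(c1)
        support_b.append(c2)
        prev_amp = (amp_id, start, end)

    h1 = list(table.consensus)
    h2 = list(table.consensus)
    hom = {v.position: next(iter(v.frequencies)) for v in table.variants
           if len(v.frequencies) == 1 and len(v.alts[0]) == 1}
    for pos, a in hom.items():
        h1[pos] = h2[pos] = a
    for pos in het:
        h1[pos] = hap_a.get(pos, table.consensus[pos])
        h2[pos] = hap_b.get(pos, table.consensus[pos])
    s1 = min(support_a) if support_a else 0
    s2 = min(support_b) if support_b else 0
    hap1, hap2 = "".join(h1), "".join(h2)
    if s2 > s1:
        hap1, hap2, s1, s2 = hap2, hap1, s2, s1

    length = len(table.consensus)
    mean_depth = sum(c.depth for c in columns.values()) / max(1, length)
    flag = "ok" if mean_depth >= min_coverage else "low_coverage"
    return HaplotypePair(individual=individual, contig_id=table.contig_id,
                         haplotype_1=hap1, haplotype_2=hap2,
                         support_1=s1, support_2=s2, coverage_flag=flag,
                         phase_confidence=phase_conf)


def genotype_matrix(pairs, reference, maf_threshold=0.05):
    """Unphased SNP genotypes across a cohort of haplotype pairs.

    Positions where any individual's haplotype differs from the reference
    become candidate variants; per-variant sample minor allele frequency
    is computed over non-missing individuals and variants with
    MAF <= ``maf_threshold`` are dropped. Genotypes are coded as the count
    of non-reference alleles (0/1/2) with NaN for missing individuals.

    Returns a pandas DataFrame (individuals x variants) whose columns are
    1-based ``pos`` labels, plus a dict of per-variant sample MAF.
    """
    import pandas as pd

    individuals = [p.individual for p in pairs]
    length = len(reference)
    candidate = set()
    for p in pairs:
        if p.haplotype_1 is None:
            continue
        for h in (p.haplotype_1, p.haplotype_2):
            for i, (a, r) in enumerate(zip(h, reference)):
                if a != r and a not in "N-":
                    candidate.add(i)
    data, mafs = {}, {}
    for pos in sorted(candidate):
        geno = []
        alt_count = tot = 0
        for p in pairs:
            if p.haplotype_1 is None or pos >= len(p.haplotype_1):
                geno.append(np.nan)
                continue
            a1, a2 = p.haplotype_1[pos], p.haplotype_2[pos]
            if a1 in "N-" or a2 in "N-":
                geno.append(np.nan)
                continue
            d = (a1 != reference[pos]) + (a2 != reference[pos])
            geno.append(float(d))
            alt_count += d
            tot += 2
        if tot == 0:
            continue
        freq = alt_count / tot
        maf = min(freq, 1 - freq)
        if maf <= maf_threshold:
            continue
        label = pos + 1  # 1-based reporting, matching SNP naming convention
        data[label] = geno
        mafs[label] = maf
    return pd.DataFrame(data, index=individuals), mafs
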