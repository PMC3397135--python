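"""Synthetic cohorts for testing the amplicon-resequencing analysis chain.

Everything downstream of the sequencer is testable against known truth:
diploid haplotypes arise from a standard neutral (Kingman) coalescent with
infinite-sites mutation, tagged amplicon reads are drawn from those
haplotypes with substitution errors, homopolymer indels and PCR chimeras,
multi-allelic SSR genotypes follow a Balding-Nichols style island model,
and quantitative phenotypes decompose into structure, polygenic, QTN and
noise components that are all returned separately.

All randomness flows from one :class:`numpy.random.Generator`; the same
seed and configuration reproduce byte-identical outputs.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np

BASES = np.array(list("ACGT"))

__all__ = [
    "ContigSpec",
    "SimConfig",
    "TruthSet",
    "TaggedRead",
    "simulate_coalescent_haplotypes",
    "simulate_truth",
    "simulate_reads",
    "simulate_ssr_genotypes",
    "simulate_phenotype",
    "make_tags",
    "qtn_dosages",
]


@dataclass(frozen=True)
class ContigSpec:
    """One reference contig and the tiling of amplicons across it.

    Amplicon intervals are 0-based half-open contig coordinates, sorted by
    start; consecutive amplicons must overlap by at least 1 bp so diploid
    phase can be chained across junctions.
    """

    id: str
    length: int
    amplicons: tuple  # of (amplicon_id, start, end)

    def __post_init__(self):
        if self.length <= 0:
            raise ValueError("contig length must be positive")
        amps = list(self.amplicons)
        for _, s, e in amps:
            if not (0 <= s < e <= self.length):
                raise ValueError("amplicon interval outside contig")
        for (_, _, e0), (_, s1, _) in zip(amps, amps[1:]):
            if e0 <= s1:
                raise ValueError("consecutive amplicons must overlap by >=1 bp")


def _default_contigs():
    # Scaled-down layout: two contigs of two overlapping amplicons each.
    # Amplicon lengths (350 bp) and overlaps (100 bp) sit inside the design
    # ranges of the emulated library (289-645 bp amplicons, 77-327 bp overlap).
    return (
        ContigSpec("contig1", 600, (("c1a1", 0, 350), ("c1a2", 250, 600))),
        ContigSpec("contig2", 600, (("c2a1", 0, 350), ("c2a2", 250, 600))),
    )


@dataclass
class SimConfig:
    """Parameters of the simulated study.

    Defaults are a desk-scale reduction of the emulated experiment
    (72 diploids x 16 amplicons in 7 contigs): 24 individuals, 2 contigs
    of 2 amplicons. Per-site theta defaults to 0.0142, the average
    candidate-gene Watterson estimate of the system being emulated; read
    length is centred on 453 bp. Error-channel rates are placeholders for
    sensitivity sweeps, not estimates of any particular instrument.
    """

    n_individuals: int = 24
    contigs: tuple = field(default_factory=_default_contigs)
    theta_per_site: float = 0.0142
    read_length_mean: float = 453.0
    read_length_sd: float = 40.0
    coverage_mean: float = 100.0
    sub_error_rate: float = 0.005
    homopolymer_indel_rate: float = 0.01
    chimera_rate: float = 0.1
    n_populations: int = 3
    fst: float = 0.15
    n_ssr_loci: int = 30
    alleles_per_locus: int = 4
    qtn: tuple | None = None  # (contig_id, position, effect)
    heritability_polygenic: float = 0.3
    seed: int = 0

    def __post_init__(self):
        for name in ("sub_error_rate", "homopolymer_indel_rate",
                     "chimera_rate", "fst", "heritability_polygenic"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1]")
        if self.fst >= 1.0:
            raise ValueError("fst must lie in [0, 1)")
        if self.n_individuals < 1 or self.n_populations < 1:
            raise ValueError("counts must be positive")
        if self.theta_per_site < 0:
            raise ValueError("theta_per_site must be >= 0")

    def rng(self, stream: str) -> np.random.Generator:
        """Deterministic substream derived from (seed, stream name)."""
        entropy = [self.seed] + [ord(c) for c in stream]
        return np.random.default_rng(np.random.SeedSequence(entropy))


@dataclass
class TruthSet:
    """Ground truth behind a simulated cohort."""

    config: SimConfig
    haplotypes: dict       # contig_id -> list of (hap1, hap2) per individual
    variant_positions: dict  # contig_id -> sorted list of segregating sites
    references: dict       # contig_id -> ancestral reference sequence
    ssr_genotypes: np.ndarray | None = None   # (n, loci, 2) allele indices
    ssr_frequencies: np.ndarray | None = None  # (pops, loci, alleles)
    Q_true: np.ndarray | None = None          # (n, pops) rows sum to 1
    phenotype_components: dict | None = None


@dataclass
class TaggedRead:
    """A simulated (or parsed) read with its demultiplexing tag prepended."""

    id: str
    seq: str
    individual: str | None = None
    amplicon_id: str | None = None
    offset: int | None = None  # contig coordinate of the first read base


def _as_rng(seed) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


def simulate_coalescent_haplotypes(n, theta_per_site, L, seed):
    """Sample ``n`` sequences of length ``L`` under the neutral coalescent.

    A Kingman genealogy (exponential waiting times with rate k(k-1)/2 in
    units of 2N generations) is decorated with Poisson mutations at rate
    ``theta_per_site * L / 2`` per unit branch length; each mutation hits a
    previously unmutated site (infinite sites) chosen uniformly on [0, L)
    and replaces the ancestral base with a uniformly chosen different one.

    Returns a list of ``n`` strings over {A,C,G,T}.
    """
    if n < 2:
        raise ValueError("need at least 2 sequences")
    if L < 1:
        raise ValueError("L must be >= 1")
    if theta_per_site < 0:
        raise ValueError("theta_per_site must be >= 0")
    rng = _as_rng(seed)

    active = [frozenset([i]) for i in range(n)]
    birth = [0.0] * n
    t = 0.0
    branches = []  # (leaf set, branch length)
    while len(active) > 1:
        k = len(active)
        t += rng.exponential(2.0 / (k * (k - 1)))
        i, j = sorted(rng.choice(k, size=2, replace=False))
        branches.append((active[i], t - birth[i]))
        branches.append((active[j], t - birth[j]))
        merged = active[i] | active[j]
        active = [lin for idx, lin in enumerate(active) if idx not in (i, j)]
        birth = [b for idx, b in enumerate(birth) if idx not in (i, j)]
        active.append(merged)
        birth.append(t)

    ancestral = rng.choice(BASES, size=L)
    seqs = np.tile(ancestral, (n, 1))
    used = set()
    mut_rate = theta_per_site * L / 2.0
    for leaves, length in branches:
        n_mut = rng.poisson(mut_rate * length)
        for _ in range(n_mut):
            if len(used) >= L:
                raise RuntimeError("infinite-sites model exhausted all sites; "
                                   "increase L or decrease theta")
            while True:
                site = int(rng.integers(L))
                if site not in used:
                    break
            used.add(site)
            current = ancestral[site]
            choices = [b for b in "ACGT" if b != current]
            derived = choices[int(rng.integers(3))]
            idx = list(leaves)
            seqs[idx, site] = derived
    return ["".join(row) for row in seqs]


def make_tags(n, rng, min_distance=3):
    """Draw ``n`` unique 8-mer tags with pairwise Hamming distance >= 3.

    The distance floor guarantees single-mismatch demultiplexing can never
    tie between two library tags.
    """
    rng = _as_rng(rng)
    tags = []
    attempts = 0
    while len(tags) < n:
        attempts += 1
        if attempts > 100000:
            raise RuntimeError("could not find enough well-separated tags")
        cand = "".join(rng.choice(BASES, size=8))
        if all(sum(a != b for a, b in zip(cand, t)) >= min_distance for t in tags):
            tags.append(cand)
    return tags


def simulate_truth(config: SimConfig) -> TruthSet:
    """Simulate the diploid haplotype truth for every contig.

    Each contig receives an independent coalescent sample of 2n haplotypes
    (no recombination within a contig, so phase across amplicon overlaps is
    well defined); consecutive haplotypes are paired into individuals.
    """
    rng = config.rng("haplotypes")
    n = config.n_individuals
    haplotypes, positions, refs = {}, {}, {}
    for contig in config.contigs:
        haps = simulate_coalescent_haplotypes(
            2 * n, config.theta_per_site, contig.length, rng)
        arr = np.array([list(h) for h in haps])
        seg = [i for i in range(contig.length) if len(set(arr[:, i])) > 1]
        # reference = majority base per column (an outgroup-free consensus)
        ref = []
        for i in range(contig.length):
            vals, counts = np.unique(arr[:, i], return_counts=True)
            ref.append(vals[np.argmax(counts)])
        haplotypes[contig.id] = [(haps[2 * i], haps[2 * i + 1]) for i in range(n)]
        positions[contig.id] = seg
        refs[contig.id] = "".join(ref)
    return TruthSet(config=config, haplotypes=haplotypes,
                    variant_positions=positions, references=refs)


def _homopolymer_runs(seq, min_len=3):
    runs = []
    i = 0
    while i < len(seq):
        j = i
        while j < len(seq) and seq[j] == seq[i]:
            j += 1
        if j - i >= min_len:
            runs.append((i, j))
        i = j
    return runs


def simulate_reads(hap_pair, contig: ContigSpec, config: SimConfig,
                   tag: str, rng, individual: str = "ind") -> list:
    """Generate tagged amplicon reads for one individual on one contig.

    Per amplicon a Poisson(coverage_mean) number of reads is drawn; each
    read copies one of the two haplotypes, or with probability
    ``chimera_rate`` a single-crossover chimera of both (uniform breakpoint
    strictly inside the amplicon, mimicking template switching during PCR
    reamplification). Reads are truncated to a Normal(read_length_mean,
    read_length_sd) length from a uniformly chosen end, substitution errors
    are applied per base, one-base indels per homopolymer run of length
    >= 3, and the full hairpin adapter built from ``tag`` is prepended.

    A zero coverage draw legitimately yields no reads for an amplicon.
    """
    from .haplotyper import build_tag

    rng = _as_rng(rng)
    adapter = build_tag(tag).full_adapter
    h1, h2 = hap_pair
    if len(h1) != contig.length or len(h2) != contig.length:
        raise ValueError("haplotype length must equal contig length")
    reads = []
    for amp_id, start, end in contig.amplicons:
        n_reads = rng.poisson(config.coverage_mean)
        for r in range(n_reads):
            if (config.chimera_rate > 0 and rng.random() < config.chimera_rate
                    and end - start > 2):
                bp = int(rng.integers(start + 1, end))
                if rng.random() < 0.5:
                    seq = h1[start:bp] + h2[bp:end]
                else:
                    seq = h2[start:bp] + h1[bp:end]
            else:
                seq = (h1 if rng.random() < 0.5 else h2)[start:end]
            amp_len = end - start
            length = int(round(rng.normal(config.read_length_mean,
                                          config.read_length_sd)))
            length = max(30, min(length, amp_len))
            if rng.random() < 0.5:  # from the left end
                seq = seq[:length]
                offset = start
            else:
                seq = seq[-length:]
                offset = end - length
            seq = list(seq)
            if config.sub_error_rate > 0:
                errs = np.nonzero(rng.random(len(seq)) <
                                  config.sub_error_rate)[0]
                for pos in errs:
                    alts = [b for b in "ACGT" if b != seq[pos]]
                    seq[pos] = alts[int(rng.integers(3))]
            if config.homopolymer_indel_rate > 0:
                out, shift = list(seq), 0
                for rs, re_ in _homopolymer_runs(seq):
                    if rng.random() < config.homopolymer_indel_rate:
                        if rng.random() < 0.5:
                            del out[rs + shift]
                            shift -= 1
                        else:
                            out.insert(rs + shift, seq[rs])
                            shift += 1
                seq = out
            reads.append(TaggedRead(
                id=f"{individual}|{contig.id}|{amp_id}|{r}",
                seq=adapter + "".join(seq),
                individual=individual, amplicon_id=amp_id, offset=offset))
    return reads


def simulate_ssr_genotypes(config: SimConfig, Q_true=None, rng=None,
                           pop_freqs=None):
    """Multi-allelic SSR genotypes under an island (Balding-Nichols) model.

    Global allele frequencies per locus are symmetric-Dirichlet; population
    frequencies are Dirichlet-distributed around them with concentration
    (1 - fst)/fst, so E[FST] ~= ``config.fst``. Each individual draws two
    allele copies independently; with admixed ``Q_true`` rows, the source
    population of each copy is drawn from the individual's memberships.

    Returns ``(genotypes, pop_freqs, Q_true)`` with genotypes shaped
    (n_individuals, n_loci, 2) as allele indices.
    """
    if config.alleles_per_locus < 2:
        raise ValueError("alleles_per_locus must be >= 2")
    rng = _as_rng(rng if rng is not None else config.rng("ssr"))
    n, L, A, P = (config.n_individuals, config.n_ssr_loci,
                  config.alleles_per_locus, config.n_populations)
    if Q_true is None:
        # hard block assignment: equal-sized subpopulations
        Q_true = np.zeros((n, P))
        for i in range(n):
            Q_true[i, i * P // n] = 1.0
    if pop_freqs is None:
        global_freq = rng.dirichlet(np.ones(A), size=L)  # (L, A)
        pop_freqs = np.empty((P, L, A))
        if config.fst == 0:
            pop_freqs[:] = global_freq[None, :, :]
        else:
            conc = (1.0 - config.fst) / config.fst
            for p in range(P):
                for l in range(L):
                    pop_freqs[p, l] = rng.dirichlet(
                        np.maximum(global_freq[l] * conc, 1e-6))
    else:
        pop_freqs = np.asarray(pop_freqs, dtype=float)
    genotypes = np.empty((n, L, 2), dtype=np.int64)
    for i in range(n):
        for copy in range(2):
            pops = rng.choice(P, size=L, p=Q_true[i] / Q_true[i].sum())
            for l in range(L):
                genotypes[i, l, copy] = rng.choice(A, p=pop_freqs[pops[l], l])
    return genotypes, pop_freqs, Q_true


def qtn_dosages(truth: TruthSet, contig_id: str, position: int) -> np.ndarray:
    """Count of the non-reference allele per individual at a truth site."""
    ref = truth.references[contig_id][position]
    return np.array([(h1[position] != ref) + (h2[position] != ref)
                     for h1, h2 in truth.haplotypes[contig_id]], dtype=float)


def simulate_phenotype(Q_true, kinship, dosage, config: SimConfig,
                       structure_effects=None, beta=None, noise_sd=1.0,
                       rng=None):
    """Quantitative trait with known variance decomposition.

    y = Q v + g + beta * dosage + e, where g is multivariate normal with
    covariance sigma_g^2 * 2K (K = kinship, diagonal floored at 1) scaled
    so the polygenic share of the non-structure, non-QTN variance equals
    ``config.heritability_polygenic``, and e is iid Normal(0, noise_sd^2).

    Returns a dict of components ('structure', 'polygenic', 'qtn', 'noise',
    'y'); the truth is available for calibration checks downstream.
    """
    h2 = config.heritability_polygenic
    if h2 >= 1.0:
        raise ValueError("heritability_polygenic must be < 1")
    rng = _as_rng(rng if rng is not None else config.rng("phenotype"))
    Q_true = np.asarray(Q_true, dtype=float)
    n = Q_true.shape[0]
    dosage = np.zeros(n) if dosage is None else np.asarray(dosage, dtype=float)
    if structure_effects is None:
        structure_effects = np.zeros(Q_true.shape[1])
    structure_effects = np.asarray(structure_effects, dtype=float)
    if beta is None:
        beta = config.qtn[2] if config.qtn is not None else 0.0
    if len(dosage) != n or Q_true.shape[1] != len(structure_effects):
        raise ValueError("component dimensions do not agree")

    structure = Q_true @ structure_effects
    sigma_e2 = noise_sd ** 2
    if h2 > 0:
        A = 2.0 * np.asarray(kinship, dtype=float)
        A = (A + A.T) / 2.0
        np.fill_diagonal(A, np.maximum(np.diag(A), 1.0))
        c = float(np.mean(np.diag(A)))
        sigma_g2 = h2 * sigma_e2 / ((1.0 - h2) * c)
        w, V = np.linalg.eigh(A)
        w = np.clip(w, 0.0, None)
        polygenic = V @ (np.sqrt(sigma_g2 * w) * rng.standard_normal(n))
    else:
        polygenic = np.zeros(n)
    qtn_part = beta * dosage
    noise = rng.normal(0.0, noise_sd, size=n)
    y = structure + polygenic + qtn_part + noise
    return {"structure": structure, "polygenic": polygenic,
            "qtn": qtn_part, "noise": noise, "y": y}
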