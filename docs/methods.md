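# Methods

## Synthetic cohorts

The generator states a world and the analysis chain is tested against it.

**Haplotypes.** Each contig receives an independent sample of 2n
sequences from the standard neutral (Kingman) coalescent: exponential
waiting times with rate k(k−1)/2 in units of 2N generations, mutations
Poisson on branches at rate θ·L/2 per unit length, each hitting a fresh
site (infinite sites) chosen uniformly on the contig and replacing the
ancestral base with a uniformly chosen different one. There is no
recombination within a contig, so diploid phase across amplicon overlaps
is a well-defined truth. Consecutive haplotypes are paired into
individuals. The per-site θ defaults to 0.0142, the average
candidate-gene Watterson estimate of the emulated system. The reference
sequence handed to the aligner is the column-majority consensus of the
sample — an outgroup-free stand-in for the primer-design reference.

**Reads.** Per amplicon and individual, Poisson(coverage) reads copy one
of the two haplotypes, or with probability `chimera_rate` a
single-crossover recombinant of both at a uniform breakpoint inside the
amplicon — chimeras form during PCR, so parents are always the same
individual's two haplotypes. Reads are truncated to
Normal(453, 40) bp from a uniformly chosen end, matching the read-length
scale of a 454 Titanium run; substitution errors are applied per base and
single-base indels per homopolymer run of length ≥ 3. The error-channel
defaults (substitution 0.005, homopolymer indel 0.01, chimera 0.1) are
placeholders for sensitivity sweeps, not instrument estimates. The
24-base hairpin adapter (tag + SrfI site + reverse-complemented tag) is
prepended. Simulated tags keep pairwise Hamming distance ≥ 3 so
single-mismatch demultiplexing can never tie.

**SSR genotypes.** A Balding–Nichols style island model: global allele
frequencies are symmetric-Dirichlet per locus; population frequencies
are Dirichlet around them with concentration (1−F_ST)/F_ST, so the
expected Weir–Cockerham estimate equals the configured F_ST (verified in
tests). Individuals draw two copies independently; by default membership
is hard (one-hot Q rows in equal blocks) because most checks need clean
subpopulation truth — admixed rows can be passed explicitly.

**Phenotypes.** y = Qv + g + β·dosage + e with g ~ MVN(0, σ_g²·2K)
(diagonal of 2K floored at 1) and e iid Normal. σ_g² is scaled so the
polygenic share of the non-structure, non-QTN variance equals the
configured heritability. All four components are returned separately so
power and type-I experiments know the truth.

**What a green test does not establish.** The generator has no
base-quality model, no coverage bias between amplicons, no
within-contig recombination, no tetraploid genotypes, and chimeras are
single-crossover only. Recovery rates measured here therefore bound the
method's behavior under these idealizations, not under an arbitrary real
library.

## Haplotype calling

Reads are anchored to one amplicon and aligned to its reference interval
(match +1, mismatch −1, gap open −3, gap extend −1, free end gaps for the
read; Biopython's `PairwiseAligner`). An ungapped fast path is accepted
only at ≥ 95% identity *and* a matching read tail — an indel shifts every
base after it, so a tail check is what keeps shifted reads out of the
pileup. Reads below 70% aligned identity are discarded with a warning.

At each pileup column, allele frequencies are read counts over depth and
**every** allele below the 5% floor is eliminated — including the
reference allele, which is an anchoring aid, not evidence. Columns
retaining ≥ 2 alleles are variants and receive the IUPAC code of their
retained bases; zero-depth columns yield `N`. Insertions passing the same
filter are reported as indel variants but excluded from haplotype
vectors (downstream LD and association use SNPs only); deletions appear
as `-` in haplotypes so reference coordinates are preserved.

Per amplicon, reads covering all heterozygous sites are grouped by their
allele vector and the two most frequent vectors are the haplotypes;
minority vectors are presumed chimeras. Ties for the second slot are
broken lexicographically (deterministic, logged). Amplicon pairs are
chained across overlaps by maximizing agreement at shared heterozygous
sites; a junction with no shared heterozygous site is flagged
`ambiguous` and joined by support rank — the flag records that the
procedure is guessing there, which is also why exact-recovery tests use
either single-amplicon contigs or condition on `joined` junctions.
Haplotype support is the weakest per-amplicon read count along the
chain, so it can never exceed any amplicon's depth. Contigs with mean
depth below 35 reads keep their haplotypes but are flagged
`low_coverage`; 35× is where sequencing errors stop being separable from
real SNPs in this design.

The cohort genotype matrix re-derives variants by comparing called
haplotypes to the reference, recomputes sample MAF, and drops variants
with MAF ≤ 0.05.

## Diversity statistics

k is the mean pairwise difference count over all C(n,2) pairs, π = k/L_eff,
θ_W = S/(a₁·L_eff) with a₁ = Σ_{i<n} 1/i. By default columns containing
any gap, `N`, or ambiguity code are excluded everywhere ("complete
deletion", the default of the standard desktop program for these
statistics); pairwise deletion is available for k/π. Tajima's
D = (k − S/a₁)/√(e₁S + e₂S(S−1)) with the 1989 constants; its two-tailed
p-value comes from the scaled-beta approximation on [D_min, D_max] with
D_min = (2/n − 1/a₁)/√e₂ and D_max = ((n+1)/2n − 1/a₁)/√e₂. The
approximation is slightly conservative: under 2000 neutral replicates at
n = 20, θL = 10 the empirical p < 0.05 rate is ≈ 0.03–0.05, which is why
the calibration test accepts [0.02, 0.08] rather than a tight band
around 0.05. D is undefined (reported as not computable) when S = 0.
Haplotype diversity uses Hd = n(1 − Σp²)/(n−1) and the large-sample
variance 2[2(n−2)(Σp³ − (Σp²)²) + Σp² − (Σp²)²]/(n(n−1)). Sliding
windows default to 100 bp / 25 bp step (the windowed analysis the field
reports does not state its parameters; these are conventional values).

## Linkage disequilibrium

SSR pairs: the genotypic log-likelihood-ratio statistic G of the
two-locus genotype table (unordered allele pairs; zero cells skipped),
with a straight permutation null (default 10,000 permutations, add-one
p-value (1+#{G* ≥ G})/(B+1)) in place of a Markov-chain exact test —
asymptotically the same null and simpler to verify; an exhaustive
enumeration mode exists for n ≤ 8 and is checked against a brute-force
oracle. Only same-chromosome pairs are tested, distances in Mb;
configured pair exclusions handle markers whose physical distance is
unreliable. SNP pairs: r² is the squared Pearson correlation of 0/1/2
dosage vectors over pairwise-complete individuals, distances in bp.
Decay is summarized per contig as the upper edge of the smallest 50 bp
distance bin whose mean r² drops below 0.1, or "no decay".

## Kinship

Ritland's moment estimator per locus,
F_ij = [Σ_a x_ia x_ja / p_a − 1]/(A−1) with x the individual's allele
dosage fractions and p the reference frequencies (full-sample estimates
by default), combined across loci with weights A−1. Loci missing in
either member of a pair drop out of that pair's average; pairs sharing
no typed locus get 0 with a warning. Negative estimates are truncated to
zero before mixed-model use. The mixed model expects a covariance with
unit-scale diagonal, so the polygenic covariance is 2K with the diagonal
floored at 1 — the self-kinship diagonal from the same formula is noisy
and can fall below ½ by sampling.

## Association

Full REML per marker (not P3D): one eigendecomposition of 2K per
trait/marker subset rotates the model so the covariance is
σ_g²·diag(λ+δ), and the profiled restricted log-likelihood is maximized
in log δ over [−5, 5] log₁₀ units by bounded Brent (xatol 1e−8). The
marker Wald F uses denominator df = n − rank(fixed effects); marker R²
is the marker sum of squares over the total sum of squares after GLS
whitening. Default marker encoding is genotype-class (a heterozygote
effect is representable); additive dosage is available. Genotype classes
below `min_class_size` (default 3) are pooled into an "other" class, and
dropped if the pool itself stays below the minimum; markers with < 2
surviving classes are skipped. One Q column is dropped against the
intercept. With 2K = 0 the fit provably collapses to ordinary least
squares, which the tests exploit as an oracle. FDR families for the
q-values are per-trait by default, global optionally — the choice is
exposed because neither is canonical.

## q-values

π₀(λ) = #{p > λ}/(m(1−λ)) on λ = 0.05…0.90 (step 0.05); a cubic
least-squares fit across the grid (standing in for the df = 3 smoothing
spline of the reference implementation) is evaluated at λ = 0.90 and
clamped to [0, 1]. For families with m < 100 the smoother is too
unstable and π₀ = 1 is used, making the q-values exactly
Benjamini–Hochberg — conservative by construction. q-values are the
usual step-up: q_(i) = min(π₀·m·p_(i)/i, q_(i+1)).

## Numerical and design notes

- All coordinates are 0-based half-open internally; reports and VCF use
  1-based positions.
- One global seed; every stage derives a named substream via
  `SeedSequence`, so identical configs reproduce byte-identical outputs.
  Reproducibility is defined as same-input determinism; the shared
  stream means independently permuting input rows does not permute the
  noise draws with them.
- Permutation p-values use the add-one estimator and so can never be 0;
  beta and F p-values are floored at the smallest positive float.
- Acceptance-scale experiments are deliberately desk-sized (e.g. 2000
  coalescent replicates, 200-diploid recovery runs, 1000-replicate
  calibration loops) so the full suite runs in about a minute.

## Known limitations

- Phase across an amplicon junction without a shared heterozygous site
  is a coin flip and is only ever reported with the `ambiguous` flag.
- Indels are called but not phased into haplotypes; insertion bases are
  not placed in the consensus.
- The Tajima significance test is an approximation; a
  simulation-conditioned null is not built in.
- Tetraploid (4-haplotype) resolution, recombination within contigs,
  and quality-aware error models are out of scope.
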