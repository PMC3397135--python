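"""End-to-end driver: simulate -> haplotype -> diversity / LD -> kinship
-> association -> q-values.

The pipeline is deterministic given (config, seed): every stage draws its
randomness from a substream derived from the global seed and the stage
name, outputs land in a run-specific directory, and a manifest records a
content hash of every artifact so reruns can be verified byte-for-byte.
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from . import association, diversity, haplotyper, linkage, multiplicity
from . import io as hio
from . import relatedness, simulate

log = logging.getLogger(__name__)

KNOWN_KEYS = {"seed", "stages", "simulate", "association", "diversity",
              "ld_snp", "ld_ssr", "kinship"}
DEFAULT_STAGES = ("simulate", "haplotype", "diversity", "ld_snp", "ld_ssr",
                  "kinship", "association")


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def call_cohort(truth, config, min_coverage=35, maf_threshold=0.05):
    """Run the full read-level chain for every individual and contig.

    Simulates tagged reads from the truth haplotypes, demultiplexes them,
    aligns, calls variants per individual, resolves haplotype pairs, and
    assembles the cross-cohort unphased genotype matrix per contig.

    Returns ``(pairs_by_contig, genotype_tables, reads_by_individual)``.
    """
    rng = config.rng("reads")
    n = config.n_individuals
    tags = simulate.make_tags(n, config.rng("tags"))
    individuals = [f"ind{i:03d}" for i in range(n)]

    all_reads = []
    for contig in config.contigs:
        for i, ind in enumerate(individuals):
            all_reads.extend(simulate.simulate_reads(
                truth.haplotypes[contig.id][i], contig, config,
                tags[i], rng, individual=ind))
    assigned, unassigned = haplotyper.demultiplex(all_reads, tags,
                                                  max_mismatch=1)
    if unassigned:
        log.info("%d reads unassigned at demultiplexing", len(unassigned))

    pairs_by_contig = {}
    genotype_tables = {}
    for contig in config.contigs:
        design = haplotyper.AmpliconDesign(contig_id=contig.id,
                                           amplicons=contig.amplicons)
        ref = truth.references[contig.id]
        pairs = []
        for i, ind in enumerate(individuals):
            reads = [r for r in assigned[tags[i]]
                     if r.id.split("|")[1] == contig.id]
            if not reads:
                pairs.append(haplotyper.HaplotypePair(
                    individual=ind, contig_id=contig.id, haplotype_1=None,
                    haplotype_2=None, coverage_flag="missing"))
                continue
            columns, read_calls = haplotyper.align_and_pileup(
                reads, ref, design)
            table = haplotyper.call_variants(columns, ref, contig.id,
                                             maf_threshold=maf_threshold)
            pairs.append(haplotyper.resolve_haplotypes(
                read_calls, table, design, columns, individual=ind,
                min_coverage=min_coverage))
        pairs_by_contig[contig.id] = pairs
        geno, mafs = haplotyper.genotype_matrix(pairs, ref,
                                                maf_threshold=maf_threshold)
        genotype_tables[contig.id] = geno
    return pairs_by_contig, genotype_tables, assigned


def run_pipeline(config: dict, outdir) -> dict:
    """Execute the enabled stages and write a manifest.

    ``config`` keys: ``seed`` (global seed), ``stages`` (list of stage
    names; default all), and optional per-stage parameter blocks
    (``simulate``, ``diversity``, ``ld_snp``, ``ld_ssr``, ``kinship``,
    ``association``). Unknown keys are rejected.
    """
    unknown = set(config) - KNOWN_KEYS
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    seed = int(config.get("seed", 0))
    stages = list(config.get("stages", DEFAULT_STAGES))
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest = {"seed": seed, "stages": stages, "outputs": {}}

    sim_params = dict(config.get("simulate", {}))
    sim_params.setdefault("seed", seed)
    sim_config = simulate.SimConfig(**sim_params)
    truth = simulate.simulate_truth(sim_config)

    def record(name, path):
        manifest["outputs"][name] = {"path": str(path),
                                     "sha256": _sha256(Path(path))}

    # --- truth / simulated inputs -------------------------------------
    if "simulate" in stages:
        for cid, ref in truth.references.items():
            p = outdir / f"reference_{cid}.fasta"
            hio.write_fasta([(cid, ref)], p)
            record(f"reference_{cid}", p)
        hap_records = []
        for cid, haps in truth.haplotypes.items():
            for i, (h1, h2) in enumerate(haps):
                hap_records.append((f"ind{i:03d}|{cid}|hap1", h1))
                hap_records.append((f"ind{i:03d}|{cid}|hap2", h2))
        p = outdir / "truth_haplotypes.fasta"
        hio.write_fasta(hap_records, p)
        record("truth_haplotypes", p)

    ssr_geno, _, Q_true = simulate.simulate_ssr_genotypes(sim_config)
    truth.ssr_genotypes, truth.Q_true = ssr_geno, Q_true
    q_df = pd.DataFrame(Q_true, columns=[f"pop{j}" for j in
                                         range(Q_true.shape[1])])
    q_df.insert(0, "individual",
                [f"ind{i:03d}" for i in range(len(q_df))])
    p = outdir / "Q_true.tsv"
    hio.write_tsv(q_df, p)
    record("Q_true", p)

    # --- haplotype calling --------------------------------------------
    genotype_tables = {}
    pairs_by_contig = {}
    if "haplotype" in stages:
        pairs_by_contig, genotype_tables, _ = call_cohort(truth, sim_config)
        hap_out = []
        for cid, pairs in pairs_by_contig.items():
            for pr in pairs:
                if pr.haplotype_1 is None:
                    continue
                hap_out.append((f"{pr.individual}|{cid}|hap1|"
                                f"{pr.support_1}|{pr.coverage_flag}",
                                pr.haplotype_1))
                hap_out.append((f"{pr.individual}|{cid}|hap2|"
                                f"{pr.support_2}|{pr.coverage_flag}",
                                pr.haplotype_2))
        p = outdir / "called_haplotypes.fasta"
        hio.write_fasta(hap_out, p)
        record("called_haplotypes", p)
        for cid, geno in genotype_tables.items():
            p = outdir / f"genotypes_{cid}.tsv"
            out = geno.copy()
            out.insert(0, "individual", out.index)
            hio.write_tsv(out, p)
            record(f"genotypes_{cid}", p)

    # --- diversity -----------------------------------------------------
    if "diversity" in stages:
        rows = []
        source = pairs_by_contig if pairs_by_contig else {
            cid: None for cid in truth.references}
        for cid in truth.references:
            if pairs_by_contig:
                aln = []
                for pr in pairs_by_contig[cid]:
                    if pr.haplotype_1 is not None:
                        aln += [pr.haplotype_1, pr.haplotype_2]
            else:
                aln = [h for pair in truth.haplotypes[cid] for h in pair]
            if len(aln) < 2:
                continue
            s = diversity.summarize(aln)
            rows.append({"contig": cid, "n": s.n, "S": s.S, "pi": s.pi,
                         "theta_w": s.theta_w, "tajima_d": s.tajima_d,
                         "d_pvalue": s.d_pvalue,
                         "n_haplotypes": s.n_haplotypes,
                         "hap_diversity": s.hap_diversity,
                         "hap_diversity_sd": s.hap_diversity_sd})
        p = outdir / "diversity.tsv"
        hio.write_tsv(pd.DataFrame(rows), p)
        record("diversity", p)

    # --- within-gene SNP LD ---------------------------------------------
    if "ld_snp" in stages and genotype_tables:
        rows = []
        for cid, geno in genotype_tables.items():
            cols = list(geno.columns)
            for i in range(len(cols)):
                for j in range(i + 1, len(cols)):
                    try:
                        r2 = linkage.snp_r2(geno[cols[i]], geno[cols[j]])
                    except ValueError:
                        continue
                    rows.append({"contig": cid, "snp_a": cols[i],
                                 "snp_b": cols[j],
                                 "distance": abs(cols[j] - cols[i]),
                                 "r2": r2})
        df = pd.DataFrame(rows)
        p = outdir / "ld_snp.tsv"
        hio.write_tsv(df, p)
        record("ld_snp", p)
        if len(df):
            decay = linkage.ld_decay_summary(df.to_dict("records"))
            p = outdir / "ld_decay.tsv"
            hio.write_tsv(decay, p)
            record("ld_decay", p)

    # --- SSR LD ---------------------------------------------------------
    if "ld_ssr" in stages:
        params = dict(config.get("ld_ssr", {}))
        n_perm = int(params.get("permutations", 500))
        rng = sim_config.rng("ld_ssr")
        n_loci = ssr_geno.shape[1]
        rows = []
        for a in range(n_loci):
            for b in range(a + 1, n_loci):
                ga = [tuple(x) for x in ssr_geno[:, a, :]]
                gb = [tuple(x) for x in ssr_geno[:, b, :]]
                try:
                    g, pval = linkage.genotypic_ld_test(
                        ga, gb, n_permutations=n_perm,
                        seed=int(rng.integers(2 ** 31)))
                except ValueError:
                    continue
                rows.append({"locus_a": a, "locus_b": b, "G": g, "P": pval})
        df = pd.DataFrame(rows)
        if len(df):
            df["q_value"] = multiplicity.qvalues(df["P"].to_numpy())
            df["neg_log10_q"] = -np.log10(df["q_value"])
        p = outdir / "ld_ssr.tsv"
        hio.write_tsv(df, p)
        record("ld_ssr", p)

    # --- kinship ---------------------------------------------------------
    K = None
    if "kinship" in stages:
        kin = relatedness.truncate_negative(
            relatedness.ritland_kinship(ssr_geno))
        K = kin
        names = [f"ind{i:03d}" for i in range(len(kin.values))]
        kdf = pd.DataFrame(kin.values, columns=names)
        kdf.insert(0, "individual", names)
        p = outdir / "kinship.tsv"
        hio.write_tsv(kdf, p)
        record("kinship", p)

    # --- association -----------------------------------------------------
    if "association" in stages and genotype_tables and K is not None:
        params = dict(config.get("association", {}))
        contig0 = sim_config.contigs[0].id
        geno = genotype_tables[contig0]
        if len(geno.columns):
            qtn_col = geno.columns[len(geno.columns) // 2]
            dosage = geno[qtn_col].to_numpy(dtype=float)
            dosage = np.nan_to_num(dosage)
        else:
            dosage = np.zeros(sim_config.n_individuals)
        comp = simulate.simulate_phenotype(
            Q_true, K.values, dosage, sim_config,
            structure_effects=np.arange(Q_true.shape[1], dtype=float),
            beta=float(params.get("qtn_beta", 1.0)))
        phen = pd.DataFrame({"trait1": comp["y"]}, index=geno.index)
        K2 = relatedness.mixed_model_covariance(K)
        df, _ = association.association_scan(
            phen, geno, Q=Q_true[:, 1:], K2=K2,
            encoding=params.get("encoding", "genotype-class"))
        p = outdir / "association.tsv"
        hio.write_tsv(df, p)
        record("association", p)
        if len(df):
            qq = association.qq_data(df["P"].to_numpy())
            p = outdir / "qq_trait1.tsv"
            hio.write_tsv(qq, p)
            record("qq_trait1", p)

    manifest_path = outdir / "manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return manifest
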