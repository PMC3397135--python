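"""File formats shared by the pipeline stages.

TSV (tab-separated, UTF-8, '.' for missing) is the lingua franca between
stages; sequences travel as FASTA/FASTQ via Biopython; SNP calls are
mirrored as minimal VCFv4.2. All writers round-trip through the matching
readers.
"""

from __future__ import annotations

import io as _io
from pathlib import Path

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

__all__ = ["read_fasta", "write_fasta", "read_fastq", "write_fastq",
           "read_tsv", "write_tsv", "read_vcf_min", "write_vcf_min"]


def read_fasta(path):
    """FASTA -> list of (id, sequence)."""
    return [(rec.id, str(rec.seq)) for rec in SeqIO.parse(str(path), "fasta")]


def write_fasta(records, path):
    recs = [SeqRecord(Seq(seq), id=name, description="")
            for name, seq in records]
    SeqIO.write(recs, str(path), "fasta")


def read_fastq(path):
    """FASTQ -> list of (id, sequence); qualities are not modeled."""
    return [(rec.id, str(rec.seq)) for rec in SeqIO.parse(str(path), "fastq")]


def write_fastq(records, path, quality=30):
    recs = []
    for name, seq in records:
        r = SeqRecord(Seq(seq), id=name, description="")
        r.letter_annotations["phred_quality"] = [quality] * len(seq)
        recs.append(r)
    SeqIO.write(recs, str(path), "fastq")


def read_tsv(path, required=None):
    """TSV with a one-line header; '.' is read as missing.

    ``required`` columns are checked and a missing one raises a
    ValueError naming it.
    """
    df = pd.read_csv(path, sep="\t", na_values=["."], comment="#")
    if required:
        for col in required:
            if col not in df.columns:
                raise ValueError(f"{path}: missing required column '{col}'")
    return df


def write_tsv(df, path):
    df.to_csv(path, sep="\t", index=False, na_rep=".")


def write_vcf_min(variants, path, contig_id=None):
    """Minimal VCFv4.2 for a list of variant records.

    ``variants`` may be :class:`haplopop.haplotyper.Variant` objects (with
    ``contig_id`` supplied) or dicts with CHROM/POS/REF/ALT/AF keys. POS
    is 1-based per the format.
    """
    lines = ["##fileformat=VCFv4.2",
             '##INFO=<ID=AF,Number=A,Type=Float,Description='
             '"Allele Frequency">',
             "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO"]
    for v in variants:
        if isinstance(v, dict):
            chrom, pos, ref, alts, afs = (v["CHROM"], v["POS"], v["REF"],
                                          v["ALT"], v["AF"])
        else:
            chrom = contig_id or "contig"
            pos = v.position_1based
            ref = v.ref
            alts = list(v.alts)
            afs = [v.frequencies.get(a, 0.0) for a in alts]
        alts = [a if a != "-" else "*" for a in alts]
        info = "AF=" + ",".join(f"{f:.6g}" for f in afs)
        lines.append(f"{chrom}\t{pos}\t.\t{ref}\t{','.join(alts)}\t.\t.\t{info}")
    Path(path).write_text("\n".join(lines) + "\n")


def read_vcf_min(path):
    """Minimal VCF -> list of dicts with CHROM/POS/REF/ALT/AF."""
    out = []
    for i, line in enumerate(Path(path).read_text().splitlines(), start=1):
        if not line or line.startswith("#"):
            continue
        fields = line.split("\t")
        if len(fields) < 8:
            raise ValueError(f"{path}:{i}: malformed VCF record")
        info = dict(kv.split("=", 1) for kv in fields[7].split(";")
                    if "=" in kv)
        afs = [float(x) for x in info.get("AF", "").split(",") if x]
        out.append({"CHROM": fields[0], "POS": int(fields[1]),
                    "REF": fields[3], "ALT": fields[4].split(","),
                    "AF": afs})
    return out
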