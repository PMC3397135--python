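"""Linkage disequilibrium for SSR and SNP markers.

Two marker classes, two tests: multi-allelic SSR pairs on the same
chromosome are tested with a genotypic log-likelihood-ratio (G) test
whose null distribution comes from permuting one locus's genotypes among
individuals; biallelic SNP pairs within a gene use the squared Pearson
correlation of 0/1/2 dosages (r^2). Physical-distance pairing, r^2 decay
binning, and FDR-based significance summaries are included.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from itertools import combinations, permutations

import numpy as np
import pandas as pd

log = logging.getLogger(__name__)

__all__ = [
    "LDRecord", "same_chromosome_pairs", "genotypic_ld_test", "snp_r2",
    "ld_decay_summary", "significance_filter",
]


@dataclass
class LDRecord:
    marker_a: str
    marker_b: str
    chromosome: str | None
    distance: float           # Mb for SSR pairs, bp for SNP pairs
    statistic: float          # G or r^2
    p_value: float | None = None
    q_value: float | None = None

    @property
    def neg_log10_q(self):
        return None if self.q_value is None else -np.log10(self.q_value)


def same_chromosome_pairs(markers, marker_map, exclude=()):
    """All unordered same-chromosome marker pairs with |distance|.

    ``marker_map`` is a DataFrame with columns marker/chromosome/position.
    Markers absent from the map are skipped with a warning; pairs listed
    in ``exclude`` (unordered) are removed.
    """
    mm = marker_map.set_index("marker")
    excl = {frozenset(p) for p in exclude}
    pairs = []
    known = []
    for m in markers:
        if m in mm.index:
            known.append(m)
        else:
            log.warning("marker %s missing from map; skipped", m)
    for a, b in combinations(known, 2):
        if mm.loc[a, "chromosome"] != mm.loc[b, "chromosome"]:
            continue
        if frozenset((a, b)) in excl:
            continue
        pairs.append({"marker_a": a, "marker_b": b,
                      "chromosome": mm.loc[a, "chromosome"],
                      "distance": abs(float(mm.loc[a, "position"]) -
                                      float(mm.loc[b, "position"]))})
    return pd.DataFrame(pairs,
                        columns=["marker_a", "marker_b", "chromosome",
                                 "distance"])


def _genotype_codes(genos):
    """Map unordered genotype tuples to integer classes; None = missing."""
    keys = []
    for g in genos:
        if g is None or any(a is None for a in g):
            keys.append(None)
        else:
            keys.append(tuple(sorted(g)))
    classes = sorted({k for k in keys if k is not None})
    index = {k: i for i, k in enumerate(classes)}
    return np.array([-1 if k is None else index[k] for k in keys]), len(classes)


def _g_statistic(codes_a, codes_b, n_a, n_b):
    counts = np.zeros((n_a, n_b))
    np.add.at(counts, (codes_a, codes_b), 1)
    total = counts.sum()
    rows = counts.sum(axis=1, keepdims=True)
    cols = counts.sum(axis=0, keepdims=True)
    with np.errstate(divide="ignore", invalid="ignore"):
        expected = rows @ cols / total
        ratio = np.where(counts > 0, counts / expected, 1.0)
        g = 2.0 * np.sum(counts * np.log(ratio))
    return float(g)


def genotypic_ld_test(genos_a, genos_b, n_permutations=10000, seed=0):
    """Permutation G-test of genotypic association between two loci.

    Genotypes are unordered allele pairs (multi-allelic allowed); missing
    genotypes at either locus drop the individual. The observed G is the
    log-likelihood-ratio statistic of the two-locus genotype contingency
    table; its p-value is the add-one permutation estimate
    ``(1 + #{G_perm >= G_obs}) / (n_permutations + 1)`` obtained by
    permuting locus-B genotypes among individuals. With
    ``n_permutations="exact"`` all n! permutations are enumerated
    (feasible for n <= 8) and the plain proportion is returned.
    """
    codes_a, n_a = _genotype_codes(genos_a)
    codes_b, n_b = _genotype_codes(genos_b)
    keep = (codes_a >= 0) & (codes_b >= 0)
    ca, cb = codes_a[keep], codes_b[keep]
    if len(ca) < 2:
        raise ValueError("need >=2 individuals complete at both loci")
    if len(set(ca)) < 2 or len(set(cb)) < 2:
        raise ValueError("test undefined: <2 genotype classes at a locus")
    g_obs = _g_statistic(ca, cb, n_a, n_b)
    tol = 1e-9
    if n_permutations == "exact":
        hits = total = 0
        for perm in permutations(range(len(cb))):
            g = _g_statistic(ca, cb[list(perm)], n_a, n_b)
            hits += g >= g_obs - tol
            total += 1
        return g_obs, hits / total
    rng = np.random.default_rng(seed)
    hits = 0
    for _ in range(int(n_permutations)):
        g = _g_statistic(ca, rng.permutation(cb), n_a, n_b)
        hits += g >= g_obs - tol
    return g_obs, (1 + hits) / (int(n_permutations) + 1)


def snp_r2(dosage_a, dosage_b):
    """Squared Pearson correlation of 0/1/2 dosages, pairwise-complete."""
    a = np.asarray(dosage_a, dtype=float)
    b = np.asarray(dosage_b, dtype=float)
    keep = ~(np.isnan(a) | np.isnan(b))
    a, b = a[keep], b[keep]
    if len(a) < 2:
        raise ValueError("need >=2 complete individuals")
    if np.var(a) == 0 or np.var(b) == 0:
        raise ValueError("zero variance at a SNP: r^2 undefined")
    r = np.corrcoef(a, b)[0, 1]
    return float(r * r)


def ld_decay_summary(records, r2_threshold=0.1, bin_bp=50):
    """Per-contig mean r^2 and the distance at which LD has decayed.

    Pairwise r^2 values (bp distances) are binned by distance
    (``bin_bp``-wide bins); the decay distance is the upper edge of the
    smallest bin whose mean r^2 falls below ``r2_threshold``, or
    ``no decay`` when no bin does.
    """
    df = pd.DataFrame(records)
    out = []
    for contig, grp in df.groupby("contig"):
        bins = (grp["distance"] // bin_bp).astype(int)
        binned = grp.groupby(bins)["r2"].mean().sort_index()
        decay = None
        for b, mean_r2 in binned.items():
            if mean_r2 < r2_threshold:
                decay = (b + 1) * bin_bp
                break
        out.append({"contig": contig, "mean_r2": grp["r2"].mean(),
                    "n_pairs": len(grp),
                    "decay_distance": decay,
                    "decayed": decay is not None})
    return pd.DataFrame(out)


def significance_filter(records: pd.DataFrame, alpha=1e-4, group_col=None,
                        q_col="q_value"):
    """Significant records at q <= alpha, with per-group counts/percentages.

    Returns ``(significant_records, summary)`` where the summary lists,
    per group (or 'overall'), the number tested, number significant, and
    the percentage of tested pairs that are significant.
    """
    sig = records[records[q_col] <= alpha]
    if group_col is None:
        groups = [("overall", records, sig)]
    else:
        groups = [(g, records[records[group_col] == g],
                   sig[sig[group_col] == g])
                  for g in records[group_col].unique()]
    rows = []
    for name, tested, hits in groups:
        n_tested = len(tested)
        n_sig = len(hits)
        pct = 100.0 * n_sig / n_tested if n_tested else 0.0
        rows.append({"group": name, "n_tested": n_tested,
                     "n_significant": n_sig, "percent": pct})
    return sig, pd.DataFrame(rows)
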