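"""Sequence diversity statistics for haplotype alignments.

Implements the classical summaries for a sample of n aligned sequences:
mean pairwise differences k and per-site nucleotide diversity pi,
Watterson's theta from the number of segregating sites, Tajima's D with
its beta-distribution significance approximation, haplotype counts and
haplotype (gene) diversity with its sampling standard deviation, and a
sliding-window Tajima's D.

By default columns containing any gap, N, or IUPAC ambiguity are excluded
from every statistic ("complete deletion"); pairwise deletion is
available for k/pi.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
from scipy import stats

VALID = set("ACGT")

__all__ = [
    "DiversitySummary", "analyzed_columns", "nucleotide_diversity",
    "segregating_sites", "watterson_theta", "tajima_constants", "tajimas_d",
    "haplotype_stats", "sliding_tajima", "summarize",
]


class UndefinedStatistic(ValueError):
    """Raised when a statistic is undefined for the given alignment."""


@dataclass
class DiversitySummary:
    n: int
    S: int
    k: float
    L_eff: int
    pi: float
    theta_w: float
    tajima_d: float | None
    d_pvalue: float | None
    n_haplotypes: int
    hap_diversity: float
    hap_diversity_sd: float


def _as_matrix(aln):
    seqs = [s.upper() for s in aln]
    if len(seqs) < 2:
        raise ValueError("need at least 2 sequences")
    if len({len(s) for s in seqs}) != 1:
        raise ValueError("sequences must be aligned to equal length")
    return np.array([list(s) for s in seqs])


def analyzed_columns(aln, deletion="complete"):
    """Boolean mask of columns used under the deletion convention."""
    m = _as_matrix(aln)
    if deletion == "complete":
        return np.isin(m, list(VALID)).all(axis=0)
    if deletion == "pairwise":
        return np.ones(m.shape[1], dtype=bool)
    raise ValueError("deletion must be 'complete' or 'pairwise'")


def nucleotide_diversity(aln, deletion="complete"):
    """Mean pairwise differences k and per-site diversity pi = k / L_eff."""
    m = _as_matrix(aln)
    n = m.shape[0]
    if deletion == "complete":
        mask = analyzed_columns(aln, "complete")
        L_eff = int(mask.sum())
        if L_eff == 0:
            raise UndefinedStatistic("no analyzed columns")
        sub = m[:, mask]
        # only varying columns can contribute differences
        sub = sub[:, (sub != sub[0]).any(axis=0)]
        diffs = [np.sum(sub[i] != sub[j]) for i, j in combinations(range(n), 2)]
        k = float(np.mean(diffs))
        return k, k / L_eff
    # pairwise deletion: per pair, compare columns valid in both
    ks, pis = [], []
    for i, j in combinations(range(n), 2):
        ok = np.array([a in VALID and b in VALID for a, b in zip(m[i], m[j])])
        if ok.sum() == 0:
            continue
        d = np.sum((m[i] != m[j]) & ok)
        ks.append(d)
        pis.append(d / ok.sum())
    if not pis:
        raise UndefinedStatistic("no comparable columns in any pair")
    return float(np.mean(ks)), float(np.mean(pis))


def segregating_sites(aln, deletion="complete"):
    m = _as_matrix(aln)
    mask = analyzed_columns(aln, deletion)
    if deletion == "complete":
        sub = m[:, mask]
        return int(((sub != sub[0]).any(axis=0)).sum())
    S = 0
    for j in np.nonzero(mask)[0]:
        col = [b for b in m[:, j] if b in VALID]
        if len(set(col)) > 1:
            S += 1
    return S


def watterson_theta(aln, deletion="complete"):
    """theta_w = S / (a1 * L_eff), a1 = sum_{i=1}^{n-1} 1/i."""
    m = _as_matrix(aln)
    n = m.shape[0]
    mask = analyzed_columns(aln, deletion)
    L_eff = int(mask.sum())
    if L_eff == 0:
        raise UndefinedStatistic("no analyzed columns")
    S = segregating_sites(aln, deletion)
    a1 = np.sum(1.0 / np.arange(1, n))
    return S / (a1 * L_eff)


def tajima_constants(n):
    """The a1..e2 constants of the D statistic as functions of n."""
    i = np.arange(1, n)
    a1 = np.sum(1.0 / i)
    a2 = np.sum(1.0 / i ** 2)
    b1 = (n + 1) / (3.0 * (n - 1))
    b2 = 2.0 * (n ** 2 + n + 3) / (9.0 * n * (n - 1))
    c1 = b1 - 1.0 / a1
    c2 = b2 - (n + 2) / (a1 * n) + a2 / a1 ** 2
    e1 = c1 / a1
    e2 = c2 / (a1 ** 2 + a2)
    return dict(a1=a1, a2=a2, b1=b1, b2=b2, c1=c1, c2=c2, e1=e1, e2=e2)


def tajimas_d(aln, deletion="complete"):
    """Tajima's D and its two-tailed beta-approximation p-value.

    D = (k - S/a1) / sqrt(e1*S + e2*S*(S-1)). The null distribution is
    approximated by a scaled beta on [D_min, D_max] with mean 0 and unit
    variance; the p-value is twice the smaller tail. Undefined when S = 0.
    """
    m = _as_matrix(aln)
    n = m.shape[0]
    S = segregating_sites(aln, deletion)
    if S == 0:
        raise UndefinedStatistic("no segregating sites: D undefined")
    k, _ = nucleotide_diversity(aln, deletion)
    c = tajima_constants(n)
    D = (k - S / c["a1"]) / np.sqrt(c["e1"] * S + c["e2"] * S * (S - 1))

    dmin = (2.0 / n - 1.0 / c["a1"]) / np.sqrt(c["e2"])
    dmax = ((n + 1.0) / (2.0 * n) - 1.0 / c["a1"]) / np.sqrt(c["e2"])
    tmp = 1.0 + dmin * dmax
    rng_ = dmax - dmin
    alpha = -tmp * dmax / rng_
    beta = tmp * dmin / rng_
    x = np.clip((D - dmin) / rng_, 0.0, 1.0)
    cdf = stats.beta.cdf(x, beta, alpha)
    p = 2.0 * min(cdf, 1.0 - cdf)
    return float(D), float(min(max(p, np.finfo(float).tiny), 1.0))


def haplotype_stats(aln, deletion="complete"):
    """Distinct haplotypes, gene diversity Hd, and its sampling SD.

    Hd = n (1 - sum p_i^2) / (n - 1); the SD is the square root of the
    large-sample variance of the gene diversity estimator.
    """
    m = _as_matrix(aln)
    n = m.shape[0]
    mask = analyzed_columns(aln, deletion)
    keys = ["".join(row) for row in m[:, mask]]
    uniq = list(dict.fromkeys(keys))
    counts = np.array([keys.count(u) for u in uniq])
    p = counts / n
    sum2 = float(np.sum(p ** 2))
    sum3 = float(np.sum(p ** 3))
    hd = n * (1.0 - sum2) / (n - 1)
    var = (2.0 / (n * (n - 1))) * (
        2.0 * (n - 2) * (sum3 - sum2 ** 2) + sum2 - sum2 ** 2)
    return len(counts), float(hd), float(np.sqrt(max(var, 0.0)))


def sliding_tajima(aln, window_bp=100, step_bp=25, deletion="complete"):
    """Tajima's D in sliding windows of alignment columns.

    Windows where S = 0 (or where D is otherwise undefined) are reported
    with ``D=None``. A window longer than the alignment collapses to one
    full-length window.
    """
    if window_bp < 1 or step_bp < 1:
        raise ValueError("window and step must be >= 1")
    m = _as_matrix(aln)
    L = m.shape[1]
    window_bp = min(window_bp, L)
    out = []
    start = 0
    while True:
        end = min(start + window_bp, L)
        sub = ["".join(row) for row in m[:, start:end]]
        try:
            D, p = tajimas_d(sub, deletion)
        except (UndefinedStatistic, ValueError):
            D, p = None, None
        out.append({"start": start, "end": end, "D": D, "p": p})
        if end >= L:
            break
        start += step_bp
    return out


def summarize(aln, deletion="complete") -> DiversitySummary:
    """All per-alignment statistics in one record (one table row)."""
    m = _as_matrix(aln)
    n = m.shape[0]
    mask = analyzed_columns(aln, deletion if deletion == "complete"
                            else "complete")
    L_eff = int(mask.sum())
    S = segregating_sites(aln, deletion)
    k, pi = nucleotide_diversity(aln, deletion)
    theta = watterson_theta(aln, deletion)
    try:
        D, p = tajimas_d(aln, deletion)
    except UndefinedStatistic:
        D, p = None, None
    nh, hd, sd = haplotype_stats(aln, deletion)
    return DiversitySummary(n=n, S=S, k=k, L_eff=L_eff, pi=pi, theta_w=theta,
                            tajima_d=D, d_pvalue=p, n_haplotypes=nh,
                            hap_diversity=hd, hap_diversity_sd=sd)
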