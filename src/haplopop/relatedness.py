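"""Ritland moment-estimator kinship from multi-allelic marker genotypes.

The pairwise coancestry of individuals i and j at a locus with A alleles
is F_ij = [ sum_a x_ia x_ja / p_a  -  1 ] / (A - 1), where x_ia is the
fraction of i's two allele copies that are allele a and p_a the reference
allele frequency. Loci are combined with weights A_l - 1 (more-allelic
loci are more informative); loci missing in either member of a pair drop
out of that pair's average. For mixed-model use, negative estimates are
truncated to zero.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

log = logging.getLogger(__name__)

__all__ = ["KinshipMatrix", "ritland_kinship", "truncate_negative",
           "mixed_model_covariance"]


@dataclass
class KinshipMatrix:
    values: np.ndarray            # (n, n), symmetric
    individuals: list
    allele_frequencies: list      # per locus: dict allele -> frequency


def _sample_frequencies(genotypes, n_alleles):
    """Per-locus allele frequencies from the sample, ignoring missing."""
    n, L, _ = genotypes.shape
    freqs = []
    for l in range(L):
        alleles = genotypes[:, l, :].ravel()
        alleles = alleles[alleles >= 0]
        counts = np.bincount(alleles, minlength=n_alleles)
        freqs.append(counts / counts.sum())
    return freqs


def ritland_kinship(genotypes, allele_frequencies=None) -> KinshipMatrix:
    """Untruncated Ritland kinship matrix.

    ``genotypes`` is an (n_individuals, n_loci, 2) integer array of allele
    indices, with -1 for missing. Frequencies default to the full-sample
    estimates; a supplied table must give positive frequency to every
    observed allele.
    """
    genotypes = np.asarray(genotypes)
    n, L, _ = genotypes.shape
    if n < 2:
        raise ValueError("need at least 2 individuals")
    n_alleles = int(genotypes.max()) + 1
    if allele_frequencies is None:
        allele_frequencies = _sample_frequencies(genotypes, n_alleles)

    # per-locus dosage fractions x_ia, and per-locus usable-allele counts
    F = np.zeros((n, n))
    W = np.zeros((n, n))
    for l in range(L):
        p = np.asarray(allele_frequencies[l], dtype=float)
        g = genotypes[:, l, :]
        missing = (g < 0).any(axis=1)
        observed = np.unique(g[~missing])
        if np.any(p[observed] <= 0):
            raise ValueError(f"locus {l}: observed allele with zero "
                             "reference frequency")
        A = int(np.sum(p > 0))
        if A < 2:
            continue
        x = np.zeros((n, len(p)))
        for copy in range(2):
            valid = g[:, copy] >= 0
            np.add.at(x, (np.nonzero(valid)[0], g[valid, copy]), 0.5)
        with np.errstate(divide="ignore", invalid="ignore"):
            xp = np.where(p > 0, x / p, 0.0)
        f_l = (x @ xp.T - 1.0) / (A - 1)
        ok = np.outer(~missing, ~missing)
        w_l = A - 1
        F += np.where(ok, w_l * f_l, 0.0)
        W += np.where(ok, w_l, 0.0)
    if np.any(W == 0):
        log.warning("some pairs share no typed locus; kinship set to 0")
    with np.errstate(invalid="ignore"):
        K = np.where(W > 0, F / np.where(W > 0, W, 1.0), 0.0)
    K = (K + K.T) / 2.0
    return KinshipMatrix(values=K, individuals=list(range(n)),
                         allele_frequencies=allele_frequencies)


def truncate_negative(kinship: KinshipMatrix) -> KinshipMatrix:
    """Elementwise max(F, 0); negative moment estimates read as unrelated."""
    return KinshipMatrix(values=np.maximum(kinship.values, 0.0),
                         individuals=list(kinship.individuals),
                         allele_frequencies=kinship.allele_frequencies)


def mixed_model_covariance(kinship: KinshipMatrix) -> np.ndarray:
    """2K with the diagonal floored at 1, the polygenic covariance scale
    expected by the unified mixed model."""
    A = 2.0 * np.maximum(kinship.values, 0.0)
    A = (A + A.T) / 2.0
    np.fill_diagonal(A, np.maximum(np.diag(A), 1.0))
    return A
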