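"""Single-marker Q+K mixed linear model association scan.

For each marker and trait the unified mixed model

    y = mu + marker + Q v + u + e,   u ~ N(0, 2K sigma_g^2),
                                     e ~ N(0, I sigma_e^2)

is fitted by REML: one eigendecomposition of the polygenic covariance 2K
rotates the model to independent errors with variances
sigma_g^2 (lambda_i + delta), delta = sigma_e^2 / sigma_g^2, and the
profiled restricted log-likelihood is maximized over log(delta) in one
dimension. The marker is tested by a Wald F on its coefficients with
denominator df = n - rank(fixed effects); marker R^2 is the marker sum
of squares over the total sum of squares on the GLS-whitened scale.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .multiplicity import qvalues

log = logging.getLogger(__name__)

__all__ = ["AssociationRecord", "fit_mlm_single_marker", "association_scan",
           "qq_data", "genotype_class_summary", "marker_design"]

_LOG_DELTA_BOUNDS = (np.log(1e-5), np.log(1e5))


@dataclass
class AssociationRecord:
    trait: str
    marker: str
    F: float
    p_value: float
    marker_r2: float
    n_used: int
    delta: float
    class_means: dict
    q_value: float | None = None


def marker_design(genotypes, encoding="genotype-class", min_class_size=3,
                  pool_label="other"):
    """Design matrix columns for one marker, plus the kept-individual mask.

    genotype-class: one indicator column per genotype class beyond the
    first; classes smaller than ``min_class_size`` are pooled into an
    'other' class (SSR convention) — if the pool itself stays below the
    minimum its individuals are dropped. additive-dosage: a single 0/1/2
    column. Returns None when fewer than two classes survive.
    """
    g = pd.Series(genotypes)
    keep = g.notna()
    if encoding == "additive-dosage":
        if keep.sum() < 2 or g[keep].nunique() < 2:
            return None
        X = g[keep].astype(float).to_numpy()[:, None]
        return X, keep.to_numpy(), ["dosage"]
    counts = g[keep].value_counts()
    small = counts[counts < min_class_size].index
    labels = g.where(~g.isin(small), pool_label)
    if (labels == pool_label).sum() < min_class_size:
        keep &= labels != pool_label
    labels = labels[keep]
    classes = sorted(labels.unique(), key=str)
    if len(classes) < 2:
        return None
    X = np.column_stack([(labels == c).to_numpy(dtype=float)
                         for c in classes[1:]])
    return X, keep.to_numpy(), [str(c) for c in classes[1:]]


def _reml_neg_loglik(log_delta, lam, yt, Xt):
    """Profiled restricted negative log-likelihood in log(delta)."""
    delta = np.exp(log_delta)
    w = lam + delta
    n, p = Xt.shape
    Wi = 1.0 / w
    XtWX = Xt.T @ (Wi[:, None] * Xt)
    XtWy = Xt.T @ (Wi * yt)
    try:
        beta = np.linalg.solve(XtWX, XtWy)
    except np.linalg.LinAlgError:
        beta = np.linalg.lstsq(XtWX, XtWy, rcond=None)[0]
    r = yt - Xt @ beta
    rss = float(r @ (Wi * r))
    sigma_g2 = rss / (n - p)
    sign, logdet_XtWX = np.linalg.slogdet(XtWX)
    ll = -0.5 * ((n - p) * np.log(sigma_g2) + np.sum(np.log(w))
                 + logdet_XtWX + (n - p))
    return -ll


def _gls_fit(lam, delta, yt, Xt):
    w = np.sqrt(lam + delta)
    yw = yt / w
    Xw = Xt / w[:, None]
    beta, _, rank, _ = np.linalg.lstsq(Xw, yw, rcond=None)
    rss = float(np.sum((yw - Xw @ beta) ** 2))
    return beta, rss, rank, yw, Xw


def fit_mlm_single_marker(y, marker_X, Q=None, K2=None, trait="trait",
                          marker="marker", class_means=None):
    """REML fit and Wald F-test for one marker.

    ``marker_X`` is the marker's design block (already encoded);
    ``Q`` optional structure covariates (one column dropped by the
    caller); ``K2`` the polygenic covariance 2K (None or all-zero
    collapses the model to ordinary least squares).
    """
    y = np.asarray(y, dtype=float)
    n = len(y)
    if np.allclose(np.var(y), 0.0):
        raise ValueError("constant phenotype: model degenerate")
    blocks = [np.ones((n, 1))]
    if Q is not None and Q.size:
        blocks.append(np.asarray(Q, dtype=float))
    X0 = np.column_stack(blocks)
    X1 = np.column_stack([X0, marker_X])
    if n < X1.shape[1] + 2:
        raise ValueError("too few observations for the fixed effects")

    if K2 is None:
        lam = np.zeros(n)
        U = np.eye(n)
    else:
        K2 = np.asarray(K2, dtype=float)
        lam, U = np.linalg.eigh((K2 + K2.T) / 2.0)
        lam = np.clip(lam, 0.0, None)
    yt = U.T @ y
    X1t = U.T @ X1
    X0t = U.T @ X0

    res = optimize.minimize_scalar(
        _reml_neg_loglik, bounds=_LOG_DELTA_BOUNDS, method="bounded",
        args=(lam, yt, X1t), options={"xatol": 1e-8})
    delta = float(np.exp(res.x))

    beta1, rss1, rank1, yw, Xw = _gls_fit(lam, delta, yt, X1t)
    beta0, rss0, rank0, _, _ = _gls_fit(lam, delta, yt, X0t)
    q = rank1 - rank0
    df_den = n - rank1
    if q < 1 or df_den < 1 or rss1 <= 0:
        raise ValueError("marker test undefined after rank reduction")
    F = ((rss0 - rss1) / q) / (rss1 / df_den)
    F = max(F, 0.0)
    p = float(stats.f.sf(F, q, df_den))
    # marker R^2 on the whitened scale: marker SS over total SS
    tot = float(np.sum((yw - np.mean(yw)) ** 2))
    r2 = float((rss0 - rss1) / tot) if tot > 0 else 0.0
    return AssociationRecord(trait=trait, marker=marker, F=float(F),
                             p_value=min(max(p, np.finfo(float).tiny), 1.0),
                             marker_r2=min(max(r2, 0.0), 1.0), n_used=n,
                             delta=delta, class_means=class_means or {})


def association_scan(phenotypes: pd.DataFrame, markers: pd.DataFrame,
                     Q=None, K2=None, encoding="genotype-class",
                     min_class_size=3, maf_threshold=0.05,
                     qvalue_family="per-trait", apply_maf_filter=True):
    """One MLM record per (trait, marker), with q-values appended.

    ``phenotypes``: individuals x traits; ``markers``: individuals x
    markers of dosages (0/1/2, NaN missing) or genotype-class labels.
    Markers with MAF <= ``maf_threshold`` (dosage-coded markers only) or
    fewer than two usable classes are skipped with a log message.
    Q-values come from the positive-FDR module, with the family either
    ``per-trait`` or ``global``.
    """
    if not phenotypes.index.equals(markers.index):
        raise ValueError("phenotype and marker tables must share the same "
                         "individual index")
    records = []
    for mk in markers.columns:
        g = markers[mk]
        if apply_maf_filter and pd.api.types.is_numeric_dtype(g):
            vals = g.dropna().astype(float)
            if len(vals) == 0:
                continue
            freq = vals.sum() / (2 * len(vals))
            if min(freq, 1 - freq) <= maf_threshold:
                log.info("marker %s skipped: MAF <= %.2f", mk, maf_threshold)
                continue
        design = marker_design(g, encoding=encoding,
                               min_class_size=min_class_size)
        if design is None:
            log.info("marker %s skipped: <2 genotype classes", mk)
            continue
        Xm, keep, _ = design
        for trait in phenotypes.columns:
            y = phenotypes[trait].to_numpy(dtype=float)
            mask = keep & ~np.isnan(y)
            # Xm rows correspond to kept individuals; subset to the joint mask
            sub = mask[keep]
            Xm_sub = Xm[sub]
            y_sub = y[mask]
            Q_sub = None if Q is None else np.asarray(Q, dtype=float)[mask]
            K2_sub = None if K2 is None else \
                np.asarray(K2, dtype=float)[np.ix_(mask, mask)]
            cls_means = {}
            if encoding == "genotype-class":
                lab = g[mask]
                cls_means = {str(c): float(np.mean(y[mask][lab == c]))
                             for c in sorted(lab.dropna().unique(), key=str)}
            try:
                rec = fit_mlm_single_marker(
                    y_sub, Xm_sub, Q=Q_sub, K2=K2_sub, trait=str(trait),
                    marker=str(mk), class_means=cls_means)
            except (ValueError, np.linalg.LinAlgError) as err:
                log.info("marker %s / trait %s skipped: %s", mk, trait, err)
                continue
            records.append(rec)
    if not records:
        return pd.DataFrame(), records
    df = pd.DataFrame([{
        "trait": r.trait, "marker": r.marker, "F": r.F, "P": r.p_value,
        "marker_r2": r.marker_r2, "n": r.n_used} for r in records])
    if qvalue_family == "per-trait":
        df["q_value"] = np.nan
        for trait, grp in df.groupby("trait"):
            df.loc[grp.index, "q_value"] = qvalues(grp["P"].to_numpy())
    elif qvalue_family == "global":
        df["q_value"] = qvalues(df["P"].to_numpy())
    else:
        raise ValueError("qvalue_family must be 'per-trait' or 'global'")
    for rec, q in zip(records, df["q_value"]):
        rec.q_value = float(q)
    return df, records


def qq_data(p_values):
    """Expected-vs-observed p-value quantiles for a QQ plot.

    Observed p-values sorted ascending against expected quantiles
    (i - 0.5)/m, returned on both the raw and -log10 scales.
    """
    p = np.sort(np.asarray(p_values, dtype=float))
    if p.size < 1:
        raise ValueError("need at least one p-value")
    m = p.size
    expected = (np.arange(1, m + 1) - 0.5) / m
    return pd.DataFrame({
        "expected": expected, "observed": p,
        "expected_neglog10": -np.log10(expected),
        "observed_neglog10": -np.log10(np.maximum(p, np.finfo(float).tiny)),
    })


def genotype_class_summary(phenotype, genotypes, groups=None):
    """Mean phenotype per genotype class and class shares per group.

    Returns ``(class_means, shares)``: shares give, for each group and
    overall, the percentage of that group's individuals carrying each
    genotype class (empty classes omitted).
    """
    df = pd.DataFrame({"y": np.asarray(phenotype, dtype=float),
                       "g": pd.Series(genotypes).to_numpy()})
    if groups is not None:
        df["group"] = pd.Series(groups).to_numpy()
    df = df[pd.notna(df["g"])]
    class_means = df.groupby("g")["y"].mean().to_dict()
    rows = []
    scopes = [("overall", df)]
    if groups is not None:
        scopes += [(g, sub) for g, sub in df.groupby("group")]
    for name, sub in scopes:
        n = len(sub)
        for cls, cnt in sub["g"].value_counts().items():
            rows.append({"group": name, "class": cls, "n": int(cnt),
                         "percent": 100.0 * cnt / n})
    return class_means, pd.DataFrame(rows)
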