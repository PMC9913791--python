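"""Negative-binomial differential expression and the sensitivity signature.

The differential-expression test is an NB generalized linear model with a
Wald test on the group coefficient, in the spirit of the standard RNA-seq
count framework: median-of-ratios size factors, a per-gene method-of-moments
dispersion estimate shrunk in log space toward a fitted mean-dispersion
trend, and a Wald p-value against a t reference whose degrees of freedom
reflect the trend-pooled dispersion information, which keeps type-I error
calibrated at the small replicate numbers typical of PDX experiments. P-values are Benjamini-Hochberg adjusted across tested genes and
genes are called differentially expressed at padj < 0.05.
"""

from __future__ import annotations

import warnings
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

#: adjusted p-value below which a gene is called differentially expressed
PADJ_CUTOFF = 0.05
#: |log2FC| cutoff and maximum length of the sensitivity signature
SIGNATURE_LFC_CUTOFF = 1.0
SIGNATURE_MAX_GENES = 70

_MIN_DISP, _MAX_DISP = 1e-8, 10.0


def size_factors(counts: pd.DataFrame) -> pd.Series:
    """Median-of-ratios size factors (geometric-mean reference).

    Genes with a zero count in any sample are excluded from the reference; if
    no gene is expressed in every sample the factors are undefined and a
    pseudo-reference (e.g. adding 0.5 to all counts) must be used instead.
    """
    mat = counts.to_numpy(float)
    positive = (mat > 0).all(axis=1)
    if not positive.any():
        raise ValueError(
            "no gene has nonzero counts in all samples; size factors undefined "
            "(consider a pseudo-reference, e.g. counts + 0.5)"
        )
    logs = np.log(mat[positive])
    ref = logs.mean(axis=1, keepdims=True)
    sf = np.exp(np.median(logs - ref, axis=0))
    return pd.Series(sf, index=counts.columns, name="size_factor")


def bh_adjust(pvalues: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjustment."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def _dispersion_estimates(q: np.ndarray, groups: np.ndarray, inv_sf_mean: float,
                          shrink_weight: float) -> np.ndarray:
    """Moment dispersions shrunk toward a 1/mean trend, in log space."""
    base_mean = q.mean(axis=1)
    n = q.shape[1]
    resid = q.copy()
    for g in np.unique(groups):
        cols = groups == g
        resid[:, cols] -= q[:, cols].mean(axis=1, keepdims=True)
    s2 = (resid ** 2).sum(axis=1) / max(n - 2, 1)
    with np.errstate(divide="ignore", invalid="ignore"):
        mom = (s2 - base_mean * inv_sf_mean) / base_mean ** 2
    mom = np.clip(np.nan_to_num(mom, nan=_MIN_DISP), _MIN_DISP, _MAX_DISP)

    # parametric trend alpha(mu) = a0 + a1/mu, fitted where the moment
    # estimate is informative; fall back to the median when degenerate
    use = mom > 1e-6
    if use.sum() >= 10:
        X = np.column_stack([np.ones(use.sum()), 1.0 / base_mean[use]])
        coef, *_ = np.linalg.lstsq(X, mom[use], rcond=None)
        a0 = max(float(coef[0]), _MIN_DISP)
        a1 = max(float(coef[1]), 0.0)
    else:
        a0, a1 = max(float(np.median(mom)), _MIN_DISP), 0.0
    trend = np.clip(a0 + a1 / base_mean, _MIN_DISP, _MAX_DISP)
    w = shrink_weight
    return np.exp(w * np.log(trend) + (1.0 - w) * np.log(mom))


def _nb_irls(y: np.ndarray, x: np.ndarray, offset: np.ndarray, alpha: np.ndarray,
             max_iter: int = 50, tol: float = 1e-10):
    """Vectorised IRLS for per-gene NB GLMs with design [1, group].

    ``y``: genes x samples counts; ``x``: 0/1 group indicator per sample;
    ``offset``: log size factors; ``alpha``: per-gene dispersion. Returns
    (intercept, coefficient, se(coefficient)) on the natural-log scale.
    """
    G, n = y.shape
    mu0 = np.maximum((y * np.exp(-offset)).mean(axis=1), 1e-8)
    b0 = np.log(mu0)
    b1 = np.zeros(G)
    a = alpha[:, None]
    for _ in range(max_iter):
        eta = b0[:, None] + b1[:, None] * x + offset
        mu = np.exp(np.clip(eta, -30.0, 30.0))
        W = mu / (1.0 + a * mu)
        z = (eta - offset) + (y - mu) / mu
        sw = W.sum(axis=1)
        swx = (W * x).sum(axis=1)
        swxx = (W * x * x).sum(axis=1)
        swz = (W * z).sum(axis=1)
        swxz = (W * x * z).sum(axis=1)
        det = sw * swxx - swx ** 2
        det = np.where(np.abs(det) < 1e-12, np.nan, det)
        b0_new = (swxx * swz - swx * swxz) / det
        b1_new = (sw * swxz - swx * swz) / det
        b0_new = np.where(np.isfinite(b0_new), b0_new, b0)
        b1_new = np.clip(np.where(np.isfinite(b1_new), b1_new, b1), -15.0, 15.0)
        delta = np.max(np.abs(b0_new - b0) + np.abs(b1_new - b1))
        b0, b1 = b0_new, b1_new
        if delta < tol:
            break
    eta = b0[:, None] + b1[:, None] * x + offset
    mu = np.exp(np.clip(eta, -30.0, 30.0))
    W = mu / (1.0 + a * mu)
    sw = W.sum(axis=1)
    swx = (W * x).sum(axis=1)
    swxx = (W * x * x).sum(axis=1)
    det = sw * swxx - swx ** 2
    se = np.sqrt(np.where(det > 0, sw / det, np.inf))
    return b0, b1, se


def de_test(counts: pd.DataFrame, condition: Sequence[str],
            levels: tuple[str, str] | None = None,
            sf: pd.Series | None = None,
            shrink_weight: float = 0.5,
            padj_cutoff: float = PADJ_CUTOFF) -> pd.DataFrame:
    """NB Wald test of a two-group contrast, gene by gene.

    ``condition`` labels each sample; ``levels=(reference, alternative)``
    orients the fold change (log2 of the second level over the first; default
    is the sorted label order). Genes with all-zero counts are excluded and
    counted in ``result.attrs['n_excluded_all_zero']``.

    Returns a DataFrame indexed by gene id with columns ``base_mean``,
    ``log2fc``, ``lfc_se``, ``stat``, ``p``, ``padj``, ``is_de``.
    """
    condition = pd.Series(list(condition), index=counts.columns)
    labels = sorted(condition.unique())
    if len(labels) != 2:
        raise ValueError(f"expected exactly two groups, got {labels}")
    if levels is None:
        levels = (labels[0], labels[1])
    if sorted(levels) != labels:
        raise ValueError(f"levels {levels} do not match group labels {labels}")
    x = (condition == levels[1]).to_numpy(float)
    n_per = [int((x == v).sum()) for v in (0.0, 1.0)]
    if min(n_per) < 2:
        raise ValueError("each group needs at least 2 samples (dispersion unidentifiable)")

    if sf is None:
        sf = size_factors(counts)
    sf = sf.reindex(counts.columns)
    mat = counts.to_numpy(float)
    nonzero = mat.sum(axis=1) > 0
    n_excluded = int((~nonzero).sum())
    genes = counts.index[nonzero]
    y = mat[nonzero]
    sfv = sf.to_numpy(float)
    q = y / sfv

    alpha = _dispersion_estimates(q, x, float(np.mean(1.0 / sfv)), shrink_weight)
    b0, b1, se = _nb_irls(y, x, np.log(sfv), alpha)

    with np.errstate(divide="ignore", invalid="ignore"):
        stat = np.where(se > 0, b1 / se, 0.0)
    stat = np.nan_to_num(stat, nan=0.0)
    # t reference on 2(n-2) df: the mean-dispersion trend pools dispersion
    # information across genes, so the effective residual df exceeds the
    # per-gene n-2; this keeps small-n type-I error near nominal
    df = max(2 * (y.shape[1] - 2), 1)
    p = 2.0 * stats.t.sf(np.abs(stat), df=df)
    p = np.clip(p, 0.0, 1.0)
    padj = bh_adjust(p)
    out = pd.DataFrame({
        "base_mean": q.mean(axis=1),
        "log2fc": b1 / np.log(2.0),
        "lfc_se": se / np.log(2.0),
        "stat": stat,
        "p": p,
        "padj": padj,
        "is_de": padj < padj_cutoff,
    }, index=genes)
    out.index.name = "gene_id"
    out.attrs["n_excluded_all_zero"] = n_excluded
    out.attrs["levels"] = tuple(levels)
    out.attrs["dispersion"] = alpha
    return out


def derive_signature(de_baseline: pd.DataFrame,
                     lfc_cutoff: float = SIGNATURE_LFC_CUTOFF,
                     padj_cutoff: float = PADJ_CUTOFF,
                     max_genes: int = SIGNATURE_MAX_GENES) -> pd.DataFrame:
    """Top differentially expressed genes at baseline as a sensitivity signature.

    Filters to |log2FC| > ``lfc_cutoff`` and padj < ``padj_cutoff`` (both
    strict), ranks by ascending padj, ties by descending |log2FC|, ties by
    gene id, and truncates to ``max_genes`` (default 70). The fold-change sign
    is reported as the side of the signature each gene belongs to.
    """
    passing = de_baseline[(de_baseline["log2fc"].abs() > lfc_cutoff)
                          & (de_baseline["padj"] < padj_cutoff)].copy()
    if passing.empty:
        warnings.warn("no genes pass the signature filter; returning an empty signature")
        return pd.DataFrame(columns=["log2fc", "padj", "side"])
    passing["abs_lfc"] = passing["log2fc"].abs()
    passing["_gene"] = passing.index.astype(str)
    passing = passing.sort_values(["padj", "abs_lfc", "_gene"],
                                  ascending=[True, False, True])
    top = passing.head(max_genes)
    out = pd.DataFrame({
        "log2fc": top["log2fc"],
        "padj": top["padj"],
        "side": np.where(top["log2fc"] > 0, "up_in_sensitive", "down_in_sensitive"),
    }, index=top.index)
    out.index.name = "gene_id"
    return out
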