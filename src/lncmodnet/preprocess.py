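"""Count-level preprocessing: expression filter, TMM, log-CPM and a
simplified two-group differential-expression test.

TMM (weighted trimmed mean of M-values) rescales library sizes so that the
bulk of genes show no fold change between samples: per sample, M-values
(log2 expression ratios vs a reference sample) are doubly trimmed (30% on M,
5% on average abundance A), precision-weighted and averaged; the
exponentiated mean is the normalization factor, rescaled to geometric mean
one across samples.  Differential expression is a per-gene Welch t-test on
log2-CPM with Benjamini-Hochberg correction — a deliberately simple,
fully specified stand-in for count-model GLMs, sufficient here because DE
results only cross-annotate hub genes.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator, TransformerMixin

from .simulate import SampleDesign

__all__ = [
    "filter_low_expression",
    "tmm_factors",
    "log_cpm",
    "bh_adjust",
    "differential_expression",
    "TMMNormalizer",
]


def _check_counts(counts: pd.DataFrame) -> None:
    if counts.index.has_duplicates or counts.columns.has_duplicates:
        raise ValueError("duplicate gene or sample identifiers")
    if (counts.values < 0).any():
        raise ValueError("negative counts")


def filter_low_expression(
    counts: pd.DataFrame, design: SampleDesign, min_cpm: float = 1.0
) -> pd.DataFrame:
    """Keep genes with CPM >= ``min_cpm`` in at least n samples.

    n is the size of the smallest treatment group in the design (4 in the
    default six-groups-of-four layout); the CPM threshold is inclusive.
    Gene order is preserved; filtering is idempotent.
    """
    _check_counts(counts)
    n = design.min_group_size()
    lib = counts.sum(axis=0).astype(float)
    if (lib == 0).any():
        raise ValueError("sample with zero library size")
    cpm = counts / lib * 1e6
    keep = (cpm >= min_cpm).sum(axis=1) >= n
    out = counts.loc[keep]
    if out.empty:
        raise ValueError("no genes survive the expression filter")
    return out


def _quantile_reference(counts: np.ndarray) -> int:
    """Sample whose upper-quartile CPM is closest to the mean upper-quartile."""
    lib = counts.sum(axis=0)
    uq = np.array(
        [np.quantile(counts[:, j] / lib[j] * 1e6, 0.75) for j in range(counts.shape[1])]
    )
    return int(np.argmin(np.abs(uq - uq.mean())))


def _tmm_pair(
    obs: np.ndarray,
    ref: np.ndarray,
    n_obs: float,
    n_ref: float,
    trim_m: float,
    trim_a: float,
) -> float:
    """Log2 TMM factor of one sample against the reference sample.

    Genes with a zero count in either sample are excluded.  The trims keep
    the central mass of M (log-ratio) and A (average log-abundance) jointly;
    the kept M-values are averaged with inverse-delta-method-variance
    weights.
    """
    pos = (obs > 0) & (ref > 0)
    o, r = obs[pos].astype(float), ref[pos].astype(float)
    if o.size == 0:
        return 0.0
    po, pr = o / n_obs, r / n_ref
    m = np.log2(po / pr)
    a = 0.5 * np.log2(po * pr)
    w = (n_obs - o) / (n_obs * o) + (n_ref - r) / (n_ref * r)
    finite = np.isfinite(m) & np.isfinite(a)
    m, a, w = m[finite], a[finite], w[finite]
    n = m.size
    if n == 0:
        return 0.0
    if np.max(np.abs(m)) < 1e-6:  # technical replicate; avoid trim artefacts
        return 0.0
    lo_m = np.floor(n * trim_m) + 1
    hi_m = n + 1 - lo_m
    lo_a = np.floor(n * trim_a) + 1
    hi_a = n + 1 - lo_a
    rank_m = stats.rankdata(m)
    rank_a = stats.rankdata(a)
    keep = (rank_m >= lo_m) & (rank_m <= hi_m) & (rank_a >= lo_a) & (rank_a <= hi_a)
    if not keep.any():
        return 0.0
    return float(np.sum(m[keep] / w[keep]) / np.sum(1.0 / w[keep]))


def tmm_factors(
    counts: pd.DataFrame, trim_M: float = 0.30, trim_A: float = 0.05
) -> pd.Series:
    """Per-sample TMM normalization factors, geometric mean one."""
    _check_counts(counts)
    if counts.shape[1] < 2:
        raise ValueError("TMM needs at least two samples")
    x = counts.to_numpy(dtype=float)
    lib = x.sum(axis=0)
    if (lib == 0).any():
        raise ValueError("sample with zero library size")
    ref = _quantile_reference(x)
    log_f = np.array(
        [
            _tmm_pair(x[:, j], x[:, ref], lib[j], lib[ref], trim_M, trim_A)
            for j in range(x.shape[1])
        ]
    )
    factors = 2.0 ** (log_f - log_f.mean())  # geometric mean 1
    return pd.Series(factors, index=counts.columns, name="tmm_factor")


def log_cpm(
    counts: pd.DataFrame,
    factors: pd.Series | None = None,
    prior_count: float = 0.5,
    prior_lib: float = 1.0,
) -> pd.DataFrame:
    """log2 counts per million over TMM-effective library sizes.

    value = log2((count + 0.5) / (libsize * factor + 1.0) * 1e6); the small
    offsets keep zeros finite and the transform strictly monotone in the
    count.
    """
    _check_counts(counts)
    if factors is None:
        factors = pd.Series(1.0, index=counts.columns)
    lib = counts.sum(axis=0).astype(float) * factors.reindex(counts.columns)
    return np.log2((counts + prior_count) / (lib + prior_lib) * 1e6)


class TMMNormalizer(BaseEstimator, TransformerMixin):
    """Sklearn-style transformer: counts (genes x samples) -> log2-CPM.

    ``fit`` learns per-sample TMM factors and library sizes from a count
    DataFrame; ``transform`` applies the effective-library-size log-CPM.
    """

    def __init__(self, trim_M: float = 0.30, trim_A: float = 0.05):
        self.trim_M = trim_M
        self.trim_A = trim_A

    def fit(self, X: pd.DataFrame, y=None):
        self.factors_ = tmm_factors(X, self.trim_M, self.trim_A)
        self.library_sizes_ = X.sum(axis=0).astype(float)
        return self

    def transform(self, X: pd.DataFrame) -> pd.DataFrame:
        return log_cpm(X, self.factors_)


def bh_adjust(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (q-values)."""
    p = np.asarray(pvalues, dtype=float)
    if p.ndim != 1:
        p = p.ravel()
    if ((p < 0) | (p > 1) | ~np.isfinite(p)).any():
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="mergesort")
    ranked = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum(1.0, np.minimum.accumulate(ranked[::-1])[::-1])
    q = np.empty(m)
    q[order] = q_sorted
    return q


def differential_expression(
    norm: pd.DataFrame,
    design: SampleDesign,
    contrast: str,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Per-gene Welch t-test on log-CPM for one drug-vehicle contrast.

    Returns a DataFrame (gene_id, contrast, log2fc, p, q, significant) with
    BH correction across all genes tested within the contrast.  Genes with
    zero variance in both groups and equal means get p = 1 by convention.
    """
    drug, vehicle = design.contrast_samples(contrast)
    if len(drug) < 2 or len(vehicle) < 2:
        raise ValueError("contrast needs >= 2 samples per side")
    a = norm[drug].to_numpy(dtype=float)
    b = norm[vehicle].to_numpy(dtype=float)
    log2fc = a.mean(axis=1) - b.mean(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        t, p = stats.ttest_ind(a, b, axis=1, equal_var=False)
    degenerate = ~np.isfinite(p)
    p = np.where(degenerate & (np.abs(log2fc) < 1e-12), 1.0, p)
    p = np.where(~np.isfinite(p), 0.0, p)  # zero variance, unequal means
    q = bh_adjust(p)
    return pd.DataFrame(
        {
            "gene_id": norm.index,
            "contrast": contrast,
            "log2fc": log2fc,
            "p": p,
            "q": q,
            "significant": q < alpha,
        }
    )


def differential_expression_all(
    norm: pd.DataFrame, design: SampleDesign, alpha: float = 0.05
) -> pd.DataFrame:
    """Run :func:`differential_expression` for every contrast in the design."""
    return pd.concat(
        [
            differential_expression(norm, design, c, alpha=alpha)
            for c in design.contrasts
        ],
        ignore_index=True,
    )
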