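"""Permutation-based module preservation between two expression datasets.

For every module defined in a reference dataset, density statistics (how
tightly the module's genes are connected in the test data) and connectivity
statistics (whether each gene's network position is reproduced) are compared
against a permutation null of random same-size gene sets.  The composite
Zsummary is the mean of the median density Z and the median connectivity Z;
Zsummary > 10 is the conventional strong-preservation cut-off, and
medianRank gives a module-size-insensitive relative ordering (rank 1 = most
preserved).

Density statistics: mean within-module adjacency, proportion of variance
explained by the module eigengene, mean own-module kME — all evaluated in
the TEST data using the reference module definition.  Connectivity
statistics: correlations between reference and test of per-gene
intramodular connectivity (kIM), of kME vectors, and of the within-module
correlation entries.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .network import _oriented_eigengene, bicor_matrix

__all__ = ["module_preservation", "observed_statistics", "PRESERVATION_STATS"]

DENSITY_STATS = ("mean_adj", "prop_var_explained", "mean_kme")
CONNECTIVITY_STATS = ("cor_kim", "cor_kme", "cor_cor")
PRESERVATION_STATS = DENSITY_STATS + CONNECTIVITY_STATS


def _safe_cor(a: np.ndarray, b: np.ndarray) -> float:
    if a.std() == 0 or b.std() == 0:
        return np.nan
    return float(np.corrcoef(a, b)[0, 1])


def _module_stats(
    idx: np.ndarray,
    ref_expr: np.ndarray,
    test_expr: np.ndarray,
    ref_abs_r: np.ndarray,
    test_abs_r: np.ndarray,
    power: float,
) -> dict[str, float]:
    """All six preservation statistics for one gene-index set."""
    sub_ref_r = ref_abs_r[np.ix_(idx, idx)]
    sub_test_r = test_abs_r[np.ix_(idx, idx)]
    a_ref = sub_ref_r**power
    a_test = sub_test_r**power
    np.fill_diagonal(a_ref, 0.0)
    np.fill_diagonal(a_test, 0.0)
    n = len(idx)
    offdiag = n * (n - 1)

    def kme(expr: np.ndarray) -> np.ndarray:
        x = expr[idx]
        e, pve = _oriented_eigengene(x)
        z = x - x.mean(axis=1, keepdims=True)
        sd = z.std(axis=1, ddof=1)
        sd[sd == 0] = np.inf
        return (z @ e) / (sd * e.std(ddof=1)) / (x.shape[1] - 1), pve

    kme_ref, _ = kme(ref_expr)
    kme_test, pve_test = kme(test_expr)
    iu = np.triu_indices(n, k=1)
    return {
        "mean_adj": float(a_test.sum() / offdiag),
        "prop_var_explained": pve_test,
        "mean_kme": float(kme_test.mean()),
        "cor_kim": _safe_cor(a_ref.sum(axis=1), a_test.sum(axis=1)),
        "cor_kme": _safe_cor(kme_ref, kme_test),
        "cor_cor": _safe_cor(sub_ref_r[iu], sub_test_r[iu]),
    }


def observed_statistics(
    module_genes,
    ref_expr: pd.DataFrame,
    test_expr: pd.DataFrame,
    power: float,
) -> dict[str, float]:
    """Density + connectivity statistics for one named module."""
    genes = list(module_genes)
    if len(genes) < 3:
        raise ValueError("module must have at least 3 genes")
    missing = [g for g in genes if g not in test_expr.index]
    if missing:
        raise KeyError(f"module genes missing from test data: {missing[:5]}")
    common = ref_expr.index
    test_expr = test_expr.loc[common]
    idx = np.array([common.get_loc(g) for g in genes])
    ref_r = np.abs(bicor_matrix(ref_expr).to_numpy())
    test_r = np.abs(bicor_matrix(test_expr).to_numpy())
    return _module_stats(
        idx,
        ref_expr.to_numpy(dtype=float),
        test_expr.to_numpy(dtype=float),
        ref_r,
        test_r,
        power,
    )


def module_preservation(
    ref_expr: pd.DataFrame,
    test_expr: pd.DataFrame,
    labels: pd.Series,
    power: float,
    n_perm: int = 100,
    seed: int = 0,
    z_threshold: float = 10.0,
) -> pd.DataFrame:
    """Zsummary and medianRank for every module of the reference network.

    Random gene sets of each module's size are drawn uniformly from all
    genes (``n_perm`` draws, child seed derived from (seed, module label)
    so results are stable when modules are added or removed).  Statistics
    whose permutation sd is zero are flagged and excluded from the medians.

    Returns a DataFrame indexed by module with the observed statistics,
    their Z-scores, Zdensity, Zconnectivity, Zsummary, medianRank, module
    size and the ``preserved`` flag (Zsummary > ``z_threshold``).
    """
    missing = test_expr.index.symmetric_difference(ref_expr.index)
    if len(missing):
        raise KeyError(f"datasets disagree on genes: {list(missing[:5])}")
    test_expr = test_expr.loc[ref_expr.index]
    ref_x = ref_expr.to_numpy(dtype=float)
    test_x = test_expr.to_numpy(dtype=float)
    ref_r = np.abs(bicor_matrix(ref_expr).to_numpy())
    test_r = np.abs(bicor_matrix(test_expr).to_numpy())
    n_genes = ref_x.shape[0]
    gene_pos = {g: i for i, g in enumerate(ref_expr.index)}

    rows = []
    for m in sorted(int(v) for v in labels.unique() if v > 0):
        genes = labels.index[labels == m]
        idx = np.array([gene_pos[g] for g in genes])
        obs = _module_stats(idx, ref_x, test_x, ref_r, test_r, power)
        rng = np.random.default_rng([seed, m])
        null = {s: [] for s in PRESERVATION_STATS}
        for _ in range(n_perm):
            perm_idx = rng.choice(n_genes, size=len(idx), replace=False)
            stats_p = _module_stats(perm_idx, ref_x, test_x, ref_r, test_r, power)
            for s in PRESERVATION_STATS:
                null[s].append(stats_p[s])
        row: dict = {"module": m, "size": len(idx)}
        for s in PRESERVATION_STATS:
            draws = np.asarray(null[s], dtype=float)
            mu = np.nanmean(draws)
            sd = np.nanstd(draws, ddof=1)
            row[s] = obs[s]
            row[f"null_mean_{s}"] = mu
            row[f"null_sd_{s}"] = sd
            row[f"z_{s}"] = (obs[s] - mu) / sd if sd > 0 else np.nan
        z_density = np.nanmedian([row[f"z_{s}"] for s in DENSITY_STATS])
        z_connectivity = np.nanmedian([row[f"z_{s}"] for s in CONNECTIVITY_STATS])
        row["z_density"] = z_density
        row["z_connectivity"] = z_connectivity
        row["z_summary"] = np.nanmean([z_density, z_connectivity])
        rows.append(row)
    result = pd.DataFrame(rows).set_index("module")
    result["preserved"] = result["z_summary"] > z_threshold

    # medianRank: rank modules on each observed statistic (1 = most
    # preserved, i.e. largest value; average ranks on ties)
    ranks = pd.DataFrame(
        {s: result[s].rank(ascending=False) for s in PRESERVATION_STATS}
    )
    result["median_rank"] = ranks.median(axis=1)
    return result
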