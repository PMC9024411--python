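"""Weighted co-expression network construction and module detection.

The network is built in the classic weighted-network fashion: a robust
pairwise correlation (biweight midcorrelation), raised element-wise to a
soft-thresholding power chosen so the weighted degree distribution is
approximately scale-free, converted to the topological overlap measure
(TOM), and clustered on 1 - TOM with average-linkage hierarchical
clustering.  Modules are branches of the dendrogram cut at a static height,
pruned of weak members by eigengene membership (kME), merged when their
eigengenes are nearly collinear, and summarised by eigengenes and kME.

Expression matrices are (genes x samples) DataFrames throughout, matching
how the field lays out such data.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform
from scipy.stats import linregress
from sklearn.base import BaseEstimator

__all__ = [
    "bicor",
    "bicor_matrix",
    "scale_free_fit",
    "pick_soft_threshold",
    "tom_similarity",
    "detect_modules",
    "prune_weak_modules",
    "module_eigengenes",
    "merge_close_modules",
    "module_membership",
    "ModuleSet",
    "WGCNA",
]

BICOR_TUNING = 9.0  # Tukey biweight tuning constant, in units of the MAD


def _bicor_prepare(x: np.ndarray) -> np.ndarray:
    """Biweight-transformed, centred copy of x (Pearson fallback on MAD 0)."""
    med = np.median(x)
    mad = np.median(np.abs(x - med))
    if mad == 0:
        c = x - x.mean()
        if np.all(c == 0):
            raise ValueError("constant vector: correlation undefined")
        return c
    u = (x - med) / (BICOR_TUNING * mad)
    w = np.where(np.abs(u) < 1, (1 - u**2) ** 2, 0.0)
    return (x - med) * w


def bicor(x, y) -> float:
    """Biweight midcorrelation of two sample vectors.

    Observations far from the median (beyond 9 MADs) get zero weight, so a
    single outlier cannot dominate the correlation the way it does for
    Pearson.  Falls back to Pearson centring for a vector with zero MAD;
    raises if either vector is constant.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 3:
        raise ValueError("need two equal-length vectors of length >= 3")
    xt = _bicor_prepare(x)
    yt = _bicor_prepare(y)
    denom = np.sqrt(np.sum(xt**2) * np.sum(yt**2))
    if denom == 0:
        raise ValueError("degenerate vector after weighting")
    return float(np.clip(np.dot(xt, yt) / denom, -1.0, 1.0))


def bicor_matrix(expr: pd.DataFrame) -> pd.DataFrame:
    """Gene x gene biweight midcorrelation matrix (rows = genes)."""
    x = expr.to_numpy(dtype=float)
    med = np.median(x, axis=1, keepdims=True)
    mad = np.median(np.abs(x - med), axis=1, keepdims=True)
    centred = x - med
    with np.errstate(divide="ignore", invalid="ignore"):
        u = centred / (BICOR_TUNING * mad)
    w = np.where(np.abs(u) < 1, (1 - u**2) ** 2, 0.0)
    xt = centred * w
    # Pearson fallback for zero-MAD rows
    zero_mad = (mad == 0).ravel()
    if zero_mad.any():
        xt[zero_mad] = x[zero_mad] - x[zero_mad].mean(axis=1, keepdims=True)
    norms = np.sqrt(np.sum(xt**2, axis=1))
    bad = norms == 0
    if bad.any():
        raise ValueError(
            "constant genes in expression matrix: "
            + ", ".join(expr.index[bad][:5])
        )
    xt /= norms[:, None]
    r = np.clip(xt @ xt.T, -1.0, 1.0)
    np.fill_diagonal(r, 1.0)
    return pd.DataFrame(r, index=expr.index, columns=expr.index)


def scale_free_fit(connectivities, n_bins: int = 10) -> float:
    """Signed R-squared of the log-log binned degree-distribution fit.

    Connectivities are binned into equal-width bins; log10 frequency is
    regressed on log10 mean connectivity over non-empty bins.  The sign is
    flipped to -sign(slope), so a decaying degree distribution (the
    scale-free signature) scores positive.  All-equal connectivities return
    0 with a warning.
    """
    k = np.asarray(connectivities, dtype=float)
    k = k[k > 0]
    if k.size < n_bins:
        raise ValueError(f"need at least {n_bins} positive connectivities")
    if np.ptp(k) == 0:
        warnings.warn("all connectivities equal; scale-free fit undefined")
        return 0.0
    edges = np.linspace(k.min(), k.max(), n_bins + 1)
    counts, _ = np.histogram(k, bins=edges)
    sums, _ = np.histogram(k, bins=edges, weights=k)
    nonempty = counts > 0
    mean_k = sums[nonempty] / counts[nonempty]
    freq = counts[nonempty] / k.size
    if nonempty.sum() < 3:
        warnings.warn("fewer than 3 non-empty bins; scale-free fit unreliable")
        return 0.0
    fit = linregress(np.log10(mean_k), np.log10(freq))
    return float(-np.sign(fit.slope) * fit.rvalue**2)


def _connectivity(abs_r: np.ndarray, beta: float) -> np.ndarray:
    a = abs_r**beta
    np.fill_diagonal(a, 0.0)
    return a.sum(axis=1)


def pick_soft_threshold(
    expr: pd.DataFrame,
    powers=range(1, 21),
    fit_threshold: float = 0.8,
    n_bins: int = 10,
    correlation: pd.DataFrame | None = None,
) -> tuple[int, pd.DataFrame]:
    """Choose the soft-thresholding power by scale-free topology fit.

    Returns the lowest candidate power whose signed fit index reaches
    ``fit_threshold`` (inclusive), plus the full fit table (power, fit,
    mean/median/max connectivity, selected flag).  If no power qualifies,
    the argmax-fit power is returned and the table carries a
    ``qualified=False`` column value throughout (with a warning).
    """
    if expr.shape[0] < 2:
        raise ValueError("need at least two genes")
    r = correlation if correlation is not None else bicor_matrix(expr)
    abs_r = np.abs(r.to_numpy(dtype=float))
    rows = []
    for beta in powers:
        k = _connectivity(abs_r, float(beta))
        fit = scale_free_fit(k, n_bins=n_bins)
        rows.append(
            {
                "power": int(beta),
                "fit": fit,
                "mean_k": float(k.mean()),
                "median_k": float(np.median(k)),
                "max_k": float(k.max()),
            }
        )
    table = pd.DataFrame(rows)
    qualifying = table[table["fit"] >= fit_threshold]
    if qualifying.empty:
        # fall back to the best-fitting power, but only consider powers at
        # or above the sample-size-based recommendation for unsigned
        # networks: the low-power end of the fit curve is dominated by the
        # unthresholded correlation noise floor, not scale-free structure
        n_samples = expr.shape[1]
        floor = 9 if n_samples < 20 else 8 if n_samples < 30 else 7 if n_samples < 40 else 6
        warnings.warn(
            f"no candidate power reaches fit {fit_threshold}; using the "
            f"best-fitting power at or above the n-based default {floor}"
        )
        eligible = table[table["power"] >= floor]
        if eligible.empty:
            eligible = table
        beta = int(eligible.loc[eligible["fit"].idxmax(), "power"])
        table["qualified"] = False
    else:
        beta = int(qualifying["power"].iloc[0])
        table["qualified"] = True
    table["selected"] = table["power"] == beta
    return beta, table


def tom_similarity(adjacency: pd.DataFrame | np.ndarray) -> pd.DataFrame | np.ndarray:
    """Topological overlap measure of a weighted adjacency matrix.

    t_ij = (l_ij + a_ij) / (min(k_i, k_j) + 1 - a_ij) with
    l_ij = sum_u a_iu * a_uj over u != i, j; the diagonal is 1.  TOM
    credits gene pairs for sharing network neighbours, denoising weak
    direct links.
    """
    index = adjacency.index if isinstance(adjacency, pd.DataFrame) else None
    a = np.asarray(adjacency, dtype=float).copy()
    if a.ndim != 2 or a.shape[0] != a.shape[1]:
        raise ValueError("adjacency must be square")
    if not np.allclose(a, a.T, atol=1e-10):
        raise ValueError("adjacency must be symmetric")
    if a.min() < 0 or a.max() > 1 + 1e-12:
        raise ValueError("adjacency values must lie in [0, 1]")
    np.fill_diagonal(a, 0.0)
    k = a.sum(axis=1)
    l = a @ a  # l[i, j] includes no i/j terms since diag(a) = 0
    denom = np.minimum.outer(k, k) + 1.0 - a
    t = (l + a) / denom
    np.fill_diagonal(t, 1.0)
    if index is not None:
        return pd.DataFrame(t, index=index, columns=index)
    return t


@dataclass
class ModuleSet:
    """Gene-module assignment with eigengene summaries.

    ``labels`` maps genes to positive integer modules (0 = unassigned);
    ``eigengenes`` is (module x sample); ``kme`` is (gene x module);
    ``prop_var_explained`` is per-module leading-eigenvalue share.
    """

    labels: pd.Series
    eigengenes: pd.DataFrame = field(default_factory=pd.DataFrame)
    kme: pd.DataFrame = field(default_factory=pd.DataFrame)
    prop_var_explained: pd.Series = field(default_factory=lambda: pd.Series(dtype=float))

    @property
    def module_ids(self) -> list[int]:
        return sorted(int(m) for m in self.labels.unique() if m > 0)

    def genes_in(self, module: int) -> list[str]:
        return list(self.labels.index[self.labels == module])

    def sizes(self) -> pd.Series:
        return self.labels[self.labels > 0].value_counts().sort_index()


def _renumber(labels: pd.Series) -> pd.Series:
    """Relabel modules 1..K by decreasing size; ties by smallest member id."""
    out = pd.Series(0, index=labels.index, dtype=int)
    groups = [
        (int(m), list(labels.index[labels == m]))
        for m in labels.unique()
        if m > 0
    ]
    groups.sort(key=lambda g: (-len(g[1]), min(g[1])))
    for new, (_old, genes) in enumerate(groups, start=1):
        out.loc[genes] = new
    return out


def detect_modules(
    dissimilarity: pd.DataFrame,
    min_module_size: int = 30,
    cut_height: float = 0.99,
) -> pd.Series:
    """Static-height tree cut on a 1-TOM dissimilarity matrix.

    Average-linkage clusters joined below the absolute height
    ``cut_height`` become candidate modules (the classic static cut:
    genuinely co-expressed branches merge well below 1 - TOM = 0.99, while
    unrelated genes only join near the top of the dendrogram); clusters
    smaller than ``min_module_size`` are unassigned (label 0).  Modules
    are renumbered by decreasing size (ties broken by smallest member
    gene id).
    """
    d = np.asarray(dissimilarity, dtype=float)
    if not np.allclose(d, d.T, atol=1e-10):
        raise ValueError("dissimilarity must be symmetric")
    if d.min() < -1e-12 or d.max() > 1 + 1e-9:
        raise ValueError("dissimilarity values must lie in [0, 1]")
    dd = d.copy()
    np.fill_diagonal(dd, 0.0)
    z = linkage(squareform(dd, checks=False), method="average")
    # cap the static cut at the 99th percentile of merge heights: on a
    # weakly-thresholded network the whole dendrogram can merge below the
    # nominal height, and an uncapped cut would return one all-gene cluster
    height = min(float(cut_height), float(np.quantile(z[:, 2], 0.99)))
    raw = fcluster(z, t=height, criterion="distance")
    labels = pd.Series(raw, index=dissimilarity.index, dtype=int)
    sizes = labels.value_counts()
    small = sizes.index[sizes < min_module_size]
    labels[labels.isin(small)] = 0
    labels = _renumber(labels)
    if (labels == 0).all():
        warnings.warn("no cluster reached the minimum module size")
    return labels


def _pc1(x: np.ndarray) -> tuple[np.ndarray, float]:
    """First principal component across samples of a standardized block.

    Returns the unit-variance sample-score vector and the leading
    eigenvalue share (proportion of variance explained).
    """
    sd = x.std(axis=1, ddof=1, keepdims=True)
    sd[sd == 0] = 1.0
    z = (x - x.mean(axis=1, keepdims=True)) / sd
    _u, s, vt = np.linalg.svd(z, full_matrices=False)
    e = vt[0]
    e = e / e.std(ddof=1)
    pve = float(s[0] ** 2 / np.sum(s**2))
    return e, pve


def _oriented_eigengene(x: np.ndarray) -> tuple[np.ndarray, float]:
    """PC1 oriented so its mean correlation with the block's genes is >= 0."""
    if x.shape[0] == 1:
        row = x[0]
        sd = row.std(ddof=1)
        if sd == 0:
            raise ValueError("single constant gene has no eigengene")
        return (row - row.mean()) / sd, 1.0
    e, pve = _pc1(x)
    z = (x - x.mean(axis=1, keepdims=True))
    z_sd = z.std(axis=1, ddof=1)
    z_sd[z_sd == 0] = 1.0
    cors = (z @ e) / (z_sd * e.std(ddof=1)) / (x.shape[1] - 1)
    if cors.mean() < 0:
        e = -e
    return e, pve


def module_eigengenes(
    expr: pd.DataFrame, labels: pd.Series
) -> tuple[pd.DataFrame, pd.Series]:
    """Eigengene (first PC across samples) per module, plus variance share.

    Each eigengene has unit variance across samples and is oriented so the
    average correlation with its member genes is non-negative.
    """
    eig = {}
    pve = {}
    for m in sorted(int(v) for v in labels.unique() if v > 0):
        genes = labels.index[labels == m]
        e, share = _oriented_eigengene(expr.loc[genes].to_numpy(dtype=float))
        eig[m] = e
        pve[m] = share
    eigengenes = pd.DataFrame(eig, index=expr.columns).T
    eigengenes.index.name = "module"
    return eigengenes, pd.Series(pve, name="prop_var_explained")


def module_membership(
    expr: pd.DataFrame, eigengenes: pd.DataFrame, method: str = "bicor"
) -> pd.DataFrame:
    """kME: correlation of every gene with every module eigengene."""
    combined = pd.concat(
        [expr, eigengenes.set_axis([f"_ME{m}" for m in eigengenes.index])]
    )
    variances = combined.var(axis=1)
    constant = variances[variances == 0].index
    work = combined.drop(index=constant)
    if method == "bicor":
        r = bicor_matrix(work)
    elif method == "pearson":
        r = work.T.corr()
    else:
        raise ValueError(f"unknown correlation method: {method}")
    me_cols = [f"_ME{m}" for m in eigengenes.index]
    kme = r.loc[r.index.difference(me_cols, sort=False), me_cols]
    kme.columns = list(eigengenes.index)
    if len(constant):
        warnings.warn(f"{len(constant)} constant genes assigned kME 0")
        pad = pd.DataFrame(0.0, index=constant, columns=kme.columns)
        kme = pd.concat([kme, pad])
    return kme.reindex(expr.index)


def prune_weak_modules(
    expr: pd.DataFrame,
    labels: pd.Series,
    min_module_size: int = 30,
    kme_min: float = 0.50,
    pve_min: float = 0.45,
    max_depth: int = 8,
) -> pd.Series:
    """Validate tree-cut clusters against the expression data.

    A static-height cut separates tight branches but also produces clusters
    of mutually unrelated background genes, can glue a genuine module to
    background leaves, and — in an unsigned network — fuses anti-correlated
    gene sets into one branch.  Each candidate cluster is therefore refined
    by sign-coherent eigengene peeling: compute the cluster eigengene, keep
    the members whose signed own-eigengene kME reaches ``kme_min``, iterate
    to convergence, and recurse on everything shed (so the anti-correlated
    half of a fused branch, or a second factor hidden in a large cluster,
    is recovered as its own module).  A refined cluster is kept only if it
    still has ``min_module_size`` genes and its eigengene explains at least
    ``pve_min`` of the member variance; random same-size gene sets stay
    well below both bars at a 24-sample design, while kme_min = 0.5 is the
    point where membership evidence beats the null kME spread (~0.21 sd).
    """
    result = pd.Series(0, index=labels.index, dtype=int)
    next_label = 1

    def signed_kme(genes: list[str]) -> tuple[np.ndarray, float]:
        x = expr.loc[genes].to_numpy(dtype=float)
        e, pve = _oriented_eigengene(x)
        z = x - x.mean(axis=1, keepdims=True)
        sd = z.std(axis=1, ddof=1)
        sd[sd == 0] = np.inf
        return (z @ e) / (sd * e.std(ddof=1)) / (x.shape[1] - 1), pve

    def refine(genes: list[str], depth: int) -> None:
        # single selection pass per level: the eigengene is estimated once
        # from the incoming cluster and NOT re-estimated from the selected
        # subset, which at 700+ genes x 24 samples would drift towards
        # whatever noise direction the selection itself favours
        nonlocal next_label
        if len(genes) < min_module_size:
            return
        kme, _ = signed_kme(genes)
        retained = [g for g, k in zip(genes, kme) if k >= kme_min]
        shed = [g for g, k in zip(genes, kme) if k < kme_min]
        if len(retained) >= min_module_size:
            _, pve = signed_kme(retained)
            if pve >= pve_min:
                result.loc[retained] = next_label
                next_label += 1
        # recurse on the remainder: it may hold the anti-correlated half of
        # a fused branch or a factor masked by the current leading one; the
        # retained genes are peeled off regardless of whether they formed a
        # module, so each level strictly shrinks
        if depth < max_depth and retained and len(shed) >= min_module_size:
            refine(shed, depth + 1)

    for m in sorted(int(v) for v in labels.unique() if v > 0):
        refine(list(labels.index[labels == m]), 0)
    return _renumber(result)


def merge_close_modules(
    expr: pd.DataFrame,
    labels: pd.Series,
    merge_height: float = 0.25,
    max_iter: int = 10,
) -> ModuleSet:
    """Merge modules whose eigengenes are closer than ``merge_height``.

    Eigengenes are clustered with dissimilarity 1 - cor; clusters joined
    below the threshold are unioned, eigengenes recomputed, and the process
    iterated to a fixed point.  Returns the final :class:`ModuleSet` with
    modules renumbered by size.
    """
    labels = labels.copy()
    for _ in range(max_iter):
        modules = sorted(int(v) for v in labels.unique() if v > 0)
        if len(modules) < 2:
            break
        eigengenes, _pve = module_eigengenes(expr, labels)
        d = 1.0 - np.corrcoef(eigengenes.to_numpy(dtype=float))
        d = np.clip((d + d.T) / 2.0, 0.0, 2.0)
        np.fill_diagonal(d, 0.0)
        z = linkage(squareform(d, checks=False), method="average")
        groups = fcluster(z, t=merge_height, criterion="distance")
        if len(set(groups)) == len(modules):
            break
        mapping = {}
        for m, grp in zip(modules, groups):
            mapping[m] = min(mm for mm, gg in zip(modules, groups) if gg == grp)
        labels = labels.map(lambda v: mapping.get(int(v), 0))
    labels = _renumber(labels)
    eigengenes, pve = module_eigengenes(expr, labels)
    kme = module_membership(expr, eigengenes)
    return ModuleSet(
        labels=labels, eigengenes=eigengenes, kme=kme, prop_var_explained=pve
    )


class WGCNA(BaseEstimator):
    """Weighted co-expression module detection as an sklearn-style estimator.

    ``fit`` takes a (genes x samples) log-expression DataFrame and runs the
    full chain: bicor matrix -> soft power (automatic scale-free selection
    unless ``power`` is an integer) -> unsigned adjacency |r|^beta -> TOM ->
    average-linkage tree cut -> kME/eigengene pruning -> eigengene merging.

    Fitted attributes: ``correlation_``, ``power_``, ``fit_table_``,
    ``adjacency_``, ``tom_``, ``labels_``, ``eigengenes_``, ``kme_``,
    ``prop_var_explained_``, ``modules_`` (the :class:`ModuleSet`).
    """

    def __init__(
        self,
        power: int | str = "auto",
        min_module_size: int = 30,
        merge_height: float = 0.25,
        cut_height: float = 0.99,
        kme_min: float = 0.30,
        pve_min: float = 0.45,
        fit_threshold: float = 0.8,
        max_power: int = 20,
    ):
        self.power = power
        self.min_module_size = min_module_size
        self.merge_height = merge_height
        self.cut_height = cut_height
        self.kme_min = kme_min
        self.pve_min = pve_min
        self.fit_threshold = fit_threshold
        self.max_power = max_power

    def fit(self, X: pd.DataFrame, y=None):
        self.correlation_ = bicor_matrix(X)
        if self.power == "auto":
            self.power_, self.fit_table_ = pick_soft_threshold(
                X,
                powers=range(1, self.max_power + 1),
                fit_threshold=self.fit_threshold,
                correlation=self.correlation_,
            )
        else:
            self.power_ = int(self.power)
            self.fit_table_ = pd.DataFrame()
        adj = np.abs(self.correlation_.to_numpy()) ** self.power_
        np.fill_diagonal(adj, 1.0)
        self.adjacency_ = pd.DataFrame(
            adj, index=X.index, columns=X.index
        )
        self.tom_ = tom_similarity(self.adjacency_)
        dissim = 1.0 - self.tom_
        raw_labels = detect_modules(
            dissim, self.min_module_size, self.cut_height
        )
        pruned = prune_weak_modules(
            X,
            raw_labels,
            min_module_size=self.min_module_size,
            kme_min=self.kme_min,
            pve_min=self.pve_min,
        )
        self.modules_ = merge_close_modules(X, pruned, self.merge_height)
        self.labels_ = self.modules_.labels
        self.eigengenes_ = self.modules_.eigengenes
        self.kme_ = self.modules_.kme
        self.prop_var_explained_ = self.modules_.prop_var_explained
        return self

    def fit_predict(self, X: pd.DataFrame, y=None) -> np.ndarray:
        return self.fit(X).labels_.to_numpy()
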