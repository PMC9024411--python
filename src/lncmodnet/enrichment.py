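"""Over-representation analysis and enrichment-map construction.

Module genes are tested against named gene sets with the one-sided
hypergeometric upper tail, P(X >= k), over a stated universe.  Sets
enriched below a raw p of 0.001 become map nodes (BH q-values are reported
alongside but the node filter is on raw p); node pairs whose gene-set
similarity — an equal-weight blend of the Jaccard and overlap coefficients
— reaches 0.375 are linked, and connected components form named clusters.
"""

from __future__ import annotations

from collections import Counter

import networkx as nx
import pandas as pd
from scipy.stats import hypergeom

from .preprocess import bh_adjust

__all__ = [
    "ora_test",
    "enrich_module",
    "set_similarity",
    "build_map",
    "enrichment_map_for_modules",
]


def ora_test(module_genes, gene_set, universe) -> tuple[int, float]:
    """Hypergeometric over-representation: overlap k and P(X >= k).

    X ~ Hypergeometric(N = |universe|, K = |set in universe|,
    n = |module|); the tail includes k itself.
    """
    universe = set(universe)
    module = set(module_genes) & universe
    geneset = set(gene_set) & universe
    if not module or not geneset:
        raise ValueError("module and gene set must be non-empty within the universe")
    k = len(module & geneset)
    p = float(hypergeom.sf(k - 1, len(universe), len(geneset), len(module)))
    return k, min(p, 1.0)


def enrich_module(
    module_genes,
    collection: dict[str, list[str]],
    universe,
    alpha_node: float = 0.001,
) -> pd.DataFrame:
    """Test a module against every set; retain map nodes at raw p < 0.001.

    Returns a DataFrame (set, k, K, n, N, p, q, node) sorted by p; ``node``
    marks sets passing the raw-p map filter.  Sets with no member in the
    universe are dropped.
    """
    universe = set(universe)
    module = set(module_genes) & universe
    rows = []
    for name, members in collection.items():
        in_universe = set(members) & universe
        if not in_universe:
            continue
        k, p = ora_test(module, in_universe, universe)
        rows.append(
            {
                "set": name,
                "k": k,
                "K": len(in_universe),
                "n": len(module),
                "N": len(universe),
                "p": p,
            }
        )
    result = pd.DataFrame(rows, columns=["set", "k", "K", "n", "N", "p"])
    if result.empty:
        result["q"] = result["node"] = pd.Series(dtype=float)
        return result
    result["q"] = bh_adjust(result["p"].to_numpy())
    result["node"] = result["p"] < alpha_node
    return result.sort_values(["p", "set"]).reset_index(drop=True)


def set_similarity(a, b) -> float:
    """Combined 50/50 Jaccard + overlap coefficient of two gene sets."""
    a, b = set(a), set(b)
    if not a or not b:
        raise ValueError("gene sets must be non-empty")
    inter = len(a & b)
    return 0.5 * inter / len(a | b) + 0.5 * inter / min(len(a), len(b))


def _cluster_label(names) -> str:
    """Most frequent name token among member sets (ties: lexicographic)."""
    tokens = Counter()
    for name in names:
        tokens.update(t for t in str(name).split("_") if t)
    if not tokens:
        return ""
    top = max(tokens.values())
    return sorted(t for t, c in tokens.items() if c == top)[0]


def build_map(
    nodes: pd.DataFrame,
    collection: dict[str, list[str]],
    edge_cutoff: float = 0.375,
) -> nx.Graph:
    """Enrichment map: significant sets as nodes, similarity >= cutoff as edges.

    ``nodes`` must carry columns set/module/p/q/k; clusters are connected
    components, labelled by the most frequent token of member set names
    and stored as node attribute ``cluster``.
    """
    g = nx.Graph(edge_cutoff=float(edge_cutoff))
    for row in nodes.itertuples(index=False):
        name = row.set
        if g.has_node(name):
            g.nodes[name]["modules"] = g.nodes[name]["modules"] + f",{row.module}"
            g.nodes[name]["p"] = min(g.nodes[name]["p"], float(row.p))
            continue
        g.add_node(
            name,
            module=str(row.module),
            modules=str(row.module),
            p=float(row.p),
            q=float(row.q),
            overlap=int(row.k),
            size=len(collection[name]),
        )
    names = sorted(g.nodes)
    for i, a in enumerate(names):
        for b in names[i + 1 :]:
            coeff = set_similarity(collection[a], collection[b])
            if coeff >= edge_cutoff:
                g.add_edge(a, b, similarity=coeff)
    for idx, component in enumerate(
        sorted(nx.connected_components(g), key=lambda c: sorted(c)[0]), start=1
    ):
        label = _cluster_label(component)
        for name in component:
            g.nodes[name]["cluster"] = idx
            g.nodes[name]["cluster_label"] = label
    return g


def enrichment_map_for_modules(
    labels: pd.Series,
    collection: dict[str, list[str]],
    universe,
    modules=None,
    alpha_node: float = 0.001,
    edge_cutoff: float = 0.375,
) -> tuple[pd.DataFrame, nx.Graph]:
    """ORA every requested module and assemble the combined enrichment map."""
    modules = (
        sorted(int(v) for v in labels.unique() if v > 0)
        if modules is None
        else list(modules)
    )
    tables = []
    for m in modules:
        genes = labels.index[labels == m]
        table = enrich_module(genes, collection, universe, alpha_node)
        table.insert(0, "module", m)
        tables.append(table)
    enrichment = (
        pd.concat(tables, ignore_index=True)
        if tables
        else pd.DataFrame(columns=["module", "set", "k", "K", "n", "N", "p", "q", "node"])
    )
    nodes = enrichment[enrichment["node"] == True]  # noqa: E712
    graph = build_map(nodes, collection, edge_cutoff)
    return enrichment, graph
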