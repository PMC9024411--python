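"""lncRNA-mRNA subnetworks of key modules and hub lncRNA identification.

Within each key module, gene pairs with a connection weight (TOM by
default) of at least 0.15 and at least one lncRNA endpoint form an
undirected weighted graph.  Hub lncRNAs are ranked by degree centrality
(raw incident-edge count), with ties broken by weighted degree and then
gene id.  Modules without any lncRNA are skipped, mirroring how such a
module drops out of a lncRNA-centric analysis.
"""

from __future__ import annotations

import warnings
from pathlib import Path

import networkx as nx
import pandas as pd

__all__ = ["extract_module_graph", "degree_centrality", "export_graph", "read_edge_list"]


def extract_module_graph(
    weights: pd.DataFrame,
    labels: pd.Series,
    biotypes: pd.Series,
    module_id: int,
    min_weight: float = 0.15,
    mode: str = "lncRNA",
) -> nx.Graph | None:
    """Thresholded weighted graph of one module.

    ``weights`` is the symmetric gene x gene connection-strength matrix
    (TOM in the default pipeline).  Edges require weight >= ``min_weight``
    (inclusive) and, in the default ``lncRNA`` mode, at least one lncRNA
    endpoint; ``mode='full-module'`` keeps every qualifying pair.  Returns
    None (with a warning) when the module holds no lncRNA in lncRNA mode.
    """
    genes = [g for g in labels.index if labels[g] == module_id]
    if not genes:
        raise ValueError(f"module {module_id} is empty")
    lnc = {g for g in genes if biotypes.get(g) == "lncRNA"}
    if mode == "lncRNA" and not lnc:
        warnings.warn(f"module {module_id} has no lncRNA; skipped")
        return None
    g = nx.Graph(module=int(module_id))
    for gene in genes:
        g.add_node(gene, biotype=biotypes.get(gene, "coding"))
    sub = weights.loc[genes, genes]
    for i, gi in enumerate(genes):
        row = sub.iloc[i]
        for gj in genes[i + 1 :]:
            w = float(row[gj])
            if w < min_weight:
                continue
            if mode == "lncRNA" and gi not in lnc and gj not in lnc:
                continue
            g.add_edge(gi, gj, weight=w)
    if g.number_of_edges() == 0:
        warnings.warn(f"module {module_id}: no edges at weight >= {min_weight}")
    return g


def degree_centrality(graph: nx.Graph, hub_top_k: int = 1) -> pd.DataFrame:
    """Per-lncRNA degree table, ranked, with hub flags.

    Rank 1 is the maximum degree; ties are broken by weighted degree, then
    lexicographic gene id.  The top ``hub_top_k`` ranked lncRNAs are
    flagged as hubs.
    """
    rows = []
    for node, data in graph.nodes(data=True):
        if data.get("biotype") != "lncRNA":
            continue
        rows.append(
            {
                "gene_id": node,
                "degree": graph.degree(node),
                "weighted_degree": float(graph.degree(node, weight="weight")),
            }
        )
    table = pd.DataFrame(rows, columns=["gene_id", "degree", "weighted_degree"])
    if table.empty:
        table["rank"] = pd.Series(dtype=int)
        table["hub"] = pd.Series(dtype=bool)
        return table
    table = table.sort_values(
        ["degree", "weighted_degree", "gene_id"], ascending=[False, False, True]
    ).reset_index(drop=True)
    table["rank"] = range(1, len(table) + 1)
    table["hub"] = table["rank"] <= hub_top_k
    return table


def export_graph(graph: nx.Graph, path: str | Path, fmt: str = "tsv") -> Path:
    """Write a deterministic edge-list TSV or a GraphML file."""
    path = Path(path)
    if graph.number_of_nodes() == 0:
        raise ValueError("refusing to export an empty graph")
    if fmt == "tsv":
        rows = []
        module = graph.graph.get("module", "")
        for u, v, data in graph.edges(data=True):
            a, b = sorted((u, v))
            rows.append(
                {
                    "source": a,
                    "target": b,
                    "weight": data["weight"],
                    "source_type": graph.nodes[a].get("biotype", ""),
                    "target_type": graph.nodes[b].get("biotype", ""),
                    "module": module,
                }
            )
        edges = pd.DataFrame(
            rows,
            columns=["source", "target", "weight", "source_type", "target_type", "module"],
        ).sort_values(["source", "target"])
        edges.to_csv(path, sep="\t", index=False, float_format="%.10g")
    elif fmt == "graphml":
        nx.write_graphml(graph, path)
    else:
        raise ValueError(f"unknown export format: {fmt}")
    return path


def read_edge_list(path: str | Path) -> nx.Graph:
    """Re-import a TSV edge list written by :func:`export_graph`."""
    edges = pd.read_csv(path, sep="\t")
    g = nx.Graph()
    if not edges.empty and edges["module"].notna().any():
        g.graph["module"] = int(edges["module"].iloc[0])
    for row in edges.itertuples(index=False):
        g.add_node(row.source, biotype=row.source_type)
        g.add_node(row.target, biotype=row.target_type)
        g.add_edge(row.source, row.target, weight=float(row.weight))
    return g
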