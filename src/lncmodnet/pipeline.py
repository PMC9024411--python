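"""End-to-end orchestration: counts -> modules -> report.

``run_all`` executes the stages in order — expression filter, TMM/log-CPM,
differential expression, co-expression network and module detection,
module preservation against an optional independent dataset, module-trait
association with the key-module rule, lncRNA-mRNA subnetworks and hubs,
cis/trans and TF annotation, and ORA with the enrichment map — writing
every stage's table under a run directory together with a resolved-config
snapshot, input checksums and a log of the thresholds applied.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx
import pandas as pd
import yaml

from . import enrichment as enr
from . import genomic, preservation, subnet, traits
from .network import WGCNA
from .preprocess import TMMNormalizer, differential_expression_all, filter_low_expression
from .simulate import CONTRASTS, SampleDesign, read_gmt

logger = logging.getLogger("lncmodnet")


@dataclass
class PipelineConfig:
    """All stage parameters with their published defaults."""

    counts: str = "counts.tsv"
    design: str = "design.tsv"
    annotation: str = "annotation.tsv"
    gmt: str = "genesets.gmt"
    tf_binding: str = "tf_binding.bed"
    test_counts: str | None = None  # independent dataset for preservation

    min_cpm: float = 1.0
    power: int | str = "auto"
    max_power: int = 20
    fit_threshold: float = 0.8
    min_module_size: int = 30
    merge_height: float = 0.25
    n_perm: int = 100
    z_threshold: float = 10.0
    alpha: float = 0.05
    min_traits: int = 3
    min_edge_weight: float = 0.15
    edge_weight: str = "bicor"  # bicor | tom | adjacency
    cis_window: int = 100_000
    promoter_upstream: int = 30_000
    promoter_downstream: int = 10_000
    alpha_node: float = 0.001
    map_cutoff: float = 0.375
    seed: int = 0

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        payload = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(payload) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**payload)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(dataclasses.asdict(self), sort_keys=True))


def read_counts(path: str | Path) -> pd.DataFrame:
    counts = pd.read_csv(path, sep="\t", index_col=0)
    if counts.empty:
        raise ValueError(f"empty count matrix: {path}")
    return counts


def read_design(path: str | Path) -> SampleDesign:
    table = pd.read_csv(path, sep="\t")
    required = {"sample", "group", "vehicle"}
    if not required.issubset(table.columns):
        raise ValueError(
            f"design file {path} lacks columns {sorted(required - set(table.columns))}"
        )
    contrasts = {
        name: pair
        for name, pair in CONTRASTS.items()
        if pair[0] in set(table["group"]) and pair[1] in set(table["group"])
    }
    return SampleDesign(table=table[["sample", "group", "vehicle"]], contrasts=contrasts)


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_all(config: PipelineConfig, out_dir: str | Path, data_dir: str | Path = ".") -> Path:
    """Run every stage and write outputs under ``out_dir``.

    Stage outputs: normalized.tsv, de_results.tsv, fit_table.tsv,
    modules.tsv, eigengenes.tsv, preservation.tsv (if a test dataset is
    configured), module_trait.tsv, key_modules.tsv, hubs.tsv,
    edges_module<k>.tsv + GraphML per key module, cis_trans.tsv,
    enrichment.tsv, map_nodes.tsv, map_edges.tsv, map.graphml,
    report.json, resolved_config.yaml, provenance.json.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    data = Path(data_dir)
    handler = logging.FileHandler(out / "run.log", mode="w")
    handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    logger.addHandler(handler)
    logger.setLevel(logging.INFO)
    try:
        return _run_all(config, out, data)
    finally:
        logger.removeHandler(handler)
        handler.close()


def _run_all(config: PipelineConfig, out: Path, data: Path) -> Path:
    inputs = {
        name: data / getattr(config, name)
        for name in ("counts", "design", "annotation", "gmt", "tf_binding")
    }
    if config.test_counts:
        inputs["test_counts"] = data / config.test_counts
    for name, path in inputs.items():
        if not path.exists():
            raise FileNotFoundError(f"{name} input missing: {path}")
    config.to_yaml(out / "resolved_config.yaml")
    (out / "provenance.json").write_text(
        json.dumps({k: _sha256(p) for k, p in inputs.items()}, indent=1, sort_keys=True)
    )

    # --- preprocess -------------------------------------------------------
    logger.info("stage preprocess: CPM filter >= %s, TMM, Welch DE", config.min_cpm)
    counts = read_counts(inputs["counts"])
    design = read_design(inputs["design"])
    missing = set(design.samples) - set(counts.columns)
    if missing:
        raise ValueError(f"design samples absent from counts: {sorted(missing)[:5]}")
    counts = counts[design.samples]
    filtered = filter_low_expression(counts, design, config.min_cpm)
    logger.info("kept %d of %d genes", filtered.shape[0], counts.shape[0])
    norm = TMMNormalizer().fit_transform(filtered)
    norm.rename_axis("gene_id").to_csv(out / "normalized.tsv", sep="\t")
    de = differential_expression_all(norm, design, alpha=config.alpha)
    de.to_csv(out / "de_results.tsv", sep="\t", index=False)

    # --- network ----------------------------------------------------------
    logger.info(
        "stage network: power=%s (fit >= %s), min module size %d, merge %.2f",
        config.power,
        config.fit_threshold,
        config.min_module_size,
        config.merge_height,
    )
    wgcna = WGCNA(
        power=config.power,
        min_module_size=config.min_module_size,
        merge_height=config.merge_height,
        fit_threshold=config.fit_threshold,
        max_power=config.max_power,
    ).fit(norm)
    modules = wgcna.modules_
    logger.info("selected power %d; %d modules", wgcna.power_, len(modules.module_ids))
    if not wgcna.fit_table_.empty:
        wgcna.fit_table_.to_csv(out / "fit_table.tsv", sep="\t", index=False)
    own_kme = [
        modules.kme.loc[g, modules.labels[g]] if modules.labels[g] > 0 else float("nan")
        for g in modules.labels.index
    ]
    pd.DataFrame(
        {"gene_id": modules.labels.index, "module": modules.labels.values, "kME_own": own_kme}
    ).to_csv(out / "modules.tsv", sep="\t", index=False)
    modules.eigengenes.to_csv(out / "eigengenes.tsv", sep="\t")

    # --- preservation -----------------------------------------------------
    preserved_ids = modules.module_ids
    pres = None
    if config.test_counts:
        logger.info("stage preservation: nperm=%d, Zsummary > %s", config.n_perm, config.z_threshold)
        test_counts = read_counts(inputs["test_counts"])
        test_counts = test_counts.loc[filtered.index, design.samples]
        test_norm = TMMNormalizer().fit_transform(test_counts)
        pres = preservation.module_preservation(
            norm,
            test_norm,
            modules.labels,
            power=wgcna.power_,
            n_perm=config.n_perm,
            seed=config.seed,
            z_threshold=config.z_threshold,
        )
        pres.to_csv(out / "preservation.tsv", sep="\t")
        preserved_ids = [int(m) for m in pres.index[pres["preserved"]]]
        logger.info("%d of %d modules strongly preserved", len(preserved_ids), len(pres))
    else:
        logger.warning(
            "no independent dataset configured: preservation skipped; the "
            "key-module filter operates on ALL modules (deviation)"
        )

    # --- module-trait -----------------------------------------------------
    logger.info("stage traits: adj p < %s in >= %d coherent contrasts", config.alpha, config.min_traits)
    mt = traits.module_trait_analysis(
        modules.eigengenes.loc[preserved_ids], design
    )
    mt_adj, summary = traits.adjust_and_flag(mt, alpha=config.alpha, min_traits=config.min_traits)
    mt_adj.to_csv(out / "module_trait.tsv", sep="\t", index=False)
    summary.to_csv(out / "key_modules.tsv", sep="\t")
    key_modules = [int(m) for m in summary.index[summary["key"]]]
    logger.info("key modules: %s", key_modules)

    # --- lncRNA subnetworks + genomic context + enrichment ---------------
    annotation = pd.read_csv(inputs["annotation"], sep="\t")
    biotypes = annotation.set_index("gene_id")["biotype"]
    weights = {
        "tom": wgcna.tom_,
        "adjacency": wgcna.adjacency_,
        "bicor": wgcna.correlation_.abs(),
    }[config.edge_weight]
    hub_tables = []
    lnc_modules = []
    for m in key_modules:
        graph = subnet.extract_module_graph(
            weights, modules.labels, biotypes, m, config.min_edge_weight
        )
        if graph is None:
            logger.warning("module %d skipped: no lncRNA members", m)
            continue
        lnc_modules.append(m)
        subnet.export_graph(graph, out / f"edges_module{m}.tsv", "tsv")
        subnet.export_graph(graph, out / f"module{m}.graphml", "graphml")
        hubs = subnet.degree_centrality(graph)
        hubs.insert(0, "module", m)
        hub_tables.append(hubs)
    hub_table = (
        pd.concat(hub_tables, ignore_index=True)
        if hub_tables
        else pd.DataFrame(columns=["module", "gene_id", "degree", "weighted_degree", "rank", "hub"])
    )
    hub_table.to_csv(out / "hubs.tsv", sep="\t", index=False)

    binding = pd.read_csv(
        inputs["tf_binding"], sep="\t", header=None,
        names=["chrom", "start", "end", "tf_gene_id"],
    )
    module_subset = modules.labels[modules.labels.isin(lnc_modules)]
    cis_trans = genomic.annotate_module_pairs(
        module_subset,
        biotypes,
        annotation,
        binding,
        tf_gene_ids=set(binding["tf_gene_id"]),
        window=config.cis_window,
    )
    cis_trans.to_csv(out / "cis_trans.tsv", sep="\t", index=False)

    collection = read_gmt(inputs["gmt"])
    enrichment_table, emap = enr.enrichment_map_for_modules(
        modules.labels,
        collection,
        universe=filtered.index,
        modules=lnc_modules,
        alpha_node=config.alpha_node,
        edge_cutoff=config.map_cutoff,
    )
    enrichment_table.to_csv(out / "enrichment.tsv", sep="\t", index=False)
    nodes = pd.DataFrame(
        [{"set": n, **d} for n, d in sorted(emap.nodes(data=True))]
    )
    nodes.to_csv(out / "map_nodes.tsv", sep="\t", index=False)
    edges = pd.DataFrame(
        [
            {"source": min(u, v), "target": max(u, v), "similarity": d["similarity"]}
            for u, v, d in emap.edges(data=True)
        ]
    ).sort_values(["source", "target"]) if emap.number_of_edges() else pd.DataFrame(
        columns=["source", "target", "similarity"]
    )
    edges.to_csv(out / "map_edges.tsv", sep="\t", index=False)
    if emap.number_of_nodes():
        nx.write_graphml(emap, out / "map.graphml")

    report(out, de=de, hub_table=hub_table, mt_adj=mt_adj, summary=summary, pres=pres,
           cis_trans=cis_trans, emap=emap, modules=modules)
    return out


def report(
    run_dir: Path,
    de: pd.DataFrame,
    hub_table: pd.DataFrame,
    mt_adj: pd.DataFrame,
    summary: pd.DataFrame,
    pres: pd.DataFrame | None,
    cis_trans: pd.DataFrame,
    emap: nx.Graph,
    modules,
) -> dict:
    """Single JSON summary: modules, hubs (with DE), cis/trans, clusters."""
    module_rows = []
    for m in modules.module_ids:
        row = {
            "module": m,
            "size": int((modules.labels == m).sum()),
            "key": bool(summary["key"].get(m, False)) if m in summary.index else False,
        }
        if pres is not None and m in pres.index:
            row.update(
                preserved=bool(pres.loc[m, "preserved"]),
                z_summary=float(pres.loc[m, "z_summary"]),
                median_rank=float(pres.loc[m, "median_rank"]),
            )
        cells = mt_adj[mt_adj["module"] == m]
        if not cells.empty:
            row["trait_pattern"] = {
                c: {"r": float(r), "adj_p": float(q)}
                for c, r, q in zip(cells["contrast"], cells["r"], cells["adj_p"])
            }
        module_rows.append(row)

    hub_rows = []
    for hub in hub_table[hub_table["hub"] == True].itertuples(index=False):  # noqa: E712
        m = int(hub.module)
        cells = mt_adj[mt_adj["module"] == m]
        top_contrast = (
            cells.loc[cells["adj_p"].idxmin(), "contrast"] if not cells.empty else None
        )
        de_cell = de[(de["gene_id"] == hub.gene_id) & (de["contrast"] == top_contrast)]
        hub_rows.append(
            {
                "module": m,
                "gene_id": hub.gene_id,
                "degree": int(hub.degree),
                "top_contrast": top_contrast,
                "de_q": float(de_cell["q"].iloc[0]) if not de_cell.empty else None,
                "de_significant": bool(de_cell["significant"].iloc[0]) if not de_cell.empty else None,
            }
        )

    clusters: dict[str, list[str]] = {}
    for n, d in emap.nodes(data=True):
        clusters.setdefault(f'{d["cluster"]}:{d["cluster_label"]}', []).append(n)
    payload = {
        "modules": module_rows,
        "hub_lncRNAs": hub_rows,
        "cis_pairs": int((cis_trans["class"] == "cis").sum()) if not cis_trans.empty else 0,
        "trans_pairs": int((cis_trans["class"] == "trans").sum()) if not cis_trans.empty else 0,
        "tf_regulated_lncRNA_pairs": int(cis_trans["tf_regulates_lncRNA"].sum())
        if not cis_trans.empty
        else 0,
        "enrichment_clusters": {k: sorted(v) for k, v in sorted(clusters.items())},
    }
    (Path(run_dir) / "report.json").write_text(json.dumps(payload, indent=1, sort_keys=True))
    return payload
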