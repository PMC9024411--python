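"""Genomic-context classification of lncRNA-mRNA module pairs.

A pair is *cis* when both genes sit on the same chromosome with TSSs at
most 100 kb apart (inclusive), otherwise *trans*.  Among trans pairs, a
module mRNA that is a transcription factor is flagged as a candidate
regulator of a module lncRNA when one of its binding intervals overlaps
the lncRNA's promoter window, -30 kb to +10 kb around the TSS in the
lncRNA's orientation.  All coordinates are 0-based half-open (BED
convention); overlap at the half-open boundary does not count.
"""

from __future__ import annotations

import logging
from collections import defaultdict

import pandas as pd
from intervaltree import IntervalTree

logger = logging.getLogger(__name__)

__all__ = [
    "tss",
    "promoter_window",
    "classify_cis_trans",
    "tf_trans_regulators",
    "annotate_module_pairs",
]

CIS_WINDOW = 100_000
PROMOTER_UPSTREAM = 30_000
PROMOTER_DOWNSTREAM = 10_000


def _annotation_index(annotation: pd.DataFrame) -> pd.DataFrame:
    ann = annotation.set_index("gene_id") if "gene_id" in annotation.columns else annotation
    bad = ann[ann["start"] >= ann["end"]]
    if not bad.empty:
        raise ValueError(f"start >= end for genes: {list(bad.index[:5])}")
    return ann


def tss(annotation_row: pd.Series) -> int:
    """Transcription start site: start on +, end - 1 on - (0-based)."""
    if annotation_row["strand"] == "+":
        return int(annotation_row["start"])
    return int(annotation_row["end"]) - 1


def promoter_window(
    annotation_row: pd.Series,
    upstream: int = PROMOTER_UPSTREAM,
    downstream: int = PROMOTER_DOWNSTREAM,
) -> tuple[str, int, int]:
    """Strand-aware (chrom, start, end) promoter interval, clipped at 0.

    + strand, TSS t: [t - upstream, t + downstream); - strand: the mirror
    image in increasing coordinates, [t - downstream + 1, t + upstream + 1).
    """
    t = tss(annotation_row)
    if annotation_row["strand"] == "+":
        lo, hi = t - upstream, t + downstream
    else:
        lo, hi = t - downstream + 1, t + upstream + 1
    return str(annotation_row["chrom"]), max(lo, 0), hi


def classify_cis_trans(
    pairs, annotation: pd.DataFrame, window: int = CIS_WINDOW
) -> pd.DataFrame:
    """Classify (lncRNA, mRNA) pairs as cis or trans by TSS distance.

    ``pairs`` is an iterable of (lncRNA id, mRNA id).  Distance is signed
    (mRNA TSS minus lncRNA TSS) and only defined on a shared chromosome;
    |distance| <= ``window`` (inclusive) means cis.
    """
    ann = _annotation_index(annotation)
    rows = []
    for lnc, mrna in pairs:
        for g in (lnc, mrna):
            if g not in ann.index:
                raise KeyError(f"gene not annotated: {g}")
        a, b = ann.loc[lnc], ann.loc[mrna]
        if a["chrom"] != b["chrom"]:
            rows.append(
                {"lncRNA": lnc, "mRNA": mrna, "class": "trans", "tss_distance": pd.NA}
            )
            continue
        dist = tss(b) - tss(a)
        cls = "cis" if abs(dist) <= window else "trans"
        rows.append(
            {"lncRNA": lnc, "mRNA": mrna, "class": cls, "tss_distance": dist}
        )
    return pd.DataFrame(rows, columns=["lncRNA", "mRNA", "class", "tss_distance"])


def tf_trans_regulators(
    lncRNAs,
    module_mRNAs,
    tf_gene_ids,
    binding: pd.DataFrame,
    annotation: pd.DataFrame,
    upstream: int = PROMOTER_UPSTREAM,
    downstream: int = PROMOTER_DOWNSTREAM,
) -> pd.DataFrame:
    """Flag TF(mRNA) -> lncRNA candidate regulation from binding intervals.

    For each module mRNA that is a transcription factor and each module
    lncRNA: the pair is flagged when any of that TF's binding intervals
    (half-open) overlaps the lncRNA's promoter window.  TFs absent from
    the binding table are logged, not errors.  Returns one row per
    (tf, lncRNA) pair with ``tf_regulates_lncRNA`` and the first
    supporting interval.
    """
    ann = _annotation_index(annotation)
    tfs = [g for g in module_mRNAs if g in set(tf_gene_ids)]
    trees: dict[tuple[str, str], IntervalTree] = defaultdict(IntervalTree)
    for row in binding.itertuples(index=False):
        trees[(str(row.tf_gene_id), str(row.chrom))].addi(
            int(row.start), int(row.end), (int(row.start), int(row.end))
        )
    known_tfs = {t for t, _c in trees}
    rows = []
    for tf in tfs:
        if tf not in known_tfs:
            logger.info("TF %s has no binding intervals; skipped", tf)
        for lnc in lncRNAs:
            chrom, lo, hi = promoter_window(ann.loc[lnc], upstream, downstream)
            hits = sorted(trees[(tf, chrom)].overlap(lo, hi)) if (tf, chrom) in trees else []
            rows.append(
                {
                    "tf": tf,
                    "lncRNA": lnc,
                    "tf_regulates_lncRNA": bool(hits),
                    "support_start": hits[0].begin if hits else pd.NA,
                    "support_end": hits[0].end if hits else pd.NA,
                }
            )
    return pd.DataFrame(
        rows,
        columns=["tf", "lncRNA", "tf_regulates_lncRNA", "support_start", "support_end"],
    )


def annotate_module_pairs(
    labels: pd.Series,
    biotypes: pd.Series,
    annotation: pd.DataFrame,
    binding: pd.DataFrame | None = None,
    tf_gene_ids=(),
    window: int = CIS_WINDOW,
) -> pd.DataFrame:
    """Cis/trans table for every lncRNA-mRNA pair of every module.

    Adds the TF-regulation flag for trans pairs whose mRNA is a listed
    transcription factor with binding evidence.
    """
    out = []
    for m in sorted(int(v) for v in labels.unique() if v > 0):
        genes = [g for g in labels.index if labels[g] == m]
        lncs = [g for g in genes if biotypes.get(g) == "lncRNA"]
        mrnas = [g for g in genes if biotypes.get(g) != "lncRNA"]
        if not lncs or not mrnas:
            continue
        pairs = [(l, c) for l in lncs for c in mrnas]
        table = classify_cis_trans(pairs, annotation, window)
        table.insert(0, "module", m)
        table["tf_regulates_lncRNA"] = False
        if binding is not None and len(tf_gene_ids):
            flags = tf_trans_regulators(
                lncs, mrnas, tf_gene_ids, binding, annotation
            )
            flagged = {
                (r.tf, r.lncRNA)
                for r in flags.itertuples(index=False)
                if r.tf_regulates_lncRNA
            }
            table["tf_regulates_lncRNA"] = [
                (mrna, lnc) in flagged and cls == "trans"
                for mrna, lnc, cls in zip(
                    table["mRNA"], table["lncRNA"], table["class"]
                )
            ]
        out.append(table)
    if not out:
        return pd.DataFrame(
            columns=[
                "module",
                "lncRNA",
                "mRNA",
                "class",
                "tss_distance",
                "tf_regulates_lncRNA",
            ]
        )
    return pd.concat(out, ignore_index=True)
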