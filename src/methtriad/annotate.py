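"""Associating regions with genes and miRNA loci with methylated cytosines.

A DMR is linked to every gene whose body +/- flank it overlaps; its feature
class is the gene sub-feature (promoter thirds, first/internal/last
exon/intron, downstream) with maximal base overlap, ties broken by the
fixed order promoter > exon > intron > downstream. A miRNA precursor locus
is "associated with mCs" when at least one methylated cytosine falls inside
it (threshold configurable).
"""
from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from intervaltree import IntervalTree

from .methylome import gene_region_intervals, methylated_mask
from .models import CONTEXTS, FEATURE_CLASSES, GeneModel

log = logging.getLogger(__name__)

LINK_COLUMNS = ["dmr_name", "chrom", "start", "end", "context", "direction",
                "gene_id", "feature_class", "overlap_bp"]

_PRIORITY = {name: i for i, name in enumerate(FEATURE_CLASSES)}


def classify_dmr_position(dmr_start: int, dmr_end: int, gene: GeneModel,
                          flank: int = 2000) -> tuple[str, int] | None:
    """(feature_class, overlap_bp) of a region against one gene, or None.

    The winning class has maximal base overlap with the region; among equal
    overlaps the class earlier in the priority order wins.
    """
    best: tuple[int, int, str] | None = None  # (-overlap, priority, name)
    for name, ivs in gene_region_intervals(gene, flank).items():
        ov = sum(max(0, min(dmr_end, e) - max(dmr_start, s)) for s, e in ivs)
        if ov <= 0:
            continue
        key = (-ov, _PRIORITY[name], name)
        if best is None or key < best:
            best = key
    if best is None:
        return None
    return best[2], -best[0]


def link_dmrs_to_genes(dmrs: pd.DataFrame, genes: list[GeneModel],
                       flank: int = 2000) -> pd.DataFrame:
    """Link each DMR to overlapping genes (body +/- flank) with a feature class.

    A DMR may link to several genes; a gene may collect several DMRs. Use
    :func:`gene_dmr_directions` to collapse links to one direction per gene.
    """
    trees: dict[str, IntervalTree] = {}
    by_id: dict[str, GeneModel] = {}
    for g in genes:
        trees.setdefault(g.chrom, IntervalTree()).addi(
            max(0, g.start - flank), g.end + flank, g.gene_id)
        by_id[g.gene_id] = g
    rows = []
    for _, dmr in dmrs.iterrows():
        tree = trees.get(dmr["chrom"])
        if tree is None:
            continue
        for hit in sorted(tree.overlap(dmr["start"], dmr["end"])):
            gene = by_id[hit.data]
            res = classify_dmr_position(int(dmr["start"]), int(dmr["end"]), gene, flank)
            if res is None:
                continue
            feature_class, overlap_bp = res
            rows.append({
                "dmr_name": dmr.get("name", f"{dmr['chrom']}:{dmr['start']}-{dmr['end']}"),
                "chrom": dmr["chrom"], "start": int(dmr["start"]), "end": int(dmr["end"]),
                "context": dmr.get("context", "combined"),
                "direction": dmr.get("direction", "."),
                "gene_id": gene.gene_id,
                "feature_class": feature_class,
                "overlap_bp": overlap_bp,
            })
    links = pd.DataFrame(rows, columns=LINK_COLUMNS)
    log.info("linked %d DMRs to %d genes (%d links)",
             links["dmr_name"].nunique(), links["gene_id"].nunique(), len(links))
    return links


def gene_dmr_directions(links: pd.DataFrame) -> pd.DataFrame:
    """One row per DMR-associated gene: direction hyper/hypo, or mixed when a
    gene collects DMRs of both directions; DMR locations are concatenated."""
    if len(links) == 0:
        return pd.DataFrame(columns=["gene_id", "dmr_direction", "dmr_locations", "n_dmrs"])
    rows = []
    for gene_id, grp in links.groupby("gene_id", sort=True):
        dirs = set(grp["direction"])
        direction = dirs.pop() if len(dirs) == 1 else "mixed"
        rows.append({
            "gene_id": gene_id,
            "dmr_direction": direction,
            "dmr_locations": ",".join(sorted(set(grp["feature_class"]))),
            "n_dmrs": grp["dmr_name"].nunique(),
        })
    return pd.DataFrame(rows)


def mirna_mc_association(
    mirna_loci: pd.DataFrame,
    calls: pd.DataFrame,
    min_meth_reads: int = 1,
    min_mc_sites: int = 1,
) -> tuple[pd.DataFrame, dict]:
    """Count methylated cytosines per context inside each miRNA locus.

    ``mirna_loci`` is a BED-like frame (chrom, start, end, name). Returns a
    per-locus table plus a summary with the fraction of loci associated
    (>= ``min_mc_sites`` mCs) and the per-context composition of all mCs
    found in loci.
    """
    mc = calls[methylated_mask(calls, min_meth_reads=min_meth_reads)]
    by_chrom = {
        chrom: (sub.sort_values("pos")["pos"].to_numpy(np.int64),
                sub.sort_values("pos")["context"].to_numpy())
        for chrom, sub in mc.groupby("chrom", sort=False)
    }
    rows = []
    for _, locus in mirna_loci.iterrows():
        counts = dict.fromkeys(CONTEXTS, 0)
        if locus["chrom"] in by_chrom:
            pos, ctx = by_chrom[locus["chrom"]]
            lo, hi = np.searchsorted(pos, [locus["start"], locus["end"]])
            for c in ctx[lo:hi]:
                counts[c] += 1
        total = sum(counts.values())
        rows.append({
            "mirna_id": locus.get("name", f"{locus['chrom']}:{locus['start']}"),
            "chrom": locus["chrom"], "start": int(locus["start"]),
            "end": int(locus["end"]),
            **{f"n_mc_{c}": counts[c] for c in CONTEXTS},
            "n_mc_total": total,
            "associated": total >= min_mc_sites,
        })
    table = pd.DataFrame(rows)
    total_mc = int(table["n_mc_total"].sum()) if len(table) else 0
    summary = {
        "n_loci": len(table),
        "n_associated": int(table["associated"].sum()) if len(table) else 0,
        "fraction_associated": float(table["associated"].mean()) if len(table) else 0.0,
        "mc_composition": {
            c: (int(table[f"n_mc_{c}"].sum()) / total_mc) if total_mc else 0.0
            for c in CONTEXTS
        },
    }
    return table, summary


def dmr_expression_summary(gene_directions: pd.DataFrame,
                           degs: pd.DataFrame) -> pd.DataFrame:
    """Cross-tabulate DMR direction (hyper/hypo/mixed) x gene DE direction.

    ``gene_directions`` is the output of :func:`gene_dmr_directions`;
    ``degs`` needs feature_id and direction. Genes absent from the DEG table
    count as ns.
    """
    deg_dir = degs.set_index("feature_id")["direction"] if len(degs) else pd.Series(dtype=object)
    rows = []
    for _, g in gene_directions.iterrows():
        rows.append({
            "gene_id": g["gene_id"],
            "dmr_direction": g["dmr_direction"],
            "expr_direction": deg_dir.get(g["gene_id"], "ns"),
        })
    joined = pd.DataFrame(rows, columns=["gene_id", "dmr_direction", "expr_direction"])
    table = (
        joined.groupby(["dmr_direction", "expr_direction"]).size()
        .unstack(fill_value=0)
        .reindex(index=["hyper", "hypo", "mixed"], columns=["up", "down", "ns"],
                 fill_value=0)
    )
    table.index.name = "dmr_direction"
    return table
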