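"""Triad building and negative-correlation classification.

A triad joins a differentially expressed gene (DEG) with the direction of
its associated DMR and the direction of a differentially expressed miRNA
(DER) predicted to target it. The "fully negative" pattern — the paper-of-
record's key-gene criterion for this kind of tri-omics design — is purely
directional: gene expression opposite to both its methylation change and
its targeting miRNA's change, i.e. (up, hypo, down) or (down, hyper, up).
"""
from __future__ import annotations

import logging

import pandas as pd

log = logging.getLogger(__name__)

LABELS = ("fully_negative", "meth_negative_only", "mirna_negative_only",
          "non_negative")

TRIAD_COLUMNS = ["gene_id", "gene_dir", "dmr_dir", "dmr_location",
                 "mirna_id", "mirna_dir", "label"]


def classify_negative(gene_dir: str, dmr_dir: str, mirna_dir: str) -> str:
    """Label one (gene, DMR, miRNA) direction tuple.

    Methylation anti-correlates when (gene up, DMR hypo) or (gene down, DMR
    hyper); the miRNA anti-correlates when its direction is opposite the
    gene's. Exactly one of the four labels applies to each of the 8 tuples.
    """
    if gene_dir not in ("up", "down"):
        raise ValueError(f"gene direction must be up/down, got {gene_dir!r}")
    if dmr_dir not in ("hyper", "hypo"):
        raise ValueError(f"DMR direction must be hyper/hypo, got {dmr_dir!r}")
    if mirna_dir not in ("up", "down"):
        raise ValueError(f"miRNA direction must be up/down, got {mirna_dir!r}")
    meth_neg = (gene_dir == "up") == (dmr_dir == "hypo")
    mirna_neg = gene_dir != mirna_dir
    if meth_neg and mirna_neg:
        return "fully_negative"
    if meth_neg:
        return "meth_negative_only"
    if mirna_neg:
        return "mirna_negative_only"
    return "non_negative"


def build_triads(degs: pd.DataFrame, gene_dmr_dirs: pd.DataFrame,
                 der_targets: pd.DataFrame) -> pd.DataFrame:
    """Join DEGs, per-gene DMR directions, and DER-target pairs into triads.

    ``degs``: feature_id + direction (up/down/ns). ``gene_dmr_dirs``: output
    of :func:`methtriad.annotate.gene_dmr_directions`. ``der_targets``: one
    row per (mirna_id, gene_id) predicted target pair with the miRNA's DER
    ``mirna_dir`` (up/down/ns). One triad per (gene, miRNA) pair where the
    gene is a DEG (up/down), has a non-mixed DMR direction, and the miRNA is
    a DER. Attrition at each join step is logged.
    """
    de_genes = degs[degs["direction"].isin(["up", "down"])]
    gene_dir = de_genes.set_index("feature_id")["direction"]
    n_mixed = int((gene_dmr_dirs["dmr_direction"] == "mixed").sum()) if len(gene_dmr_dirs) else 0
    meth = gene_dmr_dirs[gene_dmr_dirs["dmr_direction"].isin(["hyper", "hypo"])]
    meth_idx = meth.set_index("gene_id")
    pairs = der_targets[der_targets["mirna_dir"].isin(["up", "down"])]
    log.info("triad joins: %d DEGs, %d DMR-genes (%d mixed excluded), %d DER-target pairs",
             len(gene_dir), len(meth), n_mixed, len(pairs))
    rows = []
    for _, pair in pairs.iterrows():
        gid = pair["gene_id"]
        if gid not in gene_dir.index or gid not in meth_idx.index:
            continue
        gd, dd = gene_dir[gid], meth_idx.loc[gid, "dmr_direction"]
        rows.append({
            "gene_id": gid,
            "gene_dir": gd,
            "dmr_dir": dd,
            "dmr_location": meth_idx.loc[gid, "dmr_locations"],
            "mirna_id": pair["mirna_id"],
            "mirna_dir": pair["mirna_dir"],
            "label": classify_negative(gd, dd, pair["mirna_dir"]),
        })
    triads = pd.DataFrame(rows, columns=TRIAD_COLUMNS)
    log.info("built %d triads over %d genes (%d fully negative)",
             len(triads), triads["gene_id"].nunique() if len(triads) else 0,
             int((triads["label"] == "fully_negative").sum()) if len(triads) else 0)
    return triads


def key_gene_table(triads: pd.DataFrame) -> pd.DataFrame:
    """Deduplicated, deterministically sorted triad report.

    One row per (gene, miRNA); DMR locations of duplicate triads are joined.
    ``is_key_gene`` flags the fully-negative rows. Sorted by (label, gene,
    miRNA) so output is stable across runs.
    """
    if len(triads) == 0:
        return pd.DataFrame(columns=TRIAD_COLUMNS + ["is_key_gene"])
    rows = []
    for (gene, mirna), grp in triads.groupby(["gene_id", "mirna_id"], sort=True):
        locs = sorted({loc for cell in grp["dmr_location"] for loc in str(cell).split(",")})
        first = grp.iloc[0]
        rows.append({
            "gene_id": gene, "gene_dir": first["gene_dir"],
            "dmr_dir": first["dmr_dir"], "dmr_location": ",".join(locs),
            "mirna_id": mirna, "mirna_dir": first["mirna_dir"],
            "label": first["label"],
            "is_key_gene": first["label"] == "fully_negative",
        })
    out = pd.DataFrame(rows)
    return out.sort_values(["label", "gene_id", "mirna_id"]).reset_index(drop=True)
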