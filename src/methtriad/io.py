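"""Readers and writers for the external formats the pipeline touches.

Formats: 6-column cytosine report TSV (Bismark-CX-like, 1-based positions),
GFF3 gene models, BED6+ region files, and plain TSV tables. All conversions
between 1-based formats and the internal 0-based half-open convention happen
here and nowhere else.
"""
from __future__ import annotations

import logging
from pathlib import Path

import gffutils
import numpy as np
import pandas as pd

from .models import CONTEXTS, GeneModel

log = logging.getLogger(__name__)

CYTOSINE_COLUMNS = ["chrom", "pos", "strand", "context", "meth", "total"]


class ParseError(ValueError):
    """A malformed input line; the message names the offending line number."""


def read_cytosine_report(
    path: str | Path,
    sample_id: str | None = None,
    column_order: list[str] | None = None,
) -> pd.DataFrame:
    """Read per-cytosine methylation calls for one sample.

    The file is a headerless TSV with columns chrom, position (1-based),
    strand (+/-), context (CG/CHG/CHH), methylated read count, total read
    count. ``column_order`` remaps other dialects onto those names.

    Returns a DataFrame with columns chrom, pos (0-based), strand, context,
    meth, total and, when given, a ``sample_id`` column.
    """
    cols = column_order or CYTOSINE_COLUMNS
    if set(cols) != set(CYTOSINE_COLUMNS):
        raise ValueError(f"column_order must be a permutation of {CYTOSINE_COLUMNS}")
    try:
        df = pd.read_csv(
            path, sep="\t", header=None, names=cols, comment="#",
            dtype={"chrom": str, "strand": str, "context": str},
        )
    except pd.errors.EmptyDataError:
        df = pd.DataFrame(columns=CYTOSINE_COLUMNS)
    except (ValueError, pd.errors.ParserError) as exc:
        raise ParseError(f"{path}: {exc}") from exc
    df = df[CYTOSINE_COLUMNS]
    if len(df) == 0:
        log.warning("cytosine report %s is empty", path)
    _validate_calls(df, path)
    df = df.copy()
    df["pos"] = df["pos"].astype(np.int64) - 1  # to 0-based
    df["meth"] = df["meth"].astype(np.int64)
    df["total"] = df["total"].astype(np.int64)
    if sample_id is not None:
        df["sample_id"] = sample_id
    log.info("read %d cytosine calls from %s", len(df), path)
    return df


def _validate_calls(df: pd.DataFrame, path) -> None:
    def offender(mask, what):
        line = int(df.index[mask][0]) + 1
        raise ParseError(f"{path}, line {line}: {what}")

    if len(df) == 0:
        return
    for col in ("pos", "meth", "total"):
        bad = pd.to_numeric(df[col], errors="coerce").isna()
        if bad.any():
            offender(bad, f"non-numeric {col!r} field")
    if (df["pos"] < 1).any():
        offender(df["pos"] < 1, "position must be >= 1 (1-based)")
    bad_ctx = ~df["context"].isin(CONTEXTS)
    if bad_ctx.any():
        offender(bad_ctx, f"context must be one of {CONTEXTS}")
    bad_strand = ~df["strand"].isin(["+", "-"])
    if bad_strand.any():
        offender(bad_strand, "strand must be + or -")
    if (df["meth"] < 0).any() or (df["total"] < 0).any():
        offender((df["meth"] < 0) | (df["total"] < 0), "negative read count")
    bad = df["meth"] > df["total"]
    if bad.any():
        offender(bad, "meth_count exceeds total_count")


def write_cytosine_report(calls: pd.DataFrame, path: str | Path) -> None:
    """Inverse of :func:`read_cytosine_report` (positions back to 1-based)."""
    out = calls[CYTOSINE_COLUMNS].copy()
    out["pos"] = out["pos"] + 1
    out.to_csv(path, sep="\t", header=False, index=False)


def read_gff3_genes(path: str | Path) -> list[GeneModel]:
    """Parse gene and exon features from a GFF3 file into :class:`GeneModel`s.

    GFF3 coordinates are 1-based inclusive; the returned models are 0-based
    half-open. Genes without a usable strand are skipped with a warning; an
    exon outside its parent's span raises a validation error.
    """
    db = gffutils.create_db(
        str(path), ":memory:", merge_strategy="create_unique", keep_order=True
    )
    genes: list[GeneModel] = []
    for g in db.features_of_type("gene"):
        if g.strand not in ("+", "-"):
            log.warning("gene %s has no strand; skipped", g.id)
            continue
        exons = [
            (e.start - 1, e.end)
            for e in db.children(g, featuretype="exon", order_by="start")
        ]
        gene = GeneModel(
            gene_id=g.id, chrom=g.seqid, start=g.start - 1, end=g.end,
            strand=g.strand, exons=exons,
        )
        genes.append(gene)
    log.info("read %d genes from %s", len(genes), path)
    return genes


def write_gff3(genes: list[GeneModel], path: str | Path,
               chrom_lengths: dict[str, int] | None = None) -> None:
    """Write gene/exon models as GFF3 (back to 1-based inclusive)."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        if chrom_lengths:
            for chrom, ln in chrom_lengths.items():
                fh.write(f"##sequence-region {chrom} 1 {ln}\n")
        for g in sorted(genes, key=lambda x: (x.chrom, x.start)):
            fh.write(
                f"{g.chrom}\tmethtriad\tgene\t{g.start + 1}\t{g.end}\t.\t"
                f"{g.strand}\t.\tID={g.gene_id}\n"
            )
            for i, (s, e) in enumerate(g.exons, 1):
                fh.write(
                    f"{g.chrom}\tmethtriad\texon\t{s + 1}\t{e}\t.\t{g.strand}\t.\t"
                    f"ID={g.gene_id}.exon{i};Parent={g.gene_id}\n"
                )


def read_bed(path: str | Path) -> pd.DataFrame:
    """Read a BED file (>=3 columns) into chrom/start/end[/name/score/strand]."""
    names = ["chrom", "start", "end", "name", "score", "strand"]
    try:
        df = pd.read_csv(path, sep="\t", header=None, comment="#")
    except pd.errors.EmptyDataError:
        return pd.DataFrame(columns=names[:4])
    df.columns = names[: df.shape[1]] + list(df.columns[6:])
    return df


def write_bed(records: pd.DataFrame, path: str | Path) -> None:
    """Write DMRs (or plain intervals) as BED6+.

    Columns written: chrom, start, end, name, score (= -log10 q, capped at
    300), strand, then level_A, level_B, direction when present. Coordinates
    are already 0-based half-open, as BED expects.
    """
    df = records.copy()
    n = len(df)
    if "name" not in df:
        df["name"] = [f"region_{i+1}" for i in range(n)]
    if "q" in df:
        with np.errstate(divide="ignore"):
            score = -np.log10(df["q"].to_numpy(dtype=float))
        df["score"] = np.minimum(score, 300.0)
    elif "score" not in df:
        df["score"] = 0.0
    if "strand" not in df:
        df["strand"] = "."
    cols = ["chrom", "start", "end", "name", "score", "strand"]
    for extra in ("level_A", "level_B", "direction"):
        if extra in df:
            cols.append(extra)
    df[cols].to_csv(path, sep="\t", header=False, index=False)


def read_counts(path: str | Path) -> pd.DataFrame:
    """Read a features x samples count matrix (TSV, first column = feature id)."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    if (df.to_numpy() < 0).any():
        raise ParseError(f"{path}: negative counts")
    return df


def write_counts(counts: pd.DataFrame, path: str | Path) -> None:
    counts.to_csv(path, sep="\t", index_label="feature_id")


def read_target_pairs(path: str | Path) -> pd.DataFrame:
    """miRNA -> target gene pairs: TSV with columns mirna_id, gene_id."""
    df = pd.read_csv(path, sep="\t")
    missing = {"mirna_id", "gene_id"} - set(df.columns)
    if missing:
        raise ParseError(f"{path}: missing columns {sorted(missing)}")
    return df


def read_term_map(path: str | Path) -> pd.DataFrame:
    """gene -> annotation term pairs: TSV with columns gene_id, term_id."""
    df = pd.read_csv(path, sep="\t")
    missing = {"gene_id", "term_id"} - set(df.columns)
    if missing:
        raise ParseError(f"{path}: missing columns {sorted(missing)}")
    return df


def write_table(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t", index=False)
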