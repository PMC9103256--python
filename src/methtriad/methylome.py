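"""Genome-wide methylation summaries and regional profiles.

A cytosine's methylation level is the fraction of aligned reads supporting
methylation at that position. Summaries are kept per sequence context (CG,
CHG, CHH — plant methylation is tracked separately in each) and compared
between conditions with Fisher's exact test on methylated/unmethylated site
counts. Regional profiles average levels over named gene sub-features
(promoter thirds, exon/intron partition, downstream flank) and over a
fixed-bin metagene axis.
"""
from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import stats

from .models import CONTEXTS, GeneModel

log = logging.getLogger(__name__)

#: named regions of the regional profile, 5'->3' in transcription order
REGIONS = (
    "distal_promoter",
    "intermediate_promoter",
    "proximal_promoter",
    "first_exon",
    "first_intron",
    "internal_exon",
    "internal_intron",
    "last_exon",
    "last_intron",
    "downstream",
)


def site_level(meth: int, total: int) -> float:
    """Methylation level of one cytosine: supporting reads / total reads."""
    if total < 1:
        raise ValueError("site level undefined for total_count = 0")
    if not (0 <= meth <= total):
        raise ValueError("require 0 <= meth_count <= total_count")
    return meth / total


def methylated_mask(
    calls: pd.DataFrame,
    min_meth_reads: int = 1,
    binomial_rule: bool = False,
    error_rate: float = 0.005,
    alpha: float = 0.05,
) -> np.ndarray:
    """Boolean mask of calls counted as methylated cytosines (mCs).

    Default rule: at least ``min_meth_reads`` supporting reads. With
    ``binomial_rule`` the call must additionally reject a one-sided binomial
    test against a bisulfite conversion-error rate at level ``alpha``.
    """
    mask = calls["meth"].to_numpy() >= min_meth_reads
    if binomial_rule and mask.any():
        meth = calls["meth"].to_numpy()[mask]
        total = calls["total"].to_numpy()[mask]
        # P(X >= meth | Binomial(total, error_rate))
        pvals = stats.binom.sf(meth - 1, total, error_rate)
        sub = pvals < alpha
        idx = np.flatnonzero(mask)
        mask = np.zeros(len(calls), dtype=bool)
        mask[idx[sub]] = True
    return mask


def summarize_contexts(calls: pd.DataFrame, min_meth_reads: int = 1,
                       **mc_kwargs) -> pd.DataFrame:
    """Per-context site counts, mC counts, mC shares and mean levels.

    Returns one row per context plus a ``total`` row. ``mc_share`` is each
    context's fraction of all methylated cytosines; ``mean_level`` is the
    coverage-weighted mean level (pooled reads), so splitting one site's
    reads across two records does not change it.
    """
    rows = []
    is_mc = methylated_mask(calls, min_meth_reads=min_meth_reads, **mc_kwargs)
    total_mc = int(is_mc.sum())
    for ctx in CONTEXTS:
        sub = calls["context"] == ctx
        n_sites = int(sub.sum())
        n_mc = int((is_mc & sub.to_numpy()).sum())
        meth = int(calls.loc[sub, "meth"].sum())
        tot = int(calls.loc[sub, "total"].sum())
        rows.append({
            "context": ctx,
            "n_sites": n_sites,
            "n_methylated": n_mc,
            "mc_share": (n_mc / total_mc) if total_mc else 0.0,
            "mc_fraction_of_sites": (n_mc / n_sites) if n_sites else 0.0,
            "mean_level": (meth / tot) if tot else 0.0,
        })
    n_sites = len(calls)
    meth = int(calls["meth"].sum())
    tot = int(calls["total"].sum())
    rows.append({
        "context": "total",
        "n_sites": n_sites,
        "n_methylated": total_mc,
        "mc_share": 1.0 if total_mc else 0.0,
        "mc_fraction_of_sites": (total_mc / n_sites) if n_sites else 0.0,
        "mean_level": (meth / tot) if tot else 0.0,
    })
    return pd.DataFrame(rows)


def fisher_2x2(a: int, b: int, c: int, d: int) -> float:
    """Two-sided Fisher exact p for the table [[a, b], [c, d]].

    Exact two-sided p by the point-probability criterion: the sum of all
    hypergeometric table probabilities no larger than the observed table's.
    """
    if min(a, b, c, d) < 0:
        raise ValueError("table entries must be >= 0")
    if a + b + c + d == 0:
        raise ValueError("all-zero 2x2 table has no defined test")
    return float(stats.fisher_exact([[a, b], [c, d]], alternative="two-sided")[1])


def compare_context_counts(summary_a: pd.DataFrame, summary_b: pd.DataFrame) -> pd.DataFrame:
    """Fisher comparison of mC vs non-mC site counts between two samples.

    One row per context (and overall): the 2x2 table is
    (methylated sites, unmethylated sites) x (sample A, sample B).
    """
    rows = []
    for ctx in list(CONTEXTS) + ["total"]:
        ra = summary_a.set_index("context").loc[ctx]
        rb = summary_b.set_index("context").loc[ctx]
        a, b = int(ra["n_methylated"]), int(ra["n_sites"] - ra["n_methylated"])
        c, d = int(rb["n_methylated"]), int(rb["n_sites"] - rb["n_methylated"])
        p = fisher_2x2(a, b, c, d) if (a + b + c + d) else float("nan")
        rows.append({"context": ctx, "mc_A": a, "non_mc_A": b,
                     "mc_B": c, "non_mc_B": d, "p": p})
    return pd.DataFrame(rows)


def _promoter_thirds(flank: int) -> list[tuple[int, int]]:
    """Offsets of (distal, intermediate, proximal) promoter from the TSS.

    The upstream flank is cut into near-equal thirds; for the default 2 kb
    flank the widths are 667/666/667 bp.
    """
    b1 = round(flank / 3)       # 667
    b2 = round(2 * flank / 3)   # 1333
    return [(-flank, -b2), (-b2, -b1), (-b1, 0)]


def gene_region_intervals(gene: GeneModel, flank: int = 2000) -> dict[str, list[tuple[int, int]]]:
    """Genomic intervals of each named region of ``gene``, strand-aware.

    Regions that do not exist (e.g. internal exons of a 2-exon gene) are
    absent from the mapping. A single intron is classed ``first_intron``.
    """
    regions: dict[str, list[tuple[int, int]]] = {}
    if gene.strand == "+":
        for (off_s, off_e), name in zip(
            _promoter_thirds(flank),
            ("distal_promoter", "intermediate_promoter", "proximal_promoter"),
        ):
            s, e = gene.start + off_s, gene.start + off_e
            if e > max(s, 0):
                regions[name] = [(max(s, 0), e)]
        regions["downstream"] = [(gene.end, gene.end + flank)]
    else:
        # mirror: upstream flank sits to the right of the gene end
        for (off_s, off_e), name in zip(
            _promoter_thirds(flank),
            ("distal_promoter", "intermediate_promoter", "proximal_promoter"),
        ):
            s, e = gene.end - off_e, gene.end - off_s
            regions[name] = [(s, e)]
        if gene.start > 0:
            regions["downstream"] = [(max(gene.start - flank, 0), gene.start)]

    exons = gene.exons_transcription_order()
    introns = gene.introns_transcription_order()
    if exons:
        regions["first_exon"] = [exons[0]]
        if len(exons) >= 2:
            regions["last_exon"] = [exons[-1]]
        if len(exons) > 2:
            regions["internal_exon"] = exons[1:-1]
    if introns:
        regions["first_intron"] = [introns[0]]
        if len(introns) >= 2:
            regions["last_intron"] = [introns[-1]]
        if len(introns) > 2:
            regions["internal_intron"] = introns[1:-1]
    return regions


def _index_calls(calls: pd.DataFrame):
    """Per-chromosome sorted position arrays with meth/total, for fast slicing."""
    out = {}
    for chrom, sub in calls.groupby("chrom", sort=False):
        sub = sub.sort_values("pos")
        out[chrom] = (
            sub["pos"].to_numpy(np.int64),
            sub["meth"].to_numpy(np.int64),
            sub["total"].to_numpy(np.int64),
            sub["context"].to_numpy(),
        )
    return out


def regional_profile(
    calls: pd.DataFrame,
    genes: list[GeneModel],
    flank: int = 2000,
    sample_id: str | None = None,
) -> pd.DataFrame:
    """Coverage-weighted mean methylation per context per named gene region.

    Regions with no covered cytosine in any gene report NaN (missing), never
    zero. Returns a tidy frame: context, region, mean_level, n_sites.
    """
    idx = _index_calls(calls)
    acc_meth = {(c, r): 0 for c in CONTEXTS for r in REGIONS}
    acc_total = {(c, r): 0 for c in CONTEXTS for r in REGIONS}
    acc_n = {(c, r): 0 for c in CONTEXTS for r in REGIONS}
    for gene in genes:
        if gene.chrom not in idx:
            continue
        pos, meth, total, ctx = idx[gene.chrom]
        for region, ivs in gene_region_intervals(gene, flank).items():
            for (s, e) in ivs:
                lo, hi = np.searchsorted(pos, [s, e])
                if hi <= lo:
                    continue
                for context in CONTEXTS:
                    sel = ctx[lo:hi] == context
                    acc_meth[(context, region)] += int(meth[lo:hi][sel].sum())
                    acc_total[(context, region)] += int(total[lo:hi][sel].sum())
                    acc_n[(context, region)] += int(sel.sum())
    rows = []
    for context in CONTEXTS:
        for region in REGIONS:
            tot = acc_total[(context, region)]
            rows.append({
                "context": context,
                "region": region,
                "mean_level": (acc_meth[(context, region)] / tot) if tot else np.nan,
                "n_sites": acc_n[(context, region)],
            })
    df = pd.DataFrame(rows)
    if sample_id is not None:
        df.insert(0, "sample_id", sample_id)
    return df


def metagene_profile(
    calls: pd.DataFrame,
    genes: list[GeneModel],
    flank: int = 2000,
    flank_bins: int = 20,
    body_bins: int = 60,
    sample_id: str | None = None,
) -> pd.DataFrame:
    """Fixed-bin metagene curve: upstream flank, scaled gene body, downstream.

    Bin indices run 5'->3' in transcription order: 0..flank_bins-1 upstream,
    then body_bins body bins (fractional gene coordinates, so genes shorter
    than the bin count still contribute), then flank_bins downstream bins.
    Levels are coverage-weighted within bins.
    """
    n_bins = 2 * flank_bins + body_bins
    idx = _index_calls(calls)
    acc_meth = np.zeros((len(CONTEXTS), n_bins))
    acc_total = np.zeros((len(CONTEXTS), n_bins))
    ctx_row = {c: i for i, c in enumerate(CONTEXTS)}
    for gene in genes:
        if gene.chrom not in idx:
            continue
        pos, meth, total, ctx = idx[gene.chrom]
        lo, hi = np.searchsorted(pos, [gene.start - flank, gene.end + flank])
        if hi <= lo:
            continue
        p = pos[lo:hi]
        glen = gene.end - gene.start
        # signed distance in transcription direction
        if gene.strand == "+":
            upstream = p < gene.start
            body = (p >= gene.start) & (p < gene.end)
            downstream = p >= gene.end
            up_frac = (p - (gene.start - flank)) / flank
            body_frac = (p - gene.start) / glen
            down_frac = (p - gene.end) / flank
        else:
            upstream = p >= gene.end
            body = (p >= gene.start) & (p < gene.end)
            downstream = p < gene.start
            up_frac = ((gene.end + flank - 1) - p) / flank
            body_frac = ((gene.end - 1) - p) / glen
            down_frac = ((gene.start - 1) - p) / flank
        bins = np.empty(len(p), dtype=np.int64)
        bins[upstream] = np.clip((up_frac[upstream] * flank_bins).astype(int), 0, flank_bins - 1)
        bins[body] = flank_bins + np.clip(
            (body_frac[body] * body_bins).astype(int), 0, body_bins - 1)
        bins[downstream] = flank_bins + body_bins + np.clip(
            (down_frac[downstream] * flank_bins).astype(int), 0, flank_bins - 1)
        for context, row in ctx_row.items():
            sel = ctx[lo:hi] == context
            np.add.at(acc_meth[row], bins[sel], meth[lo:hi][sel])
            np.add.at(acc_total[row], bins[sel], total[lo:hi][sel])
    rows = []
    for context, row in ctx_row.items():
        with np.errstate(invalid="ignore"):
            levels = np.where(acc_total[row] > 0, acc_meth[row] / np.maximum(acc_total[row], 1), np.nan)
        for b in range(n_bins):
            rows.append({"context": context, "bin": b, "mean_level": levels[b]})
    df = pd.DataFrame(rows)
    if sample_id is not None:
        df.insert(0, "sample_id", sample_id)
    return df


def chromosome_bins(
    calls: pd.DataFrame,
    chrom_lengths: dict[str, int],
    bin_size: int = 100_000,
    sample_id: str | None = None,
) -> pd.DataFrame:
    """Per-chromosome binned mean levels per context (genome-landscape table)."""
    idx = _index_calls(calls)
    rows = []
    for chrom, ln in chrom_lengths.items():
        n_bins = int(np.ceil(ln / bin_size))
        if chrom not in idx:
            continue
        pos, meth, total, ctx = idx[chrom]
        bins = pos // bin_size
        for context in CONTEXTS:
            sel = ctx == context
            m = np.bincount(bins[sel], weights=meth[sel], minlength=n_bins)
            t = np.bincount(bins[sel], weights=total[sel], minlength=n_bins)
            with np.errstate(invalid="ignore"):
                lvl = np.where(t > 0, m / np.maximum(t, 1), np.nan)
            for b in range(n_bins):
                rows.append({
                    "chrom": chrom, "bin_start": b * bin_size,
                    "bin_end": min((b + 1) * bin_size, ln),
                    "context": context, "mean_level": lvl[b],
                })
    df = pd.DataFrame(rows)
    if sample_id is not None:
        df.insert(0, "sample_id", sample_id)
    return df
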