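"""Sliding-window differential-methylation-region (DMR) calling.

The genome is tiled with overlapping windows (default 1 kb sliding by
500 bp). Within each window the methylated/unmethylated read counts of the
two conditions are pooled over all cytosines of one context (both strands)
and compared with a two-sided Fisher exact test; Benjamini-Hochberg q-values
are computed per context over all tested windows. Windows survive when

* p < alpha_p and q < alpha_q,
* pooled read coverage >= min_window_coverage in each sample,
* |level difference| > min_level_diff percentage points (or, optionally,
  the level ratio exceeds that threshold), and
* fold change > fc_bounds[0] or < fc_bounds[1].

Surviving windows that overlap or touch, share context and direction, are
merged; merged counts are re-pooled over distinct cytosines so overlapping
windows never double-count a site.
"""
from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy.special import gammaln

from .config import PipelineConfig
from .methylome import fisher_2x2
from .models import CONTEXTS

log = logging.getLogger(__name__)

WINDOW_COLUMNS = [
    "chrom", "start", "end", "context",
    "meth_A", "total_A", "meth_B", "total_B",
    "level_A", "level_B", "p", "q",
]


def tile_windows(chrom_lengths: dict[str, int], window_size: int = 1000,
                 step_size: int = 500) -> pd.DataFrame:
    """Overlapping window tiling: starts at every multiple of ``step_size``
    below the chromosome length; windows are truncated at the chromosome end.
    """
    if not (window_size >= step_size > 0):
        raise ValueError("require window_size >= step_size > 0")
    rows = []
    for chrom, ln in chrom_lengths.items():
        starts = np.arange(0, ln, step_size, dtype=np.int64)
        ends = np.minimum(starts + window_size, ln)
        rows.append(pd.DataFrame({"chrom": chrom, "start": starts, "end": ends}))
    return pd.concat(rows, ignore_index=True) if rows else pd.DataFrame(
        columns=["chrom", "start", "end"])


def _pool_window_counts(calls: pd.DataFrame, windows: pd.DataFrame,
                        context: str) -> tuple[np.ndarray, np.ndarray]:
    """Pooled (meth, total) per window via prefix sums over sorted positions."""
    meth_out = np.zeros(len(windows), dtype=np.int64)
    total_out = np.zeros(len(windows), dtype=np.int64)
    if context == "combined":
        sub_all = calls
    else:
        sub_all = calls[calls["context"] == context]
    for chrom, sub in sub_all.groupby("chrom", sort=False):
        widx = np.flatnonzero((windows["chrom"] == chrom).to_numpy())
        if len(widx) == 0:
            continue
        sub = sub.sort_values("pos")
        pos = sub["pos"].to_numpy(np.int64)
        cm = np.concatenate([[0], np.cumsum(sub["meth"].to_numpy(np.int64))])
        ct = np.concatenate([[0], np.cumsum(sub["total"].to_numpy(np.int64))])
        lo = np.searchsorted(pos, windows["start"].to_numpy()[widx])
        hi = np.searchsorted(pos, windows["end"].to_numpy()[widx])
        meth_out[widx] = cm[hi] - cm[lo]
        total_out[widx] = ct[hi] - ct[lo]
    return meth_out, total_out


def fisher_2x2_batch(meth_a, total_a, meth_b, total_b,
                     chunk: int = 2000) -> np.ndarray:
    """Vectorized two-sided Fisher exact p for tables [[m_A, u_A], [m_B, u_B]].

    Same point-probability criterion as :func:`methtriad.methylome.fisher_2x2`
    (sum of hypergeometric probabilities not exceeding the observed table's,
    with SciPy's 1 + 1e-7 relative gate), computed by log-gamma enumeration
    over the shared support. Used for the per-window tests, where thousands
    of exact tests are needed.
    """
    ma = np.asarray(meth_a, dtype=np.int64)
    ta = np.asarray(total_a, dtype=np.int64)
    mb = np.asarray(meth_b, dtype=np.int64)
    tb = np.asarray(total_b, dtype=np.int64)
    out = np.empty(len(ma), dtype=float)
    for s in range(0, len(ma), chunk):
        sl = slice(s, min(s + chunk, len(ma)))
        out[sl] = _fisher_chunk(ma[sl], ta[sl], mb[sl], tb[sl])
    return out


def _fisher_chunk(ma, ta, mb, tb) -> np.ndarray:
    M = ta + tb          # grand total
    n = ma + mb          # methylated-column total
    K = ta               # sample-A row total
    lo = np.maximum(0, n - tb)
    hi = np.minimum(n, K)
    width = int((hi - lo).max()) + 1
    ks = lo[:, None] + np.arange(width)[None, :]
    valid = ks <= hi[:, None]
    ks = np.where(valid, ks, lo[:, None])
    const = (gammaln(K + 1) + gammaln(M - K + 1)
             + gammaln(n + 1) + gammaln(M - n + 1) - gammaln(M + 1))
    logpmf = (const[:, None]
              - gammaln(ks + 1) - gammaln(K[:, None] - ks + 1)
              - gammaln(n[:, None] - ks + 1)
              - gammaln((M - K)[:, None] - (n[:, None] - ks) + 1))
    logpmf = np.where(valid, logpmf, -np.inf)
    log_obs = np.take_along_axis(logpmf, (ma - lo)[:, None], axis=1)[:, 0]
    include = logpmf <= log_obs[:, None] + np.log1p(1e-7)
    p = np.exp(logpmf, where=include, out=np.zeros_like(logpmf)).sum(
        axis=1, where=include)
    return np.minimum(p, 1.0)


def window_test(windows: pd.DataFrame, calls_a: pd.DataFrame,
                calls_b: pd.DataFrame, context: str) -> pd.DataFrame:
    """Fisher-test pooled window counts of condition A (treatment) vs B.

    Windows with zero covered cytosines in either sample are dropped. The
    2x2 table per window is (meth, unmeth reads) x (A, B). q is BH over all
    tested windows (one family per call, i.e. per context).
    """
    if context not in CONTEXTS and context != "combined":
        raise ValueError(f"context must be one of {CONTEXTS} or 'combined'")
    ma, ta = _pool_window_counts(calls_a, windows, context)
    mb, tb = _pool_window_counts(calls_b, windows, context)
    keep = (ta > 0) & (tb > 0)
    if not keep.any():
        log.warning("no window with coverage in both samples (context=%s)", context)
        return pd.DataFrame(columns=WINDOW_COLUMNS)
    out = windows.loc[keep, ["chrom", "start", "end"]].reset_index(drop=True).copy()
    ma, ta, mb, tb = ma[keep], ta[keep], mb[keep], tb[keep]
    p = fisher_2x2_batch(ma, ta, mb, tb)
    out["context"] = context
    out["meth_A"], out["total_A"] = ma, ta
    out["meth_B"], out["total_B"] = mb, tb
    out["level_A"] = ma / ta
    out["level_B"] = mb / tb
    out["p"] = p
    out["q"] = bh_adjust(p)
    log.info("tested %d/%d windows (context=%s)", len(out), len(windows), context)
    return out[WINDOW_COLUMNS]


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (capped at 1)."""
    p = np.asarray(p_values, dtype=float)
    if p.ndim != 1:
        raise ValueError("expected a 1-d array of p-values")
    if len(p) == 0:
        return np.array([])
    if ((p < 0) | (p > 1)).any() or np.isnan(p).any():
        raise ValueError("p-values must lie in [0, 1]")
    m = len(p)
    order = np.argsort(p, kind="mergesort")
    ranked = p[order] * m / np.arange(1, m + 1)
    # enforce monotonicity from the largest p downwards
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.empty(m)
    q[order] = np.minimum(q_sorted, 1.0)
    return q


def _fold_change(level_a: float, level_b: float, floor: float) -> tuple[float, bool]:
    floored = level_b < floor
    return level_a / max(level_b, floor), floored


def _passes_filters(row, config: PipelineConfig) -> bool:
    hi, lo = config.fc_bounds
    delta = (row["level_A"] - row["level_B"]) * 100.0
    fc, _ = _fold_change(row["level_A"], row["level_B"], config.fc_floor)
    if config.level_filter == "difference":
        level_ok = abs(delta) > config.min_level_diff
    else:  # "ratio" reading of the same threshold
        ratio = max(fc, 1.0 / fc if fc > 0 else np.inf)
        level_ok = ratio > config.min_level_diff
    return bool(
        row["p"] < config.alpha_p
        and row["q"] < config.alpha_q
        and row["total_A"] >= config.min_window_coverage
        and row["total_B"] >= config.min_window_coverage
        and level_ok
        and (fc > hi or fc < lo)
    )


def filter_and_merge(stats: pd.DataFrame, calls_a: pd.DataFrame,
                     calls_b: pd.DataFrame, config: PipelineConfig) -> pd.DataFrame:
    """Apply the DMR filters and merge surviving windows into regions.

    Overlapping or adjacent surviving windows of the same chromosome,
    context and direction merge into one region. Counts for a merged region
    are re-pooled from the call tables over its span (each cytosine counted
    once); its p is re-computed by Fisher on those counts and its q is the
    smallest member-window q. ``delta`` is reported in percentage points.
    """
    if len(stats) == 0:
        return _empty_dmrs()
    kept = stats[[_passes_filters(r, config) for _, r in stats.iterrows()]].copy()
    log.info("DMR filters kept %d/%d windows", len(kept), len(stats))
    if len(kept) == 0:
        return _empty_dmrs()
    kept["direction"] = np.where(kept["level_A"] > kept["level_B"], "hyper", "hypo")
    kept = kept.sort_values(["chrom", "context", "direction", "start"])

    records = []
    for (chrom, context, direction), grp in kept.groupby(
            ["chrom", "context", "direction"], sort=False):
        cur_start, cur_end, n, qmin = None, None, 0, np.inf
        spans = []
        for _, row in grp.iterrows():
            if cur_start is None:
                cur_start, cur_end, n, qmin = row["start"], row["end"], 1, row["q"]
            elif row["start"] <= cur_end:  # overlap or adjacency
                cur_end = max(cur_end, row["end"])
                n += 1
                qmin = min(qmin, row["q"])
            else:
                spans.append((cur_start, cur_end, n, qmin))
                cur_start, cur_end, n, qmin = row["start"], row["end"], 1, row["q"]
        spans.append((cur_start, cur_end, n, qmin))
        for (s, e, n, qmin) in spans:
            records.append(_merged_record(
                chrom, int(s), int(e), context, direction, n, float(qmin),
                calls_a, calls_b, config))
    dmrs = pd.DataFrame(records)
    dmrs = dmrs.sort_values(["chrom", "start", "context"]).reset_index(drop=True)
    dmrs["name"] = [f"dmr_{i+1}" for i in range(len(dmrs))]
    return dmrs


def _merged_record(chrom, start, end, context, direction, n_windows, qmin,
                   calls_a, calls_b, config: PipelineConfig) -> dict:
    span = pd.DataFrame({"chrom": [chrom], "start": [start], "end": [end]})
    ma, ta = _pool_window_counts(calls_a, span, context)
    mb, tb = _pool_window_counts(calls_b, span, context)
    level_a = ma[0] / ta[0]
    level_b = mb[0] / tb[0]
    fc, floored = _fold_change(level_a, level_b, config.fc_floor)
    return {
        "chrom": chrom, "start": start, "end": end, "context": context,
        "meth_A": int(ma[0]), "total_A": int(ta[0]),
        "meth_B": int(mb[0]), "total_B": int(tb[0]),
        "level_A": level_a, "level_B": level_b,
        "delta": (level_a - level_b) * 100.0,
        "fold_change": fc, "fc_floored": floored,
        "direction": direction,
        "p": fisher_2x2(int(ma[0]), int(ta[0] - ma[0]), int(mb[0]), int(tb[0] - mb[0])),
        "q": qmin, "n_merged_windows": n_windows,
    }


def _empty_dmrs() -> pd.DataFrame:
    return pd.DataFrame(columns=[
        "chrom", "start", "end", "context", "meth_A", "total_A", "meth_B",
        "total_B", "level_A", "level_B", "delta", "fold_change", "fc_floored",
        "direction", "p", "q", "n_merged_windows", "name"])


def call_dmrs(calls_a: pd.DataFrame, calls_b: pd.DataFrame,
              chrom_lengths: dict[str, int], config: PipelineConfig,
              contexts: tuple[str, ...] = CONTEXTS) -> tuple[pd.DataFrame, pd.DataFrame]:
    """End-to-end DMR calling: tile, test per context, filter and merge.

    Returns ``(dmrs, window_stats)``; condition A is the treatment, so a
    hyper DMR is more methylated under treatment.
    """
    windows = tile_windows(chrom_lengths, config.window_size, config.step_size)
    stats = pd.concat(
        [window_test(windows, calls_a, calls_b, ctx) for ctx in contexts],
        ignore_index=True,
    )
    dmrs = filter_and_merge(stats, calls_a, calls_b, config)
    log.info("called %d DMRs from %d tested windows", len(dmrs), len(stats))
    return dmrs, stats
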