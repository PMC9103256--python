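"""Differential expression for small RNAs and mRNAs.

miRNAs: counts are CPM-normalized and tested per feature with a two-sided
t-test on log2(CPM + 1); significance is BH-adjusted q < alpha with no
fold-change filter. By default the test statistic uses empirical-Bayes
variance moderation with a mean-variance trend (the standard remedy for
3-replicate designs, where per-feature variance estimates at ~4 degrees of
freedom are too noisy for FDR control to retain power); a plain Welch test
is available via ``moderated=False``.

mRNAs: the canonical path ingests an externally produced differential-
expression table (e.g. an edgeR run) and applies the thresholds
|log2FC| > 1 (strict by default) and q < alpha; a built-in t-test stand-in
on log2(CPM + 1) exists for fully synthetic runs and is labelled as such in
its provenance column.
"""
from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import optimize, special, stats

from .config import PipelineConfig
from .dmr import bh_adjust

log = logging.getLogger(__name__)

RESULT_COLUMNS = [
    "feature_id", "mean_norm_A", "mean_norm_B", "log2fc", "p", "q",
    "direction", "provenance",
]


def cpm_normalize(counts: pd.DataFrame) -> pd.DataFrame:
    """Counts per million: each entry x 1e6 / its library (column) total."""
    if (counts.to_numpy() < 0).any():
        raise ValueError("counts must be nonnegative")
    totals = counts.sum(axis=0)
    zero = totals[totals == 0]
    if len(zero):
        raise ValueError(f"zero library total for sample(s): {list(zero.index)}")
    return counts * 1e6 / totals


def _split_groups(matrix: pd.DataFrame, groups: list[str]):
    """Split columns into (A, B) by sorted label; A is the treatment.

    The lexicographically first label is condition A, so swapping the two
    labels swaps the contrast (and negates log2fc downstream).
    """
    g = np.asarray(groups)
    labels = sorted(pd.unique(g))
    if len(labels) != 2:
        raise ValueError("need exactly two group labels")
    a, b = labels
    if (g == a).sum() < 2 or (g == b).sum() < 2:
        raise ValueError("need at least 2 replicates per group")
    return matrix.loc[:, g == a], matrix.loc[:, g == b]


def _moderated_t_pvalues(xa: np.ndarray, xb: np.ndarray) -> np.ndarray:
    """Two-sided p-values from an EB-moderated pooled-variance t statistic.

    Per-feature pooled variances are shrunk toward a quadratic trend of
    log-variance against average expression; the prior degrees of freedom
    d0 are estimated by method of moments on the trend residuals, and the
    reference distribution is t with d + d0 degrees of freedom.
    """
    na, nb = xa.shape[1], xb.shape[1]
    d = na + nb - 2
    ma, mb = xa.mean(axis=1), xb.mean(axis=1)
    s2 = (((xa - ma[:, None]) ** 2).sum(axis=1)
          + ((xb - mb[:, None]) ** 2).sum(axis=1)) / d
    amean = (xa.sum(axis=1) + xb.sum(axis=1)) / (na + nb)
    ok = s2 > 1e-12
    e = np.log(s2, out=np.zeros_like(s2), where=ok)
    if ok.sum() >= 10 and np.ptp(amean[ok]) > 1e-8:
        coef = np.polyfit(amean[ok], e[ok], 2)
        trend = np.polyval(coef, amean)
    else:
        trend = np.full_like(s2, e[ok].mean() if ok.any() else 0.0)
    # Method-of-moments fit of the scaled-F model for the residual spread
    evar = (e[ok] - trend[ok]).var(ddof=1) - special.polygamma(1, d / 2) \
        if ok.sum() >= 2 else -1.0
    if evar > 0:
        d0 = float(optimize.brentq(
            lambda x: special.polygamma(1, x / 2) - evar, 1e-2, 1e8))
        offset = special.polygamma(0, d0 / 2) - np.log(d0 / 2)
    else:
        d0, offset = np.inf, 0.0
    log_s02 = trend - (special.polygamma(0, d / 2) - np.log(d / 2)) + offset
    s02 = np.exp(log_s02)
    if np.isfinite(d0):
        s2_post = (d0 * s02 + d * s2) / (d0 + d)
        df_post = d + d0
    else:
        s2_post, df_post = s02, np.inf
    with np.errstate(divide="ignore", invalid="ignore"):
        t = (ma - mb) / np.sqrt(s2_post * (1.0 / na + 1.0 / nb))
    if np.isfinite(df_post):
        p = 2.0 * stats.t.sf(np.abs(t), df_post)
    else:
        p = 2.0 * stats.norm.sf(np.abs(t))
    return np.where(np.isnan(p), np.where(np.isclose(ma, mb), 1.0, 0.0), p)


def t_test_der(norm_matrix: pd.DataFrame, groups: list[str],
               config: PipelineConfig | None = None,
               log_transform: bool = True,
               moderated: bool = True) -> pd.DataFrame:
    """Per-feature t-test of condition A (first group label) vs B.

    ``norm_matrix`` holds CPM values; the test runs on log2(CPM + 1) unless
    ``log_transform`` is disabled. With ``moderated`` (default) the pooled
    variance is EB-shrunk toward a mean-variance trend; otherwise a plain
    Welch test is used. log2fc is computed from the normalized group means
    with a pseudocount of 1. Features with zero variance in both groups get
    p = 1 when the means are equal, else p = 0. Direction comes from
    q < alpha_q alone (no fold-change filter for small RNAs).
    """
    config = config or PipelineConfig()
    mat_a, mat_b = _split_groups(norm_matrix, groups)
    xa = np.log2(mat_a.to_numpy(float) + 1) if log_transform else mat_a.to_numpy(float)
    xb = np.log2(mat_b.to_numpy(float) + 1) if log_transform else mat_b.to_numpy(float)
    mean_a = mat_a.mean(axis=1).to_numpy()
    mean_b = mat_b.mean(axis=1).to_numpy()
    if moderated:
        p = _moderated_t_pvalues(xa, xb)
    else:
        with np.errstate(all="ignore"):
            _, p = stats.ttest_ind(xa, xb, axis=1, equal_var=False)
        degenerate = np.isnan(p)
        p = np.where(degenerate, np.where(np.isclose(mean_a, mean_b), 1.0, 0.0), p)
    q = bh_adjust(p)
    log2fc = np.log2((mean_a + 1) / (mean_b + 1))
    direction = np.where(q < config.alpha_q, np.where(log2fc > 0, "up", "down"), "ns")
    out = pd.DataFrame({
        "feature_id": norm_matrix.index,
        "mean_norm_A": mean_a, "mean_norm_B": mean_b,
        "log2fc": log2fc, "p": p, "q": q, "direction": direction,
        "provenance": "builtin-ttest",
    })
    log.info("DER test: %d/%d features significant (q < %g)",
             int((q < config.alpha_q).sum()), len(out), config.alpha_q)
    return out


def der_from_counts(counts: pd.DataFrame, groups: list[str],
                    config: PipelineConfig | None = None,
                    moderated: bool = True) -> pd.DataFrame:
    """CPM-normalize raw miRNA counts, then run :func:`t_test_der`."""
    return t_test_der(cpm_normalize(counts), groups, config, moderated=moderated)


def apply_deg_thresholds(de_table: pd.DataFrame,
                         config: PipelineConfig | None = None,
                         provenance: str = "external") -> pd.DataFrame:
    """Assign up/down/ns from an existing differential-expression table.

    Requires columns feature_id, log2fc, q. Direction is up when
    log2fc > deg_min_abs_log2fc and q < alpha_q (strict boundary by default,
    inclusive via ``deg_log2fc_inclusive``), down symmetrically, else ns.
    Idempotent: re-applying to its own output changes nothing.
    """
    config = config or PipelineConfig()
    missing = {"feature_id", "log2fc", "q"} - set(de_table.columns)
    if missing:
        raise ValueError(f"DE table missing columns: {sorted(missing)}")
    out = de_table.copy()
    thr = config.deg_min_abs_log2fc
    lfc = out["log2fc"].to_numpy(float)
    q = out["q"].to_numpy(float)
    if config.deg_log2fc_inclusive:
        up, down = lfc >= thr, lfc <= -thr
    else:
        up, down = lfc > thr, lfc < -thr
    sig = q < config.alpha_q
    out["direction"] = np.where(sig & up, "up", np.where(sig & down, "down", "ns"))
    if "provenance" not in out.columns:
        out["provenance"] = provenance
    return out


def deg_standin_test(counts: pd.DataFrame, groups: list[str],
                     config: PipelineConfig | None = None) -> pd.DataFrame:
    """Built-in mRNA differential-expression stand-in for synthetic runs.

    Moderated t on log2(CPM + 1) plus the standard DEG thresholds. This is
    NOT a negative-binomial GLM; results carry provenance
    ``builtin-standin`` so downstream consumers can tell them from an
    external (e.g. edgeR) table.
    """
    config = config or PipelineConfig()
    base = t_test_der(cpm_normalize(counts), groups, config)
    base["provenance"] = "builtin-standin"
    return apply_deg_thresholds(base, config, provenance="builtin-standin")


def fpkm(counts: pd.DataFrame, feature_lengths: pd.Series,
         library_totals: pd.Series | None = None) -> pd.DataFrame:
    """Fragments per kilobase per million: count x 1e9 / (length x library)."""
    lengths = feature_lengths.reindex(counts.index)
    if lengths.isna().any():
        missing = list(lengths.index[lengths.isna()][:5])
        raise ValueError(f"missing lengths for features: {missing}")
    if (lengths <= 0).any():
        raise ValueError("feature lengths must be > 0")
    totals = library_totals if library_totals is not None else counts.sum(axis=0)
    if (totals <= 0).any():
        raise ValueError("library totals must be > 0")
    return counts * 1e9 / np.outer(lengths, totals)
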