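"""Hypergeometric over-representation test with Bonferroni correction.

For a gene set of size n drawn from a background of N genes of which K
carry a term, the enrichment p is the upper tail P(X >= k) of
Hypergeometric(N, K, n). Terms with zero hits in the set are not tested and
do not enter the Bonferroni denominator.
"""
from __future__ import annotations

from collections.abc import Iterable

import pandas as pd
from scipy import stats


def hypergeom_enrich(
    gene_set: Iterable[str],
    background: Iterable[str],
    term_map: pd.DataFrame,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Test each term for over-representation in ``gene_set``.

    ``term_map`` has columns gene_id, term_id. Genes in the set must belong
    to the background. Returns rows sorted by p with columns term_id, k, n,
    K, N, p, p_bonf, significant.
    """
    genes = set(gene_set)
    bg = set(background)
    offenders = sorted(genes - bg)
    if offenders:
        raise ValueError(f"gene(s) not in background: {offenders}")
    tm = term_map[term_map["gene_id"].isin(bg)]
    N, n = len(bg), len(genes)
    rows = []
    for term, grp in tm.groupby("term_id", sort=True):
        members = set(grp["gene_id"])
        k = len(members & genes)
        if k == 0:
            continue  # untested, excluded from the correction count
        K = len(members)
        p = float(stats.hypergeom.sf(k - 1, N, K, n))
        rows.append({"term_id": term, "k": k, "n": n, "K": K, "N": N, "p": p})
    out = pd.DataFrame(rows, columns=["term_id", "k", "n", "K", "N", "p"])
    m = len(out)
    out["p_bonf"] = (out["p"] * m).clip(upper=1.0)
    out["significant"] = out["p_bonf"] < alpha
    return out.sort_values(["p", "term_id"]).reset_index(drop=True)
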