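"""Hypergeometric gene-set enrichment.

For a query of n genes drawn from a universe of N, a term covering K genes,
and an observed overlap of k, the enrichment p-value is the upper tail
P(X >= k) of Hypergeometric(N, K, n) — the chance of at least as large an
overlap under sampling without replacement.  Benjamini-Hochberg adjusted
p-values are reported alongside the raw ones.
"""

from __future__ import annotations

import logging
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from scipy.stats import hypergeom
from statsmodels.stats.multitest import multipletests

log = logging.getLogger(__name__)

__all__ = ["hypergeom_enrich", "adjust_bh"]


def adjust_bh(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (order-preserving)."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    if ((p < 0) | (p > 1)).any() or not np.isfinite(p).all():
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def hypergeom_enrich(
    query_genes: Iterable[str],
    annotations: Mapping[str, Iterable[str]],
    universe: Iterable[str],
) -> pd.DataFrame:
    """Exact upper-tail hypergeometric enrichment of a query against term sets.

    Query and term genes outside the universe are dropped with a warning.
    Returns a table sorted by raw p (ties by term) with columns
    term, N, K, n, k, p, p_adjusted.
    """
    universe = set(universe)
    if not universe:
        raise ValueError("empty universe")
    query = set(query_genes)
    outside = query - universe
    if outside:
        log.warning("dropping %d query genes outside the universe", len(outside))
        query &= universe
    if not query:
        raise ValueError("empty query after universe restriction")

    N, n = len(universe), len(query)
    rows = []
    for term, genes in annotations.items():
        term_genes = set(genes)
        out = term_genes - universe
        if out:
            log.warning("term %s: dropping %d genes outside the universe", term, len(out))
            term_genes &= universe
        K = len(term_genes)
        k = len(term_genes & query)
        # upper tail including the observed overlap: P(X >= k) = sf(k-1)
        p = float(hypergeom.sf(k - 1, N, K, n)) if K else 1.0
        rows.append((term, N, K, n, k, min(p, 1.0)))
    df = pd.DataFrame(rows, columns=["term", "N", "K", "n", "k", "p"])
    df["p_adjusted"] = adjust_bh(df["p"].to_numpy())
    return df.sort_values(["p", "term"], kind="stable").reset_index(drop=True)
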