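"""Drug-response filtering and gene-drug Spearman association.

Drugs are kept when they have at most ``max_missing`` missing GI50 entries
across the cell-line panel (the screening convention of "fewer than two
missing values").  For every surviving drug, Spearman's rank correlation is
computed between its normalized (-log10) GI50 profile and each gene's
expression over the pairwise-complete cell lines; genes with two-sided
p < alpha (either sign) form the drug's significant set.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

log = logging.getLogger(__name__)

__all__ = [
    "AssociationTable",
    "filter_drugs",
    "spearman_assoc",
    "spearman_perm_p",
    "select_significant",
]

MIN_COMPLETE_PAIRS = 4


@dataclass
class AssociationTable:
    """Gene x drug Spearman rho, two-sided p-values, and sample sizes used."""

    rho: pd.DataFrame
    p: pd.DataFrame
    n_used: pd.DataFrame

    def __post_init__(self):
        assert self.rho.shape == self.p.shape == self.n_used.shape


def filter_drugs(response: pd.DataFrame, max_missing: int = 1) -> pd.DataFrame:
    """Keep drugs with at most ``max_missing`` missing entries (NaN = missing)."""
    if response.empty:
        raise ValueError("empty drug response matrix")
    n_missing = response.isna().sum(axis=1)
    kept = response.loc[n_missing <= max_missing]
    log.info("drug filter: kept %d of %d drugs (max_missing=%d)", len(kept), len(response), max_missing)
    if kept.empty:
        raise ValueError("all drugs removed by the missing-value filter")
    return kept


def _spearman_one_drug(X: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Vectorized Spearman of every row of X against y (complete data).

    Ranks use average ties; p-values come from the t approximation
    t = rho * sqrt((n-2) / (1-rho^2)) with n-2 degrees of freedom.
    """
    n = y.size
    ry = stats.rankdata(y)
    RX = stats.rankdata(X, axis=1)
    RX = RX - RX.mean(axis=1, keepdims=True)
    ry = ry - ry.mean()
    denom = np.sqrt((RX**2).sum(axis=1) * (ry**2).sum())
    with np.errstate(invalid="ignore", divide="ignore"):
        rho = (RX @ ry) / denom
    rho = np.clip(rho, -1.0, 1.0)
    rho[denom == 0] = np.nan  # constant vector: undefined
    with np.errstate(invalid="ignore", divide="ignore"):
        t = rho * np.sqrt((n - 2) / (1.0 - rho**2))
    p = 2.0 * stats.t.sf(np.abs(t), df=n - 2)
    p[np.abs(rho) == 1.0] = 0.0  # perfect monotone: t diverges
    return rho, p


def spearman_assoc(expression: pd.DataFrame, response: pd.DataFrame) -> AssociationTable:
    """Spearman association of every gene with every drug.

    Missing GI50 cells are excluded pairwise (the gene vector is subset to the
    drug's complete cell lines).  Pairs with fewer than 4 complete
    observations are undefined (NaN rho, p) and never selected.
    """
    cells = [c for c in expression.columns if c in set(response.columns)]
    if len(cells) < MIN_COMPLETE_PAIRS:
        raise ValueError("fewer than 4 shared cell lines")
    X_full = expression[cells].to_numpy(dtype=float)
    R = response[cells]
    genes, drugs = expression.index, response.index
    rho = np.full((len(genes), len(drugs)), np.nan)
    pval = np.full_like(rho, np.nan)
    n_used = np.zeros(rho.shape, dtype=int)
    for j, d in enumerate(drugs):
        y = R.loc[d].to_numpy(dtype=float)
        mask = ~np.isnan(y)
        n = int(mask.sum())
        n_used[:, j] = n
        if n < MIN_COMPLETE_PAIRS:
            log.warning("drug %s has %d complete observations (<%d); associations undefined", d, n, MIN_COMPLETE_PAIRS)
            continue
        rho[:, j], pval[:, j] = _spearman_one_drug(X_full[:, mask], y[mask])
    mk = lambda a: pd.DataFrame(a, index=genes, columns=drugs)
    return AssociationTable(rho=mk(rho), p=mk(pval), n_used=mk(n_used))


def spearman_perm_p(x, y) -> float:
    """Exact two-sided permutation p-value for Spearman rho (n <= 8).

    Enumerates all n! orderings of y; used as an independent check of the
    t approximation on tiny samples.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = x.size
    if n > 8:
        raise ValueError("exact enumeration limited to n <= 8")
    obs = abs(stats.spearmanr(x, y).statistic)
    count = total = 0
    for perm in itertools.permutations(y):
        r = abs(stats.spearmanr(x, perm).statistic)
        count += r >= obs - 1e-12
        total += 1
    return count / total


def select_significant(assoc: AssociationTable, alpha: float = 0.05) -> dict[str, list]:
    """Per drug, the genes with two-sided p < alpha (both correlation signs)."""
    if not 0 <= alpha <= 1:
        raise ValueError("alpha must be in [0, 1]")
    out: dict[str, list] = {}
    for d in assoc.p.columns:
        p = assoc.p[d]
        out[d] = sorted(p.index[(p < alpha).fillna(False)])
    return out
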