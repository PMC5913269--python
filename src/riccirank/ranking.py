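"""Curvature-based drug ranking and linear-weight gene scoring.

Drugs are ordered by ascending mean scalar curvature of their significant
genes: a drug whose associated subnetwork is more negatively curved is, by
the curvature-robustness correspondence, attacking a more fragile part of
the network and ranks higher (rank 1 = lowest mean curvature).  With D
ranked drugs, every gene significant for the rank-r drug receives the linear
weight (D - r) + 1; a gene's score is the sum over its contributing drugs.
"""

from __future__ import annotations

import logging
from typing import Iterable, Mapping

import networkx as nx
import pandas as pd

log = logging.getLogger(__name__)

__all__ = [
    "drug_mean_curvature",
    "rank_drugs",
    "dedupe_drugs",
    "score_genes",
    "top_k",
    "path2_component",
]


def drug_mean_curvature(
    scalar_curvatures: Mapping[str, float], significant_sets: Mapping[str, Iterable[str]]
) -> dict[str, float]:
    """Mean node scalar curvature over each drug's significant genes.

    Genes outside the network are ignored (count logged); drugs left with an
    empty set are excluded with a warning.
    """
    means: dict[str, float] = {}
    n_outside = 0
    for drug, genes in significant_sets.items():
        inside = [g for g in genes if g in scalar_curvatures]
        n_outside += len(list(genes)) - len(inside)
        if not inside:
            log.warning("drug %s: no significant genes on the network; excluded from ranking", drug)
            continue
        means[drug] = sum(scalar_curvatures[g] for g in inside) / len(inside)
    if n_outside:
        log.info("ignored %d significant-gene entries outside the network", n_outside)
    return means


def rank_drugs(means: Mapping[str, float]) -> pd.DataFrame:
    """Rank drugs 1..D by ascending mean curvature; ties by drug_id."""
    if not means:
        raise ValueError("no drug has a defined mean curvature")
    df = pd.DataFrame(
        sorted(means.items(), key=lambda kv: (kv[1], kv[0])),
        columns=["drug_id", "mean_curvature"],
    )
    df.insert(0, "rank", range(1, len(df) + 1))
    return df


def dedupe_drugs(ranking: pd.DataFrame, drug_names: Mapping[str, str]) -> pd.DataFrame:
    """Collapse repeated drug names, keeping each name's best-ranked entry.

    Distinct screening identifiers can map to the same compound name; the
    representative is the entry with the numerically smallest rank, and the
    surviving rows are re-ranked 1..D' in the original order.
    """
    df = ranking.copy()
    df["drug_name"] = [drug_names.get(d, d) for d in df["drug_id"]]
    df = df.sort_values("rank", kind="stable").drop_duplicates("drug_name", keep="first")
    df = df.reset_index(drop=True)
    df["rank"] = range(1, len(df) + 1)
    return df[["rank", "drug_id", "drug_name", "mean_curvature"]]


def score_genes(
    ranking: pd.DataFrame, significant_sets: Mapping[str, Iterable[str]]
) -> pd.DataFrame:
    """Linear rank-weight gene scores.

    The rank-r drug (of D) contributes weight (D - r) + 1 to each of its
    significant genes; scores are summed and the table is sorted descending,
    ties broken by gene id.
    """
    D = len(ranking)
    weight = {row.drug_id: (D - row.rank) + 1 for row in ranking.itertuples()}
    totals: dict[str, int] = {}
    counts: dict[str, int] = {}
    for drug, genes in significant_sets.items():
        if drug not in weight:
            continue
        for g in genes:
            totals[g] = totals.get(g, 0) + weight[drug]
            counts[g] = counts.get(g, 0) + 1
    df = pd.DataFrame(
        {"gene": list(totals), "total_weight": list(totals.values()),
         "n_contributing_drugs": [counts[g] for g in totals]}
    )
    return df.sort_values(
        ["total_weight", "gene"], ascending=[False, True], kind="stable"
    ).reset_index(drop=True)


def top_k(gene_scores: pd.DataFrame, k: int = 200) -> list[str]:
    """First k genes of the descending score table (deterministic tie rule)."""
    if k > len(gene_scores):
        raise ValueError(f"k={k} exceeds the {len(gene_scores)} scored genes")
    if k < len(gene_scores) and (
        gene_scores["total_weight"].iloc[k - 1] == gene_scores["total_weight"].iloc[k]
    ):
        log.info("score tie at the top-%d boundary; lexicographically smaller gene ids retained", k)
    return gene_scores["gene"].iloc[:k].tolist()


def path2_component(topology: nx.Graph, gene_set: Iterable[str]) -> set[str]:
    """Largest subset of ``gene_set`` mutually connected by paths of length <= 2.

    Two members are linked when their hop distance through the *full* network
    is at most 2 (the intermediate node need not belong to the set); the
    largest connected component of that auxiliary graph is returned, ties
    broken by lexicographic member order.
    """
    members = sorted(set(gene_set))
    if not members:
        return set()
    missing = [g for g in members if g not in topology]
    if missing:
        raise ValueError(f"genes not in network: {missing[:5]}")
    aux = nx.Graph()
    aux.add_nodes_from(members)
    member_set = set(members)
    for g in members:
        reach = nx.single_source_shortest_path_length(topology, g, cutoff=2)
        for h in reach:
            if h != g and h in member_set:
                aux.add_edge(g, h)
    comps = sorted(nx.connected_components(aux), key=lambda c: (-len(c), sorted(c)))
    if len(comps) > 1:
        log.warning("path-2 graph has %d components; returning the largest", len(comps))
    return set(comps[0])
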