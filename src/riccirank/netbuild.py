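"""Construction of the correlation-weighted pre-treatment network.

Expression rows are aggregated probe-to-gene by arithmetic mean, intersected
with an interaction topology, restricted to the largest connected component,
and each surviving edge (i, j) is weighted by the affine transform

    w_ij = (1 + corr(i, j)) / 2

of the Pearson correlation of the two genes' expression across cell lines.
The transform maps [-1, 1] onto [0, 1] and is invertible (corr = 2w - 1), so
no sign information is lost, unlike taking absolute values.
"""

from __future__ import annotations

import logging
from typing import Mapping

import networkx as nx
import numpy as np
import pandas as pd

log = logging.getLogger(__name__)

__all__ = ["aggregate_probes", "weight_transform", "build_network"]

_CORR_TOL = 1e-9  # slack for float round-off beyond [-1, 1]


def aggregate_probes(probe_matrix: pd.DataFrame, probe_to_gene: Mapping[str, str]) -> pd.DataFrame:
    """Collapse a probe x cell-line matrix to gene level.

    Each gene's row is the arithmetic mean of its probes' rows; probes absent
    from the map (no known gene name) are dropped.
    """
    if not probe_to_gene:
        raise ValueError("probe_to_gene map is empty")
    if not np.isfinite(probe_matrix.to_numpy()).all():
        raise ValueError("probe matrix contains non-finite values")
    named = probe_matrix.index.intersection(list(probe_to_gene))
    dropped = probe_matrix.shape[0] - len(named)
    if dropped:
        log.info("dropped %d probes without a gene name", dropped)
    if len(named) == 0:
        raise ValueError("no probe in the matrix has a mapped gene name")
    sub = probe_matrix.loc[named]
    genes = pd.Index([probe_to_gene[p] for p in named], name="gene")
    return sub.groupby(genes, sort=True).mean()


def weight_transform(pearson_corr):
    """Affine map of a correlation in [-1, 1] to an edge weight in [0, 1]."""
    c = np.asarray(pearson_corr, dtype=float)
    if not np.isfinite(c).all():
        raise ValueError("correlation must be finite")
    if (np.abs(c) > 1.0 + _CORR_TOL).any():
        raise ValueError("correlation outside [-1, 1]")
    w = (1.0 + np.clip(c, -1.0, 1.0)) / 2.0
    return float(w) if np.isscalar(pearson_corr) else w


def build_network(expression: pd.DataFrame, topology: nx.Graph) -> nx.Graph:
    """Weighted pre-treatment network from expression and an interaction topology.

    Nodes are the largest connected component of the topology restricted to
    genes that (a) appear in the expression matrix and (b) have nonzero
    expression variance (Pearson is undefined for constant rows; such genes
    are dropped with a logged warning).  Each retained edge carries
    ``weight_transform(Pearson over all cell lines)``.  Filter counts are
    recorded in ``G.graph["provenance"]``.
    """
    if expression.shape[1] < 2:
        raise ValueError("need at least 2 cell lines to correlate")
    if expression.index.has_duplicates:
        raise ValueError("duplicate gene ids in expression (aggregate probes first)")
    if expression.isna().any().any():
        raise ValueError("expression matrix must be complete")

    topo_genes = set(topology.nodes)
    shared = [g for g in expression.index if g in topo_genes]
    n_topo_only = len(topo_genes) - len(shared)
    n_expr_only = expression.shape[0] - len(shared)
    if len(shared) < 2:
        raise ValueError("fewer than 2 genes shared between expression and topology")

    values = expression.loc[shared]
    variances = values.var(axis=1, ddof=0)
    zero_var = variances[variances == 0.0].index.tolist()
    if zero_var:
        log.warning("dropping %d zero-variance genes before correlation", len(zero_var))
    kept = [g for g in shared if g not in set(zero_var)]

    sub = topology.subgraph(kept)
    components = sorted(nx.connected_components(sub), key=lambda c: (-len(c), sorted(c)))
    if not components or len(components[0]) < 2:
        raise ValueError("largest connected component has fewer than 2 nodes")
    lcc = sorted(components[0])
    n_outside_lcc = len(kept) - len(lcc)

    X = expression.loc[lcc].to_numpy(dtype=float)
    corr = np.corrcoef(X)
    idx = {g: i for i, g in enumerate(lcc)}

    G = nx.Graph()
    G.add_nodes_from(lcc)
    for u, v in topology.subgraph(lcc).edges:
        G.add_edge(u, v, weight=weight_transform(corr[idx[u], idx[v]]))
    G.graph["provenance"] = {
        "n_topology_genes": len(topo_genes),
        "n_expression_genes": int(expression.shape[0]),
        "n_shared": len(shared),
        "n_topology_only": n_topo_only,
        "n_expression_only": n_expr_only,
        "n_zero_variance_dropped": len(zero_var),
        "n_outside_lcc_dropped": n_outside_lcc,
        "n_nodes": G.number_of_nodes(),
        "n_edges": G.number_of_edges(),
    }
    return G
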