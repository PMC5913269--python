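"""Readers and writers for the pipeline's plain-text formats.

All tables are TSV.  Expression: genes x cell lines with a header row of
cell-line ids.  Topology: two-column edge list.  Response: drugs x cell
lines with empty cells for missing GI50.  Annotations: GMT lines
(term, description, genes...).  Networks: weighted edge-list TSV (and
GraphML); numeric output is serialized with 10 significant digits.
"""

from __future__ import annotations

import json
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd

FLOAT_FMT = "%.10g"


def write_expression(expr: pd.DataFrame, path) -> None:
    expr.to_csv(path, sep="\t", float_format=FLOAT_FMT, index_label="gene")


def read_expression(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col=0)


def write_topology(G: nx.Graph, path) -> None:
    with open(path, "w") as fh:
        fh.write("gene_a\tgene_b\n")
        for u, v in sorted(tuple(sorted(e)) for e in G.edges):
            fh.write(f"{u}\t{v}\n")


def read_topology(path) -> nx.Graph:
    df = pd.read_csv(path, sep="\t", dtype=str)
    G = nx.Graph()
    G.add_edges_from(df.itertuples(index=False, name=None))
    return G


def write_response(resp: pd.DataFrame, path) -> None:
    # empty cell = missing GI50
    resp.to_csv(path, sep="\t", float_format=FLOAT_FMT, index_label="drug_id", na_rep="")


def read_response(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col=0)


def write_tissues(labels: dict, path) -> None:
    with open(path, "w") as fh:
        fh.write("cell_line\ttissue\n")
        for c in labels:
            fh.write(f"{c}\t{labels[c]}\n")


def read_tissues(path) -> dict:
    df = pd.read_csv(path, sep="\t", dtype=str)
    return dict(zip(df["cell_line"], df["tissue"]))


def write_gmt(annotations: dict, path) -> None:
    with open(path, "w") as fh:
        for term in annotations:
            genes = "\t".join(sorted(annotations[term]))
            fh.write(f"{term}\tsynthetic\t{genes}\n")


def read_gmt(path) -> dict:
    out = {}
    with open(path) as fh:
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if len(parts) >= 3:
                out[parts[0]] = set(parts[2:])
    return out


def write_network(G: nx.Graph, path_tsv, path_graphml=None) -> None:
    with open(path_tsv, "w") as fh:
        fh.write("gene_a\tgene_b\tweight\n")
        for u, v in sorted(tuple(sorted(e)) for e in G.edges):
            fh.write(f"{u}\t{v}\t{G[u][v]['weight']:.10g}\n")
    if path_graphml is not None:
        H = nx.Graph()  # strip provenance dict: GraphML wants scalar attributes
        H.add_nodes_from(G.nodes)
        H.add_weighted_edges_from((u, v, float(G[u][v]["weight"])) for u, v in G.edges)
        nx.write_graphml(H, path_graphml)


def read_network(path) -> nx.Graph:
    df = pd.read_csv(path, sep="\t", dtype={"gene_a": str, "gene_b": str})
    G = nx.Graph()
    for row in df.itertuples(index=False):
        G.add_edge(row.gene_a, row.gene_b, weight=float(row.weight))
    return G


def write_curvature(edge_curv: dict, scalar_curv: dict, degrees: dict, prefix) -> None:
    prefix = Path(prefix)
    with open(f"{prefix}_edges.tsv", "w") as fh:
        fh.write("gene_a\tgene_b\tcurvature\n")
        for (u, v) in sorted(edge_curv):
            fh.write(f"{u}\t{v}\t{edge_curv[(u, v)]:.10g}\n")
    with open(f"{prefix}_nodes.tsv", "w") as fh:
        fh.write("gene\tscalar_curvature\tdegree\n")
        for g in sorted(scalar_curv):
            fh.write(f"{g}\t{scalar_curv[g]:.10g}\t{degrees[g]}\n")


def read_scalar_curvature(path) -> dict:
    df = pd.read_csv(path, sep="\t", dtype={"gene": str})
    return dict(zip(df["gene"], df["scalar_curvature"]))


def write_gene_list(genes, path) -> None:
    with open(path, "w") as fh:
        for g in genes:
            fh.write(f"{g}\n")


def read_gene_list(path) -> list:
    with open(path) as fh:
        return [line.strip() for line in fh if line.strip()]


def write_json(obj, path) -> None:
    def _default(o):
        if isinstance(o, (set, frozenset)):
            return sorted(o)
        if isinstance(o, (np.integer,)):
            return int(o)
        if isinstance(o, (np.floating,)):
            return float(o)
        raise TypeError(f"not JSON serializable: {type(o)}")

    with open(path, "w") as fh:
        json.dump(obj, fh, indent=1, sort_keys=True, default=_default)
        fh.write("\n")


def read_json(path):
    with open(path) as fh:
        return json.load(fh)
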