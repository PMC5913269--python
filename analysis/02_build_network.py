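#!/usr/bin/env python
"""Build the correlation-weighted pre-treatment network.

Intersects the expression genes with the interaction topology, keeps the
largest connected component, and weights each edge by (1 + Pearson r) / 2.
"""

import argparse
from pathlib import Path

from riccirank import io as rio
from riccirank.netbuild import build_network


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--data", type=Path, default=Path("results/data"))
    ap.add_argument("--out", type=Path, default=Path("results/analysis"))
    args = ap.parse_args()

    expr = rio.read_expression(args.data / "expression.tsv")
    topo = rio.read_topology(args.data / "topology.tsv")
    G = build_network(expr, topo)
    args.out.mkdir(parents=True, exist_ok=True)
    rio.write_network(G, args.out / "network.tsv", args.out / "network.graphml")
    rio.write_json(G.graph["provenance"], args.out / "network_provenance.json")

    prov = G.graph["provenance"]
    print(f"network: {prov['n_nodes']} genes, {prov['n_edges']} edges "
          f"(dropped {prov['n_zero_variance_dropped']} zero-variance, "
          f"{prov['n_outside_lcc_dropped']} outside the largest component)")


if __name__ == "__main__":
    main()
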