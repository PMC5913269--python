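"""Synthetic NCI-60-like datasets for exercising the pipeline end to end.

The generator emulates the statistical structure the analysis assumes, not
any particular biology:

* a connected scale-free-like interaction topology (preferential attachment)
  or an explicit modular block topology;
* block-structured positive co-expression from a latent-factor model: gene g
  in module m has expression x_g = lambda * f_m + eps across cell lines,
  with f_m ~ N(0,1) per cell line and eps ~ N(0, noise_sd^2), giving a known
  within-module population correlation lambda^2 / (lambda^2 + noise_sd^2);
* drug response that is a noisy linear (hence monotone) function of the mean
  expression of each drug's planted target genes, with sporadic independent
  missingness;
* annotation terms drawn uniformly from the gene universe, plus one planted
  term that coincides with the planted signal genes.

A single master seed drives everything; per-stage substreams are derived
deterministically so each stage can be regenerated independently.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd

__all__ = [
    "SyntheticConfig",
    "SyntheticDataset",
    "make_topology",
    "make_expression",
    "make_drug_response",
    "make_annotations",
    "make_dataset",
    "make_fragility_benchmark",
    "make_duplicated_tissue_dataset",
]

# substream tags, combined with the master seed
_TOPO, _EXPR, _RESP, _ANNOT, _TISSUE = 11, 13, 17, 19, 23


def _rng(seed: int, stage: int) -> np.random.Generator:
    return np.random.default_rng([int(seed), stage])


def _gene_ids(n: int) -> list[str]:
    width = max(4, len(str(n)))
    return [f"G{i:0{width}d}" for i in range(n)]


@dataclass
class SyntheticConfig:
    """Study conditions for the synthetic panel (defaults mirror an NCI-60-like design)."""

    n_genes: int = 800
    n_cell_lines: int = 58
    n_tissues: int = 9
    topology_model: str = "preferential_attachment"
    attachment_m: int = 2
    n_modules: int = 8
    module_loading: float = 1.0  # latent-factor loading lambda
    noise_sd: float = 1.0
    n_drugs: int = 30
    targets_per_drug: int = 3
    effect_size: float = 1.0  # beta
    response_noise_sd: float = 0.5
    missing_rate: float = 0.02
    n_terms: int = 20
    seed: int = 0

    def validate(self) -> None:
        if self.n_genes < 2:
            raise ValueError("n_genes must be >= 2")
        if self.n_cell_lines < 4:
            raise ValueError("n_cell_lines must be >= 4")
        for name in ("module_loading", "noise_sd", "effect_size", "response_noise_sd"):
            v = getattr(self, name)
            if not np.isfinite(v) or (name != "effect_size" and v < 0):
                raise ValueError(f"{name} must be finite and non-negative")
        if not 0 <= self.missing_rate <= 1:
            raise ValueError("missing_rate must be in [0, 1]")
        if self.attachment_m >= self.n_genes:
            raise ValueError("attachment_m must be < n_genes")


@dataclass
class SyntheticDataset:
    expression: pd.DataFrame  # genes x cell lines, complete
    topology: nx.Graph
    response: pd.DataFrame  # drugs x cell lines, NaN = missing
    tissue_labels: dict[str, str]
    drug_names: dict[str, str]
    annotations: dict[str, set]
    truth: dict


def make_topology(
    n_genes: int,
    topology_model: str = "preferential_attachment",
    attachment_m: int = 2,
    n_modules: int = 4,
    seed: int = 0,
) -> nx.Graph:
    """Undirected simple connected interaction topology on string gene ids.

    ``preferential_attachment`` grows a Barabasi-Albert graph: m seed nodes,
    each of the remaining n - m nodes attaches with m edges, hence exactly
    m * (n - m) edges.  ``modular_blocks`` builds dense Erdos-Renyi blocks
    joined into a ring of bridges (each node carries a ``module`` attribute);
    connectivity is enforced by an in-block path.
    """
    if n_genes < 2:
        raise ValueError("n_genes must be >= 2")
    if attachment_m < 1 or attachment_m >= n_genes:
        raise ValueError("need 1 <= attachment_m < n_genes")
    ids = _gene_ids(n_genes)
    rng = _rng(seed, _TOPO)
    if topology_model == "preferential_attachment":
        G0 = nx.barabasi_albert_graph(n_genes, attachment_m, seed=int(rng.integers(2**31)))
        G = nx.relabel_nodes(G0, dict(enumerate(ids)))
    elif topology_model == "modular_blocks":
        G = nx.Graph()
        G.add_nodes_from(ids)
        blocks = np.array_split(np.arange(n_genes), n_modules)
        for b, block in enumerate(blocks):
            members = [ids[i] for i in block]
            for g in members:
                G.nodes[g]["module"] = b
            for i in range(len(members) - 1):  # in-block path keeps the block connected
                G.add_edge(members[i], members[i + 1])
            p_in = 0.3
            for i in range(len(members)):
                for j in range(i + 2, len(members)):
                    if rng.random() < p_in:
                        G.add_edge(members[i], members[j])
        for b in range(len(blocks)):  # ring of bridges between consecutive blocks
            u = ids[blocks[b][0]]
            v = ids[blocks[(b + 1) % len(blocks)][0]]
            if u != v:
                G.add_edge(u, v)
    else:
        raise ValueError(f"unknown topology_model {topology_model!r}")
    assert nx.is_connected(G)
    return G


def _module_partition(topology: nx.Graph, n_modules: int) -> dict[str, int]:
    """Module labels: node attributes if present, else contiguous chunks of sorted ids."""
    attrs = nx.get_node_attributes(topology, "module")
    if attrs:
        return attrs
    nodes = sorted(topology.nodes)
    chunks = np.array_split(np.arange(len(nodes)), n_modules)
    return {nodes[i]: m for m, chunk in enumerate(chunks) for i in chunk}


def make_expression(
    topology: nx.Graph,
    n_cell_lines: int,
    n_modules: int = 8,
    module_loading: float = 1.0,
    noise_sd: float = 1.0,
    seed: int = 0,
) -> tuple[pd.DataFrame, dict[str, int]]:
    """Latent-factor expression matrix and the module membership used.

    x_g = lambda * f_{m(g)} + eps with f per (module, cell line) standard
    normal and eps ~ N(0, noise_sd^2), so two genes of one module have
    population Pearson correlation lambda^2 / (lambda^2 + noise_sd^2) and
    genes of different modules are independent.
    """
    if n_modules < 1:
        raise ValueError("n_modules must be >= 1")
    if noise_sd == 0 and module_loading == 0:
        raise ValueError("noise_sd = 0 and loading = 0 give constant expression")
    rng = _rng(seed, _EXPR)
    genes = sorted(topology.nodes)
    modules = _module_partition(topology, n_modules)
    cells = [f"CL{i:02d}" for i in range(n_cell_lines)]
    n_mod = max(modules.values()) + 1
    F = rng.standard_normal((n_mod, n_cell_lines))
    X = module_loading * F[[modules[g] for g in genes], :]
    X = X + noise_sd * rng.standard_normal((len(genes), n_cell_lines))
    return pd.DataFrame(X, index=pd.Index(genes, name="gene"), columns=cells), modules


def make_drug_response(
    expression: pd.DataFrame,
    n_drugs: int = 30,
    targets_per_drug: int = 3,
    effect_size: float = 1.0,
    response_noise_sd: float = 0.5,
    missing_rate: float = 0.02,
    seed: int = 0,
    targets: Mapping[str, Sequence[str]] | None = None,
) -> tuple[pd.DataFrame, dict[str, list[str]]]:
    """Drug x cell-line response matrix plus the planted target truth.

    response(d, c) = beta * mean(expression of d's targets at c) + eta with
    eta ~ N(0, response_noise_sd^2); entries are masked missing independently
    with probability ``missing_rate``.  Explicit ``targets`` override random
    draws (used by benchmark fixtures).
    """
    if missing_rate >= 1:
        raise ValueError("missing_rate = 1 leaves no observations")
    if targets_per_drug < 1:
        raise ValueError("targets_per_drug must be >= 1")
    rng = _rng(seed, _RESP)
    genes = list(expression.index)
    cells = list(expression.columns)
    if targets is None:
        drug_ids = [f"D{i:03d}" for i in range(n_drugs)]
        targets = {
            d: sorted(rng.choice(genes, size=targets_per_drug, replace=False)) for d in drug_ids
        }
    else:
        targets = {d: sorted(t) for d, t in targets.items()}
        missing_genes = {g for t in targets.values() for g in t} - set(genes)
        if missing_genes:
            raise ValueError(f"target genes absent from expression: {sorted(missing_genes)[:5]}")
    rows = []
    for d in targets:
        signal = expression.loc[targets[d]].mean(axis=0).to_numpy()
        eta = response_noise_sd * rng.standard_normal(len(cells))
        rows.append(effect_size * signal + eta)
    R = pd.DataFrame(rows, index=pd.Index(list(targets), name="drug_id"), columns=cells)
    if missing_rate > 0:
        mask = rng.random(R.shape) < missing_rate
        R = R.mask(mask)
    return R, {d: list(t) for d, t in targets.items()}


def make_annotations(
    gene_universe: Sequence[str],
    n_terms: int = 20,
    term_size_range: tuple[int, int] = (10, 40),
    planted_set: Iterable[str] = (),
    seed: int = 0,
) -> tuple[dict[str, set], dict]:
    """Random annotation terms plus one planted term equal to ``planted_set``."""
    universe = sorted(set(gene_universe))
    planted = sorted(set(planted_set))
    if set(planted) - set(universe):
        raise ValueError("planted_set must be a subset of the universe")
    lo, hi = term_size_range
    if hi > len(universe):
        raise ValueError("term size range exceeds the universe")
    rng = _rng(seed, _ANNOT)
    annotations: dict[str, set] = {}
    truth_flags: dict[str, bool] = {}
    if planted:
        annotations["TERM_PLANTED"] = set(planted)
        truth_flags["TERM_PLANTED"] = True
    for i in range(n_terms):
        size = int(rng.integers(lo, hi + 1))
        term = f"TERM{i:03d}"
        annotations[term] = set(rng.choice(universe, size=size, replace=False))
        truth_flags[term] = False
    return annotations, {"enriched": truth_flags}


def _assign_tissues(cells: Sequence[str], n_tissues: int) -> dict[str, str]:
    return {c: f"T{i % n_tissues}" for i, c in enumerate(cells)}


def make_dataset(config: SyntheticConfig) -> SyntheticDataset:
    """Full synthetic panel: topology, expression, response, tissues, annotations, truth."""
    config.validate()
    topo = make_topology(
        config.n_genes, config.topology_model, config.attachment_m, config.n_modules, config.seed
    )
    expr, modules = make_expression(
        topo, config.n_cell_lines, config.n_modules, config.module_loading, config.noise_sd, config.seed
    )
    resp, targets = make_drug_response(
        expr,
        config.n_drugs,
        config.targets_per_drug,
        config.effect_size,
        config.response_noise_sd,
        config.missing_rate,
        config.seed,
    )
    planted = sorted({g for t in targets.values() for g in t})
    annotations, annot_truth = make_annotations(
        list(expr.index), config.n_terms, (10, max(11, config.n_genes // 20)), planted, config.seed
    )
    tissues = _assign_tissues(list(expr.columns), config.n_tissues)
    return SyntheticDataset(
        expression=expr,
        topology=topo,
        response=resp,
        tissue_labels=tissues,
        drug_names={d: d for d in resp.index},
        annotations=annotations,
        truth={"modules": modules, "targets": targets, **annot_truth},
    )


def make_fragility_benchmark(
    seed: int = 0,
    n_tree: int = 40,
    clique_size: int = 10,
    n_cell_lines: int = 58,
    noise_sd: float = 0.7,
    effect_size: float = 1.5,
    response_noise_sd: float = 0.3,
) -> tuple[SyntheticDataset, str, str]:
    """Two-drug recovery benchmark: fragile tree region vs dense clique.

    The topology is a preferential-attachment tree (negatively curved, sparse)
    bridged to a clique (positively curved, dense).  Expression follows one
    latent factor per region; drug ``D_TREE`` targets tree genes and
    ``D_CLIQUE`` targets clique genes, so each drug's significant genes fall
    in its own region.  A curvature ranking that tracks network fragility
    must place ``D_TREE`` ahead of ``D_CLIQUE``.

    Returns (dataset, fragile_drug_id, clique_drug_id).
    """
    rng = _rng(seed, _TOPO)
    tree = nx.barabasi_albert_graph(n_tree, 1, seed=int(rng.integers(2**31)))
    ids = _gene_ids(n_tree + clique_size)
    G = nx.relabel_nodes(tree, {i: ids[i] for i in range(n_tree)})
    clique_ids = ids[n_tree:]
    G.add_edges_from(
        (clique_ids[i], clique_ids[j]) for i in range(clique_size) for j in range(i + 1, clique_size)
    )
    G.add_edge(ids[0], clique_ids[0])  # bridge
    for g in ids[:n_tree]:
        G.nodes[g]["module"] = 0
    for g in clique_ids:
        G.nodes[g]["module"] = 1
    expr, _ = make_expression(G, n_cell_lines, 2, 1.0, noise_sd, seed)
    targets = {"D_CLIQUE": clique_ids[1:4], "D_TREE": ids[1:4]}
    resp, targets = make_drug_response(
        expr, effect_size=effect_size, response_noise_sd=response_noise_sd,
        missing_rate=0.0, seed=seed, targets=targets,
    )
    tissues = _assign_tissues(list(expr.columns), 2)
    ds = SyntheticDataset(
        expression=expr, topology=G, response=resp, tissue_labels=tissues,
        drug_names={d: d for d in resp.index}, annotations={},
        truth={"targets": targets, "fragile_drug": "D_TREE", "clique_drug": "D_CLIQUE"},
    )
    return ds, "D_TREE", "D_CLIQUE"


def _near_orthogonal_rank_factors(
    n_factors: int,
    n_cells: int,
    rng: np.random.Generator,
    max_abs_rho: float = 0.15,
    batch: int = 4000,
) -> np.ndarray:
    """Latent factors (permutations of 0..n-1) with small pairwise Spearman.

    Spearman is the Pearson correlation of ranks, so the pairwise constraint
    |rho| <= max_abs_rho is a bound on centered dot products of permutations;
    candidates are drawn in batches until one satisfies it against every
    accepted factor.  A |rho| this small stays far below any p < 0.05
    critical value for the sample sizes the duplicated-tissue fixture uses.
    """
    center = (n_cells - 1) / 2.0
    ss = n_cells * (n_cells * n_cells - 1) / 12.0  # sum of squared centered ranks
    max_dot = max_abs_rho * ss
    factors: list[np.ndarray] = [rng.permutation(n_cells).astype(float)]
    while len(factors) < n_factors:
        accepted = np.array(factors) - center
        for _ in range(200):
            cand = rng.permuted(
                np.tile(np.arange(n_cells, dtype=float), (batch, 1)), axis=1
            )
            dots = (cand - center) @ accepted.T
            hits = np.flatnonzero((np.abs(dots) <= max_dot).all(axis=1))
            if hits.size:
                factors.append(cand[hits[0]])
                break
        else:
            raise RuntimeError(
                f"no near-orthogonal permutation found for factor {len(factors)} "
                f"with n_cells={n_cells}; try a larger n_cells or max_abs_rho"
            )
    return np.array(factors)


def make_duplicated_tissue_dataset(
    seed: int = 0,
    n_tissues: int = 4,
    block_size: int = 12,
    module_size: int = 30,
    module_densities: Sequence[float] = (0.0, 0.3, 0.7, 1.0),
) -> SyntheticDataset:
    """Panel whose tissue blocks are exact copies of one base block.

    Every tissue's cell lines replicate the same expression and response
    columns, so leaving any one tissue out leaves statistically identical
    data — the fixture for ranking-stability checks.  One noise-free drug
    targets each module, and the module latent factors are built with
    mutually orthogonal rank vectors, so every gene-drug Spearman correlation
    is exactly +/-1 (own module) or exactly 0 (other modules).  Significance
    calls are then invariant to the sample-size change an exclusion causes
    (a p-value threshold moves with n, but 0 and 1 correlations cannot cross
    it), and the ranking is identical for every exclusion.  Module edge
    densities are graded path-like through near-complete so the drugs' mean
    scalar curvatures genuinely differ.
    """
    n_modules = len(module_densities)
    n_genes = n_modules * module_size
    ids = _gene_ids(n_genes)
    rng = _rng(seed, _TOPO)
    topo = nx.Graph()
    topo.add_nodes_from(ids)
    modules: dict[str, int] = {}
    for b, p_in in enumerate(module_densities):
        members = ids[b * module_size : (b + 1) * module_size]
        for g in members:
            topo.nodes[g]["module"] = b
            modules[g] = b
        for i in range(module_size - 1):  # spanning path keeps each block connected
            topo.add_edge(members[i], members[i + 1])
        for i in range(module_size):
            for j in range(i + 2, module_size):
                if rng.random() < p_in:
                    topo.add_edge(members[i], members[j])
    for b in range(n_modules - 1):  # bridge consecutive blocks
        topo.add_edge(ids[b * module_size], ids[(b + 1) * module_size])
    assert nx.is_connected(topo)

    F = _near_orthogonal_rank_factors(n_modules, block_size, rng)
    cells = [f"CL{i:02d}" for i in range(block_size)]
    base_expr = pd.DataFrame(
        F[[modules[g] for g in ids], :], index=pd.Index(ids, name="gene"), columns=cells
    )
    genes_by_module: dict[int, list[str]] = {}
    for g, m in modules.items():
        genes_by_module.setdefault(m, []).append(g)
    targets = {f"D{m:03d}": sorted(genes_by_module[m])[:3] for m in range(n_modules)}
    base_resp, targets = make_drug_response(
        base_expr, effect_size=2.0, response_noise_sd=0.0, missing_rate=0.0,
        seed=seed, targets=targets,
    )
    expr_blocks, resp_blocks, tissue_labels = [], [], {}
    for t in range(n_tissues):
        cols = [f"T{t}_CL{i:02d}" for i in range(block_size)]
        expr_blocks.append(base_expr.set_axis(cols, axis=1))
        resp_blocks.append(base_resp.set_axis(cols, axis=1))
        tissue_labels.update({c: f"T{t}" for c in cols})
    expr = pd.concat(expr_blocks, axis=1)
    resp = pd.concat(resp_blocks, axis=1)
    return SyntheticDataset(
        expression=expr, topology=topo, response=resp, tissue_labels=tissue_labels,
        drug_names={d: d for d in resp.index}, annotations={},
        truth={"modules": modules, "targets": targets},
    )
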