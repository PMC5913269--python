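"""End-to-end orchestration and leave-one-tissue-out validation.

``analyze`` runs the full chain in memory: correlation-weighted network,
Ollivier-Ricci edge and scalar curvature, GI50 completeness filter,
gene-drug Spearman associations, significance selection, ascending
mean-curvature drug ranking, duplicate-name collapse, linear-weight gene
scores, top-K genes, their path-length-2 core, and (optionally)
hypergeometric enrichment.

``loo_rankings`` repeats the whole chain once per tissue, each time dropping
every cell line of that tissue, and correlates the resulting drug-rank
vectors with each other and with the all-lines ranking — the stability
check for whether any single tissue drives the ranking.
"""

from __future__ import annotations

import hashlib
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd
import yaml
from scipy import stats

from . import io as rio
from .curvature import compute_curvature, scalar_curvature
from .drugassoc import filter_drugs, select_significant, spearman_assoc
from .enrich import hypergeom_enrich
from .netbuild import build_network
from .ranking import (
    dedupe_drugs,
    drug_mean_curvature,
    path2_component,
    rank_drugs,
    score_genes,
    top_k,
)

log = logging.getLogger(__name__)

__all__ = [
    "PipelineConfig",
    "PipelineError",
    "LooResult",
    "analyze",
    "loo_rankings",
    "ranking_correlation_matrix",
    "run_pipeline",
]


class PipelineError(RuntimeError):
    """A stage failed; the message names the stage and the cause."""


@dataclass
class PipelineConfig:
    """Paths and thresholds for one pipeline run (YAML round-trippable)."""

    expression: str = ""
    topology: str = ""
    response: str = ""
    tissues: str = ""
    annotations: str = ""  # optional GMT
    alpha: float = 0.05
    max_missing: int = 1
    top_k: int = 200
    ground_distance: str = "hop"
    seed: int = 0
    outdir: str = "results/pipeline"

    def validate(self) -> None:
        if not 0 <= self.alpha <= 1:
            raise ValueError("alpha must be in [0, 1]")
        if self.max_missing < 0 or self.top_k < 1:
            raise ValueError("max_missing >= 0 and top_k >= 1 required")
        if self.ground_distance not in ("hop", "weighted"):
            raise ValueError("ground_distance must be 'hop' or 'weighted'")

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            return cls(**yaml.safe_load(fh))


def _stage(name, fn, *args, **kwargs):
    try:
        return fn(*args, **kwargs)
    except Exception as exc:
        raise PipelineError(f"stage '{name}' failed: {exc}") from exc


def analyze(
    expression: pd.DataFrame,
    topology: nx.Graph,
    response: pd.DataFrame,
    drug_names: dict | None = None,
    annotations: dict | None = None,
    alpha: float = 0.05,
    max_missing: int = 1,
    top_k_genes: int = 200,
    ground_distance: str = "hop",
) -> dict:
    """Run the full analysis in memory and return every artifact.

    Associations are computed on the network's genes (the universe of the
    analysis); ``top_k_genes`` is clamped to the number of scored genes on
    small inputs (logged).
    """
    network = _stage("network", build_network, expression, topology)
    edge_curv = _stage("curvature", compute_curvature, network, ground_distance)
    scalar = scalar_curvature(network, edge_curv)

    filtered = _stage("drug-filter", filter_drugs, response, max_missing)
    net_expr = expression.loc[sorted(network.nodes)]
    assoc = _stage("association", spearman_assoc, net_expr, filtered)
    sig_sets = select_significant(assoc, alpha)

    means = drug_mean_curvature(scalar, sig_sets)
    ranking = _stage("rank", rank_drugs, means)
    names = drug_names or {}
    deduped = dedupe_drugs(ranking, names)
    scores = score_genes(ranking, sig_sets)
    k = min(top_k_genes, len(scores))
    if k < top_k_genes:
        log.info("top_k clamped from %d to %d scored genes", top_k_genes, k)
    top = top_k(scores, k) if k else []
    core = path2_component(network, top) if top else set()

    enrichment = None
    if annotations:
        enrichment = _stage(
            "enrichment", hypergeom_enrich, top, annotations, sorted(network.nodes)
        )
    return {
        "network": network,
        "edge_curvature": edge_curv,
        "scalar_curvature": scalar,
        "association": assoc,
        "significant_sets": sig_sets,
        "drug_mean_curvature": means,
        "ranking": ranking,
        "ranking_deduped": deduped,
        "gene_scores": scores,
        "top_genes": top,
        "path2_core": core,
        "enrichment": enrichment,
    }


@dataclass
class LooResult:
    labels: list  # tissues plus "All"
    rankings: dict  # label -> ranking DataFrame
    correlation_matrix: pd.DataFrame
    p_matrix: pd.DataFrame
    skipped: list = field(default_factory=list)


def ranking_correlation_matrix(rankings: dict[str, pd.DataFrame]) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Pairwise Spearman correlation of drug-rank vectors over the common drugs."""
    if len(rankings) < 2:
        raise ValueError("need at least 2 rankings")
    common = set.intersection(*(set(r["drug_id"]) for r in rankings.values()))
    if len(common) < 4:
        raise ValueError("common drug set smaller than 4")
    common = sorted(common)
    vectors = {
        lbl: r.set_index("drug_id").loc[common, "rank"].to_numpy() for lbl, r in rankings.items()
    }
    labels = list(rankings)
    n = len(labels)
    C = np.eye(n)
    P = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            res = stats.spearmanr(vectors[labels[i]], vectors[labels[j]])
            C[i, j] = C[j, i] = res.statistic
            P[i, j] = P[j, i] = res.pvalue
    mk = lambda a: pd.DataFrame(a, index=labels, columns=labels)
    return mk(C), mk(P)


def loo_rankings(
    expression: pd.DataFrame,
    topology: nx.Graph,
    response: pd.DataFrame,
    tissue_labels: dict,
    alpha: float = 0.05,
    max_missing: int = 1,
    ground_distance: str = "hop",
    min_cells: int = 4,
) -> LooResult:
    """Leave-one-tissue-out drug rankings and their Spearman correlation map.

    The drug list is frozen from the all-lines completeness filter so rank
    vectors are comparable; the entire chain (network weights, curvature,
    associations, ranking) is recomputed on the remaining cell lines for
    each exclusion.  Exclusions leaving fewer than ``min_cells`` lines are
    skipped with a warning.  The full-data inputs are never mutated.
    """
    tissues = sorted(set(tissue_labels.values()))
    if len(tissues) < 2:
        raise ValueError("need at least 2 tissues")
    frozen = filter_drugs(response, max_missing)

    def _rank_on(cells: list[str]) -> pd.DataFrame:
        net = build_network(expression[cells], topology)
        scalar = scalar_curvature(net, compute_curvature(net, ground_distance))
        assoc = spearman_assoc(expression.loc[sorted(net.nodes), cells], frozen[cells])
        sig = select_significant(assoc, alpha)
        return rank_drugs(drug_mean_curvature(scalar, sig))

    all_cells = [c for c in expression.columns if c in tissue_labels]
    rankings: dict[str, pd.DataFrame] = {}
    skipped = []
    for t in tissues:
        cells = [c for c in all_cells if tissue_labels[c] != t]
        if len(cells) < min_cells:
            log.warning("excluding tissue %s leaves %d cell lines (<%d); skipped", t, len(cells), min_cells)
            skipped.append(t)
            continue
        rankings[f"w/o {t}"] = _rank_on(cells)
    rankings["All"] = _rank_on(all_cells)
    C, P = ranking_correlation_matrix(rankings)
    return LooResult(labels=list(rankings), rankings=rankings,
                     correlation_matrix=C, p_matrix=P, skipped=skipped)


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_pipeline(config: PipelineConfig, loo: bool = True) -> dict:
    """File-level driver: read inputs, analyze, optionally LOO, write artifacts.

    Emits the network, curvature tables, association matrices, drug rankings,
    gene scores, top-K list, path-2 core, enrichment (when annotations are
    supplied), the LOO correlation matrix, and a provenance manifest
    (config, seed, content hashes).  Outputs are deterministic: a rerun with
    the same config is byte-identical.
    """
    config.validate()
    expression = rio.read_expression(config.expression)
    topology = rio.read_topology(config.topology)
    response = rio.read_response(config.response)
    tissue_labels = rio.read_tissues(config.tissues) if config.tissues else {}
    annotations = rio.read_gmt(config.annotations) if config.annotations else None

    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    art = analyze(
        expression, topology, response,
        annotations=annotations, alpha=config.alpha, max_missing=config.max_missing,
        top_k_genes=config.top_k, ground_distance=config.ground_distance,
    )

    net = art["network"]
    rio.write_network(net, out / "network.tsv", out / "network.graphml")
    rio.write_curvature(
        art["edge_curvature"], art["scalar_curvature"], dict(net.degree()), out / "curvature"
    )
    art["association"].rho.to_csv(out / "spearman_rho.tsv", sep="\t", float_format="%.10g")
    art["association"].p.to_csv(out / "spearman_p.tsv", sep="\t", float_format="%.10g")
    rio.write_json({d: g for d, g in art["significant_sets"].items()}, out / "significant_sets.json")
    art["ranking"].to_csv(out / "drug_ranking.tsv", sep="\t", index=False, float_format="%.10g")
    art["ranking_deduped"].to_csv(out / "drug_ranking_deduped.tsv", sep="\t", index=False, float_format="%.10g")
    art["gene_scores"].to_csv(out / "gene_scores.tsv", sep="\t", index=False)
    rio.write_gene_list(art["top_genes"], out / "top_genes.txt")
    rio.write_gene_list(sorted(art["path2_core"]), out / "path2_core.txt")
    if art["enrichment"] is not None:
        art["enrichment"].to_csv(out / "enrichment.tsv", sep="\t", index=False, float_format="%.10g")

    if loo and tissue_labels:
        res = _stage(
            "loo", loo_rankings, expression, topology, response, tissue_labels,
            config.alpha, config.max_missing, config.ground_distance,
        )
        res.correlation_matrix.to_csv(out / "loo_correlation.tsv", sep="\t", float_format="%.10g")
        res.p_matrix.to_csv(out / "loo_pvalues.tsv", sep="\t", float_format="%.10g")
        art["loo"] = res

    files = sorted(p.name for p in out.iterdir() if p.is_file() and p.name != "manifest.json")
    manifest = {
        "config": asdict(config),
        "seed": config.seed,
        "provenance": net.graph.get("provenance", {}),
        "artifacts": {name: _sha256(out / name) for name in files},
    }
    rio.write_json(manifest, out / "manifest.json")
    art["manifest"] = manifest
    return art
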