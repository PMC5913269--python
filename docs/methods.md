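# Methods

## Curvature model

The analysis treats the gene interaction network as a discrete metric
measure space.  Nodes are genes; the topology comes from a curated
interaction database (or a synthetic stand-in); edge weights are
co-expression derived.  Each node x carries the neighbour measure
μ_x(y) = w_xy / d_x with d_x = Σ_z w_xz — no mass is left on x itself
(no laziness/idleness parameter).  The Ollivier-Ricci curvature of an edge
is k(x,y) = 1 − W₁(μ_x, μ_y)/d(x,y) and the scalar curvature of a node is
the plain (unweighted) sum of its incident edge curvatures.

The justification for reading curvature as robustness is the chain from
large-deviation rate functions through entropy to Ricci curvature lower
bounds: both robustness and curvature correlate positively with entropy, so
negatively curved regions of the network are the fragile ones.  Only the
discrete curvature itself is computed here; the continuous theory motivates
but contributes no code.

**Ground distance.** Hop count (shortest path in edge count) is the
default, so d(x,y) = 1 for every existing edge and k has the familiar
[−2, 1] range for adjacent nodes.  A `weighted` mode (Dijkstra with the
edge weight as length, the convention of existing discrete-curvature
implementations) is available behind a flag; results in this package's
analyses all use hop distance.

**Transport solver.** W₁ is solved exactly as the transportation linear
program (HiGHS via `scipy.optimize.linprog`), one LP per edge, supports
being the two neighbour sets.  A second, independent exact route — scaling
rational masses to a common denominator, splitting each measure into equal
atoms, and solving the resulting assignment problem with the Hungarian
algorithm — is kept as `wasserstein1_assignment` and used by the tests to
cross-check the LP on random graphs with small integer weights (atom counts
explode for generic float masses, which is why the LP is primary).  Both
marginals are enforced to 1e−9; curvature values are kept at full float
precision and serialized with 10 significant digits.

Zero-weight edges (perfectly anti-correlated genes) stay in the topology —
they still count for hop distances — but contribute zero mass to neighbour
measures, and their atoms are dropped from measure supports.

## Network construction

Probe-level expression collapses to genes by the arithmetic mean of each
gene's probes; probes without a gene name are dropped.  The network's node
set is the largest connected component of the topology restricted to genes
present in expression; the Pearson correlation of each retained edge's two
genes across all cell lines is mapped through w = (1 + r)/2, which is
invertible (r = 2w − 1) and therefore loses no sign information.

Genes with zero expression variance have no defined Pearson correlation;
they are removed before correlation with a logged count.  The component is
taken *after* that filter so the final network is connected and all ground
distances are finite.  Gene identifiers are opaque case-sensitive strings.
Dropped-gene counts at each filter are recorded in the network's provenance
block and in the manifest.

## Associations, ranking, scoring

Drugs with more than `max_missing = 1` missing GI50 entries are discarded
(the "fewer than two missing values" screening rule).  Spearman's rho per
(gene, drug) uses average-rank ties and pairwise-complete observations
(a missing GI50 cell removes that cell line from both vectors); two-sided
p-values come from the t approximation t = ρ√((n−2)/(1−ρ²)) with ρ = ±1
mapped to p = 0.  An exact permutation p (full enumeration, n ≤ 8) exists
for testing the approximation.  Pairs with fewer than 4 complete
observations are undefined and never selected.  Selection keeps genes with
p < α = 0.05, both signs, with no multiple-testing correction — the raw
threshold is the analysis convention being studied; α is a config value.

A drug's summary statistic is the arithmetic mean of the *node scalar
curvatures* of its significant genes (genes outside the network are ignored
with a logged count; a drug whose set empties is excluded with a warning
rather than given a sentinel).  Drugs sort ascending — most negative mean
curvature first — with ties broken by drug identifier.  Duplicate drug
names (distinct screening IDs for one compound) collapse to the best-ranked
entry, and ranks are re-issued 1..D′.  Gene scores use the
*pre-deduplication* D-drug ranking: the rank-r drug contributes (D − r) + 1
to each of its significant genes.  Ties in gene scores and in component
choices break lexicographically, so every output is deterministic.

"Mutually connected by paths of length two" is implemented as: build an
auxiliary graph on the top-gene set with an edge where the hop distance
through the *full* network is ≤ 2 (the intermediate node need not be a top
gene), and return its largest connected component.

## Enrichment

Upper-tail hypergeometric p per term, including the observed overlap
(P(X ≥ k) = sf(k−1)), with the network's gene set as the default universe
(configurable).  Benjamini-Hochberg adjusted values are reported alongside;
report ordering uses the raw p, mirroring the analysis convention the
pipeline studies.

## Leave-one-tissue-out validation

The drug list is frozen by the all-lines completeness filter, then for each
tissue the *entire* chain — network weights, curvature, associations,
ranking — is recomputed on the remaining cell lines.  Rank vectors are
compared by Spearman correlation over the common drug set (the pre-dedup
drug-id ranking; identifiers are unique so name collapse is irrelevant
here).  An exclusion that would leave fewer than 4 cell lines is skipped
with a warning.  LOO runs never mutate the full-data inputs.

Note that p-value thresholds move with the sample size: excluding a tissue
lowers n, so a gene whose correlation sits near the critical value can
enter or leave a significant set even when the correlations themselves are
unchanged.  Exact rank stability under exclusion therefore requires
associations far from the threshold, which is how the duplicated-tissue
stability fixture is built (below).

## Synthetic data

The generator reproduces the statistical shape of a tumor cell-line panel:

* **Topology** — preferential attachment (Barabási-Albert, default
  m = 2: growth from m seed nodes, m edges per new node, hence m(n−m)
  edges) for a connected scale-free-like graph, or explicit modular blocks
  with per-block Erdős-Rényi density, an in-block path for connectivity and
  bridges between blocks.
* **Expression** — latent-factor co-expression: gene g in module m has
  x_g = λ f_m + ε with f_m per cell line standard normal and
  ε ~ N(0, σ²), so within-module population correlation is λ²/(λ²+σ²)
  (0.5 at the defaults λ = σ = 1) and cross-module genes are independent.
* **Drug response** — GI50-like activity β·mean(target expression) + η,
  a noisy monotone function of the planted targets' expression, with
  independent Bernoulli missingness (default rate 0.02) emulating sporadic
  missing screen values.
* **Annotations** — uniform random terms plus one planted term equal to
  the planted signal genes.

Defaults emulate the panel the analysis is designed for: 58 cell lines in
9 tissues, 800 genes, 30 drugs with 3 targets each, β = 1, response noise
0.5.  One master seed drives per-stage substreams (`default_rng([seed,
stage])`), so identical configs give byte-identical datasets and stages can
be regenerated independently.

What the generator does **not** model: probe- or batch-level microarray
noise, dose-response mechanics, drug mechanism classes, or realistic
interactome degree mixing.  Passing tests show the pipeline recovers
planted structure under its own assumptions; they are not evidence about
any real panel.

Two purpose-built fixtures support the validation suite:

* **Fragility benchmark** — a preferential-attachment tree (negatively
  curved) bridged to a clique (positively curved), one latent factor per
  region, one drug targeting each region.  A curvature ranking that tracks
  fragility must place the tree-targeting drug first; it does so in 20/20
  seeded replicates at the default settings.
* **Duplicated-tissue panel** — every tissue block is an exact copy of one
  base block, so any exclusion leaves statistically identical data.  Module
  latent factors are permutations with pairwise |Spearman| ≤ 0.15 and drug
  response is noise-free, making every gene-drug correlation exactly ±1
  (own module) or at most 0.15 (never significant at these n), so
  significance calls cannot move with sample size and the LOO correlation
  map is exactly 1 everywhere.  Module densities are graded (path-like
  through near-complete) so the ranking being stable is not vacuous.

## Problem sizes and runtime choices

The standard demonstration panel is 800 genes × 60 cell lines × 30 drugs
(≈1600 edges; full analysis a few seconds, the eleven-fold LOO recompute
under a minute on one core).  Monte Carlo checks use 1000 replicates for
the correlation-calibration examples, 100 random graphs for transport
oracle equivalence and curvature bounds, 20 seeds for the fragility
benchmark and 50 for planted-term recovery — sizes chosen so each
statistical assertion has comfortable margin at the stated thresholds.

## Known limitations

* The exact LP per edge scales with the product of endpoint degrees;
  networks with very large hubs (degree in the thousands) would need an
  approximate or entropic solver, which this package deliberately omits.
* Hop-count ground distance ignores edge weights in the metric; the
  weighted mode changes k's scale and the two modes are not comparable.
* The raw p < 0.05 selection rule inherits its multiplicity behaviour; the
  null selection rate is verified (~5%) but not corrected, by design.
* Real-panel headline values (curvature ranges, specific drug orders,
  tissue-exclusion correlation values) depend on the real expression,
  interactome and screen data and are outside what synthetic panels can
  reproduce; the package validates the machinery, not those numbers.
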