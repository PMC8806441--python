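# Methods

This note documents the models and statistics `comorbnet` implements, the
parameters that matter, what the synthetic generators do and do not
emulate, and the numerical and design choices made where the literature
leaves the details open.

## The interactome and distances

All analyses run on an undirected, unweighted simple graph over positive
integer gene identifiers (Entrez-style).  Edge lists with extra columns
(confidence scores, evidence codes) are accepted but the extras are
ignored: curated interactomes are filtered at construction time, not via
edge weights.  Self-loops and duplicate rows are dropped on load with a
logged count.

Distances are hop counts.  Every distance-based statistic is intended to
run on the **largest connected component** (ties between equal-sized
components are broken toward the one containing the smallest identifier);
genes outside the LCC are treated as absent from the network.  Unreachable
nodes are simply omitted from distance maps rather than carrying an
infinite sentinel, so feeding a disconnected graph to the proximity
machinery fails loudly instead of silently diluting averages.

Shortest paths are computed by `scipy.sparse.csgraph` on a cached CSR
adjacency matrix.  Graphs up to 4096 nodes additionally cache the full
all-pairs distance matrix (float64; ~128 MB at the cap), which turns the
thousands of set-to-set distance evaluations of a permutation null into
numpy submatrix reductions.  Larger graphs fall back to per-query
multi-source BFS.

## Network proximity

The proximity of gene sets X and Y is the symmetric closest distance

d(X,Y) = [ Σ_{x∈X} min_{y∈Y} d(x,y) + Σ_{y∈Y} min_{x∈X} d(x,y) ] / (|X|+|Y|).

Two variants are selectable: `closest-asym` (mean over Y of the min over X
only) and `average` (mean over all pairs).  The symmetric closest measure
is the default because it is the standard set-to-set proximity in the
network-medicine literature and is symmetric under swapping the diseases.

Significance comes from a degree-preserving permutation null.  Nodes are
partitioned into **degree bins** by merging adjacent degree classes upward
(lowest degree first) until each bin holds at least `min_bin_size` nodes;
an undersized top bin is merged into its predecessor.  `min_bin_size`
defaults to 100 on graphs of ≥ 2000 nodes and max(5, |V|/20) below that —
large enough that hub bins offer real sampling variety, small enough that
degrees stay matched.  Each null replicate re-samples **both** X and Y:
for every template gene one node is drawn uniformly from that gene's bin,
without replacement within the sampled set.  With `n_random` replicates
(default 1000),

z = (d_obs − μ)/σ,

where μ and σ are the null mean and standard deviation (population σ,
ddof = 0).  A pair is called significantly proximal when z ≤ −1.645, the
one-sided standard-normal 5% critical value; the empirical permutation
p-value (1 + #{d_null ≤ d_obs})/(n_random + 1) is reported alongside the
normal-tail p, since with ~1000 replicates the empirical tail is the more
defensible of the two.  A degenerate null (σ = 0, e.g. on tiny complete
graphs) returns no z and a warning rather than an infinity.

Results are reproducible bit-for-bit given (seed, n_random, min_bin_size).

## DIAMOnD modules and core genes

A disease module grows from seed genes by iteratively adding the most
significantly connected candidate.  For a candidate of degree k with ks
links into the current module (size s0, network size N), the connectivity
p-value is the hypergeometric upper tail Σ_{i≥ks} C(s0,i)C(N−s0,k−i)/C(N,k)
— the chance a random degree-k gene hits the module at least ks times.  N
is the LCC node count.  Ties are broken deterministically: larger ks, then
smaller k, then smaller gene id.  The tie rule is fixed because the
algorithm's published description leaves ties open and reproducibility
requires a total order.

Per-candidate link counts are maintained incrementally as the module
grows; p-values are memoised within an iteration by (k, ks) since module
size is constant there.  A brute-force full-rescan re-implementation (exact
integer combinatorics, no shared code) guards this in the test suite.

A seed weight ω ≥ 1 (integer) counts each link to a seed gene ω times,
with k, ks, s0 and N adjusted accordingly; ω = 1 (default) is the pure
hypergeometric.

Module size is a user parameter (`target_size`, seeds included, or
`n_iterations`): published analyses report final module sizes without
stating their stopping rules, so no convergence heuristic is imposed.  If
the candidate pool empties first the module is returned at the achieved
size with a warning.  **Core genes** are the intersection of two modules.

## Over-representation analysis

For a query of n genes in an N-gene background and a term of K genes with
observed overlap k, the raw p is the hypergeometric upper tail P(X ≥ k)
and the enrichment factor is (k/n)/(K/N).  The background defaults to the
annotation collection's universe (union of term members, or an explicit
gene list such as the network nodes).  Benjamini–Hochberg adjustment runs
over **all** terms, including zero-overlap terms (which score p = 1), so
the number of tests does not depend on the query; zero-overlap terms are
omitted from the output.  Two filter profiles are flagged on every row:
GO-style (raw p < 0.01, k ≥ 3, factor > 1.5) and KEGG-style (raw p <
0.05).  The KEGG threshold applies to the raw p — the convention names
"P-value", not adjusted — while the adjusted values are always reported.
No ontology-graph propagation or term-redundancy clustering is performed.

## Drug–gene networks and differential expression

Drug–gene interaction tables (TSV: drug, gene, interaction_type, approved,
source) are filtered to rows whose gene is in the query set (exact
identifier or case-insensitive symbol; no aliasing) and, optionally, to
approved drugs.  Surviving rows form a bipartite graph whose node names
are prefixed `drug:`/`gene:` so the partitions cannot collide in GraphML
or TSV exports; the count of distinct druggable genes is reported.

Differential expression uses a per-gene **Welch t-test** with BH
adjustment.  Microarray pipelines such as GEO2R apply limma's moderated t;
empirical-Bayes moderation is deliberately out of scope, and the filter
stage accepts externally produced GEO2R tables directly, so a moderated
analysis can be slotted in upstream.  With log2-scale input the fold
change is the difference of group means; with linear input it is log2 of
the ratio of means (which must be positive).  The `test_group` argument
names the fold-change numerator (e.g. hypertensive vs normal).  Rows with
zero variance in both groups get p = 1 when the means agree and p = 0
otherwise.  The DEG filter keeps genes with |log2FC| > 0.3 **and**
adjusted p < 0.05, both strict.  Under the benchmark conditions below the
Welch test recovers on average ~86% of planted effects — a few points
below what a moderated test would achieve, which is the documented price
of the simpler, assumption-light statistic.

## Synthetic scenarios and what they show

The generators produce every pipeline input with recorded ground truth
(`ScenarioTruth`); each is a pure function of its seed.

* **Interactome**: preferential attachment starting from a clique on m+1
  nodes; each new node attaches m distinct edges with probability
  proportional to current degree.  This gives a connected, sparse,
  heavy-tailed network — the salient features of a curated interactome —
  with exactly C(m+1,2) + m(n−m−1) edges.  Defaults n = 2000, m = 3
  (density comparable to the ~16.7k-node/~244k-edge scale of real curated
  interactomes, at desk scale).  It does **not** reproduce protein-complex
  cliquishness, pathway topology or literature-curation bias, so passing
  the planted-signal benchmarks shows the statistics behave as designed,
  not that any particular disease pair is proximal in the real interactome.
* **Proximal gene-set pairs**: a BFS-ball sample around a shared center —
  the innermost size_a + size_b nodes of the radius-r ball (whole BFS
  layers, boundary layer completed by a uniform draw), shuffled, split into
  the two sets, and each member replaced by a uniform random node with
  probability 1 − π.  The innermost-layer rule exists because a uniform
  draw from a radius-2 ball lands mostly in its sparse outer shell and
  frequently plants no detectable locality, breaking the generator's
  contract that `planted_proximal` pairs are in fact proximal.  The center
  is drawn uniformly among nodes whose ball can host both sets.  Defaults:
  sizes 30/30, radius 2, π = 0.8.
* **Dense modules**: the module_size nodes nearest a random center gain
  internal edges (uniformly among non-adjacent member pairs) until the
  internal edge count has grown by `extra_edge_fraction`; saturation is
  recorded in the truth.  Default benchmark: 30 members, +150% edges, 5
  seeds.
* **Annotations**: terms drawn uniformly from the universe; planted terms
  share ⌈overlap_fraction·size⌉ members with a designated query (sizes
  constrained to the feasible part of the range); a `disjoint` mode
  partitions the universe into non-overlapping terms for independence in
  type-I calibration.
* **Expression**: log2-scale, per-gene baseline ~ N(8,1), i.i.d. N(0,σ)
  noise, planted genes shifted by Δlog2 in the case group.  Defaults Δ = 1,
  σ = 0.5, n = 10+10, 50 planted of 500 genes.
* **Drug tables**: each (drug, gene) pair is an interaction with
  probability p_edge, approved with probability p_approved.

## Benchmark problem sizes and expected behavior

The statistical checks (test suite and `scripts/acceptance.py`) run at
desk scale, chosen so each check completes in seconds to a couple of
minutes on one CPU:

* Null calibration: 50 analyses of degree-matched random 30/30 pairs on
  the 2000-node network, 500 null replicates each — mean z within ±0.15 of
  0 (the mean of 50 ~N(0,1) draws has SE ≈ 0.14, so this band is tight)
  and ≤ 10% significant calls.
* Planted-proximity detection: 20 planted pairs (π = 0.8, radius 2) — z ≤
  −1.645 in ≥ 95%; measured detection of the generator design above is
  ~98% with mean z ≈ −4.
* DIAMOnD: step-list identity with the brute-force rescan on 20 random
  60-node instances; ≥ 80% of the first 25 additions inside a planted
  dense module over 10 replicates (measured ~87–91%).
* Enrichment calibration: 200 uniform queries of 200 genes against 10
  disjoint 100-gene terms in a 1000-gene universe — raw-p < 0.05 rate
  0.05 ± 0.02.  These sizes matter: the hypergeometric is discrete, and
  small terms or queries make P(p < 0.05) far below 0.05 (e.g. 0.020 for
  20-gene terms with 30-gene queries); at the chosen sizes the exact null
  rate is 0.0466, so the calibration check is informative rather than
  vacuously conservative.
* DE filter: ≥ 80% recall of planted DEGs with false positives ≤ 5% + 3
  standard errors among the 450 null genes.
* Determinism: two end-to-end runs of the full pipeline with equal
  configuration produce byte-identical `report.json` (per-stage seeds are
  derived from the global seed by hashing the stage name, so stages can be
  re-run in isolation).

## Known limitations

* Hop-count distances ignore interaction confidence and direction.
* Degree binning is static; extremely skewed degree sequences can leave
  the top bin wide, slightly loosening the degree match for the largest
  hubs.
* The Welch t stand-in loses a few points of power versus moderated
  statistics at small n (documented above).
* The synthetic interactome's lack of modular/pathway structure means
  enrichment and module benchmarks probe calibration and recovery of
  *planted* structure only.
* Identifier mapping (symbol ↔ Entrez) is out of scope throughout; inputs
  must share one identifier space.
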