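# Methods

## Model and procedure

The package treats disease-module detection as a greedy statistical
search on an undirected, unweighted protein–protein interaction graph.
Three assumptions underlie the whole analysis:

1. Proteins participating in the same dysregulated process cluster in the
   interactome rather than scattering randomly, so a module can be grown
   outward from the differentially abundant seed proteins.
2. Interaction evidence is symmetric and unweighted; any weights in the
   input edge list are ignored (with a warning), self-loops are dropped,
   and duplicate or reversed edges are collapsed.
3. The interactome is the statistical population. Its node count `N`
   enters the hypergeometric test, and random node sets drawn from it
   define the null for the module-size statistic.

**Growth.** At each iteration every non-member protein with at least one
link into the current module is scored by the upper-tail hypergeometric
probability `P(X ≥ ks)` with population `N`, success states `s0` (current
module size), draws `k` (candidate degree). The lowest P value wins; ties
break by larger `ks`, then smaller `k`, then lexicographic identifier.
The module is re-scored after every addition, so `s0` grows by one per
step and `ks` counts are maintained incrementally. No seed weighting is
applied (all seeds count equally); a configurable `always_include` list
can pin proteins (e.g. the knocked-out gene itself) into the starting
module without treating them as seeds.

**Break-off.** For every prefix of the growth trace the observed
module-size statistic — by default the size of the largest connected
component (LCC) of seeds + prefix — is compared against `n_samples`
random node sets of the same cardinality; `z = (observed − mean)/sd` with
the population standard deviation over the samples. The final module is
the smallest prefix at which every eligible seed lies in the module's
single largest component and `z > z_threshold`. The full trajectory is
always computed and written, so the alternative reading (evaluate z only
after integration) can be inspected post hoc; both the seed-integration
size and each per-size z are in the trajectory table.

## Parameters

| parameter | default | meaning |
|---|---|---|
| `z_threshold` | 1.96 | two-sided 5% normal point; the break-off significance level |
| `n_samples` | 1000 | random node sets per module size in the null |
| `max_added` | 2·s + 100 | growth budget per direction (s = seed count) |
| `scheme` | `uniform` | null sampling: uniform node sets, or `degree_matched` (log2-degree-binned to the observed module's degree profile) |
| `population` | `all_nodes` | hypergeometric population: every node, or `interactome_lcc` (restrict the analysis to the interactome's own LCC) |
| `statistic` | `full_module` | observed statistic: module LCC size, or `seeds_only` (most seeds reachable within one module component) |
| selection `threshold` | 0.0 | minimum absolute log2 ratio for seed eligibility |
| selection `top_k` | all | keep the strongest k annotated, regulated proteins per direction |

Defaults mirror the standard practice for this analysis (1.96, 1,000
samples); the sampling scheme and population conventions are surfaced in
every run summary because published analyses rarely state them and the
two choices change the absolute z values.

## Numerical choices

- The hypergeometric tail is computed with exact integer combinatorics
  (`math.comb`) for populations up to 600 nodes and with scipy's
  log-space survival function above that. Candidate ranking always
  compares log P, so underflow at interactome scale (tails below ~1e-308)
  cannot produce spurious ties; reported P values are clamped to the
  smallest positive double and are therefore never zero.
- Degenerate null distributions (sd = 0, e.g. set size 1 or a complete
  graph) map z to +∞ / 0 / −∞ by the sign of `observed − mean`; +∞
  satisfies any finite threshold.
- Seeds lying outside the interactome component that holds a strict
  majority of the seeds can never integrate and are excluded from the
  integration criterion with a warning. When no component holds a strict
  majority (e.g. seeds split evenly across two components) nothing is
  excluded and the criterion is simply never met; the run terminates with
  `max_iterations`/`exhausted` and the trajectory is still reported.
- Induced-subgraph LCC sizes are computed by a set-intersection BFS over
  a cached adjacency map (the null sampler evaluates tens of thousands of
  induced subgraphs per run); equal-sized components tie-break toward the
  lexicographically smallest node so membership queries are
  deterministic.
- All randomness derives from a single integer seed. Per-stage and
  per-size streams are split with `numpy.random.SeedSequence` spawn keys,
  which is why identical configs give byte-identical report bundles.

## Synthetic studies

The generator emulates the shape of a real study without any downloads:
a scale-free-like base graph (Barabási–Albert preferential attachment,
`m = 4`, matching the heavy-tailed degree distribution of curated
interactomes) or a homogeneous Erdős–Rényi graph for calibration; one or
two planted modules of 50 proteins densified with intra-member edge
probability 0.3; 10 seeds drawn from the planted members, optionally
contaminated by random outside proteins; and a differential table in
which seed proteins carry log2 ratios from a shifted normal (mean ±2,
sd 0.5, magnitude clipped to ≥ 1.2) while all other proteins are
background noise (normal(0, 0.3), clipped to |r| < 0.9). Planted members
and seeds carry the `lysosome` annotation flag, plus 5% of background
rows. The clipping makes a selection threshold of 1.0 separate seeds
from background with certainty, so seed recovery from the table is an
exact construction oracle rather than a probabilistic one.

What the generator does **not** emulate: peptide-level quantification
noise, correlated annotation structure (real lysosomal proteins are not
a random subset), pathway topology beyond a single dense clique-like
module, and interactome study bias (hub proteins being better studied).
Passing the synthetic recovery tests therefore demonstrates algorithmic
correctness — the growth follows the planted signal and the null is
calibrated — not that any particular biological module will be recovered
from real data.

A property worth knowing when reading results on these fixtures: because
the planted module is dense, its seeds integrate after only a handful of
additions and z is already very large, so the break-off fires at a small,
pure core (size ≈ s + a few) rather than at the full planted size. The
planted size is still visible in the analysis — growth stays inside the
planted set for the first 40 additions and z at the true size is ≈ 25 —
but the *final* module under the strict smallest-size criterion is a
high-precision subset. On sparse real interactomes, where seeds connect
slowly, the same criterion yields the larger modules familiar from
published analyses.

## Problem sizes used in the shipped checks

The test suite and `scripts/acceptance.py` run the planted-module study
at 2,000 nodes / 20 replicate interactomes with 1,000 null samples at the
evaluated size, the ranking replay on 50 random graphs of up to 200
nodes, the exhaustive hypergeometric grid at populations up to 12, and
null calibration on a 600-node homogeneous graph with 200 test draws
against a 1,000-sample null. Unit tests use smaller variants of the same
configurations.

## Known limitations

- Exact string identifier matching only; no gene-symbol/UniProt aliasing.
  Seeds absent from the interactome are dropped and reported, not mapped.
- The null model draws node sets independently per module size; no
  multiple-testing control is applied across trajectory sizes, matching
  standard usage of the break-off criterion.
- `degree_matched` sampling bins degrees on a log2 scale and widens bins
  when one empties; it matches the degree *profile*, not exact degrees.
- Connector analysis defines connectors as members of both final
  modules; the looser adjacent-to-both definition is available behind a
  flag but off by default.
- The greedy growth has no backtracking: an early off-module addition
  (e.g. from contaminated seeds) stays in the module.
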