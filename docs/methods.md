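# Methods

## Model

The screen treats disease-gene discovery as guilt-by-association on a
weighted PPI network. Let `A` be the symmetric weight matrix of the network
(weights are integration confidence scores in 1–999) and `M` its
column-normalized form, `M[i,j] = A[i,j] / Σ_k A[k,j]`, so that column `j`
is the step distribution of a walker at node `j`. With `m` seed nodes the
walk iterates

    P(t+1) = (1 − r)·M·P(t) + r·P0,    P0[seed] = 1/m,

and stops when `‖P(t+1) − P(t)‖₁ < tol`. The operator is applied in its
mass-conserving, column-stochastic form: the update is an affine contraction
with factor `(1 − r)`, the fixed point `P* = r (I − (1−r)M)⁻¹ P0` is unique,
and `Σ P = 1` is preserved exactly on networks without isolated nodes.
A variant sometimes written with the transpose of the normalized matrix is a
row-stochastic operator that leaks mass; we use the conserving form, which
is the standard restart-walk definition and is what the convergence and
conservation guarantees in the test suite check. Isolated nodes are allowed
in the type (synthetic inputs may contain them); their zero transition
column loses mass, which is detected and warned about, never silently
renormalized.

Candidates are non-seed nodes with stationary probability ≥ 1e-5
(inclusive). Seeds are excluded from the candidate list: the screen looks
for *novel* genes, and seed self-probability (each seed retains roughly
`r/m` of the mass) would trivially dominate every downstream filter.

## The three filters

**Permutation Z.** `n_perm` random seed sets of size `m` are drawn uniformly
without replacement from all network nodes, the walk is re-run for each, and
each candidate's probabilities are summarized by mean `ProM` and sample
(n−1) standard deviation `ProSTD`. The cut `Z > 1.96` is strict. Two
deliberate choices:

* *Self-draw exclusion (default).* A candidate drawn into a null seed set
  retains ~`r/m` of the mass — at the defaults of the synthetic benchmark
  that is 0.04, about three orders of magnitude above any propagated
  probability. Left in, these Bernoulli events dominate `ProSTD` and no
  gene, however strongly connected to the true seeds, can reach `Z = 1.96`;
  the filter degenerates to "reject everything". A candidate's null
  statistics therefore use only the permutations in which it was *not*
  itself drawn (its `n_used ≤ n_perm` is recorded); the null then measures
  what it is meant to measure — probability flowing *to* the gene under
  random seeding. The unconditional variant is available via
  `exclude_self_draws=False` (CLI `--unconditional-null`). If fewer than two
  non-self permutations remain, all draws are used for that gene, with a
  warning.
* *Uniform vs degree-matched draws.* Uniform sampling is the default;
  `--degree-matched-null` instead samples each null seed from the same
  log2-degree bin as the corresponding true seed, a stricter null for
  hub-dominated networks.

`ProSTD = 0` (a degenerate null) maps `Z` to signed infinity — or 0 when
the observed probability equals the null mean — preserving pass/fail
semantics without dividing by zero.

**Linkage.** `MLS(g)` is the maximum edge confidence from `g` to any
validated gene; the cut `≥ 900` is inclusive ("no less than"). A candidate
with no validated neighbor scores 0.

**Enrichment.** `ES(g, F) = −log10 Σ_{k=m}^{min(n,M)} C(M,k)·C(N−M,n−k)/C(N,n)`
is the hypergeometric upper-tail probability that `g`'s `n` network
neighbors overlap term `F`'s `M` genes in at least the observed `m`,
computed in log space (`scipy.stats.hypergeom.logsf`) so deep tails do not
underflow. The upper summation limit is written `min(n, M)` — identical to
summing to `n` since the extra terms vanish, but numerically explicit.
`N`, the total number of human genes, is a configuration value (default
20,000, `--total-genes`): the network does not cover the full genome, so
`N` cannot be derived from it. Neighbors are counted at any positive
confidence by default (`--neighbor-min-score` restricts them). Cosine
similarity between enrichment vectors is 0 by convention when either norm
is zero (e.g. a gene with no neighbors, whose vector is all-zero); the MES
cut `≥ 0.98` is inclusive, matching the linkage cut's reading. Validated
genes' own vectors are computed on the full network.

No multiple-testing correction is applied across candidates; the three
cascaded filters are the false-positive control.

## Parameters

| parameter | default | meaning |
|---|---|---|
| `r` | 0.8 | restart probability; larger keeps mass nearer the seeds |
| `tol` | 1e-6 | L1 stopping tolerance of the walk |
| `prob_threshold` | 1e-5 | candidate extraction floor (inclusive) |
| `n_perm` | 1000 | permutation count (≥ 2) |
| `z_cut` | 1.96 | permutation cut, strict `>` |
| `mls_cut` | 900 | linkage cut, inclusive, on the 1–999 confidence scale |
| `mes_cut` | 0.98 | enrichment-similarity cut, inclusive, in [0, 1] |
| `total_genes_N` | 20000 | hypergeometric population size |
| `max_iter` | 10000 | safety cap; convergence needs ~`log(tol)/log(1−r)` steps |

With `r = 0.8` the contraction factor is 0.2, so the walk converges in
about ten iterations; `max_iter` exists only to turn pathological input
into a clear error (exit code 4 in the CLI).

## Synthetic benchmark

`make_benchmark` emulates the three real inputs at desk scale:

* **Background network** — preferential attachment (networkx
  Barabási–Albert growth from a complete clique on `attach_degree + 1`
  nodes), because real PPI networks are hub-dominated and hubs are
  precisely the failure mode the permutation test exists for; an
  Erdős–Rényi-like alternative can be had by planting into any
  user-supplied network. Defaults: 500 nodes, `attach_degree = 3`, integer
  weights uniform in [100, 899] — background edges deliberately stay below
  the 900 band, as most STRING backbone edges do.
* **Planted module** — 40 nodes, each pair connected independently with
  probability 0.8 at weight 950 (existing edges upgraded to the maximum),
  standing in for a densely interacting disease-gene community. The module
  is split 50/50 into validated seeds and held-out truths; all non-module
  genes are decoys.
* **Annotations** — 6 module-coherent terms each covering ≥ 80% of the
  module plus up to 5 random fillers, and 30 background terms of 10–40
  random genes, so the enrichment vectors of module genes point in a shared
  direction while decoys' do not.

What the benchmark does *not* emulate: STRING's separate evidence channels
(only the combined score is modeled), realistic degree distributions of
annotation terms, literature-biased seed ascertainment, and genome-scale
sparsity. Passing the recovery test therefore shows the pipeline's
machinery is sound — probability concentrates on the planted community,
the null is calibrated, the filters compose correctly — not that any
particular biological list would be reproduced.

## Numerical and design notes

* Node order is fixed by lexicographic sort at construction; all vectors,
  matrices, files and manifests are byte-reproducible for a given
  configuration and RNG seed. The run manifest intentionally carries no
  timestamps (timings are logged to stderr).
* Duplicate edges keep the maximum score (conservative for the linkage
  test); self-loops are dropped with a warning.
* Candidate ordering breaks probability ties by gene id; results files sort
  by descending MES, then gene id.
* Permutation start vectors are propagated in batches through the shared
  transition matrix; every batch column satisfies the L1 tolerance
  individually on return.
* Test and acceptance problem sizes (networks of ≤ 500 nodes, 200–1000
  permutations, five benchmark seeds) were chosen so the full suite runs in
  seconds while keeping the Monte-Carlo assertions (recovery ≥ 70% of
  held-out truths, ≤ 10% decoys; null mean-Z within ±0.1) comfortably away
  from their noise floors.

## Limitations

* The screen is guilt-by-association: genes far from every seed in the
  network cannot be found, and literature bias in the network's confidence
  scores propagates into the results.
* The permutation null with uniform draws does not fully remove degree
  bias (the degree-matched option is stricter but slower to justify
  theoretically); Z-scores on very high-degree nodes warrant skepticism.
* The hypergeometric enrichment treats terms independently and ignores
  ontology structure; `N` is a convention, and MES values shift with it.
* At full scale (tens of thousands of nodes, thousands of permutations) the
  permutation stage dominates runtime; it scales linearly in `n_perm` and
  in the edge count.
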