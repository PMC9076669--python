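# Methods

`stressnet` implements a multi-step procedure for reducing two independent
RNA-seq experiments that contrast a binary condition (non-stress vs stress)
to a small set of condition-associated genes and an interpretable network
over them. This note documents the models, the parameters that matter, the
numerical choices, and what the synthetic benchmarks do and do not show.

## Differential-expression selection

Each study is analyzed separately. Genes with counts-per-million (CPM)
above `min_cpm` (default 0.5) in fewer than `min_samples` (default 2)
samples are removed; library sizes are the column sums of the input
matrix. Expression is transformed to
`log2((count + c) / (lib + 2c) * 1e6)` with prior count `c = 0.5`.

Per gene, a two-group linear model gives the effect estimate (difference
of group means, reported as log2 fold change) and a residual variance
`s_g^2` on `d = n - 2` degrees of freedom. The variances are shrunk with
an empirical-Bayes scaled-F prior: writing `z_g = log s_g^2`, the prior
degrees of freedom `d0` and prior variance `s0^2` are obtained by moment
matching `z` against its theoretical log-chi-square mean and variance
(digamma/trigamma identities, with a Newton inversion of the trigamma
function). The posterior variance is
`(d0 s0^2 + d s_g^2) / (d0 + d)` and the moderated t-statistic uses
`d + d0` degrees of freedom. When the observed variances are
under-dispersed relative to chi-square the moment system has no finite
solution; `d0` is set to infinity (complete shrinkage, normal reference
distribution) and the event is logged. `d0 = 0` recovers the ordinary
pooled-variance t exactly, which the tests exploit as an oracle.

P-values are adjusted by Benjamini–Hochberg; genes with adjusted p at or
below `alpha` (default 0.05, deliberately exposed because real analyses
vary in this choice) are kept, ordered by raw p, optionally truncated at
`max_n`. The two studies' lists are intersected, preserving the first
list's order. Normalization is plain library-size CPM; TMM-style
composition correction is out of scope, so the synthetic generator keeps
the planted differentially expressed (DE) fraction small (see below).

## Discretization

Each selected gene's expression vector, pooled across all samples of all
studies, is cut at its empirical 1/3 and 2/3 quantiles
(linear-interpolation "type 7") into low / medium / high. Intervals are
right-closed at each cutpoint: a value equal to a cutpoint falls in the
lower bin, and ties are logged. Discretization is rank-based, hence
invariant to strictly increasing transforms, and absorbs cross-study
location shifts — the reason the pooled (rather than per-study) variant
is used. The binary condition variable (0 non-stress, 1 stress) is
appended unchanged.

## Structure learning

Networks over the discretized variables are scored with the BDeu log
marginal likelihood with equivalent sample size `ess = 1`: per node `i`
with `r_i` states and `q_i` joint parent configurations,

    sum_j [lnG(a_ij) - lnG(a_ij + N_ij)]
      + sum_jk [lnG(a_ijk + N_ijk) - lnG(a_ijk)],

`a_ijk = ess/(r_i q_i)`, `a_ij = ess/q_i`. The score decomposes over
(node, parent-set) families; family terms are cached and reused within
and across search runs. BDeu assigns equal scores to Markov-equivalent
DAGs, which bounds what any search can recover: edge *direction* within
an equivalence class is not identifiable from observational data, only
the skeleton and colliders are.

The searcher is simulated annealing from the empty graph with local
random moves: single-edge addition, deletion, or reversal, drawn
uniformly among the valid moves (moves creating a cycle or exceeding
`max_parents` are never proposed; sampling is by rejection from the
(move-type, ordered-pair) lattice, which preserves uniformity).
Improvements are always accepted; a worsening `delta` is accepted with
probability `exp(delta / T)`. The schedule is geometric: `T` starts at
`1e4` score units and is multiplied by 0.9 every 2500 proposals; if no
move is accepted for 5000 consecutive proposals, `T` resets to its
initial value (re-annealing). Temperature zero gives plain hill
climbing, used in tests. All schedule constants sit in `SearchConfig`.
One scaling subtlety: a short run under the default schedule never gets
cold (1e5 proposals end at `T ~ 150`, which still accepts most small
worsenings on ~50-sample gene data), leaving each run a random walk and
the downstream run-to-run consensus empty. A full-length run is cold
long before it finishes, so the pipeline's scaled configuration shortens
the cooling levels (`proposals_per_level = 1000`) to preserve the
qualitative behavior — runs that end converged — at reduced cost.
The `top_n` (default 100) best *distinct* structures ever visited are
retained, keyed by edge set.

A single run is reduced to one consensus network: an arc is kept iff it
appears in strictly more than `majority_fraction` (default 0.5) of the
top networks. On very small problems (a handful of variables) the top-100
list spans essentially all structures and score equivalence splits arc
directions evenly, so no strict majority forms; small-scale tests
therefore use `top_n = 1` (the single best network). At realistic sizes
(~20 variables) the visited networks are correlated and the default is
meaningful.

## Grouped arc-weight ensemble

The search is stochastic, so it is repeated `n_runs` times (1000 at study
scale; 50 in the scaled benchmarks), each run sub-seeded from the master
seed by counter-based derivation (numpy `SeedSequence` spawn keys), so
runs are independent and the whole ensemble is a pure function of the
master seed. The per-run consensus networks are divided in run order into
groups (10 groups of 100 at study scale; 10 groups of 5 scaled). Within a
group, an arc's weight is the number of member networks containing it
(1..group size). An arc enters the final network iff its mean weight
across groups — counting 0 where absent — is at or above the threshold
(inclusive; half the group size by default). An alternative rule
(selected in at least `min_groups` groups) is available and recorded in
the manifest; the mean rule is the default because a single 1..100 weight
scale reads most naturally as an average. If both directions of an edge
pass, the higher-mean direction is kept (ties: lexicographically smaller
parent, logged). The aggregate need not be acyclic; cycles are retained
and reported rather than repaired. Variables with no selected arc are
dropped from the graph but listed as isolated.

## Network interpretation

The Markov blanket of the condition node is its parents, children, and
spouses (other parents of its children). On a DAG this is exactly the set
that renders the condition conditionally independent of the rest; on a
cyclic aggregate the definition is applied graph-theoretically and no
probabilistic claim is made.

Communities are found on the undirected skeleton with unit weights
(mean arc weights are ignored for clustering): repeatedly remove a
maximum-edge-betweenness edge — ties broken by lexicographically
smallest edge for determinism — recomputing betweenness after every
removal, and return the partition along the removal sequence that
maximizes Newman–Girvan modularity `Q = sum_c (e_cc - a_c^2)` evaluated
on the original graph (the unsplit partition included; first maximum
wins). The full removal dendrogram is kept so a partition can instead be
cut at a fixed community count. Betweenness and modularity are computed
with networkx; the tests check both against brute-force oracles
(exhaustively over all connected graphs up to 6 nodes for betweenness).

## Synthetic data

Two generators define the benchmark conditions.

*Ground-truth Bayesian networks.* Random DAGs with bounded in-degree;
CPT rows from a symmetric Dirichlet (`random_cpts`), or — when a
*recoverable* truth is required — `strong_cpts`: roots get a
non-degenerate Dirichlet(5) marginal and each child row puts mass 0.9 on
`(sum of parent states) mod r`. The latter exists because a very small
Dirichlet concentration tends to make root marginals themselves
near-constant, destroying the signal it was meant to strengthen.
Sampling is ancestral; at extreme concentrations where all gamma draws
underflow to zero, a CPT row falls back to a uniformly chosen one-hot
vector (the exact Dirichlet limit). The recovery benchmark uses a fixed
6-node, 6-edge chain-plus-shortcut graph, ternary variables, n = 500.

*Two-study counts.* Negative-binomial counts parameterized by mean and
dispersion (variance `mu + phi mu^2`, default `phi = 0.05`), per-gene
baseline log-means uniform on `log(5)..log(500)`, two groups per study
(default 12 + 13 samples, pooling to 50 across the two studies), and a
shared planted set of DE genes (default 20 of 2000) with log2 fold
change 4 and a per-gene direction shared between studies. The planted
fraction is kept near 1% deliberately: selection normalizes by plain
library size, and a large mass of strongly shifted genes would induce
composition bias in every null gene — as it would in real data analyzed
without TMM. Baselines are drawn independently per study; the two
studies share only the planted gene set.

What passing these benchmarks shows: the scoring, search, aggregation,
and analysis machinery recovers planted structure under clean,
moderately strong signal. What it does not show: robustness to batch
effects, composition bias, GC or length bias, confounded designs, or the
weak and heterogeneous effects typical of real stress transcriptomes —
none of which the generator emulates.

## Problem sizes and determinism

The scaled benchmark sizes used throughout the tests and the acceptance
script are the package's own choices: 3-variable search optimality is
checked against exhaustive enumeration over all 25 DAGs across 100
seeds at 1e5 proposals; ensemble recovery uses 50 runs x 1e5 proposals
in 10 groups of 5; the pipeline smoke run uses two studies pooling to 50
samples with ~20 selected genes plus the condition. Every source of
randomness descends from a single master seed; identical seeds give
byte-identical artifacts (manifests contain no timestamps).

## Known limitations

- Edge directions inside a Markov-equivalence class are not identifiable;
  skeleton-level metrics are the honest yardstick, and direction
  resolution in the final network is a reporting convention.
- The BDeu/annealing learner assumes complete data and categorical
  variables; there is no missing-data handling.
- The final aggregate graph may contain directed cycles; Markov-blanket
  semantics are then purely graph-theoretic.
- No TMM/RLE normalization, no voom weights, no multi-factor designs;
  two-group contrasts only.
- The moment-matched prior can degenerate (`d0 = inf`) on
  under-dispersed variances; this is logged, not an error.
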