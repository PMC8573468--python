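# Methods

## Differential expression

The input is a genes × samples matrix of log2 intensities with a two-group
labelling (control vs case); upstream normalization (quantile, RMA, probe →
symbol mapping) is assumed done and is out of scope. Per gene we compute
log2FC = mean(case) − mean(control) and a Welch two-sample *t*-test
(unequal variances; `scipy.stats.ttest_ind(equal_var=False)`), then adjust
across genes with Benjamini–Hochberg. A gene is called *up* when
log2FC ≥ fc_cutoff and adj-p < p_cutoff, *down* when log2FC ≤ −fc_cutoff
and adj-p < p_cutoff. Defaults fc_cutoff = 1.5 (log2 units; the absolute-
value reading is forced because down-regulated genes are reported) and
p_cutoff = 0.05. The moderated linear models used by microarray pipelines
are deliberately replaced by the plain Welch test: only the cutoff semantics
are the contract here. Degenerate zero-variance genes (possible on
noiseless synthetic data) get p = 0 when the group means differ and p = 1
when they coincide, with a logged warning. Multi-dataset integration is a
set union of the per-dataset DEG symbol lists.

## Network construction

Edge lists follow the STRING export convention (gene1, gene2,
combined score); integer scores are interpreted on the 0–1000 scale and
divided by 1000. An edge is kept when score ≥ threshold. The published
description of the confidence filter ("medium confidence score < 0.5") is
internally inconsistent with STRING's convention, where *medium confidence*
means score ≥ 0.4; we use ≥ 0.4 as the default and expose the threshold as a
parameter. Self-loops are dropped, duplicate pairs in either orientation
collapse to the maximum score, and node identity is the exact gene-symbol
string. Whether downstream analysis should run on the full graph or its
largest component is left to the caller; the pipeline default reduces to the
largest component because closeness and spectral splitting are
component-level notions.

## Topology

* degree — incident edge count;
* closeness — classical within-component form (n_comp − 1)/Σ_u d(v, u)
  (the harmonic variant was rejected to stay with the definition the
  standard network-analysis tools use); isolated nodes get 0;
* betweenness — unnormalized Freeman sum Σ_{s<t} σ_st(v)/σ_st, endpoints
  excluded (computed with Brandes' algorithm via networkx; the contract is
  the sum itself, which the tests pin against exhaustive path enumeration);
* eigenvector — principal eigenvector of the adjacency matrix computed per
  connected component (dense symmetric solver up to 600 nodes, Lanczos
  above), entries nonnegative, unit Euclidean norm per component; edgeless
  components get 0 because the spectrum is degenerate there.

The degree-indexed curves are plain per-degree-class averages. P(k) sums to
1 over observed degrees. For power-law fits the contract is least squares on
(log10 k, log10 value) over strictly positive points (≥ 3 required);
`r_squared` is the squared Pearson correlation of the regression. Degree
distributions are log-binned before fitting (densities normalized by bin
width, geometric-mean bin centres): the raw histogram's one-count tail
otherwise biases the slope of heavy-tailed distributions upward by roughly
a unit. A closed-form continuous MLE of the tail exponent is provided as an
independent cross-check, not as the contract. Whole-network clustering is
reported under both conventions for degree-<2 nodes (counted as zero —
default — or excluded).

## Module hierarchy

`lev_split` implements Newman's leading-eigenvector method in full: on a
connected graph, form B = A − k kᵀ/2m, split by the sign of the leading
eigenvector (entries exactly 0 join the positive side; the eigenvector sign
is canonicalized so results are reproducible without a seed), and accept the
split only when the leading eigenvalue exceeds 1e−10 *and* the modularity
gain ΔQ = sᵀB(g)s/4m does. Accepted halves are re-split recursively using
the generalized modularity matrix B(g)_ij = B_ij − δ_ij Σ_{k∈g} B_ik, which
is what prevents spurious sub-splits of structureless dense blocks. The
result is a flat partition, or "indivisible" for graphs like complete
graphs and stars.

`build_module_tree` produces the *nested* hierarchy: level 0 is the whole
network, and each module larger than `min_module_size` advances by exactly
one step per level — its connected components if it is disconnected (a
forced, modularity-neutral split), otherwise one leading-eigenvector
bipartition. One step per level is essential: the flat recursion jumps
straight to the finest stable partition (on a two-level nested benchmark it
returns all four leaf blocks at the root), which would erase the
intermediate levels the hierarchy is supposed to expose. Each split records
the modularity and CPM energy of the module's induced subgraph under its
children; modules that cannot split are leaves and carry forward unchanged
in deeper level partitions, so every level is a proper partition of the
network.

Partition quality uses Q = Σ_c [m_c/m − (d_c/2m)²] and the Constant Potts
Model energy H = −Σ_c [m_c − γ·n_c(n_c−1)/2]. Because H involves only
intra-community quantities, evaluating it on the whole network under a
level partition and summing the modules' own induced-subgraph energies give
the same number. γ defaults to 0.5 and is recorded in all outputs. H is a
*reporting* statistic over the LEV tree — the tree is never optimized for
CPM (no Louvain/Leiden here by design).

Parameters: `gamma` (> 0, default 0.5), `min_module_size` (≥ 3, default 3 —
a triangle is the smallest motif), `max_depth` (optional cap). An
edge-betweenness (Girvan–Newman) split is available behind
`method="girvan_newman"` as a slower alternative.

### Energy/modularity decline across levels

On the nested-block benchmark (n = 128, two planted levels, p = 0.5 / 0.05 /
0.005 by nesting depth) the profile analysis caps the tree at depth 3: the
planted hierarchy plus one refinement step. The cap is a resolution
statement, not a convenience: below the planted leaf blocks the generator
is an Erdős–Rényi graph, and spectral splits there cut at a density close
to γ, so the energy change per level is zero-mean noise and "decline" is
undefined. Within the capped profile, the CPM energy of the level
partitions and the mean modularity of the per-level splits decline strictly
in every benchmark instance. Note it is the energy *value* that declines
monotonically; its absolute value is not monotone because H crosses zero
near the planted depth when γ matches the leaf-block density.

## Key regulators

Hubs are the top-N nodes by degree (N default 10; ties broken by higher
betweenness, then lexicographic symbol). A gene's trace is the chain of
modules containing it from the root to the module that became a leaf; the
gene is "present at every hierarchical level" iff its chain reaches the
tree's maximum depth. Fundamental key regulators = hubs with that property,
annotated with DEG direction ("unknown" if absent from the DEG table) and
with every TF-target table row in which they appear (as regulator or
target; modes outside {activation, repression} map to "unknown"). The
published analyses count "10 hubs containing 13 key genes" without stating
the hub criterion or the hub→gene mapping; we report strictly per-gene and
expose N as a parameter.

## Synthetic benchmarks: what they emulate, what they do not

* **Expression** — log2-scale two-group design with gene-level baselines
  N(8, 1.5), planted ±effect on case means, i.i.d. Gaussian noise. Defaults
  (2000 genes, 50 up + 50 down, effect 2.0, noise sd 0.25, 10 per group)
  give a Welch-test effect size of ≈ 18 standard errors, a regime where the
  cutoffs, BH machinery, and direction logic are exercised cleanly. Not
  emulated: probe-level structure, correlated genes, batch effects,
  platform differences — so passing benchmarks demonstrate correctness of
  the calling machinery, not real-data operating characteristics.
* **Nested blocks** — balanced hierarchy (levels ℓ, branching b); the edge
  probability of a pair depends on their deepest common block
  (0.5 within leaf blocks, 0.05 / 0.005 one/two levels up in the reference
  conditions). Planted *deep hubs* (one per leaf block) receive
  ⌈p_hub·|block|⌉ extra edges into every block at every level (p_hub = 0.5),
  which keeps them inside a dense, still-splittable module at every
  partition depth. Planted *decoys* are pendant-star centres (64 pendant
  leaves, 6 attachment edges into a single leaf block): their degree rivals
  the deep hubs', but a star is spectrally indivisible, so once a split
  severs the attachment edges the decoy's chain terminates. In the
  key-regulator benchmark (n = 256) the tree is capped at depth 5, the
  depth at which typical bottom modules reach about twice the motif floor;
  deep-hub chains reach the cap, decoy chains end at depth 3–4.
* **Preferential attachment** — Barabási–Albert, m = 2; the log-binned
  degree-distribution fit recovers an exponent near −2.7 (theory −3,
  finite-size bias toward shallower slopes).
* **Hierarchical cliques** — deterministic Ravasz–Barabási construction
  (5-clique, 3 levels, 125 nodes), whose C(k) ∝ 1/k decay is the
  hierarchical-modularity signature.

## Numerical choices

Eigen-decompositions are dense (`numpy.linalg.eigh`) for the module sizes
this package targets (≲ a few thousand nodes); eigenvalue/ΔQ acceptance
tolerance 1e−10; eigenvector sign canonicalized by entry sum. Modularity
and CPM energies are exact rational-arithmetic-free sums whose agreement
with O(n²) pairwise oracles is pinned to 1e−9 in the tests. All generators
take one integer seed and create a single local RNG; identical seeds give
bit-identical outputs, and the pipeline manifest records SHA-256 checksums
of every artifact to make end-to-end determinism checkable.

## Known limitations

* The LEV tree is greedy and spectral: no Kernighan–Lin refinement after
  sign splits, so very weak planted structure may be missed slightly below
  the information-theoretic threshold.
* CPM energy is reported on the LEV tree rather than optimized, matching
  the procedure it documents; an optimized-CPM hierarchy would need Leiden.
* Closeness and eigenvector centralities are component-local; comparing
  their magnitudes across components of very different sizes is not
  meaningful.
* The synthetic decoy/deep-hub dichotomy is a clean caricature; in real
  networks hub "depth" varies continuously, and the binary
  present-at-all-levels call inherits the tree-depth cap choice.
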