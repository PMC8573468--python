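# netreg

Key-regulator discovery in gene interaction networks.

Tumour transcriptome studies routinely produce a list of differentially
expressed genes (DEGs) and a protein/gene interaction network over them. The
question this package addresses is which of those genes are *fundamental key
regulators*: high-degree hub genes that are not merely popular, but
deep-rooted — still sitting inside a coherent module at every level of the
network's hierarchical community structure, from the whole network down to
motif-sized modules. Such genes form the backbone of the network and are the
natural candidates for follow-up as disease drivers or drug targets. The
package is aimed at computational biologists who want this pipeline as
tested, scriptable library code, with synthetic planted-truth benchmarks
replacing the repository downloads (GEO expression series, STRING exports)
that the real analyses start from.

## The pipeline

1. **Differential expression** (`netreg.diff_expression`) — per-gene Welch
   two-sample *t*-test on a log2 expression matrix, Benjamini–Hochberg FDR,
   calls by |log2FC| ≥ 1.5 and adjusted *p* < 0.05.
2. **Network construction** (`netreg.network_build`) — STRING-style scored
   edge lists → simple undirected graphs: self-loops dropped, duplicate
   pairs collapsed (max score), confidence threshold (default 0.4), graph
   union across datasets, largest-component extraction.
3. **Topology** (`netreg.topology`) — degree, closeness
   `(n−1)/Σ d(v,u)`, unnormalized Freeman betweenness
   `Σ σ_st(v)/σ_st`, per-component eigenvector centrality; the
   degree-indexed curves P(k), C(k), CN(k), CB(k), CC(k); log–log
   least-squares power-law fits (log-binned degree distributions).
4. **Module hierarchy** (`netreg.hierarchy`) — Newman's leading-eigenvector
   method on the modularity matrix **B** = **A** − **k kᵀ**/2m. Flat
   partitions via `lev_split` (full recursion with the generalized
   modularity matrix and Newman's stopping rule); nested hierarchies via
   `build_module_tree` (one spectral bipartition per module per level,
   components first). Every partition is scored by modularity
   Q = Σ_c [m_c/m − (d_c/2m)²] and by the Constant Potts Model energy
   H = −Σ_c [m_c − γ·n_c(n_c−1)/2] (default γ = 0.5).
5. **Key regulators** (`netreg.key_regulators`) — hubs are the top-N degrees
   (ties by betweenness, then symbol); each hub is traced down the module
   tree; hubs whose chain reaches the tree's maximum depth are the
   fundamental key regulators, annotated with DEG direction and TF–target
   relations from a user-supplied table.

`netreg.synthetic_data` generates every input with planted ground truth:
two-group expression matrices with known fold changes, nested-block networks
with planted hierarchies, deep hubs wired into every block at every level,
pendant-star decoy hubs, preferential-attachment graphs, and deterministic
hierarchical-clique graphs.

## Worked example

The numbered scripts under `analysis/` run the whole study on synthetic
data, writing tables under `results/`:

```bash
python analysis/01_simulate_data.py
python analysis/02_differential_expression.py
...
python analysis/06_key_regulators.py
```

Stage 05 prints the per-level hierarchy profile of the benchmark network
(516 nodes: 256 block nodes in a 2-level nested hierarchy, 4 planted deep
hubs, 4 pendant-star decoys):

```
 level  n_modules  q_level  he_level  mean_q_of_split
     0          1    0.000 60988.000            0.416
     1          2    0.416 28166.000            0.387
     2          4    0.562 12090.000            0.107
     3          8    0.567  3907.000            0.056
```

Reading: at level 0 the whole network is one module (Q = 0 by definition;
the CPM energy of a single sparse community is large because γ-weighted
internal pairs dwarf internal edges). The first two splits recover the
planted 2-block and 4-block levels — split modularity 0.416 and 0.387 —
and both the energy and the split quality decline as the hierarchy descends
toward the motif level. Stage 06 then traces the hubs:

```
fundamental key regulators: ['G00175', 'G00126', 'G00059', 'G00195']
planted deep hubs: ['G00059', 'G00126', 'G00175', 'G00195']; decoys: ['D01', 'D02', 'D03', 'D04']
  G00175: degree 204, chain depth 5 of 5, fundamental=True
  ...
  D01: degree 70, chain depth 3 of 5, fundamental=False
recovery over 20 seeds: precision 1.000, recall 1.000
```

All four planted deep hubs — and none of the equally high-degree decoys —
are called fundamental key regulators.

A single-command demo (synthetic inputs + all five stages + reproducibility
manifest) is also available:

```bash
netreg demo --seed 1 --out demo/
```

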