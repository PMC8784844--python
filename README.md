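# lssd

Self-diffusion on a local-scaling cell–cell affinity (LSSD) for denoising
similarity graphs from scRNA-seq expression matrices and clustering cells,
with automatic estimation of the number of clusters.

Unsupervised clustering of single-cell transcriptomes is hampered by
sparsity, dropout and amplification noise: plain Euclidean or cosine
similarities between cells are unstable. LSSD addresses this in the space
of cells rather than genes, in three steps:

1. **Local-scaling affinity** — W(i,j) = exp(−d²(x_i,x_j)/(σ_i σ_j)),
   where σ_i is the distance from cell i to its K-th nearest neighbor
   (K = 5). The self-tuned bandwidths remove global scale differences and
   adapt to local density.
2. **Self-diffusion** — starting from S₀ = W, iterate
   S_{t+1} = τ·S_t P + (1−τ)·I (t = 4, τ = 0.8), where P is W restricted
   to each cell's k nearest neighbors and row-normalized. The random walk
   strengthens within-cluster edges and lets weak spurious edges decay.
3. **Spectral clustering** on the symmetrized diffused graph. The number
   of clusters C can be estimated by rotating the top Laplacian
   eigenvectors to an indicator-like form and scanning the separation cost
   J(R) = Σ_ij Z²_ij/M²_i over candidate C.

A grouped negative-binomial count simulator with dropout (known labels)
powers all experiments without downloads, and NMI/ARI evaluation utilities
are included. Intended users: computational biologists clustering
10²–10⁴ cells who want a transparent, dependency-light graph-denoising
pipeline.

## Worked example

Simulate 300 cells in 3 groups, cluster with the cluster number estimated
automatically, and evaluate against the planted labels:

```sh
$ lssd simulate --cells 300 --genes 400 --groups 3 --seed 1 --out sim
wrote 300 cells x 400 genes to sim

$ lssd cluster sim --cmin 2 --cmax 8 --report --seed 0 --out run
labels written to run/labels.tsv

$ lssd eval run/labels.tsv sim/truth_labels.tsv
NMI	1.000000
ARI	1.000000
```

Both concordance indices are 1: every cell is assigned to its planted
group. The separation-cost curve written by `--report` shows why C = 3 was
chosen — J is minimal near the ideal value n = 300 at C = 3 and rises for
every larger candidate:

```
$ cat run/separation_cost.tsv
C	J
2	302.0302742
3	300.3031142
4	315.8529799
5	347.2676353
6	345.2361017
7	360.7960286
8	371.947983
```

`run/manifest.json` records every parameter, seed and warning needed to
reproduce the run. The same machinery is available as a library:

```python
import lssd

X, truth = lssd.simulate_counts(lssd.SimParams(n_cells=300, n_genes=400,
                                               n_groups=3, seed=1))
solution = lssd.cluster_matrix(X, n_clusters=3, seed=0)
print(lssd.nmi(solution.labels, truth), lssd.ari(solution.labels, truth))
```

Other subcommands: `lssd sweep-steps` (clustering quality versus the
diffusion iteration count t) and `lssd sweep-sizes` (stability and wall
time versus sample size).

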