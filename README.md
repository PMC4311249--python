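# ncmce

Nonlinear population-structure detection for genotype matrices:
**non-centred Minimum Curvilinear Embedding (ncMCE)** with a PCA baseline,
a 1-D cluster-separability score, missing-data imputation, rank-sum SNP
selection, and UPGMA population dendrograms — plus synthetic generators
that reproduce the benchmark scenarios without any external data.

## Who this is for

PCA is the default first look at a genotype matrix (individuals × SNPs,
coded 0 = homozygous wild-type, 1 = heterozygous, 2 = homozygous variant,
3 = missing), but as a linear projection it can miss group structure that
lies on a curved manifold — closely related populations, or data perturbed
by structured missingness. ncMCE is a parameter-free, nonlinear companion
to PCA for exactly those cases: population geneticists and GWAS analysts
can run both and compare.

## The method

Given a data matrix `G` (n individuals × m features):

1. **Distances.** Compute the pairwise distance matrix `A` between
   individuals (Euclidean by default, or the correlation distance
   `1 − r`).
2. **MST.** Extract the minimum spanning tree `T` of the complete graph
   weighted by `A` (Prim's algorithm, deterministic lexicographic
   tie-breaks).
3. **MC-kernel.** Re-compute all pairwise distances *over the tree*:
   `D[i,j]` is the summed edge weight along the unique path `i → j`.
   `D` is an additive tree metric that approximates curvilinear
   (geodesic-like) distances through the data manifold.
4. **Embedding.** Apply the economy-size SVD to the **non-centred**
   kernel, `D = U S Vᵀ`, and place individual `j` on embedding dimension
   `k` at `√S_k · V[j,k]`. The centred variant (MCE) double-centres `D`
   with `J = I − (1/n)·11ᵀ` first; the PCA baseline is the SVD of the
   column-centred `G`.

For the non-centred kernel, dimension 1 typically carries overall
magnitude; group discrimination appears on **dimension 2** — inspect both.

Separability along a single embedding dimension is quantified by the
**C-score**: for each pair of groups, the fraction of cross-group pairs
ordered consistently (ties counting ½) is mapped to `2·|f − ½|`, and the
scores are averaged over group pairs. 1 means the groups occupy disjoint
intervals; 0 means a perfectly balanced interleave.

## Worked example

```python
import numpy as np
from ncmce import (
    CurvedClusterConfig, make_curved_clusters, embed_pipeline, best_cscore,
    PopSimConfig, simulate_genotypes, population_tree, to_newick,
)

# 1. nonlinear benchmark: two interleaved curved sheets
points, labels = make_curved_clusters(CurvedClusterConfig(seed=1))
for method in ("PCA", "ncMCE"):
    e = embed_pipeline(points, method=method, d=2)
    r = best_cscore(e, labels, dims=[1, 2])
    print(f"{method:5s} C-scores dim1={r.per_dimension[0]:.3f} "
          f"dim2={r.per_dimension[1]:.3f} best={r.best:.3f}")

# 2. four-population tree: simulate genotypes and recover the dendrogram
topology = (((("YRI", 0.15), ("CEU", 0.15)), 0.05),
            ((("CHB", 0.02), ("JPT", 0.02)), 0.12))
cfg = PopSimConfig(tree=(topology, 0.0), n_ind_per_pop=30, n_snps=2000, seed=7)
g = simulate_genotypes(cfg)
print(to_newick(population_tree(g)))
```

prints

```
PCA   C-scores dim1=0.048 dim2=0.797 best=0.797
ncMCE C-scores dim1=0.011 dim2=1.000 best=1.000
((CHB:4.95998,JPT:4.95998):6.32802,(CEU:10.7188,YRI:10.7188):0.569204);
```

The two 3-D point sheets are curved and interleaved, so no PCA axis
separates them (best C-score 0.80, mixed ordering), while ncMCE's second
dimension splits them perfectly (C-score 1.000). The simulated
four-population genotypes are summarised per population and clustered by
UPGMA: the two closely related populations (drift 0.02 from their common
ancestor) join first, exactly as built into the simulation topology.

## Command line

Every operation is also exposed as a subcommand writing TSV plus a
`.run.json` provenance record:

```sh
ncmce simulate curved --n 100 --stretch 0.0 --seed 7 --out pts.tsv
ncmce embed geno.csv --method ncmce --dims 2 --out coords.tsv
ncmce cscore --coords coords.tsv --labels labels.tsv --dims 1,2 --out scores.tsv
ncmce impute geno.csv --strategy mode --out imputed.csv
ncmce test-snps geno.csv --groups labels.tsv --alpha 0.01 --correction bh --out snps.tsv
ncmce tree geno.csv --labels labels.tsv --out tree.nwk
```

Exit codes: 0 success, 1 data error, 2 usage error.

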