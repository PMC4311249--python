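# Methods

This note documents the models, numerical conventions and design choices
behind the package, and what the synthetic benchmarks do and do not show.

## Embeddings

**Pipeline.** Individuals are rows of a numeric matrix. Pairwise distances
(Euclidean, or correlation distance `1 − r` with range [0, 2]) weight a
complete graph; its minimum spanning tree is extracted; the MC-kernel `D`
collects path distances over the tree; coordinates come from the SVD of
`D` (ncMCE), of the double-centred `J D J` (MCE), or of the column-centred
data matrix (PCA).

**Why the MST.** Path distances over the MST approximate geodesic
distances through the sampled manifold: within a dense cluster they stay
short, while any route between well-separated clusters funnels through the
single cheapest bridge, so the kernel amplifies cluster gaps that a
straight-line metric blurs. The kernel is an additive tree metric (it
satisfies the four-point condition, verified by test), and it dominates
the input metric entrywise whenever the input satisfies the triangle
inequality.

**Numerical conventions.**

- MST: Prim on the dense matrix, O(n²); weight ties break by lexicographic
  order of the sorted index pair, making the tree — and everything
  downstream — deterministic.
- All-pairs tree distances via shortest-path traversal of the sparse tree
  adjacency (O(n²) total); no Floyd–Warshall.
- The kernel is symmetric, so its SVD is computed as the eigendecomposition
  (singular values `|λ|`, vectors shared). This is exact, deterministic,
  and in degenerate subspaces returns the natural symmetric/antisymmetric
  basis. Ties in `|λ|` order the positive eigenvalue first. For n > 500
  and small d, only the top triplets are computed (Lanczos).
- Coordinates are `√S · V` columns; each dimension's sign is flipped so its
  largest-magnitude coordinate is positive (reproducible plots).
- PCA scores are `U S` of the centred matrix; the spectrum holds
  per-component variances (`S²/(n−1)`), summing to the total column
  variance.
- Reported dimensions follow spectral order. For the *non-centred* kernel
  the leading singular vector is nearly constant (overall magnitude), so
  discrimination is expected on dimension 2; `best_cscore` therefore
  always scans a dimension list (default 1–2).

## C-score

For groups `P_i`, projections `p(x)`: for each unordered pair `(P_i, P_j)`
let `f_ij = [#{p(x) > p(y)} + ½·#ties] / (|P_i|·|P_j|)` over cross pairs
`(x ∈ P_i, y ∈ P_j)`; the pair score is `2·|f_ij − ½|` and the C-score is
the unweighted mean over pairs. Properties (all property-tested):
invariant under strictly increasing transforms, reflection and group
relabelling; 1 exactly when groups occupy disjoint intervals; 0 for an
exactly balanced interleave. Ties contribute ½ per the rank-statistic
convention; multi-group aggregation is unweighted by design (a small,
well-separated group counts as much as a large one).

## Preprocessing

- **Imputation** replaces the missing code 3 column-wise by the
  mode/mean/median of observed values; mode ties break to the smaller
  genotype value (wild-type convention); mean/median keep fractional
  values unrounded, since the matrix feeds numeric embeddings. Imputation
  is idempotent and never touches observed cells.
- **Rank-sum testing** compares each SNP column between two groups,
  two-sided. With `min(|A|,|B|) ≤ 8` (and ≤ 18 pooled) the p-value is an
  exact full enumeration over group assignments with midrank ties;
  otherwise the normal approximation with tie and continuity corrections.
  Constant columns return p = 1.0 by convention. Tests are run on the
  **raw** matrix — the missing code 3 participates as a numeric value —
  matching the convention of validating group splits discovered on
  unimputed data.
- **Selection** keeps `p ≤ α` (boundary inclusive), ordered by (p, index),
  optionally after Benjamini–Hochberg adjustment at the same α = 0.01
  (no separate level is specified for the corrected analysis).
- **Heat-map transform**: elementwise `log10(1 + value)`; the missing code
  transforms like any other value.

## Population trees

Populations are summarised by per-SNP mean genotype after mode imputation
(averaging the literal code 3 would distort the means; a raw-average mode
is available), compared by Euclidean distance, and clustered by UPGMA
(unweighted average linkage, scipy). The dendrogram is ultrametric; Newick
export halves merge heights into branch lengths and quotes names when
needed. Round-trips are verified with an independent parser (dendropy).

## Synthetic generators

All generators are pure functions of their seed.

**Curved clusters.** Two sheets sampled as
`(u, r·sinθ, r·(1−stretch)·cosθ + c·gap)`, `c ∈ {0,1}`, with isotropic
Gaussian noise. Defaults (frozen): radius 3, arc half-angle 60°, axial
extent `u ∈ [0, 0.5]`, gap 0.85, noise SD 0.03, 100 points per sheet.
The defaults were chosen so that, simultaneously: (i) at stretch 0 no
hyperplane separates the sheets (each sheet's feet reach below and its
crown above the other's span), so PCA mixes them on every axis; (ii) the
gap axis always carries the second-largest variance, so once `stretch → 1`
flattens the sheets into parallel planes PCA separates them on PC2; (iii)
the sheets are vertically parallel at *every* stretch (they never cross
mid-sweep), and their minimum distance (≈ gap·cos 60° ≈ 0.43) stays well
above typical nearest-neighbour spacing (≈ 0.09), so the MST crosses
between sheets on a single bridge and ncMCE's dimension 2 splits them at
any stretch. PCA's overlap on the gap axis vanishes near stretch ≈ 0.55,
producing a sharp quality transition at intermediate stretch. Limitation:
with 100 points per sheet there is a small per-seed probability (~2% at
stretch 0) that a Poisson sampling void along a sheet exceeds the
cross-sheet distance; the MST then gains a second bridge and the clean
split degrades. The generator checks the separation margin and logs a
warning when it is violated.

**Balding–Nichols genotypes.** Per SNP an ancestral frequency
`p ~ U(0.05, 0.95)`; along each branch of a nested population topology
with drift `F ∈ (0,1)`, a child frequency
`~ Beta(p(1−F)/F, (1−p)(1−F)/F)` (mean `p`, variance `F·p(1−p)`, so `F`
acts as the branch's F_ST — verified against a Weir–Cockerham estimate);
leaf genotypes `~ Binomial(2, p_leaf)`. Frequencies are clipped to
[10⁻³, 1−10⁻³]. The model is closed-form and fast; it deliberately omits
linkage disequilibrium, coalescent noise, admixture and ascertainment
bias, so its populations are isotropic dosage clouds — linearly separable
whenever detectable. Conclusions about *nonlinear* advantages of the
embedding therefore rest on the curved-cluster and missingness scenarios,
not on clean drift simulations.

**Missingness.** MCAR sets cells to 3 independently. The group-biased
mode emulates platform artefacts: masks operate on whole (SNP, group)
blocks — per SNP, an independent Bernoulli decides whether the probe
failed for the biased tier (twice a base rate) or for the background tier
(half the base rate), the base rate solved so the expected overall
missingness hits the target. A block failure writes 3 into every cell of
that group at that SNP; when both tiers fire at one SNP the background
block is suppressed so no SNP is ever entirely missing. Cell-level
i.i.d. missingness was considered and rejected for this mode: it acts as
per-individual outlier noise, which is *not* the structured, group-aligned
perturbation the mode is meant to model, and it degrades the MST rather
than the linear projection.

**Planted differentiated SNPs.** Two groups share base frequencies
`U(0.2, 0.8)` except at a planted subset shifted by ±`freq_shift/2`
(default 0.4). Fixed displacement (rather than random drift draws) makes
"truly differentiated" well-defined, so recovery rates are meaningful.

## Benchmark scenarios and their limits

- *Curved clusters / stretch sweep*: ncMCE holds a C-score of 1.0 across
  the whole sweep; PCA rises from ≈ 0.8 at stretch 0 to 1.0 once flat,
  monotonically. These synthetic sheets are idealised: real genotype
  manifolds are noisier and higher-dimensional, so a perfect 1.0 should
  not be expected on real data.
- *Structured missingness* (two populations, per-branch drift 0.02,
  0.73 % overall group-biased missingness, 100 individuals/population ×
  5000 SNPs): ncMCE separates the populations on the raw matrix and mode
  imputation restores PCA, as expected. However, PCA on the raw matrix
  *also* separates them: at this missingness rate the perturbation energy
  (~rate·E[(3−g)²] per SNP) is comparable to — not larger than — the
  drift signal (~8F·E[p(1−p)] per SNP), and a group-aligned perturbation
  only reinforces the split. A perturbation strong enough to displace
  PCA's top two components would have to be group-unaligned and several
  times stronger, at which point it dominates the distance metric and
  breaks the MST embedding too. Within this simulator family the
  "PCA blind on raw data" behaviour is therefore not reproducible at
  these parameter values, and the corresponding check is expected to
  fail; the real-data analogue plausibly sits near PCA's detection
  threshold, a regime this clean drift model does not enter.
- *SNP-selection rescue*: with 200 planted SNPs among 5000 and 100
  individuals per group, rank-sum selection at p ≤ 0.01 recovers
  essentially all planted SNPs (power at effect 0.4 is near 1) plus ~1 %
  false positives, and PCA restricted to the selection separates the
  groups cleanly.
- *Topology recovery*: on the balanced quartet ((A,B),(C,D)) with sister
  drift half the cross drift (0.02 vs 0.04 path), UPGMA on mode-imputed
  representatives (20 individuals/population × 1000 SNPs) recovers the
  topology in ≥ 95 of 100 seeds.

Problem sizes throughout were chosen to make each scenario decisive yet
quick: the full suite runs in well under a minute of embedding time, with
the largest instance at 200 × 50 000 used only in exploratory checks.
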