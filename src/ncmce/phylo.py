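"""Population-representative construction and UPGMA dendrograms.

Each population is summarised by the per-SNP arithmetic mean over its
members (after mode imputation by default, so that missing codes do not
distort the means), representatives are compared by Euclidean distance and
hierarchically clustered with unweighted average linkage (UPGMA), giving an
ultrametric dendrogram exportable as Newick.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform

from .errors import DomainError, GenotypeStructureError, LabelError
from .genotype_io import GenotypeMatrix, MISSING
from .embedding import DistanceMatrix, pairwise_distances
from .preprocess import impute_missing


@dataclass
class LinkageTree:
    """UPGMA merge history over named leaves.

    ``merges`` holds ``(cluster_a, cluster_b, height, size)`` rows in merge
    order, using the scipy convention (clusters 0..n-1 are leaves, cluster
    ``n + k`` is created by merge *k*).  Heights are non-decreasing.
    """

    merges: list[tuple[int, int, float, int]]
    leaf_names: list[str]

    @property
    def n_leaves(self) -> int:
        return len(self.leaf_names)

    def linkage_matrix(self) -> np.ndarray:
        """The scipy ``(n-1) x 4`` linkage array."""
        return np.asarray(self.merges, dtype=float)

    def cophenetic_matrix(self) -> np.ndarray:
        """Pairwise merge heights between leaves (an ultrametric)."""
        return squareform(hierarchy.cophenet(self.linkage_matrix()))


def population_representatives(
    g: GenotypeMatrix, impute: bool = True
) -> pd.DataFrame:
    """Per-population mean genotype vectors (populations x SNPs).

    With ``impute`` (default) the matrix is mode-imputed first; otherwise
    raw values are averaged, missing code 3 included.
    """
    if g.labels is None:
        raise LabelError("population representatives need labelled samples")
    if impute and g.integer_coded and np.any(g.values == MISSING):
        g = impute_missing(g, "mode")
    frame = pd.DataFrame(g.values, index=g.label_array(), columns=g.snp_ids)
    reps = frame.groupby(level=0).mean()
    return reps.sort_index()


def upgma(d: DistanceMatrix) -> LinkageTree:
    """Unweighted pair-group average linkage over a distance matrix."""
    if d.n < 2:
        raise DomainError("UPGMA needs >= 2 populations")
    z = hierarchy.linkage(squareform(d.values, checks=False), method="average")
    merges = [(int(a), int(b), float(h), int(s)) for a, b, h, s in z]
    return LinkageTree(merges, list(d.ids))


def population_tree(g: GenotypeMatrix, impute: bool = True) -> LinkageTree:
    """Convenience flow: representatives -> Euclidean distances -> UPGMA."""
    reps = population_representatives(g, impute=impute)
    d = pairwise_distances(reps.to_numpy(), norm="euclidean", ids=list(reps.index))
    return upgma(d)


def _newick_name(name: str) -> str:
    """Quote names containing Newick metacharacters or whitespace."""
    if any(c in name for c in " \t()[]:;,'"):
        return "'" + name.replace("'", "''") + "'"
    return name


def to_newick(t: LinkageTree) -> str:
    """Newick string of the UPGMA tree (ultrametric branch lengths).

    A node merged at height ``h`` sits at depth ``h / 2`` from the leaves,
    so a child merged (or a leaf) at height ``h_c`` gets branch length
    ``(h - h_c) / 2``.
    """
    n = t.n_leaves
    if len(t.merges) != n - 1:
        raise GenotypeStructureError("linkage does not cover all leaves")
    heights = {i: 0.0 for i in range(n)}
    children: dict[int, tuple[int, int]] = {}
    for k, (a, b, h, _size) in enumerate(t.merges):
        node = n + k
        heights[node] = h
        children[node] = (a, b)

    def render(node: int, parent_h: float) -> str:
        length = (parent_h - heights[node]) / 2.0
        if node < n:
            return f"{_newick_name(t.leaf_names[node])}:{length:g}"
        a, b = children[node]
        inner = ",".join(render(c, heights[node]) for c in (a, b))
        if parent_h == heights[node]:  # root
            return f"({inner})"
        return f"({inner}):{length:g}"

    root = n + len(t.merges) - 1
    return render(root, heights[root]) + ";"


def leaf_clades(t: LinkageTree) -> set[frozenset[str]]:
    """Non-trivial clades as leaf-name sets (topology fingerprint)."""
    n = t.n_leaves
    members: dict[int, frozenset[str]] = {
        i: frozenset([t.leaf_names[i]]) for i in range(n)
    }
    clades: set[frozenset[str]] = set()
    for k, (a, b, _h, _s) in enumerate(t.merges):
        merged = members[a] | members[b]
        members[n + k] = merged
        if 1 < len(merged) < n:
            clades.add(merged)
    return clades
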