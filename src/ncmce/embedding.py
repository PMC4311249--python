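"""The algorithmic core: MST-kernel embeddings and a PCA baseline.

Minimum Curvilinearity estimates curvilinear (geodesic-like) distances
between samples as path distances over the minimum spanning tree (MST) of
the complete sample-to-sample distance graph.  The pipeline is

    data -> pairwise distances A -> MST T -> MC-kernel D -> SVD -> coords

where the MC-kernel entry ``D[i, j]`` is the summed edge weight along the
unique tree path from *i* to *j* (an additive tree metric).  ncMCE applies
an economy-size SVD directly to the non-centred kernel and places sample
*j* on embedding dimension *m* at ``sqrt(S_m) * V[j, m]``; MCE first
double-centres the kernel with ``J = I - (1/n) 11^T``.  For the
non-centred kernel, dimension 1 typically captures overall magnitude and
group discrimination appears on dimension 2 — plots and scores should
always consider both.

PCA (column-centred SVD scores) is included as the linear baseline.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import dijkstra
from scipy.spatial.distance import pdist, squareform

from .errors import (
    DimensionError,
    DomainError,
    GenotypeStructureError,
    NcmceDataError,
)
from .genotype_io import GenotypeMatrix

logger = logging.getLogger(__name__)

#: above this sample count, only the top-d singular triplets are computed
FULL_SVD_MAX_N = 500

Norm = Literal["euclidean", "correlation"]
Method = Literal["ncMCE", "MCE", "PCA"]


# -- containers ----------------------------------------------------------


@dataclass
class DistanceMatrix:
    """Symmetric zero-diagonal pairwise dissimilarities."""

    values: np.ndarray
    ids: list[str]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n = self.values.shape[0]
        if self.values.shape != (n, n) or n != len(self.ids):
            raise GenotypeStructureError("distance matrix shape/id mismatch")
        if not np.all(np.isfinite(self.values)):
            raise NcmceDataError("distance matrix contains non-finite entries")

    @property
    def n(self) -> int:
        return self.values.shape[0]


@dataclass
class SpanningTree:
    """``n - 1`` weighted edges ``(i, j, w)`` with ``i < j`` over n nodes."""

    edges: list[tuple[int, int, float]]
    n: int

    def total_weight(self) -> float:
        return float(sum(w for _, _, w in self.edges))


@dataclass
class MCKernel:
    """All-pairs path distances over the MST (additive tree metric)."""

    values: np.ndarray
    ids: list[str]


@dataclass
class Embedding:
    """Per-sample coordinates over spectrally ordered dimensions.

    ``coords[:, k]`` is embedding dimension ``k + 1``; ``spectrum`` holds the
    associated singular values (ncMCE/MCE) or explained variances (PCA),
    non-increasing.
    """

    coords: np.ndarray
    spectrum: np.ndarray
    method: Method
    ids: list[str]

    @property
    def n_dims(self) -> int:
        return self.coords.shape[1]

    def dimension(self, d: int) -> np.ndarray:
        """1-based projection onto embedding dimension ``d``."""
        if not 1 <= d <= self.n_dims:
            raise DimensionError(f"dimension {d} outside 1..{self.n_dims}")
        return self.coords[:, d - 1]


# -- pairwise distances --------------------------------------------------


def pairwise_distances(
    x: GenotypeMatrix | np.ndarray,
    norm: Norm = "euclidean",
    ids: Sequence[str] | None = None,
) -> DistanceMatrix:
    """All-pairs distances between row vectors.

    ``euclidean`` is the L2 norm; ``correlation`` is ``1 - r`` (Pearson),
    ranging over [0, 2].  Constant rows are rejected under the correlation
    norm (undefined r).
    """
    if isinstance(x, GenotypeMatrix):
        mat = x.values
        row_ids = list(x.sample_ids)
    else:
        mat = np.asarray(x, dtype=float)
        row_ids = list(ids) if ids is not None else [str(i) for i in range(len(mat))]
    if mat.ndim != 2 or mat.shape[0] < 2:
        raise DomainError("pairwise_distances needs a 2-D matrix with >= 2 rows")
    if norm == "euclidean":
        d = squareform(pdist(mat, metric="euclidean"))
    elif norm == "correlation":
        if mat.shape[1] < 2:
            raise DomainError("correlation norm needs >= 2 columns")
        sd = mat.std(axis=1)
        bad = np.flatnonzero(sd == 0)
        if bad.size:
            raise DomainError(
                f"correlation undefined for constant row(s): {[row_ids[i] for i in bad]}"
            )
        d = squareform(pdist(mat, metric="correlation"))
    else:
        raise DomainError(f"unknown norm {norm!r}")
    np.fill_diagonal(d, 0.0)
    return DistanceMatrix(d, row_ids)


# -- minimum spanning tree ----------------------------------------------


def minimum_spanning_tree(d: DistanceMatrix) -> SpanningTree:
    """Prim's algorithm on the dense matrix, O(n^2).

    Deterministic: weight ties are broken by lexicographic order of the
    sorted edge pair ``(min(i, j), max(i, j))``.
    """
    n = d.n
    if n < 2:
        raise DomainError("spanning tree needs >= 2 nodes")
    w = d.values
    in_tree = np.zeros(n, dtype=bool)
    in_tree[0] = True
    # best_w[v] / best_u[v]: cheapest edge linking outside node v to the tree
    best_w = w[0].copy()
    best_u = np.zeros(n, dtype=int)
    edges: list[tuple[int, int, float]] = []
    for _ in range(n - 1):
        cand = np.flatnonzero(~in_tree)
        # order candidates by (weight, sorted pair) — lexicographic tie rule
        keys = [
            (best_w[v], min(best_u[v], v), max(best_u[v], v)) for v in cand
        ]
        v = cand[min(range(len(cand)), key=keys.__getitem__)]
        u = best_u[v]
        edges.append((min(u, v), max(u, v), float(w[u, v])))
        in_tree[v] = True
        # relax: node v may now offer cheaper (or lexicographically smaller) links
        out = ~in_tree
        better = out & (
            (w[v] < best_w)
            | (
                (w[v] == best_w)
                & (
                    (np.minimum(v, np.arange(n)) < np.minimum(best_u, np.arange(n)))
                    | (
                        (np.minimum(v, np.arange(n)) == np.minimum(best_u, np.arange(n)))
                        & (np.maximum(v, np.arange(n)) < np.maximum(best_u, np.arange(n)))
                    )
                )
            )
        )
        best_w[better] = w[v, better]
        best_u[better] = v
    edges.sort()
    return SpanningTree(edges, n)


# -- MC-kernel -----------------------------------------------------------


def mc_kernel(t: SpanningTree, ids: Sequence[str] | None = None) -> MCKernel:
    """All-pairs path distances over the spanning tree.

    Computed by a shortest-path traversal from every node over the sparse
    tree adjacency (O(n^2) total on a tree).
    """
    n = t.n
    if len(t.edges) != n - 1:
        raise GenotypeStructureError(
            f"{len(t.edges)} edges for {n} nodes — not a spanning tree"
        )
    rows = [i for i, _, _ in t.edges] + [j for _, j, _ in t.edges]
    cols = [j for _, j, _ in t.edges] + [i for i, _, _ in t.edges]
    data = [w for _, _, w in t.edges] * 2
    adj = csr_matrix((data, (rows, cols)), shape=(n, n))
    dist = dijkstra(adj, directed=False)
    if not np.all(np.isfinite(dist)):
        raise GenotypeStructureError("edge set is disconnected")
    dist = (dist + dist.T) / 2.0
    np.fill_diagonal(dist, 0.0)
    if ids is None:
        ids = [str(i) for i in range(n)]
    return MCKernel(dist, list(ids))


# -- SVD embeddings ------------------------------------------------------


def _fix_signs(coords: np.ndarray) -> np.ndarray:
    """Flip each dimension so its largest-|coordinate| entry is positive."""
    for m in range(coords.shape[1]):
        col = coords[:, m]
        if col[np.argmax(np.abs(col))] < 0:
            coords[:, m] = -col
    return coords


def _svd_embed(k: np.ndarray, d: int) -> tuple[np.ndarray, np.ndarray]:
    """Top-d singular triplets of the symmetric kernel ``k``.

    For a symmetric matrix the SVD coincides with the eigendecomposition up
    to signs (singular values ``|lambda|``, right singular vectors the
    eigenvectors), which is what is computed here: it is deterministic and,
    in degenerate subspaces, yields the natural eigenbasis.  Ties in
    ``|lambda|`` order the positive eigenvalue first.  Coordinates are
    ``sqrt(S) * V`` columns.
    """
    n = k.shape[0]
    if not 1 <= d <= n:
        raise DimensionError(f"embedding dimension {d} outside 1..{n}")
    if n <= FULL_SVD_MAX_N or d >= n - 1:
        lam, vec = np.linalg.eigh(k)
    else:
        from scipy.sparse.linalg import eigsh

        lam, vec = eigsh(k, k=min(d + 1, n - 1), which="LM")
    order = np.lexsort((-lam, -np.abs(lam)))[:d]
    s = np.abs(lam[order])
    coords = vec[:, order] * np.sqrt(s)
    return _fix_signs(coords), s


def ncmce_embed(k: MCKernel, d: int = 2) -> Embedding:
    """Non-centred MCE: economy-size SVD of the raw MC-kernel."""
    coords, s = _svd_embed(k.values, d)
    return Embedding(coords, s, "ncMCE", list(k.ids))


def mce_embed(k: MCKernel, d: int = 2) -> Embedding:
    """Centred MCE: double-centre the kernel (J K J) before the SVD."""
    n = k.values.shape[0]
    j = np.eye(n) - np.full((n, n), 1.0 / n)
    centred = j @ k.values @ j
    coords, s = _svd_embed(centred, d)
    return Embedding(coords, s, "MCE", list(k.ids))


def pca_embed(
    x: GenotypeMatrix | np.ndarray,
    d: int = 2,
    ids: Sequence[str] | None = None,
) -> Embedding:
    """PCA baseline: scores of the column-centred matrix.

    ``spectrum`` holds per-component variances (squared singular values over
    ``n - 1``); their sum equals the total column variance.
    """
    if isinstance(x, GenotypeMatrix):
        mat = x.values
        row_ids = list(x.sample_ids)
    else:
        mat = np.asarray(x, dtype=float)
        row_ids = list(ids) if ids is not None else [str(i) for i in range(len(mat))]
    n = mat.shape[0]
    if n < 2:
        raise DomainError("PCA needs >= 2 rows")
    if not 1 <= d <= min(mat.shape):
        raise DimensionError(f"dimension {d} outside 1..{min(mat.shape)}")
    centred = mat - mat.mean(axis=0, keepdims=True)
    u, s, _ = np.linalg.svd(centred, full_matrices=False)
    scores = _fix_signs(u[:, :d] * s[:d])
    variances = (s[:d] ** 2) / (n - 1)
    return Embedding(scores, variances, "PCA", row_ids)


# -- pipeline ------------------------------------------------------------


def embed_pipeline(
    g: GenotypeMatrix | np.ndarray,
    method: Method = "ncMCE",
    norm: Norm = "euclidean",
    d: int = 2,
    ids: Sequence[str] | None = None,
) -> Embedding:
    """Full flow: distances -> MST -> MC-kernel -> SVD (or PCA directly)."""
    if method == "PCA":
        if norm != "euclidean":
            logger.info("embed_pipeline: norm %r ignored for PCA", norm)
        return pca_embed(g, d, ids=ids)
    dist = pairwise_distances(g, norm=norm, ids=ids)
    tree = minimum_spanning_tree(dist)
    kernel = mc_kernel(tree, ids=dist.ids)
    if method == "ncMCE":
        return ncmce_embed(kernel, d)
    if method == "MCE":
        return mce_embed(kernel, d)
    raise DomainError(f"unknown method {method!r}")
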