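"""Concordance score (C-score): 1-D separability of labelled groups.

The C-score quantifies how cleanly labelled groups occupy disjoint
intervals of a one-dimensional projection.  For each unordered pair of
groups (P_i, P_j),

    f_ij = [ #{(x in P_i, y in P_j) : p(x) > p(y)} + (1/2) #ties ]
           / (|P_i| |P_j|)

(the rank-statistic AUC of group i over group j), the pair score is
``s_ij = 2 |f_ij - 1/2|`` and the C-score is the unweighted mean of the
``s_ij`` over all pairs.  It ranges from 0 (exactly balanced interleaving,
no structure) to 1 (groups appear one after the other with no mixing) and
is invariant under strictly increasing transforms, reflection of the axis
and relabelling of the groups.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats

from .errors import GroupingError, NcmceUsageError
from .embedding import Embedding


@dataclass
class CScoreResult:
    """Per-dimension C-scores and their maximum."""

    per_dimension: list[float]
    best: float
    dims_considered: list[int]

    @property
    def best_dimension(self) -> int:
        """1-based index (within ``dims_considered``) achieving ``best``."""
        return self.dims_considered[int(np.argmax(self.per_dimension))]


def cscore(projection: Sequence[float], labels: Sequence[str]) -> float:
    """C-score of a 1-D projection against group labels.

    Ties in projected values contribute 1/2 to the pair count.  Requires at
    least two non-empty groups.
    """
    p = np.asarray(projection, dtype=float)
    labels = np.asarray(labels, dtype=object)
    if p.ndim != 1 or p.shape[0] != labels.shape[0]:
        raise NcmceUsageError("projection and labels must be 1-D and equal-length")
    groups = sorted(set(labels.tolist()))
    if len(groups) < 2:
        raise GroupingError("C-score needs at least two distinct groups")
    ranks = stats.rankdata(p)  # midranks: ties contribute 1/2 automatically
    by_group = {g: ranks[labels == g] for g in groups}
    scores = []
    for a_idx in range(len(groups)):
        for b_idx in range(a_idx + 1, len(groups)):
            ra = by_group[groups[a_idx]]
            rb = by_group[groups[b_idx]]
            # midranks of the pooled sample restricted to the two groups
            sub = stats.rankdata(np.concatenate([ra, rb]))
            na, nb = ra.size, rb.size
            u = sub[:na].sum() - na * (na + 1) / 2  # pairs won + ties/2
            f = u / (na * nb)
            scores.append(2.0 * abs(f - 0.5))
    return float(np.mean(scores))


def best_cscore(
    e: Embedding,
    labels: Sequence[str],
    dims: Sequence[int] = (1, 2),
) -> CScoreResult:
    """C-score per embedding dimension (1-based) and the best of them."""
    dims = list(dims)
    if not dims:
        raise NcmceUsageError("dims must be non-empty")
    per_dim = [cscore(e.dimension(d), labels) for d in dims]
    return CScoreResult(per_dim, float(max(per_dim)), dims)
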