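"""Missing-data imputation, per-SNP rank-sum testing and SNP selection.

Imputation replaces every missing code (3) in a SNP column by the mode,
mean or median of that column's observed values; mode ties break toward the
smaller genotype value (wild-type convention).  Group comparison uses the
two-sided Mann-Whitney/Wilcoxon rank-sum test applied to each SNP column of
the RAW matrix (missing codes participate as the literal value 3), followed
by selection at ``p <= alpha`` either uncorrected or with Benjamini-Hochberg
FDR control.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from itertools import combinations
from typing import Iterable, Literal, Sequence

import numpy as np
from scipy import stats

from .errors import DomainError, GroupingError, ImputationError, StateError
from .genotype_io import MISSING, GenotypeMatrix

logger = logging.getLogger(__name__)

#: group-size threshold below which exact enumeration is used
EXACT_MAX_GROUP = 8

Strategy = Literal["mode", "mean", "median"]
Correction = Literal["none", "benjamini_hochberg"]


@dataclass(frozen=True)
class SnpTestResult:
    """Two-group rank-sum test result for a single SNP column."""

    snp_index: int
    p_value: float
    adjusted_p: float | None = None


# -- missingness ---------------------------------------------------------


def missing_rate(g: GenotypeMatrix) -> float:
    """Fraction of cells equal to the missing code 3."""
    if not g.integer_coded:
        raise StateError("missing_rate requires an integer-coded matrix")
    return float(np.mean(g.values == MISSING))


def impute_missing(g: GenotypeMatrix, strategy: Strategy = "mode") -> GenotypeMatrix:
    """Column-wise imputation of the missing code 3.

    Every 3 in column *j* is replaced by the mode / mean / median of the
    observed (non-3) values of column *j*; observed cells are untouched.
    Mode ties break to the smallest genotype value.
    """
    if not g.integer_coded:
        raise StateError("impute_missing requires an integer-coded matrix")
    if strategy not in ("mode", "mean", "median"):
        raise DomainError(f"unknown imputation strategy {strategy!r}")
    values = g.values.copy()
    miss = values == MISSING
    for j in np.flatnonzero(miss.any(axis=0)):
        observed = values[~miss[:, j], j]
        if observed.size == 0:
            raise ImputationError(
                f"SNP {g.snp_ids[j]!r} (column {j}) is entirely missing"
            )
        if strategy == "mode":
            codes, counts = np.unique(observed, return_counts=True)
            fill = codes[counts == counts.max()].min()
        elif strategy == "mean":
            fill = observed.mean()
        else:
            fill = float(np.median(observed))
        values[miss[:, j], j] = fill
    return g.with_values(values)


# -- Mann-Whitney rank-sum testing ---------------------------------------


def _midrank_u(a: np.ndarray, b: np.ndarray) -> float:
    """U statistic of group *a* vs *b* with ties counted 1/2."""
    pooled = np.concatenate([a, b])
    ranks = stats.rankdata(pooled)
    return float(ranks[: a.size].sum() - a.size * (a.size + 1) / 2)


def _exact_two_sided_p(a: np.ndarray, b: np.ndarray) -> float:
    """Exact two-sided p by full enumeration of group assignments.

    Enumerates all C(n, |a|) ways of assigning the pooled values to group A
    and counts assignments whose midrank U is at least as far from the null
    mean ``|a||b|/2`` as the observed one.
    """
    pooled = np.concatenate([a, b])
    n, na = pooled.size, a.size
    ranks = stats.rankdata(pooled)
    offset = na * (na + 1) / 2
    mu = na * b.size / 2
    u_obs = ranks[:na].sum() - offset
    dev_obs = abs(u_obs - mu)
    hits = total = 0
    for idx in combinations(range(n), na):
        u = ranks[list(idx)].sum() - offset
        total += 1
        if abs(u - mu) >= dev_obs - 1e-12:
            hits += 1
    return hits / total


def rank_sum_test(a: Sequence[float], b: Sequence[float]) -> float:
    """Two-sided Mann-Whitney p-value for one column.

    Exact enumeration when ``min(|a|,|b|) <= EXACT_MAX_GROUP``; otherwise the
    normal approximation with tie and continuity corrections.  A column that
    is constant across both groups returns 1.0 by convention.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise GroupingError("both groups must be non-empty")
    pooled = np.concatenate([a, b])
    if np.all(pooled == pooled[0]):
        return 1.0
    if min(a.size, b.size) <= EXACT_MAX_GROUP and a.size + b.size <= 18:
        return _exact_two_sided_p(a, b)
    res = stats.mannwhitneyu(
        a, b, alternative="two-sided", method="asymptotic", use_continuity=True
    )
    return float(res.pvalue)


def mannwhitney_snps(
    g: GenotypeMatrix,
    group_a: Iterable[str],
    group_b: Iterable[str],
) -> list[SnpTestResult]:
    """Per-SNP two-sided rank-sum test of group A vs group B.

    Raw values are compared as-is (a missing code 3 participates as the
    numeric value 3, matching the convention of testing the unimputed
    matrix).  Constant columns get ``p = 1.0`` and are logged.
    """
    group_a = list(group_a)
    group_b = list(group_b)
    if set(group_a) & set(group_b):
        raise GroupingError("groups overlap")
    if not group_a or not group_b:
        raise GroupingError("both groups must be non-empty")
    ia = g.sample_indices(group_a)
    ib = g.sample_indices(group_b)
    xa = g.values[ia]
    xb = g.values[ib]
    n_snps = g.n_snps
    pvals = np.ones(n_snps)

    constant = np.array(
        [np.all(col == col[0]) for col in np.vstack([xa, xb]).T], dtype=bool
    )
    if constant.any():
        logger.info("mannwhitney_snps: %d constant column(s) set to p=1.0",
                    int(constant.sum()))

    if min(len(ia), len(ib)) <= EXACT_MAX_GROUP and len(ia) + len(ib) <= 18:
        for j in range(n_snps):
            if not constant[j]:
                pvals[j] = _exact_two_sided_p(xa[:, j], xb[:, j])
    else:
        keep = ~constant
        if keep.any():
            res = stats.mannwhitneyu(
                xa[:, keep], xb[:, keep], axis=0,
                alternative="two-sided", method="asymptotic", use_continuity=True,
            )
            pvals[keep] = np.clip(res.pvalue, 0.0, 1.0)
    return [SnpTestResult(j, float(pvals[j])) for j in range(n_snps)]


def benjamini_hochberg(pvalues: Sequence[float]) -> np.ndarray:
    """Step-up BH adjusted p-values (monotone, order preserving)."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p
    return stats.false_discovery_control(p, method="bh")


def select_significant(
    results: Sequence[SnpTestResult],
    alpha: float = 0.01,
    correction: Correction = "none",
) -> list[int]:
    """Indices of significant SNPs, ascending by p (ties by index).

    ``correction="none"`` selects raw ``p <= alpha`` (boundary inclusive);
    ``"benjamini_hochberg"`` selects BH-adjusted ``p <= alpha``.
    """
    if not 0 < alpha < 1:
        raise DomainError(f"alpha must lie in (0,1), got {alpha}")
    if not results:
        return []
    order_key = sorted(results, key=lambda r: (r.p_value, r.snp_index))
    if correction == "none":
        return [r.snp_index for r in order_key if r.p_value <= alpha]
    if correction == "benjamini_hochberg":
        p = [r.p_value for r in results]
        adj = benjamini_hochberg(p)
        adj_by_index = {r.snp_index: a for r, a in zip(results, adj)}
        return [r.snp_index for r in order_key if adj_by_index[r.snp_index] <= alpha]
    raise DomainError(f"unknown correction {correction!r}")


def attach_adjusted(results: Sequence[SnpTestResult]) -> list[SnpTestResult]:
    """Copies of ``results`` with BH-adjusted p-values filled in."""
    adj = benjamini_hochberg([r.p_value for r in results])
    return [
        SnpTestResult(r.snp_index, r.p_value, float(a))
        for r, a in zip(results, adj)
    ]


# -- heat-map transform --------------------------------------------------


def heatmap_transform(values: np.ndarray | GenotypeMatrix) -> np.ndarray:
    """Elementwise ``log10(1 + value)`` (the heat-map intensity scale)."""
    x = values.values if isinstance(values, GenotypeMatrix) else np.asarray(values, float)
    if np.any(x < 0):
        raise DomainError("heatmap_transform requires non-negative values")
    return np.log10(1.0 + x)
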