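"""Synthetic data generators for embedding and population-structure studies.

Three generators, all pure functions of their seed:

* :func:`make_curved_clusters` — two interleaved, nonlinearly curved 3-D
  point sheets whose curvature collapses to flat planes as a ``stretch``
  parameter goes from 0 to 1 (the linear-vs-nonlinear benchmark geometry).
* :func:`simulate_genotypes` — tree-structured multi-population SNP
  genotypes under the Balding–Nichols drift model: per SNP an ancestral
  frequency ``p``, per branch with drift ``F`` a child frequency drawn from
  ``Beta(p(1-F)/F, (1-p)(1-F)/F)`` (mean ``p``, variance ``F p(1-p)``, so
  ``F`` plays the role of F_ST), genotypes ``Binomial(2, leaf frequency)``.
* :func:`inject_missing` — MCAR or group-biased missingness masks writing
  the missing code 3 into a genotype matrix.

Curved-sheet geometry: cluster ``c`` is sampled as

    ( u,  r sin(theta),  r (1 - stretch) cos(theta) + c * gap )

with ``u`` uniform along a short axial extent and ``theta`` uniform over a
120-degree arc.  The two sheets are parallel at every stretch (vertical
offset ``gap``), no hyperplane separates them when curved, and the gap axis
always carries the second-largest variance, so a linear method recovers the
clusters only once the curvature is stretched away.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Iterable, Literal, Sequence

import numpy as np
from scipy.spatial.distance import cdist, pdist

from .errors import ConfigError, DomainError
from .genotype_io import MISSING, GenotypeMatrix

logger = logging.getLogger(__name__)

# -- curved clusters -----------------------------------------------------


@dataclass(frozen=True)
class CurvedClusterConfig:
    """Two-sheet curved-cluster benchmark configuration.

    ``stretch`` in [0, 1] interpolates from fully curved arcs (0) to flat
    planes (1); ``gap`` is the constant vertical offset between the sheets;
    ``noise_sd`` is isotropic Gaussian jitter.  The geometry constants
    (radius, arc half-angle, axial extent) define sheets that interleave
    when curved yet keep the gap axis within the top two variance
    directions when flat.
    """

    n_per_cluster: int = 100
    stretch: float = 0.0
    noise_sd: float = 0.03
    gap: float = 0.85
    seed: int = 0
    radius: float = 3.0
    arc_half_angle: float = math.pi / 3
    u_extent: float = 0.5


def make_curved_clusters(
    cfg: CurvedClusterConfig,
) -> tuple[np.ndarray, list[str]]:
    """Sample the two curved sheets; returns ``(points (2n x 3), labels)``.

    Logs a warning when the sampled inter-sheet minimum distance does not
    exceed three times the within-sheet nearest-neighbour spacing (the
    regime in which a single MST bridge is no longer near-certain).
    """
    if not 0.0 <= cfg.stretch <= 1.0:
        raise DomainError(f"stretch must lie in [0,1], got {cfg.stretch}")
    if cfg.noise_sd < 0 or cfg.gap <= 0 or cfg.n_per_cluster < 2:
        raise DomainError("invalid curved-cluster configuration")
    rng = np.random.default_rng(cfg.seed)
    points = []
    labels: list[str] = []
    for c in (0, 1):
        n = cfg.n_per_cluster
        u = rng.uniform(0.0, cfg.u_extent, size=n)
        theta = rng.uniform(-cfg.arc_half_angle, cfg.arc_half_angle, size=n)
        x = np.column_stack(
            [
                u,
                cfg.radius * np.sin(theta),
                cfg.radius * (1.0 - cfg.stretch) * np.cos(theta) + c * cfg.gap,
            ]
        )
        x += rng.normal(scale=cfg.noise_sd, size=x.shape)
        points.append(x)
        labels += [f"cluster{c}"] * n
    pts = np.vstack(points)

    # separation diagnostic: inter-sheet minimum vs within-sheet NN spacing
    inter_min = cdist(points[0], points[1]).min()
    nn = []
    for x in points:
        d = cdist(x, x)
        np.fill_diagonal(d, np.inf)
        nn.append(d.min(axis=0))
    nn_spacing = float(np.mean(np.concatenate(nn)))
    if inter_min <= 3.0 * nn_spacing:
        logger.warning(
            "curved clusters: inter-sheet min distance %.3f <= 3x NN spacing %.3f",
            inter_min, nn_spacing,
        )
    return pts, labels


# -- Balding–Nichols population simulation -------------------------------

#: nested population topology: a leaf is ``(name, F)``, an internal node is
#: ``((child, child, ...), F)``; F is the drift on the branch ABOVE the node.
PopTree = tuple


@dataclass(frozen=True)
class PopSimConfig:
    """Balding–Nichols simulation configuration.

    ``tree`` is the nested population topology with per-branch drift ``F``
    in (0, 1); frequencies are clipped away from {0, 1}; ``missing_mode``
    selects MCAR or group-biased masks applied after genotype sampling.
    """

    tree: PopTree
    n_ind_per_pop: int = 50
    n_snps: int = 1000
    ancestral_freq_range: tuple[float, float] = (0.05, 0.95)
    missing_rate: float = 0.0
    missing_mode: Literal["mcar", "group_biased"] = "mcar"
    seed: int = 0


_FREQ_CLIP = (1e-3, 1.0 - 1e-3)


def _drift(p: np.ndarray, f: float, rng: np.random.Generator) -> np.ndarray:
    """One Balding–Nichols branch: Beta-distributed child frequencies."""
    if not 0.0 <= f < 1.0:
        raise DomainError(f"branch drift F must lie in [0,1), got {f}")
    if f < 1e-12:
        return p.copy()
    a = p * (1.0 - f) / f
    b = (1.0 - p) * (1.0 - f) / f
    return np.clip(rng.beta(a, b), *_FREQ_CLIP)


def _leaf_frequencies(
    node: PopTree, p: np.ndarray, rng: np.random.Generator
) -> dict[str, np.ndarray]:
    head, f = node
    child_p = _drift(p, float(f), rng)
    if isinstance(head, str):
        return {head: child_p}
    out: dict[str, np.ndarray] = {}
    for child in head:
        sub = _leaf_frequencies(child, child_p, rng)
        dup = set(out) & set(sub)
        if dup:
            raise ConfigError(f"duplicate population name(s) in tree: {sorted(dup)}")
        out.update(sub)
    return out


def simulate_genotypes(
    cfg: PopSimConfig, return_freqs: bool = False
) -> GenotypeMatrix | tuple[GenotypeMatrix, dict[str, np.ndarray]]:
    """Simulate tree-structured multi-population genotypes.

    Returns a labelled :class:`GenotypeMatrix` (sample ids ``POP_0001``...);
    with ``return_freqs`` also the per-population leaf allele frequencies.
    Missingness is injected afterwards according to ``missing_rate`` /
    ``missing_mode`` (group-biased masks favour the first population in
    name order at twice the rate, the rest at half).
    """
    lo, hi = cfg.ancestral_freq_range
    if not 0.0 < lo < hi < 1.0:
        raise DomainError("ancestral_freq_range must satisfy 0 < low < high < 1")
    if not 0.0 <= cfg.missing_rate < 1.0:
        raise DomainError("missing_rate must lie in [0,1)")
    rng = np.random.default_rng(cfg.seed)
    p_anc = rng.uniform(lo, hi, size=cfg.n_snps)
    freqs = _leaf_frequencies(cfg.tree, p_anc, rng)
    pops = sorted(freqs)
    blocks = []
    sample_ids: list[str] = []
    labels: dict[str, str] = {}
    for pop in pops:
        geno = rng.binomial(2, freqs[pop], size=(cfg.n_ind_per_pop, cfg.n_snps))
        blocks.append(geno.astype(float))
        for i in range(cfg.n_ind_per_pop):
            sid = f"{pop}_{i:04d}"
            sample_ids.append(sid)
            labels[sid] = pop
    snp_ids = [f"snp{j + 1}" for j in range(cfg.n_snps)]
    g = GenotypeMatrix(np.vstack(blocks), sample_ids, snp_ids, labels=labels)
    if cfg.missing_rate > 0:
        biased = None
        if cfg.missing_mode == "group_biased":
            biased = [s for s in sample_ids if labels[s] == pops[0]]
        g = inject_missing(
            g,
            cfg.missing_rate,
            mode=cfg.missing_mode,
            biased_groups=biased,
            seed=int(rng.integers(2**31 - 1)),
        )
    if return_freqs:
        return g, freqs
    return g


def inject_missing(
    g: GenotypeMatrix,
    rate: float,
    mode: Literal["mcar", "group_biased"] = "mcar",
    biased_groups: Sequence[str] | Iterable[str] | None = None,
    seed: int = 0,
) -> GenotypeMatrix:
    """Write the missing code 3 into a genotype matrix.

    ``mcar``: every cell independently with probability ``rate``.

    ``group_biased`` mimics platform-style artefacts: masks operate on
    whole (SNP, group) blocks, not on individual cells.  For each SNP an
    independent Bernoulli draw decides whether the probe failed for the
    biased tier (samples in ``biased_groups``, at twice a base block rate)
    and another whether it failed for the background tier (everyone else,
    at half the base rate); a firing block sets every cell of that tier at
    that SNP to 3.  The base rate is scaled so the expected overall
    missingness equals ``rate``.  When both tiers fire at the same SNP the
    background block is suppressed so that no SNP is ever entirely missing.
    """
    if not 0.0 <= rate < 1.0:
        raise DomainError(f"missing rate must lie in [0,1), got {rate}")
    rng = np.random.default_rng(seed)
    values = g.values.copy()
    if rate == 0.0:
        return g.with_values(values)
    n, m = g.values.shape
    if mode == "mcar":
        mask = rng.random((n, m)) < rate
        values[mask] = MISSING
    elif mode == "group_biased":
        if biased_groups is None:
            raise ConfigError("group_biased missingness needs biased_groups")
        idx = g.sample_indices(list(biased_groups))
        n_b = idx.size
        if n_b == 0 or n_b == n:
            raise ConfigError("biased_groups must be a proper non-empty subset")
        # solve base so that (2*base*n_b + base/2*(n - n_b)) / n == rate
        base = rate * n / (2.0 * n_b + 0.5 * (n - n_b))
        if 2.0 * base >= 1.0:
            raise ConfigError("group-biased block rate exceeds 1; lower the target")
        fire_biased = rng.random(m) < 2.0 * base
        fire_other = rng.random(m) < base / 2.0
        fire_other &= ~fire_biased  # never produce a fully missing SNP
        other = np.setdiff1d(np.arange(n), idx)
        values[np.ix_(idx, np.flatnonzero(fire_biased))] = MISSING
        values[np.ix_(other, np.flatnonzero(fire_other))] = MISSING
    else:
        raise ConfigError(f"unknown missingness mode {mode!r}")
    return g.with_values(values)


# -- two-group matrix with a planted set of differentiated SNPs ----------


def simulate_differentiated_snps(
    n_per_group: int = 100,
    n_snps: int = 5000,
    n_differentiated: int = 200,
    freq_shift: float = 0.4,
    base_freq_range: tuple[float, float] = (0.2, 0.8),
    seed: int = 0,
) -> tuple[GenotypeMatrix, np.ndarray]:
    """Two groups identical except at a planted subset of SNPs.

    The differentiated SNPs get group frequencies ``p -/+ freq_shift / 2``
    (clipped away from 0 and 1); all other SNPs share the base frequency.
    Returns the labelled matrix and the sorted planted SNP indices.
    """
    if not 0 < n_differentiated <= n_snps:
        raise DomainError("n_differentiated must lie in 1..n_snps")
    if not 0.0 < freq_shift < 1.0:
        raise DomainError("freq_shift must lie in (0,1)")
    rng = np.random.default_rng(seed)
    p = rng.uniform(*base_freq_range, size=n_snps)
    true_idx = np.sort(rng.choice(n_snps, size=n_differentiated, replace=False))
    pa, pb = p.copy(), p.copy()
    pa[true_idx] = np.clip(p[true_idx] - freq_shift / 2.0, *_FREQ_CLIP)
    pb[true_idx] = np.clip(p[true_idx] + freq_shift / 2.0, *_FREQ_CLIP)
    ga = rng.binomial(2, pa, size=(n_per_group, n_snps)).astype(float)
    gb = rng.binomial(2, pb, size=(n_per_group, n_snps)).astype(float)
    sample_ids = [f"A_{i:04d}" for i in range(n_per_group)] + [
        f"B_{i:04d}" for i in range(n_per_group)
    ]
    labels = {s: s[0] for s in sample_ids}
    snp_ids = [f"snp{j + 1}" for j in range(n_snps)]
    g = GenotypeMatrix(np.vstack([ga, gb]), sample_ids, snp_ids, labels=labels)
    return g, true_idx
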