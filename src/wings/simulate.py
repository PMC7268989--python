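"""Planted-cluster simulation of phenotype × gene score matrices.

Each simulated matrix mimics a biobank-scale gene-level association analysis:
17,651 autosomal gene columns, and per phenotype exactly 1% (175) significant
entries, i.e. P-values below the Bonferroni threshold 0.05/17,651 ≈ 2.83×10⁻⁶.
Ground-truth structure is planted by making a stated fraction of each cluster
member's significant genes *shared*: the same genes, significant in every
member.  The construction protocol:

1. draw the number of clusters M uniformly from integers between 3% and 15%
   of the number of phenotypes N;
2. for each cluster: draw its size uniformly from {2..8}, draw members from
   the remaining phenotype pool, draw its shared significant genes from the
   remaining gene pool, then remove both from their pools (a phenotype joins
   at most one cluster; a gene is shared-and-significant in at most one
   cluster); fill each member's remaining significant slots with genes drawn
   from the remaining pool;
3. unclustered phenotypes get 175 significant genes from the remaining pool.

Nonshared significant genes of different phenotypes may coincide by chance —
only shared-cluster genes are removed from the pool.  Significant and
nonsignificant cell values are drawn from configurable score pools; the
defaults are synthetic (log-uniform significant P-values, uniform
nonsignificant ones), and any empirical P-value list can be substituted.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable

import numpy as np

from .matrix_io import PVALUE, GeneScoreMatrix

logger = logging.getLogger(__name__)

#: Bonferroni-corrected significance threshold for 17,651 autosomal genes.
DEFAULT_SIGNIFICANCE_THRESHOLD = 0.05 / 17651
DEFAULT_N_GENES = 17651
DEFAULT_N_SIGNIFICANT = 175

Sampler = Callable[[np.random.Generator, int], np.ndarray]


def round_half_away(x: float) -> int:
    """Round to the nearest integer, halves away from zero."""
    return int(math.floor(abs(x) + 0.5) * (1 if x >= 0 else -1))


def shared_gene_count(fraction: float, n_sig: int) -> int:
    """Number of shared significant genes for a cluster at the given fraction.

    Rounding is half-away-from-zero: with 175 significant genes per phenotype
    the fractions 1/10/25/50/75/100 % give 2/18/44/88/131/175 shared genes.
    """
    if not 0 < fraction <= 1:
        raise ValueError(f"shared fraction {fraction!r} not in (0, 1]")
    return round_half_away(fraction * n_sig)


@dataclass
class ScorePools:
    """Samplers for significant and nonsignificant P-values.

    ``significant`` must draw strictly below ``threshold`` and
    ``nonsignificant`` at or above it; both take ``(rng, size)`` and return a
    float array.
    """

    significant: Sampler
    nonsignificant: Sampler
    threshold: float = DEFAULT_SIGNIFICANCE_THRESHOLD


def default_pools(threshold: float = DEFAULT_SIGNIFICANCE_THRESHOLD) -> ScorePools:
    """Synthetic stand-in for an empirical gene-score distribution.

    Nonsignificant P-values are uniform on [threshold, 1]; significant ones
    are log-uniform between 10⁻²⁰ and the threshold (P = 10^(−U) with U
    uniform on [−log10 threshold, 20]), capped strictly below the threshold.
    """
    lo = -math.log10(threshold)

    def significant(rng: np.random.Generator, size: int) -> np.ndarray:
        p = 10.0 ** (-rng.uniform(lo, 20.0, size))
        return np.minimum(p, np.nextafter(threshold, 0.0))

    def nonsignificant(rng: np.random.Generator, size: int) -> np.ndarray:
        return rng.uniform(threshold, 1.0, size)

    return ScorePools(significant, nonsignificant, threshold)


def empirical_pools(
    path: str | Path, threshold: float = DEFAULT_SIGNIFICANCE_THRESHOLD
) -> ScorePools:
    """Pools backed by an empirical P-value list (one value per line).

    The file is partitioned exactly at the threshold; samplers resample each
    side with replacement.  Use this to reproduce a benchmark built on a real
    gene-score distribution.
    """
    values = np.loadtxt(path, dtype=float).ravel()
    if not ((values > 0) & (values <= 1)).all():
        raise ValueError(f"{path}: P-values must lie in (0, 1]")
    sig = values[values < threshold]
    nonsig = values[values >= threshold]
    if len(sig) == 0 or len(nonsig) == 0:
        raise ValueError(
            f"{path}: need P-values on both sides of threshold {threshold:g}"
            f" (got {len(sig)} significant, {len(nonsig)} nonsignificant)"
        )

    def significant(rng: np.random.Generator, size: int) -> np.ndarray:
        return rng.choice(sig, size, replace=True)

    def nonsignificant(rng: np.random.Generator, size: int) -> np.ndarray:
        return rng.choice(nonsig, size, replace=True)

    return ScorePools(significant, nonsignificant, threshold)


@dataclass
class SimulationConfig:
    """Parameters of one simulated benchmark matrix.

    Defaults are the standard study conditions: 17,651 genes, 175 significant
    genes per phenotype (1%), Bonferroni threshold 0.05/17,651, cluster sizes
    uniform on {2..8} and the cluster count M uniform between 3% and 15% of
    N.  ``n_clusters`` forces an exact M (used e.g. for single-instance
    sensitivity experiments); ``pools=None`` means :func:`default_pools`.
    """

    n_phenotypes: int = 100
    n_genes: int = DEFAULT_N_GENES
    n_significant_per_phenotype: int = DEFAULT_N_SIGNIFICANT
    shared_fraction: float = 0.75
    significance_threshold: float = DEFAULT_SIGNIFICANCE_THRESHOLD
    cluster_size_range: tuple[int, int] = (2, 8)
    m_fraction_range: tuple[float, float] = (0.03, 0.15)
    n_clusters: int | None = None
    pools: ScorePools | None = None

    def __post_init__(self) -> None:
        if self.n_phenotypes < 2:
            raise ValueError("n_phenotypes must be ≥ 2")
        if not 0 < self.shared_fraction <= 1:
            raise ValueError("shared_fraction must be in (0, 1]")
        if self.n_significant_per_phenotype > self.n_genes:
            raise ValueError("more significant genes per phenotype than genes")
        lo, hi = self.cluster_size_range
        if not 2 <= lo <= hi:
            raise ValueError(f"invalid cluster_size_range {self.cluster_size_range}")
        flo, fhi = self.m_fraction_range
        if not 0 < flo <= fhi:
            raise ValueError(f"invalid m_fraction_range {self.m_fraction_range}")

    def m_range(self) -> tuple[int, int]:
        """Integer bounds for the cluster count M (floor 1, nearest-int endpoints)."""
        flo, fhi = self.m_fraction_range
        lo = max(1, round_half_away(flo * self.n_phenotypes))
        hi = max(lo, round_half_away(fhi * self.n_phenotypes))
        return lo, hi


@dataclass(frozen=True)
class TruthCluster:
    members: tuple[str, ...]
    shared_genes: tuple[str, ...]


@dataclass
class SimulationTruth:
    """Planted ground truth: clusters, their shared genes, per-row significant sets."""

    clusters: list[TruthCluster]
    unclustered: tuple[str, ...]
    significant_genes: dict[str, frozenset[str]] = field(repr=False)

    @property
    def n_clusters(self) -> int:
        return len(self.clusters)

    def member_sets(self) -> list[frozenset[str]]:
        return [frozenset(c.members) for c in self.clusters]


def _as_rng(seed: int | np.random.Generator) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


def phenotype_labels(n: int) -> list[str]:
    """Spreadsheet-style labels A, B, …, Z, AA, AB, … for simulated phenotypes."""
    labels = []
    for i in range(n):
        s, k = "", i
        while True:
            s = chr(ord("A") + k % 26) + s
            k = k // 26 - 1
            if k < 0:
                break
        labels.append(s)
    return labels


def sample_cluster_structure(
    config: SimulationConfig, rng: int | np.random.Generator
) -> tuple[int, list[list[int]]]:
    """Draw the cluster count M and disjoint member index lists.

    M is uniform on the integer range from :meth:`SimulationConfig.m_range`
    (e.g. 3..15 for N=100) unless ``config.n_clusters`` pins it.  Cluster
    sizes are i.i.d. uniform on ``cluster_size_range``; members are drawn
    without replacement from the remaining phenotype pool.  If the pool runs
    short a size is truncated (or the cluster dropped when fewer than two
    phenotypes remain), with a warning.
    """
    rng = _as_rng(rng)
    n = config.n_phenotypes
    if n < 4:
        raise ValueError("need at least 4 phenotypes to plant clusters")
    lo, hi = config.m_range()
    m = config.n_clusters if config.n_clusters is not None else int(rng.integers(lo, hi + 1))
    smin, smax = config.cluster_size_range
    pool = np.arange(n)
    memberships: list[list[int]] = []
    for _ in range(m):
        if len(pool) < 2:
            logger.warning(
                "phenotype pool exhausted after %d of %d clusters", len(memberships), m
            )
            break
        size = int(rng.integers(smin, smax + 1))
        if size > len(pool):
            logger.warning("cluster size %d truncated to pool of %d", size, len(pool))
            size = len(pool)
        chosen = rng.choice(pool, size, replace=False)
        memberships.append(sorted(int(i) for i in chosen))
        pool = pool[~np.isin(pool, chosen)]
    return len(memberships), memberships


def generate_matrix(
    config: SimulationConfig, seed: int | np.random.Generator
) -> tuple[GeneScoreMatrix, SimulationTruth]:
    """Generate one P-value matrix with planted shared-architecture clusters.

    Follows the pool-removal protocol described in the module docstring;
    fully reproducible for a given integer seed.  Returns the matrix on the
    ``pvalue`` scale together with the ground truth.
    """
    rng = _as_rng(seed)
    pools = config.pools if config.pools is not None else default_pools(
        config.significance_threshold
    )
    n, g = config.n_phenotypes, config.n_genes
    n_sig = config.n_significant_per_phenotype
    k_shared = shared_gene_count(config.shared_fraction, n_sig)

    phen_ids = phenotype_labels(n)
    gene_ids = [f"G{i:05d}" for i in range(g)]

    _, memberships = sample_cluster_structure(config, rng)

    # background: every cell nonsignificant, then overwrite significant slots
    values = pools.nonsignificant(rng, n * g).reshape(n, g)

    gene_avail = np.ones(g, dtype=bool)
    sig_idx: dict[int, np.ndarray] = {}
    clusters: list[TruthCluster] = []
    for members in memberships:
        avail = np.flatnonzero(gene_avail)
        if len(avail) < k_shared:
            raise RuntimeError(
                f"gene pool exhausted: need {k_shared} shared genes, {len(avail)} left"
            )
        shared = rng.choice(avail, k_shared, replace=False)
        gene_avail[shared] = False  # a gene is shared in at most one cluster
        remaining = np.flatnonzero(gene_avail)
        n_own = n_sig - k_shared
        if len(remaining) < n_own:
            raise RuntimeError(
                f"gene pool exhausted: need {n_own} nonshared genes, {len(remaining)} left"
            )
        for p in members:
            own = rng.choice(remaining, n_own, replace=False)
            sig_idx[p] = np.concatenate([np.sort(shared), np.sort(own)])
        clusters.append(
            TruthCluster(
                members=tuple(phen_ids[p] for p in members),
                shared_genes=tuple(gene_ids[i] for i in np.sort(shared)),
            )
        )

    clustered = {p for members in memberships for p in members}
    remaining = np.flatnonzero(gene_avail)
    if len(remaining) < n_sig:
        raise RuntimeError(
            f"gene pool exhausted: need {n_sig} genes per unclustered phenotype,"
            f" {len(remaining)} left"
        )
    for p in range(n):
        if p not in clustered:
            sig_idx[p] = np.sort(rng.choice(remaining, n_sig, replace=False))

    for p in range(n):
        values[p, sig_idx[p]] = pools.significant(rng, n_sig)

    truth = SimulationTruth(
        clusters=clusters,
        unclustered=tuple(phen_ids[p] for p in range(n) if p not in clustered),
        significant_genes={
            phen_ids[p]: frozenset(gene_ids[i] for i in sig_idx[p]) for p in range(n)
        },
    )
    return GeneScoreMatrix(phen_ids, gene_ids, values, PVALUE), truth


def truth_to_dict(truth: SimulationTruth) -> dict:
    """JSON-serializable form of the ground truth."""
    return {
        "clusters": [
            {"members": list(c.members), "shared_genes": list(c.shared_genes)}
            for c in truth.clusters
        ],
        "unclustered": list(truth.unclustered),
        "significant_genes": {
            p: sorted(genes) for p, genes in truth.significant_genes.items()
        },
    }
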