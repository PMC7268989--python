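"""Cluster-recovery metrics and benchmark harnesses.

A planted cluster counts as *recovered* only when some prioritized cluster's
member set equals it exactly.  Three headline metrics:

* **power** — pooled over simulations: the percentage of all planted clusters
  that were prioritized;
* **top-x precision** — per simulation with x planted clusters, the
  percentage of them that are prioritized *and* rank within the x most
  prioritized clusters; averaged across simulations;
* **standard precision / recall / F1** — set-based: precision is the
  percentage of prioritized clusters that are planted, recall the percentage
  of planted clusters prioritized, F1 = 2pr/(p+r) on the fraction scale
  (0 when p + r = 0).

The harnesses run the full pipeline (simulate → −log10 transform → Ward →
thresholding) under a single seed tree so every benchmark is bit-reproducible.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .matrix_io import GeneScoreMatrix, neglog10_transform, shuffle_rows, PVALUE
from .prioritize import (
    CRITERIA,
    PrioritizationConfig,
    PrioritizationResult,
    prioritize,
)
from .simulate import SimulationConfig, SimulationTruth, generate_matrix
from .ward_core import ClusterNode, ward_linkage, SQRT2COST

logger = logging.getLogger(__name__)

#: Cluster size threshold used in the standard benchmarks.
BENCHMARK_T = 8


@dataclass
class MetricsReport:
    """Aggregate recovery metrics over a batch of simulations."""

    power: float
    precision_topx: float
    precision_standard: float
    recall: float
    f1: float
    n_sims: int
    n_truth_clusters: int
    n_prioritized: int
    config: dict = field(default_factory=dict)


def match_exact(
    prioritized: list[ClusterNode], truth: SimulationTruth
) -> list[bool]:
    """Per planted cluster: is its member set exactly some prioritized set?"""
    found = {frozenset(nd.members) for nd in prioritized}
    return [m in found for m in truth.member_sets()]


def _matched_ranks(
    prioritized: list[ClusterNode], truth: SimulationTruth
) -> list[int | None]:
    """1-based rank of the prioritized node matching each planted cluster."""
    rank_of = {frozenset(nd.members): i + 1 for i, nd in enumerate(prioritized)}
    return [rank_of.get(m) for m in truth.member_sets()]


def power(results: list[tuple[PrioritizationResult, SimulationTruth]]) -> float:
    """Pooled percentage of planted clusters recovered, across all simulations."""
    recovered = total = 0
    for res, truth in results:
        hits = match_exact(res.prioritized, truth)
        recovered += sum(hits)
        total += len(hits)
    return 100.0 * recovered / total if total else 0.0


def precision_topx(
    results: list[tuple[PrioritizationResult, SimulationTruth]]
) -> float:
    """Mean per-simulation percentage of planted clusters found within the top x ranks.

    x is the number of planted clusters in that simulation.
    """
    per_sim = []
    for res, truth in results:
        x = truth.n_clusters
        if x == 0:
            continue
        ranks = _matched_ranks(res.prioritized, truth)
        hit = sum(1 for r in ranks if r is not None and r <= x)
        per_sim.append(100.0 * hit / x)
    return float(np.mean(per_sim)) if per_sim else 0.0


def precision_recall_f1(
    prioritized: list[ClusterNode], truth: SimulationTruth
) -> tuple[float, float, float]:
    """Standard set-based (precision %, recall %, F1 fraction) for one run.

    Precision is 0 by convention when nothing is prioritized (undefined
    ratio, logged); F1 is 0 when precision + recall = 0.
    """
    truth_sets = set(truth.member_sets())
    pri_sets = [frozenset(nd.members) for nd in prioritized]
    if not pri_sets:
        logger.info("no prioritized clusters; precision reported as 0 by convention")
        p = 0.0
    else:
        p = 100.0 * sum(1 for s in pri_sets if s in truth_sets) / len(pri_sets)
    r = 100.0 * sum(1 for s in truth_sets if s in set(pri_sets)) / len(truth_sets) if truth_sets else 0.0
    pf, rf = p / 100.0, r / 100.0
    f1 = 2 * pf * rf / (pf + rf) if pf + rf > 0 else 0.0
    return p, r, f1


def _run_pipeline(
    sim_config: SimulationConfig,
    prio_config: PrioritizationConfig,
    seed: int | np.random.Generator,
    height_convention: str = SQRT2COST,
) -> tuple[PrioritizationResult, SimulationTruth]:
    matrix, truth = generate_matrix(sim_config, seed)
    scores = neglog10_transform(matrix)
    tree = ward_linkage(scores, height_convention)
    return prioritize(tree, prio_config), truth


def benchmark(
    n_phenotypes: int,
    shared_fraction: float,
    n_sims: int,
    seed: int,
    sim_config: SimulationConfig | None = None,
    prio_config: PrioritizationConfig | None = None,
    height_convention: str = SQRT2COST,
) -> MetricsReport:
    """Run the standard recovery benchmark for one (N, shared fraction) cell.

    Defaults follow the benchmark conditions: cluster size threshold T = 8,
    median outlier criterion, sqrt2cost heights, 17,651 genes and 175
    significant genes per phenotype.  Per-simulation seeds are spawned from
    ``seed`` so the whole cell is reproducible.
    """
    if sim_config is None:
        sim_config = SimulationConfig(
            n_phenotypes=n_phenotypes, shared_fraction=shared_fraction
        )
    if prio_config is None:
        prio_config = PrioritizationConfig(cluster_size_threshold=BENCHMARK_T)
    results = []
    for child in np.random.SeedSequence(seed).spawn(n_sims):
        rng = np.random.default_rng(child)
        results.append(_run_pipeline(sim_config, prio_config, rng, height_convention))
    pooled_p, pooled_r = _pooled_precision_recall(results)
    pf, rf = pooled_p / 100.0, pooled_r / 100.0
    return MetricsReport(
        power=power(results),
        precision_topx=precision_topx(results),
        precision_standard=pooled_p,
        recall=pooled_r,
        f1=2 * pf * rf / (pf + rf) if pf + rf > 0 else 0.0,
        n_sims=n_sims,
        n_truth_clusters=sum(t.n_clusters for _, t in results),
        n_prioritized=sum(len(r.prioritized) for r, _ in results),
        config={
            "n_phenotypes": n_phenotypes,
            "shared_fraction": shared_fraction,
            "cluster_size_threshold": prio_config.cluster_size_threshold,
            "outlier_criterion": prio_config.outlier_criterion,
            "height_convention": height_convention,
            "seed": seed,
        },
    )


def _pooled_precision_recall(
    results: list[tuple[PrioritizationResult, SimulationTruth]]
) -> tuple[float, float]:
    tp = n_pri = n_truth = 0
    for res, truth in results:
        truth_sets = set(truth.member_sets())
        pri_sets = [frozenset(nd.members) for nd in res.prioritized]
        tp += sum(1 for s in pri_sets if s in truth_sets)
        n_pri += len(pri_sets)
        n_truth += len(truth_sets)
    p = 100.0 * tp / n_pri if n_pri else 0.0
    r = 100.0 * tp / n_truth if n_truth else 0.0
    return p, r


def sensitivity_instance(
    seed: int,
    n_phenotypes: int = 100,
    shared_fraction: float = 0.75,
    n_clusters: int = 13,
    cluster_size_range: tuple[int, int] = (2, 7),
    max_tries: int = 500,
) -> tuple[GeneScoreMatrix, SimulationTruth]:
    """One simulated matrix whose planted cluster sizes span the full range.

    The sensitivity experiment is defined on a single instance with a fixed
    number of clusters whose sizes range over ``cluster_size_range`` end to
    end; sizes are drawn i.i.d., so the draw is repeated (deterministically
    under ``seed``) until both endpoints are realised.
    """
    cfg = SimulationConfig(
        n_phenotypes=n_phenotypes,
        shared_fraction=shared_fraction,
        n_clusters=n_clusters,
        cluster_size_range=cluster_size_range,
    )
    lo, hi = cluster_size_range
    for child in np.random.SeedSequence(seed).spawn(max_tries):
        matrix, truth = generate_matrix(cfg, np.random.default_rng(child))
        sizes = [len(c.members) for c in truth.clusters]
        if min(sizes) == lo and max(sizes) == hi:
            return matrix, truth
    raise RuntimeError(
        f"no draw with cluster sizes spanning {lo}..{hi} in {max_tries} tries"
    )


def parameter_sweep(
    scores: GeneScoreMatrix,
    truth: SimulationTruth,
    t_values: range | list[int] = range(2, 20),
    criteria: tuple[str, ...] = CRITERIA,
    height_convention: str = SQRT2COST,
) -> dict[tuple[int, str], tuple[float, float, float]]:
    """Sensitivity grid over (cluster size threshold T, outlier criterion).

    ``scores`` must already be on the neglog10 scale; the dendrogram is
    computed once and only the thresholding step is rerun per cell.  Returns
    ``{(T, criterion): (precision %, recall %, F1 fraction)}``.
    """
    tree = ward_linkage(scores, height_convention)
    grid: dict[tuple[int, str], tuple[float, float, float]] = {}
    for t in t_values:
        for criterion in criteria:
            cfg = PrioritizationConfig(
                cluster_size_threshold=t, outlier_criterion=criterion
            )
            res = prioritize(tree, cfg)
            grid[(t, criterion)] = precision_recall_f1(res.prioritized, truth)
    return grid


@dataclass
class ShuffleNullReport:
    """Size-stratified counts of prioritized clusters across row shuffles."""

    n_shuffles: int
    counts: np.ndarray  # (n_shuffles, max_size+1); column s = clusters of size s
    config: dict = field(default_factory=dict)

    def mean_sd_by_size(self) -> dict[int, tuple[float, float]]:
        out = {}
        for s in range(2, self.counts.shape[1]):
            col = self.counts[:, s]
            mean = float(col.mean()) if len(col) else 0.0
            sd = float(col.std(ddof=1)) if len(col) > 1 else 0.0
            out[s] = (mean, sd)
        return out

    def mean_count_at_least(self, size: int) -> float:
        if self.n_shuffles == 0:
            return 0.0
        return float(self.counts[:, size:].sum(axis=1).mean())


def shuffle_null(
    matrix: GeneScoreMatrix,
    n_shuffles: int,
    seed: int,
    prio_config: PrioritizationConfig | None = None,
    height_convention: str = SQRT2COST,
) -> ShuffleNullReport:
    """Permutation null: shuffle each row's scores, rerun the pipeline, count.

    Shuffling destroys cross-phenotype gene alignment while preserving each
    row's score distribution; structured inputs should lose essentially all
    prioritized clusters of size ≥ 4 under this null.
    """
    prio_config = prio_config or PrioritizationConfig(cluster_size_threshold=BENCHMARK_T)
    max_size = matrix.n_phenotypes
    counts = np.zeros((n_shuffles, max_size + 1), dtype=np.int64)
    for i, child in enumerate(np.random.SeedSequence(seed).spawn(n_shuffles)):
        shuffled = shuffle_rows(matrix, np.random.default_rng(child))
        if shuffled.scale == PVALUE:
            shuffled = neglog10_transform(shuffled)
        tree = ward_linkage(shuffled, height_convention)
        res = prioritize(tree, prio_config)
        for nd in res.prioritized:
            counts[i, nd.size] += 1
    return ShuffleNullReport(
        n_shuffles=n_shuffles,
        counts=counts,
        config={"seed": seed, "outlier_criterion": prio_config.outlier_criterion},
    )
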