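"""Branch-length thresholding: detect and rank prioritized phenotype clusters.

Given a Ward dendrogram, a cluster is *prioritized* when it is small (at most
T phenotypes, the cluster size threshold) and its branch length stands apart
from the rest by a gap that is a statistical outlier:

1. sort the branch lengths of all small clusters (size ≤ T);
2. take consecutive differences — the branch-length *gaps*;
3. flag outlier gaps under one of four criteria (scaled-MAD around the
   median, 3 SD around the mean, 1.5·IQR beyond the quartiles, or an
   iterative two-sided Grubbs test);
4. set the threshold to the smallest branch length that lies above the median
   of the sorted lengths and sits immediately above a flagged gap; if no such
   length exists there are no prioritized clusters.

Prioritized clusters are the small clusters whose branch length meets or
exceeds the threshold, ranked by descending branch length.  Because nested
clusters are separate dendrogram nodes, a prioritized cluster may contain
prioritized subclusters; both are reported.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .ward_core import ClusterNode, LinkageTree, branch_lengths

logger = logging.getLogger(__name__)

MEDIAN = "median"
MEAN = "mean"
QUARTILE = "quartile"
GRUBBS = "grubbs"
CRITERIA = (MEDIAN, MEAN, QUARTILE, GRUBBS)

#: Normal-consistency constant: MAD · 1.4826 estimates the SD of a Gaussian,
#: giving the "scaled median absolute deviation".
MAD_SCALE = 1.4826


@dataclass
class PrioritizationConfig:
    """Tunable parameters of the thresholding step.

    ``cluster_size_threshold`` (T) caps the size of a prioritization
    candidate; ``None`` means the conservative default ⌈N/3⌉ for an N-leaf
    tree.  Singleton leaves are excluded from the candidate pool by default:
    a leaf's branch length equals its first-merge height, which sits on the
    scale of typical inter-phenotype distances and would swamp the gap
    statistics of genuine multi-phenotype clusters (set
    ``include_singletons=True`` to put leaves back in the pool; above-
    threshold clusters smaller than ``min_reported_size`` are then reported
    separately rather than ranked).
    """

    cluster_size_threshold: int | None = None
    outlier_criterion: str = MEDIAN
    grubbs_alpha: float = 0.05
    mad_multiplier: float = 3.0
    sd_multiplier: float = 3.0
    iqr_multiplier: float = 1.5
    min_reported_size: int = 2
    include_singletons: bool = False

    def __post_init__(self) -> None:
        if self.outlier_criterion not in CRITERIA:
            raise ValueError(
                f"unknown outlier criterion {self.outlier_criterion!r};"
                f" expected one of {CRITERIA}"
            )
        if not 0 < self.grubbs_alpha < 1:
            raise ValueError("grubbs_alpha must be in (0, 1)")
        for name in ("mad_multiplier", "sd_multiplier", "iqr_multiplier"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.cluster_size_threshold is not None and self.cluster_size_threshold < 2:
            raise ValueError("cluster_size_threshold must be ≥ 2")

    def resolve_T(self, n_phenotypes: int) -> int:
        if self.cluster_size_threshold is None:
            return math.ceil(n_phenotypes / 3)
        return min(self.cluster_size_threshold, n_phenotypes)


@dataclass
class PrioritizationResult:
    """Threshold selection outcome plus the ranked prioritized clusters.

    ``candidate_nodes`` are the size-filtered clusters in ascending
    branch-length order (the data behind a sorted-branch-length plot);
    ``gaps[i]`` is ``sorted_lengths[i+1] − sorted_lengths[i]`` and
    ``outlier_flags[i]`` marks it as a gap outlier.  ``threshold`` is ``None``
    when no prioritized clusters exist.  ``suppressed`` holds above-threshold
    clusters smaller than ``min_reported_size`` (singletons by default).
    """

    candidate_nodes: list[ClusterNode]
    sorted_lengths: np.ndarray
    gaps: np.ndarray
    outlier_flags: np.ndarray
    threshold: float | None
    prioritized: list[ClusterNode]
    suppressed: list[ClusterNode]
    config: PrioritizationConfig
    cluster_size_threshold: int = 0

    @property
    def n_prioritized(self) -> int:
        return len(self.prioritized)


def sorted_gaps(
    nodes: list[ClusterNode], T: int
) -> tuple[list[ClusterNode], np.ndarray, np.ndarray]:
    """Size-filter, sort by branch length, and take consecutive differences.

    Returns ``(candidates, sorted_lengths, gaps)`` where only nodes of size
    ≤ T enter, candidates are in ascending branch-length order, and
    ``gaps[i] = lengths[i+1] − lengths[i] ≥ 0``.
    """
    candidates = [nd for nd in nodes if nd.size <= T]
    candidates.sort(key=lambda nd: (nd.branch_length, nd.size, nd.sorted_members()))
    lengths = np.array([nd.branch_length for nd in candidates], dtype=float)
    gaps = np.diff(lengths) if len(lengths) >= 2 else np.empty(0)
    return candidates, lengths, gaps


def _flag_median(gaps: np.ndarray, multiplier: float) -> np.ndarray:
    center = np.median(gaps)
    mad = np.median(np.abs(gaps - center))
    if mad == 0:
        # Limit of the rule: with zero spread any strictly larger gap is an
        # outlier; constant gap vectors stay flag-free.
        return gaps > center
    return np.abs(gaps - center) > multiplier * MAD_SCALE * mad


def _flag_mean(gaps: np.ndarray, multiplier: float) -> np.ndarray:
    center = gaps.mean()
    sd = gaps.std(ddof=1) if len(gaps) > 1 else 0.0
    if sd == 0:
        return gaps > center
    return np.abs(gaps - center) > multiplier * sd


def _flag_quartile(gaps: np.ndarray, multiplier: float) -> np.ndarray:
    # Linear interpolation between order statistics (the numpy default).
    q1, q3 = np.percentile(gaps, [25, 75])
    iqr = q3 - q1
    if iqr == 0:
        return (gaps > q3) | (gaps < q1)
    return (gaps > q3 + multiplier * iqr) | (gaps < q1 - multiplier * iqr)


def _grubbs_critical(n: int, alpha: float) -> float:
    t = stats.t.isf(alpha / (2 * n), n - 2)
    return (n - 1) / math.sqrt(n) * math.sqrt(t * t / (n - 2 + t * t))


def _flag_grubbs(gaps: np.ndarray, alpha: float) -> np.ndarray:
    flags = np.zeros(len(gaps), dtype=bool)
    remaining = list(range(len(gaps)))
    while len(remaining) >= 3:
        work = gaps[remaining]
        mean = work.mean()
        sd = work.std(ddof=1)
        if sd == 0:
            break
        dev = np.abs(work - mean)
        imax = int(dev.argmax())
        g = dev[imax] / sd
        if g > _grubbs_critical(len(work), alpha):
            flags[remaining.pop(imax)] = True
        else:
            break
    return flags


def flag_gap_outliers(
    gaps: np.ndarray, criterion: str, config: PrioritizationConfig | None = None
) -> np.ndarray:
    """Boolean outlier flag per gap under the chosen criterion.

    All four criteria are scale-equivariant: multiplying every gap by a
    positive constant leaves the flags unchanged.
    """
    config = config or PrioritizationConfig(outlier_criterion=criterion)
    gaps = np.asarray(gaps, dtype=float)
    if len(gaps) == 0:
        return np.zeros(0, dtype=bool)
    if criterion == MEDIAN:
        return _flag_median(gaps, config.mad_multiplier)
    if criterion == MEAN:
        return _flag_mean(gaps, config.sd_multiplier)
    if criterion == QUARTILE:
        return _flag_quartile(gaps, config.iqr_multiplier)
    if criterion == GRUBBS:
        return _flag_grubbs(gaps, config.grubbs_alpha)
    raise ValueError(f"unknown outlier criterion {criterion!r}")


def select_threshold(
    sorted_lengths: np.ndarray, gaps: np.ndarray, flags: np.ndarray
) -> float | None:
    """Smallest branch length above the median that sits just above a flagged gap.

    The gap ``gaps[i]`` is attributed to the branch length ``lengths[i+1]``
    above it, so the selected threshold lies on the far side of the outlier
    gap.  Returns ``None`` when no qualifying length exists — the
    no-prioritized-clusters outcome.
    """
    if len(sorted_lengths) < 2:
        return None
    med = float(np.median(sorted_lengths))
    candidates = [
        float(sorted_lengths[i + 1])
        for i in range(len(gaps))
        if flags[i] and sorted_lengths[i + 1] > med
    ]
    return min(candidates) if candidates else None


def _rank_key(nd: ClusterNode):
    return (-nd.branch_length, nd.size, nd.sorted_members())


def prioritize(
    tree: LinkageTree, config: PrioritizationConfig | None = None
) -> PrioritizationResult:
    """Run the full thresholding step on a dendrogram.

    Composes branch-length extraction → size filter and sort → gap outlier
    flags → threshold selection, then ranks the clusters at or above the
    threshold by descending branch length (ties: smaller cluster first, then
    lexicographic member lists).  Degenerate inputs (fewer than two
    candidates, e.g. a flat dendrogram of identical rows) yield an empty
    result with ``threshold=None``.
    """
    config = config or PrioritizationConfig()
    T = config.resolve_T(tree.n_leaves)
    nodes = branch_lengths(tree)
    if not config.include_singletons:
        nodes = [nd for nd in nodes if nd.size >= 2]
    candidates, lengths, gaps = sorted_gaps(nodes, T)
    if len(candidates) < 2:
        logger.info("fewer than two candidate clusters; no prioritized clusters")
        return PrioritizationResult(
            candidates, lengths, np.empty(0), np.zeros(0, dtype=bool),
            None, [], [], config, T,
        )
    flags = flag_gap_outliers(gaps, config.outlier_criterion, config)
    threshold = select_threshold(lengths, gaps, flags)
    prioritized: list[ClusterNode] = []
    suppressed: list[ClusterNode] = []
    if threshold is not None:
        above = [nd for nd in candidates if nd.branch_length >= threshold]
        above.sort(key=_rank_key)
        for nd in above:
            (prioritized if nd.size >= config.min_reported_size else suppressed).append(nd)
        if suppressed:
            logger.info(
                "%d above-threshold cluster(s) smaller than min_reported_size=%d suppressed",
                len(suppressed), config.min_reported_size,
            )
    return PrioritizationResult(
        candidates, lengths, gaps, flags, threshold, prioritized, suppressed, config, T
    )


def result_tables(result: PrioritizationResult):
    """(prioritized, branch-length) DataFrames mirroring the TSV report format."""
    import pandas as pd

    pri = pd.DataFrame(
        [
            {
                "rank": i + 1,
                "branch_length": nd.branch_length,
                "size": nd.size,
                "members": ";".join(nd.sorted_members()),
            }
            for i, nd in enumerate(result.prioritized)
        ],
        columns=["rank", "branch_length", "size", "members"],
    )
    flags = np.zeros(len(result.candidate_nodes), dtype=bool)
    # gap i sits between candidates i and i+1; mark the upper branch
    for i, f in enumerate(result.outlier_flags):
        if f:
            flags[i + 1] = True
    lengths = pd.DataFrame(
        {
            "branch_length": [nd.branch_length for nd in result.candidate_nodes],
            "size": [nd.size for nd in result.candidate_nodes],
            "members": [";".join(nd.sorted_members()) for nd in result.candidate_nodes],
            "gap_above": np.concatenate([result.gaps, [np.nan]])
            if len(result.candidate_nodes)
            else [],
            "gap_outlier_above": flags,
        }
    )
    return pri, lengths
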