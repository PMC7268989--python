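"""Ward agglomerative clustering and dendrogram branch-length extraction.

Ward's method merges, at every step, the pair of clusters R, S minimising the
merging cost

    d(R, S) = N_R · N_S / (N_R + N_S) · ‖C_R − C_S‖²

where C_R, C_S are cluster centroids — equivalently, the increase in total
within-cluster sum of squared errors caused by the merge.  The implementation
maintains merging costs with the Lance–Williams recurrence (O(N) per step),
but its semantic contract is the brute-force definition above: on any input
with distinct costs it reproduces the exact merge order and heights of a
direct recomputation from raw member coordinates.

Node identifiers follow the common linkage convention: leaves are 0..N−1 in
input row order; the cluster created at merge step s (1-based) is N + s − 1;
the root is 2N − 2.

Two height conventions are exposed because the downstream branch-length
thresholding is not invariant to monotone transforms of heights:

* ``sqrt2cost`` (default): height = √(2·cost), so merging two singletons
  records their Euclidean distance;
* ``rawcost``: height = cost itself.
"""

from __future__ import annotations

from dataclasses import dataclass
from io import StringIO

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform

from .matrix_io import NEGLOG10, GeneScoreMatrix

SQRT2COST = "sqrt2cost"
RAWCOST = "rawcost"
_CONVENTIONS = (SQRT2COST, RAWCOST)


@dataclass(frozen=True)
class MergeRecord:
    """One agglomeration step: the two node ids merged and the resulting height."""

    step: int  # 1-based
    left_id: int
    right_id: int
    height: float
    new_size: int


@dataclass
class LinkageTree:
    """A full Ward dendrogram: leaf labels plus the ordered merge sequence."""

    leaves: list[str]
    merges: list[MergeRecord]
    height_convention: str

    @property
    def n_leaves(self) -> int:
        return len(self.leaves)

    def node_id(self, record: MergeRecord) -> int:
        return self.n_leaves + record.step - 1

    @property
    def root_id(self) -> int:
        return 2 * self.n_leaves - 2


@dataclass(frozen=True)
class ClusterNode:
    """A non-root dendrogram node with its branch length to the parent merge.

    ``branch_length = parent_height − formation_height`` measures for how long
    (on the dendrogram height axis) the cluster persists before being absorbed
    into a larger one; long branches mark tight, well-separated clusters.
    Leaves have formation height 0.
    """

    node_id: int
    members: frozenset[str]
    formation_height: float
    parent_height: float

    @property
    def branch_length(self) -> float:
        return self.parent_height - self.formation_height

    @property
    def size(self) -> int:
        return len(self.members)

    def sorted_members(self) -> tuple[str, ...]:
        return tuple(sorted(self.members))


def euclidean_distance(a: np.ndarray, b: np.ndarray) -> float:
    """Plain L2 distance between two equal-length score vectors."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise ValueError(f"length mismatch: {a.shape} vs {b.shape}")
    if not (np.isfinite(a).all() and np.isfinite(b).all()):
        raise ValueError("non-finite input")
    return float(np.linalg.norm(a - b))


def ward_merge_cost(
    n_r: int, n_s: int, c_r: np.ndarray, c_s: np.ndarray
) -> float:
    """Merging cost N_R·N_S/(N_R+N_S)·‖C_R−C_S‖² for clusters of the given sizes/centroids.

    Equals the increase in within-cluster SSE caused by merging the clusters.
    """
    if n_r < 1 or n_s < 1:
        raise ValueError("cluster sizes must be ≥ 1")
    c_r = np.asarray(c_r, dtype=float)
    c_s = np.asarray(c_s, dtype=float)
    if c_r.shape != c_s.shape:
        raise ValueError(f"centroid dimension mismatch: {c_r.shape} vs {c_s.shape}")
    return (n_r * n_s) / (n_r + n_s) * float(np.sum((c_r - c_s) ** 2))


def _cost_to_height(cost: np.ndarray | float, convention: str):
    if convention == SQRT2COST:
        return np.sqrt(2.0 * cost)
    return cost


def ward_linkage_array(
    x: np.ndarray,
    leaves: list[str],
    height_convention: str = SQRT2COST,
) -> LinkageTree:
    """Greedy Ward agglomeration of the rows of ``x`` (see :func:`ward_linkage`)."""
    if height_convention not in _CONVENTIONS:
        raise ValueError(f"unknown height convention {height_convention!r}")
    x = np.asarray(x, dtype=float)
    if not np.isfinite(x).all():
        raise ValueError("non-finite values in input matrix")
    n = x.shape[0]
    if n < 2:
        raise ValueError("need at least 2 rows to cluster")
    if len(leaves) != n:
        raise ValueError("leaf labels do not match row count")

    total = 2 * n - 1
    # cost[i, j] = Ward merging cost between active nodes i and j; for two
    # singletons this is ‖x_i − x_j‖² / 2.
    cost = np.full((total, total), np.inf)
    cost[:n, :n] = squareform(pdist(x, "sqeuclidean")) / 2.0
    np.fill_diagonal(cost, np.inf)
    size = np.zeros(total, dtype=np.int64)
    size[:n] = 1
    active = np.zeros(total, dtype=bool)
    active[:n] = True

    merges: list[MergeRecord] = []
    for step in range(1, n):
        act = np.flatnonzero(active)
        sub = cost[np.ix_(act, act)]
        iu, ju = np.triu_indices(len(act), k=1)
        vals = sub[iu, ju]
        k = int(np.flatnonzero(vals == vals.min())[0])  # row-major ⇒ lexicographic tie-break
        i, j = int(act[iu[k]]), int(act[ju[k]])
        c_ij = cost[i, j]
        new = n + step - 1

        others = act[(act != i) & (act != j)]
        if others.size:
            # Lance–Williams update on merging costs:
            # c(i∪j, k) = [(n_i+n_k)c_ik + (n_j+n_k)c_jk − n_k·c_ij] / (n_i+n_j+n_k)
            nk = size[others]
            denom = size[i] + size[j] + nk
            c_new = (
                (size[i] + nk) * cost[i, others]
                + (size[j] + nk) * cost[j, others]
                - nk * c_ij
            ) / denom
            cost[new, others] = c_new
            cost[others, new] = c_new
        size[new] = size[i] + size[j]
        active[[i, j]] = False
        active[new] = True
        merges.append(
            MergeRecord(
                step=step,
                left_id=i,
                right_id=j,
                height=float(_cost_to_height(max(c_ij, 0.0), height_convention)),
                new_size=int(size[new]),
            )
        )
    return LinkageTree(list(leaves), merges, height_convention)


def ward_linkage(
    m: GeneScoreMatrix,
    height_convention: str = SQRT2COST,
    allow_pvalue_scale: bool = False,
) -> LinkageTree:
    """Ward hierarchical clustering of phenotypes by their gene-score vectors.

    The matrix is expected on the ``neglog10`` scale — clustering raw P-values
    groups phenotypes by shared *non*-significant architecture, which is
    rarely what is wanted; pass ``allow_pvalue_scale=True`` to override.

    At each step the pair of clusters with minimal merging cost is combined;
    exact cost ties are broken by the smallest ``(left_id, right_id)`` pair,
    making runs bit-reproducible.
    """
    if m.scale != NEGLOG10 and not allow_pvalue_scale:
        raise ValueError(
            "matrix is on the pvalue scale; apply neglog10_transform first "
            "or pass allow_pvalue_scale=True"
        )
    return ward_linkage_array(m.values, list(m.phenotype_ids), height_convention)


def _formation_heights(tree: LinkageTree) -> dict[int, float]:
    n = tree.n_leaves
    heights = {i: 0.0 for i in range(n)}
    for rec in tree.merges:
        heights[n + rec.step - 1] = rec.height
    return heights


def _member_sets(tree: LinkageTree) -> dict[int, frozenset[str]]:
    n = tree.n_leaves
    members: dict[int, frozenset[str]] = {
        i: frozenset((tree.leaves[i],)) for i in range(n)
    }
    for rec in tree.merges:
        members[n + rec.step - 1] = members[rec.left_id] | members[rec.right_id]
    return members


def branch_lengths(tree: LinkageTree) -> list[ClusterNode]:
    """One :class:`ClusterNode` per non-root node (leaves included), root omitted.

    Each node's branch length is the height of the merge that absorbs it minus
    its own formation height; Ward monotonicity makes all branch lengths ≥ 0.
    """
    n = tree.n_leaves
    formation = _formation_heights(tree)
    members = _member_sets(tree)
    parent_height: dict[int, float] = {}
    for rec in tree.merges:
        parent_height[rec.left_id] = rec.height
        parent_height[rec.right_id] = rec.height
    nodes = [
        ClusterNode(
            node_id=nid,
            members=members[nid],
            formation_height=formation[nid],
            parent_height=parent_height[nid],
        )
        for nid in sorted(parent_height)
    ]
    return nodes


def pc2_baseline(m: GeneScoreMatrix, height_convention: str = SQRT2COST) -> LinkageTree:
    """Ward clustering in the plane of the first two principal components.

    Column-centers the score matrix, projects phenotypes onto the two leading
    principal axes (via SVD), and clusters the 2-D coordinates.  This is the
    dimension-reduced baseline used only for comparison: projecting to two
    dimensions contracts pairwise distances and flattens cluster separation.
    """
    if m.n_phenotypes < 3:
        raise ValueError("PC baseline needs at least 3 phenotypes")
    xc = m.values - m.values.mean(axis=0, keepdims=True)
    u, s, _ = np.linalg.svd(xc, full_matrices=False)
    if len(s) < 2 or s[1] <= max(xc.shape) * np.finfo(float).eps * s[0]:
        raise ValueError("matrix has rank < 2 after centering; no 2-D projection exists")
    coords = u[:, :2] * s[:2]
    return ward_linkage_array(coords, list(m.phenotype_ids), height_convention)


# ---------------------------------------------------------------------------
# export


def linkage_table(tree: LinkageTree) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "step": r.step,
                "left": r.left_id,
                "right": r.right_id,
                "height": r.height,
                "size": r.new_size,
            }
            for r in tree.merges
        ]
    )


def to_newick(tree: LinkageTree) -> str:
    """Serialize the dendrogram as a Newick string.

    Branch lengths are ``parent_height − formation_height``; the root branch
    is omitted.  Built through dendropy so the output follows the standard
    grammar (labels quoted where needed).
    """
    import dendropy

    n = tree.n_leaves
    formation = _formation_heights(tree)
    taxa = dendropy.TaxonNamespace(tree.leaves)
    nodes: dict[int, dendropy.Node] = {}
    for i, label in enumerate(tree.leaves):
        nd = dendropy.Node()
        nd.taxon = taxa.get_taxon(label)
        nodes[i] = nd
    for rec in tree.merges:
        parent = dendropy.Node()
        for child_id in (rec.left_id, rec.right_id):
            child = nodes[child_id]
            child.edge.length = rec.height - formation[child_id]
            parent.add_child(child)
        nodes[n + rec.step - 1] = parent
    t = dendropy.Tree(taxon_namespace=taxa)
    t.seed_node = nodes[tree.root_id]
    out = StringIO()
    t.write(file=out, schema="newick", suppress_rooting=True)
    return out.getvalue().strip()
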