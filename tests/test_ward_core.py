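import itertools

import dendropy
import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.cluster import hierarchy

from wings import (
    RAWCOST,
    SQRT2COST,
    branch_lengths,
    euclidean_distance,
    pc2_baseline,
    to_newick,
    ward_linkage,
    ward_linkage_array,
    ward_merge_cost,
)
from conftest import make_scores


# --- independent oracle: greedy Ward recomputing every merging cost from raw
# member coordinates at each step (no Lance-Williams shortcut), with the same
# lexicographic tie-break.

def brute_force_ward(x):
    x = np.asarray(x, dtype=float)
    n = len(x)
    clusters = {i: [i] for i in range(n)}
    merges = []
    next_id = n
    while len(clusters) > 1:
        best = None
        for i, j in itertools.combinations(sorted(clusters), 2):
            ci = x[clusters[i]].mean(axis=0)
            cj = x[clusters[j]].mean(axis=0)
            ni, nj = len(clusters[i]), len(clusters[j])
            cost = ni * nj / (ni + nj) * float(np.sum((ci - cj) ** 2))
            if best is None or cost < best[0] or (cost == best[0] and (i, j) < best[1:]):
                best = (cost, i, j)
        cost, i, j = best
        merges.append((i, j, np.sqrt(2 * cost)))
        clusters[next_id] = clusters.pop(i) + clusters.pop(j)
        next_id += 1
    return merges


class TestDistanceAndCost:
    def test_three_four_five(self):
        assert euclidean_distance([0, 0], [3, 4]) == 5.0
        assert euclidean_distance([1, 2, 3], [1, 2, 3]) == 0.0

    def test_rejects_length_mismatch(self):
        with pytest.raises(ValueError):
            euclidean_distance([1, 2], [1, 2, 3])

    def test_matches_naive_summation(self, rng):
        for _ in range(20):
            a, b = rng.normal(size=(2, 30))
            naive = sum((ai - bi) ** 2 for ai, bi in zip(a, b)) ** 0.5
            assert euclidean_distance(a, b) == pytest.approx(naive, rel=1e-12)

    def test_singleton_cost_direct(self):
        # two 1-D singletons at 0 and 2: (1·1/2)·4 = 2
        assert ward_merge_cost(1, 1, np.array([0.0]), np.array([2.0])) == 2.0
        assert ward_merge_cost(3, 5, np.ones(4), np.ones(4)) == 0.0

    def test_cost_equals_sse_increase(self, rng):
        # merging cost == SSE(R∪S) − SSE(R) − SSE(S) on random small clusters
        def sse(points):
            c = points.mean(axis=0)
            return float(np.sum((points - c) ** 2))

        for _ in range(25):
            nr, ns = rng.integers(1, 6, 2)
            r = rng.normal(size=(nr, 3))
            s = rng.normal(size=(ns, 3))
            cost = ward_merge_cost(nr, ns, r.mean(axis=0), s.mean(axis=0))
            delta = sse(np.vstack([r, s])) - sse(r) - sse(s)
            assert cost == pytest.approx(delta, rel=1e-10, abs=1e-12)


class TestWardLinkage:
    def test_two_points_height_is_distance(self):
        m = make_scores([[0.0, 0.0], [3.0, 4.0]])
        tree = ward_linkage(m)
        assert len(tree.merges) == 1
        assert tree.merges[0].height == pytest.approx(5.0)

    def test_one_dim_triple(self):
        # points {0, 1, 5}: first merge {0,1} at height 1, root at sqrt(27)
        tree = ward_linkage(make_scores([[0.0], [1.0], [5.0]]))
        assert [r.height for r in tree.merges] == pytest.approx([1.0, np.sqrt(27)])
        assert (tree.merges[0].left_id, tree.merges[0].right_id) == (0, 1)

    def test_rawcost_convention(self):
        tree = ward_linkage(make_scores([[0.0], [1.0], [5.0]]), RAWCOST)
        assert [r.height for r in tree.merges] == pytest.approx([0.5, 13.5])

    @given(st.integers(0, 2**32 - 1), st.integers(3, 8))
    @settings(max_examples=30, deadline=None)
    def test_equals_brute_force_oracle(self, seed, n):
        rng = np.random.default_rng(seed)
        x = rng.normal(size=(n, 4))
        tree = ward_linkage_array(x, [f"P{i}" for i in range(n)])
        expected = brute_force_ward(x)
        got = [(r.left_id, r.right_id, r.height) for r in tree.merges]
        for (gi, gj, gh), (ei, ej, eh) in zip(got, expected):
            assert (gi, gj) == (ei, ej)
            assert gh == pytest.approx(eh, rel=1e-9, abs=1e-12)

    @given(st.integers(0, 2**32 - 1))
    @settings(max_examples=25, deadline=None)
    def test_heights_nondecreasing(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(2, 20))
        x = rng.normal(size=(n, 5))
        heights = [r.height for r in ward_linkage_array(x, [str(i) for i in range(n)]).merges]
        assert all(b >= a - 1e-12 for a, b in zip(heights, heights[1:]))

    def test_matches_scipy_ward(self, rng):
        # independent cross-check: same cluster family and heights as scipy
        x = rng.normal(size=(12, 6))
        tree = ward_linkage_array(x, [str(i) for i in range(12)])
        z = hierarchy.linkage(x, method="ward")
        assert sorted(r.height for r in tree.merges) == pytest.approx(
            sorted(z[:, 2]), rel=1e-9
        )
        ours = {frozenset(nd.members) for nd in branch_lengths(tree)}
        rootnode = hierarchy.to_tree(z)
        theirs = set()

        def collect(node):
            leaves = frozenset(str(i) for i in node.pre_order(lambda v: v.id))
            if node.left is not None:
                theirs.add(leaves)
                collect(node.left)
                collect(node.right)

        collect(rootnode)
        theirs.discard(frozenset(str(i) for i in range(12)))  # root has no branch
        assert {s for s in ours if len(s) > 1} == theirs

    def test_scaling_property(self, rng):
        x = rng.normal(size=(8, 5))
        h1 = [r.height for r in ward_linkage_array(x, list("abcdefgh")).merges]
        h2 = [r.height for r in ward_linkage_array(3.0 * x, list("abcdefgh")).merges]
        assert h2 == pytest.approx([3.0 * h for h in h1], rel=1e-9)
        r1 = [r.height for r in ward_linkage_array(x, list("abcdefgh"), RAWCOST).merges]
        r2 = [r.height for r in ward_linkage_array(3.0 * x, list("abcdefgh"), RAWCOST).merges]
        assert r2 == pytest.approx([9.0 * h for h in r1], rel=1e-9)

    def test_rejects_nonfinite(self):
        with pytest.raises(ValueError):
            ward_linkage_array(np.array([[np.nan, 1.0], [0.0, 2.0]]), ["a", "b"])


class TestBranchLengths:
    def test_two_leaf_tree(self):
        tree = ward_linkage(make_scores([[0.0, 0.0], [3.0, 4.0]]))
        nodes = branch_lengths(tree)
        assert len(nodes) == 2  # both leaves; root omitted
        assert all(nd.branch_length == pytest.approx(5.0) for nd in nodes)

    def test_triple_example(self):
        tree = ward_linkage(make_scores([[0.0], [1.0], [5.0]]))
        by_members = {nd.sorted_members(): nd for nd in branch_lengths(tree)}
        assert by_members[("P0", "P1")].branch_length == pytest.approx(np.sqrt(27) - 1.0)
        assert by_members[("P2",)].branch_length == pytest.approx(np.sqrt(27))

    def test_laminar_family_and_nonnegative(self, rng):
        x = rng.normal(size=(10, 4))
        tree = ward_linkage_array(x, [str(i) for i in range(10)])
        nodes = branch_lengths(tree)
        assert all(nd.branch_length >= -1e-12 for nd in nodes)
        sets = [nd.members for nd in nodes]
        for a, b in itertools.combinations(sets, 2):
            assert a <= b or b <= a or not (a & b)


class TestPC2Baseline:
    def test_lossless_when_data_is_planar(self, rng):
        # rows in a 2-D affine subspace of high-dim space: same tree either way
        basis = rng.normal(size=(2, 40))
        coeff = rng.normal(size=(6, 2))
        x = coeff @ basis + rng.normal(size=40)
        m = make_scores(x - x.min())
        t_full = ward_linkage(m)
        t_pc = pc2_baseline(m)
        assert [r.height for r in t_pc.merges] == pytest.approx(
            [r.height for r in t_full.merges], rel=1e-9
        )
        assert [(r.left_id, r.right_id) for r in t_pc.merges] == [
            (r.left_id, r.right_id) for r in t_full.merges
        ]

    def test_projection_contracts_distances(self, rng):
        x = rng.normal(size=(5, 50))
        x -= x.min()
        xc = x - x.mean(axis=0)
        u, s, _ = np.linalg.svd(xc, full_matrices=False)
        coords = u[:, :2] * s[:2]
        for i, j in itertools.combinations(range(5), 2):
            d2 = np.linalg.norm(coords[i] - coords[j])
            dfull = np.linalg.norm(xc[i] - xc[j])
            assert d2 <= dfull + 1e-9

    def test_duplicated_rows_collapse_in_pc_space(self, rng):
        x = rng.normal(size=(4, 20))
        x[1] = x[0]
        tree = pc2_baseline(make_scores(x - x.min()))
        assert tree.merges[0].height == pytest.approx(0.0, abs=1e-9)

    def test_rank_deficient_rejected(self):
        with pytest.raises(ValueError, match="rank"):
            pc2_baseline(make_scores([[1.0, 1.0], [2.0, 2.0], [3.0, 3.0]]))


class TestNewick:
    def test_roundtrips_through_dendropy(self, rng):
        x = rng.normal(size=(6, 4))
        labels = ["alpha", "beta", "gamma", "delta", "eps", "zeta"]
        tree = ward_linkage_array(x, labels)
        nwk = to_newick(tree)
        parsed = dendropy.Tree.get(data=nwk, schema="newick")
        assert sorted(t.label for t in parsed.taxon_namespace) == sorted(labels)
        # leaf root-to-tip distance equals the height of the root merge
        root_height = tree.merges[-1].height
        for leaf in parsed.leaf_node_iter():
            assert leaf.distance_from_root() == pytest.approx(root_height, rel=1e-6)
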