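import itertools
import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from algafp import phylo
from algafp.fingerprint_clustering import Dendrogram, SimilarityMatrix, upgma
from algafp.synthetic_data import mutate_sequence, random_sequence


class TestPairwiseDifferences:
    def test_identical(self):
        assert phylo.pairwise_differences("ACGT", "ACGT") == 0

    def test_single_difference(self):
        assert phylo.pairwise_differences("ACGT", "ACGA") == 1

    def test_gap_column_excluded(self):
        assert phylo.pairwise_differences("AC-GT", "ACAGA") == 1

    def test_n_excluded(self):
        assert phylo.pairwise_differences("ANGT", "ATGT") == 0

    def test_u_equals_t(self):
        assert phylo.pairwise_differences("ACGU", "ACGT") == 0

    def test_unequal_length(self):
        with pytest.raises(ValueError):
            phylo.pairwise_differences("ACG", "ACGT")

    @given(st.data())
    @settings(max_examples=50, deadline=None)
    def test_metric_on_gapfree_sequences(self, data):
        L = 30
        seqs = [
            "".join(data.draw(st.sampled_from("ACGT")) for _ in range(L))
            for _ in range(3)
        ]
        d = phylo.pairwise_differences
        a, b, c = seqs
        assert d(a, b) <= d(a, c) + d(c, b)
        assert d(a, b) == d(b, a)
        assert d(a, a) == 0


class TestKimuraDistance:
    def test_identical_no_gaps(self):
        assert phylo.kimura_distance("ACGTACGT", "ACGTACGT") == 0.0

    def test_closed_form(self):
        # P = 0.1, Q = 0.05 over 100 gap-free sites
        base = random_sequence(100, seed=3)
        a, b = mutate_sequence(base, n_transitions=10, n_transversions=5, seed=4)
        expected = -0.5 * math.log((1 - 2 * 0.1 - 0.05) * math.sqrt(1 - 2 * 0.05))
        assert phylo.kimura_distance(a, b) == pytest.approx(expected, rel=1e-12)

    def test_gap_rule(self):
        # P = 0, Q = 0, 10 one-sided gap columns, 100 comparable sites
        base = random_sequence(110, seed=5)
        a, b = mutate_sequence(base, 0, 0, n_gaps=10, seed=6)
        assert phylo.kimura_distance(a, b, gap_penalty=0.12) == pytest.approx(0.012)

    def test_transitions_only_reduces_to_one_parameter_form(self):
        base = random_sequence(200, seed=7)
        a, b = mutate_sequence(base, n_transitions=20, n_transversions=0, seed=8)
        p = 0.1
        expected = -0.5 * math.log(1 - 2 * p)
        assert phylo.kimura_distance(a, b) == pytest.approx(expected, rel=1e-12)

    def test_saturation_error(self):
        a = "A" * 40
        b = "C" * 40  # all transversions: Q = 1
        with pytest.raises(ValueError, match="saturated"):
            phylo.kimura_distance(a, b)

    @given(
        n_ts=st.integers(min_value=0, max_value=15),
        n_tv=st.integers(min_value=0, max_value=15),
    )
    @settings(max_examples=60, deadline=None)
    def test_nonnegative_and_exceeds_zero_bound(self, n_ts, n_tv):
        base = random_sequence(100, seed=11)
        a, b = mutate_sequence(base, n_ts, n_tv, seed=12)
        d = phylo.kimura_distance(a, b)
        assert d >= 0.0


# ---------------------------------------------------------------------------
# neighbor joining
# ---------------------------------------------------------------------------

def random_additive_tree(rng, n):
    """Random unrooted binary tree with positive branch lengths; returns
    (leaf labels, patristic distance matrix, splits)."""
    labels = [f"T{i}" for i in range(n)]
    # build by random sequential attachment; store as adjacency with lengths
    import collections

    adj = collections.defaultdict(dict)
    next_internal = [n]

    def new_internal():
        v = f"I{next_internal[0]}"
        next_internal[0] += 1
        return v

    edges = [(labels[0], labels[1])]
    adj[labels[0]][labels[1]] = adj[labels[1]][labels[0]] = float(rng.uniform(0.1, 1.0))
    for leaf in labels[2:]:
        a, b = edges[rng.integers(len(edges))]
        w = adj[a].pop(b)
        adj[b].pop(a)
        edges.remove((a, b))
        mid = new_internal()
        split = float(rng.uniform(0.2, 0.8)) * w
        adj[a][mid] = adj[mid][a] = split
        adj[b][mid] = adj[mid][b] = w - split
        adj[mid][leaf] = adj[leaf][mid] = float(rng.uniform(0.1, 1.0))
        edges.extend([(a, mid), (b, mid), (mid, leaf)])
    # all-pairs distances by BFS
    D = np.zeros((n, n))
    for i, src in enumerate(labels):
        dist = {src: 0.0}
        stack = [src]
        while stack:
            u = stack.pop()
            for v, w in adj[u].items():
                if v not in dist:
                    dist[v] = dist[u] + w
                    stack.append(v)
        for j, dst in enumerate(labels):
            D[i, j] = dist[dst]
    # splits
    splits = set()
    anchor = labels[0]
    for a in list(adj):
        for b in adj[a]:
            if a < b:
                # leaves on b's side when edge (a,b) removed
                seen = {a, b}
                stack = [b]
                side = set()
                while stack:
                    u = stack.pop()
                    if u in labels:
                        side.add(u)
                    for v in adj[u]:
                        if v not in seen:
                            seen.add(v)
                            stack.append(v)
                fs = frozenset(side) if anchor not in side else frozenset(set(labels) - side)
                if 1 < len(fs) < n - 1:
                    splits.add(fs)
    return labels, D, splits


def patristic_from_tree(tree: phylo.PhyloTree) -> dict:
    """Path lengths between all leaf pairs of the NJ output."""
    dists = {}

    def walk(node, acc):
        if node.is_leaf:
            dists[node.label] = acc
        for c in node.children:
            walk(c, acc + (c.edge_length or 0.0))

    # distances via common-ancestor accumulation from the (arbitrary) root
    paths = {}

    def collect(node, path):
        path = path + [(node, (node.edge_length or 0.0))]
        if node.is_leaf:
            paths[node.label] = path
        for c in node.children:
            collect(c, path)

    collect(tree.root, [])
    out = {}
    labels = tree.labels
    for a, b in itertools.combinations(labels, 2):
        pa, pb = paths[a], paths[b]
        shared = 0
        for (na, _), (nb, _) in zip(pa, pb):
            if na is nb:
                shared += 1
            else:
                break
        d = sum(w for _, w in pa[shared:]) + sum(w for _, w in pb[shared:])
        out[(a, b)] = out[(b, a)] = d
    return out


class TestNeighborJoining:
    def test_three_taxa_closed_form(self):
        D = phylo.DistanceMatrix(
            labels=["A", "B", "C"],
            D=np.array([[0.0, 0.3, 0.5], [0.3, 0.0, 0.6], [0.5, 0.6, 0.0]]),
        )
        tree = phylo.neighbor_joining(D)
        lengths = {c.label: c.edge_length for c in tree.root.children}
        assert lengths["A"] == pytest.approx((0.3 + 0.5 - 0.6) / 2)
        assert lengths["B"] == pytest.approx((0.3 + 0.6 - 0.5) / 2)
        assert lengths["C"] == pytest.approx((0.5 + 0.6 - 0.3) / 2)

    def test_four_taxa_additive_recovery_vs_exhaustive_oracle(self):
        # oracle: enumerate all 3 unrooted 4-taxon topologies with
        # least-squares branch lengths; the additive one fits exactly
        rng = np.random.default_rng(23)
        labels, D, true_splits = random_additive_tree(rng, 4)
        best = None
        leaf_pairs = list(itertools.combinations(range(4), 2))
        for split in [((0, 1), (2, 3)), ((0, 2), (1, 3)), ((0, 3), (1, 2))]:
            # design matrix: 5 branches (4 pendant + 1 internal)
            A = np.zeros((6, 5))
            y = np.zeros(6)
            for row, (i, j) in enumerate(leaf_pairs):
                A[row, i] = A[row, j] = 1.0
                same_side = any(i in side and j in side for side in split)
                if not same_side:
                    A[row, 4] = 1.0
                y[row] = D[i, j]
            coef, res, *_ = np.linalg.lstsq(A, y, rcond=None)
            rss = float(np.sum((A @ coef - y) ** 2))
            if best is None or rss < best[0]:
                best = (rss, split)
        oracle_split = frozenset(
            labels[k] for k in best[1][0] if labels[0] not in [labels[m] for m in best[1][0]]
        ) or frozenset(labels[k] for k in best[1][1])
        tree = phylo.neighbor_joining(
            phylo.DistanceMatrix(labels=labels, D=D)
        )
        got_splits = tree.splits()
        assert len(got_splits) == 1
        # NJ split matches the exhaustive least-squares oracle's best topology
        anchorless = {frozenset(labels[k] for k in side) for side in best[1]}
        assert next(iter(got_splits)) in anchorless
        # branch lengths: patristic distances reproduce the additive input
        pat = patristic_from_tree(tree)
        for i, j in leaf_pairs:
            assert pat[(labels[i], labels[j])] == pytest.approx(D[i, j], abs=1e-9)

    @pytest.mark.parametrize("n", [4, 5, 6, 7, 8])
    def test_additive_recovery_random_trees(self, n):
        rng = np.random.default_rng(100 + n)
        for _ in range(10):
            labels, D, true_splits = random_additive_tree(rng, n)
            tree = phylo.neighbor_joining(phylo.DistanceMatrix(labels=labels, D=D))
            assert tree.splits() == true_splits
            pat = patristic_from_tree(tree)
            for i, j in itertools.combinations(range(n), 2):
                assert pat[(labels[i], labels[j])] == pytest.approx(D[i, j], abs=1e-9)

    def test_ultrametric_input_matches_upgma_topology(self):
        D = np.array(
            [
                [0.0, 0.2, 0.6, 0.6],
                [0.2, 0.0, 0.6, 0.6],
                [0.6, 0.6, 0.0, 0.3],
                [0.6, 0.6, 0.3, 0.0],
            ]
        )
        labels = ["A", "B", "C", "D"]
        nj = phylo.neighbor_joining(phylo.DistanceMatrix(labels=labels, D=D))
        dendro = upgma(SimilarityMatrix(labels=labels, S=1 - D))
        # UPGMA clades -> canonical splits, compare with NJ splits
        assert phylo.robinson_foulds(dendro, nj) == 0

    def test_too_few_taxa(self):
        with pytest.raises(ValueError):
            phylo.neighbor_joining(
                phylo.DistanceMatrix(labels=["a", "b"], D=np.array([[0.0, 1.0], [1.0, 0.0]]))
            )


class TestComparePartitions:
    def _nj_from_additive(self, seed, n):
        rng = np.random.default_rng(seed)
        labels, D, _ = random_additive_tree(rng, n)
        return phylo.neighbor_joining(phylo.DistanceMatrix(labels=labels, D=D))

    def test_identical_topologies_rf_zero(self):
        tree = self._nj_from_additive(1, 6)
        # dendrogram with the same nested structure
        report = phylo.compare_partitions(
            _dendrogram_from_phylo(tree),
            tree,
            {lab: "X" for lab in tree.labels},
        )
        assert report.robinson_foulds == 0
        assert (report.class_monophyly["monophyletic_ms"] == report.class_monophyly["monophyletic_seq"]).all()

    def test_seq_resolves_classes_ms_does_not(self):
        labels = ["a1", "a2", "b1", "b2"]
        # seq tree groups (a1,a2)|(b1,b2); ms tree groups (a1,b1)|(a2,b2)
        D_seq = _split_metric(labels, {"a1", "a2"})
        D_ms = _split_metric(labels, {"a1", "b1"})
        seq_tree = phylo.neighbor_joining(phylo.DistanceMatrix(labels=labels, D=D_seq))
        ms_dendro = upgma(SimilarityMatrix(labels=labels, S=1 - D_ms))
        classes = {"a1": "A", "a2": "A", "b1": "B", "b2": "B"}
        report = phylo.compare_partitions(ms_dendro, seq_tree, classes)
        assert report.n_classes_seq_only == 2
        assert report.robinson_foulds > 0

    def test_star_vs_resolved_rf(self):
        tree = self._nj_from_additive(2, 6)
        from algafp.fingerprint_clustering import TreeNode

        star = phylo.PhyloTree(
            root=TreeNode(children=[TreeNode(label=lab, edge_length=1.0) for lab in tree.labels]),
            labels=list(tree.labels),
        )
        assert phylo.robinson_foulds(star, tree) == len(tree.splits())

    def test_leaf_mismatch(self):
        t1 = self._nj_from_additive(3, 5)
        t2 = self._nj_from_additive(4, 6)
        with pytest.raises(ValueError):
            phylo.robinson_foulds(t1, t2)


def _split_metric(labels, group_a):
    n = len(labels)
    D = np.zeros((n, n))
    for i in range(n):
        for j in range(n):
            if i != j:
                same = (labels[i] in group_a) == (labels[j] in group_a)
                D[i, j] = 0.2 if same else 0.8
    return D


def _dendrogram_from_phylo(tree: phylo.PhyloTree) -> Dendrogram:
    """Wrap a phylo tree's topology as a dendrogram (heights unused for
    split comparisons)."""
    return Dendrogram(root=tree.root, labels=list(tree.labels))


class TestRobinsonFouldsAgainstDendropy:
    def test_matches_dendropy(self):
        import dendropy

        rng = np.random.default_rng(9)
        for _ in range(5):
            labels, D1, _ = random_additive_tree(rng, 7)
            _, D2, _ = random_additive_tree(rng, 7)
            t1 = phylo.neighbor_joining(phylo.DistanceMatrix(labels=labels, D=D1))
            t2 = phylo.neighbor_joining(phylo.DistanceMatrix(labels=labels, D=D2))
            tns = dendropy.TaxonNamespace()
            d1 = dendropy.Tree.get(data=t1.to_newick(), schema="newick", taxon_namespace=tns)
            d2 = dendropy.Tree.get(data=t2.to_newick(), schema="newick", taxon_namespace=tns)
            expected = dendropy.calculate.treecompare.symmetric_difference(d1, d2)
            assert phylo.robinson_foulds(t1, t2) == expected
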