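"""Distance matrices, NJ correctness, bootstrap and Newick I/O."""

import random

import numpy as np
import pytest

from mitocomp.align import ElementAlignment
from mitocomp.phylogeny import (
    DistanceMatrix,
    PhyloTree,
    TreeNode,
    bootstrap_support,
    concat_distance_matrix,
    neighbor_joining,
    read_newick,
    to_newick,
    write_newick,
)


def random_additive_tree(rng, n_taxa):
    """Random binary tree with positive branch lengths; returns (tree root,
    taxon list, pairwise path-length matrix)."""
    nodes = [TreeNode(name=f"T{i}", length=rng.uniform(0.05, 1.0))
             for i in range(n_taxa)]
    pool = nodes[:]
    while len(pool) > 3:
        i, j = sorted(rng.sample(range(len(pool)), 2), reverse=True)
        a, b = pool.pop(i), pool.pop(j)
        parent = TreeNode(length=rng.uniform(0.05, 1.0), children=[a, b])
        pool.append(parent)
    root = TreeNode(children=pool)
    taxa = sorted(l.name for l in root.leaves())

    # path lengths by recursion
    def leaf_dists(node):
        if node.is_leaf:
            return {node.name: node.length}
        out = {}
        for c in node.children:
            for k, v in leaf_dists(c).items():
                out[k] = v + node.length
        return out

    paths = {}

    def fill(node):
        below = []
        for c in node.children:
            below.append(leaf_dists(c))
            fill(c)
        # leaf_dists(c) measures to this node, so cross-child paths just add
        for x in range(len(below)):
            for y in range(x + 1, len(below)):
                for la, da in below[x].items():
                    for lb, db in below[y].items():
                        paths[frozenset((la, lb))] = da + db

    # root has length 0 contribution
    root.length = 0.0
    fill(root)
    n = len(taxa)
    M = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            M[i, j] = M[j, i] = paths[frozenset((taxa[i], taxa[j]))]
    return root, taxa, M


class TestNeighborJoining:
    def test_four_taxon_additive_exact(self):
        taxa = ["A", "B", "C", "D"]
        d = {("A", "B"): 5, ("A", "C"): 7, ("A", "D"): 8,
             ("B", "C"): 8, ("B", "D"): 9, ("C", "D"): 9}
        M = np.zeros((4, 4))
        for (x, y), v in d.items():
            i, j = taxa.index(x), taxa.index(y)
            M[i, j] = M[j, i] = v
        tree = neighbor_joining(DistanceMatrix(taxa, M))
        assert tree.bipartitions() == {frozenset({"A", "B"})}
        lens = {l.name: l.length for l in tree.root.leaves()}
        assert lens == {"A": 2, "B": 3, "C": 4, "D": 5}

    def test_three_taxa_closed_form(self):
        M = np.array([[0, 2.0, 3.0], [2.0, 0, 4.0], [3.0, 4.0, 0]])
        tree = neighbor_joining(DistanceMatrix(["a", "b", "c"], M))
        lens = {l.name: l.length for l in tree.root.leaves()}
        assert lens["a"] == pytest.approx(0.5)
        assert lens["b"] == pytest.approx(1.5)
        assert lens["c"] == pytest.approx(2.5)

    def test_equal_distances_degenerate(self):
        M = np.ones((4, 4)) - np.eye(4)
        tree = neighbor_joining(DistanceMatrix(list("abcd"), M))
        assert sorted(tree.leaf_names()) == list("abcd")
        for node in tree.root.children:
            if not node.is_leaf:
                assert node.length == pytest.approx(0.0, abs=1e-12)

    def test_recovers_random_additive_trees(self):
        rng = random.Random(47)
        for _ in range(60):
            n = rng.randint(4, 8)
            root, taxa, M = random_additive_tree(rng, n)
            got = neighbor_joining(DistanceMatrix(taxa, M))
            want = PhyloTree(root=root)
            assert got.bipartitions() == want.bipartitions()
            # additive consistency: branch lengths reproduce the matrix
            lens = {l.name: l.length for l in got.root.leaves()}
            for leaf in got.root.leaves():
                assert leaf.length >= -1e-9

    def test_agrees_with_skbio(self):
        from skbio import DistanceMatrix as SkbioDM
        from skbio.tree import nj as skbio_nj

        rng = random.Random(53)
        for _ in range(10):
            n = rng.randint(4, 7)
            _, taxa, M = random_additive_tree(rng, n)
            ours = neighbor_joining(DistanceMatrix(taxa, M))
            theirs = skbio_nj(SkbioDM(M, ids=taxa))
            their_bips = set()
            for node in theirs.non_tips():
                side = frozenset(t.name for t in node.tips())
                if 1 < len(side) < n - 1:
                    their_bips.add(min(side, frozenset(taxa) - side, key=sorted))
            assert ours.bipartitions() == their_bips

    def test_too_few_taxa_rejected(self):
        with pytest.raises(ValueError):
            neighbor_joining(DistanceMatrix(["a", "b"], np.zeros((2, 2))))


class TestDistanceMatrix:
    def test_identical_taxa_zero_matrix(self):
        aln = ElementAlignment("e", list("abcd"), ["ACGT" * 10] * 4)
        dm = concat_distance_matrix([aln])
        assert dm.values.sum() == 0

    def test_concatenation_order_invariance(self):
        a = ElementAlignment("x", ["p", "q"], ["AAAA", "AAAT"])
        b = ElementAlignment("y", ["p", "q"], ["CCCC", "CCCC"])
        d1 = concat_distance_matrix([a, b]).values
        d2 = concat_distance_matrix([b, a]).values
        assert np.allclose(d1, d2)

    def test_asymmetric_matrix_rejected(self):
        M = np.array([[0, 1.0], [2.0, 0]])
        with pytest.raises(ValueError):
            DistanceMatrix(["a", "b"], M)


class TestBootstrap:
    def _alignment(self, seed=61, informative=40):
        rng = random.Random(seed)
        L = 400
        base = [rng.choice("ACGT") for _ in range(L)]
        rows = {k: base[:] for k in ("S1", "S2", "S3", "S4")}
        for i in rng.sample(range(L), informative):  # S1+S2 share derived state
            alt = {"A": "G", "G": "A", "C": "T", "T": "C"}[base[i]]
            rows["S1"][i] = alt
            rows["S2"][i] = alt
        for k in ("S1", "S2", "S3", "S4"):  # private noise
            for i in rng.sample(range(L), 5):
                rows[k][i] = rng.choice("ACGT")
        return ElementAlignment("e", list(rows), ["".join(v) for v in rows.values()])

    def test_strong_split_high_support(self):
        tree = bootstrap_support([self._alignment()], n_reps=200, seed=3)
        assert tree.bipartitions() == {frozenset({"S1", "S2"})}
        supports = [c.support for c in tree.root.children
                    if c.support is not None]
        assert supports and supports[0] >= 95

    def test_same_seed_identical_supports(self):
        aln = self._alignment()
        t1 = bootstrap_support([aln], n_reps=50, seed=9)
        t2 = bootstrap_support([aln], n_reps=50, seed=9)
        assert to_newick(t1) == to_newick(t2)

    def test_zero_variation_star(self):
        aln = ElementAlignment("e", list("abcd"), ["ACGT" * 25] * 4)
        tree = bootstrap_support([aln], n_reps=20, seed=1)
        for c in tree.root.children:
            if c.support is not None:
                assert c.support == 0 or c.length == 0


class TestNewick:
    def test_three_taxon_shape(self):
        M = np.array([[0, 2.0, 3.0], [2.0, 0, 4.0], [3.0, 4.0, 0]])
        tree = neighbor_joining(DistanceMatrix(["A", "B", "C"], M))
        s = to_newick(tree)
        assert s.startswith("(") and s.endswith(");")
        assert s.count(",") == 2

    def test_round_trip_preserves_structure(self, tmp_path):
        rng = random.Random(71)
        _, taxa, M = random_additive_tree(rng, 6)
        tree = neighbor_joining(DistanceMatrix(taxa, M))
        path = tmp_path / "t.nwk"
        write_newick(tree, path)
        again = read_newick(path)
        assert set(again.leaf_names()) == set(taxa)
        assert again.bipartitions() == tree.bipartitions()
        lens_a = sorted(l.length for l in tree.root.leaves())
        lens_b = sorted(l.length for l in again.root.leaves())
        assert np.allclose(lens_a, lens_b, atol=1e-9)

    def test_labels_with_spaces_quoted(self):
        leaf_a = TreeNode(name="taxon one", length=1.0)
        leaf_b = TreeNode(name="b", length=1.0)
        leaf_c = TreeNode(name="c", length=1.0)
        tree = PhyloTree(root=TreeNode(children=[leaf_a, leaf_b, leaf_c]))
        assert "'taxon one'" in to_newick(tree)

    def test_planted_tree_recovered_from_synthetic_strains(self, sim_alignments):
        dm = concat_distance_matrix(
            [a for a in sim_alignments if a.element not in ("D-loop", "OL")]
        )
        tree = neighbor_joining(dm)
        assert tree.bipartitions() == {frozenset({"S1", "S2"})}
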