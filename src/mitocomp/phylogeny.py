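"""Distance phylogeny: K2P matrix, neighbor-joining, bootstrap, Newick I/O.

Neighbor-joining follows Saitou & Nei with the Studier–Keppler Q-criterion;
it is exact on additive distance matrices.  Ties in Q are broken by taxon
label order so the topology is deterministic.  Branch supports come from
column resampling of the concatenated alignment: the support of an internal
edge is the percentage of replicate NJ trees containing the same leaf
bipartition.  Negative branch-length estimates (possible on noisy,
non-additive matrices) are clamped to zero and logged.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from itertools import combinations

import numpy as np

from .align import ElementAlignment, concatenate_alignments
from .diversity import k2p_distance

log = logging.getLogger(__name__)


@dataclass
class DistanceMatrix:
    taxa: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.shape != (len(self.taxa), len(self.taxa)):
            raise ValueError("distance matrix shape does not match taxa")
        if not np.allclose(v, v.T):
            raise ValueError("distance matrix must be symmetric")
        if not np.allclose(np.diag(v), 0):
            raise ValueError("distance matrix must have a zero diagonal")
        self.values = v
        # triangle-inequality violations are tolerated by NJ but worth noting
        n = len(self.taxa)
        for i, j, k in combinations(range(n), 3):
            if v[i, j] > v[i, k] + v[k, j] + 1e-9:
                log.info("triangle violation among %s, %s, %s",
                         self.taxa[i], self.taxa[j], self.taxa[k])
                return


def concat_distance_matrix(
    alignments: list[ElementAlignment], taxa: list[str] | None = None
) -> DistanceMatrix:
    """K2P matrix on the concatenation of element alignments (pairwise deletion)."""
    cat = concatenate_alignments(alignments, element="concat")
    taxa = taxa or list(cat.strain_ids)
    n = len(taxa)
    order = [cat.strain_ids.index(t) for t in taxa]
    mat = np.zeros((n, n))
    for a, b in combinations(range(n), 2):
        try:
            d = k2p_distance(cat.rows[order[a]], cat.rows[order[b]])
        except ValueError as exc:
            raise ValueError(f"pair {taxa[a]}/{taxa[b]}: {exc}") from exc
        mat[a, b] = mat[b, a] = d
    return DistanceMatrix(taxa=taxa, values=mat)


# ---------------------------------------------------------------------------
# Tree structure
# ---------------------------------------------------------------------------

@dataclass
class TreeNode:
    name: str | None = None
    length: float = 0.0
    support: float | None = None
    children: list["TreeNode"] = field(default_factory=list)

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def leaves(self) -> list["TreeNode"]:
        if self.is_leaf:
            return [self]
        out = []
        for c in self.children:
            out.extend(c.leaves())
        return out

    def leaf_names(self) -> list[str]:
        return [l.name for l in self.leaves()]


@dataclass
class PhyloTree:
    """Unrooted tree represented with an arbitrary internal root node."""

    root: TreeNode

    def leaf_names(self) -> list[str]:
        return self.root.leaf_names()

    def bipartitions(self) -> set[frozenset[str]]:
        """Non-trivial leaf bipartitions (each as the frozenset of one side)."""
        all_leaves = frozenset(self.leaf_names())
        parts: set[frozenset[str]] = set()

        def walk(node: TreeNode):
            for child in node.children:
                side = frozenset(child.leaf_names())
                if 1 < len(side) < len(all_leaves) - 1:
                    parts.add(min(side, all_leaves - side, key=sorted))
                walk(child)

        walk(self.root)
        return parts

    def clamp_negative_lengths(self) -> int:
        clamped = 0

        def walk(node: TreeNode):
            nonlocal clamped
            for c in node.children:
                if c.length < 0:
                    log.info("negative branch length %.4g clamped to 0", c.length)
                    c.length = 0.0
                    clamped += 1
                walk(c)

        walk(self.root)
        return clamped


# ---------------------------------------------------------------------------
# Neighbor-joining
# ---------------------------------------------------------------------------

def neighbor_joining(dm: DistanceMatrix) -> PhyloTree:
    """Saitou–Nei NJ with the Studier–Keppler criterion.

    Q(i,j) = (n−2) d(i,j) − r_i − r_j; the pair minimising Q is joined, with
    ties broken by the sorted labels of the candidate pair.  The final three
    nodes are joined in an unresolved trifurcation at the root, giving the
    conventional unrooted binary tree.
    """
    n = len(dm.taxa)
    if n < 3:
        raise ValueError("neighbor joining needs at least 3 taxa")
    nodes = [TreeNode(name=t) for t in dm.taxa]
    labels = list(dm.taxa)  # sort key per active node (smallest contained label)
    D = dm.values.copy()
    active = list(range(n))

    while len(active) > 3:
        m = len(active)
        r = {i: sum(D[i, j] for j in active if j != i) for i in active}
        best = None
        for i, j in combinations(active, 2):
            q = (m - 2) * D[i, j] - r[i] - r[j]
            key = (q, *sorted((labels[i], labels[j])))
            if best is None or key < best[0]:
                best = (key, i, j)
        _, i, j = best
        di = 0.5 * D[i, j] + (r[i] - r[j]) / (2 * (m - 2))
        dj = D[i, j] - di
        parent = TreeNode()
        nodes[i].length = di
        nodes[j].length = dj
        parent.children = [nodes[i], nodes[j]]
        # distances from the new node
        new_row = {}
        for k in active:
            if k in (i, j):
                continue
            new_row[k] = 0.5 * (D[i, k] + D[j, k] - D[i, j])
        nodes.append(parent)
        labels.append(min(labels[i], labels[j]))
        D = np.pad(D, ((0, 1), (0, 1)))
        u = len(nodes) - 1
        for k, d in new_row.items():
            D[u, k] = D[k, u] = d
        active = [k for k in active if k not in (i, j)] + [u]

    # join the last three nodes at an unresolved root
    i, j, k = active
    root = TreeNode()
    nodes[i].length = 0.5 * (D[i, j] + D[i, k] - D[j, k])
    nodes[j].length = 0.5 * (D[i, j] + D[j, k] - D[i, k])
    nodes[k].length = 0.5 * (D[i, k] + D[j, k] - D[i, j])
    root.children = [nodes[x] for x in sorted((i, j, k), key=lambda x: labels[x])]
    tree = PhyloTree(root=root)
    tree.clamp_negative_lengths()
    return tree


# ---------------------------------------------------------------------------
# Bootstrap
# ---------------------------------------------------------------------------

def bootstrap_support(
    alignments: list[ElementAlignment],
    n_reps: int = 1000,
    seed: int = 0,
) -> PhyloTree:
    """NJ tree with column-resampling bootstrap supports on internal edges."""
    cat = concatenate_alignments(alignments, element="concat")
    dm = concat_distance_matrix([cat])
    tree = neighbor_joining(dm)
    rng = np.random.default_rng(seed)
    counts: dict[frozenset[str], int] = {bp: 0 for bp in tree.bipartitions()}
    L = cat.n_columns
    rows = [np.frombuffer(r.encode(), dtype="S1") for r in cat.rows]
    for _ in range(n_reps):
        idx = rng.integers(0, L, size=L)
        rep_rows = [r[idx].tobytes().decode() for r in rows]
        rep = ElementAlignment("bootstrap", list(cat.strain_ids), rep_rows)
        try:
            rep_tree = neighbor_joining(concat_distance_matrix([rep]))
        except ValueError:
            continue  # saturated replicate: counts unchanged
        for bp in rep_tree.bipartitions():
            if bp in counts:
                counts[bp] += 1

    def annotate(node: TreeNode):
        all_leaves = frozenset(tree.leaf_names())
        for c in node.children:
            side = frozenset(c.leaf_names())
            if 1 < len(side) < len(all_leaves) - 1:
                bp = min(side, all_leaves - side, key=sorted)
                c.support = 100.0 * counts[bp] / n_reps
            annotate(c)

    annotate(tree.root)
    return tree


# ---------------------------------------------------------------------------
# Newick I/O
# ---------------------------------------------------------------------------

def _quote(label: str) -> str:
    if any(ch in label for ch in " \t()[]:;,'"):
        return "'" + label.replace("'", "''") + "'"
    return label


def to_newick(tree: PhyloTree) -> str:
    def fmt(node: TreeNode) -> str:
        if node.is_leaf:
            return f"{_quote(node.name)}:{node.length:.10g}"
        inner = ",".join(fmt(c) for c in node.children)
        label = "" if node.support is None else str(int(round(node.support)))
        return f"({inner}){label}:{node.length:.10g}"

    inner = ",".join(fmt(c) for c in tree.root.children)
    return f"({inner});"


def write_newick(tree: PhyloTree, path) -> None:
    with open(path, "w") as fh:
        fh.write(to_newick(tree) + "\n")


def read_newick(path) -> PhyloTree:
    """Read a Newick file through dendropy into the bundled tree structure."""
    import dendropy

    dtree = dendropy.Tree.get(path=str(path), schema="newick")

    def convert(dnode) -> TreeNode:
        node = TreeNode(
            name=dnode.taxon.label if dnode.taxon else None,
            length=dnode.edge.length or 0.0,
        )
        if dnode.label is not None and not dnode.is_leaf():
            try:
                node.support = float(dnode.label)
            except ValueError:
                pass
        node.children = [convert(c) for c in dnode.child_nodes()]
        return node

    return PhyloTree(root=convert(dtree.seed_node))


def distance_matrix_tsv(dm: DistanceMatrix, path) -> None:
    with open(path, "w") as fh:
        fh.write("taxon\t" + "\t".join(dm.taxa) + "\n")
        for i, t in enumerate(dm.taxa):
            fh.write(t + "\t" + "\t".join(f"{x:.6f}" for x in dm.values[i]) + "\n")
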