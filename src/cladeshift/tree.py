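"""Per-gene trees: BIONJ construction, midpoint rooting, testable nodes.

The divergence scan needs one rooted binary tree per homolog group.  Trees
are built with BIONJ (Gascuel's variance-weighted refinement of neighbour
joining) from maximum-likelihood pairwise distances, then midpoint-rooted.
Each internal node of the rooted tree partitions the leaves into the two
descendant clades and an outgroup (everything else); a node is *testable*
when both clades have at least 4 leaves and the outgroup is non-empty.

Trees are carried as :class:`dendropy.Tree` objects wrapped in a thin
:class:`GeneTree` that adds stable integer node ids and the edge iterator
used by the sequence simulator.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from typing import Iterator, Sequence

import dendropy
import numpy as np


class TreeSizeError(ValueError):
    """Raised when fewer than 3 taxa are supplied."""


# ---------------------------------------------------------------------------
# BIONJ
# ---------------------------------------------------------------------------
class _Cluster:
    __slots__ = ("newick", "min_taxon")

    def __init__(self, newick: str, min_taxon: int):
        self.newick = newick
        self.min_taxon = min_taxon


def _fmt(x: float) -> str:
    return format(max(x, 0.0), ".10g")


def build_bionj(
    distances: np.ndarray, taxa: Sequence[str]
) -> dendropy.Tree:
    """Agglomerate an unrooted tree with the BIONJ algorithm.

    BIONJ follows the neighbour-joining schedule (minimise the Q
    criterion) but models the variance of each distance estimate
    (initialised as the distance itself) and chooses the reduction weight
    ``lambda`` that minimises the variance of the updated distances.  Ties
    in Q are broken by the lowest (first-seen) taxon-index pair, so the
    result is deterministic and independent of input order up to
    relabelling.  Negative branch-length estimates are clamped to zero.

    Returns an unrooted :class:`dendropy.Tree`.
    """
    d0 = np.asarray(distances, dtype=float)
    n = d0.shape[0]
    if n < 3:
        raise TreeSizeError("BIONJ needs at least 3 taxa")
    if d0.shape != (n, n) or not np.allclose(d0, d0.T):
        raise ValueError("distance matrix must be square and symmetric")
    if not np.all(np.isfinite(d0)):
        raise ValueError("distances must be finite")
    if len(taxa) != n:
        raise ValueError("taxa/matrix size mismatch")

    D = d0.copy()
    V = d0.copy()  # variance estimates, BIONJ initialisation
    clusters = [_Cluster(name, i) for i, name in enumerate(taxa)]
    active = list(range(n))

    while len(active) > 3:
        r = len(active)
        idx = np.array(active)
        sub = D[np.ix_(idx, idx)]
        sums = sub.sum(axis=1)
        # Q criterion
        q = (r - 2) * sub - sums[:, None] - sums[None, :]
        np.fill_diagonal(q, np.inf)
        best = None
        for a in range(r):
            for b in range(a + 1, r):
                key = (q[a, b], clusters[idx[a]].min_taxon, clusters[idx[b]].min_taxon)
                if best is None or key < best[0]:
                    best = (key, a, b)
        _, a, b = best
        i, j = idx[a], idx[b]

        dij = D[i, j]
        bi = 0.5 * dij + (sums[a] - sums[b]) / (2.0 * (r - 2))
        bj = dij - bi

        # variance-minimising weight
        vij = V[i, j]
        if vij > 0:
            others = [k for k in idx if k != i and k != j]
            lam = 0.5 + sum(V[j, k] - V[i, k] for k in others) / (2.0 * (r - 2) * vij)
            lam = min(1.0, max(0.0, lam))
        else:
            lam = 0.5

        u = len(clusters)
        ci, cj = clusters[i], clusters[j]
        clusters.append(
            _Cluster(
                f"({ci.newick}:{_fmt(bi)},{cj.newick}:{_fmt(bj)})",
                min(ci.min_taxon, cj.min_taxon),
            )
        )
        # grow matrices by one row/col for the new cluster
        D = np.pad(D, ((0, 1), (0, 1)))
        V = np.pad(V, ((0, 1), (0, 1)))
        for k in active:
            if k == i or k == j:
                continue
            D[u, k] = D[k, u] = lam * (D[i, k] - bi) + (1 - lam) * (D[j, k] - bj)
            V[u, k] = V[k, u] = lam * V[i, k] + (1 - lam) * V[j, k] - lam * (1 - lam) * vij

        active = [k for k in active if k not in (i, j)] + [u]

    # resolve the final three clusters around the central node
    i, j, k = active
    a = 0.5 * (D[i, j] + D[i, k] - D[j, k])
    b = 0.5 * (D[i, j] + D[j, k] - D[i, k])
    c = 0.5 * (D[i, k] + D[j, k] - D[i, j])
    newick = (
        f"({clusters[i].newick}:{_fmt(a)},{clusters[j].newick}:{_fmt(b)},"
        f"{clusters[k].newick}:{_fmt(c)});"
    )
    tree = dendropy.Tree.get(data=newick, schema="newick", preserve_underscores=True)
    tree.is_rooted = False
    return tree


# ---------------------------------------------------------------------------
# rooted gene tree
# ---------------------------------------------------------------------------
@dataclass(frozen=True)
class NodePartition:
    """One internal node's split of the leaves into A | B | outgroup."""

    node_id: int
    clade_a: frozenset[str]
    clade_b: frozenset[str]
    outgroup: frozenset[str]

    @property
    def testable(self) -> bool:
        return (
            len(self.clade_a) >= 4 and len(self.clade_b) >= 4 and len(self.outgroup) >= 1
        )


class GeneTree:
    """Rooted binary tree over a group's sequence ids.

    Wraps a rooted :class:`dendropy.Tree`; integer node ids are assigned
    in preorder and are stable for a given topology.  Branch lengths are
    substitutions/site and clamped at zero.
    """

    def __init__(self, tree: dendropy.Tree):
        self._tree = tree
        self._assign_ids()

    def _assign_ids(self) -> None:
        for i, node in enumerate(self._tree.preorder_node_iter()):
            node.cladeshift_id = i
            if node.edge.length is None or node.edge.length < 0:
                node.edge.length = 0.0

    # -- constructors ------------------------------------------------------
    @classmethod
    def from_distances(
        cls, distances: np.ndarray, taxa: Sequence[str]
    ) -> "GeneTree":
        return root_tree(build_bionj(distances, taxa))

    @classmethod
    def from_newick(cls, newick: str) -> "GeneTree":
        tree = dendropy.Tree.get(
            data=newick, schema="newick", preserve_underscores=True
        )
        tree.is_rooted = True
        _binarise_root(tree)
        return cls(tree)

    def to_newick(self) -> str:
        return (
            self._tree.as_string(
                schema="newick", suppress_rooting=True, unquoted_underscores=True
            ).strip()
        )

    # -- geometry ----------------------------------------------------------
    @property
    def dendropy_tree(self) -> dendropy.Tree:
        return self._tree

    @property
    def root_id(self) -> int:
        return self._tree.seed_node.cladeshift_id

    @property
    def leaf_names(self) -> list[str]:
        return [lf.taxon.label for lf in self._tree.leaf_node_iter()]

    @property
    def n_leaves(self) -> int:
        return len(self.leaf_names)

    def iter_edges(self) -> Iterator[tuple[int, int, float, str | None]]:
        """Preorder edges as (parent_id, child_id, length, leaf_name|None)."""
        for node in self._tree.preorder_node_iter():
            if node.parent_node is None:
                continue
            leaf = node.taxon.label if node.is_leaf() else None
            yield (
                node.parent_node.cladeshift_id,
                node.cladeshift_id,
                float(node.edge.length or 0.0),
                leaf,
            )

    def enumerate_partitions(self) -> list[NodePartition]:
        """A/B/outgroup partition for every internal (binary) node, preorder."""
        all_leaves = frozenset(self.leaf_names)
        out = []
        for node in self._tree.preorder_node_iter():
            children = node.child_nodes()
            if len(children) != 2:
                continue
            a = frozenset(lf.taxon.label for lf in children[0].leaf_iter())
            b = frozenset(lf.taxon.label for lf in children[1].leaf_iter())
            out.append(
                NodePartition(
                    node_id=node.cladeshift_id,
                    clade_a=a,
                    clade_b=b,
                    outgroup=all_leaves - a - b,
                )
            )
        return out

    def testable_partitions(self) -> list[NodePartition]:
        return [p for p in self.enumerate_partitions() if p.testable]


def _binarise_root(tree: dendropy.Tree) -> None:
    """Ensure the seed node is a bifurcation (arbitrary but deterministic)."""
    root = tree.seed_node
    while len(root.child_nodes()) > 2:
        children = root.child_nodes()
        a, b = children[0], children[1]
        new = dendropy.Node()
        new.edge.length = 0.0
        root.remove_child(a)
        root.remove_child(b)
        new.add_child(a)
        new.add_child(b)
        root.insert_child(0, new)


def root_tree(tree: dendropy.Tree) -> GeneTree:
    """Midpoint-root an unrooted tree and return it as a :class:`GeneTree`.

    The root is placed halfway along the longest leaf-to-leaf path.  For a
    zero-diameter tree (all branch lengths 0) the root goes on the edge of
    the first leaf in taxon-label order, which is deterministic.
    """
    tree = tree.clone(depth=1)
    leaves = sorted(tree.leaf_node_iter(), key=lambda lf: lf.taxon.label)
    if len(leaves) < 3:
        raise TreeSizeError("rooting needs at least 3 taxa")
    pdm = tree.phylogenetic_distance_matrix()
    diameter = max(
        pdm.patristic_distance(t1.taxon, t2.taxon)
        for t1, t2 in itertools.combinations(leaves, 2)
    )
    if diameter <= 0:
        edge = leaves[0].edge
        tree.reroot_at_edge(edge, length1=0.0, length2=0.0)
    else:
        tree.reroot_at_midpoint()
    tree.is_rooted = True
    _binarise_root(tree)
    return GeneTree(tree)


def enumerate_testable_nodes(tree: GeneTree) -> list[NodePartition]:
    """Partitions with |clade A| >= 4, |clade B| >= 4 and >= 1 outgroup leaf."""
    return tree.testable_partitions()
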