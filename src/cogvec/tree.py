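"""Unrooted phylogenetic trees with branch lengths.

Internally a tree is stored rooted at an arbitrary internal node; for an
unrooted binary tree over n ≥ 3 taxa the storage root has three children and
every other internal node has two.  All substitution models in this package
are time reversible, so the likelihood does not depend on the storage root.
Branch lengths are expected substitutions per column and are clamped to
[MIN_BRANCH_LENGTH, MAX_BRANCH_LENGTH] during optimization.
"""

from __future__ import annotations

import io
from typing import Iterator

import dendropy

from .errors import CogvecError

MIN_BRANCH_LENGTH = 1e-6
MAX_BRANCH_LENGTH = 100.0


class Node:
    __slots__ = ("name", "children", "parent", "length")

    def __init__(self, name: str | None = None, length: float = 0.0):
        self.name = name
        self.children: list[Node] = []
        self.parent: Node | None = None
        self.length = length  # length of the edge to the parent

    def add_child(self, child: "Node") -> None:
        child.parent = self
        self.children.append(child)

    @property
    def is_leaf(self) -> bool:
        return not self.children


class PhyloTree:
    """A tree over uniquely named leaf taxa."""

    def __init__(self, root: Node):
        self.root = root
        taxa = [n.name for n in self.leaves()]
        if any(t is None for t in taxa):
            raise CogvecError("every leaf must carry a taxon name")
        if len(set(taxa)) != len(taxa):
            raise CogvecError("taxon names must be unique")

    # -- traversal ---------------------------------------------------------

    def postorder(self) -> Iterator[Node]:
        stack, out = [self.root], []
        while stack:
            node = stack.pop()
            out.append(node)
            stack.extend(node.children)
        return iter(reversed(out))

    def preorder(self) -> Iterator[Node]:
        stack = [self.root]
        while stack:
            node = stack.pop()
            yield node
            stack.extend(reversed(node.children))

    def leaves(self) -> list[Node]:
        return [n for n in self.postorder() if n.is_leaf]

    @property
    def taxa(self) -> list[str]:
        return sorted(n.name for n in self.leaves())

    def edges(self) -> list[Node]:
        """Every edge, identified by its child endpoint."""
        return [n for n in self.postorder() if n.parent is not None]

    def internal_edges(self) -> list[Node]:
        """Edges whose both endpoints are internal (the NNI candidates)."""
        return [n for n in self.edges() if not n.is_leaf]

    def n_taxa(self) -> int:
        return len(self.leaves())

    # -- construction ------------------------------------------------------

    def copy(self) -> "PhyloTree":
        def clone(node: Node) -> Node:
            new = Node(node.name, node.length)
            for child in node.children:
                new.add_child(clone(child))
            return new

        return PhyloTree(clone(self.root))

    @classmethod
    def from_newick(cls, newick: str) -> "PhyloTree":
        try:
            dtree = dendropy.Tree.get(
                data=newick, schema="newick", preserve_underscores=True
            )
        except Exception as exc:
            raise CogvecError(f"invalid Newick string: {exc}") from exc

        def convert(dnode) -> Node:
            name = dnode.taxon.label if dnode.taxon is not None else None
            length = dnode.edge.length if dnode.edge.length is not None else 0.0
            node = Node(name, float(length))
            for child in dnode.child_nodes():
                node.add_child(convert(child))
            return node

        tree = cls(convert(dtree.seed_node))
        tree.unroot()
        return tree

    def to_newick(self) -> str:
        def fmt(node: Node) -> str:
            if node.is_leaf:
                body = node.name
            else:
                body = "(" + ",".join(fmt(c) for c in node.children) + ")"
            if node.parent is None:
                return body
            return f"{body}:{node.length:.10g}"

        return fmt(self.root) + ";"

    def write_newick(self, path) -> None:
        with io.open(path, "w", encoding="utf-8") as fh:
            fh.write(self.to_newick() + "\n")

    def unroot(self) -> None:
        """Suppress a degree-2 storage root so the tree reads as unrooted."""
        while len(self.root.children) == 2 and self.n_taxa() >= 3:
            a, b = self.root.children
            internal = a if not a.is_leaf else b
            other = b if internal is a else a
            if internal.is_leaf:
                break  # 2- or 3-taxon corner cases keep the degree-2 root
            internal.parent = None
            other.length = a.length + b.length
            internal.add_child(other)
            self.root = internal

    # -- topology ----------------------------------------------------------

    def splits(self) -> frozenset[frozenset[str]]:
        """Non-trivial bipartitions, as taxon sets on the child side of each edge."""
        all_taxa = frozenset(self.taxa)
        out = set()
        below: dict[int, frozenset[str]] = {}
        for node in self.postorder():
            if node.is_leaf:
                below[id(node)] = frozenset([node.name])
            else:
                below[id(node)] = frozenset().union(
                    *(below[id(c)] for c in node.children)
                )
            if node.parent is not None and not node.is_leaf:
                side = below[id(node)]
                if 1 < len(side) < len(all_taxa) - 1:
                    out.add(min(side, all_taxa - side, key=sorted))
        return frozenset(out)

    def topology_key(self) -> frozenset[frozenset[str]]:
        """Hashable identifier of the unrooted topology (its split set)."""
        return self.splits()

    def clamp_lengths(self) -> None:
        for node in self.edges():
            node.length = min(max(node.length, MIN_BRANCH_LENGTH), MAX_BRANCH_LENGTH)


def nni_neighbors(
    tree: PhyloTree, edge_child: Node, return_edges: bool = False
) -> list[PhyloTree] | list[tuple[PhyloTree, Node]]:
    """The two NNI rearrangements around an internal edge.

    ``edge_child`` is the internal, non-root child endpoint of the edge.  The
    four subtrees around the edge are the two children of ``edge_child`` and
    the remaining neighbours of its parent; swapping each child with one fixed
    sibling of ``edge_child`` yields the two distinct neighbour topologies.
    With ``return_edges`` each neighbour is paired with its central edge node
    (the counterpart of ``edge_child`` in the new tree).
    """
    if edge_child.is_leaf or edge_child.parent is None:
        raise CogvecError("NNI requires an internal, non-root edge endpoint")
    parent = edge_child.parent
    siblings = [c for c in parent.children if c is not edge_child]
    if not siblings:
        raise CogvecError("degenerate edge for NNI")
    out = []
    for child_idx in range(len(edge_child.children)):
        neighbor = tree.copy()
        # find the corresponding nodes in the copy by structural position
        n_child, n_parent = _locate(tree, neighbor, edge_child)
        swap_a = n_child.children[child_idx]
        swap_b = [c for c in n_parent.children if c is not n_child][0]
        n_child.children[child_idx] = swap_b
        n_parent.children[n_parent.children.index(swap_b)] = swap_a
        swap_a.parent = n_parent
        swap_b.parent = n_child
        out.append((neighbor, n_child) if return_edges else neighbor)
    return out


def _locate(tree: PhyloTree, copy: PhyloTree, target: Node) -> tuple[Node, Node]:
    """Find the copy of ``target`` (and its parent) via the traversal index."""
    for orig, dup in zip(tree.postorder(), copy.postorder()):
        if orig is target:
            return dup, dup.parent
    raise CogvecError("node not found in tree")
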