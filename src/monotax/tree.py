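"""Rooted phylogenetic tree container.

The tree is deliberately minimal: labelled nodes, optional branch lengths,
and child order as given in the source file.  All computations in this
package are purely topological; branch lengths are carried along only so
that round-tripping a Newick file preserves them.

All traversals are iterative so that pathological (caterpillar) trees of
tens of thousands of leaves never hit the interpreter recursion limit.
"""

from __future__ import annotations

from typing import Iterator, Optional

from .errors import ArgumentError


class Node:
    """One node of a rooted tree.

    Leaves carry a ``label`` (the strain tag); internal nodes may be
    unlabelled.  ``length`` is the length of the branch above the node.
    """

    __slots__ = ("label", "length", "children", "parent", "_id", "_tin", "_tout")

    def __init__(self, label: Optional[str] = None, length: Optional[float] = None):
        self.label = label
        self.length = length
        self.children: list[Node] = []
        self.parent: Optional[Node] = None
        # set by PhyloTree._reindex
        self._id: int = -1
        self._tin: int = -1
        self._tout: int = -1

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def add_child(self, child: "Node") -> "Node":
        child.parent = self
        self.children.append(child)
        return child

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        kind = "leaf" if self.is_leaf else f"internal({len(self.children)})"
        return f"<Node {self.label!r} {kind}>"


class PhyloTree:
    """A rooted tree with uniquely labelled leaves.

    The structure is mutable (the fixture generator prunes and regrafts
    leaves); call :meth:`reindex` after any structural edit before relying
    on ancestry queries.
    """

    def __init__(self, root: Node):
        self.root = root
        self.reindex()

    # ------------------------------------------------------------------
    # indexing / traversal
    # ------------------------------------------------------------------
    def reindex(self) -> None:
        """Assign preorder ids and Euler intervals for O(1) ancestry tests."""
        counter = 0
        stack = [self.root]
        self.root.parent = None
        order: list[Node] = []
        while stack:
            node = stack.pop()
            node._id = counter
            node._tin = counter
            counter += 1
            order.append(node)
            for child in reversed(node.children):
                child.parent = node
                stack.append(child)
        # compute tout (max preorder id within subtree) bottom-up
        for node in reversed(order):
            node._tout = node._tin
            for child in node.children:
                if child._tout > node._tout:
                    node._tout = child._tout
        self._preorder = order
        self.n_nodes = counter

    def preorder(self) -> Iterator[Node]:
        return iter(self._preorder)

    def postorder(self) -> Iterator[Node]:
        return reversed(self._preorder_reversed_children())

    def _preorder_reversed_children(self) -> list[Node]:
        # preorder with children visited left-to-right ensures that the
        # reverse is a valid postorder (children before parents).
        out: list[Node] = []
        stack = [self.root]
        while stack:
            node = stack.pop()
            out.append(node)
            for child in node.children:
                stack.append(child)
        return out

    def leaves(self) -> list[Node]:
        return [n for n in self._preorder if n.is_leaf]

    def leaf_labels(self) -> list[str]:
        return [n.label for n in self.leaves() if n.label is not None]

    @property
    def n_leaves(self) -> int:
        return sum(1 for n in self._preorder if n.is_leaf)

    def is_ancestor(self, anc: Node, node: Node) -> bool:
        """True if ``anc`` is ``node`` or an ancestor of it (indices current)."""
        return anc._tin <= node._tin <= anc._tout

    def find_leaf(self, label: str) -> Optional[Node]:
        for n in self._preorder:
            if n.is_leaf and n.label == label:
                return n
        return None

    # ------------------------------------------------------------------
    # structural edits (used by the fixture generator)
    # ------------------------------------------------------------------
    def prune_leaf(self, leaf: Node) -> None:
        """Detach ``leaf``; a parent left with one child is spliced out."""
        if not leaf.is_leaf:
            raise ArgumentError("prune_leaf expects a leaf node")
        parent = leaf.parent
        if parent is None:
            raise ArgumentError("cannot prune the root")
        parent.children.remove(leaf)
        leaf.parent = None
        if len(parent.children) == 1 and parent.parent is not None:
            only = parent.children[0]
            grand = parent.parent
            if only.length is not None or parent.length is not None:
                only.length = (only.length or 0.0) + (parent.length or 0.0)
            idx = grand.children.index(parent)
            grand.children[idx] = only
            only.parent = grand
            parent.children = []
            parent.parent = None

    def graft_on_edge(self, node: Node, subtree: Node, split: float = 0.5) -> Node:
        """Insert a new node on the edge above ``node`` and attach ``subtree``.

        Returns the newly created junction node.
        """
        parent = node.parent
        if parent is None:
            raise ArgumentError("cannot graft on the root edge")
        junction = Node()
        if node.length is not None:
            junction.length = node.length * split
            node.length = node.length * (1.0 - split)
        idx = parent.children.index(node)
        parent.children[idx] = junction
        junction.parent = parent
        junction.add_child(node)
        junction.add_child(subtree)
        return junction

    def copy(self) -> "PhyloTree":
        mapping: dict[int, Node] = {}
        new_root = Node(self.root.label, self.root.length)
        mapping[id(self.root)] = new_root
        stack = [self.root]
        while stack:
            node = stack.pop()
            clone = mapping[id(node)]
            for child in node.children:
                cc = Node(child.label, child.length)
                clone.add_child(cc)
                mapping[id(child)] = cc
                stack.append(child)
        return PhyloTree(new_root)
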