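"""Rooted phylogeny container used throughout the pipeline.

Branch lengths are interpreted by context: generations for simulated trees,
substitution counts for neighbor-joining trees. Newick parsing and rerooting
are delegated to dendropy; this class only keeps the minimal structure the
ancestral-state and parsimony machinery needs (parent links, ordered children,
stable node names).
"""

from __future__ import annotations

from typing import Callable, Iterator

import dendropy


class Node:
    __slots__ = ("name", "parent", "children", "length", "support")

    def __init__(self, name: str, length: float | None = None):
        self.name = name
        self.parent: Node | None = None
        self.children: list[Node] = []
        self.length = length
        self.support: float | None = None

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def add_child(self, child: "Node") -> "Node":
        child.parent = self
        self.children.append(child)
        return child

    def __repr__(self) -> str:  # pragma: no cover
        return f"Node({self.name!r}, n_children={len(self.children)})"


class Phylogeny:
    """A rooted tree with named nodes and optional branch lengths."""

    def __init__(self, root: Node):
        self.root = root
        self._index: dict[str, Node] | None = None

    # -- traversal ---------------------------------------------------------

    def preorder(self) -> Iterator[Node]:
        stack = [self.root]
        while stack:
            node = stack.pop()
            yield node
            stack.extend(reversed(node.children))

    def postorder(self) -> Iterator[Node]:
        out = list(self.preorder())
        return reversed(out)

    def leaves(self) -> list[Node]:
        return [n for n in self.preorder() if n.is_leaf]

    def leaf_names(self) -> list[str]:
        return [n.name for n in self.leaves()]

    def branches(self) -> list[tuple[Node, Node]]:
        """(parent, child) pairs in preorder of the child."""
        return [(n.parent, n) for n in self.preorder() if n.parent is not None]

    def node(self, name: str) -> Node:
        if self._index is None:
            self._index = {n.name: n for n in self.preorder()}
        return self._index[name]

    def invalidate(self) -> None:
        self._index = None

    # -- summaries ---------------------------------------------------------

    def total_branch_length(self) -> float:
        return sum(n.length or 0.0 for n in self.preorder() if n.parent is not None)

    def leaf_sets(self) -> dict[str, frozenset[str]]:
        """Leaf-name set below every node, keyed by node name."""
        below: dict[str, frozenset[str]] = {}
        for node in self.postorder():
            if node.is_leaf:
                below[node.name] = frozenset([node.name])
            else:
                acc: set[str] = set()
                for c in node.children:
                    acc |= below[c.name]
                below[node.name] = frozenset(acc)
        return below

    def bipartitions(self) -> set[frozenset[str]]:
        """Non-trivial unrooted splits, canonicalized to the side not
        containing the lexicographically smallest leaf."""
        all_leaves = frozenset(self.leaf_names())
        anchor = min(all_leaves)
        splits: set[frozenset[str]] = set()
        below = self.leaf_sets()
        for node in self.preorder():
            if node.parent is None:
                continue
            side = below[node.name]
            if anchor in side:
                side = all_leaves - side
            if 1 < len(side) < len(all_leaves) - 1:
                splits.add(side)
        return splits

    # -- newick ------------------------------------------------------------

    def to_newick(self, include_support: bool = False) -> str:
        def fmt(node: Node) -> str:
            if node.is_leaf:
                label = node.name
            else:
                inner = ",".join(fmt(c) for c in node.children)
                if include_support and node.support is not None:
                    label = f"({inner}){node.support:g}"
                else:
                    label = f"({inner}){node.name}"
            if node.parent is not None and node.length is not None:
                label += f":{node.length:g}"
            return label

        return fmt(self.root) + ";"

    @classmethod
    def from_newick(cls, newick: str) -> "Phylogeny":
        dtree = dendropy.Tree.get(
            data=newick, schema="newick", preserve_underscores=True
        )
        return cls.from_dendropy(dtree)

    @classmethod
    def from_dendropy(cls, dtree: dendropy.Tree) -> "Phylogeny":
        counter = [0]

        def name_of(dnode) -> str:
            if dnode.taxon is not None and dnode.taxon.label:
                return dnode.taxon.label
            if dnode.label:
                return str(dnode.label)
            counter[0] += 1
            return f"node{counter[0]:04d}"

        def build(dnode) -> Node:
            node = Node(name_of(dnode), dnode.edge.length)
            for child in dnode.child_nodes():
                node.add_child(build(child))
            return node

        return cls(build(dtree.seed_node))

    def to_dendropy(self) -> dendropy.Tree:
        return dendropy.Tree.get(
            data=self.to_newick(), schema="newick", preserve_underscores=True
        )

    def copy(self) -> "Phylogeny":
        def dup(node: Node) -> Node:
            new = Node(node.name, node.length)
            new.support = node.support
            for c in node.children:
                new.add_child(dup(c))
            return new

        return Phylogeny(dup(self.root))

    def relabel_internal(self, namer: Callable[[int], str] | None = None) -> None:
        """Give deterministic names to unnamed/auto internal nodes (preorder)."""
        namer = namer or (lambda i: f"n{i:03d}")
        i = 0
        for node in self.preorder():
            if not node.is_leaf:
                i += 1
                node.name = namer(i)
        self.invalidate()
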