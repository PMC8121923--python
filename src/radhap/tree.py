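"""Phylogenetic tree container: topology, branch lengths, bootstrap supports.

Unrooted trees are stored with a trifurcating root node; rooted trees with a
bifurcating root. Branch lengths live on the child end of each edge, in
expected substitutions per site; integer bootstrap supports (0-100) live on
internal nodes and refer to the edge above the node.
"""

from __future__ import annotations

from pathlib import Path
from typing import Iterator

import dendropy


class Node:
    __slots__ = ("name", "length", "support", "children", "parent")

    def __init__(
        self,
        name: str | None = None,
        length: float = 0.0,
        support: int | None = None,
    ) -> None:
        self.name = name
        self.length = length
        self.support = support
        self.children: list[Node] = []
        self.parent: Node | None = None

    def add_child(self, child: "Node") -> "Node":
        child.parent = self
        self.children.append(child)
        return child

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return f"Node({self.name!r}, len={self.length:.4g}, children={len(self.children)})"


class Tree:
    """A rooted or unrooted (trifurcating-root) phylogeny over named leaves."""

    def __init__(self, root: Node) -> None:
        self.root = root

    # ------------------------------------------------------------------ basics
    def postorder(self) -> Iterator[Node]:
        stack: list[tuple[Node, bool]] = [(self.root, False)]
        while stack:
            node, expanded = stack.pop()
            if expanded:
                yield node
            else:
                stack.append((node, True))
                for child in reversed(node.children):
                    stack.append((child, False))

    def preorder(self) -> Iterator[Node]:
        stack = [self.root]
        while stack:
            node = stack.pop()
            yield node
            stack.extend(reversed(node.children))

    def leaves(self) -> list[Node]:
        return [n for n in self.postorder() if n.is_leaf]

    def leaf_names(self) -> list[str]:
        return [n.name for n in self.leaves()]

    @property
    def is_rooted(self) -> bool:
        return len(self.root.children) == 2

    def copy(self) -> "Tree":
        def clone(node: Node) -> Node:
            new = Node(node.name, node.length, node.support)
            for child in node.children:
                new.add_child(clone(child))
            return new

        return Tree(clone(self.root))

    def total_length(self) -> float:
        return sum(n.length for n in self.postorder() if n is not self.root)

    # ------------------------------------------------------------ bipartitions
    def bipartitions(self) -> dict[frozenset, Node]:
        """Non-trivial splits of the leaf set, canonicalized.

        Each split is represented by the frozenset of leaf names on the side
        NOT containing the lexicographically smallest leaf, making splits
        comparable across rootings. Maps split -> child-end node of the edge.
        """
        all_leaves = frozenset(self.leaf_names())
        ref = min(all_leaves)
        below: dict[int, frozenset] = {}
        result: dict[frozenset, Node] = {}
        for node in self.postorder():
            if node.is_leaf:
                below[id(node)] = frozenset([node.name])
            else:
                below[id(node)] = frozenset().union(*(below[id(c)] for c in node.children))
            if node is self.root or node.parent is None:
                continue
            side = below[id(node)]
            if len(side) < 2 or len(all_leaves - side) < 2:
                continue  # trivial split
            canonical = all_leaves - side if ref in side else side
            # with a bifurcating root, the two root-child edges are one edge
            if canonical not in result:
                result[canonical] = node
        return result

    # ------------------------------------------------------------------ newick
    def to_newick(
        self,
        include_supports: bool = True,
        support_threshold: int | None = None,
    ) -> str:
        """Newick string with branch lengths; supports as internal node labels.

        ``support_threshold`` produces the display variant: supports below the
        threshold are omitted.
        """

        def fmt(node: Node) -> str:
            if node.is_leaf:
                body = node.name or ""
            else:
                label = ""
                if include_supports and node.support is not None:
                    if support_threshold is None or node.support >= support_threshold:
                        label = str(int(node.support))
                body = "(" + ",".join(fmt(c) for c in node.children) + ")" + label
            if node is self.root:
                return body
            return f"{body}:{node.length:.10g}"

        return fmt(self.root) + ";"

    @classmethod
    def from_newick(cls, source: str | Path) -> "Tree":
        """Parse Newick (string or file path); internal labels become supports."""
        text = str(source)
        if "(" not in text:
            try:
                is_file = Path(text).exists()
            except OSError:
                is_file = False
            if not is_file:
                raise ValueError(f"not a Newick string or existing file: {text[:80]!r}")
            text = Path(text).read_text()
        try:
            dtree = dendropy.Tree.get(
                data=text,
                schema="newick",
                suppress_internal_node_taxa=True,
                preserve_underscores=True,
            )
        except Exception as exc:
            raise ValueError(f"malformed Newick: {exc}") from exc

        def convert(dnode) -> Node:
            if dnode.is_leaf():
                name = dnode.taxon.label if dnode.taxon else dnode.label
                node = Node(name, dnode.edge.length or 0.0)
            else:
                support = None
                if dnode.label is not None:
                    try:
                        support = int(round(float(dnode.label)))
                    except ValueError:
                        support = None
                node = Node(None, dnode.edge.length or 0.0, support)
                for dchild in dnode.child_nodes():
                    node.add_child(convert(dchild))
            return node

        return cls(convert(dtree.seed_node))

    # ----------------------------------------------------------------- rooting
    def unroot(self) -> "Tree":
        """Collapse a bifurcating root into a trifurcation (in place); returns self."""
        if len(self.root.children) != 2:
            return self
        a, b = self.root.children
        keep, merge = (a, b) if not a.is_leaf else (b, a)
        if keep.is_leaf:
            return self  # two-leaf tree cannot be unrooted further
        merge.length += keep.length
        merge.support = keep.support if keep.support is not None else merge.support
        self.root = Node(None, 0.0)
        for child in keep.children:
            self.root.add_child(child)
        self.root.add_child(merge)
        return self

    def reroot_on_edge(self, child: Node, fraction: float = 0.5) -> "Tree":
        """Return a new tree rooted on the edge above ``child``.

        The edge is split ``fraction`` (root-side) : ``1-fraction``. Supports
        stay attached to their splits.
        """
        tree = self.copy()
        # locate the corresponding node in the copy by path of child indices
        path = []
        node = child
        while node.parent is not None:
            path.append(node.parent.children.index(node))
            node = node.parent
        target = tree.root
        for idx in reversed(path):
            target = target.children[idx]
        if target.parent is None:
            raise ValueError("cannot root on the edge above the root")

        old_parent = target.parent
        edge_len = target.length
        edge_support = target.support
        new_root = Node(None, 0.0)
        old_parent.children.remove(target)
        target.parent = None
        target.length = edge_len * (1.0 - fraction)
        new_root.add_child(target)

        # reverse the path from old_parent up to the old root
        prev = new_root
        carry_len = edge_len * fraction
        carry_support = edge_support
        node = old_parent
        while node is not None:
            parent = node.parent
            next_len = node.length
            next_support = node.support
            if parent is not None:
                parent.children.remove(node)
            node.parent = None
            node.length = carry_len
            node.support = carry_support
            prev.add_child(node)
            prev = node
            carry_len = next_len
            carry_support = next_support
            node = parent
        # the old root is now a unifurcation or bifurcation tail: suppress if degree 1
        tail = prev
        if len(tail.children) == 1:
            only = tail.children[0]
            grand = tail.parent
            only.length += tail.length
            if only.support is None:
                only.support = tail.support
            grand.children[grand.children.index(tail)] = only
            only.parent = grand
        result = Tree(new_root)
        if target.is_leaf is False and target.support is not None:
            pass  # support already on target (same split as the sibling side)
        return result


def root_on_outgroup(tree: Tree, outgroup_labels: set[str] | frozenset[str]) -> Tree:
    """Root an unrooted tree so the outgroup clade is one child of the root.

    The outgroup must be monophyletic in the unrooted tree; otherwise the
    error lists the non-outgroup leaves intruding into the smallest clade
    spanning the outgroup.
    """
    outgroup = frozenset(outgroup_labels)
    leaves = frozenset(tree.leaf_names())
    if not outgroup:
        raise ValueError("empty outgroup")
    if not outgroup <= leaves:
        raise ValueError(f"outgroup labels not in tree: {sorted(outgroup - leaves)}")
    if outgroup == leaves:
        raise ValueError("outgroup cannot contain all leaves")

    below: dict[int, frozenset] = {}
    target: Node | None = None
    spanning: frozenset | None = None
    for node in tree.postorder():
        if node.is_leaf:
            below[id(node)] = frozenset([node.name])
        else:
            below[id(node)] = frozenset().union(*(below[id(c)] for c in node.children))
        if node is tree.root:
            continue
        side = below[id(node)]
        if side == outgroup or (leaves - side) == outgroup:
            target = node
        if outgroup <= side and (spanning is None or len(side) < len(spanning)):
            spanning = side
    if target is None:
        intruders = sorted((spanning or leaves) - outgroup)
        raise ValueError(f"outgroup is not monophyletic; intruding leaves: {intruders}")
    rooted = tree.reroot_on_edge(target)
    return rooted


def robinson_foulds(tree_a: Tree, tree_b: Tree) -> int:
    """Number of non-trivial splits present in exactly one of the two trees."""
    a = set(tree_a.bipartitions())
    b = set(tree_b.bipartitions())
    return len(a ^ b)
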