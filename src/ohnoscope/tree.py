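"""Lightweight rooted/unrooted phylogenetic tree container.

Newick text is parsed with dendropy and converted into a minimal node
structure that the likelihood engine can flatten into arrays.  Serialization
back to newick is a trivial recursive writer.  Branch lengths are optional on
read and live on the child node of each edge.
"""

from __future__ import annotations

import itertools
from typing import Callable, Iterator, Optional

import dendropy


class Node:
    """A tree node; ``length`` is the length of the edge to its parent."""

    __slots__ = ("name", "length", "children", "parent")

    def __init__(self, name: Optional[str] = None, length: Optional[float] = None):
        self.name = name
        self.length = length
        self.children: list["Node"] = []
        self.parent: Optional["Node"] = None

    def add_child(self, child: "Node") -> "Node":
        child.parent = self
        self.children.append(child)
        return child

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return f"Node({self.name!r}, len={self.length})"


class Tree:
    """A rooted tree; ``rooted=False`` marks the root as an unrooted
    trifurcation surrogate (likelihoods under reversible models do not
    depend on its placement)."""

    def __init__(self, root: Node, rooted: bool = True):
        self.root = root
        self.rooted = rooted

    # ------------------------------------------------------------------ I/O

    @classmethod
    def from_newick(cls, text: str, rooted: bool = True) -> "Tree":
        dt = dendropy.Tree.get(data=text, schema="newick",
                               preserve_underscores=True,
                               suppress_internal_node_taxa=True)

        def convert(dnode) -> Node:
            if dnode.taxon is not None:
                name = dnode.taxon.label
            else:
                name = dnode.label
            node = Node(name=name, length=dnode.edge.length)
            for child in dnode.child_nodes():
                node.add_child(convert(child))
            return node

        return cls(convert(dt.seed_node), rooted=rooted)

    @classmethod
    def read(cls, path, rooted: bool = True) -> "Tree":
        with open(path) as fh:
            return cls.from_newick(fh.read(), rooted=rooted)

    def to_newick(self, lengths: bool = True, internal_labels: bool = True) -> str:
        def fmt(node: Node) -> str:
            if node.is_leaf:
                s = node.name or ""
            else:
                s = "(" + ",".join(fmt(c) for c in node.children) + ")"
                if internal_labels and node.name:
                    s += node.name
            if lengths and node.length is not None and node.parent is not None:
                s += f":{node.length:.10g}"
            return s

        return fmt(self.root) + ";"

    def write(self, path, lengths: bool = True) -> None:
        if lengths:
            missing = [n.name for n in self.iter_nodes()
                       if n.parent is not None and n.length is None]
            if missing:
                raise ValueError(f"cannot write tree: branch lengths unset on {missing}")
        with open(path, "w") as fh:
            fh.write(self.to_newick(lengths=lengths) + "\n")

    # ------------------------------------------------------------- traversal

    def iter_nodes(self) -> Iterator[Node]:
        yield from self.preorder()

    def preorder(self) -> Iterator[Node]:
        stack = [self.root]
        while stack:
            node = stack.pop()
            yield node
            stack.extend(reversed(node.children))

    def postorder(self) -> Iterator[Node]:
        out = list(self.preorder())
        return iter(reversed(out))

    def leaves(self) -> list[Node]:
        return [n for n in self.preorder() if n.is_leaf]

    def leaf_names(self) -> list[str]:
        return [n.name for n in self.leaves()]

    def find(self, name: str) -> Node:
        for node in self.preorder():
            if node.name == name:
                return node
        raise KeyError(f"no node named {name!r}")

    def mrca(self, names) -> Node:
        """Most recent common ancestor of a set of leaf (or node) names."""
        want = set(names)
        below: dict[int, set] = {}
        for node in self.postorder():
            s = {node.name} if node.name else set()
            for c in node.children:
                s |= below[id(c)]
            below[id(node)] = s
        best = None
        for node in self.postorder():
            if want <= below[id(node)]:
                best = node
                break  # postorder: first covering node is the MRCA
        if best is None:
            raise KeyError(f"names {sorted(want)} not all present in tree")
        return best

    # ------------------------------------------------------------ operations

    def copy(self) -> "Tree":
        def clone(node: Node) -> Node:
            new = Node(node.name, node.length)
            for c in node.children:
                new.add_child(clone(c))
            return new

        return Tree(clone(self.root), rooted=self.rooted)

    def label_internal(self, prefix: str = "iv") -> None:
        """Give every unnamed internal node a unique deterministic label."""
        counter = itertools.count(1)
        for node in self.preorder():
            if not node.is_leaf and not node.name:
                node.name = f"{prefix}{next(counter)}"

    def prune_leaves(self, names) -> None:
        """Remove the named leaves and suppress resulting unary nodes."""
        drop = set(names)
        keep_leaves = {id(n) for n in self.leaves() if n.name not in drop}
        for leaf in [n for n in self.leaves() if n.name in drop]:
            parent = leaf.parent
            if parent is None:
                raise ValueError("cannot prune the root")
            parent.children.remove(leaf)
        # remove emptied internals and suppress unary ones (bottom-up)
        changed = True
        while changed:
            changed = False
            for node in list(self.postorder()):
                if (node.is_leaf and id(node) not in keep_leaves
                        and node.parent is not None):
                    node.parent.children.remove(node)
                    changed = True
                elif len(node.children) == 1 and node.parent is not None:
                    child = node.children[0]
                    if node.length is not None or child.length is not None:
                        child.length = (node.length or 0.0) + (child.length or 0.0)
                    node.parent.children[node.parent.children.index(node)] = child
                    child.parent = node.parent
                    changed = True
        if len(self.root.children) == 1:
            new_root = self.root.children[0]
            new_root.parent = None
            new_root.length = None
            self.root = new_root

    def bipartitions(self) -> set[frozenset]:
        """Non-trivial splits, each normalized to the side *not* containing
        the alphabetically first leaf (topology comparison oracle)."""
        names = sorted(self.leaf_names())
        ref = names[0]
        full = frozenset(names)
        below: dict[int, frozenset] = {}
        splits: set[frozenset] = set()
        for node in self.postorder():
            if node.is_leaf:
                below[id(node)] = frozenset([node.name])
                continue
            s = frozenset().union(*(below[id(c)] for c in node.children))
            below[id(node)] = s
            if node.parent is None:
                continue
            side = full - s if ref in s else s
            if 1 < len(side) < len(full) - 1:
                splits.add(side)
        return splits

    def same_topology(self, other: "Tree") -> bool:
        return (sorted(self.leaf_names()) == sorted(other.leaf_names())
                and self.bipartitions() == other.bipartitions())

    def map_names(self, fn: Callable[[str], Optional[str]]) -> None:
        for node in self.preorder():
            if node.name is not None:
                node.name = fn(node.name)
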