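"""Five-OTU topology enumeration under the 2R (1-2-4) duplication pattern.

The five operational units are: one cyclostome gene (C), the three
gnathostome subtype groups (A = alpha, B = beta, G = gamma) and the
outgroup (O).  Rooting every topology on the outgroup edge turns the
problem into enumerating rooted four-leaf trees over {C, A, B, G}: there
are 15.  A strict 2R history makes the four paralogue slots a balanced
((.,.),(.,.)) tree, so a cyclostome gene orthologous to one subtype slot
(or occupying the lost fourth, delta, slot) always ends up in a cherry with
a single extant subtype; topologies whose only cherry is purely gnathostome
would imply cyclostome-gnathostome divergence between the two duplication
rounds and are excluded.  Exactly nine topologies survive, three for each
possible cherry partner of C.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
from scipy.cluster.hierarchy import average, to_tree
from scipy.spatial.distance import squareform

from .io_formats import Alignment, GAP
from .tree import Node, Tree

ROLES = ("cyclostome", "alpha", "beta", "gamma", "outgroup")
SLOT = {"cyclostome": "C", "alpha": "A", "beta": "B", "gamma": "G",
        "outgroup": "O"}
SUBTYPE_OF_SLOT = {"A": "alpha", "B": "beta", "G": "gamma"}


@dataclass(frozen=True)
class OtuScheme:
    """Maps the five OTU roles to sequence-name groups.

    ``fixed_subtrees`` optionally gives a rooted newick (over the members)
    for each multi-member OTU; when absent, :func:`expand_otus` can fall
    back to a UPGMA subtree built once from the alignment.
    """

    members: dict[str, tuple[str, ...]]
    fixed_subtrees: dict[str, str] = field(default_factory=dict)

    def __post_init__(self):
        missing = [r for r in ROLES if r not in self.members]
        if missing:
            raise ValueError(f"OTU scheme missing roles: {missing}")
        seen: set[str] = set()
        for role, names in self.members.items():
            if not names:
                raise ValueError(f"OTU {role!r} has no members")
            overlap = seen & set(names)
            if overlap:
                raise ValueError(f"sequence(s) in multiple OTUs: {sorted(overlap)}")
            seen |= set(names)
        if len(self.members["cyclostome"]) != 1:
            raise ValueError("the cyclostome OTU must contain exactly one gene")


@dataclass(frozen=True)
class LabelledTopology:
    """An outgroup-rooted backbone topology over the slots C, A, B, G."""

    id: str
    newick_template: str  # rooted: (O,<ingroup>);
    cherry_partner_of_C: str | None  # "A" | "B" | "G" | None
    shape_class: str  # "balanced" | "caterpillar"

    def tree(self) -> Tree:
        return Tree.from_newick(self.newick_template, rooted=True)


@dataclass(frozen=True)
class DuplicationConstraint:
    pattern: str = "1-2-4"
    assume_fourth_paralogue: bool = False


@dataclass(frozen=True)
class TopologySet:
    topologies: tuple[LabelledTopology, ...]
    constrained: bool
    metadata: dict = field(default_factory=dict, compare=False)

    def __len__(self) -> int:
        return len(self.topologies)

    def __iter__(self):
        return iter(self.topologies)

    def ids(self) -> tuple[str, ...]:
        return tuple(t.id for t in self.topologies)

    def by_id(self, tid: str) -> LabelledTopology:
        for t in self.topologies:
            if t.id == tid:
                return t
        raise KeyError(tid)

    def to_tsv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("id\tnewick\tcherry_partner\tshape_class\n")
            for t in self.topologies:
                fh.write(f"{t.id}\t{t.newick_template}\t"
                         f"{t.cherry_partner_of_C or 'none'}\t{t.shape_class}\n")

    def to_newick_file(self, path) -> None:
        with open(path, "w") as fh:
            for t in self.topologies:
                fh.write(t.newick_template + "\n")


# ------------------------------------------------------------- enumeration


def _rooted_shapes(labels: tuple[str, ...]):
    """All rooted binary tree shapes over the given leaf labels, as nested
    tuples."""
    if len(labels) == 1:
        yield labels[0]
        return
    rest = labels[1:]
    first = labels[0]
    for r in range(0, len(rest)):
        for left_rest in combinations(rest, r):
            left = (first,) + left_rest
            right = tuple(x for x in rest if x not in left_rest)
            if not right:
                continue
            for lt in _rooted_shapes(left):
                for rt in _rooted_shapes(right):
                    yield (lt, rt)


def _shape_newick(shape) -> str:
    if isinstance(shape, str):
        return shape
    parts = sorted(_shape_newick(s) for s in shape)
    return "(" + ",".join(parts) + ")"


def _cherry_partner(shape, target: str = "C") -> str | None:
    """Sibling leaf of ``target`` if it sits in a cherry, else None."""
    if isinstance(shape, str):
        return None
    a, b = shape
    if a == target and isinstance(b, str):
        return b
    if b == target and isinstance(a, str):
        return a
    return _cherry_partner(a, target) or _cherry_partner(b, target)


def _shape_class(shape) -> str:
    sizes = sorted(_n_leaves(s) for s in shape)
    return "balanced" if sizes == [2, 2] else "caterpillar"


def _n_leaves(shape) -> int:
    if isinstance(shape, str):
        return 1
    return sum(_n_leaves(s) for s in shape)


def enumerate_all(otus: OtuScheme | None = None,
                  slots: tuple[str, ...] = ("C", "A", "B", "G")) -> TopologySet:
    """All distinct unrooted topologies on the five OTUs, represented as
    outgroup-rooted trees over the ingroup slots; (2n-5)!! of them."""
    canon: dict[str, object] = {}
    for shape in _rooted_shapes(slots):
        canon.setdefault(_shape_newick(shape), shape)
    topologies = []
    for i, key in enumerate(sorted(canon), start=1):
        shape = canon[key]
        topologies.append(LabelledTopology(
            id=f"T{i:02d}",
            newick_template=f"(O,{key});",
            cherry_partner_of_C=_cherry_partner(shape),
            shape_class=_shape_class(shape) if not isinstance(shape, str) else "leaf",
        ))
    return TopologySet(tuple(topologies), constrained=False,
                       metadata={"slots": slots})


RATIONALE = (
    "A strict 2R history places the four paralogue slots on a balanced "
    "((.,.),(.,.)) tree; a cyclostome gene orthologous to one slot (or "
    "occupying the lost fourth slot) is therefore always in a cherry with a "
    "single extant subtype slot.  Topologies whose cherry is purely "
    "gnathostome imply cyclostome divergence between the two duplication "
    "rounds and are excluded."
)


def enumerate_constrained(otus: OtuScheme | None = None,
                          constraint: DuplicationConstraint | None = None
                          ) -> TopologySet:
    """The topologies compatible with the 1-2-4 duplication pattern: C must
    be in a cherry with exactly one subtype slot.  Nine survive, three per
    cherry partner."""
    constraint = constraint or DuplicationConstraint()
    if constraint.pattern != "1-2-4":
        raise ValueError(f"unsupported duplication pattern {constraint.pattern!r}")
    full = enumerate_all(otus)
    kept = tuple(t for t in full if t.cherry_partner_of_C is not None)
    partition = {slot: tuple(t.id for t in kept if t.cherry_partner_of_C == slot)
                 for slot in ("A", "B", "G")}
    return TopologySet(kept, constrained=True,
                       metadata={"rationale": RATIONALE,
                                 "partition_by_cherry": partition,
                                 "assume_fourth_paralogue":
                                     constraint.assume_fourth_paralogue})


# --------------------------------------------------------------- expansion


def _p_distance_matrix(aln: Alignment) -> np.ndarray:
    arr = np.array([list(s) for s in aln.seqs])
    n = len(aln.names)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            ok = (arr[i] != GAP) & (arr[j] != GAP)
            if ok.sum() == 0:
                d[i, j] = d[j, i] = 0.75
            else:
                d[i, j] = d[j, i] = (arr[i][ok] != arr[j][ok]).mean()
    return d


def upgma_subtree(aln: Alignment, names) -> str:
    """Rooted UPGMA shape (average-linkage on p-distances) over the named
    sequences; branch lengths are left unset (they are re-optimized)."""
    names = list(names)
    if len(names) == 1:
        return names[0]
    sub = aln.subset(names)
    d = _p_distance_matrix(sub)
    Z = average(squareform(d, checks=False))
    root, _ = to_tree(Z, rd=True)

    def render(cl) -> str:
        if cl.is_leaf():
            return names[cl.id]
        return f"({render(cl.left)},{render(cl.right)})"

    return render(root)


def expand_otus(topology: LabelledTopology, otus: OtuScheme,
                aln: Alignment | None = None,
                allow_fallback: bool = True) -> Tree:
    """Replace every OTU slot of a backbone topology by its (fixed) rooted
    member subtree; branch lengths are left unset."""
    tree = topology.tree()
    slot_to_role = {v: k for k, v in SLOT.items()}
    for leaf in list(tree.leaves()):
        role = slot_to_role[leaf.name]
        members = otus.members[role]
        if len(members) == 1:
            leaf.name = members[0]
            continue
        nwk = otus.fixed_subtrees.get(role)
        if nwk is None:
            if not (allow_fallback and aln is not None):
                raise ValueError(
                    f"OTU {role!r} has {len(members)} members but no fixed "
                    "subtree, and no alignment was given for the UPGMA fallback")
            nwk = upgma_subtree(aln, members) + ";"
        elif not nwk.endswith(";"):
            nwk = nwk + ";"
        sub = Tree.from_newick(nwk)
        got = sorted(sub.leaf_names())
        if got != sorted(members):
            raise ValueError(
                f"fixed subtree for OTU {role!r} covers {got}, expected "
                f"{sorted(members)}")
        # graft: replace the slot leaf by the subtree root
        sub.root.length = leaf.length
        parent = leaf.parent
        parent.children[parent.children.index(leaf)] = sub.root
        sub.root.parent = parent
    for node in tree.preorder():
        node.length = None
    return tree


def contract_to_backbone(expanded: Tree, otus: OtuScheme) -> str:
    """Collapse each OTU's member clade back to its slot letter and return
    the canonical ingroup shape string (oracle for expand_otus)."""
    tree = expanded.copy()
    name_to_slot = {}
    for role, members in otus.members.items():
        for m in members:
            name_to_slot[m] = SLOT[role]
    for role, members in otus.members.items():
        if len(members) == 1:
            continue
        node = tree.mrca(set(members))
        if sorted(n for n in _leaf_names_below(node)) != sorted(members):
            raise ValueError(f"OTU {role!r} is not monophyletic in the tree")
        node.children = []
        node.name = members[0]
    tree.map_names(lambda n: name_to_slot.get(n, n))

    def shape(node: Node):
        if node.is_leaf:
            return node.name
        return tuple(shape(c) for c in node.children)

    shapes = [_shape_newick(shape(c)) for c in tree.root.children]
    ingroup = [s for s in shapes if s != "O"]
    if len(ingroup) != 1:
        raise ValueError("expected an outgroup-rooted tree (O, ingroup)")
    return ingroup[0]


def _leaf_names_below(node: Node):
    return [n.name for n in _iter_leaves(node)]


def _iter_leaves(node: Node):
    if node.is_leaf:
        yield node
    else:
        for c in node.children:
            yield from _iter_leaves(c)


# ----------------------------------------------------------- hypothesis map


@dataclass(frozen=True)
class HypothesisMap:
    """Topology-id support sets per orthology hypothesis."""

    scheme: str  # "three_subtype" | "four_subtype"
    sets: dict[str, tuple[str, ...]]
    dual_counted: dict[str, str] = field(default_factory=dict)
    # dual_counted: balanced topology id -> the subtype it also supports


def hypothesis_map(tset: TopologySet,
                   assume_fourth_paralogue: bool = False) -> HypothesisMap:
    """Map orthology hypotheses to supporting topology ids.

    Three-subtype mode: "C orthologous to X" is supported by all three
    topologies with cherry (C, X) — a partition of the constrained set.
    Four-subtype mode: caterpillars support only their cherry partner, while
    each balanced topology ((C,X),(Y,Z)) is compatible both with orthology
    to X and with C occupying the lost delta slot; it is counted in both the
    X and the delta sums, and the dual counting is reported explicitly.
    """
    if not tset.constrained:
        raise ValueError("hypothesis_map requires a constrained topology set")
    sets: dict[str, list[str]] = {s: [] for s in ("alpha", "beta", "gamma")}
    dual: dict[str, str] = {}
    if assume_fourth_paralogue:
        sets["delta"] = []
    for t in tset:
        subtype = SUBTYPE_OF_SLOT[t.cherry_partner_of_C]
        sets[subtype].append(t.id)
        if assume_fourth_paralogue and t.shape_class == "balanced":
            sets["delta"].append(t.id)
            dual[t.id] = subtype
    return HypothesisMap(
        scheme="four_subtype" if assume_fourth_paralogue else "three_subtype",
        sets={k: tuple(v) for k, v in sets.items()},
        dual_counted=dual)
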