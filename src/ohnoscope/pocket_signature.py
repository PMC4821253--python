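"""Ligand-binding-pocket triplet signatures and mutation-event inference.

The three subtype-diagnostic pocket positions (human RARα numbering
232/270/395, in helices H3/H5/H11) define a residue triplet per sequence or
ancestral node.  Exactly three triplets name a subtype class: Ser/Ile/Val
(alpha-like), Ala/Ile/Val (beta-like) and Ala/Met/Ala (gamma-like);
everything else — including any triplet containing an ambiguous 'X' — is
"other".  Given a rooted tree whose every node carries a triplet,
substitution events are the edge-wise state differences; an event is a
reversion when it restores a state held by an ancestor older than the most
recent change at that position.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .io_formats import Alignment, ReferenceMap
from .tree import Tree

PATTERNS = {
    ("S", "I", "V"): "alpha_like",
    ("A", "I", "V"): "beta_like",
    ("A", "M", "A"): "gamma_like",
}


@dataclass(frozen=True)
class PocketTriplet:
    h3_232: str
    h5_270: str
    h11_395: str
    owner: str = ""

    def residues(self) -> tuple[str, str, str]:
        return (self.h3_232.upper(), self.h5_270.upper(), self.h11_395.upper())


@dataclass(frozen=True)
class SignatureClass:
    label: str  # alpha_like | beta_like | gamma_like | other
    matched_pattern: tuple[str, str, str] | None


@dataclass(frozen=True)
class PocketEvent:
    branch: str  # label of the child node of the edge
    position: int
    from_state: str
    to_state: str
    reversion: bool


@dataclass(frozen=True)
class EventMap:
    events: tuple[PocketEvent, ...]

    def __len__(self) -> int:
        return len(self.events)

    def to_tsv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("branch\tposition\tfrom\tto\treversion\n")
            for e in self.events:
                fh.write(f"{e.branch}\t{e.position}\t{e.from_state}\t"
                         f"{e.to_state}\t{int(e.reversion)}\n")


def classify_signature(t: PocketTriplet) -> SignatureClass:
    """Exact-match classification against the three printed subtype
    patterns; partial matches (and any 'X') are 'other'."""
    res = t.residues()
    label = PATTERNS.get(res)
    if label is None:
        return SignatureClass("other", None)
    return SignatureClass(label, res)


def triplet_from_alignment(aln: Alignment, refmap: ReferenceMap,
                           name: str) -> PocketTriplet:
    if len(refmap.columns) != 3:
        raise ValueError("pocket signature needs exactly three reference positions")
    seq = aln.seq(name)
    r = [seq[c - 1] for c in refmap.columns]
    return PocketTriplet(r[0], r[1], r[2], owner=name)


def signature_table(aln: Alignment, refmap: ReferenceMap, owners,
                    node_rows: pd.DataFrame | None = None) -> pd.DataFrame:
    """One classified triplet row per requested sequence, plus optional
    ancestral-node rows taken from a reconstruction report."""
    rows = []
    for name in owners:
        t = triplet_from_alignment(aln, refmap, name)
        cls = classify_signature(t)
        rows.append({"owner": name, "kind": "sequence",
                     **_triplet_cols(t, refmap), "class": cls.label})
    if node_rows is not None:
        cols = [f"residue_{p}" for p in refmap.positions]
        for _, nrow in node_rows.iterrows():
            t = PocketTriplet(*(nrow[c] for c in cols), owner=nrow["node"])
            cls = classify_signature(t)
            rows.append({"owner": nrow["node"], "kind": "node",
                         **_triplet_cols(t, refmap), "class": cls.label})
    return pd.DataFrame(rows)


def _triplet_cols(t: PocketTriplet, refmap: ReferenceMap) -> dict:
    res = t.residues()
    return {f"residue_{p}": r for p, r in zip(refmap.positions, res)}


def infer_events(tree: Tree, states: dict[str, tuple], positions=(232, 270, 395)
                 ) -> EventMap:
    """Edge-wise substitution/reversion events on a rooted tree whose every
    node (by label) has a pocket triplet.

    Edges touching an ambiguous ('X') state at a position yield no call at
    that position.  Events are ordered by tree pre-order, then position.
    """
    for node in tree.preorder():
        if node.name is None:
            raise ValueError("every tree node must be labelled for event "
                             "inference")
        if node.name not in states:
            raise ValueError(f"missing pocket state for node {node.name!r}")
    n_pos = len(positions)
    events: list[PocketEvent] = []

    def visit(node, path):
        """path: per position, list of states from the root down to node's
        parent (inclusive)."""
        st = [s.upper() for s in states[node.name]]
        if len(st) != n_pos:
            raise ValueError(f"state of {node.name!r} has {len(st)} positions, "
                             f"expected {n_pos}")
        new_path = []
        for i in range(n_pos):
            trail = path[i]
            cur = st[i]
            if trail:
                parent_state = trail[-1]
                if cur != parent_state and cur != "X" and parent_state != "X":
                    reversion = False
                    # states of ancestors strictly older than the most recent
                    # change at this position
                    last_change = None
                    for j in range(len(trail) - 1, 0, -1):
                        if trail[j] != trail[j - 1]:
                            last_change = j
                            break
                    if last_change is not None:
                        older = set(trail[:last_change])
                        reversion = cur in older
                    events.append(PocketEvent(node.name, positions[i],
                                              parent_state, cur, reversion))
            new_path.append(path[i] + [cur])
        for c in node.children:
            visit(c, new_path)

    visit(tree.root, [[] for _ in range(n_pos)])
    return EventMap(tuple(events))
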