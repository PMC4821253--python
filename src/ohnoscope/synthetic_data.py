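"""Generative 2R gene-family scenarios with full ground truth.

The simulator realizes the 1-2-4 duplication history: an outgroup splits
first, the ingroup gene is duplicated twice (the pairing fixes which
subtypes are sisters), per-subtype species radiations hang off each
paralogue, a single cyclostome gene is grafted onto the stem of the subtype
it is orthologous to, and lost paralogues are pruned.  Sequences evolve
along the tree under a reversible amino-acid model with discrete-gamma rate
heterogeneity (one category drawn per column).  Three designated "pocket"
columns are overwritten post-hoc by a deterministic event scenario
(mutations and reversions on named branches), so signature and event tests
have exact ground truth while every other column exercises the stochastic
machinery.

Default condition choices (documented in the methods note): three species
per gnathostome subtype (mirroring a human/gar/catshark-like sampling),
2000 columns, gamma shape 1.0, delta lost in all lineages, duplication-era
and stem branches 0.1 and within-radiation branches 0.05 expected
substitutions per site.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

from .io_formats import Alignment
from .subst_model import GammaRates, RateModel, discrete_gamma, load_model, \
    transition_matrices
from .tree import Node, Tree
from .topology_space import OtuScheme

SUBTYPES = ("alpha", "beta", "gamma", "delta")
DEFAULT_PAIRING = (("alpha", "delta"), ("beta", "gamma"))


@dataclass(frozen=True)
class ScenarioSpec:
    pairing: tuple = DEFAULT_PAIRING
    cyclostome_orthology: str = "gamma"
    losses: tuple[str, ...] = ("delta",)
    species_per_subtype: int = 3
    branch_length_scale: float = 1.0
    alpha: float = 1.0
    gamma_categories: int = 4
    n_columns: int = 2000
    pocket_events: tuple = ()
    pocket_positions: tuple[int, ...] = ()  # 1-based columns; () = none
    single_copy: bool = False
    seed: int = 0

    def __post_init__(self):
        flat = [s for pair in self.pairing for s in pair]
        if sorted(flat) != sorted(SUBTYPES):
            raise ValueError(f"pairing must cover {SUBTYPES}, got {self.pairing}")
        if self.cyclostome_orthology not in SUBTYPES:
            raise ValueError(
                f"unknown cyclostome orthology {self.cyclostome_orthology!r}")
        if self.cyclostome_orthology in self.losses:
            raise ValueError("cyclostome orthologue subtype cannot be lost "
                             "(the gene would have nowhere to attach)")
        surviving = [s for s in SUBTYPES if s not in self.losses]
        required = ("alpha", "beta", "gamma")
        gone = [s for s in required if s not in surviving]
        if gone:
            raise ValueError(
                f"losses remove subtype(s) {gone} required by the OTU scheme")
        if self.branch_length_scale <= 0:
            raise ValueError("branch_length_scale must be positive")


@dataclass
class TruthBundle:
    tree: Tree                       # rooted, all nodes labelled
    alignment: Alignment             # leaf sequences
    node_sequences: dict[str, str]   # every node label -> full sequence
    true_orthology: str
    spec: ScenarioSpec
    pocket_columns: dict[int, int] = field(default_factory=dict)
    # position label (e.g. 232) -> 1-based alignment column
    node_triplets: dict[str, tuple[str, str, str]] = field(default_factory=dict)
    planted_events: tuple = ()

    def otu_scheme(self) -> OtuScheme:
        members: dict[str, tuple[str, ...]] = {
            "cyclostome": ("cyclostome_gene",), "outgroup": ("outgroup",)}
        for sub in ("alpha", "beta", "gamma"):
            members[sub] = tuple(
                n for n in self.alignment.names if n.startswith(sub + "_sp"))
        return OtuScheme(members=members)

    def write(self, out_dir) -> None:
        from pathlib import Path
        from .io_formats import write_alignment
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        write_alignment(self.alignment, out / "alignment.fasta")
        self.tree.write(out / "true_tree.nwk")
        truth = {
            "true_orthology": self.true_orthology,
            "pocket_columns": self.pocket_columns,
            "node_triplets": {k: list(v) for k, v in self.node_triplets.items()},
            "planted_events": [list(e) for e in self.planted_events],
            "seed": self.spec.seed,
        }
        with open(out / "truth.json", "w") as fh:
            json.dump(truth, fh, indent=2, sort_keys=True)


# ------------------------------------------------------------ tree building


def build_scenario_tree(spec: ScenarioSpec) -> Tree:
    """Labelled rooted tree realizing the 2R history of the scenario."""
    s = spec.branch_length_scale
    root = Node("root")
    og = root.add_child(Node("outgroup", length=0.25 * s))  # noqa: F841

    def species_clade(subtype: str) -> Node:
        crown = Node(f"{subtype}_crown", length=0.1 * s)
        tips = [Node(f"{subtype}_sp{i+1}", length=0.05 * s)
                for i in range(spec.species_per_subtype)]
        if len(tips) == 1:
            return tips[0]
        # ladder shape (sp1,(sp2,(sp3,...)))
        cur = tips[-1]
        for t in reversed(tips[1:-1]):
            inner = Node(length=0.05 * s)
            inner.add_child(t)
            inner.add_child(cur)
            cur = inner
        crown.add_child(tips[0])
        crown.add_child(cur)
        return crown

    if spec.single_copy:
        clade = species_clade("single")
        clade.length = 0.1 * s
        root.add_child(clade)
        tree = Tree(root)
        tree.label_internal()
        return tree

    wgd1 = root.add_child(Node("wgd1", length=0.1 * s))
    for p, pair in enumerate(spec.pairing):
        pair_node = wgd1.add_child(Node(f"wgd2_{p+1}", length=0.1 * s))
        for subtype in pair:
            stem_child = species_clade(subtype)
            if subtype == spec.cyclostome_orthology:
                split = Node(f"cg_split_{subtype}", length=0.1 * s)
                cyclo = Node("cyclostome_gene", length=0.15 * s)
                split.add_child(cyclo)
                stem_child.length = 0.1 * s
                split.add_child(stem_child)
                pair_node.add_child(split)
            else:
                pair_node.add_child(stem_child)

    tree = Tree(root)
    if spec.losses:
        lost_leaves = [n for n in tree.leaf_names()
                       if any(n.startswith(sub + "_sp") for sub in spec.losses)]
        tree.prune_leaves(lost_leaves)
    tree.label_internal()
    return tree


# -------------------------------------------------------------- simulation


def simulate_alignment(tree: Tree, model: RateModel, gamma: GammaRates,
                       n_columns: int, seed: int = 0
                       ) -> tuple[Alignment, dict[str, str]]:
    """Evolve sequences along the tree; returns the leaf alignment and the
    full node-label -> sequence map (root included)."""
    tree.label_internal()
    rng = np.random.default_rng(seed)
    S = model.n_states
    cats = rng.integers(0, gamma.k, size=n_columns)
    states: dict[int, np.ndarray] = {}
    root_state = rng.choice(S, size=n_columns, p=model.frequencies)
    states[id(tree.root)] = root_state

    for node in tree.preorder():
        if node.parent is None:
            continue
        P = transition_matrices(model, node.length or 0.0, gamma.rates)
        parent_state = states[id(node.parent)]
        probs = P[cats, parent_state, :]  # (n_columns, S)
        u = rng.random(n_columns)
        child = (probs.cumsum(axis=1) > u[:, None]).argmax(axis=1)
        states[id(node)] = child

    def to_seq(vec: np.ndarray) -> str:
        return "".join(model.alphabet[i] for i in vec)

    node_seqs = {}
    for node in tree.preorder():
        node_seqs[node.name] = to_seq(states[id(node)])
    leaf_names = tree.leaf_names()
    aln = Alignment(tuple(leaf_names), tuple(node_seqs[n] for n in leaf_names))
    return aln, node_seqs


# ------------------------------------------------------------ pocket events


def plant_pocket_events(aln: Alignment, node_seqs: dict[str, str], tree: Tree,
                        events, pocket_columns: dict[int, int],
                        root_states: dict[int, str]
                        ) -> tuple[Alignment, dict[str, str],
                                   dict[str, tuple], tuple]:
    """Overwrite the designated pocket columns with scenario-determined
    states.

    ``events``: iterable of (branch_label, position_label, from, to);
    ``pocket_columns``: position label -> 1-based alignment column;
    ``root_states``: position label -> root residue.
    Returns (alignment, node_sequences, node_triplets, events) with the
    pocket columns rewritten everywhere and per-node truth triplets.
    """
    positions = list(pocket_columns)
    ev_by_branch: dict[str, dict[int, tuple[str, str]]] = {}
    for branch, pos, frm, to in events:
        if pos not in pocket_columns:
            raise ValueError(f"event position {pos} is not a pocket position")
        per = ev_by_branch.setdefault(branch, {})
        if pos in per:
            raise ValueError(
                f"conflicting duplicate events on branch {branch!r} at "
                f"position {pos}")
        per[pos] = (frm.upper(), to.upper())
    known = {n.name for n in tree.preorder()}
    unknown = set(ev_by_branch) - known
    if unknown:
        raise ValueError(f"event branch(es) not in tree: {sorted(unknown)}")

    node_states: dict[str, dict[int, str]] = {}

    def visit(node: Node, state: dict[int, str]) -> None:
        state = dict(state)
        for pos, (frm, to) in ev_by_branch.get(node.name, {}).items():
            if state[pos] != frm:
                raise ValueError(
                    f"event on branch {node.name!r} at position {pos} expects "
                    f"state {frm!r} but the lineage carries {state[pos]!r}")
            state[pos] = to
        node_states[node.name] = state
        for c in node.children:
            visit(c, state)

    visit(tree.root, {p: root_states[p].upper() for p in positions})

    new_node_seqs = {}
    for label, seq in node_seqs.items():
        chars = list(seq)
        for pos, col in pocket_columns.items():
            chars[col - 1] = node_states[label][pos]
        new_node_seqs[label] = "".join(chars)
    new_aln = Alignment(aln.names,
                        tuple(new_node_seqs[n] for n in aln.names))
    triplets = {label: tuple(st[p] for p in positions)
                for label, st in node_states.items()}
    return new_aln, new_node_seqs, triplets, tuple(tuple(e) for e in events)


# ------------------------------------------------------------------ bundles


def make_bundle(spec: ScenarioSpec, model: RateModel | None = None
                ) -> TruthBundle:
    """Simulate a complete scenario with ground truth."""
    model = model or load_model("LG")
    tree = build_scenario_tree(spec)
    gamma = discrete_gamma(spec.alpha, spec.gamma_categories)
    aln, node_seqs = simulate_alignment(tree, model, gamma, spec.n_columns,
                                        seed=spec.seed)
    bundle = TruthBundle(tree=tree, alignment=aln, node_sequences=node_seqs,
                         true_orthology=spec.cyclostome_orthology, spec=spec)
    if spec.pocket_positions:
        if len(spec.pocket_positions) != 3:
            raise ValueError("exactly three pocket columns are designated")
        pocket_columns = {int(p): int(p) for p in spec.pocket_positions}
        root_states = {p: "SIV"[i] for i, p in enumerate(pocket_columns)}
        aln, node_seqs, triplets, ev = plant_pocket_events(
            aln, node_seqs, tree, spec.pocket_events, pocket_columns,
            root_states)
        bundle.alignment = aln
        bundle.node_sequences = node_seqs
        bundle.node_triplets = triplets
        bundle.planted_events = ev
        bundle.pocket_columns = pocket_columns
    return bundle


# --------------------------------------------------------- fig6-style fixture

FIG6_SPECIES = {
    "chondrichthyan": ("Sc",),            # catshark-like
    "actinopterygian": ("Lo", "Dr"),      # gar-, zebrafish-like
    "sarcopterygian": ("Xt", "Gg", "Hs"),  # frog-, chicken-, human-like
}

# (branch label, position, from, to): the mutation/reversion scenario for the
# three pocket positions — S->A at 232 on the beta/gamma stem, reverted on the
# cyclostome RAR1 stem and in actinopterygian and frog gamma; I->M at 270 and
# V->A at 395 on the gnathostome gamma stem.
FIG6_EVENTS = (
    ("node3", 232, "S", "A"),
    ("rar1_crown", 232, "A", "S"),
    ("gamma_crown", 270, "I", "M"),
    ("gamma_crown", 395, "V", "A"),
    ("node6", 232, "A", "S"),
    ("XtRARg", 232, "A", "S"),
)

FIG6_NODE_SPEC = {
    "node1": ("EbRAR3", "HsRARg"),   # ancestor of all vertebrate RARs
    "node2": ("EbRAR3", "HsRARa"),   # base of the alpha group (incl. RAR3)
    "node3": ("EbRAR2", "HsRARg"),   # before the beta/gamma divergence
    "node4": ("EbRAR2", "HsRARb"),   # base of the beta group (incl. RAR2)
    "node5": ("EbRAR1", "HsRARg"),   # base of the gamma group (incl. RAR1)
    "node6": ("LoRARg", "DrRARg"),   # base of actinopterygian gamma
    "node7": ("XtRARg", "HsRARg"),   # base of sarcopterygian gamma
}

_EVENT_EDGE = 0.2
_PLAIN_EDGE = 0.05


def _fig6_newick(scale: float) -> str:
    e = _EVENT_EDGE * scale
    p = _PLAIN_EDGE * scale

    def clade(g: str, crown_label: str) -> str:
        """Gnathostome subtype clade: chondrichthyan basal, then the
        actinopterygian and sarcopterygian radiations."""
        if g == "g":  # the gamma clade carries the node6/node7 labels
            acti = f"(LoRARg:{p},DrRARg:{p})node6:{e}"
            sarco = f"(XtRARg:{e},(GgRARg:{p},HsRARg:{p}):{p})node7:{p}"
        else:
            acti = f"(LoRAR{g}:{p},DrRAR{g}:{p}):{p}"
            sarco = f"(XtRAR{g}:{p},(GgRAR{g}:{p},HsRAR{g}:{p}):{p}):{p}"
        return f"(ScRAR{g}:{p},({acti},{sarco}):{p}){crown_label}"

    def cyclo(n: int) -> str:
        return f"(EbRAR{n}:{p},LjRAR{n}:{p})rar{n}_crown"

    alpha = f"({cyclo(3)}:{p},{clade('a', 'alpha_crown')}:{p})node2:{p}"
    beta = f"({cyclo(2)}:{p},{clade('b', 'beta_crown')}:{p})node4:{p}"
    gamma = f"({cyclo(1)}:{e},{clade('g', 'gamma_crown')}:{e})node5:{p}"
    node3 = f"({beta},{gamma})node3:{e}"
    node1 = f"({alpha},{node3})node1:{p}"
    return f"(BfRAR:{0.3 * scale:.6g},{node1})root;"


def make_fig6_bundle(seed: int = 0, n_columns: int = 450,
                     scale: float = 1.0, alpha: float = 1.0,
                     model: RateModel | None = None) -> TruthBundle:
    """The shipped mutation/reversion scenario fixture: cyclostome RAR1/2/3
    against gnathostome alpha/beta/gamma across chondrichthyan-,
    actinopterygian- and sarcopterygian-like species, with the pocket-event
    history planted at columns 232/270/395 of an ungapped alignment.

    Edges that carry planted events are long (0.2 substitutions/site), the
    rest short (0.05), so the planted node states dominate the marginal
    reconstruction.
    """
    if n_columns < 395:
        raise ValueError("fig6-style bundles need >= 395 columns so the "
                         "232/270/395 reference positions exist")
    model = model or load_model("LG")
    tree = Tree.from_newick(_fig6_newick(scale), rooted=True)
    tree.label_internal()
    gamma = discrete_gamma(alpha, 4)
    aln, node_seqs = simulate_alignment(tree, model, gamma, n_columns,
                                        seed=seed)
    pocket_columns = {232: 232, 270: 270, 395: 395}
    root_states = {232: "S", 270: "I", 395: "V"}
    aln, node_seqs, triplets, ev = plant_pocket_events(
        aln, node_seqs, tree, FIG6_EVENTS, pocket_columns, root_states)
    spec = ScenarioSpec(cyclostome_orthology="gamma", n_columns=n_columns,
                        alpha=alpha, pocket_events=FIG6_EVENTS,
                        pocket_positions=(232, 270, 395), seed=seed,
                        branch_length_scale=scale)
    return TruthBundle(tree=tree, alignment=aln, node_sequences=node_seqs,
                       true_orthology="gamma", spec=spec,
                       pocket_columns=pocket_columns, node_triplets=triplets,
                       planted_events=ev)
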