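"""Marginal empirical-Bayes ancestral sequence reconstruction.

For every named internal node (defined as the MRCA of a leaf set) and
every gap-filtered alignment column, the posterior distribution over
residues is computed by combining the pruning down-pass partial with the
outside (up-pass) partial under every gamma rate category; categories are
mixed by their per-site posterior weight.  The "best predicted" (MAP)
sequence takes the per-column argmax, breaking exact ties alphabetically
and flagging them.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io_formats import Alignment, ColumnMask, ReferenceMap
from .likelihood_engine import PruningEngine
from .subst_model import GammaRates, RateModel
from .tree import Tree

TIE_RTOL = 1e-9


@dataclass(frozen=True)
class NodeSpec:
    """Named internal nodes, each defined by a leaf set whose MRCA it is."""

    nodes: dict[str, tuple[str, ...]]

    @classmethod
    def from_dict(cls, d: dict) -> "NodeSpec":
        return cls({str(k): tuple(v) for k, v in d.items()})


@dataclass(frozen=True)
class NodeReconstruction:
    node_label: str
    posteriors: np.ndarray  # (n_filtered_columns, alphabet size)
    alphabet: str
    map_sequence: str
    tie_flags: np.ndarray  # bool per column

    def to_logo_tsv(self, path) -> None:
        export_logo_table(self, path)


def marginal_asr(tree: Tree, aln: Alignment, model: RateModel,
                 gamma: GammaRates, nodes: NodeSpec) -> list[NodeReconstruction]:
    """Marginal ancestral reconstruction at the named nodes of a rooted
    tree with branch lengths, on a (gap-filtered) alignment."""
    engine = PruningEngine(tree, aln, model, gamma)
    engine.down_pass()
    engine.up_pass()
    alphabet = model.alphabet
    order = np.argsort(list(alphabet))  # alphabetical preference for ties
    out = []
    for label, leaf_set in nodes.nodes.items():
        try:
            node = tree.mrca(set(leaf_set))
        except KeyError as exc:
            raise ValueError(
                f"node {label!r}: cannot resolve MRCA of {sorted(leaf_set)}: "
                f"{exc}") from exc
        post = engine.node_posteriors(node)
        best = post.max(axis=1)
        is_max = post >= best[:, None] * (1.0 - TIE_RTOL)
        tie_flags = is_max.sum(axis=1) > 1
        # pick the alphabetically first residue among the (near-)maximal ones
        pref = is_max[:, order]
        choice = order[pref.argmax(axis=1)]
        map_seq = "".join(alphabet[i] for i in choice)
        out.append(NodeReconstruction(label, post, alphabet, map_seq,
                                      tie_flags))
    return out


def reconstruction_report(recs: list[NodeReconstruction],
                          refmap: ReferenceMap,
                          mask: ColumnMask | None = None) -> pd.DataFrame:
    """Per-node table of residues and posterior probabilities at the
    reference-mapped key columns.

    ``refmap`` columns refer to the *unfiltered* alignment; ``mask`` (from
    the gap filter) translates them.  Pass ``mask=None`` when the refmap was
    built on the filtered alignment itself.
    """
    rows = []
    for rec in recs:
        row: dict = {"node": rec.node_label}
        for pos, col in zip(refmap.positions, refmap.columns):
            if mask is not None:
                if col not in mask.source_to_filtered:
                    raise ValueError(
                        f"key column {col} (position {pos}) was removed by the "
                        "gap filter; review the gap threshold")
                col = mask.source_to_filtered[col]
            i = col - 1
            residue = rec.map_sequence[i]
            prob = float(rec.posteriors[i, rec.alphabet.index(residue)])
            if rec.tie_flags[i]:
                residue = "X"
            row[f"residue_{pos}"] = residue
            row[f"prob_{pos}"] = prob
        rows.append(row)
    return pd.DataFrame(rows)


def export_logo_table(rec: NodeReconstruction, path) -> None:
    """Per-position residue-probability table (logo-ready TSV)."""
    df = pd.DataFrame(rec.posteriors, columns=list(rec.alphabet))
    df.insert(0, "position", np.arange(1, len(df) + 1))
    df.to_csv(path, sep="\t", index=False, float_format="%.10g")


def read_logo_table(path) -> np.ndarray:
    df = pd.read_csv(path, sep="\t")
    return df.drop(columns=["position"]).to_numpy()


def map_sequences_to_fasta(recs: list[NodeReconstruction], path) -> None:
    with open(path, "w") as fh:
        for rec in recs:
            fh.write(f">{rec.node_label}\n{rec.map_sequence}\n")
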