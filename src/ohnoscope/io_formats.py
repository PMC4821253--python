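"""Aligned-FASTA and newick I/O, gap-column filtering, reference numbering.

Alignments are immutable collections of equal-length gapped protein
sequences.  Columns and reference positions are 1-based in every public
interface.  The gap character is ``'-'`` only; ``'X'`` denotes a totally
ambiguous residue (it counts as sequence for the gap filter but contributes
a flat likelihood downstream).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .tree import Tree

AMINO_ACIDS = "ARNDCQEGHILKMFPSTWYV"  # PAML ordering
GAP = "-"
AMBIG = "X"


@dataclass(frozen=True)
class Alignment:
    """Named, equal-length gapped sequences over the amino-acid alphabet."""

    names: tuple[str, ...]
    seqs: tuple[str, ...]

    def __post_init__(self):
        if not self.names:
            raise ValueError("alignment has no records")
        if len(set(self.names)) != len(self.names):
            dupes = sorted({n for n in self.names if self.names.count(n) > 1})
            raise ValueError(f"duplicate record names: {dupes}")
        n = len(self.seqs[0])
        if n < 1:
            raise ValueError("alignment has zero columns")
        for i, (name, seq) in enumerate(zip(self.names, self.seqs)):
            if len(seq) != n:
                raise ValueError(
                    f"not an alignment: record {i + 1} ({name!r}) has length "
                    f"{len(seq)}, expected {n}")
            bad = set(seq) - set(AMINO_ACIDS + GAP + AMBIG)
            if bad:
                raise ValueError(
                    f"record {name!r} contains invalid residues {sorted(bad)}")

    @property
    def n_cols(self) -> int:
        return len(self.seqs[0])

    @property
    def n_seqs(self) -> int:
        return len(self.names)

    def seq(self, name: str) -> str:
        try:
            return self.seqs[self.names.index(name)]
        except ValueError:
            raise KeyError(f"no sequence named {name!r}") from None

    def subset(self, names) -> "Alignment":
        names = list(names)
        return Alignment(tuple(names), tuple(self.seq(n) for n in names))

    def take_columns(self, cols_0based) -> "Alignment":
        return Alignment(self.names,
                         tuple("".join(s[c] for c in cols_0based) for s in self.seqs))


@dataclass(frozen=True)
class ColumnMask:
    """Boolean keep-mask plus the 1-based original→filtered column map."""

    keep: tuple[bool, ...]
    source_to_filtered: dict[int, int] = field(compare=False)

    @classmethod
    def from_keep(cls, keep) -> "ColumnMask":
        keep = tuple(bool(k) for k in keep)
        mapping, j = {}, 0
        for i, k in enumerate(keep, start=1):
            if k:
                j += 1
                mapping[i] = j
        return cls(keep, mapping)

    def to_tsv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("original_column\tfiltered_column\n")
            for i in range(1, len(self.keep) + 1):
                fh.write(f"{i}\t{self.source_to_filtered.get(i, 'NA')}\n")


@dataclass(frozen=True)
class ReferenceMap:
    """Maps 1-based ungapped residue positions of a reference sequence to
    1-based alignment columns."""

    reference_name: str
    positions: tuple[int, ...]
    columns: tuple[int, ...]
    residues_at_reference: tuple[str, ...]


def read_alignment(path, ambiguous: str = "as_x") -> Alignment:
    """Read an aligned FASTA file.

    ``ambiguous`` controls non-standard residue letters (B, Z, J, U, O, *):
    ``"as_x"`` maps them to 'X', ``"error"`` rejects the record.
    """
    if ambiguous not in ("as_x", "error"):
        raise ValueError(f"unknown ambiguity policy {ambiguous!r}")
    names, seqs = [], []
    for rec in SeqIO.parse(str(path), "fasta"):
        seq = str(rec.seq).upper()
        cleaned = []
        for ch in seq:
            if ch == ".":
                raise ValueError(
                    f"record {rec.id!r} uses '.' as gap; only '-' is accepted")
            if ch in AMINO_ACIDS or ch in (GAP, AMBIG):
                cleaned.append(ch)
            elif ambiguous == "as_x":
                cleaned.append(AMBIG)
            else:
                raise ValueError(
                    f"record {rec.id!r} contains ambiguous residue {ch!r}")
        names.append(rec.id)
        seqs.append("".join(cleaned))
    if not names:
        raise ValueError(f"no FASTA records found in {path}")
    return Alignment(tuple(names), tuple(seqs))


def write_alignment(aln: Alignment, path) -> None:
    records = [SeqRecord(Seq(s), id=n, description="")
               for n, s in zip(aln.names, aln.seqs)]
    SeqIO.write(records, str(path), "fasta")


def filter_gap_columns(aln: Alignment,
                       max_gap_frac: float = 0.10) -> tuple[Alignment, ColumnMask]:
    """Drop every column whose gap fraction is *strictly greater* than
    ``max_gap_frac`` (default: more than 10% gaps)."""
    if not 0 <= max_gap_frac < 1:
        raise ValueError("max_gap_frac must be in [0, 1)")
    arr = np.array([list(s) for s in aln.seqs])
    gap_frac = (arr == GAP).mean(axis=0)
    keep = gap_frac <= max_gap_frac
    if not keep.any():
        raise ValueError("empty alignment after filtering")
    mask = ColumnMask.from_keep(keep)
    kept_idx = np.flatnonzero(keep)
    return aln.take_columns(kept_idx), mask


def map_reference_positions(aln: Alignment, reference_name: str,
                            positions) -> ReferenceMap:
    """Locate the alignment column of each 1-based ungapped reference
    position (column c maps to position p iff the reference's p-th non-gap
    residue sits in column c)."""
    seq = aln.seq(reference_name)
    ungapped_cols = [i for i, ch in enumerate(seq) if ch != GAP]
    columns, residues = [], []
    for p in positions:
        if not 1 <= p <= len(ungapped_cols):
            raise ValueError(
                f"position {p} beyond ungapped length {len(ungapped_cols)} "
                f"of reference {reference_name!r}")
        col = ungapped_cols[p - 1]
        columns.append(col + 1)
        residues.append(seq[col])
    return ReferenceMap(reference_name, tuple(int(p) for p in positions),
                        tuple(columns), tuple(residues))


def read_tree(path, rooted: bool = True, alignment: Alignment | None = None) -> Tree:
    tree = Tree.read(path, rooted=rooted)
    if alignment is not None:
        check_leaf_names(tree, alignment)
    return tree


def write_tree(tree: Tree, path, lengths: bool = True) -> None:
    tree.write(path, lengths=lengths)


def check_leaf_names(tree: Tree, aln: Alignment) -> None:
    tree_names = set(tree.leaf_names())
    aln_names = set(aln.names)
    if tree_names != aln_names:
        only_tree = sorted(tree_names - aln_names)
        only_aln = sorted(aln_names - tree_names)
        raise ValueError(
            "tree/alignment name mismatch: "
            f"only in tree {only_tree}, only in alignment {only_aln}")
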