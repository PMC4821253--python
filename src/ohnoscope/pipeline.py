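"""End-to-end analyses: the orthology panel and the ASR/signature chain.

``run_orthology_panel`` loops the single-cyclostome probabilistic orthology
assessment over several cyclostome genes against fixed gnathostome groups
(the pie-chart analysis).  ``run_asr_signature`` chains gap filtering,
marginal ancestral reconstruction, the key-position report, signature
classification and event inference on a user-supplied rooted tree.  Every
run can emit a manifest with config, seeds and input hashes so it is
reproducible bit for bit.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import __version__
from .ancestral_reconstruction import (NodeSpec, map_sequences_to_fasta,
                                       marginal_asr, reconstruction_report)
from .io_formats import (Alignment, check_leaf_names, filter_gap_columns,
                         map_reference_positions)
from .orthology_rell import OrthologyReport, run_orthology_assessment
from .pocket_signature import EventMap, infer_events, signature_table
from .subst_model import discrete_gamma, load_model
from .likelihood_engine import estimate_alpha
from .topology_space import OtuScheme
from .tree import Tree


@dataclass(frozen=True)
class RunConfig:
    """Shared run parameters; every stochastic stage has an explicit seed."""

    model_name: str = "LG"
    gamma_categories: int = 4
    gamma_policy: str = "shared-estimate"
    alpha: float | None = None
    replicates: int = 10000
    seed: int = 0
    gap_threshold: float = 0.10
    reference_name: str | None = None
    reference_positions: tuple[int, ...] = (232, 270, 395)
    scheme: str = "three_subtype"
    out_dir: str | None = None
    extra: dict = field(default_factory=dict)


def run_orthology_panel(aln: Alignment, cyclostome_genes,
                        gnathostome_groups: dict[str, tuple[str, ...]],
                        outgroup: tuple[str, ...],
                        config: RunConfig) -> dict[str, OrthologyReport]:
    """One orthology assessment per cyclostome gene against the fixed
    gnathostome subtype groups (the pie-chart panel)."""
    for role in ("alpha", "beta", "gamma"):
        if role not in gnathostome_groups:
            raise ValueError(f"gnathostome_groups missing {role!r}")
    all_needed = ([g for g in cyclostome_genes] + list(outgroup)
                  + [n for ns in gnathostome_groups.values() for n in ns])
    missing = [n for n in all_needed if n not in aln.names]
    if missing:
        raise ValueError(f"sequences absent from alignment: {missing}")

    model = load_model(config.model_name)
    reports = {}
    for gene in cyclostome_genes:
        otus = OtuScheme(members={
            "cyclostome": (gene,),
            "alpha": tuple(gnathostome_groups["alpha"]),
            "beta": tuple(gnathostome_groups["beta"]),
            "gamma": tuple(gnathostome_groups["gamma"]),
            "outgroup": tuple(outgroup),
        })
        out = (Path(config.out_dir) / gene if config.out_dir else None)
        reports[gene] = run_orthology_assessment(
            aln, otus, model=model, B=config.replicates, seed=config.seed,
            scheme=config.scheme, max_gap_frac=config.gap_threshold,
            gamma_policy=config.gamma_policy, k=config.gamma_categories,
            alpha=config.alpha, out_dir=out)
    if config.out_dir:
        _write_manifest(Path(config.out_dir), config,
                        {"alignment": _hash_alignment(aln)},
                        {g: r.prob for g, r in reports.items()})
    return reports


@dataclass
class AsrSignatureResult:
    reconstructions: list
    node_report: pd.DataFrame
    signatures: pd.DataFrame
    events: EventMap
    alpha: float


def run_asr_signature(aln: Alignment, tree: Tree, nodes: NodeSpec,
                      config: RunConfig,
                      optimize_lengths: bool = True) -> AsrSignatureResult:
    """Gap filter -> marginal ASR -> key-position report -> signature
    table -> event inference on a rooted tree."""
    if config.reference_name is None:
        raise ValueError("config.reference_name is required for the "
                         "signature analysis")
    check_leaf_names(tree, aln)
    filtered, mask = filter_gap_columns(aln, config.gap_threshold)
    refmap = map_reference_positions(aln, config.reference_name,
                                     config.reference_positions)
    for col, pos in zip(refmap.columns, refmap.positions):
        if col not in mask.source_to_filtered:
            raise ValueError(
                f"key position {pos} (column {col}) was removed by the gap "
                "filter; review the gap threshold")

    model = load_model(config.model_name)
    work = tree.copy()
    work.label_internal()
    if optimize_lengths or any(n.length is None for n in work.preorder()
                               if n.parent is not None):
        est = estimate_alpha(work, filtered, model,
                             k=config.gamma_categories, tol=1e-4, xatol=1e-4)
        work, gamma, alpha = est["tree"], est["gamma"], est["alpha"]
    else:
        alpha = config.alpha if config.alpha is not None else 1.0
        gamma = discrete_gamma(alpha, config.gamma_categories)

    recs = marginal_asr(work, filtered, model, gamma, nodes)
    node_report = reconstruction_report(recs, refmap, mask)
    signatures = signature_table(aln, refmap, aln.names, node_rows=node_report)

    # node states for event inference: MAP residues, ties poisoned to 'X'
    states: dict[str, tuple] = {}
    for _, row in node_report.iterrows():
        states[row["node"]] = tuple(row[f"residue_{p}"]
                                    for p in refmap.positions)
    filtered_cols = [mask.source_to_filtered[c] for c in refmap.columns]
    for name in filtered.names:
        seq = filtered.seq(name)
        states[name] = tuple(seq[c - 1] for c in filtered_cols)
    # remaining internal nodes (not in the node spec) also need states
    spec_nodes = set(states)
    all_nodes = NodeSpec({n.name: tuple(_leaves_below(n))
                          for n in work.preorder()
                          if not n.is_leaf and n.name not in spec_nodes})
    if all_nodes.nodes:
        extra = marginal_asr(work, filtered, model, gamma, all_nodes)
        extra_report = reconstruction_report(extra, refmap, mask)
        for _, row in extra_report.iterrows():
            states[row["node"]] = tuple(row[f"residue_{p}"]
                                        for p in refmap.positions)
    events = infer_events(work, states, positions=refmap.positions)

    result = AsrSignatureResult(recs, node_report, signatures, events, alpha)
    if config.out_dir:
        out = Path(config.out_dir)
        out.mkdir(parents=True, exist_ok=True)
        map_sequences_to_fasta(recs, out / "ancestral_map_sequences.fasta")
        for rec in recs:
            rec.to_logo_tsv(out / f"posterior_{rec.node_label}.tsv")
        node_report.to_csv(out / "key_positions.tsv", sep="\t", index=False)
        signatures.to_csv(out / "signatures.tsv", sep="\t", index=False)
        events.to_tsv(out / "events.tsv")
        mask.to_tsv(out / "column_mask.tsv")
        _write_manifest(out, config,
                        {"alignment": _hash_alignment(aln),
                         "tree": hashlib.sha256(
                             tree.to_newick().encode()).hexdigest()},
                        {"alpha": alpha, "n_events": len(events)})
    return result


def _leaves_below(node):
    return [n.name for n in _iter(node) if n.is_leaf]


def _iter(node):
    yield node
    for c in node.children:
        yield from _iter(c)


def _hash_alignment(aln: Alignment) -> str:
    h = hashlib.sha256()
    for n, s in zip(aln.names, aln.seqs):
        h.update(n.encode())
        h.update(s.encode())
    return h.hexdigest()


def _write_manifest(out: Path, config: RunConfig, input_hashes: dict,
                    summary: dict) -> None:
    out.mkdir(parents=True, exist_ok=True)
    manifest = {
        "package_version": __version__,
        "config": {k: v for k, v in config.__dict__.items() if k != "extra"},
        "input_hashes": input_hashes,
        "summary": summary,
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True, default=str)
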