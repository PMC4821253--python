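"""RELL bootstrap over a topology set and orthology-probability aggregation.

RELL (resampling of estimated log-likelihoods) draws bootstrap replicates
by resampling site indices with replacement, sums the already-estimated
per-site log-likelihoods per topology, and awards each replicate to the
best-scoring topology; no re-optimization is performed.  Exact ties split
the replicate's mass equally among the tied topologies.  Summing the
resulting bootstrap probabilities over the topologies that support each
cyclostome-gnathostome orthology hypothesis yields the orthology
probabilities (the pie-chart quantities).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

from .io_formats import Alignment, filter_gap_columns
from .likelihood_engine import SiteLoglikMatrix, site_loglik_matrix
from .subst_model import RateModel, load_model
from .topology_space import (DuplicationConstraint, HypothesisMap, OtuScheme,
                             enumerate_constrained, expand_otus,
                             hypothesis_map)

_RELL_CHUNK = 1000


@dataclass(frozen=True)
class RellResult:
    topology_ids: tuple[str, ...]
    bp: np.ndarray
    replicates: int
    seed: int
    tie_events: int

    def to_tsv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("topology\tbp\n")
            for tid, p in zip(self.topology_ids, self.bp):
                fh.write(f"{tid}\t{p:.10g}\n")


@dataclass(frozen=True)
class OrthologyReport:
    """Per-hypothesis orthology probabilities (the pie-chart analogue)."""

    cyclostome_gene_name: str
    scheme: str
    prob: dict[str, float]
    supporting_sets: dict[str, tuple[str, ...]]
    bp_table: RellResult
    dual_counted: dict[str, str] = field(default_factory=dict)
    notes: str = ""

    def to_json(self, path=None) -> str:
        payload = {
            "cyclostome_gene": self.cyclostome_gene_name,
            "scheme": self.scheme,
            "probabilities": self.prob,
            "supporting_topologies": {k: list(v)
                                      for k, v in self.supporting_sets.items()},
            "bootstrap_probabilities": dict(zip(self.bp_table.topology_ids,
                                                self.bp_table.bp.tolist())),
            "replicates": self.bp_table.replicates,
            "seed": self.bp_table.seed,
            "tie_events": self.bp_table.tie_events,
            "dual_counted": self.dual_counted,
            "notes": self.notes,
        }
        text = json.dumps(payload, indent=2, sort_keys=True)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text + "\n")
        return text

    def argmax_hypothesis(self) -> str:
        return max(self.prob, key=lambda h: self.prob[h])


def rell_bootstrap(m: SiteLoglikMatrix, B: int = 10000,
                   seed: int = 0) -> RellResult:
    """RELL bootstrap probabilities from a site log-likelihood matrix."""
    if B < 1:
        raise ValueError("replicate count B must be >= 1")
    n_topo, n_sites = m.values.shape
    if n_topo < 1 or n_sites < 1:
        raise ValueError("need at least one topology and one site")
    rng = np.random.default_rng(seed)
    mass = np.zeros(n_topo)
    ties = 0
    p = np.full(n_sites, 1.0 / n_sites)
    done = 0
    while done < B:
        chunk = min(_RELL_CHUNK, B - done)
        counts = rng.multinomial(n_sites, p, size=chunk)
        scores = counts @ m.values.T  # (chunk, n_topo)
        best = scores.max(axis=1, keepdims=True)
        tied = scores == best
        n_tied = tied.sum(axis=1)
        mass += (tied / n_tied[:, None]).sum(axis=0)
        ties += int((n_tied > 1).sum())
        done += chunk
    return RellResult(m.topology_ids, mass / B, B, seed, ties)


def aggregate_orthology(r: RellResult, hmap: HypothesisMap,
                        cyclostome_gene_name: str = "") -> OrthologyReport:
    """Sum per-topology bootstrap probabilities into per-hypothesis
    orthology probabilities."""
    known = set(r.topology_ids)
    for h, ids in hmap.sets.items():
        missing = set(ids) - known
        if missing:
            raise ValueError(
                f"hypothesis {h!r} references unknown topology ids "
                f"{sorted(missing)}")
    bp = dict(zip(r.topology_ids, r.bp))
    prob = {h: float(sum(bp[t] for t in ids)) for h, ids in hmap.sets.items()}
    notes = ""
    if hmap.scheme == "four_subtype":
        dual_mass = {t: float(bp[t]) for t in hmap.dual_counted}
        notes = (
            "four-subtype mode: balanced topologies are dual-counted; each "
            "contributes its mass both to its cherry partner's sum and to "
            "the delta sum: " + json.dumps(dual_mass, sort_keys=True))
    return OrthologyReport(cyclostome_gene_name, hmap.scheme, prob,
                           dict(hmap.sets), r, dict(hmap.dual_counted), notes)


def run_orthology_assessment(aln: Alignment, otus: OtuScheme,
                             model: RateModel | None = None,
                             B: int = 10000, seed: int = 0,
                             scheme: str = "three_subtype",
                             max_gap_frac: float = 0.10,
                             gamma_policy: str = "shared-estimate",
                             k: int = 4, alpha: float | None = None,
                             tol: float = 1e-2, xatol: float = 2e-4,
                             out_dir=None) -> OrthologyReport:
    """End-to-end probabilistic orthology assessment for one cyclostome
    gene: gap filter -> constrained topology set -> OTU expansion ->
    per-topology branch-length (and gamma-shape) optimization -> RELL ->
    hypothesis aggregation.  Deterministic given ``seed``."""
    if scheme not in ("three_subtype", "four_subtype"):
        raise ValueError(f"unknown scheme {scheme!r}")
    model = model or load_model("LG")
    used = [n for names in otus.members.values() for n in names]
    missing = [n for n in used if n not in aln.names]
    if missing:
        raise ValueError(f"OTU members absent from alignment: {missing}")
    sub = aln.subset(used)
    filtered, mask = filter_gap_columns(sub, max_gap_frac)

    tset = enumerate_constrained(
        otus, DuplicationConstraint(
            assume_fourth_paralogue=(scheme == "four_subtype")))
    expanded = [(t.id, expand_otus(t, otus, aln=filtered)) for t in tset]
    matrix = site_loglik_matrix(expanded, filtered, model,
                                gamma_policy=gamma_policy, k=k, alpha=alpha,
                                tol=tol, xatol=xatol)
    rell = rell_bootstrap(matrix, B=B, seed=seed)
    hmap = hypothesis_map(tset,
                          assume_fourth_paralogue=(scheme == "four_subtype"))
    report = aggregate_orthology(rell, hmap,
                                 cyclostome_gene_name=otus.members["cyclostome"][0])
    if out_dir is not None:
        from pathlib import Path
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        tset.to_tsv(out / "topologies.tsv")
        tset.to_newick_file(out / "topologies.nwk")
        mask.to_tsv(out / "column_mask.tsv")
        matrix.to_tsv(out / "site_logliks.tsv")
        rell.to_tsv(out / "rell_bp.tsv")
        report.to_json(out / "orthology_report.json")
        with open(out / "pie.tsv", "w") as fh:
            fh.write("hypothesis\tprobability\n")
            for h, pr in sorted(report.prob.items()):
                fh.write(f"{h}\t{pr:.10g}\n")
    return report
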