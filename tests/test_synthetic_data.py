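import numpy as np
import pytest

from ohnoscope.io_formats import read_alignment, write_alignment
from ohnoscope.subst_model import discrete_gamma, transition_matrix
from ohnoscope.synthetic_data import (ScenarioSpec, build_scenario_tree,
                                      make_bundle, make_fig6_bundle,
                                      plant_pocket_events, simulate_alignment)
from ohnoscope.topology_space import contract_to_backbone, enumerate_constrained
from ohnoscope.tree import Tree

G1 = discrete_gamma(1.0, 1)


class TestScenarioSpec:
    def test_required_subtype_loss_rejected(self):
        with pytest.raises(ValueError, match="required"):
            ScenarioSpec(losses=("beta", "delta"))

    def test_orthologue_loss_rejected(self):
        with pytest.raises(ValueError, match="nowhere to attach"):
            ScenarioSpec(cyclostome_orthology="delta")

    def test_bad_pairing_rejected(self):
        with pytest.raises(ValueError, match="pairing"):
            ScenarioSpec(pairing=(("alpha", "beta"), ("alpha", "gamma")))


class TestBuildScenarioTree:
    def _backbone(self, spec):
        tree = build_scenario_tree(spec)
        b = make_bundle_scheme(tree)
        return contract_to_backbone(tree, b), tree

    def test_alpha_orthology_delta_lost_gives_balanced(self):
        spec = ScenarioSpec(pairing=(("alpha", "delta"), ("beta", "gamma")),
                            cyclostome_orthology="alpha", losses=("delta",))
        shape, _ = self._backbone(spec)
        # C cherries with A; with delta lost the backbone is balanced
        assert shape == "((A,C),(B,G))"

    def test_beta_orthology_has_beta_cherry(self):
        spec = ScenarioSpec(cyclostome_orthology="beta")
        shape, tree = self._backbone(spec)
        assert "(B,C)" in shape
        # and matches one of the nine constrained topologies
        templates = {t.newick_template for t in enumerate_constrained()}
        assert f"(O,{shape});" in templates

    def test_every_placement_is_2r_compatible(self):
        templates = {t.newick_template for t in enumerate_constrained()}
        for placement in ("alpha", "beta", "gamma"):
            for pairing in ((("alpha", "delta"), ("beta", "gamma")),
                            (("alpha", "beta"), ("gamma", "delta")),
                            (("alpha", "gamma"), ("beta", "delta"))):
                spec = ScenarioSpec(pairing=pairing,
                                    cyclostome_orthology=placement)
                shape, _ = self._backbone(spec)
                assert f"(O,{shape});" in templates

    def test_single_copy_mode_is_species_tree(self):
        spec = ScenarioSpec(single_copy=True, species_per_subtype=4)
        tree = build_scenario_tree(spec)
        names = tree.leaf_names()
        assert "outgroup" in names
        assert sum(1 for n in names if n.startswith("single_sp")) == 4
        assert not any(n.startswith(("alpha", "beta", "gamma"))
                       for n in names)


def make_bundle_scheme(tree):
    """OTU scheme for a scenario tree (helper mirroring TruthBundle)."""
    from ohnoscope.topology_space import OtuScheme
    names = tree.leaf_names()
    members = {"cyclostome": ("cyclostome_gene",), "outgroup": ("outgroup",)}
    for sub in ("alpha", "beta", "gamma"):
        members[sub] = tuple(n for n in names if n.startswith(sub + "_sp"))
    return OtuScheme(members=members)


class TestSimulateAlignment:
    def test_zero_lengths_copy_root(self, lg_model):
        tree = Tree.from_newick("((a:0,b:0)u:0,c:0)r;")
        aln, node_seqs = simulate_alignment(tree, lg_model, G1, 50, seed=1)
        for n in ("a", "b", "c"):
            assert aln.seq(n) == node_seqs["r"]

    def test_seed_reproducibility(self, lg_model):
        tree = Tree.from_newick("((a:0.1,b:0.2)u:0.1,c:0.3)r;")
        a1, _ = simulate_alignment(tree, lg_model, G1, 100, seed=9)
        a2, _ = simulate_alignment(tree, lg_model, G1, 100, seed=9)
        a3, _ = simulate_alignment(tree, lg_model, G1, 100, seed=10)
        assert a1 == a2
        assert a1 != a3

    def test_single_edge_substitution_frequencies(self, lg_model):
        tau, n = 0.3, 100_000
        tree = Tree.from_newick(f"(a:{tau})r;")
        aln, node_seqs = simulate_alignment(tree, lg_model, G1, n, seed=4)
        P = transition_matrix(lg_model, tau)
        root = node_seqs["r"]
        child = aln.seq("a")
        # conditional transition frequencies vs P rows, 3 MC standard errors
        for x in range(3):  # a few source residues suffice
            xs = [i for i, ch in enumerate(root)
                  if ch == lg_model.alphabet[x]]
            counts = np.zeros(20)
            for i in xs:
                counts[lg_model.state_index(child[i])] += 1
            n_x = len(xs)
            phat = counts / n_x
            se = np.sqrt(P[x] * (1 - P[x]) / n_x)
            assert np.all(np.abs(phat - P[x]) <= 3 * se + 1e-9)

    def test_bundle_passes_io_round_trip(self, tmp_path, lg_model):
        b = make_bundle(ScenarioSpec(n_columns=80, seed=5), model=lg_model)
        p = tmp_path / "a.fasta"
        write_alignment(b.alignment, p)
        assert read_alignment(p) == b.alignment


class TestPlantPocketEvents:
    def test_no_events_leaves_root_state_everywhere(self, lg_model):
        tree = Tree.from_newick("((a:0.1,b:0.2)u:0.1,c:0.3)r;")
        aln, node_seqs = simulate_alignment(tree, lg_model, G1, 20, seed=0)
        new_aln, _, triplets, _ = plant_pocket_events(
            aln, node_seqs, tree, [], {232: 5, 270: 10, 395: 15},
            {232: "S", 270: "I", 395: "V"})
        for n in new_aln.names:
            s = new_aln.seq(n)
            assert (s[4], s[9], s[14]) == ("S", "I", "V")
        assert all(t == ("S", "I", "V") for t in triplets.values())

    def test_conflicting_duplicate_events_rejected(self, lg_model):
        tree = Tree.from_newick("((a:0.1,b:0.2)u:0.1,c:0.3)r;")
        aln, node_seqs = simulate_alignment(tree, lg_model, G1, 20, seed=0)
        with pytest.raises(ValueError, match="conflicting duplicate"):
            plant_pocket_events(aln, node_seqs, tree,
                                [("u", 232, "S", "A"), ("u", 232, "S", "C")],
                                {232: 5}, {232: "S"})

    def test_event_from_state_must_match_lineage(self, lg_model):
        tree = Tree.from_newick("((a:0.1,b:0.2)u:0.1,c:0.3)r;")
        aln, node_seqs = simulate_alignment(tree, lg_model, G1, 20, seed=0)
        with pytest.raises(ValueError, match="carries"):
            plant_pocket_events(aln, node_seqs, tree,
                                [("u", 232, "A", "S")], {232: 5}, {232: "S"})

    def test_unknown_branch_rejected(self, lg_model):
        tree = Tree.from_newick("((a:0.1,b:0.2)u:0.1,c:0.3)r;")
        aln, node_seqs = simulate_alignment(tree, lg_model, G1, 20, seed=0)
        with pytest.raises(ValueError, match="not in tree"):
            plant_pocket_events(aln, node_seqs, tree,
                                [("zz", 232, "S", "A")], {232: 5}, {232: "S"})


class TestFig6Bundle:
    def test_extant_leaf_pattern_matches_scenario(self, fig6_bundle):
        tri = fig6_bundle.node_triplets
        for n in ("EbRAR1", "LjRAR1", "EbRAR3", "LjRAR3",
                  "ScRARa", "LoRARa", "HsRARa"):
            assert tri[n] == ("S", "I", "V")
        for n in ("EbRAR2", "LjRAR2", "ScRARb", "HsRARb"):
            assert tri[n] == ("A", "I", "V")
        for n in ("GgRARg", "HsRARg", "ScRARg"):  # mammal/bird/chondrichthyan
            assert tri[n] == ("A", "M", "A")
        for n in ("LoRARg", "DrRARg", "XtRARg"):  # actinopterygian + frog
            assert tri[n] == ("S", "M", "A")

    def test_alignment_columns_carry_the_triplets(self, fig6_bundle):
        for name in fig6_bundle.alignment.names:
            seq = fig6_bundle.alignment.seq(name)
            tri = fig6_bundle.node_triplets[name]
            assert (seq[231], seq[269], seq[394]) == tri

    def test_deterministic_given_seed(self):
        b1 = make_fig6_bundle(seed=3, n_columns=400)
        b2 = make_fig6_bundle(seed=3, n_columns=400)
        assert b1.alignment == b2.alignment
        assert b1.tree.to_newick() == b2.tree.to_newick()

    def test_write_bundle(self, tmp_path, fig6_bundle):
        fig6_bundle.write(tmp_path)
        assert (tmp_path / "alignment.fasta").exists()
        assert (tmp_path / "true_tree.nwk").exists()
        assert (tmp_path / "truth.json").exists()
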