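"""Generator and scenario-simulator contracts."""

import dataclasses

import numpy as np
import pytest

from cytc6 import (
    C6,
    C6A,
    C6B,
    GeneratorConfig,
    ScenarioConfig,
    SequenceGenerator,
    assign_class,
    detect_lip,
    extract_features,
    find_haem_motif,
    global_align,
    simulate_scenario,
    trim_signal_peptide,
)
from cytc6.classify import LipSpec
from cytc6.synthetic_data import GeneratorConfigError


class TestGenerator:
    def test_same_seed_same_bytes(self):
        a = SequenceGenerator(GeneratorConfig(seed=9))
        b = SequenceGenerator(GeneratorConfig(seed=9))
        for label in (C6, C6A, C6B):
            ra, ta = a.generate(label, "same")
            rb, tb = b.generate(label, "same")
            assert ra == rb and ta == tb

    def test_different_seed_differs(self):
        a = SequenceGenerator(GeneratorConfig(seed=9))
        b = SequenceGenerator(GeneratorConfig(seed=10))
        assert a.generate(C6, "x")[0].residues != b.generate(C6, "x")[0].residues

    def test_generation_independent_of_order(self):
        g1 = SequenceGenerator(GeneratorConfig(seed=4))
        g2 = SequenceGenerator(GeneratorConfig(seed=4))
        first = g1.generate(C6A, "idA")
        _ = g2.generate(C6B, "idB")
        assert g2.generate(C6A, "idA") == first

    def test_exactly_one_in_window_motif(self, clean_generator):
        for i in range(60):
            rec, truth = clean_generator.generate((C6, C6A, C6B)[i % 3], f"m{i}")
            mature = rec.residues[truth.signal_len:]
            scan = find_haem_motif(mature)
            assert scan.position == truth.motif_position

    def test_planted_lip_audit_zero_noise(self, clean_generator):
        g = clean_generator
        for i in range(30):
            rec, truth = g.generate(C6A, f"a{i}")
            mature = rec.residues[truth.signal_len:]
            aln = global_align(mature, g.reference_profile.c6.residues)
            hit, _ = detect_lip(aln, LipSpec(), g.reference_profile.loop_window)
            assert hit is not None
            assert (hit.query_start, hit.query_end) == (truth.lip_start, truth.lip_end)
            assert hit.cys_count == 2

    def test_closed_loop_zero_noise(self, clean_generator, refs):
        for i, label in enumerate((C6, C6A, C6B) * 10):
            rec, _ = clean_generator.generate(label, f"cl{i}")
            matured = trim_signal_peptide(rec, refs)
            assert assign_class(extract_features(matured, refs)).label == label

    def test_adversarial_noise_can_break_features(self):
        g = SequenceGenerator(
            GeneratorConfig(seed=2, substitution_noise=0.3, adversarial=True)
        )
        refs = g.reference_profile
        labels = []
        for i in range(40):
            rec, _ = g.generate(C6, f"adv{i}")
            matured = trim_signal_peptide(rec, refs)
            labels.append(assign_class(extract_features(matured, refs)).label)
        assert "UNCLASSIFIED" in labels

    def test_impossible_config_rejected(self):
        with pytest.raises(GeneratorConfigError):
            GeneratorConfig(motif_position_range=(40, 60))
        with pytest.raises(GeneratorConfigError):
            GeneratorConfig(mature_len_range=(30, 40))
        with pytest.raises(GeneratorConfigError):
            SequenceGenerator(GeneratorConfig()).generate("C6X", "bad")


class TestScenario:
    def test_no_events_limit(self):
        sc = simulate_scenario(
            ScenarioConfig(seed=1, n_taxa=8, loss_prob=0.0, insertion=None)
        )
        for taxon, state in sc.leaf_states.items():
            assert state[C6] == "present"
            assert state["family"] == C6B
        assert [e.event for e in sc.events] == ["gain", "gain"]

    def test_explicit_loss_branch_forces_absence(self):
        base = simulate_scenario(
            ScenarioConfig(seed=5, n_taxa=8, loss_prob=0.0, insertion=None)
        )
        # pick an internal branch and delete C6 below it
        internal = next(
            n for n in base.tree.preorder_node_iter()
            if n.parent_node is not None and not n.is_leaf()
        )
        from cytc6.distribution import node_name

        branch = node_name(internal)
        below = {l.taxon.label for l in internal.leaf_iter()}
        sc = simulate_scenario(
            ScenarioConfig(
                seed=5, n_taxa=8, loss_prob=0.0, insertion=None,
                loss_branches={C6: (branch,)},
            )
        )
        for taxon, state in sc.leaf_states.items():
            assert (state[C6] == "none") == (taxon in below)

    def test_insertion_converts_subtree(self):
        sc = simulate_scenario(ScenarioConfig(seed=7, n_taxa=12, loss_prob=0.0))
        names = {sc.insertion_branch}
        from cytc6.distribution import node_name

        node = next(
            n for n in sc.tree.preorder_node_iter() if node_name(n) in names
        )
        below = {l.taxon.label for l in node.leaf_iter()}
        for taxon, state in sc.leaf_states.items():
            assert state["family"] == (C6A if taxon in below else C6B)

    def test_reproducible_and_seed_sensitive(self):
        a = simulate_scenario(ScenarioConfig(seed=3, n_taxa=10))
        b = simulate_scenario(ScenarioConfig(seed=3, n_taxa=10))
        c = simulate_scenario(ScenarioConfig(seed=4, n_taxa=10))
        assert a.newick == b.newick and a.events == b.events
        assert [r.residues for r in a.sequences] == [r.residues for r in b.sequences]
        assert a.newick != c.newick or a.events != c.events

    def test_loss_frequency_binomial(self):
        # per-branch loss draws follow the configured probability
        p = 0.1
        losses = 0
        opportunities = 0
        for rep in range(250):
            sc = simulate_scenario(
                ScenarioConfig(seed=rep, n_taxa=12, loss_prob=p,
                               insertion=None, root_genes=(C6,))
            )
            n_branches = sum(
                1 for n in sc.tree.preorder_node_iter() if n.parent_node is not None
            )
            # C6 can only be lost once per root-to-leaf path; count only
            # branches where the gene was still present at the parent
            from cytc6.distribution import node_name

            lost_on = {e.branch for e in sc.events if e.event == "loss"}
            still = {id(sc.tree.seed_node): True}
            for node in sc.tree.preorder_node_iter():
                if node.parent_node is None:
                    continue
                parent_alive = still[id(node.parent_node)]
                alive = parent_alive and node_name(node) not in lost_on
                still[id(node)] = alive
                if parent_alive:
                    opportunities += 1
                    losses += node_name(node) in lost_on
        freq = losses / opportunities
        se = (p * (1 - p) / opportunities) ** 0.5
        assert abs(freq - p) < 3 * se

    def test_presence_matrix_matches_leaf_states(self):
        sc = simulate_scenario(ScenarioConfig(seed=11, n_taxa=10, loss_prob=0.2))
        for taxon, state in sc.leaf_states.items():
            assert sc.presence.loc[taxon, C6] == int(state[C6] == "present")
            fam = state["family"]
            assert sc.presence.loc[taxon, C6A] == int(fam == C6A)
            assert sc.presence.loc[taxon, C6B] == int(fam == C6B)

    def test_invalid_configs_rejected(self):
        with pytest.raises(GeneratorConfigError):
            ScenarioConfig(loss_prob=1.5)
        with pytest.raises(GeneratorConfigError):
            ScenarioConfig(root_genes=(C6A,))
        with pytest.raises(GeneratorConfigError):
            simulate_scenario(ScenarioConfig(insertion="NOPE"))
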