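"""Newick parsing and neutral-simulation behaviour."""

import numpy as np
import pytest
from scipy.stats import chi2_contingency

from dyadsel import evolve_once, parse_newick, simulate_replicates, transition_matrix
from dyadsel.treesim import NewickError, SequenceSet, degap, encode_sequence


class TestParseNewick:
    def test_minimal_two_leaf_tree(self):
        tree = parse_newick("(A:0.1,B:0.2):0;")
        assert tree.n_leaves == 2
        assert set(tree.leaf_names) == {"A", "B"}
        # root has two children
        assert (tree.parent == 0).sum() == 2

    def test_internal_node_and_branch_lengths(self):
        tree = parse_newick("(A:0.1,(B:0.2,C:0.3):0.05);")
        assert tree.n_leaves == 3
        internal = [i for i in range(tree.n_nodes)
                    if not tree.is_leaf[i] and tree.parent[i] >= 0]
        assert len(internal) == 1
        assert tree.branch_lengths[internal[0]] == pytest.approx(0.05)

    def test_negative_branch_length_rejected(self):
        with pytest.raises(NewickError, match="negative branch"):
            parse_newick("(A:0.1,B:-0.2);")

    def test_malformed_input_rejected(self):
        with pytest.raises(NewickError):
            parse_newick("(A:0.1,B:0.2")

    def test_polytomy_preserved(self):
        tree = parse_newick("(A:0.1,B:0.1,C:0.1,D:0.1);")
        assert tree.n_leaves == 4
        assert (tree.parent == 0).sum() == 4

    def test_newick_round_trip(self):
        text = "(A:0.1,(B:0.2,C:0.3):0.05);"
        tree = parse_newick(text)
        again = parse_newick(tree.to_newick())
        assert again.leaf_names == tree.leaf_names
        np.testing.assert_allclose(again.branch_lengths, tree.branch_lengths)

    def test_branch_scaling(self):
        tree = parse_newick("(A:0.1,B:0.2);").scaled(10.0)
        assert tree.branch_lengths[1:].sum() == pytest.approx(3.0)


class TestSequenceSet:
    def test_duplicate_labels_rejected(self):
        with pytest.raises(ValueError, match="unique"):
            SequenceSet.from_records([("A", "HD"), ("A", "HD")])

    def test_unequal_lengths_rejected(self):
        with pytest.raises(ValueError, match="equal length"):
            SequenceSet.from_records([("A", "HD"), ("B", "HDA")])

    def test_fasta_round_trip(self, tmp_path):
        s = SequenceSet.from_records([("A", "HDAC"), ("B", "WYKL")])
        path = tmp_path / "s.fasta"
        s.to_fasta(path)
        assert SequenceSet.from_fasta(path) == s

    def test_gap_in_sequence_reports_position(self):
        with pytest.raises(ValueError, match="gap character.*position 2"):
            encode_sequence("HD-A")

    def test_degap_is_explicit(self):
        assert degap("H-D.A") == "HDA"


class TestEvolveOnce:
    def test_zero_length_edge_copies_root(self, model, rng):
        tree = parse_newick("(A:0.0);")
        out = evolve_once(tree, "HDWYKL", model, rng)
        assert out.records == [("A", "HDWYKL")]

    def test_same_seed_same_output(self, model, cherry):
        a = evolve_once(cherry, "HDWYKL" * 5, model, np.random.default_rng(7))
        b = evolve_once(cherry, "HDWYKL" * 5, model, np.random.default_rng(7))
        assert a == b

    def test_long_branch_leaves_sample_stationary(self, model):
        # star tree, branch 100: leaf residues should be i.i.d. from pi
        tree = parse_newick("(A:100,B:100,C:100,D:100);")
        root = "A" * 100_000
        out = evolve_once(tree, root, model, np.random.default_rng(11))
        freqs = np.bincount(out.idx.ravel(), minlength=20) / out.idx.size
        assert np.max(np.abs(freqs - model.pi)) < 0.01

    def test_single_edge_transition_frequencies(self, model):
        # 10^5-site root drawn from pi; child frequencies per parent residue
        # must match the rows of P(t) within binomial noise.
        t = 0.4
        tree = parse_newick(f"(A:{t});")
        rng = np.random.default_rng(5)
        root_idx = rng.choice(20, size=100_000, p=model.pi)
        root = model.decode(root_idx)
        out = evolve_once(tree, root, model, np.random.default_rng(17))
        child = out.idx[0]
        p = transition_matrix(model, t).p
        z_over_3 = 0
        for k in range(20):
            sel = child[root_idx == k]
            n = sel.size
            obs = np.bincount(sel, minlength=20) / n
            sd = np.sqrt(p[k] * (1 - p[k]) / n)
            z = np.abs(obs - p[k]) / np.where(sd > 0, sd, 1.0)
            z_over_3 += int((z > 3).sum())
            assert np.max(z) < 5
        # ~1 of the 400 cells is expected beyond 3 SD by chance alone
        assert z_over_3 <= 5

    def test_branch_length_additivity(self, model):
        # two consecutive edges t1, t2 vs one edge t1+t2: leaf residue
        # distributions are statistically indistinguishable.
        root = "L" * 30_000
        two = parse_newick("((A:0.4):0.3);")
        one = parse_newick("(A:0.7);")
        leaves_two = evolve_once(two, root, model, np.random.default_rng(3)).idx[0]
        leaves_one = evolve_once(one, root, model, np.random.default_rng(4)).idx[0]
        table = np.vstack([
            np.bincount(leaves_two, minlength=20),
            np.bincount(leaves_one, minlength=20),
        ])
        _, pval, _, _ = chi2_contingency(table)
        assert pval > 0.01

    def test_nonstandard_root_residue_rejected(self, model, cherry, rng):
        with pytest.raises(ValueError, match="position 1"):
            evolve_once(cherry, "HXD", model, rng)


class TestSimulateReplicates:
    def test_reproducible_from_seed(self, model, cherry):
        a = list(simulate_replicates(cherry, "HDWYKL", model, 3, seed=9))
        b = list(simulate_replicates(cherry, "HDWYKL", model, 3, seed=9))
        assert a == b

    def test_replicates_individually_reproducible(self, model, cherry):
        full = list(simulate_replicates(cherry, "HDWYKL", model, 5, seed=9))
        # regenerating only replicate 3 gives the same sequences
        from dyadsel.treesim import _evolve_indices, encode_sequence, replicate_rng

        leaves = _evolve_indices(cherry, encode_sequence("HDWYKL"), model, replicate_rng(9, 3))
        assert np.array_equal(leaves, full[3].idx)

    def test_shape_conserved_across_replicates(self, model, domain41):
        tree, root = domain41
        for rep in simulate_replicates(tree, root, model, 5, seed=1):
            assert rep.n_sequences == 41
            assert rep.length == 70

    def test_zero_replicates_rejected(self, model, cherry):
        with pytest.raises(ValueError):
            simulate_replicates(cherry, "HDWYKL", model, 0, seed=1)
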