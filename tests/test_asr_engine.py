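import numpy as np
import pytest
from Bio.Seq import Seq

from codonasr import (
    Alignment,
    SequenceRecord,
    call_variants,
    combine_codon,
    indel_asr,
    map_reference_positions,
    marginal_asr,
    residue_posteriors,
    simulate_evolution,
    simulate_tree,
)
from codonasr.asr_engine import (
    AA_STATES,
    CODONS,
    CodonPosteriorTable,
    PosteriorTable,
    recode_binary,
)
from codonasr.bruteforce import brute_force_marginals
from codonasr.io_formats import PROTEIN, Tree, parse_newick
from conftest import random_alignment


def star_tree(labels, length):
    n = len(labels)
    parent = np.array([n] * n + [-1])
    lengths = np.array([length] * n + [0.0])
    return Tree(parent=parent, lengths=lengths, names=list(labels) + [None])


class TestMarginalAsr:
    def test_near_zero_branches_give_certain_root(self, jc69):
        tree = star_tree(["a", "b", "c"], 1e-6)
        aln = Alignment([SequenceRecord(x, "A") for x in "abc"])
        post = marginal_asr(tree, aln, jc69)
        assert post.node(post.node_ids[0])[0, 0] > 0.9999

    def test_symmetric_star_minimises_unobserved_state(self, jc69):
        tree = star_tree(["a", "b", "c"], 0.3)
        aln = Alignment(
            [SequenceRecord("a", "A"), SequenceRecord("b", "C"), SequenceRecord("c", "G")]
        )
        post = marginal_asr(tree, aln, jc69)
        row = post.probs[0, 0]
        t_index = jc69.states.index("T")
        assert np.all(row[t_index] < np.delete(row, t_index))

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_enumeration_oracle(self, seed, hky):
        rng = np.random.default_rng(seed)
        tree = simulate_tree(int(rng.integers(3, 6)), 0.2, seed=seed + 100)
        aln = random_alignment(rng, tree.leaf_names(), 20, gap_frac=0.1)
        post = marginal_asr(tree, aln, hky)
        oracle, _ = brute_force_marginals(tree, aln, hky)
        assert post.node_ids == oracle.node_ids
        np.testing.assert_allclose(post.probs, oracle.probs, atol=1e-10)

    def test_rows_normalised(self, small_simulation, hky):
        tree, aln, _ = small_simulation
        post = marginal_asr(tree, aln, hky)
        np.testing.assert_allclose(post.probs.sum(axis=2), 1.0, atol=1e-9)

    def test_outgroup_rooting_changes_reported_nodes(self, hky):
        tree = parse_newick("((a:0.1,b:0.1):0.1,(c:0.1,d:0.1):0.1);")
        rng = np.random.default_rng(7)
        aln = random_alignment(rng, list("abcd"), 12)
        post = marginal_asr(tree, aln, hky, outgroup="a")
        assert len(post.node_ids) == 3


class TestIndelAsr:
    def test_recoding_convention(self):
        aln = Alignment([SequenceRecord("a", "AC-"), SequenceRecord("b", "---")])
        binary = recode_binary(aln)
        assert binary["a"].seq == "001"
        assert binary["b"].seq == "111"

    def test_all_present_column_reconstructs_present(self, jc2):
        tree = parse_newick("((a:0.05,b:0.05):0.05,(c:0.05,d:0.05):0.05);")
        aln = Alignment([SequenceRecord(x, "AAA") for x in "abcd"])
        post = indel_asr(tree, aln, jc2)
        present = post.states.index("0")
        assert np.all(post.probs[:, :, present] > 0.99)

    def test_two_leaf_disagreement_is_symmetric(self, jc2):
        tree = parse_newick("(a:0.2,b:0.2);")
        aln = Alignment([SequenceRecord("a", "A"), SequenceRecord("b", "-")])
        post = indel_asr(tree, aln, jc2)
        np.testing.assert_allclose(post.probs[0, 0], [0.5, 0.5], atol=1e-12)

    def test_matches_enumeration_oracle(self, jc2):
        rng = np.random.default_rng(11)
        tree = simulate_tree(5, 0.3, seed=21)
        aln = random_alignment(rng, tree.leaf_names(), 20, alphabet_chars="ACGT",
                               gap_frac=0.3)
        post = indel_asr(tree, aln, jc2)
        oracle, _ = brute_force_marginals(tree, recode_binary(aln), jc2)
        np.testing.assert_allclose(post.probs, oracle.probs, atol=1e-10)

    def test_branch_lengths_used_as_given(self, jc2, small_simulation):
        tree, aln, _ = small_simulation
        before = tree.lengths.copy()
        indel_asr(tree, aln, jc2)
        np.testing.assert_array_equal(tree.lengths, before)


def nucleotide_table(node_probs):
    """Build a 1-node nucleotide PosteriorTable from per-site dicts."""
    states = ("A", "C", "G", "T")
    probs = np.zeros((1, len(node_probs), 4))
    for s, d in enumerate(node_probs):
        for nt, p in d.items():
            probs[0, s, states.index(nt)] = p
    return PosteriorTable(node_ids=["node1"], states=states, probs=probs)


def indel_table(gap_probs):
    probs = np.zeros((1, len(gap_probs), 2))
    probs[0, :, 1] = gap_probs
    probs[0, :, 0] = 1 - np.asarray(gap_probs)
    return PosteriorTable(node_ids=["node1"], states=("0", "1"), probs=probs)


class TestCombineCodon:
    def test_codon_probability_is_nucleotide_product(self):
        nuc = nucleotide_table([{"A": 0.9, "C": 0.1}, {"C": 0.8, "A": 0.2}, {"G": 1.0}])
        ind = indel_table([0.0, 0.0, 0.0])
        codons = combine_codon(nuc, ind)
        assert codons.raw[0, 0, CODONS.index("ACG")] == pytest.approx(0.72)

    def test_certain_nucleotides_give_single_codon(self):
        nuc = nucleotide_table([{"A": 1.0}, {"T": 1.0}, {"G": 1.0}])
        ind = indel_table([0.0, 0.0, 0.0])
        codons = combine_codon(nuc, ind)
        assert codons.norm[0, 0, CODONS.index("ATG")] == pytest.approx(1.0)
        assert codons.raw[0, 0].sum() == pytest.approx(1.0)

    def test_gap_posterior_supersedes_codon_states(self):
        nuc = nucleotide_table([{"A": 1.0}, {"T": 1.0}, {"G": 1.0}])
        ind = indel_table([1.0, 1.0, 1.0])
        codons = combine_codon(nuc, ind)
        assert codons.gap_called[0, 0]
        residues, _ = residue_posteriors(codons)
        gap_idx = residues.states.index("-")
        assert residues.probs[0, 0, gap_idx] == pytest.approx(1.0)

    def test_frame_mismatch_raises(self):
        nuc = nucleotide_table([{"A": 1.0}, {"T": 1.0}])
        ind = indel_table([0.0, 0.0])
        with pytest.raises(ValueError, match="divisible by 3"):
            combine_codon(nuc, ind)


class TestResiduePosteriors:
    def make_codon_table(self, codon_probs):
        raw = np.zeros((1, 1, 64))
        for codon, p in codon_probs.items():
            raw[0, 0, CODONS.index(codon)] = p
        norm = raw / raw.sum()
        return CodonPosteriorTable(
            node_ids=["node1"],
            raw=raw,
            norm=norm,
            gap_prob=np.zeros((1, 1)),
            gap_called=np.zeros((1, 1), dtype=bool),
        )

    def test_synonymous_codons_summed(self):
        table = self.make_codon_table({"AAA": 0.30, "AAG": 0.25, "GGG": 0.45})
        residues, _ = residue_posteriors(table)
        assert residues.probs[0, 0, AA_STATES.index("K")] == pytest.approx(0.55)

    def test_certain_codon(self):
        table = self.make_codon_table({"ATG": 1.0})
        residues, _ = residue_posteriors(table)
        assert residues.probs[0, 0, AA_STATES.index("M")] == pytest.approx(1.0)

    def test_stop_mass_reported_separately(self):
        table = self.make_codon_table({"TAA": 0.4, "ATG": 0.6})
        residues, stop = residue_posteriors(table)
        assert stop[0, 0] == pytest.approx(0.4)
        assert residues.probs[0, 0].sum() == pytest.approx(0.6)

    def test_probability_conservation_on_random_tables(self):
        rng = np.random.default_rng(12)
        raw = rng.dirichlet(np.ones(64), size=(3, 7))
        table = CodonPosteriorTable(
            node_ids=["n1", "n2", "n3"],
            raw=raw,
            norm=raw,
            gap_prob=np.zeros((3, 7)),
            gap_called=np.zeros((3, 7), dtype=bool),
        )
        residues, stop = residue_posteriors(table)
        np.testing.assert_allclose(residues.probs.sum(axis=2) + stop, 1.0, atol=1e-9)


def residue_table(site_dicts, node="node1"):
    probs = np.zeros((1, len(site_dicts), len(AA_STATES)))
    for s, d in enumerate(site_dicts):
        for aa, p in d.items():
            probs[0, s, AA_STATES.index(aa)] = p
    return PosteriorTable(node_ids=[node], states=AA_STATES, probs=probs)


class TestCallVariants:
    def test_single_ambiguous_position_gives_two_ordered_variants(self):
        table = residue_table([{"E": 1.0}, {"N": 0.45, "D": 0.55}, {"K": 1.0}])
        vset = call_variants(table, "node1", positions=[1, 2, 3], threshold=0.3)
        assert len(vset.variants) == 2
        assert vset.variants[0].residues == "EDK"  # higher joint probability first
        assert vset.variants[1].residues == "ENK"
        assert vset.variants[0].label == "anc1.1"
        assert vset.variants[0].joint_probability == pytest.approx(0.55)

    def test_unambiguous_positions_give_single_variant(self):
        table = residue_table([{"E": 0.96, "K": 0.04}, {"M": 1.0}])
        vset = call_variants(table, "node1", positions=[1, 2])
        assert len(vset.variants) == 1
        assert vset.variants[0].residues == "EM"

    def test_cartesian_product_ordering(self):
        table = residue_table(
            [{"A": 0.6, "C": 0.4}, {"G": 0.7, "W": 0.31}]
        )
        vset = call_variants(table, "node1", positions=[1, 2])
        assert [v.residues for v in vset.variants] == ["AG", "CG", "AW", "CW"]
        joints = [v.joint_probability for v in vset.variants]
        assert joints == sorted(joints, reverse=True)

    def test_count_is_product_of_candidates(self):
        table = residue_table(
            [{"A": 0.5, "C": 0.5}, {"G": 0.4, "W": 0.35}, {"K": 0.34, "R": 0.33, "E": 0.32}]
        )
        vset = call_variants(table, "node1", positions=[1, 2, 3], max_variants=100)
        assert len(vset.variants) == 2 * 2 * 3

    def test_truncation_at_max_variants(self):
        table = residue_table([{"A": 0.5, "C": 0.5}] * 5)
        vset = call_variants(table, "node1", positions=[1, 2, 3, 4, 5], max_variants=16)
        assert len(vset.variants) == 16

    def test_map_fallback_when_nothing_clears_threshold(self, caplog):
        table = residue_table([{"A": 0.2, "C": 0.2, "G": 0.2, "W": 0.2, "K": 0.2}])
        with caplog.at_level("WARNING"):
            vset = call_variants(table, "node1", positions=[1], threshold=0.3)
        assert len(vset.variants) == 1
        assert "MAP" in caplog.text

    def test_empty_positions_rejected(self):
        table = residue_table([{"A": 1.0}])
        with pytest.raises(ValueError, match="empty"):
            call_variants(table, "node1", positions=[])


class TestReferenceMapping:
    def test_examples(self):
        aln = Alignment(
            [
                SequenceRecord("ref", "M-AC", alphabet=PROTEIN),
                SequenceRecord("x", "MMAC", alphabet=PROTEIN),
            ],
            alphabet=PROTEIN,
        )
        assert map_reference_positions(aln, "ref", [1]) == [1]
        assert map_reference_positions(aln, "ref", [2]) == [3]

    def test_out_of_range(self):
        aln = Alignment([SequenceRecord("ref", "MAC", alphabet=PROTEIN)], alphabet=PROTEIN)
        with pytest.raises(IndexError):
            map_reference_positions(aln, "ref", [5])

    def test_missing_reference(self):
        aln = Alignment([SequenceRecord("ref", "MAC", alphabet=PROTEIN)], alphabet=PROTEIN)
        with pytest.raises(KeyError):
            map_reference_positions(aln, "other", [1])


class TestEndToEndRecovery:
    def test_root_reconstruction_recovers_truth_on_short_branches(self, small_simulation):
        tree, aln, truth = small_simulation
        from codonasr import default_nucleotide_model

        model = default_nucleotide_model()
        nuc = marginal_asr(tree, aln, model)
        ind = indel_asr(tree, aln)
        codons = combine_codon(nuc, ind)
        residues, _ = residue_posteriors(codons)
        root = truth.root_name()
        true_seq = truth.sequences[root]
        true_res = [
            str(Seq(true_seq[i : i + 3]).translate()) if "-" not in true_seq[i : i + 3] else "-"
            for i in range(0, len(true_seq), 3)
        ]
        map_res = residues.map_states(root)
        accuracy = np.mean([a == b for a, b in zip(map_res, true_res)])
        assert accuracy >= 0.85  # smaller dataset than the regression fixture
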