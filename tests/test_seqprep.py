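import numpy as np
import pytest

from codonasr import (
    Alignment,
    SequenceRecord,
    deduplicate,
    filter_cds,
    simulate_evolution,
    simulate_tree,
    thread_codons,
    translate_cds,
    trim_gappy_columns,
)
from codonasr.io_formats import GAP, PROTEIN
from codonasr.seqprep import (
    REASON_INTERNAL_STOP,
    REASON_LENGTH,
    REASON_NOT_MULTIPLE_OF_THREE,
    CodonAlignment,
    SequencePatch,
    apply_patches,
)


def rec(name, seq):
    return SequenceRecord(id=name, seq=seq)


# A 12-record fixture with every violation class; length window 6..12 nt
# applied to the stop-stripped sequence.
CDS_FIXTURE = [
    rec("ok1", "ATGGCAGGT"),                 # clean, in range
    rec("ok2", "ATGGCAGGTTGA"),              # terminal stop stripped -> 9, kept
    rec("int_stop", "ATGTAAGGGTGA"),         # internal TAA at codon 2
    rec("frame", "ATGGCAG"),                 # 7 nt, not a multiple of 3
    rec("short", "ATG"),                     # 3 nt < 6 after no strip
    rec("short_after_strip", "ATGTAA"),      # strips to 3 nt < 6
    rec("long", "ATGGCAGGTGCAGCA"),          # 15 nt > 12
    rec("ok3", "ATGAATTGGGCC"),              # 12 nt, kept at the upper bound
    rec("int_stop2", "TGATGATGATGA"),        # TGA codons throughout
    rec("frame2", "ATGGCAGG"),               # 8 nt
    rec("ok4", "ATGNNNGGT"),                 # ambiguous codon is fine
    rec("ok5", "ATGGCAGGATAG"),              # terminal TAG stripped -> 9, kept
]

EXPECTED_KEPT = ["ok1", "ok2", "ok3", "ok4", "ok5"]
EXPECTED_REJECTED = {
    "int_stop": REASON_INTERNAL_STOP,
    "int_stop2": REASON_INTERNAL_STOP,
    "frame": REASON_NOT_MULTIPLE_OF_THREE,
    "frame2": REASON_NOT_MULTIPLE_OF_THREE,
    "short": REASON_LENGTH,
    "short_after_strip": REASON_LENGTH,
    "long": REASON_LENGTH,
}


class TestFilterCds:
    def test_fixture_partition_is_exact(self):
        kept, report = filter_cds(CDS_FIXTURE, min_len=6, max_len=12)
        assert report.kept == EXPECTED_KEPT
        assert dict(report.rejected) == EXPECTED_REJECTED
        assert set(report.trimmed_terminal_stop) == {"ok2", "ok5", "short_after_strip"}

    def test_every_input_id_accounted_for(self):
        kept, report = filter_cds(CDS_FIXTURE, min_len=6, max_len=12)
        accounted = set(report.kept) | {i for i, _ in report.rejected}
        assert accounted == {r.id for r in CDS_FIXTURE}

    def test_terminal_stop_stripped_from_kept_sequences(self):
        kept, _ = filter_cds(CDS_FIXTURE, min_len=6, max_len=12)
        by_id = {r.id: r.seq for r in kept}
        assert by_id["ok2"] == "ATGGCAGGT"
        assert by_id["ok5"] == "ATGGCAGGA"

    def test_internal_stop_detected_mid_sequence(self):
        _, report = filter_cds([rec("x", "ATGTAAGGGTGA")], min_len=1, max_len=100)
        assert report.rejected == [("x", REASON_INTERNAL_STOP)]

    def test_boundary_lengths_inclusive(self):
        # 2400 exactly is kept; 2399 after stop-stripping is not
        ok = rec("edge", "ATG" * 800)
        _, report = filter_cds([ok], min_len=2400, max_len=2800)
        assert report.kept == ["edge"]
        near = rec("below", "ATG" * 799 + "TGA")  # strips to 2397
        _, report = filter_cds([near], min_len=2400, max_len=2800)
        assert report.rejected == [("below", REASON_LENGTH)]

    def test_idempotent(self):
        kept1, _ = filter_cds(CDS_FIXTURE, min_len=6, max_len=12)
        kept2, report2 = filter_cds(kept1, min_len=6, max_len=12)
        assert [r.seq for r in kept2] == [r.seq for r in kept1]
        assert not report2.rejected and not report2.trimmed_terminal_stop


class TestTranslate:
    @pytest.mark.parametrize(
        "cds,expected", [("ATGGCA", "MA"), ("ATGNNN", "MX"), ("ATGGCATGA", "MA")]
    )
    def test_standard_code(self, cds, expected):
        assert translate_cds(rec("x", cds)).seq == expected

    def test_internal_stop_raises(self):
        with pytest.raises(ValueError, match="internal stop"):
            translate_cds(rec("x", "ATGTAAGCA"))

    def test_frame_violation_raises(self):
        with pytest.raises(ValueError, match="multiple of 3"):
            translate_cds(rec("x", "ATGG"))


class TestThreading:
    def test_gap_becomes_triple_gap(self):
        prot = Alignment([SequenceRecord("x", "M-A", alphabet=PROTEIN)], alphabet=PROTEIN)
        threaded = thread_codons(prot, [rec("x", "ATGGCA")])
        assert threaded.alignment["x"].seq == "ATG---GCA"

    def test_mismatch_reports_residue_index(self):
        prot = Alignment([SequenceRecord("x", "MA", alphabet=PROTEIN)], alphabet=PROTEIN)
        with pytest.raises(ValueError, match="residue 2"):
            thread_codons(prot, [rec("x", "ATGGTA")])  # translates MV

    def test_missing_cds_raises(self):
        prot = Alignment([SequenceRecord("x", "MA", alphabet=PROTEIN)], alphabet=PROTEIN)
        with pytest.raises(KeyError):
            thread_codons(prot, [rec("y", "ATGGCA")])

    def test_ungap_recovers_cds_on_simulated_data(self):
        tree = simulate_tree(8, 0.05, seed=2)
        aln, _ = simulate_evolution(tree, 40, seed=3)
        from Bio.Seq import Seq

        cds = [
            SequenceRecord(id=r.id, seq=r.ungapped()) for r in aln.alignment.records
        ]
        # derive the aligned protein rows from the simulated codon alignment
        rows = []
        for r in aln.alignment.records:
            aa = []
            for k in range(0, len(r.seq), 3):
                codon = r.seq[k : k + 3]
                aa.append("-" if codon == "---" else str(Seq(codon).translate()))
            rows.append(SequenceRecord(id=r.id, seq="".join(aa), alphabet=PROTEIN))
        threaded = thread_codons(Alignment(rows, alphabet=PROTEIN), cds)
        for r in threaded.alignment.records:
            assert r.ungapped() == dict((c.id, c.seq) for c in cds)[r.id]
        # and threading reproduces the original simulated alignment rows
        for r in threaded.alignment.records:
            assert r.seq == aln.alignment[r.id].seq


class TestTrimming:
    def make_aln(self, columns):
        """Build an alignment from a list of column strings."""
        n_rows = len(columns[0])
        rows = ["".join(col[i] for col in columns) for i in range(n_rows)]
        return Alignment([SequenceRecord(f"s{i}", row) for i, row in enumerate(rows)])

    def test_all_gap_column_removed_at_default(self):
        aln = self.make_aln(["A" * 10, "-" * 10, "C" * 10])
        trimmed, kept = trim_gappy_columns(aln, g=0.9)
        assert kept == [0, 2]
        assert trimmed.n_columns == 2

    def test_boundary_gap_fraction_retained(self):
        # 9 gaps out of 10: 0.9 is not > 0.9
        col = "-" * 9 + "A"
        aln = self.make_aln([col])
        trimmed, kept = trim_gappy_columns(aln, g=0.9)
        assert kept == [0]

    def test_gap_free_alignment_is_identity(self):
        aln = self.make_aln(["ACGTACGTAC", "CCCCCCCCCC"])
        trimmed, kept = trim_gappy_columns(aln, g=0.9)
        assert kept == list(range(2))
        assert [r.seq for r in trimmed.records] == [r.seq for r in aln.records]

    def test_codon_alignment_trims_whole_triples(self):
        rows = ["ATG---", "ATGGCA", "---GCA"]
        aln = CodonAlignment(
            alignment=Alignment([SequenceRecord(f"s{i}", r) for i, r in enumerate(rows)])
        )
        # both codon columns have pooled gap fraction 1/3 > 0.2: trimming
        # everything is degenerate and rejected loudly
        with pytest.raises(ValueError, match="every codon column"):
            trim_gappy_columns(aln, g=0.2)
        trimmed, kept = trim_gappy_columns(aln, g=0.5)
        assert kept == [0, 1, 2, 3, 4, 5]
        assert trimmed.alignment.n_columns % 3 == 0

    def test_monotone_in_threshold(self):
        rng = np.random.default_rng(4)
        aln = Alignment(
            [
                SequenceRecord(f"s{i}", "".join(rng.choice(list("ACGT-"), size=30)))
                for i in range(12)
            ]
        )
        widths = [
            trim_gappy_columns(aln, g=g)[0].n_columns for g in (0.1, 0.3, 0.5, 0.9, 1.0)
        ]
        assert widths == sorted(widths)


class TestDeduplicate:
    def test_first_occurrence_is_representative(self):
        records = [rec("a", "ATG"), rec("b", "ATG"), rec("c", "AAA")]
        reps, clusters = deduplicate(records)
        assert [r.id for r in reps] == ["a", "c"]
        assert clusters == {"a": ["a", "b"], "c": ["c"]}

    def test_all_unique_is_identity(self):
        records = [rec("a", "ATG"), rec("b", "AAA")]
        reps, clusters = deduplicate(records)
        assert [r.id for r in reps] == ["a", "b"]

    def test_kept_count_equals_distinct_sequences(self):
        rng = np.random.default_rng(5)
        records = [
            rec(f"s{i}", "".join(rng.choice(list("ACGT"), size=6))) for i in range(200)
        ]
        reps, clusters = deduplicate(records)
        assert len(reps) == len({r.seq for r in records})
        assert sum(len(m) for m in clusters.values()) == len(records)


class TestPatches:
    def test_patch_counts_residues_not_columns(self):
        aln = Alignment(
            [SequenceRecord("x", "M--AC", alphabet=PROTEIN)], alphabet=PROTEIN
        )
        patched = apply_patches(aln, [SequencePatch("x", 2, "T")])
        assert patched["x"].seq == "M--TC"

    def test_position_beyond_reference_raises(self):
        aln = Alignment([SequenceRecord("x", "MA", alphabet=PROTEIN)], alphabet=PROTEIN)
        with pytest.raises(IndexError):
            apply_patches(aln, [SequencePatch("x", 5, "T")])
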